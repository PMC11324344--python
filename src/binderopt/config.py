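"""Run configuration: a YAML dialect mapped onto the package's typed specs.

``load_config`` validates aggressively and reports *every* problem at once;
``dump_config`` emits the fully defaulted configuration, so load -> dump ->
load is idempotent and the run log always records the effective settings.
"""

from __future__ import annotations

import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .chooser import ChooserPolicy
from .errors import ConfigValidationError
from .model import ComplexModel
from .prune import PrunerSpec
from .sample import SamplerParams
from .scoring import DECOMPOSABLE_KINDS, ScorerSpec
from .optimize import EpochSchedule

_INTERVAL_RE = re.compile(r"^(?P<chain>[A-Za-z0-9]):(?P<start>\d+)(?:-(?P<end>\d+))?$")


def parse_interval(s: str) -> tuple[str, int, int]:
    """Parse ``"A:2-11"`` or ``"A:5"`` into ``(chain, start, end)``, inclusive."""
    m = _INTERVAL_RE.match(s.strip())
    if not m:
        raise ValueError(f"malformed position interval {s!r} (expected 'A:2-11' or 'A:5')")
    start = int(m.group("start"))
    end = int(m.group("end")) if m.group("end") else start
    if start < 1 or end < start:
        raise ValueError(f"invalid interval bounds in {s!r}")
    return m.group("chain"), start, end


def expand_intervals(
    intervals: Sequence[str], complex: Optional[ComplexModel] = None
) -> set[tuple[str, int]]:
    """Expand interval strings to ``(chain, position)`` pairs.

    With a complex given, positions are restricted to residues that exist
    (and an empty expansion is an error).
    """
    out: set[tuple[str, int]] = set()
    for s in intervals:
        chain, start, end = parse_interval(s)
        positions = range(start, end + 1)
        if complex is not None:
            existing = {r.position for r in complex.chain_residues(chain)}
            hit = [p for p in positions if p in existing]
            if not hit:
                raise ValueError(f"interval {s!r} matches no residue in the complex")
            positions = hit
        out.update((chain, p) for p in positions)
    return out


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one optimization run."""

    input_pdb: str
    binder_chains: frozenset[str]
    target_chains: frozenset[str]
    mutable_positions: tuple[str, ...]  # interval strings, e.g. ("A:2-11",)
    chooser: ChooserPolicy = field(default_factory=ChooserPolicy)
    sampler: SamplerParams = field(default_factory=SamplerParams)
    scorers: tuple[ScorerSpec, ...] = ()
    pruner: PrunerSpec = field(default_factory=PrunerSpec)
    schedule: EpochSchedule = field(default_factory=EpochSchedule)
    seed: int = 0
    workers: int = 1


def _build_section(cls, data, label, problems, **extra):
    try:
        return cls(**{**data, **extra})
    except ConfigValidationError as exc:
        problems.extend(f"{label}: {p}" for p in exc.problems)
    except (TypeError, ValueError) as exc:
        problems.append(f"{label}: {exc}")
    return None


def config_from_dict(data: dict) -> RunConfig:
    """Build and validate a RunConfig from a plain mapping (parsed YAML)."""
    problems: list[str] = []
    data = dict(data)

    for key in ("input_pdb", "binder_chains", "target_chains", "mutable_positions"):
        if key not in data:
            problems.append(f"missing required key {key!r}")
    binder = frozenset(data.get("binder_chains") or ())
    target = frozenset(data.get("target_chains") or ())
    if binder & target:
        problems.append(f"chains {sorted(binder & target)} appear as both binder and target")

    intervals = tuple(data.get("mutable_positions") or ())
    for s in intervals:
        try:
            chain, _, _ = parse_interval(s)
            if binder and chain not in binder:
                problems.append(f"mutable interval {s!r} is not on a binder chain")
        except ValueError as exc:
            problems.append(str(exc))

    chooser_data = dict(data.get("chooser") or {})
    if "groups" in chooser_data:
        chooser_data["groups"] = {k: frozenset(v) for k, v in chooser_data["groups"].items()}
    chooser = _build_section(ChooserPolicy, chooser_data, "chooser", problems)
    sampler = _build_section(SamplerParams, dict(data.get("sampler") or {}),
                             "sampler", problems)
    pruner = _build_section(PrunerSpec, dict(data.get("pruner") or {}), "pruner", problems)
    schedule = _build_section(EpochSchedule, dict(data.get("schedule") or {}),
                              "schedule", problems)

    scorers: list[ScorerSpec] = []
    raw_scorers = data.get("scorers") or []
    if not raw_scorers:
        problems.append("at least one scorer is required")
    for i, raw in enumerate(raw_scorers):
        raw = dict(raw)
        name = raw.pop("name", f"scorer{i}")
        kind = raw.pop("kind", None)
        sign = int(raw.pop("sign", 1))
        spec = _build_section(ScorerSpec, {}, f"scorer {name!r}", problems,
                              name=name, kind=kind, params=raw, sign=sign)
        if spec is not None:
            scorers.append(spec)
    names = [s.name for s in scorers]
    if len(set(names)) != len(names):
        problems.append(f"duplicate scorer names: {names}")

    # cross-references
    if pruner is not None and scorers:
        if pruner.kind == "consensus_threshold" and pruner.consensus_k > len(scorers):
            problems.append(
                f"consensus_k={pruner.consensus_k} exceeds the {len(scorers)} configured scorers"
            )
        if pruner.kind in ("metropolis", "top_n") and pruner.reference_scorer is not None:
            if pruner.reference_scorer not in names:
                problems.append(
                    f"reference_scorer {pruner.reference_scorer!r} is not a configured scorer"
                )
    if chooser is not None and chooser.site_mode == "guided" and scorers:
        if not any(s.kind in DECOMPOSABLE_KINDS for s in scorers):
            problems.append(
                "guided site mode requires at least one decomposable scorer "
                f"(one of kinds {DECOMPOSABLE_KINDS})"
            )

    seed = data.get("seed", 0)
    workers = data.get("workers", 1)
    if not isinstance(seed, int):
        problems.append(f"seed must be an integer, got {seed!r}")
    if not isinstance(workers, int) or workers < 1:
        problems.append(f"workers must be a positive integer, got {workers!r}")

    if problems:
        raise ConfigValidationError(problems)
    return RunConfig(
        input_pdb=str(data["input_pdb"]),
        binder_chains=binder,
        target_chains=target,
        mutable_positions=intervals,
        chooser=chooser,
        sampler=sampler,
        scorers=tuple(scorers),
        pruner=pruner,
        schedule=schedule,
        seed=seed,
        workers=workers,
    )


def load_config(path: Path | str) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigValidationError(["configuration file must hold a mapping"])
    return config_from_dict(data)


def config_to_dict(cfg: RunConfig) -> dict:
    """Plain mapping with every default materialized (inverse of config_from_dict)."""
    scorers = []
    for s in cfg.scorers:
        entry = {"name": s.name, "kind": s.kind, "sign": s.sign}
        entry.update(s.params)
        scorers.append(entry)
    chooser = asdict(cfg.chooser)
    chooser["groups"] = {k: sorted(v) for k, v in cfg.chooser.groups.items()}
    return {
        "input_pdb": cfg.input_pdb,
        "binder_chains": sorted(cfg.binder_chains),
        "target_chains": sorted(cfg.target_chains),
        "mutable_positions": list(cfg.mutable_positions),
        "chooser": chooser,
        "sampler": asdict(cfg.sampler),
        "scorers": scorers,
        "pruner": asdict(cfg.pruner),
        "schedule": asdict(cfg.schedule),
        "seed": cfg.seed,
        "workers": cfg.workers,
    }


def dump_config(cfg: RunConfig, path: Optional[Path | str] = None) -> str:
    """Serialize a RunConfig to YAML; optionally also write it to ``path``."""
    text = yaml.safe_dump(config_to_dict(cfg), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
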