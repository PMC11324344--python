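"""Complex Scorers: coarse-grained interface scoring with a uniform sign convention.

Every scorer returns one real number per frame, and after the per-spec sign
multiplier is applied LOWER IS ALWAYS BETTER.  That single convention is what
lets consensus pruning compare heterogeneous scorers with one predicate.

Built-in kinds
--------------
contact_potential
    Sum of a symmetric 20x20 residue-pair potential over all cross-interface
    side-chain contacts (default matrix shipped with the package:
    hydrophobic-hydrophobic favorable, like charges unfavorable).
screened_electrostatic
    Debye-screened Coulomb term q_i q_j exp(-d/lambda)/d over cross-interface
    pairs, with integer side-chain charges (D/E -1, K/R +1, H +0.5).
contact_count
    Minus the number of cross-interface contacts; a crude packing reward.
hidden_oracle
    Test oracle with a planted optimal sequence (see :mod:`binderopt.toys`).
external
    Adapter contract: a registered callable scores a written PDB frame.

The first three (and the hidden oracle) decompose per residue by splitting
each pair term half-and-half between its two residues, so the contributions
sum exactly to the total — the property guided site selection relies on.
"""

from __future__ import annotations

import tempfile
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigValidationError, NotDecomposableError
from .model import (
    AA_CODES,
    DEFAULT_CUTOFF,
    RESIDUE_CHARGE,
    ComplexModel,
    ScoreTable,
    contact_pairs,
)
from .sample import Ensemble

SCORER_KINDS = (
    "contact_potential",
    "screened_electrostatic",
    "contact_count",
    "hidden_oracle",
    "external",
)
DECOMPOSABLE_KINDS = (
    "contact_potential",
    "screened_electrostatic",
    "contact_count",
    "hidden_oracle",
)


@dataclass(frozen=True)
class ScorerSpec:
    """Named, parameterized scorer; ``sign`` flips conventions to lower-is-better."""

    name: str
    kind: str
    params: Mapping[str, object] = field(default_factory=dict)
    sign: int = 1

    def __post_init__(self):
        object.__setattr__(self, "params", dict(self.params))
        problems = []
        if self.kind not in SCORER_KINDS:
            problems.append(f"unknown scorer kind {self.kind!r} (expected one of {SCORER_KINDS})")
        if self.sign not in (1, -1):
            problems.append(f"scorer sign must be +1 or -1, got {self.sign}")
        if problems:
            raise ConfigValidationError(problems)


def load_contact_matrix(path: Optional[Path] = None) -> dict[str, dict[str, float]]:
    """Read a whitespace-delimited 20x20 matrix with one-letter header row/column.

    Without ``path`` the package's default matrix is loaded.  Asymmetry is an
    error: the potential must not depend on which side of the interface a
    residue sits on.
    """
    if path is None:
        text = resources.files("binderopt").joinpath("data/contact_matrix.txt").read_text()
    else:
        text = Path(path).read_text()
    rows = [ln.split() for ln in text.splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")]
    header = rows[0]
    if sorted(header) != sorted(AA_CODES):
        raise ValueError("contact matrix header must list the 20 one-letter codes")
    matrix: dict[str, dict[str, float]] = {}
    for row in rows[1:]:
        aa, values = row[0], [float(x) for x in row[1:]]
        if len(values) != 20:
            raise ValueError(f"row {aa!r} has {len(values)} values, expected 20")
        matrix[aa] = dict(zip(header, values))
    if sorted(matrix) != sorted(AA_CODES):
        raise ValueError("contact matrix must have one row per amino acid")
    _check_symmetric(matrix)
    return matrix


def _check_symmetric(matrix: Mapping[str, Mapping[str, float]]) -> None:
    for a in AA_CODES:
        for b in AA_CODES:
            if abs(matrix[a][b] - matrix[b][a]) > 1e-9:
                raise ValueError(f"contact matrix is asymmetric at ({a},{b})")


# --- pairwise scorer core -------------------------------------------------


class Scorer:
    """A built scorer: ``score(frame)`` and, if supported, ``decompose(frame)``."""

    def __init__(self, spec: ScorerSpec):
        self.spec = spec

    @property
    def name(self) -> str:
        return self.spec.name

    def score(self, frame: ComplexModel) -> float:
        raise NotImplementedError

    def decompose(self, frame: ComplexModel) -> dict[tuple[str, int], float]:
        raise NotDecomposableError(
            f"scorer {self.spec.name!r} (kind {self.spec.kind!r}) is not decomposable"
        )


class _PairwiseScorer(Scorer):
    """Scorers of the form sum over contacts of a pair term, plus optional
    per-residue terms; decomposition splits each pair term half to each residue."""

    def __init__(self, spec: ScorerSpec):
        super().__init__(spec)
        self.cutoff = float(spec.params.get("cutoff", DEFAULT_CUTOFF))
        if self.cutoff <= 0:
            raise ConfigValidationError([f"scorer {spec.name!r}: cutoff must be positive"])

    def _pair_term(self, frame: ComplexModel, b: tuple[str, int], t: tuple[str, int]) -> float:
        raise NotImplementedError

    def _residue_terms(self, frame: ComplexModel) -> dict[tuple[str, int], float]:
        return {}

    def score(self, frame: ComplexModel) -> float:
        total = sum(self._pair_term(frame, b, t) for b, t in contact_pairs(frame, self.cutoff))
        total += sum(self._residue_terms(frame).values())
        return self.spec.sign * total

    def decompose(self, frame: ComplexModel) -> dict[tuple[str, int], float]:
        out = {(r.chain_id, r.position): 0.0 for r in frame.residues}
        for b, t in contact_pairs(frame, self.cutoff):
            term = self._pair_term(frame, b, t)
            out[b] += 0.5 * term
            out[t] += 0.5 * term
        for key, term in self._residue_terms(frame).items():
            out[key] += term
        return {k: self.spec.sign * v for k, v in out.items()}


class ContactPotentialScorer(_PairwiseScorer):
    def __init__(self, spec: ScorerSpec):
        super().__init__(spec)
        m = spec.params.get("matrix")
        if m is None:
            mf = spec.params.get("matrix_file")
            m = load_contact_matrix(Path(mf) if mf else None)
        else:
            _check_symmetric(m)
        self.matrix = m

    def _pair_term(self, frame, b, t):
        return self.matrix[frame.residue_at(*b).aa][frame.residue_at(*t).aa]


class ScreenedElectrostaticScorer(_PairwiseScorer):
    def __init__(self, spec: ScorerSpec):
        super().__init__(spec)
        self.screen_len = float(spec.params.get("screen_len", 10.0))
        if self.screen_len <= 0:
            raise ConfigValidationError([f"scorer {spec.name!r}: screen_len must be positive"])

    def _pair_term(self, frame, b, t):
        rb, rt = frame.residue_at(*b), frame.residue_at(*t)
        qb = RESIDUE_CHARGE.get(rb.aa, 0.0)
        qt = RESIDUE_CHARGE.get(rt.aa, 0.0)
        if qb == 0.0 or qt == 0.0:
            return 0.0
        d = float(np.linalg.norm(rb.side_xyz - rt.side_xyz))
        if d == 0.0:
            warnings.warn(
                f"coincident pseudo-atoms {b} / {t}; electrostatic pair skipped",
                stacklevel=2,
            )
            return 0.0
        return qb * qt * np.exp(-d / self.screen_len) / d


class ContactCountScorer(_PairwiseScorer):
    def _pair_term(self, frame, b, t):
        return -1.0


class HiddenOracleScorer(_PairwiseScorer):
    """Contact count plus a planted sequence-mismatch penalty (test oracle)."""

    def __init__(self, spec: ScorerSpec):
        super().__init__(spec)
        raw = spec.params.get("optimal_seq")
        if not raw:
            raise ConfigValidationError([f"scorer {spec.name!r}: optimal_seq is required"])
        self.optimal_seq = {_parse_poskey(k): v for k, v in dict(raw).items()}
        self.weight = float(spec.params.get("weight", 1.0))

    def _pair_term(self, frame, b, t):
        return -1.0

    def _residue_terms(self, frame):
        seq = frame.sequence()
        return {
            key: self.weight
            for key, aa in self.optimal_seq.items()
            if seq.get(key) != aa
        }


def _parse_poskey(key) -> tuple[str, int]:
    if isinstance(key, str):  # "A:12" config form
        chain, pos = key.split(":")
        return chain, int(pos)
    chain, pos = key
    return str(chain), int(pos)


# --- external scorer adapters --------------------------------------------

#: An adapter takes a written single-frame PDB and returns one real score.
ScorerAdapter = Callable[[Path], float]

_SCORER_REGISTRY: dict[str, ScorerAdapter] = {}


def register_scorer_adapter(name: str, adapter: ScorerAdapter) -> None:
    _SCORER_REGISTRY[name] = adapter


class ExternalScorer(Scorer):
    def __init__(self, spec: ScorerSpec):
        super().__init__(spec)
        adapter_name = spec.params.get("adapter")
        if adapter_name not in _SCORER_REGISTRY:
            raise ConfigValidationError(
                [f"scorer {spec.name!r}: no scorer adapter registered under {adapter_name!r}"]
            )
        self.adapter = _SCORER_REGISTRY[adapter_name]

    def score(self, frame: ComplexModel) -> float:
        from .pdbio import write_pdb

        with tempfile.TemporaryDirectory() as td:
            p = Path(td) / "frame.pdb"
            write_pdb(frame, p)
            return self.spec.sign * float(self.adapter(p))


_BUILDERS = {
    "contact_potential": ContactPotentialScorer,
    "screened_electrostatic": ScreenedElectrostaticScorer,
    "contact_count": ContactCountScorer,
    "hidden_oracle": HiddenOracleScorer,
    "external": ExternalScorer,
}


def build_scorer(spec: ScorerSpec) -> Scorer:
    """Construct a scorer; configuration problems surface here, not per frame."""
    return _BUILDERS[spec.kind](spec)


def build_scorers(specs: Sequence[ScorerSpec]) -> list[Scorer]:
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ConfigValidationError([f"duplicate scorer names: {sorted(names)}"])
    return [build_scorer(s) for s in specs]


# --- public operations ----------------------------------------------------


def contact_score(frame: ComplexModel, matrix=None, cutoff: float = DEFAULT_CUTOFF) -> float:
    """Contact-potential score with the given (or default) matrix."""
    params = {"cutoff": cutoff}
    if matrix is not None:
        params["matrix"] = matrix
    return build_scorer(ScorerSpec("contact", "contact_potential", params)).score(frame)


def electro_score(
    frame: ComplexModel, cutoff: float = DEFAULT_CUTOFF, screen_len: float = 10.0
) -> float:
    """Screened electrostatic score."""
    return build_scorer(
        ScorerSpec("electro", "screened_electrostatic",
                   {"cutoff": cutoff, "screen_len": screen_len})
    ).score(frame)


def contact_count_score(frame: ComplexModel, cutoff: float = DEFAULT_CUTOFF) -> float:
    """Minus the number of cross-interface contacts."""
    return build_scorer(ScorerSpec("ncontacts", "contact_count", {"cutoff": cutoff})).score(frame)


def per_residue_decomposition(
    frame: ComplexModel, scorer: ScorerSpec | Scorer
) -> dict[tuple[str, int], float]:
    """Per-residue contributions (half-split pair terms); sums to the total score."""
    s = scorer if isinstance(scorer, Scorer) else build_scorer(scorer)
    return s.decompose(frame)


def score_ensemble(
    ensemble: Ensemble, scorers: Sequence[ScorerSpec] | Sequence[Scorer]
) -> ScoreTable:
    """Score every frame with every scorer and average per scorer."""
    if not scorers:
        raise ValueError("score_ensemble needs at least one scorer")
    built = [s if isinstance(s, Scorer) else build_scorer(s) for s in scorers]
    per_frame = {
        s.name: tuple(s.score(frame) for frame in ensemble.frames) for s in built
    }
    return ScoreTable.from_frames(per_frame)
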