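"""Pruners: decide which mutated binders survive to the next epoch.

All comparisons operate on per-scorer *average* scores after the global
sign normalization (lower is better).  Three built-in pruners:

consensus_threshold
    A mutant survives when at least ``consensus_k`` scorers judge it improved
    over its parent by more than ``tolerance``.
metropolis
    Monte Carlo acceptance on a single reference scorer: improvements always
    survive; a worsening of Delta survives with probability exp(-Delta/T),
    giving slightly unfavourable mutations a chance.
top_n
    Deterministic: the ``keep_n`` mutants with the lowest reference-scorer
    average, ties broken by branch id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .errors import ConfigValidationError
from .model import ScoreTable

PRUNER_KINDS = ("consensus_threshold", "metropolis", "top_n")


@dataclass(frozen=True)
class PrunerSpec:
    kind: str = "consensus_threshold"
    consensus_k: int = 1
    tolerance: float = 0.0
    temperature: float = 1.0
    keep_n: int = 1
    reference_scorer: Optional[str] = None

    def __post_init__(self):
        problems = []
        if self.kind not in PRUNER_KINDS:
            problems.append(f"unknown pruner kind {self.kind!r} (expected one of {PRUNER_KINDS})")
        if self.tolerance < 0:
            problems.append(f"tolerance must be >= 0, got {self.tolerance}")
        if self.kind == "metropolis" and self.temperature <= 0:
            problems.append(f"metropolis temperature must be positive, got {self.temperature}")
        if self.kind == "top_n" and self.keep_n < 1:
            problems.append(f"keep_n must be >= 1, got {self.keep_n}")
        if problems:
            raise ConfigValidationError(problems)


def _check_same_scorers(parent: ScoreTable, mutants: Mapping[str, ScoreTable]) -> None:
    ref = set(parent.scorer_names)
    for bid, table in mutants.items():
        if set(table.scorer_names) != ref:
            raise ValueError(
                f"scorer-name mismatch for branch {bid!r}: "
                f"{sorted(table.scorer_names)} vs parent {sorted(ref)}"
            )


def improvement_vector(parent: ScoreTable, mutant: ScoreTable, tolerance: float = 0.0
                       ) -> dict[str, bool]:
    """Per scorer: did the mutant improve on the parent by more than ``tolerance``?"""
    return {
        s: mutant.averages[s] < parent.averages[s] - tolerance
        for s in parent.scorer_names
    }


def consensus_prune(
    parent: ScoreTable, mutants: Mapping[str, ScoreTable], spec: PrunerSpec
) -> set[str]:
    """Branch ids improving on the parent under >= ``consensus_k`` scorers."""
    _check_same_scorers(parent, mutants)
    retained = set()
    for bid, table in mutants.items():
        n_improved = sum(improvement_vector(parent, table, spec.tolerance).values())
        if n_improved >= spec.consensus_k:
            retained.add(bid)
    return retained


def metropolis_accept_probability(parent_avg: float, mutant_avg: float,
                                  temperature: float) -> float:
    delta = mutant_avg - parent_avg
    return min(1.0, math.exp(-delta / temperature))


def metropolis_prune(
    parent_avg: float,
    mutant_avg: float,
    spec: PrunerSpec,
    rng: np.random.Generator,
) -> bool:
    """Accept with probability min(1, exp(-(mutant-parent)/T)); improvement always."""
    if not (math.isfinite(parent_avg) and math.isfinite(mutant_avg)):
        raise ValueError(
            f"metropolis_prune requires finite scores, got parent={parent_avg}, "
            f"mutant={mutant_avg}"
        )
    delta = mutant_avg - parent_avg
    if delta <= 0:
        return True
    return float(rng.random()) < math.exp(-delta / spec.temperature)


def top_prune(mutants: Mapping[str, ScoreTable], spec: PrunerSpec) -> set[str]:
    """The ``keep_n`` branches with lowest reference-scorer average."""
    if spec.keep_n < 1:
        raise ConfigValidationError([f"keep_n must be >= 1, got {spec.keep_n}"])
    if not mutants:
        return set()
    ref = spec.reference_scorer
    if ref is None:
        ref = next(iter(mutants.values())).scorer_names[0]
    for bid, table in mutants.items():
        if ref not in table.scorer_names:
            raise ValueError(f"reference scorer {ref!r} missing from branch {bid!r}")
    ranked = sorted(mutants, key=lambda bid: (mutants[bid].averages[ref], bid))
    return set(ranked[: spec.keep_n])
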