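"""Synthetic toy complexes and a planted-optimum test oracle.

Nothing here resembles real protein geometry or sequence statistics; the
fixtures exist so the whole optimization protocol can be exercised and
verified without any real system.  Two chains (binder ``A``, target ``B``)
face each other across a configurable gap in one of three geometries, with
idealized 3.8 A anchor spacing and side pseudo-atoms pointing toward the
partner so the interface is well populated at the default 8 A cutoff.

The *hidden oracle* scorer adds a per-residue mismatch penalty against a
planted optimal sequence to the contact-count score.  Its global minimum sits
at the planted sequence, so it is a testable analogue of "improving affinity"
with a known answer; being frame-dependent through the contact term, it
behaves like a genuine scorer, and it decomposes per residue (the penalty is
attributed to the mismatched residue), which makes it usable for guided site
selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ConfigValidationError
from .model import AA_CODES, CB_BOND_LENGTH, ComplexModel, Mutation, ResidueRecord
from .mutate import apply_mutation
from .scoring import ScorerSpec

GEOMETRIES = ("two_helices", "two_strands", "random_blob")

_SPACING = 3.8  # consecutive-anchor distance, A


@dataclass(frozen=True)
class ToySpec:
    """Recipe for a toy binder/target complex."""

    n_binder: int = 12
    n_target: int = 12
    geometry: str = "two_strands"
    interface_gap: float = 5.0
    seed: int = 0

    def __post_init__(self):
        problems = []
        if self.n_binder < 3 or self.n_target < 3:
            problems.append("n_binder and n_target must be >= 3")
        if self.interface_gap <= 0:
            problems.append(f"interface_gap must be positive, got {self.interface_gap}")
        if self.geometry not in GEOMETRIES:
            problems.append(f"unknown geometry {self.geometry!r} (expected one of {GEOMETRIES})")
        if problems:
            raise ConfigValidationError(problems)


def _strand_anchors(n: int, y: float) -> np.ndarray:
    return np.stack([np.arange(n) * _SPACING,
                     np.full(n, y), np.zeros(n)], axis=1)


def _helix_anchors(n: int, y: float) -> np.ndarray:
    # idealized alpha-helix-like curve: 1.5 A rise, 100 deg turn, 2.3 A radius
    t = np.deg2rad(100.0) * np.arange(n)
    return np.stack([
        1.5 * np.arange(n),
        y + 2.3 * np.cos(t),
        2.3 * np.sin(t),
    ], axis=1)


def _blob_anchors(n: int, y: float, rng: np.random.Generator) -> np.ndarray:
    # seeded self-avoiding-ish random walk with fixed step length
    pts = [np.array([0.0, y, 0.0])]
    while len(pts) < n:
        step = rng.normal(size=3)
        step[1] *= 0.2  # stay roughly in the chain's own half-space
        step = step / np.linalg.norm(step) * _SPACING
        nxt = pts[-1] + step
        if abs(nxt[1] - y) > 1.5:  # keep the blob near its plane
            continue
        pts.append(nxt)
    return np.array(pts)


def make_toy_complex(spec: ToySpec) -> ComplexModel:
    """Deterministic (per seed) two-chain complex; all binder positions mutable."""
    rng = np.random.default_rng(spec.seed)
    gap = spec.interface_gap
    if spec.geometry == "two_strands":
        a_xyz = _strand_anchors(spec.n_binder, 0.0)
        b_xyz = _strand_anchors(spec.n_target, gap)
    elif spec.geometry == "two_helices":
        a_xyz = _helix_anchors(spec.n_binder, 0.0)
        b_xyz = _helix_anchors(spec.n_target, gap)
    else:
        a_xyz = _blob_anchors(spec.n_binder, 0.0, rng)
        b_xyz = _blob_anchors(spec.n_target, gap, rng)

    seq_a = [AA_CODES[i] for i in rng.integers(0, 20, spec.n_binder)]
    seq_b = [AA_CODES[i] for i in rng.integers(0, 20, spec.n_target)]

    residues = []
    for chain, xyz, seq, toward in (("A", a_xyz, seq_a, +1.0), ("B", b_xyz, seq_b, -1.0)):
        for i, (anchor, aa) in enumerate(zip(xyz, seq), start=1):
            # side pseudo-atom points across the interface (+y for A, -y for B)
            side = anchor if aa == "G" else anchor + np.array([0.0, toward * CB_BOND_LENGTH, 0.0])
            residues.append(ResidueRecord(chain, i, aa, anchor, side))
    return ComplexModel(
        residues=tuple(residues),
        binder_chains=frozenset("A"),
        target_chains=frozenset("B"),
        mutable_positions=frozenset(("A", i) for i in range(1, spec.n_binder + 1)),
    )


def hidden_oracle_scorer(
    optimal_seq: Mapping[tuple[str, int], str],
    weight: float = 1.0,
    cutoff: float = 8.0,
    name: str = "oracle",
) -> ScorerSpec:
    """Scorer spec whose global minimum is the planted sequence.

    frame score = contact_count + weight x (positions differing from
    ``optimal_seq``); lower is better.
    """
    return ScorerSpec(
        name=name,
        kind="hidden_oracle",
        params={
            "optimal_seq": {f"{c}:{p}": aa for (c, p), aa in optimal_seq.items()},
            "weight": weight,
            "cutoff": cutoff,
        },
    )


def plant_suboptimal(
    complex: ComplexModel,
    optimal_seq: Mapping[tuple[str, int], str],
    k_sites: int,
    rng: np.random.Generator,
) -> ComplexModel:
    """Return the complex at Hamming distance exactly ``k_sites`` from the optimum.

    All positions covered by ``optimal_seq`` are first set to their optimal
    residue, then ``k_sites`` of them (seeded choice) are corrupted to a
    seeded wrong residue.
    """
    positions = sorted(optimal_seq)
    if k_sites > len(positions):
        raise ValueError(
            f"k_sites={k_sites} exceeds the {len(positions)} planted positions"
        )
    seq = complex.sequence()
    to_optimal = [
        Mutation(c, p, seq[(c, p)], optimal_seq[(c, p)])
        for c, p in positions if seq[(c, p)] != optimal_seq[(c, p)]
    ]
    out = apply_mutation(complex, to_optimal)
    if k_sites == 0:
        return out
    picked = rng.choice(len(positions), size=k_sites, replace=False)
    corruptions = []
    for i in sorted(int(j) for j in picked):
        c, p = positions[i]
        wrong = [aa for aa in AA_CODES if aa != optimal_seq[(c, p)]]
        corruptions.append(Mutation(c, p, optimal_seq[(c, p)],
                                    wrong[int(rng.integers(len(wrong)))]))
    return apply_mutation(out, corruptions)


def default_optimal_seq(complex: ComplexModel, rng: np.random.Generator,
                        avoid_glycine: bool = True) -> dict[tuple[str, int], str]:
    """A seeded planted sequence over all mutable positions.

    Glycine is avoided by default so planting/corrupting never moves side
    pseudo-atoms (glycine collapses them onto the anchor), keeping the
    contact term of the oracle constant across sequence space.
    """
    pool = [aa for aa in AA_CODES if not (avoid_glycine and aa == "G")]
    return {
        pos: pool[int(rng.integers(len(pool)))]
        for pos in sorted(complex.mutable_positions)
    }
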