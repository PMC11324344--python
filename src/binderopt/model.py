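"""Coarse-grained structural model of a binder/target complex.

Each residue is reduced to two pseudo-atoms: a backbone anchor (the alpha
carbon) and one side-chain pseudo-atom (the beta carbon where one exists;
glycine's side pseudo-atom coincides with its anchor).  A complex is an
ordered residue list partitioned into binder chains and target chains, plus
the set of binder positions the optimization is allowed to mutate.

All interface geometry used by the built-in scorers lives here: two residues
on opposite sides of the partition are "in contact" when their side-chain
pseudo-atoms are within a distance cutoff (default 8 A, a standard
coarse-grained contact convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import MalformedComplexError, MutationError

#: Canonical one-letter amino-acid codes, alphabetical.
AA_CODES: str = "ACDEFGHIKLMNPQRSTVWY"

AA_THREE_TO_ONE: Mapping[str, str] = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
AA_ONE_TO_THREE: Mapping[str, str] = {v: k for k, v in AA_THREE_TO_ONE.items()}

#: Integer (half-integer for His) side-chain charges used by the screened
#: electrostatic scorer.
RESIDUE_CHARGE: Mapping[str, float] = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.5}

#: Default side-chain contact cutoff in Angstrom.
DEFAULT_CUTOFF: float = 8.0

#: Ideal CA-CB bond length in Angstrom, used when a side pseudo-atom has to
#: be rebuilt (mutating away from glycine).
CB_BOND_LENGTH: float = 1.53


def _as_xyz(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    a.flags.writeable = False
    return a


@dataclass(frozen=True)
class ResidueRecord:
    """One residue: identity plus anchor and side-chain pseudo-atom positions."""

    chain_id: str
    position: int
    aa: str
    anchor_xyz: np.ndarray
    side_xyz: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "anchor_xyz", _as_xyz(self.anchor_xyz))
        object.__setattr__(self, "side_xyz", _as_xyz(self.side_xyz))
        if len(self.chain_id) != 1:
            raise MalformedComplexError(f"chain id must be one character, got {self.chain_id!r}")
        if self.position < 1:
            raise MalformedComplexError(f"residue position must be >= 1, got {self.position}")
        if self.aa not in AA_CODES:
            raise MalformedComplexError(f"unknown amino-acid code {self.aa!r}")
        if self.aa == "G" and not np.array_equal(self.anchor_xyz, self.side_xyz):
            raise MalformedComplexError(
                f"glycine {self.chain_id}{self.position} must have side_xyz == anchor_xyz"
            )

    def __eq__(self, other):
        if not isinstance(other, ResidueRecord):
            return NotImplemented
        return (
            self.chain_id == other.chain_id
            and self.position == other.position
            and self.aa == other.aa
            and np.array_equal(self.anchor_xyz, other.anchor_xyz)
            and np.array_equal(self.side_xyz, other.side_xyz)
        )

    def __hash__(self):
        return hash((self.chain_id, self.position, self.aa,
                     self.anchor_xyz.tobytes(), self.side_xyz.tobytes()))


@dataclass(frozen=True)
class Mutation:
    """A single amino-acid substitution on the binder, e.g. ``A:I45W``."""

    chain_id: str
    position: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self):
        if self.wt_aa not in AA_CODES:
            raise MutationError(f"invalid wild-type code {self.wt_aa!r}")
        if self.mut_aa not in AA_CODES:
            raise MutationError(f"invalid mutant code {self.mut_aa!r}")
        if self.wt_aa == self.mut_aa:
            raise MutationError(f"mutation {self} does not change the residue")
        if self.position < 1:
            raise MutationError(f"position must be >= 1, got {self.position}")

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass(frozen=True)
class ComplexModel:
    """A binder/target complex at coarse grain.

    Parameters
    ----------
    residues
        Ordered residue records; positions strictly increasing within a chain.
    binder_chains, target_chains
        Disjoint, non-empty chain-label sets partitioning the residues.
    mutable_positions
        ``(chain_id, position)`` pairs the optimizer may mutate; all must be
        binder residues.
    """

    residues: tuple[ResidueRecord, ...]
    binder_chains: frozenset[str]
    target_chains: frozenset[str]
    mutable_positions: frozenset[tuple[str, int]] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "residues", tuple(self.residues))
        object.__setattr__(self, "binder_chains", frozenset(self.binder_chains))
        object.__setattr__(self, "target_chains", frozenset(self.target_chains))
        object.__setattr__(self, "mutable_positions",
                           frozenset(tuple(p) for p in self.mutable_positions))
        if not self.binder_chains or not self.target_chains:
            raise MalformedComplexError("binder and target chain sets must be non-empty")
        if self.binder_chains & self.target_chains:
            raise MalformedComplexError(
                f"chains {sorted(self.binder_chains & self.target_chains)} appear on both sides"
            )
        known = self.binder_chains | self.target_chains
        last: dict[str, int] = {}
        for r in self.residues:
            if r.chain_id not in known:
                raise MalformedComplexError(
                    f"residue {r.chain_id}{r.position} belongs to no declared chain"
                )
            if r.chain_id in last and r.position <= last[r.chain_id]:
                raise MalformedComplexError(
                    f"positions not strictly increasing in chain {r.chain_id} "
                    f"(... {last[r.chain_id]}, {r.position})"
                )
            last[r.chain_id] = r.position
        index = {(r.chain_id, r.position) for r in self.residues}
        for chain, pos in self.mutable_positions:
            if chain not in self.binder_chains:
                raise MalformedComplexError(
                    f"mutable position {chain}:{pos} is not on a binder chain"
                )
            if (chain, pos) not in index:
                raise MalformedComplexError(f"mutable position {chain}:{pos} does not exist")

    # -- lookups -----------------------------------------------------------

    def residue_at(self, chain_id: str, position: int) -> ResidueRecord:
        for r in self.residues:
            if r.chain_id == chain_id and r.position == position:
                return r
        raise KeyError(f"no residue {chain_id}:{position}")

    def sequence(self) -> dict[tuple[str, int], str]:
        """Mapping ``(chain, position) -> one-letter code``."""
        return {(r.chain_id, r.position): r.aa for r in self.residues}

    def binder_residues(self) -> tuple[ResidueRecord, ...]:
        return tuple(r for r in self.residues if r.chain_id in self.binder_chains)

    def target_residues(self) -> tuple[ResidueRecord, ...]:
        return tuple(r for r in self.residues if r.chain_id in self.target_chains)

    def binder_anchor_centroid(self) -> np.ndarray:
        res = self.binder_residues()
        if not res:
            raise MalformedComplexError("complex has no binder residues")
        return np.mean([r.anchor_xyz for r in res], axis=0)

    def chain_residues(self, chain_id: str) -> tuple[ResidueRecord, ...]:
        return tuple(r for r in self.residues if r.chain_id == chain_id)

    # -- geometry helpers --------------------------------------------------

    def with_residues(self, residues: Iterable[ResidueRecord]) -> "ComplexModel":
        return replace(self, residues=tuple(residues))

    def translated(self, vec) -> "ComplexModel":
        v = np.asarray(vec, dtype=float)
        return self.with_residues(
            ResidueRecord(r.chain_id, r.position, r.aa, r.anchor_xyz + v, r.side_xyz + v)
            for r in self.residues
        )


def _partition_or_raise(complex: ComplexModel):
    binder = complex.binder_residues()
    target = complex.target_residues()
    if not binder or not target:
        raise MalformedComplexError(
            "malformed partition: complex has %d binder and %d target residues"
            % (len(binder), len(target))
        )
    return binder, target


def contact_pairs(
    complex: ComplexModel, cutoff: float = DEFAULT_CUTOFF
) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    """All binder-target residue pairs whose side pseudo-atoms lie within ``cutoff``.

    Ordered by binder residue index, then target residue index (both in
    ``complex.residues`` order), so the output is deterministic.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    binder, target = _partition_or_raise(complex)
    bxyz = np.array([r.side_xyz for r in binder])
    txyz = np.array([r.side_xyz for r in target])
    d = cdist(bxyz, txyz)
    pairs = []
    for i, j in np.argwhere(d <= cutoff):
        pairs.append(((binder[i].chain_id, binder[i].position),
                      (target[j].chain_id, target[j].position)))
    return pairs


def interface_residues(
    complex: ComplexModel, cutoff: float = DEFAULT_CUTOFF
) -> set[tuple[str, int]]:
    """Residues (either side) with >= 1 cross-interface contact at ``cutoff``."""
    out: set[tuple[str, int]] = set()
    for b, t in contact_pairs(complex, cutoff):
        out.add(b)
        out.add(t)
    return out


@dataclass(frozen=True)
class ScoreTable:
    """Per-scorer, per-frame scores for one complex variant, with averages."""

    scorer_names: tuple[str, ...]
    per_frame: Mapping[str, tuple[float, ...]]
    averages: Mapping[str, float]

    def __post_init__(self):
        object.__setattr__(self, "scorer_names", tuple(self.scorer_names))
        object.__setattr__(self, "per_frame",
                           {k: tuple(float(x) for x in v) for k, v in self.per_frame.items()})
        object.__setattr__(self, "averages",
                           {k: float(v) for k, v in self.averages.items()})
        if set(self.per_frame) != set(self.scorer_names) or set(self.averages) != set(self.scorer_names):
            raise ValueError("per_frame/averages keys must match scorer_names")
        lengths = {len(v) for v in self.per_frame.values()}
        if len(lengths) != 1 or min(lengths) < 1:
            raise ValueError(f"per-frame score sequences must share one length >= 1, got {lengths}")
        for name in self.scorer_names:
            mean = float(np.mean(self.per_frame[name]))
            if abs(mean - self.averages[name]) > 1e-9:
                raise ValueError(
                    f"average for {name!r} ({self.averages[name]}) is not the mean "
                    f"of its per-frame scores ({mean})"
                )

    @classmethod
    def from_frames(cls, per_frame: Mapping[str, Sequence[float]]) -> "ScoreTable":
        names = tuple(per_frame)
        return cls(
            scorer_names=names,
            per_frame={k: tuple(float(x) for x in v) for k, v in per_frame.items()},
            averages={k: float(np.mean(v)) for k, v in per_frame.items()},
        )

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.per_frame.values())))
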