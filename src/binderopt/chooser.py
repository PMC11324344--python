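"""Mutation Chooser: pick mutation site(s) and replacement amino acid(s).

Site selection is either uniformly random over the declared mutable positions
or *guided*: given a per-residue contribution map from a decomposable scorer
(lower is better throughout the package), the guided mode targets the residue
contributing least to binding, i.e. the one with the largest contribution.

Amino-acid selection supports three schemes: uniform over the 19 non-wild-type
residues, custom per-residue probabilities, and uniform within a named group
(e.g. "polar", "aliphatic").  The current residue is always excluded, so a
chosen mutation is guaranteed to change the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ChooserExhaustionError, ConfigValidationError
from .model import AA_CODES, ComplexModel, Mutation

#: Default amino-acid grouping by physicochemical class.
DEFAULT_GROUPS: dict[str, frozenset[str]] = {
    "negative": frozenset("DE"),
    "positive": frozenset("KRH"),
    "polar": frozenset("STNQCY"),
    "aliphatic": frozenset("AVLIMGP"),
    "aromatic": frozenset("FW"),
}

SITE_MODES = ("random", "guided")
AA_SCHEMES = ("uniform", "custom", "grouped")


@dataclass(frozen=True)
class ChooserPolicy:
    """Configuration of the Mutation Chooser.

    ``aa_probs`` (custom scheme) need not be normalized; it is renormalized
    internally after zeroing the current residue.  ``groups`` defaults to the
    package's physicochemical grouping.
    """

    site_mode: str = "random"
    aa_scheme: str = "uniform"
    aa_probs: Mapping[str, float] = field(default_factory=dict)
    groups: Mapping[str, frozenset[str]] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    active_group: Optional[str] = None
    sites_per_mutant: int = 1

    def __post_init__(self):
        problems = []
        if self.site_mode not in SITE_MODES:
            problems.append(f"unknown site_mode {self.site_mode!r} (expected one of {SITE_MODES})")
        if self.aa_scheme not in AA_SCHEMES:
            problems.append(f"unknown aa_scheme {self.aa_scheme!r} (expected one of {AA_SCHEMES})")
        if self.sites_per_mutant < 1:
            problems.append(f"sites_per_mutant must be >= 1, got {self.sites_per_mutant}")
        if self.aa_scheme == "custom":
            bad = sorted(set(self.aa_probs) - set(AA_CODES))
            if bad:
                problems.append(f"aa_probs contains unknown codes {bad}")
            if any(p < 0 for p in self.aa_probs.values()):
                problems.append("aa_probs must be non-negative")
            elif sum(self.aa_probs.values()) <= 0:
                problems.append("aa_probs must sum to a positive value")
        if self.aa_scheme == "grouped":
            if self.active_group is None:
                problems.append("grouped scheme requires active_group")
            elif self.active_group not in self.groups:
                problems.append(f"active_group {self.active_group!r} not among groups "
                                f"{sorted(self.groups)}")
            elif not self.groups[self.active_group]:
                problems.append(f"group {self.active_group!r} is empty")
        if problems:
            raise ConfigValidationError(problems)


def _aa_weights(current_aa: str, policy: ChooserPolicy) -> dict[str, float]:
    """Unnormalized selection weights over replacement residues (current excluded)."""
    if policy.aa_scheme == "uniform":
        w = {aa: 1.0 for aa in AA_CODES}
    elif policy.aa_scheme == "custom":
        w = {aa: float(policy.aa_probs.get(aa, 0.0)) for aa in AA_CODES}
    else:  # grouped
        group = policy.groups[policy.active_group]
        w = {aa: (1.0 if aa in group else 0.0) for aa in AA_CODES}
    w[current_aa] = 0.0
    return {aa: p for aa, p in w.items() if p > 0}


def choose_aa(current_aa: str, policy: ChooserPolicy, rng: np.random.Generator) -> str:
    """Draw a replacement amino acid != ``current_aa`` under the policy's scheme."""
    if current_aa not in AA_CODES:
        raise ValueError(f"invalid current amino acid {current_aa!r}")
    weights = _aa_weights(current_aa, policy)
    if not weights:
        raise ChooserExhaustionError(
            f"no replacement available for {current_aa!r} under scheme "
            f"{policy.aa_scheme!r} (empty choice set)", achievable=0,
        )
    codes = sorted(weights)
    p = np.array([weights[a] for a in codes])
    return codes[int(rng.choice(len(codes), p=p / p.sum()))]


def _check_guided_coverage(complex: ComplexModel,
                           contrib: Optional[Mapping[tuple[str, int], float]]):
    if contrib is None:
        raise ValueError("guided site mode requires a per-residue contribution map")
    missing = sorted(set(complex.mutable_positions) - set(contrib))
    if missing:
        raise ValueError(
            "guided site mode: contributions missing for mutable positions "
            + ", ".join(f"{c}:{p}" for c, p in missing)
        )


def choose_site(
    complex: ComplexModel,
    policy: ChooserPolicy,
    per_residue_contrib: Optional[Mapping[tuple[str, int], float]] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[str, int]:
    """Select one mutable site.

    Random mode draws uniformly over the mutable positions.  Guided mode
    returns the position with the *largest* contribution (worst contributor
    under the lower-is-better convention); ties break lexicographically by
    ``(chain_id, position)``.
    """
    sites = sorted(complex.mutable_positions)
    if not sites:
        raise ValueError("complex declares no mutable positions")
    if policy.site_mode == "guided":
        _check_guided_coverage(complex, per_residue_contrib)
        return max(sites, key=lambda s: (per_residue_contrib[s], [-ord(c) for c in s[0]], -s[1]))
    if rng is None:
        raise ValueError("random site mode requires an rng")
    return sites[int(rng.integers(len(sites)))]


def _guided_site_ranking(complex, contrib) -> list[tuple[str, int]]:
    """Mutable sites from worst to best contributor, lexicographic tie-break."""
    sites = sorted(complex.mutable_positions)
    return sorted(sites, key=lambda s: (-contrib[s], s))


def _enumerate_single_site(
    complex: ComplexModel,
    policy: ChooserPolicy,
    per_residue_contrib,
) -> tuple[list[Mutation], np.ndarray]:
    """All single-site mutations with their selection probabilities."""
    seq = complex.sequence()
    if policy.site_mode == "guided":
        _check_guided_coverage(complex, per_residue_contrib)
        sites = [_guided_site_ranking(complex, per_residue_contrib)[0]]
        site_p = [1.0]
    else:
        sites = sorted(complex.mutable_positions)
        site_p = [1.0 / len(sites)] * len(sites)
    muts, probs = [], []
    for (chain, pos), sp in zip(sites, site_p):
        wt = seq[(chain, pos)]
        weights = _aa_weights(wt, policy)
        total = sum(weights.values())
        for aa in sorted(weights):
            muts.append(Mutation(chain, pos, wt, aa))
            probs.append(sp * weights[aa] / total)
    return muts, np.asarray(probs)


def generate_mutations(
    complex: ComplexModel,
    policy: ChooserPolicy,
    n_branches: int,
    per_residue_contrib: Optional[Mapping[tuple[str, int], float]] = None,
    rng: Optional[np.random.Generator] = None,
    max_retries: int = 100,
) -> list[frozenset[Mutation]]:
    """Produce ``n_branches`` pairwise-distinct mutation sets.

    Each set contains ``policy.sites_per_mutant`` mutations at distinct
    positions.  Single-site proposals are drawn without replacement from the
    exact candidate distribution, so an exhaustive request (``n_branches`` ==
    number of possible substitutions) always succeeds.  Multi-site proposals
    use bounded rejection sampling (``max_retries`` consecutive duplicate
    draws abort).
    """
    if n_branches < 1:
        raise ValueError(f"n_branches must be >= 1, got {n_branches}")
    if rng is None:
        raise ValueError("generate_mutations requires an rng")
    if not complex.mutable_positions:
        raise ValueError("complex declares no mutable positions")

    if policy.sites_per_mutant == 1:
        muts, probs = _enumerate_single_site(complex, policy, per_residue_contrib)
        if len(muts) < n_branches:
            raise ChooserExhaustionError(
                f"requested {n_branches} distinct mutations but only {len(muts)} exist",
                achievable=len(muts),
            )
        idx = rng.choice(len(muts), size=n_branches, replace=False, p=probs)
        return [frozenset([muts[int(i)]]) for i in idx]

    if policy.sites_per_mutant > len(complex.mutable_positions):
        raise ChooserExhaustionError(
            f"sites_per_mutant={policy.sites_per_mutant} exceeds the "
            f"{len(complex.mutable_positions)} mutable positions", achievable=0,
        )
    seq = complex.sequence()
    sites_sorted = sorted(complex.mutable_positions)
    if policy.site_mode == "guided":
        _check_guided_coverage(complex, per_residue_contrib)
        ranked = _guided_site_ranking(complex, per_residue_contrib)
        fixed_sites = ranked[: policy.sites_per_mutant]

    chosen: list[frozenset[Mutation]] = []
    seen: set[frozenset[Mutation]] = set()
    misses = 0
    while len(chosen) < n_branches:
        if policy.site_mode == "guided":
            sites = fixed_sites
        else:
            pick = rng.choice(len(sites_sorted), size=policy.sites_per_mutant, replace=False)
            sites = [sites_sorted[int(i)] for i in sorted(pick)]
        try:
            mset = frozenset(
                Mutation(c, p, seq[(c, p)], choose_aa(seq[(c, p)], policy, rng))
                for c, p in sites
            )
        except ChooserExhaustionError:
            raise ChooserExhaustionError(
                "a selected site admits no replacement under the amino-acid scheme",
                achievable=len(chosen),
            )
        if mset in seen:
            misses += 1
            if misses >= max_retries:
                raise ChooserExhaustionError(
                    f"could not find {n_branches} distinct mutation sets after "
                    f"{max_retries} consecutive duplicate draws "
                    f"({len(chosen)} found)", achievable=len(chosen),
                )
            continue
        misses = 0
        seen.add(mset)
        chosen.append(mset)
    return chosen
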