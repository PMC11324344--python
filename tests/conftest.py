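import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from binderopt.model import ComplexModel, ResidueRecord
from binderopt.toys import ToySpec, make_toy_complex

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def build_complex(binder, target, mutable=None):
    """Small helper: residues given as (chain, pos, aa, anchor, side-or-None)."""
    def rec(chain, pos, aa, anchor, side):
        if side is None or aa == "G":
            side = anchor
        return ResidueRecord(chain, pos, aa, np.asarray(anchor, float),
                             np.asarray(side, float))

    residues = [rec(*r) for r in binder] + [rec(*r) for r in target]
    b_chains = {r[0] for r in binder}
    t_chains = {r[0] for r in target}
    if mutable is None:
        mutable = {(r[0], r[1]) for r in binder}
    return ComplexModel(tuple(residues), frozenset(b_chains), frozenset(t_chains),
                        frozenset(mutable))


@pytest.fixture
def tiny_pair():
    """One binder and one target residue 5 A apart."""
    return build_complex(
        [("A", 1, "L", (0.0, 0.0, 0.0), None)],
        [("B", 1, "F", (0.0, 0.0, 5.0), None)],
    )


@pytest.fixture
def toy_complex():
    return make_toy_complex(ToySpec(n_binder=12, n_target=12, seed=42))


@pytest.fixture
def blob_complex():
    return make_toy_complex(
        ToySpec(n_binder=30, n_target=30, geometry="random_blob", seed=7)
    )


def brute_force_pairs(complex, cutoff):
    """Independent all-pairs O(n^2) contact enumeration."""
    import math

    pairs = []
    binder = [r for r in complex.residues if r.chain_id in complex.binder_chains]
    target = [r for r in complex.residues if r.chain_id in complex.target_chains]
    for b in binder:
        for t in target:
            if math.dist(b.side_xyz, t.side_xyz) <= cutoff:
                pairs.append(((b.chain_id, b.position), (t.chain_id, t.position)))
    return pairs
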