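"""Scorers: closed forms, brute-force oracles, decomposition conservation."""

import math

import numpy as np
import pytest

from binderopt.errors import ConfigValidationError, NotDecomposableError
from binderopt.model import RESIDUE_CHARGE, ScoreTable
from binderopt.sample import Ensemble, SamplerParams, jitter_sample
from binderopt.scoring import (
    ScorerSpec,
    build_scorer,
    contact_count_score,
    contact_score,
    electro_score,
    load_contact_matrix,
    per_residue_decomposition,
    score_ensemble,
)
from binderopt.toys import ToySpec, make_toy_complex

from conftest import brute_force_pairs, build_complex


def brute_contact(complex, matrix, cutoff):
    seq = complex.sequence()
    return sum(matrix[seq[b]][seq[t]] for b, t in brute_force_pairs(complex, cutoff))


def brute_electro(complex, cutoff, lam):
    total = 0.0
    lookup = {(r.chain_id, r.position): r for r in complex.residues}
    for b, t in brute_force_pairs(complex, cutoff):
        rb, rt = lookup[b], lookup[t]
        qb = RESIDUE_CHARGE.get(rb.aa, 0.0)
        qt = RESIDUE_CHARGE.get(rt.aa, 0.0)
        d = math.dist(rb.side_xyz, rt.side_xyz)
        if qb and qt and d > 0:
            total += qb * qt * math.exp(-d / lam) / d
    return total


class TestContactScore:
    def test_no_contacts_scores_zero(self):
        c = make_toy_complex(ToySpec(interface_gap=100.0, seed=0))
        assert contact_score(c) == 0.0

    def test_single_pair_reads_matrix_entry(self):
        c = build_complex([("A", 1, "L", (0, 0, 0), None)],
                          [("B", 1, "F", (0, 0, 5), None)])
        matrix = {a: {b: 0.0 for b in "ACDEFGHIKLMNPQRSTVWY"}
                  for a in "ACDEFGHIKLMNPQRSTVWY"}
        matrix["L"]["F"] = matrix["F"]["L"] = -0.5
        assert contact_score(c, matrix=matrix) == pytest.approx(-0.5, abs=1e-12)

    def test_asymmetric_matrix_rejected_at_construction(self):
        matrix = {a: {b: 0.0 for b in "ACDEFGHIKLMNPQRSTVWY"}
                  for a in "ACDEFGHIKLMNPQRSTVWY"}
        matrix["L"]["F"] = -0.5  # symmetric partner left at 0
        with pytest.raises(ValueError, match="asymmetric"):
            build_scorer(ScorerSpec("c", "contact_potential", {"matrix": matrix}))

    def test_default_matrix_is_symmetric_with_plausible_structure(self):
        m = load_contact_matrix()
        assert m["I"]["L"] < 0  # hydrophobic pair favorable
        assert m["D"]["E"] > 0 and m["K"]["R"] > 0  # like charges unfavorable
        assert m["D"]["K"] < m["D"]["E"]  # salt bridge beats repulsion


class TestElectroScore:
    def test_neutral_interface_scores_zero(self):
        c = build_complex([("A", 1, "L", (0, 0, 0), None)],
                          [("B", 1, "F", (0, 0, 5), None)])
        assert electro_score(c) == 0.0

    def test_single_salt_bridge_closed_form(self):
        c = build_complex([("A", 1, "D", (0, 0, 0), None)],
                          [("B", 1, "K", (0, 0, 5), None)])
        expected = (-1) * (+1) * math.exp(-0.5) / 5  # = -0.12131...
        assert electro_score(c, screen_len=10.0) == pytest.approx(expected, abs=1e-9)
        assert electro_score(c, screen_len=10.0) == pytest.approx(-0.12131, abs=1e-5)

    def test_coincident_pseudo_atoms_skipped_with_warning(self):
        c = build_complex([("A", 1, "D", (0, 0, 0), (1, 1, 1))],
                          [("B", 1, "K", (0, 0, 5), (1, 1, 1))])
        with pytest.warns(UserWarning, match="coincident"):
            assert electro_score(c) == 0.0


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_all_scorers_match_brute_force(self, seed):
        c = make_toy_complex(ToySpec(n_binder=15, n_target=15,
                                     geometry="random_blob", seed=seed))
        matrix = load_contact_matrix()
        assert contact_score(c) == pytest.approx(brute_contact(c, matrix, 8.0), abs=1e-9)
        assert electro_score(c) == pytest.approx(brute_electro(c, 8.0, 10.0), abs=1e-9)
        assert contact_count_score(c) == -len(brute_force_pairs(c, 8.0))


class TestScoreEnsemble:
    SPECS = [ScorerSpec("c", "contact_potential"), ScorerSpec("n", "contact_count")]

    def test_single_frame_average_equals_frame_score(self, toy_complex):
        table = score_ensemble(Ensemble((toy_complex,), None, 0), self.SPECS)
        for s in table.scorer_names:
            assert table.averages[s] == table.per_frame[s][0]

    def test_averages_are_means_and_bounded(self, toy_complex):
        ens = jitter_sample(toy_complex, SamplerParams(n_frames=6),
                            np.random.default_rng(1))
        table = score_ensemble(ens, self.SPECS)
        for s in table.scorer_names:
            scores = table.per_frame[s]
            assert table.averages[s] == pytest.approx(np.mean(scores), abs=1e-12)
            assert min(scores) <= table.averages[s] <= max(scores)

    def test_frame_order_invariance(self, toy_complex):
        ens = jitter_sample(toy_complex, SamplerParams(n_frames=5),
                            np.random.default_rng(2))
        fwd = score_ensemble(ens, self.SPECS)
        rev = score_ensemble(Ensemble(tuple(reversed(ens.frames)), None, 0), self.SPECS)
        for s in fwd.scorer_names:
            assert fwd.averages[s] == pytest.approx(rev.averages[s], abs=1e-12)

    def test_sign_flips_scores(self, toy_complex):
        plus = score_ensemble(Ensemble((toy_complex,), None, 0),
                              [ScorerSpec("n", "contact_count", sign=1)])
        minus = score_ensemble(Ensemble((toy_complex,), None, 0),
                               [ScorerSpec("n", "contact_count", sign=-1)])
        assert plus.averages["n"] == -minus.averages["n"]

    def test_unknown_kind_rejected_at_spec_construction(self):
        with pytest.raises(ConfigValidationError):
            ScorerSpec("x", "quantum_oracle")

    def test_rigid_translation_invariance(self, toy_complex):
        shifted = toy_complex.translated([11.0, -3.0, 2.0])
        for spec in self.SPECS + [ScorerSpec("e", "screened_electrostatic")]:
            s0 = build_scorer(spec).score(toy_complex)
            s1 = build_scorer(spec).score(shifted)
            assert s1 == pytest.approx(s0, abs=1e-9)


class TestDecomposition:
    @pytest.mark.parametrize("kind", ["contact_potential", "screened_electrostatic",
                                      "contact_count"])
    def test_contributions_reconstitute_total(self, blob_complex, kind):
        spec = ScorerSpec("s", kind)
        total = build_scorer(spec).score(blob_complex)
        decomp = per_residue_decomposition(blob_complex, spec)
        assert sum(decomp.values()) == pytest.approx(total, abs=1e-9)
        assert set(decomp) == {(r.chain_id, r.position) for r in blob_complex.residues}

    def test_single_pair_half_split(self):
        c = build_complex([("A", 1, "L", (0, 0, 0), None)],
                          [("B", 1, "F", (0, 0, 5), None)])
        decomp = per_residue_decomposition(c, ScorerSpec("n", "contact_count"))
        assert decomp[("A", 1)] == decomp[("B", 1)] == -0.5

    def test_empty_interface_all_zeros(self):
        c = make_toy_complex(ToySpec(interface_gap=100.0, seed=3))
        decomp = per_residue_decomposition(c, ScorerSpec("n", "contact_count"))
        assert all(v == 0.0 for v in decomp.values())

    def test_non_decomposable_scorer_errors(self, toy_complex):
        from binderopt.scoring import register_scorer_adapter

        register_scorer_adapter("null", lambda pdb: 0.0)
        spec = ScorerSpec("x", "external", {"adapter": "null"})
        with pytest.raises(NotDecomposableError):
            per_residue_decomposition(toy_complex, spec)

    def test_external_adapter_scores_written_frames(self, toy_complex):
        from binderopt.scoring import register_scorer_adapter

        def count_atoms(pdb_path):
            return -sum(1 for l in pdb_path.read_text().splitlines()
                        if l.startswith("ATOM"))

        register_scorer_adapter("atoms", count_atoms)
        spec = ScorerSpec("x", "external", {"adapter": "atoms"})
        n_atoms = sum(2 if r.aa != "G" else 1 for r in toy_complex.residues)
        assert build_scorer(spec).score(toy_complex) == -n_atoms
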