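"""Mutation Chooser: site and amino-acid selection under each policy."""

import numpy as np
import pytest
from scipy import stats

from binderopt.chooser import ChooserPolicy, choose_aa, choose_site, generate_mutations
from binderopt.errors import ChooserExhaustionError, ConfigValidationError
from binderopt.model import AA_CODES
from binderopt.toys import ToySpec, make_toy_complex

from conftest import build_complex


def one_site_complex(aa="A"):
    return build_complex(
        [("A", 1, aa, (0, 0, 0), None), ("A", 2, "L", (3.8, 0, 0), None),
         ("A", 3, "K", (7.6, 0, 0), None)],
        [("B", 1, "F", (0, 5, 0), None)],
        mutable={("A", 1)},
    )


class TestChooseSite:
    def test_single_site_returned_any_mode(self):
        c = one_site_complex()
        rng = np.random.default_rng(0)
        assert choose_site(c, ChooserPolicy(), rng=rng) == ("A", 1)
        guided = ChooserPolicy(site_mode="guided")
        assert choose_site(c, guided, {("A", 1): -1.0}) == ("A", 1)

    def test_guided_picks_worst_contributor(self, toy_complex):
        # lower-is-better: +1.5 is the worst contribution
        contrib = {pos: -3.0 for pos in toy_complex.mutable_positions}
        contrib[("A", 12)] = 1.5
        contrib[("A", 10)] = -0.2
        got = choose_site(toy_complex, ChooserPolicy(site_mode="guided"), contrib)
        assert got == ("A", 12)

    def test_guided_tie_breaks_lexicographically(self, toy_complex):
        contrib = dict.fromkeys(toy_complex.mutable_positions, 2.0)
        got = choose_site(toy_complex, ChooserPolicy(site_mode="guided"), contrib)
        assert got == ("A", 1)

    def test_guided_missing_contributions_error_names_positions(self, toy_complex):
        contrib = {pos: 0.0 for pos in toy_complex.mutable_positions if pos != ("A", 7)}
        with pytest.raises(ValueError, match="A:7"):
            choose_site(toy_complex, ChooserPolicy(site_mode="guided"), contrib)

    def test_random_mode_is_uniform(self):
        c = build_complex(
            [("A", i, "L", (3.8 * i, 0, 0), None) for i in range(1, 5)],
            [("B", 1, "F", (0, 5, 0), None)],
        )
        rng = np.random.default_rng(123)
        counts = {}
        n = 40_000
        for _ in range(n):
            s = choose_site(c, ChooserPolicy(), rng=rng)
            counts[s] = counts.get(s, 0) + 1
        for site, k in counts.items():
            assert abs(k / n - 0.25) < 0.01, site


class TestChooseAA:
    def test_never_returns_current(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            assert choose_aa("W", ChooserPolicy(), rng) != "W"

    def test_grouped_forced_choice(self):
        policy = ChooserPolicy(aa_scheme="grouped",
                               groups={"neg": frozenset("DE")}, active_group="neg")
        rng = np.random.default_rng(2)
        assert choose_aa("D", policy, rng) == "E"

    def test_grouped_empty_choice_set_errors(self):
        policy = ChooserPolicy(aa_scheme="grouped",
                               groups={"solo": frozenset("D")}, active_group="solo")
        with pytest.raises(ChooserExhaustionError):
            choose_aa("D", policy, np.random.default_rng(0))

    def test_custom_point_mass(self):
        policy = ChooserPolicy(aa_scheme="custom", aa_probs={"W": 1.0})
        rng = np.random.default_rng(3)
        assert all(choose_aa("A", policy, rng) == "W" for _ in range(20))

    def test_uniform_frequencies_within_3_sigma(self):
        rng = np.random.default_rng(4)
        n = 19_000
        counts = dict.fromkeys(AA_CODES, 0)
        for _ in range(n):
            counts[choose_aa("G", ChooserPolicy(), rng)] += 1
        assert counts["G"] == 0
        p = 1 / 19
        sigma = np.sqrt(p * (1 - p) / n)
        for aa in AA_CODES.replace("G", ""):
            assert abs(counts[aa] / n - p) < 3.5 * sigma, aa

    def test_custom_frequencies_chi_square(self):
        probs = {"W": 4.0, "F": 2.0, "Y": 1.0, "L": 1.0}
        policy = ChooserPolicy(aa_scheme="custom", aa_probs=probs)
        rng = np.random.default_rng(5)
        n = 10_000
        counts = dict.fromkeys(probs, 0)
        for _ in range(n):
            counts[choose_aa("A", policy, rng)] += 1
        total = sum(probs.values())
        expected = [n * probs[aa] / total for aa in probs]
        _, pval = stats.chisquare([counts[aa] for aa in probs], expected)
        assert pval > 0.001

    def test_invalid_policies_rejected(self):
        with pytest.raises(ConfigValidationError):
            ChooserPolicy(aa_scheme="custom", aa_probs={"W": -1.0})
        with pytest.raises(ConfigValidationError):
            ChooserPolicy(aa_scheme="grouped")  # no active group


class TestGenerateMutations:
    def test_exhaustive_single_site_returns_all_19(self):
        c = one_site_complex("A")
        rng = np.random.default_rng(6)
        sets = generate_mutations(c, ChooserPolicy(), 19, rng=rng)
        muts = {next(iter(s)).mut_aa for s in sets}
        assert len(sets) == 19 and muts == set(AA_CODES) - {"A"}

    def test_pigeonhole_error_reports_achievable_maximum(self):
        c = one_site_complex("D")
        policy = ChooserPolicy(aa_scheme="grouped",
                               groups={"g": frozenset("DEK")}, active_group="g")
        with pytest.raises(ChooserExhaustionError) as exc:
            generate_mutations(c, policy, 3, rng=np.random.default_rng(7))
        assert exc.value.achievable == 2

    def test_two_site_sets_are_pairwise_distinct(self, toy_complex):
        policy = ChooserPolicy(sites_per_mutant=2)
        rng = np.random.default_rng(8)
        sets = generate_mutations(toy_complex, policy, 8, rng=rng)
        assert len(sets) == 8
        assert len({frozenset(s) for s in sets}) == 8
        for s in sets:
            assert len({(m.chain_id, m.position) for m in s}) == 2

    def test_same_seed_reproduces(self, toy_complex):
        a = generate_mutations(toy_complex, ChooserPolicy(), 6,
                               rng=np.random.default_rng(9))
        b = generate_mutations(toy_complex, ChooserPolicy(), 6,
                               rng=np.random.default_rng(9))
        assert a == b

    def test_guided_targets_single_worst_site(self, toy_complex):
        contrib = {pos: float(-pos[1]) for pos in toy_complex.mutable_positions}
        policy = ChooserPolicy(site_mode="guided")
        sets = generate_mutations(toy_complex, policy, 5, contrib,
                                  rng=np.random.default_rng(10))
        sites = {next(iter(s)).position for s in sets}
        assert sites == {1}  # -1 is the largest contribution

    def test_single_site_frequencies_match_policy(self):
        # uniform over 3 sites x 19 aa: each specific mutation p = 1/57
        c = make_toy_complex(ToySpec(seed=0))
        c = type(c)(c.residues, c.binder_chains, c.target_chains,
                    frozenset({("A", 1), ("A", 2), ("A", 3)}))
        rng = np.random.default_rng(11)
        counts = {}
        n = 10_000
        for _ in range(n):
            (m,) = generate_mutations(c, ChooserPolicy(), 1, rng=rng)[0]
            counts[str(m)] = counts.get(str(m), 0) + 1
        observed = np.array([counts.get(k, 0) for k in sorted(counts)])
        _, pval = stats.chisquare(observed)
        assert len(counts) == 57 and pval > 0.001
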