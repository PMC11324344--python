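"""Epoch engine: DAG structure, width control, restart rule, determinism."""

import json

import numpy as np
import pytest

from binderopt.config import config_from_dict
from binderopt.errors import AllLineagesFailedError
from binderopt.model import ScoreTable
from binderopt.optimize import (
    EpochSchedule,
    enforce_width,
    lineage_record,
    run_epoch,
    run_optimization,
    trajectory_table,
    write_run_directory,
)
from binderopt.toys import ToySpec, make_toy_complex


def make_config(**overrides):
    base = {
        "input_pdb": "unused.pdb",
        "binder_chains": ["A"],
        "target_chains": ["B"],
        "mutable_positions": ["A:1-12"],
        "sampler": {"n_frames": 3},
        "scorers": [
            {"name": "contact", "kind": "contact_potential"},
            {"name": "nc", "kind": "contact_count"},
        ],
        "pruner": {"kind": "consensus_threshold", "consensus_k": 1},
        "schedule": {"total_epochs": 3, "branches_per_node": 3},
        "seed": 7,
        "workers": 1,
    }
    base.update(overrides)
    return config_from_dict(base)


ZERO_SAMPLER = {"n_frames": 1, "rigid_rot_max": 0.0, "rigid_trans_max": 0.0,
                "residue_noise_sd": 0.0}


@pytest.fixture
def complex12():
    return make_toy_complex(ToySpec(seed=20))


class TestEpochSchedule:
    def test_restrained_phase_boundaries(self):
        s = EpochSchedule(total_epochs=18, restrained_epochs=5)
        assert s.restrained_at(0) and s.restrained_at(5)
        assert not s.restrained_at(6) and not s.restrained_at(18)

    def test_restrained_epochs_bounded_by_total(self):
        from binderopt.errors import ConfigValidationError

        with pytest.raises(ConfigValidationError):
            EpochSchedule(total_epochs=3, restrained_epochs=4)


class TestRunEpoch:
    def test_all_retained_variable_mode_widens(self, complex12):
        cfg = make_config(
            pruner={"kind": "consensus_threshold", "consensus_k": 0},
            schedule={"total_epochs": 2, "branches_per_node": 4},
        )
        dag = run_optimization(cfg, complex=complex12)
        assert len(dag.active_ids(1)) == 4
        assert len(dag.active_ids(2)) == 16

    def test_never_retaining_pruner_reuses_parents(self, complex12):
        cfg = make_config(
            pruner={"kind": "consensus_threshold", "consensus_k": 2,
                    "tolerance": 1e9},
            schedule={"total_epochs": 4, "branches_per_node": 3},
        )
        dag = run_optimization(cfg, complex=complex12)
        assert dag.meta["epochs_run"] == 4
        root_seq = complex12.sequence()
        for epoch in range(1, 5):
            active = dag.active_ids(epoch)
            assert len(active) == 1
            node = dag.nodes[active[0]]
            assert node.mutations_from_parent == frozenset()
            assert node.complex.sequence() == root_seq
            assert node.diagnostics.get("reused_parent")

    def test_reused_parent_scores_are_cached_not_recomputed(self, complex12):
        cfg = make_config(
            pruner={"kind": "consensus_threshold", "consensus_k": 2,
                    "tolerance": 1e9},
            schedule={"total_epochs": 2, "branches_per_node": 2},
        )
        dag = run_optimization(cfg, complex=complex12)
        root = dag.nodes["00-000"]
        for epoch in (1, 2):
            carried = dag.nodes[dag.active_ids(epoch)[0]]
            assert carried.scores is root.scores

    def test_constant_mode_caps_width(self, complex12):
        cfg = make_config(
            pruner={"kind": "consensus_threshold", "consensus_k": 0},
            schedule={"total_epochs": 5, "branches_per_node": 4,
                      "width_mode": "constant", "max_width": 2},
        )
        dag = run_optimization(cfg, complex=complex12)
        for epoch in range(1, 6):
            assert len(dag.active_ids(epoch)) <= 2

    def test_all_lineages_failed_raises(self, complex12):
        cfg = make_config()
        dag = run_optimization(cfg, complex=complex12)
        for nid in dag.active_ids(dag.last_epoch):
            dag.nodes[nid].status = "failed"
        with pytest.raises(AllLineagesFailedError):
            run_epoch(dag, cfg)

    def test_chooser_exhaustion_stops_run_early(self, complex12):
        # 1 mutable site, 3-residue support: the root branches into all 3
        # substitutions, then every child has only 2 options < 3 branches.
        cfg = make_config(
            mutable_positions=["A:5"],
            chooser={"aa_scheme": "custom",
                     "aa_probs": {"D": 1.0, "E": 1.0, "K": 1.0}},
            pruner={"kind": "consensus_threshold", "consensus_k": 0},
            schedule={"total_epochs": 4, "branches_per_node": 3},
            sampler=ZERO_SAMPLER,
        )
        wt = complex12.sequence()[("A", 5)]
        assert wt not in "DEK"  # seed 20 toy: support is all 3 codes
        dag = run_optimization(cfg, complex=complex12)
        assert dag.meta["stopped_early"]
        assert dag.meta["epochs_run"] == 1
        # the DAG widened to all 3 substitutions, then every lineage was
        # marked failed when it could not supply 3 distinct mutants
        assert len(dag.epochs[1]) == 3
        assert all(dag.nodes[n].status == "failed" for n in dag.epochs[1])


class TestEnforceWidth:
    def table(self, *vals):
        return ScoreTable.from_frames({f"s{i}": (v,) for i, v in enumerate(vals)})

    def test_variable_mode_is_identity(self):
        survivors = {"a": self.table(1.0, 2.0), "b": self.table(0.0, 5.0)}
        assert enforce_width(survivors, "variable", 1) == {"a", "b"}

    def test_single_survivor_kept_regardless(self):
        assert enforce_width({"x": self.table(9.0)}, "constant", 3) == {"x"}

    def test_matches_ranking_oracle(self):
        rng = np.random.default_rng(0)
        names = [f"n{i}" for i in range(6)]
        parent = self.table(*rng.normal(size=3))
        survivors = {n: self.table(*rng.normal(size=3)) for n in names}
        parents = {n: parent for n in names}
        got = enforce_width(survivors, "constant", 2, parents)
        # independent ranking: improvements desc, mean rank asc, id
        import scipy.stats

        improved = {n: sum(survivors[n].averages[s] < parent.averages[s]
                           for s in parent.scorer_names) for n in names}
        mean_rank = {n: 0.0 for n in names}
        for s in parent.scorer_names:
            r = scipy.stats.rankdata([survivors[n].averages[s] for n in sorted(names)])
            for n, rr in zip(sorted(names), r):
                mean_rank[n] += rr / 3
        expected = set(sorted(names,
                              key=lambda n: (-improved[n], mean_rank[n], n))[:2])
        assert got == expected


class TestRunOptimization:
    def test_zero_epochs_scores_root_only(self, complex12):
        cfg = make_config(schedule={"total_epochs": 0})
        dag = run_optimization(cfg, complex=complex12)
        assert list(dag.nodes) == ["00-000"]
        assert dag.nodes["00-000"].scores is not None

    def test_two_phase_schedule_runs_18_epochs_with_boundary(self, complex12):
        cfg = make_config(
            pruner={"kind": "consensus_threshold", "consensus_k": 0},
            schedule={"total_epochs": 18, "restrained_epochs": 5,
                      "branches_per_node": 2, "width_mode": "constant",
                      "max_width": 1},
            sampler={"n_frames": 3},
        )
        dag = run_optimization(cfg, complex=complex12)
        assert dag.meta["epochs_run"] == 18
        table = trajectory_table(dag, cfg)
        phases = table.drop_duplicates("epoch").set_index("epoch")["phase"]
        assert (phases.loc[:5] == "restrained").all()
        assert (phases.loc[6:] == "unrestrained").all()

    def test_same_config_and_seed_bit_identical_records(self, complex12, tmp_path):
        cfg = make_config()
        texts = []
        for name in ("one", "two"):
            dag = run_optimization(cfg, complex=complex12)
            d = tmp_path / name
            write_run_directory(dag, cfg, d)
            texts.append((d / "lineage.json").read_text())
        assert texts[0] == texts[1]

    def test_greedy_regime_is_monotone(self, complex12):
        cfg = make_config(
            sampler=ZERO_SAMPLER,
            scorers=[{"name": "contact", "kind": "contact_potential"}],
            pruner={"kind": "top_n", "keep_n": 1, "reference_scorer": "contact"},
            schedule={"total_epochs": 10, "branches_per_node": 5},
        )
        dag = run_optimization(cfg, complex=complex12)
        best = [dag.best_average(e, "contact") for e in range(len(dag.epochs))]
        assert all(b2 <= b1 + 1e-12 for b1, b2 in zip(best, best[1:]))

    def test_lineage_replay_reproduces_sequences(self, complex12):
        cfg = make_config(schedule={"total_epochs": 4, "branches_per_node": 3})
        dag = run_optimization(cfg, complex=complex12)
        for nid, node in dag.nodes.items():
            assert dag.replay_sequence(nid) == node.complex.sequence(), nid

    def test_dag_is_epoch_layered(self, complex12):
        cfg = make_config()
        dag = run_optimization(cfg, complex=complex12)
        for nid, node in dag.nodes.items():
            if node.parent_id is not None:
                assert dag.nodes[node.parent_id].epoch == node.epoch - 1
                # non-root active nodes descend from previously active parents
                assert dag.nodes[node.parent_id].status in ("active", "failed")

    def test_run_directory_layout(self, complex12, tmp_path):
        cfg = make_config(schedule={"total_epochs": 2, "branches_per_node": 2})
        dag = run_optimization(cfg, complex=complex12, output_dir=tmp_path / "run")
        rd = tmp_path / "run"
        assert (rd / "lineage.json").exists()
        assert (rd / "trajectory_report.csv").exists()
        assert (rd / "config_effective.yaml").exists()
        node_dir = rd / "epoch_01" / "01-000"
        for f in ("input.pdb", "mutated.pdb", "ensemble.pdb", "scores.csv"):
            assert (node_dir / f).exists(), f
        record = json.loads((rd / "lineage.json").read_text())
        assert {n["node_id"] for n in record["nodes"]} == set(dag.nodes)
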