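"""The epoch engine: branch, mutate, sample, score, prune, manage DAG width.

One *epoch* takes every active lineage, proposes ``branches_per_node`` mutant
complexes from each, relaxes each mutant with the sampler, scores the
resulting ensemble with every configured scorer, and prunes the mutants
against their parent.  Surviving mutants become the next epoch's active
nodes; when nothing survives, the parent binders are reused and re-branched
(the restart rule).  The accumulated parent/child record is an epoch-layered
directed acyclic graph (edges only from epoch e to e+1).

Width control:

variable
    every survivor stays active; the DAG widens as retention allows.
constant
    survivors are ranked (scorers improved vs parent, then mean across-scorer
    rank, then node id) and only ``max_width`` stay active.

Reproducibility: every stochastic stage draws from a substream derived by
counter-based seeding from ``(master seed, epoch, lineage index, stage)``, so
results are invariant to worker count and execution order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .chooser import generate_mutations
from .dispatch import TaskSpec, run_tasks
from .errors import AllLineagesFailedError, ChooserExhaustionError, ConfigValidationError
from .model import ComplexModel, Mutation, ScoreTable
from .mutate import apply_mutation
from .prune import consensus_prune, improvement_vector, metropolis_prune, top_prune
from .sample import Ensemble, jitter_sample
from .scoring import DECOMPOSABLE_KINDS, Scorer, build_scorers, score_ensemble

if TYPE_CHECKING:  # config imports EpochSchedule from here; avoid the cycle
    from .config import RunConfig

log = logging.getLogger("binderopt.optimize")

# stage codes for substream derivation
_STAGE_CHOOSER, _STAGE_SAMPLE, _STAGE_PRUNE, _STAGE_ROOT = 0, 1, 2, 3


@dataclass(frozen=True)
class EpochSchedule:
    """How many epochs to run and how the DAG may widen.

    The first ``restrained_epochs`` epochs sample with positional restraints
    (reduced perturbation amplitudes) to keep the starting pose intact; the
    remainder run unrestrained.
    """

    total_epochs: int = 10
    restrained_epochs: int = 0
    branches_per_node: int = 4
    width_mode: str = "variable"
    max_width: int = 4

    def __post_init__(self):
        problems = []
        if self.total_epochs < 0:
            problems.append(f"total_epochs must be >= 0, got {self.total_epochs}")
        if not (0 <= self.restrained_epochs <= max(self.total_epochs, 0)):
            problems.append(
                f"restrained_epochs must lie in [0, total_epochs], got "
                f"{self.restrained_epochs} with total_epochs={self.total_epochs}"
            )
        if self.branches_per_node < 1:
            problems.append(f"branches_per_node must be >= 1, got {self.branches_per_node}")
        if self.width_mode not in ("variable", "constant"):
            problems.append(f"unknown width_mode {self.width_mode!r}")
        if self.max_width < 1:
            problems.append(f"max_width must be >= 1, got {self.max_width}")
        if problems:
            raise ConfigValidationError(problems)

    def restrained_at(self, epoch: int) -> bool:
        """Is sampling restrained at this epoch?  Epoch 0 (the root) follows
        the first phase."""
        if epoch == 0:
            return self.restrained_epochs > 0
        return epoch <= self.restrained_epochs


@dataclass
class NodeState:
    """One complex variant in the lineage DAG."""

    node_id: str
    parent_id: Optional[str]
    complex: ComplexModel
    mutations_from_parent: frozenset[Mutation]
    epoch: int
    scores: Optional[ScoreTable] = None
    status: str = "active"  # active | pruned | failed
    ensemble: Optional[Ensemble] = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.parent_id is None and self.mutations_from_parent:
            raise ValueError("the root node cannot carry mutations")


@dataclass
class LineageDAG:
    """Epoch-layered record of every variant visited during a run."""

    nodes: dict[str, NodeState] = field(default_factory=dict)
    epochs: list[list[str]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def add_node(self, node: NodeState) -> None:
        if node.node_id in self.nodes:
            raise ValueError(f"duplicate node id {node.node_id!r}")
        if node.parent_id is not None:
            parent = self.nodes.get(node.parent_id)
            if parent is None:
                raise ValueError(f"unknown parent {node.parent_id!r}")
            if parent.epoch != node.epoch - 1:
                raise ValueError(
                    f"edge {node.parent_id} -> {node.node_id} is not epoch e -> e+1"
                )
        self.nodes[node.node_id] = node

    def active_ids(self, epoch: int) -> list[str]:
        return [nid for nid in self.epochs[epoch] if self.nodes[nid].status == "active"]

    @property
    def last_epoch(self) -> int:
        return len(self.epochs) - 1

    def replay_sequence(self, node_id: str) -> dict[tuple[str, int], str]:
        """Sequence obtained by replaying the mutation chain from the root."""
        chain: list[NodeState] = []
        node = self.nodes[node_id]
        while node is not None:
            chain.append(node)
            node = self.nodes[node.parent_id] if node.parent_id else None
        seq = dict(chain[-1].complex.sequence())
        for node in reversed(chain):
            for m in sorted(node.mutations_from_parent, key=str):
                seq[(m.chain_id, m.position)] = m.mut_aa
        return seq

    def best_average(self, epoch: int, scorer: str) -> float:
        """Lowest (best) average among the epoch's active, scored nodes."""
        vals = [self.nodes[nid].scores.averages[scorer]
                for nid in self.active_ids(epoch) if self.nodes[nid].scores]
        if not vals:
            raise ValueError(f"epoch {epoch} has no scored active nodes")
        return min(vals)


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def _substream_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0])


def _sample_and_score(
    complex: ComplexModel,
    sampler_params,
    scorers: list[Scorer],
    seed_record: int,
    rng: np.random.Generator,
):
    ensemble = jitter_sample(complex, sampler_params, rng, seed_record=seed_record)
    table = score_ensemble(ensemble, scorers)
    disp = ensemble.binder_centroid_displacements()
    diagnostics = {
        "mean_binder_centroid_displacement": float(disp[1:].mean()) if len(disp) > 1 else 0.0,
        "restrained": bool(sampler_params.restrained),
    }
    return ensemble, table, diagnostics


def _guided_contributions(
    complex: ComplexModel, scorers: list[Scorer]
) -> Optional[dict[tuple[str, int], float]]:
    for s in scorers:
        if s.spec.kind in DECOMPOSABLE_KINDS:
            return s.decompose(complex)
    return None


def enforce_width(
    survivors: Mapping[str, ScoreTable],
    mode: str,
    max_width: int,
    parent_tables: Optional[Mapping[str, Optional[ScoreTable]]] = None,
) -> set[str]:
    """Select which survivors stay active.

    Variable mode keeps everything.  Constant mode ranks survivors by
    (1) number of scorers improved over their parent, descending;
    (2) mean across-scorer rank of their averages among survivors, ascending;
    (3) node id — and keeps the top ``max_width``.  Survivors without a
    parent table (reused parents) count zero improvements.
    """
    if not survivors:
        raise ValueError("enforce_width requires at least one survivor")
    if mode == "variable":
        return set(survivors)
    ids = sorted(survivors)
    scorer_names = survivors[ids[0]].scorer_names
    improved = {}
    for nid in ids:
        ptable = (parent_tables or {}).get(nid)
        improved[nid] = (
            sum(improvement_vector(ptable, survivors[nid]).values()) if ptable else 0
        )
    mean_rank = dict.fromkeys(ids, 0.0)
    for s in scorer_names:
        ranks = rankdata([survivors[nid].averages[s] for nid in ids], method="average")
        for nid, r in zip(ids, ranks):
            mean_rank[nid] += r / len(scorer_names)
    ranked = sorted(ids, key=lambda nid: (-improved[nid], mean_rank[nid], nid))
    return set(ranked[:max_width])


def _prune_node(
    parent: NodeState,
    mutant_tables: dict[str, ScoreTable],
    config: "RunConfig",
    rng: np.random.Generator,
) -> set[str]:
    spec = config.pruner
    if not mutant_tables:
        return set()
    if spec.kind == "consensus_threshold":
        return consensus_prune(parent.scores, mutant_tables, spec)
    ref = spec.reference_scorer or parent.scores.scorer_names[0]
    if spec.kind == "metropolis":
        return {
            bid
            for bid in sorted(mutant_tables)
            if metropolis_prune(parent.scores.averages[ref],
                                mutant_tables[bid].averages[ref], spec, rng)
        }
    # top_n: keep the best keep_n, then drop any strictly worse than the
    # parent so the restart rule stays reachable and greedy descent monotone.
    kept = top_prune(mutant_tables, spec)
    return {
        bid for bid in kept
        if mutant_tables[bid].averages[ref] <= parent.scores.averages[ref]
    }


def run_epoch(dag: LineageDAG, config: "RunConfig") -> LineageDAG:
    """Advance the DAG by one epoch in place (and return it).

    Raises :class:`AllLineagesFailedError` when no active lineage can branch.
    """
    epoch = len(dag.epochs)
    schedule = config.schedule
    parent_ids = dag.active_ids(epoch - 1)
    if not parent_ids:
        raise AllLineagesFailedError(f"epoch {epoch}: no active lineages to branch")
    scorers = build_scorers(config.scorers)
    restrained = schedule.restrained_at(epoch)
    sampler_params = config.sampler.as_restrained(restrained)

    # --- propose mutants (chooser + mutator) -----------------------------
    proposals: list[tuple[str, frozenset[Mutation], ComplexModel]] = []
    for p_idx, pid in enumerate(sorted(parent_ids)):
        parent = dag.nodes[pid]
        rng = _substream(config.seed, epoch, p_idx, _STAGE_CHOOSER)
        contrib = (
            _guided_contributions(parent.complex, scorers)
            if config.chooser.site_mode == "guided" else None
        )
        try:
            mutation_sets = generate_mutations(
                parent.complex, config.chooser, schedule.branches_per_node,
                per_residue_contrib=contrib, rng=rng,
            )
        except ChooserExhaustionError as exc:
            parent.status = "failed"
            parent.diagnostics["failure"] = str(exc)
            log.warning("epoch %d: lineage %s failed to branch: %s", epoch, pid, exc)
            continue
        for mset in mutation_sets:
            proposals.append((pid, mset, apply_mutation(parent.complex, mset)))

    if not proposals:
        raise AllLineagesFailedError(
            f"epoch {epoch}: every active lineage failed to produce mutants"
        )

    # --- sample + score over the worker pool -----------------------------
    tasks = []
    for b_idx, (pid, mset, mutated) in enumerate(proposals):
        sub = _substream_seed(config.seed, epoch, b_idx, _STAGE_SAMPLE)
        tasks.append(TaskSpec(
            task_id=(epoch, b_idx),
            fn=_sample_and_score,
            payload={
                "complex": mutated,
                "sampler_params": sampler_params,
                "scorers": scorers,
                "seed_record": sub,
            },
            substream_seed=sub,
        ))
    results = run_tasks(tasks, config.workers)

    # --- materialize nodes ----------------------------------------------
    epoch_ids: list[str] = []
    by_parent: dict[str, dict[str, NodeState]] = {}
    for b_idx, (pid, mset, mutated) in enumerate(proposals):
        nid = f"{epoch:02d}-{b_idx:03d}"
        res = results[(epoch, b_idx)]
        node = NodeState(
            node_id=nid, parent_id=pid, complex=mutated,
            mutations_from_parent=mset, epoch=epoch,
        )
        if res.ok:
            node.ensemble, node.scores, node.diagnostics = res.value
        else:
            node.status = "failed"
            node.diagnostics["failure"] = res.error
            log.warning("epoch %d: branch %s failed: %s", epoch, nid, res.error)
        dag.add_node(node)
        epoch_ids.append(nid)
        if res.ok:
            by_parent.setdefault(pid, {})[nid] = node

    # --- prune against parents -------------------------------------------
    retained: set[str] = set()
    empty_parents: list[str] = []
    for p_idx, pid in enumerate(sorted(parent_ids)):
        if dag.nodes[pid].status != "active" or pid not in by_parent:
            if dag.nodes[pid].status == "active":
                empty_parents.append(pid)
            continue
        children = by_parent[pid]
        rng = _substream(config.seed, epoch, p_idx, _STAGE_PRUNE)
        tables = {nid: n.scores for nid, n in children.items()}
        kept = _prune_node(dag.nodes[pid], tables, config, rng)
        retained |= kept
        if not kept:
            empty_parents.append(pid)

    # --- restart rule: reuse parents whose lineages retained nothing ------
    carried: list[str] = []
    if schedule.width_mode == "variable":
        reuse = sorted(parent_ids) if not retained else []
    else:
        reuse = empty_parents
    next_idx = len(proposals)
    for pid in reuse:
        parent = dag.nodes[pid]
        if parent.status != "active":
            continue
        nid = f"{epoch:02d}-{next_idx:03d}"
        next_idx += 1
        dag.add_node(NodeState(
            node_id=nid, parent_id=pid, complex=parent.complex,
            mutations_from_parent=frozenset(), epoch=epoch,
            scores=parent.scores,          # cached, never re-computed
            ensemble=parent.ensemble,
            diagnostics={**parent.diagnostics, "reused_parent": True},
        ))
        epoch_ids.append(nid)
        carried.append(nid)

    survivors = sorted(retained) + carried
    if not survivors:
        # constant mode with every parent failed outright
        dag.epochs.append(epoch_ids)
        raise AllLineagesFailedError(f"epoch {epoch}: no survivors and no reusable parents")

    survivor_tables = {nid: dag.nodes[nid].scores for nid in survivors}
    parent_tables = {
        nid: (dag.nodes[dag.nodes[nid].parent_id].scores
              if dag.nodes[nid].mutations_from_parent else None)
        for nid in survivors
    }
    active = enforce_width(survivor_tables, schedule.width_mode,
                           schedule.max_width, parent_tables)

    for nid in epoch_ids:
        node = dag.nodes[nid]
        if node.status == "failed":
            continue
        node.status = "active" if nid in active else "pruned"
    dag.epochs.append(epoch_ids)
    log.info(
        "epoch %d: %d proposals, %d retained, %d reused, %d active (restrained=%s)",
        epoch, len(proposals), len(retained), len(carried), len(active), restrained,
    )
    return dag


def _score_root(complex: ComplexModel, config: "RunConfig") -> NodeState:
    scorers = build_scorers(config.scorers)
    params = config.sampler.as_restrained(config.schedule.restrained_at(0))
    sub = _substream_seed(config.seed, 0, 0, _STAGE_ROOT)
    ensemble, table, diagnostics = _sample_and_score(
        complex, params, scorers, sub, np.random.default_rng(sub)
    )
    return NodeState(
        node_id="00-000", parent_id=None, complex=complex,
        mutations_from_parent=frozenset(), epoch=0,
        scores=table, ensemble=ensemble, diagnostics=diagnostics,
    )


def run_optimization(
    config: "RunConfig",
    complex: Optional[ComplexModel] = None,
    output_dir: Optional[Path | str] = None,
) -> LineageDAG:
    """Run the full schedule; optionally write the run directory.

    The starting complex is read from ``config.input_pdb`` unless supplied
    directly.  The run stops early (without raising) if every lineage fails.
    """
    from .config import expand_intervals

    if complex is None:
        from .pdbio import read_pdb

        complex = read_pdb(config.input_pdb, config.binder_chains, config.target_chains)
    if config.mutable_positions:  # the config declares the mutable surface
        complex = ComplexModel(
            residues=complex.residues,
            binder_chains=complex.binder_chains,
            target_chains=complex.target_chains,
            mutable_positions=expand_intervals(config.mutable_positions, complex),
        )

    dag = LineageDAG(meta={
        "seed": config.seed,
        "total_epochs": config.schedule.total_epochs,
        "restrained_epochs": config.schedule.restrained_epochs,
        "width_mode": config.schedule.width_mode,
        "stopped_early": False,
    })
    root = _score_root(complex, config)
    dag.add_node(root)
    dag.epochs.append([root.node_id])

    for _ in range(config.schedule.total_epochs):
        try:
            run_epoch(dag, config)
        except AllLineagesFailedError as exc:
            dag.meta["stopped_early"] = True
            dag.meta["stop_reason"] = str(exc)
            log.warning("optimization stopped early: %s", exc)
            break
    dag.meta["epochs_run"] = dag.last_epoch

    if output_dir is not None:
        write_run_directory(dag, config, Path(output_dir))
    return dag


# --- reporting ------------------------------------------------------------


def lineage_record(dag: LineageDAG) -> dict:
    """JSON-serializable lineage: nodes, edges, mutations, statuses, scores."""
    nodes = []
    for nid in sorted(dag.nodes):
        n = dag.nodes[nid]
        nodes.append({
            "node_id": n.node_id,
            "parent_id": n.parent_id,
            "epoch": n.epoch,
            "status": n.status,
            "mutations": sorted(str(m) for m in n.mutations_from_parent),
            "averages": dict(sorted(n.scores.averages.items())) if n.scores else None,
            "diagnostics": {k: n.diagnostics[k] for k in sorted(n.diagnostics)},
        })
    return {"meta": dict(sorted(dag.meta.items())), "nodes": nodes}


def trajectory_table(dag: LineageDAG, config: "RunConfig") -> pd.DataFrame:
    """Per-epoch, per-scorer mean and best average over active nodes.

    The ``phase`` column marks the restrained/unrestrained boundary.
    """
    rows = []
    for epoch in range(len(dag.epochs)):
        active = [dag.nodes[nid] for nid in dag.active_ids(epoch) if dag.nodes[nid].scores]
        if not active:
            continue
        phase = "restrained" if config.schedule.restrained_at(epoch) else "unrestrained"
        for s in config.scorers:
            vals = [n.scores.averages[s.name] for n in active]
            rows.append({
                "epoch": epoch, "phase": phase, "scorer": s.name,
                "mean_average": float(np.mean(vals)),
                "best_average": float(np.min(vals)),
                "n_active": len(active),
            })
    return pd.DataFrame(rows)


def scores_table(node: NodeState, epoch: int) -> pd.DataFrame:
    rows = []
    for s in node.scores.scorer_names:
        for frame, score in enumerate(node.scores.per_frame[s], start=1):
            rows.append({
                "epoch": epoch, "branch": node.node_id, "scorer": s,
                "frame": frame, "score": score, "average": node.scores.averages[s],
            })
    return pd.DataFrame(rows)


def write_run_directory(dag: LineageDAG, config: "RunConfig", outdir: Path) -> None:
    """Write the run directory: per-node structures and scores, lineage.json,
    trajectory_report.csv, and the effective configuration."""
    from .config import dump_config
    from .pdbio import write_ensemble, write_pdb

    outdir.mkdir(parents=True, exist_ok=True)
    dump_config(config, outdir / "config_effective.yaml")
    for epoch, ids in enumerate(dag.epochs):
        for nid in ids:
            node = dag.nodes[nid]
            ndir = outdir / f"epoch_{epoch:02d}" / nid
            ndir.mkdir(parents=True, exist_ok=True)
            if node.parent_id is not None:
                write_pdb(dag.nodes[node.parent_id].complex, ndir / "input.pdb")
            write_pdb(node.complex, ndir / "mutated.pdb")
            if node.ensemble is not None:
                write_ensemble(node.ensemble, ndir / "ensemble.pdb")
            if node.scores is not None:
                scores_table(node, epoch).to_csv(ndir / "scores.csv", index=False)
    with open(outdir / "lineage.json", "w") as fh:
        json.dump(lineage_record(dag), fh, indent=1, sort_keys=True)
        fh.write("\n")
    trajectory_table(dag, config).to_csv(outdir / "trajectory_report.csv", index=False)
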