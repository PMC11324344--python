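# binderopt

Evolutionary optimization of protein binder affinity, at desk scale.

Engineering a high-affinity binder (an antibody fragment, a nanobody, a
designed miniprotein) against a target epitope usually means screening large
mutational neighborhoods experimentally.  In-silico affinity maturation
replaces much of that screening with a compute loop: **mutate** the binder,
**sample** conformations of the mutated complex, **score** the interface
with one or more scoring functions, and **prune** mutation lineages that are
not improving.  `binderopt` implements that loop as five interchangeable
blocks — Mutation Chooser, Mutator, Sampler, Complex Scorer, Pruner —
iterated over *epochs*, with parallel mutation *branches* forming a lineage
DAG whose width can grow freely or be capped.

The package ships coarse-grained built-ins for every block (two pseudo-atoms
per residue; a rigid-body + jitter sampler in place of MD; contact-potential,
screened-electrostatic and contact-count scorers), so the entire protocol
runs in seconds on a laptop, plus adapter contracts for plugging in external
mutators, MD engines and scorer binaries where production fidelity is
needed.  See `docs/methods.md` for the model and its assumptions.

## The core loop

Starting from a binder/target complex with declared mutable positions, each
epoch does, for every active lineage:

1. propose `branches_per_node` distinct mutation sets (random or
   score-guided site choice; uniform / custom / grouped amino-acid schemes);
2. apply them to the structure;
3. sample an ensemble around each mutant (restrained in early epochs if a
   two-phase schedule is configured);
4. score every frame with every scorer and average per scorer
   (lower = better throughout);
5. prune against the parent: consensus over ≥ k scorers, Metropolis
   acceptance min(1, e^(−ΔS/T)), or deterministic top-N.

Survivors seed the next epoch; if nothing survives, the parent binders are
reused and re-branched.  Results are bit-reproducible from (config, seed)
for any worker count.

## Worked example

Build a toy complex and run an 8-epoch, two-phase optimization with three
scorers and consensus pruning:

```bash
python -c "
from binderopt.toys import ToySpec, make_toy_complex
from binderopt.pdbio import write_pdb
write_pdb(make_toy_complex(ToySpec(seed=8)), 'complex.pdb')"

cat > config.yaml <<'EOF'
input_pdb: complex.pdb
binder_chains: [A]
target_chains: [B]
mutable_positions: ["A:1-12"]
chooser: {site_mode: random, aa_scheme: uniform}
sampler: {n_frames: 6}
scorers:
  - {name: contact, kind: contact_potential}
  - {name: elec, kind: screened_electrostatic, screen_len: 10.0}
  - {name: ncontacts, kind: contact_count}
pruner: {kind: consensus_threshold, consensus_k: 2}
schedule: {total_epochs: 8, restrained_epochs: 3, branches_per_node: 4,
           width_mode: constant, max_width: 2}
seed: 17
workers: 2
EOF

binderopt run -c config.yaml -o run1
binderopt report run1
```

Output (abridged):

```
completed 8 epoch(s); 66 nodes, 2 active in the last epoch

 epoch        phase    scorer  mean_average  best_average  n_active
     0   restrained   contact     -4.854000     -4.854000         1
     1   restrained   contact     -5.373000     -5.630000         2
     3   restrained   contact     -6.744167     -7.217333         2
     5 unrestrained   contact     -8.753667     -9.593500         2
     ...

phase switch (restrained -> unrestrained) at epoch 4
```

Each row is one scorer's average over the epoch's active lineages (and the
best single lineage); scores are in the built-ins' arbitrary energy units,
lower is better.  Here the contact-potential average improved from −4.85 to
below −8.7 across 8 epochs, and the phase switch after the 3 restrained
epochs is flagged.  The run directory holds `lineage.json` (every node, its
mutations, status and averages), `trajectory_report.csv`, the effective
configuration, and per-branch PDBs/ensembles/score tables under
`epoch_XX/<node>/`.

The same machinery is available as a library:

```python
from binderopt import run_optimization, load_config
dag = run_optimization(load_config("config.yaml"))
best = dag.active_ids(dag.last_epoch)
```

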