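# Methods

## The optimization protocol

`binderopt` performs in-silico affinity maturation of a protein binder
against a fixed target.  The engine is a cycle of five interchangeable
blocks, iterated over *epochs*:

1. **Mutation Chooser** — select mutation site(s) on the binder and a
   replacement amino acid for each.
2. **Mutator** — apply the substitutions to the structure.
3. **Sampler** — generate a conformational ensemble around the mutated
   complex.
4. **Complex Scorer** — score binder–target affinity of every frame with one
   or more scoring functions and average per scorer.
5. **Pruner** — compare each mutant's averages against its parent's and
   decide which mutation lineages continue.

Each epoch every active lineage proposes `branches_per_node` mutants;
survivors become the next epoch's active lineages, so the accumulated record
is an epoch-layered directed acyclic graph (every edge goes from epoch *e*
to *e+1*).  When no mutant of any lineage survives, the parent binders are
reused unchanged and re-branched the following epoch, so a run always
completes its schedule unless every lineage is unable even to propose
mutants.

All scorers share one sign convention — **lower is better** after each
spec's `sign` multiplier — which is what lets heterogeneous scorers feed a
single consensus predicate.

## Coarse-grained structural model

Full-atom molecular dynamics and external scoring binaries are out of scope
here; the built-in blocks operate on a two-pseudo-atom-per-residue model:

* **anchor** — the alpha-carbon position;
* **side pseudo-atom** — the beta carbon where one exists; glycine's side
  pseudo-atom coincides with its anchor.

Two residues on opposite sides of the binder/target partition are *in
contact* when their side pseudo-atoms lie within a cutoff (default **8 Å**, a
standard coarse-grained contact convention; the choice is configurable
because no single value is canonical).  Mutations change residue identity
and leave coordinates untouched — side-chain repacking belongs to full-atom
mutators, which plug in through the adapter contract.  The two glycine edge
cases are geometric: mutating *to* glycine collapses the side pseudo-atom
onto the anchor; mutating *from* glycine rebuilds a pseudo-C<sub>β</sub> at
1.53 Å from the anchor along the direction from the centroid of the two
flanking anchors to the residue anchor (chain-terminal residues use a
deterministic perpendicular of the single neighbour direction; a one-residue
chain falls back to +x; exactly collinear flanking anchors — as in ideal
strand geometry — also fall back to +x).  These rules are deterministic and
rotation-covariant except in the degenerate collinear/terminal cases, where
any fixed convention is equally arbitrary.

## Sampler

The role MD plays in a production pipeline — relaxing the mutated complex
and producing conformations to average scores over — is filled by a
stochastic perturbation model:

* frame 1 is always the unperturbed input pose, so every ensemble contains
  the reference conformation and score averages are stabilized at small
  ensemble sizes;
* frames 2..n apply to the binder only a uniform-axis random rotation
  (angle ~ U[0, `rigid_rot_max`]) about the binder anchor centroid and a
  translation drawn uniformly from a ball of radius `rigid_trans_max`,
  then add isotropic Gaussian noise (`residue_noise_sd`) to every
  pseudo-atom of both partners.  Glycine receives one displacement for
  anchor and side jointly, preserving its side==anchor invariant.

*Restrained* sampling — the early-phase positional restraints that keep a
docked pose intact while the sequence is still poor — multiplies all three
amplitudes by `restraint_factor`.  A schedule of `restrained_epochs` followed
by unrestrained epochs expresses the common two-phase protocol (pose-
preserving refinement, then free optimization); the trajectory report labels
each epoch's phase so the switch is visible in the output.

Defaults: `n_frames` 10, `rigid_rot_max` 5°, `rigid_trans_max` 1 Å,
`residue_noise_sd` 0.3 Å, `restraint_factor` 0.2 — perturbations small
enough that the interface stays intact at the default cutoff while still
producing measurable score variance across frames.

## Built-in scorers

| kind | definition | default params |
|---|---|---|
| `contact_potential` | Σ over cross-interface contacts of a symmetric 20×20 residue-pair table | packaged matrix, cutoff 8 Å |
| `screened_electrostatic` | Σ q_i q_j e^(−d/λ)/d over contacts; q ∈ {D,E: −1; K,R: +1; H: +0.5} | λ = 10 Å, cutoff 8 Å |
| `contact_count` | −(number of cross-interface contacts) | cutoff 8 Å |
| `hidden_oracle` | contact_count + weight × (mismatches vs a planted sequence) | weight 1.0 |
| `external` | registered adapter scores a written PDB frame | — |

The packaged contact matrix is constructed as
`m(a,b) = −0.05 − max(h_a,0)·max(h_b,0)/20 + 0.5·q_a·q_b`
(h = Kyte–Doolittle hydrophobicity, q = side-chain charge): hydrophobic
pairs are favorable, like charges unfavorable, salt bridges favorable.  It
is a plausible, documented stand-in — not a fitted potential — and can be
overridden per scorer with a whitespace-delimited matrix file.

**Per-residue decomposition.**  Every pairwise scorer decomposes by
splitting each contact's term half-and-half between its two residues (the
hidden oracle additionally attributes each mismatch penalty wholly to the
mismatched residue); contributions sum exactly to the total score.  This is
what *guided* site selection consumes: the mutable position with the largest
(worst) contribution is targeted, mirroring the practice of mutating the
residues that contribute least to binding.  Half-splitting is one defensible
convention among several; nothing downstream depends on more than
conservation and locality.

## Pruners

* `consensus_threshold` — a mutant survives when ≥ `consensus_k` scorers
  improve on the parent by more than `tolerance` (strict inequality,
  additive margin, default 0).
* `metropolis` — single-scorer Monte Carlo acceptance with probability
  min(1, e^(−ΔS/T)); improvements always survive, slightly worse mutants
  survive occasionally, allowing escape from local minima.
* `top_n` — deterministic: the `keep_n` lowest reference-scorer averages,
  ties broken by branch id.  In the epoch loop, `top_n` survivors whose
  reference average is strictly worse than the parent's are additionally
  dropped: pure top-N can never return an empty set, which would make the
  parent-reuse rule unreachable and would let the best retained score rise
  under a greedy schedule.  With the parent comparison, greedy descent
  (top-1, single scorer, zero-noise sampler) is provably monotone.

The parent-reuse (restart) rule is applied globally in variable-width mode
(parents return only when *no* mutant anywhere survived) and per lineage in
constant-width mode (each barren lineage keeps its own parent), which
prevents width collapse under a cap.  Reused parents keep their cached
scores; re-scoring under a stochastic sampler would make pruning decisions
irreproducible.

## DAG width control

`variable` keeps every survivor active.  `constant` ranks survivors by
(1) number of scorers improved over their parent, descending; (2) mean
across-scorer rank of their averages among the survivors, ascending;
(3) node id — and keeps `max_width`.  The composite key rewards consensus
improvement first, overall score second, and is fully deterministic.

## Dispatch and reproducibility

Sampling-and-scoring tasks are drained over a bounded worker pool in
submission (first come, first served) order.  Determinism is a hard
contract: every stochastic stage draws from a `numpy` substream seeded by
`SeedSequence([master_seed, epoch, lineage_index, stage])`, never from
worker identity or timing, so `lineage.json` and all score CSVs are
bit-identical for any `--workers` value.  Task failures are recorded
per-branch (the node is marked `failed`) and never abort the batch; a run
errors out only when every lineage has failed.

## Synthetic fixtures

The toy generator builds two chains facing across `interface_gap` (default
5 Å) in strand, helix or random-blob geometry, 3.8 Å anchor spacing, seeded
random sequences, side pseudo-atoms pointing across the interface.  It
emulates exactly what the engine needs — a populated, partitioned interface
with mutable binder positions — and none of what real complexes have:
realistic packing, sequence statistics, correlated motions, or scorer
landscapes with physical meaning.  Tests passing on these fixtures therefore
validate the *protocol machinery* (branching, scoring plumbing, pruning
logic, reproducibility), not predictive power on real binders.

The planted-optimum recovery experiment corrupts 3 positions of a 12+12
strand complex away from a planted sequence and checks that the engine
repairs them: hidden oracle as sole scorer, guided site selection, top-1
pruning, 10 branches per epoch, zero-noise sampler, 15 epochs.  Two settings
in that experiment are analysis-driven:

* **oracle weight 2.0** — guided selection targets the largest per-residue
  contribution; on this geometry the half-split contact contributions span
  [−2.5, −1.5], so a mismatch penalty must exceed their 1.0 spread for a
  mismatched residue to outrank every matched one.  At the default weight
  1.0 a mismatched interior residue exactly ties a matched edge residue and
  deterministic tie-breaking can stall the search; at 2.0 the separation is
  strict.
* **planted sequences avoid glycine** — glycine moves the side pseudo-atom,
  which would couple the sequence search to the contact term; excluding it
  keeps the planted signal purely sequence-based.

Under these conditions the probability that one epoch's 10 distinct
amino-acid proposals at the targeted site include the planted residue is
10/19, so ~6 epochs repair 3 sites on average and 15 epochs suffice in
nearly every seeded run (measured: ≥ 0.95 recovery over 20 seeds).

## Numerical choices and degenerate inputs

* Contacts use ≤ cutoff; interface membership is monotone in the cutoff.
* Score-table averages are arithmetic means, checked to 1e-9; decomposition
  conservation is checked to 1e-9.
* Coincident pseudo-atoms (d = 0) skip the electrostatic pair with a
  warning rather than propagating an infinity.
* Ties: guided site selection and constant-width ranking break ties
  lexicographically by (chain, position) / node id; `top_n` by branch id.
* Single-site mutation proposals are drawn without replacement from the
  exact candidate distribution, so an exhaustive request (all 19
  substitutions) always succeeds; multi-site proposals use bounded rejection
  sampling (100 consecutive duplicates abort with the achievable count).
* PDB coordinates round-trip to the format's 1e-3 Å precision; model
  equality inside one process is bit-exact.
* Zero-amplitude sampling skips the recenter–rotate–shift entirely so the
  frames are bit-identical to the input, not merely close.

## Problem sizes

Tests and the acceptance script run on 12+12- to 30+30-residue toys,
ensembles of 1–10 frames, 3–18 epochs, 2–10 branches per node, and 20-seed
replicates — sizes chosen so the full protocol, including the 18-epoch
two-phase run and the 20-run recovery experiment, executes in seconds while
every code path (width capping, restarts, failures, both phases) is still
exercised.

## Known limitations

* The structural model has no rotamers, hydrogens, solvent, or backbone
  relaxation; scorer values are not physical energies and should not be
  interpreted beyond their ordering role.
* The sampler's ensemble is a noise model, not thermodynamic sampling; it
  reproduces ensemble-averaging semantics, not Boltzmann statistics.
* Guided selection uses a single scorer's decomposition (the first
  decomposable one configured); no consensus decomposition is attempted.
* Multi-site mutants are proposed independently per site; epistasis-aware
  design is out of scope.
* The external adapter contracts validate topology and identity, not
  chemistry: a physically absurd external result that preserves both will
  pass validation.
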