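# Methods

## The editing MDP

Molecule optimization is cast as a finite-horizon Markov decision process.
A state is a pair *(m, t)* of a valid molecule (canonical SMILES, `""` for
the empty molecule) and a step counter; episodes end when *t* reaches the
horizon *T*. Actions are the single-step graph edits of *m*:

* **atom additions** — each element of the configured element set attached
  to each atom with free valence, with every valence-allowed bond order;
  hydrogens are implicit, so additions replace implicit hydrogens. From the
  empty molecule the additions are the single-atom seed molecules.
* **bond additions** — creating a bond (single/double/triple) between two
  atoms with free valence, or raising an existing non-aromatic bond's order
  by one or two.
* **bond removals** — lowering or deleting an existing non-aromatic bond.
  A deletion is kept only when the product has at most one disconnected
  atom; that atom is then removed, so products are always single fragments.
* **no modification** — an explicit no-op, which lets a policy stop
  improving before the horizon and guarantees a non-empty action set.

Two strain heuristics restrict bond addition: atom pairs that are *both*
already in rings may not gain a bond (the `ring_pair_rule` config option
also offers the stricter either-endpoint variant and an off switch), and a
newly closed ring must have a whitelisted size (default {5, 6}; {5, 6, 7}
for the single-property tasks). Larger rings can still appear indirectly —
close a bicyclic system and remove the bridging bond. Aromatic bonds are
never edited directly, but aromaticity can arise (alternating single/double
additions re-perceived on sanitization) or be lost (edits elsewhere in the
ring system).

Every candidate edit is applied on a Kekulé copy and accepted only if the
product passes full RDKit sanitization, which is what makes every reachable
molecule chemically valid by construction. An action is *identified by its
product*: candidate successors are deduplicated by canonical SMILES, so
symmetry-equivalent edits collapse (cyclohexane + {C, O} gives 4 atom
additions, not 6 positions × 2 elements × orders). Transitions are
deterministic. Stereochemistry is dropped on input (with a warning): the
edit operators are stereo-agnostic. Charged species, isotopes and radicals
are outside the action space; only neutral standard-valence edits are
generated, and free valence is the default element valence minus the
explicit bond-order sum.

## Rewards

* **Penalized logP** = logP − SA − max(0, largest ring − 6). By default
  each term is z-standardized with the ZINC250k moments fixed by the
  JT-VAE/GCPN benchmark — that is the scale on which published scores for
  this task live (a long alkyl chain scores ≈ 11, not ≈ 14).
  `standardize=False` gives the raw difference, and `cycle_penalty` also
  offers the literal count-of-long-cycles reading.
* **QED** — RDKit's desirability score in [0, 1].
* **Similarity** — Tanimoto coefficient on radius-2 Morgan fingerprints
  (2048 bits; the length is a convention, exposed in the module constants).
* **Scalarized multi-objective** — `w^T r` for a property vector, e.g.
  `w·SIM + (1−w)·QED` for scaffold-preserving QED optimization.
* **Similarity-constrained** — property minus `λ(δ − SIM)` when similarity
  to the reference drops below δ (λ = 100 by default); the boundary SIM = δ
  is unpenalized, and both branches agree there, so the reward is
  continuous in SIM.
* **Range targeting** — negative distance of a property to a target
  interval, zero inside it.

The empty molecule has no properties: all scorers return 0 for it by
convention. Rewards are granted at *every* step, scaled by the reversed
discount γ^(T−t) (γ = 0.9 by default): the terminal state is rewarded
undiscounted and early states are down-weighted, which pushes credit toward
the end point of the episode. This factor is folded into the stored step
reward, so the Q-learning target adds no further discount.

## Featurization and the value network

A state is encoded as its radius-3/2048-bit binary Morgan fingerprint with
the raw steps-remaining count appended (length 2049); the clock makes the
optimal time-dependent policy learnable. The Q-function is parameterized
over *successor states*: because the action set varies per molecule, the
network cannot index a fixed output layer, so Q(s, a) is the network
evaluated on the featurized product of *a*, and V(s) is a max over the
candidate set.

The network is a ReLU MLP with hidden sizes [1024, 512, 128, 32] and one
linear output per bootstrap head, implemented directly in NumPy (forward,
manual backprop, Adam, global-norm-10 gradient clipping). Training
minimizes the Huber loss (½x² below |x| = 1, |x| − ½ above) of the
double-Q residual: the online network selects the best successor action,
the periodically synced target network evaluates it; terminal transitions
regress on the reward alone.

Exploration combines ε-greedy (ε annealed piecewise-linearly from 1 to
0.01 over the episode budget) with randomized value functions: H heads
share all hidden layers, each head trains only on transitions whose
Bernoulli(0.5) bootstrap mask selects it, and a uniformly drawn head drives
each episode. With H = 1, mask probability 1 and per-step target sync the
learner reduces exactly to vanilla deep Q-learning (covered by a
regression test).

Learner defaults (all exposed in `AgentConfig`): learning rate 1e-4, H = 10
heads, replay capacity 5 000 transitions, batch 128, target sync every 20
training steps, one training step per environment step after a 50-step
warm-up. Network shape, learning rate and the ε schedule follow the
method's published settings; the replay/bootstrap machinery is standard
DQN practice chosen once.

## Baselines

`random` picks uniformly over the full valid action set (no-op included);
`greedy` picks the successor with the highest raw reward, breaking ties
toward the lexicographically lowest canonical SMILES so runs are
deterministic across platforms; `eps_greedy` mixes the two. One ranking
rule matters: the empty molecule is scored −∞ as a *candidate successor*
(its properties are undefined; the zero convention applies to reward
traces). Without it the no-op at the empty start (reward 0) would dominate
the negative-scoring one-atom seeds and a greedy rollout could never leave
the empty state.

Reports aggregate the last 100 terminal states of a run (configurable),
deduplicate by canonical SMILES, and rank by score; the top-k set is a pure
function of the terminal multiset, independent of episode order.

## Experiment procedures

* **Two-step QED** — train from the empty molecule, collect the five
  distinct highest-QED terminals, then continue training with episode
  starts drawn uniformly from them (fewer than five distinct molecules:
  use what exists, logged). The report merges both phases.
* **Constrained optimization** — one model trained with episode starts
  drawn uniformly from a user-supplied lead set (horizon 20), each episode
  rewarded by the constrained reward anchored at its own start; evaluation
  is one deterministic argmax episode per lead, reporting penalized-logP
  improvement and the SIM ≥ δ success flag. The benchmark lead sets
  (ZINC/ChEMBL selections) are external data supplied as SMILES files.
* **Diversity sampling** at evaluation: fixed-head argmax (deterministic),
  per-episode uniform head, Q-proportional action sampling (probabilities
  proportional to the min-shifted Q-values, since Q may be negative; a flat
  vector degenerates to uniform), or non-zero ε.

## Interpretation outputs

`action_value_map` exports every valid action's raw Q-value with a min-max
rescaling to [0, 1] (an all-equal map rescales to 1.0 by convention,
logged; the rescaling is monotone, so orderings survive). The default view
is a single evaluation head; an ensemble-mean option averages heads.
`trajectory_summary` tabulates the property after each step, per-step
deltas (flagging non-monotone steps, which a value-maximizing policy may
deliberately take) and the total improvement, which telescopes to the sum
of the deltas.

## Problem sizes and numerical choices

The test suite and the reproduction script run desk-scale versions of the
experiments: greedy rollouts at their full horizons (38/40 steps), random
and ε-greedy baselines at 100 episodes × 3 seeds, validity audits over
~1,200–11,400 visited states, and a 300-episode DQN run at horizon 20 with
a [128, 32]-hidden network, batch 16, a training step every 2 environment
steps and learning rate 5e-4 — sizes at which learning is demonstrable (the
run must strictly beat its matched random-walk baseline) while the whole
suite stays inexpensive. Full-scale settings (5 000 episodes, the
[1024, 512, 128, 32] network) remain the library defaults.

Determinism: a single run seed drives network init, ε draws, head and mask
sampling and start-molecule choice; greedy baselines are seed-independent
by construction. Enumeration results, fingerprints and property values are
memoized by canonical SMILES (rollouts revisit states constantly), with
bounded caches.

## Known limitations

* **Descriptor-version sensitivity.** Myopic trajectories are knife-edge
  functions of the property implementations. The greedy penalized-logP
  rollout is the worst case: under the current RDKit the SA score of the
  one-atom seeds ranks O below C, so the greedy path locks in an ether and
  ends near 9.7 instead of the ≈ 11.2 of a pure C38 chain (the level the
  original benchmark run reported). The enumeration itself is verified
  against a brute-force oracle; the divergence is entirely in the scorer's
  fragment statistics. Learned policies are far less brittle: they optimize
  returns, not single-step margins.
* Properties are desk-computable surrogates (logP, SA, QED); no docking,
  measured endpoints or trained predictors.
* The action space excludes charged/radical chemistry, stereochemistry and
  any 3-D considerations beyond the ring-size heuristics.
* The NumPy learner is single-threaded; full-scale (5 000-episode) training
  is hours of CPU, and no GPU path is provided.
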