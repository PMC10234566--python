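# Methods

## Model

The package treats task decomposition as a three-level optimization.

1. **Action-level planning.** A search algorithm solves a single-subgoal
   shortest-path task on an undirected simple graph. Four algorithms are
   implemented, each with an explicit run-time unit:
   - *random walk* (RW): steps of a uniform walk until the target is hit;
   - *depth-first search* (DFS): recursive calls; the search remembers only
     the states on the current candidate plan and backtracks at dead ends;
   - *breadth-first search* (BFS): dequeue-and-expand iterations up to and
     including the one that visits the target (each state is enqueued at
     most once, so run-time never exceeds the state count);
   - *iterative-deepening DFS* (IDDFS): total recursive calls of
     depth-limited DFS passes at limits 1, 2, …, where limit d admits
     plans with at most d edges.

   Neighbor order is freshly shuffled at every expansion so that no
   systematic preference leaks into the plans. The goal test happens when a
   state is *processed* (entered in DFS/IDDFS, dequeued in BFS).
   The algorithm-specific reward of a task is E[R(π) − t] with
   R(π) = −|π|. For RW this is analytic: plan length equals run-time plus
   one, so the expectation is −2·H(s, z) − 1 in raw units; the affine
   constants do not affect which subgoals are preferred, so the
   implementation uses −H(s, z) with H the hitting time, solved exactly as
   a linear system. The systematic searchers are estimated by Monte Carlo.

2. **Subgoal-level planning.** Given subgoals Z and goal g, the value
   V_Z^g(s) is the fixed point of the Bellman recursion over options
   Z ∪ {g} with V_Z^g(g) = 0. All rewards are negative, so the fixed point
   is a shortest-cost path on the complete directed graph over the option
   set; it is computed by label-correcting relaxation (at most |options|
   sweeps), not value iteration. Selecting the state one currently
   occupies is excluded from the max: the (s, s) reward is degenerate (a
   one-state plan) and the recursion never needs it.

3. **Task decomposition.** V(Z) averages V_Z^g(s₀) over the task
   distribution, by default uniform over ordered distinct (start, goal)
   pairs (optionally excluding adjacent pairs, the long-trial convention).
   Per-state model predictions score each state as the sole subgoal. For
   the RW variant the subgoal is *mandatory* — a detour through z can only
   lengthen a walk, so with an optional subgoal the model would be
   uniformly indifferent — giving the closed form −[H(s₀, z) + H(z, g)].
   For the systematic searchers the goal remains an option, so a subgoal
   is used only where it pays for itself.

## Graph census and eligibility filter

Connected simple graphs are enumerated one representative per isomorphism
class by inductive node addition: each graph on n nodes arises from a
graph on n − 1 nodes (connected or not) by attaching the new node to a
nonempty subset of old nodes; candidates are deduplicated by an exact
canonical form (igraph's BLISS canonical permutation). The census matches
the known counts 1, 1, 2, 6, 21, 112, 853, 11 117 for n = 1…8, and a
brute-force labelled enumerator cross-checks n ≤ 6 in the tests.

The experiment-eligibility filter keeps graphs with at least 10 tasks
whose optimal solution needs at least 3 actions. "Tasks" are **ordered**
(start, goal) pairs: with that convention the filter keeps exactly 1,676
of the 11,117 eight-node graphs, matching the stimulus-set construction
this filter reproduces; counting unordered pairs would keep 189, so the
ordered convention is the one the package uses throughout.

## Parameters and defaults

- `expected_reward` Monte-Carlo samples: default 1,000 per (task,
  algorithm). The source experiments do not state their sample counts;
  1,000 keeps the standard error of an 8-node IDDFS reward well under one
  run-time unit.
- The model-comparison pipeline (`default_scorers`) defaults to 100
  samples per ordered state pair. Per-graph Pearson correlations over
  eight states are insensitive to this residual noise (attenuation only),
  and it keeps a 500-graph comparison around half a minute on one core.
- Monte-Carlo streams are spawned per ordered pair from the root seed, so
  cached rewards do not depend on evaluation order and every run is
  reproducible bit-for-bit given (graph, task, seed).
- RW simulation carries a step cap (default 10⁶) that *raises* rather than
  truncates, so pathological walks can never silently bias an estimate.
- Choice-model scores are standardized to mean 0 and *population* (divide
  by n) standard deviation 1 before fitting; the convention only rescales
  the fitted temperature. Softmax temperature is fit by bounded 1-D
  search (|β| ≤ 50, tolerance 1e−8); the two-stage path-choice model is
  fit by L-BFGS-B from (β₁, β₂) = (1, 1) under nonnegativity.

## Heuristic scorers

Degree and betweenness scores are the logarithms of the networkx
centrality fractions, betweenness computed with `endpoints=True`:
endpoint inclusion makes every state's fraction strictly positive (finite
logs) and matches the interpretation "probability that a uniformly chosen
optimal path of a uniformly chosen task contains the state", which the
tests verify against an exhaustive optimal-path enumerator on the full
6-node census. The spectral (normalized-cut) score embeds states by the
eigenvector of the second-smallest eigenvalue of the symmetric normalized
Laplacian and scores −v_s²; it is sign-invariant, and a numerically
repeated second eigenvalue is flagged (`meta["degenerate"]`) with the
deterministic eigensolver's choice of vector retained. The occupancy
baseline scores log(1 + visit count) so unvisited states stay finite.

## Cross-model comparison

Per-graph Pearson correlations between per-state score vectors (Spearman
behind a flag — the correlation type is a free choice here), averaged over
graphs. A model predicting a uniform distribution (constant scores within
1e−12) has no defined correlation on that graph; such pairs are discarded
and the per-cell count of contributing graphs is reported so discards are
auditable. BFS-based decomposition is the main source of discards on small
graphs: its search cost is linear in the state count, so on many 8-node
graphs no subgoal pays for itself.

## Grid demonstration geometry

The grid task used to illustrate algorithm-dependence is a 7×7 lattice
with start and goal at the midpoints of opposite edges and the subgoal at
the lattice centre (optimal length 6, split 3 + 3). Geometry matters for
the BFS direction of this demonstration: with corner-to-corner endpoints
on a small square grid the distance balls are clipped by the boundary and
the split search expands *more* states than the direct one. Interior-ish
endpoint placement avoids that boundary artifact, and with it the
demonstration shows the expected ordering (midpoint subgoal reduces BFS
and IDDFS cost, increases RW cost).

## Synthetic experiment generator

The fixture generator reproduces the trial-construction logic of the
behavioral paradigm the choice models target: 30 *long* navigation trials
(uniform over non-adjacent ordered pairs) strictly alternating with 30
adaptively selected one-action *filler* trials; 10 probe tasks (optimal
length ≥ 3) reused, shuffled, across implicit and explicit probe phases;
and a task-independent teleport probe. Filler selection excludes tasks
touching a most-visited state (argmax set of the visit tally — set
semantics are what make the documented fallback meaningful), then samples
uniformly among tasks with the greatest summed start/goal visits, skipping
the exclusion when it would empty the pool. Both directions of every edge
are filler candidates. Simulated agents follow a uniformly sampled
shortest path, optionally deviating to a random neighbour with probability
ε per step and re-planning. Visit counts include each trial's start state
and every state entered, matching the occupancy scorer's counting.

What the generator does *not* emulate: learning of the graph across
trials, memory limits, response times, lapses, or any within-participant
heterogeneity. Passing recovery tests on these fixtures shows the
estimators are consistent under the generating model, not that real
participants satisfy it.

## Numerical and degenerate-input choices

- Disconnected graphs raise informative errors wherever an operation
  requires connectivity (shortest paths name an unreachable pair; hitting
  times would be infinite).
- Tasks forbid start = goal by construction.
- The two-stage path-choice model requires at least two optimal paths per
  observation; single-path observations are uninformative and rejected at
  construction.
- Explicit-probe fixtures can attach a per-task goal-option value (the
  no-subgoal value for decomposition models); heuristic models fall back
  to the goal state's own score, a documented divergence since heuristics
  define no "no subgoal" quantity.

## Problem sizes used in the shipped checks

The full eight-node census (11,117 graphs) and eligibility filter run in
seconds and are recomputed exactly. The cross-model cluster check uses 500
graphs sampled from the census with 100 Monte-Carlo samples per pair; the
grid demonstration uses 1,000 samples per condition; softmax recovery uses
2,000 synthetic choices and two-stage recovery 5,000 observations. These
sizes are the package's reference configuration; all are arguments.

## Known limitations

- Decompositions are single-level and subgoals are single states; no
  option-style or multi-level hierarchies.
- Heuristic search (A*-family) and memory costs are out of scope; only
  run-time enters the resource term.
- The partition-based alternatives from the literature (description-length
  and nonparametric-inference accounts) are not implemented; comparisons
  cover the decomposition variants and the centrality/spectral heuristics.
- Hierarchical (random-effects) choice regression is not implemented; all
  fits are fixed-effects maximum likelihood.
- Enumeration is practical to n ≈ 9; beyond that a canonical-augmentation
  generator would be needed.
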