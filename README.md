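# rrtd — resource-rational task decomposition

Tools for studying **how planning costs shape the choice of subgoals** in
graph-structured navigation tasks.

People break large tasks into subtasks. A normative account of *which*
subgoals they should pick is that a good decomposition maximizes task
reward net of the computational cost of planning. This package implements
that account for shortest-path tasks on undirected graphs and compares it
against classic graph-theoretic heuristics, at the scale of the complete
census of small graphs.

## The model

A task is a pair of states (s₀, g) on a graph (S, T). An *action-level
planner* Alg (random walk, DFS, BFS, or iterative-deepening DFS) solves a
single-subgoal task stochastically, inducing a distribution over plans π
and run-times t. Its expected reward is

    R_Alg(s, z) = E[ R(π) − t ],      R(π) = −|π|,

where run-time is counted in the algorithm's own units (walk steps,
recursive calls, dequeue iterations). *Subgoal-level planning* chains these
subtasks through a set of subgoals Z by the Bellman recursion

    V_Z^g(s) = max over z in Z ∪ {g} of [ R_Alg(s, z) + V_Z^g(z) ],   V_Z^g(g) = 0,

and a decomposition is valued by averaging over the environment's task
distribution: V(Z) = Σ p(s₀, g) · V_Z^g(s₀). Scoring every state as the
sole subgoal gives a per-state prediction that can be compared to
heuristics — log degree centrality, log endpoint-inclusive betweenness
centrality, and a spectral normalized-cut score — and to behavioral probe
choices through softmax (multinomial) choice models.

For the random walk the expectation is analytic: R_RW(s, z) = −H(s, z),
the walk's hitting time, and a subgoal can only lengthen the walk, so the
single-subgoal value is the negated detour −[H(s₀, z) + H(z, g)].

## A worked example

`examples/grid_subgoal_demo.py` builds a 7×7 grid task spanning opposite
edge midpoints and compares expected search cost with and without the path
midpoint as a subgoal:

```
random walk   direct   133.3   via midpoint   173.7  (expected steps)
BFS           direct    36.8   via midpoint    35.7  (expected iterations)
IDDFS         direct   553.5   via midpoint    81.7  (expected iterations)
```

Splitting the task at its midpoint reduces the cost of the systematic
searchers — mildly for BFS, roughly sevenfold for iterative deepening,
whose cost grows steeply with search depth — but a random walk usually
reaches the goal without passing through the midpoint, so forcing the
subgoal only adds steps. Which decomposition is best depends on the
algorithm doing the planning.

The other examples score a bottleneck graph under every model
(`score_bottleneck_graph.py`), enumerate the census of small connected
graphs and reproduce the model cluster structure
(`census_and_model_clusters.py` — decomposition-via-iterative-deepening
correlates with betweenness centrality, decomposition-via-random-walk with
degree centrality), and run a synthetic probe session through the choice
models (`synthetic_session_and_fit.py`).

A thin CLI mirrors the batch steps: `rrtd enumerate`, `rrtd filter`,
`rrtd plan`, `rrtd score`, `rrtd compare`, `rrtd simulate`.

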