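"""Action-level planners with explicit run-time accounting.

Four search algorithms solve single-subgoal tasks on an unweighted graph:

* random walk (RW) — repeatedly moves to a uniformly sampled neighbour;
  run-time is the number of walk steps.
* depth-first search (DFS) — recursive search that tracks only the states
  on the current candidate plan; run-time is the number of recursive calls.
* breadth-first search (BFS) — explores in order of increasing distance;
  run-time is the number of dequeue-and-expand iterations up to and
  including the one that visits the goal (never more than the state count).
* iterative-deepening DFS (IDDFS) — depth-limited DFS at limits 1, 2, ...;
  run-time is the total number of recursive calls across all passes.

Neighbour order is freshly shuffled at every expansion to avoid order bias.
The algorithm-specific reward of a task is the expected value of
``R(plan) - runtime`` where the plan reward is the negated number of plan
states, R(pi) = -|pi|.  For RW this expectation has a closed form in terms
of random-walk hitting times; for the systematic searchers it is estimated
by Monte Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .graph import Task, TaskGraph

__all__ = [
    "Plan",
    "PlanOutcome",
    "RewardEstimate",
    "plan_reward",
    "hitting_time",
    "hitting_time_matrix",
    "simulate_rw",
    "simulate_dfs",
    "simulate_bfs",
    "simulate_iddfs",
    "SIMULATORS",
    "ALGORITHMS",
    "expected_reward",
    "RewardTable",
]

Plan = tuple  # sequence of state indices from start to target


@dataclass(frozen=True)
class PlanOutcome:
    """A plan plus the run-time the producing algorithm consumed."""

    plan: Plan
    runtime: int

    def to_json(self) -> dict:
        return {"plan": list(self.plan), "runtime": self.runtime}


@dataclass(frozen=True)
class RewardEstimate:
    mean: float
    standard_error: float
    n_samples: int
    method: str  # "analytic" or "monte_carlo"


def plan_reward(plan: Plan) -> float:
    """Task reward of executing a plan: the negated number of plan states."""
    return -float(len(plan))


# ---------------------------------------------------------------------------
# Random-walk hitting times


def hitting_time(graph: TaskGraph, target: int) -> np.ndarray:
    """Expected steps of a uniform random walk until first reaching ``target``.

    Solves the linear system  H(s) = 1 + mean over neighbours s' of H(s')
    for s != target, with H(target) = 0, exactly.
    """
    graph.require_connected()
    n = graph.n_states
    others = [s for s in range(n) if s != target]
    pos = {s: k for k, s in enumerate(others)}
    A = np.eye(n - 1)
    b = np.ones(n - 1)
    for s in others:
        w = 1.0 / graph.degree(s)
        for v in graph.adjacency[s]:
            if v != target:
                A[pos[s], pos[v]] -= w
    h = np.linalg.solve(A, b)
    out = np.zeros(n)
    out[others] = h
    return out


def hitting_time_matrix(graph: TaskGraph) -> np.ndarray:
    """H[s, z] = expected walk steps from s to first visit of z."""
    n = graph.n_states
    H = np.zeros((n, n))
    for z in range(n):
        H[:, z] = hitting_time(graph, z)
    return H


# ---------------------------------------------------------------------------
# Simulators


def simulate_rw(
    graph: TaskGraph,
    task: Task,
    rng: np.random.Generator,
    step_cap: int = 1_000_000,
) -> PlanOutcome:
    """Uniform random walk from start until the goal is first reached."""
    s = task.start
    path = [s]
    adj = graph.adjacency
    steps = 0
    while s != task.goal:
        if steps >= step_cap:
            raise RuntimeError(f"random walk exceeded step cap of {step_cap}")
        nbrs = adj[s]
        s = nbrs[rng.integers(len(nbrs))]
        path.append(s)
        steps += 1
    return PlanOutcome(tuple(path), steps)


def simulate_dfs(graph: TaskGraph, task: Task, rng: np.random.Generator) -> PlanOutcome:
    """Depth-first search remembering only the current candidate plan."""
    adj = graph.adjacency
    goal = task.goal
    calls = 0
    on_path = {task.start}

    def visit(s: int, path: list[int]):
        nonlocal calls
        calls += 1
        if s == goal:
            return path
        nbrs = list(adj[s])
        rng.shuffle(nbrs)
        for v in nbrs:
            if v in on_path:
                continue
            on_path.add(v)
            found = visit(v, path + [v])
            if found is not None:
                return found
            on_path.discard(v)
        return None

    plan = visit(task.start, [task.start])
    assert plan is not None, "connected graph must contain a simple path"
    return PlanOutcome(tuple(plan), calls)


def simulate_bfs(graph: TaskGraph, task: Task, rng: np.random.Generator) -> PlanOutcome:
    """Breadth-first search; goal test on dequeue, states enqueued once."""
    from collections import deque

    adj = graph.adjacency
    parent = {task.start: None}
    queue = deque([task.start])
    iterations = 0
    while queue:
        s = queue.popleft()
        iterations += 1
        if s == task.goal:
            path = []
            while s is not None:
                path.append(s)
                s = parent[s]
            return PlanOutcome(tuple(reversed(path)), iterations)
        nbrs = list(adj[s])
        rng.shuffle(nbrs)
        for v in nbrs:
            if v not in parent:
                parent[v] = s
                queue.append(v)
    raise ValueError("goal unreachable: graph is disconnected")


def simulate_iddfs(
    graph: TaskGraph, task: Task, rng: np.random.Generator
) -> PlanOutcome:
    """Depth-limited DFS at limits 1, 2, ... until the goal is found.

    A limit ``d`` admits plans with at most ``d`` edges.  Run-time is the
    total number of recursive calls summed over all passes.
    """
    adj = graph.adjacency
    goal = task.goal
    total_calls = 0

    def visit(s: int, path: list[int], on_path: set, limit: int):
        nonlocal total_calls
        total_calls += 1
        if s == goal:
            return path
        if len(path) - 1 >= limit:
            return None
        nbrs = list(adj[s])
        rng.shuffle(nbrs)
        for v in nbrs:
            if v in on_path:
                continue
            on_path.add(v)
            found = visit(v, path + [v], on_path, limit)
            if found is not None:
                return found
            on_path.discard(v)
        return None

    limit = 1
    while True:
        plan = visit(task.start, [task.start], {task.start}, limit)
        if plan is not None:
            return PlanOutcome(tuple(plan), total_calls)
        limit += 1
        if limit > graph.n_states:
            raise ValueError("goal unreachable: graph is disconnected")


SIMULATORS: dict[str, Callable] = {
    "rw": simulate_rw,
    "dfs": simulate_dfs,
    "bfs": simulate_bfs,
    "iddfs": simulate_iddfs,
}

ALGORITHMS = tuple(SIMULATORS)


# ---------------------------------------------------------------------------
# Algorithm-specific expected reward


def expected_reward(
    graph: TaskGraph,
    task: Task,
    algorithm: str,
    n_samples: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> RewardEstimate:
    """Expected ``R(plan) - runtime`` for one algorithm on one task.

    For RW the expectation is analytic: plan states equal walk steps plus
    one, so up to an additive constant and a factor of two (dropped, as it
    does not affect which subgoals are preferred) the expected reward is the
    negated hitting time -H(start, goal).  The systematic searchers are
    estimated by Monte Carlo with a seeded generator.
    """
    alg = algorithm.lower()
    if alg not in SIMULATORS:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    if alg == "rw":
        H = hitting_time(graph, task.goal)
        return RewardEstimate(-float(H[task.start]), 0.0, 0, "analytic")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1 for Monte Carlo estimation")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sim = SIMULATORS[alg]
    vals = np.empty(n_samples)
    for i in range(n_samples):
        out = sim(graph, task, rng)
        vals[i] = plan_reward(out.plan) - out.runtime
    se = float(vals.std(ddof=1) / np.sqrt(n_samples)) if n_samples > 1 else 0.0
    return RewardEstimate(float(vals.mean()), se, n_samples, "monte_carlo")


class RewardTable:
    """Memoized R_alg(s, z) over ordered state pairs of one graph.

    Each pair draws its Monte-Carlo stream from a seed spawned off the root
    seed by pair index, so values do not depend on evaluation order.
    """

    def __init__(
        self,
        graph: TaskGraph,
        algorithm: str,
        n_samples: int = 1000,
        seed: int | None = None,
    ):
        self.graph = graph
        self.algorithm = algorithm.lower()
        if self.algorithm not in SIMULATORS:
            raise ValueError(f"unknown algorithm {algorithm!r}")
        self.n_samples = n_samples
        self._seed = seed
        self._cache: dict[tuple[int, int], float] = {}
        self._H = hitting_time_matrix(graph) if self.algorithm == "rw" else None

    def __call__(self, s: int, z: int) -> float:
        if s == z:
            raise ValueError("reward of a degenerate (s, s) task is undefined")
        if self.algorithm == "rw":
            return -float(self._H[s, z])
        key = (s, z)
        if key not in self._cache:
            n = self.graph.n_states
            pair_seed = np.random.SeedSequence([self._seed or 0, s * n + z])
            est = expected_reward(
                self.graph,
                Task(s, z),
                self.algorithm,
                n_samples=self.n_samples,
                seed=np.random.default_rng(pair_seed),
            )
            self._cache[key] = est.mean
        return self._cache[key]
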