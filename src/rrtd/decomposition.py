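"""Valuing task decompositions by task reward net of planning cost.

A decomposition is a set of candidate subgoals Z.  Subgoal-level planning
chains action-level plans: from a state ``s`` the planner picks the next
target among Z and the goal, paying the algorithm-specific expected reward
R_alg(s, z) (a negative number combining plan length and search run-time)
and continuing from ``z``:

    V_Z^g(s) = max over z in (Z or {g}), z != s  of  R_alg(s, z) + V_Z^g(z)

with V_Z^g(g) = 0.  The value of a decomposition is the expectation of
V_Z^g(start) over the environment's task distribution.  Since all rewards
are negative, the fixed point is a shortest-cost path over the complete
directed graph on {s} + Z + {g} and is computed by label-correcting
relaxation rather than value iteration.

The random-walk variant uses the closed form: a walk reaches the goal with
or without the subgoal, so a subgoal can only lengthen the walk; the model
therefore *requires* passing through one subgoal and values it by the
negated round-trip hitting time -[H(s, z) + H(z, g)].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .graph import Task, TaskDistribution, TaskGraph, uniform_task_distribution
from .planners import RewardTable, expected_reward, hitting_time_matrix

__all__ = [
    "SubgoalScores",
    "DecompositionValue",
    "subgoal_plan_value",
    "decomposition_value",
    "rrtd_rw_value",
    "no_subgoal_value",
    "score_single_subgoals",
    "RRTD_MODELS",
]

RRTD_MODELS = ("rrtd-rw", "rrtd-dfs", "rrtd-bfs", "rrtd-iddfs")


@dataclass
class SubgoalScores:
    """Per-state predictions (utilities or log-probabilities) of one model."""

    model: str
    graph: TaskGraph
    scores: dict[int, float]
    meta: dict = field(default_factory=dict)

    def as_array(self) -> np.ndarray:
        return np.array([self.scores[s] for s in sorted(self.scores)])

    def argmax(self) -> int:
        return max(self.scores, key=self.scores.get)


@dataclass(frozen=True)
class DecompositionValue:
    value: float
    per_task_values: dict


def subgoal_plan_value(
    graph: TaskGraph,
    subgoals,
    goal: int,
    reward_fn,
) -> dict[int, float]:
    """Fixed point of the subgoal-level Bellman recursion, for every state.

    ``reward_fn(s, z)`` must return a finite expected reward for every
    ordered pair of distinct states.  Choosing the state one currently
    occupies is excluded; the goal is always an admissible target.
    """
    options = sorted(set(subgoals) | {goal})
    for z in options:
        if not 0 <= z < graph.n_states:
            raise ValueError(f"subgoal {z} is not a state of the graph")
    # Shortest-cost values on the complete digraph over the option set,
    # Bellman-Ford style (node count is tiny; costs -reward_fn are >= 0).
    V = {z: (0.0 if z == goal else -math.inf) for z in options}
    for _ in range(len(options)):
        changed = False
        for s in options:
            if s == goal:
                continue
            best = -math.inf
            for z in options:
                if z == s:
                    continue
                r = reward_fn(s, z)
                if not math.isfinite(r):
                    raise ValueError(f"non-finite reward for pair ({s}, {z})")
                cand = r + V[z]
                if cand > best:
                    best = cand
            if best > V[s] + 1e-15:
                V[s] = best
                changed = True
        if not changed:
            break
    # One step from every non-option state into the option set.
    out = dict(V)
    for s in range(graph.n_states):
        if s in out:
            continue
        out[s] = max(reward_fn(s, z) + V[z] for z in options if z != s)
    return out


def decomposition_value(
    graph: TaskGraph,
    subgoals,
    task_dist: TaskDistribution,
    algorithm: str,
    n_samples: int = 1000,
    seed: int | None = None,
    reward_fn=None,
) -> DecompositionValue:
    """Expected subgoal-level value of Z over the task distribution."""
    if reward_fn is None:
        reward_fn = RewardTable(graph, algorithm, n_samples=n_samples, seed=seed)
    per_task = {}
    by_goal: dict[int, dict[int, float]] = {}
    for task, _w in task_dist:
        if task.goal not in by_goal:
            by_goal[task.goal] = subgoal_plan_value(graph, subgoals, task.goal, reward_fn)
        per_task[task] = by_goal[task.goal][task.start]
    total = sum(w * per_task[t] for t, w in task_dist)
    return DecompositionValue(total, per_task)


def rrtd_rw_value(
    graph: TaskGraph, subgoal: int, task: Task, H: np.ndarray | None = None
) -> float:
    """Closed-form value of a mandatory single subgoal under random-walk search."""
    if H is None:
        H = hitting_time_matrix(graph)
    return -float(H[task.start, subgoal] + H[subgoal, task.goal])


def no_subgoal_value(
    graph: TaskGraph,
    task: Task,
    algorithm: str,
    n_samples: int = 1000,
    seed: int | None = None,
) -> float:
    """Value of solving the task directly: reward plus negated planning cost."""
    return expected_reward(graph, task, algorithm, n_samples=n_samples, seed=seed).mean


def score_single_subgoals(
    graph: TaskGraph,
    algorithm: str,
    task_dist: TaskDistribution | None = None,
    n_samples: int = 1000,
    seed: int | None = None,
) -> SubgoalScores:
    """Score every state by the value of using it as the sole subgoal.

    For the systematic searchers the subgoal is optional (the goal is always
    available); for the random walk the subgoal is mandatory and valued by
    the negated detour hitting time.
    """
    graph.require_connected()
    alg = algorithm.lower().replace("rrtd-", "")
    if task_dist is None:
        task_dist = uniform_task_distribution(graph)
    scores: dict[int, float] = {}
    if alg == "rw":
        H = hitting_time_matrix(graph)
        for z in range(graph.n_states):
            scores[z] = sum(
                -w * float(H[t.start, z] + H[z, t.goal]) for t, w in task_dist
            )
    else:
        reward_fn = RewardTable(graph, alg, n_samples=n_samples, seed=seed)
        for z in range(graph.n_states):
            total = 0.0
            for t, w in task_dist:
                direct = reward_fn(t.start, t.goal)
                if z == t.start or z == t.goal:
                    v = direct
                else:
                    v = max(direct, reward_fn(t.start, z) + reward_fn(z, t.goal))
                total += w * v
            scores[z] = total
    return SubgoalScores(f"rrtd-{alg}", graph, scores)
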