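"""Synthetic experiment sessions: trial construction and simulated agents.

Reproduces the behavioral study's trial-construction logic so that the
choice models can be exercised end-to-end without any participant data:

* *long* navigation trials are drawn uniformly from tasks optimally solved
  with more than one action (start and goal not adjacent);
* *filler* trials are one-action tasks selected adaptively to rebalance
  state visit counts — tasks touching a currently most-visited state are
  excluded, then a task is drawn uniformly among those with the greatest
  summed visits to start and goal (the exclusion is skipped when it would
  empty the candidate set);
* long and filler trials strictly alternate;
* *probe* tasks are drawn uniformly without replacement from tasks needing
  at least three actions, and are reused (shuffled) across the implicit and
  explicit probe phases.

Agents navigate either optimally (a uniformly sampled shortest path) or
with epsilon-noise (deviating to a random neighbour with probability
epsilon per step, then re-planning).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .choice import ProbeChoice, probe_candidates
from .decomposition import SubgoalScores
from .graph import Task, TaskGraph, eligible_for_experiment, shortest_path_lengths

__all__ = [
    "Trial",
    "TrialSchedule",
    "VisitCounts",
    "select_filler_task",
    "sample_probe_tasks",
    "sample_long_task",
    "make_schedule",
    "simulate_agent",
    "generate_choice_fixture",
]

VisitCounts = dict  # state -> visit tally


@dataclass(frozen=True)
class Trial:
    kind: str  # long | filler | probe_implicit | probe_explicit | teleport
    task: Task | None  # None for adaptive fillers (chosen at run time) and teleport


@dataclass
class TrialSchedule:
    trials: list[Trial] = field(default_factory=list)

    def __iter__(self):
        return iter(self.trials)

    def __len__(self):
        return len(self.trials)


def _edge_tasks(graph: TaskGraph) -> list[Task]:
    """Both directions of every edge: the one-action (filler) tasks."""
    out = []
    for u, v in sorted(graph.edges):
        out.append(Task(u, v))
        out.append(Task(v, u))
    return out


def select_filler_task(
    graph: TaskGraph, visit_counts: VisitCounts, rng: np.random.Generator
) -> Task:
    """Adaptive one-action task selection rebalancing visit counts.

    Tasks touching a most-visited state (argmax set of the tally) are
    excluded first; among the remainder, a task with the greatest sum of
    start and goal visits is sampled uniformly.  When every task touches a
    most-visited state, the exclusion step is skipped.
    """
    if not graph.edges:
        raise ValueError("graph has no edges; no one-action tasks exist")
    counts = {s: visit_counts.get(s, 0) for s in range(graph.n_states)}
    top = max(counts.values())
    most_visited = {s for s, c in counts.items() if c == top}
    tasks = _edge_tasks(graph)
    kept = [
        t for t in tasks if t.start not in most_visited and t.goal not in most_visited
    ]
    if not kept:
        kept = tasks
    sums = [counts[t.start] + counts[t.goal] for t in kept]
    best = max(sums)
    finalists = [t for t, s in zip(kept, sums) if s == best]
    return finalists[rng.integers(len(finalists))]


def sample_long_task(graph: TaskGraph, rng: np.random.Generator) -> Task:
    """Uniform draw from tasks optimally solved with more than one action."""
    dist = shortest_path_lengths(graph)
    tasks = [
        Task(s, g)
        for s in range(graph.n_states)
        for g in range(graph.n_states)
        if s != g and dist[s, g] >= 2
    ]
    if not tasks:
        raise ValueError("graph has no multi-action tasks")
    return tasks[rng.integers(len(tasks))]


def sample_probe_tasks(
    graph: TaskGraph, n_tasks: int, rng: np.random.Generator, min_distance: int = 3
) -> list[Task]:
    """Distinct probe tasks needing >= min_distance actions, drawn uniformly."""
    if not eligible_for_experiment(graph, n_tasks, min_distance):
        raise ValueError(
            f"graph has fewer than {n_tasks} tasks at distance >= {min_distance}"
        )
    dist = shortest_path_lengths(graph)
    pool = [
        Task(s, g)
        for s in range(graph.n_states)
        for g in range(graph.n_states)
        if s != g and dist[s, g] >= min_distance
    ]
    picks = rng.choice(len(pool), size=n_tasks, replace=False)
    return [pool[i] for i in picks]


def make_schedule(
    graph: TaskGraph,
    rng: np.random.Generator,
    n_long: int = 30,
    n_filler: int = 30,
    n_probe_tasks: int = 10,
) -> TrialSchedule:
    """Alternating long/adaptive-filler navigation, then the probe phases."""
    trials: list[Trial] = []
    for i in range(max(n_long, n_filler)):
        if i < n_long:
            trials.append(Trial("long", sample_long_task(graph, rng)))
        if i < n_filler:
            trials.append(Trial("filler", None))  # resolved adaptively at run time
    probes = sample_probe_tasks(graph, n_probe_tasks, rng)
    order = rng.permutation(n_probe_tasks)
    trials.extend(Trial("probe_implicit", probes[i]) for i in order)
    order = rng.permutation(n_probe_tasks)
    trials.extend(Trial("probe_explicit", probes[i]) for i in order)
    trials.append(Trial("teleport", None))
    return TrialSchedule(trials)


def _navigate(
    graph: TaskGraph, task: Task, epsilon: float, rng: np.random.Generator
) -> list[int]:
    g = graph.to_networkx()

    def fresh_plan(src):
        paths = list(nx.all_shortest_paths(g, src, task.goal))
        return list(paths[rng.integers(len(paths))])

    plan = fresh_plan(task.start)
    traj = [task.start]
    pos = 0
    while traj[-1] != task.goal:
        if epsilon > 0 and rng.random() < epsilon:
            nbrs = graph.adjacency[traj[-1]]
            step = nbrs[rng.integers(len(nbrs))]
            traj.append(step)
            plan = fresh_plan(step)
            pos = 0
        else:
            pos += 1
            traj.append(plan[pos])
    return traj


def simulate_agent(
    graph: TaskGraph,
    schedule: TrialSchedule,
    rng: np.random.Generator,
    epsilon: float = 0.0,
) -> tuple[list[list[int]], VisitCounts]:
    """Run the navigation trials of a schedule, tallying state visits.

    Adaptive filler trials (``task is None``) are resolved against the
    visit tally accumulated so far.  Returns one trajectory per navigation
    trial; visits count the start state and every state entered.
    """
    visits: VisitCounts = {s: 0 for s in range(graph.n_states)}
    trajectories: list[list[int]] = []
    for trial in schedule:
        if trial.kind not in ("long", "filler"):
            continue
        task = trial.task
        if task is None:
            if trial.kind != "filler":
                raise ValueError("only filler trials may be adaptive")
            task = select_filler_task(graph, visits, rng)
        traj = _navigate(graph, task, epsilon, rng)
        trajectories.append(traj)
        for s in traj:
            visits[s] += 1
    return trajectories, visits


def generate_choice_fixture(
    graph: TaskGraph,
    scores: SubgoalScores,
    beta: float,
    rng: np.random.Generator,
    schedule: TrialSchedule | None = None,
    graph_id: str = "g0",
    goal_scores: dict[Task, float] | None = None,
) -> list[ProbeChoice]:
    """Synthetic probe responses sampled by softmax(beta * score).

    ``scores`` should be standardized.  For explicit probes the goal option
    uses ``goal_scores[task]`` when supplied (e.g. a no-subgoal value) and
    the goal's own score otherwise.  The generating beta is recorded in
    every row's scores for recovery tests.
    """
    if schedule is None:
        schedule = make_schedule(graph, rng)
    kind_map = {
        "probe_implicit": "implicit",
        "probe_explicit": "explicit",
        "teleport": "teleport",
    }
    rows: list[ProbeChoice] = []
    for trial in schedule:
        if trial.kind not in kind_map:
            continue
        ptype = kind_map[trial.kind]
        cands = probe_candidates(graph, ptype, trial.task)
        x = {c: scores.scores[c] for c in cands}
        if ptype == "explicit" and goal_scores is not None:
            x[trial.task.goal] = goal_scores[trial.task]
        u = np.array([beta * x[c] for c in cands])
        u -= u.max()
        p = np.exp(u)
        p /= p.sum()
        chosen = cands[rng.choice(len(cands), p=p)]
        rows.append(ProbeChoice(graph_id, ptype, trial.task, cands, chosen, x))
    return rows


def write_trajectories(trajectories, path) -> None:
    with open(path, "w") as fh:
        for traj in trajectories:
            fh.write(json.dumps(list(map(int, traj))) + "\n")
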