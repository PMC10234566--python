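"""Task graphs, task distributions, and the experiment-eligibility filter.

A planning environment is an undirected simple graph whose nodes are states
and whose edges are the reversible transitions an agent can take.  A *task*
is an ordered (start, goal) pair of distinct states.  Everything downstream
(planners, subgoal valuation, heuristic scorers) operates on these objects.

States are 0-based integer indices internally; arbitrary labels are
preserved on I/O.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "TaskGraph",
    "Task",
    "TaskDistribution",
    "grid_graph",
    "shortest_path_lengths",
    "count_distant_tasks",
    "eligible_for_experiment",
    "uniform_task_distribution",
    "read_json_graph",
    "write_json_graph",
    "read_graph6",
    "write_graph6",
]


class TaskGraph:
    """Undirected simple graph with labelled states.

    Parameters
    ----------
    states
        State labels, one per node.  Order fixes the internal 0-based index.
    edges
        Unordered pairs of state *indices* (ints) or labels.  Self-loops and
        duplicate edges are rejected.
    """

    __slots__ = ("states", "edges", "adjacency", "_nx", "_spl")

    def __init__(self, states: Sequence, edges: Iterable[tuple]):
        self.states = tuple(states)
        index = {s: i for i, s in enumerate(self.states)}
        if len(index) != len(self.states):
            raise ValueError("duplicate state labels")
        norm = set()
        for u, v in edges:
            if u not in index and isinstance(u, int) and 0 <= u < len(self.states):
                iu = u
            else:
                iu = index[u]
            if v not in index and isinstance(v, int) and 0 <= v < len(self.states):
                iv = v
            else:
                iv = index[v]
            if iu == iv:
                raise ValueError(f"self-loop at state {self.states[iu]!r}")
            norm.add((min(iu, iv), max(iu, iv)))
        self.edges = frozenset(norm)
        adj: list[list[int]] = [[] for _ in self.states]
        for u, v in sorted(self.edges):
            adj[u].append(v)
            adj[v].append(u)
        self.adjacency = tuple(tuple(a) for a in adj)
        self._nx = None
        self._spl = None

    @property
    def n_states(self) -> int:
        return len(self.states)

    def neighbors(self, s: int) -> tuple[int, ...]:
        return self.adjacency[s]

    def degree(self, s: int) -> int:
        return len(self.adjacency[s])

    def is_connected(self) -> bool:
        if self.n_states == 0:
            return False
        seen = {0}
        stack = [0]
        while stack:
            for v in self.adjacency[stack.pop()]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return len(seen) == self.n_states

    def require_connected(self) -> None:
        if not self.is_connected():
            raise ValueError("graph is not connected")

    def to_networkx(self) -> nx.Graph:
        if self._nx is None:
            g = nx.Graph()
            g.add_nodes_from(range(self.n_states))
            g.add_edges_from(self.edges)
            self._nx = g
        return self._nx

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "TaskGraph":
        nodes = list(g.nodes())
        index = {s: i for i, s in enumerate(nodes)}
        return cls(nodes, [(index[u], index[v]) for u, v in g.edges()])

    def edge_key(self) -> tuple[tuple[int, int], ...]:
        """Sorted edge tuple; a label-sensitive identity for hashing/caching."""
        return tuple(sorted(self.edges))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TaskGraph)
            and self.states == other.states
            and self.edges == other.edges
        )

    def __hash__(self) -> int:
        return hash((self.states, self.edges))

    def __repr__(self) -> str:
        return f"TaskGraph(n={self.n_states}, m={len(self.edges)})"


@dataclass(frozen=True)
class Task:
    """An ordered (start, goal) pair of distinct states."""

    start: int
    goal: int

    def __post_init__(self):
        if self.start == self.goal:
            raise ValueError("task start and goal must be distinct")


@dataclass(frozen=True)
class TaskDistribution:
    """A weighted set of tasks; weights are nonnegative and sum to one."""

    tasks: tuple[Task, ...]
    weights: tuple[float, ...]

    def __post_init__(self):
        if len(self.tasks) != len(self.weights):
            raise ValueError("tasks and weights must have equal length")
        if len(set(self.tasks)) != len(self.tasks):
            raise ValueError("tasks must be distinct")
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        if not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError(f"weights sum to {w.sum()}, expected 1")

    @classmethod
    def uniform(cls, tasks: Sequence[Task]) -> "TaskDistribution":
        tasks = tuple(tasks)
        if not tasks:
            raise ValueError("empty task set")
        return cls(tasks, (1.0 / len(tasks),) * len(tasks))

    def __iter__(self):
        return iter(zip(self.tasks, self.weights))


def grid_graph(width: int, height: int) -> TaskGraph:
    """4-neighbour lattice; state ``(x, y)`` has index ``y * width + x``."""
    if width < 1 or height < 1:
        raise ValueError("grid dimensions must be >= 1")
    states = [(x, y) for y in range(height) for x in range(width)]
    idx = lambda x, y: y * width + x
    edges = []
    for y in range(height):
        for x in range(width):
            if x + 1 < width:
                edges.append((idx(x, y), idx(x + 1, y)))
            if y + 1 < height:
                edges.append((idx(x, y), idx(x, y + 1)))
    return TaskGraph(states, edges)


def shortest_path_lengths(graph: TaskGraph) -> np.ndarray:
    """All-pairs shortest-path distances in edges, as an (n, n) int matrix.

    Raises on disconnected graphs, naming an unreachable pair.
    """
    if graph._spl is not None:
        return graph._spl
    n = graph.n_states
    dist = np.full((n, n), -1, dtype=np.int64)
    for s in range(n):
        dist[s, s] = 0
        frontier = [s]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in graph.adjacency[u]:
                    if dist[s, v] < 0:
                        dist[s, v] = d
                        nxt.append(v)
            frontier = nxt
    if (dist < 0).any():
        s, t = map(int, np.argwhere(dist < 0)[0])
        raise ValueError(
            f"graph is disconnected: no path between states "
            f"{graph.states[s]!r} and {graph.states[t]!r}"
        )
    graph._spl = dist
    return dist


def count_distant_tasks(graph: TaskGraph, min_distance: int) -> int:
    """Number of ordered (start, goal) tasks with optimal length >= min_distance."""
    dist = shortest_path_lengths(graph)
    n = graph.n_states
    off = dist[~np.eye(n, dtype=bool)]
    return int((off >= min_distance).sum())


def eligible_for_experiment(
    graph: TaskGraph, min_tasks: int = 10, min_distance: int = 3
) -> bool:
    """Whether the graph admits enough sufficiently long tasks for probing.

    Counts ordered (start, goal) pairs whose optimal solution needs at least
    ``min_distance`` actions and requires at least ``min_tasks`` of them.
    The ordered-pair convention is the one that, applied to the full set of
    eight-node connected graphs with the defaults, retains 1,676 of them.
    """
    return count_distant_tasks(graph, min_distance) >= min_tasks


def uniform_task_distribution(
    graph: TaskGraph, exclude_neighbors: bool = False
) -> TaskDistribution:
    """Uniform distribution over ordered distinct (start, goal) pairs.

    With ``exclude_neighbors``, pairs joined by an edge are removed (the
    long-trial convention: tasks optimally solved with more than one action).
    """
    if graph.n_states < 2:
        raise ValueError("need at least 2 states")
    tasks = []
    for s in range(graph.n_states):
        for g in range(graph.n_states):
            if s == g:
                continue
            if exclude_neighbors and (min(s, g), max(s, g)) in graph.edges:
                continue
            tasks.append(Task(s, g))
    if not tasks:
        raise ValueError("no tasks remain after excluding neighboring pairs")
    return TaskDistribution.uniform(tasks)


# ---------------------------------------------------------------------------
# I/O


def write_json_graph(graph: TaskGraph, path) -> None:
    data = {
        "states": list(graph.states),
        "edges": [[graph.states[u], graph.states[v]] for u, v in sorted(graph.edges)],
    }
    with open(path, "w") as fh:
        json.dump(data, fh)


def read_json_graph(path) -> TaskGraph:
    with open(path) as fh:
        data = json.load(fh)
    states = [tuple(s) if isinstance(s, list) else s for s in data["states"]]
    index = {s: i for i, s in enumerate(states)}
    edges = [
        (index[tuple(u) if isinstance(u, list) else u],
         index[tuple(v) if isinstance(v, list) else v])
        for u, v in data["edges"]
    ]
    return TaskGraph(states, edges)


def write_graph6(graphs: Iterable[TaskGraph], path) -> None:
    with open(path, "wb") as fh:
        for g in graphs:
            fh.write(nx.to_graph6_bytes(g.to_networkx(), header=False))


def read_graph6(path) -> list[TaskGraph]:
    out = []
    with open(path, "rb") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            out.append(TaskGraph.from_networkx(nx.from_graph6_bytes(line)))
    return out
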