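"""Heuristic subgoal scorers based on graph-theoretic centrality.

Each scorer returns a log-scale per-state prediction so that, downstream,
a multinomial choice model's coefficient on the score is interpretable as
a probability-matching weight.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.linalg

from .decomposition import SubgoalScores
from .graph import TaskGraph

__all__ = [
    "degree_score",
    "betweenness_score",
    "qcut_score",
    "occupancy_score",
    "HEURISTIC_MODELS",
]

HEURISTIC_MODELS = ("degree", "betweenness", "qcut")


def degree_score(graph: TaskGraph) -> SubgoalScores:
    """Log fraction of other states each state is connected to."""
    graph.require_connected()
    if graph.n_states < 2:
        raise ValueError("need at least 2 states")
    cent = nx.degree_centrality(graph.to_networkx())
    scores = {}
    for s, c in cent.items():
        if c <= 0:
            raise ValueError(f"state {s} is isolated; log-degree undefined")
        scores[s] = math.log(c)
    return SubgoalScores("degree", graph, scores)


def betweenness_score(graph: TaskGraph) -> SubgoalScores:
    """Log endpoint-inclusive betweenness fraction.

    For each (start, goal) pair the state gets credit equal to the fraction
    of optimal paths containing it, endpoints included; averaging over pairs
    gives the probability that a uniformly drawn optimal path of a uniformly
    drawn task contains the state.  Endpoint inclusion keeps every fraction
    strictly positive, so the log is always finite.
    """
    graph.require_connected()
    cent = nx.betweenness_centrality(graph.to_networkx(), endpoints=True)
    return SubgoalScores(
        "betweenness", graph, {s: math.log(c) for s, c in cent.items()}
    )


def qcut_score(graph: TaskGraph) -> SubgoalScores:
    """Spectral two-group partition score.

    Embeds states by the eigenvector v of the second-smallest eigenvalue of
    the symmetric normalized Laplacian and scores each state as -v_s^2:
    states near the embedding mean (the partition boundary) are most
    central.  Invariant to the sign of v.  A repeated second eigenvalue is
    flagged in ``meta['degenerate']``; the eigenvector is then whichever the
    (deterministic) symmetric eigensolver returns.
    """
    graph.require_connected()
    if graph.n_states < 2:
        raise ValueError("need at least 2 states")
    L = nx.normalized_laplacian_matrix(
        graph.to_networkx(), nodelist=range(graph.n_states)
    ).toarray()
    evals, evecs = scipy.linalg.eigh(L)
    v = evecs[:, 1]
    degenerate = bool(
        graph.n_states > 2 and abs(evals[2] - evals[1]) < 1e-9
    )
    scores = {s: -float(v[s] ** 2) for s in range(graph.n_states)}
    return SubgoalScores("qcut", graph, scores, meta={"degenerate": degenerate})


def occupancy_score(
    trajectories: Iterable[Sequence[int]], graph: TaskGraph
) -> SubgoalScores:
    """Log (1 + visit count) across trajectories; every occurrence counts."""
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("need at least one trajectory")
    counts = np.zeros(graph.n_states)
    for traj in trajectories:
        for s in traj:
            counts[s] += 1
    scores = {s: math.log(counts[s] + 1) for s in range(graph.n_states)}
    return SubgoalScores("occupancy", graph, scores)
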