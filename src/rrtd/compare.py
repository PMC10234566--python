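"""Cross-model comparison of per-state subgoal predictions.

For every graph, each pair of models is compared by the correlation of
their per-state score vectors; correlations are then averaged across
graphs.  A model that predicts a uniform distribution over subgoals (a
constant score vector) has no defined correlation on that graph, so such
pairs are discarded from the average and the discard count is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .decomposition import SubgoalScores, score_single_subgoals
from .graph import TaskGraph
from . import heuristics

__all__ = [
    "ModelCorrelationMatrix",
    "pairwise_correlation",
    "correlation_matrix",
    "default_scorers",
]

_CONSTANT_TOL = 1e-12


@dataclass
class ModelCorrelationMatrix:
    models: tuple[str, ...]
    mean_r: pd.DataFrame
    n_graphs_used: pd.DataFrame

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.mean_r.loc[a, b])


def pairwise_correlation(
    scores_a: SubgoalScores,
    scores_b: SubgoalScores,
    method: str = "pearson",
) -> float | None:
    """Correlation of two models' per-state scores; None when undefined."""
    if set(scores_a.scores) != set(scores_b.scores):
        raise ValueError("score vectors cover different state sets")
    a = scores_a.as_array()
    b = scores_b.as_array()
    if np.ptp(a) < _CONSTANT_TOL or np.ptp(b) < _CONSTANT_TOL:
        return None
    if method == "pearson":
        r = scipy.stats.pearsonr(a, b).statistic
    elif method == "spearman":
        r = scipy.stats.spearmanr(a, b).statistic
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r)


def default_scorers(
    models: Sequence[str],
    n_samples: int = 100,
    seed: int | None = None,
) -> dict[str, Callable[[TaskGraph], SubgoalScores]]:
    """Standard scorer callables keyed by model name.

    RRTD models score by the single-subgoal decomposition value under the
    uniform task distribution; heuristics are the centrality-based scorers.
    ``n_samples`` controls the Monte-Carlo effort for the systematic-search
    RRTD variants (the random-walk variant is analytic).
    """
    out: dict[str, Callable] = {}
    for name in models:
        key = name.lower()
        if key.startswith("rrtd-"):
            alg = key.removeprefix("rrtd-")

            def scorer(g, _alg=alg):
                return score_single_subgoals(g, _alg, n_samples=n_samples, seed=seed)

            out[name] = scorer
        elif key == "degree":
            out[name] = heuristics.degree_score
        elif key == "betweenness":
            out[name] = heuristics.betweenness_score
        elif key == "qcut":
            out[name] = heuristics.qcut_score
        else:
            raise ValueError(f"unknown model {name!r}")
    return out


def correlation_matrix(
    graphs: Sequence[TaskGraph],
    scorers: Mapping[str, Callable[[TaskGraph], SubgoalScores]],
    method: str = "pearson",
) -> ModelCorrelationMatrix:
    """Mean per-graph correlation between every pair of models.

    Undefined (constant-prediction) correlations are skipped; the number of
    graphs actually contributing to each cell is reported alongside the
    means so the discards are auditable.
    """
    if not graphs:
        raise ValueError("need at least one graph")
    names = tuple(scorers)
    if len(names) < 2:
        raise ValueError("need at least two models")
    k = len(names)
    sums = np.zeros((k, k))
    counts = np.zeros((k, k), dtype=int)
    for gi, graph in enumerate(graphs):
        per_model = []
        for name in names:
            try:
                per_model.append(scorers[name](graph))
            except Exception as exc:
                raise RuntimeError(
                    f"model {name!r} failed on graph #{gi} ({graph!r})"
                ) from exc
        for i in range(k):
            for j in range(i, k):
                r = pairwise_correlation(per_model[i], per_model[j], method=method)
                if r is None:
                    continue
                sums[i, j] += r
                counts[i, j] += 1
    mean = np.full((k, k), np.nan)
    np.divide(sums, counts, out=mean, where=counts > 0)
    mean = np.where(np.tril(np.ones((k, k)), -1) > 0, mean.T, mean)
    counts = np.maximum(counts, counts.T)
    return ModelCorrelationMatrix(
        names,
        pd.DataFrame(mean, index=names, columns=names),
        pd.DataFrame(counts, index=names, columns=names),
    )
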