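"""Softmax choice models linking subgoal scores to probe responses.

Two models are provided:

* a fixed-effects multinomial (softmax) model of probe choice, where the
  probability of choosing candidate state ``c`` is proportional to
  ``exp(beta * x_c)`` over the probe's candidate set, ``x`` being the
  model's standardized per-state score; and
* a two-stage model of choice among multiple optimal paths, where a subgoal
  is first sampled with probability proportional to ``exp(beta1 * x_z)``
  and then a path is sampled with weight ``exp(beta2)`` if it contains the
  subgoal and ``exp(0)`` otherwise, the subgoal being marginalized out in
  the likelihood.

Probe candidate-set rules: the implicit probe excludes the task's start and
goal; the explicit probe excludes only the start (choosing the goal means
"no subgoal"); the teleport probe offers every state and has no task.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .decomposition import SubgoalScores
from .graph import Task, TaskGraph

__all__ = [
    "ProbeChoice",
    "ChoiceTable",
    "PathChoice",
    "TwoStageFit",
    "probe_candidates",
    "standardize_scores",
    "softmax_loglik",
    "fit_softmax",
    "two_stage_loglik",
    "fit_two_stage",
    "choice_table_to_frame",
    "choice_table_from_frame",
]

PROBE_TYPES = ("implicit", "explicit", "teleport")


@dataclass(frozen=True)
class ProbeChoice:
    """One probe response: a candidate set, per-candidate scores, a choice."""

    graph_id: str
    probe_type: str
    task: Task | None
    candidates: tuple[int, ...]
    chosen: int
    scores: dict[int, float] | None = None

    def __post_init__(self):
        if self.probe_type not in PROBE_TYPES:
            raise ValueError(f"unknown probe type {self.probe_type!r}")
        if self.chosen not in self.candidates:
            raise ValueError("chosen state is not among the candidates")


ChoiceTable = list  # of ProbeChoice


def probe_candidates(graph: TaskGraph, probe_type: str, task: Task | None) -> tuple:
    """Candidate states offered by each probe type."""
    states = range(graph.n_states)
    if probe_type == "implicit":
        return tuple(s for s in states if s not in (task.start, task.goal))
    if probe_type == "explicit":
        return tuple(s for s in states if s != task.start)
    if probe_type == "teleport":
        return tuple(states)
    raise ValueError(f"unknown probe type {probe_type!r}")


def standardize_scores(scores: SubgoalScores) -> SubgoalScores:
    """Center to mean 0 and scale to (population) standard deviation 1."""
    vals = scores.as_array()
    sd = vals.std()  # divide-by-n convention
    if sd < 1e-12:
        raise ValueError("constant scores cannot be standardized")
    mu = vals.mean()
    return SubgoalScores(
        scores.model,
        scores.graph,
        {s: (v - mu) / sd for s, v in scores.scores.items()},
        dict(scores.meta),
    )


def _row_scores(row: ProbeChoice) -> dict[int, float]:
    if row.scores is None:
        raise ValueError("probe row carries no scores; attach them first")
    missing = [c for c in row.candidates if c not in row.scores]
    if missing:
        raise ValueError(f"candidates without a score: {missing}")
    return row.scores


def softmax_loglik(table: Iterable[ProbeChoice], beta: float) -> float:
    """Log likelihood of the chosen options under softmax(beta * score)."""
    total = 0.0
    for row in table:
        x = _row_scores(row)
        u = np.array([beta * x[c] for c in row.candidates])
        u -= u.max()  # overflow guard
        total += u[row.candidates.index(row.chosen)] - math.log(np.exp(u).sum())
    return float(total)


def fit_softmax(
    table: Sequence[ProbeChoice],
    init_beta: float = 1.0,
    bound: float = 50.0,
) -> tuple[float, float]:
    """Maximum-likelihood inverse temperature by bounded 1-D optimization."""
    table = list(table)
    if not table:
        raise ValueError("empty choice table")
    res = scipy.optimize.minimize_scalar(
        lambda b: -softmax_loglik(table, b),
        bounds=(-bound, bound),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(f"softmax fit did not converge: {res.message}")
    return float(res.x), float(-res.fun)


# ---------------------------------------------------------------------------
# Two-stage model of choice among optimal paths


@dataclass(frozen=True)
class PathChoice:
    """A navigation trial with several optimal paths and the one taken.

    ``candidate_scores`` are the subgoal-stage scores over the candidate
    subgoal states (all states except the task's start and goal).
    """

    task: Task
    optimal_paths: tuple[tuple[int, ...], ...]
    chosen_path: tuple[int, ...]
    candidate_scores: dict[int, float]

    def __post_init__(self):
        if len(self.optimal_paths) < 2:
            raise ValueError("need at least two optimal paths")
        if self.chosen_path not in self.optimal_paths:
            raise ValueError("chosen path is not among the optimal paths")


@dataclass(frozen=True)
class TwoStageFit:
    beta1: float
    beta2: float
    loglik: float
    n_obs: int

    def __post_init__(self):
        if self.beta1 < 0 or self.beta2 < 0:
            raise ValueError("betas must be nonnegative")


def two_stage_loglik(
    observations: Iterable[PathChoice], beta1: float, beta2: float
) -> float:
    """Marginal log likelihood of path choices under the two-stage model."""
    total = 0.0
    for obs in observations:
        cands = sorted(obs.candidate_scores)
        w = np.array([beta1 * obs.candidate_scores[z] for z in cands])
        w -= w.max()
        pz = np.exp(w)
        pz /= pz.sum()
        lik = 0.0
        for z, p in zip(cands, pz):
            contains = np.array(
                [beta2 if z in path else 0.0 for path in obs.optimal_paths]
            )
            contains -= contains.max()
            ppath = np.exp(contains)
            ppath /= ppath.sum()
            lik += p * ppath[obs.optimal_paths.index(obs.chosen_path)]
        total += math.log(lik)
    return float(total)


def fit_two_stage(
    observations: Sequence[PathChoice],
    init: tuple[float, float] = (1.0, 1.0),
) -> TwoStageFit:
    """Nonnegative maximum-likelihood fit of (beta1, beta2) from (1, 1)."""
    observations = list(observations)
    if not observations:
        raise ValueError("no observations")
    res = scipy.optimize.minimize(
        lambda b: -two_stage_loglik(observations, b[0], b[1]),
        x0=np.asarray(init, dtype=float),
        method="L-BFGS-B",
        bounds=[(0.0, None), (0.0, None)],
    )
    if not res.success:
        raise RuntimeError(f"two-stage fit did not converge: {res.message}")
    return TwoStageFit(float(res.x[0]), float(res.x[1]), float(-res.fun), len(observations))


# ---------------------------------------------------------------------------
# CSV round-trip for choice tables


def choice_table_to_frame(table: Iterable[ProbeChoice]) -> pd.DataFrame:
    rows = []
    for r in table:
        rows.append(
            {
                "graph_id": r.graph_id,
                "probe_type": r.probe_type,
                "start": r.task.start if r.task else "",
                "goal": r.task.goal if r.task else "",
                "candidates": ";".join(map(str, r.candidates)),
                "chosen": r.chosen,
            }
        )
    return pd.DataFrame(rows)


def choice_table_from_frame(frame: pd.DataFrame) -> ChoiceTable:
    out = []
    for _, row in frame.iterrows():
        task = None
        if row["start"] != "" and not pd.isna(row["start"]):
            task = Task(int(row["start"]), int(row["goal"]))
        out.append(
            ProbeChoice(
                str(row["graph_id"]),
                row["probe_type"],
                task,
                tuple(int(c) for c in str(row["candidates"]).split(";")),
                int(row["chosen"]),
            )
        )
    return out
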