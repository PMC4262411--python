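"""Pareto dominance, non-dominated filtering and the current-best decision maker.

The variable-selection search minimises two objectives simultaneously:
the prediction error (RMSEP on the evaluation split) and the number of
selected variables.  Solutions are compared by Pareto dominance; the
"current best" is picked from the non-dominated front as the member
closest to the utopian point after per-objective min-max normalisation.
"""

from __future__ import annotations

import math
from typing import NamedTuple, Sequence, TypeVar

import numpy as np

__all__ = ["ObjectiveVector", "dominates", "pareto_front", "decision_maker"]

S = TypeVar("S")


class ObjectiveVector(NamedTuple):
    """(prediction error, number of selected variables) — both minimised.

    Infeasible solutions (empty variable mask) carry ``error = inf`` so
    any feasible solution dominates them.
    """

    error: float
    n_vars: int


def dominates(a: ObjectiveVector, b: ObjectiveVector) -> bool:
    """True iff ``a`` is no worse than ``b`` in both objectives and
    strictly better in at least one."""
    if a.error > b.error or a.n_vars > b.n_vars:
        return False
    return a.error < b.error or a.n_vars < b.n_vars


def pareto_front(points: Sequence[ObjectiveVector]) -> list[int]:
    """Indices of all non-dominated points (duplicates of a front point
    are all retained).

    Runs in O(n log n): after sorting by error, a point is dominated
    iff some point with strictly smaller error has n_vars <= its own,
    or some point with error <= its own has strictly smaller n_vars.
    """
    if len(points) == 0:
        raise ValueError("pareto_front of an empty list")
    err = np.array([p[0] for p in points], dtype=float)
    nv = np.array([p[1] for p in points], dtype=float)
    order = np.argsort(err, kind="stable")
    front: list[int] = []
    best_nv_strict = math.inf  # min n_vars over points with error < current
    i = 0
    n = len(points)
    while i < n:
        # process the group of equal-error points together
        j = i
        while j < n and err[order[j]] == err[order[i]]:
            j += 1
        group = order[i:j]
        group_min_nv = nv[group].min()
        for idx in group:
            if nv[idx] < best_nv_strict and nv[idx] == group_min_nv:
                front.append(int(idx))
        best_nv_strict = min(best_nv_strict, group_min_nv)
        i = j
    return sorted(front)


def decision_maker(front: Sequence[tuple[ObjectiveVector, S]]) -> S:
    """Pick the current best from a mutually non-dominated front.

    Each objective is min-max normalised over the front (a zero range
    normalises to 0), and the member with the smallest Euclidean
    distance to the normalised utopian point (0, 0) wins.  Ties are
    broken by fewer variables, then lower error, then first occurrence.
    """
    if len(front) == 0:
        raise ValueError("decision maker needs a non-empty front")
    errs = np.array([obj.error for obj, _ in front], dtype=float)
    nvs = np.array([obj.n_vars for obj, _ in front], dtype=float)

    def _norm(v: np.ndarray) -> np.ndarray:
        lo, hi = v.min(), v.max()
        if hi == lo:
            return np.zeros_like(v)
        return (v - lo) / (hi - lo)

    dist = np.hypot(_norm(errs), _norm(nvs))
    best = min(
        range(len(front)), key=lambda i: (dist[i], nvs[i], errs[i], i)
    )
    return front[best][1]
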