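"""The multiobjective firefly search for variable selection (FA-MLR).

Each firefly is a continuous position in [0, 1]^K; components above a
threshold switch the corresponding spectral variable into the model
(binary encoding).  Fireflies attract one another with strength
``beta0 * exp(-gamma * r^2)`` decaying with Euclidean distance ``r``,
plus a uniform random walk scaled by ``alpha``.  A firefly moves toward
any firefly whose objective vector — (RMSEP on the evaluation split,
number of selected variables) — Pareto-dominates its own.  A
non-dominated archive accumulates every evaluated solution; after the
final iteration a decision maker picks the current best from the
archive, which is then re-fitted and scored on the prediction set.

Brightness (light intensity) is the negative prediction error, so the
brightest firefly is the one with the smallest RMSEP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dataio import CalibrationDataset, RunConfig, get_logger
from .moo import ObjectiveVector, decision_maker, dominates
from .preprocess import DataSplit
from .regression import ModelFit, evaluate_subset

__all__ = [
    "Firefly",
    "FAState",
    "init_population",
    "encode",
    "distance",
    "attractiveness",
    "move",
    "batch_evaluate",
    "run_fa_mlr",
]

logger = get_logger()

# empty-mask sentinel: infinite error so any feasible solution dominates
# it; the size component is likewise infinite (a 0 there would make the
# sentinel minimal in the size objective and hence non-dominated)
INFEASIBLE = ObjectiveVector(math.inf, 2**31)


@dataclass
class Firefly:
    """One candidate solution: continuous position plus derived mask."""

    position: np.ndarray
    mask: np.ndarray
    objectives: ObjectiveVector | None = None

    @property
    def intensity(self) -> float:
        """Light intensity: brighter = lower prediction error."""
        if self.objectives is None:
            raise ValueError("firefly not yet evaluated")
        return -self.objectives.error


@dataclass
class FAState:
    """Search state: population, iteration counter, archive, trace, best."""

    population: list[Firefly]
    iteration: int
    archive: list[tuple[ObjectiveVector, np.ndarray]]
    best: ModelFit | None = None
    trace: list[dict] = field(default_factory=list)
    n_evaluations: int = 0


def encode(position: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary mask: 1 where the component strictly exceeds the threshold."""
    position = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(position)):
        raise ValueError("position components must be finite")
    return (position > threshold).astype(np.uint8)


def distance(a: np.ndarray, b: np.ndarray) -> float:
    """Cartesian (Euclidean) distance between two positions."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    return float(np.linalg.norm(a - b))


def attractiveness(r: float, beta0: float = 1.0, gamma: float = 1.0) -> float:
    """Attractiveness ``beta0 * exp(-gamma * r^2)``; equals beta0 at r = 0."""
    if r < 0:
        raise ValueError("distance must be non-negative")
    return float(beta0 * math.exp(-gamma * r * r))


def move(
    x_i: np.ndarray,
    x_j: np.ndarray,
    params: RunConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Move firefly i toward brighter firefly j.

    ``x_i + beta0 exp(-gamma r^2) (x_j - x_i) + alpha (rand - 1/2)``
    with one fresh uniform draw per component, then clamped to [0, 1].
    """
    x_i = np.asarray(x_i, dtype=float).ravel()
    x_j = np.asarray(x_j, dtype=float).ravel()
    if x_i.shape != x_j.shape:
        raise ValueError("positions must have equal length")
    beta = attractiveness(distance(x_i, x_j), params.beta0, params.gamma)
    new = x_i + beta * (x_j - x_i) + params.alpha * (rng.random(x_i.shape[0]) - 0.5)
    return np.clip(new, 0.0, 1.0)


def init_population(
    n: int,
    K: int,
    seed: int | np.random.Generator = 0,
    threshold: float = 0.5,
) -> list[Firefly]:
    """n fireflies with i.i.d. uniform positions on [0, 1]^K, masks derived."""
    if n < 2:
        raise ValueError("need at least 2 fireflies for pairwise dynamics")
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    positions = rng.random((n, K))
    return [Firefly(position=p, mask=encode(p, threshold)) for p in positions]


class _Evaluator:
    """Mask-pure objective evaluation with caching.

    The objective vector depends only on the binary mask, so each
    distinct mask is fitted at most once per run.  Subset fits reuse a
    precomputed calibration Gram matrix: for a subset S the normal
    equations of the intercept-augmented system are assembled from
    X'X, X'y and the column sums, then solved by Cholesky — the same
    minimum-norm solution :func:`~ffavarsel.regression.fit_mlr` returns
    on these full-rank overdetermined systems, at a fraction of the
    cost.  Ill-conditioned subsets fall back to the full
    :func:`~ffavarsel.regression.evaluate_subset` path.
    """

    def __init__(
        self, dataset: CalibrationDataset, split: DataSplit, eval_split: str
    ) -> None:
        self.dataset = dataset
        self.split = split
        self.eval_split = eval_split
        self.cache: dict[bytes, ObjectiveVector] = {}
        self.n_evaluations = 0
        cal = list(split.calibration_idx)
        ev = list(split.indices_for(eval_split))
        X_cal = dataset.X[cal]
        self._n_cal = len(cal)
        self._gram = X_cal.T @ X_cal
        self._xty = X_cal.T @ dataset.y[cal]
        self._col_sums = X_cal.sum(axis=0)
        self._y_cal_sum = float(dataset.y[cal].sum())
        self._X_ev = dataset.X[ev]
        self._y_ev = dataset.y[ev]

    def _rmsep_fast(self, selected: np.ndarray) -> float | None:
        """Subset RMSEP via the precomputed Gram; None if ill-conditioned."""
        import scipy.linalg

        k = selected.shape[0]
        if k + 1 >= self._n_cal:
            return None  # not safely overdetermined; use the general path
        G = np.empty((k + 1, k + 1))
        G[0, 0] = self._n_cal
        G[0, 1:] = self._col_sums[selected]
        G[1:, 0] = G[0, 1:]
        G[1:, 1:] = self._gram[np.ix_(selected, selected)]
        b = np.empty(k + 1)
        b[0] = self._y_cal_sum
        b[1:] = self._xty[selected]
        try:
            c, low = scipy.linalg.cho_factor(G, check_finite=False)
        except scipy.linalg.LinAlgError:
            return None
        d = np.diag(c)
        if d.min() <= d.max() * 1e-5:  # sqrt of the rcond floor in fit_mlr
            return None
        coef = scipy.linalg.cho_solve((c, low), b, check_finite=False)
        y_hat = coef[0] + self._X_ev[:, selected] @ coef[1:]
        return float(np.sqrt(np.mean((self._y_ev - y_hat) ** 2)))

    def __call__(self, mask: np.ndarray) -> ObjectiveVector:
        key = mask.tobytes()
        hit = self.cache.get(key)
        if hit is not None:
            return hit
        n_sel = int(mask.sum())
        if n_sel == 0:
            obj = INFEASIBLE
        else:
            selected = np.flatnonzero(mask)
            err = self._rmsep_fast(selected)
            if err is None:
                fit = evaluate_subset(
                    self.dataset, self.split, selected, eval_split=self.eval_split
                )
                err = fit.metrics["rmsep"]
            obj = ObjectiveVector(err, n_sel)
            self.n_evaluations += 1
        self.cache[key] = obj
        return obj


def batch_evaluate(
    population: list[Firefly],
    dataset: CalibrationDataset,
    split: DataSplit,
    eval_split: str = "validation",
) -> list[ObjectiveVector]:
    """Objective vectors for a whole population.

    A pure map with no cross-firefly dependence: element-wise identical
    to sequential :func:`evaluate_subset` calls (empty masks receive the
    infeasible sentinel), and order-preserving.  Implementations are free
    to parallelise; this one evaluates sequentially with mask caching.
    """
    if len(population) == 0:
        raise ValueError("population must be non-empty")
    out: list[ObjectiveVector] = []
    cache: dict[bytes, ObjectiveVector] = {}
    for f in population:
        key = f.mask.tobytes()
        if key not in cache:
            n_sel = int(f.mask.sum())
            if n_sel == 0:
                cache[key] = INFEASIBLE
            else:
                fit = evaluate_subset(
                    dataset, split, np.flatnonzero(f.mask), eval_split=eval_split
                )
                cache[key] = ObjectiveVector(fit.metrics["rmsep"], n_sel)
        out.append(cache[key])
    return out


def _archive_add(
    archive: list[tuple[ObjectiveVector, np.ndarray, np.ndarray]],
    obj: ObjectiveVector,
    mask: np.ndarray,
    position: np.ndarray,
) -> None:
    """Insert a feasible solution, keeping the archive mutually non-dominated."""
    if not math.isfinite(obj.error):
        return
    for a_obj, a_mask, _ in archive:
        if dominates(a_obj, obj):
            return
        if a_obj == obj and np.array_equal(a_mask, mask):
            return
    archive[:] = [a for a in archive if not dominates(obj, a[0])]
    archive.append((obj, mask.copy(), position.copy()))


def _exploration_walk(
    anchor_position: np.ndarray,
    anchor_mask: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Add/drop step around an archive anchor.

    With probability 1/2 one randomly chosen selected channel is
    reflected across the threshold (dropped), and independently with
    probability 1/2 one unselected channel is reflected in (added).
    This is the subset-neighbourhood analogue of the random walk that
    multiobjective firefly formulations give to non-dominated fireflies:
    a full-width uniform perturbation in [0,1]^K flips a number of
    channels that grows with K, which destroys sparse solutions, whereas
    the add/drop step explores one Hamming neighbour at a time.
    """
    pos = anchor_position.copy()
    on = np.flatnonzero(anchor_mask)
    off = np.flatnonzero(anchor_mask == 0)
    if rng.random() < 0.5 and on.size:
        c = on[int(rng.integers(on.size))]
        pos[c] = 1.0 - pos[c]
    if rng.random() < 0.5 and off.size:
        c = off[int(rng.integers(off.size))]
        pos[c] = 1.0 - pos[c]
    return pos


def run_fa_mlr(
    dataset: CalibrationDataset,
    split: DataSplit,
    config: RunConfig,
) -> tuple[ModelFit, FAState]:
    """Run the multiobjective firefly search for variable selection.

    Every firefly is evaluated on the ``config.objective_set`` split
    (validation by default).  Within each iteration, ordered pairs
    (i, j) are scanned in ascending index order; whenever firefly j's
    objectives dominate firefly i's, firefly i moves toward j and, if
    the move changed its mask, is re-evaluated immediately (in-place
    update).  The non-dominated archive is updated at every evaluation,
    so the best archived error is non-increasing across iterations.
    The decision maker's pick from the final archive is re-evaluated on
    the prediction split and returned together with the final state.
    """
    K = dataset.n_variables
    if len(split.calibration_idx) < 2:
        raise ValueError("calibration set must contain at least 2 samples")
    rng = np.random.default_rng(config.seed)
    population = init_population(
        config.n_fireflies, K, seed=rng, threshold=config.threshold
    )
    evaluator = _Evaluator(dataset, split, config.objective_set)
    archive: list[tuple[ObjectiveVector, np.ndarray, np.ndarray]] = []
    for f in population:
        f.objectives = evaluator(f.mask)
        _archive_add(archive, f.objectives, f.mask, f.position)
    state = FAState(population=population, iteration=0, archive=[])

    n = config.n_fireflies
    for iteration in range(1, config.max_iterations + 1):
        for i in range(n):
            fi = population[i]
            moved = False
            for j in range(n):
                if i == j:
                    continue
                fj = population[j]
                if dominates(fj.objectives, fi.objectives):
                    fi.position = move(fi.position, fj.position, config, rng)
                    moved = True
                    new_mask = encode(fi.position, config.threshold)
                    if not np.array_equal(new_mask, fi.mask):
                        fi.mask = new_mask
                        fi.objectives = evaluator(new_mask)
                        _archive_add(archive, fi.objectives, fi.mask, fi.position)
            if not moved and config.alpha > 0 and archive:
                # non-dominated firefly: explore around a randomly chosen
                # archive member (the multiobjective-FA random walk for
                # non-dominated solutions); without it the swarm deadlocks
                # once the population is mutually non-dominated.  alpha = 0
                # switches all randomisation off, so no walk either.
                g_obj, g_mask, g_pos = archive[int(rng.integers(len(archive)))]
                fi.position = _exploration_walk(g_pos, g_mask, rng)
                new_mask = encode(fi.position, config.threshold)
                if not np.array_equal(new_mask, fi.mask):
                    fi.mask = new_mask
                    fi.objectives = evaluator(new_mask)
                    _archive_add(archive, fi.objectives, fi.mask, fi.position)
        state.iteration = iteration
        errors = [f.objectives.error for f in population]
        finite = [e for e in errors if math.isfinite(e)]
        best_obj = min(archive, key=lambda t: (t[0].error, t[0].n_vars))[0]
        entry = {
            "iteration": iteration,
            "mean_error": float(np.mean(finite)) if finite else math.inf,
            "archive_size": len(archive),
            "best_error": best_obj.error,
            "best_n_vars": best_obj.n_vars,
        }
        state.trace.append(entry)
        logger.info(
            "iter %(iteration)d: mean_error=%(mean_error).6g "
            "archive=%(archive_size)d best=(%(best_error).6g, %(best_n_vars)d)",
            entry,
        )

    state.n_evaluations = evaluator.n_evaluations
    state.archive = [(obj, mask) for obj, mask, _ in archive]
    chosen_mask = decision_maker([(obj, mask) for obj, mask, _ in archive])
    best = evaluate_subset(
        dataset, split, np.flatnonzero(chosen_mask), eval_split="prediction"
    )
    state.best = best
    return best, state
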