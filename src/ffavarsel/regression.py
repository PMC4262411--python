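"""MLR fitting via the Moore-Penrose pseudoinverse and model-assessment metrics.

The calibration model is ``y = b0 + X_sub @ b + e``: an ordinary linear
model on a selected subset of spectral variables, with an intercept.
Coefficients are the minimum-norm least-squares solution of the
intercept-augmented system, so the fit is defined even when the subset
has more variables than there are calibration samples.

Model quality on a held-out split is summarised by five statistics:
RMSEP (root mean squared error of prediction), MAPE (mean absolute
percentage error), PRESS (sum of squared prediction residuals), and the
AIC/BIC information criteria computed from the MLE residual variance
with the intercept counted as a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg

from .dataio import CalibrationDataset
from .preprocess import DataSplit

__all__ = [
    "ModelFit",
    "fit_mlr",
    "predict",
    "rmsep",
    "mape",
    "press",
    "aic_bic",
    "evaluate_subset",
]

# reciprocal-condition floor below which the Cholesky fast path defers to SVD
_CHOL_RCOND_FLOOR = 1e-10


@dataclass(frozen=True)
class ModelFit:
    """A fitted subset model and its metric suite on a stated split."""

    selected: tuple[int, ...]
    coefficients: np.ndarray  # intercept first
    metrics: Mapping[str, float]
    eval_split: str = "validation"

    def __post_init__(self) -> None:
        sel = tuple(int(i) for i in self.selected)
        object.__setattr__(self, "selected", sel)
        coef = np.asarray(self.coefficients, dtype=float).ravel()
        object.__setattr__(self, "coefficients", coef)
        object.__setattr__(self, "metrics", dict(self.metrics))
        if len(sel) < 1:
            raise ValueError("a model must select at least one variable")
        if coef.shape[0] != len(sel) + 1:
            raise ValueError(
                f"expected {len(sel) + 1} coefficients (intercept first), "
                f"got {coef.shape[0]}"
            )
        if not np.all(np.isfinite(coef)):
            raise ValueError("coefficients must be finite")
        for key in ("rmsep", "press", "mape"):
            if key in self.metrics and self.metrics[key] < 0:
                raise ValueError(f"{key} must be non-negative")
        if self.eval_split not in ("validation", "prediction", "calibration"):
            raise ValueError(f"unknown eval_split {self.eval_split!r}")

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    @property
    def selected_1based(self) -> tuple[int, ...]:
        return tuple(i + 1 for i in self.selected)


def fit_mlr(X_sub: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Minimum-norm least-squares coefficients of ``[1 | X_sub] b ~ y``.

    Returns the Moore-Penrose pseudoinverse solution (intercept first).
    Singular values below ``eps * max(m, n) * s_max`` are treated as
    zero, so rank-deficient and underdetermined systems (more variables
    than samples) yield the minimum-norm solution.  Well-conditioned
    overdetermined systems are solved through the normal equations with
    a Cholesky factorisation, which gives the same (unique) solution at
    a fraction of the cost; the SVD route is the general fallback.
    """
    X_sub = np.atleast_2d(np.asarray(X_sub, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X_sub.shape[1] < 1:
        raise ValueError("X_sub must have at least one column")
    if X_sub.shape[0] != y.shape[0]:
        raise ValueError(
            f"X_sub has {X_sub.shape[0]} rows but y has {y.shape[0]} entries"
        )
    if not (np.all(np.isfinite(X_sub)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    m, k = X_sub.shape
    A = np.empty((m, k + 1))
    A[:, 0] = 1.0
    A[:, 1:] = X_sub
    if m > k + 1:
        coef = _solve_normal_equations(A, y)
        if coef is not None:
            return coef
    rcond = np.finfo(float).eps * max(A.shape)
    coef, *_ = np.linalg.lstsq(A, y, rcond=rcond)
    return coef


def _solve_normal_equations(A: np.ndarray, y: np.ndarray) -> np.ndarray | None:
    """Cholesky solve of A'A b = A'y; None when too ill-conditioned to trust."""
    G = A.T @ A
    try:
        c, low = scipy.linalg.cho_factor(G, check_finite=False)
    except scipy.linalg.LinAlgError:
        return None
    d = np.diag(c)
    if d.min() <= d.max() * np.sqrt(_CHOL_RCOND_FLOOR):
        return None
    return scipy.linalg.cho_solve((c, low), A.T @ y, check_finite=False)


def predict(coefficients: np.ndarray, X_sub: np.ndarray) -> np.ndarray:
    """Model predictions ``b0 + X_sub @ b`` for intercept-first coefficients."""
    coefficients = np.asarray(coefficients, dtype=float).ravel()
    X_sub = np.atleast_2d(np.asarray(X_sub, dtype=float))
    if coefficients.shape[0] != X_sub.shape[1] + 1:
        raise ValueError(
            f"{coefficients.shape[0]} coefficients do not match "
            f"{X_sub.shape[1]} columns + intercept"
        )
    return coefficients[0] + X_sub @ coefficients[1:]


def _check_pair(y: np.ndarray, y_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape[0] == 0:
        raise ValueError("empty vectors")
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape[0]} vs {y_hat.shape[0]}")
    return y, y_hat


def rmsep(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root mean squared error of prediction."""
    y, y_hat = _check_pair(y, y_hat)
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def mape(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean absolute percentage error (in percent); every y must be nonzero."""
    y, y_hat = _check_pair(y, y_hat)
    if np.any(y == 0):
        raise ValueError("MAPE undefined: reference vector contains zeros")
    return float(100.0 * np.mean(np.abs((y - y_hat) / y)))


def press(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Predicted residual sum of squares over the supplied evaluation set."""
    y, y_hat = _check_pair(y, y_hat)
    return float(np.sum((y - y_hat) ** 2))


def aic_bic(residuals: np.ndarray, p: int) -> tuple[float, float]:
    """Akaike and Bayesian information criteria from evaluation residuals.

    With ``sigma2 = sum(residuals^2) / N`` (maximum-likelihood variance):
    ``AIC = N ln(sigma2) + 2 p`` and ``BIC = N ln(sigma2) + p ln(N)``,
    where ``p`` counts every estimated parameter including the intercept.
    Smaller values indicate better parsimony.
    """
    residuals = np.asarray(residuals, dtype=float).ravel()
    N = residuals.shape[0]
    if N < 1:
        raise ValueError("residual vector must be non-empty")
    if p < 1:
        raise ValueError("p must be a positive integer")
    ssr = float(np.sum(residuals**2))
    if ssr == 0.0:
        raise ValueError(
            "zero residual sum of squares: information criteria undefined "
            "for an exact fit"
        )
    sigma2 = ssr / N
    aic = N * np.log(sigma2) + 2 * p
    bic = N * np.log(sigma2) + p * np.log(N)
    return float(aic), float(bic)


def evaluate_subset(
    dataset: CalibrationDataset,
    split: DataSplit,
    selected: Sequence[int],
    eval_split: str = "validation",
) -> ModelFit:
    """Fit a subset model on the calibration set and score it on a split.

    The MLR model uses only the ``selected`` columns, is fitted on the
    calibration rows, and all five metrics (RMSEP, MAPE, PRESS, AIC,
    BIC) are computed on the rows of ``eval_split`` with
    ``p = |selected| + 1`` parameters and ``N`` equal to that split's
    size.  A pure function of its inputs: equal inputs yield an equal
    :class:`ModelFit`.
    """
    selected = tuple(sorted(int(i) for i in selected))
    if len(selected) == 0:
        raise ValueError("selected variable set must be non-empty")
    if selected[0] < 0 or selected[-1] >= dataset.n_variables:
        raise ValueError("selected indices out of range")
    cal = list(split.calibration_idx)
    if len(cal) < 2:
        raise ValueError("calibration set must contain at least 2 samples")
    ev = list(split.indices_for(eval_split))
    cols = list(selected)
    coef = fit_mlr(dataset.X[np.ix_(cal, cols)], dataset.y[cal])
    y_ev = dataset.y[ev]
    y_hat = predict(coef, dataset.X[np.ix_(ev, cols)])
    residuals = y_ev - y_hat
    if np.sum(residuals**2) == 0.0:
        # exact fit: information criteria diverge to -inf; keep the model
        # usable instead of failing the whole search on a degenerate case
        aic, bic = -np.inf, -np.inf
    else:
        aic, bic = aic_bic(residuals, p=len(selected) + 1)
    metrics = {
        "rmsep": rmsep(y_ev, y_hat),
        "mape": mape(y_ev, y_hat),
        "press": press(y_ev, y_hat),
        "aic": aic,
        "bic": bic,
    }
    return ModelFit(
        selected=selected, coefficients=coef, metrics=metrics, eval_split=eval_split
    )
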