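"""Spectral preprocessing, representative sample splitting and noise injection.

Three standard chemometric steps surround the variable-selection search:

* Savitzky-Golay first-derivative filtering removes baseline offsets
  from raw spectra before any modelling;
* Kennard-Stone max-min selection partitions samples into calibration,
  validation and prediction sets that each cover the spectral space;
* zero-mean white Gaussian noise injection, scaled per column to a
  fraction of that column's standard deviation, probes the robustness
  of a fitted model to measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "DataSplit",
    "savgol_first_derivative",
    "kennard_stone_split",
    "inject_noise",
]


@dataclass(frozen=True)
class DataSplit:
    """Disjoint calibration/validation/prediction index sets over samples."""

    calibration_idx: tuple[int, ...]
    validation_idx: tuple[int, ...]
    prediction_idx: tuple[int, ...]

    def __post_init__(self) -> None:
        cal = tuple(int(i) for i in self.calibration_idx)
        val = tuple(int(i) for i in self.validation_idx)
        pred = tuple(int(i) for i in self.prediction_idx)
        object.__setattr__(self, "calibration_idx", cal)
        object.__setattr__(self, "validation_idx", val)
        object.__setattr__(self, "prediction_idx", pred)
        for name, idx in (
            ("calibration", cal),
            ("validation", val),
            ("prediction", pred),
        ):
            if len(idx) == 0:
                raise ValueError(f"{name} set must be non-empty")
            if any(i < 0 for i in idx):
                raise ValueError(f"{name} set contains negative indices")
        all_idx = cal + val + pred
        if len(set(all_idx)) != len(all_idx):
            raise ValueError("split sets must be pairwise disjoint")

    def indices_for(self, which: str) -> tuple[int, ...]:
        try:
            return getattr(self, f"{which}_idx")
        except AttributeError:
            raise ValueError(f"unknown split set {which!r}") from None


def savgol_first_derivative(
    X: np.ndarray, window: int = 11, poly_order: int = 2
) -> np.ndarray:
    """Per-row Savitzky-Golay first derivative with edge points dropped.

    Each spectrum (row) is filtered with a local polynomial of degree
    ``poly_order`` over ``window`` points and differentiated once at unit
    channel spacing.  The ``(window - 1) / 2`` points at each edge, where
    the centred window does not fit, are dropped rather than padded, so
    the output has ``n_variables - (window - 1)`` columns.  The filter is
    exact on polynomial rows up to degree ``poly_order``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window <= poly_order:
        raise ValueError(
            f"window ({window}) must exceed poly_order ({poly_order})"
        )
    if window > X.shape[1]:
        raise ValueError(
            f"window ({window}) exceeds spectrum length ({X.shape[1]})"
        )
    half = (window - 1) // 2
    D = savgol_filter(X, window, poly_order, deriv=1, delta=1.0, axis=1)
    return D[:, half: X.shape[1] - half].copy()


def _max_distance_pair(D: np.ndarray) -> tuple[int, int]:
    # lexicographically smallest (i, j), i < j, among maximal-distance pairs
    n = D.shape[0]
    masked = D.copy()
    masked[np.tril_indices(n)] = -np.inf
    flat = int(np.argmax(masked))
    return flat // n, flat % n


def kennard_stone_split(
    X: np.ndarray, sizes: tuple[int, int, int]
) -> DataSplit:
    """Kennard-Stone calibration/validation/prediction split.

    The calibration set is grown first by the max-min Euclidean rule:
    initialise with the two most mutually distant samples, then
    repeatedly add the sample whose minimum distance to the already
    selected ones is largest.  The validation set is grown by the same
    rule over the remaining samples, then the prediction set.  Samples
    beyond ``sum(sizes)`` are left unassigned.  Ties are broken by the
    lowest sample index, so the split is deterministic.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    sizes = tuple(int(s) for s in sizes)
    if len(sizes) != 3:
        raise ValueError("sizes must be a (calibration, validation, prediction) triple")
    if any(s < 1 for s in sizes):
        raise ValueError("each split size must be >= 1")
    if sizes[0] < 2:
        raise ValueError("calibration size must be >= 2")
    if sum(sizes) > n:
        raise ValueError(
            f"split sizes {sizes} exceed the {n} available samples"
        )
    D = squareform(pdist(X))

    remaining = np.arange(n)
    sets: list[tuple[int, ...]] = []
    for size in sizes:
        chosen = _ks_select(D, remaining, size)
        sets.append(tuple(int(i) for i in chosen))
        keep = ~np.isin(remaining, chosen)
        remaining = remaining[keep]
    return DataSplit(*sets)


def _ks_select(D: np.ndarray, pool: np.ndarray, k: int) -> np.ndarray:
    """Select k of `pool` by the Kennard-Stone max-min rule (ties: lowest index)."""
    pool = np.asarray(pool)
    m = len(pool)
    if k > m:
        raise ValueError("cannot select more samples than available")
    sub = D[np.ix_(pool, pool)]
    if m == 1:
        return pool[:1]
    i, j = _max_distance_pair(sub)
    if k == 1:
        # degenerate request: keep the lower-index endpoint of the extreme pair
        return pool[[min(i, j)]]
    selected = [i, j]
    mindist = np.minimum(sub[i], sub[j])
    mindist[selected] = -np.inf
    while len(selected) < k:
        nxt = int(np.argmax(mindist))  # first occurrence = lowest index
        selected.append(nxt)
        mindist = np.minimum(mindist, sub[nxt])
        mindist[nxt] = -np.inf
    return pool[np.array(selected)]


def inject_noise(
    X: np.ndarray, factor: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Add per-column white Gaussian noise scaled to the column spread.

    Column ``j`` of the returned matrix is ``X[:, j]`` plus i.i.d.
    zero-mean Gaussian noise with standard deviation
    ``factor * sd(X[:, j])``, where ``sd`` is the sample standard
    deviation (n-1 denominator).  The input is not modified.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.isfinite(factor) or factor < 0:
        raise ValueError("noise factor must be finite and >= 0")
    if factor == 0:
        return X.copy()
    if X.shape[0] < 2:
        raise ValueError("column standard deviation undefined for a single row")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    col_sd = X.std(axis=0, ddof=1)
    E = rng.standard_normal(X.shape) * (factor * col_sd)
    return X + E
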