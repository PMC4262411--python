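"""Reading and writing of calibration data, run configurations and results.

Conventions used throughout the package:

* samples are rows, variables (wavelength channels) are columns;
* variable indices are 0-based internally and 1-based in every
  human-facing report, matching the numbering chemometric papers use
  when listing selected wavelengths;
* delimited text (CSV by default) is the only supported matrix format;
* results are JSON records with a schema ``version`` field.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CalibrationDataset",
    "RunConfig",
    "read_matrix",
    "write_matrix",
    "assemble_dataset",
    "write_result",
    "load_result",
    "get_logger",
]

RESULT_SCHEMA_VERSION = 1

logger = logging.getLogger("ffavarsel")


def get_logger() -> logging.Logger:
    """Package-wide logger (handlers are attached by the CLI)."""
    return logger


@dataclass(frozen=True)
class CalibrationDataset:
    """An X/y pair for multivariate calibration.

    Parameters
    ----------
    X : ndarray, shape (n_samples, n_variables)
        Instrument responses, e.g. NIR absorbance or derivative spectra.
    y : ndarray, shape (n_samples,)
        Property of interest, e.g. % protein.
    wavelengths : ndarray, optional
        Strictly increasing wavelength axis (nm), one per variable.
    sample_ids : sequence of str, optional
        One identifier per sample.
    """

    X: np.ndarray
    y: np.ndarray
    wavelengths: np.ndarray | None = None
    sample_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float).ravel()
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {X.shape}")
        if X.shape[0] != y.shape[0]:
            raise ValueError(
                f"X has {X.shape[0]} rows but y has {y.shape[0]} entries"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite entries")
        if not np.all(np.isfinite(y)):
            raise ValueError("y contains non-finite entries")
        if self.wavelengths is not None:
            w = np.asarray(self.wavelengths, dtype=float).ravel()
            object.__setattr__(self, "wavelengths", w)
            if w.shape[0] != X.shape[1]:
                raise ValueError(
                    f"wavelength axis has {w.shape[0]} entries for "
                    f"{X.shape[1]} variables"
                )
            if not np.all(np.diff(w) > 0):
                raise ValueError("wavelengths must be strictly increasing")
        if self.sample_ids is not None:
            ids = tuple(str(s) for s in self.sample_ids)
            object.__setattr__(self, "sample_ids", ids)
            if len(ids) != X.shape[0]:
                raise ValueError("sample_ids length must equal n_samples")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_variables(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one firefly-search run.

    ``alpha`` scales the uniform random walk, ``beta0`` the attractiveness
    at distance zero and ``gamma`` the light-absorption rate; ``threshold``
    is the cut above which a position component selects its variable.
    ``split_sizes`` are the Kennard-Stone calibration/validation/prediction
    sizes; ``objective_set`` names the split on which the search objective
    (prediction error) is evaluated.
    """

    n_fireflies: int = 250
    max_iterations: int = 100
    alpha: float = 0.2
    beta0: float = 1.0
    gamma: float = 1.0
    threshold: float = 0.5
    seed: int = 0
    split_sizes: tuple[int, int, int] = (389, 193, 193)
    objective_set: str = "validation"

    def __post_init__(self) -> None:
        if self.n_fireflies < 2:
            raise ValueError("n_fireflies must be >= 2 (pairwise dynamics)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be a positive integer")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.beta0 <= 0:
            raise ValueError("beta0 must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        sizes = tuple(int(s) for s in self.split_sizes)
        object.__setattr__(self, "split_sizes", sizes)
        if len(sizes) != 3 or any(s < 1 for s in sizes):
            raise ValueError("split_sizes must be three positive integers")
        if self.objective_set not in ("validation", "prediction"):
            raise ValueError("objective_set must be 'validation' or 'prediction'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["split_sizes"] = list(self.split_sizes)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in d.items() if k in known}
        if "split_sizes" in kwargs:
            kwargs["split_sizes"] = tuple(kwargs["split_sizes"])
        return cls(**kwargs)


def read_matrix(path: str | Path, delimiter: str = ",") -> np.ndarray:
    """Read a delimited-text numeric matrix.

    Every row must have the same number of numeric fields.  Errors name
    the offending line (1-based) so malformed files are easy to fix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    rows: list[list[float]] = []
    width: int | None = None
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(delimiter)
            try:
                row = [float(tok) for tok in fields]
            except ValueError as exc:
                raise ValueError(
                    f"{path}, line {lineno}: non-numeric token ({exc})"
                ) from None
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise ValueError(
                    f"{path}, line {lineno}: ragged row "
                    f"({len(row)} fields, expected {width})"
                )
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: empty matrix file")
    M = np.asarray(rows, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError(f"{path}: matrix contains non-finite entries")
    logger.info("read %d x %d matrix from %s", M.shape[0], M.shape[1], path)
    return M


def write_matrix(M: np.ndarray, path: str | Path, delimiter: str = ",") -> None:
    """Write a numeric matrix as delimited text at full double precision."""
    M = np.atleast_2d(np.asarray(M, dtype=float))
    with open(path, "w") as fh:
        for row in M:
            fh.write(delimiter.join(format(v, ".17g") for v in row))
            fh.write("\n")


def assemble_dataset(
    X: np.ndarray,
    y: np.ndarray,
    wavelengths: np.ndarray | None = None,
    sample_ids: Sequence[str] | None = None,
) -> CalibrationDataset:
    """Validate and bundle X/y (plus optional axes) into a dataset.

    Any invariant violation (shape mismatch, non-finite entry,
    non-monotone wavelength axis) raises ``ValueError``.
    """
    return CalibrationDataset(
        X=np.asarray(X, dtype=float),
        y=np.asarray(y, dtype=float),
        wavelengths=wavelengths,
        sample_ids=tuple(sample_ids) if sample_ids is not None else None,
    )


def _fit_to_record(fit) -> dict:
    # late import: regression depends on nothing here, avoid cycle at module load
    if len(fit.selected) < 1:
        raise ValueError("cannot serialize a model with no selected variables")
    return {
        "selected_variables": [int(i) + 1 for i in fit.selected],  # 1-based report
        "coefficients": [float(c) for c in fit.coefficients],
        "rmsep": float(fit.metrics["rmsep"]),
        "mape": float(fit.metrics["mape"]),
        "press": float(fit.metrics["press"]),
        "aic": float(fit.metrics["aic"]),
        "bic": float(fit.metrics["bic"]),
        "n_selected": len(fit.selected),
        "eval_split": fit.eval_split,
    }


def write_result(
    fit,
    path: str | Path,
    config: RunConfig | None = None,
    extra: Mapping | None = None,
) -> None:
    """Serialize a fitted model to a JSON result record.

    The record reports variable indices 1-based, echoes the run
    configuration and seed, and is loadable back to an equal
    ``ModelFit`` via :func:`load_result`.
    """
    record = {"version": RESULT_SCHEMA_VERSION}
    record.update(_fit_to_record(fit))
    if config is not None:
        record["config"] = config.to_dict()
        record["seed"] = config.seed
    if extra:
        for k, v in extra.items():
            record[k] = v
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("wrote result record to %s", path)


def load_result(path: str | Path):
    """Load a result record written by :func:`write_result` into a ModelFit."""
    from .regression import ModelFit

    with open(path) as fh:
        record = json.load(fh)
    selected = tuple(int(i) - 1 for i in record["selected_variables"])
    metrics = {k: float(record[k]) for k in ("rmsep", "mape", "press", "aic", "bic")}
    return ModelFit(
        selected=selected,
        coefficients=np.asarray(record["coefficients"], dtype=float),
        metrics=metrics,
        eval_split=record.get("eval_split", "prediction"),
    )
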