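"""Model/Results interface for firefly-based variable selection.

:class:`FireflyMLR` bundles a calibration dataset, a sample split and a
run configuration; its :meth:`~FireflyMLR.fit` runs the multiobjective
firefly search and returns a :class:`FireflyMLRResults` carrying the
selected variables, regression coefficients, the metric suite on the
prediction set, the final Pareto front and the per-iteration trace.

Example
-------
>>> from ffavarsel import FireflyMLR, synthetic
>>> data, spec = synthetic.scenario("five_var", seed=0)
>>> model = FireflyMLR(data, n_fireflies=100, max_iterations=50, seed=0)
>>> res = model.fit()
>>> res.selected_1based          # doctest: +SKIP
(23, 33, 41)
>>> print(res.summary())         # doctest: +SKIP
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .dataio import CalibrationDataset, RunConfig, assemble_dataset
from .firefly import FAState, run_fa_mlr
from .moo import ObjectiveVector
from .preprocess import DataSplit, kennard_stone_split
from .regression import ModelFit

__all__ = ["FireflyMLR", "FireflyMLRResults"]


class FireflyMLR:
    """Multiobjective firefly variable selection over an MLR calibration model.

    Parameters
    ----------
    dataset : CalibrationDataset
        The X/y calibration data (use :func:`FireflyMLR.from_arrays` or
        :func:`FireflyMLR.from_dataframe` for raw inputs).
    split : DataSplit, optional
        Calibration/validation/prediction partition.  When omitted, a
        Kennard-Stone split with the configured ``split_sizes`` is
        computed from ``dataset.X``.
    **config
        :class:`~ffavarsel.dataio.RunConfig` fields (``n_fireflies``,
        ``max_iterations``, ``alpha``, ``beta0``, ``gamma``,
        ``threshold``, ``seed``, ``split_sizes``, ``objective_set``).
    """

    def __init__(
        self,
        dataset: CalibrationDataset,
        split: DataSplit | None = None,
        **config,
    ) -> None:
        self.dataset = dataset
        if "split_sizes" not in config and split is None:
            config["split_sizes"] = _default_split_sizes(dataset.n_samples)
        self.config = RunConfig(**config)
        if split is None:
            split = kennard_stone_split(dataset.X, self.config.split_sizes)
        self.split = split

    @classmethod
    def from_arrays(
        cls,
        X: np.ndarray,
        y: np.ndarray,
        wavelengths: np.ndarray | None = None,
        split: DataSplit | None = None,
        **config,
    ) -> "FireflyMLR":
        return cls(assemble_dataset(X, y, wavelengths), split=split, **config)

    @classmethod
    def from_dataframe(
        cls,
        df,
        response: str,
        features: Sequence[str] | None = None,
        split: DataSplit | None = None,
        **config,
    ) -> "FireflyMLR":
        """Build from a pandas DataFrame: one response column, the rest features."""
        if features is None:
            features = [c for c in df.columns if c != response]
        X = df.loc[:, list(features)].to_numpy(dtype=float)
        y = df.loc[:, response].to_numpy(dtype=float)
        return cls(
            assemble_dataset(X, y, sample_ids=[str(i) for i in df.index]),
            split=split,
            **config,
        )

    def fit(self) -> "FireflyMLRResults":
        """Run the firefly search and return the results object."""
        best, state = run_fa_mlr(self.dataset, self.split, self.config)
        return FireflyMLRResults(self, best, state)


def _default_split_sizes(n: int) -> tuple[int, int, int]:
    """Roughly 2:1:1 calibration/validation/prediction covering all samples."""
    cal = max(2, n - 2 * (n // 4))
    val = max(1, n // 4)
    pred = max(1, n - cal - val)
    return (cal, val, pred)


class FireflyMLRResults:
    """Results of a firefly variable-selection run.

    Attributes
    ----------
    fit : ModelFit
        The decision-maker's choice re-evaluated on the prediction set.
    state : FAState
        Final search state (population, archive, per-iteration trace).
    """

    def __init__(self, model: FireflyMLR, fit: ModelFit, state: FAState) -> None:
        self.model = model
        self.fit = fit
        self.state = state

    # -- estimates -----------------------------------------------------
    @property
    def params(self) -> np.ndarray:
        """Regression coefficients, intercept first."""
        return self.fit.coefficients

    @property
    def selected(self) -> tuple[int, ...]:
        """Selected variable indices (0-based)."""
        return self.fit.selected

    @property
    def selected_1based(self) -> tuple[int, ...]:
        return self.fit.selected_1based

    @property
    def n_selected(self) -> int:
        return self.fit.n_selected

    @property
    def metrics(self) -> dict:
        """RMSEP, MAPE, PRESS, AIC, BIC on the prediction set."""
        return dict(self.fit.metrics)

    @property
    def front(self) -> list[tuple[ObjectiveVector, tuple[int, ...]]]:
        """Final non-dominated archive as (objectives, 0-based variables)."""
        return [
            (obj, tuple(int(i) for i in np.flatnonzero(mask)))
            for obj, mask in self.state.archive
        ]

    @property
    def trace(self) -> list[dict]:
        """Per-iteration log: mean error, archive size, best point."""
        return list(self.state.trace)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict the property of interest for new full-width spectra."""
        from .regression import predict

        X = np.atleast_2d(np.asarray(X, dtype=float))
        return predict(self.fit.coefficients, X[:, list(self.fit.selected)])

    def summary(self) -> str:
        """Plain-text summary table in the spirit of statsmodels results."""
        cfg = self.model.config
        m = self.fit.metrics
        lines = [
            "Firefly variable selection (FA-MLR) results",
            "=" * 54,
            f"{'samples':<28}{self.model.dataset.n_samples:>26}",
            f"{'candidate variables':<28}{self.model.dataset.n_variables:>26}",
            f"{'fireflies / iterations':<28}"
            f"{f'{cfg.n_fireflies} / {cfg.max_iterations}':>26}",
            f"{'alpha, beta0, gamma':<28}"
            f"{f'{cfg.alpha}, {cfg.beta0}, {cfg.gamma}':>26}",
            f"{'seed':<28}{cfg.seed:>26}",
            f"{'objective split':<28}{cfg.objective_set:>26}",
            f"{'regression evaluations':<28}{self.state.n_evaluations:>26}",
            f"{'archive (front) size':<28}{len(self.state.archive):>26}",
            "-" * 54,
            f"{'selected variables (1-based)':<28}"
            f"{', '.join(map(str, self.selected_1based)):>26}",
            f"{'n selected':<28}{self.n_selected:>26}",
            "-" * 54,
            "metrics on the prediction set",
            f"{'  RMSEP':<28}{m['rmsep']:>26.6g}",
            f"{'  MAPE (%)':<28}{m['mape']:>26.6g}",
            f"{'  PRESS':<28}{m['press']:>26.6g}",
            f"{'  AIC':<28}{m['aic']:>26.6g}",
            f"{'  BIC':<28}{m['bic']:>26.6g}",
            "-" * 54,
            "coefficients (intercept first)",
        ]
        names = ["const"] + [f"x{i}" for i in self.selected_1based]
        for name, c in zip(names, self.fit.coefficients):
            lines.append(f"{'  ' + name:<28}{c:>26.6g}")
        return "\n".join(lines)

    def save(self, path, extra=None) -> None:
        """Write the JSON result record (see :func:`ffavarsel.dataio.write_result`)."""
        from .dataio import write_result

        payload = {
            "front": [
                {"error": obj.error, "n_vars": obj.n_vars,
                 "variables": [i + 1 for i in vars_]}
                for obj, vars_ in self.front
            ],
            "trace": self.trace,
            "split": {
                "calibration": [i + 1 for i in self.model.split.calibration_idx],
                "validation": [i + 1 for i in self.model.split.validation_idx],
                "prediction": [i + 1 for i in self.model.split.prediction_idx],
            },
        }
        if extra:
            payload.update(extra)
        write_result(self.fit, path, config=self.model.config, extra=payload)
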