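"""Calibration of the Y1 feature against analyte concentration.

The assay's standard curve maps the four-line feature value Y1 to
concentration with epsilon-insensitive support-vector regression (RBF
kernel).  The objective is the usual soft-margin trade-off

    min_{w,b,xi}  ||w||^2 / 2 + C_penalty * sum_i xi_i

with the penalty chosen, together with the kernel width gamma and the tube
half-width epsilon, by exhaustive deterministic grid search minimizing the
training residual sum of squares.  Concentrations span 0-1500 ug/mL, so the
regression target is log10(1 + c) and predictions are back-transformed
(and clipped at zero) before any statistic is computed; goodness of fit

    R^2 = 1 - SS_res / SS_tot,   SS_tot = sum (y_i - ybar)^2,
                                 SS_res = sum (y_i - f_i)^2

is therefore always reported on the original concentration scale.

The module follows the statsmodels idiom: :class:`CalibrationModel` holds
the data and grid, ``fit()`` returns a :class:`CalibrationResults` carrying
the chosen hyperparameters, fit statistics, prediction and a ``summary()``
table.  ``fit_calibration`` / ``predict_concentration`` are thin functional
wrappers over the same objects.
"""

from __future__ import annotations

import io
import itertools
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .exceptions import DegenerateResponseError, InsufficientCalibrationDataError

__all__ = [
    "CalibrationPair",
    "GridConfig",
    "FitStatistics",
    "BandScheme",
    "CalibrationModel",
    "CalibrationResults",
    "fit_calibration",
    "goodness_of_fit",
    "predict_concentration",
    "evaluate_accuracy",
    "load_pairs",
    "reference_pairs",
]

logger = logging.getLogger(__name__)

MIN_PAIRS = 5
MIN_DISTINCT_CONCENTRATIONS = 3


@dataclass(frozen=True)
class CalibrationPair:
    """One (feature value, concentration) calibration sample."""

    y1: float
    concentration: float

    def __post_init__(self) -> None:
        if self.y1 < 0 or self.concentration < 0:
            raise ValueError("y1 and concentration must be >= 0")


@dataclass(frozen=True)
class GridConfig:
    """Deterministic SVR hyperparameter grid (RBF kernel).

    ``svm_penalty`` is the soft-margin penalty (named to avoid clashing
    with the control-line signal C).  Combinations are searched in fixed
    product order; ties on training SS_res keep the first combination.
    """

    svm_penalty: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0)
    gamma: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    epsilon: tuple[float, ...] = (0.001, 0.01, 0.1)

    def combinations(self):
        return itertools.product(self.svm_penalty, self.gamma, self.epsilon)


@dataclass(frozen=True)
class FitStatistics:
    """R-squared and its sum-of-squares decomposition, original scale."""

    r2: float
    ss_tot: float
    ss_res: float
    residuals: np.ndarray


@dataclass(frozen=True)
class BandScheme:
    """Concentration strata for accuracy scoring (ug/mL).

    A prediction counts as correct when its relative error is at most
    ``tolerance``; a zero truth is scored on absolute error against
    ``tolerance`` times the low band's upper edge.
    """

    low: tuple[float, float] = (0.0, 50.0)
    medium: tuple[float, float] = (80.0, 500.0)
    high: tuple[float, float] = (800.0, 1500.0)
    tolerance: float = 0.20

    def __post_init__(self) -> None:
        bands = [self.low, self.medium, self.high]
        for (a, b), (c, d) in zip(bands, bands[1:]):
            if not a <= b < c <= d:
                raise ValueError("bands must be disjoint and ordered")

    def band_of(self, concentration: float) -> str:
        for name in ("low", "medium", "high"):
            lo, hi = getattr(self, name)
            if lo <= concentration <= hi:
                return name
        # Outside every band: assign by the nearest band edge.
        logger.warning("concentration %.3g outside all bands; assigning nearest", concentration)
        edges = []
        for name in ("low", "medium", "high"):
            lo, hi = getattr(self, name)
            edges.append((min(abs(concentration - lo), abs(concentration - hi)), name))
        return min(edges)[1]


def goodness_of_fit(y, f) -> FitStatistics:
    """Exact sum-of-squares R-squared of fitted values ``f`` against ``y``.

    Raises :class:`DegenerateResponseError` when all ``y`` are identical
    (SS_tot = 0, R-squared undefined).
    """
    y = np.asarray(y, dtype=np.float64)
    f = np.asarray(f, dtype=np.float64)
    if y.shape != f.shape or y.ndim != 1:
        raise ValueError("y and f must be 1-D arrays of equal length")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    residuals = y - f
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateResponseError("degenerate response: SS_tot = 0")
    return FitStatistics(r2=1.0 - ss_res / ss_tot, ss_tot=ss_tot, ss_res=ss_res,
                         residuals=residuals)


def _forward(c: np.ndarray) -> np.ndarray:
    return np.log10(1.0 + c)


def _backward(t: np.ndarray) -> np.ndarray:
    return np.clip(10.0**t - 1.0, 0.0, None)


class CalibrationModel:
    """SVR standard-curve model for (Y1, concentration) pairs.

    Parameters
    ----------
    y1, concentration
        Training samples; at least five pairs spanning at least three
        distinct concentrations.
    grid
        Hyperparameter grid searched at ``fit()`` time.
    """

    def __init__(self, y1, concentration, grid: GridConfig | None = None):
        y1 = np.asarray(y1, dtype=np.float64).ravel()
        conc = np.asarray(concentration, dtype=np.float64).ravel()
        if y1.shape != conc.shape:
            raise ValueError("y1 and concentration must have equal length")
        if y1.size < MIN_PAIRS or np.unique(conc).size < MIN_DISTINCT_CONCENTRATIONS:
            raise InsufficientCalibrationDataError(
                f"insufficient calibration data: need >= {MIN_PAIRS} pairs spanning "
                f">= {MIN_DISTINCT_CONCENTRATIONS} distinct concentrations "
                f"(got {y1.size} pairs, {np.unique(conc).size} distinct)"
            )
        if (y1 < 0).any() or (conc < 0).any():
            raise ValueError("y1 and concentration must be >= 0")
        self.y1 = y1
        self.concentration = conc
        self.grid = grid if grid is not None else GridConfig()

    @classmethod
    def from_pairs(cls, pairs, grid: GridConfig | None = None) -> "CalibrationModel":
        return cls([p.y1 for p in pairs], [p.concentration for p in pairs], grid=grid)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, grid: GridConfig | None = None) -> "CalibrationModel":
        return cls(df["y1"], df["concentration_ug_ml"], grid=grid)

    @classmethod
    def from_csv(cls, path, grid: GridConfig | None = None) -> "CalibrationModel":
        return cls.from_dataframe(pd.read_csv(path), grid=grid)

    def _fit_one(self, penalty: float, gamma: float, epsilon: float) -> SVR:
        svr = SVR(kernel="rbf", C=penalty, gamma=gamma, epsilon=epsilon)
        svr.fit(self.y1[:, None], _forward(self.concentration))
        return svr

    def fit(self) -> "CalibrationResults":
        """Grid-search the SVR and return results with training statistics."""
        best = None
        for penalty, gamma, epsilon in self.grid.combinations():
            svr = self._fit_one(penalty, gamma, epsilon)
            fitted = _backward(svr.predict(self.y1[:, None]))
            ss_res = float(np.sum((self.concentration - fitted) ** 2))
            if best is None or ss_res < best[0]:
                best = (ss_res, (penalty, gamma, epsilon), svr)
        ss_res, hyperparams, svr = best
        stats = goodness_of_fit(self.concentration,
                                _backward(svr.predict(self.y1[:, None])))
        logger.info(
            "calibration fit: penalty=%g gamma=%g epsilon=%g R2=%.5f",
            *hyperparams, stats.r2,
        )
        return CalibrationResults(model=self, hyperparams=hyperparams, svr=svr,
                                  stats=stats)


@dataclass
class CalibrationResults:
    """A fitted standard curve: hyperparameters, statistics, prediction."""

    model: CalibrationModel
    hyperparams: tuple[float, float, float]
    svr: SVR
    stats: FitStatistics

    @property
    def svm_penalty(self) -> float:
        return self.hyperparams[0]

    @property
    def gamma(self) -> float:
        return self.hyperparams[1]

    @property
    def epsilon(self) -> float:
        return self.hyperparams[2]

    def predict(self, y1) -> np.ndarray:
        """Back-transformed concentration prediction, clipped below at zero."""
        y1 = np.atleast_1d(np.asarray(y1, dtype=np.float64))
        return _backward(self.svr.predict(y1[:, None]))

    def summary(self) -> str:
        n = self.model.y1.size
        lines = [
            "SVR calibration (RBF kernel, target log10(1 + c))",
            "=" * 52,
            f"n pairs               {n:>10d}",
            f"distinct conc.        {np.unique(self.model.concentration).size:>10d}",
            f"svm_penalty           {self.svm_penalty:>10g}",
            f"gamma                 {self.gamma:>10g}",
            f"epsilon               {self.epsilon:>10g}",
            f"support vectors       {len(self.svr.support_):>10d}",
            f"SS_tot                {self.stats.ss_tot:>10.4g}",
            f"SS_res                {self.stats.ss_res:>10.4g}",
            f"R-squared             {self.stats.r2:>10.5f}",
            "=" * 52,
        ]
        return "\n".join(lines)

    # --- serialization -------------------------------------------------
    # The training pairs plus the chosen hyperparameters determine the SVR
    # exactly (libsvm is deterministic), so persisting them and refitting on
    # load reproduces predictions bit-identically.

    def to_json(self) -> str:
        return json.dumps(
            {
                "kernel": "rbf",
                "transform": "log10_1p",
                "svm_penalty": self.svm_penalty,
                "gamma": self.gamma,
                "epsilon": self.epsilon,
                "y1": self.model.y1.tolist(),
                "concentration": self.model.concentration.tolist(),
                "r2": self.stats.r2,
                "ss_tot": self.stats.ss_tot,
                "ss_res": self.stats.ss_res,
            },
            indent=2,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "CalibrationResults":
        obj = json.loads(text)
        model = CalibrationModel(obj["y1"], obj["concentration"])
        hyper = (obj["svm_penalty"], obj["gamma"], obj["epsilon"])
        svr = model._fit_one(*hyper)
        stats = goodness_of_fit(model.concentration,
                                _backward(svr.predict(model.y1[:, None])))
        return cls(model=model, hyperparams=hyper, svr=svr, stats=stats)

    @classmethod
    def load(cls, path) -> "CalibrationResults":
        with open(path) as fh:
            return cls.from_json(fh.read())


def fit_calibration(pairs, config: GridConfig | None = None) -> CalibrationResults:
    """Fit the standard curve to CalibrationPair samples (see CalibrationModel)."""
    return CalibrationModel.from_pairs(pairs, grid=config).fit()


def predict_concentration(results: CalibrationResults, y1: float) -> float:
    """Concentration (ug/mL) predicted for one feature value."""
    if not isinstance(results, CalibrationResults):
        raise TypeError("predict_concentration requires a fitted CalibrationResults")
    return float(results.predict(y1)[0])


def evaluate_accuracy(predictions, truths, scheme: BandScheme | None = None) -> dict:
    """Band-level and total accuracy (%) of predicted concentrations.

    A prediction is correct when ``|pred - truth| / truth <= tolerance``;
    zero truths use ``|pred| <= tolerance * low_band_upper`` instead.
    Returns ``{"low": ..., "medium": ..., "high": ..., "total": ...}`` with
    percentages (NaN for bands with no samples).
    """
    if scheme is None:
        scheme = BandScheme()
    predictions = np.asarray(predictions, dtype=np.float64)
    truths = np.asarray(truths, dtype=np.float64)
    if predictions.shape != truths.shape:
        raise ValueError("predictions and truths must have equal length")
    correct = {"low": 0, "medium": 0, "high": 0}
    counts = {"low": 0, "medium": 0, "high": 0}
    n_correct = 0
    for pred, truth in zip(predictions, truths):
        band = scheme.band_of(truth)
        counts[band] += 1
        if truth == 0:
            ok = abs(pred) <= scheme.tolerance * scheme.low[1]
        else:
            ok = abs(pred - truth) / truth <= scheme.tolerance
        correct[band] += ok
        n_correct += ok
    out = {
        band: (100.0 * correct[band] / counts[band] if counts[band] else float("nan"))
        for band in counts
    }
    out["total"] = 100.0 * n_correct / truths.size if truths.size else float("nan")
    return out


def load_pairs(path) -> list[CalibrationPair]:
    """Read calibration pairs from CSV (columns y1, concentration_ug_ml)."""
    df = pd.read_csv(path)
    return [CalibrationPair(float(r.y1), float(r.concentration_ug_ml))
            for r in df.itertuples()]


def reference_pairs() -> list[CalibrationPair]:
    """The packaged reference calibration table: 5 replicate Y1 readings at
    each of 13 concentrations from 0 to 1500 ug/mL (65 pairs)."""
    from importlib.resources import files

    data = files("lfiaquant").joinpath("fixtures/table2.csv").read_text()
    return load_pairs(io.StringIO(data))
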