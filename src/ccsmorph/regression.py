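"""Bivariate cardiac-to-CCS inclination regressions.

Each conduction-component projection angle is modelled as an ordinary
linear function of the cardiac projection angle measured in the same body
plane, ``y = slope * x + intercept``, fitted by ordinary least squares on
raw (unwrapped) degree values.  The cohort angle ranges are narrow enough
that circular regression is unnecessary; the one angle family living near
the 0/360 seam (the horizontal sinus-node angle) is generated and fitted in
a contiguous branch around 272 degrees.

The module follows the statsmodels idiom: :class:`InclinationModel` is
built from an angle table (one row per heart) and its :meth:`fit` returns
an :class:`InclinationResults` carrying the eight fitted
:class:`RegressionModel` entries, a parameter table, ``summary()``, and
prediction/plotting helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .defaults import PAIR_IDS, PAIR_TO_CARDIAC
from .exceptions import DegenerateFitError, InvalidInputError, InvalidParamsError
from .frames import wrap_degrees

__all__ = [
    "RegressionModel",
    "fit_ols",
    "predict_ccs_angle",
    "fit_all_pairs",
    "InclinationModel",
    "InclinationResults",
    "RecoveryReport",
    "recover_parameters",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 at one decimal rounds to 0.1)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RegressionModel:
    """One fitted (or configured) cardiac-to-CCS angle regression.

    ``slope`` is in degrees per degree, ``intercept`` and ``residual_sd``
    in degrees.  ``n`` and ``r2`` are set when the model was fitted to data
    and None when it is a configured (published or generator) model.
    """

    pair_id: str
    slope: float
    intercept: float
    residual_sd: float
    n: Optional[int] = None
    r2: Optional[float] = None

    def __post_init__(self):
        if self.pair_id not in PAIR_TO_CARDIAC:
            raise InvalidParamsError(f"unknown pair_id {self.pair_id!r}")
        for name in ("slope", "intercept", "residual_sd"):
            if not np.isfinite(getattr(self, name)):
                raise InvalidParamsError(f"{name} must be finite")
        if self.residual_sd < 0:
            raise InvalidParamsError("residual_sd must be >= 0")
        if self.n is not None and self.n < 2:
            raise InvalidParamsError("a fitted model needs n >= 2")

    @property
    def cardiac_column(self) -> str:
        return PAIR_TO_CARDIAC[self.pair_id]

    def predict(self, x, wrap: bool = False):
        """Predicted CCS angle(s) at cardiac angle(s) ``x`` (degrees).

        Raw (unwrapped) by default because one published equation yields
        out-of-range raw values; pass ``wrap=True`` for [0, 360).
        """
        y = self.slope * np.asarray(x, dtype=float) + self.intercept
        if wrap:
            y = wrap_degrees(y)
        return float(y) if np.isscalar(x) else y


def fit_ols(x: Sequence[float], y: Sequence[float], pair_id: str = "alpha_sgt") -> RegressionModel:
    """Ordinary least squares fit of ``y = slope * x + intercept``.

    ``residual_sd`` is the root mean squared error on n - 2 degrees of
    freedom; the fitted line passes through (mean x, mean y) exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise InvalidInputError("need at least 3 points to fit")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidInputError("x and y must be finite")
    if np.ptp(x) < 1e-12:
        raise DegenerateFitError("constant x: slope is not identified")

    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = res.params
    sse = float(res.ssr)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst < 1e-30 else 1.0 - sse / sst
    return RegressionModel(
        pair_id=pair_id,
        slope=float(slope),
        intercept=float(intercept),
        residual_sd=float(np.sqrt(max(sse, 0.0) / (len(x) - 2))),
        n=len(x),
        r2=r2,
    )


def predict_ccs_angle(model: RegressionModel, x, wrap: bool = False):
    """Evaluate a regression model at cardiac angle(s) ``x`` (degrees)."""
    return model.predict(x, wrap=wrap)


def fit_all_pairs(
    angle_table: pd.DataFrame, pairs: Iterable[str] = PAIR_IDS
) -> dict[str, RegressionModel]:
    """Fit every cardiac-to-CCS pair present in an angle table.

    The pairing is fixed: sagittal/frontal/horizontal SN and proximal-AVCA
    angles against the cardiac angle of the same plane, and the two
    bundle-branch angles against the horizontal cardiac angle only.
    """
    models: dict[str, RegressionModel] = {}
    for pair in pairs:
        xcol = PAIR_TO_CARDIAC[pair]
        for col in (xcol, pair):
            if col not in angle_table.columns:
                raise InvalidInputError(f"angle table is missing column {col!r}")
        sub = angle_table[[xcol, pair]].dropna()
        models[pair] = fit_ols(sub[xcol].to_numpy(), sub[pair].to_numpy(), pair_id=pair)
    return models


def models_to_frame(models: Mapping[str, RegressionModel]) -> pd.DataFrame:
    """Tabulate regression models (one row per pair)."""
    rows = [
        {
            "pair_id": m.pair_id,
            "cardiac_angle": m.cardiac_column,
            "slope": m.slope,
            "intercept": m.intercept,
            "residual_sd": m.residual_sd,
            "r2": m.r2,
            "n": m.n,
        }
        for m in models.values()
    ]
    return pd.DataFrame(rows)


class InclinationModel:
    """Cardiac-to-CCS inclination regression model for one cohort.

    Parameters
    ----------
    angle_table
        One row per heart with the cardiac angle columns (``X_sgt``,
        ``X_frt``, ``X_hzt``) and the CCS angle columns; degrees.
    pairs
        Subset of pair ids to fit (default: all eight).
    """

    def __init__(self, angle_table: pd.DataFrame, pairs: Iterable[str] = PAIR_IDS):
        self.angle_table = angle_table.reset_index(drop=True)
        self.pairs = tuple(pairs)

    @classmethod
    def from_cohort(cls, params=None, **kwargs) -> "InclinationModel":
        """Build the model from a synthetic cohort's angle table."""
        from . import synth  # local import: synth depends on this module

        if params is None:
            params = synth.CohortParams.default(**kwargs)
        return cls(synth.sample_angle_table(params))

    def fit(self) -> "InclinationResults":
        return InclinationResults(self, fit_all_pairs(self.angle_table, self.pairs))


class InclinationResults:
    """Fitted inclination regressions with estimates and diagnostics."""

    def __init__(self, model: InclinationModel, models: dict[str, RegressionModel]):
        self.model = model
        self.models = models
        self.nobs = len(model.angle_table)

    @property
    def params(self) -> pd.DataFrame:
        return models_to_frame(self.models)

    def predict(self, pair_id: str, x, wrap: bool = False):
        return self.models[pair_id].predict(x, wrap=wrap)

    def summary(self) -> str:
        """Plain-text summary table of the eight fitted lines."""
        lines = [
            "Cardiac-to-CCS inclination regressions (OLS, degrees)",
            f"hearts: {self.nobs}",
            f"{'pair':<10}{'x':<7}{'slope':>9}{'intercept':>11}{'resid SD':>10}{'R^2':>7}{'n':>5}",
        ]
        for m in self.models.values():
            r2 = f"{m.r2:.3f}" if m.r2 is not None else "NA"
            lines.append(
                f"{m.pair_id:<10}{m.cardiac_column:<7}{m.slope:>9.4f}{m.intercept:>11.3f}"
                f"{m.residual_sd:>10.3f}{r2:>7}{m.n or 0:>5d}"
            )
        return "\n".join(lines)

    def plot_fits(self, pairs: Iterable[str] | None = None, axes=None):
        """Scatterplots with fitted lines, one panel per pair."""
        import matplotlib.pyplot as plt

        pairs = list(pairs or self.models)
        if axes is None:
            ncol = min(4, len(pairs))
            nrow = int(np.ceil(len(pairs) / ncol))
            _, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 3.0 * nrow), squeeze=False)
            axes = axes.ravel()
        tab = self.model.angle_table
        for ax, pair in zip(axes, pairs):
            m = self.models[pair]
            x = tab[m.cardiac_column].to_numpy()
            ax.scatter(x, tab[pair].to_numpy(), s=12, alpha=0.7)
            xs = np.linspace(x.min(), x.max(), 2)
            ax.plot(xs, m.predict(xs), "k-")
            ax.set_xlabel(m.cardiac_column + " (deg)")
            ax.set_ylabel(pair + " (deg)")
        return axes


@dataclass
class RecoveryReport:
    """Parameter-recovery summary over simulated cohorts.

    ``table`` has one row per pair with the generating (true) coefficients,
    mean estimates, bias, and RMSE; ``slope_estimates`` keeps the raw
    per-replicate slopes for Monte-Carlo error computations.
    """

    table: pd.DataFrame
    replicates: int
    n: int
    seed: int
    slope_estimates: pd.DataFrame

    def monte_carlo_se(self, pair_id: str) -> float:
        """Standard error of the mean slope estimate for one pair."""
        s = self.slope_estimates[pair_id].to_numpy()
        return float(s.std(ddof=1) / np.sqrt(len(s)))


def recover_parameters(
    params=None,
    replicates: int = 1000,
    seed: int = 0,
    n: int | None = None,
    pairs: Iterable[str] = PAIR_IDS,
) -> RecoveryReport:
    """Simulate-and-refit validation of the inclination regressions.

    Generates ``replicates`` synthetic cohorts from ``params`` (default:
    the published cohort conditions at n = 23), refits every pair by OLS,
    and reports the mean estimate, bias, and RMSE of each slope and
    intercept against the generating values.
    """
    from . import synth  # local import: synth depends on this module

    if replicates < 2:
        raise InvalidParamsError("need at least 2 replicates")
    if params is None:
        params = synth.CohortParams.default()
    if n is not None:
        params = replace(params, n=n)
    pairs = tuple(pairs)

    child_seeds = np.random.SeedSequence(seed).spawn(replicates)
    slopes = np.empty((replicates, len(pairs)))
    intercepts = np.empty((replicates, len(pairs)))
    for r, ss in enumerate(child_seeds):
        table = synth.sample_angle_table(params, seed_sequence=ss)
        fitted = fit_all_pairs(table, pairs)
        for j, pair in enumerate(pairs):
            slopes[r, j] = fitted[pair].slope
            intercepts[r, j] = fitted[pair].intercept

    rows = []
    for j, pair in enumerate(pairs):
        truth = params.regression_models[pair]
        rows.append(
            {
                "pair_id": pair,
                "true_slope": truth.slope,
                "true_intercept": truth.intercept,
                "mean_slope": slopes[:, j].mean(),
                "mean_intercept": intercepts[:, j].mean(),
                "slope_bias": slopes[:, j].mean() - truth.slope,
                "slope_rmse": float(np.sqrt(np.mean((slopes[:, j] - truth.slope) ** 2))),
                "intercept_bias": intercepts[:, j].mean() - truth.intercept,
                "intercept_rmse": float(
                    np.sqrt(np.mean((intercepts[:, j] - truth.intercept) ** 2))
                ),
                "replicates": replicates,
                "n": params.n,
                "seed": seed,
            }
        )
    return RecoveryReport(
        table=pd.DataFrame(rows),
        replicates=replicates,
        n=params.n,
        seed=seed,
        slope_estimates=pd.DataFrame(slopes, columns=pairs),
    )
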