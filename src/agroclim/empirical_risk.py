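"""Empirical animal-health risk: a climate-driven occurrence model and a
dairy temperature-humidity index.

The occurrence model relates observed presence/absence of a climate-driven
condition — the motivating case is pasture sporulation of
*Pseudopithomyces chartarum*, the fungus behind facial eczema in sheep —
to period (monthly) temperature and rainfall summaries through a logistic
regression.  The same machinery serves any binary climate-driven health
outcome (e.g. barber's-pole-worm risk) by swapping the covariate builder
and training records; there is no separate code path.

The model object follows the fit/results convention of statistical
modelling packages: build :class:`OccurrenceRiskModel` from a records
frame, call :meth:`~OccurrenceRiskModel.fit`, and read estimates,
standard errors and diagnostics off the returned
:class:`OccurrenceRiskResults` (whose ``summary()`` prints a coefficient
table).  Projection onto future climate series maps fitted coefficients
over per-period covariates and returns probabilities.

The heat-stress index is the familiar dairy THI
``0.8 T + (RH/100) (T - 14.4) + 46.4`` on daily mean temperature, with
exceedance counted against a configurable threshold (default 68, the
conventional onset of mild heat stress in dairy cattle).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .climate import DailyClimateSeries
from .errors import FitError, InputError

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("temp", "rain")
DEFAULT_THI_THRESHOLD = 68.0


# ----------------------------------------------------------------------
# covariates
# ----------------------------------------------------------------------
def monthly_covariates(
    series: DailyClimateSeries, slice_years: tuple[int, int] | None = None
) -> pd.DataFrame:
    """Per-month covariate frame: mean temperature (degC) and rainfall
    total (mm), one row per calendar month of the (optionally sliced)
    series."""
    if slice_years is not None:
        series = series.subset_years(*slice_years)
    df = series.data
    period = df.index.to_period("M")
    out = pd.DataFrame(
        {
            "temp": series.tmean.groupby(period).mean(),
            "rain": df["precip"].groupby(period).sum(),
        }
    )
    out.insert(0, "cell_id", series.cell_id)
    out.index.name = "period"
    return out.reset_index()


# ----------------------------------------------------------------------
# model / results
# ----------------------------------------------------------------------
class OccurrenceRiskModel:
    """Logistic occurrence model of a climate-driven risk.

    Parameters
    ----------
    records :
        Frame with an ``occurrence`` column (0/1, or counts which are
        reduced to exceedance > 0) and one column per covariate.
    covariates :
        Covariate column names; default ``("temp", "rain")``.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        covariates: Sequence[str] = DEFAULT_COVARIATES,
    ) -> None:
        covariates = tuple(covariates)
        missing = [c for c in ("occurrence", *covariates) if c not in records.columns]
        if missing:
            raise InputError(f"records missing columns: {', '.join(missing)}")
        if len(records) < 30:
            raise FitError(f"need >= 30 records, got {len(records)}")
        y = (records["occurrence"].to_numpy(float) > 0).astype(float)
        X = records[list(covariates)].to_numpy(float)
        if not np.all(np.isfinite(X)):
            raise InputError("covariates contain non-finite values")
        if y.min() == y.max():
            raise FitError("both outcome classes must be present "
                           f"(all occurrences are {int(y[0])})")
        self._check_separation(y, X, covariates)
        self.endog = y
        self.exog = sm.add_constant(X, prepend=True)
        self.covariate_names = covariates
        self.param_names = ("intercept", *covariates)
        #: training covariate ranges, used to flag extrapolation at projection
        self.training_range = {
            name: (float(X[:, j].min()), float(X[:, j].max()))
            for j, name in enumerate(covariates)
        }

    @classmethod
    def from_dataframe(cls, records: pd.DataFrame,
                       covariates: Sequence[str] = DEFAULT_COVARIATES):
        return cls(records, covariates)

    @staticmethod
    def _check_separation(y, X, names) -> None:
        for j, name in enumerate(names):
            x = X[:, j]
            if max(x[y == 0]) < min(x[y == 1]) or max(x[y == 1]) < min(x[y == 0]):
                raise FitError(
                    f"covariate {name!r} perfectly separates the outcomes"
                )

    def fit(self) -> "OccurrenceRiskResults":
        """Maximum-likelihood logistic fit (deterministic in the records)."""
        glm = sm.GLM(self.endog, self.exog, family=sm.families.Binomial())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", category=RuntimeWarning)
                res = glm.fit()
        except Exception as exc:  # pragma: no cover - degenerate designs
            raise FitError(f"logistic fit failed: {exc}") from exc
        if not np.all(np.isfinite(res.params)):
            raise FitError("logistic fit produced non-finite coefficients")
        return OccurrenceRiskResults(self, res)


@dataclass
class OccurrenceRiskResults:
    """Fitted coefficients, uncertainties and diagnostics."""

    model: OccurrenceRiskModel
    _res: "sm.GLM"  # statsmodels GLMResults

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._res.params, index=self.model.param_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self._res.bse, index=self.model.param_names)

    @property
    def deviance(self) -> float:
        return float(self._res.deviance)

    @property
    def llf(self) -> float:
        return float(self._res.llf)

    @property
    def nobs(self) -> int:
        return int(self._res.nobs)

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return self.model.covariate_names

    @property
    def training_range(self) -> dict[str, tuple[float, float]]:
        return self.model.training_range

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self._res.conf_int(alpha)
        return pd.DataFrame(ci, index=self.model.param_names,
                            columns=["lower", "upper"])

    def predict(self, covariates: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Occurrence probability for rows of covariate values."""
        return _logistic_predict(self.params, self.covariate_names, covariates)

    def summary(self) -> str:
        lines = [
            "Occurrence risk model (logistic)",
            f"  n = {self.nobs}, deviance = {self.deviance:.2f}, "
            f"log-likelihood = {self.llf:.2f}",
            f"  {'term':<12}{'coef':>10}{'std err':>10}",
        ]
        for name in self.model.param_names:
            lines.append(
                f"  {name:<12}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
            )
        return "\n".join(lines)


def _logistic_predict(params: pd.Series, covariate_names, covariates) -> np.ndarray:
    if isinstance(covariates, pd.DataFrame):
        X = covariates[list(covariate_names)].to_numpy(float)
    else:
        X = np.atleast_2d(np.asarray(covariates, float))
    eta = params.iloc[0] + X @ params.iloc[1:].to_numpy()
    return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class CoefficientBundle:
    """Serialisable fitted coefficients, sufficient for projection."""

    params: pd.Series  # intercept first, then one per covariate
    covariate_names: tuple[str, ...]
    training_range: dict[str, tuple[float, float]]

    def predict(self, covariates) -> np.ndarray:
        return _logistic_predict(self.params, self.covariate_names, covariates)


def save_coefficients(results, path) -> None:
    """Write fitted coefficients and training ranges as YAML."""
    import yaml

    doc = dict(
        link="logistic",
        params={k: float(v) for k, v in results.params.items()},
        covariates=list(results.covariate_names),
        training_range={
            k: [float(lo), float(hi)]
            for k, (lo, hi) in results.training_range.items()
        },
    )
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_coefficients(path) -> CoefficientBundle:
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    names = tuple(doc["covariates"])
    params = pd.Series(
        [doc["params"]["intercept"]] + [doc["params"][c] for c in names],
        index=("intercept", *names),
    )
    return CoefficientBundle(
        params=params,
        covariate_names=names,
        training_range={k: (v[0], v[1]) for k, v in doc["training_range"].items()},
    )


def fit_occurrence_model(
    records: pd.DataFrame, covariates: Sequence[str] = DEFAULT_COVARIATES
) -> OccurrenceRiskResults:
    """Convenience wrapper: build the model and fit in one call."""
    return OccurrenceRiskModel(records, covariates).fit()


# ----------------------------------------------------------------------
# projection
# ----------------------------------------------------------------------
def project_risk(
    results: "OccurrenceRiskResults | CoefficientBundle",
    series: DailyClimateSeries,
    slice_years: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-period occurrence probability for one cell under one climate.

    Covariates more than three training-range widths outside the training
    interval are flagged (``extrapolated`` column) and logged as a
    warning; the probability is still returned.
    """
    cov = monthly_covariates(series, slice_years)
    cov["risk"] = results.predict(cov)
    extrapolated = np.zeros(len(cov), dtype=bool)
    for name in results.covariate_names:
        lo, hi = results.training_range[name]
        width = max(hi - lo, 1e-12)
        x = cov[name].to_numpy(float)
        extrapolated |= (x < lo - 3 * width) | (x > hi + 3 * width)
    cov["extrapolated"] = extrapolated
    if extrapolated.any():
        logger.warning(
            "%d of %d periods extrapolate beyond 3x the training covariate "
            "range (cell %s)", int(extrapolated.sum()), len(cov), series.cell_id,
        )
    return cov


def simulate_occurrence_records(
    n: int,
    coefficients: Sequence[float],
    seed: int,
    temp_range: tuple[float, float] = (5.0, 25.0),
    rain_range: tuple[float, float] = (0.0, 300.0),
) -> pd.DataFrame:
    """Synthetic training records from known logistic coefficients
    ``(intercept, beta_temp, beta_rain)`` — the ground truth for
    parameter-recovery experiments."""
    b0, bt, br = coefficients
    rng = np.random.default_rng(seed)
    temp = rng.uniform(*temp_range, n)
    rain = rng.uniform(*rain_range, n)
    p = 1.0 / (1.0 + np.exp(-(b0 + bt * temp + br * rain)))
    occurrence = rng.random(n) < p
    return pd.DataFrame(
        {"occurrence": occurrence.astype(int), "temp": temp, "rain": rain}
    )


# ----------------------------------------------------------------------
# temperature-humidity index
# ----------------------------------------------------------------------
def thi(temp, rel_humidity):
    """Dairy temperature-humidity index from mean temperature (degC) and
    relative humidity (%)."""
    t = np.asarray(temp, float)
    rh = np.asarray(rel_humidity, float)
    out = 0.8 * t + rh / 100.0 * (t - 14.4) + 46.4
    return float(out) if out.ndim == 0 else out


def thi_series(
    series: DailyClimateSeries, threshold: float = DEFAULT_THI_THRESHOLD
) -> tuple[pd.DataFrame, pd.Series]:
    """Daily THI with exceedance flags, plus exceedance-day counts per
    calendar year."""
    values = thi(series.tmean.to_numpy(), series.data["rel_humidity"].to_numpy())
    daily = pd.DataFrame(
        {"thi": values, "exceedance": values > threshold}, index=series.data.index
    )
    annual = (
        daily["exceedance"].groupby(daily.index.year).sum().astype(int)
        .rename("exceedance_days")
    )
    annual.index.name = "year"
    return daily, annual
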