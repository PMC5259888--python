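"""Scikit-learn style estimators wrapping the prevalence-to-incidence model.

``IncidenceTrend`` is a minimal regressor (OLS of rate on calendar year
relative to a reference year) so trend fits compose with sklearn model
selection; ``PrevalenceToIncidence`` is the fit-shaped front end to the
whole pipeline: wave pairing, per-stratum estimation, direct
standardization, hospitalization adjustment and trend extraction, with
results exposed as fitted attributes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from . import core, standardize as stdz, trend as trend_mod
from .errors import ConfigurationError, TrendFitError

__all__ = ["IncidenceTrend", "PrevalenceToIncidence"]


class IncidenceTrend(RegressorMixin, BaseEstimator):
    """Ordinary least squares of incidence rates on calendar year.

    Parameters
    ----------
    reference_year : int, default 2000
        Year at which the intercept is evaluated; the regressor is
        ``year - reference_year``.

    Attributes
    ----------
    intercept_ : float
        Fitted rate at the reference year.
    slope_ : float
        Rate change per year.
    """

    def __init__(self, reference_year: int = 2000):
        self.reference_year = reference_year

    @staticmethod
    def _as_years(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be a single column of calendar years")
            X = X[:, 0]
        return X

    def fit(self, X, y):
        years = self._as_years(X)
        y = np.asarray(y, dtype=float)
        if years.shape[0] != y.shape[0]:
            raise ValueError("X and y have different lengths")
        if years.shape[0] < 3:
            raise TrendFitError("trend fit requires at least 3 points")
        if len(np.unique(years)) != years.shape[0]:
            raise TrendFitError("trend fit requires distinct years")
        x = years - float(self.reference_year)
        res = sm.OLS(y, sm.add_constant(x)).fit()
        self.intercept_ = float(res.params[0])
        self.slope_ = float(res.params[1])
        self.ols_result_ = res
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        years = self._as_years(X)
        return self.intercept_ + self.slope_ * (years - float(self.reference_year))

    def to_trend_fit(self) -> trend_mod.TrendFit:
        return trend_mod.TrendFit(
            intercept=self.intercept_,
            slope=self.slope_,
            reference_year=self.reference_year,
            n_points=int(self.ols_result_.nobs),
        )

    def annual_percent_decline(self) -> float:
        return trend_mod.annual_percent_decline(self.to_trend_fit())

    def percent_reduction(self, years: float) -> float:
        return trend_mod.percent_reduction(self.to_trend_fit(), years)


class PrevalenceToIncidence(BaseEstimator):
    """Estimate stratified and standardized incidence from survey waves.

    ``fit`` consumes a long-form prevalence table (one row per stratum per
    wave) and produces incidence estimates for every pair of consecutive
    waves, optionally standardized, adjusted to hospitalized events, and
    summarized by a linear trend.

    Parameters
    ----------
    survival : DataFrame or callable
        Survival table (``sex, age_lo, age_hi, SP, SN, T``), or a callable
        ``survival(year) -> DataFrame`` evaluated at each interval's start
        year (use this to apply a secular case-mortality decline).
    standard_population : StandardPopulation, optional
        Census structure for direct standardization.
    min_age : float, optional
        Restrict analysis (and the standard population) to ages >= min_age.
    ci_level : float or None, default 0.95
        Garwood CI level for strata with respondent counts.
    substitute_zeros : bool, default True
        Apply the zero-prevalence substitution rule per wave before pairing.
    adjustment : EventAdjustment, optional
        Fatal/silent fractions converting all-event to hospitalized rates.
    reference_year : int, default 2000
        Reference year for the trend fit.

    Attributes
    ----------
    estimates_ : DataFrame
        Per-stratum estimates for every wave pair.
    standardized_ : DataFrame
        One row per interval: full-precision and presentation (integer)
        standardized rates, negative-stratum counts, and adjusted rates
        when an adjustment is configured. Only when a standard population
        is supplied.
    trend_, adjusted_trend_ : TrendFit or None
        OLS on the presentation-integer rates, when >= 3 intervals exist.
    """

    def __init__(
        self,
        survival=None,
        standard_population=None,
        min_age=None,
        ci_level: float | None = 0.95,
        substitute_zeros: bool = True,
        adjustment=None,
        reference_year: int = 2000,
    ):
        self.survival = survival
        self.standard_population = standard_population
        self.min_age = min_age
        self.ci_level = ci_level
        self.substitute_zeros = substitute_zeros
        self.adjustment = adjustment
        self.reference_year = reference_year

    def _survival_for(self, year: int) -> pd.DataFrame:
        if self.survival is None:
            raise ConfigurationError("a survival table (or builder) is required")
        if callable(self.survival):
            return self.survival(year)
        return self.survival

    def fit(self, X: pd.DataFrame, y=None):
        required = {"sex", "age_lo", "age_hi", "wave_start_year", "p"}
        missing = required - set(X.columns)
        if missing:
            raise ConfigurationError(f"prevalence input lacks columns {sorted(missing)}")
        data = X.copy()
        if self.min_age is not None:
            data = data[data["age_lo"] >= self.min_age]
        wave_years = sorted(data["wave_start_year"].unique())
        if len(wave_years) < 2:
            raise ConfigurationError("need >= 2 survey waves to estimate incidence")

        waves = []
        for wy in wave_years:
            tab = data[data["wave_start_year"] == wy].reset_index(drop=True)
            if self.substitute_zeros:
                tab = stdz.substitute_zero_prevalence(tab)
            waves.append(tab)
        self.waves_ = waves
        self.n_waves_ = len(waves)

        std = self.standard_population
        if std is not None and self.min_age is not None:
            std = std.restrict(self.min_age)

        est_frames, std_rows = [], []
        for w0, wT in zip(waves, waves[1:]):
            label0 = w0["wave_label"].iloc[0] if "wave_label" in w0.columns else None
            y0 = core.wave_reference_year(int(w0["wave_start_year"].iloc[0]), label0)
            surv = self._survival_for(y0)
            if self.min_age is not None:
                surv = surv[surv["age_lo"] >= self.min_age]
            est = core.estimate_wave_pair(w0, wT, surv, ci_level=self.ci_level)
            est_frames.append(est)
            if std is not None:
                sr = stdz.direct_standardize(est, std)
                row = {
                    "interval_start_year": est["interval_start_year"].iloc[0],
                    "interval": est["interval"].iloc[0],
                    "rate_per_100k": sr.per_100k,
                    "rate": sr.rounded,
                    "n_negative_strata": sr.n_negative_strata,
                }
                if self.adjustment is not None:
                    adj = trend_mod.adjust_incidence(sr.per_100k, self.adjustment)
                    row["adjusted_per_100k"] = adj
                    row["adjusted"] = int(round(adj))
                std_rows.append(row)
        self.estimates_ = pd.concat(est_frames, ignore_index=True)
        self.standardized_ = pd.DataFrame(std_rows) if std_rows else None

        self.trend_ = self.adjusted_trend_ = None
        if self.standardized_ is not None and len(self.standardized_) >= 3:
            pts = list(
                zip(self.standardized_["interval_start_year"], self.standardized_["rate"])
            )
            self.trend_ = trend_mod.fit_trend(pts, self.reference_year)
            if self.adjustment is not None:
                pts = list(
                    zip(
                        self.standardized_["interval_start_year"],
                        self.standardized_["adjusted"],
                    )
                )
                self.adjusted_trend_ = trend_mod.fit_trend(pts, self.reference_year)
        return self
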