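"""Hospitalization adjustment and linear time-trend summaries.

An all-event incidence estimate from self-reported survey prevalence
captures fatal and silent events that hospital-discharge statistics never
see. With a fatal fraction f and a silent fraction s of all events, the
hospitalized share is (1 - f)(1 - s) (e.g. 0.30 and 0.20 give 0.56), and a
comparable hospitalized rate is the all-event rate times that product.

Trends over survey intervals are summarized by ordinary least squares of
the presented (integer, per-100,000) standardized rates on
``year - reference_year``; the fitted value at the reference year is the
intercept. Derived summaries: annual percent decline ``100*|slope|/intercept``
and the projected percent reduction over a horizon,
``100*years*|slope|/intercept`` (capped at 100).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, TrendFitError

__all__ = [
    "EventAdjustment",
    "TrendFit",
    "hospitalized_fraction",
    "adjust_incidence",
    "fit_trend",
    "annual_percent_decline",
    "percent_reduction",
]


@dataclass(frozen=True)
class EventAdjustment:
    """Fatal and silent fractions of all events, each in [0, 1)."""

    fatal_fraction: float
    silent_fraction: float

    def __post_init__(self):
        for name in ("fatal_fraction", "silent_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise DomainError(name, v, f"{name}={v!r} must lie in [0, 1)")


@dataclass(frozen=True)
class TrendFit:
    """An OLS line ``rate = intercept + slope * (year - reference_year)``."""

    intercept: float  # fitted rate per 100,000 at the reference year
    slope: float  # change per 100,000 per year
    reference_year: int = 2000
    n_points: int = 0

    def predict(self, year) -> np.ndarray:
        year = np.asarray(year, dtype=float)
        return self.intercept + self.slope * (year - self.reference_year)


def hospitalized_fraction(adj: EventAdjustment) -> float:
    """Share of all events that are hospitalized: ``(1-fatal)(1-silent)``."""
    return (1.0 - adj.fatal_fraction) * (1.0 - adj.silent_fraction)


def adjust_incidence(rate: float, adj: EventAdjustment) -> float:
    """Convert an all-event rate to a hospitalized-event rate.

    Full precision is returned; presentation rounds to integer per 100,000.
    """
    if not np.isfinite(rate):
        raise DomainError("rate", rate, f"rate={rate!r} must be finite")
    return rate * hospitalized_fraction(adj)


def fit_trend(
    points: Iterable[tuple[float, float]] | pd.DataFrame,
    reference_year: int = 2000,
) -> TrendFit:
    """OLS fit of rate on ``year - reference_year``.

    ``points`` is a sequence of ``(year, rate)`` pairs or a DataFrame with
    ``year`` and ``rate`` columns; at least 3 points with distinct years
    are required.
    """
    from .estimators import IncidenceTrend  # thin wrapper over the estimator

    if isinstance(points, pd.DataFrame):
        years = points["year"].to_numpy(dtype=float)
        rates = points["rate"].to_numpy(dtype=float)
    else:
        pts = list(points)
        years = np.array([p[0] for p in pts], dtype=float)
        rates = np.array([p[1] for p in pts], dtype=float)
    est = IncidenceTrend(reference_year=reference_year).fit(years, rates)
    return TrendFit(
        intercept=float(est.intercept_),
        slope=float(est.slope_),
        reference_year=reference_year,
        n_points=len(years),
    )


def _check_intercept(fit: TrendFit) -> None:
    if not fit.intercept > 0:
        raise TrendFitError(
            f"percent summaries need a positive fitted baseline rate; "
            f"intercept={fit.intercept!r}"
        )


def annual_percent_decline(fit: TrendFit) -> float:
    """``100 * |slope| / intercept``: percent change per year at baseline."""
    _check_intercept(fit)
    return 100.0 * abs(fit.slope) / fit.intercept


def percent_reduction(fit: TrendFit, years: float) -> float:
    """Projected percent reduction over ``years``, capped at 100."""
    _check_intercept(fit)
    if years < 0:
        raise DomainError("years", years, "projection horizon must be >= 0")
    return min(100.0, 100.0 * years * abs(fit.slope) / fit.intercept)
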