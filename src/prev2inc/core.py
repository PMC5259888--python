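"""Closed-form prevalence-to-incidence estimation for one survey interval.

The model treats an irreversible chronic condition in an open population
observed by two cross-sectional surveys a fixed interval ``T`` apart.
Within a sex × age stratum, let ``p0`` and ``pT`` be the prevalences at
the two surveys, ``SP`` the probability that a disease-positive person at
the first survey is alive at the second, and ``SN`` the same for a
disease-negative person. The whole-stratum survival (cohort-size factor)
is the mixture

    F = SP * p0 + SN * (1 - p0)

and the incidence rate (new cases per person-year among those at risk) is
estimated by

    I = 2 * (F * pT - SP * p0) / (T * (1 - p0 + F * (1 - pT)))

The numerator counts incident cases per first-survey respondent that are
still alive at the second survey; the denominator is twice the person-years
at risk per respondent, a trapezoid of the disease-negative fraction at the
two endpoints. Prevalence and mortality are assumed constant within the
interval. Confidence intervals treat the implied event count as Poisson
(exact Garwood limits), the survey as a simple random sample.

Negative estimates (a prevalence drop larger than mortality attrition can
explain) are reported raw with ``negative_flag`` set — never floored — so
that downstream standardization stays unbiased.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateStratumError,
    DomainError,
    NegativeRateError,
    StratumMismatchError,
)
from .strata import STRATUM_COLS, Stratum, keyed

__all__ = [
    "SurvivalPair",
    "IncidenceEstimate",
    "cohort_factor",
    "incidence",
    "poisson_ci",
    "estimate_wave_pair",
    "wave_reference_year",
    "interval_label",
]


def _check_proportion(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise DomainError(name, value, f"{name}={value!r} must lie in [0, 1]")
    return value


@dataclass(frozen=True)
class SurvivalPair:
    """Interval survival fractions for one stratum.

    SP: probability a disease-positive person at the first survey survives
        to the second; SN: the disease-negative analogue; T: interval length
        in years.
    """

    SP: float
    SN: float
    T: float = 2.0
    stratum: Stratum | None = None

    def __post_init__(self):
        _check_proportion("SP", self.SP)
        _check_proportion("SN", self.SN)
        if not self.T > 0:
            raise DomainError("T", self.T, f"T={self.T!r} must be positive")


@dataclass
class IncidenceEstimate:
    """A per-stratum incidence estimate over one inter-survey interval."""

    rate: float  # events per person-year (raw; may be negative)
    person_years_per_respondent: float
    negative_flag: bool
    stratum: Stratum | None = None
    interval_start: date | None = None
    interval_end: date | None = None
    implied_events: float | None = None
    ci_lo: float | None = None
    ci_hi: float | None = None
    extras: dict = field(default_factory=dict)


def cohort_factor(p0: float, surv: SurvivalPair) -> float:
    """Whole-stratum survival over the interval: ``SP*p0 + SN*(1-p0)``.

    Approximates the proportional cohort-size change between the two
    surveys; lies between min(SP, SN) and max(SP, SN).
    """
    p0 = _check_proportion("p0", p0)
    return 1.0 - (1.0 - surv.SP) * p0 - (1.0 - surv.SN) * (1.0 - p0)


def incidence(
    p0: float,
    pT: float,
    surv: SurvivalPair,
    *,
    stratum: Stratum | None = None,
    interval_start: date | None = None,
    interval_end: date | None = None,
) -> IncidenceEstimate:
    """Point estimate of the incidence rate from one pair of prevalences.

    Returns the raw rate (negative values preserved, ``negative_flag`` set
    exactly when ``F*pT < SP*p0``) and the person-years at risk per
    first-survey respondent, ``T*(1 - p0 + F*(1 - pT))/2``.

    Raises :class:`DegenerateStratumError` when the person-time denominator
    is not positive (e.g. universal prevalence at both surveys).
    """
    p0 = _check_proportion("p0", p0)
    pT = _check_proportion("pT", pT)
    F = cohort_factor(p0, surv)
    denom = surv.T * (1.0 - p0 + F * (1.0 - pT))
    if denom <= 0.0:
        raise DegenerateStratumError(
            f"non-positive person-time denominator ({denom!r}) for "
            f"p0={p0}, pT={pT}, SP={surv.SP}, SN={surv.SN}, T={surv.T}"
        )
    numer = F * pT - surv.SP * p0
    rate = 2.0 * numer / denom
    return IncidenceEstimate(
        rate=rate,
        person_years_per_respondent=denom / 2.0,
        negative_flag=bool(numer < 0.0),
        stratum=stratum,
        interval_start=interval_start,
        interval_end=interval_end,
        extras={"F": F, "p0": p0, "pT": pT, "SP": surv.SP, "SN": surv.SN, "T": surv.T},
    )


def poisson_ci(
    est: IncidenceEstimate, n: float, level: float = 0.95
) -> tuple[float, float]:
    """Exact (Garwood) Poisson limits for an incidence estimate.

    The implied event count is ``rate * n * person_years_per_respondent``
    with ``n`` the first-survey respondent count; the chi-square-based
    limits on that count are divided back by the person-years. The lower
    limit is 0 when the implied count is 0. Updates ``est`` in place
    (``implied_events``, ``ci_lo``, ``ci_hi``) and returns ``(lo, hi)``.
    """
    if not n > 0:
        raise DomainError("n", n, f"n={n!r} must be positive")
    if not 0.0 < level < 1.0:
        raise DomainError("level", level, f"level={level!r} must lie in (0, 1)")
    if est.rate < 0.0:
        raise NegativeRateError(
            "confidence interval undefined for a negative rate; inspect "
            "negative_flag before requesting a CI"
        )
    person_years = n * est.person_years_per_respondent
    events = est.rate * person_years
    alpha = 1.0 - level
    lo = 0.0 if events == 0.0 else stats.chi2.ppf(alpha / 2.0, 2.0 * events) / 2.0
    hi = stats.chi2.ppf(1.0 - alpha / 2.0, 2.0 * events + 2.0) / 2.0
    est.implied_events = events
    est.ci_lo = lo / person_years
    est.ci_hi = hi / person_years
    return est.ci_lo, est.ci_hi


_LABEL_YEARS = re.compile(r"(\d{4})")


def wave_reference_year(wave_start_year: int, wave_label: str | None = None) -> int:
    """Calendar year at which a survey wave's prevalence is referenced.

    A two-year wave label (``"1999–2000"``) dates the survey at January 1
    of its second year; a single-year label (``"2001"``) or no label dates
    it at January 1 of the start year. This is the labelling convention
    under which both the NHANES-style and CCHS-style printed trend fits are
    reproducible.
    """
    if wave_label:
        years = [int(y) for y in _LABEL_YEARS.findall(str(wave_label))]
        if len(years) >= 2:
            return years[-1]
        if len(years) == 1:
            return years[0]
    return int(wave_start_year)


def interval_label(ref0: int, refT: int, wave_span: int = 1) -> str:
    """Presentation label for the estimate interval [Jan 1 ref0, Jan 1 refT).

    Two-year waves label the interval by the calendar years it covers
    (``2000, 2002 -> "2000–2001"``); single-year waves label it endpoint to
    endpoint (``2001, 2003 -> "2001–2003"``), matching the conventions of
    the two source surveys.
    """
    if wave_span >= 2:
        return f"{ref0}–{refT - 1}"
    return f"{ref0}–{refT}"


def _wave_span(wave_label) -> int:
    if wave_label:
        years = [int(y) for y in _LABEL_YEARS.findall(str(wave_label))]
        if len(years) >= 2:
            return years[-1] - years[0] + 1
    return 1


def estimate_wave_pair(
    prev0: pd.DataFrame,
    prevT: pd.DataFrame,
    surv: pd.DataFrame,
    *,
    ci_level: float | None = 0.95,
) -> pd.DataFrame:
    """Per-stratum incidence estimates from two prevalence tables.

    Parameters
    ----------
    prev0, prevT
        Prevalence tables (columns ``sex, age_lo, age_hi, p`` plus optional
        ``n``, ``wave_start_year``, ``wave_label``) for the first and second
        survey. The three tables must share an identical stratum set.
    surv
        Survival table with columns ``sex, age_lo, age_hi, SP, SN, T``.
    ci_level
        Garwood CI level for strata with ``n`` available and a non-negative
        rate; ``None`` skips CIs.

    Returns
    -------
    DataFrame with one row per stratum: the inputs, the cohort factor
    ``F``, ``rate``, ``person_years_per_respondent``, ``implied_events``,
    ``ci_lo``/``ci_hi``, ``negative_flag`` and the interval attribution
    (``interval_start_year``, ``interval_end_year``, ``interval``).
    """
    k0, kT, ks = keyed(prev0), keyed(prevT), keyed(surv)
    for name, ktab in [("second prevalence table", kT), ("survival table", ks)]:
        missing = set(k0.index) - set(ktab.index)
        if missing:
            raise StratumMismatchError(
                {str(Stratum(*m)) for m in missing}, where=name
            )
    for name, ktab in [("first prevalence table", k0)]:
        extra = (set(kT.index) | set(ks.index)) - set(ktab.index)
        if extra:
            raise StratumMismatchError(
                {str(Stratum(*m)) for m in extra}, where=name
            )

    cols0 = k0.columns
    y0 = kT0 = None
    span = 1
    if "wave_start_year" in cols0 and "wave_start_year" in kT.columns and len(k0):
        span = _wave_span(k0["wave_label"].iloc[0] if "wave_label" in cols0 else None)
        y0 = wave_reference_year(
            int(k0["wave_start_year"].iloc[0]),
            k0["wave_label"].iloc[0] if "wave_label" in cols0 else None,
        )
        kT0 = wave_reference_year(
            int(kT["wave_start_year"].iloc[0]),
            kT["wave_label"].iloc[0] if "wave_label" in kT.columns else None,
        )

    rows = []
    for key in k0.index:
        sex, lo, hi = key
        r0, rT, rs = k0.loc[key], kT.loc[key], ks.loc[key]
        pair = SurvivalPair(
            SP=float(rs["SP"]), SN=float(rs["SN"]), T=float(rs["T"]),
            stratum=Stratum(sex, lo, hi),
        )
        est = incidence(float(r0["p"]), float(rT["p"]), pair)
        n = float(r0["n"]) if "n" in cols0 and pd.notna(r0.get("n")) else None
        if ci_level is not None and n is not None and est.rate >= 0.0:
            poisson_ci(est, n, ci_level)
        rows.append(
            {
                "sex": sex,
                "age_lo": lo,
                "age_hi": hi if math.isfinite(hi) else np.nan,
                "p0": est.extras["p0"],
                "pT": est.extras["pT"],
                "SP": pair.SP,
                "SN": pair.SN,
                "T": pair.T,
                "F": est.extras["F"],
                "rate": est.rate,
                "person_years_per_respondent": est.person_years_per_respondent,
                "n": n,
                "implied_events": est.implied_events,
                "ci_lo": est.ci_lo,
                "ci_hi": est.ci_hi,
                "negative_flag": est.negative_flag,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=STRATUM_COLS
        + [
            "p0", "pT", "SP", "SN", "T", "F", "rate",
            "person_years_per_respondent", "n", "implied_events",
            "ci_lo", "ci_hi", "negative_flag",
        ],
    )
    if y0 is not None:
        out["interval_start_year"] = y0
        out["interval_end_year"] = kT0
        out["interval"] = interval_label(y0, kT0, span)
    return out
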