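"""Build interval survival fractions SP and SN from mortality inputs.

For myocardial infarction the 2-year mortality of a prevalent case is
composed from in-hospital case fatality and post-discharge mortality,

    M_MI = M_MIin + (1 - M_MIin) * M_MIout,

equivalently 1 - M_MI = (1 - M_MIin)(1 - M_MIout), and SP_MI = 1 - M_MI.
A secular improvement in case survival is modelled as a constant
proportional decline per calendar year (default 3%/yr, from the acute-MI
survival literature), applied to the combined 2-year mortality:

    M(year) = M(baseline) * (1 - decline)^(year - baseline).

For a composite "heart disease" outcome (MI + angina + heart failure) the
positive-survival fraction mixes the component mortalities with prevalence
weights w that sum to 1:

    SP_HD = 1 - M_MI*w_MI - M_AG*w_AG - M_HF*w_HF.

Disease-negative survival comes from vital statistics as the complement of
background mortality net of the disease's own contribution:

    SN = 1 - (MV_all_cause - MV_disease),

where both terms must already be cumulative mortality proportions over the
inter-survey interval (the I/O layer is responsible for any rate-to-risk
conversion; this module refuses MV_disease > MV_all_cause rather than
clamping).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataConsistencyError, DomainError

__all__ = [
    "MortalityInputs",
    "mi_two_year_mortality",
    "decline_mortality",
    "sp_mi",
    "sp_heart_disease",
    "sn_from_vitals",
    "build_survival_table",
    "broadcast_sex_level",
]

_WEIGHT_TOL = 1e-9


def _check_prop(name, value):
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise DomainError(name, value, f"{name}={value!r} must lie in [0, 1]")
    return value


@dataclass(frozen=True)
class MortalityInputs:
    """Mortality components and mixture weights for one stratum.

    All M_* are cumulative mortality proportions over the survey interval;
    MV_* are vital-statistics mortality for the whole population
    (all-cause) and the disease (cause-specific), on the same cumulative
    scale. Weights are the prevalence shares of MI / angina / heart
    failure among the three and must sum to 1.
    """

    M_MIin: float
    M_MIout: float
    M_AG: float = 0.0
    M_HF: float = 0.0
    w_MI: float = 1.0
    w_AG: float = 0.0
    w_HF: float = 0.0
    MV_all_cause: float = 0.0
    MV_disease: float = 0.0
    baseline_year: int = 1999
    annual_decline: float = 0.03

    def __post_init__(self):
        for name in ("M_MIin", "M_MIout", "M_AG", "M_HF", "w_MI", "w_AG", "w_HF"):
            _check_prop(name, getattr(self, name))
        if abs(self.w_MI + self.w_AG + self.w_HF - 1.0) > _WEIGHT_TOL:
            raise ConfigurationError(
                f"component weights must sum to 1, got "
                f"{self.w_MI + self.w_AG + self.w_HF!r}"
            )
        if self.MV_disease > self.MV_all_cause:
            raise DataConsistencyError(
                f"cause-specific mortality ({self.MV_disease!r}) exceeds "
                f"all-cause mortality ({self.MV_all_cause!r})"
            )
        if not 0.0 <= self.annual_decline < 1.0:
            raise DomainError("annual_decline", self.annual_decline)


def mi_two_year_mortality(M_MIin: float, M_MIout: float) -> float:
    """Combined interval mortality: die in hospital, or survive and die after."""
    M_MIin = _check_prop("M_MIin", M_MIin)
    M_MIout = _check_prop("M_MIout", M_MIout)
    return M_MIin + (1.0 - M_MIin) * M_MIout


def decline_mortality(
    M_base: float, baseline_year: int, target_year: int, annual_decline: float = 0.03
) -> float:
    """Project case mortality forward with a constant proportional decline.

    No back-extrapolation: ``target_year`` must not precede ``baseline_year``.
    """
    M_base = _check_prop("M_base", M_base)
    if not 0.0 <= annual_decline < 1.0:
        raise DomainError("annual_decline", annual_decline)
    if target_year < baseline_year:
        raise DomainError(
            "target_year",
            target_year,
            f"target_year={target_year} precedes baseline_year={baseline_year}; "
            "back-extrapolation of the mortality decline is not supported",
        )
    return M_base * (1.0 - annual_decline) ** (target_year - baseline_year)


def sp_mi(M_MI: float) -> float:
    """Interval survival fraction of prevalent MI cases: ``1 - M_MI``."""
    return 1.0 - _check_prop("M_MI", M_MI)


def sp_heart_disease(inputs: MortalityInputs, *, target_year: int | None = None) -> float:
    """Positive-survival fraction for the composite heart-disease outcome.

    The MI component is composed via :func:`mi_two_year_mortality` (and
    projected to ``target_year`` when given); angina and heart-failure
    mortalities enter as supplied.
    """
    M_MI = mi_two_year_mortality(inputs.M_MIin, inputs.M_MIout)
    if target_year is not None:
        M_MI = decline_mortality(
            M_MI, inputs.baseline_year, target_year, inputs.annual_decline
        )
    return 1.0 - M_MI * inputs.w_MI - inputs.M_AG * inputs.w_AG - inputs.M_HF * inputs.w_HF


def sn_from_vitals(MV_all_cause: float, MV_disease: float, T: float = 2.0) -> float:
    """Negative-survival fraction from vital statistics.

    Both arguments must already be cumulative mortality proportions over
    the interval ``T``; the function is the complement of their difference.
    """
    if MV_disease > MV_all_cause:
        raise DataConsistencyError(
            f"cause-specific mortality ({MV_disease!r}) exceeds all-cause "
            f"mortality ({MV_all_cause!r}); refusing to clamp"
        )
    _check_prop("MV_all_cause", MV_all_cause)
    _check_prop("MV_disease", MV_disease)
    if not T > 0:
        raise DomainError("T", T)
    return 1.0 - (MV_all_cause - MV_disease)


def broadcast_sex_level(mortality: pd.DataFrame) -> pd.DataFrame:
    """Broadcast sex-only rows (NaN age_lo) across that sex's age bands.

    Case-fatality inputs are often published per sex only while vital
    statistics are per sex × age band; a row with missing ``age_lo`` donates
    its non-missing values to every aged row of the same sex.
    """
    if "age_lo" not in mortality.columns or mortality["age_lo"].notna().all():
        return mortality
    sexless = mortality[mortality["age_lo"].isna()]
    aged = mortality[mortality["age_lo"].notna()].copy()
    value_cols = [c for c in mortality.columns if c not in ("sex", "age_lo", "age_hi")]
    for _, donor in sexless.iterrows():
        mask = aged["sex"] == donor["sex"]
        for col in value_cols:
            if pd.notna(donor[col]):
                aged.loc[mask, col] = aged.loc[mask, col].where(
                    aged.loc[mask, col].notna(), float(donor[col])
                )
    return aged.reset_index(drop=True)


def build_survival_table(
    mortality: pd.DataFrame,
    *,
    T: float = 2.0,
    target_year: int | None = None,
    baseline_year: int = 1999,
    annual_decline: float = 0.03,
    weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Construct a per-stratum survival table (SP, SN, T) from mortality inputs.

    Parameters
    ----------
    mortality
        Columns ``sex, age_lo, age_hi, M_MIin, M_MIout, MV_all_cause,
        MV_disease`` and, for the composite outcome, ``M_AG, M_HF``.
        Sex-only rows (empty age_lo) are broadcast across age bands.
    T
        Inter-survey interval in years; MV_* and M_* must be cumulative
        over this interval.
    target_year
        Calendar year the SP applies to; the MI mortality component is
        projected from ``baseline_year`` by ``annual_decline`` per year.
    weights
        ``{"w_MI": ..., "w_AG": ..., "w_HF": ...}`` for the composite
        heart-disease outcome; omit for the single-disease (MI) outcome.
    """
    mort = broadcast_sex_level(mortality)
    w = {"w_MI": 1.0, "w_AG": 0.0, "w_HF": 0.0}
    if weights:
        w.update(weights)
    if abs(w["w_MI"] + w["w_AG"] + w["w_HF"] - 1.0) > _WEIGHT_TOL:
        raise ConfigurationError(
            f"component weights must sum to 1, got {sum(w.values())!r}"
        )
    rows = []
    for _, r in mort.iterrows():
        M_MI = mi_two_year_mortality(float(r["M_MIin"]), float(r["M_MIout"]))
        if target_year is not None:
            M_MI = decline_mortality(M_MI, baseline_year, target_year, annual_decline)
        M_AG = float(r.get("M_AG", 0.0) or 0.0)
        M_HF = float(r.get("M_HF", 0.0) or 0.0)
        SP = 1.0 - M_MI * w["w_MI"] - M_AG * w["w_AG"] - M_HF * w["w_HF"]
        SN = sn_from_vitals(float(r["MV_all_cause"]), float(r["MV_disease"]), T)
        rows.append(
            {
                "sex": r["sex"],
                "age_lo": float(r["age_lo"]),
                "age_hi": float(r["age_hi"]) if pd.notna(r["age_hi"]) else np.nan,
                "SP": SP,
                "SN": SN,
                "T": float(T),
            }
        )
    return pd.DataFrame(rows, columns=["sex", "age_lo", "age_hi", "SP", "SN", "T"])
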