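"""Bundled published incidence series used in examples and cross-checks.

These are small published national series (age-standardized rates per
100,000 person-years, by two-year survey interval) that exercise the
adjustment and trend operations without any large input data. They are
presentation-precision integers, which is exactly what the trend module is
specified to consume.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["us_mi_series", "canadian_hd_series"]


def us_mi_series() -> pd.DataFrame:
    """US myocardial-infarction incidence estimates, ages 35+, 2000–2011.

    Model-based estimates from serial national examination-survey
    prevalence, standardized to the US 2000 population. ``all_mi`` counts
    every event (including fatal and silent); ``hospitalized`` is the
    all-event rate scaled by the hospitalized share 0.56 (30% of events
    fatal, 20% silent) and rounded. ``year`` is the first calendar year of
    each two-year estimate interval.
    """
    return pd.DataFrame(
        {
            "year": [2000, 2002, 2004, 2006, 2008, 2010],
            "interval": [
                "2000–2001", "2002–2003", "2004–2005",
                "2006–2007", "2008–2009", "2010–2011",
            ],
            "all_mi": [843, 998, 546, 498, 543, 678],
            "hospitalized": [472, 559, 306, 279, 304, 380],
        }
    )


def canadian_hd_series() -> pd.DataFrame:
    """Canadian heart-disease incidence, ages 12+, 2001–2011.

    ``observed`` is the cohort (longitudinal survey) incidence with its 95%
    confidence limits; ``estimated_cohort_std`` is the model estimate
    standardized to the cohort's age structure (directly comparable to
    ``observed``); ``estimated_census_std`` is the same estimate
    standardized to the 2001 census population (comparable across years).
    ``year`` is the first calendar year of each two-year estimate interval.
    """
    return pd.DataFrame(
        {
            "year": [2001, 2003, 2005, 2007, 2009],
            "interval": [
                "2001–2003", "2003–2005", "2005–2007", "2007–2009", "2009–2011",
            ],
            "observed": [983, 1025, 1003, 1031, 1016],
            "observed_lo": [831, 845, 840, 852, 802],
            "observed_hi": [1136, 1204, 1165, 1209, 1230],
            "estimated_cohort_std": [1018, 888, 918, 1097, 1023],
            "estimated_census_std": [927, 779, 783, 873, 752],
        }
    )
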