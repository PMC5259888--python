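"""Stratum keys and stratified-table helpers.

Every table in this package is a pandas DataFrame keyed by sex and a
half-open age band ``[age_lo, age_hi)``; a missing (NaN) ``age_hi`` marks
the open-ended top band. Sex-specific five-year age groups are the smallest
analytic unit of the method, but the code accepts any non-overlapping
partition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParseError

#: key columns shared by every stratified table
STRATUM_COLS = ["sex", "age_lo", "age_hi"]


@dataclass(frozen=True, order=True)
class Stratum:
    """A sex × age-band key. ``age_hi`` is exclusive; ``inf`` = open-ended."""

    sex: str
    age_lo: float
    age_hi: float = math.inf

    def __post_init__(self):
        if not self.age_lo < self.age_hi:
            raise ValueError(
                f"age_lo ({self.age_lo}) must be < age_hi ({self.age_hi})"
            )

    def __str__(self) -> str:
        hi = "" if math.isinf(self.age_hi) else f"{self.age_hi:g}"
        return f"{self.sex}:{self.age_lo:g}-{hi}"


def stratum_index(df: pd.DataFrame) -> pd.MultiIndex:
    """MultiIndex of (sex, age_lo, age_hi) with open top bands as +inf."""
    hi = pd.to_numeric(df["age_hi"], errors="coerce").fillna(np.inf)
    return pd.MultiIndex.from_arrays(
        [df["sex"].astype(str), df["age_lo"].astype(float), hi.astype(float)],
        names=STRATUM_COLS,
    )


def strata_of(df: pd.DataFrame) -> set[Stratum]:
    return {Stratum(*key) for key in stratum_index(df)}


def keyed(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy indexed by the stratum MultiIndex, sorted."""
    out = df.copy()
    out.index = stratum_index(df)
    return out.sort_index()


def sort_table(df: pd.DataFrame) -> pd.DataFrame:
    """Sort by sex then age_lo, resetting the positional index."""
    return df.sort_values(["sex", "age_lo"], kind="stable").reset_index(drop=True)


def check_age_partition(df: pd.DataFrame, *, source: str = "table") -> None:
    """Verify bands within each sex do not overlap.

    Raises :class:`ParseError` naming the offending pair. Gaps are allowed
    (a study may restrict to e.g. ages 35+).
    """
    for sex, grp in df.groupby("sex", sort=False):
        bands = sorted(
            (float(lo), float(hi) if pd.notna(hi) else math.inf)
            for lo, hi in zip(grp["age_lo"], grp["age_hi"])
        )
        for (lo1, hi1), (lo2, hi2) in zip(bands, bands[1:]):
            if lo2 < hi1:
                raise ParseError(
                    f"{source}: overlapping age bands for sex={sex!r}: "
                    f"[{lo1:g}, {hi1:g}) and [{lo2:g}, {hi2:g})"
                )
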