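"""Direct age–sex standardization and the zero-prevalence substitution rule.

Direct standardization weights per-stratum rates by a fixed census
population's stratum shares, making rates comparable across surveys and
populations. Because young age groups of a rare chronic disease often show
zero sampled prevalence, a substitution rule borrows the first non-zero
prevalence from the next-older band of the same sex before estimation —
otherwise a structural zero at the first survey forces the stratum's
incidence to absorb all of the second survey's prevalence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, StratumMismatchError, ZeroPrevalenceWarning
from .strata import Stratum, check_age_partition, keyed

__all__ = [
    "StandardPopulation",
    "StandardizedRate",
    "substitute_zero_prevalence",
    "direct_standardize",
]


@dataclass(frozen=True)
class StandardPopulation:
    """A census age–sex structure used as the standardization reference."""

    table: pd.DataFrame  # columns: sex, age_lo, age_hi, count
    label: str = ""

    def __post_init__(self):
        tab = self.table
        if (tab["count"] < 0).any():
            raise ConfigurationError("standard-population counts must be >= 0")
        if not tab["count"].sum() > 0:
            raise ConfigurationError("standard population has zero total count")
        check_age_partition(tab, source=f"standard population {self.label!r}")

    def restrict(self, min_age: float | None) -> "StandardPopulation":
        """Truncate to bands with ``age_lo >= min_age`` (before weighting).

        ``min_age`` must fall on a band boundary; a cut strictly inside a
        band would silently mis-weight it.
        """
        if min_age is None:
            return self
        tab = self.table
        inside = (tab["age_lo"] < min_age) & (
            tab["age_hi"].fillna(np.inf) > min_age
        )
        if inside.any():
            bad = tab.loc[inside].iloc[0]
            raise ConfigurationError(
                f"min_age={min_age} falls inside band "
                f"[{bad['age_lo']:g}, {bad['age_hi']:g}) of the standard "
                "population; age filters must align with band edges"
            )
        kept = tab[tab["age_lo"] >= min_age].reset_index(drop=True)
        return StandardPopulation(kept, self.label)


@dataclass
class StandardizedRate:
    """A directly standardized rate with its presentation rounding.

    ``per_100k`` keeps full precision; ``rounded`` is the integer
    presentation value the trend module consumes. ``n_negative_strata``
    counts strata whose raw estimate was negative (they enter the weighted
    mean as-is).
    """

    per_100k: float
    n_negative_strata: int = 0
    n_strata: int = 0
    label: str = ""
    weights: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def rounded(self) -> int:
        return int(round(self.per_100k))

    def __float__(self) -> float:
        return float(self.per_100k)


def substitute_zero_prevalence(prev: pd.DataFrame) -> pd.DataFrame:
    """Replace zero prevalences in young bands with the next-older non-zero.

    Within each sex (ordered by age), a zero ``p`` takes the first non-zero
    value found scanning toward older bands; zeros older than the last
    non-zero band are left untouched. An all-zero sex group is returned
    unchanged with a :class:`ZeroPrevalenceWarning`.
    """
    out = prev.copy()
    for sex, grp in out.groupby("sex", sort=False):
        grp = grp.sort_values("age_lo")
        p = grp["p"].to_numpy(dtype=float)
        if not (p > 0).any():
            if len(p):
                warnings.warn(
                    f"all prevalences are zero for sex={sex!r}; "
                    "zero-substitution rule has no donor band",
                    ZeroPrevalenceWarning,
                    stacklevel=2,
                )
            continue
        # donor[i] = first non-zero at or above age index i
        donor = p.copy()
        for i in range(len(p) - 2, -1, -1):
            if donor[i] == 0.0:
                donor[i] = donor[i + 1]
        filled = np.where(p == 0.0, donor, p)
        out.loc[grp.index, "p"] = filled
    return out


def direct_standardize(
    rates: pd.DataFrame,
    std: StandardPopulation,
    *,
    min_age: float | None = None,
    label: str = "",
) -> StandardizedRate:
    """Directly standardized rate per 100,000 person-years.

    Every stratum of the (possibly age-restricted) standard population must
    have a matching row in ``rates`` (column ``rate``, events per
    person-year). Weights are the standard population's stratum shares
    after restriction; negative stratum estimates enter as-is and are
    counted in ``n_negative_strata``.
    """
    std = std.restrict(min_age)
    kstd = keyed(std.table)
    krates = keyed(rates)
    missing = set(kstd.index) - set(krates.index)
    if missing:
        raise StratumMismatchError(
            {str(Stratum(*m)) for m in missing}, where="rates table"
        )
    aligned = krates.loc[kstd.index]
    counts = kstd["count"].to_numpy(dtype=float)
    w = counts / counts.sum()
    r = aligned["rate"].to_numpy(dtype=float)
    value = float(np.dot(w, r)) * 1e5
    n_neg = (
        int(aligned["negative_flag"].sum())
        if "negative_flag" in aligned.columns
        else int((r < 0).sum())
    )
    weights = pd.DataFrame(
        [(s, lo, hi if math.isfinite(hi) else np.nan) for s, lo, hi in kstd.index],
        columns=["sex", "age_lo", "age_hi"],
    ).assign(count=counts, weight=w, rate=r)
    return StandardizedRate(
        per_100k=value,
        n_negative_strata=n_neg,
        n_strata=len(w),
        label=label or std.label,
        weights=weights,
    )
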