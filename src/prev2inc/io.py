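"""CSV/YAML readers and writers, run configuration, and the pipeline driver.

All file proportions are on the [0, 1] scale; per-100,000 scaling is
confined to reports. Age bands are half-open ``[age_lo, age_hi)`` with an
empty ``age_hi`` marking the open-ended top band. Validation errors cite
the file and the 1-based CSV row (header = row 1).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, ParseError
from .estimators import PrevalenceToIncidence
from .standardize import StandardPopulation
from .strata import check_age_partition, sort_table
from .survival import build_survival_table
from .trend import EventAdjustment, annual_percent_decline

logger = logging.getLogger("prev2inc")

_FLOAT_FMT = "%.12g"  # lossless round-trip at 12 significant digits


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        return pd.read_csv(path)
    except Exception as exc:  # malformed CSV structure
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")


def _numeric(df: pd.DataFrame, col: str, path, *, allow_na: bool = False) -> pd.Series:
    raw = df[col]
    vals = pd.to_numeric(raw, errors="coerce")
    bad = vals.isna() & raw.notna() if allow_na else vals.isna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ParseError(f"{path}: non-numeric value {raw[bad.idxmax()]!r} in column "
                         f"{col!r} at row {row}")
    return vals


def _check_range(vals: pd.Series, col: str, lo: float, hi: float, path) -> None:
    bad = vals.notna() & ((vals < lo) | (vals > hi))
    if bad.any():
        row = int(bad.idxmax()) + 2
        raise ParseError(
            f"{path}: {col}={vals[bad.idxmax()]!r} outside [{lo:g}, {hi:g}] at row {row}"
        )


def read_prevalence_table(path) -> pd.DataFrame:
    """Read and validate a per-stratum prevalence CSV.

    Required columns ``sex, age_lo, p``; optional ``age_hi`` (empty = open
    top band), ``n``, ``wave_start_year``, ``wave_label``. Returns a table
    sorted by sex then age, with range-checked proportions and
    non-overlapping bands.
    """
    df = _read_csv(path)
    _require_columns(df, ["sex", "age_lo", "p"], path)
    if "age_hi" not in df.columns:
        df["age_hi"] = np.nan
    df["age_lo"] = _numeric(df, "age_lo", path)
    df["age_hi"] = _numeric(df, "age_hi", path, allow_na=True)
    p = _numeric(df, "p", path)
    _check_range(p, "p", 0.0, 1.0, path)
    df["p"] = p
    if "n" in df.columns:
        n = _numeric(df, "n", path, allow_na=True)
        bad = n.notna() & (n <= 0)
        if bad.any():
            raise ParseError(
                f"{path}: n={n[bad.idxmax()]!r} must be > 0 at row {int(bad.idxmax()) + 2}"
            )
        df["n"] = n
    check_age_partition(df, source=str(path))
    return sort_table(df)


def read_survival_table(path) -> pd.DataFrame:
    """Read a survival CSV: ``sex, age_lo, age_hi, SP, SN, T``."""
    df = _read_csv(path)
    _require_columns(df, ["sex", "age_lo", "SP", "SN", "T"], path)
    if "age_hi" not in df.columns:
        df["age_hi"] = np.nan
    df["age_lo"] = _numeric(df, "age_lo", path)
    df["age_hi"] = _numeric(df, "age_hi", path, allow_na=True)
    for col in ("SP", "SN"):
        v = _numeric(df, col, path)
        _check_range(v, col, 0.0, 1.0, path)
        df[col] = v
    T = _numeric(df, "T", path)
    if (T <= 0).any():
        raise ParseError(f"{path}: T must be > 0")
    df["T"] = T
    check_age_partition(df, source=str(path))
    return sort_table(df)


def read_mortality_table(path) -> pd.DataFrame:
    """Read a mortality-components CSV.

    Columns ``sex, M_MIin, M_MIout, MV_all_cause, MV_disease`` plus
    optional ``age_lo, age_hi, M_AG, M_HF``; rows with empty ``age_lo`` are
    sex-level and broadcast later. All M_*/MV_* are cumulative proportions
    over the survey interval.
    """
    df = _read_csv(path)
    _require_columns(df, ["sex", "M_MIin", "M_MIout"], path)
    for col in ("age_lo", "age_hi"):
        if col not in df.columns:
            df[col] = np.nan
        df[col] = _numeric(df, col, path, allow_na=True)
    for col in ("M_MIin", "M_MIout", "M_AG", "M_HF", "MV_all_cause", "MV_disease"):
        if col in df.columns:
            v = _numeric(df, col, path, allow_na=True)
            _check_range(v, col, 0.0, 1.0, path)
            df[col] = v
    return df


def read_standard_population(path, label: str | None = None) -> StandardPopulation:
    """Read a standard-population CSV: ``sex, age_lo, age_hi, count``."""
    df = _read_csv(path)
    _require_columns(df, ["sex", "age_lo", "count"], path)
    if "age_hi" not in df.columns:
        df["age_hi"] = np.nan
    df["age_lo"] = _numeric(df, "age_lo", path)
    df["age_hi"] = _numeric(df, "age_hi", path, allow_na=True)
    df["count"] = _numeric(df, "count", path)
    return StandardPopulation(sort_table(df), label=label or Path(path).stem)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table CSV losslessly (12 significant digits)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


@dataclass
class RunConfig:
    """Configuration for a full estimation run."""

    prevalence_files: list = field(default_factory=list)
    survival_file: str | None = None
    mortality_file: str | None = None
    standard_population_file: str | None = None
    min_age: float | None = None
    ci_level: float = 0.95
    fatal_fraction: float | None = None
    silent_fraction: float | None = None
    output_dir: str = "prev2inc_out"
    reference_year: int = 2000
    baseline_year: int = 1999
    annual_decline: float = 0.03
    weights: dict | None = None
    T: float = 2.0
    log_level: str = "INFO"

    def __post_init__(self):
        if len(self.prevalence_files) < 2:
            raise ConfigurationError(
                "need >= 2 prevalence files (2 survey waves) for estimation"
            )
        if self.survival_file is None and self.mortality_file is None:
            raise ConfigurationError("either survival_file or mortality_file required")
        if (self.fatal_fraction is None) != (self.silent_fraction is None):
            raise ConfigurationError(
                "fatal_fraction and silent_fraction must be given together"
            )


def load_run_config(path, **overrides) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    doc.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**doc)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(
        {k: str(v) for k, v in vars(config).items()}, sort_keys=True
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_estimate(config: RunConfig) -> dict:
    """Run the full pipeline described by ``config`` and write results.

    Reads the wave prevalence tables in order, builds (or reads) the
    survival table, estimates per-stratum incidence for each consecutive
    wave pair, standardizes, adjusts, and fits the trend when at least
    three intervals exist. Writes ``estimates.csv``, ``standardized.csv``
    and ``summary.txt`` to the output directory and returns a report dict.
    """
    logger.setLevel(config.log_level.upper())
    logger.info("prev2inc %s run, config hash %s", __version__, _config_hash(config))
    for f in config.prevalence_files:
        logger.info("input prevalence: %s", f)

    waves = [read_prevalence_table(f) for f in config.prevalence_files]
    for i, w in enumerate(waves):
        if "wave_start_year" not in w.columns:
            raise ConfigurationError(
                f"{config.prevalence_files[i]}: wave_start_year column required "
                "for multi-wave estimation"
            )
    long = pd.concat(waves, ignore_index=True)

    if config.survival_file:
        survival = read_survival_table(config.survival_file)
    else:
        mort = read_mortality_table(config.mortality_file)

        def survival(year, _mort=mort):
            return build_survival_table(
                _mort,
                T=config.T,
                target_year=year,
                baseline_year=config.baseline_year,
                annual_decline=config.annual_decline,
                weights=config.weights,
            )

    std = (
        read_standard_population(config.standard_population_file)
        if config.standard_population_file
        else None
    )
    adjustment = (
        EventAdjustment(config.fatal_fraction, config.silent_fraction)
        if config.fatal_fraction is not None
        else None
    )

    model = PrevalenceToIncidence(
        survival=survival,
        standard_population=std,
        min_age=config.min_age,
        ci_level=config.ci_level,
        adjustment=adjustment,
        reference_year=config.reference_year,
    ).fit(long)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(model.estimates_, outdir / "estimates.csv")
    report = {
        "n_waves": model.n_waves_,
        "n_intervals": model.n_waves_ - 1,
        "estimates_file": str(outdir / "estimates.csv"),
    }
    lines = [
        f"prev2inc {__version__} estimation report",
        f"config hash: {_config_hash(config)}",
        f"waves: {model.n_waves_}  intervals: {model.n_waves_ - 1}",
    ]
    if model.standardized_ is not None:
        write_table(model.standardized_, outdir / "standardized.csv")
        report["standardized_file"] = str(outdir / "standardized.csv")
        report["standardized"] = model.standardized_.to_dict(orient="records")
        lines.append("")
        lines.append("standardized incidence per 100,000 person-years:")
        for _, r in model.standardized_.iterrows():
            extra = (
                f"  hospitalized {r['adjusted']:d}" if "adjusted" in r.index else ""
            )
            lines.append(
                f"  {r['interval']}: {r['rate']:d}"
                f" (negative strata: {r['n_negative_strata']:d}){extra}"
            )
    if model.trend_ is not None:
        t = model.trend_
        report["trend"] = {
            "intercept": t.intercept,
            "slope": t.slope,
            "reference_year": t.reference_year,
        }
        sign = "-" if t.slope < 0 else "+"
        lines.append("")
        lines.append(
            f"trend: rate = {t.intercept:.1f} {sign} {abs(t.slope):.1f}"
            f"*(year - {t.reference_year})"
        )
        if t.intercept > 0:
            lines.append(
                f"annual percent change: {annual_percent_decline(t):.1f}%"
            )
    if model.adjusted_trend_ is not None:
        t = model.adjusted_trend_
        report["adjusted_trend"] = {
            "intercept": t.intercept,
            "slope": t.slope,
            "reference_year": t.reference_year,
        }
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    report["summary_file"] = str(outdir / "summary.txt")
    logger.info("wrote %s", outdir)
    return report
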