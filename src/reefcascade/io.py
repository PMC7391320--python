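"""Reading, validation and writing of the package's CSV interchange tables.

Two inputs drive every analysis: ``surveys.csv`` (one row per transect-level
trophic-group total) and ``locations.csv`` (latitude, exploitation status and
reserve year per location).  All tables are UTF-8 CSV with a header row;
missing numeric values are empty fields.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd

from reefcascade.datamodel import (
    EXPLOITATION_STATUSES,
    LOCATION_COLUMNS,
    REGIONS,
    SURVEY_COLUMNS,
    TROPHIC_GROUPS,
    VALUE_KINDS,
    LocationMeta,
    SeriesCheck,
    ValidationReport,
)
from reefcascade.errors import FormatError, ReferenceError_, ValidationError

PathLike = Union[str, Path]

MIN_YEARS = 3
MIN_SURVEYS = 12


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} is missing column(s): {', '.join(missing)}")


def read_survey_table(path: PathLike) -> pd.DataFrame:
    """Read and validate a transect-level survey table.

    Returns a DataFrame with exactly the ``SURVEY_COLUMNS`` schema.  Every
    row is either parsed or reported: structural problems raise
    :class:`FormatError`, content problems raise :class:`ValidationError`
    listing the offending 1-based data row numbers.
    """
    df = pd.read_csv(path, dtype={"location_id": str, "site_id": str, "transect_id": str})
    _require_columns(df, SURVEY_COLUMNS, f"survey table {path}")
    df = df[SURVEY_COLUMNS].copy()
    return validate_survey_frame(df)


def validate_survey_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory survey frame against the row-level invariants."""
    _require_columns(df, SURVEY_COLUMNS, "survey frame")
    problems: list[str] = []

    def _bad(mask: pd.Series, why: str) -> None:
        if mask.any():
            rows = (np.flatnonzero(mask.to_numpy()) + 1)[:20]
            problems.append(f"{why} (rows {', '.join(map(str, rows))})")

    value = pd.to_numeric(df["value"], errors="coerce")
    year = pd.to_numeric(df["year"], errors="coerce")
    _bad(value.isna(), "non-numeric or missing value")
    _bad(value < 0, "negative value")
    _bad(year.isna() | (year != year.round()), "non-integer year")
    _bad(~df["region"].isin(REGIONS), "unknown region")
    _bad(~df["trophic_group"].isin(TROPHIC_GROUPS), "unknown trophic_group")
    _bad(~df["value_kind"].isin(VALUE_KINDS), "unknown value_kind")
    # Planar (tropical) cover cannot exceed 100%; 3-D temperate cover can.
    _bad(
        (df["region"] == "tropical")
        & (df["value_kind"] == "percent_cover")
        & (value > 100),
        "tropical percent cover > 100",
    )
    key = ["location_id", "site_id", "transect_id", "year", "trophic_group"]
    _bad(df.duplicated(subset=key, keep=False), "duplicate survey key")
    if problems:
        raise ValidationError("; ".join(problems))

    out = df.copy()
    out["year"] = year.astype(int)
    out["value"] = value.astype(float)
    return out


def write_survey_table(df: pd.DataFrame, path: PathLike) -> None:
    _require_columns(df, SURVEY_COLUMNS, "survey frame")
    df[SURVEY_COLUMNS].to_csv(path, index=False)


def read_location_table(path: PathLike) -> pd.DataFrame:
    """Read the location metadata table.

    ``reserve_start_year`` may be empty (non-reserve locations).  An optional
    ``analysis_start_year`` column is honoured if present; otherwise the
    start year is resolved as the reserve year for reserves and left
    unresolved for fished locations (see :func:`resolve_start_years`).
    """
    df = pd.read_csv(path, dtype={"location_id": str})
    _require_columns(df, LOCATION_COLUMNS, f"location table {path}")
    problems = []
    if df["location_id"].duplicated().any():
        problems.append("duplicate location_id")
    bad_status = ~df["exploitation_status"].isin(EXPLOITATION_STATUSES)
    if bad_status.any():
        problems.append(
            f"unknown exploitation_status: {sorted(df.loc[bad_status, 'exploitation_status'].unique())}"
        )
    lat = pd.to_numeric(df["latitude"], errors="coerce")
    if (lat.isna() | (lat.abs() > 90)).any():
        problems.append("latitude missing or outside [-90, 90]")
    reserve = df["exploitation_status"].isin(["early_reserve", "late_reserve"])
    if df.loc[reserve, "reserve_start_year"].isna().any():
        problems.append("reserve location missing reserve_start_year")
    if problems:
        raise ValidationError("; ".join(problems))
    df = df.copy()
    df["latitude"] = lat
    if "analysis_start_year" not in df.columns:
        df["analysis_start_year"] = np.nan
    return df


def write_location_table(
    df: pd.DataFrame, path: PathLike, include_extras: bool = False
) -> None:
    """Write ``locations.csv`` (exactly the four canonical columns).

    With ``include_extras=True`` any resolved ``analysis_start_year`` column
    is carried along too (useful when fished locations have matched start
    years that cannot be re-derived).
    """
    cols = list(LOCATION_COLUMNS)
    if include_extras and "analysis_start_year" in df.columns:
        cols.append("analysis_start_year")
    out = df[cols].copy()
    for col in ("reserve_start_year", "analysis_start_year"):
        if col in out.columns:
            out[col] = out[col].map(
                lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v)) else int(v)
            )
    out.to_csv(path, index=False)


def meta_frame_to_records(df: pd.DataFrame) -> dict[str, LocationMeta]:
    """Convert a metadata frame into typed :class:`LocationMeta` records."""

    def _opt_year(v) -> int | None:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return int(v)

    out = {}
    for row in df.itertuples(index=False):
        out[row.location_id] = LocationMeta(
            location_id=row.location_id,
            latitude=float(row.latitude),
            exploitation_status=row.exploitation_status,
            reserve_start_year=_opt_year(row.reserve_start_year),
            analysis_start_year=_opt_year(getattr(row, "analysis_start_year", None)),
        )
    return out


def resolve_start_years(meta: pd.DataFrame) -> pd.DataFrame:
    """Fill ``analysis_start_year`` where it is unset.

    Reserves start at their implementation year.  Fished locations keep any
    explicitly supplied matched start year (the matched geographic area's
    reserve year); without one, their full series is used.
    """
    out = meta.copy()
    if "analysis_start_year" not in out.columns:
        out["analysis_start_year"] = np.nan
    reserve = out["exploitation_status"].isin(["early_reserve", "late_reserve"])
    unresolved = out["analysis_start_year"].isna()
    out.loc[reserve & unresolved, "analysis_start_year"] = out.loc[
        reserve & unresolved, "reserve_start_year"
    ]
    return out


def validate_dataset(
    records: pd.DataFrame, meta: pd.DataFrame | Mapping[str, LocationMeta]
) -> ValidationReport:
    """Quality-control every location x trophic-group series.

    Flags series spanning fewer than three distinct years, series with fewer
    than twelve surveys (unique year x site combinations), constant-valued
    series (impossible to standardize), and uneven site sampling across
    years (which only restricts the AR-1 model).  Reports rather than
    excludes: the caller decides what to do with failures.
    """
    if records.empty:
        raise ValidationError("empty survey table")
    if isinstance(meta, Mapping):
        known = set(meta)
    else:
        known = set(meta["location_id"])
    missing = sorted(set(records["location_id"]) - known)
    if missing:
        raise ReferenceError_(
            f"locations absent from metadata: {', '.join(missing[:10])}"
        )

    report = ValidationReport()
    for (loc, group), sub in records.groupby(["location_id", "trophic_group"], sort=True):
        years = sub["year"].unique()
        n_years = len(years)
        n_surveys = len(sub[["year", "site_id"]].drop_duplicates())
        # Annual means across sites of site-year means; constant iff sd == 0.
        annual = (
            sub.groupby(["year", "site_id"])["value"].mean().groupby("year").mean()
        )
        constant = bool(np.isclose(annual.std(ddof=1), 0.0)) if n_years > 1 else True
        sites_per_year = sub.groupby("year")["site_id"].nunique()
        site_sets = sub.groupby("year")["site_id"].agg(frozenset)
        uneven = len(set(site_sets)) > 1 or sites_per_year.nunique() > 1
        report.checks.append(
            SeriesCheck(
                location_id=loc,
                trophic_group=group,
                n_years=n_years,
                n_surveys=n_surveys,
                too_short=n_years < MIN_YEARS,
                too_few_surveys=n_surveys < MIN_SURVEYS,
                constant=constant,
                uneven_sites=uneven,
            )
        )
    return report


def report_frame(report: ValidationReport) -> pd.DataFrame:
    """Tabular view of a :class:`ValidationReport`."""
    return pd.DataFrame(
        [
            {
                "location_id": c.location_id,
                "trophic_group": c.trophic_group,
                "n_years": c.n_years,
                "n_surveys": c.n_surveys,
                "too_short": c.too_short,
                "too_few_surveys": c.too_few_surveys,
                "constant": c.constant,
                "uneven_sites": c.uneven_sites,
                "passed": c.passed,
            }
            for c in report.checks
        ]
    )
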