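"""Hierarchy collapse: transects -> site-year means -> location annual series.

The site is the unit of replication: transect totals are averaged within a
site-year, site-year means are averaged (unweighted) across the sites
surveyed that year, and each location x trophic-group annual series is then
standardized to mean zero, sample standard deviation one.  The
standardization constants come from the location-level annual means and are
re-applied to the site-year means so the trend regression's replicate points
live on the same scale.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping

import numpy as np
import pandas as pd

from reefcascade.datamodel import LocationMeta, LocationSeries
from reefcascade.errors import ConstantSeriesError

SITE_YEAR_COLUMNS = [
    "location_id",
    "site_id",
    "year",
    "trophic_group",
    "mean_value",
]


def apply_start_year(
    records: pd.DataFrame, meta: pd.DataFrame | Mapping[str, LocationMeta]
) -> pd.DataFrame:
    """Drop survey rows before each location's analysis start year.

    Reserves are analysed from their implementation year; fished locations
    use their matched geographic area's reserve year when one is supplied.
    Locations without a resolved start year keep all records.
    """
    if isinstance(meta, Mapping):
        start = {
            k: m.analysis_start_year
            for k, m in meta.items()
            if m.analysis_start_year is not None
        }
    elif "analysis_start_year" in meta.columns:
        sub = meta.dropna(subset=["analysis_start_year"])
        start = dict(
            zip(sub["location_id"], sub["analysis_start_year"].astype(int))
        )
    else:
        start = {}
    if not start:
        return records.copy()
    cutoff = records["location_id"].map(start)
    keep = cutoff.isna() | (records["year"] >= cutoff)
    return records.loc[keep].copy()


def site_year_means(records: pd.DataFrame) -> pd.DataFrame:
    """Mean transect value per (location, site, year, trophic group)."""
    out = (
        records.groupby(
            ["location_id", "site_id", "year", "trophic_group"], sort=True, as_index=False
        )["value"]
        .mean()
        .rename(columns={"value": "mean_value"})
    )
    return out[SITE_YEAR_COLUMNS]


def location_year_series(site_year: pd.DataFrame) -> dict[tuple[str, str], LocationSeries]:
    """Assemble year-ordered raw annual series per location x group.

    Each year averages only the sites observed that year; missing years are
    simply absent (no imputation).
    """
    if site_year.empty:
        raise ValueError("empty site-year table")
    annual = (
        site_year.groupby(["location_id", "trophic_group", "year"], sort=True)[
            "mean_value"
        ]
        .agg(["mean", "count"])
        .reset_index()
    )
    out: dict[tuple[str, str], LocationSeries] = {}
    for (loc, group), sub in annual.groupby(["location_id", "trophic_group"], sort=True):
        sub = sub.sort_values("year")
        out[(loc, group)] = LocationSeries(
            location_id=loc,
            trophic_group=group,
            years=sub["year"].to_numpy(),
            raw_means=sub["mean"].to_numpy(),
            n_sites=sub["count"].to_numpy(),
        )
    return out


def standardize_series(series: LocationSeries) -> LocationSeries:
    """Rescale a raw annual series to mean 0, sample (n-1) sd 1.

    The constants are stored on the result so site-level replicates of the
    same location/group can be standardized identically.  Raises
    :class:`ConstantSeriesError` when the series has zero variance.
    """
    if series.n_years < 3:
        raise ValueError(
            f"series {series.location_id}/{series.trophic_group} has "
            f"{series.n_years} years; need >= 3"
        )
    mean = float(np.mean(series.raw_means))
    sd = float(np.std(series.raw_means, ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise ConstantSeriesError(
            f"constant series: {series.location_id}/{series.trophic_group}"
        )
    return replace(
        series,
        std_means=(series.raw_means - mean) / sd,
        series_mean=mean,
        series_sd=sd,
    )


def standardized_replicates(
    site_year: pd.DataFrame, series: Mapping[tuple[str, str], LocationSeries]
) -> pd.DataFrame:
    """Site-year means standardized with their location/group constants.

    Output columns: location_id, site_id, year, trophic_group, std_value.
    Rows whose series could not be standardized are omitted.
    """
    constants = pd.DataFrame(
        [
            {
                "location_id": loc,
                "trophic_group": group,
                "_mean": s.series_mean,
                "_sd": s.series_sd,
            }
            for (loc, group), s in series.items()
            if s.series_sd is not None
        ]
    )
    if constants.empty:
        return pd.DataFrame(
            columns=["location_id", "site_id", "year", "trophic_group", "std_value"]
        )
    merged = site_year.merge(constants, on=["location_id", "trophic_group"], how="inner")
    merged["std_value"] = (merged["mean_value"] - merged["_mean"]) / merged["_sd"]
    return merged[["location_id", "site_id", "year", "trophic_group", "std_value"]]


def build_location_series(
    records: pd.DataFrame, meta: pd.DataFrame | Mapping[str, LocationMeta] | None = None
) -> tuple[dict[tuple[str, str], LocationSeries], pd.DataFrame, list[tuple[str, str]]]:
    """Full aggregation chain from transect records to standardized series.

    Applies the start-year truncation (when *meta* is given), collapses the
    hierarchy, standardizes each series, and returns ``(series, replicates,
    constant)`` where *constant* lists the (location, group) pairs that had
    zero variance and were left unstandardized.
    """
    if meta is not None:
        records = apply_start_year(records, meta)
    site_year = site_year_means(records)
    series = location_year_series(site_year)
    constant: list[tuple[str, str]] = []
    for key, s in list(series.items()):
        try:
            series[key] = standardize_series(s)
        except ConstantSeriesError:
            constant.append(key)
    replicates = standardized_replicates(site_year, series)
    return series, replicates, constant


def series_frame(series: Mapping[tuple[str, str], LocationSeries]) -> pd.DataFrame:
    """Long-format view of annual series (one row per location/group/year)."""
    rows = []
    for (loc, group), s in sorted(series.items()):
        std = s.std_means if s.std_means is not None else [np.nan] * s.n_years
        n_sites = s.n_sites if s.n_sites is not None else [np.nan] * s.n_years
        for i in range(s.n_years):
            rows.append(
                {
                    "location_id": loc,
                    "trophic_group": group,
                    "year": int(s.years[i]),
                    "raw_mean": float(s.raw_means[i]),
                    "std_mean": float(std[i]),
                    "n_sites": n_sites[i],
                }
            )
    return pd.DataFrame(rows)


def frame_to_series(df: pd.DataFrame) -> dict[tuple[str, str], LocationSeries]:
    """Inverse of :func:`series_frame` (used by the CLI to reload series)."""
    out: dict[tuple[str, str], LocationSeries] = {}
    for (loc, group), sub in df.groupby(["location_id", "trophic_group"], sort=True):
        sub = sub.sort_values("year")
        raw = sub["raw_mean"].to_numpy(dtype=float)
        mean = float(np.mean(raw))
        sd = float(np.std(raw, ddof=1))
        std = sub["std_mean"].to_numpy(dtype=float)
        has_std = not np.isnan(std).any()
        out[(loc, group)] = LocationSeries(
            location_id=loc,
            trophic_group=group,
            years=sub["year"].to_numpy(dtype=int),
            raw_means=raw,
            std_means=std if has_std else None,
            series_mean=mean if has_std else None,
            series_sd=sd if has_std else None,
            n_sites=sub["n_sites"].to_numpy() if "n_sites" in sub else None,
        )
    return out
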