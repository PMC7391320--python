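"""Domain types for hierarchical reef-survey trend analysis.

The tabular interchange format is a pandas DataFrame with one row per
transect-level trophic-group total (``SURVEY_COLUMNS``) plus a location
metadata table (``LOCATION_COLUMNS``).  The dataclasses here are the typed
row/result views used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Ecoregions, ordered from low to high (southern) latitude.
REGIONS = ("tropical", "warm_temperate", "cool_temperate")

#: The three trophic groups, ordered top of the food web downward.
TROPHIC_GROUPS = ("predators", "herbivores", "algae")

#: The four exploitation categories.
EXPLOITATION_STATUSES = (
    "early_reserve",
    "late_reserve",
    "always_fished",
    "newly_fished",
)

#: Adjacent consumer-resource pairs used for forcing diagnosis.
ADJACENT_PAIRS = (
    ("predators", "herbivores", "predator_herbivore"),
    ("herbivores", "algae", "herbivore_algae"),
)

VALUE_KINDS = ("density", "percent_cover")

SURVEY_COLUMNS = [
    "region",
    "location_id",
    "site_id",
    "transect_id",
    "year",
    "trophic_group",
    "value",
    "value_kind",
]

LOCATION_COLUMNS = [
    "location_id",
    "latitude",
    "exploitation_status",
    "reserve_start_year",
]


@dataclass(frozen=True)
class SurveyRecord:
    """One transect-level trophic-group total at a site in one year.

    ``value`` is individuals per transect for predators and herbivores
    (``value_kind='density'``) and percent cover for algae
    (``value_kind='percent_cover'``).  Temperate cover is measured in three
    dimensions (benthos to canopy) and may exceed 100%; tropical cover is
    planar and may not.
    """

    region: str
    location_id: str
    site_id: str
    transect_id: str
    year: int
    trophic_group: str
    value: float
    value_kind: str

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.trophic_group not in TROPHIC_GROUPS:
            raise ValueError(f"unknown trophic group {self.trophic_group!r}")
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value kind {self.value_kind!r}")
        if not np.isfinite(self.value) or self.value < 0:
            raise ValueError(f"value must be finite and >= 0, got {self.value}")
        if (
            self.value_kind == "percent_cover"
            and self.value > 100
            and self.region == "tropical"
        ):
            raise ValueError(
                "tropical percent cover is planar and cannot exceed 100"
            )


@dataclass(frozen=True)
class LocationMeta:
    """Location-level metadata.

    Latitude is signed decimal degrees (negative = southern hemisphere), so
    the equator sits at zero and temperate locations have the most negative
    values.  ``analysis_start_year`` is the year trend analysis begins: the
    reserve-implementation year for reserves, the matched geographic area's
    reserve year for fished locations, or ``None`` (keep the full series).
    """

    location_id: str
    latitude: float
    exploitation_status: str
    reserve_start_year: Optional[int] = None
    analysis_start_year: Optional[int] = None

    def __post_init__(self) -> None:
        if self.exploitation_status not in EXPLOITATION_STATUSES:
            raise ValueError(
                f"unknown exploitation status {self.exploitation_status!r}"
            )
        if not -90 <= self.latitude <= 90:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if (
            self.exploitation_status in ("early_reserve", "late_reserve")
            and self.reserve_start_year is None
        ):
            raise ValueError(
                f"{self.exploitation_status} requires reserve_start_year"
            )


@dataclass
class SeriesCheck:
    """Per location x trophic-group quality-control summary."""

    location_id: str
    trophic_group: str
    n_years: int
    n_surveys: int
    too_short: bool
    too_few_surveys: bool
    constant: bool
    uneven_sites: bool

    @property
    def passed(self) -> bool:
        return not (self.too_short or self.too_few_surveys or self.constant)


@dataclass
class ValidationReport:
    """Dataset-level quality-control report.

    A series passes only if it spans at least three distinct years and at
    least twelve surveys (unique year x site combinations), and is not
    constant.  Uneven site sampling is informational: it only restricts the
    AR-1 model's applicability, it does not fail the series.
    """

    checks: list[SeriesCheck] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> list[SeriesCheck]:
        return [c for c in self.checks if not c.passed]


@dataclass
class LocationSeries:
    """A standardized annual series of one trophic group at one location.

    ``raw_means`` are the unweighted means across sites of the site-year
    means; ``std_means`` are those values rescaled to sample mean zero and
    sample (n-1) standard deviation one.  The standardization constants are
    retained so site-level replicates can be put on the same scale.
    """

    location_id: str
    trophic_group: str
    years: np.ndarray
    raw_means: np.ndarray
    std_means: Optional[np.ndarray] = None
    series_mean: Optional[float] = None
    series_sd: Optional[float] = None
    n_sites: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.raw_means = np.asarray(self.raw_means, dtype=float)
        if self.years.ndim != 1 or self.years.shape != self.raw_means.shape:
            raise ValueError("years and raw_means must be 1-d and aligned")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")

    @property
    def n_years(self) -> int:
        return int(self.years.size)


@dataclass
class TrendResult:
    """A per-location, per-group linear time-trend fit."""

    location_id: str
    trophic_group: str
    slope: float
    slope_se: float
    t_stat: float
    p_value: float
    r_squared: float
    n_points: int
    n_years: int
    direction: str  # increasing | decreasing | none
    method: str = "ols"  # ols | ar1
    rho: Optional[float] = None
    exact_fit: bool = False
    converged: bool = True

    @property
    def significant(self) -> bool:
        return self.direction != "none"


@dataclass
class PairCorrelation:
    """Pearson correlation between two adjacent groups' annual series.

    ``z`` is Fisher's transform atanh(r), approximately normal with variance
    1/(n-3) for n paired years; the inverse variance (n-3, floored at zero)
    serves as the meta-analytic regression weight.
    """

    location_id: str
    pair: str  # predator_herbivore | herbivore_algae
    r: float
    n_years: int
    z: Optional[float] = None
    z_var: Optional[float] = None
    weight: Optional[float] = None
    undefined: bool = False


def order_groups(groups: Sequence[str]) -> list[str]:
    """Return *groups* in canonical trophic order (predators first)."""
    rank = {g: i for i, g in enumerate(TROPHIC_GROUPS)}
    return sorted(groups, key=lambda g: rank[g])
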