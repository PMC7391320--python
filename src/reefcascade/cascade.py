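"""Alternating-trend (community-level trophic cascade) classification.

A location qualifies as *alternating* when all three trophic groups show
statistically significant density trends and adjacent groups trend in
opposite directions — predators up, herbivores down, algae up, or the mirror
pattern.  A significant predator trend is the prerequisite: only when the
top group changes would lower groups be expected to respond under top-down
control, so prevalence is reported as a fraction of predator-significant
locations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from reefcascade.datamodel import TROPHIC_GROUPS, TrendResult
from reefcascade.errors import IncompleteLocationError

_SIGN = {"increasing": "+", "decreasing": "-", "none": "0"}


@dataclass
class CascadeClassification:
    """Three-group alternating-trend verdict for one location."""

    location_id: str
    predator_direction: str
    herbivore_direction: str
    algae_direction: str
    predator_significant: bool
    alternating: bool
    partial_alternating: bool
    pattern: str

    def as_dict(self) -> dict:
        return {
            "location_id": self.location_id,
            "predator_direction": self.predator_direction,
            "herbivore_direction": self.herbivore_direction,
            "algae_direction": self.algae_direction,
            "predator_significant": self.predator_significant,
            "alternating": self.alternating,
            "partial_alternating": self.partial_alternating,
            "pattern": self.pattern,
        }


def classify_location(trends: Sequence[TrendResult]) -> CascadeClassification:
    """Apply the alternating-trend criterion to one location's three fits.

    Both sign-symmetric patterns qualify (P+H-A+ and P-H+A-).  Opposing
    significant predator and herbivore trends without a significant algae
    trend are tallied under ``partial_alternating``.
    """
    by_group = {t.trophic_group: t for t in trends}
    missing = [g for g in TROPHIC_GROUPS if g not in by_group]
    if missing or len(trends) != 3:
        raise IncompleteLocationError(
            f"need exactly one result per trophic group; missing {missing}"
        )
    loc = trends[0].location_id
    if any(t.location_id != loc for t in trends):
        raise ValueError("results come from different locations")
    p, h, a = (by_group[g] for g in TROPHIC_GROUPS)
    dirs = (p.direction, h.direction, a.direction)
    pred_sig = p.direction != "none"
    all_sig = all(d != "none" for d in dirs)
    sign = {"increasing": 1, "decreasing": -1, "none": 0}
    sp, sh, sa = (sign[d] for d in dirs)
    alternating = bool(all_sig and sp == -sh and sh == -sa)
    partial = bool(
        not alternating and sp != 0 and sh != 0 and sp == -sh
    )
    pattern = f"P{_SIGN[p.direction]}H{_SIGN[h.direction]}A{_SIGN[a.direction]}"
    return CascadeClassification(
        location_id=loc,
        predator_direction=p.direction,
        herbivore_direction=h.direction,
        algae_direction=a.direction,
        predator_significant=pred_sig,
        alternating=alternating,
        partial_alternating=partial,
        pattern=pattern,
    )


def classify_all(trends: Sequence[TrendResult]) -> list[CascadeClassification]:
    """Classify every location given a flat list of trend results.

    When results from several methods are present, the OLS fits are used.
    """
    ols = [t for t in trends if t.method == "ols"] or list(trends)
    by_loc: dict[str, list[TrendResult]] = {}
    for t in ols:
        by_loc.setdefault(t.location_id, []).append(t)
    return [classify_location(by_loc[loc]) for loc in sorted(by_loc)]


def classifications_frame(classifications: Sequence[CascadeClassification]) -> pd.DataFrame:
    return pd.DataFrame([c.as_dict() for c in classifications])


def summarize_prevalence(
    classifications: Sequence[CascadeClassification],
    meta: Optional[pd.DataFrame] = None,
    grouping: str = "all",
) -> pd.DataFrame:
    """Prevalence of alternating trends among predator-significant locations.

    *grouping* is ``all``, ``region`` (tropical vs warm/cool temperate,
    derived from the survey region recorded in *meta*) or
    ``exploitation_status``.  Percentage = alternating / predator-significant
    x 100, reported both exactly and rounded to the nearest integer for
    display; a group with no predator-significant locations has an undefined
    (NaN) percentage, not 0.
    """
    if not classifications:
        raise ValueError("no classifications to summarize")
    df = classifications_frame(classifications)
    if grouping == "all":
        df["_group"] = "all"
    elif grouping in ("region", "exploitation_status"):
        if meta is None or grouping not in meta.columns:
            raise ValueError(f"grouping {grouping!r} requires metadata with that column")
        df = df.merge(
            meta[["location_id", grouping]], on="location_id", how="left"
        ).rename(columns={grouping: "_group"})
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    rows = []
    for name, sub in df.groupby("_group", sort=True):
        n_sig = int(sub["predator_significant"].sum())
        n_alt = int(sub["alternating"].sum())
        n_partial = int(sub["partial_alternating"].sum())
        pct = 100.0 * n_alt / n_sig if n_sig > 0 else np.nan
        rows.append(
            {
                "group": name,
                "n_locations": len(sub),
                "n_predator_significant": n_sig,
                "n_alternating": n_alt,
                "n_partial_alternating": n_partial,
                "pct_alternating": pct,
                "pct_alternating_display": int(round(pct)) if n_sig > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def excess_over_chance(n_significant: int, n_tests: int, alpha: float = 0.05) -> float:
    """Ratio of observed significant trends to the chance expectation.

    With *n_tests* independent tests at level *alpha*, ``n_tests * alpha``
    significant results are expected under the null; the ratio expresses how
    many times that expectation was observed (round for display).
    """
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return n_significant / (n_tests * alpha)
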