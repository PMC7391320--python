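"""Per-location trend fits and adjacent-group correlation diagnostics.

Two trend estimators are provided.  The ordinary least squares fit regresses
standardized site-year values on (centred) calendar year and tests the slope
with a t statistic on ``n_points - 2`` degrees of freedom.  The AR-1 variant
is a generalized least squares fit in which sites nested within a year share
a latent year effect whose autocorrelation decays as ``rho**|dt|``; it is
more conservative when consecutive years are dependent, and applies only to
locations whose site set is identical across years.

The forcing diagnosis uses the Pearson correlation between adjacent groups'
annual series (negative: top-down; positive: bottom-up), carried to the
cross-location models as Fisher z values with inverse-variance weights
``n - 3``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from reefcascade.datamodel import (
    ADJACENT_PAIRS,
    LocationSeries,
    PairCorrelation,
    TrendResult,
)
from reefcascade.errors import (
    DegenerateDesignError,
    InfiniteZError,
    InsufficientOverlapError,
    NotApplicableError,
)

DEFAULT_ALPHA = 0.05
RHO_BOUNDS = (0.0, 0.95)


def _direction(slope: float, p_value: float, alpha: float) -> str:
    if not np.isfinite(slope) or p_value > alpha:
        return "none"
    return "increasing" if slope > 0 else "decreasing"


def fit_linear_trend(
    years: np.ndarray,
    values: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    location_id: str = "",
    trophic_group: str = "",
) -> TrendResult:
    """OLS trend of standardized values on year.

    *years*/*values* are site-year replicates (a year may appear once per
    site).  Years are centred internally; the slope is in standardized
    density units per year.  Zero residual variance is reported as an exact
    fit with p = 0.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if years.size != values.size or years.size < 3:
        raise DegenerateDesignError("need >= 3 (year, value) points")
    distinct = np.unique(years)
    if distinct.size < 3:
        raise DegenerateDesignError(
            f"need >= 3 distinct years, got {distinct.size}"
        )
    x = years - years.mean()
    n = years.size
    sxx = float(np.sum(x * x))
    slope = float(np.sum(x * (values - values.mean())) / sxx)
    intercept = float(values.mean())
    resid = values - intercept - slope * x
    sse = float(np.sum(resid**2))
    sst = float(np.sum((values - values.mean()) ** 2))
    df = n - 2
    exact = sse <= 1e-12 * max(sst, 1.0)
    if exact:
        se, t_stat, p, r2 = 0.0, np.inf, 0.0, 1.0
    else:
        s2 = sse / df
        se = float(np.sqrt(s2 / sxx))
        t_stat = slope / se
        p = float(2.0 * stats.t.sf(abs(t_stat), df))
        r2 = 1.0 - sse / sst if sst > 0 else 0.0
    if sst == 0:  # constant values: slope 0, no trend
        slope, t_stat, p, r2, exact = 0.0, 0.0, 1.0, 0.0, False
    return TrendResult(
        location_id=location_id,
        trophic_group=trophic_group,
        slope=slope,
        slope_se=se,
        t_stat=float(t_stat),
        p_value=p,
        r_squared=float(r2),
        n_points=int(n),
        n_years=int(distinct.size),
        direction=_direction(slope, p, alpha),
        method="ols",
        exact_fit=exact,
    )


def _ar1_neg2loglik(
    params: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    year_vals: np.ndarray,
) -> float:
    rho, log_v = params
    R = rho ** np.abs(year_vals[:, None] - year_vals[None, :])
    C = np.exp(log_v) * (Z @ R @ Z.T) + np.eye(y.size)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        return 1e12
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    Ci_y = np.linalg.solve(C, y)
    Ci_X = np.linalg.solve(C, X)
    XtCiX = X.T @ Ci_X
    beta = np.linalg.solve(XtCiX, X.T @ Ci_y)
    r = y - X @ beta
    rss = float(r @ np.linalg.solve(C, r))
    # Restricted likelihood: profiling the scale on n - p df and adding
    # log|X' C^-1 X| removes most of the downward bias in rho that plain ML
    # incurs from estimating the trend.
    n, p = y.size, X.shape[1]
    sigma2 = rss / (n - p)
    sign, logdet_x = np.linalg.slogdet(XtCiX)
    if sign <= 0:
        return 1e12
    return (n - p) * np.log(sigma2) + logdet + logdet_x + (n - p)


def fit_ar1_trend(
    replicates: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    location_id: str = "",
    trophic_group: str = "",
) -> TrendResult:
    """AR-1 generalized least squares trend fit.

    *replicates* must have columns ``year``, ``site_id`` and ``std_value``.
    The residual model is ``y = a + b*year + u_year + e`` with the year
    effects following a stationary AR-1 process; variance components and rho
    are estimated by restricted maximum likelihood (rho profiled on
    [0, 0.95]).  The slope test uses ``n_years - 2`` degrees of freedom,
    treating the year as the effective replication unit.

    Raises :class:`NotApplicableError` unless the same sites were surveyed
    every year (the even-sampling applicability condition) and the series
    spans >= 4 years.
    """
    years = replicates["year"].to_numpy(dtype=float)
    y = replicates["std_value"].to_numpy(dtype=float)
    site_sets = replicates.groupby("year")["site_id"].agg(frozenset)
    if len(set(site_sets)) > 1:
        raise NotApplicableError(
            "uneven site-level sampling across years; AR-1 model not applicable"
        )
    year_vals, year_idx = np.unique(years, return_inverse=True)
    T = year_vals.size
    if T < 4:
        raise NotApplicableError("AR-1 model needs >= 4 years")

    n = y.size
    X = np.column_stack([np.ones(n), years - years.mean()])
    Z = np.zeros((n, T))
    Z[np.arange(n), year_idx] = 1.0

    best = None
    for start in ((0.2, np.log(0.5)), (0.6, np.log(0.1)), (0.05, np.log(2.0))):
        res = optimize.minimize(
            _ar1_neg2loglik,
            x0=np.asarray(start),
            args=(y, X, Z, year_vals),
            method="L-BFGS-B",
            bounds=[RHO_BOUNDS, (-12.0, 8.0)],
        )
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best.success) and best.fun < 1e11
    rho, log_v = best.x
    if np.exp(log_v) < 1e-4:
        rho = 0.0  # no detectable year-effect process; rho unidentified

    R = rho ** np.abs(year_vals[:, None] - year_vals[None, :])
    C = np.exp(log_v) * (Z @ R @ Z.T) + np.eye(n)
    Ci_y = np.linalg.solve(C, y)
    Ci_X = np.linalg.solve(C, X)
    XtCiX = X.T @ Ci_X
    beta = np.linalg.solve(XtCiX, X.T @ Ci_y)
    r = y - X @ beta
    rss = float(r @ np.linalg.solve(C, r))
    df = T - 2
    sigma2 = rss / max(n - 2, 1)
    cov_beta = sigma2 * np.linalg.inv(XtCiX)
    slope = float(beta[1])
    se = float(np.sqrt(cov_beta[1, 1]))
    t_stat = slope / se if se > 0 else np.inf
    p = float(2.0 * stats.t.sf(abs(t_stat), df))
    sst = float(np.sum((y - y.mean()) ** 2))
    ols_resid = float(np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2))
    r2 = 1.0 - ols_resid / sst if sst > 0 else 0.0
    return TrendResult(
        location_id=location_id,
        trophic_group=trophic_group,
        slope=slope,
        slope_se=se,
        t_stat=float(t_stat),
        p_value=p,
        r_squared=float(r2),
        n_points=int(n),
        n_years=int(T),
        direction=_direction(slope, p, alpha),
        method="ar1",
        rho=float(rho),
        converged=converged,
    )


def fit_all_trends(
    replicates: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    method: str = "ols",
) -> list[TrendResult]:
    """Fit trends for every location x trophic group in a replicate table.

    *method* is ``ols``, ``ar1`` or ``both``.  AR-1 fits that are not
    applicable (uneven sampling, short series) or fail to converge fall back
    to the OLS result for that series when ``method='ar1'``; with ``both``,
    the OLS result is always emitted and the AR-1 result whenever available.
    """
    if method not in ("ols", "ar1", "both"):
        raise ValueError(f"unknown method {method!r}")
    results: list[TrendResult] = []
    for (loc, group), sub in replicates.groupby(
        ["location_id", "trophic_group"], sort=True
    ):
        ols = fit_linear_trend(
            sub["year"].to_numpy(),
            sub["std_value"].to_numpy(),
            alpha=alpha,
            location_id=loc,
            trophic_group=group,
        )
        if method in ("ols", "both"):
            results.append(ols)
        if method in ("ar1", "both"):
            try:
                ar1 = fit_ar1_trend(sub, alpha=alpha, location_id=loc, trophic_group=group)
            except NotApplicableError:
                ar1 = None
            if ar1 is not None and ar1.converged:
                results.append(ar1)
            elif method == "ar1":
                results.append(ols)
    return results


def trends_frame(results: list[TrendResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "location_id": t.location_id,
                "trophic_group": t.trophic_group,
                "method": t.method,
                "slope": t.slope,
                "se": t.slope_se,
                "t": t.t_stat,
                "p": t.p_value,
                "r2": t.r_squared,
                "n_points": t.n_points,
                "n_years": t.n_years,
                "direction": t.direction,
                "rho": t.rho,
            }
            for t in results
        ]
    )


def adjacent_pair_correlation(
    series_a: LocationSeries, series_b: LocationSeries
) -> PairCorrelation:
    """Pearson r between two adjacent groups' annual series.

    Computed over the intersection of surveyed years; scale invariance of r
    makes it immaterial whether raw or standardized values are used.
    """
    if series_a.location_id != series_b.location_id:
        raise ValueError("series come from different locations")
    pair = None
    for upper, lower, label in ADJACENT_PAIRS:
        if {series_a.trophic_group, series_b.trophic_group} == {upper, lower}:
            pair = label
            if series_a.trophic_group != upper:
                series_a, series_b = series_b, series_a
            break
    if pair is None:
        raise ValueError(
            f"{series_a.trophic_group}/{series_b.trophic_group} is not an "
            "adjacent consumer-resource pair"
        )
    common, ia, ib = np.intersect1d(series_a.years, series_b.years, return_indices=True)
    if common.size < 3:
        raise InsufficientOverlapError(
            f"only {common.size} common years at {series_a.location_id}"
        )
    va = series_a.raw_means[ia]
    vb = series_b.raw_means[ib]
    if np.std(va) == 0 or np.std(vb) == 0:
        return PairCorrelation(
            location_id=series_a.location_id,
            pair=pair,
            r=np.nan,
            n_years=int(common.size),
            undefined=True,
        )
    r = float(stats.pearsonr(va, vb).statistic)
    return PairCorrelation(
        location_id=series_a.location_id,
        pair=pair,
        r=r,
        n_years=int(common.size),
    )


def fisher_transform(pc: PairCorrelation) -> PairCorrelation:
    """Fill a correlation's Fisher z, variance and meta-analytic weight.

    z = atanh(r) = 0.5*ln((1+r)/(1-r)), with sampling variance 1/(n-3) for
    n > 3 paired years.  Series of exactly three years receive weight zero
    (they carry no information in the inverse-variance scheme); |r| = 1 has
    an infinite transform and is rejected.
    """
    if pc.undefined or not np.isfinite(pc.r):
        raise ValueError("correlation undefined; cannot transform")
    if abs(pc.r) >= 1.0:
        raise InfiniteZError(f"|r| = 1 at {pc.location_id} ({pc.pair})")
    z = float(np.arctanh(pc.r))
    n = pc.n_years
    z_var = 1.0 / (n - 3) if n > 3 else None
    weight = float(max(n - 3, 0))
    return PairCorrelation(
        location_id=pc.location_id,
        pair=pc.pair,
        r=pc.r,
        n_years=n,
        z=z,
        z_var=z_var,
        weight=weight,
    )


def all_pair_correlations(
    series: dict[tuple[str, str], LocationSeries]
) -> list[PairCorrelation]:
    """Adjacent-pair correlations (with Fisher fields) for every location.

    Undefined or |r| = 1 correlations are emitted with weight zero and the
    ``undefined`` flag so weighted models can exclude and count them.
    """
    out: list[PairCorrelation] = []
    locations = sorted({loc for loc, _ in series})
    for loc in locations:
        for upper, lower, label in ADJACENT_PAIRS:
            a = series.get((loc, upper))
            b = series.get((loc, lower))
            if a is None or b is None:
                continue
            try:
                pc = adjacent_pair_correlation(a, b)
            except InsufficientOverlapError:
                continue
            if not pc.undefined:
                try:
                    pc = fisher_transform(pc)
                except InfiniteZError:
                    pc = PairCorrelation(
                        location_id=loc,
                        pair=label,
                        r=pc.r,
                        n_years=pc.n_years,
                        weight=0.0,
                        undefined=True,
                    )
            else:
                pc.weight = 0.0
            out.append(pc)
    return out


def correlations_frame(correlations: list[PairCorrelation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "location_id": c.location_id,
                "pair": c.pair,
                "r": c.r,
                "n_years": c.n_years,
                "z": c.z,
                "z_var": c.z_var,
                "weight": c.weight,
            }
            for c in correlations
        ]
    )
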