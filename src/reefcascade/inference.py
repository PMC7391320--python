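"""Cross-location models: weighted meta-regression and the cascade GLM.

Correlation coefficients are sample-size sensitive and bounded, so the
cross-location regressions operate on Fisher z values weighted by the
inverse of their sampling variance (n - 3); fits and confidence bands are
mapped back through tanh for presentation on the correlation scale.  The
occurrence of alternating trends among predator-significant locations is
modelled with a binomial GLM (logit link) in latitude and exploitation
status, simplified by backward stepwise removal of nonsignificant terms
(p > .05) guided by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from reefcascade.errors import DegenerateDesignError, DegenerateResponseError

EXPLOITATION_TERM = 'C(exploitation_status, Treatment("always_fished"))'

#: |coefficient| on the log-odds scale beyond which we call quasi-separation.
SEPARATION_COEF = 12.0

SMALL_CATEGORY = 5


@dataclass
class WLSFit:
    """An inverse-variance-weighted least squares fit."""

    formula: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r_squared: float
    f_stat: float
    f_df: tuple[float, float]
    f_pvalue: float
    aic: float
    n_used: int
    n_excluded: int
    fitted: pd.DataFrame  # columns: fit, se, ci_low, ci_high (+ back-transformed)
    is_fisher_z: bool
    result: object = field(repr=False, default=None)

    @property
    def terms(self) -> list[str]:
        return [t.strip() for t in self.formula.split("~")[1].split("+") if t.strip() != "1"]


@dataclass
class GLMFit:
    """A binomial (logit) GLM fit."""

    formula: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    aic: float
    log_likelihood: float
    converged: bool
    separation_flag: bool
    n_used: int
    fitted_probabilities: np.ndarray
    result: object = field(repr=False, default=None)

    @property
    def terms(self) -> list[str]:
        return [t.strip() for t in self.formula.split("~")[1].split("+") if t.strip() != "1"]


@dataclass
class StepwiseTrace:
    """Record of a backward-stepwise model search."""

    steps: list[dict] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def _check_full_rank(exog: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # Identify columns involved in the deficiency via pivoted correlation.
        r = np.linalg.qr(exog, mode="r")
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(exog.shape) * np.finfo(float).eps
        bad = [names[i] for i in np.flatnonzero(diag < tol)]
        raise DegenerateDesignError(
            f"design is rank deficient (rank {rank} < {exog.shape[1]}); "
            f"collinear term(s): {bad or names}"
        )


def weighted_regression(
    data: pd.DataFrame,
    formula: str,
    weights: str | np.ndarray = "weight",
    fisher_z: Optional[bool] = None,
) -> WLSFit:
    """Weighted least squares minimizing sum w_i (y_i - x_i' beta)^2.

    Points with weight zero (or negative) are excluded and counted.  When the
    response is a Fisher z value (``fisher_z=True``, or inferred from a
    response named ``z``), fitted values and 95% confidence bands are also
    back-transformed through tanh onto the correlation scale.
    """
    w = data[weights] if isinstance(weights, str) else pd.Series(np.asarray(weights), index=data.index)
    keep = w.notna() & (w > 0)
    response = formula.split("~")[0].strip()
    keep &= data[response].notna()
    used = data.loc[keep]
    n_excluded = int((~keep).sum())
    if len(used) < 2:
        raise DegenerateDesignError("need >= 2 points with positive weight")
    if fisher_z is None:
        fisher_z = response == "z"

    model = smf.wls(formula, data=used, weights=w.loc[keep])
    _check_full_rank(model.exog, list(model.exog_names))
    if len(used) < model.exog.shape[1]:
        raise DegenerateDesignError(
            f"{len(used)} points cannot identify {model.exog.shape[1]} coefficients"
        )
    res = model.fit()

    pred = res.get_prediction(used)
    sf = pred.summary_frame(alpha=0.05)
    fitted = pd.DataFrame(
        {
            "fit": sf["mean"].to_numpy(),
            "se": sf["mean_se"].to_numpy(),
            "ci_low": sf["mean_ci_lower"].to_numpy(),
            "ci_high": sf["mean_ci_upper"].to_numpy(),
        },
        index=used.index,
    )
    if fisher_z:
        for col in ("fit", "ci_low", "ci_high"):
            fitted[f"r_{col}"] = np.tanh(fitted[col])
    return WLSFit(
        formula=formula,
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        r_squared=float(res.rsquared),
        f_stat=float(res.fvalue) if res.df_model > 0 else np.nan,
        f_df=(float(res.df_model), float(res.df_resid)),
        f_pvalue=float(res.f_pvalue) if res.df_model > 0 else np.nan,
        aic=float(res.aic),
        n_used=int(len(used)),
        n_excluded=n_excluded,
        fitted=fitted,
        is_fisher_z=bool(fisher_z),
        result=res,
    )


def logistic_cascade_model(
    data: pd.DataFrame,
    formula: str = f"alternating ~ latitude + {EXPLOITATION_TERM}",
) -> GLMFit:
    """Binomial GLM with logit link for alternating-trend occurrence.

    Fit by iteratively reweighted least squares; exploitation status enters
    through treatment contrasts with ``always_fished`` as the reference.
    Complete or quasi-complete separation is flagged, not corrected.
    """
    response = formula.split("~")[0].strip()
    y = data[response].astype(float)
    if y.nunique() < 2:
        raise DegenerateResponseError(
            f"response {response!r} is constant ({y.iloc[0]:g}); cannot fit"
        )
    if "exploitation_status" in formula and "exploitation_status" in data.columns:
        counts = data["exploitation_status"].value_counts()
        small = counts[counts < SMALL_CATEGORY]
        if len(small):
            import warnings

            warnings.warn(
                "exploitation categories with < "
                f"{SMALL_CATEGORY} locations: {dict(small)}",
                stacklevel=2,
            )
    model = smf.glm(formula, data=data, family=sm.families.Binomial())
    _check_full_rank(model.exog, list(model.exog_names))
    res = model.fit(maxiter=200)
    mu = np.asarray(res.fittedvalues)
    separation = bool(
        np.any(np.abs(res.params.to_numpy()) > SEPARATION_COEF)
        or np.all((mu < 1e-8) | (mu > 1 - 1e-8))
    )
    if separation:
        import warnings

        warnings.warn(
            "possible (quasi-)separation in the cascade GLM; coefficients unreliable",
            stacklevel=2,
        )
    return GLMFit(
        formula=formula,
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        aic=float(res.aic),
        log_likelihood=float(res.llf),
        converged=bool(res.converged),
        separation_flag=separation,
        n_used=int(res.nobs),
        fitted_probabilities=mu,
        result=res,
    )


def _refit(template: WLSFit | GLMFit, data: pd.DataFrame, formula: str, **kw):
    if isinstance(template, GLMFit):
        return logistic_cascade_model(data, formula=formula)
    return weighted_regression(
        data, formula, fisher_z=template.is_fisher_z, **kw
    )


def _term_pvalue(
    full: WLSFit | GLMFit, term: str, data: pd.DataFrame, **kw
) -> float:
    """Significance of one model term.

    Single-coefficient terms use their Wald p-value; multi-level categorical
    terms are tested as a block with a likelihood-ratio test (GLM) or an F
    test (weighted least squares).
    """
    cols = [name for name in full.params.index if name.startswith(term)]
    if len(cols) == 1:
        return float(full.pvalues[cols[0]])
    reduced_terms = [t for t in full.terms if t != term]
    rhs = " + ".join(reduced_terms) if reduced_terms else "1"
    response = full.formula.split("~")[0].strip()
    reduced = _refit(full, data, f"{response} ~ {rhs}", **kw)
    if isinstance(full, GLMFit):
        lr = 2.0 * (full.log_likelihood - reduced.log_likelihood)
        df = len(full.params) - len(reduced.params)
        return float(stats.chi2.sf(max(lr, 0.0), df))
    return float(full.result.compare_f_test(reduced.result)[1])


def backward_stepwise(
    full: WLSFit | GLMFit,
    data: pd.DataFrame,
    alpha: float = 0.05,
    **kw,
) -> tuple[WLSFit | GLMFit, StepwiseTrace]:
    """Backward stepwise simplification guided by AIC.

    At each step, among terms with p > *alpha*, the term whose removal
    lowers AIC the most is dropped; the search stops when every remaining
    term is significant or no removal lowers AIC.  An intercept-only model
    is a valid endpoint.  Extra keyword arguments (e.g. ``weights``) are
    passed through to the refits.
    """
    response = full.formula.split("~")[0].strip()
    current = full
    trace = StepwiseTrace()
    while True:
        term_ps = {t: _term_pvalue(current, t, data, **kw) for t in current.terms}
        trace.steps.append(
            {
                "terms": " + ".join(current.terms) or "1",
                "aic": current.aic,
                "term_pvalues": "; ".join(f"{t}={p:.4g}" for t, p in term_ps.items()),
                "dropped": "",
                "drop_pvalue": np.nan,
            }
        )
        candidates = [t for t, p in term_ps.items() if p > alpha]
        if not candidates:
            break
        best_term, best_fit = None, None
        for term in candidates:
            rhs = " + ".join(t for t in current.terms if t != term) or "1"
            fit = _refit(current, data, f"{response} ~ {rhs}", **kw)
            if best_fit is None or fit.aic < best_fit.aic:
                best_term, best_fit = term, fit
        if best_fit.aic >= current.aic:
            break
        trace.steps[-1]["dropped"] = best_term
        trace.steps[-1]["drop_pvalue"] = term_ps[best_term]
        current = best_fit
    return current, trace


def trend_vs_covariate_models(
    trends: pd.DataFrame,
    meta: pd.DataFrame,
    alpha: float = 0.05,
) -> dict:
    """Per-group models of trend slopes against latitude and exploitation.

    For each trophic group the standardized trend slope is regressed,
    weighted by the inverse squared slope standard error, on latitude
    (continuous) and separately on exploitation status (categorical), each
    simplified by backward stepwise selection.  Also returns per-category
    mean trends with normal-approximation 95% confidence intervals for
    reporting.
    """
    data = trends[trends["method"] == "ols"].merge(
        meta[["location_id", "latitude", "exploitation_status"]], on="location_id"
    )
    data = data.copy()
    with np.errstate(divide="ignore"):
        data["w"] = np.where(data["se"] > 0, 1.0 / data["se"] ** 2, 0.0)
    out: dict = {"models": {}, "category_means": None}
    cat_rows = []
    for group, sub in data.groupby("trophic_group", sort=True):
        sub = sub.reset_index(drop=True)
        models = {}
        if len(sub) < 3:
            import warnings

            warnings.warn(
                f"only {len(sub)} locations for {group}; covariate models skipped",
                stacklevel=2,
            )
            out["models"][group] = models
            continue
        full_lat = weighted_regression(sub, "slope ~ latitude", weights="w", fisher_z=False)
        models["latitude"] = backward_stepwise(full_lat, sub, alpha=alpha, weights="w")
        if sub["exploitation_status"].nunique() > 1:
            full_exp = weighted_regression(
                sub, f"slope ~ {EXPLOITATION_TERM}", weights="w", fisher_z=False
            )
            models["exploitation"] = backward_stepwise(
                full_exp, sub, alpha=alpha, weights="w"
            )
        else:
            import warnings

            warnings.warn(
                f"single exploitation category for {group}; categorical model skipped",
                stacklevel=2,
            )
        out["models"][group] = models
        for status, cat in sub.groupby("exploitation_status", sort=True):
            w = cat["w"].to_numpy()
            s = cat["slope"].to_numpy()
            if w.sum() > 0:
                m = float(np.average(s, weights=w))
                se = float(np.sqrt(1.0 / w.sum()))
            else:
                m, se = float(np.mean(s)), float(np.std(s, ddof=1) / np.sqrt(len(s)))
            cat_rows.append(
                {
                    "trophic_group": group,
                    "exploitation_status": status,
                    "n": len(cat),
                    "mean_slope": m,
                    "ci_low": m - 1.96 * se,
                    "ci_high": m + 1.96 * se,
                }
            )
    out["category_means"] = pd.DataFrame(cat_rows)
    return out
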