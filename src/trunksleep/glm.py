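"""Cohort statistics: normality checks, GLM family/link selection, effects.

Sleep parameters in population cohorts are typically right-skewed, so each
parameter is modelled with a generalized linear model whose residual family
(normal or gamma) and link (identity, log, inverse, inverse squared) are
chosen jointly by AIC over all eight candidates.  The design is
age group (decades, 10s-80s) + gender + recording month, with an
age-by-gender interaction judged by a scaled-deviance F test at the
analysis alpha; a significant interaction triggers stratified
simple-main-effect analyses.  Pairwise age contrasts compare every group against the 20s
reference with Bonferroni adjustment within each contrast family.

Log-likelihoods are full maximum likelihood — the normal variance is the
MLE and the gamma shape is profiled out numerically — so AIC values are
comparable across families, with the dispersion parameter counted for both.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import optimize, special, stats

from .types import InputError, MINUTES_PER_DAY

__all__ = [
    "AnalysisError",
    "GLMFit",
    "EffectReport",
    "DISTRIBUTIONS",
    "LINKS",
    "bonferroni_adjust",
    "f_test_nested",
    "likelihood_ratio_test",
    "normality_checks",
    "fit_glm",
    "select_model",
    "analyze_parameter",
    "estimate_linear_effects",
    "summarize_by_group",
    "build_cohort_table",
    "clock_mean",
]

DISTRIBUTIONS = ("normal", "gamma")
LINKS = ("identity", "log", "inverse", "inverse_squared")

#: columns analysed on the minutes-from-midnight clock scale (wraparound)
CLOCK_COLUMNS = {"ibt_mfm", "gut_mfm"}

PARAM_COLUMNS = {
    "tib": "tib_min",
    "sl": "sl_min",
    "waso": "waso_min",
    "tst": "tst_min",
    "se": "se_pct",
    "ibt": "ibt_shifted_min",
    "gut": "gut_mfm",
}

_AGE_TERM = "C(age_group, Treatment('20s'))"


class AnalysisError(RuntimeError):
    """No candidate model could be fitted for a response."""


def _make_link(name: str):
    links = sm.families.links
    return {
        "identity": links.Identity(),
        "log": links.Log(),
        "inverse": links.InversePower(),
        "inverse_squared": links.Power(power=-2.0),
    }[name]


def _make_family(distribution: str, link: str):
    link_obj = _make_link(link)
    # check_link=False admits the inverse-squared (power -2) link, which
    # statsmodels does not list among the conventional links for these
    # families; fits that wander outside the valid mean domain are caught
    # and reported as non-converged instead.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if distribution == "normal":
            return sm.families.Gaussian(link=link_obj, check_link=False)
        if distribution == "gamma":
            return sm.families.Gamma(link=link_obj, check_link=False)
    raise InputError(f"unknown distribution '{distribution}'")


def _gamma_shape_mle(y: np.ndarray, mu: np.ndarray) -> float:
    """Profile MLE of the gamma shape given fitted means."""
    r = y / mu
    s = float(np.mean(r - np.log(r))) - 1.0
    if s <= 1e-12:
        return 1e8
    f = lambda a: np.log(a) - special.digamma(a) - s
    lo, hi = 1e-8, 1e8
    return float(optimize.brentq(f, lo, hi, maxiter=200))


def _full_loglik(distribution: str, y: np.ndarray, mu: np.ndarray) -> tuple[float, float]:
    """(log-likelihood, dispersion estimate) at the fitted means."""
    n = y.size
    if distribution == "normal":
        sigma2 = float(np.mean((y - mu) ** 2))
        if sigma2 <= 0:
            return float("inf"), 0.0
        ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        return ll, sigma2
    a = _gamma_shape_mle(y, mu)
    ll = float(
        np.sum(a * np.log(a) - special.gammaln(a) + (a - 1) * np.log(y) - a * np.log(mu) - a * y / mu)
    )
    return ll, a


@dataclass
class GLMFit:
    """One fitted candidate model for a cohort response."""

    distribution: str
    link: str
    formula: str
    converged: bool
    n: int = 0
    k: int = 0  # mean parameters + 1 dispersion parameter
    loglik: float = float("-inf")
    aic: float = float("inf")
    dispersion: float = float("nan")
    params: Optional[pd.Series] = None
    bse: Optional[pd.Series] = None
    pvalues: Optional[pd.Series] = None
    message: str = ""
    result: object = field(default=None, repr=False)


def fit_glm(
    data: pd.DataFrame,
    response: str,
    rhs: str,
    distribution: str = "normal",
    link: str = "identity",
) -> GLMFit:
    """Fit one (distribution, link) candidate by IRLS.

    Non-convergence and numerically invalid fits (e.g. a gamma mean driven
    non-positive by an identity or inverse link) are reported in the
    returned object, not raised; genuinely invalid input (non-positive
    responses under a gamma family) is an error naming the offending rows.
    """
    if distribution not in DISTRIBUTIONS or link not in LINKS:
        raise InputError(f"unknown candidate {distribution}/{link}")
    y = data[response].to_numpy(dtype=float)
    if distribution == "gamma":
        bad = np.flatnonzero(y <= 0)
        if bad.size:
            raise InputError(
                f"gamma family requires positive responses; offending rows: "
                f"{bad[:10].tolist()}{'...' if bad.size > 10 else ''}")

    formula = f"{response} ~ {rhs}"
    family = _make_family(distribution, link)
    fit = GLMFit(distribution=distribution, link=link, formula=formula, converged=False)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.glm(formula, data=data, family=family)
            res = model.fit(maxiter=200)
        mu = np.asarray(res.fittedvalues, dtype=float)
        ok = bool(getattr(res, "converged", True))
        if not np.all(np.isfinite(res.params)):
            ok, fit.message = False, "non-finite coefficients"
        elif not np.all(np.isfinite(mu)):
            ok, fit.message = False, "non-finite fitted means"
        elif distribution == "gamma" and np.any(mu <= 0):
            ok, fit.message = False, "fitted gamma mean not positive"
        elif not ok:
            fit.message = "IRLS did not converge"
        if ok:
            yv = np.asarray(model.endog, dtype=float)
            ll, disp = _full_loglik(distribution, yv, mu)
            k = int(res.df_model) + 1 + 1  # mean params incl. intercept + dispersion
            fit = GLMFit(
                distribution=distribution,
                link=link,
                formula=formula,
                converged=np.isfinite(ll),
                n=yv.size,
                k=k,
                loglik=ll,
                aic=2 * k - 2 * ll,
                dispersion=disp,
                params=res.params,
                bse=res.bse,
                pvalues=res.pvalues,
                result=res,
            )
            if not fit.converged:
                fit.message = "non-finite log-likelihood"
    except Exception as exc:  # statsmodels raises a zoo of types here
        fit.message = f"{type(exc).__name__}: {exc}"
    return fit


def select_model(
    data: pd.DataFrame,
    response: str,
    rhs: str,
    candidates: Optional[Sequence[tuple[str, str]]] = None,
) -> tuple[GLMFit, pd.DataFrame]:
    """Fit all distribution/link candidates; return (minimum-AIC fit, table).

    Candidates that fail to converge (or cannot be fitted at all, e.g.
    gamma on a response with zeros) are retained in the table with their
    failure message but excluded from selection.
    """
    if candidates is None:
        candidates = [(d, l) for d in DISTRIBUTIONS for l in LINKS]
    fits: list[GLMFit] = []
    for dist, link in candidates:
        try:
            fits.append(fit_glm(data, response, rhs, dist, link))
        except InputError as exc:
            fits.append(
                GLMFit(distribution=dist, link=link, formula=f"{response} ~ {rhs}",
                       converged=False, message=str(exc))
            )
    table = pd.DataFrame(
        {
            "distribution": [f.distribution for f in fits],
            "link": [f.link for f in fits],
            "converged": [f.converged for f in fits],
            "aic": [f.aic for f in fits],
            "loglik": [f.loglik for f in fits],
            "message": [f.message for f in fits],
        }
    )
    ok = [f for f in fits if f.converged]
    if not ok:
        raise AnalysisError(f"no candidate model converged for '{response}'")
    best = min(ok, key=lambda f: f.aic)
    return best, table


def likelihood_ratio_test(full: GLMFit, reduced: GLMFit) -> float:
    """Chi-square LRT p-value for nested fits sharing a family.

    Uses the full-ML log-likelihoods (dispersion profiled out).  With an
    estimated dispersion this test is mildly anticonservative in moderate
    samples; :func:`f_test_nested` is the calibrated choice and is what
    :func:`analyze_parameter` uses.
    """
    if not (full.converged and reduced.converged):
        return float("nan")
    df = full.k - reduced.k
    if df <= 0:
        raise InputError("'full' must have more parameters than 'reduced'")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return float(stats.chi2.sf(stat, df))


def f_test_nested(full: GLMFit, reduced: GLMFit) -> float:
    """Scaled-deviance F test for nested GLMs with estimated dispersion.

    F = ((D_reduced - D_full) / df) / phi_hat with phi_hat the Pearson
    dispersion of the full model; exact for the normal family and the
    standard dispersion-adjusted deviance test for gamma responses.
    """
    if not (full.converged and reduced.converged):
        return float("nan")
    df = full.k - reduced.k
    if df <= 0:
        raise InputError("'full' must have more parameters than 'reduced'")
    rf, rr = full.result, reduced.result
    if rf is None or rr is None or rf.df_resid <= 0:
        return float("nan")
    phi = rf.pearson_chi2 / rf.df_resid
    if not np.isfinite(phi) or phi <= 0:
        return float("nan")
    fstat = max(0.0, (rr.deviance - rf.deviance) / (df * phi))
    return float(stats.f.sf(fstat, df, rf.df_resid))


def bonferroni_adjust(p: float | np.ndarray, m: int) -> np.ndarray | float:
    """min(1, m * p) for a family of m simultaneous contrasts."""
    return np.minimum(1.0, m * np.asarray(p, dtype=float))


# ---------------------------------------------------------------------------
# normality diagnostics


def normality_checks(
    values: np.ndarray,
    alpha: float = 0.01,
    n_mc: int = 199,
    seed: Optional[int] = None,
) -> dict:
    """EDF goodness-of-fit tests against a normal with estimated parameters.

    Kolmogorov-Smirnov, Cramer-von Mises and Anderson-Darling statistics
    with parametric-bootstrap (Monte Carlo) p-values that account for the
    estimated mean and standard deviation, plus quantile-quantile plot
    coordinates for visual inspection.

    The smallest achievable Monte-Carlo p-value is 1/(n_mc + 1), so a
    decision at significance ``alpha`` needs n_mc >= 1/alpha (the default
    supports alpha = 0.01).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 8:
        raise InputError("need at least 8 observations")
    if np.ptp(values) == 0:
        raise InputError("degenerate input: zero variance")

    rng = np.random.default_rng(seed)
    out: dict = {"n": int(values.size), "alpha": float(alpha), "tests": {}}
    for name, statistic in (("ks", "ks"), ("cvm", "cvm"), ("ad", "ad")):
        res = stats.goodness_of_fit(
            stats.norm, values, statistic=statistic, n_mc_samples=n_mc, rng=rng
        )
        out["tests"][name] = {
            "statistic": float(res.statistic),
            "pvalue": float(res.pvalue),
            "reject_normal": bool(res.pvalue < alpha),
        }
    mean, sd = float(values.mean()), float(values.std(ddof=1))
    order = np.sort(values)
    probs = (np.arange(1, values.size + 1) - 0.5) / values.size
    out["qq"] = pd.DataFrame(
        {"theoretical": stats.norm.ppf(probs, loc=mean, scale=sd), "sample": order}
    )
    return out


# ---------------------------------------------------------------------------
# cohort table construction and summaries


def _age_group(age: int) -> str:
    return f"{int(age // 10) * 10}s"


def build_cohort_table(rows: pd.DataFrame) -> pd.DataFrame:
    """Attach modelling columns to a per-subject sleep-parameter table.

    Expects at least ``age``, ``gender``, ``month`` and the parameter
    columns (``tib_min`` ... ``se_pct``; clock times as minutes from
    midnight ``ibt_mfm``/``gut_mfm``).  Adds ``age_group`` (10s..80s) and
    ``ibt_shifted_min`` — bedtime shifted by +12 h so the nocturnal
    distribution does not wrap around midnight.
    """
    table = rows.copy()
    table["age_group"] = pd.Categorical(
        [_age_group(a) for a in table["age"]],
        categories=[f"{d}0s" for d in range(1, 9)],
        ordered=True,
    )
    if "ibt_mfm" in table.columns:
        table["ibt_shifted_min"] = (table["ibt_mfm"] + 720.0) % MINUTES_PER_DAY
    if "month" in table.columns:
        table["month"] = table["month"].astype(int)
    return table


def clock_mean(minutes_from_midnight: np.ndarray) -> float:
    """Mean clock time in minutes from midnight, robust to the midnight wrap
    for nocturnal times (computed on a +12 h shifted scale)."""
    shifted = (np.asarray(minutes_from_midnight, dtype=float) + 720.0) % MINUTES_PER_DAY
    return float((shifted.mean() - 720.0) % MINUTES_PER_DAY)


def summarize_by_group(
    table: pd.DataFrame,
    parameters: Optional[Sequence[str]] = None,
    by_gender: bool = False,
) -> pd.DataFrame:
    """Group summary: mean, SEM (sd/sqrt(n)) and n per age group.

    Clock-time columns are averaged on the +12 h shifted scale and mapped
    back, so bedtimes spanning midnight average correctly.  Cells with a
    single subject report SEM as NaN with ``sem_defined`` False.
    """
    if table.empty:
        raise InputError("empty cohort table")
    if parameters is None:
        parameters = [c for c in
                      ("tib_min", "sl_min", "waso_min", "tst_min", "se_pct", "ibt_mfm", "gut_mfm")
                      if c in table.columns]
    keys = ["age_group", "gender"] if by_gender else ["age_group"]
    records = []
    grouped = table.groupby(keys, observed=True)
    for key, sub in grouped:
        key = key if isinstance(key, tuple) else (key,)
        for param in parameters:
            vals = sub[param].dropna().to_numpy(dtype=float)
            n = vals.size
            if n == 0:
                continue
            if param in CLOCK_COLUMNS:
                shifted = (vals + 720.0) % MINUTES_PER_DAY
                mean = (shifted.mean() - 720.0) % MINUTES_PER_DAY
                sem = float(shifted.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
            else:
                mean = float(vals.mean())
                sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
            rec = dict(zip(keys, key))
            rec.update(parameter=param, mean=float(mean), sem=sem, n=int(n),
                       sem_defined=n > 1)
            records.append(rec)
    return pd.DataFrame(records)


def estimate_linear_effects(table: pd.DataFrame) -> dict:
    """Linear-trend effect estimates matching the cohort's headline numbers.

    Treating age as continuous (in decades), estimates the bedtime advance
    per decade after the 20s, the WASO slope per decade above age 30, and
    the gender difference in TST (female minus male, age-group adjusted).
    Returns estimates with standard errors.
    """
    out: dict = {}
    sub = table[table["age"] >= 25]
    fit = smf.ols("ibt_shifted_min ~ I(age / 10) + C(gender)", data=sub).fit()
    out["ibt_slope_min_per_decade"] = {
        "estimate": float(fit.params["I(age / 10)"]),
        "se": float(fit.bse["I(age / 10)"]),
    }
    fit = smf.ols("gut_mfm ~ I(age / 10) + C(gender)", data=sub).fit()
    out["gut_slope_min_per_decade"] = {
        "estimate": float(fit.params["I(age / 10)"]),
        "se": float(fit.bse["I(age / 10)"]),
    }
    subw = table[table["age"] >= 35]
    fit = smf.ols("waso_min ~ I(age / 10) + C(gender)", data=subw).fit()
    out["waso_slope_min_per_decade"] = {
        "estimate": float(fit.params["I(age / 10)"]),
        "se": float(fit.bse["I(age / 10)"]),
    }
    both = table[table["gender"].isin(["male", "female"])].copy()
    both["is_female"] = (both["gender"] == "female").astype(float)
    fit = smf.ols("tst_min ~ is_female + C(age_group)", data=both).fit()
    out["gender_tst_gap_min"] = {
        "estimate": float(fit.params["is_female"]),
        "se": float(fit.bse["is_female"]),
    }
    return out


# ---------------------------------------------------------------------------
# full per-parameter analysis


@dataclass
class EffectReport:
    """Age/gender/month effects on one sleep parameter."""

    parameter: str
    response_column: str
    distribution: str
    link: str
    alpha: float
    interaction_p: float
    interaction_significant: bool
    path: str  # {main_effects, stratified}
    main_effects: dict
    contrasts: pd.DataFrame
    aic_table: pd.DataFrame
    n: int


def _age_contrasts(fit: GLMFit, stratum: str, alpha: float) -> pd.DataFrame:
    pattern = re.compile(r"^C\(age_group, Treatment\('20s'\)\)\[T\.(.+)\]$")
    rows = []
    for name in fit.params.index:
        m = pattern.match(name)
        if m:
            rows.append(
                {
                    "stratum": stratum,
                    "group": m.group(1),
                    "reference": "20s",
                    "estimate": float(fit.params[name]),
                    "se": float(fit.bse[name]),
                    "p_raw": float(fit.pvalues[name]),
                }
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = bonferroni_adjust(out["p_raw"].to_numpy(), len(out))
        out["significant"] = out["p_adj"] < alpha
    return out


def _drop_term_p(data, response, rhs_terms, term, dist, link, full_fit) -> float:
    reduced_rhs = " + ".join(t for t in rhs_terms if t != term)
    if not reduced_rhs:
        reduced_rhs = "1"
    reduced = fit_glm(data, response, reduced_rhs, dist, link)
    if not reduced.converged:
        return float("nan")
    return f_test_nested(full_fit, reduced)


def analyze_parameter(
    table: pd.DataFrame,
    parameter: str,
    alpha: float = 0.01,
    candidates: Optional[Sequence[tuple[str, str]]] = None,
) -> EffectReport:
    """The full analysis path for one sleep parameter.

    Selects the residual family and link by AIC on the interaction design,
    judges the age-by-gender interaction by a likelihood-ratio test at
    ``alpha``, then either reports main effects from the interaction-free
    refit or stratifies by gender (simple age effects, Bonferroni within
    gender) and by age group (gender contrasts, Bonferroni across groups).
    """
    col = PARAM_COLUMNS.get(parameter, parameter)
    if col not in table.columns:
        raise InputError(f"parameter column '{col}' not found in table")
    data = table.dropna(subset=[col]).copy()
    data = data[data["gender"].isin(["male", "female"])]
    data["age_group"] = data["age_group"].cat.remove_unused_categories()
    if data["age_group"].nunique() < 2 or data["gender"].nunique() < 2:
        raise InputError("need at least two age groups and both genders")

    terms = [_AGE_TERM, "C(gender)", "C(month)"]
    rhs_main = " + ".join(terms)
    rhs_int = rhs_main + f" + {_AGE_TERM}:C(gender)"

    best_int, aic_table = select_model(data, col, rhs_int, candidates=candidates)
    dist, link = best_int.distribution, best_int.link
    fit_main = fit_glm(data, col, rhs_main, dist, link)
    interaction_p = f_test_nested(best_int, fit_main)
    significant = bool(np.isfinite(interaction_p) and interaction_p < alpha)

    if not significant:
        main_effects = {
            "age_group": _drop_term_p(data, col, terms, _AGE_TERM, dist, link, fit_main),
            "gender": _drop_term_p(data, col, terms, "C(gender)", dist, link, fit_main),
            "month": _drop_term_p(data, col, terms, "C(month)", dist, link, fit_main),
        }
        contrasts = _age_contrasts(fit_main, stratum="all", alpha=alpha)
        path = "main_effects"
    else:
        main_effects = {"interaction": interaction_p}
        frames = []
        strat_terms = [_AGE_TERM, "C(month)"]
        for gender, sub in data.groupby("gender", observed=True):
            sub = sub.copy()
            sub["age_group"] = sub["age_group"].cat.remove_unused_categories()
            if "20s" not in list(sub["age_group"].cat.categories):
                continue
            gfit = fit_glm(sub, col, " + ".join(strat_terms), dist, link)
            if gfit.converged:
                frames.append(_age_contrasts(gfit, stratum=str(gender), alpha=alpha))
                main_effects[f"age_group|{gender}"] = _drop_term_p(
                    sub, col, strat_terms, _AGE_TERM, dist, link, gfit
                )
        gender_rows = []
        for group, sub in data.groupby("age_group", observed=True):
            if sub["gender"].nunique() < 2:
                continue
            gfit = fit_glm(sub, col, "C(gender) + C(month)", dist, link)
            if not gfit.converged:
                continue
            name = [n for n in gfit.params.index if n.startswith("C(gender)")]
            if name:
                gender_rows.append(
                    {
                        "stratum": str(group),
                        "group": "gender",
                        "reference": "female",
                        "estimate": float(gfit.params[name[0]]),
                        "se": float(gfit.bse[name[0]]),
                        "p_raw": float(gfit.pvalues[name[0]]),
                    }
                )
        gdf = pd.DataFrame(gender_rows)
        if not gdf.empty:
            gdf["p_adj"] = bonferroni_adjust(gdf["p_raw"].to_numpy(), len(gdf))
            gdf["significant"] = gdf["p_adj"] < alpha
            frames.append(gdf)
        contrasts = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        path = "stratified"

    return EffectReport(
        parameter=parameter,
        response_column=col,
        distribution=dist,
        link=link,
        alpha=alpha,
        interaction_p=float(interaction_p),
        interaction_significant=significant,
        path=path,
        main_effects=main_effects,
        contrasts=contrasts,
        aic_table=aic_table,
        n=int(len(data)),
    )
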