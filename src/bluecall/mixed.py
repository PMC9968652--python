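"""Mixed-model year contrasts and the summer-foraging -> fall-song
regression.

Year effects on summer (Jan 1 - Feb 28) conditions and D calling are
tested with linear mixed models carrying a random intercept per hydrophone
site; significance comes from a likelihood-ratio test of the year factor
(ML, not REML), and pairwise year contrasts get a Tukey
(studentized-range) correction. The reproduction link is the same model
with the site-year summer D-call mean predicting the subsequent fall song
intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf


@dataclass
class PairwiseContrast:
    pair: tuple[str, str]
    estimate: float
    se: float
    adjusted_p: float


@dataclass
class MixedModelResult:
    response: str
    fixed_effect: str
    chi_square: float
    p_value: float
    df: int
    random_intercept_sd: float
    coefficients: pd.Series = field(repr=False)
    cov_params: pd.DataFrame = field(repr=False)
    n_obs: int = 0
    n_groups: int = 0
    resid_df: int = 0
    pairwise: list[PairwiseContrast] | None = None
    slope: float | None = None
    slope_ci: tuple[float, float] | None = None
    degenerate: bool = False
    single_site_fallback: bool = False


def summer_subset(daily: pd.DataFrame, years: list[int]) -> pd.DataFrame:
    """Rows with date in Jan 1 - Feb 28 of the requested years (Feb 29 is
    outside the window by definition)."""
    dates = pd.DatetimeIndex(daily["date"])
    mask = (
        dates.year.isin(years)
        & ((dates.month == 1) | ((dates.month == 2) & (dates.day <= 28)))
    )
    out = daily[mask].copy()
    if out.empty:
        raise ValueError("no rows in the summer window for the requested years")
    out["year"] = pd.DatetimeIndex(out["date"]).year
    return out


def _loglik_lrt(ll_full: float, ll_null: float, df: int) -> tuple[float, float]:
    chi2 = max(2.0 * (ll_full - ll_null), 0.0)
    return chi2, float(stats.chi2.sf(chi2, df))


def fit_year_lmm(panel: pd.DataFrame, response: str, site_col: str = "site_id") -> MixedModelResult:
    """``response ~ C(year)`` with a random intercept per site.

    The chi-square is the likelihood-ratio statistic against the
    intercept-only model (both fit by ML). With a single site the model
    falls back to ordinary least squares with a warning.
    """
    panel = panel.dropna(subset=[response]).copy()
    years = sorted(panel["year"].unique())
    if len(years) < 2:
        raise ValueError("need at least two years")
    if float(panel[response].var()) == 0:
        res = _degenerate_result(response, panel, site_col)
        return res
    formula = f"{response} ~ C(year)"
    single_site = panel[site_col].nunique() < 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if single_site:
            full = smf.ols(formula, data=panel).fit()
            null = smf.ols(f"{response} ~ 1", data=panel).fit()
            re_sd = 0.0
            resid_df = int(full.df_resid)
        else:
            full = smf.mixedlm(formula, data=panel, groups=panel[site_col]).fit(reml=False)
            null = smf.mixedlm(f"{response} ~ 1", data=panel, groups=panel[site_col]).fit(
                reml=False
            )
            re_sd = float(np.sqrt(max(np.asarray(full.cov_re).ravel()[0], 0.0)))
            resid_df = int(len(panel) - len(years) - panel[site_col].nunique())
    if single_site:
        warnings.warn("single site: fixed-effects fallback", stacklevel=2)
    chi2, p = _loglik_lrt(full.llf, null.llf, len(years) - 1)
    coef = full.params
    cov = pd.DataFrame(full.cov_params(), index=coef.index, columns=coef.index)
    return MixedModelResult(
        response=response,
        fixed_effect="year",
        chi_square=chi2,
        p_value=p,
        df=len(years) - 1,
        random_intercept_sd=re_sd,
        coefficients=coef,
        cov_params=cov,
        n_obs=len(panel),
        n_groups=panel[site_col].nunique(),
        resid_df=max(resid_df, 2),
        single_site_fallback=single_site,
    )


def _degenerate_result(response: str, panel: pd.DataFrame, site_col: str) -> MixedModelResult:
    warnings.warn("constant response: degenerate fit", stacklevel=3)
    return MixedModelResult(
        response=response,
        fixed_effect="year",
        chi_square=0.0,
        p_value=1.0,
        df=0,
        random_intercept_sd=0.0,
        coefficients=pd.Series(dtype=float),
        cov_params=pd.DataFrame(),
        n_obs=len(panel),
        n_groups=panel[site_col].nunique(),
        degenerate=True,
    )


def _year_level_terms(coefficients: pd.Series) -> dict[str, str]:
    """Map year labels to their design-matrix terms (reference year -> None)."""
    terms = {}
    for name in coefficients.index:
        if name.startswith("C(year)[T."):
            level = name[len("C(year)[T.") : -1]
            terms[level] = name
    return terms


def tukey_pairwise(result: MixedModelResult, alpha: float = 0.05) -> list[PairwiseContrast]:
    """All pairwise year contrasts with studentized-range (Tukey-family)
    adjusted p-values computed from the fitted fixed effects."""
    if result.degenerate:
        return []
    terms = _year_level_terms(result.coefficients)
    ref_levels = [lv for lv in terms]
    # reconstruct the full level list: reference level is the intercept
    all_levels = ["<ref>"] + ref_levels
    k = len(all_levels)
    if k < 2:
        raise ValueError("factor fixed effect with >= 2 levels required")

    def contrast(l1: str, l2: str) -> tuple[float, float]:
        v1 = result.coefficients.get(terms.get(l1, ""), 0.0) if l1 != "<ref>" else 0.0
        v2 = result.coefficients.get(terms.get(l2, ""), 0.0) if l2 != "<ref>" else 0.0
        est = v1 - v2
        names = result.cov_params.index
        w = pd.Series(0.0, index=names)
        if l1 != "<ref>":
            w[terms[l1]] = 1.0
        if l2 != "<ref>":
            w[terms[l2]] -= 1.0
        var = float(w @ result.cov_params @ w)
        return est, np.sqrt(max(var, 1e-300))

    out = []
    df = result.resid_df
    for i in range(k):
        for j in range(i + 1, k):
            l1, l2 = all_levels[i], all_levels[j]
            est, se = contrast(l2, l1)
            q = abs(est) / se * np.sqrt(2.0)
            p_adj = float(np.clip(stats.studentized_range.sf(q, k, df), 0.0, 1.0))
            out.append(
                PairwiseContrast(
                    pair=(l1 if l1 != "<ref>" else "ref", l2 if l2 != "<ref>" else "ref"),
                    estimate=est,
                    se=se,
                    adjusted_p=p_adj,
                )
            )
    result.pairwise = out
    return out


def tukey_pairwise_labeled(result: MixedModelResult, reference_label: str) -> list[PairwiseContrast]:
    """tukey_pairwise with the reference level given its real label."""
    out = tukey_pairwise(result)
    return [
        PairwiseContrast(
            pair=tuple(reference_label if p == "ref" else p for p in c.pair),
            estimate=c.estimate,
            se=c.se,
            adjusted_p=c.adjusted_p,
        )
        for c in out
    ]


def foraging_reproduction_lmm(
    pairs: pd.DataFrame,
    summer_col: str = "summer_dcall_mean",
    fall_col: str = "fall_sii_mean",
    site_col: str = "site_id",
) -> MixedModelResult:
    """Fall song intensity against summer D-call activity.

    ``pairs`` carries one row per site-year with the summer (Jan 1-Feb 28)
    mean D-call count and the subsequent fall (Apr 1-Jun 30) mean song
    intensity index. Fits fall ~ summer with a random site intercept (ML)
    and reports the slope, its Wald CI, and the LRT against the no-slope
    model.
    """
    pairs = pairs.dropna(subset=[summer_col, fall_col])
    if len(pairs) < 4:
        raise ValueError("need at least 4 site-year pairs")
    if float(pairs[fall_col].var()) == 0:
        return _degenerate_result(fall_col, pairs, site_col)
    formula = f"{fall_col} ~ {summer_col}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if pairs[site_col].nunique() < 2:
            full = smf.ols(formula, data=pairs).fit()
            null = smf.ols(f"{fall_col} ~ 1", data=pairs).fit()
            report = full
            re_sd, single = 0.0, True
        else:
            full = smf.mixedlm(formula, data=pairs, groups=pairs[site_col]).fit(reml=False)
            null = smf.mixedlm(f"{fall_col} ~ 1", data=pairs, groups=pairs[site_col]).fit(
                reml=False
            )
            # ML pair drives the LRT; REML refit reports the slope and its
            # interval (ML variance is biased low at these small panels)
            report = smf.mixedlm(formula, data=pairs, groups=pairs[site_col]).fit(reml=True)
            re_sd = float(np.sqrt(max(np.asarray(report.cov_re).ravel()[0], 0.0)))
            single = False
    chi2, p = _loglik_lrt(full.llf, null.llf, 1)
    slope = float(report.params[summer_col])
    se = float(np.sqrt(max(report.cov_params().loc[summer_col, summer_col], 0.0)))
    # containment degrees of freedom: with a site random intercept the
    # slope is carried by within-site variation, df = n - groups - 1
    if single:
        df_t = max(len(pairs) - 2, 1)
    else:
        df_t = max(len(pairs) - pairs[site_col].nunique() - 1, 1)
    tcrit = float(stats.t.ppf(0.975, df_t))
    ci = (slope - tcrit * se, slope + tcrit * se)
    coef = report.params
    cov = pd.DataFrame(report.cov_params(), index=coef.index, columns=coef.index)
    return MixedModelResult(
        response=fall_col,
        fixed_effect=summer_col,
        chi_square=chi2,
        p_value=p,
        df=1,
        random_intercept_sd=re_sd,
        coefficients=coef,
        cov_params=cov,
        n_obs=len(pairs),
        n_groups=pairs[site_col].nunique(),
        slope=slope,
        slope_ci=ci,
        single_site_fallback=single,
    )
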