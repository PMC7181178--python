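"""Between-map summary measures and their ANOVA comparisons.

Each (hemisphere, map, subject) cell is reduced to summary measures over its
non-excluded recording sites: surface area, mean variance explained, mean
compressive exponent, mean preferred duration/period and their interquartile
ranges, mean extents, aspect ratio, and the circular mean of the response
function orientation (axial data with period pi).

Measures are compared with main-effects-only ANOVAs (hemisphere, map and
subject as factors; Type-II sums of squares since real designs are
unbalanced).  When the hemisphere effect is not significant the model is
refit as a two-way ANOVA (map, subject).  Map differences are localized with
population marginal means, 95% confidence intervals and Tukey-style
honestly-significant-difference pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import studentized_range, t as t_dist

SUMMARY_MEASURES = [
    "surface_area",
    "mean_ve",
    "mean_exp_freq",
    "mean_pref_duration",
    "mean_pref_period",
    "iqr_duration",
    "iqr_period",
    "mean_theta",
    "mean_sigma_maj",
    "mean_sigma_min",
    "mean_aspect_ratio",
]


def circular_mean_axial(theta: np.ndarray) -> float:
    """Mean orientation of axial data (period pi), reported in [0, pi)."""
    theta = np.asarray(theta, float)
    theta = theta[~np.isnan(theta)]
    if theta.size == 0:
        return float("nan")
    s = np.sin(2 * theta).mean()
    c = np.cos(2 * theta).mean()
    return float((0.5 * np.arctan2(s, c)) % np.pi)


def summarize_map(sites: pd.DataFrame) -> pd.Series:
    """Summary measures for one map's non-excluded site fits.

    ``sites`` needs the per-site fit columns (ve_full, exp_freq,
    preferred_duration, preferred_period, sigma_maj, sigma_min, theta,
    aspect_ratio, excluded) and per-site ``area_mm2`` geometry.
    """
    if "excluded" in sites:
        sites = sites.loc[~sites["excluded"].astype(bool)]
    if len(sites) == 0:
        raise ValueError("map has no included sites")

    def iqr(v):
        v = v.dropna()
        if len(v) == 0:
            return float("nan")
        return float(np.percentile(v, 75) - np.percentile(v, 25))

    return pd.Series(
        {
            "surface_area": float(sites["area_mm2"].sum()) if "area_mm2" in sites else float("nan"),
            "mean_ve": float(sites["ve_full"].mean()),
            "mean_exp_freq": float(sites["exp_freq"].mean()),
            "mean_pref_duration": float(sites["preferred_duration"].mean()),
            "mean_pref_period": float(sites["preferred_period"].mean()),
            "iqr_duration": iqr(sites["preferred_duration"]),
            "iqr_period": iqr(sites["preferred_period"]),
            "mean_theta": circular_mean_axial(sites["theta"].to_numpy(float)),
            "mean_sigma_maj": float(sites["sigma_maj"].mean()),
            "mean_sigma_min": float(sites["sigma_min"].mean()),
            "mean_aspect_ratio": float(sites["aspect_ratio"].mean()),
            "n_sites": int(len(sites)),
        }
    )


def summarize_maps(
    fits: pd.DataFrame, group_cols: tuple[str, ...] = ("hemisphere", "map", "subject")
) -> pd.DataFrame:
    """One :func:`summarize_map` row per (hemisphere, map, subject) cell."""
    rows = []
    for key, g in fits.groupby(list(group_cols)):
        row = summarize_map(g)
        for c, v in zip(group_cols, np.atleast_1d(key)):
            row[c] = v
        rows.append(row)
    return pd.DataFrame(rows).reset_index(drop=True)


@dataclass
class AnovaResult:
    measure: str
    anova_table: pd.DataFrame
    factors: tuple[str, ...]
    hemisphere_dropped: bool
    marginal_means: pd.DataFrame
    pairwise: pd.DataFrame
    degenerate: bool = False


def _fit_main_effects(data: pd.DataFrame, measure: str, factors: tuple[str, ...]):
    formula = f"{measure} ~ " + " + ".join(f"C({f})" for f in factors)
    model = smf.ols(formula, data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return model, table


def _marginal_means(model, data: pd.DataFrame, factors: tuple[str, ...], factor: str):
    """Population marginal means for one factor: predictions averaged over a
    balanced grid of the other factors, with 95% CIs from the fit covariance."""
    others = [f for f in factors if f != factor]
    levels = {f: sorted(data[f].unique()) for f in factors}
    rows = []
    for lev in levels[factor]:
        grid = pd.DataFrame(
            [
                {factor: lev, **dict(zip(others, combo))}
                for combo in _product([levels[f] for f in others])
            ]
        )
        pred = model.get_prediction(grid)
        mean = float(pred.predicted_mean.mean())
        # variance of the average prediction: w' V w with equal weights
        import patsy

        X = patsy.dmatrix(model.model.data.design_info, grid, return_type="dataframe")
        w = np.full(len(X), 1.0 / len(X))
        var = float(w @ X.to_numpy() @ model.cov_params().to_numpy() @ X.to_numpy().T @ w)
        se = np.sqrt(var)
        df = model.df_resid
        half = t_dist.ppf(0.975, df) * se
        rows.append(
            {factor: lev, "marginal_mean": mean, "se": se, "ci_low": mean - half, "ci_high": mean + half}
        )
    return pd.DataFrame(rows)


def _product(list_of_levels):
    import itertools

    if not list_of_levels:
        return [()]
    return list(itertools.product(*list_of_levels))


def _tukey_pairwise(mm: pd.DataFrame, factor: str, df_resid: float) -> pd.DataFrame:
    """Tukey HSD on marginal means (studentized-range correction)."""
    k = len(mm)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = mm["marginal_mean"].iloc[i] - mm["marginal_mean"].iloc[j]
            se = np.sqrt(mm["se"].iloc[i] ** 2 + mm["se"].iloc[j] ** 2)
            if se == 0:
                q, p = np.inf if diff else 0.0, 0.0 if diff else 1.0
            else:
                q = abs(diff) / (se / np.sqrt(2))
                p = float(studentized_range.sf(q, k, df_resid))
            rows.append(
                {
                    "level_1": mm[factor].iloc[i],
                    "level_2": mm[factor].iloc[j],
                    "diff": diff,
                    "q": q,
                    "p_adj": p,
                }
            )
    return pd.DataFrame(rows)


def anova_measures(
    summaries: pd.DataFrame,
    measure: str,
    factors: tuple[str, ...] = ("hemisphere", "map", "subject"),
    hemisphere_alpha: float = 0.05,
) -> AnovaResult:
    """Main-effects ANOVA of one summary measure across maps.

    Starts three-way (hemisphere, map, subject); if the hemisphere effect is
    not significant the model is refit two-way.  Degenerate (zero-variance)
    inputs are flagged rather than tested.
    """
    data = summaries.dropna(subset=[measure]).copy()
    factors = tuple(f for f in factors if data[f].nunique() > 1)
    if len(factors) < 2:
        raise ValueError("need >= 2 levels in at least two factors")
    if np.isclose(data[measure].std(ddof=0), 0.0):
        return AnovaResult(
            measure=measure,
            anova_table=pd.DataFrame(),
            factors=factors,
            hemisphere_dropped=False,
            marginal_means=pd.DataFrame(),
            pairwise=pd.DataFrame(),
            degenerate=True,
        )
    model, table = _fit_main_effects(data, measure, factors)
    dropped = False
    if "hemisphere" in factors:
        p_hemi = float(table.loc["C(hemisphere)", "PR(>F)"])
        if p_hemi >= hemisphere_alpha:
            factors = tuple(f for f in factors if f != "hemisphere")
            model, table = _fit_main_effects(data, measure, factors)
            dropped = True
    mm = _marginal_means(model, data, factors, "map")
    pw = _tukey_pairwise(mm, "map", model.df_resid)
    return AnovaResult(
        measure=measure,
        anova_table=table,
        factors=factors,
        hemisphere_dropped=dropped,
        marginal_means=mm,
        pairwise=pw,
    )
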