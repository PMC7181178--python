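"""Within-map progressions of timing preferences and extents.

Each recording site's position along a timing map is summarized by a single
coordinate: the ratio of its cortical distances to the map's low- and
high-preference border lines, scaled by the mean map length.  Preferences
are binned every 2 mm for display and logarithmic progression fitting
(bootstrap over bins; median slope/intercept with percentile confidence
intervals); statistical significance of progressions uses Pearson
correlations on raw sites with degrees of freedom deflated by the
surface-upsampling factor and false-discovery-rate correction across all
map x subject tests.

Extent-versus-preference structure is tested with a balanced-bootstrap GLM:
sites are split at the middle of the presented range (0.5 s), the larger
side is repeatedly subsampled to balance counts, and a three-predictor
model (preferred duration, |preference - 0.5 s|, constant) is fit per
permutation, averaging the t statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MIDDLE_OF_RANGE = 0.5  # s
MIN_BIN_AREA = 1.77  # mm^2, one voxel; 2.0 mm^2 is the 7T point-spread bound


def distance_along_map(
    d_low: np.ndarray, d_high: np.ndarray, mean_map_length: float
) -> np.ndarray:
    """Normalized border-distance ratio scaled to a coordinate in mm.

    coordinate = d_low / (d_low + d_high) * mean_map_length.
    """
    d_low = np.asarray(d_low, float)
    d_high = np.asarray(d_high, float)
    if np.any(d_low < 0) or np.any(d_high < 0):
        raise ValueError("border distances must be >= 0")
    total = d_low + d_high
    if np.any(total == 0):
        raise ValueError("site with zero distance to both borders")
    return d_low / total * mean_map_length


@dataclass
class ProgressionFit:
    """Bootstrapped fit of value = intercept + slope * f(distance)."""

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    n_boot: int
    model: str  # 'log' or 'linear'
    eps: float


def _design(x: np.ndarray, model: str, eps: float) -> np.ndarray:
    if model == "log":
        return np.log(x + eps)
    if model == "linear":
        return x.astype(float)
    raise ValueError("model must be 'log' or 'linear'")


def bin_sites(
    coords: np.ndarray,
    values: np.ndarray,
    areas: np.ndarray,
    upsampling: float = 1.0,
    bin_width: float = 2.0,
    min_area: float = MIN_BIN_AREA,
    design: np.ndarray | None = None,
) -> pd.DataFrame:
    """Bin sites every ``bin_width`` mm; drop bins with too little surface.

    Bin SEs are corrected for surface upsampling (effective n = n/upsampling).
    When a per-site ``design`` regressor is given (e.g. log distance), its
    within-bin mean is kept so progression fits average the regressor the
    same way as the response, avoiding binning bias.
    """
    coords = np.asarray(coords, float)
    values = np.asarray(values, float)
    areas = np.asarray(areas, float)
    idx = np.floor(coords / bin_width).astype(int)
    rows = []
    for b in np.unique(idx):
        m = idx == b
        n = int(m.sum())
        n_eff = max(n / upsampling, 1.0)
        v = values[m]
        rows.append(
            {
                "center": (b + 0.5) * bin_width,
                "site_count": n,
                "mean": v.mean(),
                "se": v.std(ddof=1) / np.sqrt(n_eff) if n > 1 else np.nan,
                "represented_area": areas[m].sum(),
                "design_mean": design[m].mean() if design is not None else np.nan,
            }
        )
    bins = pd.DataFrame(rows)
    bins["excluded"] = bins["represented_area"] < min_area
    return bins


def fit_progression(
    bins: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    model: str = "log",
    eps: float = 1.0,
) -> ProgressionFit:
    """Bootstrap bins with replacement; median fit and 2.5/97.5% CIs."""
    keep = bins.loc[~bins["excluded"]]
    if len(keep) < 3:
        raise ValueError(f"need >= 3 surviving bins, have {len(keep)}")
    if "design_mean" in keep and keep["design_mean"].notna().all():
        x = keep["design_mean"].to_numpy()
    else:
        x = _design(keep["center"].to_numpy(), model, eps)
    y = keep["mean"].to_numpy()
    rng = np.random.default_rng(seed)
    k = len(x)
    idx = rng.integers(0, k, size=(n_boot, k))
    xb, yb = x[idx], y[idx]
    xm = xb.mean(axis=1, keepdims=True)
    ym = yb.mean(axis=1, keepdims=True)
    varx = ((xb - xm) ** 2).sum(axis=1)
    cov = ((xb - xm) * (yb - ym)).sum(axis=1)
    good = varx > 0
    slopes = np.where(good, cov / np.where(varx > 0, varx, 1.0), np.nan)
    inters = ym[:, 0] - slopes * xm[:, 0]
    return ProgressionFit(
        slope=float(np.nanmedian(slopes)),
        intercept=float(np.nanmedian(inters)),
        slope_ci=(float(np.nanpercentile(slopes, 2.5)), float(np.nanpercentile(slopes, 97.5))),
        intercept_ci=(
            float(np.nanpercentile(inters, 2.5)),
            float(np.nanpercentile(inters, 97.5)),
        ),
        n_boot=n_boot,
        model=model,
        eps=eps,
    )


def bin_and_fit(
    sites: pd.DataFrame,
    value_cols: tuple[str, ...] = ("preferred_duration", "preferred_period"),
    coord_col: str = "coordinate_mm",
    area_col: str = "area_mm2",
    upsampling: float = 1.0,
    bin_width: float = 2.0,
    min_area: float = MIN_BIN_AREA,
    n_boot: int = 1000,
    seed: int = 0,
    model: str = "log",
    eps: float | None = None,
) -> tuple[dict[str, pd.DataFrame], dict[str, ProgressionFit]]:
    """Bin each value column along the map and fit its progression."""
    eps = bin_width / 2 if eps is None else eps
    bins_out, fits_out = {}, {}
    for col in value_cols:
        ok = sites[col].notna()
        coords = sites.loc[ok, coord_col].to_numpy()
        bins = bin_sites(
            coords,
            sites.loc[ok, col].to_numpy(),
            sites.loc[ok, area_col].to_numpy(),
            upsampling=upsampling,
            bin_width=bin_width,
            min_area=min_area,
            design=_design(coords, model, eps),
        )
        bins_out[col] = bins
        fits_out[col] = fit_progression(bins, n_boot=n_boot, seed=seed, model=model, eps=eps)
    return bins_out, fits_out


def _corrected_pearson(x: np.ndarray, y: np.ndarray, upsampling: float):
    """Pearson r with p from df = n/upsampling - 2."""
    n = len(x)
    df = n / upsampling - 2
    if df < 1:
        raise ValueError("effective degrees of freedom < 1")
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0, 1.0, df
    r = float(np.corrcoef(x, y)[0, 1])
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt(df / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), df)
    return r, float(p), df


def progression_correlations(
    sites: pd.DataFrame,
    value_col: str = "preferred_duration",
    coord_col: str = "coordinate_mm",
    group_cols: tuple[str, ...] = ("subject", "hemisphere", "map"),
    upsampling_col: str = "upsampling",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-map Pearson correlation of preference vs cortical distance.

    p values use upsampling-corrected degrees of freedom;
    Benjamini-Hochberg FDR runs across all map x subject tests.
    """
    rows = []
    for key, g in sites.groupby(list(group_cols)):
        g = g.loc[g[value_col].notna()]
        if len(g) < 3:
            continue
        up = float(g[upsampling_col].iloc[0]) if upsampling_col in g else 1.0
        r, p, df = _corrected_pearson(
            g[coord_col].to_numpy(float), g[value_col].to_numpy(float), up
        )
        rows.append(dict(zip(group_cols, np.atleast_1d(key))) | {"r": r, "p": p, "df": df, "n": len(g)})
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no map had >= 3 usable sites")
    rej, q, *_ = multipletests(out["p"], alpha=alpha, method="fdr_bh")
    out["q"] = q
    out["significant"] = rej
    return out


def split_half_repeatability(
    odd: pd.DataFrame,
    even: pd.DataFrame,
    value_col: str = "preferred_duration",
    group_cols: tuple[str, ...] = ("subject", "hemisphere", "map"),
    site_col: str = "site_id",
    upsampling_col: str = "upsampling",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate preferences fitted on odd vs even runs, per map."""
    keys = list(group_cols) + [site_col]
    merged = odd.merge(even, on=keys, suffixes=("_odd", "_even"))
    rows = []
    for key, g in merged.groupby(list(group_cols)):
        vo = g[f"{value_col}_odd"].to_numpy(float)
        ve = g[f"{value_col}_even"].to_numpy(float)
        ok = ~np.isnan(vo) & ~np.isnan(ve)
        if ok.sum() < 3:
            raise ValueError("fewer than 3 shared sites in a map")
        up_col = f"{upsampling_col}_odd" if f"{upsampling_col}_odd" in g else upsampling_col
        up = float(g[up_col].iloc[0]) if up_col in g else 1.0
        r, p, df = _corrected_pearson(vo[ok], ve[ok], up)
        rows.append(dict(zip(group_cols, np.atleast_1d(key))) | {"r": r, "p": p, "df": df, "n": int(ok.sum())})
    out = pd.DataFrame(rows)
    rej, q, *_ = multipletests(out["p"], alpha=alpha, method="fdr_bh")
    out["q"] = q
    out["significant"] = rej
    return out


def extent_glm(
    preferred: np.ndarray,
    extents: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    upsampling: float = 1.0,
    middle: float = MIDDLE_OF_RANGE,
) -> pd.DataFrame:
    """Balanced-bootstrap GLM of extent on preference and range-middle distance.

    Predictors: preferred duration, |preference - middle|, constant.  Each of
    ``n_perm`` permutations discards a random subset of the larger side of the
    middle so both sides contribute equally, fits the GLM by least squares and
    records per-predictor t statistics; reported t is the mean across
    permutations, converted to p at the fixed balanced n with
    upsampling-corrected degrees of freedom.
    """
    pref = np.asarray(preferred, float)
    ext = np.asarray(extents, float)
    below = np.flatnonzero(pref < middle)
    above = np.flatnonzero(pref >= middle)
    if below.size == 0 or above.size == 0:
        raise ValueError("need sites on both sides of the middle of the range")
    n_bal = min(below.size, above.size)
    rng = np.random.default_rng(seed)
    tstats = np.empty((n_perm, 3))
    for it in range(n_perm):
        b = below if below.size == n_bal else rng.choice(below, n_bal, replace=False)
        a = above if above.size == n_bal else rng.choice(above, n_bal, replace=False)
        sel = np.concatenate([b, a])
        X = np.column_stack(
            [pref[sel], np.abs(pref[sel] - middle), np.ones(sel.size)]
        )
        y = ext[sel]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = sel.size - 3
        sigma2 = resid @ resid / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        tstats[it] = beta / np.sqrt(np.diag(cov))
    mean_t = tstats.mean(axis=0)
    df = 2 * n_bal / upsampling - 3
    if df < 1:
        raise ValueError("effective degrees of freedom < 1")
    p = 2 * stats.t.sf(np.abs(mean_t), df)
    return pd.DataFrame(
        {
            "predictor": ["preferred_duration", "abs_distance_from_middle", "constant"],
            "mean_t": mean_t,
            "p": p,
            "n_balanced": 2 * n_bal,
            "df": df,
        }
    )


def define_rois(
    ve: np.ndarray,
    edges: list[tuple[int, int]],
    thresholds: np.ndarray | None = None,
) -> tuple[np.ndarray, float, pd.DataFrame]:
    """Threshold-sweep surface clustering with knee selection.

    Sweeps variance-explained thresholds, counts connected components of
    supra-threshold vertices, finds the widest contiguous threshold interval
    with a stable nonzero cluster count, and returns cluster labels at that
    interval's lowest threshold (the knee).  Labels are -1 for vertices
    below threshold; clusters are numbered in vertex order.
    """
    import networkx as nx

    ve = np.asarray(ve, float)
    if thresholds is None:
        thresholds = np.round(np.arange(0.05, 0.951, 0.025), 10)
    g_all = nx.Graph()
    g_all.add_nodes_from(range(len(ve)))
    g_all.add_edges_from(edges)

    counts = []
    for thr in thresholds:
        keep = np.flatnonzero(ve >= thr)
        sub = g_all.subgraph(keep)
        counts.append(nx.number_connected_components(sub) if keep.size else 0)
    counts = np.array(counts)
    if not np.any(counts >= 1):
        raise ValueError("no threshold yields any cluster")

    best_len, best_start = 0, None
    i = 0
    while i < len(counts):
        j = i
        while j < len(counts) and counts[j] == counts[i]:
            j += 1
        if counts[i] >= 1 and (j - i) > best_len:
            best_len, best_start = j - i, i
        i = j
    knee = float(thresholds[best_start])

    keep = np.flatnonzero(ve >= knee)
    labels = np.full(len(ve), -1)
    comps = sorted(
        nx.connected_components(g_all.subgraph(keep)), key=lambda c: min(c)
    )
    for lab, comp in enumerate(comps):
        labels[list(comp)] = lab
    sweep = pd.DataFrame({"threshold": thresholds, "n_clusters": counts})
    return labels, knee, sweep
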