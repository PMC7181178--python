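"""Per-site model fitting, cross-validation and model comparison.

Fitting follows the standard coarse-to-fine population receptive field
recipe: an exhaustive, deterministic grid search over candidate parameter
combinations, followed by derivative-free simplex (Nelder-Mead) refinement
started from the best grid point(s).  The objective is the squared Pearson
correlation between the predicted and measured timecourse, so response gain
and baseline are absorbed.

Candidate preferred durations and periods extend beyond the presented 50 to
1000 ms range, so preferences inside the range are genuine optima rather
than boundary artifacts; sites whose fitted preferences fall outside the
range, or whose full-fit variance explained is below 0.10, are flagged
excluded.

Model comparison uses cross-validated variance explained (fit on the odd-run
average, score on the even-run average, and vice versa), which penalizes the
extra flexibility of larger model families; sites enter the comparison if at
least one candidate model reaches 20% cross-validated variance explained.

The core is exposed as the scikit-learn style estimator :class:`TimingPRF`;
the module-level functions are thin wrappers over it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .forward import ForwardDesign, HRFParams, variance_explained
from .models import (
    MONOTONIC_FAMILIES,
    ModelSpec,
    TUNED_FAMILIES,
    params_from_vector,
    space_to_state,
)

PREF_RANGE = (0.05, 1.0)  # presented timing range, s
VE_EXCLUDE = 0.10
VE_COMPARE = 0.20

DERIVED_COLUMNS = [
    "preferred_duration",
    "preferred_period",
    "sigma_maj",
    "sigma_min",
    "theta",
    "exp_freq",
    "aspect_ratio",
]


# ---------------------------------------------------------------------------
# parameter grids


def _axis2_grid(space: str) -> np.ndarray:
    if space == "period_occupancy":
        return np.round(np.arange(0.1, 1.001, 0.1), 10)
    return np.round(np.arange(0.05, 1.1501, 0.1), 10)


def default_grid(spec: ModelSpec) -> np.ndarray:
    """Deterministic candidate parameter lattice for one model family.

    Low-dimensional families get dense grids; the 2-D families get coarser
    lattices (preferences in 0.1 s steps out to 1.15 s, log-spaced extents,
    4 orientations) that the simplex refinement then polishes.  Preference
    grids extend beyond the presented 0.05-1.0 s range so out-of-range
    optima exist and can trigger exclusion.
    """
    fam = spec.family
    exp_freq_dense = np.round(np.arange(0.1, 1.001, 0.1), 10)
    exp_freq_coarse = np.round(np.arange(0.2, 1.001, 0.2), 10)
    sigmas_dense = np.geomspace(0.05, 3.0, 12)
    sigmas_coarse = np.geomspace(0.05, 3.0, 6)
    pref_dense = np.round(np.arange(0.025, 1.2001, 0.025), 10)
    pref_coarse = _axis2_grid("duration_period")  # 0.05..1.15 step 0.1
    if spec.scale == "log":
        pref_dense = np.log(pref_dense)
        pref_coarse = np.log(pref_coarse)

    def product(*axes):
        return np.array(list(itertools.product(*axes)), dtype=float)

    if fam == "constant":
        return np.zeros((1, 0))
    if fam == "linear_monotonic":
        ar = np.concatenate([[0.0], np.geomspace(0.01, 100.0, 25)])
        return ar[:, None]
    if fam == "compressive_monotonic":
        ar = np.concatenate([[0.0], np.geomspace(0.01, 100.0, 13)])
        return product(ar, exp_freq_dense, exp_freq_dense)
    if fam == "tuned_1d":
        return product(pref_dense, sigmas_dense, exp_freq_dense)
    ax2 = _axis2_grid(spec.space)
    if spec.scale == "log":
        ax2 = np.log(ax2)
    if fam == "tuned_2d_isotropic":
        return product(pref_coarse, ax2, sigmas_dense, exp_freq_dense)
    if fam == "tuned_2d_anisotropic":
        sig_pairs = [
            (a, b) for a in sigmas_coarse for b in sigmas_coarse if a >= b
        ]
        thetas = np.arange(4) * np.pi / 4
        rows = [
            (p1, p2, smaj, smin, th, ef)
            for p1 in pref_coarse
            for p2 in ax2
            for smaj, smin in sig_pairs
            for th in thetas
            for ef in exp_freq_coarse
        ]
        return np.array(rows, dtype=float)
    raise ValueError(f"no default grid for family {fam!r}")


def _canonicalize(spec: ModelSpec, vec: np.ndarray) -> np.ndarray:
    """Enforce sigma_maj >= sigma_min (swapping rotates theta by pi/2)."""
    vec = vec.copy()
    if spec.family == "tuned_2d_anisotropic":
        smaj, smin, th = vec[2], vec[3], vec[4]
        smaj, smin = abs(smaj), abs(smin)
        if smin > smaj:
            smaj, smin = smin, smaj
            th = th + np.pi / 2
        vec[2], vec[3], vec[4] = smaj, smin, th % np.pi
        vec[5] = np.clip(vec[5], 0.0, 1.0)
    elif spec.family == "tuned_2d_isotropic":
        vec[2] = abs(vec[2])
        vec[3] = np.clip(vec[3], 0.0, 1.0)
    elif spec.family == "tuned_1d":
        vec[1] = abs(vec[1])
        vec[2] = np.clip(vec[2], 0.0, 1.0)
    elif spec.family == "compressive_monotonic":
        vec[0] = max(vec[0], 0.0)
        vec[1] = np.clip(vec[1], 1e-3, 1.0)
        vec[2] = np.clip(vec[2], 0.0, 1.0)
    elif spec.family == "linear_monotonic":
        vec[0] = max(vec[0], 0.0)
    return vec


def derived_quantities(spec: ModelSpec, vec: np.ndarray) -> dict[str, float]:
    """Preferred duration/period in seconds plus extents and orientation."""
    nan = float("nan")
    out = dict.fromkeys(DERIVED_COLUMNS, nan)
    fam = spec.family
    if fam in MONOTONIC_FAMILIES:
        if fam != "constant":
            out["exp_freq"] = 1.0 if fam == "linear_monotonic" else vec[2]
        else:
            out["exp_freq"] = 1.0
        return out
    if fam == "tuned_1d":
        pref = np.exp(vec[0]) if spec.scale == "log" else vec[0]
        out.update(preferred_duration=pref, sigma_maj=vec[1], exp_freq=vec[2])
        return out
    if fam in TUNED_FAMILIES:
        a1, a2 = vec[0], vec[1]
        if spec.scale == "log":
            a1, a2 = np.exp(a1), np.exp(a2)
        dur, per = space_to_state(a1, a2, spec.space)
        if fam == "tuned_2d_isotropic":
            smaj = smin = vec[2]
            theta, ef = 0.0, vec[3]
        else:
            smaj, smin, theta, ef = vec[2], vec[3], vec[4], vec[5]
        out.update(
            preferred_duration=dur,
            preferred_period=per,
            sigma_maj=smaj,
            sigma_min=smin,
            theta=theta,
            exp_freq=ef,
            aspect_ratio=smaj / smin,
        )
        return out
    return out


def exclusion_flags(derived: pd.DataFrame, ve_full: np.ndarray) -> pd.DataFrame:
    """Range and goodness-of-fit exclusions; idempotent and order-independent."""
    lo, hi = PREF_RANGE
    dur = derived["preferred_duration"].to_numpy(float)
    per = derived["preferred_period"].to_numpy(float)
    out_of_range = (~np.isnan(dur) & ((dur < lo) | (dur > hi))) | (
        ~np.isnan(per) & ((per < lo) | (per > hi))
    )
    low_ve = np.asarray(ve_full, float) < VE_EXCLUDE
    reason = np.where(
        out_of_range & low_ve,
        "out_of_range;low_ve",
        np.where(out_of_range, "out_of_range", np.where(low_ve, "low_ve", "")),
    )
    return pd.DataFrame({"excluded": out_of_range | low_ve, "exclusion_reason": reason})


# ---------------------------------------------------------------------------
# the estimator


class TimingPRF(BaseEstimator):
    """Timing population receptive field model, one candidate family.

    Parameters
    ----------
    spec : ModelSpec
        Which response function family/space/scale to fit.
    schedule : EventSchedule or RunSchedule
        Stimulus timing shared by all sites.
    hrf : HRFParams
        Hemodynamic response used in the forward model.
    grid : ndarray or None
        Candidate parameter lattice; ``None`` uses :func:`default_grid`.
    refine : bool
        Run Nelder-Mead refinement from the best grid points.
    n_starts : int
        Number of top grid points used as refinement starts.

    Attributes (after :meth:`fit`)
    ------------------------------
    params_ : DataFrame (n_sites x named parameters)
    ve_ : ndarray of full-fit variance explained
    derived_ : DataFrame of preferred duration/period, extents, orientation
    excluded_ : boolean ndarray with ``exclusion_reason_`` strings
    """

    def __init__(
        self,
        spec: ModelSpec = ModelSpec("tuned_2d_anisotropic"),
        schedule=None,
        hrf: HRFParams = HRFParams(),
        grid: np.ndarray | None = None,
        refine: bool = True,
        n_starts: int = 3,
        max_iter: int = 200,
        xatol: float = 1e-4,
    ):
        self.spec = spec
        self.schedule = schedule
        self.hrf = hrf
        self.grid = grid
        self.refine = refine
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.xatol = xatol

    # -- internal caches (per schedule+hrf+grid) -------------------------
    def _design(self) -> ForwardDesign:
        if getattr(self, "_design_cache", None) is None:
            self._design_cache = ForwardDesign(self.schedule, hrf=self.hrf)
        return self._design_cache

    def _grid_predictions(self):
        if getattr(self, "_grid_cache", None) is None:
            G = self.grid if self.grid is not None else default_grid(self.spec)
            design = self._design()
            P = design.predict(self.spec, G)
            P = np.atleast_2d(P)
            norms = np.linalg.norm(P, axis=1)
            norms[norms == 0] = 1.0
            self._grid_cache = (G, P / norms[:, None])
        return self._grid_cache

    def fit(self, X, y=None):
        """Fit every site (row of ``X``) with grid search + refinement."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if np.isnan(X).all(axis=1).any():
            raise ValueError("all-NaN measured series")
        design = self._design()
        if X.shape[1] != design.n_volumes:
            raise ValueError(
                f"X has {X.shape[1]} volumes, schedule implies {design.n_volumes}"
            )
        G, Pn = self._grid_predictions()
        Xc = X - X.mean(axis=1, keepdims=True)
        xnorm = np.linalg.norm(Xc, axis=1)
        xnorm[xnorm == 0] = 1.0
        Xn = Xc / xnorm[:, None]
        R = Xn @ Pn.T  # site x grid correlations
        best_idx = np.argmax(R * R, axis=1)

        vecs, ves = [], []
        for i, site_r2 in enumerate(R * R):
            gi = best_idx[i]
            vec, ve = G[gi].copy(), float(site_r2[gi])
            if self.refine and G.shape[1] > 0:
                order = np.argsort(site_r2)[::-1][: self.n_starts]
                for start in order:
                    v2, ve2 = self._refine_one(G[start], Xn[i], design)
                    if ve2 > ve:
                        vec, ve = v2, ve2
            vecs.append(_canonicalize(self.spec, vec))
            ves.append(ve)

        self.params_ = pd.DataFrame(vecs, columns=list(self.spec.param_names))
        self.ve_ = np.array(ves)
        self.derived_ = pd.DataFrame(
            [derived_quantities(self.spec, v) for v in vecs]
        )
        flags = exclusion_flags(self.derived_, self.ve_)
        self.excluded_ = flags["excluded"].to_numpy()
        self.exclusion_reason_ = flags["exclusion_reason"].to_numpy()
        return self

    def _refine_one(self, start, xn, design):
        spec = self.spec

        def neg_r2(vec):
            v = _canonicalize(spec, np.asarray(vec, float))
            if spec.family in TUNED_FAMILIES and np.any(
                v[np.array([n.startswith("sigma") for n in spec.param_names])] <= 1e-6
            ):
                return 1.0
            pred = design.predict(spec, v)
            n = np.linalg.norm(pred)
            if n == 0 or not np.isfinite(n):
                return 1.0
            r = (pred / n) @ xn
            return -(r * r)

        res = optimize.minimize(
            neg_r2,
            start,
            method="Nelder-Mead",
            options={"maxiter": self.max_iter, "xatol": self.xatol, "fatol": 1e-8},
        )
        return _canonicalize(spec, res.x), float(-res.fun)

    def predict(self, site_indices=None) -> np.ndarray:
        """Predicted (demeaned) timecourses for fitted sites."""
        design = self._design()
        P = self.params_.to_numpy(float)
        if site_indices is not None:
            P = P[np.atleast_1d(site_indices)]
        return np.atleast_2d(design.predict(self.spec, P))

    def score(self, X, y=None) -> float:
        """Mean variance explained of the fitted parameters on ``X``."""
        X = np.atleast_2d(np.asarray(X, float))
        preds = self.predict()
        return float(
            np.mean([variance_explained(p, x) for p, x in zip(preds, X)])
        )

    def score_sites(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        preds = self.predict()
        return np.array([variance_explained(p, x) for p, x in zip(preds, X)])

    def results_table(self, site_ids=None) -> pd.DataFrame:
        """Tidy per-site table: parameters, VE, derived values, exclusions."""
        n = len(self.ve_)
        tab = pd.DataFrame(
            {
                "site_id": site_ids if site_ids is not None else np.arange(n),
                "family": self.spec.family,
                "space": self.spec.space,
                "scale": self.spec.scale,
                "ve_full": self.ve_,
            }
        )
        derived = self.derived_.drop(
            columns=[c for c in self.derived_.columns if c in self.params_.columns]
        )
        tab = pd.concat(
            [tab, self.params_.reset_index(drop=True), derived.reset_index(drop=True)],
            axis=1,
        )
        tab["excluded"] = self.excluded_
        tab["exclusion_reason"] = self.exclusion_reason_
        return tab


# ---------------------------------------------------------------------------
# functional wrappers


def grid_fit(
    spec: ModelSpec,
    measured: np.ndarray,
    schedule,
    hrf: HRFParams = HRFParams(),
    grid: np.ndarray | None = None,
    refine: bool = True,
    **kw,
) -> TimingPRF:
    """Fit one candidate model to one or many sites; returns the estimator."""
    est = TimingPRF(spec=spec, schedule=schedule, hrf=hrf, grid=grid, refine=refine, **kw)
    return est.fit(np.atleast_2d(measured))


def cross_validate(
    spec: ModelSpec,
    odd_avg: np.ndarray,
    even_avg: np.ndarray,
    schedule,
    hrf: HRFParams = HRFParams(),
    refine: bool = False,
    grid: np.ndarray | None = None,
    _estimators: tuple[TimingPRF, TimingPRF] | None = None,
) -> pd.DataFrame:
    """Split-half cross-validation: fit on one half, score the other.

    Returns per-site ``ve_cv_oddtrain``, ``ve_cv_eventrain`` and their mean
    ``ve_cv`` (raw; may be negative only in the degenerate zero-variance
    sense where it is defined as 0).  Refinement is off by default: grid-level
    fits are sufficient for model ranking and keep comparisons fast.
    """
    if odd_avg is None or even_avg is None:
        raise ValueError("both odd and even split averages are required")
    if _estimators is not None:
        est_o, est_e = _estimators
    else:
        est_o = TimingPRF(spec=spec, schedule=schedule, hrf=hrf, grid=grid, refine=refine)
        est_e = TimingPRF(spec=spec, schedule=schedule, hrf=hrf, grid=grid, refine=refine)
        est_e._design_cache = est_o._design()
    est_o.fit(odd_avg)
    est_e._grid_cache = est_o._grid_cache
    ve_odd_train = est_o.score_sites(even_avg)
    est_e.fit(even_avg)
    ve_even_train = est_e.score_sites(odd_avg)
    return pd.DataFrame(
        {
            "ve_cv_oddtrain": ve_odd_train,
            "ve_cv_eventrain": ve_even_train,
            "ve_cv": 0.5 * (ve_odd_train + ve_even_train),
        }
    )


def compare_models(
    cv_table: pd.DataFrame,
    group_col: str = "map",
    model_col: str = "model",
    ve_col: str = "ve_cv",
    site_col: str = "site_id",
    include_threshold: float = VE_COMPARE,
) -> pd.DataFrame:
    """Paired model comparison on group-mean cross-validated VE.

    ``cv_table`` is long-form: one row per site x model.  Sites whose best
    model reaches ``include_threshold`` are kept; VE is averaged per group
    per model; the best model (highest grand mean) is compared against every
    other with a paired t-test across groups.
    """
    wide = cv_table.pivot_table(index=[group_col, site_col], columns=model_col, values=ve_col)
    if wide.shape[1] < 2:
        raise ValueError("need at least 2 models to compare")
    wide = wide[wide.max(axis=1) >= include_threshold]
    by_group = wide.groupby(level=0).mean()
    if by_group.shape[0] < 2:
        raise ValueError("need at least 2 groups for a paired comparison")
    means = by_group.mean()
    best = means.idxmax()
    rows = []
    for model in by_group.columns:
        if model == best:
            rows.append((model, means[model], np.nan, np.nan, len(by_group), True))
            continue
        diffs = by_group[best] - by_group[model]
        if np.allclose(diffs, 0):
            t, p = 0.0, 1.0
        elif np.isclose(diffs.std(ddof=1), 0):
            t, p = np.inf * np.sign(diffs.mean()), 0.0
        else:
            t, p = stats.ttest_rel(by_group[best], by_group[model])
        rows.append((model, means[model], float(t), float(p), len(by_group), False))
    out = pd.DataFrame(
        rows, columns=["model", "mean_cv_ve", "t_vs_best", "p_vs_best", "n_groups", "is_best"]
    )
    return out.sort_values("mean_cv_ve", ascending=False).reset_index(drop=True)


@dataclass
class NullDistribution:
    """Variance-explained null from fitting noise-only (white matter) sites."""

    values: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        v = np.sort(np.asarray(self.values, float))
        if v.size == 0:
            raise ValueError("empty null distribution")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("null VE values must lie in [0, 1]")
        self.values = v

    @property
    def count(self) -> int:
        return self.values.size

    def p_value(self, observed_ve: float) -> float:
        """Proportion of the null at or above ``observed_ve``."""
        return float(np.mean(self.values >= observed_ve))


def empirical_null(noise_fits: np.ndarray, observed_ve: float) -> float:
    """p = (# null VE >= observed) / count, from noise-only site fits."""
    return NullDistribution(np.asarray(noise_fits)).p_value(observed_ve)
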