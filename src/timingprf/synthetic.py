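"""Synthetic recording sites, timing maps and noise-only null sites.

Because no measured cortical dataset ships with the package, every input the
pipeline consumes can be generated here: ground-truth timing-selective sites
whose timecourses follow the full forward model with additive run noise;
1-D cortical-strip "maps" whose preferred durations progress along a
coordinate (logarithmically or linearly, as observed in cortical timing
maps) with preferred periods slightly above preferred durations; and
pure-noise white-matter-like sites for the empirical null distribution.

Forward predictions are normalized to unit standard deviation per site, so
the run-level ``noise_sd`` maps monotonically onto expected variance
explained: after averaging R runs, VE ~= 1 / (1 + noise_sd**2 / R)
(:func:`calibrate_noise_sd` inverts this).  All generators are deterministic
given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forward import ForwardDesign, HRFParams
from .models import ModelSpec

MIDDLE_OF_RANGE = 0.5  # s; center of the presented 50-1000 ms range


@dataclass
class GroundTruth:
    """Generating model, per-site parameters and noise settings."""

    spec: ModelSpec
    params: pd.DataFrame  # one row per site, columns = spec.param_names
    noise_sd: float
    n_runs: int
    seed: int
    ar_coef: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_runs < 2 or self.n_runs % 2:
            raise ValueError("n_runs must be even and >= 2")


@dataclass
class SyntheticMap:
    """1-D cortical strip: geometry table plus generating truth."""

    geometry: pd.DataFrame
    truth: GroundTruth
    map_length_mm: float
    progression: str
    slope: float
    intercept: float
    extent_rule: str = "linear"
    log_eps: float = 1.0


def calibrate_noise_sd(target_ve: float, n_runs: int) -> float:
    """Run-level noise SD giving the expected VE after run averaging.

    Assumes unit-variance signal (the generator's normalization):
    VE = 1 / (1 + sd^2/R)  =>  sd = sqrt(R (1 - VE) / VE).
    """
    if not (0 < target_ve < 1):
        raise ValueError("target_ve must lie in (0, 1)")
    return float(np.sqrt(n_runs * (1 - target_ve) / target_ve))


def _noise(rng: np.random.Generator, shape, sd: float, ar_coef: float) -> np.ndarray:
    eps = rng.normal(0.0, sd, size=shape)
    if ar_coef:
        out = np.empty_like(eps)
        out[..., 0] = eps[..., 0]
        scale = np.sqrt(1 - ar_coef**2)
        for t in range(1, eps.shape[-1]):
            out[..., t] = ar_coef * out[..., t - 1] + scale * eps[..., t]
        return out
    return eps


def simulate_sites(
    truth: GroundTruth,
    schedule,
    hrf: HRFParams = HRFParams(),
    design: ForwardDesign | None = None,
) -> dict[str, pd.DataFrame]:
    """Noisy per-site timecourses: run-averaged 'full', 'odd' and 'even'.

    Per run the noiseless forward prediction (normalized to unit SD) gets
    i.i.d. Gaussian noise (optionally AR(1)); runs are averaged overall and
    within the odd/even split.
    """
    rng = np.random.default_rng(truth.seed)
    design = design or ForwardDesign(schedule, hrf=hrf)
    P = truth.params.to_numpy(float)
    pred = np.atleast_2d(design.predict(truth.spec, P))
    sd = pred.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    pred = pred / sd
    n_sites, n_vol = pred.shape
    runs = pred[None, :, :] + _noise(
        rng, (truth.n_runs, n_sites, n_vol), truth.noise_sd, truth.ar_coef
    )
    out = {
        "full": runs.mean(axis=0),
        "odd": runs[0::2].mean(axis=0),
        "even": runs[1::2].mean(axis=0),
    }
    cols = [f"vol_{i:03d}" for i in range(n_vol)]

    def table(arr):
        tab = pd.DataFrame(arr, columns=cols)
        tab.insert(0, "site_id", np.arange(n_sites))
        return tab

    return {k: table(v) for k, v in out.items()}


def _truncnorm_offsets(rng, n, mean=0.1, sd=0.05):
    off = rng.normal(mean, sd, size=n)
    while np.any(off < 0):
        bad = off < 0
        off[bad] = rng.normal(mean, sd, size=bad.sum())
    return off


def simulate_map(
    n_sites: int = 60,
    duration_range: tuple[float, float] = (0.1, 0.9),
    progression: str = "log",
    extent_rule: str = "linear",
    seed: int = 0,
    map_length_mm: float = 20.0,
    strip_width_mm: float = 2.0,
    jitter_sd: float = 0.0,
    noise_sd: float = 0.0,
    n_runs: int = 4,
    upsampling: float = 4.0,
    aspect_ratio: float = 2.0,
    theta: float = np.pi / 4,
    exp_freq_range: tuple[float, float] = (0.2, 1.0),
    log_eps: float = 1.0,
    hemisphere: str = "left",
    map_label: str = "SIM",
    subject: str = "S1",
) -> SyntheticMap:
    """Generate a map-like cortical strip with a timing-preference progression.

    Preferred duration follows ``a + b*ln(x + log_eps)`` (progression='log')
    or ``a + b*x`` along the strip coordinate x, spanning ``duration_range``;
    optional Gaussian jitter emulates measurement scatter.  Preferred period
    is the duration plus a positive offset ~ N(0.10 s, 0.05 s) truncated at
    0, echoing the observed coupling of duration and period preferences.
    Major extents follow the ``extent_rule``: 'linear' (grows with preferred
    duration), 'v_shape' (grows with |preference - 0.5 s|) or 'constant'.
    """
    if n_sites < 10:
        raise ValueError("n_sites must be >= 10")
    d0, d1 = duration_range
    if not (0 < d0 < d1):
        raise ValueError("degenerate duration_range")
    rng = np.random.default_rng(seed)
    x = np.sort(rng.uniform(0.0, map_length_mm, size=n_sites))
    if progression == "log":
        g = np.log(x + log_eps)
        g0, g1 = np.log(log_eps), np.log(map_length_mm + log_eps)
    elif progression == "linear":
        g = x
        g0, g1 = 0.0, map_length_mm
    else:
        raise ValueError("progression must be 'log' or 'linear'")
    slope = (d1 - d0) / (g1 - g0)
    intercept = d0 - slope * g0
    dur = intercept + slope * g
    if jitter_sd:
        dur = dur + rng.normal(0.0, jitter_sd, size=n_sites)
    dur = np.clip(dur, 0.06, 0.99)
    per = dur + _truncnorm_offsets(rng, n_sites)

    if extent_rule == "linear":
        smaj = 0.15 + 0.6 * dur
    elif extent_rule == "v_shape":
        smaj = 0.15 + 1.2 * np.abs(dur - MIDDLE_OF_RANGE)
    elif extent_rule == "constant":
        smaj = np.full(n_sites, 0.4)
    else:
        raise ValueError("extent_rule must be linear|v_shape|constant")
    smin = smaj / aspect_ratio
    exp_freq = rng.uniform(*exp_freq_range, size=n_sites)

    params = pd.DataFrame(
        {
            "pref_1": dur,
            "pref_2": per,
            "sigma_maj": smaj,
            "sigma_min": smin,
            "theta": np.full(n_sites, float(theta)),
            "exp_freq": exp_freq,
        }
    )
    truth = GroundTruth(
        spec=ModelSpec("tuned_2d_anisotropic"),
        params=params,
        noise_sd=noise_sd,
        n_runs=n_runs,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    area = map_length_mm * strip_width_mm / n_sites
    geometry = pd.DataFrame(
        {
            "site_id": np.arange(n_sites),
            "d_low_mm": x,
            "d_high_mm": map_length_mm - x,
            "area_mm2": np.full(n_sites, area),
            "upsampling": np.full(n_sites, upsampling),
            "hemisphere": hemisphere,
            "map": map_label,
            "subject": subject,
        }
    )
    return SyntheticMap(
        geometry=geometry,
        truth=truth,
        map_length_mm=map_length_mm,
        progression=progression,
        slope=slope,
        intercept=intercept,
        extent_rule=extent_rule,
        log_eps=log_eps,
    )


def simulate_noise_sites(
    n: int, noise_sd: float, n_volumes: int, seed: int = 0
) -> pd.DataFrame:
    """Pure-noise sites (white-matter analog) for the empirical null."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    arr = rng.normal(0.0, noise_sd, size=(n, n_volumes))
    tab = pd.DataFrame(arr, columns=[f"vol_{i:03d}" for i in range(n_volumes)])
    tab.insert(0, "site_id", np.arange(n))
    return tab


def timecourse_matrix(tab: pd.DataFrame) -> np.ndarray:
    """Extract the (n_sites, n_volumes) float matrix from a site table."""
    cols = [c for c in tab.columns if c.startswith("vol_")]
    if not cols:
        raise ValueError("site table has no vol_* columns")
    return tab[cols].to_numpy(float)
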