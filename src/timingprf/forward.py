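"""Hemodynamic forward model: neural impulses -> predicted fMRI timecourses.

The candidate response function is evaluated at every event offset, scaled by
the per-event frequency multiplier, placed as an impulse on the 50 ms event
grid, convolved with a difference-of-gammas hemodynamic response function
(HRF), averaged within each TR window (volume acquisition integrates over the
TR) and demeaned.  Predictions are scored against measured timecourses by the
squared Pearson correlation (variance explained), which absorbs response
amplitude and offset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.stats import gamma as gamma_dist

from . import models as _models
from .models import ModelSpec, TFParams, amplitude_matrix, luminance_trace, tf_amplitude
from .stimuli import GRID, EventSchedule, RunSchedule


@dataclass(frozen=True)
class HRFParams:
    """Difference-of-gammas HRF (SPM-style parameterization).

    peak/undershoot delays are the gamma means in seconds; dispersions their
    scale parameters; undershoot_ratio the relative undershoot amplitude.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        if min(self.peak_delay, self.undershoot_delay, self.peak_dispersion,
               self.undershoot_dispersion) <= 0:
            raise ValueError("delays and dispersions must be > 0")
        if self.undershoot_ratio < 0:
            raise ValueError("undershoot_ratio must be >= 0")


def hrf_kernel(hrf: HRFParams = HRFParams(), dt: float = GRID, length: float = 32.0) -> np.ndarray:
    """Sample the HRF on the event grid, peak normalized to 1."""
    t = np.arange(0, length, dt)
    peak = gamma_dist.pdf(t, hrf.peak_delay / hrf.peak_dispersion, scale=hrf.peak_dispersion)
    under = gamma_dist.pdf(
        t, hrf.undershoot_delay / hrf.undershoot_dispersion, scale=hrf.undershoot_dispersion
    )
    k = peak - hrf.undershoot_ratio * under
    return k / np.max(np.abs(k))


def _event_arrays(schedule: EventSchedule | RunSchedule):
    ev = schedule.events
    offs = np.round(ev["offset"].to_numpy() / GRID).astype(int)
    return (
        ev["duration"].to_numpy(float),
        ev["period"].to_numpy(float),
        offs,
    )


def neural_timecourse(spec: ModelSpec, params, schedule) -> np.ndarray:
    """Impulse series on the 50 ms grid: one impulse at each event offset.

    Impulse height = response amplitude at the event's timing state times the
    frequency multiplier Frequency**(exp_freq - 1).
    """
    dur, per, offs = _event_arrays(schedule)
    n = schedule.n_ticks
    series = np.zeros(n)
    if spec.family == "temporal_frequency":
        heights = _tf_heights(spec, params, schedule, dur, per, offs)
    else:
        vec = _models.params_to_vector(spec, params)
        heights = amplitude_matrix(spec, vec[None, :], dur, per)[0]
        if spec.family in ("constant", "linear_monotonic"):
            # exponents fixed at 1: multiplier is 1
            pass
    np.add.at(series, np.minimum(offs, n - 1), heights)
    return series


def _tf_heights(spec, params: TFParams, schedule, dur, per, offs) -> np.ndarray:
    trace = luminance_trace(schedule.events, schedule.n_ticks)
    if spec.tf_variant == "per_event":
        heights = np.empty(len(offs))
        for i, (o, p) in enumerate(zip(offs, per)):
            w = max(int(round(p / GRID)), 1)
            lo = max(o - w, 0)
            heights[i] = tf_amplitude(params, trace[lo:o] if o > lo else trace[:1])
        return heights * per ** (1.0 - params.exp_freq)
    raise ValueError("per_tr variant is handled by tf_timecourse")


def tf_timecourse(params: TFParams, schedule, tr_ticks: int | None = None) -> np.ndarray:
    """per-TR temporal-frequency variant: one impulse per TR at its midpoint."""
    n = schedule.n_ticks
    trace = luminance_trace(schedule.events, n)
    tr_ticks = tr_ticks or int(round(schedule.tr / GRID))
    series = np.zeros(n)
    for start in range(0, n, tr_ticks):
        amp = tf_amplitude(params, trace[start : start + tr_ticks])
        series[start + tr_ticks // 2] = amp
    return series


def predict_fmri(
    neural: np.ndarray, hrf: HRFParams = HRFParams(), tr: float = 2.1
) -> np.ndarray:
    """Convolve a neural impulse series with the HRF and sample per TR.

    The convolved series is averaged within each TR window and demeaned.
    """
    tr_ticks = int(round(tr / GRID))
    if abs(tr_ticks * GRID - tr) > 1e-9:
        raise ValueError("tr must be a multiple of the event grid step")
    kernel = hrf_kernel(hrf)
    conv = signal.fftconvolve(neural, kernel)[: len(neural)]
    n_vol = len(neural) // tr_ticks
    per_tr = conv[: n_vol * tr_ticks].reshape(n_vol, tr_ticks).mean(axis=1)
    return per_tr - per_tr.mean()


def variance_explained(pred: np.ndarray, measured: np.ndarray) -> float:
    """Squared Pearson correlation between prediction and measurement.

    Defined as 0 when either series has zero variance.
    """
    pred = np.asarray(pred, float)
    measured = np.asarray(measured, float)
    if pred.shape != measured.shape or pred.size < 3:
        raise ValueError("series must have equal length >= 3")
    p = pred - pred.mean()
    m = measured - measured.mean()
    denom = np.sqrt((p @ p) * (m @ m))
    if denom == 0 or not np.isfinite(denom):
        return 0.0
    r = (p @ m) / denom
    return float(r * r)


# ---------------------------------------------------------------------------
# per-event regressor design, shared across parameter sets and sites


class ForwardDesign:
    """Precomputed linear map from per-event impulse heights to TR predictions.

    Since the prediction is linear in impulse heights, each event contributes
    a fixed HRF-convolved, TR-averaged, demeaned regressor; the prediction for
    any parameter set is ``heights @ E``.  Build once per (schedule, HRF).
    """

    def __init__(self, schedule, hrf: HRFParams = HRFParams(), tr: float | None = None):
        self.schedule = schedule
        self.hrf = hrf
        self.tr = tr or schedule.tr
        self.tr_ticks = int(round(self.tr / GRID))
        self.durations, self.periods, self.offsets = _event_arrays(schedule)
        self.n_ticks = schedule.n_ticks
        self.n_volumes = self.n_ticks // self.tr_ticks
        self._build()

    def _build(self) -> None:
        kernel = hrf_kernel(self.hrf)
        m = len(kernel)
        n_ev = len(self.offsets)
        full = np.zeros((n_ev, self.n_ticks))
        for i, o in enumerate(np.minimum(self.offsets, self.n_ticks - 1)):
            hi = min(o + m, self.n_ticks)
            full[i, o:hi] = kernel[: hi - o]
        E = full.reshape(n_ev, self.n_volumes, self.tr_ticks).mean(axis=2)
        E -= E.mean(axis=1, keepdims=True)
        self.E = E

    def predict(self, spec: ModelSpec, P: np.ndarray) -> np.ndarray:
        """Demeaned TR predictions for one or many parameter vectors."""
        A = amplitude_matrix(spec, P, self.durations, self.periods)
        out = A @ self.E
        return out[0] if np.ndim(P) == 1 else out

    def with_hrf(self, hrf: HRFParams) -> "ForwardDesign":
        return ForwardDesign(self.schedule, hrf=hrf, tr=self.tr)


def fit_hrf(
    measured: np.ndarray,
    specs_and_params: list[tuple[ModelSpec, np.ndarray]],
    schedule,
    ve_threshold: float = 0.2,
    peak_delays: np.ndarray | None = None,
    undershoot_ratios: np.ndarray | None = None,
    tr: float | None = None,
) -> HRFParams:
    """Grid-search HRF peak delay and undershoot ratio across recording sites.

    Holds each site's fitted neural parameters fixed and picks the HRF
    maximizing summed variance explained over sites whose fit under the
    default HRF clears ``ve_threshold``.  Callers then re-fit the neural
    model under the returned HRF.
    """
    measured = np.atleast_2d(np.asarray(measured, float))
    if len(specs_and_params) != measured.shape[0]:
        raise ValueError("one (spec, params) pair per measured site required")
    peak_delays = np.arange(4.0, 8.01, 0.5) if peak_delays is None else peak_delays
    undershoot_ratios = (
        np.array([0.0, 1 / 12, 1 / 6, 1 / 4, 1 / 3])
        if undershoot_ratios is None
        else undershoot_ratios
    )
    base = ForwardDesign(schedule, tr=tr)
    keep = [
        i
        for i, (spec, vec) in enumerate(specs_and_params)
        if variance_explained(base.predict(spec, np.asarray(vec)), measured[i])
        >= ve_threshold
    ]
    if not keep:
        raise ValueError(f"no site reaches VE >= {ve_threshold}")
    best, best_score = None, -np.inf
    for pd_ in peak_delays:
        for ur in undershoot_ratios:
            hrf = replace(HRFParams(), peak_delay=float(pd_), undershoot_ratio=float(ur))
            design = base.with_hrf(hrf)
            score = sum(
                variance_explained(
                    design.predict(specs_and_params[i][0], np.asarray(specs_and_params[i][1])),
                    measured[i],
                )
                for i in keep
            )
            if score > best_score:
                best, best_score = hrf, score
    return best
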