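"""Candidate neural response functions for event timing.

Each model maps a presented timing state (duration, period) to a per-event
neural response amplitude.  The family ladder runs from untuned monotonic
responses to tuned Gaussian response functions:

``constant``
    every event produces the same amplitude, so the accumulated fMRI
    response grows linearly with event frequency.
``linear_monotonic``
    amplitude = duration * amplitude_ratio + 1; the duration term accumulates
    into an occupancy (mean luminance) response, the constant term into a
    transient onset-frequency response.
``compressive_monotonic``
    amplitude = duration**exp_dur * amplitude_ratio + 1, with a free
    compressive exponent on event frequency applied per event (below).
``tuned_1d``
    Gaussian tuning to duration only.
``tuned_2d_isotropic`` / ``tuned_2d_anisotropic``
    2-D Gaussian tuning over a two-parameter timing space, optionally
    rotated (anisotropic) with extents sigma_maj >= sigma_min along the
    major/minor axes.
``temporal_frequency``
    a control model tuned to the Fourier power spectrum of the display
    luminance timecourse rather than to event timing itself.

Tuned families can be parameterized in any of the three mathematically
equivalent timing spaces (duration/period, duration/inter-event-interval,
period/occupancy) and on linear or natural-log axes; comparing fits across
spaces distinguishes parametric response functions that are not equivalent
under these coordinate transforms.

Sub-additive temporal summation is captured by a per-event frequency
multiplier Frequency**(exp_freq - 1): summed over one second the response is
then proportional to Frequency**exp_freq, so at exp_freq = 1 the response to
10 events/s is 10x the response to 1 event/s, while at exp_freq = 0 the two
are identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from math import cos, exp, log, sin

import numpy as np

from .stimuli import TimingState

MONOTONIC_FAMILIES = ("constant", "linear_monotonic", "compressive_monotonic")
TUNED_FAMILIES = ("tuned_1d", "tuned_2d_isotropic", "tuned_2d_anisotropic")
FAMILIES = MONOTONIC_FAMILIES + TUNED_FAMILIES + ("temporal_frequency",)
SPACES = ("duration_period", "duration_interval", "period_occupancy")

#: axis value floor used before log transforms in vectorized evaluation
#: (half the event grid; the inter-event interval can be exactly 0)
LOG_FLOOR = 0.025


@dataclass(frozen=True)
class ModelSpec:
    """Identity of one candidate response model."""

    family: str
    space: str = "duration_period"
    scale: str = "linear"
    tf_variant: str | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family in TUNED_FAMILIES[1:] and self.space not in SPACES:
            raise ValueError(f"unknown space {self.space!r}")
        if self.scale not in ("linear", "log"):
            raise ValueError(f"scale must be linear or log, got {self.scale!r}")
        if self.family == "temporal_frequency":
            if self.tf_variant not in ("per_tr", "per_event"):
                raise ValueError("temporal_frequency requires tf_variant per_tr|per_event")
        elif self.tf_variant is not None:
            raise ValueError("tf_variant only applies to the temporal_frequency family")

    @property
    def param_names(self) -> tuple[str, ...]:
        return PARAM_NAMES[self.family] if self.family != "temporal_frequency" else (
            ("freq_pref", "sigma_f", "exp_freq")
            if self.tf_variant == "per_event"
            else ("freq_pref", "sigma_f")
        )


PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "constant": (),
    "linear_monotonic": ("amplitude_ratio",),
    "compressive_monotonic": ("amplitude_ratio", "exp_dur", "exp_freq"),
    "tuned_1d": ("pref_1", "sigma_maj", "exp_freq"),
    "tuned_2d_isotropic": ("pref_1", "pref_2", "sigma_maj", "exp_freq"),
    "tuned_2d_anisotropic": (
        "pref_1",
        "pref_2",
        "sigma_maj",
        "sigma_min",
        "theta",
        "exp_freq",
    ),
}


@dataclass(frozen=True)
class MonotonicParams:
    """Parameters of the monotonic families (Constant term fixed to 1)."""

    amplitude_ratio: float = 0.0
    exp_dur: float = 1.0
    exp_freq: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude_ratio < 0:
            raise ValueError("amplitude_ratio must be >= 0")
        if not (0 < self.exp_dur <= 1) or not (0 <= self.exp_freq <= 1):
            raise ValueError("exponents must lie in (0,1] / [0,1]")


@dataclass(frozen=True)
class TunedParams:
    """Parameters of the tuned Gaussian families.

    ``pref_1``/``pref_2`` are the preferred values along the two axes of the
    model's timing space (log-units under scale='log'); ``sigma_maj`` and
    ``sigma_min`` are the extents (standard deviations) along the major and
    minor axes; ``theta`` is the major-axis orientation in [0, pi).
    """

    pref_1: float
    pref_2: float | None = None
    sigma_maj: float = 0.2
    sigma_min: float | None = None
    theta: float = 0.0
    exp_freq: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_maj <= 0:
            raise ValueError("sigma_maj must be > 0")
        if self.sigma_min is not None:
            if self.sigma_min <= 0:
                raise ValueError("sigma_min must be > 0")
            if self.sigma_maj < self.sigma_min - 1e-12:
                raise ValueError("require sigma_maj >= sigma_min")
        if not (0 <= self.exp_freq <= 1):
            raise ValueError("exp_freq must lie in [0,1]")


@dataclass(frozen=True)
class TFParams:
    """Gaussian tuning over the display-luminance Fourier power spectrum."""

    freq_pref: float
    sigma_f: float
    exp_freq: float = 1.0

    def __post_init__(self) -> None:
        if self.freq_pref <= 0 or self.sigma_f <= 0:
            raise ValueError("freq_pref and sigma_f must be > 0")


def state_to_space(
    duration: float, period: float, space: str
) -> tuple[float, float]:
    """Map a (duration, period) state into one of the three timing spaces."""
    if space == "duration_period":
        return duration, period
    if space == "duration_interval":
        return duration, period - duration
    if space == "period_occupancy":
        return period, duration / period
    raise ValueError(f"unknown space {space!r}")


def space_to_state(axis_1: float, axis_2: float, space: str) -> tuple[float, float]:
    """Inverse of :func:`state_to_space`: recover (duration, period)."""
    if space == "duration_period":
        return axis_1, axis_2
    if space == "duration_interval":
        return axis_1, axis_1 + axis_2
    if space == "period_occupancy":
        return axis_1 * axis_2, axis_1
    raise ValueError(f"unknown space {space!r}")


def evaluate_amplitude(spec: ModelSpec, params, state: TimingState) -> float:
    """Per-event response amplitude of ``params`` at ``state``.

    The frequency multiplier (:func:`frequency_scale`) is *not* applied here;
    it scales each event at the forward-model stage.
    """
    fam = spec.family
    if fam == "constant":
        return 1.0
    if fam in ("linear_monotonic", "compressive_monotonic"):
        return state.duration ** params.exp_dur * params.amplitude_ratio + 1.0
    if fam == "tuned_1d":
        x = state.duration
        if spec.scale == "log":
            if x <= 0:
                raise ValueError("nonpositive duration under log scale")
            x = log(x)
        return exp(-0.5 * ((x - params.pref_1) / params.sigma_maj) ** 2)
    if fam in ("tuned_2d_isotropic", "tuned_2d_anisotropic"):
        a1, a2 = state_to_space(state.duration, state.period, spec.space)
        if spec.scale == "log":
            if a1 <= 0 or a2 <= 0:
                raise ValueError("nonpositive axis value under log scale")
            a1, a2 = log(a1), log(a2)
        d1 = a1 - params.pref_1
        d2 = a2 - params.pref_2
        if fam == "tuned_2d_isotropic":
            s = params.sigma_maj
            return exp(-0.5 * (d1 * d1 + d2 * d2) / (s * s))
        th = params.theta
        x = d1 * cos(th) - d2 * sin(th)
        y = d1 * sin(th) + d2 * cos(th)
        sig_min = params.sigma_min if params.sigma_min is not None else params.sigma_maj
        return exp(-0.5 * ((y / params.sigma_maj) ** 2 + (x / sig_min) ** 2))
    raise ValueError(
        f"evaluate_amplitude does not apply to family {fam!r}"
    )


def frequency_scale(exp_freq: float, period: float) -> float:
    """Per-event frequency multiplier Frequency**(exp_freq - 1).

    With events at frequency F = 1/period, the per-second summed response is
    F * multiplier = F**exp_freq: linear accumulation at exp_freq = 1,
    frequency-independent at exp_freq = 0.
    """
    if period <= 0:
        raise ValueError("period must be > 0")
    if not (0 <= exp_freq <= 1):
        raise ValueError("exp_freq must lie in [0,1]")
    return (1.0 / period) ** (exp_freq - 1.0)


# ---------------------------------------------------------------------------
# vectorized evaluation used by grid fitting


def amplitude_matrix(
    spec: ModelSpec, P: np.ndarray, durations: np.ndarray, periods: np.ndarray
) -> np.ndarray:
    """Evaluate many parameter vectors over many events at once.

    ``P`` has shape (n_sets, n_params) with columns ordered as
    ``spec.param_names``.  Returns (n_sets, n_events) per-event impulse
    heights *including* the frequency multiplier.  Under scale='log' axis
    values are floored at :data:`LOG_FLOOR` before the transform so that
    zero inter-event intervals stay finite.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    dur = np.asarray(durations, dtype=float)[None, :]
    per = np.asarray(periods, dtype=float)[None, :]
    fam = spec.family
    if fam == "constant":
        amp = np.ones((P.shape[0], dur.shape[1]))
        return amp
    if fam == "linear_monotonic":
        ar = P[:, [0]]
        return dur * ar + 1.0
    if fam == "compressive_monotonic":
        ar, ed, ef = P[:, [0]], P[:, [1]], P[:, [2]]
        amp = dur**ed * ar + 1.0
        return amp * per ** (1.0 - ef)
    if fam == "tuned_1d":
        x = np.log(np.maximum(dur, LOG_FLOOR)) if spec.scale == "log" else dur
        pref, sig, ef = P[:, [0]], P[:, [1]], P[:, [2]]
        amp = np.exp(-0.5 * ((x - pref) / sig) ** 2)
        return amp * per ** (1.0 - ef)
    if fam in ("tuned_2d_isotropic", "tuned_2d_anisotropic"):
        a1, a2 = state_to_space(dur, per, spec.space)
        if spec.scale == "log":
            a1 = np.log(np.maximum(a1, LOG_FLOOR))
            a2 = np.log(np.maximum(a2, LOG_FLOOR))
        d1 = a1 - P[:, [0]]
        d2 = a2 - P[:, [1]]
        if fam == "tuned_2d_isotropic":
            sig, ef = P[:, [2]], P[:, [3]]
            amp = np.exp(-0.5 * (d1 * d1 + d2 * d2) / (sig * sig))
        else:
            smaj, smin, th, ef = P[:, [2]], P[:, [3]], P[:, [4]], P[:, [5]]
            x = d1 * np.cos(th) - d2 * np.sin(th)
            y = d1 * np.sin(th) + d2 * np.cos(th)
            amp = np.exp(-0.5 * ((y / smaj) ** 2 + (x / smin) ** 2))
        return amp * per ** (1.0 - ef)
    raise ValueError(f"amplitude_matrix does not apply to family {fam!r}")


# ---------------------------------------------------------------------------
# temporal-frequency control model

DISPLAY_RATE = 20.0  # Hz


def luminance_trace(events: "np.ndarray | object", n_ticks: int) -> np.ndarray:
    """Binary on/off display-luminance trace on the 50 ms grid (20 Hz)."""
    import pandas as pd

    if hasattr(events, "events"):
        events = events.events
    tab = events if isinstance(events, pd.DataFrame) else pd.DataFrame(events)
    trace = np.zeros(n_ticks)
    on = np.round(tab["onset"].to_numpy() * DISPLAY_RATE).astype(int)
    off = np.round(tab["offset"].to_numpy() * DISPLAY_RATE).astype(int)
    for a, b in zip(on, off):
        trace[a : min(b, n_ticks)] = 1.0
    return trace


def window_power(window: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fourier power spectrum of one luminance window (no taper)."""
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("empty luminance window")
    spec = np.fft.rfft(window)
    power = np.abs(spec) ** 2 / window.size
    freqs = np.fft.rfftfreq(window.size, d=1.0 / DISPLAY_RATE)
    return freqs, power


def tf_amplitude(params: TFParams, luminance_window: np.ndarray) -> float:
    """Response to one window: power spectrum weighted by Gaussian tuning."""
    freqs, power = window_power(luminance_window)
    tuning = np.exp(-0.5 * ((freqs - params.freq_pref) / params.sigma_f) ** 2)
    return float(power @ tuning)


# ---------------------------------------------------------------------------
# (de)serialization


def spec_to_dict(spec: ModelSpec, params) -> dict:
    d = {"family": spec.family, "space": spec.space, "scale": spec.scale}
    if spec.tf_variant:
        d["tf_variant"] = spec.tf_variant
    d["params"] = asdict(params) if params is not None else {}
    return d


def spec_to_json(spec: ModelSpec, params) -> str:
    return json.dumps(spec_to_dict(spec, params))


def params_from_vector(spec: ModelSpec, vector: np.ndarray):
    """Build the typed parameter object from a flat named vector."""
    names = spec.param_names
    kv = dict(zip(names, np.asarray(vector, dtype=float).tolist()))
    if spec.family in MONOTONIC_FAMILIES:
        return MonotonicParams(**kv)
    if spec.family in TUNED_FAMILIES:
        return TunedParams(**kv)
    return TFParams(**kv)


def params_to_vector(spec: ModelSpec, params) -> np.ndarray:
    return np.array([getattr(params, n) for n in spec.param_names], dtype=float)
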