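"""Candidate response functions: amplitudes, scaling, symmetries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from timingprf.models import (
    ModelSpec,
    MonotonicParams,
    TFParams,
    TunedParams,
    amplitude_matrix,
    evaluate_amplitude,
    frequency_scale,
    params_from_vector,
    params_to_vector,
    spec_to_json,
    state_to_space,
    space_to_state,
    tf_amplitude,
    window_power,
)
from timingprf.stimuli import CONFIGURATIONS, TimingState, make_configuration

ANISO = ModelSpec("tuned_2d_anisotropic")


def test_constant_family_is_flat():
    spec = ModelSpec("constant")
    for state in (TimingState(0.05, 0.95), TimingState(1.0, 1.0)):
        assert evaluate_amplitude(spec, MonotonicParams(), state) == 1.0


def test_gaussian_peak_and_one_sigma_point():
    p = TunedParams(pref_1=0.4, pref_2=0.6, sigma_maj=0.3, sigma_min=0.3, theta=0.0)
    assert evaluate_amplitude(ANISO, p, TimingState(0.4, 0.6)) == pytest.approx(1.0)
    # offset one sigma along the period axis only
    val = evaluate_amplitude(ANISO, p, TimingState(0.4, 0.9))
    assert val == pytest.approx(np.exp(-0.5), abs=1e-12)


def test_rotated_gaussian_matches_stepwise_oracle():
    """Frozen value from composing the rotation and Gaussian exactly:

    theta=pi/4, prefs (0.5, 0.6), state (0.6, 0.7): X = 0, Y = 0.1*sqrt(2),
    amplitude = exp(-0.5 * (Y/0.4)**2) = exp(-1/16).
    """
    p = TunedParams(pref_1=0.5, pref_2=0.6, sigma_maj=0.4, sigma_min=0.1, theta=np.pi / 4)
    val = evaluate_amplitude(ANISO, p, TimingState(0.6, 0.7))
    assert val == pytest.approx(0.9394130628134758, abs=1e-12)


def test_monotonic_family_degeneracies():
    """The compressive form reduces to linear at unit exponents and to the
    constant response at zero amplitude ratio."""
    states = [TimingState(d, p) for d, p in [(0.05, 0.5), (0.3, 0.3), (1.0, 1.0)]]
    lin = MonotonicParams(amplitude_ratio=2.0)
    comp = MonotonicParams(amplitude_ratio=2.0, exp_dur=1.0, exp_freq=1.0)
    for s in states:
        assert evaluate_amplitude(
            ModelSpec("compressive_monotonic"), comp, s
        ) == pytest.approx(
            evaluate_amplitude(ModelSpec("linear_monotonic"), lin, s)
        )
    flat = MonotonicParams(amplitude_ratio=0.0)
    for s in states:
        assert evaluate_amplitude(ModelSpec("linear_monotonic"), flat, s) == 1.0


@pytest.mark.parametrize("theta", np.linspace(0, np.pi, 5))
def test_anisotropic_with_equal_sigmas_is_isotropic(theta):
    iso = ModelSpec("tuned_2d_isotropic")
    pa = TunedParams(0.4, 0.5, sigma_maj=0.25, sigma_min=0.25, theta=theta)
    pi_ = TunedParams(0.4, 0.5, sigma_maj=0.25)
    for state in (TimingState(0.2, 0.9), TimingState(0.6, 0.6)):
        assert evaluate_amplitude(ANISO, pa, state) == pytest.approx(
            evaluate_amplitude(iso, pi_, state), abs=1e-12
        )


def test_theta_periodicity_and_radial_decay():
    base = dict(pref_1=0.5, pref_2=0.6, sigma_maj=0.4, sigma_min=0.15)
    p1 = TunedParams(**base, theta=0.7)
    p2 = TunedParams(**base, theta=0.7 + np.pi)
    state = TimingState(0.3, 0.8)
    assert evaluate_amplitude(ANISO, p1, state) == pytest.approx(
        evaluate_amplitude(ANISO, p2, state), abs=1e-12
    )
    # monotone decreasing along a ray from the preferred point
    amps = [
        evaluate_amplitude(ANISO, p1, TimingState(0.5 - 0.05 * k, 0.6 + 0.05 * k))
        for k in range(5)
    ]
    assert all(a > b for a, b in zip(amps, amps[1:]))


def test_space_transforms_invert():
    for dur, per in [(0.05, 0.95), (0.3, 0.5), (1.0, 1.0)]:
        for space in ("duration_period", "duration_interval", "period_occupancy"):
            a1, a2 = state_to_space(dur, per, space)
            back = space_to_state(a1, a2, space)
            assert back == pytest.approx((dur, per), abs=1e-12)


def test_space_equivalence_on_stimulus_grid():
    """A tuned model in duration/interval space equals a duration/period-space
    evaluation through the coordinate transform, for every presented state."""
    spec_di = ModelSpec("tuned_2d_anisotropic", space="duration_interval")
    p = TunedParams(pref_1=0.3, pref_2=0.2, sigma_maj=0.3, sigma_min=0.1, theta=0.5)
    states = set()
    for name in CONFIGURATIONS:
        s = make_configuration(name)
        states |= set(map(tuple, s.events[["duration", "period"]].to_numpy()))
    for dur, per in states:
        via_di = evaluate_amplitude(spec_di, p, TimingState(dur, per))
        # manual transform then evaluate in the native space of the params
        d1 = dur - p.pref_1
        d2 = (per - dur) - p.pref_2
        x = d1 * np.cos(p.theta) - d2 * np.sin(p.theta)
        y = d1 * np.sin(p.theta) + d2 * np.cos(p.theta)
        direct = np.exp(-0.5 * ((y / p.sigma_maj) ** 2 + (x / p.sigma_min) ** 2))
        assert via_di == pytest.approx(direct, abs=1e-12)


def test_log_scale_requires_positive_axes():
    spec = ModelSpec("tuned_2d_anisotropic", space="duration_interval", scale="log")
    p = TunedParams(pref_1=-1.0, pref_2=-1.0, sigma_maj=0.5, sigma_min=0.5)
    with pytest.raises(ValueError):
        evaluate_amplitude(spec, p, TimingState(0.5, 0.5))  # zero interval


def test_frequency_scale_semantics():
    """Summed per-second response is Frequency**exp_freq."""

    def summed(freq_hz, exp_freq):
        period = 1.0 / freq_hz
        n_events = int(round(freq_hz))  # events in a 1 s window
        return n_events * 1.0 * frequency_scale(exp_freq, period)

    assert summed(10, 1.0) / summed(1, 1.0) == pytest.approx(10.0)
    assert summed(10, 0.0) / summed(1, 0.0) == pytest.approx(1.0)
    assert summed(4, 0.5) / summed(1, 0.5) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        frequency_scale(0.5, 0.0)
    with pytest.raises(ValueError):
        frequency_scale(1.5, 1.0)


def test_amplitude_matrix_matches_scalar_evaluation(rng):
    durs = rng.uniform(0.05, 1.0, 20)
    pers = durs + rng.uniform(0.0, 0.5, 20)
    p = TunedParams(0.4, 0.55, sigma_maj=0.35, sigma_min=0.12, theta=1.1, exp_freq=0.6)
    vec = params_to_vector(ANISO, p)
    A = amplitude_matrix(ANISO, vec[None, :], durs, pers)[0]
    for i in range(20):
        expected = evaluate_amplitude(
            ANISO, p, TimingState(durs[i], pers[i])
        ) * frequency_scale(p.exp_freq, pers[i])
        assert A[i] == pytest.approx(expected, rel=1e-12)


def test_param_vector_roundtrip_and_json():
    p = TunedParams(0.4, 0.55, sigma_maj=0.35, sigma_min=0.12, theta=1.1, exp_freq=0.6)
    vec = params_to_vector(ANISO, p)
    back = params_from_vector(ANISO, vec)
    assert back == p
    s = spec_to_json(ANISO, p)
    assert '"family": "tuned_2d_anisotropic"' in s
    with pytest.raises(ValueError):
        TunedParams(0.4, 0.5, sigma_maj=0.1, sigma_min=0.2)  # maj < min
    with pytest.raises(ValueError):
        ModelSpec("tuned_1d", tf_variant="per_tr")


# -- temporal-frequency control model ---------------------------------------


def _square_wave(period_s: float, length_s: float) -> np.ndarray:
    t = np.arange(0, length_s, 0.05)
    return ((t % period_s) < period_s / 2).astype(float)


def test_tf_constant_window_gives_no_response():
    params = TFParams(freq_pref=2.0, sigma_f=0.2)
    assert tf_amplitude(params, np.ones(42)) < 1e-10


def test_tf_time_reversal_invariance():
    """Power spectra cannot distinguish an event from its inter-event gap."""
    w = _square_wave(0.5, 2.1)
    params = TFParams(freq_pref=2.0, sigma_f=0.5)
    assert tf_amplitude(params, w) == pytest.approx(
        tf_amplitude(params, w[::-1].copy()), rel=1e-12
    )


def test_tf_pure_tone_peak():
    """A sinusoid at the preferred frequency passes with unit tuning weight."""
    n = 40  # 2 s at 20 Hz; bin spacing 0.5 Hz
    t = np.arange(n) / 20.0
    w = np.sin(2 * np.pi * 2.0 * t)
    freqs, power = window_power(w)
    k = np.argmin(np.abs(freqs - 2.0))
    params = TFParams(freq_pref=2.0, sigma_f=0.05)
    assert tf_amplitude(params, w) == pytest.approx(power[k], rel=1e-9)
    with pytest.raises(ValueError):
        tf_amplitude(params, np.array([]))


@given(
    dur=st.floats(0.05, 1.0),
    gap=st.floats(0.0, 0.5),
    theta=st.floats(0, np.pi),
)
def test_amplitude_bounded_unit(dur, gap, theta):
    p = TunedParams(0.5, 0.6, sigma_maj=0.4, sigma_min=0.2, theta=theta)
    a = evaluate_amplitude(ANISO, p, TimingState(dur, dur + gap))
    assert 0.0 <= a <= 1.0
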