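"""Grid + simplex fitting, cross-validation, comparison, exclusions."""

import numpy as np
import pandas as pd
import pytest

from timingprf.fitting import (
    TimingPRF,
    compare_models,
    cross_validate,
    default_grid,
    empirical_null,
    exclusion_flags,
    grid_fit,
)
from timingprf.models import ModelSpec, TunedParams, params_to_vector
from timingprf.synthetic import (
    GroundTruth,
    calibrate_noise_sd,
    simulate_noise_sites,
    simulate_sites,
    timecourse_matrix,
)

ANISO = ModelSpec("tuned_2d_anisotropic")
ISO = ModelSpec("tuned_2d_isotropic")


def test_on_grid_exact_recovery(estimator_factory, shared_design):
    """A noiseless site generated at a grid point is recovered exactly."""
    spec = ModelSpec("tuned_1d")
    G = default_grid(spec)
    vec = G[1234]
    y = shared_design.predict(spec, vec)
    est = estimator_factory("tuned_1d", refine=False)
    est.fit(y[None, :])
    assert np.allclose(est.params_.iloc[0].to_numpy(), vec)
    assert est.ve_[0] == pytest.approx(1.0, abs=1e-9)


def test_off_grid_refinement_recovery(estimator_factory, shared_design):
    """Simplex refinement recovers off-grid parameters to ~1e-3 s."""
    truth = TunedParams(0.437, 0.552, sigma_maj=0.31, exp_freq=0.63)
    vec = params_to_vector(ISO, truth)
    y = shared_design.predict(ISO, vec)
    est = estimator_factory("tuned_2d_isotropic", refine=True)
    est.fit(y[None, :])
    assert est.params_["pref_1"][0] == pytest.approx(0.437, abs=1e-3)
    assert est.params_["pref_2"][0] == pytest.approx(0.552, abs=1e-3)
    assert est.ve_[0] > 0.9999


def test_refinement_never_decreases_ve(estimator_factory, rng):
    y = rng.normal(size=(3, 224))
    est0 = estimator_factory("tuned_2d_isotropic", refine=False)
    est0.fit(y)
    est1 = estimator_factory("tuned_2d_isotropic", refine=True)
    est1.fit(y)
    assert np.all(est1.ve_ >= est0.ve_ - 1e-12)


def test_all_nan_series_rejected(estimator_factory):
    est = estimator_factory("tuned_1d")
    with pytest.raises(ValueError, match="NaN"):
        est.fit(np.full((1, 224), np.nan))


def test_cross_validate_identical_splits_equals_full(run_schedule, estimator_factory, shared_design):
    vec = params_to_vector(ISO, TunedParams(0.4, 0.5, sigma_maj=0.3, exp_freq=0.8))
    y = shared_design.predict(ISO, vec)[None, :]
    pair = (estimator_factory("tuned_2d_isotropic"), estimator_factory("tuned_2d_isotropic"))
    cv = cross_validate(ISO, y, y, run_schedule, _estimators=pair)
    full = grid_fit(ISO, y, run_schedule, refine=False, grid=None).ve_[0]
    # identical halves: out-of-sample score equals in-sample score
    assert cv["ve_cv"][0] == pytest.approx(full, abs=1e-9)


def test_cross_validated_ve_below_full_ve_on_noisy_splits(
    run_schedule, estimator_factory, rng
):
    """Out-of-sample VE is on average below in-sample VE."""
    n = 30
    dur = rng.uniform(0.2, 0.8, n)
    params = pd.DataFrame(
        {
            "pref_1": dur,
            "pref_2": dur + 0.1,
            "sigma_maj": 0.15 + 0.3 * dur,
            "sigma_min": (0.15 + 0.3 * dur) / 2,
            "theta": np.full(n, np.pi / 4),
            "exp_freq": rng.uniform(0.2, 1.0, n),
        }
    )
    gt = GroundTruth(ANISO, params, noise_sd=calibrate_noise_sd(0.3, 4), n_runs=4, seed=5)
    est = estimator_factory("tuned_2d_anisotropic")
    data = simulate_sites(gt, run_schedule, design=est._design())
    odd, even = timecourse_matrix(data["odd"]), timecourse_matrix(data["even"])
    pair = (est, estimator_factory("tuned_2d_anisotropic"))
    cv = cross_validate(ANISO, odd, even, run_schedule, _estimators=pair)
    full_on_odd = grid_fit(ANISO, odd, run_schedule, refine=False, grid=None)
    assert cv["ve_cv"].mean() < full_on_odd.ve_.mean()

    with pytest.raises(ValueError):
        cross_validate(ANISO, odd, None, run_schedule)


def test_pure_noise_cv_near_zero(run_schedule, estimator_factory):
    noise_o = timecourse_matrix(simulate_noise_sites(20, 1.0, 224, seed=8))
    noise_e = timecourse_matrix(simulate_noise_sites(20, 1.0, 224, seed=9))
    pair = (estimator_factory("tuned_1d"), estimator_factory("tuned_1d"))
    cv = cross_validate(ModelSpec("tuned_1d"), noise_o, noise_e, run_schedule, _estimators=pair)
    assert abs(cv["ve_cv"].mean()) < 0.02


def test_compare_models_identical_columns():
    rows = []
    for m in ("a", "b"):
        for g in range(4):
            for s in range(5):
                rows.append({"model": m, "map": g, "site_id": s, "ve_cv": 0.4 + 0.01 * s})
    tab = pd.DataFrame(rows)
    out = compare_models(tab)
    other = out[~out["is_best"]].iloc[0]
    assert other["t_vs_best"] == 0.0 and other["p_vs_best"] == 1.0
    with pytest.raises(ValueError):
        compare_models(tab[tab.model == "a"])
    with pytest.raises(ValueError):
        compare_models(tab[tab["map"] == 0])


def test_compare_models_inclusion_threshold():
    rows = []
    for g in range(3):
        for s in range(4):
            good = s < 2
            rows.append({"model": "a", "map": g, "site_id": s, "ve_cv": 0.5 if good else 0.05})
            rows.append({"model": "b", "map": g, "site_id": s, "ve_cv": 0.3 if good else 0.04})
    out = compare_models(pd.DataFrame(rows))
    # below-threshold sites are dropped before averaging
    assert out.loc[out["is_best"], "mean_cv_ve"].iloc[0] == pytest.approx(0.5)


def test_noise_overfitting_floor(estimator_factory, run_schedule):
    """Best-model fits to pure noise have a small positive VE floor that
    shrinks with series length, and the empirical null puts a low
    probability on the 10% VE exclusion threshold."""
    from timingprf.stimuli import make_configuration

    spec = ModelSpec("tuned_1d")
    noise = timecourse_matrix(simulate_noise_sites(300, 1.0, 224, seed=21))
    est_long = estimator_factory("tuned_1d")
    est_long.fit(noise)
    block = make_configuration("constant_luminance")
    est_short = TimingPRF(spec=spec, schedule=block, refine=False)
    est_short.fit(noise[:, :56])
    assert 0 < est_long.ve_.mean() < est_short.ve_.mean()
    assert empirical_null(est_long.ve_, 0.10) < 0.05


def test_empirical_null_probabilities():
    null = np.linspace(0.0, 0.2, 101)
    assert empirical_null(null, 0.5) == 0.0
    assert empirical_null(null, np.median(null)) == pytest.approx(0.5, abs=0.01)
    with pytest.raises(ValueError):
        empirical_null(np.array([]), 0.1)
    with pytest.raises(ValueError):
        empirical_null(np.array([1.5]), 0.1)


def test_exclusion_rules_idempotent_and_order_independent():
    derived = pd.DataFrame(
        {
            "preferred_duration": [0.5, 1.1, 0.04, 0.5, np.nan],
            "preferred_period": [0.6, 1.2, 0.5, 0.7, np.nan],
        }
    )
    ve = np.array([0.5, 0.5, 0.5, 0.05, 0.5])
    flags = exclusion_flags(derived, ve)
    assert flags["excluded"].tolist() == [False, True, True, True, False]
    assert flags["exclusion_reason"].tolist()[1:4] == ["out_of_range", "out_of_range", "low_ve"]
    # idempotent: flags derived only from inputs, order-independent
    perm = [4, 2, 0, 3, 1]
    flags_perm = exclusion_flags(derived.iloc[perm].reset_index(drop=True), ve[perm])
    assert flags_perm["excluded"].tolist() == [flags["excluded"][i] for i in perm]


def test_results_table_schema(estimator_factory, shared_design):
    vec = params_to_vector(ISO, TunedParams(0.4, 0.5, sigma_maj=0.3, exp_freq=0.8))
    y = shared_design.predict(ISO, vec)[None, :]
    est = estimator_factory("tuned_2d_isotropic")
    est.fit(y)
    tab = est.results_table(site_ids=["v1"])
    for col in ("site_id", "family", "ve_full", "preferred_duration", "excluded"):
        assert col in tab.columns
    assert tab["site_id"][0] == "v1"


def test_sklearn_params_interface():
    est = TimingPRF(refine=False, n_starts=5)
    p = est.get_params()
    assert p["n_starts"] == 5
    est.set_params(max_iter=50)
    assert est.max_iter == 50
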