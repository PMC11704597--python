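"""Particle-filter posterior, assimilation, and full-record index traces."""

import numpy as np
import pytest
from scipy import stats

from o2index import (
    ChannelKind,
    PhysioParams,
    Posterior,
    assimilate,
    index_value,
    init_posterior,
    run_filter,
)
from o2index.filtering import IVO2, ICO
from conftest import constant_record


def small_posterior(svo2_fracs, weights):
    n = len(svo2_fracs)
    # pad to the 100-particle minimum with zero-weight filler
    pad = 100 - n
    X = np.tile([[250.0], [12.0], [0.97], [2.0], [5.0], [250.0]], (1, 100))
    svo2 = np.concatenate([np.asarray(svo2_fracs, float), np.full(pad, 0.97)])
    w = np.concatenate([np.asarray(weights, float), np.zeros(pad)])
    means = {"vo2_ml_min": 250.0, "hgb_g_dl": 12.0, "sao2_frac": 0.97, "k_sv": 2.0, "co_l_min": 5.0}
    return Posterior(0.0, X, svo2, w / w.sum(), means)


class TestIndexValue:
    def test_all_above_threshold_is_zero(self):
        post = small_posterior([0.6, 0.7, 0.8], [1, 1, 1])
        assert index_value(post, 50.0) == 0.0

    def test_equal_weight_half_below(self):
        post = small_posterior([0.4, 0.6], [1, 1])
        assert index_value(post, 50.0) == pytest.approx(0.5)

    def test_weighted_mixture(self):
        post = small_posterior([0.40, 0.60, 0.48], [0.2, 0.3, 0.5])
        assert index_value(post, 50.0) == pytest.approx(0.7)

    def test_boundary_particle_counts_as_positive(self):
        post = small_posterior([0.50], [1.0])
        assert index_value(post, 50.0) == pytest.approx(1.0)


class TestInitPosterior:
    def test_seeded_determinism(self, params_small):
        rec = constant_record(hours=0.05)
        a = init_posterior(rec, params_small, np.random.default_rng(5))
        b = init_posterior(rec, params_small, np.random.default_rng(5))
        assert np.array_equal(a.states, b.states) and np.array_equal(a.weights, b.weights)

    def test_zero_variance_priors_collapse_ensemble(self):
        p = PhysioParams(
            n_particles=200, vo2_prior_sigma_log=0.0, vo2_mean_prior_sigma_log=0.0,
            co_prior_sigma_log=0.0, hgb_prior_sd_g_dl=0.0, sao2_prior_sd_frac=0.0,
        )
        post = init_posterior(constant_record(hours=0.05), p, np.random.default_rng(0))
        assert np.all(post.states == post.states[:, :1])

    def test_prior_centers_on_first_hgb_lab(self, params_small):
        rec = constant_record(hours=0.05, hgb=9.0)
        post = init_posterior(rec, params_small, np.random.default_rng(0))
        ens_mean = post.weights @ post.states[1]
        assert abs(ens_mean - 9.0) / 9.0 < 0.05

    def test_weights_uniform_simplex(self, params_small):
        post = init_posterior(constant_record(hours=0.05), params_small, np.random.default_rng(0))
        assert abs(post.weights.sum() - 1.0) < 1e-12
        assert np.allclose(post.weights, 1.0 / post.n_particles)


class TestAssimilate:
    def test_no_observations_keeps_weights(self, params_small, rng):
        post = init_posterior(constant_record(hours=0.05), params_small, rng)
        out = assimilate(post, {}, 5.0, params_small, rng)
        assert np.array_equal(out.weights, post.weights)
        assert out.time == 5.0

    def test_time_regression_rejected(self, params_small, rng):
        post = init_posterior(constant_record(hours=0.05), params_small, rng, t0=10.0)
        with pytest.raises(ValueError, match="regression"):
            assimilate(post, {}, 5.0, params_small, rng)

    def test_sharp_lab_pins_posterior_mean(self, rng):
        p = PhysioParams(n_particles=4000, svo2_lab_sd_pct=0.5)
        post = init_posterior(constant_record(hours=0.05), p, rng)
        out = assimilate(post, {ChannelKind.SVO2_LAB: 45.0}, 5.0, p, rng)
        mean_svo2 = 100.0 * (out.weights @ out.svo2)
        assert abs(mean_svo2 - 45.0) < 1.0
        assert abs(out.weights.sum() - 1.0) < 1e-9

    def test_second_identical_lab_shifts_less(self, rng):
        # Bayesian shrinkage: repeated evidence moves the mean by less
        p = PhysioParams(n_particles=4000)
        post = init_posterior(constant_record(hours=0.05), p, rng)
        m0 = 100.0 * (post.weights @ post.svo2)
        one = assimilate(post, {ChannelKind.SVO2_LAB: 55.0}, 5.0, p, rng)
        m1 = 100.0 * (one.weights @ one.svo2)
        two = assimilate(one, {ChannelKind.SVO2_LAB: 55.0}, 10.0, p, rng)
        m2 = 100.0 * (two.weights @ two.svo2)
        assert abs(m1 - m0) > abs(m2 - m1)

    def test_weight_normalization_after_every_update(self, params_small, rng):
        post = init_posterior(constant_record(hours=0.05), params_small, rng)
        t = 0.0
        for obs in ({ChannelKind.SPO2: 96.0}, {ChannelKind.HGB_LAB: 10.0}, {ChannelKind.CI_CONT: 2.4}, {}):
            t += 5.0
            post = assimilate(post, obs, t, params_small, rng)
            assert abs(post.weights.sum() - 1.0) < 1e-9
            assert 0.0 <= index_value(post, 50.0) <= 1.0


def _record_with_labs(svo2_pct, hours=2.0, every_s=900.0):
    extra = [(t, "SVO2_LAB", svo2_pct) for t in np.arange(300.0, hours * 3600.0, every_s)]
    return constant_record(hours=hours, extra_rows=extra)


class TestRunFilter:
    def test_never_gated_record_yields_empty_trace(self, params_small):
        # vitals present but no hemoglobin lab anywhere
        rec = constant_record(hours=0.2)
        rec.samples = rec.samples[rec.samples["channel"] != "HGB_LAB"].reset_index(drop=True)
        trace = run_filter(rec, params_small, "baseline", np.random.default_rng(0))
        assert np.all(~np.isfinite(trace.values))

    def test_high_svo2_patient_scores_low(self, params_small):
        trace = run_filter(_record_with_labs(65.0), params_small, "baseline", np.random.default_rng(0))
        assert np.nanmean(trace.values) < 0.2

    def test_low_svo2_patient_scores_high(self, params_small):
        trace = run_filter(_record_with_labs(40.0), params_small, "baseline", np.random.default_rng(0))
        assert np.nanmean(trace.values) > 0.8

    def test_same_seed_identical_trace(self, params_small):
        rec = _record_with_labs(55.0, hours=0.5)
        a = run_filter(rec, params_small, "baseline", np.random.default_rng(3))
        b = run_filter(rec, params_small, "baseline", np.random.default_rng(3))
        assert np.array_equal(a.values, b.values, equal_nan=True)

    def test_index_stays_in_unit_interval(self, params_small):
        trace = run_filter(_record_with_labs(50.0, hours=0.5), params_small, "baseline", np.random.default_rng(0))
        v = trace.values[np.isfinite(trace.values)]
        assert v.size and v.min() >= 0.0 and v.max() <= 1.0

    def test_gating_gap_masks_output_but_filter_continues(self, params_small):
        # drop CVP for a 5-minute stretch: index withheld there, resumes after
        rec = constant_record(hours=0.5)
        s = rec.samples
        gap = (s["channel"] == "CVP") & (s["time_s"] >= 600.0) & (s["time_s"] < 900.0)
        rec.samples = s[~gap].reset_index(drop=True)
        trace = run_filter(rec, params_small, "baseline", np.random.default_rng(0))
        in_gap = (trace.times >= 700.0) & (trace.times < 900.0)
        after = trace.times >= 960.0
        assert np.all(~np.isfinite(trace.values[in_gap]))
        assert np.all(np.isfinite(trace.values[after]))


class TestEngineEquivalence:
    def test_deterministic_settings_bitwise_equal(self):
        p = PhysioParams(
            n_particles=200, vo2_sd_frac=0, ksv_sd_frac=0, hgb_sd_frac=0, sao2_sd_frac=0,
            co_sd_frac=0, vo2_mean_sd_frac=0, ess_fraction=0.0, resample_bandwidth=0.0,
        )
        rec = _record_with_labs(55.0, hours=0.5)
        a = run_filter(rec, p, "baseline", np.random.default_rng(1), engine="numpy")
        b = run_filter(rec, p, "baseline", np.random.default_rng(1), engine="numba")
        assert np.nanmax(np.abs(a.values - b.values)) < 1e-12

    def test_stochastic_settings_statistically_close(self, params_small):
        rec = _record_with_labs(52.0, hours=1.0)
        means = {}
        for eng in ("numpy", "numba"):
            ms = [
                np.nanmean(run_filter(rec, params_small, "baseline", np.random.default_rng(s), engine=eng).values)
                for s in range(5)
            ]
            means[eng] = np.mean(ms)
        assert abs(means["numpy"] - means["numba"]) < 0.1


def test_information_monotonicity_across_cohort(cohort_study):
    """Posterior-mean SvO2 error is no worse with full monitoring than in the
    central-line-only scenario (paired across cohort seeds, alpha=0.05)."""
    t = cohort_study.table.pivot(index="seed", columns="scenario", values="mae_svo2_pct")
    diff = t["C"] - t["baseline"]
    res = stats.ttest_rel(t["C"], t["baseline"], alternative="greater")
    assert diff.mean() > 0
    assert res.pvalue < 0.05
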