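"""Windowing, dichotomization, ROC/AUC, bootstrap, and scenario tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import roc_auc_score

from o2index import (
    IndexTrace,
    ReferencePair,
    auc_trapezoid,
    bootstrap_ci,
    build_pairs,
    dichotomize,
    evaluate_scenarios,
    roc_curve,
    window_mean,
)
from o2index.streams import PatientRecord
from o2index.physiology import PhysioParams


def make_pairs(scores, labels):
    return [
        ReferencePair(f"p{i}", 0.0, float(s), 40.0 if y else 60.0, bool(y))
        for i, (s, y) in enumerate(zip(scores, labels))
    ]


def brute_force_auc(scores, labels):
    """Independent oracle: exhaustive pairwise concordance with half-credit ties."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos, neg = s[y], s[~y]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (pos.size * neg.size)


def trace_of(values, dt=5.0):
    v = np.asarray(values, float)
    return IndexTrace(np.arange(v.size) * dt, v, 50.0)


class TestWindowMean:
    def test_constant_trace(self):
        assert window_mean(trace_of([0.3] * 720), 1800.0) == pytest.approx(0.3)

    def test_sample_at_lab_timestamp_excluded(self):
        v = np.zeros(721)
        v[360] = 1.0  # exactly at lab time 1800 s
        assert window_mean(trace_of(v), 1800.0) == pytest.approx(0.0)

    def test_weighted_mean_of_mixed_window(self):
        # 10 samples at 0.2 then 30 samples at 0.6 in a 200 s window
        v = np.r_[np.full(10, 0.2), np.full(30, 0.6)]
        tr = trace_of(v)
        assert window_mean(tr, 200.0, width_s=200.0) == pytest.approx(0.5)

    def test_empty_window_is_missing(self):
        tr = trace_of([np.nan] * 100)
        assert np.isnan(window_mean(tr, 300.0))

    def test_window_is_lookback_only(self):
        v = np.r_[np.full(60, 0.1), np.full(60, 0.9)]
        assert window_mean(trace_of(v), 300.0, width_s=300.0) == pytest.approx(0.1)


class TestDichotomize:
    @pytest.mark.parametrize("svo2,expected", [(50.0, True), (50.1, False), (49.9, True), (0.0, True), (100.0, False)])
    def test_boundary_inclusive_positive(self, svo2, expected):
        assert dichotomize(svo2) is expected

    def test_threshold_configurable(self):
        assert dichotomize(35.0, threshold_pct=30.0) is False
        assert dichotomize(30.0, threshold_pct=30.0) is True


class TestROC:
    def test_perfect_separation_auc_one(self):
        r = roc_curve(make_pairs([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]))
        assert r.auc == pytest.approx(1.0)

    def test_all_tied_scores_chance_auc(self):
        r = roc_curve(make_pairs([0.5] * 6, [1, 1, 1, 0, 0, 0]))
        assert r.auc == pytest.approx(0.5)
        # single interior operating point plus endpoints
        assert len(r.fpr) == 2 or (len(r.fpr) == 3 and r.fpr[1] not in (0.0, 1.0))

    def test_worked_six_pair_instance(self):
        scores = [0.9, 0.8, 0.7, 0.4, 0.3, 0.1]
        labels = [1, 1, 0, 1, 0, 0]
        r = roc_curve(make_pairs(scores, labels))
        assert r.auc == pytest.approx(8.0 / 9.0, abs=1e-12)
        assert r.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-15)

    def test_single_class_rejected_with_named_class(self):
        with pytest.raises(ValueError, match="positive"):
            roc_curve(make_pairs([0.1, 0.2], [0, 0]))
        with pytest.raises(ValueError, match="negative"):
            roc_curve(make_pairs([0.1, 0.2], [1, 1]))

    def test_operating_points_monotone_with_endpoints(self):
        rng = np.random.default_rng(0)
        r = roc_curve(make_pairs(rng.random(50).round(1), rng.integers(0, 2, 50)))
        assert r.fpr[0] == 0.0 and r.tpr[0] == 0.0
        assert r.fpr[-1] == 1.0 and r.tpr[-1] == 1.0
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)

    @given(st.integers(0, 500))
    def test_trapezoid_equals_mann_whitney_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        scores = rng.random(n).round(2)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        r = roc_curve(make_pairs(scores, labels))
        assert auc_trapezoid(r) == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
        assert r.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    @given(st.integers(0, 200))
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(40)
        labels = np.r_[np.ones(15, int), np.zeros(25, int)]
        a = roc_curve(make_pairs(scores, labels)).auc
        b = roc_curve(make_pairs(np.expm1(3 * scores) / np.expm1(3.0), labels)).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_two_point_diagonal_and_step_curve(self):
        r = roc_curve(make_pairs([0.5, 0.5], [1, 0]))
        assert auc_trapezoid(r) == pytest.approx(0.5)
        r2 = roc_curve(make_pairs([1.0, 0.0], [1, 0]))
        assert auc_trapezoid(r2) == pytest.approx(1.0)


class TestBootstrap:
    def test_perfect_separation_degenerate_interval(self):
        pairs = make_pairs([0.9, 0.8, 0.7, 0.2, 0.1, 0.05], [1, 1, 1, 0, 0, 0])
        lo, hi = bootstrap_ci(pairs, B=200, rng=0)
        assert lo == 1.0 and hi == 1.0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(0)
        pairs = make_pairs(rng.random(40), rng.integers(0, 2, 40))
        a = bootstrap_ci(pairs, B=300, rng=42)
        b = bootstrap_ci(pairs, B=300, rng=42)
        assert a == b

    def test_small_b_warns(self):
        pairs = make_pairs([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        with pytest.warns(UserWarning):
            bootstrap_ci(pairs, B=50, rng=0)

    def test_cluster_bootstrap_resamples_patients(self):
        rng = np.random.default_rng(3)
        pairs = []
        for pid in range(10):
            for _ in range(3):
                y = rng.random() < 0.3
                pairs.append(ReferencePair(f"p{pid}", 0.0, float(np.clip(rng.normal(0.7 if y else 0.3, 0.15), 0, 1)), 40.0 if y else 60.0, y))
        lo, hi = bootstrap_ci(pairs, B=300, rng=1, cluster_by_patient=True)
        assert 0.0 <= lo <= hi <= 1.0


class TestBuildPairs:
    def test_accounting_identity_labs_with_coverage(self):
        # 3 labs; the middle one has an all-missing window and is dropped
        v = np.full(1440, 0.4)
        v[680:740] = np.nan
        trace = IndexTrace(np.arange(1440) * 5.0, v, 50.0)
        rows = [(3500.0, "SVO2_LAB", 55.0), (3650.0, "SVO2_LAB", 45.0), (7000.0, "SVO2_LAB", 60.0)]
        rec = PatientRecord("p", 64.0, 1.9, pd.DataFrame(rows, columns=["time_s", "channel", "value"]))
        # make the middle lab's whole 30-min window missing
        v2 = v.copy()
        v2[int((3650 - 1800) / 5):int(3650 / 5)] = np.nan
        trace2 = IndexTrace(np.arange(1440) * 5.0, v2, 50.0)
        pairs, dropped = build_pairs(rec, trace2)
        assert len(pairs) + dropped == 3
        assert dropped == 1
        assert {p.lab_time_s for p in pairs} == {3500.0, 7000.0}
        assert all(p.label == (p.svo2_lab_pct <= 50.0) for p in pairs)


class TestEvaluateScenarios:
    def test_no_labs_yields_empty_table(self, params_small, caplog):
        from conftest import constant_record
        rec = constant_record(hours=0.2)
        table = evaluate_scenarios([rec], params_small, scenarios=("baseline",), seed=0, B=100)
        assert len(table) == 0

    def test_deterministic_given_seed(self, params_small):
        from conftest import constant_record
        extra = [(t, "SVO2_LAB", v) for t, v in [(600.0, 45.0), (1200.0, 55.0), (1500.0, 48.0), (1700.0, 61.0)]]
        rec = constant_record(hours=0.5, extra_rows=extra)
        kw = dict(scenarios=("baseline", "C"), seed=11, B=100)
        a = evaluate_scenarios([rec], params_small, **kw)
        b = evaluate_scenarios([rec], params_small, **kw)
        pd.testing.assert_frame_equal(a, b)
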