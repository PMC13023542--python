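"""Fusion, event extraction, matching and clinical metrics."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from apneaseg.events import EventInterval
from apneaseg.postproc import (
    PostprocConfig, ahi_errors, aggregate_reports, cohens_kappa,
    estimate_ahi, evaluate_night, fuse_windows, grade_severity,
    interval_iou, match_events, precision_recall_f1, probability_to_events,
    severity_confusion,
)
from conftest import random_disjoint_intervals


def brute_force_max_matching(pred, truth, theta):
    """Exhaustive search over all one-to-one matchings (oracle, <=8 a side)."""
    edges = [[j for j, t in enumerate(truth) if interval_iou(p, t) > theta]
             for p in pred]
    best = 0

    def rec(i, used, count):
        nonlocal best
        best = max(best, count)
        if i == len(pred) or count + (len(pred) - i) <= best:
            return
        rec(i + 1, used, count)
        for j in edges[i]:
            if j not in used:
                rec(i + 1, used | {j}, count + 1)

    rec(0, frozenset(), 0)
    return best


class TestFuseWindows:
    def test_overlap_mean(self):
        probs = np.array([[0.3, 0.3], [0.7, 0.7]])
        fused = fuse_windows(probs, [0, 1], L=3)
        assert np.allclose(fused.p_hat, [0.3, 0.5, 0.7])
        assert fused.coverage.tolist() == [1, 2, 1]

    def test_single_window_identity(self):
        p = np.linspace(0, 1, 10)[None]
        fused = fuse_windows(p, [0], L=10)
        assert np.allclose(fused.p_hat, p[0])

    def test_matches_bruteforce_oracle(self, rng):
        L, T = 500, 64
        starts = np.sort(rng.integers(0, L - T, size=20))
        starts[0] = 0
        starts[-1] = L - T
        # force coverage by adding a ladder of windows
        ladder = np.arange(0, L - T + 1, T // 2)
        starts = np.concatenate([starts, ladder])
        probs = rng.uniform(size=(len(starts), T))
        fused = fuse_windows(probs, starts, L)
        acc = np.zeros(L)
        cov = np.zeros(L)
        for p, s in zip(probs, starts):
            acc[s:s + T] += p
            cov[s:s + T] += 1
        assert np.all(cov > 0)
        assert np.allclose(fused.p_hat, acc / cov, atol=1e-12)

    def test_uncovered_gap_raises(self):
        with pytest.raises(ValueError, match="uncovered"):
            fuse_windows(np.ones((1, 10)), [0], L=20)


class TestProbabilityToEvents:
    def test_gap_merge(self):
        # two runs separated by 3 s (<= 6 s) merge into one event
        p = np.zeros(1000)
        p[0:500] = 1.0
        p[530:1000] = 1.0
        ev = probability_to_events(p, PostprocConfig(), fs=10.0)
        assert [(e.start, e.end) for e in ev] == [(0, 1000)]

    def test_min_duration_filter(self):
        # 9 s run < 10 s minimum is discarded
        p = np.zeros(1000)
        p[100:190] = 1.0
        assert probability_to_events(p, PostprocConfig(), fs=10.0) == []

    def test_constant_one_single_event(self):
        p = np.ones(2000)
        ev = probability_to_events(p, PostprocConfig(), fs=10.0)
        assert [(e.start, e.end) for e in ev] == [(0, 2000)]

    def test_idempotent_on_own_output(self, rng):
        cfg = PostprocConfig()
        for _ in range(20):
            p = (rng.uniform(size=3000) < 0.3).astype(float)
            ev = probability_to_events(p, cfg, fs=10.0)
            raster = np.zeros(3000)
            for e in ev:
                raster[e.start:e.end] = 1.0
            again = probability_to_events(raster, cfg, fs=10.0)
            assert [(e.start, e.end) for e in again] == \
                   [(e.start, e.end) for e in ev]

    def test_raising_tau_shrinks_positive_duration(self, rng):
        p = rng.uniform(size=5000)
        prev = np.inf
        for tau in (0.2, 0.4, 0.6, 0.8):
            dur = int(np.sum(p >= tau))
            assert dur <= prev
            prev = dur


class TestMatching:
    def test_iou_hand_value(self):
        a = EventInterval(0, 100)
        b = EventInterval(50, 150)
        assert interval_iou(a, b) == pytest.approx(1 / 3)
        assert interval_iou(a, a) == 1.0
        assert interval_iou(a, EventInterval(200, 300)) == 0.0

    def test_perfect_match(self):
        ev = [EventInterval(0, 100), EventInterval(200, 300)]
        tp, fp, fn, pairs = match_events(ev, ev, 0.1)
        assert (tp, fp, fn) == (2, 0, 0)
        assert pairs == [(0, 0), (1, 1)]

    def test_one_pred_two_truths_single_count(self):
        pred = [EventInterval(0, 200)]
        truth = [EventInterval(0, 90), EventInterval(110, 200)]
        tp, fp, fn, _ = match_events(pred, truth, 0.1)
        assert (tp, fp, fn) == (1, 0, 1)

    def test_straddling_prediction_does_not_strand_neighbour(self):
        # a greedy descending-IoU pairing would strand one event here
        truth = [EventInterval(0, 100), EventInterval(110, 210)]
        pred = [EventInterval(50, 160), EventInterval(0, 30)]
        tp, _, _, _ = match_events(pred, truth, 0.1)
        assert tp == 2

    def test_equals_exhaustive_oracle(self, rng):
        for _ in range(100):
            pred = random_disjoint_intervals(rng, int(rng.integers(0, 9)), 400)
            truth = random_disjoint_intervals(rng, int(rng.integers(0, 9)), 400)
            theta = float(rng.choice([0.0, 0.1, 0.3]))
            tp, fp, fn, pairs = match_events(pred, truth, theta)
            assert tp == brute_force_max_matching(pred, truth, theta)
            assert fp == len(pred) - tp and fn == len(truth) - tp
            assert len({i for i, _ in pairs}) == len(pairs)
            assert len({j for _, j in pairs}) == len(pairs)

    def test_overlapping_inputs_rejected(self):
        with pytest.raises(ValueError):
            match_events([EventInterval(0, 10), EventInterval(5, 15)], [], 0.1)


class TestRecordingMetrics:
    def test_precision_recall_f1_hand(self):
        m = precision_recall_f1(2, 1, 1)
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["recall"] == pytest.approx(2 / 3)
        assert m["f1"] == pytest.approx(2 / 3)
        assert precision_recall_f1(0, 0, 0) == \
               {"precision": 0.0, "recall": 0.0, "f1": 0.0}
        assert precision_recall_f1(5, 0, 0)["f1"] == 1.0

    def test_ahi_unit_arithmetic(self):
        assert estimate_ahi(8, 288000, 10.0) == pytest.approx(1.0)
        assert estimate_ahi(0, 1000, 10.0) == 0.0
        assert estimate_ahi(21, 3 * 3600 * 10, 10.0) == pytest.approx(7.0)
        with pytest.raises(ValueError):
            estimate_ahi(1, 0, 10.0)

    def test_ahi_errors_oracle(self, rng):
        pred = rng.uniform(0, 40, size=10)
        true = rng.uniform(0, 40, size=10)
        out = ahi_errors(pred, true)
        assert out["mae"] == pytest.approx(np.mean(np.abs(pred - true)), abs=1e-10)
        assert out["rmse"] == pytest.approx(
            np.sqrt(np.mean((pred - true) ** 2)), abs=1e-10)
        assert out["pearson"] == pytest.approx(
            stats.pearsonr(pred, true).statistic)
        identical = ahi_errors(true, true)
        assert identical["mae"] == 0 and identical["pearson"] == pytest.approx(1.0)
        shifted = ahi_errors(true + 2, true)
        assert shifted["mae"] == pytest.approx(2.0)
        assert shifted["rmse"] == pytest.approx(2.0)

    @pytest.mark.parametrize("ahi,cls", [
        (0.0, 0), (4.9, 0), (5.0, 1), (14.9, 1), (15.0, 2),
        (29.9, 2), (30.0, 3), (80.0, 3)])
    def test_severity_cutoffs(self, ahi, cls):
        assert grade_severity(ahi) == cls

    def test_negative_ahi_rejected(self):
        with pytest.raises(ValueError):
            grade_severity(-1.0)

    def test_kappa_hand_value(self):
        conf = np.array([[25, 5], [10, 60]])
        po, pe = 0.85, 0.56
        assert cohens_kappa(conf) == pytest.approx((po - pe) / (1 - pe))

    def test_kappa_perfect_and_sklearn_crosscheck(self, rng):
        assert cohens_kappa(np.diag([3, 4, 5, 6])) == pytest.approx(1.0)
        # independent implementation: sklearn from label pairs
        y1 = rng.integers(0, 4, size=200)
        y2 = np.where(rng.uniform(size=200) < 0.6, y1,
                      rng.integers(0, 4, size=200))
        conf = np.zeros((4, 4), dtype=int)
        for a, b in zip(y1, y2):
            conf[a, b] += 1
        assert cohens_kappa(conf) == pytest.approx(
            cohen_kappa_score(y1, y2), abs=1e-10)

    def test_kappa_near_zero_under_independence(self, rng):
        y1 = rng.integers(0, 4, size=20000)
        y2 = rng.integers(0, 4, size=20000)
        conf = np.zeros((4, 4), dtype=int)
        for a, b in zip(y1, y2):
            conf[a, b] += 1
        assert abs(cohens_kappa(conf)) < 0.03


class TestEvaluateNight:
    def _truth(self):
        return [EventInterval(200, 400), EventInterval(1000, 1300)]

    def test_truth_probabilities_are_perfect(self):
        truth = self._truth()
        L, T = 2000, 512
        starts = np.arange(0, L - T + 1, 300)
        if starts[-1] + T < L:
            starts = np.append(starts, L - T)
        raster = np.zeros(L)
        for e in truth:
            raster[e.start:e.end] = 1.0
        probs = np.stack([raster[s:s + T] for s in starts])
        rec = evaluate_night(probs, starts, truth, L, 10.0, PostprocConfig())
        assert rec["tp"] == len(truth) and rec["fp"] == 0 and rec["fn"] == 0
        assert rec["ahi_pred"] == pytest.approx(rec["ahi_true"])

    def test_all_zero_probabilities(self):
        truth = self._truth()
        L, T = 2000, 512
        starts = np.arange(0, L - T + 1, 300)
        starts = np.append(starts, L - T)
        probs = np.zeros((len(starts), T))
        rec = evaluate_night(probs, starts, truth, L, 10.0, PostprocConfig())
        assert rec["fp"] == 0 and rec["fn"] == len(truth)
        assert rec["ahi_pred"] == 0.0

    def test_aggregation_pools_counts(self):
        recs = [
            {"tp": 3, "fp": 1, "fn": 0, "ahi_pred": 10.0, "ahi_true": 9.0},
            {"tp": 0, "fp": 0, "fn": 4, "ahi_pred": 0.0, "ahi_true": 8.0},
        ]
        rep = aggregate_reports(recs)
        # pooled: P = 3/4, R = 3/7 -- not the mean of per-night F1s
        assert rep.precision == pytest.approx(3 / 4)
        assert rep.recall == pytest.approx(3 / 7)
        assert rep.severity_confusion.sum() == 2
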