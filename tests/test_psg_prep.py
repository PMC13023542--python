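"""Annotation parsing, event cleaning, normalization and windowing."""

import io

import numpy as np
import pandas as pd
import pytest

from apneaseg.events import EventInterval
from apneaseg.psg_prep import (
    AnnotationRow, NightRecord, binarize_labels, build_night_record,
    decimate_signal, extract_intervals, parse_annotations, parse_event_string,
    rasterize_labels, resolve_events, robust_normalize, window_night,
)


def _df(rows):
    return pd.DataFrame(rows, columns=["epoch", "time", "duration", "event"])


class TestParseAnnotations:
    def test_both_prefixes_map_to_same_code(self):
        rows = parse_annotations(_df([
            (1, 10.0, 20.0, "Respiratory Event Hypopnea"),
            (2, 50.0, 15.0, "RespEvent Hypopnea"),
        ]))
        assert [r.code for r in rows] == [4, 4]

    def test_invalid_rows_dropped(self):
        rows = parse_annotations(_df([
            (1, 10.0, -3.0, "RespEvent Hypopnea"),          # bad duration
            (2, np.nan, 10.0, "RespEvent Hypopnea"),        # missing time
            (3, 5.0, 12.0, "SomeUnknownThing"),             # unknown event
            (4, 100.0, 12.0, "RespEvent ObstructiveApnea"),  # valid
        ]))
        assert len(rows) == 1 and rows[0].code == 1

    def test_empty_table(self):
        assert parse_annotations(_df([])) == []

    def test_missing_column_raises(self):
        with pytest.raises(ValueError, match="missing required column"):
            parse_annotations(pd.DataFrame({"time": [1.0]}))

    @pytest.mark.parametrize("s,code", [
        ("Respiratory Event ObstructiveApnea", 1),
        ("RespEvent CentralApnea", 2),
        ("respevent mixed apnea", 3),
        ("Hypopnea", 4),
        ("RespEvent RERA", 5),
        ("nonsense", None)])
    def test_string_dictionary(self, s, code):
        assert parse_event_string(s) == code


class TestResolveEvents:
    def test_midnight_wrap_correction(self):
        # clock-difference duration: 00:00:10 - 23:59:50 = -86380 s
        rows = parse_annotations(_df([
            (1, 86390.0, -86380.0, "RespEvent ObstructiveApnea")]))
        assert len(rows) == 1
        ev = resolve_events(rows, fs=10.0)
        assert len(ev) == 1
        assert ev[0].length == 200  # 20 s at 10 Hz

    def test_apnea_dominates_hypopnea_overlap(self):
        rows = [AnnotationRow(0, 100.0, 40.0, 4),   # hypopnea [100,140)
                AnnotationRow(0, 120.0, 30.0, 1)]   # apnea    [120,150)
        ev = resolve_events(rows, fs=1.0)
        assert [(e.start, e.end, e.code) for e in ev] == \
               [(100, 120, 4), (120, 150, 1)]

    def test_longer_event_wins_same_priority(self):
        rows = [AnnotationRow(0, 0.0, 20.0, 4),
                AnnotationRow(0, 10.0, 40.0, 4)]
        ev = resolve_events(rows, fs=1.0)
        # longer hypopnea keeps [10,50); shorter keeps [0,10); same code and
        # zero gap -> merged
        assert [(e.start, e.end) for e in ev] == [(0, 50)]

    def test_small_gap_same_code_merged(self):
        rows = [AnnotationRow(0, 0.0, 20.0, 4),
                AnnotationRow(0, 22.5, 17.5, 4)]   # gap 2.5 s <= 3 s
        ev = resolve_events(rows, fs=1.0)
        assert [(e.start, e.end, e.code) for e in ev] == [(0, 40, 4)]

    def test_cross_code_gap_not_merged(self):
        rows = [AnnotationRow(0, 0.0, 20.0, 4),
                AnnotationRow(0, 22.0, 20.0, 1)]
        ev = resolve_events(rows, fs=1.0)
        assert len(ev) == 2

    def test_idempotent(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 10))
            rows = [AnnotationRow(0, float(t), float(d),
                                  int(rng.choice([1, 2, 3, 4])))
                    for t, d in zip(np.cumsum(rng.integers(5, 60, n)),
                                    rng.integers(10, 40, n))]
            ev1 = resolve_events(rows, fs=10.0)
            rows2 = [AnnotationRow(0, e.start / 10.0, e.length / 10.0, e.code)
                     for e in ev1]
            ev2 = resolve_events(rows2, fs=10.0)
            assert ev1 == ev2
            starts = [e.start for e in ev1]
            assert starts == sorted(starts)
            for a, b in zip(ev1, ev1[1:]):
                assert a.end <= b.start

    def test_raster_roundtrip(self, rng):
        """resolve -> rasterize -> re-extract returns the same intervals."""
        for _ in range(100):
            n = int(rng.integers(1, 8))
            t = 0.0
            rows = []
            for _ in range(n):
                t += float(rng.integers(4, 60))
                d = float(rng.integers(10, 40))
                rows.append(AnnotationRow(0, t, d,
                                          int(rng.choice([1, 2, 3, 4]))))
                t += d
            ev = resolve_events(rows, fs=10.0)
            L = int((t + 100) * 10)
            labels = rasterize_labels(ev, L)
            assert extract_intervals(labels) == ev


class TestRasterizeBinarize:
    def test_index_arithmetic(self):
        ev = [EventInterval(30, 50, 4)]   # 3.0-5.0 s at 10 Hz
        labels = rasterize_labels(ev, 100)
        assert labels[30:50].tolist() == [4] * 20
        assert labels.sum() == 4 * 20

    def test_no_events_all_zero(self):
        assert rasterize_labels([], 50).sum() == 0

    def test_event_past_end_clipped(self):
        labels = rasterize_labels([EventInterval(90, 150, 2)], 100)
        assert labels[90:].tolist() == [2] * 10

    def test_binarize_codebook(self):
        assert binarize_labels(np.array([0, 1, 4, 5, 2])).tolist() == \
               [0, 1, 1, 0, 1]
        assert binarize_labels(np.zeros(5, dtype=int)).sum() == 0
        assert binarize_labels(np.full(5, 5)).sum() == 0

    def test_binarize_rejects_bad_codes(self):
        with pytest.raises(ValueError):
            binarize_labels(np.array([0, 7]))


class TestRobustNormalize:
    def test_constant_signal_zeros(self):
        out = robust_normalize(np.full(100, 3.7))
        assert np.all(out == 0)

    def test_clip_at_four_iqr(self):
        # a point more than 4 IQR above the median clips to exactly 4.0
        rng = np.random.default_rng(3)
        x = rng.normal(10.0, 2.0, size=1000)
        med = np.median(x)
        q75, q25 = np.percentile(x, [75, 25])
        x[0] = med + 5.0 * (q75 - q25)      # beyond the clip bound
        out = robust_normalize(x)
        assert out.max() == pytest.approx(4.0, abs=1e-2)
        assert out[0] == out.max()

    def test_nan_inf_sanitized(self):
        x = np.sin(np.linspace(0, 20, 500))
        x[10] = np.nan
        x[20] = np.inf
        out = robust_normalize(x)
        assert np.all(np.isfinite(out))

    def test_median_zero_and_bounded(self, rng):
        for _ in range(20):
            x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 10), 1000)
            out = robust_normalize(x)
            assert abs(np.median(out)) < 1e-9
            assert np.max(np.abs(out)) <= 4.0 + 1e-9


class TestDecimate:
    def test_factor_20_length(self):
        assert len(decimate_signal(np.zeros(40000), 200, 10)) == 2000

    def test_factor_5_length(self):
        assert len(decimate_signal(np.zeros(5000), 50, 10)) == 1000

    def test_sinusoid_preserved(self):
        t = np.arange(0, 120, 1 / 200)
        x = np.sin(2 * np.pi * 0.3 * t)
        y = decimate_signal(x, 200, 10)
        # spectral oracle: amplitude at 0.3 Hz within 2 %
        f = np.fft.rfftfreq(len(y), d=0.1)
        amp = 2 * np.abs(np.fft.rfft(y * np.hanning(len(y)))) / np.sum(
            np.hanning(len(y)))
        assert amp[np.argmin(np.abs(f - 0.3))] == pytest.approx(1.0, rel=0.02)

    def test_constant_preserved(self):
        y = decimate_signal(np.full(1000, 2.5), 50, 10)
        assert np.allclose(y, 2.5, atol=1e-6)

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError):
            decimate_signal(np.zeros(100), 50, 15)


class TestWindowing:
    def _night(self, L):
        sig = np.random.default_rng(0).normal(size=(L, 2))
        labels = np.zeros(L, dtype=int)
        labels[L // 2:L // 2 + 300] = 1
        return NightRecord(signal=sig, labels=labels)

    def test_window_count_formula(self):
        ws = window_night(self._night(3848), T=2048, S=300)
        assert ws.n_windows == 7
        assert ws.starts.tolist() == [0, 300, 600, 900, 1200, 1500, 1800]

    def test_exact_length_single_window(self):
        ws = window_night(self._night(2048), T=2048, S=300)
        assert ws.n_windows == 1

    def test_window_duration_at_10hz(self):
        assert 2048 / 10.0 == pytest.approx(204.8)

    def test_short_night_rejected(self):
        with pytest.raises(ValueError, match="pad"):
            window_night(self._night(2000), T=2048)

    def test_label_slices_match_full_night(self, rng):
        night = self._night(4000)
        ws = window_night(night, T=512, S=300)
        binary = night.binary_labels
        for k in rng.choice(ws.n_windows, size=5, replace=False):
            s = ws.starts[k]
            assert np.array_equal(ws.y[k, :, 0], binary[s:s + 512])
            assert np.array_equal(ws.X[k],
                                  night.signal[s:s + 512].astype(np.float32))


def test_build_night_record_trims_and_normalizes():
    chest = np.sin(np.linspace(0, 100, 1000))
    abd = np.sin(np.linspace(0, 100, 998))
    labels = np.zeros(999, dtype=int)
    rec = build_night_record(chest, abd, labels)
    assert rec.n_samples == 998
    assert abs(np.median(rec.signal[:, 0])) < 1e-6
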