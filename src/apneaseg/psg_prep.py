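"""Annotation parsing, event cleaning, label rasterization and windowing.

Takes tabular respiratory-event annotations in the (epoch, time, duration,
event) dialect plus two-channel effort signals and produces model-ready
tensors: per-night 10 Hz signal matrices, per-sample integer/binary labels and
overlapping 2048-sample windows with a 300-sample stride.

Conventions
-----------
* sample intervals are 0-based half-open; seconds map to samples via
  ``floor(start*fs)`` / ``ceil(end*fs)``;
* overlapping annotations are resolved by priority: apnea subtypes (codes
  1-3) dominate hypopnea (4); among equal priority the longer event wins and
  the loser keeps only its non-overlapping remainder;
* same-code neighbours separated by <= 3 s are merged (cross-code adjacency
  is left to the priority rule);
* a negative tabulated duration whose value + 24 h is a plausible event
  length (< 1 h) is treated as a midnight wrap and corrected by adding 24 h;
  other non-positive durations are invalid and dropped.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from apneaseg.events import (
    APNEA_CODES,
    CODE_NAMES,
    EventInterval,
    POSITIVE_CODES,
)
from apneaseg.radar_dsp import decimate_signal  # shared implementation

logger = logging.getLogger(__name__)

SECONDS_PER_DAY = 86400.0
# longest single event we accept when un-wrapping midnight-crossing rows
_MAX_PLAUSIBLE_EVENT_S = 3600.0
MERGE_GAP_S = 3.0

# Explicit event-string dictionary.  Annotations appear with two related
# prefixes ("Respiratory Event" and "RespEvent"); the canonical subtype names
# also occur with internal spaces.
_PREFIXES = ("respiratory event", "respevent")
_CANONICAL = {
    "normal": 0,
    "obstructiveapnea": 1,
    "obstructive apnea": 1,
    "centralapnea": 2,
    "central apnea": 2,
    "mixedapnea": 3,
    "mixed apnea": 3,
    "hypopnea": 4,
    "otherrespevent": 5,
    "other": 5,
    "rera": 5,
    "partial obstructive": 5,
    "partialobstructive": 5,
}


@dataclass(frozen=True)
class AnnotationRow:
    epoch: int
    time_s: float
    duration_s: float
    code: int


@dataclass
class NightRecord:
    """Full-night two-channel 10 Hz respiration with per-sample labels."""

    signal: np.ndarray          # (L, 2) chest, abd
    labels: np.ndarray          # (L,) integer codes 0-5
    fs: float = 10.0
    severity: int | None = None
    night_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.signal.ndim != 2 or self.signal.shape[1] != 2:
            raise ValueError("signal must be (L, 2)")
        if self.signal.shape[0] != self.labels.shape[0]:
            raise ValueError("signal and labels lengths differ")

    @property
    def binary_labels(self) -> np.ndarray:
        return binarize_labels(self.labels)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]


@dataclass
class WindowSet:
    """Stacked overlapping windows of one night: X (N,T,2), y (N,T,1)."""

    X: np.ndarray
    y: np.ndarray
    starts: np.ndarray
    night_id: str = ""

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]


def parse_event_string(raw: str) -> int | None:
    """Map a raw annotation string to an integer code, or None if unknown."""
    s = re.sub(r"[\s_\-:]+", " ", str(raw)).strip().lower()
    for pref in _PREFIXES:
        if s.startswith(pref):
            s = s[len(pref):].strip()
            break
    s_nospace = s.replace(" ", "")
    if s in _CANONICAL:
        return _CANONICAL[s]
    if s_nospace in _CANONICAL:
        return _CANONICAL[s_nospace]
    return None


def parse_annotations(source) -> list[AnnotationRow]:
    """Parse an (epoch, time, duration, event) table into clean rows.

    ``source`` is a CSV path or a DataFrame.  Numeric fields are coerced;
    rows with missing time, implausible duration or unknown event strings are
    dropped (counts logged).  Midnight-wrapped rows (negative duration that
    becomes a plausible event length after +24 h) are retained uncorrected;
    :func:`resolve_events` applies the 24 h fix.
    """
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source)
    else:
        df = pd.DataFrame(source)
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in ("epoch", "time", "duration", "event"):
        if col not in df.columns:
            raise ValueError(f"annotation table missing required column {col!r}")
    if df.empty:
        return []
    time_s = pd.to_numeric(df["time"], errors="coerce")
    dur_s = pd.to_numeric(df["duration"], errors="coerce")
    epoch = pd.to_numeric(df["epoch"], errors="coerce").fillna(0)

    rows: list[AnnotationRow] = []
    n_bad_num, n_bad_dur, n_unknown = 0, 0, 0
    for t, d, ep, ev in zip(time_s, dur_s, epoch, df["event"]):
        if not np.isfinite(t) or not np.isfinite(d):
            n_bad_num += 1
            continue
        if d <= 0 and not (0.0 < d + SECONDS_PER_DAY < _MAX_PLAUSIBLE_EVENT_S):
            n_bad_dur += 1
            continue
        code = parse_event_string(ev)
        if code is None:
            n_unknown += 1
            continue
        rows.append(AnnotationRow(epoch=int(ep), time_s=float(t),
                                  duration_s=float(d), code=code))
    if n_bad_num or n_bad_dur or n_unknown:
        logger.info("parse_annotations dropped %d non-numeric, %d bad-duration,"
                    " %d unknown-event rows", n_bad_num, n_bad_dur, n_unknown)
    return rows


def _subtract_occupied(start: int, end: int,
                       occupied: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Fragments of [start, end) not covered by any occupied interval."""
    frags = [(start, end)]
    for os_, oe in occupied:
        nxt = []
        for a, b in frags:
            if oe <= a or os_ >= b:
                nxt.append((a, b))
                continue
            if a < os_:
                nxt.append((a, os_))
            if oe < b:
                nxt.append((oe, b))
        frags = nxt
        if not frags:
            break
    return frags


def resolve_events(rows: list[AnnotationRow], fs: float) -> list[EventInterval]:
    """Clean annotation rows into sorted, disjoint sample intervals.

    Applies, in order: midnight-wrap correction (+24 h on negative
    durations), priority overlap resolution (apnea codes beat hypopnea,
    ties by longer duration), and merging of same-code neighbours with a
    gap <= 3 s.  Idempotent: feeding the output back reproduces it.
    """
    fixed: list[AnnotationRow] = []
    for r in rows:
        d = r.duration_s
        if d <= 0:
            d += SECONDS_PER_DAY
            if not 0 < d < _MAX_PLAUSIBLE_EVENT_S:
                continue
            logger.info("midnight wrap corrected for event at t=%.1f s", r.time_s)
        if r.code == 0:
            continue  # Normal rows carry no interval
        fixed.append(AnnotationRow(r.epoch, r.time_s, d, r.code))

    intervals = []
    for r in fixed:
        start = math.floor(r.time_s * fs)
        end = math.ceil((r.time_s + r.duration_s) * fs)
        if end > start:
            intervals.append(EventInterval(start, end, r.code))

    # priority: apnea subtypes first, then longer, then earlier
    def priority(e: EventInterval):
        return (0 if e.code in APNEA_CODES else 1, -e.length, e.start)

    occupied: list[tuple[int, int]] = []
    resolved: list[EventInterval] = []
    for e in sorted(intervals, key=priority):
        for a, b in _subtract_occupied(e.start, e.end, occupied):
            resolved.append(EventInterval(a, b, e.code))
            occupied.append((a, b))
    resolved.sort(key=lambda e: e.start)

    # merge same-code neighbours with gap <= 3 s
    max_gap = MERGE_GAP_S * fs
    merged: list[EventInterval] = []
    for e in resolved:
        if (merged and e.code == merged[-1].code
                and (e.start - merged[-1].end) <= max_gap):
            merged[-1] = EventInterval(merged[-1].start, e.end, e.code)
        else:
            merged.append(e)
    return merged


def rasterize_labels(events: list[EventInterval], L: int,
                     fs: float | None = None) -> np.ndarray:
    """Per-sample integer codes from cleaned events; out-of-range parts clipped."""
    labels = np.zeros(L, dtype=np.int64)
    for e in events:
        a, b = max(e.start, 0), min(e.end, L)
        if b <= a:
            logger.info("event [%d, %d) entirely outside [0, %d); skipped",
                        e.start, e.end, L)
            continue
        if e.end > L or e.start < 0:
            logger.info("event [%d, %d) clipped to [0, %d)", e.start, e.end, L)
        labels[a:b] = e.code
    return labels


def extract_intervals(labels: np.ndarray) -> list[EventInterval]:
    """Inverse of rasterization: maximal constant nonzero runs as intervals."""
    labels = np.asarray(labels)
    change = np.flatnonzero(np.diff(labels) != 0) + 1
    bounds = np.concatenate(([0], change, [labels.size]))
    return [EventInterval(int(a), int(b), int(labels[a]))
            for a, b in zip(bounds[:-1], bounds[1:]) if labels[a] != 0]


def binarize_labels(labels: np.ndarray) -> np.ndarray:
    """Codes {1,2,3,4} -> 1 (apnea/hypopnea); {0,5} -> 0."""
    labels = np.asarray(labels)
    if labels.size and (labels.min() < 0 or labels.max() > 5):
        raise ValueError("label codes must lie in 0..5")
    return np.isin(labels, POSITIVE_CODES).astype(np.uint8)


def robust_normalize(x: np.ndarray, tol_factor: float = 1e-6) -> np.ndarray:
    """Night-wise robust per-channel normalization.

    NaN/Inf are zeroed, the channel is centred by its median, clipped to
    +/- 4 IQR and scaled by the IQR; when the IQR is degenerate the standard
    deviation is used instead, and when both are degenerate the output is
    all zeros.
    """
    x = np.nan_to_num(np.asarray(x, dtype=float), nan=0.0,
                      posinf=0.0, neginf=0.0)
    med = np.median(x)
    centred = x - med
    mad_scale = float(np.mean(np.abs(centred)))
    tol = tol_factor * mad_scale if mad_scale > 0 else 1e-12
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    scale = iqr if iqr >= tol else float(np.std(x))
    if scale < tol:
        logger.info("degenerate channel (IQR and SD ~ 0): normalized to zeros")
        return np.zeros_like(x)
    return np.clip(centred, -4.0 * scale, 4.0 * scale) / scale


def build_night_record(chest: np.ndarray, abd: np.ndarray,
                       labels: np.ndarray, fs: float = 10.0,
                       night_id: str = "", normalize: bool = True) -> NightRecord:
    """Assemble a NightRecord, tail-trimming to the common length."""
    L = min(len(chest), len(abd), len(labels))
    if L == 0:
        raise ValueError("empty inputs")
    chest, abd, labels = chest[:L], abd[:L], np.asarray(labels[:L])
    if normalize:
        chest = robust_normalize(chest)
        abd = robust_normalize(abd)
    sig = np.stack([chest, abd], axis=1)
    return NightRecord(signal=sig, labels=labels, fs=fs, night_id=night_id)


def window_night(night: NightRecord, T: int = 2048, S: int = 300,
                 binary: bool = True) -> WindowSet:
    """Slice a night into overlapping windows: N = floor((L-T)/S) + 1.

    Window k covers samples [kS, kS+T); labels are sliced identically.
    """
    L = night.n_samples
    if L < T:
        raise ValueError(
            f"night length {L} < window {T}; pad the night or shorten T")
    N = (L - T) // S + 1
    starts = np.arange(N, dtype=np.int64) * S
    X = np.stack([night.signal[s:s + T] for s in starts]).astype(np.float32)
    lab = night.binary_labels if binary else night.labels
    y = np.stack([lab[s:s + T] for s in starts]).astype(np.float32)[..., None]
    return WindowSet(X=X, y=y, starts=starts, night_id=night.night_id)


# re-export the shared decimator under this module's surface
__all__ = [
    "AnnotationRow", "NightRecord", "WindowSet",
    "parse_annotations", "parse_event_string", "resolve_events",
    "rasterize_labels", "extract_intervals", "binarize_labels",
    "robust_normalize", "build_night_record", "window_night",
    "decimate_signal",
]
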