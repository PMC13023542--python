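"""Full-night probability fusion, event extraction, matching and clinical metrics.

Converts dense per-sample probabilities into clinically interpretable event
detections and recording-level summaries:

1. overlapping window predictions are fused by unbiased (coverage-weighted)
   averaging;
2. the fused trajectory is thresholded at ``tau``, runs of positives are merged
   across gaps of at most ``g_min_s`` seconds, and candidates shorter than
   ``d_min_s`` seconds are discarded (the AASM minimum event duration of 10 s);
3. predicted events are matched one-to-one to reference events by interval
   IoU > ``iou_theta``, yielding TP/FP/FN and precision/recall/F1;
4. per-recording AHI = events per hour of analyzed record, graded into
   Normal/Mild/Moderate/Severe at the 5/15/30 events/h cutoffs, with Cohen's
   kappa for chance-corrected severity agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment

from apneaseg.events import EventInterval, intervals_sorted_disjoint

SEVERITY_NAMES = ("Normal", "Mild", "Moderate", "Severe")
SEVERITY_CUTOFFS = (5.0, 15.0, 30.0)


@dataclass
class PostprocConfig:
    """Temporal regularization and matching parameters.

    tau         : probability threshold in (0, 1)
    g_min_s     : merge consecutive events separated by <= g_min_s seconds
    d_min_s     : drop events shorter than d_min_s seconds (AASM: 10 s)
    iou_theta   : IoU threshold for one-to-one event matching
    """

    tau: float = 0.5
    g_min_s: float = 6.0
    d_min_s: float = 10.0
    iou_theta: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.tau < 1.0:
            raise ValueError(f"tau must lie in (0,1), got {self.tau}")
        if self.g_min_s <= 0 or self.d_min_s <= 0:
            raise ValueError("g_min_s and d_min_s must be positive")
        if not 0.0 <= self.iou_theta < 1.0:
            raise ValueError(f"iou_theta must lie in [0,1), got {self.iou_theta}")


@dataclass
class FusedNightProbability:
    """Full-night fused probability trajectory with per-sample window coverage."""

    p_hat: np.ndarray
    fs: float
    coverage: np.ndarray


@dataclass
class EvalReport:
    """Event-level and recording-level evaluation summary."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    ahi_mae: float = float("nan")
    ahi_rmse: float = float("nan")
    pearson: float = float("nan")
    spearman: float = float("nan")
    severity_confusion: np.ndarray = field(
        default_factory=lambda: np.zeros((4, 4), dtype=int))
    severity_accuracy: float = float("nan")
    kappa: float = float("nan")

    def as_dict(self) -> dict:
        d = {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "ahi_mae": self.ahi_mae, "ahi_rmse": self.ahi_rmse,
            "pearson": self.pearson, "spearman": self.spearman,
            "severity_confusion": self.severity_confusion.tolist(),
            "severity_accuracy": self.severity_accuracy,
            "kappa": self.kappa,
        }
        return d


def fuse_windows(window_probs: np.ndarray, starts: np.ndarray,
                 L: int, fs: float = 10.0) -> FusedNightProbability:
    """Fuse overlapping window predictions by unbiased per-sample averaging.

    window_probs : (N, T) per-window probability sequences
    starts       : (N,) window start samples
    L            : full-night length in samples

    Every sample in [0, L) must be covered by at least one window.
    """
    window_probs = np.asarray(window_probs, dtype=float)
    if window_probs.ndim == 3:  # accept (N, T, 1)
        window_probs = window_probs[..., 0]
    starts = np.asarray(starts, dtype=int)
    if window_probs.shape[0] != starts.shape[0]:
        raise ValueError("window_probs and starts disagree on window count")
    T = window_probs.shape[1]
    acc = np.zeros(L, dtype=float)
    cov = np.zeros(L, dtype=np.int64)
    for p, s in zip(window_probs, starts):
        if s < 0 or s + T > L:
            raise ValueError(f"window [{s}, {s + T}) outside night [0, {L})")
        acc[s:s + T] += p
        cov[s:s + T] += 1
    if np.any(cov == 0):
        gaps = np.flatnonzero(cov == 0)
        raise ValueError(
            f"{gaps.size} uncovered samples (first gap at {gaps[0]})")
    return FusedNightProbability(p_hat=acc / cov, fs=fs, coverage=cov)


def _runs_of_ones(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, end) pairs."""
    padded = np.concatenate(([0], mask.astype(np.int8), [0]))
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def probability_to_events(p: FusedNightProbability | np.ndarray,
                          cfg: PostprocConfig,
                          fs: float | None = None) -> list[EventInterval]:
    """Threshold, gap-merge and duration-filter a fused probability sequence."""
    if isinstance(p, FusedNightProbability):
        prob, fs = p.p_hat, p.fs
    else:
        prob = np.asarray(p, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    runs = _runs_of_ones(prob >= cfg.tau)
    if not runs:
        return []
    g_min = cfg.g_min_s * fs
    merged: list[list[int]] = [list(runs[0])]
    for a, b in runs[1:]:
        if a - merged[-1][1] <= g_min:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    d_min = cfg.d_min_s * fs
    return [EventInterval(a, b) for a, b in merged if (b - a) >= d_min]


def interval_iou(a: EventInterval, b: EventInterval) -> float:
    """Intersection-over-union of two half-open intervals (0 when disjoint)."""
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    union = max(a.end, b.end) - min(a.start, b.start)
    return inter / union


def match_events(pred: list[EventInterval], truth: list[EventInterval],
                 iou_theta: float = 0.1) -> tuple[int, int, int, list[tuple[int, int]]]:
    """One-to-one matching of predicted to reference events.

    Among pairs with IoU > iou_theta, the maximum-cardinality one-to-one
    matching is found (ties in cardinality broken toward larger total IoU)
    via the Hungarian assignment with a cardinality-dominant weight; each
    event participates in at most one pair, preventing double counting.
    A purely greedy descending-IoU pairing can strand a matchable neighbour
    when one prediction straddles two truths, so the optimal assignment is
    used instead.

    Returns (tp, fp, fn, matched index pairs sorted by predicted start).
    """
    if not intervals_sorted_disjoint(sorted(pred, key=lambda e: e.start)):
        raise ValueError("predicted events overlap")
    if not intervals_sorted_disjoint(sorted(truth, key=lambda e: e.start)):
        raise ValueError("truth events overlap")
    if not pred or not truth:
        return 0, len(pred), len(truth), []
    iou = np.zeros((len(pred), len(truth)))
    for i, pe in enumerate(pred):
        for j, te in enumerate(truth):
            iou[i, j] = interval_iou(pe, te)
    edges = iou > iou_theta
    # cardinality dominates total IoU: C exceeds any achievable IoU sum
    C = float(edges.size + 1)
    weights = np.where(edges, C + iou, 0.0)
    rows, cols = linear_sum_assignment(weights, maximize=True)
    pairs = sorted((int(i), int(j)) for i, j in zip(rows, cols)
                   if edges[i, j])
    tp = len(pairs)
    return tp, len(pred) - tp, len(truth) - tp, pairs


def precision_recall_f1(tp: int, fp: int, fn: int) -> dict[str, float]:
    """Event counts to precision/recall/F1; 0/0 ratios resolve to 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return {"precision": precision, "recall": recall, "f1": f1}


def estimate_ahi(n_events: int, L: int, fs: float) -> float:
    """Events per hour of analyzed record: n_events / (L / (3600 fs))."""
    if L <= 0:
        raise ValueError("record length must be positive")
    return n_events / (L / (3600.0 * fs))


def ahi_errors(pred_ahis, true_ahis) -> dict[str, float]:
    """MAE, RMSE and Pearson/Spearman correlation of predicted vs true AHI."""
    pred = np.asarray(pred_ahis, dtype=float)
    true = np.asarray(true_ahis, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("pred and true AHI lists differ in length")
    err = pred - true
    out = {
        "mae": float(np.mean(np.abs(err))),
        "rmse": float(np.sqrt(np.mean(err ** 2))),
    }
    if pred.size >= 2 and np.std(pred) > 0 and np.std(true) > 0:
        out["pearson"] = float(stats.pearsonr(pred, true).statistic)
        out["spearman"] = float(stats.spearmanr(pred, true).statistic)
    else:
        out["pearson"] = float("nan")
        out["spearman"] = float("nan")
    return out


def grade_severity(ahi: float) -> int:
    """AASM severity class: <5 Normal, [5,15) Mild, [15,30) Moderate, >=30 Severe."""
    if ahi < 0:
        raise ValueError("AHI cannot be negative")
    for k, cut in enumerate(SEVERITY_CUTOFFS):
        if ahi < cut:
            return k
    return 3


def severity_confusion(pred_ahis, true_ahis) -> np.ndarray:
    """4x4 confusion matrix, rows = true severity, cols = predicted severity."""
    conf = np.zeros((4, 4), dtype=int)
    for p, t in zip(pred_ahis, true_ahis):
        conf[grade_severity(t), grade_severity(p)] += 1
    return conf


def cohens_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement kappa = (po - pe) / (1 - pe) from a confusion table."""
    conf = np.asarray(confusion, dtype=float)
    total = conf.sum()
    if total <= 0 or np.any(conf < 0):
        raise ValueError("confusion table must be non-negative with positive total")
    po = np.trace(conf) / total
    pe = float(np.sum(conf.sum(axis=1) * conf.sum(axis=0)) / total ** 2)
    if pe >= 1.0:
        # degenerate single-cell table: perfect agreement by construction
        if po >= 1.0:
            return 1.0
        raise ValueError("expected agreement pe = 1 with imperfect po")
    return float((po - pe) / (1.0 - pe))


def evaluate_night(window_probs: np.ndarray, starts: np.ndarray,
                   truth_events: list[EventInterval], L: int, fs: float,
                   cfg: PostprocConfig) -> dict:
    """Fuse -> events -> match -> per-night counts and predicted/true AHI."""
    fused = fuse_windows(window_probs, starts, L, fs)
    pred_events = probability_to_events(fused, cfg)
    tp, fp, fn, pairs = match_events(pred_events, truth_events, cfg.iou_theta)
    return {
        "tp": tp, "fp": fp, "fn": fn,
        "pred_events": pred_events,
        "matched_pairs": pairs,
        "ahi_pred": estimate_ahi(len(pred_events), L, fs),
        "ahi_true": estimate_ahi(len(truth_events), L, fs),
        "fused": fused,
    }


def aggregate_reports(night_records: list[dict]) -> EvalReport:
    """Pool TP/FP/FN across nights and attach recording-level AHI metrics.

    Pooled counts (not the mean of per-night F1s) define precision/recall/F1.
    """
    tp = sum(r["tp"] for r in night_records)
    fp = sum(r["fp"] for r in night_records)
    fn = sum(r["fn"] for r in night_records)
    prf = precision_recall_f1(tp, fp, fn)
    pred_ahis = [r["ahi_pred"] for r in night_records]
    true_ahis = [r["ahi_true"] for r in night_records]
    errs = ahi_errors(pred_ahis, true_ahis)
    conf = severity_confusion(pred_ahis, true_ahis)
    acc = float(np.trace(conf) / conf.sum()) if conf.sum() else float("nan")
    try:
        kappa = cohens_kappa(conf)
    except ValueError:
        kappa = float("nan")
    return EvalReport(
        tp=tp, fp=fp, fn=fn,
        precision=prf["precision"], recall=prf["recall"], f1=prf["f1"],
        ahi_mae=errs["mae"], ahi_rmse=errs["rmse"],
        pearson=errs["pearson"], spearman=errs["spearman"],
        severity_confusion=conf, severity_accuracy=acc, kappa=kappa,
    )
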