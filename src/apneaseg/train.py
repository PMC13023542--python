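"""Losses, pre-training, transfer fine-tuning and cross-validation.

Training minimizes ``alpha * Dice + (1 - alpha) * weighted BCE`` (alpha=0.8,
w_pos=2, w_neg=1) with Adam (lr 1e-4 pre-training, 5e-5 fine-tuning),
gradient-norm clipping at 1.0 and batch size 96.  Model selection is by
event-level F1 on held-out nights, computed after every epoch by running the
full sliding-window fusion + post-processing pipeline; early stopping uses
patience 3 with best weights restored, and the learning rate halves on
validation-loss plateaus (patience 2, floor 1e-6).

Transfer fine-tuning initializes from a teacher checkpoint whose serialized
configuration must match exactly, freezes the first ``floor(rho * L)`` layers
of the definition-ordered layer list (encoder -> bottleneck -> decoder ->
head; rho = 0.6 by default) and freezes every normalization layer's
parameters and running statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.preprocessing import StandardScaler

from apneaseg.events import EventInterval
from apneaseg.nn import Adam, BatchNorm1d, EarlyStopping, ReduceLROnPlateau, Tensor
from apneaseg.postproc import PostprocConfig, aggregate_reports, evaluate_night
from apneaseg.psg_prep import NightRecord, WindowSet, build_night_record, window_night
from apneaseg.segnet import ModelConfig, SegNet, build_model, load_checkpoint, save_checkpoint
from apneaseg.sim import SyntheticNight, stream_rng

logger = logging.getLogger(__name__)


@dataclass
class LossConfig:
    """Dice/weighted-BCE mixture: L = alpha*Dice + (1-alpha)*wBCE."""

    alpha_mix: float = 0.8
    w_pos: float = 2.0
    w_neg: float = 1.0
    epsilon: float = 1e-6
    bce_delta: float = 1e-7

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_mix <= 1.0:
            raise ValueError("alpha_mix must lie in [0,1]")
        if self.w_pos <= 0 or self.w_neg <= 0:
            raise ValueError("class weights must be positive")


@dataclass
class TrainConfig:
    lr: float = 1e-4
    clipnorm: float = 1.0
    batch_size: int = 96
    max_epochs: int = 80
    freeze_ratio: float = 0.0
    bn_freeze: bool = False
    early_stop_patience: int = 3
    plateau_factor: float = 0.5
    plateau_patience: int = 2
    min_lr: float = 1e-6
    selection: str = "event_f1"       # or "val_loss"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.freeze_ratio < 1.0:
            raise ValueError("freeze_ratio must lie in [0,1) -- freezing "
                             "everything leaves nothing to train")
        if self.selection not in ("event_f1", "val_loss"):
            raise ValueError("selection must be 'event_f1' or 'val_loss'")

    @classmethod
    def pretrain_defaults(cls, **kw) -> "TrainConfig":
        return cls(**{**dict(lr=1e-4, max_epochs=80), **kw})

    @classmethod
    def finetune_defaults(cls, **kw) -> "TrainConfig":
        return cls(**{**dict(lr=5e-5, max_epochs=50, freeze_ratio=0.6,
                             bn_freeze=True), **kw})

    # Desk-scale profile for the tiny model on small synthetic cohorts:
    # tens (not tens of thousands) of windows mean few optimizer steps per
    # epoch, so the batch shrinks and the learning rate rises to keep the
    # number and size of updates adequate within a <=10-epoch budget.
    @classmethod
    def tiny_pretrain(cls, **kw) -> "TrainConfig":
        return cls(**{**dict(lr=1e-3, batch_size=16, max_epochs=10), **kw})

    @classmethod
    def tiny_finetune(cls, **kw) -> "TrainConfig":
        return cls(**{**dict(lr=2e-4, batch_size=16, max_epochs=6,
                             freeze_ratio=0.6, bn_freeze=True), **kw})


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _pair(y, y_hat) -> tuple[Tensor, Tensor]:
    y_t = y if isinstance(y, Tensor) else Tensor(np.asarray(y, dtype=float))
    p_t = y_hat if isinstance(y_hat, Tensor) else Tensor(np.asarray(y_hat, dtype=float))
    if y_t.shape != p_t.shape:
        raise ValueError(f"shape mismatch: y {y_t.shape} vs y_hat {p_t.shape}")
    return y_t, p_t


def dice_loss(y, y_hat, epsilon: float = 1e-6) -> Tensor:
    """1 - (2 sum(y*yhat) + eps) / (sum(y) + sum(yhat) + eps)."""
    y_t, p_t = _pair(y, y_hat)
    num = (y_t * p_t).sum() * 2.0 + epsilon
    den = y_t.sum() + p_t.sum() + epsilon
    return 1.0 - num / den


def weighted_bce(y, y_hat, w_pos: float = 2.0, w_neg: float = 1.0,
                 delta: float = 1e-7) -> Tensor:
    """-mean[ w_pos y log(yhat) + w_neg (1-y) log(1-yhat) ]."""
    y_t, p_t = _pair(y, y_hat)
    p_c = p_t.clip(delta, 1.0 - delta)
    term = y_t * p_c.log() * w_pos + (1.0 - y_t) * (1.0 - p_c).log() * w_neg
    return -term.mean()


def combined_loss(y, y_hat, cfg: LossConfig) -> Tensor:
    a = cfg.alpha_mix
    out = None
    if a > 0:
        out = dice_loss(y, y_hat, cfg.epsilon) * a
    if a < 1:
        bce = weighted_bce(y, y_hat, cfg.w_pos, cfg.w_neg, cfg.bce_delta) * (1.0 - a)
        out = bce if out is None else out + bce
    return out


# ---------------------------------------------------------------------------
# freezing
# ---------------------------------------------------------------------------

def freeze_layers(model: SegNet, rho: float, bn_freeze: bool = True) -> SegNet:
    """Freeze the first floor(rho*L) definition-order layers; optionally
    freeze every normalization layer's parameters and running statistics."""
    if rho >= 1.0:
        raise ValueError("rho >= 1 would freeze the whole network")
    layers = model.layer_list()
    n_frozen = math.floor(rho * len(layers))
    for layer in layers[:n_frozen]:
        layer.set_trainable(False)
    if bn_freeze:
        for m in model.modules():
            if isinstance(m, BatchNorm1d):
                m.set_trainable(False)
                m.stats_frozen = True
    logger.info("froze %d/%d layers (rho=%.2f), bn_freeze=%s",
                n_frozen, len(layers), rho, bn_freeze)
    return model


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class NightData:
    """One night ready for training/evaluation.

    ``tail_X``/``tail_start`` hold one extra window anchored at ``L - T``
    when the regular 300-stride grid does not reach the end of the night,
    so that full-night fusion covers every sample.
    """

    windows: WindowSet
    truth_events: list[EventInterval]
    L: int
    fs: float
    night_id: str = ""
    severity: int | None = None
    tail_X: np.ndarray | None = None
    tail_start: int | None = None

    def inference_windows(self) -> tuple[np.ndarray, np.ndarray]:
        """Window stack and starts guaranteeing full-night coverage."""
        if self.tail_X is None:
            return self.windows.X, self.windows.starts
        X = np.concatenate([self.windows.X, self.tail_X[None]], axis=0)
        starts = np.concatenate([self.windows.starts, [self.tail_start]])
        return X, starts


def prepare_night(night: SyntheticNight | NightRecord,
                  cfg: ModelConfig, stride: int = 300,
                  truth_events: list[EventInterval] | None = None) -> NightData:
    """Normalize, window and package a night for the training loop."""
    if isinstance(night, SyntheticNight):
        rec = build_night_record(night.chest, night.abd, night.labels,
                                 fs=night.fs, night_id=night.night_id)
        truth = night.events
    else:
        rec = night
        truth = truth_events or []
    ws = window_night(rec, T=cfg.input_len, S=stride)
    tail_X, tail_start = None, None
    last_end = int(ws.starts[-1]) + cfg.input_len
    if last_end < rec.n_samples:
        tail_start = rec.n_samples - cfg.input_len
        tail_X = rec.signal[tail_start:].astype(np.float32)
    return NightData(windows=ws, truth_events=truth, L=rec.n_samples,
                     fs=rec.fs, night_id=rec.night_id,
                     tail_X=tail_X, tail_start=tail_start)


def _stack_windows(nights: list[NightData]) -> tuple[np.ndarray, np.ndarray]:
    X = np.concatenate([n.windows.X for n in nights], axis=0)
    y = np.concatenate([n.windows.y for n in nights], axis=0)
    return X, y


# ---------------------------------------------------------------------------
# event-level validation callback
# ---------------------------------------------------------------------------

def event_f1_callback(model: SegNet, val_nights: list[NightData],
                      postproc_cfg: PostprocConfig) -> float:
    """Pooled event F1 over validation nights via full-night fusion.

    TP/FP/FN are summed over nights before forming F1 (not a mean of
    per-night F1 values).
    """
    if not val_nights:
        raise ValueError("no validation nights")
    records = []
    for nd in val_nights:
        X, starts = nd.inference_windows()
        probs = model.predict(X)[..., 0]
        records.append(evaluate_night(probs, starts, nd.truth_events,
                                      nd.L, nd.fs, postproc_cfg))
    return aggregate_reports(records).f1


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class TrainingLog:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_metric: float = float("nan")

    def append(self, **kw) -> None:
        self.epochs.append(kw)


def fit(model: SegNet, train_nights: list[NightData],
        val_nights: list[NightData], loss_cfg: LossConfig,
        train_cfg: TrainConfig, postproc_cfg: PostprocConfig | None = None,
        ckpt_path=None) -> TrainingLog:
    """Mini-batch training with event-F1 (or val-loss) model selection.

    Restores the best epoch's weights in place and optionally saves a
    checkpoint carrying the model configuration and the best metric.
    """
    if not train_nights:
        raise ValueError("empty training set")
    train_ids = {n.night_id for n in train_nights}
    if train_ids & {n.night_id for n in val_nights}:
        raise ValueError("train and validation nights must be disjoint")
    postproc_cfg = postproc_cfg or PostprocConfig()
    X, y = _stack_windows(train_nights)
    Xv, yv = (_stack_windows(val_nights) if val_nights else (None, None))
    rng = stream_rng(train_cfg.seed, "batches")
    params = model.trainable_parameters()
    if not params:
        raise ValueError("no trainable parameters (over-frozen model)")
    opt = Adam(params, lr=train_cfg.lr, clipnorm=train_cfg.clipnorm)
    plateau = ReduceLROnPlateau(opt, train_cfg.plateau_factor,
                                train_cfg.plateau_patience, train_cfg.min_lr)
    mode = "max" if train_cfg.selection == "event_f1" else "min"
    stopper = EarlyStopping(train_cfg.early_stop_patience, mode=mode)
    log = TrainingLog()
    best_state = model.state_dict()

    n = len(X)
    for epoch in range(train_cfg.max_epochs):
        model.train()
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, train_cfg.batch_size):
            idx = order[i:i + train_cfg.batch_size]
            opt.zero_grad()
            model.zero_grad()
            y_hat = model.forward(X[idx])
            loss = combined_loss(y[idx], y_hat, loss_cfg)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        train_loss = float(np.mean(losses))

        val_loss = float("nan")
        val_f1 = float("nan")
        if val_nights:
            model.eval()
            vlosses = []
            for i in range(0, len(Xv), train_cfg.batch_size):
                y_hat = model.forward(Xv[i:i + train_cfg.batch_size])
                vlosses.append(float(
                    combined_loss(yv[i:i + train_cfg.batch_size],
                                  y_hat, loss_cfg).data))
            val_loss = float(np.mean(vlosses))
            val_f1 = event_f1_callback(model, val_nights, postproc_cfg)
            plateau.step(val_loss)
        log.append(epoch=epoch, train_loss=train_loss, val_loss=val_loss,
                   val_event_f1=val_f1, lr=opt.lr)
        logger.info("epoch %d: train %.4f, val %.4f, val event-F1 %.4f",
                    epoch, train_loss, val_loss, val_f1)

        metric = val_f1 if train_cfg.selection == "event_f1" else val_loss
        if val_nights and not math.isnan(metric):
            improved_epoch = epoch
            stop = stopper.update(metric, epoch)
            if stopper.best_epoch == improved_epoch:
                best_state = model.state_dict()
            if stop:
                logger.info("early stop at epoch %d (best %d)",
                            epoch, stopper.best_epoch)
                break
        else:
            best_state = model.state_dict()
            stopper.best_epoch = epoch
            stopper.best = metric

    model.load_state_dict(best_state)
    log.best_epoch = stopper.best_epoch
    log.best_metric = stopper.best
    if ckpt_path is not None:
        save_checkpoint(model, ckpt_path,
                        extra={"selection": train_cfg.selection,
                               "best_metric": float(stopper.best),
                               "best_epoch": int(stopper.best_epoch)})
    return log


def pretrain(model: SegNet, train_nights: list[NightData],
             val_nights: list[NightData],
             loss_cfg: LossConfig | None = None,
             train_cfg: TrainConfig | None = None,
             postproc_cfg: PostprocConfig | None = None,
             ckpt_path=None) -> TrainingLog:
    """Source-domain pre-training with event-F1 checkpoint selection."""
    return fit(model, train_nights, val_nights, loss_cfg or LossConfig(),
               train_cfg or TrainConfig.pretrain_defaults(),
               postproc_cfg, ckpt_path)


def finetune(teacher, radar_train: list[NightData],
             radar_val: list[NightData],
             loss_cfg: LossConfig | None = None,
             train_cfg: TrainConfig | None = None,
             postproc_cfg: PostprocConfig | None = None,
             expect_cfg: ModelConfig | None = None,
             ckpt_path=None) -> tuple[SegNet, TrainingLog]:
    """Target-domain fine-tuning from a teacher checkpoint.

    ``teacher`` is a checkpoint path or a SegNet; the stored configuration
    must match ``expect_cfg`` exactly when given (no silent mismatches).
    Applies rho-layer freezing and BN freezing per ``train_cfg`` before
    optimizing at the fine-tuning learning rate.
    """
    if isinstance(teacher, SegNet):
        student = build_model(teacher.cfg, seed=teacher.seed)
        student.load_state_dict(teacher.state_dict())
        if expect_cfg is not None and teacher.cfg.to_json() != expect_cfg.to_json():
            raise ValueError("teacher configuration mismatch")
    else:
        student, _ = load_checkpoint(teacher, expect_cfg=expect_cfg)
    train_cfg = train_cfg or TrainConfig.finetune_defaults()
    if train_cfg.freeze_ratio > 0 or train_cfg.bn_freeze:
        freeze_layers(student, train_cfg.freeze_ratio, train_cfg.bn_freeze)
    log = fit(student, radar_train, radar_val, loss_cfg or LossConfig(),
              train_cfg, postproc_cfg, ckpt_path)
    return student, log


# ---------------------------------------------------------------------------
# cross-validation folds
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    K: int
    assignments: dict[str, int]
    severities: dict[str, int]

    def fold_nights(self, k: int) -> list[str]:
        return sorted(n for n, f in self.assignments.items() if f == k)


def stratified_folds(severities: dict[str, int], K: int = 3,
                     seed: int = 0) -> FoldPlan:
    """Severity-stratified K-fold partition of nights.

    Within each severity class the (sorted) nights are shuffled with the
    seeded generator and dealt round-robin, rotating the starting fold per
    class so totals stay balanced; per-class fold counts differ by at most
    one.  Deterministic given the seed.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > len(severities):
        raise ValueError(f"K={K} exceeds the {len(severities)} nights")
    rng = stream_rng(seed, "folds")
    assignments: dict[str, int] = {}
    start = 0
    for sev in sorted(set(severities.values())):
        members = sorted(n for n, s in severities.items() if s == sev)
        rng.shuffle(members)
        for i, nid in enumerate(members):
            assignments[nid] = (start + i) % K
        start = (start + len(members)) % K
    return FoldPlan(K=K, assignments=assignments, severities=dict(severities))


# ---------------------------------------------------------------------------
# domain-gap diagnostics
# ---------------------------------------------------------------------------

@dataclass
class DomainGapReport:
    probe_auc: float
    mmd2: float
    coral: float
    knn_mixing: float

    def as_dict(self) -> dict[str, float]:
        return {"probe_auc": self.probe_auc, "mmd2": self.mmd2,
                "coral": self.coral, "knn_mixing": self.knn_mixing}


def _rbf_mmd2(a: np.ndarray, b: np.ndarray) -> float:
    """MMD^2 (biased V-statistic) with an RBF kernel at the
    median-heuristic bandwidth; exactly zero for identical samples."""
    both = np.vstack([a, b])
    d2 = np.sum((both[:, None, :] - both[None, :, :]) ** 2, axis=-1)
    med = np.median(d2[np.triu_indices_from(d2, k=1)])
    gamma = 1.0 / (2.0 * med) if med > 0 else 1.0
    K = np.exp(-gamma * d2)
    n = len(a)
    Kxx = K[:n, :n]
    Kyy = K[n:, n:]
    Kxy = K[:n, n:]
    return float(Kxx.mean() + Kyy.mean() - 2.0 * Kxy.mean())


def domain_gap_report(features_a: np.ndarray, features_b: np.ndarray,
                      k: int = 10, seed: int = 0) -> DomainGapReport:
    """Feature-space discrepancy between two domains.

    probe_auc  : 5-fold CV AUC of a linear domain classifier on
                 standardized features (0.5 = maximal confusion)
    mmd2       : unbiased RBF-kernel MMD^2, median-heuristic bandwidth
    coral      : ||cov_a - cov_b||_F^2 / (4 d^2)
    knn_mixing : mean fraction of opposite-domain points among the k
                 nearest neighbours of each point
    """
    a = np.asarray(features_a, dtype=float)
    b = np.asarray(features_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("feature matrices must be 2D with equal dimension")
    if min(len(a), len(b)) <= k:
        raise ValueError(f"need more than k={k} samples per domain")
    X = np.vstack([a, b])
    ylab = np.concatenate([np.zeros(len(a)), np.ones(len(b))])
    Xs = StandardScaler().fit_transform(X)

    clf = LogisticRegression(max_iter=1000)
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    scores = cross_val_predict(clf, Xs, ylab, cv=cv,
                               method="decision_function")
    probe_auc = float(roc_auc_score(ylab, scores))

    mmd2 = _rbf_mmd2(Xs[ylab == 0], Xs[ylab == 1])

    d = a.shape[1]
    ca = np.cov(a, rowvar=False)
    cb = np.cov(b, rowvar=False)
    coral = float(np.sum((ca - cb) ** 2) / (4.0 * d * d))

    d2 = np.sum((Xs[:, None, :] - Xs[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    nn_idx = np.argsort(d2, axis=1)[:, :k]
    mixing = float(np.mean(ylab[nn_idx] != ylab[:, None]))

    return DomainGapReport(probe_auc=probe_auc, mmd2=mmd2, coral=coral,
                           knn_mixing=mixing)
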