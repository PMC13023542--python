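"""Model/Results front door in the statsmodels idiom.

``ApneaSegmentationModel`` is built from prepared nights (endogenous labels
live inside the windowed tensors); ``fit()`` trains the segmentation network
and returns a ``SegmentationResults`` carrying the fitted network, the
training log, and evaluation / prediction methods with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from apneaseg.postproc import (
    EvalReport, PostprocConfig, aggregate_reports, evaluate_night,
)
from apneaseg.segnet import ModelConfig, SegNet, build_model
from apneaseg.train import (
    LossConfig, NightData, TrainConfig, TrainingLog, finetune, fit,
    prepare_night,
)


class ApneaSegmentationModel:
    """Dense apnea/hypopnea segmentation model over a set of nights.

    Parameters
    ----------
    train_nights, val_nights
        Prepared :class:`~apneaseg.train.NightData` (see
        :func:`~apneaseg.train.prepare_night`); validation nights drive
        event-F1 model selection.
    config, loss_config, train_config, postproc_config
        Architecture, loss mixture, optimization and post-processing
        settings (all default to the reference configuration).
    """

    def __init__(self, train_nights: list[NightData],
                 val_nights: list[NightData] | None = None,
                 config: ModelConfig | None = None,
                 loss_config: LossConfig | None = None,
                 train_config: TrainConfig | None = None,
                 postproc_config: PostprocConfig | None = None,
                 seed: int = 0):
        self.train_nights = list(train_nights)
        self.val_nights = list(val_nights or [])
        self.config = config or ModelConfig()
        self.loss_config = loss_config or LossConfig()
        self.train_config = train_config or TrainConfig.pretrain_defaults()
        self.postproc_config = postproc_config or PostprocConfig()
        self.seed = seed

    @classmethod
    def from_nights(cls, nights, config: ModelConfig | None = None,
                    val_fraction: float = 0.2, stride: int = 300,
                    **kwargs) -> "ApneaSegmentationModel":
        """Build from raw synthetic/recorded nights, holding out the last
        ``val_fraction`` of nights for validation."""
        config = config or ModelConfig()
        prepared = [prepare_night(n, config, stride=stride) for n in nights]
        n_val = max(int(round(val_fraction * len(prepared))), 1) \
            if len(prepared) > 1 else 0
        return cls(prepared[:len(prepared) - n_val],
                   prepared[len(prepared) - n_val:],
                   config=config, **kwargs)

    def fit(self, teacher=None, ckpt_path=None) -> "SegmentationResults":
        """Train (optionally from a teacher checkpoint with freezing)."""
        if teacher is not None:
            net, log = finetune(teacher, self.train_nights, self.val_nights,
                                self.loss_config, self.train_config,
                                self.postproc_config,
                                expect_cfg=self.config, ckpt_path=ckpt_path)
        else:
            net = build_model(self.config, seed=self.seed)
            log = fit(net, self.train_nights, self.val_nights,
                      self.loss_config, self.train_config,
                      self.postproc_config, ckpt_path=ckpt_path)
        return SegmentationResults(self, net, log)


@dataclass
class SegmentationResults:
    """Fitted segmentation network plus its training history."""

    model: ApneaSegmentationModel
    network: SegNet
    log: TrainingLog
    report: EvalReport | None = field(default=None)

    def predict_night(self, night: NightData) -> dict:
        """Fused full-night probabilities, events and AHI for one night."""
        X, starts = night.inference_windows()
        probs = self.network.predict(X)[..., 0]
        return evaluate_night(probs, starts, night.truth_events,
                              night.L, night.fs,
                              self.model.postproc_config)

    def evaluate(self, nights: list[NightData]) -> EvalReport:
        """Event- and recording-level evaluation pooled over nights."""
        records = [self.predict_night(n) for n in nights]
        self.report = aggregate_reports(records)
        return self.report

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "          Apnea-Hypopnea Event Segmentation Results",
            "=" * 64,
            f"Windows (train/val):  {sum(n.windows.n_windows for n in self.model.train_nights)}"
            f" / {sum(n.windows.n_windows for n in self.model.val_nights)}",
            f"Architecture:         U-Net d={cfg.depth} f={cfg.base_filters}"
            f" aspp={cfg.use_aspp} mhsa={cfg.use_transformer}",
            f"Window / stride:      {cfg.input_len} samples / 300 samples @10 Hz",
            f"Best epoch:           {self.log.best_epoch}"
            f"  (val event-F1 {self.log.best_metric:.4f})",
        ]
        if self.report is not None:
            r = self.report
            lines += [
                "-" * 64,
                f"Event level:   P={r.precision:.4f}  R={r.recall:.4f}  "
                f"F1={r.f1:.4f}  (TP={r.tp} FP={r.fp} FN={r.fn})",
                f"AHI:           MAE={r.ahi_mae:.4f}  RMSE={r.ahi_rmse:.4f}  "
                f"r={r.pearson:.4f}  rho={r.spearman:.4f}",
                f"Severity:      acc={r.severity_accuracy:.4f}  "
                f"kappa={r.kappa:.4f}",
            ]
        lines.append("=" * 64)
        return "\n".join(lines)
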