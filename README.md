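# apneaseg

Event-level apnea–hypopnea detection from respiratory waveforms, with a
full cross-modality pipeline: FMCW-radar respiration extraction, dense 1D
segmentation with a U-Net + ASPP + transformer-bottleneck network,
PSG→radar transfer fine-tuning with partial layer freezing, and clinically
grounded event- and recording-level evaluation (AHI, severity, Cohen's κ).

## Who this is for

Sleep-medicine and biomedical-signal researchers who want a tested,
self-contained reference implementation of an event-segmentation pipeline
for sleep-disordered breathing — runnable end to end without any clinical
data, because a seeded synthetic-night generator with known ground truth is
a first-class part of the package.

## The problem and the model

Apnea (near-complete cessation of breathing effort) and hypopnea (partial
reduction) are scored as events of ≥ 10 s; disease burden is summarized by
the apnea–hypopnea index AHI = events per hour, graded
Normal/Mild/Moderate/Severe at 5/15/30 events/h. The pipeline:

1. **Radar front end.** Each torso range bin of a 60 GHz FMCW radar carries
   a complex slow-time signal whose phase encodes chest-wall motion,
   Δφ(t) = 4π·d(t)/λ. Per bin, the static (clutter) component is removed
   (complex mean refined by a least-squares circle-centre fit), the phase is
   unwrapped and scaled by λ/4π to displacement; bins are band-passed to the
   respiration band (0.1–0.6 Hz). The 40-bin displacement matrix X is
   projected onto chest/abdomen targets by ridge regressions
   w = argmin ‖Xw − y‖² + α‖w‖² whose two weight vectors are alternately
   re-solved in each other's orthogonal complement; weights are estimated
   in 120 s windows (30 s stride) and merged by overlap-add averaging, then
   decimated 50 → 10 Hz.
2. **Label preparation.** Tabular annotations (epoch, time, duration,
   event) are parsed with a robust string dictionary, cleaned (midnight
   wrap, overlap priority — apnea subtypes dominate hypopnea, longer wins —
   and ≤ 3 s same-code merge), rasterized to per-sample codes, binarized
   ({1,2,3,4} positive), and the night is robustly normalized
   (median-centred, clipped at ±4·IQR, IQR-scaled) and cut into 2048-sample
   windows with a 300-sample stride at 10 Hz.
3. **Segmentation network.** A 1D residual U-Net (base 32 filters, depth 4,
   stride-2 conv downsampling, dilations (1,2)) with an ASPP-lite module
   (dilations 1/2/4/8) and 3 pre-norm multi-head self-attention blocks
   (4 heads, sinusoidal positions) at the 128-sample bottleneck, a mirrored
   decoder with skip concatenation, a large-kernel (k=31) smoothing
   convolution and a sigmoid head: ŷ = σ(f_θ(X)) ∈ (0,1)^T per window.
4. **Loss and transfer.** L = α·L_Dice + (1−α)·L_wBCE with α = 0.8,
   w_pos = 2, w_neg = 1, optimized by Adam (lr 1e−4 pre-train, 5e−5
   fine-tune, clipnorm 1, batch 96). Fine-tuning initializes from a teacher
   checkpoint (configuration must match exactly), freezes the first
   ⌊ρL⌋ layers (ρ = 0.6) and all BatchNorm layers (parameters and running
   statistics), and selects checkpoints by event-level F1 on held-out
   nights; severity-stratified 3-fold plans are provided for small cohorts.
5. **Post-processing and metrics.** Overlapping window probabilities are
   fused by unbiased averaging, thresholded at τ, gap-merged (≤ 6 s) and
   duration-filtered (≥ 10 s); events are matched one-to-one by interval
   IoU > 0.1 (maximum-cardinality assignment) giving precision/recall/F1;
   per recording AHI = N̂/(L/3600 f_s), severity class, MAE/RMSE,
   Pearson/Spearman, confusion matrix and Cohen's κ. Feature-space
   domain-gap diagnostics (linear probe AUC, RBF-MMD², CORAL, k-NN mixing)
   quantify PSG–radar alignment before vs after fine-tuning.

The network and its training loop are implemented in numpy on a compact
reverse-mode autodiff engine (`apneaseg.nn`) whose gradients are verified
against finite differences in the test suite.

## Worked example

```python
import numpy as np
from apneaseg import sim
from apneaseg.api import ApneaSegmentationModel
from apneaseg.segnet import ModelConfig
from apneaseg.train import TrainConfig

nights = sim.simulate_cohort(10, seed=3, base=sim.SimParams(duration_s=1800.0))
model = ApneaSegmentationModel.from_nights(
    nights, config=ModelConfig.tiny(),
    train_config=TrainConfig.tiny_pretrain(seed=3))
results = model.fit()
results.evaluate(model.val_nights)
print(results.summary())
```

prints

```
          Apnea-Hypopnea Event Segmentation Results
================================================================
Windows (train/val):  472 / 118
Architecture:         U-Net d=3 f=8 aspp=True mhsa=True
Window / stride:      512 samples / 300 samples @10 Hz
Best epoch:           3  (val event-F1 1.0000)
----------------------------------------------------------------
Event level:   P=1.0000  R=1.0000  F1=1.0000  (TP=5 FP=0 FN=0)
AHI:           MAE=0.0000  RMSE=0.0000  r=1.0000  rho=1.0000
Severity:      acc=1.0000  kappa=1.0000
================================================================
```

Ten synthetic half-hour nights are generated with a severity-mixed AHI
distribution; the desk-scale (tiny) network is trained on eight of them and
evaluated on the two held-out nights. All five held-out events are detected
with correct boundaries (TP=5, no false alarms), so the per-night AHI — and
hence the severity grade — is exact; in the low-noise synthetic regime this
is the expected outcome, and the interesting failure modes appear as noise,
drift and domain shift are dialled up (see `docs/methods.md`).

A `apnea-seg` command-line tool exposes the same stages
(`simulate`, `radar-extract`, `prep`, `folds`, `pretrain`, `finetune`,
`evaluate`) for shell-driven workflows.

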