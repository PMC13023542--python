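# Methods

This note documents the modelling assumptions, parameter choices and known
limitations of the package, in the spirit of a model card for the pipeline.

## Task formulation

Apnea/hypopnea detection is cast as dense 1D segmentation: a two-channel
respiration window X ∈ R^{T×2} (thoracic and abdominal motion at 10 Hz) is
mapped to per-sample event probabilities ŷ = σ(f_θ(X)). Dense prediction,
rather than 30 s epoch classification, preserves event boundaries, which is
what AHI and severity grading actually depend on. Events are defined on
0-based half-open sample intervals [a, b); seconds convert to samples as
floor(start·fs) and ceil(end·fs), so partially covered edge samples are
included. This convention is applied uniformly across annotation parsing,
rasterization, post-processing and matching.

## Synthetic nights: what they emulate and what they do not

The generator produces quasi-periodic two-channel respiration: a shared
amplitude envelope and a slowly wandering instantaneous frequency
(0.15–0.4 Hz band), with the abdominal channel an amplitude-scaled
(default ratio 0.8), phase-lagged (0.3 rad) copy plus independent Gaussian
noise and a slow sinusoidal baseline drift. Events are realized as
multiplicative suppression of the envelope — apnea to ≤ 5 % of baseline,
hypopnea to (1 − reduction) with reduction default 0.5 — with raised-cosine
2 s onset/offset ramps. Event plans draw durations uniformly from
[10, 60] s and keep inter-event gaps above 10 s and a 15 s event-free
margin at the night edges, so the 6 s post-processing merge can never fuse
two distinct ground-truth events; the per-night event count is
round(target AHI × hours). Cohorts draw per-night severity from the
48.6/34.3/8.6/8.6 % Normal/Mild/Moderate/Severe mix of a 35-night clinical
radar cohort, with AHI uniform within class bands (0.5–5, 5–15, 15–30,
30–45 events/h).

The radar simulator writes, per range bin b, z_b(t) = g_b · exp(j·(4π/λ)·
(m_b·chest(t) + (1−m_b)·abd(t)) + jθ_b) + c_b + phase noise, with static
complex clutter c_b, random gains, and a belt-unit→meter scale of 0.4 mm
(typical chest-wall excursion well below the λ/4 ≈ 1.25 mm unwrap-ambiguity
bound at 60 GHz; exceeding it triggers a warning, not an error).

What the generator does **not** model: body-movement artifacts, posture
changes, desaturation/arousal physiology that drives some clinical hypopnea
scores, sensor dropout, multipath dynamics, or chirp-level radar effects
(the cube is synthesized directly at the range-bin phase level). Passing
tests on synthetic nights therefore demonstrate the correctness and
learnability of the pipeline, not clinical-grade performance on real
recordings.

All randomness flows from one integer seed through named sub-streams
(waveform, events, codes, radar, cohort, batches, folds), so every
generator is bit-reproducible per seed and components can be regenerated
independently.

## Radar signal processing

Static-offset removal per bin subtracts the complex mean refined by a
least-squares (Kåsa) circle-centre fit. Plain mean subtraction leaves a
J₀(A)-weighted bias of the phase modulation (the temporal mean of
exp(jφ(t)) is not zero), which limits displacement recovery to ~10 µm; the
circle fit is exact in the noiseless limit and the package's round-trip
tests hold at 1e−9 m. Bins with no temporal variation are emitted as zeros
and logged.

The respiration passband is 0.1–0.6 Hz (6–36 breaths/min), applied as a
4th-order Butterworth with forward–backward filtering (zero phase). The
ridge penalty is α = 1.0 on column-standardized displacements;
orthogonalization runs 2 alternating passes, each re-solving one weight
vector in the orthogonal complement of the other, which monotonically
reduces |cos(w_c, w_a)| on the tested instances. Projection weights are
estimated in 120 s windows with a 30 s stride and merged by coverage-count
averaging; a trailing window anchored at the night end guarantees full
coverage. Decimation (200→10 Hz belts, 50→10 Hz radar) uses a zero-phase
FIR low-pass (unit DC gain, cutoff 0.8·Nyquist of the target rate) so that
constants and passband amplitudes are preserved; nights are aligned by
tail-trimming only, preserving the shared t = 0 synchronization point.

During training-data construction the regression targets are the
synchronized reference belts. A reference-free surrogate mode (first two
principal components of X) is provided for deployments without belts but is
not used by the default pipeline and carries no accuracy claim.

## Network

Reference configuration: input 2048×2; encoder depth 4 with residual
dilated Conv1D blocks (kernel 3, dilations (1,2), BatchNorm, Swish,
dropout 0.2 inside the block) and stride-2 convolutional downsampling,
channels 32→64→128→256; bottleneck at 128 samples with an ASPP-lite module
(parallel dilated branches 1/2/4/8 at embed/4 channels each, concatenated
and fused by a 1×1 convolution) and 3 pre-norm transformer blocks (4 heads,
FFN ×4, sinusoidal positional encoding added, not concatenated); decoder
mirrors the encoder with nearest-neighbour upsampling + convolution and
skip concatenation followed by a residual block; a k=31 smoothing
convolution (≈ 3.1 s at 10 Hz) at full resolution precedes the 1×1 sigmoid
head. The embedding dimension is derived as base_filters·2^(depth−1) and
checked for consistency. Ablation switches build the plain CNN U-Net
(no ASPP, no attention, non-residual blocks) from the same configuration.

The implementation is a numpy reverse-mode autodiff engine written for this
package (float32 forward/backward; convolution via per-tap einsum;
normalization as a fused primitive with a hand-derived backward). Every
vector-Jacobian product is checked against finite differences in the test
suite, and a gradient-flow test asserts a nonzero gradient for every
trainable parameter after one step (catching dead branches).

## Training, transfer and selection

Loss: L = 0.8·Dice + 0.2·weighted BCE (w_pos = 2, w_neg = 1, Dice ε = 1e−6,
BCE clipping δ = 1e−7). Class imbalance is handled only through the loss
weights (no resampling). Reference optimization: Adam, lr 1e−4 (pre-train)
or 5e−5 (fine-tune), global gradient-norm clipping at 1.0, batch 96, up to
80/50 epochs, early stopping patience 3 with best weights restored, and
learning-rate halving on validation-loss plateaus (patience 2, floor 1e−6).

Model selection is by event-level F1 on held-out nights: after each epoch,
validation nights are fused (unbiased window averaging), post-processed
(τ = 0.5, 6 s merge, 10 s minimum) and matched (IoU > 0.1), with TP/FP/FN
pooled across nights before forming F1 (not a mean of per-night F1 values).
A `selection="val_loss"` switch selects on validation loss instead; both
quantities are logged every epoch.

Fine-tuning loads a teacher checkpoint that stores weights together with
the serialized model configuration; the identical graph is rebuilt before
weight assignment and any mismatch is a hard error. "Layer" for ρ-freezing
means the flattened definition-order layer list (encoder blocks and
downsamplers, ASPP, transformer blocks, decoder stages, smoothing
convolution, head); the first ⌊ρL⌋ layers are frozen, ρ = 0.6 by default
and ρ = 0 for scratch training. BN freezing makes normalization parameters
non-trainable *and* pins the running statistics during training. Frozen
parameters have `requires_grad=False` at the tensor level, so their
gradient norms are identically zero and their values are bit-identical
across training.

**Desk-scale profile.** The tiny preset (base 8 filters, depth 3, 512-sample
windows) targets CPU-scale experiments on cohorts of tens of nights. At
that scale an epoch contains only tens of optimizer steps, so the profile
uses batch 16 and lr 1e−3 (pre-train) / 2e−4 (fine-tune) within a
≤ 10-epoch budget; the reference batch-96/lr-1e−4 profile is tuned for
cohorts three orders of magnitude larger and underfits badly in ten
desk-scale epochs. The acceptance script and heavy tests use 20 half-hour
nights (12 train / 3 validation / 5 test) for the source domain and 8
quarter-hour nights for the radar chain.

Severity-stratified K-fold plans shuffle each severity class with the
seeded generator and deal members round-robin with a rotating starting
fold; per-class fold counts differ by at most one and the plan is
deterministic per seed.

## Post-processing and evaluation

Fusion averages overlapping window probabilities per sample by coverage
count and refuses uncovered samples. Thresholding at τ = 0.5 (exposed in
config; the operating threshold is a free parameter of the method) is
followed by merging of runs separated by ≤ 6 s and removal of events
shorter than 10 s (the AASM minimum event duration). Matching maximizes
the number of one-to-one pairs with IoU > 0.1 via the Hungarian assignment
with a cardinality-dominant weight; a greedy descending-IoU pairing is not
equivalent (a prediction straddling two references can strand a matchable
neighbour) and the optimal matcher is validated against exhaustive search
on all instances with ≤ 8 events per side. Conventions: 0/0 ratios are 0;
AHI uses the analyzed record length (no sleep-staging correction, which is
out of scope); severity cutoffs are left-closed (5.0 is Mild, 15.0
Moderate, 30.0 Severe); κ uses po = trace/total, pe = Σ rowᵢ·colᵢ/total²,
with the degenerate single-cell table defined as κ = 1 when po = 1.

Domain-gap diagnostics operate on temporal mean-pooled activations of a
named layer (default `smooth_conv`): linear-probe AUC via 5-fold
cross-validated logistic regression on standardized features, MMD² as the
biased V-statistic of an RBF kernel at the median-heuristic bandwidth
(exactly zero for identical samples, positive O(1/n) bias otherwise),
CORAL = ‖C_a − C_b‖²_F/(4d²), and k-NN mixing as the mean opposite-domain
fraction among k = 10 nearest neighbours.

## Numerical and degenerate-input choices

- Robust normalization: NaN/Inf → 0 before statistics; IQR fallback to
  standard deviation when IQR < 1e−6 of the channel's mean absolute
  deviation; all-degenerate channels normalize to zeros (logged).
- Midnight-wrapped annotation rows (negative tabulated duration whose
  value + 24 h is a plausible event length < 1 h) are corrected by +24 h;
  other non-positive durations are dropped at parse time.
- The ≤ 3 s adjacency merge applies to same-code neighbours only;
  cross-code adjacency is governed by the overlap priority rule.
- Nights shorter than one projection window fall back to a single global
  ridge fit (logged); nights shorter than one model window are an error
  with a padding hint.
- Event-envelope ramps shrink to half the event length when events are
  short, so suppression depth is always reached for ≥ 10 s events.

## Known limitations

- Synthetic-only validation: no claim transfers to clinical recordings
  (see the generator's non-goals above).
- The easy synthetic regime is nearly separable, so desk-scale training
  saturates near-perfect event F1; the transfer-vs-scratch comparison is
  therefore qualitative (teacher ≥ scratch at equal budget), not a
  replication of cohort-scale effect sizes.
- Torso-bin selection from the full range axis is taken as given (the cube
  is the input); no bin-quality heuristics are applied.
- Sleep staging (and hence sleep-time-corrected AHI) is out of scope; AHI
  uses total analyzed record length.
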