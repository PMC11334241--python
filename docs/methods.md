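# Methods

This note documents the scientific and numerical choices behind
`siamquality`: what is modelled, which knobs matter, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## 1. Problem setting

A PPG stream is cut into non-overlapping 30 s segments. Each segment
`x_i` carries an artifact fraction `y_i ∈ [0, 1]` (the fraction of its
samples corrupted by localized artifacts) and a collection time `t_i`.
The goal of pretraining is an encoder whose representation of a segment
depends on the underlying physiological state (heart rate, waveform
morphology) and not on its corruption level.

## 2. Synthetic PPG generator

Only the essentials of ICU PPG are emulated; nothing more.

**Clean waveform.** One cardiac cycle is modelled as two Gaussians in
time: a systolic peak (amplitude 1.0, width 0.08 s, 0.15 s after beat
onset) and a diastolic/dicrotic bump (amplitude 0.45, width 0.12 s,
offset 0.42 s). Beats repeat at interval 60/HR s with a log-free
multiplicative jitter (default 2 % standard deviation). This gives an
analytically checkable signal: the dominant non-DC spectral component is
HR/60 Hz, and zero jitter yields exact periodicity.

**Noise families.** Three families, each with a level in [0, 1] scaling
its amplitude linearly relative to the clean signal's peak-to-peak
range:

* *drift* — Gaussian noise band-passed to 0.05–0.5 Hz (baseline
  wander);
* *powerline* — a mains sinusoid (50/60 Hz, random phase);
* *motion* — non-overlapping bursts (0.5–2 s) of low-passed (≤ 10 Hz)
  Gaussian noise at amplitude `(0.5 + 1.5·level) × ptp`, covering
  approximately `motion_window_fraction × level` of the samples.

**Ground truth.** Only motion bursts define the artifact mask and hence
`y`; drift and powerline are global confounders recorded in metadata. An
artifact *fraction* is only meaningful for corruption that is
localizable within a window, and the pairing rule needs exactly that
quantity. Levels are treated as additive; whether the original noise
sweep was additive or multiplicative is unknown, so this is a documented
stand-in.

**Corpus builder.** One continuous recording per synthetic patient at
240 Hz (the ICU monitor rate), with a patient-specific heart rate drawn
from 50–120 bpm. 30 s blocks are independently selected as artifact
blocks (probability 0.4, motion level uniform in 0.3–0.8); block 0 is
forced clean and block 1 forced corrupted so every patient admits at
least one (anchor, within-5-min neighbour) pair.

**What the generator does not emulate** — and therefore what a green
test does not establish: real pulse-morphology variability (arrhythmia,
damping, perfusion changes), sensor-specific artifact shapes, correlated
noise between patients, and clinical label structure. Green training
tests show the *mechanism* works on signals whose only nuisance factors
are the injected ones; they are not evidence about clinical data.

## 3. Preprocessing

Segmentation is a strict partition (trailing remainder dropped).
Downsampling 240 → 40 Hz applies a zero-phase 8th-order Butterworth
low-pass at 0.45 × target rate before decimation; the anti-aliasing
method was not prescribed, so a standard zero-phase filter testable by a
spectral invariant was chosen. Min-max normalization is per-segment
(the pipeline order is segment → downsample → normalize); a constant
segment maps to all zeros rather than raising, because flatline
artifacts occur and downstream code must survive them.

## 4. Quality stand-in

The learned quality models used in production settings are not
reproducible here, so a rule-based stand-in provides the binary
high/low label and the artifact-fraction estimate: over 2 s windows
(0.5 s hop) a sample is flagged if its window (a) is a flatline
(std < 1 % of segment range), (b) has a peak-to-peak excursion above
2 × the *median* window peak-to-peak, or (c) has a dominant frequency
outside 0.5–3.7 Hz (30–222 bpm). Rule (b) is deliberately relative to
the median rather than the segment range: on a clean quasi-periodic
segment every window spans nearly the full range, so a
fraction-of-range threshold cannot separate bursts from beats. The
stand-in only needs to *rank* segments correctly (Spearman > 0.5 against
ground truth on simulated corpora — measured ≈ 0.97); pairing and
training default to simulator ground truth.

## 5. Pairing and curriculum

Anchors are segments with `y ≤ anchor_threshold` (default exactly 0;
configurable because estimated labels are continuous). Candidates are
same-patient segments with `y > 0.2` and `|Δt| < 300 s` (strict, two-
sided); the candidate at the greatest `|Δt|` wins, ties broken by later
timestamp then higher `y` (determinism). A `max_index` selection rule
(latest candidate) is available for the literal one-sided reading. The
difficulty of a pair is `c = |y_bad − y_good|`.

Curriculum ordering has three modes: `strict_sort` (stable ascending
sort on `c`), `staged_buckets` (default: five equal-width bins over
[0, 1] consumed in order, seeded shuffle within each bin — strict
sorting would make the sample order deterministic and hurt stochastic
optimization), and `shuffled_control` (no curriculum, for ablation).
Re-ordering happens each epoch with an epoch-dependent seed; one low-
quality segment may serve many anchors (no cap — none was warranted).

## 6. Model

The encoder is a 1-D translation of a residual CNN: length-7 stem
convolution (stride 2), max pooling, residual blocks, global average
pooling. `tiny_1d` (4 basic blocks, 16→64 channels, feature dim 64) is
the CPU-scale default used by every test; `resnet50/101/152_1d`
(bottleneck blocks, feature dim 2048) are implemented and shape-tested
but not trained at full scale. Projector: three FC layers
(64→64→64→32) with batch norm, ReLU hidden activations and a
batch-normalized output. Predictor: three FC layers (32→16→16→32) —
equal input/output width, bottleneck hidden — without output norm. The
hidden widths were not prescribed anywhere; these defaults follow the
reference siamese design scaled to the tiny encoder.

The loss is `scale × [−cos(p₁, sg(z₂)) − cos(p₂, sg(z₁))]`. `scale`
defaults to 1 (the two-term sum); 0.5 gives the averaged form — both
appear in the literature and differ only by a constant. The
stop-gradient on the projection argument is essential for collapse
avoidance in negative-pair-free siamese training and is exposed as a
config flag (`stop_gradient=False`) so its role can be ablated.

Everything runs on a purpose-built numpy reverse-mode autodiff engine
(`siamquality.nn`) in float64: no deep-learning framework is required,
training is bit-reproducible given a seed, and every layer's gradient is
verified against central finite differences in the test suite.

## 7. Training

**Pretraining.** Batches of pairs are consumed in curriculum order; both
branches share one parameter store. Default optimizer: Adam, learning
rate 0.02, batch size 8, no weight decay, constant rate. The classic
recipe for this architecture (SGD + momentum, lr 0.05 with cosine decay)
is implemented and config-selectable, but at desk scale (10²–10³ pairs,
≤ 5 epochs) it converges too slowly and too variably across seeds to be
a sensible default; Adam reaches a usable alignment in a few hundred
steps. A per-epoch **collapse diagnostic** — the mean per-dimension
standard deviation of length-normalized projections — is recorded;
values near zero indicate collapse (independent random unit vectors in
dimension d give ≈ 1/√d, here ≈ 0.18).

**Fine-tuning.** Three strategies: `fine_tune_all` (encoder + newly
initialized linear head on `h`), `fine_tune_last` (encoder frozen —
verified bit-identical — head only), and `in_domain_pretrain_then_last`
(quality-pair pretraining on the target data, then head only).
Regression targets are standardized internally; classification uses a
linear head with softmax cross-entropy. On the synthetic heart-rate
task, fine-tune-all reaches < 5 beats/min held-out MAE and beats
fine-tune-last under paired seeds, qualitatively reproducing the
strategy ordering observed on real benchmarks.

## 8. Evaluation

The AT-curve uses cumulative subgroups (`quality ≤ u`, default grid
0.0–1.0 in steps of 0.1): only the cumulative reading makes the top bin
the whole test set, and the reported subgroup sizes are likewise
cumulative. Empty subgroups get size 0 and a NaN metric. F1 follows the
standard zero-rule (tp = 0 with fp + fn > 0 → 0). Latent diagnostics are
computed in the native embedding space (cosine similarity within vs
between heart-rate groups, silhouette score); 2-D projection for
visualization is out of scope — the clustering claim is quantitative
and needs no particular reducer. When noise levels are supplied, the
within-group statistic is restricted to clean/noisy pairs and compared
against between-group similarity over the *same* pair composition, so
the two means differ only in whether heart rates match.

## 9. Desk-scale experiments

`experiments.representation_robustness` builds a grid of segments at
heart rates {60, 90, 120} bpm × motion levels {0, 0.3, 0.7}
(`motion_window_fraction = 0.5`, 40 repeats per cell), pretrains for 5
epochs, and measures the clean/noisy similarity gap defined above
against an untrained encoder with the same initialization.
`motion_window_fraction = 1.0` at level 0.7 would corrupt 70 % of every
sample span and physically destroy the heart-rate information the claim
is about — no encoder could align what is no longer in the signal — so
the partial-coverage default (level scales amplitude, coverage stays
≤ 35 %) is used.

`experiments.finetune_strategy_comparison` pretrains on a 20-patient
corpus with patient-specific heart rates, fine-tunes with both
strategies from the same checkpoint and seed, and evaluates on clean
segments from held-out patients.

## 10. Known limitations

* The waveform model is a two-Gaussian caricature; none of the results
  here transfer to clinical data without re-validation.
* The quality stand-in is heuristic and tuned for the simulator's
  artifact families only.
* The curriculum's *benefit* (vs `shuffled_control`) is not asserted at
  desk scale — the comparison is runnable but tiny corpora do not
  reliably show a direction.
* WFDB input is not supported in this build (no `wfdb` dependency);
  recordings are two-column CSV plus a JSON sidecar.
* The deep encoder variants (50/101/152 layers) are implemented but far
  too slow to train meaningfully on one CPU; only `tiny_1d` is exercised
  end to end.
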