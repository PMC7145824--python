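# Methods

This note documents the models and procedures implemented in `ecgdx`,
the choices made where the design was genuinely open, and what the
synthetic experiments do and do not establish.

## Synthetic 12-lead ECG model

Each beat is a sum of five Gaussian bumps. A wave with amplitude *a*
(mV), width *w* (ms) and center *c* (ms relative to the R peak)
contributes *a·W·exp(−(t−c)²/2σ²)* with σ = w/4, so the nominal support
is ±2σ; *W* is a fixed 12-entry projection vector per wave. Defaults:
P (0.15 mV, 80 ms), Q (−0.10 mV), R (1.00 mV), S (−0.25 mV) — the QRS
waves share the QRS support, Q and S in the outer quarters, R in the
middle half — and T (0.30 mV, 160 ms), whose center tracks √RR to mimic
rate-dependent QT shortening. The projection matrix encodes a normal
frontal axis with an rS pattern in V1 and qR in V6; amplitudes are
nominal (no device statistics are published for the recorders this
emulates, so R ≈ 1 mV in lead DII is a convention).

Class flags map to parameters drawn away from diagnostic boundaries so
generated positives are unambiguous under the rule engine:

| flag | parameter draw |
|---|---|
| none | HR ~ U(58, 95) bpm, PR ~ U(130, 180) ms, QRS ~ U(70, 100) ms |
| SB | HR ~ U(38, 48) |
| ST | HR ~ U(105, 150) |
| 1dAVb | PR ~ U(cutoff+20, cutoff+100); generator cutoff 200 ms (consensus definition, configurable), deliberately above the rule engine's 190 ms |
| RBBB / LBBB | QRS ~ U(120, 150) ms plus opposite-polarity V1/V6 projection edits |
| AF | log-normal RR (σ = 0.75, clipped to [0.25, 3.5] s), P waves absent |

Rhythm classes are mutually exclusive; additionally the dataset sampler
never pairs RBBB with LBBB (their projection edits would cancel) nor
1dAVb with AF (PR is undefined without P waves), redistributing
probability so every requested marginal prevalence is preserved exactly.
1dAVb records draw HR from U(55, 80) so the prolonged P wave stays clear
of the preceding T wave. Sinus RR jitter defaults to 25 ms; the AF RR
law's standard deviation (≈790 ms at the default 72 bpm, by numerical
integration of the clipped log-normal) exceeds the 646 SDNN acceptance
boundary by construction — that boundary is printed unitless in its
source and is physiologically implausible as milliseconds, so it is
treated as a configurable number, not a unit assertion. Noise is
additive white Gaussian (0.01 mV) plus a 0.33 Hz baseline sine
(0.05 mV); nothing else (muscle artifact, electrode pop, mains hum) is
modeled. Default prevalences follow the source study's training
population (1.5/2.7/1.7/1.6/1.8/2.1%).

A green test against this generator therefore establishes that the
pipeline recovers *parameter-separable* classes from clean morphology;
it says nothing about robustness to real-world noise, electrode
placement, or morphological variants the Gaussian model cannot express.

## Preprocessing and measurement oracle

Tracings are polyphase-resampled to 400 Hz and zero-padded (at the end
by default; symmetric is available) to 4096 samples per lead; records
longer than 4096 samples after resampling are rejected unless
center-cropping is requested. R peaks are detected on a 5–30 Hz
band-passed lead DII by thresholding at 45% of the maximum with a
200 ms refractory period. Heart rate is 60/mean(RR); SDNN is the sample
standard deviation of RR in ms. PR and QRS come from a median beat:
windows of ±min(0.42, RR/2) s around each R peak are stacked, the
median taken, the isoelectric line estimated as the densest amplitude
cluster (a mean or running median is dragged by the P/QRS/T lobes), and
onsets/offsets located where the rectified beat stays below 1% of the R
amplitude for ≥12 ms. The P wave is sought up to 360 ms before the QRS
onset and must exceed 0.03 mV — atrial fibrillation therefore yields a
missing PR, which downstream rules treat as non-firing.

On noise-free synthetic records this oracle recovers heart rate within
±2 bpm and PR/QRS within ±10 ms (verified over all six classes). With
default noise and wander the QRS estimate can degrade by tens of ms at
fast rates; the labeling pipeline uses the generator's ground-truth
measurements where they exist, and the oracle is not of delineation
research quality.

## Label pipeline

Free text is lower-cased, punctuation-stripped and stop-word-filtered
before n-grams (default order 2) are formed, so grams may bridge removed
stop-words. The lazy associative classifier mines rules
antecedent → class only over antecedents present in the query *and* the
corpus (default minimum support 0.01, confidence 0.5, antecedent size
≤ 2 — all unstated in the source and exposed in the model object); a
class's score is the mean confidence of its qualifying rules, and the
implementation is tested to coincide with brute-force enumeration on
small corpora. Disambiguation is a documented stand-in (the original
rule content is private): candidates below 0.6 confidence are dropped
(0.6 sits above the ~0.5 confidence that generic single tokens such as
"bloqueio" reach by class-prevalence alone, and below the ~1.0 of
specific phrases), negated mentions (cue within three tokens before a
trigger phrase) are suppressed, and only the best-scoring rhythm class
survives. A templated Portuguese report generator ships for testing;
the original report corpus and dictionary are private.

Harmonization decides each class exactly once. Stage 1 (agreement) is
final: expert ∧ (either automatic source) accepts; a lone automatic
source against everyone else rejects; no source at all rejects
("S0-absent"). Stage 2 applies the four measurement rejections *to the
remainder only* — a stage-1 acceptance is never overturned. All
boundaries are strict inequalities read literally from their wording:
heart rate exactly 100 survives the ST rule, exactly 50 survives the SB
rule, QRS exactly 115 ms and PR exactly 190 ms survive, and AF
auto-acceptance requires SDNN strictly above 646. Stage 3 accepts
expert-positive RBBB/1dAVb/SB/ST and SDNN-gated AF; everything else is
queued for review with its audit trail. Missing measurements never
reject (conservative) and never auto-accept AF.

## Network and training

The architecture is fixed by construction: initial convolution (kernel
16, 64 filters) → four pre-activation residual blocks (BN → ReLU →
Dropout → Conv, twice; the second convolution carries the stride-4
subsampling; skip paths max-pool by 4 and use a 1×1 convolution when
widths change) → flatten (16 × 128) → dense → sigmoid. The filter rule
"+64 every second block" is read literally as (64, 64, 128, 128); the
schedule is a config list because the alternative reading
(64, 128, 128, 192) is one line away. Convolutions use same-length zero
padding so only the strides govern temporal length (4096/4ᵏ after block
k). Weights are He-initialized, biases zero; builds are deterministic
per seed. Dropout defaults to 0.8 as in the source configuration
menu's strongest setting; the rate is configurable.

Everything runs in numpy with channels-last activations: convolutions
are im2col plus one BLAS matmul, backward passes are hand-derived and
verified against float64 finite differences, Adam is implemented
directly (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸). Training clips predictions
to [10⁻⁷, 1 − 10⁻⁷] inside the loss, treats "improvement" as a strictly
lower validation loss (no minimum delta), reduces the learning rate by
10 after seven consecutive non-improving epochs, caps at 50 epochs, and
restores the best-on-validation checkpoint (validation *loss* is the
selection signal; the source wording "best validation results" is not
more specific). Determinism is guaranteed single-threaded; BLAS
threading may reorder reductions.

## The scaled label-recovery experiment

The headline test trains a quarter-scale network — 2 residual blocks,
16 initial filters — on 4000 synthetic records (balanced 20%
prevalences, fixed seed) and requires macro-F1 ≥ 0.90 against generator
ground truth on 500 held-out records, with per-class F1-maximizing
thresholds chosen on the held-out scores (mirroring how the original
operating points were set). The remaining hyperparameters are not
pinned by that specification; they were chosen by validation loss on a
*separate* 1000-record rehearsal set and then frozen: kernel length 8
(from the tuning menu {8, 16, 32} — a quarter-size network takes the
smaller menu kernel), dropout 0 (menu {0, 0.5, 0.8}; heavy dropout is
matched to millions of records and starves a 16-filter net on 4000),
batch 32, 8 epochs. The 4000 records are split 3600 for fitting and 400
for validation-based checkpointing. The frozen configuration reached
macro-F1 0.944 on its first acceptance-scale run; 1dAVb is consistently
the weakest class (F1 ≈ 0.78), which matches the intuition that sharp
interval cutoffs are the hardest feature for a convolutional network to
encode. The experiment runs in about six minutes on one CPU.

## Evaluation conventions

A record is predicted positive when its score is **at or above** the
threshold. PR curves carry one point per distinct score; average
precision is the step-wise sum (identical to scikit-learn's
convention, against which it is tested). The F1-maximizing threshold is
found by exhaustive search over observed scores with ties broken toward
the highest threshold. Undefined ratios (0/0) are reported as NaN,
never coerced to 0. "Micro average precision" means average precision
over the flattened record × class pairs; the mean of per-class APs is
available separately. Bootstrap intervals use 1000 resamples with
replacement at full sample size; resamples where a metric is undefined
are recorded as NaN and excluded from the percentiles rather than
redrawn. McNemar defaults to the uncorrected statistic (b−c)²/(b+c)
with an exact two-sided binomial p-value when b+c < 25 (continuity
correction selectable); Cohen's kappa returns 1.0 in the doubly
degenerate all-agree case. The helper that picks, from a set of runs,
the one whose micro AP is immediately above the median implements the
stated model-selection rule verbatim.

## Known limitations

* The simulator's class separability is by construction; borderline
  cases (HR hovering at 50 or 100 bpm, QRS near 115 ms) are
  deliberately absent from generated positives.
* P waves overlapping the preceding T wave (fast rates with long PR)
  defeat the measurement oracle's P search; real pipelines face the
  same physiology.
* The text classifier's accuracy is only meaningful on the synthetic
  report templates; no claim transfers to real clinical text.
* Training determinism holds for one BLAS thread; results with
  multi-threaded BLAS can differ in the last float digits.
* The full-scale (4-block, 64-filter) configuration is buildable and
  trainable but not exercised at scale in the tests — CPU budgets
  confine training experiments to the quarter-scale network.
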