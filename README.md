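# ecgdx

Automatic classification of six abnormalities in short (7–10 s) standard
12-lead electrocardiograms: first-degree AV block (1dAVb), right and left
bundle branch block (RBBB, LBBB), sinus bradycardia (SB), atrial
fibrillation (AF) and sinus tachycardia (ST).  The package is aimed at
researchers who want to study, extend or stress-test this kind of
end-to-end ECG classification system without access to a large clinical
archive: every stage — from raw tracing to evaluated classifier — runs at
desk scale against a built-in synthetic ECG simulator with ground-truth
labels.

## What's inside

**The classifier** is a unidimensional residual network. The input is a
4096-sample × 12-lead tensor (every recording is resampled to 400 Hz and
zero-padded). An initial convolution (kernel length 16, 64 filters) feeds
four pre-activation residual blocks — BN → ReLU → Dropout → Conv, twice
per block — each subsampling time by 4, with max-pooling and 1×1
convolutions on the skip paths; filters grow by 64 every second block
(64, 64, 128, 128). A dense head with sigmoid outputs gives one
probability per class, σ(z)ᵢ ∈ (0, 1), because the abnormalities are not
mutually exclusive. Training minimizes the average binary cross-entropy

    L = −mean_{i,c} [ y_ic log p_ic + (1 − y_ic) log(1 − p_ic) ]

with Adam (lr = 10⁻³), reducing the learning rate tenfold after seven
epochs without validation improvement, for up to 50 epochs, keeping the
best-on-validation weights. The network and its trainer are implemented
directly in numpy (im2col convolutions, manual backpropagation,
hand-written Adam) — no deep-learning framework is required.

**The labeling engine** reproduces a weak-supervision pipeline for
building training labels from free-text cardiology reports: stop-word
removal and n-gram features, a lazy associative classifier (association
rules mined on demand from the corpus projected onto the query), and
rule-based disambiguation. A three-stage harmonization step then
combines the expert text label with two automatic classifiers: (1)
accept on expert/automatic agreement, reject a lone automatic source;
(2) measurement-based rejections on the remainder — ST with heart rate
below 100 bpm, SB above 50 bpm, RBBB/LBBB with QRS below 115 ms, 1dAVb
with PR below 190 ms; (3) residual acceptances — expert-positive RBBB,
1dAVb, SB, ST outright, AF only when the SDNN of the NN intervals
exceeds 646. Whatever remains goes to a manual-review queue.

**The evaluation suite** provides per-class precision/recall/
specificity/F1 with confusion counts, precision–recall curves,
F1-maximizing threshold selection (verified against exhaustive
cut-point search), micro average precision, bootstrap percentile
intervals (1000 resamples with replacement at full size), the McNemar
test on paired misclassifications and Cohen's kappa.

**The simulator** renders each beat as a sum of five Gaussian bumps
(P, Q, R, S, T) projected through a fixed 12-lead matrix, with regular
(jittered) or irregular (log-normal, P-absent) RR models. Class flags
map to unambiguous parameter ranges (SB → HR < 50 bpm, ST → HR > 100,
1dAVb → PR ≥ 200 ms, BBB → QRS ≥ 120 ms with opposite V1/V6 polarity,
AF → irregular RR without P waves), and the generator returns its
ground-truth measurements alongside each record.

## Worked example

```python
from ecgdx.synthetic import SyntheticRecordSpec, synthesize_record
from ecgdx.measure import measure_record
from ecgdx.textlabels import (AnnotationBundle, TextReport,
                              build_synthetic_lac_model, extract_labels, harmonize)

spec = SyntheticRecordSpec(labels={"1dAVb": True}, seed=7, noise_sd=0.0, baseline_amp=0.0)
rec, labels, truth = synthesize_record(spec)
m = measure_record(rec)
print(f"ground truth: HR {truth.heart_rate:.1f} bpm, PR {truth.pr_interval:.0f} ms, QRS {truth.qrs_duration:.0f} ms")
print(f"measured:     HR {m.heart_rate:.1f} bpm, PR {m.pr_interval:.0f} ms, QRS {m.qrs_duration:.0f} ms")

model = build_synthetic_lac_model(seed=0)
expert = extract_labels(TextReport("ex1", "Ritmo sinusal. Bloqueio atrioventricular de primeiro grau."), model)
result = harmonize(AnnotationBundle("ex1", expert, {}, {}, m))
print("harmonized 1dAVb:", result.status["1dAVb"], "via", result.rule_id["1dAVb"])
```

prints

```
ground truth: HR 71.0 bpm, PR 292 ms, QRS 93 ms
measured:     HR 71.0 bpm, PR 292 ms, QRS 95 ms
harmonized 1dAVb: accepted via S3-accept-expert
```

The simulated first-degree AV block record has its prolonged PR interval
recovered within 1 ms and its QRS within 2 ms by the measurement oracle;
the text pipeline reads the Portuguese report, the rule engine finds no
automatic source agreeing, sees PR ≥ 190 ms (so the stage-2 rejection
does not fire), and accepts the expert diagnosis at stage 3.

The same flow is available from the shell:

```bash
ecgdx simulate --n 1000 --seed 1 --out data/
ecgdx preprocess --in data/tracings.h5 --in-csv data/labels.csv --out pre/
ecgdx train --train-h5 pre/tracings.h5 --train-csv pre/labels.csv \
            --val-h5 pre/tracings.h5 --val-csv pre/labels.csv --out model.npz
ecgdx predict --checkpoint model.npz --in pre/tracings.h5 --out scores.csv
ecgdx evaluate --scores scores.csv --labels data/labels.csv --out report.json
```

## Acceptance script

`scripts/acceptance.py` re-derives the decision boundaries of the
harmonization engine from scratch: it sweeps expert-only annotation
bundles through integer measurement grids (heart rate 40–160 and 30–120
bpm, QRS 80–160 ms, PR 120–260 ms, SDNN 600–700) in seeded-random order
and reports, per rule, the boundary value at which the accept/reject
decision changes.

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Scope

The simulator is a statistical stand-in, not a physiological model; see
`docs/methods.md` for the model, its assumptions, parameter defaults and
known limitations. Reproducing published clinical test-set scores
requires the original training archive and trained weights and is out of
scope here.
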