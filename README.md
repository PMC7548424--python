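# verpmark

Visual event-related potential (VERP) P1-topography biomarkers for
classifying a history of congenital vs. developmental bilateral cataracts,
implemented as a reusable, fully synthetic-testable pipeline:

1. **Synthetic cohorts** (`verpmark.synthetic`) — seeded multi-trial EEG
   epochs for three groups (CC / DC / Control) on a 32-electrode 10/20
   montage, with a posterior P1 (~145 ms) attenuated in the CC group
   (including a numerically-absent-P1 subgroup), a field-polarity-inverting
   C1, an N1, age-dependent amplitude scaling, alpha + 1/f background, and
   blink/saccade artifacts with ground-truth source time courses.
2. **Preprocessing** (`verpmark.preprocessing`) — average reference,
   zero-phase 40 Hz low-pass (optional 50 Hz notch), ocular-component
   rejection (5×SD frontopolar / 3×SD F9-F10 thresholds in −25..175 ms),
   500 ms response rejection, left-field mirror swap, per-condition
   trial averaging.
3. **P1 features** (`verpmark.features`) — per-electrode peak search
   (100–200 ms), individual latency at the maximal posterior electrode,
   fixed 120–170 ms windowed means, across-montage z-standardization
   (cancels age-related gain), and the **MPP1** biomarker (mean of the 13
   posterior z-scores).
4. **Classification** (`verpmark.classification`) — **SVMP1**: linear
   soft-margin SVM over the 13 posterior z-scores with grid-searched cost;
   scores oriented CC-low; fixed, transferable threshold rules.
5. **Evaluation** (`verpmark.evaluation`) — ROC + Youden-J thresholds,
   DeLong AUC CIs, paired stratified-bootstrap AUC comparison, confusion
   metrics with likelihood ratios, Cohen's κ, a spatiotemporal cluster
   permutation test, and the group/confound regressions.
6. **Pipeline + CLI** (`verpmark.pipeline`, `verpmark.cli`) — develop on
   cohort 1, freeze model + thresholds (content-hashed), validate on
   cohort 2 without refitting.

## CLI

```sh
verpmark simulate --preset exp1 --scaled --seed 1 --out exp1.h5
verpmark features --cohort exp1.h5 --out features1.csv
verpmark develop  --features features1.csv --groups all --seed 1 --out dev/
verpmark simulate --preset exp2 --scaled --seed 2 --out exp2.h5
verpmark features --cohort exp2.h5 --out features2.csv
verpmark validate --features features2.csv --artifacts dev/artifacts.json --out val/
verpmark report   --report val/validation_report.json
```

`--scaled` selects the reduced preset (short epochs, 125 Hz, 24
trials/condition) used throughout the tests; omit it for the full-scale
presets (−1000..1000 ms epochs at 250 Hz, trial counts calibrated so the
mean artifact-free upper-field trial count lands near the reference
cohort values).

The Python API mirrors the CLI:

```python
from verpmark.pipeline import RunConfig, run_develop, run_validate

cfg = RunConfig(seed=1, scaled=True)
dev = run_develop(cfg)                       # simulate + preprocess + train
val = run_validate(cfg, dev["artifacts"])    # frozen-threshold validation
```

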