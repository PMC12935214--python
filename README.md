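# brugadanet

Benchmarking machine-learning strategies for **Brugada-pattern ECG
classification under scarce training data**, on a fully synthetic 12-lead
ECG cohort generator.

Brugada syndrome is a rare inherited arrhythmia diagnosed from a
characteristic right-praecordial ECG signature — coved (type 1) or
saddleback (type 2) ST elevation in leads V1–V2 — that is easily confused
with mimics such as right bundle branch block (RBBB), early
repolarisation or anterior STEMI.  Because positive cases are rare, deep
classifiers for it must be trained from small labelled sets, and the
practical question is which strategies actually help in that regime:

1. **supervised pretraining** on a large labelled cohort of related
   patterns (RBBB vs normal), then fine-tuning;
2. **self-supervised contrastive pretraining** (SimCLR, MoCo-V2) with
   ECG-plausible augmentations (baseline drift, Gaussian noise) on
   unlabelled ECGs;
3. **SMOTE oversampling** of the minority class on raw beat tensors,
   where each synthetic beat is x_i + u·(x_nn − x_i) with u ~ U(0,1) and
   x_nn a k-nearest minority neighbour.

Everything runs on numpy/scipy/scikit-learn on one CPU: the package
contains its own 12-lead ECG generator (dipole-projected P-QRS-T beats
with geometrically constructed, measurable J-point amplitude and β angle),
a compact reverse-mode autograd with a 1D-DenseNet feature extractor and
per-block freeze control, beat-level evaluation with paired statistics
(DeLong, McNemar, Holm, paired bootstrap), a Brugada-mimic false-positive
stress test, and expected-gradients explainability with the
parameter-randomisation sanity check.  See `docs/methods.md` for the
model and all design choices.

## Layout

```
src/brugadanet/      library: synth_ecg generator, WFDB IO, preprocessing,
                     nn + backbone, training strategies, SMOTE, statistics,
                     explainability, pipeline orchestration, CLI
analysis/            numbered narrative drivers (01 cohorts ... 05 explain)
scripts/acceptance.py   recompute the headline quantities from scratch
tests/               pytest suite incl. end-to-end acceptance checks
```

## Worked example

Generate a type-1 Brugada record, preprocess it, and read the diagnostic
features back:

```python
from brugadanet import (default_params, generate_record,
                        measure_brugada_features)
from brugadanet.preprocess import extract_beats, resample_to_target

params = default_params("brugada_type1", j_point_amplitude_mV=0.3)
record = generate_record(params, fs_hz=500, duration_s=10.0, rng_seed=1)
record = resample_to_target(record)            # 500 Hz -> 100 Hz
beats = extract_beats(record, record.true_r_peak_samples)
print(measure_brugada_features(beats[3], lead="V1"))
```

prints `(0.31908104265753356, 30.348814221748487)` — the measured J-point
elevation (mV) recovers the 0.3 mV parameter within 10%, and the measured
β angle sits near the class default of 35° (a coved type-1 angle; type 2
defaults to 80°).

The headline comparison (also `analysis/04_scarce_benchmark.py`):

```python
from brugadanet import scarce_benchmark
table = scarce_benchmark(n_seeds=10, master_seed=42)
print(table.groupby("strategy")[["auc", "accuracy"]].median())
```

```
                            auc  accuracy
strategy
baseline               0.963749  0.912638
supervised_pretrained  0.997907  0.986629
```

Each of the 10 repetitions draws a fresh 240-patient cohort, keeps only a
25% patient-stratified training split (~15 Brugada patients), and
evaluates both arms on the identical frozen test partition.  The
from-scratch baseline is unstable in this regime — in some repetitions it
fails badly — while the model fine-tuned from RBBB-vs-normal pretrained
weights is uniformly strong: the median test AUC rises from 0.964 to
0.998.  That is the scarce-data effect this package exists to measure.

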