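# sttkit

Toolkit for the **simple tracing test (STT)**: an objective, tablet-based
assessment of hand dexterity designed for screening compressive spinal-cord
disorders such as cervical spondylotic myelopathy (CSM), whose hallmark
"myelopathy hand" makes everyday pen use clumsy.  The subject traces a
printed 4-cycle sine wave (amplitude 35 mm, wavelength 62 mm) on a pen
tablet at their own pace; the digitized trace is reduced to four variables
and a small neural network converts them into a 0–100 dexterity score.

Intended users: clinical-movement researchers and biostatisticians who want
to run the full pipeline — trace handling, feature extraction, scoring,
diagnostic evaluation — on their own recordings, and methodologists who
want a fully seeded synthetic testbed for it.

## The method

Over the central 3 cycles of the figure (the first and last half cycles
are excluded) each trace yields:

| variable | definition | behaviour |
|---|---|---|
| tracing accuracy | Σᵢ dist((xᵢ, yᵢ), curve), mm | grows as the trace deviates |
| pressure change sum | Σᵢ \|pᵢ₊₁ − pᵢ\| | grows with rough, hesitant tracing |
| pressure change max | maxᵢ \|pᵢ₊₁ − pᵢ\| | spikes when the pen lifts off |
| duration | (t_last − t_first)/1000, s | slow tracing |

The four variables (z-scored by training-set statistics) feed a 4-3-2
multilayer perceptron — tanh hidden layer, softmax output pair — trained by
full-batch backpropagation on labeled cohorts.  The **STT score** is
100 × P(healthy); scores near 0 flag impairment.  The originally published
weights of this network can be loaded with
`sttkit.load_reference_params()` (their normalization constants were never
published, so scoring with them requires supplying norms explicitly).

Diagnostic evaluation follows the screening literature: empirical ROC
curves with thresholds at score midpoints, trapezoidal AUC (equal to the
Mann–Whitney pair statistic), DeLong or stratified-bootstrap 95% CIs, and
the cutoff chosen by minimizing (1 − sensitivity)² + (1 − specificity)².
Reliability across the three one-cycle segments of a trace is quantified
with a two-way mixed, single-measure consistency ICC; group contrasts use
the unpaired t-test and rank correlations use Spearman's ρ.

A seeded simulator (`sttkit.simulate`) generates healthy and impaired pen
traces — tracking noise, tremor, Poisson pen lifts, erratic pressure, slow
speed — so every stage is testable without clinical data.

## Worked example

```bash
stt simulate --n-patients 3 --n-controls 3 --seed 11 --out traces
stt extract traces/manifest.csv --out features.csv
stt train features.csv --seed 5 --out params.json
stt score features.csv --params params.json --out scores.csv
stt evaluate scores.csv --out report.json
stt reliability traces/manifest.csv --params params.json --out icc.json
```

`scores.csv` holds one 0–100 score per subject — simulated patients score
near 0, controls near 100:

```
subject_id,group,stt_score
P000,patient,0.0009576556677280534
P001,patient,0.000947932953288457
P002,patient,0.017594622878705113
C000,control,99.98465136896476
C001,control,99.9883117754042
C002,control,99.98859847996772
```

`stt evaluate` prints the ROC summary for the score column:

```
stt_score  {"direction": "lower_is_positive", "cutoff": 50.0, "sensitivity": 1.0,
            "specificity": 1.0, "auc": 1.0, "auc_ci95": [0.0, 1.0], ...}
```

i.e. on this tiny perfectly separated cohort the distance-to-corner rule
places the cutoff at 50.0 with sensitivity = specificity = 1.0 and AUC 1.0
(the CI is reported at its widest because a fully separated sample carries
no variance information).  `stt reliability` scores each of the three
one-cycle segments per subject and reports their agreement:

```
{"icc": 0.32, "ci95": [-0.17, 0.83],
 "model": "ICC(3,1) two-way mixed, single measures, consistency", ...}
```

All commands are deterministic given their `--seed`.

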