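# Methods

This note documents the models, conventions and numerical choices behind
sttkit, and what its synthetic experiments do and do not demonstrate.

## Task geometry

The task figure is y = A·sin(2π(x − x₀)/λ) with defaults A = 35 mm,
λ = 62 mm, 4 cycles, x₀ = 0.  Coordinates follow the tracing direction: x
increases left→right, y upward, both in mm, origin at the wave start on
the centerline.  The scored analysis window drops the first and last half
cycles, leaving the central n − 1 cycles ([31, 217] mm by default); it is
partitioned into one-wavelength cycle windows for reliability analysis.

Two point-to-curve distances are provided.  *Vertical* is |y − f(x)| at
the sample's own x.  *Nearest* is the minimum Euclidean distance to the
curve, computed by bracketing the global minimum on a grid of 2048 curve
samples per wavelength and shrinking the bracket with 60 vectorized
golden-section iterations (bracket ≪ 1e-9 mm, well inside the 1e-6 mm
tolerance; unit tests verify agreement with a brute-force 10⁴-point oracle
to 1e-3 mm and with a Brent-refined oracle to 1e-4 mm on summed
distances).  Nearest is the default because it stays well defined where a
trace doubles back in x; neither mode is claimed to replicate the original
device software, whose distance definition is unpublished.

## Traces and features

A trace is ≥ 2 strictly time-ordered samples of (t ms, x mm, y mm,
pressure).  Pressure is kept in raw device units with the device maximum
as metadata (default 1023), and pen lifts are pressure-0 samples rather
than gaps, preserving the sudden pressure changes the features measure.
The CSV format (sorted `# key=value` metadata, fixed header, repr-faithful
numbers) makes writing byte-deterministic and write→read the identity.

Feature sums run over recorded samples with no resampling; the sampling
rate is therefore part of the measurement and travels with the trace.
Clipping to a window keeps the contiguous run of recorded samples between
the first and last in-window x, without interpolating boundary crossings —
the simplest defensible reading, and documented rather than hidden.  The
start and end of the test are the first and last samples of the clipped
trace.

One naming subtlety: the variable historically called the "total sum of
pen pressures" is, by its own definition, the total sum of *changes* in
pen pressure; sttkit implements the definition (Σ|Δp|) under the name
`pressure_change_sum` and offers the raw Σp as `pressure_total` for
sensitivity analyses only.

## Scoring network

The network is fixed at 4-3-2: tanh hidden units, softmax output pair, the
score being 100 × P(healthy).  Softmax with cross-entropy was chosen
because the published output-layer weights form a near-antisymmetric pair
and the score is described as a probability; only the hidden activation
(tanh) is fixed by the original description.  Inputs are z-scored with
training-set statistics stored inside the parameter object, so a params
file is self-contained.  The class-to-output mapping is an explicit,
serialized field (unit 0 = patient, unit 1 = healthy by default).

Training is full-batch gradient descent with momentum; defaults
learning_rate 0.1, momentum 0.9, max_epochs 2000, loss_tolerance 1e-8
(absolute loss decrease), init_scale 0.5 (uniform seeded init).  These are
chosen for stable convergence on ~30-example cohorts; with momentum the
per-epoch loss may overshoot transiently, so the guarantee asserted in
tests is final < initial loss, alongside an analytic-vs-finite-difference
gradient check at 1e-6 relative tolerance.  A constant training variable
(sd = 0) is given sd 1, i.e. it carries no information rather than
producing a division error.

The published reference weights are loadable, but their normalization
constants were never published; the loader therefore leaves `input_norm`
unset and scoring refuses to run until norms are supplied (e.g. from a
training split).  Any score computed with the reference weights under
substitute norms is an assumption-laden reconstruction, and is treated as
such in the tests.

## Diagnostic statistics

ROC thresholds sit at midpoints between consecutive distinct scores plus
∓∞ sentinels — this is why reported cutoffs are generally not observed
scores.  The AUC is the trapezoid over the empirical curve with
equal-false-positive-rate points ordered by sensitivity; it equals the
Mann–Whitney pair statistic with ties counted ½ (property-tested to
1e-12).  The optimal cutoff minimizes (1 − sens)² + (1 − spec)², ties
broken by higher sensitivity, then higher specificity, then smaller
threshold.  The default AUC interval is DeLong's (deterministic); a
stratified percentile bootstrap (2000 resamples, mandatory seed) is
available.  A fully separated sample has zero DeLong variance; the widest
sensible interval [0, 1] is returned with a warning rather than a
spuriously tight one.

The ICC defaults to two-way mixed, single measures, consistency —
ICC(3,1) = (MS_rows − MS_err)/(MS_rows + (k − 1)MS_err) with the exact
F-based 95% interval — because cycle order is a fixed facet of a single
trace; the absolute-agreement variant ICC(2,1) is selectable and every
report labels the variant used.  Spearman and the unpaired t-test are
delegated to scipy; Student's pooled test is the default with Welch
selectable.  Presentation rounding is half-up, 2 dp for proportions and
correlations, 1 dp for means and cutoffs; result objects always keep full
precision.

## Synthetic tracers

`simulate_trace` moves the pen at constant speed along x, samples at
100 Hz (typical consumer pen-tablet rate; pressure range 0–1023), and sets
y = f(x) + N(0, σ_dev) + tremor·sin(2πf_t t + φ) with seeded phase.
Pressure is N(μ, σ_p) clipped at 0, with Poisson-many lift events zeroing
it for a fixed duration.  All randomness flows from one root seed through
per-subject child streams (`SeedSequence([root, index])`), so cohorts are
reproducible regardless of generation order.

Default profiles (control → patient): deviation 0.8 → 2.5 mm, tremor
0 → 1.5 mm at 4 Hz, lifts 0 → 2 per trace (120 ms), speed 40 → 20 mm/s,
pressure sd 8 → 25 units — every impairment axis at least doubled.  One
parameter extends the minimal profile: `subject_variability` (default
0.35), a lognormal coefficient of variation applied per trace to
deviation, tremor, lift rate and speed.  Without it every group member
would produce an identical duration and near-identical features, making
the cohorts degenerate (zero within-group variance); with it the groups
overlap realistically while remaining separable.

These defaults are calibrated to reproduce *orderings and separability*
only: patients deviate more, score lower, and the score's AUC clears 0.9.
They do not, and are not meant to, reproduce any real cohort's group
means, per-variable AUC profile (real duration discriminates far worse
than simulated duration, since real patients vary less systematically in
pace), pressure distributions, or the correlation structure among the
four variables.  Passing synthetic tests therefore demonstrates that the
pipeline is correct and that the method recovers a known group structure —
not that it attains any particular clinical accuracy.

## Experiment sizes

The end-to-end recovery experiment mirrors the original design: train on
10 patients + 20 controls, validate on 15 patients + 18 controls, with 20
seeded replicates in the test suite and a single replicate in
`scripts/acceptance.py`.  These sizes keep a full run in the low minutes
on one CPU while leaving the replicate count large enough to assert
frequency statements (ordering in 20/20, AUC ≥ 0.9 in ≥ 18/20).

## Known limitations

* No biomechanical hand model: tremor is a single sinusoid, noise is
  white, speed is constant within a trace.
* Vendor tablet formats and live acquisition are out of scope; traces
  enter via the documented CSV.
* Only the 4-3-2 architecture is supported — no regularization,
  cross-validation or architecture search.
* Single-rater reliability only (cycles within one trace); multi-rater
  designs are not implemented.
* The original study's supplementary feature tables are not
  redistributable here, so the per-variable validation AUCs of the real
  cohort can only be recomputed after the user supplies that file
  (see `tests/test_acceptance.py::test_single_variable_rocs_on_reference_feature_tables`).
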