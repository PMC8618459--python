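# Methods

`readmitrisk` models the daily probability of hospital readmission over the
60 days following surgical discharge.  The package has four moving parts:
a label generator that turns administrative discharge scores into per-day
risk-probability trajectories; a preprocessing pipeline for daily
behavioral feature tables (smartphone / wearable summaries plus symptom
self-reports); an autoregressive LSTM trained leave-one-patient-out; and a
rank-sum system for selecting among competing model configurations.  A
synthetic-cohort generator reproduces the statistical structure of the
(private) study population so every stage is testable.

## Risk-trajectory labels

True daily readmission risk is unobservable, so labels are simulated from
three anchors: an initial probability on day 1 after discharge, obtained by
linear normalisation of the LACE index (score/19), the HOSPITAL score
(score/15) or the mean of the two normalised values; a probability of 1 on
the readmission day for readmitted patients; and 0 on day 60, by which time
surgery-related readmissions are no longer expected.  Day 1 is the first
day after discharge, and trajectories run inclusively over days 1..60.

Between anchors the trajectory follows one of four families:

* **linear** `p_n = a·n + b`;
* **exponential** `p_n = a^n' + b`;
* **logarithmic** `p_n = log_a(n') + b`;
* **weighted linear** `p_n = w_n·l_n + (1−w_n)·p_{n−1}`, where `l_n` is the
  linear value and `w_n = 4/(d1−d2)² · (n − (d1+d2)/2)²` is a parabolic
  weight equal to 1 at both segment endpoints and 0 at the midpoint.

For exponential and logarithmic segments the day index is re-mapped to a
local origin `n' = n − d1 + 1` so every segment starts at `n' = 1`: the
logarithm is finite and fits are well-posed wherever the segment sits.
Exponential parameters come from root-finding on `a^L − a = Δ`
(`L` the segment length, `Δ` the endpoint difference) with Brent's method
at tolerance ~1e-14; logarithmic parameters are closed-form
(`b = p_start`, `a = L^{1/Δ}`).  Degenerate segments (`Δ = 0`) are emitted
as constants.

**Steep exponential falls.** The family `a^n' + b` with `a ∈ (0,1)` can
drop at most `max_a (a − a^L) ≈ 0.89` over a segment, so falls such as
1 → 0 after a second discharge have no real solution.  When a fall exceeds
the representable drop, the package fits the always-feasible *rising*
exponential between the swapped endpoints and reverses it in time.  The
result passes through both endpoints exactly, is monotone, and keeps an
exponential shape (fast-then-slow decay, matching the feasible branch);
it is recorded as segment kind `exponential_reversed` in the JSON sidecar.

Readmitted patients support two in-hospital conventions: hold the
probability at 1 from readmission to second discharge
(`continue_from_one`), or fall back to the initial probability
(`reset_to_initial`) before the final decay to 0.  The rising pre-readmission
segment uses the same configured function family as the falls.  Anchor days
(day 1, readmission day, day 60) are set exactly, all other values are
clamped to [0,1]; endpoint constraints hold to well below 1e-8.

## Feature pipeline

Input is a long table (patient, day, feature columns; empty cells missing).
Steps, in order:

1. **Deviation features** — per base feature, today's value minus the mean
   of the previous 7 days (strictly prior days, non-missing only); missing
   when the base value is missing or no prior observation exists.  Day 1
   deviations are therefore structurally missing.
2. **Column filters** — drop columns with more than 80% of cells missing
   (pooled over patients; strictly more), sample variance of the raw
   non-missing values below 0.3, or — when the first-day filter is on — a
   missing day-1 value for any patient.  Deviation columns are exempt from
   the first-day rule, since their day-1 cell is missing by construction
   and says nothing about measurement quality.  Variance is computed
   before scaling, where the 0.3 threshold is meaningful.
3. **Data range** — optionally truncate readmitted patients' rows at the
   readmission day.  On panels anchored at discharge (no pre-surgery rows)
   the three truncating settings coincide; the default keeps the full
   60 days, the best-performing setting.
4. **Imputation** — moving-average fill: each missing cell takes the mean
   of up to `k_prev` previous non-missing values of that patient/feature
   (default `k_prev = 2`).  The fill is streaming and causal: a cell filled
   earlier in the pass is usable by later fills, the reading of a
   "moving average algorithm" we adopt (single-gap cases are identical
   either way).  Cells with no usable history get the constant −1, chosen
   to be distinguishable from real values.  Cell provenance (observed /
   moving-average / constant) is tracked explicitly rather than by
   sentinel, so −1 never collides with data.
5. **Min–max scaling** — each feature to [0,1] with min/max pooled over all
   patients and days; constant features map to 0.  Constant-filled cells
   are excluded from the fit and left at −1, preserving their
   "distinguishable marker" role after scaling.  Pooling across patients
   reproduces the original protocol, which leaks scale information across
   cross-validation folds; we keep it for fidelity (fitting per training
   fold is a one-line change in `preprocess_panel` callers).
6. **Auxiliary columns** — optionally a normalised day index (day/60) and
   the previous-day probability: day `n` carries the label of day `n−1`,
   day 1 the initial probability (known at discharge from the scores).

## Sequence model

A stacked LSTM (default two layers, tanh cell activations) with a single
sigmoid output unit emits one probability per day.  The input at day `t`
is the day-`t` feature vector; the target is the day-`t+1` label, so a
60-day panel yields 59 prediction steps and the day-1 probability is taken
from the discharge scores rather than predicted.  Hidden size defaults to
the number of input features.  Training is full-batch Adam (learning rate
0.01) on mean-absolute error, with early stopping once the training loss
has not decreased for 50 consecutive epochs (no validation split; minimum
delta 0) and the best-loss weights restored; a `max_epochs` cap bounds the
run.  The network is implemented in NumPy (float32 arithmetic, the
field's standard precision for this model class); its backward pass is
verified against numerical differentiation in float64.

**Injection.** The previous day's probability can be appended as an input
feature in two modes.  `actual_prev` injects the known label — an oracle
mode, usable when risk can be recomputed from known probabilities, and the
strongest configuration.  `predicted_prev` injects the model's own
previous output: teacher-forced with labels during training (the standard
stable choice; the training signal is then identical in both modes) and
rolled out autoregressively at inference, where the input at day `t` takes
the model's prediction for day `t−1` (produced two steps earlier; the
first two inputs use the known initial probability).

**Leave-one-patient-out.** Each patient's full sequence is held out once;
a model is trained from scratch (same seed, so folds differ only by data)
on all other patients' sequences, packed into one padded batch with a
per-step loss mask, and produces the held-out patient's next-day
predictions.  "Trained for multiple rounds" is read as multiple epochs to
early stopping, not restarts.

## Evaluation and ranking

Two metrics — MSE and sample covariance (n−1 denominator, actual risk as
the independent variable) between predicted and actual daily probabilities
— are each computed over six slices: {all, readmitted, non-readmitted}
patients × {first k days (default 20), all K days (default 60)}, pooling
patient-days within the slice.  Covariance measures whether predictions
track the actual trend; the first-k slices emphasise the early
post-discharge window where readmissions concentrate.

Competing models are ranked per submetric (rank 1 = smallest MSE, rank 1 =
largest covariance) and each contributes `(nm − rank)/(nm − 1)` points,
`nm` the number of models; tied values receive the average of the tied
rank positions, so a dead heat splits points evenly (this also makes point
totals invariant to monotone transforms of a metric and conserves the
total at `nm/2` per metric).  Points are summed over the submetrics
present in every report (a stratum absent from any report — e.g. no
readmitted patients — is excluded) and the largest total ranks first.

## Baselines

Multiple linear regression, a CART regression tree and RBF support-vector
regression (scikit-learn, library defaults, hyperparameters recorded in
the results manifest) consume the same rows as the LSTM — day-`t` features
predicting the day-`t+1` label — but as independent observations: no
recurrence and no injected probability column.  Whatever the sequence
model gains must come from the sequential structure.  Their raw outputs
may leave [0,1]; they are clipped for evaluation since labels are
probabilities.

## Synthetic cohorts

The generator emulates the study population's structure: `n_patients`
(default 49) with 34% readmitted (rounded to nearest; readmission day
uniform on days 5–40, second discharge 2–7 days later, capped at day 60);
integer LACE/HOSPITAL scores drawn so the normalised mean spreads over
[0.2, 0.8] (a latent uniform severity plus integer rounding noise); a
latent risk trajectory built by the labels module (defaults: exponential
function, averaged scores, reset-to-initial — the best-performing label
configuration); 10 daily symptom scores `round(clip(10·s·risk·envelope +
N(0,1), 0, 10))` with an extra recovery envelope `exp(−rate·(n−1)/60)` and
a sharpened triangular peak around the readmission day; sensor columns of
which half are affine in the latent risk (slopes of either sign, noise sd
0.8) and half pure-noise distractors; and Bernoulli cell-level missingness
(default 10%, day-1 cells retained by default so the first-day filter has
its intended semantics).  `feature_signal_strength` scales every
risk-related term; at 0 the features carry no information, giving a null
cohort for calibration checks.  All randomness flows through one seed with
per-patient substreams, so cohorts are byte-identical across runs.

What the generator does **not** emulate: the raw 263-feature behavioral
panel (it emits tens of columns), feature autocorrelation beyond what the
risk trajectory induces, block (multi-day, multi-sensor) missingness, and
any real coupling between behavior and readmission beyond the assumed
monotone link to latent risk.  Passing tests on these cohorts therefore
demonstrate that the machinery recovers the structure it assumes — not
that the assumed structure holds in real patients.

## Study problem sizes

The packaged studies (`scripts/acceptance.py`, mirrored by the acceptance
tests) run leave-one-patient-out sweeps over 5 seeds on one CPU, and are
sized accordingly: recovery and injection-ordering studies use 50-patient
cohorts with 6 sensor columns and a 50-epoch cap (convergence under
actual-probability injection is much faster than that); the
model-family comparison uses 20-patient cohorts at signal strength 0.5
with a 120-epoch cap.  General-use defaults are larger (12 sensor
columns, 400-epoch cap).

## Numerical choices and edge cases

* Exponential root-finding brackets the gradual branch above the minimiser
  of `a^L − a` (falls) or `a > 1` (rises); tolerance 1e-14.
* Flat exponential/logarithmic segments (`Δ = 0`) become constants rather
  than degenerate fits.
* Trajectory values are clamped to [0,1]; anchor days are set exactly.
* A second discharge on day 60 leaves no room for the final fall; the
  final-day probability is forced to 0, which the horizon defines.
* Constant features scale to 0 (not an error); an all-dropped panel raises
  an explicit empty-panel error.
* Rank ties use average ranks; the final ranking breaks point ties by
  assigning the smallest rank to all tied models.
* Baseline tree seeds are pinned; identical model seeds reproduce
  prediction tables bit for bit (single-threaded NumPy arithmetic).

## Known limitations

* Exact error tables from the original cohort are not reproducible
  without the private data; the packaged studies check the qualitative
  claims (recovery below a fixed error bound, actual- beats
  predicted-probability injection, the sequence model out-ranks per-day
  baselines) on synthetic cohorts instead.
* The `actual_prev` injection and the pooled min–max scaling both use
  information a deployed system would not have; they are faithful to the
  original protocol and flagged as oracle modes.
* Early stopping monitors training loss, so it bounds fit time rather
  than guarding against overfitting in the usual validation sense.
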