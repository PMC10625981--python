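# Methods

## Problem

Routine-visit notes from a diabetes outpatient clinic often mention a
patient's cardiovascular (CVD) events in free text, while the structured
record of those events lives in a separate hospital-discharge registry.
`cvdnlp` implements, end to end, the task of deciding from a visit's
text alone whether the patient had a CVD hospitalisation within a
look-back window ending on the visit date — infinite, 24, 12 or 6
months in the standard presets. The ground truth is built by linking
the visit table to the discharge registry; the classifier then has to
recover that label from the note's wording.

## Cohort construction

**Qualifying discharges.** A discharge is cardiovascular when any
ICD-9-CM diagnosis code has its leading three-digit category in 390–459
(the circulatory chapter) or any procedure code matches a
revascularisation entry (00.61–66, 36.03, 36.06–07, 36.10–19, 00.55,
39.50, 39.52, 38.48, 39.71, 39.90). Codes are compared dot-free;
ranges expand to explicit sets at load time; longer procedure codes
match by prefix at the entry's stated precision.

**Harmonisation.** Visits are kept when they fall inside the
observation period and the patient's healthcare-eligibility period;
patients then need at least one visit per calendar year in at least
three distinct (not necessarily consecutive) years.

**Windowed labels.** For width `w` months the window is
`[visit_date − w months, visit_date]`, with calendar-month arithmetic
(day-of-month overflow clamps to the month end) and both endpoints
inclusive — a discharge on the visit date itself counts as prior.
Visits whose patient's eligibility started less than `w` months before
the visit are removed (their label cannot be established over the whole
window). The by-patient label is the OR of the patient's visit labels.

**Splits.** Patients — never visits — are partitioned 80/10/10 into
train/validation/test by largest-remainder apportionment of a shuffled
patient list; all windows and the by-patient view reuse one assignment.

## Text preprocessing

Fixed order: lowercase → Italian stop-word removal → stemming →
rare-token pruning → minimum-length filter. The stop-word list is
frozen in the package (`data/stopwords_it.txt`); the stemmer is a
direct implementation of the Snowball Italian algorithm. Pruning drops
the `⌈0.01 × |distinct tokens|⌉` lowest-frequency *types* (ties broken
lexicographically), counted after stemming, on the training split only.
Visits with fewer than 3 cleaned tokens are excluded. Sequences are
encoded against the training vocabulary (index 0 = padding, 1 =
out-of-vocabulary) and right-padded/truncated to `max_len`, by default
the 99th percentile of training-sequence lengths.

## Classifier

Embedding → single bidirectional LSTM (tanh cell output, sigmoid
gates; final hidden states of the two directions concatenated) → a
cascade of ReLU dense layers, each half the width of its predecessor,
→ one sigmoid output unit. The layer widths, LSTM input dropout and
dense dropout span the tuning grid (embedding 32–256, LSTM 16–128,
LSTM dropout {0, .15, .3}, 2–6 dense layers of max width 16–128, dense
dropout {0, .1}). The whole network, including backpropagation through
time and the Adam optimiser, is implemented in NumPy (float32; float64
available and used for gradient checking).

Training minimises unweighted binary cross-entropy (class weighting is
available but off by default: re-balancing did not help at these
prevalences). Adam starts at learning rate 5×10⁻⁵ with time-based
decay `lr₀ / (1 + d·epoch)`, `d = lr₀ / max_epochs`. Early stopping
halts after `patience` epochs without a validation-loss improvement of
at least 10⁻⁴ (the min-delta is a package choice) and the
best-validation weights are restored. The padding embedding row is
frozen at zero. Batch size defaults to 64.

**Model selection.** Random search samples configurations uniformly
without replacement from the grid and scores each by the mean
validation binary cross-entropy over patient-disjoint CV folds; the
best configuration is then retrained several times from different
random initialisations and the restart with the lowest validation loss
becomes the final model. Shipped presets (one per window) record the
configurations selected at full scale: infinite → (64, 128, 0.3, 5
dense, 128, 0); 24- and 12-month → (64, 128, 0.15, 4, 64, 0); 6-month
→ (256, 128, 0.3, 2, 16, 0).

**Desk-scale budgets.** A NumPy epoch at the heaviest preset costs a
few seconds on one CPU, so the default configuration runs the search
with 3 CV folds and a 6-epoch / patience-2 budget per fold, 20 search
draws, 5 restarts, and 60 epochs (patience 10) for final training. `full_scale: true` restores the full protocol — 5 folds,
200 draws, 200 epochs, patience 20, 100 restarts — which is impractical
on a single CPU but preserved as configuration.

## Thresholding

The network outputs a probability per visit. Two operating-point
schemes:

* **single threshold** `th`: positive iff `p ≥ th`; chosen by scanning
  every unique validation probability and maximising F1 (ties go to the
  lowest threshold, favouring recall);
* **double threshold** `(th_low, th_high)` with a reject band: positive
  iff `p ≥ th_high`, negative iff `p ≤ th_low`, otherwise uncertain
  (−1). For each target uncertain fraction `U ∈ {5, 10, 15, 20}%` the
  pair minimising

      J = |F1 − 1| + |U_achieved − U|

  is selected on the validation set, with F1 computed on non-uncertain
  decisions only. Candidate pairs are all ordered pairs of unique
  validation probabilities when that count is within the 500,000-pair
  budget, else a uniform seeded subsample of that size; ties resolve
  toward the smaller achieved uncertainty, then the smaller `th_low`.

## Evaluation

By-visit: AUPRC on raw probabilities (step-curve / average-precision
integration — trapezoidal interpolation is optimistically biased under
class imbalance), plus precision, recall and F1 after thresholding,
with uncertain visits removed from the counted population. By-patient:
visit decisions aggregate per patient with an OR (any certain-positive
visit → 1; else any certain-negative → 0; else the patient is fully
uncertain, excluded and counted); AUPRC is undefined here because the
patient decision only exists after thresholding. Metrics with a zero
denominator are reported as 0 with an explicit `degenerate` flag.

## Synthetic cohorts

The generator emulates the statistical structure the analysis needs
without any clinical data. Per patient: an eligibility period (the
full 2011-01-01 – 2018-09-30 observation window for 90% of patients, a
random sub-interval otherwise), a Poisson stream of discharges
(`hosp_rate`, default 0.02/patient-year; a quarter carry only non-CVD
codes), and 6–17 visits at uniform dates (mean ≈ 11.5 per patient,
matching the per-patient visit density of the corpus the analysis
regime is modelled on; fewer visits per patient would leave so few
positive visits per validation subset that threshold selection becomes
shot noise). Notes are templated
pseudo-Italian clinical phrases (glycaemia, diet, therapy, ...). A note
within `mention_horizon_months` (24) after a qualifying discharge
mentions CVD with probability `mention_given_recent_hosp` (0.9),
drawing from an acute/event phrase pool ("ricovero", "dimissione", ...)
with share 0.95 and from a generic history pool otherwise; any other
note carries a history-pool mention with probability
`spurious_mention_rate` (0.02). The defaults give ≈3% positive visits
under the 24-month window, matching the imbalance regime the method is
designed for. The acute-pool share was fixed from the Bayes arithmetic
of the task: with it, a perfect lexical classifier attains by-visit
F1 ≈ 0.92 under the strong-signal conditions, so the pipeline has
headroom to demonstrate signal recovery, while history-pool mentions
create the genuinely ambiguous mid-probability visits that the reject
option should absorb.

What the generator deliberately does not model: fluent Italian syntax,
visit-frequency dependence on health state, coding errors, multiple
eligibility periods per patient, or drift over calendar time. Passing
tests therefore demonstrate that the machinery recovers a planted
lexical signal under realistic imbalance and noise — not that the
models reach any particular performance on real clinical text.

## Numerical and design choices

* Month arithmetic uses calendar months with day-clamping; both window
  endpoints inclusive (a discharge exactly `w` months back qualifies).
* "Complete window" is anchored at the patient's earliest eligibility
  start.
* Probabilities are clipped inside the sigmoid only (±60 on the logit);
  the loss adds 10⁻¹² inside the logarithms.
* Early-stopping "no improvement" means an improvement smaller than
  10⁻⁴; with `patience = 1` and frozen weights training stops after two
  epochs (the second epoch cannot improve on the first).
* The single-threshold tie-break (lowest threshold) and double-threshold
  tie-breaks (smaller achieved uncertainty, then smaller `th_low`) make
  the optimisers deterministic and testable against exhaustive oracles.
* Predictions are batch-order invariant up to float32 BLAS accumulation
  (~10⁻⁷); tests assert equality at 10⁻⁶.
* The stemmer is not strictly idempotent (true of the Snowball
  algorithm itself: "coronarica" → "coronar" → "coron"); the iteration
  reaches a fixed point within two passes.

## Known limitations

* Training determinism is exact for a fixed seed on a fixed BLAS;
  across BLAS builds results can differ in the last float32 bits.
* The 12- and 6-month presets are shipped but the desk-scale synthetic
  experiments focus on the 24-month window, where the ≈3% regime of the
  original corpus is reproduced.
* No probability calibration (Platt/isotonic) and no confidence
  intervals on metrics; both are out of scope.
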