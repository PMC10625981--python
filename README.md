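# cvdnlp

Identify prior cardiovascular-disease (CVD) hospitalisations of
patients with diabetes from the free-form text of their routine
clinic visits.

## The problem

Diabetes outpatient clinics record most of what happens to a patient as
free text. Whether the patient was recently hospitalised for a
cardiovascular event — the most relevant diabetes complication — is
often mentioned only in the note, while the structured record of the
event sits in a separate administrative discharge registry. `cvdnlp`
implements the full pipeline for turning that text into a structured
CVD-history label:

1. **Linkage / labelling.** A visit is positive when the registry holds
   a qualifying CVD discharge (ICD-9-CM diagnosis category 390–459 or a
   revascularisation procedure code) in a look-back window ending on
   the visit date — infinite, 24, 12 or 6 months. Narrower windows are
   harder: the same wording can describe a hospitalisation that is now
   stale.
2. **Text preprocessing.** Lowercasing, Italian stop-word removal,
   Snowball stemming, pruning of the 1% rarest token types, exclusion
   of visits under 3 tokens.
3. **Classifier.** An embedding → bidirectional LSTM → halving dense
   cascade → sigmoid network (implemented in NumPy, trained with Adam,
   lr 5·10⁻⁵ with time-based decay, early stopping), tuned by random
   search over patient-disjoint CV folds and finalised by
   multi-restart selection on validation loss.
4. **Thresholding.** Either a single cut-off `th` (max-F1 on the
   validation set) or a double cut-off `(th_low, th_high)` with a
   reject band: probabilities inside the band are *uncertain* (−1,
   e.g. routed to manual review). For a target uncertain fraction
   `U ∈ {5, 10, 15, 20}%` the pair minimises
   `J = |F1 − 1| + |U_achieved − U|`.
5. **Evaluation.** By-visit AUPRC / precision / recall / F1 with
   uncertain visits excluded, and a by-patient view where visit
   decisions aggregate with an OR.

Everything runs on synthetic EHR cohorts produced by the package's own
generator (visit table, discharge registry, eligibility periods), which
reproduces the statistical structure of the task — ≈3% positive visits
at the 24-month window, notes that omit a real hospitalisation, and
spurious CVD-history mentions with no discharge behind them — so the
whole pipeline is testable without any clinical data. See
`docs/methods.md` for the model and generator details.

## Worked example

Generate a cohort and label it under the 24-month window:

```bash
$ cvdnlp generate --seed 7 --out demo_cohort
wrote 22966 visits, 258 discharges to demo_cohort
$ cvdnlp label --cohort demo_cohort --window 24 --out demo_labelled.csv --seed 7
15812 visits, 442 positive (2.8%) -> demo_labelled.csv
```

22,966 generated visits shrink to 15,812 after harmonisation (visits
must fall in the observation period and the patient's eligibility
period, patients need visits in ≥3 distinct years) and removal of
visits whose 24-month look-back is not fully observed; 2.8% of the
retained visits have a qualifying discharge in the window — the class
imbalance the method is designed around.

The full experiment — generate, label, preprocess, tune, train,
threshold, evaluate — runs from one config:

```python
from cvdnlp.pipeline import load_config, run_experiment

config = load_config(None, {
    "seed": 1,
    "generator": {"n_patients": 2000, "seed": 1},
    "windows": ["24m"],
    "model": {"search": True},          # or {"preset": "24m"}
    "search": {"n_search": 10, "cv_folds": 3, "max_epochs": 6, "patience": 2},
    "train": {"max_epochs": 60, "patience": 10},
    "n_restarts": 3,
})
results = run_experiment(config, out_dir="runs/demo")
for r in results["24m"]["reports"]:
    print(r.setting, r.uncertainty_level, round(r.f1, 3))
```

On this seed the run prints (abridged; ~14 min on one CPU):

```
by_visit   U=0.00 P=1.000 R=0.825 F1=0.904
by_patient U=0.00 P=1.000 R=0.913 F1=0.955
by_visit   U=0.05 P=1.000 R=0.852 F1=0.920
by_visit   U=0.20 P=1.000 R=0.867 F1=0.929
```

Reading the numbers: at the single threshold (0% uncertainty) the
classifier finds 82.5% of positive visits with no false positives —
misses are mostly notes that never mention the hospitalisation, which
no text model could recover. Allowing the model to abstain on 5–20% of
visits (double threshold) removes the ambiguous ones and lifts F1; the
by-patient view is better still because a patient is recovered if *any*
of their visits is recognised.

Each window directory under `runs/demo/` holds the labelled dataset
(CSV), vocabulary (TSV), model checkpoint (npz), threshold rules
(JSON), search/restart logs (JSON-lines) and the evaluation table
(CSV/JSON).

## Configuration

`cvdnlp all --config experiment.yaml` accepts a YAML file mirroring
`cvdnlp.pipeline.default_config`: generator settings, window list,
split fractions, text options, model preset / search grid, training
budgets, uncertainty targets and output directory. `full_scale: true`
switches to the full protocol (5 CV folds, 200 search draws, 200
epochs, patience 20, 100 restarts) — faithful but impractical on a
single CPU; the desk-scale defaults are documented in
`docs/methods.md`.
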