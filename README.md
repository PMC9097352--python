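# mciscreen

Predicting **mild cognitive impairment (MCI)** from free-text clinical notes
in the absence of structured screening.

Patients and families often report memory complaints that clinicians record
only as free text: no MMSE/MoCA score, no diagnosis code. `mciscreen`
implements an end-to-end system that turns those notes into a screening-style
risk score:

1. **Concept extraction** — a configurable dictionary maps terms and phrases
   to 42 concept unique identifiers (CUIs) such as `WANDER`, `DECLINE`,
   `CALLED` (a family member calling about the patient). Phrase patterns are
   matched per sentence with a gap tolerance: `loss cognitive ability`
   matches *"loss of cognitive ability"* (up to two intervening words per
   step). Single-word terms are expanded with rule-generated inflections
   (`call` → `called`, `calling`, `calls`).
2. **Boilerplate removal** — a mention is discarded as template language when
   the 180 characters before it *or* after it are shared verbatim with a
   mention from another patient (EHR smart-phrases, after-visit summaries).
3. **Cohort construction** — index dates (first structured MCI diagnosis, or
   first CASI ≤ 85 in a longitudinal cohort), sequential eligibility
   exclusions (prior ADRD/psychosis/MCI/bipolar diagnoses, dementia or
   antipsychotic medications), 1:1 matched controls that inherit the case's
   index date, notes restricted to the 730 days before index and to Family
   Practice / Behavioral Health departments, and a patient-level 60/40
   train/validation split.
4. **Risk model** — per-patient binary CUI indicators, three clinically
   specified aggregate sums (Symptom 0–9, Behavior 0–7, Forgetful 0–3) and
   demographics feed an L1-penalized logistic regression,

   `min_β  (1/n) Σᵢ log(1 + exp(−yᵢ xᵢᵀβ))  +  λ ‖β₋₀‖₁`

   with the shrinkage weight λ chosen by stratified tenfold cross-validation
   (minimum mean held-out binomial deviance; one-standard-error rule
   available). Coefficients are reported on the original feature scale, so
   an age coefficient reads as log-odds per year.
5. **Screening evaluation** — sensitivity/specificity/PPV/NPV/F1 across
   probability cutoffs, Mann–Whitney AUC with bootstrap (or DeLong)
   confidence intervals, and Bayes-rule PPV/NPV re-projection at other
   prevalences.

Real clinical text cannot be distributed, so the package ships a
**synthetic corpus generator** with construction-time ground truth: multi-note
patients over a two-year lookback, notes of a few hundred words with
dictionary phrases planted at rates that depend on a latent MCI state, shared
boilerplate blocks, demographic strata and age/sex MCI gradients mirroring
the published cohort tables, and MMSE scores whose ≤ 26 positivity agrees
with the latent state up to a configurable noise rate. Every planted span is
recorded, so extraction recall and boilerplate flagging are checked exactly.

## Worked example

```bash
# generate a synthetic corpus and run the whole pipeline
mciscreen synth --n-patients 300 --seed 7 --out scratch/demo
mciscreen run --notes scratch/demo/notes.ndjson \
              --patients scratch/demo/patients.csv \
              --out scratch/demo/run --seed 7
```

which prints (stderr log lines omitted):

```
wrote 3087 notes for 300 patients to scratch/demo
{
 "n_cohort": 300,
 "n_mentions": 1696
}
```

`scratch/demo/run/` then contains `mentions.csv` (one row per extracted
concept mention with its boilerplate flag), `exclusion_tally.csv` (patients
removed by each eligibility filter, in order), `features.csv` (one row per
patient: 42 CUI flags, the three aggregate sums, demographics, label),
`model.json` + `coefficients.csv` (the fitted LASSO model; zero-coefficient
features are not retained), `sweep_train.csv` / `sweep_validation.csv`
(operating points at cutoffs 0.3/0.4/0.5/0.6) and `metrics.json` with the
train/validation AUC. For this seed the validation cohort has 120 patients at
prevalence 0.367 and the model reaches

```json
"validation": {"auc": 0.8275, "auc_ci": [0.7406, 0.9022]}
```

with `coefficients.csv` led by `cui_DONEPEZIL` (0.957) and `forgetful_sum`
(0.551) — the planted synthetic signal concentrates on the signal concepts,
and everything else is shrunk away. Rerunning with the same seed reproduces
byte-identical artifacts (hashes in `manifest.json`).

The same stages are available as a library — e.g.

```python
from mciscreen import (load_bundled_dictionary, extract_mentions,
                       flag_boilerplate, fit_lasso_logistic)
```

`LassoScreeningClassifier`, `BoilerplateFlagger` and `FeatureBuilder` follow
the scikit-learn estimator conventions (`fit`/`transform`/`predict_proba`,
`get_params`, trailing-underscore fitted attributes) and compose with
sklearn tooling.

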