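# Methods

## Problem setting

Mild cognitive impairment is frequently described in primary-care and
behavioral-health notes long before any structured diagnosis or instrument
score exists. The package treats MCI detection as a screening problem: given
a patient's free-text notes from the two years before an anchor date, produce
a probability that a cognitive instrument administered at that date would be
positive (MMSE or MoCA ≤ 26). The system is deliberately simple — dictionary
lookup, a linear model — because its intended deployment surface is an EHR
that can evaluate a logistic score natively.

## Concept dictionary

Concepts are identified by short uppercase CUIs with one of four roles:
`feature` (model predictor), `patient_exclusion` (evidence such as stroke or
traumatic brain injury that removes the patient from analysis),
`mention_exclusion` and `negation_guard` (available for site-specific rules,
unused by the bundled dictionary). The bundled 42-concept dictionary is a
**reconstruction from published concept descriptions** (versioned
`table1-reconstruction-1.0`, 2–8 plausible patterns per concept); it is not a
verbatim copy of any deployed term list and should be treated as approximate.
Sites replace it with a single flat TSV file (`cui`, `role`, `max_gap`,
`description`, `patterns`) documented in `src/mciscreen/data/` — one record
per line, phrases as space-separated words, alternatives separated by `|`.
`WELLNESS` deliberately ships with zero patterns (defined but inactive);
`validate_dictionary` reports it, along with any phrase claimed by two CUIs.

Negation is handled lexically, not by a modifier algorithm: dedicated
concepts (`DENIAL`, `NEGATE`, `EXM_EXCL`, …) capture negating language and
enter the model as ordinary predictors, which is why several concepts whose
names suggest exclusion (`ICD_EXCL`, `HAL_EXCL`, `EXM_EXCL`, `EXCLUDE`)
default to role `feature`; only `S_EXCL` and `W_EXCL` default to
`patient_exclusion`. Roles are overridable in the dictionary file.

Single-word patterns are expanded once, at pattern-compilation time, into
rule-generated -s/-ed/-ing inflections (with e-drop, consonant+y and
final-consonant-doubling adjustments). The rules are purely orthographic and
intentionally over-generate (e.g. `forgeted` alongside `forgetting`): bogus
forms cannot match real text, and a static expansion keeps matching a pure
lookup that can be audited. Multi-word phrases are matched as written — the
gap rule already gives them flexibility, and combinatorial expansion of every
phrase word would multiply the pattern table for little benefit.

## Matching

Notes are split into sentences (terminal `.`/`!`/`?` followed by whitespace
and a capital or digit, with a small abbreviation list; blank lines also
terminate, since EHR notes are fragmentary), then tokenized into maximal runs
of letters/digits with internal apostrophes. A phrase pattern matches an
increasing token subsequence with at most `max_gap` (default 2) intervening
tokens between consecutive pattern words. Matches never cross sentence
boundaries. Because punctuation is tokenized away, only word tokens count
toward the gap. Within one pattern, matches are selected leftmost-starting
then shortest (the minimal-end completion is found by a bounded backtracking
search — a greedy earliest-next scan can miss completions), are
non-overlapping, and scanning resumes after each match. Different CUIs may
claim overlapping spans; ambiguity is preserved because downstream features
are per-CUI indicators. Each mention records its character span and up to 180
characters of context on each side, measured in raw characters of the
original note.

## Boilerplate

A mention is template language when its left *or* right context (exact string
after trimming surrounding whitespace) is shared with a mention from at least
one other patient (`min_other_patients`, default 1, configurable for
sensitivity analyses). Contexts shorter than 180 characters (note boundaries)
participate as-is. Sharing is evaluated corpus-wide, not within department
strata. Copy-paste within a single patient's chart is deliberately not
removed — only cross-patient templates are, since within-patient repetition
may still be informative about that patient.

## Cohort construction

The index date is the first structured MCI diagnosis (general population) or
the first CASI ≤ 85 (longitudinal cohort); matched controls inherit their
case's index date. Matching is greedy in randomized case order under the run
seed (optimal bipartite matching is out of scope) and requires identical sex,
race, ethnicity, the same 5-year age band (configurable to exact year), and a
health-care visit in the case's calendar quarter — the package's reading of
"the same 3-month period". The note window is half-open,
`[index − 730 d, index)`: "preceding" is taken to exclude the index day
itself. Neurology and Speech/Language Pathology notes are always excluded
(patients there already have recognized deficits). Eligibility filters run
sequentially — continuous enrollment for the full lookback, then ADRD,
psychosis, prior MCI, bipolar diagnoses, then dementia/antipsychotic
medications, study overlap, and finally no-notes-in-window — each patient
counted once, at the first filter that removes them. Code lists are
configuration (`exclusion_codes.yaml`), not hard-coded: the published work
names conditions, not code sets. The train/validation split is patient-level,
never note-level.

## Features and labels

Each feature-role CUI contributes a binary indicator: 1 if the patient has at
least one non-boilerplate mention in the window. Three aggregate sums pool
indicators on clinical grounds: Symptom (9 components), Behavior (7),
Forgetful (3); `FORGET` appears in both Symptom and Forgetful sums by design.
Presence indicators (not occurrence counts) are the default because only they
produce the documented 0–9 / 0–7 / 0–3 ranges; an occurrence-count mode is
available behind `count_mode="occurrence"`. The formula component named
`FORGETFUL` in the published sum definition does not exist as a CUI and is
mapped to `FORGETFL`, resolving an apparent typographical slip. A formula
component absent from the dictionary is a hard error by default (it catches
typos); `allow_missing_sum_components=True` supports deliberately reduced
dictionaries, where absent components contribute zero.

Demographics: age in whole years at index; sex as a male indicator; race as
indicators against a White reference level; ethnicity as Hispanic and
unknown indicators; neighborhood income and education as the published binary
strata (< $25,000; < 25% college) with missing-indicator columns. Census
covariates are offered to the model by default even though penalized
selection may drop them. The label is 1 iff the index-date MMSE or MoCA score
is ≤ 26; CASI scores are rejected at labelling time because the CASI
threshold (≤ 85) belongs to index-date assignment.

## Penalized model

The classifier minimizes mean binomial negative log-likelihood plus
λ·Σ|βⱼ| with an unpenalized intercept. Predictors are standardized to unit
variance internally; during cross-validation the scaler is fitted inside each
training fold only, so no held-out information leaks into the scaling.
Coefficients are mapped back to the original feature scale (an age
coefficient is log-odds per year). The λ grid has 100 log-spaced points from
the data-derived λ_max — the smallest penalty at which the all-zero slope
vector is optimal, max|X̃ᵀ(y − ȳ)|/n — down to λ_max·10⁻⁴. λ is chosen to
minimize mean held-out deviance over stratified tenfold CV (folds stratified
by outcome to stabilize CV at moderate prevalence); the one-standard-error
rule is available (`selection="1se"`). For λ ≥ λ_max the exact analytic
solution (zero slopes, intercept = logit ȳ) is returned; for λ = 0 an
unpenalized fit with tight tolerance is used; otherwise the saga solver with
warm starts along the descending path (scikit-learn behind this module's
surface). Constant columns get coefficient 0 with a warning. Predicted
probabilities are clipped to (10⁻¹⁵, 1 − 10⁻¹⁵) so extreme linear predictors
never report impossible certainty.

## Evaluation

A prediction is positive at probability ≥ cutoff (the boundary convention is
the package's choice). Undefined ratios (0/0) are NaN, never zero. F1 is
derived from PPV and sensitivity. AUC is the Mann–Whitney statistic with
midrank ties, identical to the trapezoidal ROC area; its CI is a stratified
bootstrap (2000 replicates by default, positives and negatives resampled
separately, percentile interval) with DeLong's closed form as an alternative
— the bootstrap is the default because no CI method is prescribed for this
setting. `ppv_npv_at_prevalence` re-projects an operating point to another
prevalence by Bayes' rule.

## Synthetic corpus

The generator's defaults emulate the published study population: 2391
patients; ~10 notes per patient (1 + Poisson(9)) in the 730-day lookback;
~260 words per note (normal, SD 120, floor 30); age bands, sex, race,
ethnicity and neighborhood strata at the published cohort proportions; a
latent MCI state from `logit p = −0.95 + 0.0626·(age − 75) + 0.18·female`,
calibrated so overall prevalence is ≈ 0.31 with the published monotone age
gradient and small female excess; and an MMSE score at the index date that
disagrees with the latent state with probability 0.10 (imperfect instrument
measurement). Dictionary phrases are planted per note at per-CUI
status-dependent rates; multi-word phrases occasionally receive 1–2 filler
words inside the phrase (still within the matcher's gap tolerance).
Boilerplate is simulated as a pool of fixed template blocks (default 12, one
inserted per note with probability 0.25), each carrying at least 180
characters of fixed text on both sides of any embedded phrase so that both
context windows of a template mention lie inside the block.

Three constructions make ground truth exact rather than probabilistic:
every note opens and closes with a sentence containing its unique note id;
every planted (non-template) phrase sentence embeds the note id on both
sides of the phrase; and the filler vocabulary is filtered against every
dictionary pattern word. Consequently the only cross-patient identical
contexts are inside template blocks, filler text can never complete a
pattern, and extraction/flagging can be compared to the ground-truth table
set-exactly.

What the generator does **not** model: real clinical language (filler is a
neutral word salad), within-patient disease progression (note content is
independent across notes given the latent state), department-specific
language, spelling errors, and section structure. Passing tests therefore
demonstrate the pipeline's mechanical correctness and its statistical
behaviour under known signal, not performance on real notes.

All randomness flows from one root seed through named substreams (patient
attributes; one stream per note keyed by patient and note index; scores), so
partial regeneration is stable.

## Problem sizes used in checks

The matcher is verified against a brute-force all-subsequence oracle on 200
random corpora (≤ 50 sentences, ≤ 5 patterns each). Recall/boilerplate
exactness uses 150 patients × ~3 notes with the 3-concept toy dictionary.
Planted-coefficient recovery uses 20 simulations at n = 2000 with 3 true
effects (|β| = 0.8) among 45 Gaussian features, fitted with a 40-point λ
grid — a coarser grid than the default 100, chosen as sufficient resolution
for selection while keeping the simulation cheap. End-to-end discrimination
checks use 2000 patients with ~5 notes of ~120 words (signal strength does
not depend on note size). The strong-signal configuration sets the
label-noise rate to 0.02 rather than the default 0.10: with label noise ε
independent of the notes, no score can exceed AUC ≈ 1 − ε against the noisy
label, so a configuration intended to demonstrate high attainable
discrimination must keep ε small. The null configuration zeroes the age and
sex effects as well as the rate differences, so no feature carries signal.

## Known limitations

* The bundled dictionary is a plausible reconstruction; term-for-term
  fidelity to any deployed system is not claimed.
* Greedy matching of controls may leave matchable cases unmatched; it is
  seeded and reported, not optimized.
* The boilerplate rule requires exact 180-character equality; near-duplicate
  templates (one edited character) escape it, as they would in the original
  definition.
* Aggregate-sum presence semantics cap each component's contribution at 1;
  occurrence mode changes the documented ranges.
* The published real-cohort coefficients and AUC cannot be reproduced here —
  the clinical text is not available — so model-level checks are analytic
  limits, oracle agreement, and synthetic-signal recovery.
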