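# Methods

## The audit

A *spell* is a continuous hospital stay from admission to discharge and may
contain several consultant *episodes*, each with an ordered ICD-10
diagnosis list.  For each condition the audit:

1. normalizes codes (uppercase, dots stripped; `E11.5` ≡ `E115`) and finds
   each patient's **index spell** — the earliest spell whose pooled episode
   codes match an index pattern, with ties broken by discharge date then
   spell id;
2. removes spells that carry no diagnostic information or would bias the
   denominator: pooled codes empty or ⊆ {R69}; dialysis regular attendances
   (procedure X40/X43, or a regular-attendance spell coding N18.5); and all
   spells of patients below a minimum index age (PDD < 40, DMPC < 18),
   where the index diagnosis is most plausibly a coding error;
3. labels each **subsequent spell** (admitted on or after the index
   admission; overlapping transfer spells count, since transfers appear as
   separate spells) as consistent iff at least one episode mentions a
   consistency-set code — equivalent to testing the pooled union;
4. computes `days_since_index` as subsequent admission minus index
   discharge, floored at 0, and restricts trend analyses to a fixed 3-year
   (1095-day) follow-up for patients whose index discharge precedes a
   cutoff (default 2018-04-01), so all contributing patients share the same
   maximum follow-up.

Design points that the source conventions leave open, decided here: spell
attributes (trust, specialty, admission method, dates) come from the first
episode; a day case is a spell with length of stay 0 days; "record" in the
R69 rule is read at spell level (pooled codes); regular attendance is an
admission-method level in the schema.  The dementia consistency set accepts
exactly the listed codes (e.g. G30.1/.8/.9 but not G30.0), and the autism
set accepts only F84.0/F84.1/F84.5 — not other F84.x codes.

## Covariates

Each subsequent spell yields: age (continuous years; reports use bands),
length of stay, days since index, Charlson comorbidity index, a hospital
frailty risk score, deprivation quintile, a placeholder numeric frailty
covariate, sex, ethnicity, admission method, main specialty, day-case flag,
change-of-trust and change-of-specialty flags (vs the index spell), and
`related_code_absent` — no G20 coded for PDD, no F70–F83 code for autism;
constant false for DMPC, which has no related set.

Comorbidity instruments are weighted ICD-10 pattern tables summed over
*distinct* pattern groups among the pooled codes of spells admitted in
`[reference − lookback, reference)`: Charlson uses the Quan ICD-10 mapping
with original weights and a 1-year lookback; the frailty score uses a
2-year lookback over a **synthetic stand-in** weight table
(`hfrs_weights_synthetic.csv`) with the real instrument's structure —
3-character prefix stems, weights 0.1–7.1, heaviest on dementia, delirium,
falls and mobility codes — because the full published table is not
redistributable here.  Tests exercise scoring semantics with toy tables, so
nothing downstream depends on the stand-in's specific weights.

Missing values are imputed with the training-split mean (numeric) or mode
(categorical, ties to the lexicographically smallest level).  Imputation is
deliberately *not* stratified by the outcome class: class-conditional
imputation would leak labels into features.  Categoricals are one-hot
encoded with a column map that remembers which matrix columns belong to
each feature, so attributions can be aggregated back; categories unseen at
transform time encode as all-zeros and are logged.

## Classifier

Rows (spells) are split 70/15/15 into train/validation/test uniformly at
random.  Splitting by spell mirrors the spell-level unit of analysis but
lets one patient straddle splits; `group_by_patient=True` offers the
grouped alternative.  Hyperparameters of a random forest are drawn without
replacement from a configurable grid (default: 200/500 trees, depth
8/16/none, min leaf 1/5/20, class weight none/balanced; 20 draws) and
selected by validation AUPRC (average precision); the search log keeps
every candidate.  All randomness derives from one seed.

## Evaluation statistics

AUROC is the Mann–Whitney statistic (ties count ½).  Its CI uses DeLong's
variance from per-observation placement values with midranks, a
normal-theory interval truncated to [0, 1]; perfect separation returns a
degenerate zero-width interval with a warning.  AUPRC is average precision
(no linear interpolation, which is known to be optimistic).
Precision-gain/recall-gain curves map precision and recall through
`gain(v) = (v − π)/((1 − π)v)` with π the prevalence; the area integrates
precision gain (floored at 0) over recall gain in [0, 1], with the boundary
value at recall gain 0 linearly interpolated.  Kendall tau-b uses the
standard tie corrections and is undefined (NaN with warning) for constant
vectors.

## Attribution

Shapley values on the model's probability output are computed by an exact
path-dependent tree-Shapley algorithm (EXTEND/UNWIND over each tree's
root-to-leaf paths, feature absence modelled by training-cover weighting),
implemented in `treeshap.py` and compiled with numba.  Local accuracy —
base value plus contributions equals the prediction — holds to 1e-6 on
every row and is asserted in tests against a brute-force
subset-enumeration oracle.  Importance is mean |Shapley value| per original
feature (one-hot members summed via the column map); directionality is
tau-b between feature values and contributions, reported per indicator
level for multi-level categoricals, which have no single value ordering.
Attribution defaults to test rows.

## Synthetic generator

The generator emulates the structure of English hospital-episode extracts:
per condition, demographics echo the published first-spell marginals
(autism young and deprived, DMPC mid/late life, PDD old), one index spell
is placed uniformly in the 2013-04-01..2021-03-31 window, and a
Poisson(2.5) number of subsequent spells follow at exponential gaps (mean
240 days, truncated at the window end).  The mandatory code is omitted from
a subsequent spell with probability

    sigmoid(b0 + b_trust·chg_trust + b_spec·chg_spec
            + b_days·log1p(days)/log1p(1095) + b_case·day_case
            + b_age·(age−50)/50 + b_sex·female + b_rel·related_absent)

Binary features enter as 0/1 and the continuous ones are scaled to roughly
unit range, so a coefficient of 1 means about one logit across a feature's
span.  Default intercepts reproduce the published per-condition rates
(43.7%, 8.6%, 31.2%); default slopes are modest positive values, with the
elapsed-time effect entering through log(1+days) to give the saturating
trend seen in real audits after ~20 weeks.  A consistent spell carries one
consistency-set code (the patient's own index code for autism; a broader
diabetes/dementia code otherwise); an omitted spell carries none —
distractor codes are drawn from a pool chosen to be disjoint from every
consistency set, and include Charlson/frailty-matching codes so the
comorbidity features are non-degenerate.  Exclusion artefacts (R69-only or
empty-diagnosis spells, dialysis regular attenders with X40 + N18.5,
under-age DMPC/PDD patients) are injected at configurable rates, 1% each by
default.  A master seed fans out to fixed named substreams (demographics,
spells, omission, noise, exclusions), so adding a stage never perturbs
earlier draws and a fixed seed reproduces CSVs byte for byte.

What the generator does **not** emulate: realistic national volumes, trust
catchment structure, within-spell specialty changes, coder-behaviour
correlation across a patient's spells, or real covariate joint
distributions (only the published marginals are available as calibration).
Passing recovery tests therefore demonstrates that the pipeline measures
what it claims on data whose generating mechanism is known — not that real
extracts satisfy these mechanisms.

## Problem sizes and test design

Tests use sizes chosen to make the statistical checks sharp but cheap:
oracle-equivalence checks run ≥1000 random instances; intercept-only
recovery uses ~5500 subsequent spells per run at the three published rates
across 5 seeds (within 3 binomial SEs); classifier/attribution recovery
uses ~22 000 subsequent spells with |coefficients| ≥ 1, 150-tree forests of
depth 8, and 500 attributed test rows per seed across 10 seeds (test AUROC
≥ 0.70, tau-b sign recovery ≥ 6/7 features in ≥ 8/10 seeds); DeLong
coverage uses 500 binormal simulations at true AUROC 0.75 with n = 200.

## Known limitations

- The audit cannot distinguish a mandatory code missing from subsequent
  spells from a code misused on the index spell (false-positive index).
- Tau-b directionality for multi-level categoricals is only defined per
  indicator level.
- The frailty weight table is a labelled synthetic stand-in; absolute
  frailty scores are not comparable to published instrument values.
- Intervals assume independent spells; repeated spells of one patient are
  correlated in reality, so real-data CIs would be somewhat anticonservative.
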