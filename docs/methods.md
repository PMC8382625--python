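# Methods

## Scientific setting

Type 2 diabetes is heterogeneous. A widely used stratification assigns
newly diagnosed adults to data-driven subtypes by k-means clustering of a
handful of clinical variables; with age, BMI, HbA1c, C-peptide and
HDL-cholesterol (all measurable in routine care, avoiding HOMA2 indices
that require fasting samples) the five-cluster solution comprises:

| Archetype | Defining profile |
|---|---|
| SIDD | severe insulin-deficient: high HbA1c, younger, lower BMI/C-peptide/HDL |
| SIRD | severe insulin-resistant: high C-peptide, older |
| MOD  | mild obesity-related: high BMI, youngest |
| MD   | mild: no extreme characteristic |
| MDH  | mild with high HDL-cholesterol: older, high HDL, slowest progression |

`diaclust` implements the full analysis chain -- inclusion filtering,
sex-stratified clustering, gap-statistic model selection, archetype naming,
cross-cohort validation, a composite time-to-insulin-requirement endpoint,
and one-vs-rest Cox hazard ratios pooled by random-effects meta-analysis --
and, because the underlying registries are access-controlled, a synthetic
multi-cohort generator with known ground truth against which every stage is
validated.

## Clustering (module `clustering`)

* **Standardization.** Per cohort *and* per sex, each of the five variables
  is z-scored with the population (ddof=0) standard deviation. Unscaled
  k-means would be dominated by HbA1c's numeric range (mmol/mol values an
  order of magnitude larger than HDL in mmol/l), which is incompatible with
  clusters defined by several variables at once; scaling is exposed for
  sensitivity analysis.
* **k-means.** Lloyd's algorithm (scikit-learn backend), squared Euclidean
  distance, random-point initialisation, best of `n_restarts` restarts
  (default 100), `max_iter` 300, deterministic given the pipeline seed.
  Exact distance ties in assignment go to the lowest cluster index.
* **Gap statistic.** For k = 1..kmax, `Gap(k) = mean_b log W*_kb - log W_k`
  with B (default 50) reference sets drawn uniformly over each column's
  observed range (the simplest Tibshirani reference, not PCA-rotated), and
  `s_k = sd_b(log W*_kb) * sqrt(1 + 1/B)`. Two selection rules are
  provided: `one_se` (smallest k with `Gap(k) >= Gap(k+1) - s_{k+1}`; valid
  under the one-cluster null) and `flatten` (smallest k whose forward
  increment drops below `flatten_eps` = 0.25 of the largest increment;
  mirrors "the curve flattens" reading but presumes a structured curve, so
  the null case is always judged with `one_se`). The headline pipeline
  fixes k = 5.
* **Sex merging.** The two per-sex solutions are aligned by the permutation
  minimising total squared distance between matched centroids (Hungarian
  algorithm; exact for this additive cost, verified in tests against
  brute-force enumeration of all 120 pairings). Unified ids follow the male
  solution's order; serialized outputs number clusters 1..k.

## Archetype naming and cross-validation (module `archetypes`)

Naming is a sequential argmax over the sex-averaged z-centroids:
highest HbA1c -> SIDD; then highest C-peptide -> SIRD; then highest BMI ->
MOD; then highest HDL -> MDH; the remainder is MD. The evidence matrix is
retained. For transfer between cohorts, a model acts as a self-contained
classifier: subjects of cohort A are standardized with model B's per-sex
scaler and assigned to B's nearest centroid. Agreement is summarised by a
confusion matrix aligned through archetype names (falling back to
minimal-cost centroid matching for unnamed models is deliberately *not*
done -- naming is required, keeping results invariant to internal cluster
numbering), with per-archetype sensitivity TP/(TP+FN) and one-vs-rest
specificity TN/(TN+FP), both with exact Clopper-Pearson 95% intervals
(valid at proportions near 1, where Wald intervals degenerate).
`compare_to_external` additionally supports pooling predicted archetypes
(e.g. MD+MDH against a single external mild-age-related class) and aligns
differing label vocabularies by maximum overlap.

## Composite endpoint (module `endpoint`)

Time zero is the diagnosis date (configurable to first visit). The event is
the earlier of:

1. **Sustained insulin**: first insulin treatment episode longer than 183
   days, where prescription intervals of a drug class separated by at most
   90 days are merged into episodes; the event date is the episode start.
2. **Glycaemic requirement**: two HbA1c measurements strictly greater than
   69 mmol/mol (8.5%) at least 90 days apart, each taken while at least two
   distinct non-insulin glucose-lowering drug classes are active; the event
   date is the second measurement, when the requirement is established.

Inequalities follow the definition verbatim: strict at 69 mmol/mol,
inclusive at the 90-day separation, strict at the 183-day sustainment.
"On >= 2 drugs" is evaluated from active merged episodes at each
measurement date (issue-date prescription data are sparse in registries,
so same-day co-prescription would undercount). Subjects without an event
are censored at the last observation date. The derivation is monotone:
adding prescriptions or measurements can only introduce or advance an
event, never delay it (property-tested).

## Survival analysis and pooling (module `survival`)

Per cohort and archetype, a Cox proportional-hazards model with the single
binary covariate "subject in archetype" (reference: the other four
clusters), Efron tie handling, no further covariates. Per-archetype log
hazard ratios are pooled across cohorts with the DerSimonian-Laird
random-effects estimator (formulas in the module docstring), Wald CI and
two-sided p on the log scale, no Knapp-Hartung adjustment (exposed as a
possible extension; plain DL matches the reporting convention of wide
symmetric-log CIs).

## Synthetic generator (module `synthetic`)

**Cross-section.** Per sex, a five-component mixture on a transformed scale
(age linear, truncated to [35, 95] years; BMI, HbA1c, C-peptide, HDL
log-normal, so positive-scale variables are strictly positive and IQRs are
right-skewed). Component weights default to (0.15, 0.15, 0.20, 0.32, 0.18)
for (SIDD, SIRD, MOD, MD, MDH), inside the observed cohort shares; natural-
scale component medians (e.g. SIDD HbA1c 85 mmol/mol, MOD BMI 38 kg/m^2,
MDH HDL 1.70 mmol/l) were chosen so cohort-level marginal medians land
near the published cohort tables (BMI ~30 kg/m^2, HbA1c ~52 mmol/mol, age
~60 y, male fraction 0.58). Within-component covariances are diagonal by
default (the sources report no within-cluster covariances) with SDs of
5 y (age) and 0.08-0.18 (log scale); both are configurable. A `separation`
scalar moves component means away from the mixture centre without shifting
the overall marginals; at the default (1.0) the downstream clustering
recovers truth with per-archetype sensitivity ~0.95-0.99, consistent with
the high end of published cross-cohort sensitivities.

**Follow-up.** Annual visits for 10 years. HbA1c follows
`setpoint_c + drift_c * years + noise` with per-cluster setpoints
(51, 47, 49, 47, 44) mmol/mol, drifts (0.7, 0.45, 0.6, 0.4, 0.25)
mmol/mol/year, subject-level setpoint SD 4 and measurement SD 3 --
treated glycaemia that deteriorates slowly, so the glycaemic pathway is a
rare late-follow-up contributor and the endpoint's hazard structure is
governed by the insulin-initiation model. Oral therapy escalates
deterministically (one additional class at any visit above 58 mmol/mol, up
to 3 classes); only insulin initiation is stochastic, drawn from an
exponential proportional-hazards model with baseline 0.02 initiations per
person-year.

**Hazard calibration.** The published progression contrasts are
*one-vs-rest* hazard ratios, i.e. each cluster against the weighted
average of the rest. Setting per-cluster log hazards directly to the log
of those ratios would make the true one-vs-rest contrast of the fast
cluster ~4.4 rather than 3.40 (the rest-average is 0.78, not 1), so
`calibrate_cluster_hazards` inverts the one-vs-rest algebra
`x_c = H_c * sum_{j!=c} w_j x_j / (1 - w_c)` for relative hazards `x`.
The five target ratios are not exactly jointly consistent with any weight
vector (one redundant degree of freedom), so the system is solved in
weighted least squares on the log scale with the extreme SIDD contrast
pinned to numerical exactness and the small residual spread over the other
clusters; the achieved one-vs-rest truths are (3.40, 0.554, 1.03, 0.70,
0.415), preserving every ordering margin. Scale is fixed by
`sum w_c x_c = 1`.

**What the generator does not emulate.** No mortality or competing risks,
no dose/adherence pharmacoepidemiology, no secular assay drift, no
between-cohort heterogeneity in cluster structure (the three synthetic
cohorts differ only by seed, so meta-analytic tau^2 is near zero -- real
cohorts differ in assay conditions and case mix and show wider pooled CIs),
and cluster overlap at the default separation is at the optimistic end of
what real registries show. Passing tests therefore demonstrate correctness
of the machinery and recoverability of a known truth, not expected
performance on any real registry.

## Numerical and design choices

* Durations are fixed-length calendar constants: 2 years = 730 days,
  3 months = 90 days, 6 months = 183 days.
* HbA1c is stored on the IFCC scale; NGSP percent is an I/O conversion via
  the master equation `NGSP% = 0.09148 * IFCC + 2.152` (inverse exact to
  float precision).
* Inclusion filtering attributes each exclusion to the first failing rule
  in the fixed order (age, window, GAD, completeness); a rule whose inputs
  are missing fails that rule. GAD handling defaults to excluding only
  measured-positive subjects (`require_negative` available), since antibody
  coverage differs between registries. The two-year data-availability
  window is applied at visit level, not per variable.
* All randomness flows from one pipeline seed via CRC32-derived substreams
  per stage/cohort/sex (all below 2^31), so pipeline outputs are
  bit-identical across runs.
* Problem sizes in the test suite are chosen to give each stochastic check
  adequate power while keeping the default run short: gap-statistic
  selection at n = 2000 (20 seeds), cross-cohort validation at n = 3000,
  end-to-end hazard recovery at 3 cohorts x 4000 subjects x 20 replicates
  with 20 k-means restarts (at the default separation the restart basin is
  stable from ~10 restarts).
* Two stochastic module checks are formulated at the statistically sound
  level: CI-calibration of the Cox fit uses 30 replicates with a mean-bias
  bound (a perfectly calibrated interval fails stricter per-replicate
  tallies too often by binomial noise alone), and the crude event-rate
  ordering of the two slowest clusters -- whose true 10-year cumulative
  rates differ by only ~2 percentage points -- is asserted on mean rates
  across replicates, with the sharp ordering check carried by the pooled
  hazard ratios.

## Known limitations

* Archetype naming assumes k = 5; other k require manual labelling.
* The glycaemic pathway's "on >= 2 drugs" reading (active at both
  measurement dates, rather than continuously between them) is one of two
  defensible operationalisations; the alternative would only delay events.
* No proportional-hazards diagnostics beyond the model contract; the
  one-vs-rest "rest" group is a mixture and mildly non-proportional by
  construction.
* The cross-sectional generator draws age at diagnosis from age at visit
  minus a uniform delay, floored at 35, producing a small atom at the
  inclusion boundary.
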