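# diaclust

Clinical-variable subtyping of type 2 diabetes: sex-stratified k-means
clustering of five routinely measured variables, cross-cohort validation of
the resulting clusters, and comparison of their progression to insulin
requirement.

## What it does, and for whom

Newly diagnosed adults with type 2 diabetes can be stratified into
clinically meaningful subtypes by k-means clustering of **age at first
visit (years), BMI (kg/m²), HbA1c (mmol/mol), C-peptide (nmol/l) and
HDL-cholesterol (mmol/l)** — variables available in routine care, unlike
the HOMA2 indices used in earlier subtype work. The five-cluster solution
comprises SIDD (severe insulin-deficient, high HbA1c), SIRD (severe
insulin-resistant, high C-peptide), MOD (mild obesity-related, high BMI),
MD (mild, no extreme characteristic) and MDH (mild with high
HDL-cholesterol, the slowest-progressing group).

The package is aimed at biostatisticians and epidemiologists who want a
tested, reproducible implementation of this analysis chain to run on their
own registry extracts, or to study its statistical behaviour in
simulation. It provides:

* **data_model** — typed cohort records, CSV/JSON I/O, IFCC↔NGSP HbA1c
  conversion (`NGSP% = 0.09148·IFCC + 2.152`), and the inclusion filters
  (diagnosis age ≥ 35 y, first visit within 730 days of diagnosis, not
  GAD-positive, complete clustering variables).
* **clustering** — per-sex z-scoring, best-of-restarts Lloyd k-means, the
  gap statistic Gap(k) = E*[log W*ₖ] − log Wₖ with uniform reference sets
  and two selection rules, and merging of per-sex solutions by optimal
  centroid matching.
* **archetypes** — naming of the five clusters from their z-profiles,
  nearest-centroid transfer of one cohort's model to another, confusion
  matrices with per-archetype sensitivity/specificity and exact
  Clopper–Pearson 95% CIs, and pooled comparisons against external labels.
* **endpoint** — the composite time-to-insulin-requirement outcome:
  sustained (> 183 days) insulin treatment, or two HbA1c values
  > 69 mmol/mol (8.5%) ≥ 90 days apart while on ≥ 2 non-insulin
  glucose-lowering drug classes.
* **survival** — per-cohort one-vs-rest Cox models (Efron ties) and
  DerSimonian–Laird random-effects pooling of log hazard ratios.
* **synthetic** — a three-cohort generator with known five-cluster ground
  truth and longitudinal follow-up whose per-cluster one-vs-rest hazard
  ratios are calibrated to the published progression contrasts
  (SIDD 3.40 … MDH 0.44), so every stage is testable without data access.
* **cli** — `diaclust simulate | fit | assign | crossval | endpoint |
  survival | report`.

See `docs/methods.md` for the model, its assumptions and the design
choices.

## Worked example

Simulate three cohorts, cluster each, cross-validate between cohorts and
pool the progression hazard ratios:

```python
from diaclust import (fit_sex_stratified, name_archetypes, cross_validate,
                      simulate_cross_section, simulate_followup, endpoint_table,
                      cox_one_vs_rest, survival_table, ARCHETYPES)
from diaclust.synthetic import MixtureConfig, FollowupConfig

models, cohorts, estimates = {}, {}, []
for i, cid in enumerate(("cohort_a", "cohort_b", "cohort_c")):
    cohort, truth = simulate_cross_section(MixtureConfig(n_subjects=3000, seed=10 + i), cid)
    model = fit_sex_stratified(cohort, k=5, n_restarts=50, seed=10 + i)
    name_archetypes(model)
    cohorts[cid], models[cid] = cohort, model
    labels = {s: model.archetypes[c] for s, c in model.training_assignment.items()}
    records = simulate_followup(cohort, truth, FollowupConfig(seed=20 + i))
    table = endpoint_table(records)
    for a in ARCHETYPES:
        estimates.append(cox_one_vs_rest(table, labels, a, cohort_id=cid))

conf = cross_validate(cohorts["cohort_a"], models["cohort_a"], models["cohort_c"])
print(conf.metrics[["archetype", "sensitivity", "sens_ci_low", "sens_ci_high"]]
      .round(3).to_string(index=False))
print(survival_table(estimates).round(3).to_string(index=False))
```

Output:

```
archetype  sensitivity  sens_ci_low  sens_ci_high
     SIDD        0.998        0.988         1.000
     SIRD        0.998        0.987         1.000
      MOD        1.000        0.994         1.000
       MD        0.991        0.983         0.996
      MDH        1.000        0.994         1.000

archetype    hr  ci_low  ci_high     p  tau2     q  n_cohorts
     SIDD 3.003   2.702    3.337 0.000   0.0 0.942          3
     SIRD 0.523   0.439    0.623 0.000   0.0 0.173          3
      MOD 1.060   0.940    1.195 0.342   0.0 1.423          3
       MD 0.806   0.722    0.899 0.000   0.0 0.194          3
      MDH 0.512   0.436    0.602 0.000   0.0 0.854          3
```

The first block says that subjects of the first synthetic cohort, when
re-assigned using the third cohort's cluster centres, land in their own
cohort's archetype with ≥ 99% sensitivity (exact binomial CIs) — the
clusters transfer between cohorts. The second block is the pooled
one-vs-rest survival contrast per archetype: SIDD progresses to insulin
requirement about three times as fast as the rest, MDH about half as fast,
reproducing the simulated hazard structure within sampling error (at this
single-replicate size, hr estimates scatter around the calibrated truths
3.40, 0.55, 1.03, 0.70, 0.41; tau² ≈ 0 because the synthetic cohorts are
exchangeable).

The same study can be run from the shell:

```bash
diaclust report --seed 7 --n-subjects 2000 --out-dir out/
```

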