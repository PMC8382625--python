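"""Archetype naming, nearest-centroid transfer and agreement statistics."""

import numpy as np
import pytest

from diaclust.archetypes import (
    assign,
    compare_to_external,
    cross_validate,
    name_archetypes,
)
from diaclust.clustering import ClusterModel, Scaler, fit_sex_stratified
from diaclust.data_model import ARCHETYPES, Cohort, SubjectRecord
from diaclust.synthetic import MixtureConfig, simulate_cross_section


def _toy_model(centroids, k=None, archetypes=None):
    centroids = np.asarray(centroids, dtype=float)
    k = k or centroids.shape[0]
    scaler = Scaler(mean=np.zeros(5), sd=np.ones(5))
    return ClusterModel(
        cohort_id="toy", k=k,
        scalers={"male": scaler, "female": scaler},
        centroids={"male": centroids.copy(), "female": centroids.copy()},
        merge_permutation=list(range(k)), seed=0, archetypes=archetypes)


class TestNameArchetypes:
    def test_one_hot_profiles_get_the_obvious_names(self):
        # +2 z on the defining variable of each archetype, in shuffled order
        centroids = np.zeros((5, 5))
        centroids[0, 4] = 2.0   # hdl -> MDH
        centroids[1, 2] = 2.0   # hba1c -> SIDD
        centroids[2, 1] = 2.0   # bmi -> MOD
        centroids[3, 3] = 2.0   # c-peptide -> SIRD
        model = _toy_model(centroids)
        naming = name_archetypes(model)
        assert naming.mapping == {1: "SIDD", 3: "SIRD", 2: "MOD", 0: "MDH", 4: "MD"}
        assert model.archetypes == naming.mapping

    def test_naming_is_invariant_to_cluster_numbering(self):
        rng = np.random.default_rng(0)
        centroids = rng.normal(size=(5, 5))
        base = name_archetypes(_toy_model(centroids)).mapping
        perm = [2, 0, 4, 1, 3]
        permuted = name_archetypes(_toy_model(centroids[perm])).mapping
        assert all(permuted[i] == base[perm[i]] for i in range(5))

    def test_requires_five_clusters(self):
        model = _toy_model(np.zeros((4, 5)) + np.eye(4, 5), k=4)
        with pytest.raises(ValueError, match="k=5"):
            name_archetypes(model)

    def test_synthetic_truth_archetypes_recovered(self):
        """Across seeds, naming agrees with ground truth for >=4/5 clusters."""
        for seed in range(5):
            cohort, labels = simulate_cross_section(
                MixtureConfig(n_subjects=2000, seed=seed), "nm")
            model = fit_sex_stratified(cohort, k=5, n_restarts=25, seed=seed)
            name_archetypes(model)
            agree = 0
            for c in range(5):
                members = [s for s, lab in model.training_assignment.items()
                           if lab == c]
                truths = [labels.archetype_of(s) for s in members]
                majority = max(set(truths), key=truths.count)
                agree += majority == model.archetypes[c]
            assert agree >= 4


def _subject_at(sid, values, sex="male"):
    age, bmi, hba1c, cpep, hdl = values
    return SubjectRecord(subject_id=sid, cohort_id="c", sex=sex,
                         age_at_first_visit=age, bmi=bmi, hba1c=hba1c,
                         c_peptide=cpep, hdl=hdl)


class TestAssign:
    def test_training_cohort_reproduces_training_assignment(
            self, study_cohort, study_model):
        cohort, _ = study_cohort
        labels = assign(cohort, study_model)
        assert labels == study_model.training_assignment

    def test_subject_exactly_at_centroid(self):
        centroids = np.vstack([np.zeros(5), np.ones(5) * 3])
        model = _toy_model(centroids, k=2)
        cohort = Cohort("c", [_subject_at("hit", (3, 3, 3, 3, 3))])
        assert assign(cohort, model) == {"hit": 1}

    def test_distance_tie_goes_to_lowest_index(self):
        centroids = np.zeros((4, 5))
        centroids[1] = [2, 0, 0, 0, 0]
        centroids[3] = [-2, 0, 0, 0, 0]  # clusters 1 and 3 equidistant from origin-ish
        model = _toy_model(centroids, k=4)
        cohort = Cohort("c", [_subject_at("tie", (0, 0, 0, 0, 0))])
        # ties with clusters 0 and 2 (both at origin): index 0 wins
        assert assign(cohort, model) == {"tie": 0}

    def test_unknown_sex_scaler_is_error(self, study_model):
        model = ClusterModel(
            cohort_id=study_model.cohort_id, k=5,
            scalers={"male": study_model.scalers["male"]},
            centroids={"male": study_model.centroids["male"]},
            merge_permutation=list(range(5)), seed=0)
        cohort = Cohort("c", [_subject_at("f", (60, 30, 50, 1, 1.2), sex="female")])
        with pytest.raises(ValueError, match="no scaler"):
            assign(cohort, model)


class TestCrossValidate:
    def test_self_comparison_is_diagonal(self, study_cohort, study_model):
        cohort, _ = study_cohort
        result = cross_validate(cohort, study_model, study_model)
        assert np.all(result.matrix == np.diag(np.diag(result.matrix)))
        assert np.allclose(result.metrics.sensitivity, 1.0)
        assert np.allclose(result.metrics.specificity, 1.0)

    def test_metrics_equal_brute_force_recomputation(self, study_cohort, study_model):
        cohort, labels = study_cohort
        other = fit_sex_stratified(cohort, k=5, n_restarts=10, seed=99)
        name_archetypes(other)
        result = cross_validate(cohort, study_model, other)
        ref = {s: study_model.archetypes[c]
               for s, c in assign(cohort, study_model).items()}
        pred = {s: other.archetypes[c] for s, c in assign(cohort, other).items()}
        for row in result.metrics.itertuples():
            a = row.archetype
            tp = sum(ref[s] == a and pred[s] == a for s in ref)
            fn = sum(ref[s] == a and pred[s] != a for s in ref)
            fp = sum(ref[s] != a and pred[s] == a for s in ref)
            tn = len(ref) - tp - fn - fp
            assert row.sensitivity == pytest.approx(tp / (tp + fn))
            assert row.specificity == pytest.approx(tn / (tn + fp))

    def test_invariant_to_internal_relabeling(self, study_cohort, study_model):
        cohort, _ = study_cohort
        other = fit_sex_stratified(cohort, k=5, n_restarts=10, seed=99)
        name_archetypes(other)
        baseline = cross_validate(cohort, study_model, other)
        perm = [4, 2, 0, 1, 3]
        inverse = {perm[i]: i for i in range(5)}
        shuffled = ClusterModel(
            cohort_id=other.cohort_id, k=5, scalers=other.scalers,
            centroids={sex: c[perm] for sex, c in other.centroids.items()},
            merge_permutation=list(range(5)), seed=other.seed,
            archetypes={inverse[c]: a for c, a in other.archetypes.items()})
        assert np.array_equal(
            cross_validate(cohort, study_model, shuffled).matrix, baseline.matrix)

    def test_unnamed_models_rejected(self, study_cohort, study_model):
        cohort, _ = study_cohort
        anon = fit_sex_stratified(cohort, k=5, n_restarts=5, seed=1)
        with pytest.raises(ValueError, match="archetype"):
            cross_validate(cohort, study_model, anon)


class TestConfusionIntervals:
    def test_hand_confusion_sensitivity_specificity(self):
        predicted, external = {}, {}
        for i in range(100):
            external[f"a{i}"] = "A"
            predicted[f"a{i}"] = "A" if i < 90 else "B"
        for i in range(100):
            external[f"b{i}"] = "B"
            predicted[f"b{i}"] = "A" if i < 20 else "B"
        result = compare_to_external(predicted, external)
        assert result.sensitivity("A") == pytest.approx(0.90)
        assert result.specificity("A") == pytest.approx(0.80)

    def test_clopper_pearson_contains_point_and_narrows_with_n(self):
        from statsmodels.stats.proportion import proportion_confint
        for n in (20, 200, 2000):
            k = int(0.85 * n)
            lo, hi = proportion_confint(k, n, method="beta")
            assert lo <= k / n <= hi
        widths = []
        for n in (20, 200, 2000):
            k = int(0.85 * n)
            lo, hi = proportion_confint(k, n, method="beta")
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_ci_bounds_present_in_metrics(self, study_cohort, study_model):
        cohort, _ = study_cohort
        result = cross_validate(cohort, study_model, study_model)
        m = result.metrics
        assert ((m.sens_ci_low <= m.sensitivity)
                & (m.sensitivity <= m.sens_ci_high)).all()


class TestCompareToExternal:
    def test_pooling_two_mild_clusters_against_single_external_class(self):
        external, predicted = {}, {}
        for i in range(50):
            external[f"m{i}"] = "MARD"
            predicted[f"m{i}"] = "MD" if i % 2 else "MDH"
        for i in range(30):
            external[f"s{i}"] = "SIDD"
            predicted[f"s{i}"] = "SIDD"
        result = compare_to_external(predicted, external, merge={"MD", "MDH"})
        assert result.sensitivity("MARD") == pytest.approx(1.0)

    def test_no_merge_identity_labels(self):
        labels = {f"s{i}": ARCHETYPES[i % 5] for i in range(50)}
        result = compare_to_external(labels, labels)
        assert np.all(result.matrix == np.diag(np.diag(result.matrix)))
        assert result.n == 50

    def test_pooled_sensitivity_at_least_unpooled_max(self):
        rng = np.random.default_rng(3)
        external, predicted = {}, {}
        for i in range(300):
            sid = f"x{i}"
            external[sid] = rng.choice(["MARD", "SIDD", "SIRD", "MOD"])
            if external[sid] == "MARD":
                predicted[sid] = rng.choice(["MD", "MDH", "SIRD"], p=[.45, .45, .1])
            else:
                predicted[sid] = external[sid]
        pooled = compare_to_external(predicted, external, merge={"MD", "MDH"})
        # pooling can only add true positives for the external mild class
        unpooled = compare_to_external(predicted, external)
        assert (pooled.sensitivity("MARD")
                >= unpooled.sensitivity("MARD") - 1e-12)

    def test_subject_mismatch_reports_offenders(self):
        with pytest.raises(ValueError, match="s2"):
            compare_to_external({"s1": "MD"}, {"s1": "MD", "s2": "MDH"})
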