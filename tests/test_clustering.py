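"""Standardization, k-means restarts, gap statistic and sex merging."""

import itertools

import numpy as np
import pytest

from diaclust.clustering import (
    GapCurve,
    Scaler,
    fit_sex_stratified,
    gap_statistic,
    kmeans_restarts,
    merge_sexes,
    select_k,
    standardize,
)
from diaclust.data_model import Cohort, SubjectRecord


def _subject(sid, sex, values):
    age, bmi, hba1c, cpep, hdl = values
    return SubjectRecord(subject_id=sid, cohort_id="c", sex=sex,
                         age_at_first_visit=age, bmi=bmi, hba1c=hba1c,
                         c_peptide=cpep, hdl=hdl)


class TestStandardize:
    def test_two_symmetric_subjects_map_to_plus_minus_one(self):
        # population-sd convention: z = +/-1, not +/-1/sqrt(2)
        cohort = Cohort("c", [
            _subject("a", "male", (50, 28, 45, 0.8, 1.0)),
            _subject("b", "male", (70, 32, 55, 1.2, 1.4)),
        ])
        z, scaler = standardize(cohort, "male")
        assert np.allclose(np.abs(z), 1.0)
        assert np.allclose(scaler.mean, [60, 30, 50, 1.0, 1.2])

    def test_constant_column_error_names_variable(self):
        cohort = Cohort("c", [
            _subject("a", "male", (50, 28, 45, 0.8, 1.1)),
            _subject("b", "male", (70, 32, 55, 1.2, 1.1)),
        ])
        with pytest.raises(ValueError, match="hdl"):
            standardize(cohort, "male")

    def test_small_matrix_against_hand_computation(self):
        rows = [(40, 25, 40, 0.5, 1.0), (50, 30, 50, 1.0, 1.2),
                (60, 35, 60, 1.5, 1.4), (70, 40, 70, 2.0, 1.6)]
        cohort = Cohort("c", [_subject(f"s{i}", "female", v)
                              for i, v in enumerate(rows)])
        z, _ = standardize(cohort, "female")
        # columns are affine in row index, so z is the same for every column:
        # deviations (-15,-5,5,15)/sd with population sd sqrt(125) -> +/-1.3416, +/-0.4472
        expected_col = np.array([-1.34164079, -0.4472136, 0.4472136, 1.34164079])
        assert np.allclose(z, np.column_stack([expected_col] * 5))

    def test_z_columns_have_zero_mean_unit_sd(self, study_cohort):
        z, _ = standardize(study_cohort[0], "male")
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(z.std(axis=0), 1.0, atol=1e-10)

    def test_scaler_requires_positive_sd(self):
        with pytest.raises(ValueError):
            Scaler(mean=np.zeros(5), sd=np.array([1, 1, 0, 1, 1.0]))


class TestKmeansRestarts:
    def test_two_point_dataset_is_solved_exactly(self):
        X = np.tile(np.array([[0.0, 0, 0, 0, 0], [1.0, 1, 1, 1, 1]]), (10, 1))
        sol = kmeans_restarts(X, k=2, n_restarts=5, seed=0)
        assert sol.objective == pytest.approx(0.0, abs=1e-12)
        assert {tuple(c) for c in sol.centroids} == {(0.0,) * 5, (1.0,) * 5}

    def test_k_equal_one_closed_form(self, rng):
        X = rng.normal(size=(40, 5))
        sol = kmeans_restarts(X, k=1, n_restarts=3, seed=0)
        assert np.allclose(sol.centroids[0], X.mean(axis=0))
        assert sol.objective == pytest.approx(((X - X.mean(0)) ** 2).sum())

    def test_k_beyond_distinct_rows_rejected(self):
        X = np.tile(np.array([[0.0, 0], [1.0, 1]]), (5, 1))
        with pytest.raises(ValueError, match="distinct"):
            kmeans_restarts(X, k=3, n_restarts=2, seed=0)

    def test_objective_matches_assignment_implied_sum(self, rng):
        X = rng.normal(size=(200, 5))
        sol = kmeans_restarts(X, k=4, n_restarts=10, seed=1)
        implied = sum(
            ((X[sol.assignment == c] - sol.centroids[c]) ** 2).sum()
            for c in range(4))
        assert sol.objective == pytest.approx(implied, abs=1e-8)

    def test_recovers_separated_gaussians_across_seeds(self):
        centres = np.array([[0.0, 0], [10.0, 0], [0.0, 10]])
        for seed in range(20):
            g = np.random.default_rng(seed)
            X = np.vstack([c + g.normal(size=(20, 2)) for c in centres])
            truth = np.repeat([0, 1, 2], 20)
            sol = kmeans_restarts(X, k=3, n_restarts=10, seed=seed)
            # agreement up to relabeling
            relabel = {}
            for c in range(3):
                relabel[c] = np.bincount(truth[sol.assignment == c]).argmax()
            assert all(relabel[a] == t for a, t in zip(sol.assignment, truth))

    def test_objective_non_increasing_in_restarts(self, rng):
        X = rng.normal(size=(150, 5))
        objectives = [
            kmeans_restarts(X, k=6, n_restarts=n, seed=3).objective
            for n in (1, 5, 20, 60)]
        assert all(a >= b - 1e-12 for a, b in zip(objectives, objectives[1:]))

    def test_wk_non_increasing_in_k(self, rng):
        X = rng.normal(size=(150, 5))
        w = [kmeans_restarts(X, k=k, n_restarts=20, seed=2).objective
             for k in range(1, 7)]
        assert all(a >= b - 1e-9 for a, b in zip(w, w[1:]))


class TestSelectK:
    def _curve(self, gap, s):
        gap = np.asarray(gap, dtype=float)
        s = np.asarray(s, dtype=float)
        k = np.arange(1, len(gap) + 1)
        zeros = np.zeros_like(gap)
        return GapCurve(k, zeros, zeros, zeros, gap, s, n_reference=50)

    def test_one_se_rule_on_hand_curve(self):
        curve = self._curve([0.2, 0.5, 0.7, 0.9, 0.92, 0.93], [0.05] * 6)
        assert select_k(curve, "one_se") == 4

    def test_huge_uncertainty_collapses_to_one_cluster(self):
        curve = self._curve([0.2, 0.5, 0.7, 0.9, 0.92, 0.93], [10.0] * 6)
        assert select_k(curve, "one_se") == 1

    def test_flatten_rule_on_hand_curve(self):
        # increments (.3,.2,.2,.02,.01); threshold 0.25*0.3=0.075 -> k=4
        curve = self._curve([0.2, 0.5, 0.7, 0.9, 0.92, 0.93], [0.05] * 6)
        assert select_k(curve, "flatten") == 4

    def test_monotone_curve_returns_kmax(self):
        curve = self._curve([0.1, 0.3, 0.5, 0.7], [0.0001] * 4)
        assert select_k(curve, "one_se") == 4


class TestGapStatistic:
    def test_reference_size_consistency(self, rng):
        """Gap values for B=10 vs B=50 agree within 3 combined SEs."""
        X = rng.normal(size=(300, 5))
        c10 = gap_statistic(X, kmax=4, B=10, seed=4)
        c50 = gap_statistic(X, kmax=4, B=50, seed=5)
        for j in range(4):
            combined = np.hypot(c10.s[j], c50.s[j])
            assert abs(c10.gap[j] - c50.gap[j]) <= 3 * combined

    def test_invalid_parameters_rejected(self, rng):
        X = rng.normal(size=(50, 5))
        with pytest.raises(ValueError):
            gap_statistic(X, kmax=1, B=50, seed=0)
        with pytest.raises(ValueError):
            gap_statistic(X, kmax=3, B=5, seed=0)

    def test_curve_fields_are_populated_and_consistent(self, rng):
        X = rng.normal(size=(200, 3))
        curve = gap_statistic(X, kmax=3, B=12, seed=6)
        assert curve.gap == pytest.approx(curve.log_wstar_mean - curve.log_wk)
        assert np.allclose(
            curve.s, curve.log_wstar_sd * np.sqrt(1 + 1 / 12), atol=1e-12)
        assert np.all(np.diff(curve.log_wk) <= 1e-9)


class TestMergeSexes:
    def test_identical_sets_give_identity_at_zero_cost(self, rng):
        c = rng.normal(size=(5, 5))
        assert merge_sexes(c, c) == [0, 1, 2, 3, 4]

    def test_recovers_known_shuffle(self, rng):
        c = rng.normal(size=(5, 5))
        perm = [3, 0, 4, 1, 2]
        assert merge_sexes(c, c[perm]) == [perm.index(i) for i in range(5)]

    def test_matches_brute_force_minimum(self, rng):
        """Hungarian matching equals exhaustive 120-permutation search."""
        for _ in range(10):
            a = rng.normal(size=(5, 5))
            b = rng.normal(size=(5, 5))
            perm = merge_sexes(a, b)
            cost = ((a - b[perm]) ** 2).sum()
            brute = min(
                ((a - b[list(p)]) ** 2).sum()
                for p in itertools.permutations(range(5)))
            assert cost == pytest.approx(brute, abs=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            merge_sexes(rng.normal(size=(5, 5)), rng.normal(size=(4, 5)))


class TestFitSexStratified:
    def test_every_complete_subject_gets_unified_label(self, study_cohort, study_model):
        cohort, _ = study_cohort
        complete = [s.subject_id for s in cohort if s.has_complete_clustering_variables]
        assert set(study_model.training_assignment) == set(complete)
        assert set(study_model.training_assignment.values()) <= set(range(5))

    def test_both_sexes_share_k_and_permutation_is_bijection(self, study_model):
        assert study_model.centroids["male"].shape == (5, 5)
        assert study_model.centroids["female"].shape == (5, 5)
        assert sorted(study_model.merge_permutation) == [0, 1, 2, 3, 4]

    def test_sex_floor_is_enforced(self, study_cohort):
        cohort, _ = study_cohort
        males_only = cohort.subset([s for s in cohort if s.sex == "male"][:200])
        with pytest.raises(ValueError, match="female"):
            fit_sex_stratified(males_only, k=5, n_restarts=5, seed=0)

    def test_model_json_round_trip(self, study_model, tmp_path):
        from diaclust.clustering import ClusterModel
        path = tmp_path / "model.json"
        study_model.to_json(path)
        back = ClusterModel.from_json(path)
        assert back.cohort_id == study_model.cohort_id
        assert back.k == study_model.k
        assert back.archetypes == study_model.archetypes
        for sex in ("male", "female"):
            assert np.allclose(back.centroids[sex], study_model.centroids[sex])
            assert np.allclose(back.scalers[sex].mean, study_model.scalers[sex].mean)
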