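"""Logistic predictor fitting, CV ensembles, AUC, scoring, and PRS."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eqtlrank as er
from eqtlrank.errors import DataError, ValidationError

from oracles import auc_pairwise


def _noise_fm(n_per_class, n_features, seed, standardized=True):
    rng = np.random.default_rng(seed)
    descs = [er.FeatureDescriptor(f"f{j}", "snp_only", f"rs{j}", allele="A")
             for j in range(n_features)]
    fm = er.FeatureMatrix(
        [f"s{i}" for i in range(2 * n_per_class)], descs,
        rng.normal(size=(2 * n_per_class, n_features)),
        np.r_[np.ones(n_per_class, int), np.zeros(n_per_class, int)])
    return er.standardize(fm) if standardized else fm


class TestAuc:
    def test_perfect_separation(self):
        assert er.auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(10, 80))
            scores = np.round(rng.normal(size=n), 1)  # coarse -> ties occur
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert er.auc(scores, labels) == pytest.approx(
                auc_pairwise(scores, labels), abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_negation_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=40)
        labels = np.r_[np.ones(20, int), np.zeros(20, int)]
        assert er.auc(scores, labels) + er.auc(-scores, labels) == pytest.approx(1.0)

    def test_null_sampling_distribution(self):
        """Independent scores at n=1000/1000 stay within 0.5 +- 0.04."""
        labels = np.r_[np.ones(1000, int), np.zeros(1000, int)]
        inside = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = er.auc(rng.normal(size=2000), labels)
            inside += abs(a - 0.5) <= 0.04
        assert inside >= 19

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=400) + np.r_[np.full(200, 0.5), np.zeros(200)]
        labels = np.r_[np.ones(200, int), np.zeros(200, int)]
        a, lo, hi = er.evaluate_auc(scores, labels, n_boot=500, seed=0)
        assert lo <= a <= hi
        assert 0 < hi - lo < 0.2

    def test_single_class_is_error(self):
        with pytest.raises(DataError):
            er.auc([0.1, 0.2], [1, 1])


class TestFitting:
    def test_extreme_penalty_gives_base_rate_intercept(self):
        fm = _noise_fm(60, 5, 0)
        fm2 = er.FeatureMatrix(fm.sample_ids, fm.descriptors, fm.values,
                               np.r_[np.ones(80, int), np.zeros(40, int)],
                               fm.column_stats)
        model = er.fit_final_model(fm2, er.HyperParams("l2", 1e-10), seed=0)
        assert np.abs(model.coef_vector).max() < 1e-4
        assert model.intercept == pytest.approx(np.log(80 / 40), abs=1e-3)

    def test_duplicated_column_l2_symmetry(self):
        fm = _noise_fm(100, 4, 1)
        vals = fm.values.copy()
        vals[:, 3] = vals[:, 0]  # exact duplicate
        fm2 = er.FeatureMatrix(fm.sample_ids, fm.descriptors, vals,
                               fm.labels, fm.column_stats)
        model = er.fit_final_model(fm2, er.HyperParams("l2", 1.0), seed=0)
        c = model.coef_vector
        assert abs(c[0] - c[3]) < 1e-6

    def test_refit_is_deterministic(self, recovery_run):
        fmk, hp = recovery_run["fm_kept"], recovery_run["hp"]
        m1 = er.fit_final_model(fmk, hp, seed=11)
        m2 = er.fit_final_model(fmk, hp, seed=11)
        np.testing.assert_array_equal(m1.coef_vector, m2.coef_vector)
        assert m1.intercept == m2.intercept

    def test_l1_path_sparsity_roughly_monotone(self):
        fm = _noise_fm(150, 30, 2)
        fm.values[:, :5] += 0.4 * fm.labels[:, None]  # weak planted signal
        counts = []
        for c in [1.0, 0.3, 0.1, 0.03, 0.01]:
            m = er.fit_final_model(fm, er.HyperParams("l1", c), seed=0)
            counts.append(len(m.nonzero_features))
        for a, b in zip(counts, counts[1:]):
            assert b <= a + 2  # stronger penalty never adds beyond jitter


class TestEnsemble:
    def test_five_repeats_ten_folds_gives_fifty_models(self, recovery_run):
        ens = recovery_run["ensemble"]
        assert len(ens.models) == 50
        assert len(ens.fold_aucs) == 50

    def test_mean_sd_consistent_with_fold_scores(self, recovery_run):
        ens = recovery_run["ensemble"]
        labels = recovery_run["fm_kept"].labels
        recomputed = [er.auc(s, labels[idx]) for idx, s in ens.fold_scores]
        assert ens.mean_auc == pytest.approx(float(np.mean(recomputed)))
        assert ens.sd_auc == pytest.approx(float(np.std(recomputed, ddof=1)))

    def test_pure_noise_cv_auc_near_half(self):
        fm = _noise_fm(200, 20, 4)
        hp, ens = er.tune_hyperparameters(
            fm, [er.HyperParams("elastic_net", 0.1, 0.5),
                 er.HyperParams("elastic_net", 1.0, 0.5)],
            repeats=2, folds=5, seed=0)
        assert abs(ens.mean_auc - 0.5) <= 0.06

    def test_planted_signal_cv_auc_tracks_population_auc(self, recovery_run):
        # generator calibrated to population AUC 0.70
        assert 0.63 <= recovery_run["ensemble"].mean_auc <= 0.74

    def test_empty_grid_is_error(self, recovery_run):
        with pytest.raises(ValidationError):
            er.tune_hyperparameters(recovery_run["fm_kept"], [])

    def test_too_few_samples_per_fold_is_error(self):
        fm = _noise_fm(4, 3, 0)
        with pytest.raises(DataError):
            er.cv_ensemble(fm, er.HyperParams("l2", 1.0), repeats=1, folds=10)


class TestPredict:
    def _toy_model(self):
        return er.FittedRiskModel(
            intercept=-0.4,
            coefficients={"fA": 0.5, "fB": -0.25},
            hyperparams=er.HyperParams("l2", 1.0),
            train_auc=0.6,
            feature_order=["fA", "fB"],
            replay_stats={"mean": [0.0, 0.0], "sd": [1.0, 1.0],
                          "zero_variance": [False, False]},
        )

    def _fm(self, values, ids):
        descs = [er.FeatureDescriptor(f, "snp_only", f, allele="A") for f in ids]
        n = values.shape[0]
        return er.FeatureMatrix([f"s{i}" for i in range(n)], descs, values,
                                np.r_[np.ones(n - 1, int), [0]])

    def test_all_zero_row_scores_sigmoid_intercept(self):
        model = self._toy_model()
        fm = self._fm(np.zeros((3, 2)), ["fA", "fB"])
        scores = er.predict_scores(model, fm)
        np.testing.assert_allclose(scores, 1 / (1 + np.exp(0.4)))

    def test_column_permutation_invariance(self):
        model = self._toy_model()
        rng = np.random.default_rng(0)
        v = rng.normal(size=(5, 2))
        s1 = er.predict_scores(model, self._fm(v, ["fA", "fB"]))
        s2 = er.predict_scores(model, self._fm(v[:, ::-1], ["fB", "fA"]))
        np.testing.assert_allclose(s1, s2)

    def test_absent_feature_equals_zero_filled_feature(self):
        model = self._toy_model()
        rng = np.random.default_rng(1)
        v = rng.normal(size=(5, 1))
        s_absent = er.predict_scores(model, self._fm(v, ["fA"]))
        with_zero = np.hstack([v, np.zeros((5, 1))])
        s_zero = er.predict_scores(model, self._fm(with_zero, ["fA", "fB"]))
        np.testing.assert_allclose(s_absent, s_zero)

    def test_strict_mode_escalates_many_missing(self):
        model = self._toy_model()
        fm = self._fm(np.zeros((3, 0)).reshape(3, 0), [])
        with pytest.raises(DataError):
            er.predict_scores(model, fm, strict=True)

    def test_standardized_input_rejected(self, recovery_run):
        model, fm = recovery_run["model"], recovery_run["fm_kept"]
        with pytest.raises(ValidationError):
            er.predict_scores(model, fm)  # fm already standardized


class TestPrs:
    def _gm(self):
        return er.GenotypeMatrix(
            ["s1", "s2", "s3"], ["rs1", "rs2"],
            np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]]),
            {"rs1": "A", "rs2": "C"}, {"rs1": "G", "rs2": "T"},
            np.array([1, 1, 0]))

    def test_single_snp_unit_beta_returns_dosages(self):
        gm = self._gm()
        scores = er.compute_prs(gm, {"rs1": 1.0}, {"rs1": "A"})
        np.testing.assert_allclose(scores, [0.0, 1.0, 2.0])

    def test_allele_flip_negates_contribution(self):
        gm = self._gm()
        beta = {"rs1": 0.7}
        direct = er.compute_prs(gm, beta, {"rs1": "A"})
        flipped = er.compute_prs(gm, beta, {"rs1": "G"})  # other allele
        # score with flip = beta*(2 - d) = 2*beta - score without
        np.testing.assert_allclose(flipped, 2 * 0.7 - direct)

    def test_zero_betas_constant_scores_auc_half(self):
        gm = self._gm()
        scores = er.compute_prs(gm, {"rs1": 0.0, "rs2": 0.0})
        assert (scores == scores[0]).all()
        assert er.auc(scores, gm.labels) == 0.5

    def test_no_overlap_fatal(self):
        with pytest.raises(DataError):
            er.compute_prs(self._gm(), {"rs99": 1.0})
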