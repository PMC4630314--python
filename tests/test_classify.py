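import numpy as np
import pytest

import sicenet as sn
from sicenet.classify import _orient_pair
from sicenet.types import FeatureMatrix


def make_features(values, labels, modality="PET"):
    values = np.asarray(values, float)
    return FeatureMatrix(
        values=values,
        labels=np.asarray(labels, dtype=object),
        region_ids=tuple(range(1, values.shape[1] + 1)),
        modality=modality,
    )


class TestRegressionCoefficients:
    def test_diagonal_precision_gives_zero_beta(self):
        beta = sn.regression_coefficients(np.diag([2.0, 3.0, 4.0]))
        np.testing.assert_allclose(beta, 0.0)

    def test_two_by_two_arithmetic(self):
        beta = sn.regression_coefficients(np.array([[2.0, -1.0], [-1.0, 2.0]]))
        np.testing.assert_allclose(beta, [[0.0, 0.5], [0.5, 0.0]])

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ValueError):
            sn.regression_coefficients(np.array([[0.0, 0.0], [0.0, 1.0]]))

    def test_matches_least_squares_on_simulated_data(self, truth10):
        f = sn.sample_subjects(truth10, 10000, seed=3)
        beta = sn.regression_coefficients(truth10.theta_by_group["CN"])
        x = f.values - f.values.mean(axis=0)
        i = 0
        others = np.delete(np.arange(10), i)
        coef, *_ = np.linalg.lstsq(x[:, others], x[:, i], rcond=None)
        np.testing.assert_allclose(beta[i, others], coef, atol=0.05)


class TestReconstructionErrors:
    def _models(self, p, beta_a, beta_b):
        return sn.ClassModels(beta_by_class={"CN": beta_a, "AD": beta_b}, class_order=("CN", "AD"))

    def test_zero_beta_returns_features(self):
        f = make_features([[1.0, 2.0, 3.0]], ["CN"])
        models = self._models(3, np.zeros((3, 3)), np.zeros((3, 3)))
        res = sn.reconstruction_errors(f, models)
        np.testing.assert_allclose(res.residuals_by_class["CN"], f.values)
        assert res.concatenated.shape == (1, 6)

    def test_exact_fit_gives_zero_residual(self):
        beta = np.array([[0.0, 0.5], [0.5, 0.0]])
        f = make_features([[1.0, 2.0]], ["CN"])  # f1 = 0.5*f2 requires f=(1,2)
        models = self._models(2, beta, beta)
        res = sn.reconstruction_errors(make_features([[2.0, 4.0]], ["CN"]), models)
        # f1 - 0.5 f2 = 0 and f2 - 0.5 f1 = 3: only region 1 reconstructs
        np.testing.assert_allclose(res.residuals_by_class["CN"][0, 0], 0.0)

    def test_residual_variance_matches_precision_diagonal(self, truth10):
        f = sn.sample_subjects(truth10, 10000, seed=6)
        theta = truth10.theta_by_group["CN"]
        beta = sn.regression_coefficients(theta)
        models = self._models(10, beta, beta)
        res = sn.reconstruction_errors(f, models)
        var = res.residuals_by_class["CN"].var(axis=0)
        np.testing.assert_allclose(var, 1.0 / np.diag(theta), rtol=0.05)

    def test_own_class_residuals_dominate(self):
        truth = sn.default_scenario(seed=9)
        f = sn.sample_subjects(truth, 300, seed=10)
        beta = {g: sn.regression_coefficients(truth.theta_by_group[g]) for g in ("CN", "AD")}
        for g in ("CN", "AD"):
            other = "AD" if g == "CN" else "CN"
            x = f.group(g)
            x = x - x.mean(axis=0)
            own = (x - x @ beta[g].T) ** 2
            cross = (x - x @ beta[other].T) ** 2
            assert own.mean() <= cross.mean()


class TestTrainSvm:
    def test_two_point_geometry(self):
        x = np.array([[0.0, 0.0], [2.0, 0.0]])
        labels = np.array(["CN", "AD"], dtype=object)
        clf = sn.train_svm(x, labels, ("CN", "AD"))
        w = clf.weight_vector
        assert w[0] > 0 and abs(w[1]) < 1e-8
        np.testing.assert_allclose(clf.decision_scores(np.array([[1.0, 0.0]])), 0.0, atol=1e-8)

    def test_dual_reconstruction_matches_primal_weights(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 1, (20, 5)), rng.normal(1.5, 1, (20, 5))])
        labels = np.array(["CN"] * 20 + ["AD"] * 20, dtype=object)
        clf = sn.train_svm(x, labels, ("CN", "AD"))
        np.testing.assert_allclose(clf.dual_weight_vector(), clf.weight_vector, atol=1e-6)

    def test_duplicating_points_keeps_hyperplane(self):
        # separable data, effectively hard margin: the maximal-margin
        # hyperplane depends only on the support set, not multiplicity
        rng = np.random.default_rng(1)
        x = np.vstack([rng.normal(0, 0.3, (15, 3)), rng.normal(4, 0.3, (15, 3))])
        labels = np.array(["CN"] * 15 + ["AD"] * 15, dtype=object)
        a = sn.train_svm(x, labels, ("CN", "AD"), soft_margin=1e6)
        b = sn.train_svm(np.vstack([x, x]), np.concatenate([labels, labels]), ("CN", "AD"), soft_margin=1e6)
        np.testing.assert_allclose(a.weight_vector, b.weight_vector, atol=1e-5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sn.train_svm(np.zeros((4, 2)), np.array(["CN"] * 4, dtype=object), ("CN", "AD"))

    def test_worse_group_is_positive_class(self):
        assert _orient_pair(("CN", "AD")) == ("CN", "AD")
        assert _orient_pair(("AD", "MCI")) == ("MCI", "AD")
        assert _orient_pair(("MCI", "CN")) == ("CN", "MCI")


class TestEvaluateMetrics:
    def test_perfect_separation(self):
        scores = np.array([-2.0, -1.0, 1.0, 2.0])
        truth = np.array(["CN", "CN", "AD", "AD"])
        m = sn.evaluate_metrics(scores, truth, positive="AD")
        assert m["accuracy"] == 1.0 and m["auc"] == 1.0

    def test_confusion_count_arithmetic(self):
        # TP=3, FN=1, TN=2, FP=2
        scores = np.array([1, 1, 1, -1, 1, 1, -1, -1], dtype=float)
        truth = np.array(["AD", "AD", "AD", "AD", "CN", "CN", "CN", "CN"])
        m = sn.evaluate_metrics(scores, truth, positive="AD")
        assert m["sensitivity"] == 0.75
        assert m["specificity"] == 0.5

    def test_random_scores_give_chance_auc(self):
        rng = np.random.default_rng(2)
        aucs = []
        for _ in range(2000):
            scores = rng.standard_normal(20)
            truth = np.array(["AD"] * 10 + ["CN"] * 10)
            aucs.append(sn.evaluate_metrics(scores, truth, positive="AD")["auc"])
        assert abs(np.mean(aucs) - 0.5) < 0.02

    def test_single_class_auc_not_available(self):
        m = sn.evaluate_metrics(np.array([1.0, 2.0]), np.array(["AD", "AD"]), positive="AD")
        assert np.isnan(m["auc"])


class TestRankRegions:
    def _clf(self, w):
        return sn.TrainedClassifier(
            weight_vector=np.asarray(w, float), bias=0.0,
            support_vectors=np.zeros((1, len(w))), dual_signed_alphas=np.zeros(1),
            classes=("CN", "AD"), regularization=1.0,
        )

    def test_single_nonzero_combined_weight(self):
        w = np.zeros(84)
        w[4] = 2.0  # region 5, class-A slot
        r = sn.rank_regions(self._clf(w), 42)
        assert r.rescaled[4] == 42.0
        assert (np.delete(r.rescaled, 4) == 1.0).all()

    def test_rescale_spans_one_to_p(self):
        rng = np.random.default_rng(3)
        r = sn.rank_regions(self._clf(rng.standard_normal(20)), 10)
        assert r.rescaled.min() == 1.0 and r.rescaled.max() == 10.0

    def test_all_equal_weights_degenerate(self):
        r = sn.rank_regions(self._clf(np.ones(10)), 5)
        assert (r.rescaled == 1.0).all()

    def test_planted_regions_top_ranked(self, partition10):
        # only regions 3 and 7 differ between groups (mean shift)
        truth = sn.make_group_precision(
            partition10, seed=2, groups=("CN", "AD"),
            mean_shifts={"AD": {3: -1.5, 7: -1.5}},
        )
        f = sn.sample_subjects(truth, 100, seed=3)
        models = sn.class_models(f, ("CN", "AD"), target_arcs=15)
        res = sn.reconstruction_errors(f, models)
        clf = sn.train_svm(res.concatenated, f.labels, ("CN", "AD"))
        ranking = sn.rank_regions(clf, 10)
        assert set(ranking.top(2)) == {3, 7}


class TestCrossValidate:
    def test_fold_partition_contract(self, truth10):
        truth = sn.make_group_precision(truth10.partition, seed=1, groups=("CN", "AD"),
                                        mean_shifts={"AD": {1: -1.0}})
        f = sn.sample_subjects(truth, 20, seed=2)
        rep = sn.cross_validate(f, ("CN", "AD"), target_arcs=10, k=4, seed=0)
        folds = rep.fold_assignments
        assert (folds >= 0).all()
        for fold in range(4):
            members = f.labels[folds == fold]
            assert (members == "CN").sum() == 5 and (members == "AD").sum() == 5

    def test_class_smaller_than_k_rejected(self, truth10):
        truth = sn.make_group_precision(truth10.partition, seed=1, groups=("CN", "AD"))
        f = sn.sample_subjects(truth, 5, seed=2)
        with pytest.raises(ValueError, match="smaller than k"):
            sn.cross_validate(f, ("CN", "AD"), k=10)

    def test_multimodal_concatenation_not_worse_than_single(self, partition10):
        truth = sn.make_group_precision(
            partition10, seed=4, groups=("CN", "AD"),
            mean_shifts={"AD": {2: -1.2, 5: -1.2}},
        )
        pet = sn.sample_subjects(truth, 50, seed=5)
        gm_truth = sn.make_group_precision(
            partition10, seed=6, groups=("CN", "AD"),
            mean_shifts={"AD": {8: -1.2, 9: -1.2}},
        )
        gm = sn.sample_subjects(gm_truth, 50, seed=7)
        gm.modality = "GM"
        acc_pet = sn.cross_validate(pet, ("CN", "AD"), target_arcs=10, k=5, seed=1).accuracy
        acc_gm = sn.cross_validate(gm, ("CN", "AD"), target_arcs=10, k=5, seed=1).accuracy
        acc_both = sn.cross_validate([pet, gm], ("CN", "AD"), target_arcs=10, k=5, seed=1).accuracy
        assert acc_both >= max(acc_pet, acc_gm) - 0.05
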