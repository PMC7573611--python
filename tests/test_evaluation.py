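import numpy as np
import pytest

import represp as rp
from represp import evaluation as ev
from represp.feedback import REGRESSION, ResponseMatrix
from represp.predictors import RepModel


def brute_force_auc(y, s):
    pos = s[y == 1]
    neg = s[y == -1]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAccuracy:
    def test_perfect_and_hand_counted(self):
        assert rp.accuracy([1, -1, 1], [1, -1, 1]) == 1.0
        assert rp.accuracy([1, 1, -1, -1], [1, -1, -1, 1]) == 0.5

    def test_base_rate_of_constant_predictor(self):
        y = np.array([1] * 7 + [-1] * 3)
        assert rp.accuracy(y, np.ones(10)) == pytest.approx(0.7)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rp.accuracy([], [])


class TestAuc:
    def test_trivial_cases(self):
        assert rp.auc([1, -1, 1, -1], [1, -1, 1, -1]) == 1.0
        assert rp.auc([1, -1, 1, -1], [0.3, 0.3, 0.3, 0.3]) == 0.5

    def test_hand_enumerated_pairs(self):
        y = np.array([1, -1, 1, -1])
        s = np.array([0.9, 0.8, 0.3, 0.1])
        assert rp.auc(y, s) == pytest.approx(0.75)
        assert rp.auc(y, s) == pytest.approx(brute_force_auc(y, s))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            rp.auc([1, 1], [0.5, 0.4])

    def test_matches_pair_counting_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(4, 60))
            y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
            if len(np.unique(y)) < 2:
                continue
            s = rng.integers(0, 5, size=n).astype(float)  # many ties
            assert rp.auc(y, s) == pytest.approx(brute_force_auc(y, s), abs=1e-12)


class TestRegressionMetrics:
    def test_perfect_predictions(self):
        mse, mae, _ = rp.regression_metrics(np.array([[1.0, 2.0]]), np.array([[1.0, 2.0]]))
        assert (mse, mae) == (0.0, 0.0)

    def test_hand_computation(self):
        mse, mae, per_time = rp.regression_metrics(
            np.array([[2.0, 4.0]]), np.array([[3.0, 2.0]]))
        assert mse == pytest.approx(2.5)
        assert mae == pytest.approx(1.5)
        assert per_time["mse"].tolist() == [1.0, 4.0]

    def test_constant_predictor_approaches_variance(self):
        rng = np.random.default_rng(1)
        y = rng.normal(3.0, 2.0, size=(1000, 1))
        mse, _, _ = rp.regression_metrics(y, np.full_like(y, y.mean()))
        assert mse == pytest.approx(4.0, rel=0.15)

    def test_paper_mse_scales_by_patients_only(self):
        Y = np.array([[1.0, 2.0], [3.0, 4.0]])
        P = np.zeros((2, 2))
        assert rp.paper_mse(Y, P) == pytest.approx((1 + 4 + 9 + 16) / 2)

    def test_no_scored_pairs_rejected(self):
        with pytest.raises(ValueError, match="no scored"):
            rp.regression_metrics(np.full((2, 2), np.nan), np.zeros((2, 2)))


class TestInjectMissingness:
    def test_zero_fraction_is_identity(self, small_cohort):
        t = rp.inject_missingness(small_cohort.tensor, 0.0, seed=1)
        np.testing.assert_array_equal(t.mask, small_cohort.tensor.mask)

    def test_exact_count_hidden(self):
        c = rp.generate_cohort(I=27, J=76, K=7, noise_sd=0.0, miss_frac=0.0, seed=0)
        t = rp.inject_missingness(c.tensor, 0.2, seed=5)
        assert t.n_observed == 27 * 76 * 7 - int(0.2 * 27 * 76 * 7)

    def test_same_seed_same_mask(self, small_cohort):
        t1 = rp.inject_missingness(small_cohort.tensor, 0.3, seed=9)
        t2 = rp.inject_missingness(small_cohort.tensor, 0.3, seed=9)
        np.testing.assert_array_equal(t1.mask, t2.mask)

    def test_infeasible_fraction_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            rp.inject_missingness(small_cohort.tensor, 0.999, seed=0)


class TestImputeBaseline:
    def make(self, missing_at=(0, 0, 0)):
        vals = np.array([
            [[1.0, 5.0]], [[3.0, 5.0]], [[2.0, 9.0]],
        ])  # 3 patients x 1 gene x 2 times
        mask = np.ones_like(vals, dtype=bool)
        mask[missing_at] = False
        return rp.GexTensor(vals, mask)

    def test_mean_and_median_fill(self):
        t = self.make()
        assert rp.impute_baseline(t, "mean").values[0, 0, 0] == pytest.approx(2.5)
        assert rp.impute_baseline(t, "median").values[0, 0, 0] == pytest.approx(2.5)

    def test_median_of_three(self):
        vals = np.array([[[1.0]], [[2.0]], [[9.0]], [[5.0]]])
        mask = np.ones_like(vals, dtype=bool)
        mask[3] = False
        t = rp.GexTensor(vals, mask)
        assert rp.impute_baseline(t, "median").values[3, 0, 0] == pytest.approx(2.0)

    def test_knn_with_identical_twin(self):
        rng = np.random.default_rng(2)
        base = rng.random((1, 4, 3))
        vals = np.concatenate([base, base, 5 + rng.random((3, 4, 3))])
        mask = np.ones_like(vals, dtype=bool)
        mask[0, 2, 1] = False
        t = rp.GexTensor(vals, mask)
        out = rp.impute_baseline(t, "knn", k=1)
        assert out.values[0, 2, 1] == pytest.approx(base[0, 2, 1])

    def test_unsupported_method_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="unsupported"):
            rp.impute_baseline(small_cohort.tensor, "magic")


class TestRankGenes:
    def mk(self, u):
        u = np.asarray(u, dtype=float)
        return RepModel(u, np.zeros(2), 0.0, 1.0, 0.1, "classification", "rep_svm", u.size)

    def test_orders_by_magnitude_keeping_sign(self):
        out = rp.rank_genes([self.mk([0.1, -5.0, 2.0])], top_n=2,
                            gene_names=["a", "b", "c"])
        assert out == [("b", -5.0), ("c", 2.0)]

    def test_averaged_zero_ranks_last(self):
        ms = [self.mk([1.0, 1.0, 1.0]), self.mk([-1.0, 1.0, 1.0])]
        out = rp.rank_genes(ms, top_n=3)
        assert out[-1][0] == "G0" and out[-1][1] == 0.0

    def test_mixed_gene_orders_rejected(self):
        with pytest.raises(ValueError, match="gene order"):
            rp.rank_genes([self.mk([1.0, 2.0]), self.mk([1.0, 2.0, 3.0])], top_n=1)

    def test_planted_driver_gene_recovered(self):
        hits = 0
        for seed in range(20):
            c = rp.generate_cohort(I=20, J=20, K=5, F=2, noise_sd=0.5, miss_frac=0.0,
                                   response_params={"n_informative": 1, "u_norm": 3.0,
                                                    "eps_sd": 0.1, "feedback_weight": 0.5},
                                   seed=seed)
            fb = rp.build_feedback_tensor(c.responses)
            d = rp.assemble_training_design(c.tensor, fb, c.responses, rho=100.0)
            try:
                m = rp.train_rep_svm(d, lam=0.1)
            except ValueError:  # degenerate single-class draw
                continue
            top = rp.rank_genes([m], 1)
            hits += top[0][0] == f"G{int(np.argmax(np.abs(c.u_true)))}"
        assert hits >= 18


class TestLooCv:
    def test_fold_count_equals_patients_and_no_self_training(self, monkeypatch):
        c = rp.generate_cohort(I=6, J=8, K=4, F=2, noise_sd=0.05, miss_frac=0.1, seed=3)
        seen = []
        orig = ev.fit_cp_completion

        def spy(tensor, *a, **k):
            seen.append(list(tensor.patient_ids))
            return orig(tensor, *a, **k)

        monkeypatch.setattr(ev, "fit_cp_completion", spy)
        res = rp.loo_cv(c.tensor, c.responses, rp.EstimatorSpec("rep_svm"),
                        rp.CompletionSettings(rank=2, mu=0.1), seed=0)
        assert len(res.folds) == 6
        for fold, ids in zip(res.folds, seen):
            assert fold.patient_id not in ids  # completion never sees the test patient

    def test_null_cohort_accuracy_near_chance(self):
        accs = []
        for seed in range(20):
            c = rp.generate_cohort(I=5, J=6, K=4, F=2, noise_sd=0.05, miss_frac=0.0,
                                   response_params={"u_norm": 0.0, "feedback_weight": 0.0,
                                                    "eps_sd": 1.0}, seed=seed)
            try:
                r = rp.loo_cv(c.tensor, c.responses,
                              rp.EstimatorSpec("rep_svm", grid=[{"lam": 0.1, "rho": 50.0}]),
                              None, seed=seed)
            except ValueError:  # a fold with single-class training labels
                continue
            accs.append(r.aggregate["acc"])
        assert abs(np.mean(accs) - 0.5) < 0.12

    def test_aggregate_recomputable_from_folds(self, small_cohort):
        c = small_cohort
        res = rp.loo_cv(c.tensor, c.responses,
                        rp.EstimatorSpec("rep_svm", grid=[{"lam": 0.1, "rho": 100.0}]),
                        None, seed=1)
        truths, preds, _ = res.scored_pairs()
        assert res.aggregate["acc"] == pytest.approx(rp.accuracy(truths, preds))

    def test_regression_reports_stratified_errors(self):
        c = rp.generate_cohort(I=8, J=8, K=4, F=2, noise_sd=0.05, miss_frac=0.0,
                               task=REGRESSION, seed=2)
        res = rp.loo_cv(c.tensor, c.responses, rp.EstimatorSpec("rep_svr", REGRESSION),
                        None, seed=0)
        assert {"mse", "mae", "paper_mse"} <= set(res.aggregate)
        assert len(res.aggregate["per_time"]) == 4

    def test_too_few_patients_rejected(self, small_cohort):
        t = small_cohort.tensor.subset_patients([0, 1])
        Y = ResponseMatrix(small_cohort.responses.values[:2])
        with pytest.raises(ValueError, match="at least 3"):
            rp.loo_cv(t, Y, rp.EstimatorSpec("rep_svm"), None)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rp.EstimatorSpec("rep_svm", grid=[])
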