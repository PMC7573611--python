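import numpy as np
import pytest

import represp as rp
from conftest import hinge_qp_oracle
from represp.feedback import REGRESSION, ResponseMatrix, TrainingDesign
from represp.predictors import RepEstimator, RepModel, hinge_objective


def make_design(X, y, J, rho=1.0, task="classification"):
    return TrainingDesign(np.asarray(X, float), np.asarray(y, float),
                          [(n, 0) for n in range(len(y))], rho, J, task)


SEPARABLE = make_design(
    [[2.0, 0.0, 0.0], [3.0, 0.5, 0.0], [-2.0, 0.0, 0.0], [-3.0, -0.5, 0.0]],
    [1, 1, -1, -1], J=2)


class TestTrainRepSvm:
    def test_separable_toy_has_zero_hinge_loss(self):
        m = rp.train_rep_svm(SEPARABLE, lam=0.01)
        w = np.concatenate([m.u, m.v])
        obj = hinge_objective(SEPARABLE.features, SEPARABLE.labels, w, m.intercept, 0.01)
        assert obj == pytest.approx(0.5 * 0.01 * np.dot(w, w), rel=1e-6)
        for x, y in zip(SEPARABLE.features, SEPARABLE.labels):
            lab, _ = rp.predict_response(m, x[:2], x[2:])
            assert lab == y

    def test_zero_feedback_block_matches_baseline(self, small_cohort):
        c = small_cohort
        fb = rp.build_feedback_tensor(c.responses)
        d = rp.assemble_training_design(c.tensor, fb, c.responses, rho=100.0)
        d0 = TrainingDesign(
            np.concatenate([d.gene_block, np.zeros_like(d.feedback_block)], axis=1),
            d.labels, d.row_index, d.rho, d.feature_split, d.task)
        m = rp.train_rep_svm(d0, lam=0.2)
        b = rp.train_baseline_svm(d.gene_block, d.labels, lam=0.2)
        np.testing.assert_allclose(m.u, b.u, atol=1e-5)
        assert m.intercept == pytest.approx(b.intercept, abs=1e-5)
        assert np.abs(m.v).max() < 1e-8

    def test_matches_convex_solver_on_30_rows(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 8))
        y = np.where(rng.random(30) < 0.5, -1.0, 1.0)
        d = make_design(X, y, J=5, rho=100.0)
        m = rp.train_rep_svm(d, lam=0.1)
        ours = hinge_objective(X, y, np.concatenate([m.u, m.v]), m.intercept, 0.1)
        oracle = hinge_qp_oracle(X, y, 0.1)
        assert abs(ours - oracle) / oracle < 1e-4

    def test_single_class_rejected_with_counts(self):
        d = make_design([[1.0, 0.0], [2.0, 0.0]], [1, 1], J=2)
        with pytest.raises(ValueError, match="2 positive, 0 negative"):
            rp.train_rep_svm(d, lam=0.1)

    def test_l1_ball_constraint_enforced(self):
        m = rp.train_rep_svm(SEPARABLE, lam=0.01, l1_radius=0.5)
        assert np.abs(np.concatenate([m.u, m.v])).sum() <= 0.5 + 1e-12


class TestBaselineSvm:
    @pytest.mark.parametrize("lam", [0.01, 0.1, 1.0, 10.0])
    def test_lambda_grid_accepted(self, lam):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 4))
        y = np.where(rng.random(20) < 0.5, -1.0, 1.0)
        m = rp.train_baseline_svm(X, y, lam)
        assert m.u.shape == (4,) and m.v.size == 0

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(24, 5))
        y = np.where(rng.random(24) < 0.5, -1.0, 1.0)
        m1 = rp.train_baseline_svm(X, y, 0.5)
        m2 = rp.train_baseline_svm(X, -y, 0.5)
        np.testing.assert_allclose(m1.u, -m2.u, atol=1e-6)
        assert m1.intercept == pytest.approx(-m2.intercept, abs=1e-6)


class TestPredictResponse:
    def test_constant_positive_intercept(self):
        m = RepModel(np.zeros(2), np.zeros(1), 0.5, 10.0, 0.1, "classification", "rep_svm", 2)
        lab, score = rp.predict_response(m, [7.0, -3.0], [1.0])
        assert (lab, score) == (1.0, 0.5)

    def test_hand_evaluated_linear_rule(self):
        m = RepModel(np.array([1.0, 0.0]), np.array([2.0]), 0.0, 10.0, 0.1,
                     "classification", "rep_svm", 2)
        lab, score = rp.predict_response(m, [0.3, 9.0], [-1.0])
        assert score == pytest.approx(0.3 + 10 * 2 * (-1))
        assert lab == -1.0

    def test_tie_at_zero_predicts_positive(self):
        m = RepModel(np.zeros(1), np.zeros(1), 0.0, 1.0, 0.1, "classification", "rep_svm", 1)
        assert rp.predict_response(m, [5.0], [0.0])[0] == 1.0

    def test_length_mismatch_rejected(self):
        m = RepModel(np.zeros(3), np.zeros(2), 0.0, 1.0, 0.1, "classification", "rep_svm", 3)
        with pytest.raises(ValueError, match="length"):
            rp.predict_response(m, [1.0, 2.0], [0.0, 0.0])

    def test_model_archive_round_trip(self, tmp_path, trained_rep):
        m, _ = trained_rep
        path = tmp_path / "model.npz"
        m.save(path)
        m2 = RepModel.load(path)
        np.testing.assert_array_equal(m.u, m2.u)
        np.testing.assert_array_equal(m.v, m2.v)
        assert (m2.rho, m2.lam, m2.task) == (m.rho, m.lam, m.task)


class TestRepWrap:
    def test_unknown_learner_rejected(self):
        with pytest.raises(ValueError, match="unknown base learner"):
            rp.rep_wrap({"name": "rep_deepnet", "task": "classification"})

    def test_knn_learns_alternating_sequence_from_feedback(self):
        # strictly alternating labels: the previous response determines the
        # next one exactly, and only the feedback coordinate separates rows
        I, J, K = 12, 3, 6
        rng = np.random.default_rng(0)
        Z = rp.GexTensor(np.full((I, J, K), 1.0) + 0.01 * rng.random((I, J, K)),
                         np.ones((I, J, K), dtype=bool))
        start = np.where(np.arange(I) % 2 == 0, 1.0, -1.0)
        Yv = np.array([[s * (-1.0) ** t for t in range(K)] for s in start])
        Y = ResponseMatrix(Yv)
        est = rp.rep_wrap({"name": "rep_knn", "task": "classification",
                           "n_neighbors": 10}, rho=1.0)
        fb = rp.build_feedback_tensor(Y)
        est.fit(rp.assemble_training_design(Z, fb, Y, rho=1.0))
        for i in range(I):
            preds, _ = rp.predict_patient_course(est, Z.values[i], Yv[i])
            np.testing.assert_array_equal(preds[1:], Yv[i][1:])

    def test_randomforest_and_svr_specs_accepted(self):
        est = rp.rep_wrap({"name": "rep_randomforest", "task": REGRESSION,
                           "n_estimators": 20})
        assert est.params["n_estimators"] == 20
        est = rp.rep_wrap({"name": "rep_svr", "task": REGRESSION})
        assert est.task == REGRESSION and est.with_feedback

    def test_deterministic_given_seed(self, small_cohort):
        c = small_cohort
        fb = rp.build_feedback_tensor(c.responses)
        d = rp.assemble_training_design(c.tensor, fb, c.responses, rho=1.0)
        out = []
        for _ in range(2):
            est = RepEstimator("randomforest", "classification", 1.0, seed=3,
                               n_estimators=10)
            est.fit(d)
            out.append([est.predict(c.tensor.values[i, :, 0], np.zeros(4))[0]
                        for i in range(12)])
        assert out[0] == out[1]

    def test_elasticnet_exposes_linear_weights(self, small_cohort):
        c = small_cohort
        fb = rp.build_feedback_tensor(c.responses)
        d = rp.assemble_training_design(c.tensor, fb, c.responses, rho=1.0)
        est = RepEstimator("elasticnet", "classification", 1.0)
        est.fit(d)
        assert est.model.u.shape == (10,)


class TestRhoZeroLimit:
    def test_tiny_rho_reproduces_baseline_predictions(self, small_cohort):
        c = small_cohort
        fb = rp.build_feedback_tensor(c.responses)
        d = rp.assemble_training_design(c.tensor, fb, c.responses, rho=1e-8)
        m_rep = rp.train_rep_svm(d, lam=0.2)
        m_base = rp.train_baseline_svm(d.gene_block, d.labels, lam=0.2)
        for i in range(c.tensor.shape[0]):
            for t in range(c.tensor.shape[2]):
                z = c.tensor.values[i, :, t]
                yt = fb.values[i, t]
                lab_r, _ = rp.predict_response(m_rep, z, yt)
                lab_b, _ = rp.predict_response(m_base, z, np.zeros(0))
                assert lab_r == lab_b
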