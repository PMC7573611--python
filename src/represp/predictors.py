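"""Max-margin recursive predictors and wrapped base learners.

The recursive SVM (REP-SVM) minimises

    (1/N) sum_n max(0, 1 - y_n (u.z_n + rho v.ytilde_n + b))
        + (lambda/2) (||u||^2 + ||v||^2)

over gene weights u, feedback weights v and an unpenalized intercept b,
where N is the number of training rows. Because the training design carries
the feedback block pre-scaled by rho, this is an ordinary linear hinge-loss
SVM on the design: the exact libsvm solver is used with the conversion
C = 1 / (lambda * N) between the two parameterizations (libsvm solves
(1/2)||w||^2 + C sum hinge with an unpenalized intercept; multiplying our
objective by 1/lambda shows the optima coincide).

The same feedback construction wraps any scikit-learn base learner
(elastic net, SVR, random forest, k-nearest-neighbours) for classification
or regression — the framework is learner-agnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import ElasticNet, LogisticRegression
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.svm import SVC, SVR

from .feedback import CLASSIFICATION, REGRESSION, TrainingDesign, build_feedback_vector

__all__ = [
    "RepModel",
    "RepEstimator",
    "train_rep_svm",
    "train_baseline_svm",
    "rep_wrap",
    "predict_response",
    "hinge_objective",
    "predict_patient_course",
]


@dataclass
class RepModel:
    """A trained recursive predictor.

    For linear bases the decision score of an input pair (z, ytilde) is
    ``u.z + rho * v.ytilde + intercept``; non-linear bases keep their fitted
    scikit-learn estimator in ``fitted_state``.
    """

    u: Optional[np.ndarray]
    v: Optional[np.ndarray]
    intercept: float
    rho: float
    lam: Optional[float]
    task: str
    base: str
    feature_split: int
    fitted_state: object = field(default=None, repr=False)

    @property
    def is_linear(self) -> bool:
        return self.u is not None

    def save(self, path):
        if not self.is_linear:
            raise ValueError(f"only linear models serialize to archives (base={self.base})")
        np.savez(
            path, u=self.u, v=self.v, intercept=self.intercept, rho=self.rho,
            lam=np.nan if self.lam is None else self.lam, task=self.task,
            base=self.base, feature_split=self.feature_split,
        )

    @classmethod
    def load(cls, path) -> "RepModel":
        with np.load(path) as z:
            lam = float(z["lam"])
            return cls(
                z["u"], z["v"], float(z["intercept"]), float(z["rho"]),
                None if np.isnan(lam) else lam, str(z["task"]), str(z["base"]),
                int(z["feature_split"]),
            )


def hinge_objective(X: np.ndarray, y: np.ndarray, w: np.ndarray, b: float, lam: float) -> float:
    """(1/N) sum hinge + (lam/2) ||w||^2 on an already-scaled design."""
    margins = y * (X @ w + b)
    return float(np.mean(np.maximum(0.0, 1.0 - margins)) + 0.5 * lam * np.dot(w, w))


def _project_l1(w: np.ndarray, radius: float) -> np.ndarray:
    """Euclidean projection onto the l1 ball of the given radius."""
    if np.abs(w).sum() <= radius:
        return w
    u = np.sort(np.abs(w))[::-1]
    css = np.cumsum(u)
    k = np.nonzero(u * np.arange(1, len(u) + 1) > css - radius)[0][-1]
    tau = (css[k] - radius) / (k + 1.0)
    return np.sign(w) * np.maximum(np.abs(w) - tau, 0.0)


def _check_two_classes(y: np.ndarray):
    pos, neg = int(np.sum(y == 1)), int(np.sum(y == -1))
    if pos == 0 or neg == 0:
        raise ValueError(
            f"training labels contain a single class ({pos} positive, {neg} negative)"
        )


def _fit_linear_hinge(X: np.ndarray, y: np.ndarray, lam: float, tol: float = 1e-8):
    """Exact linear hinge-loss fit; returns (w, b)."""
    _check_two_classes(y)
    if lam <= 0:
        raise ValueError("lam must be > 0")
    N = X.shape[0]
    C = 1.0 / (lam * N)
    # iteration cap guards against rare libsvm stalls on badly scaled folds;
    # it is far beyond what the exactness checks need
    svc = SVC(kernel="linear", C=C, tol=tol, max_iter=200_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        svc.fit(X, y)
    return svc.coef_[0].copy(), float(svc.intercept_[0])


def train_rep_svm(design: TrainingDesign, lam: float, l1_radius: float = None) -> RepModel:
    """Train the recursive hinge-loss SVM on a rho-scaled design."""
    if design.task != CLASSIFICATION:
        raise ValueError("train_rep_svm requires a classification design")
    w, b = _fit_linear_hinge(design.features, design.labels, lam)
    if l1_radius is not None:
        w = _project_l1(w, l1_radius)
    J = design.feature_split
    return RepModel(w[:J], w[J:], b, design.rho, lam, CLASSIFICATION, "rep_svm", J)


def train_baseline_svm(Z_rows: np.ndarray, labels, lam: float) -> RepModel:
    """Hinge-loss linear SVM on gene features only (no feedback)."""
    Z_rows = np.asarray(Z_rows, dtype=float)
    labels = np.asarray(labels, dtype=float)
    w, b = _fit_linear_hinge(Z_rows, labels, lam)
    J = Z_rows.shape[1]
    return RepModel(w, np.zeros(0), b, 1.0, lam, CLASSIFICATION, "svm", J)


def predict_response(model: RepModel, z: np.ndarray, ytilde: np.ndarray):
    """Predict one response from an expression fiber and a feedback vector.

    Returns ``(label, score)`` for classification (tie at score 0 -> +1) and
    ``(value, value)`` for regression.
    """
    z = np.asarray(z, dtype=float)
    ytilde = np.asarray(ytilde, dtype=float)
    if z.shape != (model.feature_split,):
        raise ValueError(f"expression vector length {z.size} != {model.feature_split}")
    if model.is_linear:
        if model.v.size and ytilde.shape != (model.v.size,):
            raise ValueError(f"feedback vector length {ytilde.size} != {model.v.size}")
        score = float(model.u @ z + model.rho * (model.v @ ytilde if model.v.size else 0.0)
                      + model.intercept)
    else:
        est, with_fb, n_fb = model.fitted_state
        if with_fb and ytilde.shape != (n_fb,):
            raise ValueError(f"feedback vector length {ytilde.size} != {n_fb}")
        x = np.concatenate([z, model.rho * ytilde]) if with_fb else z
        x = x[None, :]
        if model.task == REGRESSION:
            score = float(est.predict(x)[0])
        elif hasattr(est, "decision_function"):
            score = float(est.decision_function(x)[0])
        else:
            score = float(est.predict_proba(x)[0, list(est.classes_).index(1.0)])
    if model.task == REGRESSION:
        return score, score
    label = 1.0 if score >= 0 else -1.0
    if not model.is_linear and not hasattr(model.fitted_state[0], "decision_function"):
        label = 1.0 if score >= 0.5 else -1.0
    return label, score


_BASES = {
    (CLASSIFICATION, "svm"),
    (CLASSIFICATION, "knn"),
    (CLASSIFICATION, "elasticnet"),
    (CLASSIFICATION, "randomforest"),
    (REGRESSION, "svr"),
    (REGRESSION, "knn"),
    (REGRESSION, "elasticnet"),
    (REGRESSION, "randomforest"),
}


class RepEstimator:
    """A base learner wrapped with (or without) the response-feedback block.

    ``fit`` consumes a :class:`TrainingDesign`; ``predict`` consumes a
    single (z, ytilde) pair. Setting ``with_feedback=False`` yields the
    identical learner trained on the gene block alone (the ablation).
    """

    def __init__(self, base: str, task: str, rho: float = 100.0, *,
                 with_feedback: bool = True, seed: int = 0, **params):
        base = base.removeprefix("rep_")
        if base == "rep" or (task, base) not in _BASES:
            raise ValueError(f"unknown base learner {base!r} for task {task!r}")
        self.base, self.task, self.rho = base, task, float(rho)
        self.with_feedback = with_feedback
        self.seed = seed
        self.params = params
        self.model: RepModel = None

    def _make(self):
        p = self.params
        if self.task == CLASSIFICATION:
            if self.base == "knn":
                return KNeighborsClassifier(n_neighbors=p.get("n_neighbors", 10))
            if self.base == "elasticnet":
                return LogisticRegression(solver="saga", l1_ratio=p.get("l1_ratio", 0.5),
                                          C=p.get("C", 1.0), max_iter=5000)
            if self.base == "randomforest":
                return RandomForestClassifier(n_estimators=p.get("n_estimators", 20),
                                              random_state=self.seed)
        else:
            if self.base == "svr":
                return SVR(**{k: v for k, v in p.items()})
            if self.base == "knn":
                return KNeighborsRegressor(n_neighbors=p.get("n_neighbors", 10))
            if self.base == "elasticnet":
                return ElasticNet(alpha=p.get("alpha", 1.0),
                                  l1_ratio=p.get("l1_ratio", 0.5), max_iter=10000)
            if self.base == "randomforest":
                return RandomForestRegressor(n_estimators=p.get("n_estimators", 20),
                                             random_state=self.seed)
        return None  # svm handled in fit

    def fit(self, design: TrainingDesign) -> "RepEstimator":
        J = design.feature_split
        X = design.features if self.with_feedback else design.gene_block
        rho = design.rho if self.with_feedback else 1.0
        if self.base == "svm":
            lam = self.params.get("lam", 0.1)
            if self.with_feedback:
                self.model = train_rep_svm(design, lam,
                                           l1_radius=self.params.get("l1_radius"))
                self.model.base = "rep_svm"
            else:
                self.model = train_baseline_svm(X, design.labels, lam)
            return self
        est = self._make()
        est.fit(X, design.labels)
        name = ("rep_" if self.with_feedback else "") + self.base
        n_fb = design.features.shape[1] - J
        if self.base == "elasticnet":
            # linear in both tasks: coefficients on the rho-scaled design give
            # score = u.z + rho*(v.ytilde) + b, identical to sklearn's
            # decision_function / predict
            coef = np.ravel(est.coef_)
            u = coef[:J].copy()
            v = coef[J:].copy() if self.with_feedback else np.zeros(0)
            b = float(np.ravel(est.intercept_)[0]) if np.size(est.intercept_) else 0.0
            self.model = RepModel(u, v, b, rho, None, self.task, name, J)
        else:
            self.model = RepModel(None, None, 0.0, rho, None, self.task, name, J,
                                  fitted_state=(est, self.with_feedback, n_fb))
        return self

    def predict(self, z, ytilde):
        if self.model is None:
            raise RuntimeError("estimator is not fitted")
        return predict_response(self.model, z, ytilde)


def rep_wrap(base_spec, rho: float = 100.0) -> RepEstimator:
    """Build a feedback-wrapped estimator from a learner spec.

    ``base_spec`` is either a learner name (``rep_svm``, ``rep_svr``,
    ``rep_elasticnet``, ``rep_randomforest``, ``rep_knn`` or their baseline
    variants without the prefix) or a dict with keys ``name``, ``task`` and
    optional hyper-parameters.
    """
    if isinstance(base_spec, str):
        base_spec = {"name": base_spec}
    spec = dict(base_spec)
    name = spec.pop("name")
    task = spec.pop("task", CLASSIFICATION if name.removeprefix("rep_") in ("svm",) else None)
    if task is None:
        task = REGRESSION if name.removeprefix("rep_") in ("svr", "elasticnet", "randomforest") else CLASSIFICATION
    with_feedback = name.startswith("rep_")
    seed = spec.pop("seed", 0)
    return RepEstimator(name, task, rho, with_feedback=with_feedback, seed=seed, **spec)


def predict_patient_course(predictor, fibers: np.ndarray, y_known: np.ndarray = None):
    """Predict one patient's whole time course, feeding responses forward.

    ``fibers`` is the patient's completed J x K expression matrix. At each
    time t the feedback history uses the actual response where ``y_known``
    provides one (finite value) and the previous prediction otherwise.

    Returns (predictions, scores), each of length K.
    """
    J, K = fibers.shape
    if y_known is None:
        y_known = np.full(K, np.nan)
    y_known = np.asarray(y_known, dtype=float)
    hist = np.full(K, np.nan)
    preds = np.zeros(K)
    scores = np.zeros(K)
    predict = predictor.predict if isinstance(predictor, RepEstimator) else (
        lambda z, yt: predict_response(predictor, z, yt))
    for t in range(K):
        ytilde = build_feedback_vector(hist[:t], K)
        preds[t], scores[t] = predict(fibers[:, t], ytilde)
        hist[t] = y_known[t] if np.isfinite(y_known[t]) else preds[t]
    return preds, scores
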