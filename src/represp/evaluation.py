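"""Metrics, leave-one-out cross-validation and baseline comparisons.

Evaluation follows a patient-level leave-one-out protocol: each fold holds
out one patient's entire time course, fits the tensor completion on the
remaining patients only, selects hyper-parameters on a single inner
validation patient, refits on the full training fold, and predicts the test
patient recursively (actual responses fed back where observed, predicted
ones otherwise). Classification is scored by accuracy and rank-based AUC;
regression by per-element MSE/MAE with per-time breakdowns.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .feedback import (
    CLASSIFICATION,
    REGRESSION,
    ResponseMatrix,
    assemble_training_design,
    build_feedback_tensor,
)
from .patient_inference import estimate_latent, complete_patient_vector
from .predictors import RepEstimator, predict_patient_course
from .tensor_model import GexTensor, complete, fit_cp_completion

logger = logging.getLogger(__name__)

__all__ = [
    "accuracy",
    "auc",
    "regression_metrics",
    "paper_mse",
    "loo_cv",
    "inject_missingness",
    "impute_baseline",
    "rank_genes",
    "EstimatorSpec",
    "CompletionSettings",
    "CvResult",
]


def accuracy(y_true, y_pred) -> float:
    """(TP + TN) / (TP + FP + FN + TN) for +/-1 labels."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if not np.all(np.isin(y, (-1.0, 1.0))):
            raise ValueError(f"{name} must contain only +1/-1 labels")
    return float(np.mean(y_true == y_pred))


def auc(y_true, scores) -> float:
    """Rank-based (Mann-Whitney) AUC; tied scores count 1/2 per pair."""
    y_true = np.asarray(y_true, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if not ((y_true == 1).any() and (y_true == -1).any()):
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y_true == 1, scores))


def regression_metrics(Y_true, Y_pred):
    """Per-element MSE and MAE over scored (patient, time) pairs.

    ``Y_true`` may be a :class:`ResponseMatrix` (its mask selects the scored
    pairs) or a plain array with NaN marking unscored entries. Returns
    ``(mse, mae, per_time)`` where ``per_time`` is a DataFrame with per-time
    columns of both metrics.
    """
    if isinstance(Y_true, ResponseMatrix):
        truth, mask = Y_true.values, Y_true.mask
    else:
        truth = np.asarray(Y_true, dtype=float)
        mask = np.isfinite(truth)
    pred = np.asarray(Y_pred, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch between truths and predictions")
    mask = mask & np.isfinite(pred)
    if not mask.any():
        raise ValueError("no scored (patient, time) pairs")
    err = np.where(mask, truth - pred, np.nan)
    mse = float(np.nanmean(err ** 2))
    mae = float(np.nanmean(np.abs(err)))
    with np.errstate(invalid="ignore"):
        per_time = pd.DataFrame({
            "mse": np.nanmean(err ** 2, axis=0),
            "mae": np.nanmean(np.abs(err), axis=0),
            "n": mask.sum(axis=0),
        })
    per_time.index.name = "time"
    return mse, mae, per_time


def paper_mse(Y_true, Y_pred) -> float:
    """Mean over patients of the squared time-course error norm.

    A literal-comparison variant whose normalization divides by the number of
    patients only (not by the number of time points, unlike the per-element
    MSE used everywhere else in this package).
    """
    if isinstance(Y_true, ResponseMatrix):
        truth, mask = Y_true.values, Y_true.mask
    else:
        truth = np.asarray(Y_true, dtype=float)
        mask = np.isfinite(truth)
    pred = np.asarray(Y_pred, dtype=float)
    err = np.where(mask & np.isfinite(pred), truth - pred, 0.0)
    return float(np.mean(np.sum(err ** 2, axis=1)))


def inject_missingness(tensor: GexTensor, fraction: float, seed: int = 0) -> GexTensor:
    """Hide exactly floor(fraction * n_observed) currently observed entries.

    Entries are chosen uniformly at random; draws that would empty a patient,
    gene or time slab are resampled, and an infeasible fraction is rejected.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_hide = int(np.floor(fraction * tensor.n_observed))
    if n_hide == 0:
        return GexTensor(tensor.values.copy(), tensor.mask.copy(),
                         list(tensor.patient_ids), list(tensor.gene_names),
                         list(tensor.time_labels))
    flat_obs = np.flatnonzero(tensor.mask)
    for _ in range(200):
        hide = rng.choice(flat_obs, size=n_hide, replace=False)
        mask = tensor.mask.copy()
        mask.flat[hide] = False
        cand = GexTensor(tensor.values, mask, list(tensor.patient_ids),
                         list(tensor.gene_names), list(tensor.time_labels))
        try:
            cand.check_slabs()
        except ValueError:
            continue
        return cand
    raise ValueError(
        f"cannot hide {n_hide} entries without emptying a patient/gene/time slab"
    )


def impute_baseline(tensor: GexTensor, method: str, k: int = 5) -> GexTensor:
    """Classical imputation baselines: per-(gene, time) mean/median or patient-KNN.

    ``mean`` / ``median`` replace each missing entry by the statistic of the
    other patients at the same (gene, time) coordinate; ``knn`` fills each
    patient's missing entries from its k nearest patients by Euclidean
    distance over commonly observed coordinates. A coordinate with no
    observations anywhere falls back to the global observed mean (logged).
    """
    if method not in ("mean", "median", "knn"):
        raise ValueError(f"unsupported imputation method {method!r}")
    vals = tensor.values.copy()
    mask = tensor.mask
    global_mean = float(np.nanmean(np.where(mask, vals, np.nan)))
    if method in ("mean", "median"):
        stat = np.nanmean if method == "mean" else np.nanmedian
        with np.errstate(invalid="ignore", all="ignore"):
            col = stat(np.where(mask, vals, np.nan), axis=0)  # J x K
        empty = ~np.isfinite(col)
        if empty.any():
            logger.warning(
                "%d gene-time columns have no observations; using the global mean",
                int(empty.sum()),
            )
            col[empty] = global_mean
        fill = np.broadcast_to(col, vals.shape)
        vals = np.where(mask, vals, fill)
    else:
        I = vals.shape[0]
        flat = np.where(mask, vals, np.nan).reshape(I, -1)
        for i in range(I):
            miss = ~mask[i]
            if not miss.any():
                continue
            d = np.full(I, np.inf)
            for other in range(I):
                if other == i:
                    continue
                common = np.isfinite(flat[i]) & np.isfinite(flat[other])
                if common.any():
                    d[other] = np.mean((flat[i, common] - flat[other, common]) ** 2)
            nbrs = np.argsort(d)[:k]
            nbrs = nbrs[np.isfinite(d[nbrs])]
            if nbrs.size:
                with np.errstate(invalid="ignore"):
                    fill = np.nanmean(np.where(mask[nbrs], vals[nbrs], np.nan), axis=0)
            else:
                fill = np.full(vals.shape[1:], np.nan)
            bad = ~np.isfinite(fill)
            if bad.any():
                with np.errstate(invalid="ignore"):
                    colmean = np.nanmean(np.where(mask, vals, np.nan), axis=0)
                fill[bad] = colmean[bad]
                still = ~np.isfinite(fill)
                if still.any():
                    logger.warning("KNN imputation fell back to the global mean")
                    fill[still] = global_mean
            vals[i][miss] = fill[miss]
    return GexTensor(vals, np.ones_like(mask), list(tensor.patient_ids),
                     list(tensor.gene_names), list(tensor.time_labels))


def rank_genes(models, top_n: int, gene_names=None):
    """Rank genes by the magnitude of the model-averaged gene weights.

    All models must be linear and share the same gene order; the averaged
    signed weight is reported alongside each gene.
    """
    models = list(models)
    if not models:
        raise ValueError("no models given")
    J = models[0].feature_split
    names = gene_names if gene_names is not None else [f"G{j}" for j in range(J)]
    for m in models:
        if m.u is None:
            raise ValueError(f"model with base {m.base!r} has no linear gene weights")
        if m.feature_split != J or m.u.size != J:
            raise ValueError("models do not share the same gene order")
    if len(names) != J:
        raise ValueError("gene_names length does not match the models")
    avg = np.mean([m.u for m in models], axis=0)
    order = np.argsort(-np.abs(avg), kind="stable")[:top_n]
    return [(names[j], float(avg[j])) for j in order]


@dataclass
class CompletionSettings:
    rank: int = 3
    mu: float = 1.0
    tol: float = 1e-6
    max_iters: int = 500


@dataclass
class EstimatorSpec:
    """Which learner to cross-validate and over which hyper-parameter grid."""

    base: str = "rep_svm"
    task: str = CLASSIFICATION
    grid: list = None  # list of param dicts; each may carry "rho"

    def __post_init__(self):
        if self.grid is None:
            self.grid = default_grid(self.base, self.task)
        if not self.grid:
            raise ValueError("hyper-parameter grid is empty")

    @property
    def with_feedback(self) -> bool:
        return self.base.startswith("rep_")


def default_grid(base: str, task: str):
    """Hyper-parameter grids used throughout: the recursive SVM searches
    lambda in {0.1, 0.5} x rho in {50, 100}; the plain SVM searches lambda in
    {0.01, 0.1, 1, 10}; KNN classification searches neighbors {3, 5, 8, 10}."""
    if base == "rep_svm":
        return [{"lam": l, "rho": r} for l, r in itertools.product((0.1, 0.5), (50.0, 100.0))]
    if base == "svm":
        return [{"lam": l} for l in (0.01, 0.1, 1.0, 10.0)]
    if base.removeprefix("rep_") == "knn" and task == CLASSIFICATION:
        return [{"n_neighbors": n} for n in (3, 5, 8, 10)]
    return [{}]


@dataclass
class FoldResult:
    patient_id: str
    patient_index: int
    selected_params: dict
    times: np.ndarray
    truths: np.ndarray
    predictions: np.ndarray
    scores: np.ndarray


@dataclass
class CvResult:
    """Leave-one-out results: one fold per patient plus aggregate metrics."""

    folds: list = field(default_factory=list)
    task: str = CLASSIFICATION
    aggregate: dict = field(default_factory=dict)

    def scored_pairs(self):
        truths, preds, scores = [], [], []
        for f in self.folds:
            keep = np.isfinite(f.truths)
            truths.append(f.truths[keep])
            preds.append(f.predictions[keep])
            scores.append(f.scores[keep])
        return (np.concatenate(truths), np.concatenate(preds), np.concatenate(scores))

    def compute_aggregate(self, responses: ResponseMatrix = None) -> dict:
        truths, preds, scores = self.scored_pairs()
        out = {"n_folds": len(self.folds), "n_scored": int(truths.size)}
        if self.task == CLASSIFICATION:
            out["acc"] = accuracy(truths, preds)
            try:
                out["auc"] = auc(truths, scores)
            except ValueError:
                out["auc"] = float("nan")
        else:
            K = max(len(f.truths) for f in self.folds)
            T = np.full((len(self.folds), K), np.nan)
            P = np.full((len(self.folds), K), np.nan)
            for r, f in enumerate(self.folds):
                T[r, : len(f.truths)] = f.truths
                P[r, : len(f.predictions)] = f.predictions
            mse, mae, per_time = regression_metrics(T, P)
            out.update(mse=mse, mae=mae, paper_mse=paper_mse(T, P))
            out["per_time"] = per_time
            constant = np.array([
                np.unique(f.truths[np.isfinite(f.truths)]).size <= 1 for f in self.folds
            ])
            for label, sel in (("constant", constant), ("varying", ~constant)):
                if sel.any():
                    m2, a2, _ = regression_metrics(T[sel], P[sel])
                    out[f"mse_{label}"] = m2
                    out[f"mae_{label}"] = a2
        self.aggregate = out
        return out


def _default_rho(spec) -> float:
    """rho = 100 compensates the l2 penalty for the max-margin learner; the
    distance/tree-based wrapped learners use the neutral 1.0."""
    if not spec.with_feedback:
        return 1.0
    return 100.0 if spec.base.removeprefix("rep_") == "svm" else 1.0


def _fit_and_predict(spec, params, design, fibers, y_known, seed):
    rho = params.get("rho", _default_rho(spec))
    est = RepEstimator(spec.base, spec.task, rho, with_feedback=spec.with_feedback,
                       seed=seed, **{k: v for k, v in params.items() if k != "rho"})
    est.fit(design)
    return est, predict_patient_course(est, fibers, y_known)


def _patient_fibers(tensor: GexTensor, i: int, factors, K: int):
    """Completed J x K fibers of one held-out patient via the NLS path."""
    x = tensor.values[i]  # J x K, NaN = missing
    if np.isfinite(x).all() or factors is None:
        return x
    seen = [t for t in range(K) if np.isfinite(x[:, t]).any()]
    latent = estimate_latent(x[:, seen], factors.B, factors.C, seen)
    out = x.copy()
    for t in range(K):
        out[:, t] = complete_patient_vector(x[:, t], latent, factors.B, factors.C, t)
    return out


def loo_cv(
    tensor: GexTensor,
    responses: ResponseMatrix,
    estimator_spec: EstimatorSpec,
    completion: CompletionSettings = None,
    seed: int = 0,
) -> CvResult:
    """Patient-level leave-one-out cross-validation with inner model selection.

    Per fold: the completion is fitted on the training patients only; each
    grid point is trained on all training patients but one (an inner
    validation patient drawn by ``seed``) and scored on that patient
    (accuracy for classification, MAE for regression); the winning
    hyper-parameters are refitted on the whole training fold; the held-out
    patient's missing expression is completed through the non-negative
    least-squares latent path and the time course is predicted recursively
    with actual responses fed back where observed.

    ``completion=None`` skips tensor completion (requires a fully observed
    tensor).
    """
    I, J, K = tensor.shape
    if I < 3:
        raise ValueError("leave-one-out needs at least 3 patients")
    if responses.shape != (I, K):
        raise ValueError("responses do not match the tensor's patient/time axes")
    if completion is None and not tensor.fully_observed:
        raise ValueError("completion settings required for a tensor with missing entries")
    rng = np.random.default_rng(seed)
    result = CvResult(task=estimator_spec.task)
    higher_better = estimator_spec.task == CLASSIFICATION

    for test_i in range(I):
        train_idx = np.array([i for i in range(I) if i != test_i])
        sub = tensor.subset_patients(train_idx)
        Y_sub = ResponseMatrix(responses.values[train_idx], responses.mask[train_idx],
                               responses.task)
        if completion is not None:
            factors = fit_cp_completion(sub, completion.rank, completion.mu,
                                        completion.max_iters, completion.tol,
                                        seed=int(rng.integers(2 ** 31)))
            Z = complete(sub, factors)
        else:
            factors = None
            Z = sub
        fb = build_feedback_tensor(Y_sub)

        val_pos = int(rng.integers(len(train_idx)))
        inner_idx = np.array([r for r in range(len(train_idx)) if r != val_pos])
        best, best_score = None, None
        if len(estimator_spec.grid) == 1:
            best = estimator_spec.grid[0]
        else:
            Z_in = Z.subset_patients(inner_idx)
            Y_in = ResponseMatrix(Y_sub.values[inner_idx], Y_sub.mask[inner_idx], Y_sub.task)
            fb_in = build_feedback_tensor(Y_in)
            val_truth = Y_sub.values[val_pos]
            val_fibers = Z.values[val_pos]
            for params in estimator_spec.grid:
                rho = params.get("rho", _default_rho(estimator_spec))
                design = assemble_training_design(Z_in, fb_in, Y_in, rho)
                _, (preds, scores) = _fit_and_predict(
                    estimator_spec, params, design, val_fibers, val_truth, seed)
                keep = np.isfinite(val_truth)
                if not keep.any():
                    score = -np.inf if higher_better else np.inf
                elif higher_better:
                    score = accuracy(val_truth[keep], preds[keep])
                else:
                    score = float(np.mean(np.abs(val_truth[keep] - preds[keep])))
                better = (best_score is None or
                          (score > best_score if higher_better else score < best_score))
                if better:
                    best, best_score = params, score

        rho = best.get("rho", _default_rho(estimator_spec))
        design = assemble_training_design(Z, fb, Y_sub, rho)
        test_fibers = _patient_fibers(tensor, test_i, factors, K)
        test_truth = responses.values[test_i]
        _, (preds, scores) = _fit_and_predict(
            estimator_spec, best, design, test_fibers, test_truth, seed)
        result.folds.append(FoldResult(
            tensor.patient_ids[test_i], test_i, dict(best), np.arange(K),
            test_truth.copy(), preds, scores,
        ))
    result.compute_aggregate(responses)
    return result
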