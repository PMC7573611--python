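"""Recursive drug-response history features.

The recursive-prediction idea treats a patient's past drug responses as
features for the current prediction. For a treatment with K time points, the
history at time t is packed into a length-(K-1) feedback vector

    ytilde(t) = [y(t-1), y(t-2), ..., y(0), 0, ..., 0],

most recent response first, zero-padded so the model can learn from recent
trends. Stacking the vectors of all patients and times gives an
I x K x (K-1) feedback tensor; the training design concatenates each
expression fiber with its rho-scaled feedback vector.

Binary responses are coded +1/-1 so that the zero padding is neutral: a zero
slot always means "no information". Missing past labels inside a history
contribute 0 at their slot at training time (at prediction time the recursive
loop substitutes predicted labels instead, see ``patient_inference``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tensor_model import GexTensor

__all__ = [
    "ResponseMatrix",
    "FeedbackTensor",
    "TrainingDesign",
    "build_feedback_vector",
    "build_feedback_tensor",
    "assemble_training_design",
]

CLASSIFICATION = "classification"
REGRESSION = "regression"


@dataclass
class ResponseMatrix:
    """Patient x time responses, binary (+1/-1) or continuous (e.g. EDSS)."""

    values: np.ndarray
    mask: np.ndarray = None
    task: str = CLASSIFICATION
    patient_ids: list = None
    time_labels: list = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("responses must be a patient x time matrix")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("response mask shape mismatch")
        if self.task not in (CLASSIFICATION, REGRESSION):
            raise ValueError(f"unknown task {self.task!r}")
        obs = self.values[self.mask]
        if not np.all(np.isfinite(obs)):
            raise ValueError("observed responses must be finite")
        if self.task == CLASSIFICATION and obs.size and not np.all(np.isin(obs, (-1.0, 1.0))):
            raise ValueError("classification responses must be coded +1/-1")
        self.values = self.values.copy()
        self.values[~self.mask] = np.nan

    @property
    def shape(self):
        return self.values.shape


@dataclass
class FeedbackTensor:
    """I x K x (K-1) tensor of per-patient, per-time history vectors."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        I, K, Km1 = self.values.shape
        if Km1 != K - 1:
            raise ValueError(f"last axis must have length K-1, got {Km1} for K={K}")


def build_feedback_vector(history, K: int) -> np.ndarray:
    """Pack past responses into a length-(K-1) vector, most recent first.

    ``history`` is the ordered sequence y(0), ..., y(t-1); NaN entries
    (missing past labels) contribute 0 at their slot.
    """
    history = np.asarray(list(history), dtype=float)
    if len(history) > K - 1:
        raise ValueError(f"history of length {len(history)} exceeds K-1 = {K - 1}")
    out = np.zeros(K - 1)
    if len(history):
        rev = history[::-1]
        rev = np.where(np.isfinite(rev), rev, 0.0)
        out[: len(rev)] = rev
    return out


def build_feedback_tensor(Y: ResponseMatrix, center: bool = False) -> FeedbackTensor:
    """All feedback vectors of a cohort as an I x K x (K-1) tensor.

    With ``center=True`` the fed-back values are mean-centered (over observed
    responses) before packing — for response scales where 0 is meaningful.
    Padding and missing slots stay exactly 0 either way.
    """
    I, K = Y.shape
    vals = Y.values.copy()
    if center:
        m = float(np.nanmean(vals)) if np.isfinite(vals).any() else 0.0
        vals = vals - m
    out = np.zeros((I, K, K - 1))
    for i in range(I):
        for t in range(K):
            out[i, t] = build_feedback_vector(vals[i, :t], K)
    return FeedbackTensor(out)


@dataclass
class TrainingDesign:
    """Stacked [expression fiber ; rho * feedback vector] rows with labels."""

    features: np.ndarray
    labels: np.ndarray
    row_index: list  # (patient index, time index) per row
    rho: float
    feature_split: int  # number of gene columns
    task: str = CLASSIFICATION

    @property
    def gene_block(self) -> np.ndarray:
        return self.features[:, : self.feature_split]

    @property
    def feedback_block(self) -> np.ndarray:
        return self.features[:, self.feature_split:]


def assemble_training_design(
    Z: GexTensor, fb: FeedbackTensor, Y: ResponseMatrix, rho: float
) -> TrainingDesign:
    """One training row per observed (patient, time) label.

    ``Z`` must be a completed (fully observed) tensor. The feedback block is
    pre-scaled by rho, so a standard linear max-margin solver on this design
    optimizes the margin u.z + rho v.ytilde with penalty ||u||^2 + ||v||^2.
    """
    if rho <= 0:
        raise ValueError("rho must be > 0 (use a no-feedback baseline for the ablation)")
    if not Z.fully_observed:
        raise ValueError("expression tensor must be completed (fully observed) first")
    I, J, K = Z.shape
    if fb.values.shape != (I, K, K - 1):
        raise ValueError("feedback tensor shape mismatch")
    if Y.shape != (I, K):
        raise ValueError("response matrix shape mismatch")
    rows, labels, index = [], [], []
    for i in range(I):
        for t in range(K):
            if not Y.mask[i, t]:
                continue
            rows.append(np.concatenate([Z.values[i, :, t], rho * fb.values[i, t]]))
            labels.append(Y.values[i, t])
            index.append((i, t))
    if not rows:
        raise ValueError("no observed labels; empty training design")
    return TrainingDesign(
        np.asarray(rows), np.asarray(labels), index, float(rho), J, Y.task
    )
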