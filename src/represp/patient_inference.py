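"""New-patient latent inference and recursive forecasting.

Once the cohort factors are fitted, a new patient is described by a single
non-negative latent vector ``a`` of length F: the expression of gene j at
time t is (C(t,:) . B(j,:)) a (a Khatri-Rao design row). Estimating ``a``
from a partially observed fiber is a non-negative least-squares problem —
convex, solved to global optimality — and needs at least F observed entries
to be identifiable. With ``a`` in hand the model can fill in missing genes,
forecast whole unseen fibers at later time points, and run the recursive
prediction loop in which each predicted response is fed forward as history
for the next time point (actual measurements override forecasts and
predictions whenever they are available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .feedback import build_feedback_vector
from .predictors import RepModel, predict_response

__all__ = [
    "PatientLatent",
    "PredictionRecord",
    "PredictionTrace",
    "estimate_latent",
    "complete_patient_vector",
    "forecast_gex",
    "recursive_predict",
]


@dataclass
class PatientLatent:
    """Non-negative latent vector of one patient with its NLS diagnostics."""

    a: np.ndarray
    n_observed: int
    residual: float

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        if (self.a < 0).any():
            raise ValueError("latent vector must be non-negative")
        if self.n_observed < self.a.size:
            raise ValueError("latent built from fewer observations than its rank")


def _kr_rows(B: np.ndarray, C: np.ndarray, genes: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Khatri-Rao design rows C(t,:) * B(j,:) for paired (gene, time) indices."""
    return C[times] * B[genes]


def estimate_latent(x_partial: np.ndarray, B: np.ndarray, C: np.ndarray, t) -> PatientLatent:
    """Estimate a patient's latent vector from observed expression entries.

    Parameters
    ----------
    x_partial : ndarray
        Length-J fiber (single time index ``t``) or J x T matrix (``t`` a
        sequence of T time indices). NaN marks missing entries.
    B, C : ndarray
        Gene (J x F) and time (K x F) factor matrices from the training fit.
    t : int or sequence of int
        Time index (or indices) the observations belong to.
    """
    B = np.asarray(B, dtype=float)
    C = np.asarray(C, dtype=float)
    F = B.shape[1]
    x = np.asarray(x_partial, dtype=float)
    times = np.atleast_1d(np.asarray(t, dtype=int))
    if (times < 0).any() or (times >= C.shape[0]).any():
        raise ValueError(f"time index out of range for K={C.shape[0]}")
    if x.ndim == 1:
        x = x[:, None]
    if x.shape != (B.shape[0], times.size):
        raise ValueError(f"expected fiber shape {(B.shape[0], times.size)}, got {x.shape}")
    jj, tt = np.nonzero(np.isfinite(x))
    if jj.size < F:
        raise ValueError(
            f"only {jj.size} observed entries; at least F={F} are required for a "
            "unique latent estimate"
        )
    M = _kr_rows(B, C, jj, times[tt])
    if np.any(~M.any(axis=1)):
        j = int(jj[np.nonzero(~M.any(axis=1))[0][0]])
        raise ValueError(f"design row for gene {j} is all zeros; entry carries no information")
    a, rnorm = nnls(M, x[jj, tt])
    return PatientLatent(a, int(jj.size), float(rnorm ** 2))


def complete_patient_vector(x_partial, latent: PatientLatent, B, C, t: int) -> np.ndarray:
    """Copy observed coordinates; fill missing ones from the latent model."""
    x = np.asarray(x_partial, dtype=float).copy()
    g = np.asarray(B) @ (np.asarray(C)[t] * latent.a)
    miss = ~np.isfinite(x)
    x[miss] = g[miss]
    return x


def forecast_gex(latent: PatientLatent, B, C, horizon) -> np.ndarray:
    """Forecast whole fibers: column for time t is (C(t,:) . B) a-hat."""
    B = np.asarray(B, dtype=float)
    C = np.asarray(C, dtype=float)
    horizon = np.atleast_1d(np.asarray(horizon, dtype=int))
    if (horizon < 0).any() or (horizon >= C.shape[0]).any():
        raise ValueError(f"horizon index out of range for K={C.shape[0]}")
    return B @ (C[horizon] * latent.a).T


@dataclass
class PredictionRecord:
    time: int
    gex_source: str       # observed | completed | forecast
    feedback_source: str  # actual | predicted
    prediction: float
    score: float


@dataclass
class PredictionTrace:
    """Per-time record of a recursive prediction run."""

    records: list = field(default_factory=list)

    @property
    def predictions(self) -> np.ndarray:
        return np.array([r.prediction for r in self.records])

    @property
    def scores(self) -> np.ndarray:
        return np.array([r.score for r in self.records])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(r.time, r.gex_source, r.feedback_source, r.prediction, r.score)
             for r in self.records],
            columns=["time", "gex_source", "feedback_source", "prediction", "score"],
        )


def recursive_predict(
    model: RepModel,
    B: np.ndarray,
    C: np.ndarray,
    x0: np.ndarray,
    y0: float = None,
    K: int = None,
    x_later: np.ndarray = None,
    y_known: np.ndarray = None,
) -> PredictionTrace:
    """Predict a patient's whole treatment from initial measurements.

    The latent vector is estimated from the observed entries of the initial
    fiber ``x0`` (time 0) and re-estimated as actual later fibers arrive;
    unseen expression is forecast from it. At each time t the feedback
    history uses actual responses where available (``y0``/``y_known``) and
    previously predicted ones otherwise, most recent first. No record ever
    depends on later-time inputs.

    Parameters
    ----------
    x0 : length-J fiber at time 0, NaN = missing (needs >= F observed).
    y0 : optional actual response at time 0.
    K : prediction horizon; defaults to the number of fitted time points.
    x_later : optional J x K array of actual later expression (NaN = missing).
    y_known : optional length-K array of actual responses (NaN = missing).
    """
    B = np.asarray(B, dtype=float)
    C = np.asarray(C, dtype=float)
    J, F = B.shape
    if K is None:
        K = C.shape[0]
    if K < 1 or K > C.shape[0]:
        raise ValueError(f"horizon K={K} out of range for {C.shape[0]} fitted time points")
    x0 = np.asarray(x0, dtype=float)
    if y_known is None:
        y_known = np.full(K, np.nan)
    y_known = np.asarray(y_known, dtype=float).copy()
    if y0 is not None:
        y_known[0] = y0

    obs = np.full((J, K), np.nan)
    obs[:, 0] = x0
    if x_later is not None:
        x_later = np.asarray(x_later, dtype=float)
        obs[:, 1:K] = x_later[:, 1:K]

    trace = PredictionTrace()
    responses = np.full(K, np.nan)
    latent = estimate_latent(obs[:, [0]], B, C, [0])
    for t in range(K):
        if t > 0 and np.isfinite(obs[:, t]).any():
            # fold this time point's actual measurements into the latent
            seen = [s for s in range(t + 1) if np.isfinite(obs[:, s]).any()]
            latent = estimate_latent(obs[:, seen], B, C, seen)
        n_obs = int(np.isfinite(obs[:, t]).sum())
        if n_obs == J:
            z, src = obs[:, t], "observed"
        elif n_obs > 0:
            z, src = complete_patient_vector(obs[:, t], latent, B, C, t), "completed"
        else:
            z, src = B @ (C[t] * latent.a), "forecast"
        hist = responses[:t]
        fb_src = "actual" if np.all(np.isfinite(y_known[:t])) else "predicted"
        ytilde = build_feedback_vector(hist, C.shape[0])
        pred, score = predict_response(model, z, ytilde)
        trace.records.append(PredictionRecord(t, src, fb_src, float(pred), float(score)))
        responses[t] = y_known[t] if np.isfinite(y_known[t]) else pred
    return trace
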