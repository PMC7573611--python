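"""Masked non-negative CP factorization of patient x gene x time expression tensors.

A time-course expression study is modelled as a 3-way tensor ``X`` of shape
``I x J x K`` (patients x genes x time points) whose noiseless part is assumed
to admit a low-rank canonical polyadic (CP) decomposition

    g_ijk = sum_f a_if * b_jf * c_kf,   A >= 0, B >= 0, C >= 0,

with an observation mask ``Omega`` marking which entries were measured.
Fitting minimises the masked, ridge-regularized least-squares objective

    sum_{(i,j,k) in Omega} (x_ijk - g_ijk)^2
        + mu * (||A||_F^2 + ||B||_F^2 + ||C||_F^2)

by block-coordinate descent: each row of one factor is an independent
ridge-regularized non-negative least-squares problem over that row's observed
entries, solved exactly (Lawson-Hanson active set), which guarantees a
monotonically non-increasing objective. Missing entries are then completed by
the fitted CP reconstruction while observed entries are preserved verbatim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

logger = logging.getLogger(__name__)

__all__ = ["GexTensor", "CPFactors", "fit_cp_completion", "reconstruct", "complete"]


@dataclass
class GexTensor:
    """Non-negative 3-way expression array with an observation mask.

    Parameters
    ----------
    values : ndarray, shape (I, J, K)
        Expression levels, patients x genes x time. Unobserved entries are
        stored as NaN and are never read by numeric code except through
        ``mask``.
    mask : ndarray of bool, same shape
        True where the entry was observed.
    patient_ids, gene_names, time_labels : lists of str
        Axis labels; ``time_labels`` follow treatment chronology.
    """

    values: np.ndarray
    mask: np.ndarray
    patient_ids: list = None
    gene_names: list = None
    time_labels: list = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-way array, got ndim={self.values.ndim}")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != values shape {self.values.shape}"
            )
        obs = self.values[self.mask]
        if obs.size and not np.all(np.isfinite(obs)):
            idx = tuple(np.argwhere(self.mask & ~np.isfinite(self.values))[0])
            raise ValueError(f"observed entry at {idx} is not finite")
        if obs.size and (obs < 0).any():
            bad = self.values.copy()
            bad[~self.mask] = 0.0
            idx = tuple(int(x) for x in np.argwhere(self.mask & (bad < 0))[0])
            raise ValueError(
                f"negative expression value {self.values[idx]} at (patient, gene, time)={idx}"
            )
        # sentinel for unobserved entries
        self.values = self.values.copy()
        self.values[~self.mask] = np.nan
        I, J, K = self.values.shape
        if self.patient_ids is None:
            self.patient_ids = [f"P{i}" for i in range(I)]
        if self.gene_names is None:
            self.gene_names = [f"G{j}" for j in range(J)]
        if self.time_labels is None:
            self.time_labels = [f"t{k}" for k in range(K)]
        if not (len(self.patient_ids), len(self.gene_names), len(self.time_labels)) == (I, J, K):
            raise ValueError("axis label lengths do not match tensor shape")

    @property
    def shape(self):
        return self.values.shape

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())

    @property
    def fully_observed(self) -> bool:
        return bool(self.mask.all())

    def subset_patients(self, indices) -> "GexTensor":
        indices = np.asarray(indices)
        return GexTensor(
            self.values[indices],
            self.mask[indices],
            [self.patient_ids[i] for i in indices],
            list(self.gene_names),
            list(self.time_labels),
        )

    def check_slabs(self):
        """Every patient, gene and time slab must contain >= 1 observed entry."""
        for axis, name in ((0, "patient"), (1, "gene"), (2, "time")):
            counts = self.mask.sum(axis=tuple(a for a in range(3) if a != axis))
            if (counts == 0).any():
                i = int(np.argmin(counts))
                raise ValueError(
                    f"{name} slab {i} has no observed entries; its latent row is unidentifiable"
                )


@dataclass
class CPFactors:
    """Non-negative CP factor matrices A (patients), B (genes), C (time)."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    rank: int
    mu: float = 0.0
    objective_trace: list = field(default_factory=list)

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        for name, M in (("A", self.A), ("B", self.B), ("C", self.C)):
            if M.ndim != 2 or M.shape[1] != self.rank:
                raise ValueError(f"factor {name} must be 2-D with {self.rank} columns")
            if (M < 0).any():
                raise ValueError(f"factor {name} has negative entries")

    @property
    def shape(self):
        return (self.A.shape[0], self.B.shape[0], self.C.shape[0])

    def save(self, path):
        np.savez(path, A=self.A, B=self.B, C=self.C, rank=self.rank, mu=self.mu,
                 objective_trace=np.asarray(self.objective_trace, dtype=float))

    @classmethod
    def load(cls, path) -> "CPFactors":
        with np.load(path) as z:
            return cls(z["A"], z["B"], z["C"], int(z["rank"]), float(z["mu"]),
                       list(z["objective_trace"]))


def reconstruct(factors: CPFactors) -> np.ndarray:
    """Dense CP reconstruction: entry (i,j,k) = sum_f a_if b_jf c_kf."""
    return np.einsum("if,jf,kf->ijk", factors.A, factors.B, factors.C)


def _ridge_nnls(M: np.ndarray, y: np.ndarray, mu: float, F: int) -> np.ndarray:
    """Exact solution of min_{a>=0} ||y - M a||^2 + mu ||a||^2."""
    if mu > 0:
        M = np.vstack([M, np.sqrt(mu) * np.eye(F)])
        y = np.concatenate([y, np.zeros(F)])
    sol, _ = nnls(M, y)
    return sol


def _masked_objective(vals, rows_A, rows_B, rows_C, mu, A, B, C):
    fit = np.einsum("nf,nf,nf->n", rows_A, rows_B, rows_C)
    reg = mu * (np.sum(A * A) + np.sum(B * B) + np.sum(C * C))
    return float(np.sum((vals - fit) ** 2) + reg)


def fit_cp_completion(
    tensor: GexTensor,
    rank: int,
    mu: float = 1.0,
    max_iters: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> CPFactors:
    """Fit the masked ridge-regularized non-negative CP model.

    Alternates exact ridge-NNLS updates of the rows of A, B and C, using only
    each row's observed entries. The objective trace (recorded after every
    block update) is non-increasing by construction.

    Parameters
    ----------
    tensor : GexTensor
    rank : int
        CP rank F >= 1.
    mu : float
        Ridge weight on all three factors (>= 0).
    max_iters : int
        Maximum number of full A/B/C sweeps.
    tol : float
        Stop when the relative objective change over one sweep falls below
        this value.
    seed : int
        Seeds the uniform factor initialization.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if mu < 0:
        raise ValueError("mu must be >= 0")
    tensor.check_slabs()
    I, J, K = tensor.shape
    F = rank
    rng = np.random.default_rng(seed)

    ii, jj, kk = np.nonzero(tensor.mask)
    vals = tensor.values[ii, jj, kk]

    # uniform (0, 1] init, rescaled so the initial reconstruction's mean
    # matches the observed-entry mean (avoids dead zero blocks)
    A = 1.0 - rng.random((I, F))
    B = 1.0 - rng.random((J, F))
    C = 1.0 - rng.random((K, F))
    init_mean = float(np.mean(np.einsum("nf,nf,nf->n", A[ii], B[jj], C[kk])))
    target_mean = float(np.mean(vals)) if vals.size else 1.0
    if init_mean > 0 and target_mean > 0:
        s = (target_mean / init_mean) ** (1.0 / 3.0)
        A *= s
        B *= s
        C *= s

    idx_by = []
    for axis, n in ((ii, I), (jj, J), (kk, K)):
        order = np.argsort(axis, kind="stable")
        bounds = np.searchsorted(axis[order], np.arange(n + 1))
        idx_by.append([order[bounds[r]:bounds[r + 1]] for r in range(n)])
    idx_i, idx_j, idx_k = idx_by

    reseeded = set()

    def update_factor(M, own_idx, rows_other):
        for r, sel in enumerate(own_idx):
            M[r] = _ridge_nnls(rows_other[sel], vals[sel], mu, F)

    def objective():
        return _masked_objective(vals, A[ii], B[jj], C[kk], mu, A, B, C)

    def reseed_collapsed(M, which):
        """Reseed an all-zero factor column once from the positive residual.

        The reseeded column is scaled back geometrically until the objective
        stays within 1e-10 of its pre-reseed value, so the descent trace
        remains monotone; later exact block solves amplify the direction if
        it is useful.
        """
        fit = np.einsum("nf,nf,nf->n", A[ii], B[jj], C[kk])
        resid = vals - fit
        pos = resid[resid > 0]
        scale = float(np.mean(pos)) ** (1.0 / 3.0) if pos.size else 1e-3
        for f in range(F):
            if np.all(M[:, f] == 0.0):
                key = (which, f)
                if key in reseeded:
                    continue  # second collapse: keep as effective rank reduction
                reseeded.add(key)
                pre = objective()
                M[:, f] = scale * (1.0 - rng.random(M.shape[0]))
                for _ in range(40):
                    if objective() <= pre + 1e-10:
                        break
                    M[:, f] *= 0.1
                else:
                    M[:, f] = 0.0
                logger.info("reseeded collapsed column %d of factor %s", f, which)

    trace = [_masked_objective(vals, A[ii], B[jj], C[kk], mu, A, B, C)]
    for _ in range(max_iters):
        prev = trace[-1]
        update_factor(A, idx_i, B[jj] * C[kk])
        reseed_collapsed(A, "A")
        trace.append(_masked_objective(vals, A[ii], B[jj], C[kk], mu, A, B, C))
        update_factor(B, idx_j, A[ii] * C[kk])
        reseed_collapsed(B, "B")
        trace.append(_masked_objective(vals, A[ii], B[jj], C[kk], mu, A, B, C))
        update_factor(C, idx_k, A[ii] * B[jj])
        reseed_collapsed(C, "C")
        trace.append(_masked_objective(vals, A[ii], B[jj], C[kk], mu, A, B, C))
        if prev > 0 and (prev - trace[-1]) / prev < tol:
            break

    return CPFactors(A, B, C, rank=F, mu=mu, objective_trace=trace)


def complete(tensor: GexTensor, factors: CPFactors) -> GexTensor:
    """Fill missing entries from the CP reconstruction, keeping observed ones.

    The result equals the input bit-identically on observed entries and the
    CP reconstruction elsewhere; its mask is all-True.
    """
    if factors.shape != tensor.shape:
        raise ValueError(f"factor shapes {factors.shape} != tensor shape {tensor.shape}")
    out = tensor.values.copy()
    if not tensor.fully_observed:
        recon = reconstruct(factors)
        out[~tensor.mask] = recon[~tensor.mask]
    return GexTensor(
        out,
        np.ones_like(tensor.mask),
        list(tensor.patient_ids),
        list(tensor.gene_names),
        list(tensor.time_labels),
    )
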