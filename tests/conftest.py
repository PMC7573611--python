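import numpy as np
import pytest
from scipy.optimize import minimize

import represp as rp


def hinge_qp_oracle(X, y, lam):
    """Independent primal solve of the hinge-loss SVM as a slack-variable QP.

    min_{w,b,xi} (1/N) sum xi + (lam/2)||w||^2
    s.t. xi >= 0, xi >= 1 - y (Xw + b)

    Solved with SLSQP; returns the optimal objective value.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    N, d = X.shape

    def obj(p):
        return np.mean(p[d + 1:]) + 0.5 * lam * np.dot(p[:d], p[:d])

    cons = [
        {"type": "ineq", "fun": lambda p: p[d + 1:]},
        {"type": "ineq", "fun": lambda p: y * (X @ p[:d] + p[d]) - 1 + p[d + 1:]},
    ]
    p0 = np.zeros(d + 1 + N)
    p0[d + 1:] = 1.0
    res = minimize(obj, p0, constraints=cons, method="SLSQP",
                   options={"maxiter": 1000, "ftol": 1e-12})
    assert res.success, res.message
    return obj(res.x)


@pytest.fixture(scope="session")
def small_cohort():
    """Fully observed classification cohort, autoregressive labels."""
    return rp.generate_cohort(I=12, J=10, K=5, F=2, noise_sd=0.05, miss_frac=0.0, seed=42)


@pytest.fixture(scope="session")
def masked_cohort():
    """Rank-3 noiseless cohort with 20% of entries hidden."""
    return rp.generate_cohort(I=10, J=12, K=5, F=3, noise_sd=0.0, miss_frac=0.2, seed=7)


@pytest.fixture(scope="session")
def trained_rep(small_cohort):
    c = small_cohort
    fb = rp.build_feedback_tensor(c.responses)
    design = rp.assemble_training_design(c.tensor, fb, c.responses, rho=100.0)
    return rp.train_rep_svm(design, lam=0.1), design
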