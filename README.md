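# represp

Recursive prediction of time-course drug response from gene expression.

Long-term treatments (for example interferon-β therapy in multiple
sclerosis) produce *time-course* expression data: a patient × gene × time
tensor of measurements, paired with a per-time drug-response record — a
good/poor responder label or an ordinal disability score such as EDSS
(0–7). Most predictors use only one or two time points and ignore two
facts this package is built around: a patient's past responses are strong
predictors of the next one, and the expression tensor is approximately
low-rank, which lets missing and even entirely unseen future measurements
be reconstructed.

`represp` implements this recursive framework end to end:

1. **Masked non-negative CP completion.** The noiseless expression is
   modelled as `g_ijk = Σ_f a_if b_jf c_kf` with non-negative factors
   `A (I×F)`, `B (J×F)`, `C (K×F)`. Fitting minimises

   `Σ_{(i,j,k)∈Ω} (x_ijk − g_ijk)² + μ(‖A‖²_F + ‖B‖²_F + ‖C‖²_F)`

   over the observed set Ω by block-coordinate descent (exact ridge
   non-negative least squares per factor row), then fills missing entries
   from the reconstruction while keeping observed entries verbatim.
2. **Response feedback.** At time *t* the history is packed
   most-recent-first into `ỹ(t) = [y(t−1), …, y(0), 0, …, 0]` of length
   K−1, zero-padded so a zero slot always means "no information"
   (binary responses are coded ±1).
3. **Recursive max-margin training (REP-SVM).** A linear hinge-loss model

   `min_{u,v,b} (1/IK) Σ max(0, 1 − y_it(uᵀz_it + ρ vᵀỹ_it + b)) + (λ/2)(‖u‖² + ‖v‖²)`

   with a fixed weight ρ (default 100) that keeps the ±1 feedback features
   competitive with the larger expression values. Any scikit-learn base
   learner can be wrapped with the same feedback block (REP-SVR,
   REP-ElasticNet, REP-RandomForest, REP-KNN).
4. **New-patient inference.** A new patient's non-negative latent vector
   `a` is estimated from ≥ F observed expression values by NNLS on
   Khatri-Rao design rows `C(t,:) ⊙ B(j,:)`; unseen fibers are forecast as
   `(C(t,:) ⊙ B) â`, and the prediction loop feeds each predicted response
   forward as history for the next time point — so a whole treatment can
   be scored from the initial measurements alone. Actual measurements
   override forecasts whenever they exist.
5. **Evaluation harness.** Patient-level leave-one-out cross-validation
   with an inner one-patient validation split for hyper-parameter
   selection (λ ∈ {0.1, 0.5} × ρ ∈ {50, 100} for REP-SVM; λ ∈
   {0.01, 0.1, 1, 10} for the plain SVM), accuracy/rank-based AUC and
   MSE/MAE metrics, missingness-injection experiments, mean/median/KNN
   imputation baselines and gene ranking by model-averaged weights.

A synthetic-cohort generator with exactly this statistical structure
(low-rank non-negative CP + truncated Gaussian noise + uniform missingness
+ autoregressive responses) makes every stage testable without any
external download.

## Worked example

```python
import numpy as np
import represp as rp

cohort = rp.generate_cohort(I=27, J=76, K=7, F=3, noise_sd=0.05,
                            miss_frac=0.05, seed=1)
print(f"observed entries: {cohort.tensor.n_observed} / {np.prod(cohort.tensor.shape)}")

factors = rp.fit_cp_completion(cohort.tensor, rank=3, mu=1.0, seed=0)
completed = rp.complete(cohort.tensor, factors)
hidden = ~cohort.tensor.mask
err = (np.linalg.norm((rp.reconstruct(factors) - cohort.noiseless)[hidden])
       / np.linalg.norm(cohort.noiseless[hidden]))
print(f"hidden-entry relative error: {err:.4f}")

result = rp.loo_cv(cohort.tensor, cohort.responses, rp.EstimatorSpec("rep_svm"),
                   rp.CompletionSettings(rank=3, mu=1.0), seed=1)
print(f"REP-SVM leave-one-out: ACC {result.aggregate['acc']:.3f}, "
      f"AUC {result.aggregate['auc']:.3f}")

baseline = rp.loo_cv(cohort.tensor, cohort.responses, rp.EstimatorSpec("svm"),
                     rp.CompletionSettings(rank=3, mu=1.0), seed=1)
print(f"plain SVM leave-one-out: ACC {baseline.aggregate['acc']:.3f}, "
      f"AUC {baseline.aggregate['auc']:.3f}")
```

prints

```
observed entries: 13646 / 14364
hidden-entry relative error: 0.0140
REP-SVM leave-one-out: ACC 0.947, AUC 0.990
plain SVM leave-one-out: ACC 0.672, AUC 0.663
```

The tensor model recovers the 5% hidden entries to 1.4% relative error
despite 5% measurement noise; feeding past responses back raises
leave-one-out accuracy from 0.672 to 0.947 on a cohort whose labels
persist from one time point to the next about 90% of the time while
remaining driven by expression.

The same pipeline is available from the shell:

```sh
represp simulate --seed 1 --out run/sim
represp complete --expression run/sim/expression.csv --rank 3 --mu 1 --out run/comp
represp evaluate --expression run/sim/expression.csv \
                 --responses run/sim/responses.csv \
                 --rank 3 --mu 1 --seed 1 --out run/eval
```

Every run directory receives a `config.yaml` echo and a log; re-running
from the echo reproduces all numeric outputs.

## Layout

- `src/represp/tensor_model.py` — tensors, CP factors, masked completion
- `src/represp/feedback.py` — feedback vectors/tensors, training design
- `src/represp/predictors.py` — REP-SVM, baseline SVM, wrapped learners
- `src/represp/patient_inference.py` — latent NLS, forecasting, recursion
- `src/represp/evaluation.py` — metrics, LOO harness, imputers, gene ranks
- `src/represp/synthetic.py` — cohort generator with known ground truth
- `src/represp/io.py`, `src/represp/cli.py` — delimited-text IO and CLI
- `docs/methods.md` — model, assumptions, parameter choices, limitations
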