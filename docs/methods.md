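# Methods

## Model

Time-course expression data are held as a 3-way tensor `X` of shape
I × J × K (patients × genes × time points) with an observation mask Ω;
all axis order in this package is patient × gene × time. The noiseless
signal is assumed to admit a rank-F canonical polyadic (CP) decomposition
with non-negative factors,

    g_ijk = Σ_f a_if b_jf c_kf ,  A, B, C ≥ 0 ,

so that the gene factor `B` and time factor `C` are shared across the
cohort and each patient is summarised by one row of `A`. Observations are
the noiseless signal plus noise, restricted to Ω. Non-negativity reflects
raw expression scales; data that were z-scored upstream are rejected
rather than silently transformed (the reader refuses negative values and
names the offending coordinate).

Responses form a patient × time matrix: ±1 responder labels
(classification) or continuous scores on the EDSS-like 0–7 scale
(regression). The recursive hypothesis is that the response at time t
depends on current expression *and* on earlier responses; histories are
packed most-recent-first into zero-padded length-(K−1) feedback vectors.
Labels are coded ±1 (not 1/0) precisely so the zero padding is neutral.
For response scales where 0 is itself meaningful, `build_feedback_tensor`
accepts a mean-centering flag; EDSS values are fed back on their natural
scale by default.

## Completion solver

The completion objective couples a masked least-squares fit with ridge
penalties on all three factors:

    min_{A,B,C ≥ 0}  Σ_{(i,j,k)∈Ω} (x_ijk − Σ_f a_if b_jf c_kf)²
                     + μ (‖A‖²_F + ‖B‖²_F + ‖C‖²_F).

Rather than carrying a dense auxiliary tensor constrained to match `X` on
Ω, the solver works directly on the observed entries; the completed
tensor is defined afterwards as `X` on Ω and the CP reconstruction on the
complement, so observed values are preserved bit-identically.

Numerical choices:

- **Block updates.** Each sweep updates A, then B, then C. The rows of one
  factor are independent given the other two, and each row is an exact
  ridge-regularized non-negative least-squares problem over that row's
  observed entries (Lawson–Hanson active set, with the ridge applied by
  augmenting √μ·I rows). Exact per-block minimisation makes the objective
  trace non-increasing by construction; the trace is recorded after every
  block update and checked to ≤ +1e-9 per step in the tests.
- **Initialisation.** Factor entries i.i.d. uniform on (0, 1], rescaled so
  the initial reconstruction's mean matches the observed-entry mean; the
  seed is an explicit argument and fully determines the fit.
- **Convergence.** Relative objective change < 1e-6 per sweep (default
  `tol`) or 500 sweeps (default `max_iters`).
- **Collapsed columns.** If a factor column reaches exactly zero it is a
  fixed point of the block updates. The column is reseeded once from the
  scale of the positive residual, with its magnitude backed off
  geometrically until the objective sits within 1e-10 of its pre-reseed
  value — the escape direction is preserved without breaking monotone
  descent. A second collapse is kept as an effective rank reduction.
- **Identifiability guard.** A patient, gene or time slab with zero
  observed entries makes the corresponding factor row unidentifiable; the
  fit rejects such inputs up front.

CP factors are identifiable only up to column permutation and scaling, so
no contract in this package ever compares factor matrices across fits;
all checks are stated on reconstructions, which are invariant.

## Recursive max-margin training

The classification model is a linear hinge-loss SVM over the concatenated
features [expression fiber ; ρ·feedback vector]:

    min_{u,v,b} (1/N) Σ_n max(0, 1 − y_n(uᵀz_n + ρ vᵀỹ_n + b))
                + (λ/2)(‖u‖² + ‖v‖²),

with the intercept unpenalized. ρ is not a learned weight: it rescales
the ±1 feedback features so they can compete with the larger expression
values under the shared ℓ2 penalty; large values (default 100, grid
{50, 100}) effectively make feedback a must-have feature.

Because the training design carries the feedback block pre-scaled by ρ,
this is an ordinary linear SVM on the design and is delegated to the
exact libsvm solver with the conversion `C = 1/(λN)` (multiplying the
objective by 1/λ maps it onto libsvm's `(1/2)‖w‖² + C Σ hinge` form with
an unpenalized intercept). The conversion is unit-tested against an
independent slack-variable quadratic-program solve of the primal. A hard
iteration cap (2·10⁵) guards against rare solver stalls on badly scaled
folds; the cap is orders of magnitude beyond what the exactness checks
consume. An optional ℓ1-ball constraint on [u; v] is supported for
feature selection and is enforced by Euclidean projection after the
unconstrained solve — a documented heuristic, adequate for ranking but
not an exact constrained optimum. Ties at decision score exactly 0
predict +1. No class reweighting is applied.

Any scikit-learn base learner can be wrapped with the same feedback
block (`rep_wrap` / `RepEstimator`): elastic net (linear — its gene
weights are exposed for ranking), support-vector regression, random
forests (20 trees by default, seeded) and k-nearest-neighbours (10
neighbours by default in regression, grid {3, 5, 8, 10} in
classification). The ρ=100 compensation is specific to the max-margin
geometry; distance- and tree-based wrapped learners default to the
neutral ρ=1, which preserves their feature geometry. Every wrapped
learner has an identical no-feedback ablation (`with_feedback=False`).

## New-patient inference

A new patient's latent vector solves the convex NLS problem

    â = argmin_{a ≥ 0} Σ_{j∈Ω̄} (x_j(t) − (C(t,:) ⊙ B(j,:)) a)² ,

where ⊙ denotes the Khatri–Rao (column-wise Kronecker) structure of the
design rows. At least F observed entries are required for a unique
estimate; fewer are rejected, as are all-zero design rows. The operation
accepts a single time index or a set of indices whose rows are stacked
jointly — inside the evaluation harness a held-out patient's latent
vector is estimated jointly from all of its observed entries across time
(rather than per time point), so times with fewer than F observed genes
remain completable. Fiber completion copies observed coordinates verbatim
and fills the rest with `(C(t,:) ⊙ B) â`; forecasting evaluates the same
expression at future time indices.

The recursive loop estimates the latent from the initial fiber,
re-estimates it as actual later fibers arrive, forecasts unseen
expression, and at each time step builds the feedback vector from actual
responses where available and previously predicted ones otherwise. If no
initial response is given, the first prediction (made with an all-zero
history) is fed forward. Every emitted record carries its expression
source (observed / completed / forecast) and feedback source (actual /
predicted), and no record depends on later-time inputs — a property the
tests verify by perturbing future inputs.

## Evaluation protocol

Leave-one-out cross-validation at the patient level: each fold holds out
one patient's whole time course. The tensor completion is fitted on the
training patients only; the held-out patient is completed through the
NLS latent path against the training-fold `B` and `C`, never by refitting
the factors with the test patient included. Hyper-parameters are selected
on a single inner validation patient drawn by the run seed — validation
accuracy for classification, validation MAE for regression — then the
winner is refitted on the full training fold. Test-time prediction is
recursive, feeding actual labels back when present and predictions
otherwise.

Metrics: accuracy as (TP+TN)/(TP+FP+FN+TN); AUC as the rank-based
Mann–Whitney statistic with tied scores counting 1/2 per pair (checked
exactly against exhaustive pair counting); regression errors as
per-element means over all scored (patient, time) pairs, with per-time
breakdowns and a stratification into constant-response and
time-varying-response patients. A `paper_mse` variant that divides the
summed squared per-patient error norms by the number of patients only is
provided for literal comparison with conventions that omit the per-time
divisor. Imputation baselines (per-(gene, time) mean/median across
patients, and patient-KNN over commonly observed coordinates, k = 5 by
default) allow the completion to be swapped out; a coordinate with no
observations anywhere falls back to the global observed mean and logs a
warning. Gene ranking averages the linear gene weights across models and
orders by magnitude, keeping the sign in the output.

## Synthetic cohorts

The generator draws non-negative factors (uniform by default,
folded-normal optional), adds Gaussian noise truncated at zero — σ is
quoted relative to the mean noiseless signal so non-negativity is
preserved — and hides a uniform-at-random fraction of entries, resampling
draws that would empty a slab. The default shape, 27 patients × 76 genes
× 7 time points at rank 3 with μ = 1 as the completion operating point,
mirrors a real interferon-β multiple-sclerosis time course.

Responses follow a linear rule over the *measured* (standardized)
expression plus the patient's own past responses:

- classification: `y(t) = sign(u*ᵀ zs(t) + v*ᵀ ỹ(t) + b* + ε)` with ±1
  coding and `v*` concentrated on the most recent slot;
- regression: `y(t) = clip(3.5 + u*ᵀ zs(t) + β(y(t−1) − 3.5) + ε, 0, 7)`,
  an AR(1) pull toward the scale midpoint.

Two generator decisions matter for interpretation. First, expression is
standardized per gene across patients and times (one affine map per
gene), so the generating rule is exactly representable by a single linear
predictor on raw expression — a per-(gene, time) standardization would
make the true rule time-varying and no time-invariant linear model could
be well-specified against it. Second, the rule is driven by the measured
tensor rather than its noiseless CP part: under an exactly low-rank
signal the gene features span only an F-dimensional subspace, so *which*
gene drives the labels would be unidentifiable to any weight-based
ranking; the driving gene's own noise component restores
identifiability, and the planted-signal recovery test therefore runs at
noise_sd = 0.5.

Default response parameters (classification): unit-norm expression
weights, feedback weight 1.5, intercept 0, label-noise sd 0.5. Under a
Gaussian approximation (exact when the expression weight is zero) the
label persists with probability Φ(1.5/√(1+0.25)) ≈ 0.91 — the
"persistent but expression-driven" regime the comparison experiments
target. `persistence_probability` computes this quantity, and the
simulated persistence matches it to three decimals in the tests.

What the generator does not emulate: microarray platform or probe-level
effects, batch structure, non-stationary gene programs, informative
(non-uniform) missingness, and patient dropout. Passing tests therefore
show that the pipeline is correct under its own modelling assumptions —
low-rank expression, linear response rules, uniform missingness — not
that those assumptions hold for any particular clinical dataset.

## Problem sizes and study conditions

The comparison experiments (tests and the acceptance script) use 20
cohorts of 14 patients × 16 genes × 5 time points at rank 2, fully
observed, so the two-learner leave-one-out comparison stays a
seconds-scale computation; the completion experiments run at the full
27 × 76 × 7 scale. The feedback-benefit comparison uses the default
autoregressive conditions above; its null arm zeroes the generating
feedback weight and compares REP-SVM against the identical no-feedback
learner on a matched λ grid {0.1, 0.5}, where the accuracy difference is
expected to vanish (observed ≈ 0.00 with standard error 0.016 over 20
seeds).

## Known limitations

- The ℓ1-ball constraint is projection-based, not an exact constrained
  hinge optimum.
- Non-linear wrapped models (random forest, KNN, SVR) do not serialize to
  the named-array model archive; only linear models do.
- KNN imputation is O(I²) in patients — fine at cohort scales here.
- The completion solver is dense; cohorts far beyond ~10⁵ observed
  entries would want a sparse refactor.
- Forecasting assumes the new patient is drawn from the same factor space
  as the training cohort ("common gene and time evolution bases"); no
  uncertainty intervals are attached to forecasts.
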