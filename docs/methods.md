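# Methods

## Setting and model

The target sample is a feature matrix `X ∈ R^{n×d}` (rows = instances, e.g.
differential-entropy EEG features) with labels for only `l ≪ n` instances
(integer class IDs; `−1` marks unlabeled). In addition, `q` pre-trained source
classifiers are available, each expressed as dual coefficients `α_iˢ` over the
*target* sample so that all models share one reference representation
(`W_iˢ = K α_iˢ`). A model trained elsewhere is re-expressed by kernel
least-squares projection: its decision values on the target points are solved
back through the target Gram matrix (`sources.project_model`).

The decision function is the representer expansion `f(x) = αᵀ k(x)`; classes
are encoded as one-hot targets, and the class prototypes `c_m` are the one-hot
basis vectors of label space, so labeled targets and cluster prototypes live
in the same M-dimensional output space. Prediction assigns the class whose
prototype is nearest to `f(x)` (ties to the lowest class index).

The objective combines

1. squared losses of the labeled instances and of their local weighted means
   (LWM) against the labels (weights 1 and `λ_s`),
2. membership-weighted squared losses of the unlabeled instances and their
   LWMs against the class prototypes,
3. the RKHS penalty `λ tr(αᵀKα)`,
4. the fuzzy entropy `C Σ (v² ln v² − v²)` over the per-class possibilistic
   memberships `v_m(x_j) ∈ (0, 1]` of the unlabeled instances, and
5. the adaptation term `β(Σ_i γ_i A_i + η‖γ‖²)` with
   `A_i = (1/n) ‖K(α − α_iˢ)‖²_F`, the empirical scatter-weighted divergence
   between target and source models (the identity-divergence ablation
   `A_i = (1/n)‖α − α_iˢ‖²_F` is selectable via `divergence="identity"`).

Because memberships are per-class and unnormalized, an instance far from every
class in decision space receives uniformly low memberships — this is the
mechanism that suppresses outliers, and the entropy weight `C` sets how
sharply memberships decay with distance.

## Graph and LWM conventions

Neighbors are exact Euclidean k-NN; ties at the k-th distance break toward
the lowest index (stable argsort), and an instance is never its own neighbor.
Edge weights are `exp(−τ‖x_i − x_j‖²)`. The stored graph matrix is
symmetrized with the elementwise maximum of the two directed assignments,
while the LWM of instance i uses its *directed* neighbor set — the one-sided
sum that defines the LWM. Defaults: `k = 5`;
`τ = 1/(2 · median pairwise squared distance)` when unset, a scale-robust
choice (the width is otherwise a free parameter). A τ so large that a row of
neighbor weights underflows raises a dedicated error advising to reduce τ.

## Kernels

Four bounded families with unit value at zero distance: Gaussian
`exp(−σr²)`, inverse square distance `1/(1+σr²)`, Laplacian `exp(−σr)` and
inverse distance `1/(1+σr)`. All four are positive semidefinite (the inverse
families are scale mixtures of the first two), and `σ` defaults to `1/d`.
Multi-kernel learning concatenates feature maps; since inner products are
additive across concatenated blocks, the effective Gram matrix is exactly the
sum of the member Gram matrices — no solver shape changes, no learned kernel
weights. No centering or normalization is applied. Source models must be
trained and projected in the same kernel space as the fit that consumes them;
a mismatch raises an error.

## Optimization

Alternating exact block updates:

* **α-update.** Stationarity of the objective in α gives `Hα = B` with
  `H = K S_L K + λ_s K̄ᵀS_L K̄ + K V̂ K + λ_s K̄ᵀV̂ K̄ + λK + (β/n)(Σγ_i)KK` and
  `B = K S_L Ỹ + λ_s K̄ᵀS_L Ỹ + (K + λ_s K̄ᵀ)V₂C + (β/n)KK Σγ_i α_iˢ`, where
  `S_L` is the labeled indicator, `V₂` the squared memberships (zero on
  labeled rows), `V̂` their row sums, `Ỹ` the zero-padded targets and `C` the
  prototype matrix. The system is solved symmetrically; a ridge jitter
  `1e−10·tr(H)/n` is added only if the plain solve fails, and a still-singular
  system raises an error advising a larger `λ`.
* **V-update.** `v_mj = exp(−(‖f(x_j)−c_m‖² + w‖f(x̂_j)−c_m‖²)/(2C))` with
  `w = λ_s` by default (`membership_lwm_weighted=True`, the form consistent
  with the objective's gradient); `w = 1` is available since the closed-form
  variant without the weight is also in circulation. Values are clamped below
  at 1e−300; `v² ln v²` is evaluated as 0 at `v = 0` (continuous limit).
* **γ-update.** The subproblem `min γᵀA + η‖γ‖²` on the simplex is solved by
  exact pairwise exchanges: for a pair (i, j) with mass `s`,
  `γ_i ← clip(s/2 + (A_j − A_i)/(4η), 0, s)`. Sweeps over all pairs repeat
  until no coordinate moves by more than 1e−13 (cap 500 sweeps). At
  convergence this equals the Euclidean projection of `−A/(2η)` onto the
  simplex, which the tests use as an independent oracle. `η → ∞` flattens the
  weights to `1/q`; small `η` concentrates them on the closest sources; a
  smaller `A_i` never receives a smaller weight.

Initialization follows the standard recipe: `γ⁰ = 1/q`, memberships start at
zero (so the first α-solve uses the labeled data plus the source pull), then
memberships from the closed form. Each cycle runs α → V → γ; by exactness of
every update the objective is non-increasing at every partial step, which the
solver also monitors — three consecutive increasing cycles raise a diagnostic
error, since that can only indicate a bug or severe ill-conditioning. Note the
objective may legitimately be negative: at the optimal membership the
per-entry contribution of an unlabeled instance is `−C v²`.

**Stopping.** Window rule with ℏ = 5, ε = 1e−4, N = 50 by default: stop when
`ς = |max Θ − min Θ| / |max Θ| < ε` over the last ℏ objective values (the
absolute value in the denominator guards against negative objectives), or
when the iteration budget is exhausted; the reason is logged and recorded.

**Degenerate cases.** `β = 0` reduces to the adaptation-free semi-supervised
model (`fit_sspca`; numerically identical path, sources ignored). `q = 1`
forces `γ = [1]`. `q = 0` is allowed only with `β = 0`.

## Source weighting schemes

`optimal` (the γ QP), `uniform` (`1/q`, the mean-fusion ablation),
`distance` (softmax of `−δ·MMD²` between domains, δ = 100 by default;
the squared kernel maximum mean discrepancy with the active kernel is used as
the domain distance because it is distribution-level, kernel-consistent and
cheap), and `fixed` (validated pass-through). The no-adaptation baseline
fuses decision values of independently trained classifiers by an unweighted
mean (`sources.fuse_decision_values`).

## Synthetic data and the recovery benchmark

`synthdata.make_domain` draws one isotropic Gaussian blob per class
(`n_per_class` each), optionally rotated (first two dimensions) and
translated; outliers replace a fraction of instances with uniform draws from
a doubled bounding box and carry *random* ground-truth labels; exactly
`⌈labeled_fraction·n⌉` instances are labeled, stratified over the inlier
class pools. The generator emulates EEG-style features only in scale
(moderate d, continuous, roughly Gaussian per class); it has no channel
structure, temporal correlation or heavy-tailed noise, so passing tests
demonstrate the optimization and adaptation machinery, not performance on
real recordings.

The frozen recovery benchmark (`make_recovery_task`): target with M = 3,
d = 4, 40 instances per class, class means at distance 3 along the axes,
10% labeled; a *relevant* source with the same law (different draw, fully
labeled) and a *misleading* source whose class means are rolled by one
position — classes swap places, a maximal conditional shift — plus a small
translation (0.5 per coordinate) and rotation (0.3 rad). The misleading
source deliberately overlaps the target's support: a source translated far
away would project to a near-zero model whose admixture merely shrinks
decision values without changing predictions, which would make the
uniform-fusion comparison vacuous.

Benchmark hyperparameters (`recovery_hyperparams`): solver defaults except
`β = 100` and `η = 0.01`. Both follow from the objective's structure rather
than tuning: the adaptation term is a per-sample *average* while the data
terms are sums over n ≈ 120 instances, so β must be of order n for source
knowledge to carry comparable weight; and weight *selectivity* requires the
γ-ridge to be small against the divergence scale (large η forces uniform
weights by construction). Accuracy on synthetic tasks is transductive —
unlabeled, non-outlier instances only, since outlier labels are random by
construction.

## Numerical conventions and problem sizes

Tolerances: α-residual checked at 1e−8 (relative), descent at 1e−9
(relative), γ against the projection oracle at 1e−8, membership against a
20001-point grid search at 1e−4. The test suite and the acceptance script
use tiny random instances (n = 10–20) for the oracle checks, n = 30 blob
instances for descent, and the n = 120 benchmark over 20 seeds (10 for the
multi-kernel comparison); these sizes make every check exact or
statistically stable while keeping the whole suite in the seconds range.

## Known limitations

* Dense `n×n` linear algebra throughout — intended for desk-scale n (up to a
  few thousand), not for large-scale EEG corpora.
* No automatic hyperparameter selection beyond the exhaustive grid helper;
  cross-validation is deliberately not offered for the adaptation setting,
  where training and test distributions differ.
* The membership argmax and the decision-rule argmin can disagree for points
  whose LWM sits in a different class region; predictions use the decision
  rule, memberships quantify confidence.
* Source models must share the target's class set and kernel space; the
  library validates both but does not attempt label-space alignment.
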