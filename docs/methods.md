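# Methods

## Model

`mtkernel` fits a Bayesian multitrait kernel regression to multienvironment
trial data. For `n` line × environment cells (environment-major order) and
`nT` traits, the phenotype matrix `Y` (n × nT) is modelled as

    Y = X_E B_E + U_L + U_LE + E

- `X_E B_E` — one fixed mean per environment per trait (flat prior). The
  global trait intercept and the environment effects of the usual
  `1 μ' + X_E B_E` parameterization are jointly non-identifiable, so the model
  fits the full-rank environment coding only; the overall trait mean is the
  average of environment means. This reproduces the same mean surface exactly.
- `U_L` — genetic effects of lines, `vec(U_L) ~ N(0, Σ_T ⊗ KL)`, where
  `KL = Z_L K_l Z_L'` is the chosen J × J genomic kernel expanded to cells and
  `Σ_T` is an unstructured nT × nT genetic trait covariance.
- `U_LE` — genotype × environment interaction, `vec(U_LE) ~ N(0, Σ_TE ⊗ KLE)`
  with `KLE = KL ∘ KE` the Hadamard product with the environment block kernel
  (`KE[c,c'] = 1` iff same environment). With complete env-major cells this
  equals block-diagonal copies of `K_l` — the Kronecker form with an identity
  environment covariance. Environment-scale differences are absorbed into
  `Σ_TE`, which is a separate unstructured trait covariance rather than a
  reuse of `Σ_T`; one covariance per random term matches the semantics of
  standard multitrait MCMC software and keeps the two terms separately
  interpretable.
- `E` — residuals, rows iid `N(0, R)` with unstructured `R`.

### Kernels

All four kernels consume the same scaled marker matrix: columns centered,
non-constant columns standardized to unit (population) variance, the whole
matrix divided by √p. Row inner products and squared distances are then O(1)
regardless of marker count, so `γ = 1` is scale-free for every kernel.
Monomorphic marker columns are zeroed rather than rejected (they carry no
signal and are common after subsetting).

| kernel | formula | defaults | PSD |
|---|---|---|---|
| linear (GBLUP) | `x_i'x_j` | — | yes |
| polynomial | `(γ x_i'x_j + a)^d` | γ=1, a=0, d=3 | yes for a ≥ 0 |
| sigmoid | `tanh(x_i'x_j + a)` | a=0 | not guaranteed |
| gaussian (RBF) | `exp(−γ‖x_i−x_j‖²)` | γ=1 | yes |

The sigmoid offset is fixed at 0 by default (tanh's natural zero, consistent
with the polynomial default). Squared distances for the Gaussian kernel are
computed on the same √p-scaled rows as all other kernels.

Indefinite or rank-deficient kernels are prepared for use as covariances by
symmetric eigendecomposition: eigenpairs with `λ ≤ tol·λ_max` (default
`tol = 1e−8`) are dropped and the kernel replaced by its truncated
reconstruction. Truncation rather than diagonal loading keeps the eigenspace
sampler exact on the repaired operator.

## Gibbs sampler

Each random term is parameterized in the eigenbasis of its repaired cell-level
kernel `K = V diag(λ) V'` (retained rank r): `U = V B` with independent rows
`b_m ~ N(0, λ_m Σ)`. Because the eigenvectors are orthonormal, each row's
full conditional factorizes:

    b_m | · ~ N(P_m⁻¹ R⁻¹ ẽ_m, P_m⁻¹),   P_m = R⁻¹ + Σ⁻¹/λ_m

with `ẽ_m = v_m' W` the projection of the term's partial residual. All r
rows are sampled in one batched solve. One sweep updates, in order: the
environment means, each term's coefficients, each term's trait covariance
`Σ ~ IW(v₀ + r, S₀ + B'D⁻¹B)`, the residual covariance
`R ~ IW(v_R + n, S_R + E'E)`, and finally every missing trait entry, redrawn
from the Gaussian conditional of its row's linear predictor given the row's
observed traits. That last step is what makes the MT_P scenario work: an
observed auxiliary trait pulls the imputation of a masked target trait
through the off-diagonals of `R`.

Numerical choices and degenerate inputs:

- inverse-Wishart convention: prior mean `S/(v − nT − 1)`; draws via
  `scipy.stats.invwishart` (Wishart-of-inverse route). df conventions differ
  across software, hence this explicit statement.
- default priors: `v₀ = nT + 2` for every covariance (weakly informative,
  finite mean); `S₀` set so the prior mean of each random term's trait
  covariance is `(0.5/#terms)·diag(sample trait variances of observed Y)` and
  the prior mean of `R` is `0.5·`the same diagonal — a standard
  variance-partition heuristic.
- default chain: 10 000 iterations, 2 000 burn-in, thin 5 (production);
  the test suite uses shorter chains (400–6 000) at small J.
- missing entries start at their trait's observed within-environment mean,
  falling back to the global trait mean; environments with < 2 observed cells
  for a trait trigger a logged warning (their mean is weakly determined).
- covariances can be pinned to known matrices (`fix_sigma_t`, `fix_residual`,
  `include_env_means=False`), which turns the sampler into a conjugate model
  with a closed-form posterior mean — the basis of the BLUP and ridge
  equivalence tests.
- one `numpy` Generator seeded from `ModelSpec.seed` drives the whole chain;
  identical (data, spec, seed) gives bit-identical draws. Library-level
  utilities use named substreams of a single process seed.

Ties and degeneracies: a kernel with no positive eigenvalue raises; a
singular observed-trait block in the imputation conditional raises with the
offending indices; non-PSD row covariances are rejected at a relative
tolerance of 1e−8.

## Cross-validation protocol

Cells (not lines) are partitioned uniformly at random into k = 5 folds with
sizes differing by at most one, so lines are typically trained in some
environments and predicted in others (the CV2 design of incomplete trials).
Scenario MT masks every trait of test cells; MT_P masks only the target
traits. Prediction for a masked entry is the posterior mean of its imputed
value; MSE is computed per (fold, environment, trait) over entries that are
observed in the truth but masked for fitting, averaged over folds, and then
averaged (unweighted) over environments — not pooled over cells. Methods in
a grid share byte-identical folds and masks (paired design), and comparisons
are reported as `100·(MSE_ref − MSE_cand)/MSE_cand`. The CLI exposes `brr`
as a method name but fits the linear-kernel model: Gaussian iid marker
effects are posterior-predictive-equivalent to linear-kernel GBLUP, and an
explicit marker-effect sampler is deliberately out of scope.

## Synthetic data

The simulator draws from the generative model itself: marker codes {0,1,2}
with per-marker allele frequencies uniform on (0.1, 0.9); genetic effects in
kernel space (matrix-normal with row covariance `K`), so any kernel —
including Gaussian — can be the true architecture; G×E effects on `KL ∘ KE`;
iid residual rows; completely-at-random missingness. A marker-effect mode
draws iid multivariate-normal marker effects instead, creating an exactly
linear truth for the GBLUP/ridge equivalence checks. All components are
stored, and they reconstruct the unmasked phenotypes with zero error.

Default shape: J = 150 lines, p = 300 markers, I = 3 environments, nT = 2
traits, genetic trait correlation 0.9 (variance 1), G×E variance 0.3 with the
same correlation, residual variance 0.5 with correlation 0.9, environment
mean sd 1. This is a desk-scale rendition of an elite yield trial — real
trials of this kind have 700–1000 lines, ~2000 markers, 4–5 environments,
and maturity traits correlated up to ~0.98 — sized so a full fit takes
seconds rather than hours.

For the kernel-discrimination experiment (Gaussian vs linear under a
nonlinear truth) the truth uses `γ = 5` and a high-heritability setting
(genetic variance 1, G×E 0.1, residual 0.2). With `γ = 1` the Gaussian
kernel on scaled markers is nearly an affine transform of the linear kernel
(inner products are O(0.1), so the exponential is locally linear), and the
two models are statistically indistinguishable at desk scale; `γ = 5` makes
the kernel genuinely local and the mis-specification cost of the linear
model material, which is what the experiment is designed to measure.

## What the synthetic tests do and do not show

Passing recovery and ordering tests show the sampler targets the right
posterior and the protocol measures what it claims under the model's own
assumptions: unlinked markers, Gaussian effects, homogeneous residual
covariance across environments, missingness completely at random. Real
trials violate all of these to some degree — linkage disequilibrium and
pedigree structure among lines, non-Gaussian trait distributions,
heterogeneous error variances per environment, structured missingness — so
synthetic results say nothing about the size of kernel-method advantages on
any particular real dataset, only that the machinery is correct.

## Known limitations

- No REML/frequentist fitting, no convergence diagnostics beyond stored
  covariance traces (effective sample size can be computed externally from
  the saved draws), no per-environment residual covariances.
- Kernel hyperparameters are not tuned internally; the grid is the user's.
- The environment covariance of the interaction term is fixed at identity
  (absorbed into `Σ_TE`); a free diagonal environment covariance is not
  estimable from the Hadamard construction alone.
- Cell-level kernels are eigendecomposed densely; fine up to a few thousand
  cells, not intended for n ≫ 10⁴.
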