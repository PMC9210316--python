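"""Gibbs sampler for the Bayesian multitrait multienvironment kernel model.

The model for the n x nT phenotype matrix Y (n = line x environment cells,
nT traits, cells ordered environment-major) is

    Y = X_E B_E + U_L + U_LE + E

where X_E B_E are per-environment, per-trait fixed means (the global trait
intercept is absorbed into the environment means, which keeps the mean part
identifiable), U_L is the cell-level genetic effect with covariance
KL (x) Sigma_T, U_LE the genotype-by-environment effect with covariance
KLE (x) Sigma_TE, and the rows of E are iid N(0, R).  KL is the expanded line
kernel, KLE = KL o KE its Hadamard product with the environment block kernel,
and Sigma_T, Sigma_TE, R are unstructured nT x nT covariances with
inverse-Wishart priors.

Sampling works in the eigenbasis of each (spectrally repaired) cell-level
kernel: writing K = V diag(lambda) V', the effect is U = V B with independent
rows b_m ~ N(0, lambda_m Sigma).  Because the eigenvectors are orthonormal,
the full conditional of each row factorizes:

    b_m | rest ~ N(P_m^-1 R^-1 e_m, P_m^-1),  P_m = R^-1 + Sigma^-1 / lambda_m

with e_m = v_m' W the projection of the partial residual W onto eigenvector m.
Covariance updates are conjugate inverse-Wisharts; missing trait entries are
re-imputed each sweep from the Gaussian conditional of the row's linear
predictor given its observed traits (the mechanism that powers the MT_P
scenario).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .kernels import (
    InvalidInputError,
    KernelMatrix,
    KernelParams,
    MarkerMatrix,
    build_kernel,
    env_block_kernel,
    expand_line_kernel,
    interaction_kernel,
    scale_markers,
    spectral_decompose,
)
from .mvsampling import InverseWishartPrior, conditional_normal_split, sample_inverse_wishart

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeTable",
    "ModelSpec",
    "FittedModel",
    "fit_multitrait",
    "predict",
    "genetic_correlations",
]


@dataclass
class PhenotypeTable:
    """n cells x nT traits with an observed/missing mask and cell-to-line/env maps.

    ``mask`` is True where the trait value is observed; stored values under
    masked-out entries carry no information.  ``line_of_cell``/``env_of_cell``
    are integer indices into ``line_ids``/``env_ids``.
    """

    values: np.ndarray
    mask: np.ndarray
    line_of_cell: np.ndarray
    env_of_cell: np.ndarray
    trait_names: list
    line_ids: list
    env_ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.line_of_cell = np.asarray(self.line_of_cell, dtype=int)
        self.env_of_cell = np.asarray(self.env_of_cell, dtype=int)
        self.trait_names = list(self.trait_names)
        self.line_ids = list(self.line_ids)
        self.env_ids = list(self.env_ids)
        n, nT = self.values.shape
        if self.mask.shape != (n, nT):
            raise InvalidInputError("mask shape must match values")
        if len(self.trait_names) != nT:
            raise InvalidInputError("trait_names length must equal number of trait columns")
        if self.line_of_cell.shape != (n,) or self.env_of_cell.shape != (n,):
            raise InvalidInputError("cell maps must have one entry per row")
        pairs = set(zip(self.line_of_cell.tolist(), self.env_of_cell.tolist()))
        if len(pairs) != n:
            raise InvalidInputError("(line, environment) pairs must be unique")
        if set(range(len(self.line_ids))) - set(self.line_of_cell.tolist()):
            raise InvalidInputError("every line must occur in at least one cell")
        if set(range(len(self.env_ids))) - set(self.env_of_cell.tolist()):
            raise InvalidInputError("every environment must occur in at least one cell")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    @property
    def n_envs(self) -> int:
        return len(self.env_ids)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)


@dataclass
class ModelSpec:
    """Configuration of one model fit.

    kernel_name/kernel_params select the genomic kernel; include_gxe adds the
    Hadamard interaction term.  Priors default to weakly informative
    inverse-Wisharts with df = nT + 2 and scale chosen so the prior mean of
    each random term's trait covariance is (0.5 / #terms) x diag(sample trait
    variances) and the prior mean of R is 0.5 x the same diagonal.

    ``fix_sigma_t`` / ``fix_sigma_te`` / ``fix_residual`` pin the corresponding
    covariance to a known matrix and disable its update — used for conjugate
    closed-form cross-checks.  ``include_env_means=False`` drops the fixed
    mean part (data must then be pre-centered).  ``save_effects=True``
    additionally stores per-saved-iteration cell-level genetic effects.
    """

    kernel_name: str = "linear"
    kernel_params: KernelParams = field(default_factory=KernelParams)
    include_gxe: bool = False
    n_iter: int = 10_000
    burn_in: int = 2_000
    thin: int = 5
    seed: int = 0
    prior_sigma_t: InverseWishartPrior | None = None
    prior_sigma_te: InverseWishartPrior | None = None
    prior_residual: InverseWishartPrior | None = None
    fix_sigma_t: np.ndarray | None = None
    fix_sigma_te: np.ndarray | None = None
    fix_residual: np.ndarray | None = None
    include_env_means: bool = True
    save_effects: bool = False

    def __post_init__(self) -> None:
        if self.n_iter <= 0 or self.thin <= 0:
            raise InvalidInputError("n_iter and thin must be positive")
        if not (0 <= self.burn_in < self.n_iter):
            raise InvalidInputError(
                f"burn_in must lie in [0, n_iter); got burn_in={self.burn_in}, n_iter={self.n_iter}"
            )

    @property
    def n_saved(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class FittedModel:
    """Posterior draws and summaries from one Gibbs run.

    draws hold, per saved iteration: environment means (S x I x nT), each
    random term's trait covariance and R (S x nT x nT).  The linear predictor
    and the imputed phenotype matrix are summarized online (posterior mean and
    sd over saved iterations) for every cell; optional full effect draws per
    term when requested.
    """

    spec: ModelSpec
    data: PhenotypeTable
    term_names: list
    env_means_draws: np.ndarray
    sigma_draws: dict
    residual_draws: np.ndarray
    linear_predictor_mean: np.ndarray
    linear_predictor_sd: np.ndarray
    imputed_mean: np.ndarray
    imputed_sd: np.ndarray
    effect_mean: dict
    effect_sd: dict
    effect_draws: dict | None = None

    @property
    def n_saved(self) -> int:
        return self.residual_draws.shape[0]


class _Welford:
    """Online mean/sd accumulator for matrices."""

    def __init__(self, shape):
        self.n = 0
        self.mean = np.zeros(shape)
        self.m2 = np.zeros(shape)

    def update(self, x):
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self.m2 += delta * (x - self.mean)

    @property
    def sd(self):
        if self.n < 2:
            return np.zeros_like(self.mean)
        return np.sqrt(self.m2 / (self.n - 1))


def _default_priors(data: PhenotypeTable, spec: ModelSpec, n_terms: int):
    """Variance-partition heuristic priors (see ModelSpec docstring)."""
    nT = data.n_traits
    obs_var = np.array([
        np.var(data.values[data.mask[:, t], t], ddof=1) if data.mask[:, t].sum() > 1 else 1.0
        for t in range(nT)
    ])
    obs_var = np.where(np.isfinite(obs_var) & (obs_var > 0), obs_var, 1.0)
    df = nT + 2  # prior mean = scale / (df - nT - 1) = scale
    term_scale = np.diag(0.5 * obs_var / n_terms)
    res_scale = np.diag(0.5 * obs_var)
    prior_t = spec.prior_sigma_t or InverseWishartPrior(df=df, scale=term_scale)
    prior_te = spec.prior_sigma_te or InverseWishartPrior(df=df, scale=term_scale)
    prior_r = spec.prior_residual or InverseWishartPrior(df=df, scale=res_scale)
    return prior_t, prior_te, prior_r


def _initial_imputation(data: PhenotypeTable) -> np.ndarray:
    """Start missing entries at the trait's observed within-environment mean."""
    Y = data.values.copy()
    for t in range(data.n_traits):
        obs_t = data.mask[:, t]
        global_mean = Y[obs_t, t].mean() if obs_t.any() else 0.0
        for e in range(data.n_envs):
            in_env = data.env_of_cell == e
            fill = in_env & ~data.mask[:, t]
            if not fill.any():
                continue
            obs_e = in_env & obs_t
            Y[fill, t] = Y[obs_e, t].mean() if obs_e.any() else global_mean
    return Y


def _build_cell_kernels(data: PhenotypeTable, markers: MarkerMatrix, spec: ModelSpec):
    """Line kernel -> expanded cell kernels, spectrally prepared for the sampler."""
    if set(data.line_ids) - set(markers.line_ids):
        missing = sorted(set(data.line_ids) - set(markers.line_ids))[:5]
        raise InvalidInputError(f"phenotype lines missing from marker matrix: {missing} ...")
    order = [markers.line_ids.index(lid) for lid in data.line_ids]
    markers = MarkerMatrix(markers.values[order], list(data.line_ids), scaled=markers.scaled)
    X = scale_markers(markers) if not markers.scaled else markers
    K_line = build_kernel(X, spec.kernel_name, spec.kernel_params)
    KL = expand_line_kernel(K_line, data.line_of_cell)
    terms: dict[str, KernelMatrix] = {"lines": spectral_decompose(KL)}
    if spec.include_gxe:
        KE = env_block_kernel(data.env_of_cell, row_ids=KL.row_ids)
        terms["gxe"] = spectral_decompose(interaction_kernel(KL, KE))
    return terms


def fit_multitrait(data: PhenotypeTable, markers: MarkerMatrix, spec: ModelSpec) -> FittedModel:
    """Run the Gibbs sampler and return draws plus online posterior summaries.

    Each sweep samples, in order: the per-environment fixed means (flat
    prior), the eigenbasis coefficients of each random term, each term's trait
    covariance (inverse-Wishart), the residual covariance R, and finally new
    imputations for every missing trait entry.  Deterministic given
    (seed, spec, data).
    """
    n, nT = data.n_cells, data.n_traits
    rng = np.random.default_rng(np.random.SeedSequence(int(spec.seed)))
    kernels_by_term = _build_cell_kernels(data, markers, spec)
    term_names = list(kernels_by_term)
    prior_t, prior_te, prior_r = _default_priors(data, spec, len(term_names))
    priors = {"lines": prior_t, "gxe": prior_te}
    fixed_cov = {"lines": spec.fix_sigma_t, "gxe": spec.fix_sigma_te}
    for name, mat in fixed_cov.items():
        if mat is not None:
            fixed_cov[name] = np.atleast_2d(np.asarray(mat, dtype=float))
    fix_R = None if spec.fix_residual is None else np.atleast_2d(np.asarray(spec.fix_residual, float))

    if spec.include_env_means:
        for e in range(data.n_envs):
            for t in range(nT):
                n_obs = int((data.mask[:, t] & (data.env_of_cell == e)).sum())
                if n_obs < 2:
                    logger.warning(
                        "environment %s has %d observed cells for trait %s; "
                        "its mean is weakly determined",
                        data.env_ids[e], n_obs, data.trait_names[t],
                    )

    # state
    Yimp = _initial_imputation(data)
    V = {name: k.eigenvectors for name, k in kernels_by_term.items()}
    lam = {name: k.eigenvalues for name, k in kernels_by_term.items()}
    B = {name: np.zeros((len(lam[name]), nT)) for name in term_names}
    U = {name: np.zeros((n, nT)) for name in term_names}
    Sigma = {
        name: (fixed_cov[name] if fixed_cov[name] is not None
               else priors[name].scale / (priors[name].df - nT - 1))
        for name in term_names
    }
    R = fix_R if fix_R is not None else prior_r.scale / (prior_r.df - nT - 1)
    beta = np.zeros((data.n_envs, nT))
    env_counts = np.bincount(data.env_of_cell, minlength=data.n_envs)
    miss_any = (~data.mask).any()
    patterns = _missing_patterns(data.mask) if miss_any else []

    n_saved = spec.n_saved
    env_means_draws = np.zeros((n_saved, data.n_envs, nT))
    sigma_draws = {name: np.zeros((n_saved, nT, nT)) for name in term_names}
    residual_draws = np.zeros((n_saved, nT, nT))
    mu_acc = _Welford((n, nT))
    imp_acc = _Welford((n, nT))
    eff_acc = {name: _Welford((n, nT)) for name in term_names}
    effect_draws = {name: np.zeros((n_saved, n, nT)) for name in term_names} if spec.save_effects else None

    saved = 0
    for it in range(spec.n_iter):
        U_total = sum(U.values()) if term_names else np.zeros((n, nT))

        # (1) fixed environment means, flat prior
        if spec.include_env_means:
            W = Yimp - U_total
            chol_R = np.linalg.cholesky(R)
            for e in range(data.n_envs):
                rows = data.env_of_cell == e
                zb = rng.standard_normal(nT)
                beta[e] = W[rows].mean(axis=0) + (chol_R @ zb) / np.sqrt(env_counts[e])
        F = beta[data.env_of_cell] if spec.include_env_means else np.zeros((n, nT))

        # (2) eigenbasis coefficients of each random term
        R_inv = np.linalg.inv(R)
        for name in term_names:
            W = Yimp - F - (U_total - U[name])
            E_proj = V[name].T @ W  # r x nT
            S_inv = np.linalg.inv(Sigma[name])
            P = R_inv[None, :, :] + S_inv[None, :, :] / lam[name][:, None, None]
            b_mean = np.linalg.solve(P, (E_proj @ R_inv)[:, :, None])[:, :, 0]
            L = np.linalg.cholesky(P)
            z = rng.standard_normal(E_proj.shape)
            noise = np.linalg.solve(np.transpose(L, (0, 2, 1)), z[:, :, None])[:, :, 0]
            B[name] = b_mean + noise
            U[name] = V[name] @ B[name]
            U_total = sum(U.values())

            # (3) trait covariance of the term
            if fixed_cov[name] is None:
                r_rank = len(lam[name])
                S_post = priors[name].scale + B[name].T @ (B[name] / lam[name][:, None])
                Sigma[name] = sample_inverse_wishart(
                    InverseWishartPrior(df=priors[name].df + r_rank, scale=S_post), rng
                )

        # (4) residual covariance
        E_resid = Yimp - F - U_total
        if fix_R is None:
            R = sample_inverse_wishart(
                InverseWishartPrior(df=prior_r.df + n, scale=prior_r.scale + E_resid.T @ E_resid),
                rng,
            )

        # (5) re-impute missing traits from the row-wise Gaussian conditional
        Mu = F + U_total
        if miss_any:
            _impute(Yimp, data.values, Mu, R, patterns, rng)

        if it + 1 > spec.burn_in and (it + 1 - spec.burn_in) % spec.thin == 0:
            env_means_draws[saved] = beta
            for name in term_names:
                sigma_draws[name][saved] = Sigma[name]
                if effect_draws is not None:
                    effect_draws[name][saved] = U[name]
                eff_acc[name].update(U[name])
            residual_draws[saved] = R
            mu_acc.update(Mu)
            imp_acc.update(Yimp)
            saved += 1

        if (it + 1) % 100 == 0:
            corr = _corr_from_cov(Sigma[term_names[0]]) if term_names else np.eye(nT)
            logger.debug(
                "iter %d/%d | resid var %s | trait corr %s",
                it + 1, spec.n_iter, np.round(np.diag(R), 3), np.round(corr[0, -1], 3),
            )

    return FittedModel(
        spec=spec,
        data=data,
        term_names=term_names,
        env_means_draws=env_means_draws,
        sigma_draws=sigma_draws,
        residual_draws=residual_draws,
        linear_predictor_mean=mu_acc.mean,
        linear_predictor_sd=mu_acc.sd,
        imputed_mean=imp_acc.mean,
        imputed_sd=imp_acc.sd,
        effect_mean={name: eff_acc[name].mean for name in term_names},
        effect_sd={name: eff_acc[name].sd for name in term_names},
        effect_draws=effect_draws,
    )


def _missing_patterns(mask: np.ndarray):
    """Group row indices by missing pattern for vectorized imputation."""
    patterns = []
    pat, inverse = np.unique(~mask, axis=0, return_inverse=True)
    for k, p in enumerate(pat):
        if not p.any():
            continue
        patterns.append((p, np.where(inverse == k)[0]))
    return patterns


def _impute(Yimp, Yobs, Mu, R, patterns, rng):
    for miss, rows in patterns:
        obs = ~miss
        m_idx = np.where(miss)[0]
        if not obs.any():
            chol_R = np.linalg.cholesky(R)
            z = rng.standard_normal((len(rows), len(m_idx)))
            Yimp[np.ix_(rows, m_idx)] = Mu[rows] + z @ chol_R.T
            continue
        o_idx = np.where(obs)[0]
        S_oo = R[np.ix_(o_idx, o_idx)]
        S_om = R[np.ix_(o_idx, m_idx)]
        S_mm = R[np.ix_(m_idx, m_idx)]
        A = np.linalg.solve(S_oo, S_om)  # (n_o x n_m)
        cond_cov = S_mm - S_om.T @ A
        cond_cov = 0.5 * (cond_cov + cond_cov.T)
        chol_c = np.linalg.cholesky(cond_cov)
        resid_o = Yobs[np.ix_(rows, o_idx)] - Mu[np.ix_(rows, o_idx)]
        cond_mean = Mu[np.ix_(rows, m_idx)] + resid_o @ A
        z = rng.standard_normal((len(rows), len(m_idx)))
        Yimp[np.ix_(rows, m_idx)] = cond_mean + z @ chol_c.T


def predict(fit: FittedModel, cells: Sequence[int] | None = None) -> np.ndarray:
    """Posterior-mean predictions for the requested cells (default: all).

    Entries that were missing during fitting get the posterior mean of their
    imputed value — which conditions on the row's observed traits through R
    (the MT_P mechanism) — while observed entries get the posterior mean of
    the linear predictor.
    """
    n = fit.data.n_cells
    if cells is None:
        idx = np.arange(n)
    else:
        idx = np.asarray(cells, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= n):
            raise KeyError(f"cell index outside 0..{n - 1}")
    out = np.where(fit.data.mask, fit.linear_predictor_mean, fit.imputed_mean)
    return out[idx]


def _corr_from_cov(S: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(S))
    C = S / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return C


def genetic_correlations(fit: FittedModel, term: str = "lines") -> np.ndarray:
    """Posterior mean of the trait correlation matrix of a random term.

    The correlation is computed per saved Sigma draw and then averaged, so the
    diagonal is exactly 1 and entries lie in [-1, 1].
    """
    draws = fit.sigma_draws[term]
    C = np.mean([_corr_from_cov(S) for S in draws], axis=0)
    np.fill_diagonal(C, 1.0)
    return C
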