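"""Synthetic marker and multitrait multienvironment phenotype generator.

Data are drawn from the same generative model the sampler fits: biallelic
marker codes {0,1,2} with per-marker allele frequencies, a genomic kernel
built from the scaled markers, line effects g ~ MN(0, K_line, Sigma_T),
genotype-by-environment effects gE ~ MN(0, KL o KE, Sigma_TE), per-environment
trait means, and iid residual rows N(0, R).  All generating components are
stored so recovery and scenario tests have exact ground truth.

The default shape is a desk-scale version of an elite multienvironment wheat
trial: J=150 lines, p=300 markers, I=3 environments, nT=2 traits with genetic
correlation 0.9 (real trials of this kind run to hundreds of lines, ~2000
markers, 4-5 environments, and maturity-trait correlations up to ~0.98).
A marker-effect mode (g = X beta with iid multivariate-normal marker effects)
provides an exactly-linear truth for GBLUP/ridge equivalence checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import (
    InvalidInputError,
    KernelParams,
    MarkerMatrix,
    build_kernel,
    env_block_kernel,
    expand_line_kernel,
    interaction_kernel,
    scale_markers,
    spectral_decompose,
)
from .model import PhenotypeTable
from .mvsampling import sample_matrix_normal, substream

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate_markers", "simulate_multitrait"]


def _corr_cov(var: float, corr: float, nT: int) -> np.ndarray:
    C = np.full((nT, nT), corr, dtype=float)
    np.fill_diagonal(C, 1.0)
    return var * C


@dataclass
class SimulationConfig:
    """Shapes, generating covariances, and kernel of the synthetic trial.

    Defaults: genetic trait correlation 0.9 (variance 1), G x E at 30% of the
    genetic variance with the same correlation, residual variance 0.5 with
    correlation 0.9 (the trait pairs of interest are highly correlated both
    genetically and residually), environment mean sd 1, no missing data.
    """

    n_lines: int = 150
    n_markers: int = 300
    n_envs: int = 3
    n_traits: int = 2
    freq_range: tuple = (0.1, 0.9)
    env_effect_sd: float = 1.0
    kernel_name: str = "linear"
    kernel_params: KernelParams = field(default_factory=KernelParams)
    sigma_t: np.ndarray | None = None
    sigma_te: np.ndarray | None = None
    residual_cov: np.ndarray | None = None
    marker_effect_mode: bool = False
    missing_rate: float = 0.0
    seed: int = 0
    marker_seed: int | None = None  # fix the marker panel across replicate seeds

    def __post_init__(self) -> None:
        if min(self.n_lines, self.n_markers, self.n_envs, self.n_traits) < 1:
            raise InvalidInputError("J, p, I, nT must all be >= 1")
        lo, hi = self.freq_range
        if not (0 < lo <= hi < 1):
            raise InvalidInputError(f"allele frequency range must lie inside (0,1), got {self.freq_range}")
        if not 0 <= self.missing_rate < 1:
            raise InvalidInputError("missing_rate must lie in [0, 1)")
        nT = self.n_traits
        if self.sigma_t is None:
            self.sigma_t = _corr_cov(1.0, 0.9 if nT > 1 else 0.0, nT)
        if self.sigma_te is None:
            self.sigma_te = _corr_cov(0.3, 0.9 if nT > 1 else 0.0, nT)
        if self.residual_cov is None:
            self.residual_cov = _corr_cov(0.5, 0.9 if nT > 1 else 0.0, nT)
        for name in ("sigma_t", "sigma_te", "residual_cov"):
            M = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            if M.shape != (nT, nT):
                raise InvalidInputError(f"{name} must be {nT}x{nT}")
            try:
                np.linalg.cholesky(M)
            except np.linalg.LinAlgError as exc:
                raise InvalidInputError(f"{name} must be positive definite") from exc
            setattr(self, name, M)


@dataclass
class SimulatedDataset:
    """Markers, phenotypes, and the exact generating components."""

    markers: MarkerMatrix
    phenotypes: PhenotypeTable
    env_means: np.ndarray          # I x nT
    g: np.ndarray                  # J x nT line effects
    gE: np.ndarray                 # n x nT interaction effects
    residuals: np.ndarray          # n x nT
    linear_predictor: np.ndarray   # n x nT (fixed + genetic + interaction)
    config: SimulationConfig


def simulate_markers(config: SimulationConfig) -> MarkerMatrix:
    """Biallelic genotype codes: freq ~ U(range) per marker, codes ~ Binomial(2, freq)."""
    seed = config.seed if config.marker_seed is None else config.marker_seed
    rng = substream(seed, "markers")
    freqs = rng.uniform(*config.freq_range, size=config.n_markers)
    codes = rng.binomial(2, freqs, size=(config.n_lines, config.n_markers)).astype(float)
    line_ids = [f"L{i + 1:04d}" for i in range(config.n_lines)]
    return MarkerMatrix(values=codes, line_ids=line_ids, scaled=False)


def simulate_multitrait(config: SimulationConfig) -> SimulatedDataset:
    """Draw one complete dataset, environment-major cell order, with stored truth."""
    markers = simulate_markers(config)
    X = scale_markers(markers)
    J, I, nT = config.n_lines, config.n_envs, config.n_traits
    n = J * I
    # env-major complete layout: cells ordered by (environment, line)
    env_of_cell = np.repeat(np.arange(I), J)
    line_of_cell = np.tile(np.arange(J), I)

    if config.marker_effect_mode:
        beta = sample_matrix_normal(
            np.eye(config.n_markers), config.sigma_t, substream(config.seed, "marker_effects")
        )
        g = X.values @ beta  # implies g ~ MN(0, X X', Sigma_T): the linear-kernel truth
        K_line = build_kernel(X, "linear")
    else:
        K_line = build_kernel(X, config.kernel_name, config.kernel_params)
        K_rep = spectral_decompose(K_line)
        g = sample_matrix_normal(K_rep.values, config.sigma_t, substream(config.seed, "g"))

    KL = expand_line_kernel(K_line, line_of_cell)
    KE = env_block_kernel(env_of_cell)
    KLE = spectral_decompose(interaction_kernel(KL, KE))
    gE = sample_matrix_normal(KLE.values, config.sigma_te, substream(config.seed, "gE"))

    rng_env = substream(config.seed, "env_means")
    env_means = config.env_effect_sd * rng_env.standard_normal((I, nT))
    eps = sample_matrix_normal(np.eye(n), config.residual_cov, substream(config.seed, "residual"))

    linear_predictor = env_means[env_of_cell] + g[line_of_cell] + gE
    Y = linear_predictor + eps

    mask = np.ones((n, nT), dtype=bool)
    if config.missing_rate > 0:
        rng_miss = substream(config.seed, "missing")
        mask = rng_miss.uniform(size=(n, nT)) >= config.missing_rate
        # keep every line/env represented: never blank out an entire trait column
        for t in range(nT):
            if not mask[:, t].any():
                mask[rng_miss.integers(n), t] = True

    phenotypes = PhenotypeTable(
        values=Y,
        mask=mask,
        line_of_cell=line_of_cell,
        env_of_cell=env_of_cell,
        trait_names=[f"trait{t + 1}" for t in range(nT)],
        line_ids=list(markers.line_ids),
        env_ids=[f"E{e + 1}" for e in range(I)],
    )
    return SimulatedDataset(
        markers=markers,
        phenotypes=phenotypes,
        env_means=env_means,
        g=g,
        gE=gE,
        residuals=eps,
        linear_predictor=linear_predictor,
        config=config,
    )
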