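"""Distributional primitives for the Gibbs sampler.

Three operations:

* matrix-variate normal draws ``G ~ MN(0, U, V)`` (vec(G) ~ N(0, V (x) U)),
  with rank-deficient row covariances handled through their positive
  eigenpairs so repaired kernels are accepted;
* inverse-Wishart draws for trait and residual covariance matrices, with the
  convention that the prior mean is ``S / (v - nT - 1)`` (df conventions differ
  across software, so this is stated explicitly);
* Gaussian conditioning of a trait vector on an observed subset, the mechanism
  behind missing-trait imputation and the MT_P prediction scenario.

All randomness flows through numpy Generators.  :func:`substream` derives a
named, reproducible substream from one process-wide seed so whole-pipeline
runs are reproducible from a single integer.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.stats import invwishart

__all__ = [
    "InvalidCovarianceError",
    "InvalidPriorError",
    "InverseWishartPrior",
    "substream",
    "as_rng",
    "sample_matrix_normal",
    "sample_inverse_wishart",
    "conditional_normal_split",
]

#: eigenvalues below -PSD_TOL * lambda_max flag a non-PSD covariance
PSD_TOL = 1e-8


class InvalidCovarianceError(ValueError):
    """Raised when a matrix offered as a covariance is not (numerically) PSD."""


class InvalidPriorError(ValueError):
    """Raised when inverse-Wishart prior parameters are out of range."""


@dataclass
class InverseWishartPrior:
    """Inverse-Wishart prior IW(df, scale) for an nT x nT covariance.

    Requires df > nT - 1; the prior mean is scale / (df - nT - 1) when
    df > nT + 1.
    """

    df: float
    scale: np.ndarray

    def __post_init__(self) -> None:
        self.scale = np.asarray(self.scale, dtype=float)
        if self.scale.ndim == 0:
            self.scale = self.scale.reshape(1, 1)
        p = self.scale.shape[0]
        if self.scale.shape != (p, p):
            raise InvalidPriorError("scale must be square")
        if not np.allclose(self.scale, self.scale.T):
            raise InvalidPriorError("scale must be symmetric")
        if self.df <= p - 1:
            raise InvalidPriorError(f"df must exceed dim-1 = {p - 1}, got {self.df}")
        try:
            np.linalg.cholesky(self.scale)
        except np.linalg.LinAlgError as exc:
            raise InvalidPriorError("scale matrix is not positive definite") from exc

    @property
    def dim(self) -> int:
        return self.scale.shape[0]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named reproducible substream of a single process-wide seed."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _row_cov_factor(row_cov: np.ndarray) -> np.ndarray:
    """Square-root factor of a PSD (possibly rank-deficient) row covariance.

    Uses the positive eigenpairs only, so spectrally repaired kernels pass
    through exactly.  Returns an m x r matrix F with F F' = row_cov.
    """
    row_cov = np.asarray(row_cov, dtype=float)
    w, V = np.linalg.eigh(0.5 * (row_cov + row_cov.T))
    lam_max = max(w[-1], 0.0)
    if w[0] < -PSD_TOL * max(lam_max, 1.0):
        raise InvalidCovarianceError(
            f"row covariance has negative eigenvalue {w[0]:g}"
        )
    keep = w > 0
    return V[:, keep] * np.sqrt(w[keep])


def sample_matrix_normal(row_cov, col_cov, rng_seed) -> np.ndarray:
    """Draw G ~ MN(0, row_cov, col_cov), i.e. vec(G) ~ N(0, col_cov (x) row_cov).

    ``row_cov`` may be rank-deficient (handled by eigendecomposition);
    ``col_cov`` must be SPD.  Deterministic given the seed / generator state.
    """
    rng = as_rng(rng_seed)
    F = _row_cov_factor(row_cov)
    col_cov = np.atleast_2d(np.asarray(col_cov, dtype=float))
    L = np.linalg.cholesky(col_cov)
    m, r = np.asarray(row_cov).shape[0], F.shape[1]
    Z = rng.standard_normal((r, col_cov.shape[0]))
    return F @ Z @ L.T


def sample_inverse_wishart(prior: InverseWishartPrior, rng_seed) -> np.ndarray:
    """One SPD draw from IW(df, scale); prior mean is scale/(df - nT - 1)."""
    rng = as_rng(rng_seed)
    draw = invwishart.rvs(df=prior.df, scale=prior.scale, random_state=rng)
    return np.atleast_2d(draw)


def conditional_normal_split(mean, cov, observed_idx, observed_values):
    """Condition N(mean, cov) on a subset of observed coordinates.

    Returns (cond_mean, cond_cov) for the missing coordinates, in their
    original order:

        mu_m + S_mo S_oo^-1 (y_o - mu_o),   S_mm - S_mo S_oo^-1 S_om

    With no observed coordinates the input mean and covariance are returned;
    with all coordinates observed the result is an empty vector and matrix.
    """
    mean = np.asarray(mean, dtype=float)
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    p = mean.shape[0]
    obs = np.zeros(p, dtype=bool)
    obs[np.asarray(observed_idx, dtype=int)] = True
    miss = ~obs
    if not obs.any():
        return mean.copy(), cov.copy()
    y_o = np.asarray(observed_values, dtype=float)
    S_oo = cov[np.ix_(obs, obs)]
    S_mo = cov[np.ix_(miss, obs)]
    S_mm = cov[np.ix_(miss, miss)]
    try:
        A = np.linalg.solve(S_oo, S_mo.T)  # S_oo^-1 S_om
    except np.linalg.LinAlgError as exc:
        raise InvalidCovarianceError(
            f"observed-block covariance is singular (observed idx {np.where(obs)[0]})"
        ) from exc
    cond_mean = mean[miss] + A.T @ (y_o - mean[obs])
    cond_cov = S_mm - S_mo @ A
    cond_cov = 0.5 * (cond_cov + cond_cov.T)
    return cond_mean, cond_cov
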