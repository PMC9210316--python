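"""Marker scaling, genomic kernels, and kernel expansion to line x environment cells.

The genetic similarity between lines is encoded in a J x J kernel matrix built
from the scaled marker matrix X.  Four kernels are supported:

* linear   : K(x_i, x_j) = x_i' x_j            (the VanRaden-style genomic
             relationship matrix; random effects with this kernel are GBLUP)
* polynomial: K(x_i, x_j) = (gamma x_i' x_j + a)^d
* sigmoid  : K(x_i, x_j) = tanh(x_i' x_j + a)  (not guaranteed PSD)
* gaussian : K(x_i, x_j) = exp(-gamma ||x_i - x_j||^2)   (radial basis function)

All kernels consume the same scaled marker matrix: columns centered, non-constant
columns standardized to unit variance, and the whole matrix divided by sqrt(p).
With that scaling row inner products and squared distances are O(1) regardless
of the number of markers, so gamma = 1 is a sensible default for every kernel.

For a multienvironment trial with n line x environment cells, the line kernel is
expanded cell-wise (KL = Z_L K_l Z_L'), environments contribute a block kernel of
ones within environment (KE = X_E X_E'), and genotype-by-environment interaction
uses the Hadamard product KLE = KL o KE.  Indefinite kernels (sigmoid) are
repaired by eigenvalue truncation before use as covariances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

logger = logging.getLogger(__name__)

#: relative tolerance for symmetry checks on kernel matrices
SYMMETRY_RTOL = 1e-10
#: default relative eigenvalue threshold for spectral repair
SPECTRAL_TOL = 1e-8

KERNEL_NAMES = ("linear", "gaussian", "polynomial", "sigmoid")


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


class DegenerateKernelError(ValueError):
    """Raised when a kernel has no positive eigenvalue and cannot act as a covariance."""


@dataclass
class KernelParams:
    """Hyperparameters shared by the kernel family.

    gamma  -- scale of the inner product / squared distance (> 0 where used)
    offset -- additive constant ``a`` for polynomial and sigmoid kernels
    degree -- polynomial degree ``d`` (positive integer)
    """

    gamma: float = 1.0
    offset: float = 0.0
    degree: int = 3

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise InvalidInputError(f"gamma must be positive, got {self.gamma}")
        if not float(self.degree).is_integer():
            raise InvalidInputError(f"degree must be an integer, got {self.degree}")
        if self.degree < 1:
            raise InvalidInputError(f"degree must be >= 1, got {self.degree}")
        self.degree = int(self.degree)


@dataclass
class MarkerMatrix:
    """J x p matrix of numeric marker codes with line identifiers.

    ``scaled`` records whether :func:`scale_markers` has been applied.
    """

    values: np.ndarray
    line_ids: list
    scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError("marker matrix must be 2-dimensional")
        self.line_ids = list(self.line_ids)
        if len(self.line_ids) != self.values.shape[0]:
            raise InvalidInputError(
                f"{len(self.line_ids)} line ids for {self.values.shape[0]} rows"
            )
        if len(set(self.line_ids)) != len(self.line_ids):
            raise InvalidInputError("line ids must be unique")
        if np.isnan(self.values).any():
            raise InvalidInputError(
                "marker matrix contains missing values; impute before construction"
            )

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]


@dataclass
class KernelMatrix:
    """Labelled symmetric similarity matrix with optional spectral decomposition.

    After :func:`spectral_decompose`, ``eigenvalues``/``eigenvectors`` hold the
    retained positive eigenpairs and ``values`` the repaired (PSD) matrix.
    """

    values: np.ndarray
    row_ids: list
    eigenvalues: np.ndarray | None = field(default=None)
    eigenvectors: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise InvalidInputError("kernel matrix must be square")
        self.row_ids = list(self.row_ids)
        if len(self.row_ids) != self.values.shape[0]:
            raise InvalidInputError("row_ids length must match matrix dimension")
        scale = max(np.abs(self.values).max(), 1.0)
        asym = np.abs(self.values - self.values.T).max()
        if asym > SYMMETRY_RTOL * scale:
            raise InvalidInputError(f"kernel matrix not symmetric (max asymmetry {asym:g})")
        # exact symmetry simplifies downstream eigensolves
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def size(self) -> int:
        return self.values.shape[0]

    @property
    def rank(self) -> int | None:
        return None if self.eigenvalues is None else len(self.eigenvalues)


# ---------------------------------------------------------------------------
# marker scaling
# ---------------------------------------------------------------------------

def scale_markers(raw: MarkerMatrix) -> MarkerMatrix:
    """Center, standardize, and divide the marker matrix by sqrt(p).

    Each column is centered to mean zero; columns with positive variance are
    scaled to unit (population) variance; the whole matrix is then divided by
    the square root of the number of markers, so each non-constant column ends
    with variance 1/p and rows have O(1) norms.  Constant (monomorphic) columns
    become all-zero rather than raising.
    """
    if raw.scaled:
        return raw
    if raw.n_lines < 2:
        raise InvalidInputError("need at least 2 lines to scale markers")
    X = raw.values - raw.values.mean(axis=0)
    sd = X.std(axis=0)  # ddof=0: unit population variance
    nonconst = sd > 0
    X[:, nonconst] /= sd[nonconst]
    X /= np.sqrt(raw.n_markers)
    return MarkerMatrix(values=X, line_ids=raw.line_ids, scaled=True)


def _require_scaled(X: MarkerMatrix) -> MarkerMatrix:
    if not X.scaled:
        logger.warning("marker matrix not scaled; applying scale_markers automatically")
        return scale_markers(X)
    return X


# ---------------------------------------------------------------------------
# the four line-level kernels
# ---------------------------------------------------------------------------

def linear_kernel(X: MarkerMatrix) -> KernelMatrix:
    """Genomic relationship matrix K = X X' on scaled markers (GBLUP kernel)."""
    X = _require_scaled(X)
    K = X.values @ X.values.T
    return KernelMatrix(values=K, row_ids=X.line_ids)


def polynomial_kernel(X: MarkerMatrix, params: KernelParams | None = None) -> KernelMatrix:
    """Polynomial kernel K_ij = (gamma x_i'x_j + a)^d, defaults gamma=1, a=0, d=3."""
    X = _require_scaled(X)
    params = params or KernelParams()
    K = (params.gamma * (X.values @ X.values.T) + params.offset) ** params.degree
    return KernelMatrix(values=K, row_ids=X.line_ids)


def sigmoid_kernel(X: MarkerMatrix, params: KernelParams | None = None) -> KernelMatrix:
    """Sigmoid kernel K_ij = tanh(x_i'x_j + a).

    May be indefinite; run :func:`spectral_decompose` before use as a covariance.
    """
    X = _require_scaled(X)
    params = params or KernelParams()
    K = np.tanh(X.values @ X.values.T + params.offset)
    return KernelMatrix(values=K, row_ids=X.line_ids)


def gaussian_kernel(X: MarkerMatrix, params: KernelParams | None = None) -> KernelMatrix:
    """Gaussian (RBF) kernel K_ij = exp(-gamma ||x_i - x_j||^2), diagonal exactly 1."""
    X = _require_scaled(X)
    params = params or KernelParams()
    D2 = squareform(pdist(X.values, metric="sqeuclidean"))
    K = np.exp(-params.gamma * D2)
    return KernelMatrix(values=K, row_ids=X.line_ids)


_KERNEL_FUNCS = {
    "linear": lambda X, params: linear_kernel(X),
    "gaussian": gaussian_kernel,
    "polynomial": polynomial_kernel,
    "sigmoid": sigmoid_kernel,
}


def build_kernel(X: MarkerMatrix, name: str, params: KernelParams | None = None) -> KernelMatrix:
    """Dispatch to one of the four kernels by name."""
    if name not in _KERNEL_FUNCS:
        raise InvalidInputError(f"unknown kernel {name!r}; choose from {KERNEL_NAMES}")
    return _KERNEL_FUNCS[name](X, params)


# ---------------------------------------------------------------------------
# expansion to line x environment cells
# ---------------------------------------------------------------------------

def expand_line_kernel(
    K_line: KernelMatrix,
    line_of_cell: Sequence[int],
    row_ids: Sequence | None = None,
) -> KernelMatrix:
    """Expand a J x J line kernel to the n cells: KL[c,c'] = K_line[line(c), line(c')].

    Equivalent to Z_L K_l Z_L' with Z_L the n x J cell-to-line indicator matrix.
    ``line_of_cell`` holds integer indices into ``K_line``.
    """
    idx = np.asarray(line_of_cell, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= K_line.size):
        raise KeyError(
            f"cell mapped to line index outside 0..{K_line.size - 1}"
        )
    KL = K_line.values[np.ix_(idx, idx)]
    ids = list(row_ids) if row_ids is not None else [K_line.row_ids[i] for i in idx]
    return KernelMatrix(values=KL, row_ids=ids)


def env_block_kernel(env_of_cell: Sequence[int], row_ids: Sequence | None = None) -> KernelMatrix:
    """Environment block kernel KE[c,c'] = 1 if env(c) = env(c') else 0.

    Equals X_E X_E' with X_E the cell-to-environment indicator matrix.
    """
    env = np.asarray(env_of_cell)
    KE = (env[:, None] == env[None, :]).astype(float)
    ids = list(row_ids) if row_ids is not None else list(range(len(env)))
    return KernelMatrix(values=KE, row_ids=ids)


def interaction_kernel(KL: KernelMatrix, KE: KernelMatrix) -> KernelMatrix:
    """Genotype-by-environment kernel KLE = KL o KE (Hadamard product).

    With environment-major complete-cell ordering this is block-diagonal copies
    of the line kernel, one block per environment.  PSD whenever both factors
    are PSD (Schur product theorem).
    """
    if KL.size != KE.size:
        raise InvalidInputError(
            f"dimension mismatch: KL is {KL.size}x{KL.size}, KE is {KE.size}x{KE.size}"
        )
    return KernelMatrix(values=KL.values * KE.values, row_ids=KL.row_ids)


# ---------------------------------------------------------------------------
# spectral preparation
# ---------------------------------------------------------------------------

def spectral_decompose(K: KernelMatrix, tol: float = SPECTRAL_TOL) -> KernelMatrix:
    """Symmetric eigendecomposition retaining eigenpairs with lambda > tol * lambda_max.

    Negative and near-zero eigenvalues are dropped, which repairs indefinite
    kernels (e.g. sigmoid) into their closest-in-spectrum PSD operator; the
    sampler then works exactly in the retained eigenbasis.  Raises
    :class:`DegenerateKernelError` when no positive eigenvalue exists.
    """
    w, V = np.linalg.eigh(K.values)
    lam_max = w[-1]
    if lam_max <= 0:
        raise DegenerateKernelError("kernel has no positive eigenvalue")
    keep = w > tol * lam_max
    w, V = w[keep], V[:, keep]
    repaired = (V * w) @ V.T
    return replace(K, values=0.5 * (repaired + repaired.T), eigenvalues=w, eigenvectors=V)
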