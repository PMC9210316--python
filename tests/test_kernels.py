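"""Kernel constructions against brute-force oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mtkernel.kernels import (
    DegenerateKernelError,
    InvalidInputError,
    KernelMatrix,
    KernelParams,
    MarkerMatrix,
    build_kernel,
    env_block_kernel,
    expand_line_kernel,
    gaussian_kernel,
    interaction_kernel,
    linear_kernel,
    polynomial_kernel,
    scale_markers,
    sigmoid_kernel,
    spectral_decompose,
)

TOL = 1e-10


def brute_force_kernel(X, name, gamma=1.0, offset=0.0, degree=3):
    """Entry-wise double-loop evaluation of the four kernel formulas."""
    J = X.shape[0]
    K = np.empty((J, J))
    for i in range(J):
        for j in range(J):
            dot = float(X[i] @ X[j])
            if name == "linear":
                K[i, j] = dot
            elif name == "polynomial":
                K[i, j] = (gamma * dot + offset) ** degree
            elif name == "sigmoid":
                K[i, j] = np.tanh(dot + offset)
            elif name == "gaussian":
                K[i, j] = np.exp(-gamma * np.sum((X[i] - X[j]) ** 2))
    return K


class TestScaleMarkers:
    def test_single_binary_column(self):
        out = scale_markers(MarkerMatrix([[0.0], [2.0]], ["a", "b"]))
        np.testing.assert_allclose(out.values, [[-1.0], [1.0]], atol=TOL)
        assert out.scaled

    def test_constant_column_becomes_zero(self):
        out = scale_markers(MarkerMatrix([[1.0, 0.0], [1.0, 2.0]], ["a", "b"]))
        np.testing.assert_allclose(out.values[:, 0], 0.0, atol=TOL)

    def test_column_moments(self):
        rng = np.random.default_rng(1)
        raw = MarkerMatrix(rng.integers(0, 3, size=(4, 3)).astype(float),
                           [f"L{i}" for i in range(4)])
        out = scale_markers(raw)
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=TOL)
        np.testing.assert_allclose(out.values.var(axis=0), 1.0 / 3, atol=TOL)

    def test_rejects_single_line(self):
        with pytest.raises(InvalidInputError, match="2 lines"):
            scale_markers(MarkerMatrix([[0.0, 1.0]], ["a"]))

    def test_rejects_missing_values(self):
        with pytest.raises(InvalidInputError, match="missing"):
            MarkerMatrix([[0.0], [np.nan]], ["a", "b"])


class TestKernelOracles:
    @pytest.mark.parametrize("name", ["linear", "polynomial", "sigmoid", "gaussian"])
    @pytest.mark.parametrize("J,p,seed", [(5, 20, 0), (17, 40, 1), (50, 60, 2)])
    def test_matches_brute_force(self, name, J, p, seed):
        rng = np.random.default_rng(seed)
        X = scale_markers(MarkerMatrix(
            rng.binomial(2, 0.5, (J, p)).astype(float), [f"L{i}" for i in range(J)]))
        K = build_kernel(X, name).values
        np.testing.assert_allclose(K, brute_force_kernel(X.values, name), atol=TOL)

    def test_linear_orthonormal_rows(self):
        X = MarkerMatrix(np.eye(2), ["a", "b"], scaled=True)
        np.testing.assert_allclose(linear_kernel(X).values, np.eye(2), atol=TOL)
        r = 1 / np.sqrt(2)
        X2 = MarkerMatrix([[r, r], [r, -r]], ["a", "b"], scaled=True)
        np.testing.assert_allclose(linear_kernel(X2).values, np.eye(2), atol=TOL)

    def test_polynomial_closed_forms(self, scaled_markers):
        # cube of the inner product at the defaults
        lin = linear_kernel(scaled_markers).values
        np.testing.assert_allclose(polynomial_kernel(scaled_markers).values, lin**3, atol=TOL)
        # degree-1 reduction to linear
        pk1 = polynomial_kernel(scaled_markers, KernelParams(gamma=1, offset=0, degree=1))
        np.testing.assert_array_equal(pk1.values, lin)
        # (0 + 1)^3 = 1 at zero inner product
        X = MarkerMatrix(np.eye(2), ["a", "b"], scaled=True)
        K = polynomial_kernel(X, KernelParams(offset=1, degree=3)).values
        assert K[0, 1] == pytest.approx(1.0)

    def test_sigmoid_closed_forms_and_range(self, scaled_markers):
        X = MarkerMatrix([[1.0, 0.0], [0.0, 1.0]], ["a", "b"], scaled=True)
        K = sigmoid_kernel(X).values
        assert K[0, 1] == pytest.approx(0.0)
        assert K[0, 0] == pytest.approx(np.tanh(1.0))
        Kr = sigmoid_kernel(scaled_markers).values
        assert np.all(Kr > -1) and np.all(Kr < 1)

    def test_gaussian_diagonal_and_closed_form(self, scaled_markers):
        K = gaussian_kernel(scaled_markers).values
        np.testing.assert_array_equal(np.diag(K), 1.0)
        X = MarkerMatrix([[0.0, 0.0], [1.0, 0.0]], ["a", "b"], scaled=True)
        assert gaussian_kernel(X).values[0, 1] == pytest.approx(np.exp(-1.0))

    def test_gaussian_small_gamma_limit(self, scaled_markers):
        K = gaussian_kernel(scaled_markers, KernelParams(gamma=1e-12)).values
        np.testing.assert_allclose(K, 1.0, atol=1e-9)

    def test_invalid_params(self):
        with pytest.raises(InvalidInputError):
            KernelParams(degree=2.5)
        with pytest.raises(InvalidInputError):
            KernelParams(gamma=-1.0)
        with pytest.raises(InvalidInputError):
            KernelParams(degree=0)

    def test_unscaled_input_autoscaled_with_warning(self, raw_markers, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            K = linear_kernel(raw_markers)
        assert "not scaled" in caplog.text
        np.testing.assert_allclose(
            K.values, linear_kernel(scale_markers(raw_markers)).values, atol=TOL)

    @pytest.mark.parametrize("name", ["linear", "polynomial", "gaussian"])
    def test_psd_on_random_inputs(self, name):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            J = int(rng.integers(5, 51))
            X = scale_markers(MarkerMatrix(
                rng.binomial(2, 0.4, (J, 30)).astype(float), [f"L{i}" for i in range(J)]))
            w = np.linalg.eigvalsh(build_kernel(X, name).values)
            assert w.min() >= -1e-8 * max(w.max(), 1.0)


class TestExpansion:
    def test_lookup_expansion(self):
        K_line = KernelMatrix([[1.0, 0.5], [0.5, 1.0]], ["a", "b"])
        KL = expand_line_kernel(K_line, [0, 1, 0, 1])  # env-major, 2 envs
        expected = np.array([
            [1.0, 0.5, 1.0, 0.5],
            [0.5, 1.0, 0.5, 1.0],
            [1.0, 0.5, 1.0, 0.5],
            [0.5, 1.0, 0.5, 1.0],
        ])
        np.testing.assert_array_equal(KL.values, expected)

    def test_single_environment_is_identity_expansion(self):
        K_line = KernelMatrix([[2.0, 0.3], [0.3, 1.0]], ["a", "b"])
        np.testing.assert_array_equal(expand_line_kernel(K_line, [0, 1]).values, K_line.values)

    def test_matches_dense_design_matrix_product(self, rng):
        J, n = 7, 15
        A = rng.standard_normal((J, J))
        K_line = KernelMatrix(A @ A.T, [f"L{i}" for i in range(J)])
        cells = rng.integers(0, J, size=n)
        Z = np.zeros((n, J))
        Z[np.arange(n), cells] = 1.0
        np.testing.assert_allclose(
            expand_line_kernel(K_line, cells).values, Z @ K_line.values @ Z.T, atol=TOL)

    def test_unknown_line_raises(self):
        K_line = KernelMatrix(np.eye(2), ["a", "b"])
        with pytest.raises(KeyError):
            expand_line_kernel(K_line, [0, 2])

    def test_env_block_kernel(self, rng):
        np.testing.assert_array_equal(
            env_block_kernel([1, 1, 2]).values,
            [[1, 1, 0], [1, 1, 0], [0, 0, 1]])
        np.testing.assert_array_equal(env_block_kernel([0] * 5).values, np.ones((5, 5)))
        envs = rng.integers(0, 4, size=12)
        XE = np.zeros((12, 4))
        XE[np.arange(12), envs] = 1.0
        np.testing.assert_allclose(env_block_kernel(envs).values, XE @ XE.T, atol=TOL)

    def test_interaction_kernel(self, rng):
        K_line = KernelMatrix([[1.0, 0.5], [0.5, 1.0]], ["a", "b"])
        KL = expand_line_kernel(K_line, [0, 1, 0, 1])
        KE = env_block_kernel([0, 0, 1, 1], row_ids=KL.row_ids)
        KLE = interaction_kernel(KL, KE).values
        block = np.array([[1.0, 0.5], [0.5, 1.0]])
        expected = np.zeros((4, 4))
        expected[:2, :2] = block
        expected[2:, 2:] = block
        np.testing.assert_array_equal(KLE, expected)
        # all-ones KE is the Hadamard identity
        ones = KernelMatrix(np.ones((4, 4)), KL.row_ids)
        np.testing.assert_array_equal(interaction_kernel(KL, ones).values, KL.values)
        # Schur product of PSD matrices stays PSD
        A = rng.standard_normal((6, 6))
        B = rng.standard_normal((6, 6))
        P = KernelMatrix(A @ A.T, list(range(6)))
        Q = KernelMatrix(B @ B.T, list(range(6)))
        w = np.linalg.eigvalsh(interaction_kernel(P, Q).values)
        assert w.min() >= -1e-8 * max(w.max(), 1.0)

    def test_interaction_dimension_mismatch(self):
        with pytest.raises(InvalidInputError, match="mismatch"):
            interaction_kernel(KernelMatrix(np.eye(3), list("abc")),
                               KernelMatrix(np.eye(2), list("ab")))


class TestSpectralDecompose:
    def test_identity_passes_through(self):
        out = spectral_decompose(KernelMatrix(np.eye(3), list("abc")))
        np.testing.assert_allclose(out.values, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(out.eigenvalues, np.ones(3))

    def test_indefinite_rank_one_repair(self):
        # eigenvalues 3 and -1; repair keeps 3 v v' with v = (1,-1)/sqrt(2)
        K = KernelMatrix([[1.0, -2.0], [-2.0, 1.0]], ["a", "b"])
        out = spectral_decompose(K)
        np.testing.assert_allclose(out.values, [[1.5, -1.5], [-1.5, 1.5]], atol=1e-10)
        assert out.rank == 1

    def test_psd_reconstruction(self, rng):
        A = rng.standard_normal((8, 4))
        K = KernelMatrix(A @ A.T, list(range(8)))
        out = spectral_decompose(K)
        np.testing.assert_allclose(out.values, K.values, atol=1e-8)
        recon = (out.eigenvectors * out.eigenvalues) @ out.eigenvectors.T
        np.testing.assert_allclose(recon, out.values, atol=1e-8)

    def test_degenerate_kernel_raises(self):
        with pytest.raises(DegenerateKernelError):
            spectral_decompose(KernelMatrix(-np.eye(2), ["a", "b"]))


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000),
       st.sampled_from(["linear", "polynomial", "sigmoid", "gaussian"]))
def test_kernels_are_symmetric(seed, name):
    rng = np.random.default_rng(seed)
    J = int(rng.integers(3, 20))
    X = scale_markers(MarkerMatrix(
        rng.binomial(2, 0.5, (J, 15)).astype(float), [f"L{i}" for i in range(J)]))
    K = build_kernel(X, name).values
    assert np.abs(K - K.T).max() <= 1e-10 * max(np.abs(K).max(), 1.0)
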