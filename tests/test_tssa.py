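"""Coding-rate statistics, the variational bound, and the linear-time update."""

import numpy as np
import pytest

from wavedetr import nn
from wavedetr.tssa import (
    ProjectionSet,
    TSSALayer,
    compression_rate,
    energy_membership,
    expansion_rate,
    f_prime,
    naive_attention_flops,
    naive_softmax_attention,
    rate_reduction,
    second_moment_diag,
    tssa_flops,
    tssa_update,
    variational_compression,
)


def random_membership(rng, n, K):
    return rng.dirichlet(np.ones(K), size=n)


def eigen_projections(Z, Pi, eps):
    """Per-group eigenbasis of the weighted second-moment matrix (oracle basis)."""
    basis = []
    for k in range(Pi.shape[1]):
        nk = Pi[:, k].sum()
        M = (Z * Pi[:, k]) @ Z.T / nk
        _, V = np.linalg.eigh(M)
        basis.append(V)
    return ProjectionSet(basis=basis, epsilon=eps)


class TestExpansionRate:
    def test_zero_tokens(self):
        assert expansion_rate(np.zeros((3, 5)), 1.0) == 0.0

    def test_isotropic_closed_form(self):
        """Z Z^T = (n eps^2 / d) I gives (d/2) log 2 exactly."""
        d, n, eps = 4, 8, 0.7
        Z = np.zeros((d, n))
        Z[:, :d] = np.eye(d) * np.sqrt(n * eps**2 / d)
        assert expansion_rate(Z, eps) == pytest.approx(d / 2 * np.log(2), rel=1e-12)

    def test_matches_eigenvalue_oracle(self, rng):
        Z = rng.normal(size=(4, 6))
        d, n, eps = 4, 6, 1.0
        lam = np.linalg.eigvalsh(Z @ Z.T / n)
        oracle = 0.5 * np.sum(np.log(1 + (d / eps**2) * lam))
        assert expansion_rate(Z, eps) == pytest.approx(oracle, rel=1e-10)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            expansion_rate(np.array([[np.nan, 1.0]]))


class TestCompressionRate:
    def test_single_group_equals_expansion(self, rng):
        Z = rng.normal(size=(5, 7))
        Pi = np.ones((7, 1))
        assert compression_rate(Z, Pi, 0.8) == pytest.approx(expansion_rate(Z, 0.8), rel=1e-12)
        assert rate_reduction(Z, Pi, 0.8) == pytest.approx(0.0, abs=1e-12)

    def test_zero_tokens(self, rng):
        Pi = random_membership(rng, 6, 3)
        assert compression_rate(np.zeros((4, 6)), Pi) == 0.0

    def test_matches_per_group_eigendecomposition(self, rng):
        """Exact rates vs dense eigendecomposition, 50 random instances."""
        for _ in range(50):
            d = int(rng.integers(2, 9))
            n = int(rng.integers(2, 33))
            K = int(rng.integers(1, 4))
            eps = float(rng.uniform(0.3, 1.5))
            Z = rng.normal(size=(d, n))
            Pi = random_membership(rng, n, K)
            oracle = 0.0
            for k in range(K):
                nk = Pi[:, k].sum()
                lam = np.linalg.eigvalsh((Z * Pi[:, k]) @ Z.T / nk)
                lam = np.clip(lam, 0, None)
                oracle += 0.5 * (nk / n) * np.sum(np.log1p((d / eps**2) * lam))
            assert compression_rate(Z, Pi, eps) == pytest.approx(oracle, rel=1e-8, abs=1e-10)

    def test_negative_membership_rejected(self, rng):
        Z = rng.normal(size=(3, 4))
        Pi = np.array([[1.2, -0.2]] * 4)
        with pytest.raises(ValueError):
            compression_rate(Z, Pi)


class TestVariationalBound:
    def test_equality_at_eigenbasis(self, rng):
        Z = rng.normal(size=(5, 12))
        Pi = random_membership(rng, 12, 3)
        proj = eigen_projections(Z, Pi, eps=0.9)
        assert variational_compression(Z, Pi, proj) == pytest.approx(
            compression_rate(Z, Pi, 0.9), abs=1e-6
        )

    def test_zero_tokens_zero_bound(self, rng):
        Pi = random_membership(rng, 6, 2)
        proj = ProjectionSet(basis=[np.eye(4), np.eye(4)])
        assert variational_compression(np.zeros((4, 6)), Pi, proj) == 0.0

    def test_dominance_over_random_orthogonal_draws(self, rng):
        """Schur-concavity: the bound dominates the exact rate for any
        orthogonal projection, over >= 100 Haar-random draws."""
        Z = np.random.default_rng(3).normal(size=(5, 10))
        Pi = random_membership(rng, 10, 2)
        exact = compression_rate(Z, Pi, 0.5)
        for _ in range(120):
            basis = [np.linalg.qr(rng.normal(size=(5, 5)))[0] for _ in range(2)]
            bound = variational_compression(Z, Pi, ProjectionSet(basis=basis, epsilon=0.5))
            assert bound >= exact - 1e-10


class TestSecondMomentDiag:
    def test_zero_tokens(self):
        d = second_moment_diag(np.zeros((3, 4)), np.ones(4), np.eye(3), eps=0.5)
        np.testing.assert_allclose(d, f_prime(0.0, 3, 0.5))

    def test_inactive_group_returns_zeros(self, rng):
        Z = rng.normal(size=(3, 4))
        np.testing.assert_allclose(second_moment_diag(Z, np.zeros(4), np.eye(3)), 0.0)

    def test_single_token_hand_computation(self):
        """n=1, pi=1, U=I, d=2: D_ii = f'(z_i^2) = c / (1 + c z_i^2)."""
        z = np.array([[0.5], [2.0]])
        c = 2 / 0.5**2
        expected = c / (1 + c * np.array([0.25, 4.0]))
        np.testing.assert_allclose(second_moment_diag(z, np.ones(1), np.eye(2), 0.5), expected)

    def test_matches_double_loop(self, rng):
        Z = rng.normal(size=(4, 8))
        pi = rng.uniform(0.1, 1.0, 8)
        U = np.linalg.qr(rng.normal(size=(4, 3)))[0]
        nk = pi.sum()
        ref = np.zeros(3)
        for i in range(3):
            m = sum(pi[j] * (U[:, i] @ Z[:, j]) ** 2 for j in range(8)) / nk
            ref[i] = f_prime(m, 4, 0.5)
        np.testing.assert_allclose(second_moment_diag(Z, pi, U, 0.5), ref, rtol=1e-10)


class TestTokenUpdate:
    def test_zero_step_is_identity(self, rng):
        Z = rng.normal(size=(4, 6))
        Pi = random_membership(rng, 6, 2)
        proj = ProjectionSet(basis=[np.eye(4)] * 2, step=0.0)
        np.testing.assert_allclose(tssa_update(Z, Pi, proj), Z)

    def test_zero_tokens_fixed_point(self, rng):
        Pi = random_membership(rng, 6, 2)
        proj = ProjectionSet(basis=[np.eye(4)] * 2)
        np.testing.assert_allclose(tssa_update(np.zeros((4, 6)), Pi, proj), 0.0)

    def test_negative_step_rejected(self, rng):
        Z = rng.normal(size=(2, 3))
        Pi = np.ones((3, 1))
        with pytest.raises(ValueError):
            tssa_update(Z, Pi, ProjectionSet(basis=[np.eye(2)], step=-1.0))

    def test_batched_equals_explicit_loop_50_instances(self, rng):
        """Vectorized update vs the explicit per-token/per-group formula."""
        for _ in range(50):
            d = int(rng.integers(2, 6))
            n = int(rng.integers(2, 12))
            K = int(rng.integers(1, 4))
            Z = rng.normal(size=(d, n))
            Pi = random_membership(rng, n, K)
            proj = ProjectionSet(
                basis=[np.linalg.qr(rng.normal(size=(d, d)))[0] for _ in range(K)],
                epsilon=0.5,
                step=float(rng.uniform(0.1, 2.0)),
            )
            ref = Z.copy()
            for j in range(n):
                for k in range(K):
                    U = proj.basis[k]
                    D = second_moment_diag(Z, Pi[:, k], U, proj.epsilon)
                    ref[:, j] -= (proj.step / n) * Pi[j, k] * (U @ (D * (U.T @ Z[:, j])))
            np.testing.assert_allclose(tssa_update(Z, Pi, proj), ref, atol=1e-6)

    def test_token_permutation_equivariance(self, rng):
        Z = rng.normal(size=(4, 9))
        Pi = random_membership(rng, 9, 3)
        proj = ProjectionSet(basis=[np.linalg.qr(rng.normal(size=(4, 4)))[0] for _ in range(3)])
        perm = rng.permutation(9)
        out = tssa_update(Z, Pi, proj)
        out_p = tssa_update(Z[:, perm], Pi[perm], proj)
        np.testing.assert_allclose(out_p, out[:, perm], atol=1e-10)


class TestMembership:
    def test_rows_stochastic(self, rng):
        Z = rng.normal(size=(6, 20))
        proj = ProjectionSet(basis=[np.linalg.qr(rng.normal(size=(6, 2)))[0] for _ in range(4)])
        Pi = energy_membership(Z, proj)
        assert Pi.shape == (20, 4)
        assert np.all(Pi >= 0)
        np.testing.assert_allclose(Pi.sum(axis=1), 1.0, atol=1e-6)


class TestLayerAndComplexity:
    def test_zero_update_branch_is_identity(self, rng):
        layer = TSSALayer(8, groups=2, rng=rng)
        for U in layer.U:
            U.data[:] = 0.0
        x = rng.normal(size=(2, 5, 8)).astype(np.float32)
        out = layer(nn.Tensor(x))
        np.testing.assert_allclose(out.data, x, atol=1e-7)

    def test_layer_token_permutation_equivariance(self, rng):
        layer = TSSALayer(8, groups=2, rng=rng)
        x = rng.normal(size=(1, 7, 8)).astype(np.float32)
        perm = rng.permutation(7)
        out = layer(nn.Tensor(x)).data
        out_p = layer(nn.Tensor(x[:, perm])).data
        np.testing.assert_allclose(out_p, out[:, perm], atol=1e-6)

    def test_empty_token_set_rejected(self, rng):
        layer = TSSALayer(4, groups=2, rng=rng)
        with pytest.raises(ValueError):
            layer(nn.Tensor(np.zeros((1, 0, 4), dtype=np.float32)))

    def test_op_count_affine_in_n(self):
        """ops(2n)/ops(n) in [1.9, 2.1] at n >= 1024 (linear complexity)."""
        for n in (1024, 4096):
            r = tssa_flops(2 * n, 256, 8, 32) / tssa_flops(n, 256, 8, 32)
            assert 1.9 <= r <= 2.1
        # the naive baseline is quadratic: ratio approaches 4
        r_naive = naive_attention_flops(8192, 256) / naive_attention_flops(4096, 256)
        assert r_naive > 3.0

    def test_naive_reference_runs_and_differs(self, rng):
        Z = rng.normal(size=(6, 10))
        out = naive_softmax_attention(Z)
        assert out.shape == Z.shape
        assert np.all(np.isfinite(out))

    def test_layer_matches_math_core_on_shared_membership(self, rng):
        """The trainable layer's update equals tssa_update when both use the
        same memberships and orthonormal bases (cross-implementation parity)."""
        d, n = 6, 9
        layer = TSSALayer(d, groups=2, proj_rank=3, epsilon=0.5, step_init=1.0,
                          temperature=1.0, rng=rng)
        x = rng.normal(size=(1, n, d)).astype(np.float32)
        out = layer(nn.Tensor(x)).data[0]
        Z = x[0].T.astype(np.float64)
        proj = ProjectionSet(basis=[U.data.astype(np.float64) for U in layer.U],
                             epsilon=0.5, step=1.0, enforce_orthogonal=False)
        Pi = energy_membership(Z, proj, temperature=1.0)
        ref = tssa_update(Z, Pi, proj)
        np.testing.assert_allclose(out, ref.T, atol=2e-4)
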