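"""Token Statistics Self-Attention: coding-rate statistics and the token update.

Attention here is not pairwise similarity: tokens are updated by descending a
variational upper bound of the maximal-coding-rate-reduction (MCR^2)
compression term, which only needs per-group *second-moment statistics* of
projected tokens — cost linear in the token count n.

Notation: ``Z`` is d x n (columns are tokens), ``Pi`` is n x K row-stochastic
group memberships, ``U_k`` are (near-)orthogonal d x p projections,
``eps`` the coding precision, ``step`` the descent step size.

The concave function is fixed to ``f(x) = log(1 + (d/eps^2) x)``, which makes
the variational bound tight at each group's eigenbasis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TokenMatrix",
    "MembershipMatrix",
    "ProjectionSet",
    "expansion_rate",
    "compression_rate",
    "rate_reduction",
    "variational_compression",
    "second_moment_diag",
    "tssa_update",
    "energy_membership",
    "tssa_flops",
    "naive_attention_flops",
    "naive_softmax_attention",
]


def _check_tokens(Z: np.ndarray) -> np.ndarray:
    Z = np.asarray(Z, dtype=np.float64)
    if Z.ndim != 2 or Z.shape[0] < 1 or Z.shape[1] < 1:
        raise ValueError(f"token matrix must be d x n with d,n >= 1, got {Z.shape}")
    if not np.all(np.isfinite(Z)):
        raise ValueError("token matrix contains non-finite entries")
    return Z


def _check_membership(Pi: np.ndarray, n: int) -> np.ndarray:
    Pi = np.asarray(Pi, dtype=np.float64)
    if Pi.ndim != 2 or Pi.shape[0] != n:
        raise ValueError(f"membership must be n x K with n={n}, got {Pi.shape}")
    if np.any(Pi < -1e-12):
        raise ValueError("membership probabilities must be nonnegative")
    rows = Pi.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-6):
        raise ValueError("membership rows must sum to 1")
    return np.clip(Pi, 0.0, None)


# Thin aliases so call sites can be explicit about the roles of plain arrays.
TokenMatrix = np.ndarray
MembershipMatrix = np.ndarray


@dataclass
class ProjectionSet:
    """Per-group projections plus the scalar knobs of the update.

    ``basis`` holds K matrices of shape d x p. When ``enforce_orthogonal`` is
    on, each is passed through a QR factorization so columns are orthonormal.
    """

    basis: list[np.ndarray] = field(default_factory=list)
    epsilon: float = 0.5
    step: float = 1.0
    enforce_orthogonal: bool = True

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        self.basis = [np.asarray(U, dtype=np.float64) for U in self.basis]
        if self.enforce_orthogonal:
            self.basis = [np.linalg.qr(U)[0] for U in self.basis]

    @property
    def K(self) -> int:
        return len(self.basis)


def _c(d: int, eps: float) -> float:
    return d / (eps * eps)


def f_concave(x: np.ndarray, d: int, eps: float) -> np.ndarray:
    """f(x) = log(1 + (d/eps^2) x); concave, f(0) = 0."""
    return np.log1p(_c(d, eps) * x)


def f_prime(x: np.ndarray, d: int, eps: float) -> np.ndarray:
    c = _c(d, eps)
    return c / (1.0 + c * x)


def expansion_rate(Z: TokenMatrix, eps: float = 0.5) -> float:
    """Coding rate of all tokens: (1/2) logdet(I + (d/eps^2) Z Z^T / n), in nats."""
    Z = _check_tokens(Z)
    if eps <= 0:
        raise ValueError("eps must be > 0")
    d, n = Z.shape
    M = np.eye(d) + (_c(d, eps) / n) * (Z @ Z.T)
    sign, logdet = np.linalg.slogdet(M)
    assert sign > 0
    return 0.5 * float(logdet)


def compression_rate(Z: TokenMatrix, Pi: MembershipMatrix, eps: float = 0.5) -> float:
    """Membership-weighted sum of per-group coding rates, in nats.

    Groups with zero mass contribute nothing. With K=1 this equals
    :func:`expansion_rate` exactly.
    """
    Z = _check_tokens(Z)
    d, n = Z.shape
    Pi = _check_membership(Pi, n)
    c = _c(d, eps)
    total = 0.0
    for k in range(Pi.shape[1]):
        pik = Pi[:, k]
        nk = pik.sum()
        if nk <= 0:
            continue
        M = np.eye(d) + (c / nk) * ((Z * pik) @ Z.T)
        sign, logdet = np.linalg.slogdet(M)
        assert sign > 0
        total += 0.5 * (nk / n) * float(logdet)
    return total


def rate_reduction(Z: TokenMatrix, Pi: MembershipMatrix, eps: float = 0.5) -> float:
    """MCR^2 objective: expansion minus compression (>= 0 for valid memberships)."""
    return expansion_rate(Z, eps) - compression_rate(Z, Pi, eps)


def variational_compression(
    Z: TokenMatrix, Pi: MembershipMatrix, proj: ProjectionSet
) -> float:
    """Variational upper bound of the compression term.

    (1/2) sum_k (n_k/n) sum_i f( (U_k^T Z Diag(pi_k) Z^T U_k)_ii / n_k )
    computed from diagonals only — no d x d Gram matrix, O(n d p) work.
    Equals :func:`compression_rate` when each U_k spans the eigenbasis of its
    group's second-moment matrix.
    """
    Z = _check_tokens(Z)
    d, n = Z.shape
    Pi = _check_membership(Pi, n)
    if proj.K != Pi.shape[1]:
        raise ValueError("one projection per group required")
    total = 0.0
    for k in range(proj.K):
        pik = Pi[:, k]
        nk = pik.sum()
        if nk <= 0:
            continue
        W = proj.basis[k].T @ Z  # p x n
        diag = (W * W) @ pik / nk  # per-coordinate weighted second moments
        total += 0.5 * (nk / n) * float(np.sum(f_concave(diag, d, proj.epsilon)))
    return total


def second_moment_diag(
    Z: TokenMatrix, pi_k: np.ndarray, U_k: np.ndarray, eps: float = 0.5
) -> np.ndarray:
    """Diagonal of the weighting operator D(Z, pi_k | U_k) in the token update.

    Entry i is f'(m_i) where m_i = (1/n_k) sum_j pi_k[j] (U_k^T z_j)_i^2 is the
    weighted second moment of projected coordinate i. An inactive group
    (all-zero pi_k) returns zeros.
    """
    Z = _check_tokens(Z)
    pi_k = np.asarray(pi_k, dtype=np.float64)
    if np.any(pi_k < 0):
        raise ValueError("membership column must be nonnegative")
    nk = pi_k.sum()
    if nk <= 0:
        return np.zeros(U_k.shape[1])
    W = np.asarray(U_k).T @ Z
    m = (W * W) @ pi_k / nk
    return f_prime(m, Z.shape[0], eps)


def tssa_update(
    Z: TokenMatrix, Pi: MembershipMatrix, proj: ProjectionSet
) -> TokenMatrix:
    """One descent step on the variational compression bound.

    z_j^+ = z_j - (step/n) sum_k Pi[j,k] U_k D(Z, pi_k | U_k) U_k^T z_j

    Vectorized over tokens and groups; cost O(n d p K), memory O(n (d+p)).
    """
    Z = _check_tokens(Z)
    d, n = Z.shape
    Pi = _check_membership(Pi, n)
    if proj.step < 0:
        raise ValueError("step must be >= 0")
    out = Z.copy()
    for k in range(proj.K):
        pik = Pi[:, k]
        nk = pik.sum()
        if nk <= 0:
            continue
        U = proj.basis[k]
        W = U.T @ Z  # p x n
        Dk = f_prime((W * W) @ pik / nk, d, proj.epsilon)  # p
        out -= (proj.step / n) * (U @ (Dk[:, None] * W)) * pik[None, :]
    return out


def energy_membership(
    Z: TokenMatrix, proj: ProjectionSet, temperature: float = 1.0
) -> MembershipMatrix:
    """Soft memberships from projected energies.

    Pi[j, k] = softmax_k( -||U_k^T z_j||^2 / temperature ): tokens join the
    group whose subspace holds the least of their energy, i.e. the group that
    compresses them best.
    """
    Z = _check_tokens(Z)
    energies = np.stack(
        [np.sum((U.T @ Z) ** 2, axis=0) for U in proj.basis], axis=1
    )  # n x K
    logits = -energies / max(temperature, 1e-8)
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


# --- analytic operation counts ----------------------------------------------


def tssa_flops(n: int, d: int, K: int, p: int | None = None, include_qr: bool = False) -> int:
    """Multiply-accumulate count of one TSSA update over n tokens (affine in n).

    Per group: project (2 d p n), membership energies (p n), second moments
    (2 p n), diagonal weights (O(p)), weighted back-projection (2 d p n + p n),
    membership softmax (O(K n)), residual add (d n).
    """
    p = d if p is None else p
    per_group = 2 * d * p * n + p * n + 2 * p * n + 4 * p + 2 * d * p * n + p * n
    total = K * per_group + 3 * K * n + d * n
    if include_qr:
        total += K * 2 * d * p * p  # one-off orthogonalization, n-independent
    return int(total)


def naive_attention_flops(n: int, d: int) -> int:
    """MAC count of single-head softmax attention: quadratic in n."""
    qkv = 3 * 2 * d * d * n
    scores = 2 * d * n * n
    softmax = 5 * n * n
    weighted = 2 * d * n * n
    out = 2 * d * d * n
    return int(qkv + scores + softmax + weighted + out)


def naive_softmax_attention(Z: TokenMatrix, scale: float | None = None) -> TokenMatrix:
    """Reference O(n^2) single-head softmax self-attention (queries=keys=values=Z).

    Exported only as the comparison baseline for complexity and ablation tests.
    """
    Z = _check_tokens(Z)
    d, n = Z.shape
    scale = scale if scale is not None else 1.0 / np.sqrt(d)
    S = (Z.T @ Z) * scale  # n x n — the quadratic object TSSA avoids
    S -= S.max(axis=1, keepdims=True)
    A = np.exp(S)
    A /= A.sum(axis=1, keepdims=True)
    return Z @ A.T


# --- trainable layer ---------------------------------------------------------


class TSSALayer:
    """Trainable TSSA over batched token tensors (B, n, d).

    Implements exactly the statistics update: project with per-group bases
    U_k, form soft memberships from projected energies, weight projected
    coordinates by the derivative of the concave rate at their weighted
    second moments, and subtract the back-projected result from the tokens
    (the residual connection is intrinsic to the update). All intermediates
    are O(n) in the token count.

    ``enforce_orthogonal`` keeps each U_k orthonormal by re-projecting the
    parameter onto the Stiefel manifold (QR) after every optimizer step — a
    projected-gradient scheme that avoids differentiating through QR.
    """

    def __init__(
        self,
        dim: int,
        groups: int = 4,
        proj_rank: int | None = None,
        epsilon: float = 0.5,
        step_init: float = 1.0,
        temperature: float = 1.0,
        enforce_orthogonal: bool = True,
        rng: np.random.Generator | None = None,
    ):
        from . import nn

        rng = rng or np.random.default_rng(0)
        self.dim = dim
        self.groups = groups
        self.proj_rank = proj_rank if proj_rank is not None else max(1, dim // groups)
        self.epsilon = epsilon
        self.enforce_orthogonal = enforce_orthogonal
        self.U = [
            nn.Parameter(np.linalg.qr(rng.normal(0, 1, (dim, self.proj_rank)))[0])
            for _ in range(groups)
        ]
        self.log_step = nn.Parameter(np.array([np.log(step_init)]))
        self.log_temp = nn.Parameter(np.array([np.log(temperature)]))
        if enforce_orthogonal:
            self.orthonormalize()

    def orthonormalize(self) -> None:
        for p in self.U:
            p.data = np.linalg.qr(p.data.astype(np.float64))[0].astype(np.float32)

    # Module protocol (duck-typed; nn.Module discovers Parameters in lists)
    def parameters(self):
        return [*self.U, self.log_step, self.log_temp]

    def __call__(self, tokens):
        return self.forward(tokens)

    def forward(self, tokens):
        from . import nn

        B, n, d = tokens.shape
        if n == 0:
            raise ValueError("empty token set")
        c = d / (self.epsilon**2)
        W = [tokens @ U for U in self.U]                      # K x (B, n, p)
        energies = nn.stack([(w * w).sum(axis=2) for w in W], axis=2)  # B, n, K
        temp = self.log_temp.exp()
        Pi = nn.softmax(energies * (-1.0) / temp, axis=2)
        step = self.log_step.exp()
        out = tokens
        for k in range(self.groups):
            pik = Pi[:, :, k]                                  # B, n
            # small floor keeps empty groups inert (their pik weights are ~0)
            nk = pik.sum(axis=1, keepdims=True) + 1e-6         # B, 1
            w2 = W[k] * W[k]
            m = (w2 * pik.reshape(B, n, 1)).sum(axis=1) / nk   # B, p
            Dk = c / (1.0 + m * c)                             # f'(m)
            weighted = W[k] * Dk.reshape(B, 1, -1)
            back = weighted @ self.U[k].transpose(1, 0)        # B, n, d
            out = out - back * pik.reshape(B, n, 1) * (step * (1.0 / n))
        return out
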