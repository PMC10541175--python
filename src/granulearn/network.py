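"""Expansion-layer networks: embeddings, weights, activity and geometry.

The expansion layer (model granule cells) recodes input-layer (mossy
fiber) activity through a thresholded nonlinearity,

    h = phi(J_eff x - theta)^p,   phi(u) = max(u, 0),

where J_eff = J A collects the input-to-expansion weights J and the
embedding A of the D task variables into the N input-layer neurons. A
single shared threshold theta sets the coding level f, the average
fraction of expansion neurons active per pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EmbeddingMatrix",
    "ExpansionNetwork",
    "ExpansionActivity",
    "make_embedding",
    "make_expansion_weights",
    "build_network",
    "calibrate_threshold",
    "expand",
    "winner_take_all",
    "coding_level",
    "participation_dimension",
    "effective_weight_correlations",
]

EMBEDDING_KINDS = ("distributed_orthonormal", "clustered_blocks")
WEIGHT_KINDS = ("dense_gaussian", "sparse_homogeneous", "sparse_truncnorm")


@dataclass
class EmbeddingMatrix:
    """N x D embedding of task variables into the input layer."""

    A: np.ndarray
    kind: str


@dataclass
class ExpansionActivity:
    """M x P nonnegative expansion-layer activity with measured coding level."""

    H: np.ndarray
    measured_f: float


@dataclass
class ExpansionNetwork:
    """An expansion layer characterized by its effective weights.

    ``J_eff`` is M x D for task-subspace inputs (or M x N for
    direct-input-layer tasks, where the embedding is the identity).
    ``theta`` is the shared activation threshold (set by
    :func:`calibrate_threshold`); ``power`` the exponent of the
    threshold-polynomial nonlinearity.
    """

    J_eff: np.ndarray
    theta: float | None = None
    power: int = 1
    target_f: float | None = None
    config: dict = field(default_factory=dict)

    @property
    def M(self) -> int:
        return self.J_eff.shape[0]

    @property
    def input_dim(self) -> int:
        return self.J_eff.shape[1]

    def preactivations(self, X: np.ndarray, dtype=None) -> np.ndarray:
        """J_eff x for a batch of inputs X (P x D); returns M x P."""
        X = np.atleast_2d(np.asarray(X))
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"input dimension {X.shape[1]} does not match network "
                f"dimension {self.input_dim}"
            )
        J = self.J_eff if dtype is None else self.J_eff.astype(dtype, copy=False)
        return J @ (X.T if dtype is None else X.T.astype(dtype, copy=False))


def make_embedding(N: int, D: int, kind: str = "distributed_orthonormal", seed=None) -> EmbeddingMatrix:
    """Sample an input-layer embedding matrix.

    ``distributed_orthonormal``: N x D with orthonormal columns (each
    input neuron responds to a random combination of task variables).
    ``clustered_blocks``: 0/1 block matrix in which each group of N/D
    input neurons encodes a single task variable.
    """
    if kind not in EMBEDDING_KINDS:
        raise ValueError(f"unknown embedding kind {kind!r}")
    if kind == "distributed_orthonormal":
        if N < D:
            raise ValueError("distributed embedding requires N >= D")
        rng = np.random.default_rng(seed)
        G = rng.standard_normal((N, D))
        Q, R = np.linalg.qr(G)
        # fix signs for determinism across LAPACK implementations
        Q = Q * np.sign(np.diag(R))
        return EmbeddingMatrix(A=Q, kind=kind)
    if N % D != 0:
        raise ValueError("clustered embedding requires D to divide N")
    block = N // D
    A = np.zeros((N, D))
    for d in range(D):
        A[d * block:(d + 1) * block, d] = 1.0
    return EmbeddingMatrix(A=A, kind=kind)


def _sparse_row_indices(M: int, N: int, K: int, rng: np.random.Generator) -> np.ndarray:
    """M x K matrix of distinct column indices per row, uniformly at random."""
    if not 1 <= K <= N:
        raise ValueError("sparse connectivity requires 1 <= K <= N")
    if K > N // 2:
        return np.array([rng.choice(N, size=K, replace=False) for _ in range(M)])
    idx = rng.integers(0, N, size=(M, K))
    bad = np.array([len(set(row)) < K for row in idx])
    while np.any(bad):
        idx[bad] = rng.integers(0, N, size=(int(bad.sum()), K))
        bad = np.array([len(set(row)) < K for row in idx])
    return idx


def make_expansion_weights(
    M: int,
    N: int,
    K: int | None = None,
    kind: str = "dense_gaussian",
    global_inhibition: bool = False,
    seed=None,
) -> np.ndarray:
    """Sample an M x N input-to-expansion weight matrix (dense ndarray).

    ``dense_gaussian``: i.i.d. unit normal entries. ``sparse_homogeneous``
    / ``sparse_truncnorm``: exactly K excitatory entries per row at random
    positions, with value 1 or |normal| (a unit normal conditioned on
    nonnegativity), respectively. Global inhibition subtracts the grand
    mean of the excitatory matrix from every entry, so the total sum is
    zero.
    """
    if kind not in WEIGHT_KINDS:
        raise ValueError(f"unknown weight kind {kind!r}")
    rng = np.random.default_rng(seed)
    if kind == "dense_gaussian":
        J = rng.standard_normal((M, N))
        if global_inhibition:
            J -= J.mean()
        return J
    if K is None:
        raise ValueError("sparse weight kinds require an in-degree K")
    idx = _sparse_row_indices(M, N, K, rng)
    if kind == "sparse_homogeneous":
        vals = np.ones((M, K))
    else:
        vals = np.abs(rng.standard_normal((M, K)))
    J = np.zeros((M, N))
    np.put_along_axis(J, idx, vals, axis=1)
    if global_inhibition:
        J -= vals.sum() / (M * N)
    return J


def build_network(
    M: int,
    D: int,
    *,
    N: int | None = None,
    K: int | None = None,
    weight_kind: str = "dense_gaussian",
    embedding_kind: str = "distributed_orthonormal",
    global_inhibition: bool = False,
    power: int = 1,
    direct_input: bool = False,
    seed=None,
) -> ExpansionNetwork:
    """Build an expansion network and its effective weights J_eff = J A.

    For dense Gaussian weights with a distributed (orthonormal)
    embedding, J_eff is itself i.i.d. Gaussian, so it is sampled
    directly as an M x D matrix without materializing J. Sparse and
    clustered variants build J (in sparse form) and A explicitly. For
    ``direct_input=True`` the embedding is bypassed (J_eff = J, N = D
    input channels), as in tasks whose inputs are raw input-layer
    activities.
    """
    if power < 1:
        raise ValueError("nonlinearity exponent must be >= 1")
    rng = np.random.default_rng(seed)
    cfg = dict(M=M, D=D, N=N, K=K, weight_kind=weight_kind,
               embedding_kind=embedding_kind,
               global_inhibition=global_inhibition, power=power,
               direct_input=direct_input, seed=seed)
    if direct_input:
        if weight_kind != "dense_gaussian":
            raise ValueError("direct-input networks use dense Gaussian weights")
        J_eff = rng.standard_normal((M, D))
        return ExpansionNetwork(J_eff=J_eff, power=power, config=cfg)
    if weight_kind == "dense_gaussian":
        J_eff = rng.standard_normal((M, D))
        return ExpansionNetwork(J_eff=J_eff, power=power, config=cfg)
    if N is None or K is None:
        raise ValueError("sparse weight kinds require N and K")
    A = make_embedding(N, D, embedding_kind, seed=rng.integers(2**31)).A
    idx = _sparse_row_indices(M, N, K, rng)
    if weight_kind == "sparse_homogeneous":
        vals = np.ones((M, K))
    else:
        vals = np.abs(rng.standard_normal((M, K)))
    # J_eff = J_E A - (grand mean of J_E) 1 1^T A, without densifying J_E
    J_eff = np.einsum("mk,mkd->md", vals, A[idx])
    if global_inhibition:
        J_eff -= (vals.sum() / (M * N)) * A.sum(axis=0)
    return ExpansionNetwork(J_eff=J_eff, power=power, config=cfg)


def calibrate_threshold(
    network: ExpansionNetwork,
    calibration_inputs: np.ndarray,
    f: float,
    max_samples: int = 2_000_000,
    seed: int = 0,
) -> float:
    """Set the shared threshold to reach coding level ``f``.

    theta is the (1 - f) quantile of the preactivations pooled over all
    neurons and calibration patterns (subsampled beyond ``max_samples``
    values for speed). The network's ``theta`` and ``target_f`` are
    updated in place and theta is returned.
    """
    if not 0.0 < f < 1.0:
        raise ValueError("target coding level must lie in (0, 1)")
    pre = network.preactivations(calibration_inputs).ravel()
    if pre.size == 0 or np.ptp(pre) == 0.0:
        raise ValueError("degenerate preactivations: threshold calibration failed")
    if pre.size > max_samples:
        rng = np.random.default_rng(seed)
        pre = pre[rng.integers(0, pre.size, size=max_samples)]
    theta = float(np.quantile(pre, 1.0 - f))
    network.theta = theta
    network.target_f = f
    return theta


def _activity_from_preactivations(pre: np.ndarray, theta: float, power: int) -> ExpansionActivity:
    H = np.maximum(pre - theta, 0.0)
    measured = float(np.mean(H > 0))
    if power != 1:
        H **= power
    return ExpansionActivity(H=H, measured_f=measured)


def expand(network: ExpansionNetwork, inputs: np.ndarray) -> ExpansionActivity:
    """Expansion-layer activity h = max(J_eff x - theta, 0)^p for a batch."""
    if network.theta is None:
        raise ValueError("network threshold is unset; calibrate it first")
    pre = network.preactivations(inputs)
    return _activity_from_preactivations(pre, network.theta, network.power)


def winner_take_all(preactivations: np.ndarray, f: float) -> ExpansionActivity:
    """Fix the per-pattern coding level by winner-take-all inhibition.

    For each pattern (column), the ceil(f M) units with the largest
    preactivations keep max(preactivation - cutoff, 0), where the cutoff
    is the largest excluded preactivation (the per-pattern minimum when
    all units are selected); all other units are silenced. Ties at the
    cutoff are broken toward the lowest neuron index.
    """
    if not 0.0 < f <= 1.0:
        raise ValueError("coding level must lie in (0, 1]")
    pre = np.atleast_2d(np.asarray(preactivations, dtype=float))
    M, P = pre.shape
    n_active = min(M, int(np.ceil(f * M)))
    if n_active < M:
        # largest excluded value per pattern; every selected unit sits
        # strictly above it (ties at the cutoff rectify to zero either
        # way, so partial selection does not change the activity)
        cutoff = -np.partition(-pre, n_active, axis=0)[n_active:n_active + 1]
    else:
        cutoff = pre.min(axis=0, keepdims=True)
    H = np.maximum(pre - cutoff, 0.0)
    return ExpansionActivity(H=H, measured_f=float(np.mean(H > 0)))


def coding_level(H: np.ndarray) -> float:
    """Average fraction of strictly positive entries per pattern."""
    H = np.asarray(H)
    if H.size == 0:
        raise ValueError("empty activity matrix")
    if np.any(H < 0):
        raise ValueError("activity must be nonnegative")
    return float(np.mean(H > 0))


def participation_dimension(H: np.ndarray) -> float:
    """Participation ratio (sum lambda)^2 / sum lambda^2 of the neuron
    covariance of activity across patterns.

    Computed through the pattern-by-pattern Gram matrix of centered
    activity, which shares its nonzero spectrum with the M x M neuron
    covariance: tr C = ||Hc||_F^2 / (P-1) and tr C^2 = ||Hc^T Hc||_F^2 /
    (P-1)^2.
    """
    H = np.atleast_2d(np.asarray(H, dtype=float))
    M, P = H.shape
    if P < 2:
        raise ValueError("participation dimension needs at least 2 patterns")
    Hc = H - H.mean(axis=1, keepdims=True)
    tr = float(np.sum(Hc * Hc)) / (P - 1)
    if tr == 0.0:
        warnings.warn("zero activity covariance; dimension undefined, returning 0")
        return 0.0
    # Frobenius norm of the smaller Gram matrix; both share the nonzero
    # singular values of Hc, so tr(C^2) = ||G||_F^2 / (P-1)^2 either way
    G = Hc.T @ Hc if P <= M else Hc @ Hc.T
    tr2 = float(np.sum(G * G)) / (P - 1) ** 2
    return tr * tr / tr2


def effective_weight_correlations(
    network: ExpansionNetwork, n_pairs: int, seed=None
) -> np.ndarray:
    """Cosine correlations of effective-weight rows for random neuron pairs.

    Uncentered cosine similarity Corr(J_eff_i, J_eff_j); for dense
    Gaussian weights in D = 3 this distribution is uniform on [-1, 1].
    Pairs involving a zero-norm row are excluded with a warning.
    """
    if network.input_dim < 2:
        raise ValueError("weight correlations require input dimension >= 2")
    rng = np.random.default_rng(seed)
    M = network.M
    i = rng.integers(0, M, size=n_pairs)
    j = rng.integers(0, M, size=n_pairs)
    resample = i == j
    while np.any(resample):
        j[resample] = rng.integers(0, M, size=int(resample.sum()))
        resample = i == j
    norms = np.linalg.norm(network.J_eff, axis=1)
    ok = (norms[i] > 0) & (norms[j] > 0)
    if not np.all(ok):
        warnings.warn("excluded pairs with zero-norm effective weight rows")
    i, j = i[ok], j[ok]
    dots = np.einsum("pd,pd->p", network.J_eff[i], network.J_eff[j])
    return dots / (norms[i] * norms[j])
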