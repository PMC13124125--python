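"""Domain feature construction.

The domain modality is built in three stages:

1. a binary protein x domain adjacency from the association table;
2. a weighted protein x domain matrix that propagates each association to
   similar domains, where domain-domain similarity is the Gaussian
   interaction profile (GIP) kernel on adjacency columns; and
3. compression of the weighted matrix rows to a low-dimensional embedding
   with a single-hidden-layer sparse autoencoder whose hidden and output
   activations are the saturating-linear (Satlin) function.

The GIP bandwidth is normalized by the mean squared column norm, so the
kernel adapts to the density of the association table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from ._autograd import Adam, Parameter, Tensor

__all__ = [
    "ProteinDomainAdjacency",
    "GipKernel",
    "build_adjacency",
    "gip_similarity",
    "build_weighted_matrix",
    "satlin",
    "SparseAutoencoder",
    "train_sparse_autoencoder",
    "encode_domain_features",
]


@dataclass
class ProteinDomainAdjacency:
    """Binary m x n protein-domain incidence matrix with its axis labels."""

    matrix: np.ndarray
    protein_ids: list[str]
    domain_ids: list[str]


@dataclass
class GipKernel:
    """Symmetric domain-domain GIP similarity with its effective bandwidth."""

    similarity: np.ndarray
    alpha: float
    alpha_prime: float


def build_adjacency(pairs, protein_ids, domain_ids) -> ProteinDomainAdjacency:
    """Binary adjacency from (protein, domain) association pairs.

    Raises ``KeyError`` for pairs naming an id absent from the indices.
    """
    p_pos = {p: i for i, p in enumerate(protein_ids)}
    d_pos = {d: j for j, d in enumerate(domain_ids)}
    M = np.zeros((len(protein_ids), len(domain_ids)))
    for p, d in pairs:
        if p not in p_pos:
            raise KeyError(f"unknown protein id in domain table: {p!r}")
        if d not in d_pos:
            raise KeyError(f"unknown domain id in domain table: {d!r}")
        M[p_pos[p], d_pos[d]] = 1.0
    return ProteinDomainAdjacency(M, list(protein_ids), list(domain_ids))


def gip_similarity(adj: ProteinDomainAdjacency | np.ndarray, alpha_prime: float = 1.0) -> GipKernel:
    """GIP kernel over domains (columns of the adjacency).

    The bandwidth is ``alpha = alpha_prime / mean_k ||col_k||^2``; similarity
    between domains i and j is ``exp(-alpha * ||col_i - col_j||^2)``.
    """
    M = adj.matrix if isinstance(adj, ProteinDomainAdjacency) else np.asarray(adj, dtype=float)
    if alpha_prime <= 0:
        raise ValueError("alpha_prime must be positive")
    norms = (M**2).sum(axis=0)
    mean_norm = norms.mean() if norms.size else 0.0
    if mean_norm == 0.0:
        raise ValueError("bandwidth undefined: adjacency has no associations")
    alpha = alpha_prime / mean_norm
    d2 = cdist(M.T, M.T, metric="sqeuclidean")
    SD = np.exp(-alpha * d2)
    # enforce exact symmetry/diagonal against cdist round-off
    SD = 0.5 * (SD + SD.T)
    np.fill_diagonal(SD, 1.0)
    return GipKernel(SD, float(alpha), float(alpha_prime))


def build_weighted_matrix(adj: ProteinDomainAdjacency | np.ndarray, kernel: GipKernel) -> np.ndarray:
    """Weighted protein-domain scores.

    Entry (i, j) is the maximum over domains k of the average of the
    propagated similarity ``M[i,k] * SD[k,j]`` and the direct association
    ``M[i,j]``. Since the direct term does not depend on k, this equals
    ``(max_k M[i,k] * SD[k,j] + M[i,j]) / 2``; existing associations keep
    score 1 (k = j contributes similarity 1) and domain-less proteins keep
    all-zero rows.
    """
    M = adj.matrix if isinstance(adj, ProteinDomainAdjacency) else np.asarray(adj, dtype=float)
    SD = kernel.similarity
    if M.shape[1] != SD.shape[0]:
        raise ValueError("adjacency / kernel shape mismatch")
    m, n = M.shape
    best = np.zeros((m, n))
    for i in range(m):
        cols = np.flatnonzero(M[i])
        if cols.size:
            best[i] = SD[cols].max(axis=0)
    return (best + M) / 2.0


def satlin(x):
    """Saturating linear activation: clip to [0, 1]."""
    return np.clip(x, 0.0, 1.0)


@dataclass
class SparseAutoencoder:
    """Single-hidden-layer Satlin autoencoder with KL sparsity penalty.

    Attributes hold the trained weights; ``losses`` records the total
    training objective per epoch and ``recon_losses`` the reconstruction
    term alone.
    """

    w_ih: np.ndarray
    b_ih: np.ndarray
    w_ho: np.ndarray
    b_ho: np.ndarray
    hidden: int
    sparsity_weight: float
    sparsity_target: float
    l2_weight: float
    losses: list[float] = field(default_factory=list)
    recon_losses: list[float] = field(default_factory=list)

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Hidden activations for samples in rows of X; returns (n_samples, f)."""
        return satlin(X @ self.w_ih.T + self.b_ih)

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return satlin(self.encode(X) @ self.w_ho.T + self.b_ho)


def train_sparse_autoencoder(
    X: np.ndarray,
    hidden: int = 36,
    sparsity_weight: float = 4.0,
    sparsity_target: float = 0.05,
    l2_weight: float = 0.01,
    epochs: int = 500,
    lr: float = 1e-3,
    seed: int = 0,
) -> SparseAutoencoder:
    """Fit the sparse autoencoder by full-batch Adam.

    Objective: mean squared reconstruction error
    + ``l2_weight/2 * sum(W^2)`` over both weight matrices
    + ``sparsity_weight * KL(target || mean hidden activation)`` summed over
    hidden units. Deterministic for a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    n_samples, n_in = X.shape
    if not 1 < hidden:
        raise ValueError("hidden width must exceed 1")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in autoencoder input")
    rng = np.random.default_rng(seed)
    bound = np.sqrt(6.0 / (n_in + hidden))
    w_ih = Parameter(rng.uniform(-bound, bound, size=(hidden, n_in)))
    b_ih = Parameter(np.full(hidden, 0.5))  # start hidden units mid-range of Satlin
    w_ho = Parameter(rng.uniform(-bound, bound, size=(n_in, hidden)))
    b_ho = Parameter(np.full(n_in, 0.5))
    opt = Adam([w_ih, b_ih, w_ho, b_ho], lr=lr)
    Xt = Tensor(X)
    rho = sparsity_target
    eps = 1e-8
    losses: list[float] = []
    recon_losses: list[float] = []
    for epoch in range(epochs):
        opt.zero_grad()
        hidden_act = (Xt @ w_ih.transpose_2d() + b_ih).satlin()
        recon = (hidden_act @ w_ho.transpose_2d() + b_ho).satlin()
        mse = ((recon - Xt) ** 2).mean()
        l2 = ((w_ih**2).sum() + (w_ho**2).sum()) * (0.5 * l2_weight)
        rho_hat = hidden_act.mean(axis=0)
        kl = (
            Tensor(rho) * ((Tensor(rho) / (rho_hat + eps)).log())
            + Tensor(1 - rho) * ((Tensor(1 - rho) / (Tensor(1.0) - rho_hat + eps)).log())
        ).sum() * sparsity_weight
        loss = mse + l2 + kl
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"non-finite autoencoder loss at epoch {epoch}")
        losses.append(float(loss.data))
        recon_losses.append(float(mse.data))
        loss.backward()
        opt.step()
    return SparseAutoencoder(
        w_ih=w_ih.data.copy(),
        b_ih=b_ih.data.copy(),
        w_ho=w_ho.data.copy(),
        b_ho=b_ho.data.copy(),
        hidden=hidden,
        sparsity_weight=sparsity_weight,
        sparsity_target=sparsity_target,
        l2_weight=l2_weight,
        losses=losses,
        recon_losses=recon_losses,
    )


def encode_domain_features(model: SparseAutoencoder, weighted: np.ndarray) -> np.ndarray:
    """Domain feature matrix: Satlin(W . M^T + b), one column per protein (f x m)."""
    weighted = np.asarray(weighted, dtype=float)
    if weighted.shape[1] != model.w_ih.shape[1]:
        raise ValueError(
            f"weighted matrix has {weighted.shape[1]} domains, "
            f"encoder expects {model.w_ih.shape[1]}"
        )
    return satlin(model.w_ih @ weighted.T + model.b_ih[:, None])
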