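"""Subcellular-localization, orthology, and network-topology feature blocks.

Subcellular features score each localization by how many proteins it hosts
and give every protein the score vector of its localizations. Orthology is a
single conservation score per protein, expanded to a t-dimensional vector of
powers after min-max normalization so the higher powers stay in [0, 1].
Topology descriptors are the log-degree and k-core index of the PPI graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SubcellularMatrix",
    "OrthologyExpansion",
    "subcellular_scores",
    "build_subcellular_matrix",
    "expand_orthology",
    "topology_descriptors",
]

logger = logging.getLogger(__name__)


@dataclass
class SubcellularMatrix:
    """N x m localization-score matrix; column j is protein j's feature vector."""

    matrix: np.ndarray
    localization_ids: list[str]
    protein_ids: list[str]
    scores: np.ndarray  # SC per localization

    def protein_vectors(self) -> np.ndarray:
        """Row-per-protein view (m x N)."""
        return self.matrix.T


def subcellular_scores(table: pd.DataFrame, localization_ids: list[str]) -> np.ndarray:
    """Number of distinct proteins associated with each localization."""
    if table.empty:
        return np.zeros(len(localization_ids))
    counts = table.drop_duplicates().groupby("item")["protein"].nunique()
    return np.array([float(counts.get(s, 0)) for s in localization_ids])


def build_subcellular_matrix(
    table: pd.DataFrame,
    protein_ids: list[str],
    localization_ids: list[str] | None = None,
) -> SubcellularMatrix:
    """Score matrix with entry (i, j) = SC(s_i) if protein j sits in s_i, else 0."""
    if localization_ids is None:
        localization_ids = sorted(table["item"].unique())
    sc = subcellular_scores(table, localization_ids)
    loc_pos = {s: i for i, s in enumerate(localization_ids)}
    prot_pos = {p: j for j, p in enumerate(protein_ids)}
    M = np.zeros((len(localization_ids), len(protein_ids)))
    for p, s in table.drop_duplicates().itertuples(index=False, name=None):
        if s in loc_pos and p in prot_pos:
            M[loc_pos[s], prot_pos[p]] = sc[loc_pos[s]]
    return SubcellularMatrix(M, list(localization_ids), list(protein_ids), sc)


@dataclass
class OrthologyExpansion:
    """Per-protein vector of powers 1..t of the normalized conservation score."""

    vectors: np.ndarray
    t: int
    lo: float
    hi: float

    def transform(self, scores: np.ndarray) -> np.ndarray:
        """Expand new scores with the stored (train-split) range."""
        return _powers(_minmax(np.asarray(scores, dtype=float), self.lo, self.hi), self.t)


def _minmax(s: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi == lo:
        return np.full_like(s, 0.5)
    return np.clip((s - lo) / (hi - lo), 0.0, 1.0)


def _powers(s: np.ndarray, t: int) -> np.ndarray:
    return np.column_stack([s ** k for k in range(1, t + 1)])


def expand_orthology(
    scores: np.ndarray, t: int = 12, train_indices: np.ndarray | None = None
) -> OrthologyExpansion:
    """Min-max normalize scores (train-split range) and expand to powers 1..t.

    ``train_indices=None`` uses the full-data range. A degenerate training
    range (max == min) maps every score to 0.5 and is logged.
    """
    scores = np.asarray(scores, dtype=float)
    if t < 1:
        raise ValueError("t must be >= 1")
    if (scores < 0).any():
        raise ValueError("orthology scores must be nonnegative")
    ref = scores if train_indices is None else scores[np.asarray(train_indices)]
    lo, hi = float(ref.min()), float(ref.max())
    if hi == lo:
        logger.warning("degenerate orthology training range; all scores map to 0.5")
    return OrthologyExpansion(_powers(_minmax(scores, lo, hi), t), t, lo, hi)


def topology_descriptors(
    edges: list[tuple[str, str]], protein_ids: list[str] | None = None
) -> pd.DataFrame:
    """Per-protein (log-degree, k-core index) from the PPI graph.

    log-degree is log(1 + degree); nodes absent from the edge list get both
    descriptors 0.
    """
    g = nx.Graph()
    if protein_ids is not None:
        g.add_nodes_from(protein_ids)
    g.add_edges_from(edges)
    g.remove_edges_from(nx.selfloop_edges(g))
    core = nx.core_number(g)
    rows = []
    ids = protein_ids if protein_ids is not None else sorted(g.nodes)
    for p in ids:
        deg = g.degree(p) if p in g else 0
        rows.append((p, np.log1p(deg), float(core.get(p, 0))))
    return pd.DataFrame(rows, columns=["protein", "log_degree", "k_core"])
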