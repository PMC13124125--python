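"""End-to-end assembly: input files -> labeled multi-modal dataset.

This is the glue the CLI and the examples use: read the file bundle,
harmonize identifiers, build the weighted protein-domain matrix, train the
sparse autoencoder for the domain embedding, construct the subcellular and
orthology blocks, and assemble everything into a
:class:`~dlam.data_io.ModalityDataset` aligned to the PPI node set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_io
from .aux_features import build_subcellular_matrix, topology_descriptors
from .data_io import ModalityDataset, ProteinIndex
from .domain_features import (
    build_adjacency,
    build_weighted_matrix,
    encode_domain_features,
    gip_similarity,
    train_sparse_autoencoder,
)

__all__ = ["FeatureConfig", "load_tables", "build_dataset"]


@dataclass
class FeatureConfig:
    sae_hidden: int = 36
    sae_epochs: int = 500
    sae_lr: float = 1e-3
    sae_sparsity_weight: float = 4.0
    sae_sparsity_target: float = 0.05
    sae_l2: float = 0.01
    gip_alpha_prime: float = 1.0
    orthology_t: int = 12
    n_samples: int = 36
    use_topology: bool = False
    seed: int = 0


def load_tables(data_dir) -> dict:
    """Read the file bundle from a directory (see data_io for the dialect)."""
    d = Path(data_dir)
    edges, index = data_io.read_ppi_edges(d / "ppi.tsv")
    tables = {
        "domain": data_io.read_association_table(d / "domains.tsv", "domain"),
        "subcellular": data_io.read_association_table(d / "subcellular.tsv", "subcellular"),
        "orthology": data_io.read_orthology(d / "orthology.tsv"),
        "expression": data_io.read_expression(d / "expression.tsv"),
    }
    mapping = None
    if (d / "idmap.tsv").exists():
        mapping = data_io.read_idmap(d / "idmap.tsv")
    essential = data_io.read_essential(d / "essential.txt")
    return {
        "edges": edges,
        "index": index,
        "tables": tables,
        "mapping": mapping,
        "essential": essential,
    }


def build_dataset(
    data_dir, cfg: FeatureConfig | None = None
) -> tuple[ModalityDataset, dict]:
    """Build the dataset from a study directory.

    Returns the dataset plus an artifacts dict (autoencoder, weighted matrix,
    exclusion report) for inspection. Proteins outside the PPI node set are
    dropped from every modality; the label universe is the node set.
    """
    cfg = cfg or FeatureConfig()
    loaded = load_tables(data_dir)
    tables, report = data_io.harmonize_ids(loaded["tables"], loaded["mapping"])
    index: ProteinIndex = loaded["index"]
    keep = set(index.ids) - report.excluded_ids
    protein_ids = sorted(keep)

    dom_tab = tables["domain"]
    dom_tab = dom_tab[dom_tab["protein"].isin(keep)]
    dom_block = None
    sae = None
    weighted = None
    if not dom_tab.empty:
        dom_proteins = sorted(dom_tab["protein"].unique())
        domain_ids = sorted(dom_tab["item"].unique())
        adj = build_adjacency(
            list(dom_tab.itertuples(index=False, name=None)), dom_proteins, domain_ids
        )
        kernel = gip_similarity(adj, cfg.gip_alpha_prime)
        weighted = build_weighted_matrix(adj, kernel)
        sae = train_sparse_autoencoder(
            weighted,
            hidden=cfg.sae_hidden,
            sparsity_weight=cfg.sae_sparsity_weight,
            sparsity_target=cfg.sae_sparsity_target,
            l2_weight=cfg.sae_l2,
            epochs=cfg.sae_epochs,
            lr=cfg.sae_lr,
            seed=cfg.seed,
        )
        v_dom = encode_domain_features(sae, weighted)  # (f, m_dom)
        dom_block = pd.DataFrame(v_dom.T, columns=[f"dom{i}" for i in range(cfg.sae_hidden)])
        dom_block.insert(0, "protein", dom_proteins)

    sub_tab = tables["subcellular"]
    sub_tab = sub_tab[sub_tab["protein"].isin(keep)]
    sub_block = None
    if not sub_tab.empty:
        sub_proteins = sorted(sub_tab["protein"].unique())
        sub_mat = build_subcellular_matrix(sub_tab, sub_proteins)
        sub_block = pd.DataFrame(
            sub_mat.protein_vectors(),
            columns=[f"loc_{s}" for s in sub_mat.localization_ids],
        )
        sub_block.insert(0, "protein", sub_proteins)

    expr = tables["expression"]
    expr = expr[expr["protein"].isin(keep)]
    orth = tables["orthology"]
    orth = orth[orth["protein"].isin(keep)]

    topo = None
    if cfg.use_topology:
        topo = topology_descriptors(loaded["edges"], protein_ids)

    dataset = data_io.assemble_dataset(
        protein_ids,
        expression=expr if not expr.empty else None,
        domain_vec=dom_block,
        subcellular_vec=sub_block,
        orthology=orth if not orth.empty else None,
        essential=loaded["essential"],
        n_samples=cfg.n_samples,
        orthology_t=cfg.orthology_t,
        topo_vec=topo,
    )
    artifacts = {
        "autoencoder": sae,
        "weighted_matrix": weighted,
        "exclusion_report": report,
        "edges": loaded["edges"],
    }
    return dataset, artifacts
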