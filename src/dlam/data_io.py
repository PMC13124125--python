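"""Reading, harmonizing, and assembling the multi-modal input tables.

All inputs are tab-separated UTF-8 text with a header row:

* ``ppi.tsv`` — two columns of interacting protein ids;
* ``domains.tsv`` — (protein, domain) association pairs;
* ``subcellular.tsv`` — (protein, localization) association pairs;
* ``orthology.tsv`` — (protein, score) with a nonnegative conservation score;
* ``expression.tsv`` — protein id followed by one column per expression sample;
* ``essential.txt`` — one known-essential protein id per line (no header);
* ``idmap.tsv`` — optional (source_id, canonical_id) mapping.

Proteins are ordered by lexicographic sort of canonical ids throughout, so a
dataset assembled twice from the same files is bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProteinIndex",
    "ModalityDataset",
    "Normalizer",
    "ExclusionReport",
    "MODALITIES",
    "read_ppi_edges",
    "read_association_table",
    "read_orthology",
    "read_expression",
    "read_essential",
    "read_idmap",
    "harmonize_ids",
    "assemble_dataset",
    "fit_normalizer",
    "apply_normalizer",
]

logger = logging.getLogger(__name__)

#: fixed modality order used for availability flags and model fusion
MODALITIES = ("expression", "domain", "subcellular", "orthology")


@dataclass
class ProteinIndex:
    """Deterministically ordered universe of canonical protein ids."""

    ids: list[str]
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate protein ids in index")
        self._pos = {p: i for i, p in enumerate(self.ids)}

    def __len__(self):
        return len(self.ids)

    def __contains__(self, pid):
        return pid in self._pos

    def position(self, pid: str) -> int:
        return self._pos[pid]


@dataclass
class ExclusionReport:
    """Protein ids dropped during harmonization, with the reason."""

    ambiguous: list[str] = field(default_factory=list)

    @property
    def excluded_ids(self) -> set[str]:
        return set(self.ambiguous)


@dataclass
class ModalityDataset:
    """Per-protein feature blocks sharing one protein axis.

    ``flags`` column order follows :data:`MODALITIES`; a 0 flag implies the
    corresponding feature row is all-zero. ``orthology_scores`` keeps the raw
    conservation scores so cross-validation can redo the polynomial expansion
    with fold-local normalization; ``orthology_vec`` is a convenience
    expansion using the full-data range.
    """

    protein_ids: list[str]
    expression: np.ndarray
    domain_vec: np.ndarray
    subcellular_vec: np.ndarray
    orthology_scores: np.ndarray
    orthology_vec: np.ndarray
    flags: np.ndarray
    labels: np.ndarray
    topo_vec: np.ndarray | None = None

    def __len__(self):
        return len(self.protein_ids)

    def block(self, name: str) -> np.ndarray:
        if name == "topology":
            if self.topo_vec is None:
                raise KeyError("topology block not present")
            return self.topo_vec
        return {
            "expression": self.expression,
            "domain": self.domain_vec,
            "subcellular": self.subcellular_vec,
            "orthology": self.orthology_vec,
        }[name]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_ppi_edges(path) -> tuple[list[tuple[str, str]], ProteinIndex]:
    """Read an undirected edge list, dropping self-loops and duplicate edges.

    Duplicates are collapsed regardless of orientation. Raises ``ValueError``
    naming the offending line for malformed rows, and for an empty file.
    """
    edges: set[tuple[str, str]] = set()
    nodes: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"empty PPI file: {path}")
    for lineno, line in enumerate(lines[1:], start=2):  # line 1 is the header
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
            raise ValueError(f"malformed PPI line {lineno} in {path}: {line!r}")
        a, b = parts[0].strip(), parts[1].strip()
        nodes.update((a, b))
        if a == b:
            continue
        edges.add((min(a, b), max(a, b)))
    return sorted(edges), ProteinIndex(sorted(nodes))


def read_association_table(path, kind: str) -> pd.DataFrame:
    """Read a (protein, item) association table; ``kind`` is recorded in attrs."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = ["protein", "item"]
    df.attrs["kind"] = kind
    return df


def read_orthology(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df.columns = ["protein", "score"]
    df["score"] = df["score"].astype(float)
    if (df["score"] < 0).any():
        raise ValueError("orthology scores must be nonnegative")
    return df


def read_expression(path) -> pd.DataFrame:
    """Expression matrix: first column protein id, remaining columns samples."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = df.rename(columns={df.columns[0]: "protein"})
    return df


def read_essential(path) -> set[str]:
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


def read_idmap(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = ["source", "canonical"]
    return list(df.itertuples(index=False, name=None))


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def harmonize_ids(
    tables: dict[str, pd.DataFrame],
    mapping: list[tuple[str, str]] | None = None,
    protein_columns: dict[str, str] | None = None,
) -> tuple[dict[str, pd.DataFrame], ExclusionReport]:
    """Rename protein ids to canonical ids; drop ambiguously mapped proteins.

    A source id mapped to more than one canonical id, or a canonical id fed
    by more than one source, is ambiguous: every id involved is excluded from
    every table and listed in the report. Ids absent from the mapping pass
    through unchanged (identity mapping).
    """
    protein_columns = protein_columns or {}
    report = ExclusionReport()
    rename: dict[str, str] = {}
    if mapping:
        pairs = sorted(set(mapping))
        src_count: dict[str, int] = {}
        dst_count: dict[str, int] = {}
        for s, c in pairs:
            src_count[s] = src_count.get(s, 0) + 1
            dst_count[c] = dst_count.get(c, 0) + 1
        bad_src = {s for s, c in pairs if src_count[s] > 1 or dst_count[c] > 1}
        report.ambiguous = sorted(bad_src)
        rename = {s: c for s, c in pairs if s not in bad_src}
    excluded = report.excluded_ids
    out: dict[str, pd.DataFrame] = {}
    for name, df in tables.items():
        col = protein_columns.get(name, "protein")
        df = df[~df[col].isin(excluded)].copy()
        df[col] = df[col].map(lambda p: rename.get(p, p))
        df.attrs.update(tables[name].attrs)
        out[name] = df
    return out, report


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _align_block(
    block: pd.DataFrame | None, protein_ids: list[str], width: int
) -> tuple[np.ndarray, np.ndarray]:
    """Reindex a protein-keyed block to the canonical order.

    Returns the zero-filled (m, width) matrix and the availability flags.
    """
    m = len(protein_ids)
    out = np.zeros((m, width))
    flag = np.zeros(m)
    if block is None or block.empty:
        return out, flag
    values = block.set_index("protein")
    present = values.index.intersection(protein_ids)
    pos = {p: i for i, p in enumerate(protein_ids)}
    for p in present:
        out[pos[p]] = values.loc[p].to_numpy(dtype=float)
        flag[pos[p]] = 1.0
    return out, flag


def assemble_dataset(
    protein_ids: list[str],
    expression: pd.DataFrame | None,
    domain_vec: pd.DataFrame | None,
    subcellular_vec: pd.DataFrame | None,
    orthology: pd.DataFrame | None,
    essential: set[str],
    n_samples: int = 36,
    orthology_t: int = 12,
    topo_vec: pd.DataFrame | None = None,
) -> ModalityDataset:
    """Assemble harmonized feature blocks into one labeled dataset.

    Feature blocks are DataFrames with a ``protein`` column followed by the
    feature columns. Proteins missing a modality get an all-zero row and a 0
    availability flag; a protein with no modality at all is retained (and
    logged) so the label universe stays the PPI node set. Labels are 1 iff
    the id is in ``essential``.
    """
    from .aux_features import expand_orthology  # local import to avoid a cycle

    protein_ids = sorted(protein_ids)
    m = len(protein_ids)

    expr, f_expr = _align_block(expression, protein_ids, n_samples)
    dom_width = 0 if domain_vec is None or domain_vec.empty else domain_vec.shape[1] - 1
    dom, f_dom = _align_block(domain_vec, protein_ids, max(dom_width, 1))
    sub_width = (
        0 if subcellular_vec is None or subcellular_vec.empty else subcellular_vec.shape[1] - 1
    )
    sub, f_sub = _align_block(subcellular_vec, protein_ids, max(sub_width, 1))

    scores = np.zeros(m)
    f_ort = np.zeros(m)
    if orthology is not None and not orthology.empty:
        ser = orthology.set_index("protein")["score"]
        for p in ser.index.intersection(protein_ids):
            scores[protein_ids.index(p)] = float(ser.loc[p])
            f_ort[protein_ids.index(p)] = 1.0
    avail = np.flatnonzero(f_ort)
    ort = np.zeros((m, orthology_t))
    if avail.size:
        ort[avail] = expand_orthology(scores[avail], orthology_t, train_indices=None).vectors

    flags = np.column_stack([f_expr, f_dom, f_sub, f_ort])
    orphans = np.flatnonzero(flags.sum(axis=1) == 0)
    if orphans.size:
        logger.warning(
            "%d protein(s) have no modality at all; retained with all-zero features",
            orphans.size,
        )
    labels = np.array([1 if p in essential else 0 for p in protein_ids], dtype=int)

    topo = None
    if topo_vec is not None and not topo_vec.empty:
        topo, _ = _align_block(topo_vec, protein_ids, topo_vec.shape[1] - 1)

    return ModalityDataset(
        protein_ids=protein_ids,
        expression=expr,
        domain_vec=dom,
        subcellular_vec=sub,
        orthology_scores=scores,
        orthology_vec=ort,
        flags=flags,
        labels=labels,
        topo_vec=topo,
    )


# ---------------------------------------------------------------------------
# fold-aware normalization
# ---------------------------------------------------------------------------

@dataclass
class Normalizer:
    """Per-feature z-scoring parameters fitted on one training split.

    Constant (zero-variance) features are mapped to 0 by recording scale 1
    and the training mean as location. Availability flags are never passed
    through the normalizer.
    """

    mean: dict[str, np.ndarray]
    scale: dict[str, np.ndarray]
    fit_split: str = "train"


def fit_normalizer(
    blocks: dict[str, np.ndarray], train_indices: np.ndarray, fit_split: str = "train"
) -> Normalizer:
    train_indices = np.asarray(train_indices)
    if train_indices.size == 0:
        raise ValueError("empty training split")
    mean: dict[str, np.ndarray] = {}
    scale: dict[str, np.ndarray] = {}
    for name, X in blocks.items():
        sub = np.asarray(X)[train_indices]
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=0)
        sd = np.where(sd == 0.0, 1.0, sd)
        mean[name] = mu
        scale[name] = sd
    return Normalizer(mean=mean, scale=scale, fit_split=fit_split)


def apply_normalizer(norm: Normalizer, blocks: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    out = {}
    for name, X in blocks.items():
        out[name] = (np.asarray(X) - norm.mean[name]) / norm.scale[name]
    return out
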