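"""Metrics, ROC/PR curves, stratified cross-validation, and paired tests.

Scalar metrics follow the usual confusion-matrix definitions with the
zero-denominator convention that precision/recall/F default to 0 (this keeps
reports NaN-free; accuracy of an empty confusion is 1). Ranking metrics are
the trapezoidal ROC-AUC and step-interpolated average precision, delegated
to scikit-learn; the test suite checks them against brute-force pairwise and
cumulative-sum oracles. Cross-validation is stratified k-fold with a
train/validation split inside each development set (60/20/20 overall at
k=5), fold-local feature normalization, and validation-based threshold
selection. Paired per-fold comparisons use the paired t-test and an exact
Wilcoxon signed-rank test, Holm-adjusted across the comparison family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold, train_test_split
from statsmodels.stats.multitest import multipletests

from .aux_features import expand_orthology
from .data_io import ModalityDataset, Normalizer, apply_normalizer, fit_normalizer
from .model import DlamModel, ModelConfig
from .training import TrainConfig, TrainResult, train

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "CvResult",
    "confusion_counts",
    "classification_metrics",
    "roc_auc",
    "pr_ap",
    "evaluate_scores",
    "stratified_kfold",
    "prepare_fold_blocks",
    "run_cv",
    "paired_tests",
    "exact_wilcoxon",
    "holm_adjust",
]

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalReport:
    threshold: float
    counts: ConfusionCounts
    accuracy: float
    precision: float
    recall: float
    f_measure: float
    auc: float
    ap: float
    roc_points: tuple[np.ndarray, np.ndarray]  # (fpr, tpr)
    pr_points: tuple[np.ndarray, np.ndarray]  # (recall, precision)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "tn": self.counts.tn,
            "fn": self.counts.fn,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "auc": self.auc,
            "ap": self.ap,
        }


@dataclass
class CvResult:
    fold_reports: list[EvalReport]
    fold_assignments: np.ndarray
    train_results: list[TrainResult] = field(default_factory=list)

    METRICS = ("accuracy", "precision", "recall", "f_measure", "auc", "ap")

    def summary(self) -> dict[str, tuple[float, float]]:
        """Mean and standard deviation of each metric across folds."""
        out = {}
        for m in self.METRICS:
            vals = np.array([getattr(r, m) for r in self.fold_reports])
            out[m] = (float(vals.mean()), float(vals.std(ddof=1) if len(vals) > 1 else 0.0))
        return out

    def per_fold(self, metric: str) -> np.ndarray:
        return np.array([getattr(r, metric) for r in self.fold_reports])


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------

def confusion_counts(pred: np.ndarray, labels: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred, dtype=int)
    labels = np.asarray(labels, dtype=int)
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (labels == 1))),
        fp=int(np.sum((pred == 1) & (labels == 0))),
        tn=int(np.sum((pred == 0) & (labels == 0))),
        fn=int(np.sum((pred == 0) & (labels == 1))),
    )


def classification_metrics(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, F-measure) with 0 on empty denominators."""
    total = c.total
    acc = (c.tp + c.tn) / total if total else 1.0
    prec = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    rec = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    f = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return acc, prec, rec, f


def roc_auc(scores: np.ndarray, labels: np.ndarray):
    """ROC curve points and trapezoidal AUC; requires both classes present."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC is undefined with a single class")
    fpr, tpr, _ = roc_curve(labels, scores)
    return (fpr, tpr), float(roc_auc_score(labels, scores))


def pr_ap(scores: np.ndarray, labels: np.ndarray):
    """Precision-recall points and step-interpolated average precision."""
    labels = np.asarray(labels, dtype=int)
    if labels.sum() == 0:
        raise ValueError("AP is undefined without positives")
    precision, recall, _ = precision_recall_curve(labels, scores)
    return (recall, precision), float(average_precision_score(labels, scores))


def evaluate_scores(scores: np.ndarray, labels: np.ndarray, threshold: float) -> EvalReport:
    """Full report: confusion at the threshold plus ROC/PR summaries."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    counts = confusion_counts((scores >= threshold).astype(int), labels)
    acc, prec, rec, f = classification_metrics(counts)
    roc_pts, auc = roc_auc(scores, labels)
    pr_pts, ap = pr_ap(scores, labels)
    return EvalReport(
        threshold=float(threshold),
        counts=counts,
        accuracy=acc,
        precision=prec,
        recall=rec,
        f_measure=f,
        auc=auc,
        ap=ap,
        roc_points=roc_pts,
        pr_points=(pr_pts[0], pr_pts[1]),
    )


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def stratified_kfold(labels: np.ndarray, k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold index (0..k-1) per sample; folds preserve the class ratio."""
    labels = np.asarray(labels, dtype=int)
    for cls, count in zip(*np.unique(labels, return_counts=True)):
        if count < k:
            raise ValueError(f"class {cls} has {count} samples, fewer than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = fold
    return assignment


def prepare_fold_blocks(
    dataset: ModalityDataset,
    train_idx: np.ndarray,
    modalities: tuple[str, ...],
    orthology_t: int = 12,
    use_topology: bool = False,
) -> tuple[dict[str, np.ndarray], np.ndarray | None, Normalizer]:
    """Fold-local feature preparation.

    The orthology expansion and every per-feature z-score are computed from
    the training split only, then applied to all rows; availability flags
    pass through untouched.
    """
    blocks: dict[str, np.ndarray] = {}
    for name in modalities:
        if name == "orthology":
            exp = expand_orthology(dataset.orthology_scores, orthology_t, train_indices=train_idx)
            vec = exp.vectors.copy()
            missing = dataset.flags[:, 3] == 0
            vec[missing] = 0.0
            blocks[name] = vec
        else:
            blocks[name] = dataset.block(name)
    extra_raw = dataset.topo_vec if use_topology else None
    if extra_raw is not None:
        blocks["_topology"] = extra_raw
    norm = fit_normalizer(blocks, train_idx)
    normed = apply_normalizer(norm, blocks)
    extra = normed.pop("_topology", None)
    return normed, extra, norm


def run_cv(
    dataset: ModalityDataset,
    k: int = 5,
    train_cfg: TrainConfig | None = None,
    model_cfg: ModelConfig | None = None,
    seed: int = 0,
    val_fraction: float = 0.25,
    use_topology: bool = False,
    orthology_t: int = 12,
) -> CvResult:
    """Stratified k-fold cross-validation of the full pipeline.

    Per fold: the held-out fold is the test set; the development set is
    split (stratified) into train and validation — ``val_fraction=0.25`` of
    the development set yields the 60/20/20 overall ratio at k=5. Feature
    normalization and orthology expansion are fitted on the training split
    only; the decision threshold is chosen on the validation split.
    """
    train_cfg = train_cfg or TrainConfig()
    labels = dataset.labels
    assignment = stratified_kfold(labels, k=k, seed=seed)
    modalities = (model_cfg or ModelConfig()).modalities
    reports: list[EvalReport] = []
    results: list[TrainResult] = []
    for fold in range(k):
        test_idx = np.flatnonzero(assignment == fold)
        dev_idx = np.flatnonzero(assignment != fold)
        tr_idx, val_idx = train_test_split(
            dev_idx,
            test_size=val_fraction,
            stratify=labels[dev_idx],
            random_state=seed + fold,
        )
        blocks, extra, _ = prepare_fold_blocks(
            dataset, tr_idx, modalities, orthology_t=orthology_t, use_topology=use_topology
        )
        cfg = model_cfg or ModelConfig()
        if extra is not None:
            cfg.n_extra = extra.shape[1]
        fold_model = DlamModel(cfg, seed=train_cfg.seed + fold)
        fold_train_cfg = TrainConfig(
            lr=train_cfg.lr,
            batch_size=train_cfg.batch_size,
            patience=train_cfg.patience,
            max_epochs=train_cfg.max_epochs,
            seed=train_cfg.seed + fold,
            undersample_ratio=train_cfg.undersample_ratio,
            threshold_grid=train_cfg.threshold_grid,
            class_weight=train_cfg.class_weight,
        )
        flag_cols = [("expression", "domain", "subcellular", "orthology").index(m) for m in modalities]
        flags = dataset.flags[:, flag_cols]
        result = train(
            fold_model, blocks, flags, labels, tr_idx, val_idx, fold_train_cfg, extra=extra
        )
        test_blocks = {name: X[test_idx] for name, X in blocks.items()}
        test_probs = fold_model.predict_proba(
            test_blocks, flags[test_idx], extra=extra[test_idx] if extra is not None else None
        )
        reports.append(evaluate_scores(test_probs[:, 1], labels[test_idx], result.threshold))
        results.append(result)
    return CvResult(fold_reports=reports, fold_assignments=assignment, train_results=results)


# ---------------------------------------------------------------------------
# paired significance tests
# ---------------------------------------------------------------------------

def exact_wilcoxon(differences: np.ndarray) -> float:
    """Two-sided exact Wilcoxon signed-rank p-value.

    Zero differences are dropped (if all are zero the test is undefined and
    p = 1 is returned, logged). Tied magnitudes get midranks; the null
    distribution of W+ is built exactly by dynamic programming over sign
    assignments, so ties are handled without a normal approximation.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        logger.info("all paired differences are zero; Wilcoxon p set to 1")
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    # integer grid: midranks are multiples of 0.5
    r2 = np.round(ranks * 2).astype(int)
    total = r2.sum()
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(w_plus * 2))
    lo = dist[: w2 + 1].sum()
    hi = dist[w2:].sum()
    return float(min(1.0, 2 * min(lo, hi)))


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="holm")[1]


def paired_tests(scores_a: np.ndarray, scores_b: np.ndarray) -> dict[str, float]:
    """Paired t-test and exact Wilcoxon on per-fold scores of two methods."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need paired score vectors of equal length >= 2")
    d = a - b
    if np.allclose(d, 0):
        t_p = 1.0
    else:
        t_p = float(stats.ttest_rel(a, b).pvalue)
        if not np.isfinite(t_p):
            t_p = 1.0
    return {"t_p": t_p, "wilcoxon_p": exact_wilcoxon(d)}
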