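"""Downstream evaluation: count matrices, clustering, morphology analysis.

Expression side: transcript assignments become a cell-by-gene count
matrix (restricted to aligned cells), which is library-size normalized,
log-transformed, reduced by PCA, embedded in a kNN graph and Leiden-
clustered with the resolution tuned by bisection to a target of k = 10
clusters (k in {9, 11} accepted as fallback, then {8, 12}).  Cluster
agreement between two labelings is quantified by ARI, AMI, homogeneity
and completeness.

Morphology side: per-cell shape features are z-scored and embedded with
UMAP (n_neighbors = 30, min_dist = 0.01, Euclidean), with per
dataset-and-type centroids for tissue-level visualization; a random
forest (500 trees, inverse-frequency class weights) predicts the five
most abundant cell types from morphology alone under a stratified 80/20
split, scored by accuracy, macro-F1 and macro one-vs-rest ROC-AUC.

The classification metrics (confusion counts, precision/recall/F1, ROC
AUC via the tie-averaged Mann–Whitney statistic) are implemented here
from first principles so they are pure functions of the predictions,
independent of any learner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import rankdata
from sklearn.metrics import (
    adjusted_mutual_info_score,
    adjusted_rand_score,
    completeness_score,
    homogeneity_score,
)

__all__ = [
    "CountMatrix",
    "ClusterAgreement",
    "ClassMetrics",
    "ClassificationReport",
    "ClusterCountError",
    "count_matrix",
    "cluster_cells",
    "agreement",
    "roc_auc",
    "classification_report_from_predictions",
    "MorphoEmbedding",
    "morpho_embed",
    "rf_evaluate",
]


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Cell-by-gene transcript counts (dense; desk-scale matrices)."""

    cells: list
    genes: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.cells), len(self.genes)):
            raise ValueError("count matrix shape does not match cell/gene axes")
        if self.counts.min(initial=0) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def write_mtx(self, prefix) -> None:
        """Write MatrixMarket counts plus row (cells) / column (genes) TSVs."""
        from pathlib import Path

        from scipy.io import mmwrite

        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        mmwrite(str(prefix) + ".mtx", sparse.csr_matrix(self.counts))
        Path(str(prefix) + ".cells.tsv").write_text("\n".join(str(c) for c in self.cells) + "\n")
        Path(str(prefix) + ".genes.tsv").write_text("\n".join(self.genes) + "\n")


def count_matrix(
    assignment: np.ndarray,
    t: pd.DataFrame,
    cells: Sequence[int],
    genes: Sequence[str] | None = None,
) -> CountMatrix:
    """Tally transcripts per (cell, gene); cells outside ``cells`` are dropped.

    ``genes`` fixes the column order (default: sorted genes of the table),
    keeping matrices from different segmentations comparable.
    """
    assignment = np.asarray(assignment)
    if len(assignment) != len(t):
        raise ValueError("assignment does not cover the transcript table")
    cells = sorted(cells)
    genes = sorted(t["gene"].unique()) if genes is None else list(genes)
    ci = {c: i for i, c in enumerate(cells)}
    gi = {g: i for i, g in enumerate(genes)}
    counts = np.zeros((len(cells), len(genes)), dtype=np.int64)
    keep = np.isin(assignment, cells)
    for lab, gene in zip(assignment[keep], t["gene"].to_numpy()[keep]):
        if gene in gi:
            counts[ci[lab], gi[gene]] += 1
    return CountMatrix(cells=cells, genes=genes, counts=counts)


# ---------------------------------------------------------------------------
# clustering to a target cluster count
# ---------------------------------------------------------------------------


class ClusterCountError(RuntimeError):
    """No resolution yielded a cluster count in the accepted sets."""

    def __init__(self, target: int, trace: list[tuple[float, int]]):
        self.trace = trace
        ks = sorted({k for _, k in trace}, key=lambda k: abs(k - target))
        super().__init__(
            f"could not reach k={target} (or fallbacks); closest k found was "
            f"{ks[0] if ks else 'none'}; resolution trace: {trace}"
        )


def cluster_cells(
    m: CountMatrix,
    target_k: int = 10,
    seed: int = 0,
    n_pcs: int = 50,
    n_neighbors: int = 15,
    max_evals: int = 40,
) -> np.ndarray:
    """Normalize → log1p → PCA → kNN → Leiden, tuned to ``target_k`` clusters.

    The Leiden resolution is searched by bisection over [0.01, 3.0],
    exploiting the (approximately monotone) growth of cluster count with
    resolution; every evaluated (resolution, k) pair is cached so
    non-monotone blips still count as hits.  Accepted cluster counts, in
    relaxation order: {target_k}, {target_k ± 1}, {target_k ± 2}; anything
    else raises :class:`ClusterCountError` with the resolution trace.
    Deterministic for a fixed seed.
    """
    import anndata as ad
    import scanpy as sc

    if len(m.cells) < target_k:
        raise ValueError(f"need at least {target_k} cells, have {len(m.cells)}")
    if len(m.genes) < 2:
        raise ValueError("need at least 2 genes")

    adata = ad.AnnData(
        X=sparse.csr_matrix(m.counts.astype(np.float32)),
        obs=pd.DataFrame(index=[str(c) for c in m.cells]),
        var=pd.DataFrame(index=list(m.genes)),
    )
    sc.pp.normalize_total(adata)  # target = median library size
    sc.pp.log1p(adata)
    n_comps = min(n_pcs, len(m.cells) - 1, len(m.genes) - 1)
    sc.pp.pca(adata, n_comps=n_comps, random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=n_neighbors, random_state=seed)

    cache: dict[float, np.ndarray] = {}
    trace: list[tuple[float, int]] = []

    def k_at(res: float) -> int:
        res = round(res, 6)
        if res not in cache:
            sc.tl.leiden(
                adata,
                resolution=res,
                random_state=seed,
                key_added="leiden_tmp",
                flavor="igraph",
                n_iterations=2,
                directed=False,
            )
            cache[res] = adata.obs["leiden_tmp"].astype(int).to_numpy()
            trace.append((res, int(cache[res].max()) + 1))
        return int(cache[res].max()) + 1

    lo, hi = 0.01, 3.0
    k_at(lo)
    k_at(hi)
    evals = 2
    while evals < max_evals and hi - lo > 1e-4:
        mid = (lo + hi) / 2
        k = k_at(mid)
        evals += 1
        if k == target_k:
            break
        if k < target_k:
            lo = mid
        else:
            hi = mid

    for accepted in ({target_k}, {target_k - 1, target_k + 1}, {target_k - 2, target_k + 2}):
        for res in sorted(cache):
            k = int(cache[res].max()) + 1
            if k in accepted:
                return cache[res]
    raise ClusterCountError(target_k, trace)


@dataclass(frozen=True)
class ClusterAgreement:
    ari: float
    ami: float
    homogeneity: float
    completeness: float

    def as_dict(self) -> dict[str, float]:
        return {
            "ari": self.ari,
            "ami": self.ami,
            "homogeneity": self.homogeneity,
            "completeness": self.completeness,
        }


def agreement(a, b) -> ClusterAgreement:
    """Chance-adjusted and information-theoretic concordance of two labelings.

    ``a`` is treated as the reference for homogeneity/completeness
    (homogeneity(a, b) = completeness(b, a)); ARI and AMI are symmetric.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"labelings have different lengths: {a.shape} vs {b.shape}")
    return ClusterAgreement(
        ari=float(adjusted_rand_score(a, b)),
        ami=float(adjusted_mutual_info_score(a, b)),
        homogeneity=float(homogeneity_score(a, b)),
        completeness=float(completeness_score(a, b)),
    )


# ---------------------------------------------------------------------------
# classification metrics (pure functions of predictions)
# ---------------------------------------------------------------------------


def roc_auc(y_true_binary, scores) -> float:
    """One-vs-rest ROC AUC via the tie-averaged Mann–Whitney statistic.

    Equivalent to the trapezoidal area under the ROC curve with tied
    scores averaged.  NaN when either class is empty.
    """
    y = np.asarray(y_true_binary, dtype=bool)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(s)  # average ranks on ties
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    auc: float
    tp: int
    fp: int
    fn: int


@dataclass
class ClassificationReport:
    accuracy: float
    macro_f1: float
    macro_auc: float
    per_class: dict
    classes: list
    excluded: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "macro_auc": self.macro_auc,
            "classes": [str(c) for c in self.classes],
            "excluded": [str(c) for c in self.excluded],
            "per_class": {
                str(c): vars(m).copy() for c, m in self.per_class.items()
            },
        }


def classification_report_from_predictions(
    y_true, y_pred, scores=None, classes=None
) -> ClassificationReport:
    """Accuracy, one-vs-rest precision/recall/F1 and macro means.

    ``scores`` is an optional (n, K) array of predicted class
    probabilities (columns ordered like ``classes``) used for per-class
    ROC-AUC.  Classes absent from ``y_true`` have undefined recall/AUC
    and are excluded from the macro averages (reported in ``excluded``).
    Zero-denominator precision/recall/F1 follow the 0 convention.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    classes = list(classes)

    per_class: dict = {}
    excluded: list = []
    for k, c in enumerate(classes):
        is_c = y_true == c
        pred_c = y_pred == c
        tp = int(np.sum(is_c & pred_c))
        fp = int(np.sum(~is_c & pred_c))
        fn = int(np.sum(is_c & ~pred_c))
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        auc = float("nan")
        if scores is not None:
            auc = roc_auc(is_c, np.asarray(scores)[:, k])
        per_class[c] = ClassMetrics(precision, recall, f1, auc, tp, fp, fn)
        if not is_c.any():
            excluded.append(c)

    scored = [c for c in classes if c not in excluded]
    if not scored:
        raise ValueError("no class present in y_true")
    macro_f1 = float(np.mean([per_class[c].f1 for c in scored]))
    aucs = [per_class[c].auc for c in scored if not np.isnan(per_class[c].auc)]
    macro_auc = float(np.mean(aucs)) if aucs else float("nan")
    return ClassificationReport(
        accuracy=float(np.mean(y_true == y_pred)),
        macro_f1=macro_f1,
        macro_auc=macro_auc,
        per_class=per_class,
        classes=classes,
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# morphology embedding and classification
# ---------------------------------------------------------------------------


@dataclass
class MorphoEmbedding:
    embedding: np.ndarray  # (n_cells, 2)
    centroids: pd.DataFrame  # index (dataset, type), columns umap1/umap2
    dropped_features: list[str] = field(default_factory=list)


def zscore_features(features: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Z-score each feature column; constant columns are dropped with a warning."""
    sd = features.std(ddof=0)
    dropped = list(features.columns[sd <= 0])
    if dropped:
        warnings.warn(f"dropping constant features (z-score undefined): {dropped}")
    kept = features.drop(columns=dropped)
    return (kept - kept.mean()) / kept.std(ddof=0), dropped


def morpho_embed(
    features: pd.DataFrame,
    datasets,
    types,
    n_neighbors: int = 30,
    min_dist: float = 0.01,
    seed: int = 0,
) -> MorphoEmbedding:
    """UMAP of z-scored morphology features plus dataset×type centroids."""
    import umap

    if len(features) < n_neighbors:
        raise ValueError(f"need at least n_neighbors={n_neighbors} cells")
    z, dropped = zscore_features(features)
    emb = umap.UMAP(
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        metric="euclidean",
        random_state=seed,
    ).fit_transform(z.to_numpy())
    df = pd.DataFrame(
        {
            "dataset": np.asarray(datasets),
            "type": np.asarray(types),
            "umap1": emb[:, 0],
            "umap2": emb[:, 1],
        }
    )
    centroids = df.groupby(["dataset", "type"])[["umap1", "umap2"]].mean()
    return MorphoEmbedding(embedding=emb, centroids=centroids, dropped_features=dropped)


EXCLUDED_TYPE_LABELS = {"unknown", "unassigned"}


def rf_evaluate(
    features: pd.DataFrame,
    types,
    seed: int = 0,
    n_top_classes: int = 5,
    test_size: float = 0.2,
    n_trees: int = 500,
    min_cells_per_class: int = 10,
) -> ClassificationReport:
    """Predict cell type from morphology with a random forest.

    Cells labeled unknown/unassigned are excluded; the analysis is
    restricted to the ``n_top_classes`` most abundant types (classes with
    fewer than ``min_cells_per_class`` cells are dropped with a warning).
    A stratified split holds out ~20 % of cells; the forest uses 500
    trees and class weights inversely proportional to training-set class
    frequency.  Metrics are computed on the held-out set by
    :func:`classification_report_from_predictions`.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import train_test_split

    types = np.asarray(types)
    keep = ~np.isin(np.char.lower(types.astype(str)), list(EXCLUDED_TYPE_LABELS))
    X = features.loc[keep].select_dtypes("number").to_numpy()
    y = types[keep]

    order = pd.Series(y).value_counts()
    top = list(order.index[:n_top_classes])
    small = [c for c in top if order[c] < min_cells_per_class]
    if small:
        warnings.warn(f"classes below {min_cells_per_class} cells retained with caution: {small}")
    sel = np.isin(y, top)
    X, y = X[sel], y[sel]
    classes = sorted(top, key=str)

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=seed
    )
    freq = pd.Series(y_tr).value_counts()
    class_weight = {c: len(y_tr) / (len(freq) * freq[c]) for c in freq.index}
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        class_weight=class_weight,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X_tr, y_tr)
    proba = rf.predict_proba(X_te)
    # align probability columns to the sorted class list
    col = {c: i for i, c in enumerate(rf.classes_)}
    scores = np.column_stack([proba[:, col[c]] for c in classes])
    return classification_report_from_predictions(
        y_te, rf.predict(X_te), scores=scores, classes=classes
    )
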