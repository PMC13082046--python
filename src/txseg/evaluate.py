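"""Segmentation quality metrics: image IoU, gene IoU, cell alignment.

Two parallel constructions quantify agreement between a predicted and a
ground-truth instance mask:

* **Image IoU** works on pixel sets.  ``IoU(i, j) = |G_i ∩ P_j| / |G_i ∪
  P_j|`` over ground-truth cells ``i`` (rows) and predicted cells ``j``
  (columns); each predicted cell scores its best-overlapping ground-truth
  cell, ``IoU_j = max_i IoU(i, j)``, and the tile score is the mean of
  ``IoU_j`` over all predicted cells.  Tile scores are averaged
  (unweighted) across tiles for dataset-level summaries.
* **Gene IoU** applies the same construction to per-cell *transcript
  index sets* obtained by spatial containment: a molecule belongs to the
  cell whose mask pixel contains its coordinate.  Predicted cells with no
  assigned molecules are excluded from the tile mean (0/0 is undefined).

**Cell alignment** derives a one-to-one ground-truth ↔ prediction
correspondence: a pair is kept iff its IoU is at least the threshold
(default 0.3) and each member is the other's unique best match (mutual
argmax, ties broken toward the smaller label).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .io_types import FrameMismatchError, LabelMask, PixelFrame

__all__ = [
    "IoUMatrix",
    "AlignmentMap",
    "iou_matrix",
    "image_iou",
    "assign_transcripts",
    "gene_iou",
    "align_cells",
    "aggregate_tiles",
]


@dataclass
class IoUMatrix:
    """Ground-truth × predicted overlap scores with explicit label axes."""

    gt_labels: np.ndarray
    pred_labels: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gt_labels = np.asarray(self.gt_labels)
        self.pred_labels = np.asarray(self.pred_labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.gt_labels.size, self.pred_labels.size):
            raise ValueError("IoU matrix shape does not match label axes")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1 + 1e-12):
            raise ValueError("IoU values must lie in [0, 1]")


@dataclass
class AlignmentMap:
    """One-to-one (gt_label, pred_label) pairs, each with IoU >= threshold."""

    pairs: list[tuple[int, int]]
    threshold: float
    tied: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        gts = [g for g, _ in self.pairs]
        preds = [p for _, p in self.pairs]
        if len(set(gts)) != len(gts) or len(set(preds)) != len(preds):
            raise ValueError("alignment is not one-to-one")

    def gt_to_pred(self) -> dict[int, int]:
        return dict(self.pairs)

    def pred_to_gt(self) -> dict[int, int]:
        return {p: g for g, p in self.pairs}


def _contingency(a: np.ndarray, b: np.ndarray):
    """Sparse co-occurrence counts of two equally shaped label arrays,
    restricted to entries where both are positive."""
    both = (a > 0) & (b > 0)
    ga, gb = a[both], b[both]
    al = np.unique(a[a > 0])
    bl = np.unique(b[b > 0])
    ai = {l: i for i, l in enumerate(al)}
    bi = {l: i for i, l in enumerate(bl)}
    if ga.size:
        rows = np.fromiter((ai[v] for v in ga), count=ga.size, dtype=np.int64)
        cols = np.fromiter((bi[v] for v in gb), count=gb.size, dtype=np.int64)
        inter = sparse.coo_matrix(
            (np.ones(ga.size), (rows, cols)), shape=(al.size, bl.size)
        ).toarray()
    else:
        inter = np.zeros((al.size, bl.size))
    size_a = np.array([np.count_nonzero(a == l) for l in al], dtype=float)
    size_b = np.array([np.count_nonzero(b == l) for l in bl], dtype=float)
    return al, bl, inter, size_a, size_b


def iou_matrix(gt: LabelMask, pred: LabelMask) -> IoUMatrix:
    """Pixel-set IoU between every ground-truth / predicted cell pair.

    Background (label 0) is excluded from both sides.
    """
    if gt.frame != pred.frame:
        raise FrameMismatchError("masks must share a frame")
    gl, pl, inter, sg, sp = _contingency(gt.labels.ravel(), pred.labels.ravel())
    union = sg[:, None] + sp[None, :] - inter
    with np.errstate(invalid="ignore"):
        vals = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    return IoUMatrix(gt_labels=gl, pred_labels=pl, values=vals)


def image_iou(m: IoUMatrix) -> tuple[dict[int, float], float]:
    """Per-predicted-cell best IoU and the tile mean.

    A predicted cell with no ground-truth overlap contributes 0 (the max
    over an empty/all-zero column).  A tile with no predicted cells has no
    defined mean and returns NaN; callers exclude such tiles from dataset
    averaging (see :func:`aggregate_tiles`).
    """
    if m.pred_labels.size == 0:
        return {}, math.nan
    col_max = m.values.max(axis=0) if m.gt_labels.size else np.zeros(m.pred_labels.size)
    per_pred = {int(p): float(v) for p, v in zip(m.pred_labels, col_max)}
    return per_pred, float(col_max.mean())


def assign_transcripts(mask: LabelMask, t: pd.DataFrame) -> np.ndarray:
    """Assign each molecule the label of the mask pixel containing it.

    Returns an int array aligned with the table's rows; 0 means
    unassigned (background pixel or outside the frame).  Apply Q-score
    filtering before calling if only QC-passing molecules should count.
    """
    row, col = mask.frame.um_to_px(t["x"].to_numpy(), t["y"].to_numpy())
    inside = mask.frame.contains(row, col)
    out = np.zeros(len(t), dtype=np.int64)
    out[inside] = mask.labels[row[inside], col[inside]]
    return out


def gene_iou(gt_a: np.ndarray, pred_a: np.ndarray) -> tuple[dict[int, float], float]:
    """IoU over per-cell transcript index sets.

    Both assignment arrays must index the same transcript table.
    Predicted cells with zero assigned transcripts are excluded from the
    tile mean; a tile where no predicted cell has transcripts returns NaN.
    """
    gt_a = np.asarray(gt_a)
    pred_a = np.asarray(pred_a)
    if gt_a.shape != pred_a.shape:
        raise ValueError(
            f"assignments cover different transcript sets: {gt_a.shape} vs {pred_a.shape}"
        )
    gl, pl, inter, sg, sp = _contingency(gt_a, pred_a)
    if pl.size == 0:
        return {}, math.nan
    union = sg[:, None] + sp[None, :] - inter
    vals = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    col_max = vals.max(axis=0) if gl.size else np.zeros(pl.size)
    per_pred = {int(p): float(v) for p, v in zip(pl, col_max)}
    return per_pred, float(col_max.mean())


def align_cells(m: IoUMatrix, threshold: float = 0.3) -> AlignmentMap:
    """Mutual-best-match alignment at an IoU threshold.

    ``(g, p)`` is kept iff ``IoU(g, p) >= threshold``, ``p`` is the argmax
    of row ``g`` and ``g`` is the argmax of column ``p``.  Exact argmax
    ties are broken toward the smaller label and reported in ``tied``.
    """
    pairs: list[tuple[int, int]] = []
    tied: list[tuple[int, int]] = []
    if m.gt_labels.size == 0 or m.pred_labels.size == 0:
        return AlignmentMap(pairs=pairs, threshold=threshold)
    row_arg = m.values.argmax(axis=1)  # first max = smaller label (axes sorted)
    col_arg = m.values.argmax(axis=0)
    for gi, g in enumerate(m.gt_labels):
        pj = row_arg[gi]
        if col_arg[pj] != gi:
            continue
        v = m.values[gi, pj]
        if v < threshold:
            continue
        if (m.values[gi] == v).sum() > 1 or (m.values[:, pj] == v).sum() > 1:
            tied.append((int(g), int(m.pred_labels[pj])))
        pairs.append((int(g), int(m.pred_labels[pj])))
    return AlignmentMap(pairs=pairs, threshold=threshold, tied=tied)


def aggregate_tiles(tile_means) -> float:
    """Unweighted mean over tiles, skipping tiles whose mean is undefined."""
    vals = [v for v in tile_means if not math.isnan(v)]
    return float(np.mean(vals)) if vals else math.nan
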