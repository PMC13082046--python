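"""Transcript QC, tile selection and train/test splitting.

Transcripts are filtered at Q-score >= 20 (threshold inclusive).  Tiles
are sampled from a stride grid of candidate windows and qualify when they
contain at least ``min_cell_pixels`` pixels inside cellular regions and at
least ``min_cells`` distinct cell labels intersecting the window (a cell
counts as soon as one of its pixels lies inside).  Qualifying tiles are
then randomly partitioned into train and test sets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_types import LabelMask, Window, crop, write_intensity_image, write_label_mask
from .pseudoimage import ChannelStack

__all__ = ["Tile", "filter_transcripts", "select_tiles", "split_tiles", "export_training_pairs", "TRAINING_HYPERPARAMETERS"]

#: Reference fine-tuning configuration recorded alongside exported
#: image/mask pairs for provenance; training itself is delegated to an
#: external GPU segmentation backend.
TRAINING_HYPERPARAMETERS = {"epochs": 300, "learning_rate": 0.001, "weight_decay": 1e-5}


@dataclass(frozen=True)
class Tile:
    id: str
    window: Window
    split: str = "unassigned"  # train | test | unassigned
    cell_pixels: int = 0
    n_cells: int = 0


def filter_transcripts(t: pd.DataFrame, qv_min: float = 20.0) -> pd.DataFrame:
    """Keep exactly the records with ``qv >= qv_min``, order preserved."""
    return t.loc[t["qv"] >= qv_min].copy()


def select_tiles(
    cell_mask: LabelMask,
    tile_size: int = 256,
    n_tiles: int = 1000,
    min_cell_pixels: int = 200,
    min_cells: int = 15,
    seed: int = 0,
    stride: int | None = None,
) -> list[Tile]:
    """Sample qualifying tile windows uniformly without replacement.

    Candidate windows sit on a stride grid (default stride = tile_size/2);
    they are visited in a seeded random order until ``n_tiles`` qualify or
    candidates are exhausted, in which case the shortfall is reported via
    ``warnings.warn`` and whatever was found is returned.
    """
    H, W = cell_mask.frame.shape
    if tile_size > H or tile_size > W:
        raise ValueError("tile_size does not fit in the frame")
    stride = stride or max(tile_size // 2, 1)
    rows = list(range(0, H - tile_size + 1, stride))
    cols = list(range(0, W - tile_size + 1, stride))
    candidates = [(r, c) for r in rows for c in cols]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(candidates))

    tiles: list[Tile] = []
    for k in order:
        if len(tiles) >= n_tiles:
            break
        r, c = candidates[k]
        win = cell_mask.labels[r : r + tile_size, c : c + tile_size]
        cell_pixels = int(np.count_nonzero(win))
        if cell_pixels < min_cell_pixels:
            continue
        n_cells = int(np.unique(win[win > 0]).size)
        if n_cells < min_cells:
            continue
        tiles.append(
            Tile(
                id=f"tile{len(tiles):04d}",
                window=Window(row=r, col=c, height=tile_size, width=tile_size),
                cell_pixels=cell_pixels,
                n_cells=n_cells,
            )
        )
    if len(tiles) < n_tiles:
        warnings.warn(
            f"only {len(tiles)}/{n_tiles} qualifying tiles found "
            f"({len(candidates)} candidate windows examined)"
        )
    return tiles


def split_tiles(tiles: list[Tile], n_train: int = 800, n_test: int = 200, seed: int = 0) -> list[Tile]:
    """Randomly partition tiles into disjoint train/test sets."""
    if n_train + n_test > len(tiles):
        raise ValueError(
            f"cannot split {len(tiles)} tiles into {n_train} train + {n_test} test"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(tiles))
    assignment = {}
    for k in order[:n_train]:
        assignment[k] = "train"
    for k in order[n_train : n_train + n_test]:
        assignment[k] = "test"
    return [
        replace(t, split=assignment.get(i, "unassigned")) for i, t in enumerate(tiles)
    ]


def export_training_pairs(
    tiles: list[Tile],
    stack: ChannelStack,
    cell_mask: LabelMask,
    outdir,
) -> Path:
    """Write per-tile two-channel images and masks for an external trainer.

    Emits ``<id>_dapi.tif`` / ``<id>_density.tif`` / ``<id>_mask.tif`` per
    tile plus a ``manifest.json`` recording windows, splits, per-tile
    stats and the reference training hyperparameters.  Returns the
    manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for t in tiles:
        write_intensity_image(crop(stack.dapi, t.window), outdir / f"{t.id}_dapi.tif")
        write_intensity_image(crop(stack.density, t.window), outdir / f"{t.id}_density.tif")
        write_label_mask(crop(cell_mask, t.window), outdir / f"{t.id}_mask.tif")
        records.append(
            {
                "id": t.id,
                "window": [t.window.row, t.window.col, t.window.height, t.window.width],
                "split": t.split,
                "cell_pixels": t.cell_pixels,
                "n_cells": t.n_cells,
            }
        )
    manifest = {
        "tiles": records,
        "training": dict(TRAINING_HYPERPARAMETERS),
        "frame": stack.frame.to_dict(),
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path
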