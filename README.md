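# txseg

Whole-cell segmentation toolkit for image-based spatial transcriptomics
(Xenium-style data), built around a simple observation: most RNA
molecules lie inside cells, so their spatial distribution sketches cell
extents that a nuclear stain alone cannot show.

## Who this is for

Experiments on platforms such as 10x Xenium report per-molecule
transcript coordinates plus a DAPI image that labels only nuclei.  The
standard way to get whole-cell boundaries from that — segment nuclei,
then grow every nucleus by a fixed 5 µm unless it collides with a
neighbor — systematically produces round, oversized cells, misassigns
transcripts, and flattens cell-shape differences between cell types.
`txseg` provides the machinery to build transcript-aware segmentation
inputs, run and plug in segmenters, and quantify exactly how much better
(or worse) any whole-cell segmentation is than that baseline.

## What it computes

**Transcript-density pseudoimage.** Given retained molecule coordinates
{x_i} (Q-score ≥ 20), the density channel at pixel center u is

    f(u) = Σ_i exp(−‖u − x_i‖² / (2σ²)),   σ = 2.5 px by default,

min–max scaled to [0, 1] and stacked with the DAPI channel (capped at
its 99th percentile, then scaled) as a two-channel input for any
instance-segmentation backend.

**Segmenters.** A boundary-constrained 5 µm nuclear-expansion baseline
(nearest-nucleus collision rule, deterministic ties), a classical
watershed fallback that runs on one CPU, and an adapter contract for
external pretrained models, plus an exporter of per-tile image/mask
training pairs.

**Evaluation.** Pixel-set IoU matrices with per-predicted-cell maxima
(image IoU), the same construction on per-cell transcript sets (gene
IoU), mutual-best-match cell alignment at IoU ≥ 0.3, eight polygon
morphometrics (area, perimeter, Feret diameter, eccentricity, roundness,
circularity 4πA/P², solidity, aspect ratio), Leiden clustering tuned to
k = 10 with ARI/AMI/homogeneity/completeness agreement, UMAP morphology
embeddings, and random-forest cell-type prediction from shape alone
(accuracy, macro-F1, macro ROC-AUC).

**Synthetic tissue.** A simulator with known ground truth — packed
anisotropic cells, off-center nuclei, type-specific expression profiles,
low-quality background molecules — so the entire stack runs end-to-end
with no downloads and no GPU.

## Worked example

```python
from txseg.pipeline import RunConfig, run_pipeline

cfg = RunConfig(seed=2, outdir="demo_run", n_cells=30, frame_px=256,
                pixel_size=0.4, transcripts_per_cell_mean=80.0,
                run_clustering=False)
report = run_pipeline(cfg)
```

writes masks, the pseudoimage, feature tables and `report.json`:

```json
{
 "evaluate":   {"image_iou": 0.6609, "gene_iou": 0.6914, "n_aligned": 30},
 "morphology": {"gt_mean_aspect_ratio": 1.526, "pred_mean_aspect_ratio": 1.258,
                "gt_mean_roundness": 0.534,   "pred_mean_roundness": 0.690},
 "segment":    {"backend": "expand", "n_cells": 30},
 "simulate":   {"n_cells": 30, "n_transcripts": 2893}
}
```

Reading: on this synthetic tissue the 5 µm nuclear-expansion baseline
recovers the true cell boundaries at a mean image IoU of 0.66 and
assigns transcripts at a gene IoU of 0.69 — far from the ceiling of 1.0
an exact segmentation would reach — and it compresses shape variation:
mean aspect ratio drops from 1.53 (truth) to 1.26, mean roundness is
inflated from 0.53 to 0.69.  Elongated cells come out as discs.

The same stages are available as a CLI (`txseg simulate`, `pseudoimage`,
`prep`, `expand`, `segment`, `eval`, `morpho`, `cluster-eval`,
`export-training`, `run`); see `txseg --help`.

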