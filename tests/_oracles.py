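"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — O(N·pixels) sums, per-pair python
set arithmetic, exhaustive pair/triple searches — and shares no code with
the package internals it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# pseudoimage
# ---------------------------------------------------------------------------


def brute_density(transcripts, frame, sigma_px, qv_min):
    """Exact untruncated Gaussian kernel sum at every pixel center."""
    t = transcripts[transcripts["qv"] >= qv_min]
    s = frame.pixel_size
    px = (t["x"].to_numpy() - frame.origin[0]) / s
    py = (t["y"].to_numpy() - frame.origin[1]) / s
    H, W = frame.shape
    out = np.zeros((H, W))
    cx = np.arange(W) + 0.5
    cy = np.arange(H) + 0.5
    for x, y in zip(px, py):
        d2 = (cy[:, None] - y) ** 2 + (cx[None, :] - x) ** 2
        out += np.exp(-d2 / (2 * sigma_px**2))
    return out


# ---------------------------------------------------------------------------
# IoU metrics
# ---------------------------------------------------------------------------


def brute_iou_matrix(gt_labels, pred_labels):
    """Per-pair pixel-set IoU via python sets."""
    gl = sorted(set(gt_labels.ravel()) - {0})
    pl = sorted(set(pred_labels.ravel()) - {0})
    gsets = {l: set(zip(*np.nonzero(gt_labels == l))) for l in gl}
    psets = {l: set(zip(*np.nonzero(pred_labels == l))) for l in pl}
    out = np.zeros((len(gl), len(pl)))
    for i, g in enumerate(gl):
        for j, p in enumerate(pl):
            inter = len(gsets[g] & psets[p])
            union = len(gsets[g] | psets[p])
            out[i, j] = inter / union if union else 0.0
    return np.array(gl), np.array(pl), out


def brute_gene_iou(gt_a, pred_a):
    """Transcript-index-set IoU: double loop over cells, python sets."""
    gl = sorted(set(gt_a) - {0})
    pl = sorted(set(pred_a) - {0})
    ksets = {g: set(np.nonzero(gt_a == g)[0]) for g in gl}
    lsets = {p: set(np.nonzero(pred_a == p)[0]) for p in pl}
    per_pred = {}
    for p in pl:
        best = 0.0
        for g in gl:
            inter = len(ksets[g] & lsets[p])
            union = len(ksets[g] | lsets[p])
            if union:
                best = max(best, inter / union)
        per_pred[p] = best
    mean = float(np.mean(list(per_pred.values()))) if per_pred else float("nan")
    return per_pred, mean


def brute_align(gt_labels, pred_labels, values, threshold=0.3):
    """Exhaustively check the three mutual-best-match conditions, with
    argmax ties broken toward the smaller label."""

    def argmax_smallest(labels, vals):
        best = vals.max()
        return labels[np.nonzero(vals == best)[0][0]]

    pairs = set()
    for gi, g in enumerate(gt_labels):
        for pj, p in enumerate(pred_labels):
            v = values[gi, pj]
            if v < threshold:
                continue
            if argmax_smallest(pred_labels, values[gi, :]) != p:
                continue
            if argmax_smallest(gt_labels, values[:, pj]) != g:
                continue
            pairs.add((int(g), int(p)))
    return pairs


# ---------------------------------------------------------------------------
# nuclear expansion
# ---------------------------------------------------------------------------


def brute_expand(nuclei_labels, distance_um, pixel_size):
    """Per-pixel nearest-nucleus search: min pixel-center distance over
    every nucleus pixel of every label, ties to the smaller label."""
    H, W = nuclei_labels.shape
    labels = sorted(set(nuclei_labels.ravel()) - {0})
    pix = {l: np.argwhere(nuclei_labels == l) for l in labels}
    out = np.zeros_like(nuclei_labels)
    for r in range(H):
        for c in range(W):
            best_d, best_l = np.inf, 0
            for l in labels:
                d = np.sqrt(((pix[l] - (r, c)) ** 2).sum(axis=1)).min() * pixel_size
                if d < best_d - 1e-12:  # strict: ties keep smaller label
                    best_d, best_l = d, l
            if best_d <= distance_um + 1e-9:
                out[r, c] = best_l
    return out


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def brute_min_circle(points):
    """Smallest enclosing circle by exhaustive pair/triple search."""
    pts = np.unique(np.asarray(points, float), axis=0)
    best = (None, np.inf)

    def covers(center, r):
        return np.all(np.hypot(*(pts - center).T) <= r + 1e-9)

    for a, b in itertools.combinations(pts, 2):
        c = (a + b) / 2
        r = np.hypot(*(a - c))
        if r < best[1] and covers(c, r):
            best = (c, r)
    for a, b, c in itertools.combinations(pts, 3):
        d = 2 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
        if abs(d) < 1e-12:
            continue
        ux = ((a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1]) + (c @ c) * (a[1] - b[1])) / d
        uy = ((a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0]) + (c @ c) * (b[0] - a[0])) / d
        center = np.array([ux, uy])
        r = np.hypot(*(a - center))
        if r < best[1] and covers(center, r):
            best = (center, r)
    return best


def brute_feret(points):
    pts = np.asarray(points, float)
    d2 = ((pts[:, None] - pts[None, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def brute_min_rect_ratios(points, rel_tol=1e-9):
    """Side ratios of all near-minimal rotated bounding rectangles.

    Sweeps hull-edge directions (the min-area rectangle has a side
    collinear with a hull edge).  The minimum-area rectangle is not always
    unique — distinct orientations can tie in area with different side
    ratios — so every ratio within ``rel_tol`` of the minimal area is a
    valid answer.
    """
    from scipy.spatial import ConvexHull

    pts = np.asarray(points, float)
    hull = pts[ConvexHull(pts).vertices]
    n = len(hull)
    rects = []
    for i in range(n):
        e = hull[(i + 1) % n] - hull[i]
        e = e / np.hypot(*e)
        u = hull @ e
        v = hull @ np.array([-e[1], e[0]])
        w, h = u.max() - u.min(), v.max() - v.min()
        rects.append((w * h, max(w, h) / min(w, h)))
    best = min(a for a, _ in rects)
    return [r for a, r in rects if a <= best * (1 + rel_tol)]


def fan_area(verts):
    """Triangulation-fan area (convex polygons)."""
    v = np.asarray(verts, float)
    total = 0.0
    for i in range(1, len(v) - 1):
        a, b = v[i] - v[0], v[i + 1] - v[0]
        total += 0.5 * (a[0] * b[1] - a[1] * b[0])
    return abs(total)


# ---------------------------------------------------------------------------
# random shape generators
# ---------------------------------------------------------------------------


def random_convex_polygon(rng, n=12, scale=5.0):
    """Convex hull of n gaussian points, vertices in hull order."""
    from scipy.spatial import ConvexHull

    while True:
        pts = rng.normal(0, scale, (n, 2))
        try:
            hull = ConvexHull(pts)
        except Exception:
            continue
        return pts[hull.vertices]


def random_star_polygon(rng, n=10, r_lo=1.0, r_hi=5.0):
    """Simple (possibly concave) polygon: random radii at sorted angles."""
    th = np.sort(rng.uniform(0, 2 * np.pi, n))
    while np.min(np.diff(th, append=th[0] + 2 * np.pi)) < 1e-3:
        th = np.sort(rng.uniform(0, 2 * np.pi, n))
    r = rng.uniform(r_lo, r_hi, n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def random_label_mask(rng, shape=(32, 32), n_blobs=4, r_lo=2, r_hi=6):
    """Random disjoint-ish disk blobs as an instance mask."""
    H, W = shape
    out = np.zeros(shape, dtype=np.int64)
    rr, cc = np.mgrid[0:H, 0:W]
    for lab in range(1, n_blobs + 1):
        r0, c0 = rng.uniform(0, H), rng.uniform(0, W)
        rad = rng.uniform(r_lo, r_hi)
        out[(rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2] = lab
    return out
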