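"""Per-cell shape descriptors computed from boundary polygons.

Eight features are computed per cell, all from the cell's boundary polygon
in µm: area ``A`` (shoelace), perimeter ``P`` (closed polyline length),
Feret's diameter (largest pairwise distance between convex-hull points),
eccentricity (``1 - lambda2/lambda1`` from a PCA of the raw vertex
coordinates), roundness (``A / (pi r^2)`` with ``r`` the radius of the
*exact* minimum enclosing circle), circularity (``4 pi A / P^2``),
solidity (``A`` over the convex-hull area), and aspect ratio (long/short
side of the minimum-area rotated bounding rectangle, normalized to >= 1
so larger always means more elongated).

Masks are bridged to polygons by tracing the outer boundary along pixel
*corners*, so the polygon area equals pixel count x pixel_size^2 exactly;
interior holes are ignored.

Caveat: eccentricity operates on the raw, unweighted vertex set, so vertex
density along the boundary influences the estimate; for corner-traced
pixel polygons this is deterministic and consistent across cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon as _ShapelyPolygon
from shapely.ops import unary_union

from .io_types import CellPolygon, LabelMask

__all__ = [
    "MorphologyFeatures",
    "polygon_from_mask",
    "polygons_from_mask",
    "area",
    "perimeter",
    "feret",
    "eccentricity",
    "roundness",
    "circularity",
    "solidity",
    "aspect_ratio",
    "minimum_enclosing_circle",
    "compute_features",
    "features_table",
]


@dataclass(frozen=True)
class MorphologyFeatures:
    area: float  # µm²
    perimeter: float  # µm
    feret: float  # µm
    eccentricity: float
    roundness: float
    circularity: float
    solidity: float
    aspect_ratio: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


FEATURE_NAMES = tuple(f.name for f in fields(MorphologyFeatures))


def _verts(p) -> np.ndarray:
    if isinstance(p, CellPolygon):
        return p.vertices
    v = np.asarray(p, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise ValueError("expected an (n, 2) vertex array or CellPolygon")
    return v


# ---------------------------------------------------------------------------
# mask -> polygon
# ---------------------------------------------------------------------------


def polygon_from_mask(mask: LabelMask, label: int) -> CellPolygon:
    """Trace the outer pixel-corner boundary of one 4-connected instance.

    The polygon is the exterior of the union of the instance's pixel
    squares, so its shoelace area equals ``pixel count * pixel_size**2``
    when the instance has no holes (holes are ignored by construction).
    """
    rows, cols = np.nonzero(mask.labels == label)
    if rows.size == 0:
        raise ValueError(f"label {label} not present in mask")
    boxes = []
    # merge each row into horizontal runs to keep the union cheap
    order = np.lexsort((cols, rows))
    rows, cols = rows[order], cols[order]
    for r in np.unique(rows):
        cs = cols[rows == r]
        breaks = np.nonzero(np.diff(cs) > 1)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [cs.size - 1]])
        for a, b in zip(starts, ends):
            boxes.append(shapely.box(cs[a], r, cs[b] + 1, r + 1))
    merged = unary_union(boxes)
    if not isinstance(merged, _ShapelyPolygon):
        raise ValueError(f"label {label} is not 4-connected")
    corners = np.asarray(merged.exterior.coords)[:-1]  # drop closing vertex
    s = mask.frame.pixel_size
    ox, oy = mask.frame.origin
    verts = np.column_stack([ox + corners[:, 0] * s, oy + corners[:, 1] * s])
    return CellPolygon(vertices=verts, label=int(label))


def polygons_from_mask(mask: LabelMask) -> list[CellPolygon]:
    return [polygon_from_mask(mask, int(l)) for l in mask.instance_labels]


# ---------------------------------------------------------------------------
# individual features
# ---------------------------------------------------------------------------


def area(p) -> float:
    """Polygon area via the shoelace formula (absolute value), in µm²."""
    v = _verts(p)
    x, y = v[:, 0], v[:, 1]
    a = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if a <= 0:
        raise ValueError("degenerate (zero-area) polygon")
    return float(a)


def perimeter(p) -> float:
    """Closed polyline length in µm, including the closing edge."""
    v = _verts(p)
    d = np.diff(np.vstack([v, v[:1]]), axis=0)
    out = float(np.hypot(d[:, 0], d[:, 1]).sum())
    if out <= 0:
        raise ValueError("degenerate polygon")
    return out


def _hull_points(v: np.ndarray) -> np.ndarray:
    try:
        from scipy.spatial import ConvexHull

        return v[ConvexHull(v).vertices]
    except Exception:  # collinear / tiny inputs: fall back to the raw points
        return v


def feret(p) -> float:
    """Maximum pairwise distance between convex-hull points, in µm."""
    v = _verts(p)
    h = _hull_points(np.unique(v, axis=0))
    d2 = ((h[:, None, :] - h[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def eccentricity(p) -> float:
    """1 - lambda2/lambda1 from a PCA of the polygon vertex coordinates.

    0 for isotropic vertex clouds (e.g. a square), approaching 1 for
    elongated shapes.  Collinear vertices (lambda2 = 0) return the
    boundary value 1.0 with a warning.
    """
    v = _verts(p)
    centered = v - v.mean(axis=0)
    cov = centered.T @ centered / len(v)
    lam2, lam1 = np.linalg.eigvalsh(cov)  # ascending
    if lam1 <= 0:
        raise ValueError("degenerate polygon: all vertices coincide")
    if lam2 <= 1e-15 * lam1:
        warnings.warn("collinear vertices: eccentricity pinned to 1.0")
        return 1.0
    return float(1.0 - lam2 / lam1)


# -- exact minimum enclosing circle (Welzl, move-to-front) ------------------


def _circle_two(a, b):
    c = (a + b) / 2.0
    return c, float(np.hypot(*(a - c)))


def _circle_three(a, b, c):
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-30:
        return None
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, float(np.hypot(*(a - center)))


def _in_circle(pt, circle, eps) -> bool:
    center, r = circle
    return np.hypot(*(pt - center)) <= r * (1 + eps) + eps


def minimum_enclosing_circle(points, eps: float = 1e-12):
    """Exact smallest enclosing circle of a 2-D point set.

    Welzl's randomized incremental algorithm with a deterministic shuffle;
    expected O(n).  Returns ``(center, radius)``.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) == 0:
        raise ValueError("no points")
    if len(pts) == 1:
        return pts[0].copy(), 0.0
    rng = np.random.default_rng(0)
    pts = pts[rng.permutation(len(pts))]

    circle = _circle_two(pts[0], pts[1])
    for i in range(2, len(pts)):
        if _in_circle(pts[i], circle, eps):
            continue
        # pts[i] is on the boundary of the circle over pts[:i+1]
        circle = _circle_two(pts[0], pts[i])
        for j in range(1, i):
            if _in_circle(pts[j], circle, eps):
                continue
            circle = _circle_two(pts[i], pts[j])
            for k in range(j):
                if _in_circle(pts[k], circle, eps):
                    continue
                c3 = _circle_three(pts[i], pts[j], pts[k])
                if c3 is not None:
                    circle = c3
    return circle


def roundness(p) -> float:
    """Area over the area of the exact minimum bounding circle; 1 for a
    circle, smaller for elongated or irregular shapes."""
    v = _verts(p)
    _, r = minimum_enclosing_circle(v)
    if r <= 0:
        raise ValueError("degenerate polygon")
    return float(area(p) / (np.pi * r * r))


def circularity(p) -> float:
    """4 pi A / P^2; 1 for a perfect circle (isoperimetric bound)."""
    P = perimeter(p)
    return float(4.0 * np.pi * area(p) / (P * P))


def solidity(p) -> float:
    """Area over convex-hull area; 1 exactly for convex polygons."""
    v = _verts(p)
    hull = _ShapelyPolygon(v).convex_hull
    if hull.area <= 0:
        raise ValueError("degenerate polygon")
    return float(area(p) / hull.area)


def aspect_ratio(p) -> float:
    """Long/short side ratio of the minimum-area rotated bounding rectangle.

    Normalized to >= 1 so larger values always mean more elongated shapes,
    independent of the rectangle's orientation.
    """
    v = _verts(p)
    rect = _ShapelyPolygon(v).minimum_rotated_rectangle
    coords = np.asarray(rect.exterior.coords)
    if coords.shape[0] < 4:
        raise ValueError("degenerate polygon: no rotated rectangle")
    s1 = float(np.hypot(*(coords[1] - coords[0])))
    s2 = float(np.hypot(*(coords[2] - coords[1])))
    if min(s1, s2) <= 0:
        raise ValueError("degenerate polygon: zero-width rectangle")
    return max(s1, s2) / min(s1, s2)


def compute_features(p) -> MorphologyFeatures:
    """Bundle all eight descriptors for one polygon."""
    return MorphologyFeatures(
        area=area(p),
        perimeter=perimeter(p),
        feret=feret(p),
        eccentricity=eccentricity(p),
        roundness=roundness(p),
        circularity=circularity(p),
        solidity=solidity(p),
        aspect_ratio=aspect_ratio(p),
    )


def features_table(mask: LabelMask) -> pd.DataFrame:
    """Per-cell feature table for every instance in a mask (index = label)."""
    rows = {}
    for lab in mask.instance_labels:
        rows[int(lab)] = compute_features(polygon_from_mask(mask, int(lab))).as_dict()
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))
    df.index.name = "label"
    return df
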