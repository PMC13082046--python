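"""Shared spatial data model and file I/O.

Coordinate conventions
----------------------
Global coordinates are micrometres (µm) with *y increasing downward* and
the frame origin at the top-left corner, matching common imaging practice.
Pixel ``(r, c)`` of a :class:`PixelFrame` with pixel size ``s`` covers the
half-open box::

    x in [origin_x + c*s, origin_x + (c+1)*s)
    y in [origin_y + r*s, origin_y + (r+1)*s)

so every point maps to exactly one pixel and tiling a frame partitions its
transcripts.  ``px_to_um`` returns pixel *centers*.

Transcript tables are plain :class:`pandas.DataFrame` objects with the
canonical columns ``("x", "y", "gene", "qv")``: x/y in µm, ``gene`` a
non-empty string identifier and ``qv`` the per-molecule decoding quality
score (Xenium Q-score).  Label masks are integer instance images with
0 = background; their µm geometry travels in a JSON sidecar next to the
TIFF so the TIFF itself stays standard-compliant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "FormatError",
    "UnsupportedGeometryError",
    "FrameMismatchError",
    "PackingError",
    "PixelFrame",
    "Window",
    "IntensityImage",
    "LabelMask",
    "CellPolygon",
    "TRANSCRIPT_COLUMNS",
    "XENIUM_COLUMNS",
    "ensure_transcripts",
    "read_transcripts",
    "write_transcripts",
    "read_label_mask",
    "write_label_mask",
    "read_intensity_image",
    "write_intensity_image",
    "read_polygons",
    "write_polygons",
    "crop",
    "crop_transcripts",
]

DEFAULT_PIXEL_SIZE = 0.2125
"""Default pixel size in µm/px (Xenium morphology image convention)."""


class FormatError(ValueError):
    """A file does not conform to the expected format."""


class UnsupportedGeometryError(FormatError):
    """GeoJSON geometry is not a simple single-ring polygon."""


class FrameMismatchError(ValueError):
    """Two spatial objects that must share a frame do not."""


class PackingError(RuntimeError):
    """Requested cells cannot be packed into the frame."""


# ---------------------------------------------------------------------------
# frames and coordinates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PixelFrame:
    """Discrete pixel grid embedded in global µm coordinates.

    Parameters
    ----------
    width, height
        Grid size in pixels (columns, rows).
    pixel_size
        Edge length of one pixel in µm.
    origin
        Global ``(x, y)`` µm coordinate of the frame's top-left corner.
    """

    width: int
    height: int
    pixel_size: float = DEFAULT_PIXEL_SIZE
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("frame dimensions must be positive")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(height, width)``."""
        return (self.height, self.width)

    def um_to_px(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map µm points to ``(row, col)`` indices (half-open convention).

        Out-of-frame points yield out-of-range indices; callers decide how
        to flag them (see :meth:`contains`).
        """
        s = self.pixel_size
        col = np.floor((np.asarray(x, dtype=float) - self.origin[0]) / s)
        row = np.floor((np.asarray(y, dtype=float) - self.origin[1]) / s)
        return row.astype(np.int64), col.astype(np.int64)

    def px_to_um(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        """Map pixel indices to the µm coordinates of their centers."""
        s = self.pixel_size
        x = self.origin[0] + (np.asarray(col, dtype=float) + 0.5) * s
        y = self.origin[1] + (np.asarray(row, dtype=float) + 0.5) * s
        return x, y

    def contains(self, row, col) -> np.ndarray:
        row = np.asarray(row)
        col = np.asarray(col)
        return (row >= 0) & (row < self.height) & (col >= 0) & (col < self.width)

    def to_dict(self) -> dict:
        return {
            "width": int(self.width),
            "height": int(self.height),
            "pixel_size": float(self.pixel_size),
            "origin": [float(self.origin[0]), float(self.origin[1])],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PixelFrame":
        return cls(
            width=int(d["width"]),
            height=int(d["height"]),
            pixel_size=float(d["pixel_size"]),
            origin=tuple(d.get("origin", (0.0, 0.0))),
        )


@dataclass(frozen=True)
class Window:
    """Rectangular pixel window ``[row, row+height) x [col, col+width)``."""

    row: int
    col: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("window must be non-empty")

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row, self.row + self.height),
            slice(self.col, self.col + self.width),
        )


# ---------------------------------------------------------------------------
# images and masks
# ---------------------------------------------------------------------------


@dataclass
class IntensityImage:
    """Single-channel non-negative image on a :class:`PixelFrame`."""

    values: np.ndarray
    frame: PixelFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("intensity image must be 2-D")
        if self.values.shape != self.frame.shape:
            raise FrameMismatchError(
                f"image shape {self.values.shape} != frame shape {self.frame.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("intensity values must be non-negative")


@dataclass
class LabelMask:
    """Integer instance image: 0 = background, each positive label one cell."""

    labels: np.ndarray
    frame: PixelFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.dtype.kind not in "iu":
            raise ValueError("label mask must be integer-valued")
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2-D")
        if self.labels.shape != self.frame.shape:
            raise FrameMismatchError(
                f"mask shape {self.labels.shape} != frame shape {self.frame.shape}"
            )
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")

    @property
    def instance_labels(self) -> np.ndarray:
        """Sorted array of positive labels present."""
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def n_instances(self) -> int:
        return int(self.instance_labels.size)


@dataclass
class CellPolygon:
    """Simple closed polygon in µm; the last vertex implicitly connects
    to the first."""

    vertices: np.ndarray
    label: Union[int, str]

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if len(self.vertices) >= 2 and np.allclose(
            self.vertices[0], self.vertices[-1]
        ):
            self.vertices = self.vertices[:-1]
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")

    def shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)


# ---------------------------------------------------------------------------
# transcript tables
# ---------------------------------------------------------------------------

TRANSCRIPT_COLUMNS = ("x", "y", "gene", "qv")
XENIUM_COLUMNS = {
    "x_location": "x",
    "y_location": "y",
    "feature_name": "gene",
    "qv": "qv",
}


def ensure_transcripts(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a transcript table to the canonical columns."""
    for col in TRANSCRIPT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"transcript table missing required column {col!r}")
    out = df.loc[:, list(TRANSCRIPT_COLUMNS)].copy()
    out["x"] = out["x"].astype(float)
    out["y"] = out["y"].astype(float)
    out["qv"] = out["qv"].astype(float)
    out["gene"] = out["gene"].astype(str)
    if not np.isfinite(out[["x", "y"]].to_numpy()).all():
        raise FormatError("transcript coordinates must be finite")
    if (out["qv"] < 0).any():
        raise FormatError("qv must be non-negative")
    if (out["gene"].str.len() == 0).any():
        raise FormatError("gene identifiers must be non-empty")
    return out


def read_transcripts(path, dialect: str = "auto") -> pd.DataFrame:
    """Read a transcript table.

    ``dialect`` is one of ``xenium-csv`` (columns x_location / y_location /
    feature_name / qv), ``generic-csv`` (x / y / gene / qv), ``parquet``, or
    ``auto`` which picks parquet by file suffix and otherwise sniffs the CSV
    header.  No filtering is applied at read time.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"transcript file not found: {path}")
    if dialect == "auto":
        if path.suffix.lower() in {".parquet", ".pq"}:
            dialect = "parquet"
        else:
            header = pd.read_csv(path, nrows=0).columns
            dialect = "xenium-csv" if "x_location" in header else "generic-csv"
    if dialect == "parquet":
        df = pd.read_parquet(path)
    elif dialect in {"xenium-csv", "generic-csv"}:
        df = pd.read_csv(path)
    else:
        raise ValueError(f"unknown transcript dialect {dialect!r}")
    if dialect == "xenium-csv":
        for src in XENIUM_COLUMNS:
            if src not in df.columns:
                raise FormatError(f"xenium-csv table missing column {src!r}")
        df = df.rename(columns=XENIUM_COLUMNS)
    return ensure_transcripts(df)


def write_transcripts(df: pd.DataFrame, path) -> None:
    """Write a canonical transcript table (parquet or CSV by suffix)."""
    df = ensure_transcripts(df)
    path = Path(path)
    if path.suffix.lower() in {".parquet", ".pq"}:
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# TIFF I/O with JSON geometry sidecars
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _read_frame_sidecar(path: Path, shape: tuple[int, int]) -> PixelFrame:
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        return PixelFrame.from_dict(json.loads(sidecar.read_text()))
    return PixelFrame(width=shape[1], height=shape[0])


def _write_frame_sidecar(path: Path, frame: PixelFrame) -> None:
    _sidecar_path(path).write_text(json.dumps(frame.to_dict()))


def read_label_mask(path) -> LabelMask:
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise FormatError(f"label mask must be single-channel 2-D, got shape {arr.shape}")
    if arr.dtype.kind not in "iu":
        raise FormatError(f"label mask must be integer TIFF, got dtype {arr.dtype}")
    return LabelMask(labels=arr.astype(np.int64), frame=_read_frame_sidecar(path, arr.shape))


def write_label_mask(mask: LabelMask, path) -> None:
    path = Path(path)
    hi = int(mask.labels.max(initial=0))
    dtype = np.uint16 if hi < 2**16 else np.uint32
    tifffile.imwrite(path, mask.labels.astype(dtype))
    _write_frame_sidecar(path, mask.frame)


def read_intensity_image(path) -> IntensityImage:
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise FormatError(f"intensity image must be single-channel 2-D, got shape {arr.shape}")
    return IntensityImage(values=arr.astype(float), frame=_read_frame_sidecar(path, arr.shape))


def write_intensity_image(img: IntensityImage, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, img.values.astype(np.float32))
    _write_frame_sidecar(path, img.frame)


# ---------------------------------------------------------------------------
# GeoJSON polygons
# ---------------------------------------------------------------------------


def read_polygons(path) -> list[CellPolygon]:
    """Read a GeoJSON FeatureCollection of single-ring polygons."""
    data = json.loads(Path(path).read_text())
    if data.get("type") != "FeatureCollection":
        raise FormatError("expected a GeoJSON FeatureCollection")
    out = []
    for feat in data.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise UnsupportedGeometryError(
                f"unsupported geometry type {geom.get('type')!r}; only Polygon is supported"
            )
        rings = geom.get("coordinates", [])
        if len(rings) != 1:
            raise UnsupportedGeometryError("polygons with holes are not supported")
        props = feat.get("properties") or {}
        if "label" not in props:
            raise FormatError("polygon feature missing 'label' property")
        out.append(CellPolygon(vertices=np.asarray(rings[0], dtype=float), label=props["label"]))
    return out


def write_polygons(polygons: Sequence[CellPolygon], path) -> None:
    features = []
    for p in polygons:
        ring = np.vstack([p.vertices, p.vertices[:1]])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring.tolist()]},
                "properties": {"label": p.label},
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


# ---------------------------------------------------------------------------
# cropping
# ---------------------------------------------------------------------------


def _cropped_frame(frame: PixelFrame, window: Window) -> PixelFrame:
    if (
        window.row < 0
        or window.col < 0
        or window.row + window.height > frame.height
        or window.col + window.width > frame.width
    ):
        raise ValueError("window must lie inside the frame")
    s = frame.pixel_size
    return PixelFrame(
        width=window.width,
        height=window.height,
        pixel_size=s,
        origin=(frame.origin[0] + window.col * s, frame.origin[1] + window.row * s),
    )


def crop(obj: Union[IntensityImage, LabelMask], window: Window):
    """Restrict an image or mask to a pixel window, updating the origin."""
    new_frame = _cropped_frame(obj.frame, window)
    rs, cs = window.slices()
    if isinstance(obj, LabelMask):
        return LabelMask(labels=obj.labels[rs, cs].copy(), frame=new_frame)
    if isinstance(obj, IntensityImage):
        return IntensityImage(values=obj.values[rs, cs].copy(), frame=new_frame)
    raise TypeError(f"cannot crop object of type {type(obj).__name__}")


def crop_transcripts(df: pd.DataFrame, window: Window, frame: PixelFrame) -> pd.DataFrame:
    """Keep transcripts whose half-open pixel falls inside ``window``.

    Because pixels are half-open boxes, cropping a frame into disjoint
    windows partitions its transcripts without loss or duplication.
    """
    _cropped_frame(frame, window)  # validates
    row, col = frame.um_to_px(df["x"].to_numpy(), df["y"].to_numpy())
    keep = (
        (row >= window.row)
        & (row < window.row + window.height)
        & (col >= window.col)
        & (col < window.col + window.width)
    )
    return df.loc[keep].copy()
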