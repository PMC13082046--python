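"""Whole-cell mask producers.

Three routes to a whole-cell :class:`~txseg.io_types.LabelMask`:

* :func:`expand_nuclei` — the standard baseline: every nucleus is grown
  uniformly by a fixed µm distance, except where the expansion front of a
  neighboring cell is closer.  The collision rule is formalized as a
  nearest-nucleus (Voronoi) constraint: a background pixel joins the
  nucleus whose pixel set is nearest (pixel-center Euclidean distance),
  provided that distance does not exceed the expansion radius.  Exact ties
  go to the smaller label, deterministically.
* :func:`segment_fallback` — a self-contained classical pipeline
  (Otsu foreground, seeded watershed on the combined intensity) so the
  full evaluation stack can run end-to-end on one CPU.  It is a simple,
  fully deterministic segmenter by design.
* :func:`segment_external` — adapter handing the two-channel stack to a
  pluggable pretrained segmentation backend (e.g. a fine-tuned
  Cellpose-SAM) and validating/relabeling its output.
"""

from __future__ import annotations

import importlib
import warnings
from typing import Callable, Protocol, Union, runtime_checkable

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import relabel_sequential, watershed

from .io_types import FrameMismatchError, LabelMask
from .pseudoimage import ChannelStack

__all__ = ["expand_nuclei", "segment_fallback", "segment_external", "SegmentationBackend", "ExternalBackendError"]


class ExternalBackendError(RuntimeError):
    """An external segmentation backend could not be resolved or run."""


@runtime_checkable
class SegmentationBackend(Protocol):
    """Anything that maps a ChannelStack to a LabelMask on the same frame."""

    def __call__(self, stack: ChannelStack) -> LabelMask: ...


def expand_nuclei(nuclei: LabelMask, distance: float) -> LabelMask:
    """Uniform nuclear expansion by ``distance`` µm with a Voronoi collision rule.

    Each background pixel receives the label of the nearest nucleus
    (Euclidean distance between pixel centers, converted to µm through the
    frame's pixel size) iff that distance is at most ``distance``.
    Nucleus pixels keep their labels; equidistant pixels go to the smaller
    label.  Output instances are pairwise disjoint and each contains its
    nucleus; ``distance = 0`` is the identity.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    if nuclei.frame.pixel_size <= 0:
        raise ValueError("pixel_size required: expansion distance is in µm")
    labels = nuclei.instance_labels
    out = np.zeros_like(nuclei.labels)
    if labels.size == 0 or distance == 0:
        return LabelMask(labels=nuclei.labels.copy(), frame=nuclei.frame)

    s = nuclei.frame.pixel_size
    best = np.full(nuclei.frame.shape, np.inf)
    # ascending label order + strict improvement = ties keep the smaller
    # label; EDT distances for identical integer offsets are bit-identical,
    # so the tie comparison is exact
    for lab in labels:
        d = ndimage.distance_transform_edt(nuclei.labels != lab, sampling=s)
        upd = d < best
        out[upd] = lab
        best[upd] = d[upd]
    out[best > distance + 1e-9] = 0
    return LabelMask(labels=out, frame=nuclei.frame)


def segment_fallback(stack: ChannelStack, nuclei: LabelMask | None = None) -> LabelMask:
    """Deterministic classical whole-cell segmentation.

    Foreground is the union of Otsu-thresholded density and DAPI pixels;
    seeds are the provided nuclei, else local maxima of the smoothed DAPI;
    instances come from a watershed of the inverted combined intensity
    restricted to the foreground.  Every output instance contains at
    least one seed.  Returns an empty mask (with a warning) when no seeds
    are found.
    """
    dapi = stack.dapi.values
    dens = stack.density.values
    fg = np.zeros(stack.frame.shape, dtype=bool)
    for ch in (dens, dapi):
        if ch.max() > ch.min():
            fg |= ch > threshold_otsu(ch)

    if nuclei is not None:
        if nuclei.frame != stack.frame:
            raise FrameMismatchError("nuclei frame does not match stack frame")
        markers = nuclei.labels.astype(np.int32)
        fg |= markers > 0
    else:
        smooth = gaussian(dapi, sigma=2.0)
        peaks = peak_local_max(
            smooth, min_distance=5, threshold_abs=1e-3, exclude_border=False
        )
        markers = np.zeros(stack.frame.shape, dtype=np.int32)
        markers[peaks[:, 0], peaks[:, 1]] = np.arange(1, len(peaks) + 1)
        fg |= markers > 0

    if not (markers > 0).any():
        warnings.warn("fallback segmentation found no seeds; returning empty mask")
        return LabelMask(labels=np.zeros(stack.frame.shape, dtype=np.int32), frame=stack.frame)

    combined = dapi + dens
    labels = watershed(-combined, markers=markers, mask=fg, connectivity=1)
    labels, _, _ = relabel_sequential(labels)
    return LabelMask(labels=labels.astype(np.int32), frame=stack.frame)


def _resolve_backend(spec: Union[str, SegmentationBackend, Callable]) -> Callable:
    if callable(spec):
        return spec
    if isinstance(spec, str) and ":" in spec:
        mod_name, attr = spec.split(":", 1)
        try:
            mod = importlib.import_module(mod_name)
        except ImportError as exc:
            raise ExternalBackendError(
                f"backend module {mod_name!r} is not importable; install it or "
                f"pick --backend fallback"
            ) from exc
        try:
            obj = getattr(mod, attr)
        except AttributeError as exc:
            raise ExternalBackendError(f"module {mod_name!r} has no attribute {attr!r}") from exc
        return obj() if isinstance(obj, type) else obj
    raise ExternalBackendError(f"cannot interpret backend spec {spec!r}; expected 'module:attr' or a callable")


def segment_external(stack: ChannelStack, backend_spec) -> LabelMask:
    """Run a pretrained external backend on the two-channel stack.

    The adapter validates that the backend returns a mask on the same
    frame and re-indexes its labels to contiguous positive integers.
    """
    backend = _resolve_backend(backend_spec)
    result = backend(stack)
    if not isinstance(result, LabelMask):
        raise ExternalBackendError(
            f"backend returned {type(result).__name__}, expected LabelMask"
        )
    if result.frame != stack.frame:
        raise FrameMismatchError("backend returned a mask on a different frame")
    labels, _, _ = relabel_sequential(result.labels)
    return LabelMask(labels=labels.astype(np.int32), frame=stack.frame)
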