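"""Colony-edge detection and expansion-rate fitting.

The expanding biomass is imaged so that growth runs left→right across
the field.  Each frame is binarised with Otsu's threshold, small
objects are removed, and the x-position of the right-most foreground
pixel is recorded as the edge.  Frames after the edge reaches the far
border of the image are marked invalid (the front has left the field),
and an ordinary least-squares line through the valid ``(t, edge_x)``
points gives the expansion rate in μm/min.

The Otsu threshold is recomputed independently for every frame:
photobleaching and biomass accumulation drift the intensity histogram
over a multi-hour movie, so a single global threshold would bias late
frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .io import ImageStack


class SegmentationError(ValueError):
    """A frame cannot be segmented (e.g. constant intensity)."""


@dataclass
class EdgeTrace:
    """Per-frame edge position (μm) with a validity mask.

    ``valid`` is False for frames after the front first reached the far
    border (that arrival frame itself is still valid) and for frames
    with no foreground.
    """

    t_min: np.ndarray
    edge_x_um: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.edge_x_um = np.asarray(self.edge_x_um, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.t_min) == len(self.edge_x_um) == len(self.valid)):
            raise ValueError("t_min/edge_x_um/valid length mismatch")

    @property
    def valid_frames(self) -> np.ndarray:
        return np.flatnonzero(self.valid)

    def __len__(self) -> int:
        return len(self.t_min)


@dataclass(frozen=True)
class ExpansionFit:
    """OLS line through the valid edge positions; rate is the slope."""

    rate_um_min: float
    intercept_um: float
    r_squared: float
    n_frames_used: int


def segment_frame(frame: np.ndarray, min_object_px: int = 10) -> np.ndarray:
    """Otsu-threshold one frame and drop specks below ``min_object_px``.

    Pixels strictly above the Otsu threshold are foreground; connected
    components (8-connectivity) smaller than ``min_object_px`` pixels
    are removed so isolated hot pixels cannot masquerade as the
    right-most edge.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("segment_frame expects a 2D frame")
    if np.all(frame == frame.flat[0]):
        raise SegmentationError("constant frame cannot be segmented")
    mask = frame > threshold_otsu(frame)
    if min_object_px > 1:
        # objects of fewer than min_object_px pixels are removed
        mask = remove_small_objects(mask, max_size=min_object_px - 1, connectivity=2)
    return mask


def trace_edge(stack: ImageStack, min_object_px: int = 10) -> EdgeTrace:
    """Record the right-most segmented x-position for every frame.

    Volumetric stacks are max-intensity projected along z first.  The
    far-edge stop criterion marks frames invalid once the edge has
    reached ``width − 2`` pixels; the arrival frame is kept.
    """
    data = stack.data
    if stack.axes == "TZYX":
        data = data.max(axis=1)
    n_t, _, width = data.shape
    edge_px = np.full(n_t, -1, dtype=float)
    for t in range(n_t):
        try:
            mask = segment_frame(data[t], min_object_px)
        except SegmentationError:
            continue
        cols = np.flatnonzero(mask.any(axis=0))
        if cols.size:
            edge_px[t] = cols[-1]
    if np.all(edge_px < 0):
        raise SegmentationError("no foreground detected in any frame")
    valid = edge_px >= 0
    at_border = np.flatnonzero(edge_px >= width - 2)
    if at_border.size:
        valid[at_border[0] + 1:] = False
    edge_um = np.where(edge_px >= 0, edge_px, 0.0) * stack.pixel_size_um
    return EdgeTrace(stack.t_min(), edge_um, valid)


def fit_expansion(trace: EdgeTrace) -> ExpansionFit:
    """Expansion rate (μm/min) from an OLS fit over the valid frames."""
    idx = trace.valid_frames
    if idx.size < 3:
        raise ValueError(f"need ≥ 3 valid frames to fit, got {idx.size}")
    t = trace.t_min[idx]
    x = trace.edge_x_um[idx]
    res = stats.linregress(t, x)
    r2 = res.rvalue**2 if np.std(x) > 0 else 1.0  # constant trace: perfect flat fit
    return ExpansionFit(
        rate_um_min=float(res.slope),
        intercept_um=float(res.intercept),
        r_squared=float(r2),
        n_frames_used=int(idx.size),
    )
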