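"""Whole-colony morphometrics: footprint area, biomass volume from
z-stack top surfaces, thickness ratios between time points, and the
internal biomass flow rate from landmark tracks.

Volumes follow a column model: each z-stack is segmented slice by
slice, and for every (y, x) column the height of the upper-most
segmented voxel above the agar reference plane (z index 0) defines the
column height.  Total volume is the sum of column heights times the
pixel area, which deliberately fills internal voids — consistent with
treating the biofilm as the solid under its top surface.  A
segmented-voxel mode counts only foreground voxels instead.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import remove_small_objects

from .edge import SegmentationError
from .io import ImageStack, PointTrack


@dataclass
class SurfaceMap:
    """Per-column top-surface height (μm) above the reference plane.

    Columns with no segmented voxel carry height 0; ``coverage`` is the
    fraction of columns with any foreground.
    """

    top_z_um: np.ndarray
    coverage: float


@dataclass(frozen=True)
class VolumeResult:
    volume_um3: float
    n_columns_fg: int


def footprint_area(
    image: np.ndarray, pixel_size_um: float, min_object_px: int = 10
) -> float:
    """Colony footprint area (μm²) from a reflected-light macro image.

    Otsu segmentation, then only the largest connected component is
    kept — a whole colony is a single object, and debris or reflections
    elsewhere on the plate must not inflate the area.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("footprint_area expects a 2D image")
    if np.all(image == image.flat[0]):
        raise SegmentationError("constant image cannot be segmented")
    mask = image > threshold_otsu(image)
    labels = label(mask, connectivity=2)
    if labels.max() == 0:
        return 0.0
    counts = np.bincount(labels.ravel())[1:]
    largest = counts.max()
    if largest < min_object_px:
        return 0.0
    return float(largest) * pixel_size_um**2


def _segment_slices(volume: np.ndarray, min_object_px: int) -> np.ndarray:
    """Per-slice Otsu segmentation of a (z, y, x) volume.

    Slices that contain only one intensity class (e.g. every deep slice
    of a thick slab is pure biomass) have no bimodal histogram for Otsu
    to split; such slices are classified against a global whole-stack
    threshold instead of letting a per-slice threshold cut through pure
    noise.
    """
    flat = volume.ravel()
    if np.all(flat == flat[0]):
        return np.zeros(volume.shape, dtype=bool)
    global_thr = threshold_otsu(volume)
    masks = np.empty(volume.shape, dtype=bool)
    for k in range(volume.shape[0]):
        sl = volume[k]
        above = sl > global_thr
        frac = above.mean()
        if 0.02 < frac < 0.98 and sl.min() < sl.max():
            masks[k] = sl > threshold_otsu(sl)
        else:
            masks[k] = above
        if min_object_px > 1 and masks[k].any():
            masks[k] = remove_small_objects(
                masks[k], max_size=min_object_px - 1, connectivity=2
            )
    return masks


def surface_and_volume(
    stack: ImageStack,
    min_object_px: int = 10,
    mode: str = "solid-columns",
) -> tuple[SurfaceMap, VolumeResult]:
    """Top-surface map and total biomass volume of a volumetric stack.

    The stack must be ``TZYX`` (a single time point is the usual case);
    z index 0 is the agar-proximal reference plane.  Column height is
    ``(max foreground z index + 1) · z_step`` — a voxel occupies the
    full z-step above its plane.  ``mode`` selects the volume model:
    ``"solid-columns"`` (default) sums column heights, filling internal
    voids; ``"segmented-voxels"`` counts only segmented voxels.
    """
    if stack.axes != "TZYX":
        raise ValueError("surface_and_volume requires a TZYX stack")
    if mode not in ("solid-columns", "segmented-voxels"):
        raise ValueError(f"unknown mode {mode!r}")
    if stack.n_frames != 1:
        raise ValueError("pass one time point at a time")
    volume = stack.data[0]
    masks = _segment_slices(volume, min_object_px)
    any_fg = masks.any(axis=0)
    n_fg = int(any_fg.sum())
    z_index = np.arange(volume.shape[0])[:, None, None]
    top_index = np.where(any_fg, (masks * (z_index + 1)).max(axis=0) - 1, -1)
    top_z_um = np.where(top_index >= 0, (top_index + 1) * stack.z_step_um, 0.0)
    surface = SurfaceMap(top_z_um=top_z_um, coverage=float(any_fg.mean()))
    px_area = stack.pixel_size_um**2
    if mode == "solid-columns":
        total = float(top_z_um.sum()) * px_area
    else:
        total = float(masks.sum()) * stack.z_step_um * px_area
    if n_fg == 0:
        warnings.warn("no foreground anywhere in the stack; volume is 0")
    return surface, VolumeResult(volume_um3=total, n_columns_fg=n_fg)


def thickness_ratio(
    stack_early: ImageStack,
    stack_late: ImageStack,
    min_object_px: int = 10,
    mode: str = "solid-columns",
) -> float:
    """Biomass volume ratio late/early between two z-stacks.

    A ratio of 1 means no thickening; wild-type biofilms thicken
    substantially between 48 h and 72 h while matrix mutants do not.
    """
    if stack_early.pixel_size_um != stack_late.pixel_size_um:
        raise ValueError("stacks must share pixel_size_um")
    if stack_early.z_step_um != stack_late.z_step_um:
        raise ValueError("stacks must share z_step_um")
    _, early = surface_and_volume(stack_early, min_object_px, mode)
    _, late = surface_and_volume(stack_late, min_object_px, mode)
    if early.volume_um3 == 0:
        raise ValueError("early stack has zero biomass volume")
    return late.volume_um3 / early.volume_um3


def internal_flow_rate(
    tracks: list[PointTrack], pixel_size_um: float, dt_min: float
) -> tuple[dict[str, float], float]:
    """Mean landmark movement rate (μm/min) per track and pooled.

    The per-interval rate is the Euclidean step divided by the frame
    interval; the pooled value is the mean of per-track means, so every
    landmark counts equally regardless of track length.
    """
    if not tracks:
        raise ValueError("no tracks given")
    if dt_min <= 0:
        raise ValueError("dt_min must be > 0")
    per_track: dict[str, float] = {}
    for t in tracks:
        if len(t) < 2:
            raise ValueError(f"track {t.track_id}: need ≥ 2 points")
        steps = np.hypot(np.diff(t.x_px), np.diff(t.y_px)) * pixel_size_um
        per_track[t.track_id] = float(steps.mean() / dt_min)
    pooled = float(np.mean(list(per_track.values())))
    return per_track, pooled
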