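"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its spec (including the RNG seed):
regenerating with the same spec is bit-identical.  Every generator
returns the ground-truth parameters alongside the rendered data, so
parameter-recovery tests never re-derive truth from the rendering.

What is emulated
----------------
* :func:`make_front_stack` — a bright biomass front advancing left→right
  at a constant speed over dark agar, as seen in expansion-rate movies.
* :func:`make_growth_curve` — logistic fluorescence accumulation in a
  static square ROI (sigmoid proxy for surface-colonising cell density).
* :func:`make_pedigree` — z-ring first-appearance events forming binary
  parent/daughter pedigrees sampled on a fixed frame interval, with
  division intervals drawn from a truncated Normal.
* :func:`make_volume_stack` — a confocal-style z-stack with a defined
  biomass top-surface height map over the agar reference plane.
* :func:`make_tracks` — landmark point tracks whose per-interval
  displacements follow a configurable step model (drift, isotropic
  Gaussian steps, or a mixture of modes).
* :func:`make_colony_image` — a macro reflected-light image with a
  single bright colony footprint on dark agar.

Noise is additive Gaussian applied after the geometry and clipped at
zero — the simplest model that stresses Otsu thresholding.  Fronts are
rendered as hard steps (a pixel is foreground iff its x-position in μm
is ≤ the true edge position), which keeps the segmentation oracle exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ImageStack, PointTrack, PedigreeTable, SquareROI, ROOT_ID

#: Default lateral calibration: a 1024-px scan across an 890 μm field.
DEFAULT_PIXEL_SIZE_UM = 890.0 / 1024.0
#: Default frame interval (minutes) of the time-lapse assays.
DEFAULT_DT_MIN = 10.0
#: Default confocal z-step (μm).
DEFAULT_Z_STEP_UM = 3.87


def _noisy(clean: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd > 0:
        clean = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    return np.clip(clean, 0.0, None).astype(np.float32)


# ---------------------------------------------------------------------------
# advancing front
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrontSpec:
    """A biomass front advancing rightward at constant speed.

    ``rate_um_min`` is the true edge speed; frame ``t`` has every pixel
    with ``x·pixel_size ≤ x0_um + rate·dt·t`` at ``fg_level`` (before
    noise) and the rest at ``bg_level``.
    """

    rate_um_min: float
    x0_um: float = 50.0
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    dt_min: float = DEFAULT_DT_MIN
    n_frames: int = 60
    width_px: int = 1024
    height_px: int = 64
    fg_level: float = 100.0
    bg_level: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_um_min < 0:
            raise ValueError("rate_um_min must be ≥ 0")
        if self.fg_level <= self.bg_level:
            raise ValueError("fg_level must exceed bg_level")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be ≥ 0")
        if self.n_frames < 1 or self.width_px < 1 or self.height_px < 1:
            raise ValueError("n_frames, width_px, height_px must be ≥ 1")


def make_front_stack(spec: FrontSpec) -> tuple[ImageStack, dict]:
    """Render an advancing-front time-lapse; returns ``(stack, truth)``.

    ``truth`` carries the generating rate, the per-frame true edge
    position in μm, and the per-frame index of the right-most foreground
    pixel (−1 where the front has not entered the frame).
    """
    rng = np.random.default_rng(spec.seed)
    x_um = np.arange(spec.width_px) * spec.pixel_size_um
    t = np.arange(spec.n_frames)
    edge_um = spec.x0_um + spec.rate_um_min * spec.dt_min * t
    frames = np.where(
        x_um[None, :] <= edge_um[:, None], spec.fg_level, spec.bg_level
    )
    clean = np.broadcast_to(
        frames[:, None, :], (spec.n_frames, spec.height_px, spec.width_px)
    ).copy()
    data = _noisy(clean, spec.noise_sd, rng)
    stack = ImageStack(data, spec.pixel_size_um, spec.dt_min, axes="TYX")
    edge_px = np.floor(edge_um / spec.pixel_size_um).astype(int)
    edge_px = np.minimum(edge_px, spec.width_px - 1)
    edge_px[edge_um < 0] = -1
    truth = {
        "rate_um_min": spec.rate_um_min,
        "x0_um": spec.x0_um,
        "edge_um": edge_um.tolist(),
        "edge_px": edge_px.tolist(),
    }
    return stack, truth


# ---------------------------------------------------------------------------
# logistic growth curve
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthCurveSpec:
    """Logistic fluorescence growth in a static ROI.

    The clean curve is ``i(t) = K / (1 + ((K − i0)/i0)·2^(−t/T))`` with
    ``T = doubling_time_min`` and ``K = carrying_capacity``; at early
    times (``i0 ≪ K``) it reduces to exponential doubling every ``T``
    minutes.
    """

    doubling_time_min: float
    carrying_capacity: float = 1000.0
    i0: float = 1.0
    dt_min: float = DEFAULT_DT_MIN
    n_frames: int = 120
    noise_sd: float = 0.0
    seed: int = 0
    frame_px: int = 64
    roi_side_px: int = 24

    def __post_init__(self) -> None:
        if self.doubling_time_min <= 0:
            raise ValueError("doubling_time_min must be > 0")
        if not (0 < self.i0 < self.carrying_capacity):
            raise ValueError("need 0 < i0 < carrying_capacity")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be ≥ 0")
        if self.roi_side_px + 2 > self.frame_px:
            raise ValueError("ROI must fit inside the frame")


def logistic_curve(spec: GrowthCurveSpec) -> tuple[np.ndarray, np.ndarray]:
    """Clean logistic trajectory; returns ``(t_min, intensity)``."""
    t = np.arange(spec.n_frames, dtype=float) * spec.dt_min
    K, i0 = spec.carrying_capacity, spec.i0
    i = K / (1.0 + ((K - i0) / i0) * np.power(2.0, -t / spec.doubling_time_min))
    return t, i


def make_growth_curve(
    spec: GrowthCurveSpec,
) -> tuple[np.ndarray, ImageStack, SquareROI, dict]:
    """Generate a logistic curve and its stack rendering.

    Returns ``(intensity, stack, roi, truth)``.  Every frame of the
    stack is uniform at the curve value before noise, so the ROI mean
    equals the curve exactly in the noise-free case and in expectation
    otherwise.
    """
    rng = np.random.default_rng(spec.seed)
    t, curve = logistic_curve(spec)
    clean = np.broadcast_to(
        curve[:, None, None], (spec.n_frames, spec.frame_px, spec.frame_px)
    ).copy()
    data = _noisy(clean, spec.noise_sd, rng)
    stack = ImageStack(data, DEFAULT_PIXEL_SIZE_UM, spec.dt_min, axes="TYX")
    margin = (spec.frame_px - spec.roi_side_px) // 2
    roi = SquareROI(margin, margin, spec.roi_side_px, label="synthetic")
    half_t = spec.doubling_time_min * math.log2(
        (spec.carrying_capacity - spec.i0) / spec.i0
    )
    truth = {
        "doubling_time_min": spec.doubling_time_min,
        "carrying_capacity": spec.carrying_capacity,
        "i0": spec.i0,
        "t_half_min": half_t,  # time at which i(t) = K/2, from the closed form
        "t_min": t.tolist(),
        "intensity": curve.tolist(),
    }
    return data.mean(axis=(1, 2)) if spec.noise_sd > 0 else curve.copy(), stack, roi, truth


# ---------------------------------------------------------------------------
# division pedigrees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PedigreeSpec:
    """Binary-division pedigrees with truncated-Normal intervals.

    Each node spawns two daughters after an interval drawn from
    ``Normal(mean_interval_min, sd_interval_min)`` truncated to
    ``≥ dt_min``; appearance frames are the interval rounded to the
    sampling grid.  A pedigree with ``n_generations = g`` has ``g``
    levels (roots are level 0), hence ``2^g − 2`` parent→child edges
    per root.
    """

    mean_interval_min: float
    sd_interval_min: float = 0.0
    n_generations: int = 4
    n_roots: int = 11
    dt_min: float = DEFAULT_DT_MIN
    drift_um_min: float = 0.0
    seed: int = 0
    root_frame: int = 3

    def __post_init__(self) -> None:
        if self.mean_interval_min <= 0:
            raise ValueError("mean_interval_min must be > 0")
        if self.sd_interval_min < 0:
            raise ValueError("sd_interval_min must be ≥ 0")
        if self.n_generations < 1 or self.n_roots < 1:
            raise ValueError("n_generations and n_roots must be ≥ 1")
        if self.dt_min <= 0:
            raise ValueError("dt_min must be > 0")


def _sample_interval(spec: PedigreeSpec, rng: np.random.Generator) -> float:
    if spec.sd_interval_min == 0:
        return max(spec.mean_interval_min, spec.dt_min)
    while True:  # rejection sampling of Normal truncated to ≥ dt_min
        x = rng.normal(spec.mean_interval_min, spec.sd_interval_min)
        if x >= spec.dt_min:
            return x


def make_pedigree(spec: PedigreeSpec) -> tuple[PedigreeTable, dict]:
    """Generate pedigree event rows; returns ``(table, truth)``.

    ``truth`` records the generating mean/SD, the number of edges, and
    the exact (pre-rounding) sampled intervals in node order.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    intervals: list[float] = []
    next_id = 1
    for _ in range(spec.n_roots):
        root_id = str(next_id)
        next_id += 1
        rows.append((root_id, spec.root_frame, 0.0, 0.0, ROOT_ID))
        level = [(root_id, spec.root_frame, 0.0, 0.0)]
        for _gen in range(1, spec.n_generations):
            nxt = []
            for pid, pframe, px, py in level:
                for _child in range(2):
                    iv = _sample_interval(spec, rng)
                    intervals.append(iv)
                    frame = pframe + max(1, round(iv / spec.dt_min))
                    dx = spec.drift_um_min * iv + rng.normal(0.0, 1.0)
                    dy = rng.normal(0.0, 1.0)
                    cid = str(next_id)
                    next_id += 1
                    rows.append((cid, frame, px + dx, py + dy, pid))
                    nxt.append((cid, frame, px + dx, py + dy))
            level = nxt
    df = pd.DataFrame(rows, columns=["roi_id", "frame", "x_px", "y_px", "parent_id"])
    table = PedigreeTable(df)
    truth = {
        "mean_interval_min": spec.mean_interval_min,
        "sd_interval_min": spec.sd_interval_min,
        "n_edges": len(intervals),
        "sampled_intervals_min": intervals,
    }
    return table, truth


# ---------------------------------------------------------------------------
# volumetric stacks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurfaceSpec:
    """A z-stack with a defined biomass top surface over the agar plane.

    Voxel ``(z, y, x)`` is foreground iff ``z·z_step ≤ height_map[y, x]``;
    z index 0 is the agar-proximal reference plane.
    """

    height_map_um: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    z_step_um: float = DEFAULT_Z_STEP_UM
    fg_level: float = 100.0
    bg_level: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0
    n_z: int | None = None

    def __post_init__(self) -> None:
        h = np.asarray(self.height_map_um, dtype=float)
        object.__setattr__(self, "height_map_um", h)
        if h.ndim != 2:
            raise ValueError("height_map_um must be 2D (y, x)")
        if np.any(h < 0) or not np.all(np.isfinite(h)):
            raise ValueError("heights must be finite and ≥ 0")
        if self.fg_level <= self.bg_level:
            raise ValueError("fg_level must exceed bg_level")
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be > 0")
        n_z = self.n_z
        if n_z is None:
            n_z = int(np.floor(h.max() / self.z_step_um)) + 2
            object.__setattr__(self, "n_z", n_z)
        if h.max() > (n_z - 1) * self.z_step_um + self.z_step_um:
            raise ValueError("height map exceeds the z-extent of the stack")


def make_volume_stack(spec: SurfaceSpec) -> tuple[ImageStack, dict]:
    """Render a TZYX stack (T = 1) from a height map; returns ``(stack, truth)``.

    ``truth`` includes the exact column volume implied by the voxel fill
    (counting every foreground voxel as one full z-step).
    """
    rng = np.random.default_rng(spec.seed)
    h = spec.height_map_um
    z_um = np.arange(spec.n_z) * spec.z_step_um
    fg = z_um[:, None, None] <= h[None, :, :]
    clean = np.where(fg, spec.fg_level, spec.bg_level)
    data = _noisy(clean, spec.noise_sd, rng)[None]  # T axis
    stack = ImageStack(
        data, spec.pixel_size_um, DEFAULT_DT_MIN, z_step_um=spec.z_step_um, axes="TZYX"
    )
    top_index = np.where(h >= 0, np.floor(h / spec.z_step_um).astype(int), -1)
    voxel_volume = fg.sum(axis=0) * spec.z_step_um * spec.pixel_size_um**2
    truth = {
        "true_height_sum_um": float(h.sum()),
        "true_volume_um3": float(voxel_volume.sum()),
        "top_index": top_index.tolist(),
    }
    return stack, truth


# ---------------------------------------------------------------------------
# landmark tracks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StepModel:
    """Per-interval displacement distribution for landmark tracks.

    ``kind``:

    * ``"drift"`` — deterministic displacement ``rate·dt`` along
      ``direction_deg``.
    * ``"gaussian"`` — isotropic direction, step length
      ``Normal(mean_step_um, sd_step_um)`` truncated at 0.
    * ``"mixture"`` — each track draws one component (by ``weights``)
      and keeps it for its whole life, giving a multi-modal pooled
      step-size histogram.
    """

    kind: str = "drift"
    rate_um_min: float = 0.0
    direction_deg: float = 0.0
    mean_step_um: float = 0.0
    sd_step_um: float = 0.0
    components: tuple["StepModel", ...] = ()
    weights: tuple[float, ...] = ()

    @staticmethod
    def drift(rate_um_min: float, direction_deg: float = 0.0) -> "StepModel":
        return StepModel(kind="drift", rate_um_min=rate_um_min, direction_deg=direction_deg)

    @staticmethod
    def gaussian(mean_step_um: float, sd_step_um: float) -> "StepModel":
        return StepModel(kind="gaussian", mean_step_um=mean_step_um, sd_step_um=sd_step_um)

    @staticmethod
    def mixture(components: list["StepModel"], weights: list[float]) -> "StepModel":
        if len(components) != len(weights) or not components:
            raise ValueError("components and weights must be non-empty and equal length")
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        return StepModel(
            kind="mixture", components=tuple(components), weights=tuple(w / w.sum())
        )

    def mean_speed_um_min(self, dt_min: float) -> float:
        """Expected per-interval speed implied by the model."""
        if self.kind == "drift":
            return self.rate_um_min
        if self.kind == "gaussian":
            return max(self.mean_step_um, 0.0) / dt_min
        if self.kind == "mixture":
            return float(
                sum(w * c.mean_speed_um_min(dt_min) for c, w in zip(self.components, self.weights))
            )
        raise ValueError(f"unknown step model kind {self.kind!r}")


def _draw_step(model: StepModel, dt_min: float, rng: np.random.Generator) -> tuple[float, float]:
    if model.kind == "drift":
        theta = math.radians(model.direction_deg)
        r = model.rate_um_min * dt_min
        return r * math.cos(theta), r * math.sin(theta)
    if model.kind == "gaussian":
        r = max(0.0, rng.normal(model.mean_step_um, model.sd_step_um))
        theta = rng.uniform(0.0, 2.0 * math.pi)
        return r * math.cos(theta), r * math.sin(theta)
    raise ValueError(f"unknown step model kind {model.kind!r}")


def make_tracks(
    n_tracks: int,
    step_model: StepModel,
    dt_min: float,
    n_frames: int,
    seed: int = 0,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    start_box_px: float = 100.0,
) -> tuple[list[PointTrack], dict]:
    """Generate landmark tracks from a step model; returns ``(tracks, truth)``.

    Starting positions are uniform in ``[0, start_box_px)²``.  ``truth``
    reports the model's expected mean speed (μm/min) and, for mixtures,
    each track's assigned component.
    """
    if n_tracks < 1 or n_frames < 1:
        raise ValueError("n_tracks and n_frames must be ≥ 1")
    if dt_min <= 0 or pixel_size_um <= 0:
        raise ValueError("dt_min and pixel_size_um must be > 0")
    rng = np.random.default_rng(seed)
    tracks = []
    assignment = []
    for i in range(n_tracks):
        model = step_model
        if step_model.kind == "mixture":
            k = rng.choice(len(step_model.components), p=np.asarray(step_model.weights))
            model = step_model.components[k]
            assignment.append(int(k))
        x = [rng.uniform(0.0, start_box_px)]
        y = [rng.uniform(0.0, start_box_px)]
        for _ in range(n_frames - 1):
            dx_um, dy_um = _draw_step(model, dt_min, rng)
            x.append(x[-1] + dx_um / pixel_size_um)
            y.append(y[-1] + dy_um / pixel_size_um)
        tracks.append(PointTrack(str(i + 1), np.arange(n_frames), np.array(x), np.array(y)))
    truth = {
        "mean_speed_um_min": step_model.mean_speed_um_min(dt_min),
        "dt_min": dt_min,
        "component_assignment": assignment,
    }
    return tracks, truth


# ---------------------------------------------------------------------------
# macro colony image
# ---------------------------------------------------------------------------


def make_colony_image(
    radius_px: float,
    size_px: int = 256,
    pixel_size_um: float = 20.0,
    fg_level: float = 100.0,
    bg_level: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Render a bright circular colony footprint on dark agar.

    Returns ``(image, truth)`` where truth holds the exact rendered
    foreground pixel count and the implied area in μm².
    """
    if radius_px <= 0 or size_px < 3:
        raise ValueError("radius_px must be > 0 and size_px ≥ 3")
    rng = np.random.default_rng(seed)
    c = (size_px - 1) / 2.0
    yy, xx = np.mgrid[0:size_px, 0:size_px]
    disk = (xx - c) ** 2 + (yy - c) ** 2 <= radius_px**2
    clean = np.where(disk, fg_level, bg_level)
    image = _noisy(clean, noise_sd, rng)
    truth = {
        "n_fg_px": int(disk.sum()),
        "area_um2": float(disk.sum()) * pixel_size_um**2,
        "pixel_size_um": pixel_size_um,
    }
    return image, truth
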