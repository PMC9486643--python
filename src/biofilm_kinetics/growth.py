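"""Initial doubling time from ROI fluorescence growth curves.

Early surface colonisation is quantified by placing static square ROIs
on the interior of the newly-spotted colony and following their mean
fluorescence over the time-lapse.  The intensity acts as a proxy for
cell density: during unrestricted growth it doubles with the population,
so the slope of log2(intensity) against time, in doublings per minute,
is the reciprocal of the doubling time.  Because the curve saturates
into a sigmoid as the field fills, the estimator slides a centred
linear-regression window along the log2 curve and takes the maximum
slope, excluding windows that touch the plateau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ImageStack, SquareROI


class NoGrowthError(ValueError):
    """The curve shows no detectable exponential increase."""


@dataclass
class GrowthCurve:
    """ROI mean intensity against time (minutes)."""

    t_min: np.ndarray
    intensity: np.ndarray
    roi: SquareROI | None = None

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.t_min.shape != self.intensity.shape:
            raise ValueError("t_min and intensity lengths differ")
        if len(self.t_min) > 1 and np.any(np.diff(self.t_min) <= 0):
            raise ValueError("t_min must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t_min)


@dataclass(frozen=True)
class DoublingEstimate:
    """Result of the max-log-gradient doubling-time estimator.

    ``max_gradient_per_min`` is in doublings/min, so
    ``doubling_time_min * max_gradient_per_min == 1`` by construction.
    """

    doubling_time_min: float
    max_gradient_per_min: float
    window_frames: int
    t_at_max_min: float


def roi_mean_curve(stack: ImageStack, roi: SquareROI) -> GrowthCurve:
    """Mean intensity of a static square ROI per frame.

    The ROI is propagated unchanged through every time point; the curve
    time base is ``frame_index * dt_min``.
    """
    if stack.axes != "TYX":
        raise ValueError("roi_mean_curve requires a 2D time-lapse (TYX); "
                         "project volumetric stacks first")
    n_t, h, w = stack.data.shape
    roi.check_inside(h, w)
    ys, xs = roi.slices()
    intensity = stack.data[:, ys, xs].mean(axis=(1, 2))
    return GrowthCurve(stack.t_min(), intensity, roi)


def normalise_curve(curve: GrowthCurve) -> GrowthCurve:
    """Divide intensities by their maximum (the sigmoid plateaus at 1)."""
    peak = float(np.max(curve.intensity))
    if peak <= 0:
        raise ValueError("cannot normalise an all-zero curve")
    return GrowthCurve(curve.t_min.copy(), curve.intensity / peak, curve.roi)


def estimate_doubling_time(
    curve: GrowthCurve,
    window_frames: int = 5,
    background: float | str = 0.0,
    plateau_fraction: float = 0.9,
    min_gradient: float = 1e-9,
) -> DoublingEstimate:
    """Doubling time from the maximum sliding-window log2 gradient.

    A centred ordinary-least-squares window of ``window_frames`` points
    slides along ``log2(intensity − background)``; the maximum slope
    (doublings/min) defines the doubling time as its reciprocal.  The
    estimate is invariant to positive rescaling of the curve, so it can
    be applied before or after :func:`normalise_curve`.

    Parameters
    ----------
    window_frames:
        Odd integer ≥ 3; the regression window length.
    background:
        Intensity offset subtracted before the log.  Default 0 (pure
        signal); pass ``"auto"`` to subtract the minimum of the first
        three frames, appropriate for curves riding on an
        autofluorescent-agar baseline.
    plateau_fraction:
        Windows containing any point above this fraction of the curve
        maximum are excluded from the max-slope search: logistic
        saturation only biases the slope downward, so exclusion cannot
        inflate the growth estimate.
    min_gradient:
        Slopes at or below this (doublings/min) count as no growth.
    """
    if window_frames < 3 or window_frames % 2 == 0:
        raise ValueError("window_frames must be an odd integer ≥ 3")
    if len(curve) < window_frames:
        raise ValueError(
            f"curve has {len(curve)} points; needs ≥ window_frames = {window_frames}"
        )
    if background == "auto":
        background = float(np.min(curve.intensity[:3]))
    signal = curve.intensity - float(background)
    rel = curve.intensity / float(np.max(curve.intensity))

    best_slope = -np.inf
    best_centre = np.nan
    n = len(curve)
    half = window_frames // 2
    for start in range(n - window_frames + 1):
        stop = start + window_frames
        win_sig = signal[start:stop]
        if np.any(win_sig <= 0):
            continue
        if np.any(rel[start:stop] > plateau_fraction):
            continue
        res = stats.linregress(curve.t_min[start:stop], np.log2(win_sig))
        if res.slope > best_slope:
            best_slope = res.slope
            best_centre = curve.t_min[start + half]
    if not np.isfinite(best_slope):
        raise NoGrowthError(
            "no window with positive background-subtracted intensity below the plateau"
        )
    if best_slope <= min_gradient:
        raise NoGrowthError(f"no growth detected (max gradient {best_slope:.3g}/min)")
    return DoublingEstimate(
        doubling_time_min=1.0 / best_slope,
        max_gradient_per_min=best_slope,
        window_frames=window_frames,
        t_at_max_min=float(best_centre),
    )
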