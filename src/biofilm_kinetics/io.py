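"""Readers, writers and validated domain containers.

All downstream analysis consumes the types defined here:

* :class:`ImageStack` — a 2D+t (``TYX``) or 3D+t (``TZYX``) grayscale
  intensity array with explicit physical calibration (pixel size in μm,
  frame interval in minutes, z-step in μm for volumetric data).
* :class:`SquareROI` — a static square region used for fluorescence
  growth curves.
* :class:`PointTrack` — one manually-tracked landmark as an ordered list
  of per-frame sub-pixel coordinates.
* :class:`PedigreeTable` — point annotations of z-ring first appearances
  with parent links, forming a forest of division pedigrees.
* measurement tables — tidy per-replicate result rows
  ``(strain, replicate, metric, value, units)``.

Conventions: pixel coordinates are 0-based with the origin at the
top-left; x increases rightward (the direction of colony expansion in
all edge analyses) and y downward.  Times are minutes, lengths μm,
areas μm², volumes μm³ everywhere downstream.

Calibration travels both in ImageJ-style TIFF tags and in a sidecar
JSON file (``<name>.tif.json``); on conflict the sidecar wins, because
many tools strip TIFF tags but leave neighbouring files alone.  Readers
reject violated invariants instead of repairing them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

#: Sentinel parent id marking the root of a pedigree.
ROOT_ID = "0"

TRACK_COLUMNS = ["track_id", "frame", "x_px", "y_px"]
PEDIGREE_COLUMNS = ["roi_id", "frame", "x_px", "y_px", "parent_id"]
MEASUREMENT_COLUMNS = ["strain", "replicate", "metric", "value", "units"]


class CalibrationError(ValueError):
    """Physical calibration is missing or invalid."""


class SchemaError(ValueError):
    """A table file does not match its required schema."""


class PedigreeError(ValueError):
    """A pedigree table violates the forest/ordering invariants."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ImageStack:
    """Calibrated grayscale intensity stack.

    Parameters
    ----------
    data:
        Array indexed ``(t, y, x)`` or ``(t, z, y, x)``; finite and
        non-negative.
    pixel_size_um:
        Lateral calibration, μm per pixel (> 0).
    dt_min:
        Frame interval in minutes (> 0).
    z_step_um:
        Axial step in μm (> 0); required for ``TZYX`` data.
    axes:
        ``"TYX"`` or ``"TZYX"``; must match the array rank.
    """

    data: np.ndarray
    pixel_size_um: float
    dt_min: float
    z_step_um: float | None = None
    axes: str = "TYX"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.axes not in ("TYX", "TZYX"):
            raise ValueError(f"axes must be 'TYX' or 'TZYX', got {self.axes!r}")
        if self.data.ndim != len(self.axes):
            raise ValueError(
                f"axes {self.axes!r} requires a {len(self.axes)}D array, "
                f"got {self.data.ndim}D"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite intensities")
        if np.any(self.data < 0):
            raise ValueError("stack contains negative intensities")
        if not self.pixel_size_um or self.pixel_size_um <= 0:
            raise CalibrationError("pixel_size_um must be > 0")
        if not self.dt_min or self.dt_min <= 0:
            raise CalibrationError("dt_min must be > 0")
        if self.axes == "TZYX":
            if self.z_step_um is None or self.z_step_um <= 0:
                raise CalibrationError("TZYX stack requires z_step_um > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def t_min(self) -> np.ndarray:
        """Frame times in minutes (frame index × dt)."""
        return np.arange(self.n_frames, dtype=float) * self.dt_min


@dataclass(frozen=True)
class SquareROI:
    """Axis-aligned square region, 0-based top-left corner."""

    x0: int
    y0: int
    side_px: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.side_px <= 0:
            raise ValueError("side_px must be > 0")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("ROI corner must be non-negative")

    def check_inside(self, height: int, width: int) -> None:
        if self.x0 + self.side_px > width or self.y0 + self.side_px > height:
            raise ValueError(
                f"ROI {self.label or (self.x0, self.y0, self.side_px)} "
                f"exceeds image bounds {height}×{width}"
            )

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.y0, self.y0 + self.side_px),
            slice(self.x0, self.x0 + self.side_px),
        )


@dataclass
class PointTrack:
    """One tracked landmark: strictly increasing frames, sub-pixel x/y."""

    track_id: str
    frames: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        if not (len(self.frames) == len(self.x_px) == len(self.y_px)):
            raise ValueError("frames/x/y length mismatch")
        if len(self.frames) and np.any(np.diff(self.frames) <= 0):
            raise ValueError(f"track {self.track_id}: frames not strictly increasing")
        if not (np.all(np.isfinite(self.x_px)) and np.all(np.isfinite(self.y_px))):
            raise ValueError(f"track {self.track_id}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class PedigreeTable:
    """Z-ring first-appearance events with parent links (a forest).

    ``parent_id == "0"`` marks a pedigree root, matching the annotation
    convention in which a root ROI carries the comment ``0`` and every
    daughter carries its parent's ROI id.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.rows
        missing = [c for c in PEDIGREE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"pedigree table missing columns: {missing}")
        df = df[PEDIGREE_COLUMNS].copy()
        df["roi_id"] = df["roi_id"].astype(str)
        df["parent_id"] = df["parent_id"].astype(str)
        df["frame"] = df["frame"].astype(int)
        if df["roi_id"].duplicated().any():
            dup = df.loc[df["roi_id"].duplicated(), "roi_id"].iloc[0]
            raise PedigreeError(f"duplicate roi_id {dup!r}")
        known = dict(zip(df["roi_id"], df["frame"]))
        for roi, frame, parent in zip(df["roi_id"], df["frame"], df["parent_id"]):
            if parent == ROOT_ID:
                continue
            if parent == roi:
                raise PedigreeError(f"roi {roi!r} is its own parent (cycle)")
            if parent not in known:
                raise PedigreeError(f"roi {roi!r} has dangling parent_id {parent!r}")
            if frame <= known[parent]:
                raise PedigreeError(
                    f"roi {roi!r} (frame {frame}) does not appear strictly "
                    f"after its parent {parent!r} (frame {known[parent]})"
                )
        # frames strictly increase along every edge, so any parent chain
        # strictly decreases in frame and must terminate: no cycles possible
        self.rows = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def roots(self) -> pd.DataFrame:
        return self.rows[self.rows["parent_id"] == ROOT_ID]


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Check a tidy measurement table against its schema and invariants."""
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"measurement table missing columns: {missing}")
    df = df[MEASUREMENT_COLUMNS].copy()
    for col in ("strain", "replicate", "metric", "units"):
        df[col] = df[col].astype(str)
    df["value"] = pd.to_numeric(df["value"], errors="raise")
    if not np.all(np.isfinite(df["value"])):
        raise ValueError("measurement values must be finite")
    key = df[["strain", "replicate", "metric"]]
    if key.duplicated().any():
        raise ValueError("duplicate (strain, replicate, metric) rows")
    return df


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

_IMAGEJ_DTYPES = (np.uint8, np.uint16, np.float32)


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as grayscale TIFF plus a JSON calibration sidecar.

    Calibration is embedded as ImageJ-style tags where the dtype allows
    and always mirrored into ``<name>.tif.json``.  Pixel data round-trip
    bit-exactly through :func:`read_stack`.
    """
    path = Path(path)
    data = stack.data
    kwargs: dict = {"photometric": "minisblack"}
    if data.dtype.type in _IMAGEJ_DTYPES:
        metadata = {
            "axes": stack.axes,
            "unit": "um",
            "finterval": stack.dt_min * 60.0,
        }
        if stack.z_step_um is not None:
            metadata["spacing"] = stack.z_step_um
        kwargs = {
            "photometric": "minisblack",
            "imagej": True,
            "resolution": (1.0 / stack.pixel_size_um, 1.0 / stack.pixel_size_um),
            "metadata": metadata,
        }
    tifffile.imwrite(path, data, **kwargs)
    sidecar = {
        "pixel_size_um": stack.pixel_size_um,
        "dt_min": stack.dt_min,
        "z_step_um": stack.z_step_um,
        "axes": stack.axes,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _imagej_calibration(tif: tifffile.TiffFile) -> dict:
    cal: dict = {}
    page = tif.pages[0]
    try:
        xres = page.tags["XResolution"].value
        if xres[0]:
            cal["pixel_size_um"] = xres[1] / xres[0]
    except (KeyError, ZeroDivisionError):
        pass
    meta = tif.imagej_metadata or {}
    if "finterval" in meta:
        cal["dt_min"] = float(meta["finterval"]) / 60.0
    if "spacing" in meta:
        cal["z_step_um"] = float(meta["spacing"])
    if "axes" in meta:
        cal["axes"] = meta["axes"]
    return cal


def read_stack(
    path: str | Path,
    *,
    pixel_size_um: float | None = None,
    dt_min: float | None = None,
    z_step_um: float | None = None,
    axes: str | None = None,
) -> ImageStack:
    """Read a grayscale TIFF time-lapse into an :class:`ImageStack`.

    Calibration precedence: keyword overrides > sidecar JSON > ImageJ
    TIFF tags.  Missing calibration with no override raises
    :class:`CalibrationError` — it is never silently defaulted.
    RGB input is rejected.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        if tif.pages[0].samplesperpixel > 1:
            raise ValueError(f"{path}: RGB/multichannel TIFF; grayscale required")
        data = tif.asarray()
        cal = _imagej_calibration(tif)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        cal.update({k: v for k, v in json.loads(sidecar.read_text()).items() if v is not None})
    overrides = {
        "pixel_size_um": pixel_size_um,
        "dt_min": dt_min,
        "z_step_um": z_step_um,
        "axes": axes,
    }
    cal.update({k: v for k, v in overrides.items() if v is not None})
    if cal.get("axes") is None:
        cal["axes"] = {3: "TYX", 4: "TZYX"}.get(data.ndim)
        if cal["axes"] is None:
            raise ValueError(f"{path}: cannot infer axes for {data.ndim}D data")
    if "pixel_size_um" not in cal:
        raise CalibrationError(f"{path}: pixel size not in metadata and no override given")
    if "dt_min" not in cal:
        raise CalibrationError(f"{path}: frame interval not in metadata and no override given")
    if cal["axes"] == "TZYX" and "z_step_um" not in cal:
        raise CalibrationError(f"{path}: volumetric stack lacks z_step_um")
    return ImageStack(
        data=data,
        pixel_size_um=cal["pixel_size_um"],
        dt_min=cal["dt_min"],
        z_step_um=cal.get("z_step_um"),
        axes=cal["axes"],
    )


def write_image(image: np.ndarray, path: str | Path, pixel_size_um: float) -> Path:
    """Write a single 2D grayscale image with pixel-size calibration."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image), photometric="minisblack")
    _sidecar_path(path).write_text(json.dumps({"pixel_size_um": pixel_size_um}))
    return path


def read_image(path: str | Path, *, pixel_size_um: float | None = None):
    """Read a single 2D grayscale image; returns ``(array, pixel_size_um)``."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        if tif.pages[0].samplesperpixel > 1:
            raise ValueError(f"{path}: RGB/multichannel TIFF; grayscale required")
        data = tif.asarray()
        cal = _imagej_calibration(tif)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        cal.update({k: v for k, v in json.loads(sidecar.read_text()).items() if v is not None})
    if pixel_size_um is not None:
        cal["pixel_size_um"] = pixel_size_um
    if "pixel_size_um" not in cal:
        raise CalibrationError(f"{path}: pixel size not in metadata and no override given")
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single 2D image, got {data.ndim}D")
    return data, cal["pixel_size_um"]


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def write_tracks(tracks: list[PointTrack], path: str | Path) -> Path:
    path = Path(path)
    frames = [
        pd.DataFrame(
            {"track_id": t.track_id, "frame": t.frames, "x_px": t.x_px, "y_px": t.y_px}
        )
        for t in tracks
    ]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TRACK_COLUMNS)
    df.to_csv(path, index=False)
    return path


def read_tracks(path: str | Path) -> list[PointTrack]:
    """Read a tracks CSV (``track_id,frame,x_px,y_px``) into PointTracks.

    Rows are sorted by frame within each track; duplicate
    ``(track_id, frame)`` pairs and non-numeric coordinates are rejected.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: tracks CSV missing columns {missing}")
    try:
        df["frame"] = df["frame"].astype(int)
        df["x_px"] = pd.to_numeric(df["x_px"], errors="raise")
        df["y_px"] = pd.to_numeric(df["y_px"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path}: non-numeric track data: {exc}") from exc
    if df.duplicated(subset=["track_id", "frame"]).any():
        raise SchemaError(f"{path}: duplicate (track_id, frame) rows")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(
            PointTrack(
                track_id=str(tid),
                frames=grp["frame"].to_numpy(),
                x_px=grp["x_px"].to_numpy(),
                y_px=grp["y_px"].to_numpy(),
            )
        )
    return tracks


def write_pedigree(table: PedigreeTable, path: str | Path) -> Path:
    path = Path(path)
    table.rows.to_csv(path, index=False)
    return path


def read_pedigree(path: str | Path) -> PedigreeTable:
    """Read and validate a pedigree CSV (``roi_id,frame,x_px,y_px,parent_id``)."""
    df = pd.read_csv(path, dtype={"roi_id": str, "parent_id": str})
    missing = [c for c in PEDIGREE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: pedigree CSV missing columns {missing}")
    return PedigreeTable(df)


def write_rois(rois: list[SquareROI], path: str | Path) -> Path:
    path = Path(path)
    payload = [
        {"x0": r.x0, "y0": r.y0, "side_px": r.side_px, "label": r.label} for r in rois
    ]
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_rois(path: str | Path) -> list[SquareROI]:
    """Read square-ROI definitions from a JSON list of objects."""
    payload = json.loads(Path(path).read_text())
    if not isinstance(payload, list):
        raise SchemaError(f"{path}: expected a JSON list of ROI objects")
    rois = []
    for i, entry in enumerate(payload):
        try:
            rois.append(
                SquareROI(
                    x0=int(entry["x0"]),
                    y0=int(entry["y0"]),
                    side_px=int(entry["side_px"]),
                    label=str(entry.get("label", f"roi{i}")),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: bad ROI entry {i}: {exc}") from exc
    return rois


def write_measurements(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_measurements(df).to_csv(path, index=False)
    return path


def read_measurements(path: str | Path) -> pd.DataFrame:
    return validate_measurements(pd.read_csv(path))
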