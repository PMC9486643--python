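"""Multi-strain, multi-replicate orchestration.

A YAML config lists the strains in a panel, their per-assay input
files (one entry per replicate) and shared analysis parameters.  The
pipeline runs every assay for every replicate, pools the results into
one tidy measurement table, and compares every mutant strain against
the control per metric with Dunnett's many-to-one test.  Per-replicate
failures are logged and skipped — a bad movie must not silently vanish,
so the run summary counts them and the exit status reflects them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import growth, io, morphometrics, pedigree as ped
from .edge import fit_expansion, trace_edge
from .stats import comparisons_frame, dunnett_vs_control

log = logging.getLogger("biofilm_kinetics.pipeline")

KNOWN_ASSAYS = ("expansion", "doubling", "divisions", "flow", "footprint", "thickness")

DEFAULT_PARAMETERS = {
    "window_frames": 5,
    "min_object_px": 10,
    "bin_width_um": 2.0,
    "flow_dt_min": 18.0,
    "divisions_dt_min": 10.0,
    "min_generation": 1,
    "alpha": 0.05,
}


@dataclass
class StrainConfig:
    label: str
    assays: dict[str, list[dict]]


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    strains: list[StrainConfig]
    control_strain: str
    output_dir: Path
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [s.label for s in self.strains]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate strain labels in config")
        if self.control_strain not in labels:
            raise ValueError(
                f"control_strain {self.control_strain!r} not among strains {labels}"
            )
        params = dict(DEFAULT_PARAMETERS)
        params.update(self.parameters)
        self.parameters = params


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ValueError(f"config error: {context} is missing required key {key!r}")
    return mapping[key]


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Expected layout::

        control_strain: WT
        output_dir: results
        parameters: {window_frames: 5, min_object_px: 10, ...}
        strains:
          - label: WT
            assays:
              expansion: [{stack: wt1.tif}, {stack: wt2.tif}]
              divisions: [{pedigree: wt_ped.csv}]

    Every referenced input file must exist; unknown assay names are
    rejected.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    strains_raw = _require(raw, "strains", str(path))
    strains = []
    for i, entry in enumerate(strains_raw):
        label = _require(entry, "label", f"strains[{i}]")
        assays = entry.get("assays", {})
        for assay, reps in assays.items():
            if assay not in KNOWN_ASSAYS:
                raise ValueError(
                    f"config error: unknown assay {assay!r} for strain {label!r}; "
                    f"known: {KNOWN_ASSAYS}"
                )
            if not isinstance(reps, list):
                raise ValueError(
                    f"config error: assays.{assay} for strain {label!r} must be a list"
                )
            for rep in reps:
                for v in rep.values():
                    if isinstance(v, str):
                        p = (path.parent / v).resolve()
                        if not p.exists():
                            raise ValueError(f"config error: input file not found: {v}")
        strains.append(StrainConfig(label=str(label), assays=assays))
    return RunConfig(
        strains=strains,
        control_strain=str(_require(raw, "control_strain", str(path))),
        output_dir=Path(raw.get("output_dir", "biofilm_kinetics_out")),
        parameters=raw.get("parameters", {}),
        seed=int(raw.get("seed", 0)),
    )


def _resolve(base: Path, rel: str) -> Path:
    return (base / rel).resolve()


def _run_assay(
    assay: str, rep: dict, base: Path, params: dict
) -> list[tuple[str, float, str]]:
    """Execute one replicate of one assay; returns (metric, value, units) rows."""
    if assay == "expansion":
        stack = io.read_stack(_resolve(base, rep["stack"]))
        fit = fit_expansion(trace_edge(stack, params["min_object_px"]))
        return [("expansion_rate_um_min", fit.rate_um_min, "um/min")]
    if assay == "doubling":
        stack = io.read_stack(_resolve(base, rep["stack"]))
        rois = io.read_rois(_resolve(base, rep["rois"]))
        rows = []
        for roi in rois:
            curve = growth.normalise_curve(growth.roi_mean_curve(stack, roi))
            est = growth.estimate_doubling_time(curve, params["window_frames"])
            rows.append(
                (f"doubling_time_min[{roi.label}]", est.doubling_time_min, "min")
            )
        return rows
    if assay == "divisions":
        table = io.read_pedigree(_resolve(base, rep["pedigree"]))
        dt = float(rep.get("dt_min", params["divisions_dt_min"]))
        records = ped.division_intervals(
            ped.build_pedigrees(table), dt, params["min_generation"]
        )
        iv = np.array([r.interval_min for r in records])
        return [("division_interval_mean_min", float(iv.mean()), "min")]
    if assay == "flow":
        tracks = io.read_tracks(_resolve(base, rep["tracks"]))
        dt = float(rep.get("dt_min", params["flow_dt_min"]))
        px = float(rep.get("pixel_size_um", 890.0 / 1024.0))
        _, pooled = morphometrics.internal_flow_rate(tracks, px, dt)
        return [("internal_flow_um_min", pooled, "um/min")]
    if assay == "footprint":
        image, px = io.read_image(_resolve(base, rep["image"]))
        area = morphometrics.footprint_area(image, px, params["min_object_px"])
        return [("footprint_area_um2", area, "um2")]
    if assay == "thickness":
        early = io.read_stack(_resolve(base, rep["early"]))
        late = io.read_stack(_resolve(base, rep["late"]))
        ratio = morphometrics.thickness_ratio(early, late, params["min_object_px"])
        return [("thickness_ratio", ratio, "fold")]
    raise ValueError(f"unknown assay {assay!r}")


def run_pipeline(
    config: RunConfig, base_dir: str | Path = "."
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Run every configured assay and the control-vs-mutant statistics.

    Returns ``(measurements, comparisons, n_failures)``.  Outputs are
    also written to ``config.output_dir`` as ``measurements.csv``,
    ``comparisons.csv`` and ``pipeline.log``.
    """
    base = Path(base_dir)
    out = base / config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s")
    )
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    rows = []
    failures = 0
    try:
        log.info("run start: %d strains, control=%s, parameters=%s",
                 len(config.strains), config.control_strain, config.parameters)
        for strain in config.strains:
            for assay, reps in strain.assays.items():
                for r_i, rep in enumerate(reps, start=1):
                    try:
                        results = _run_assay(assay, rep, base, config.parameters)
                    except Exception as exc:  # noqa: BLE001 — log & skip, never drop silently
                        failures += 1
                        log.error(
                            "stage=%s strain=%s replicate=%d inputs=%s FAILED: %s",
                            assay, strain.label, r_i, rep, exc,
                        )
                        continue
                    for metric, value, units in results:
                        rows.append(
                            (strain.label, str(r_i), metric, value, units)
                        )
                    log.info(
                        "stage=%s strain=%s replicate=%d inputs=%s n=%d ok",
                        assay, strain.label, r_i, rep, len(results),
                    )
        measurements = io.validate_measurements(
            pd.DataFrame(
                rows, columns=["strain", "replicate", "metric", "value", "units"]
            )
        )
        comparisons = compare_to_control(
            measurements, config.control_strain, config.parameters["alpha"]
        )
        io.write_measurements(measurements, out / "measurements.csv")
        comparisons.to_csv(out / "comparisons.csv", index=False)
        log.info("run done: %d measurement rows, %d comparisons, %d failures",
                 len(measurements), len(comparisons), failures)
    finally:
        log.removeHandler(handler)
        handler.close()
    return measurements, comparisons, failures


def compare_to_control(
    measurements: pd.DataFrame, control: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Dunnett comparisons per metric; metrics without ≥ 2 groups of ≥ 2
    replicates are skipped (nothing to test)."""
    all_results = []
    for metric, sub in measurements.groupby("metric"):
        groups = {
            strain: grp["value"].to_numpy()
            for strain, grp in sub.groupby("strain")
        }
        if control not in groups:
            continue
        groups = {g: v for g, v in groups.items() if len(v) >= 2}
        if control not in groups or len(groups) < 2:
            continue
        all_results.extend(
            dunnett_vs_control(groups, control, alpha=alpha, metric=str(metric))
        )
    return comparisons_frame(all_results)
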