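"""Division pedigrees from z-ring first-appearance annotations.

FtsZ forms a ring at the incipient division plane, so the first
sighting of a new z-ring marks the start of a division cycle.  Each
z-ring is annotated as a point event ``(roi_id, frame, x, y)`` whose
comment carries the parent ROI id ("0" for a pedigree root).  Linking
events through those comments yields a forest of binary pedigrees; the
frame difference between a parent's and a daughter's first appearance,
times the sampling interval, is one single-cell division interval.
Both daughters contribute an interval, so a fully observed node yields
two division events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PedigreeTable, ROOT_ID


@dataclass
class PedigreeNode:
    roi_id: str
    frame: int
    x_px: float
    y_px: float
    generation: int = 0
    children: list["PedigreeNode"] = field(default_factory=list)


@dataclass(frozen=True)
class DivisionRecord:
    """One parent→child edge: a single observed division interval."""

    parent_roi: str
    child_roi: str
    interval_min: float
    generation: int  # depth of the child; root is generation 0


def build_pedigrees(table: PedigreeTable) -> list[PedigreeNode]:
    """Link annotation rows into a forest of pedigree trees.

    Roots are the rows whose ``parent_id`` is the sentinel "0"; every
    other row is attached under its parent.  Node count is preserved and
    generation depth is assigned top-down.
    """
    nodes = {
        r.roi_id: PedigreeNode(r.roi_id, int(r.frame), float(r.x_px), float(r.y_px))
        for r in table.rows.itertuples()
    }
    roots = []
    for r in table.rows.itertuples():
        if r.parent_id == ROOT_ID:
            roots.append(nodes[r.roi_id])
        else:
            nodes[r.parent_id].children.append(nodes[r.roi_id])
    for root in roots:
        stack = [root]
        while stack:
            node = stack.pop()
            for child in node.children:
                child.generation = node.generation + 1
                stack.append(child)
    return roots


def division_intervals(
    forest: list[PedigreeNode], dt_min: float, min_generation: int = 1
) -> list[DivisionRecord]:
    """One record per parent→child edge; interval = Δframe × dt.

    ``min_generation`` filters shallow edges: the default 1 keeps every
    edge, while 2 drops root→daughter intervals (a root's true
    appearance time may precede the start of observation).
    """
    if dt_min <= 0:
        raise ValueError("dt_min must be > 0")
    records = []
    stack = list(forest)
    while stack:
        node = stack.pop()
        for child in node.children:
            if child.generation >= min_generation:
                records.append(
                    DivisionRecord(
                        parent_roi=node.roi_id,
                        child_roi=child.roi_id,
                        interval_min=(child.frame - node.frame) * dt_min,
                        generation=child.generation,
                    )
                )
            stack.append(child)
    return records


def records_frame(records: list[DivisionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parent_roi": r.parent_roi,
                "child_roi": r.child_roi,
                "interval_min": r.interval_min,
                "generation": r.generation,
            }
            for r in records
        ]
    )


def summarise_divisions(
    records: list[DivisionRecord], strain: str, replicate: str = "1"
) -> pd.DataFrame:
    """Mean, sample SD (n−1) and count of the intervals, as tidy rows."""
    if not records:
        raise ValueError("no division records to summarise")
    iv = np.array([r.interval_min for r in records], dtype=float)
    sd = float(iv.std(ddof=1)) if iv.size > 1 else 0.0
    rows = [
        (strain, replicate, "division_interval_mean_min", float(iv.mean()), "min"),
        (strain, replicate, "division_interval_sd_min", sd, "min"),
        (strain, replicate, "division_interval_n", float(iv.size), "count"),
    ]
    return pd.DataFrame(
        rows, columns=["strain", "replicate", "metric", "value", "units"]
    )
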