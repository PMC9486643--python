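"""Control-vs-mutant group comparisons.

Strain panels are compared metric by metric in a one-way ANOVA layout
with Dunnett's many-to-one procedure: every mutant group is tested
against the single control (wild-type) group, with the family-wise
error controlled across those comparisons via the multivariate-t
distribution of the Dunnett statistics.  Significance is assessed on
the adjusted p-values at ``alpha`` (default 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ComparisonResult:
    """One strain-vs-control comparison for one metric."""

    metric: str
    strain: str
    mean_diff: float
    p_adj: float
    significant: bool


def dunnett_vs_control(
    groups: dict[str, np.ndarray],
    control: str,
    alpha: float = 0.05,
    metric: str = "",
) -> list[ComparisonResult]:
    """Dunnett many-to-one comparisons of every group against a control.

    Parameters
    ----------
    groups:
        Mapping of group label to 1D value array; must include
        ``control`` and at least one other group, each with ≥ 2 values.
    control:
        Label of the reference group (absent from the results — every
        row is a comparison *against* it).
    alpha:
        Family-wise significance level on the adjusted p-values.

    Degenerate input in which every value in every group is identical
    has no within-group variance to test against; it is reported as not
    significant (p = 1) with a warning rather than raising, so batch
    runs survive pathological replicates.
    """
    if control not in groups:
        raise ValueError(f"control group {control!r} missing")
    if len(groups) < 2:
        raise ValueError("need the control plus at least one other group")
    for name, vals in groups.items():
        if np.asarray(vals).size < 2:
            raise ValueError(f"group {name!r} has < 2 values")
    others = [g for g in groups if g != control]
    ctrl = np.asarray(groups[control], dtype=float)
    samples = [np.asarray(groups[g], dtype=float) for g in others]

    pooled = np.concatenate([ctrl, *samples])
    if np.ptp(pooled) == 0.0:
        warnings.warn("all groups identical: zero variance, reporting not significant")
        return [
            ComparisonResult(metric, g, 0.0, 1.0, False) for g in others
        ]
    with warnings.catch_warnings():
        # near-identical replicates make the pooled variance vanish;
        # the resulting non-finite statistics are handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.dunnett(*samples, control=ctrl)
    out = []
    for g, sample, p in zip(others, samples, res.pvalue):
        if not np.isfinite(p):
            warnings.warn(
                f"group {g!r}: degenerate variance, reporting not significant"
            )
            p = 1.0
        p = float(min(max(p, 0.0), 1.0))
        out.append(
            ComparisonResult(
                metric=metric,
                strain=g,
                mean_diff=float(sample.mean() - ctrl.mean()),
                p_adj=p,
                significant=p < alpha,
            )
        )
    return out


def comparisons_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metric": r.metric,
                "strain": r.strain,
                "mean_diff": r.mean_diff,
                "p_adj": r.p_adj,
                "significant": r.significant,
            }
            for r in results
        ]
    )
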