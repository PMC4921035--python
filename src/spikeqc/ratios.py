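"""Pairwise-pool Bland-Altman (MA) ratio analysis with expected-ratio curves.

For any two pools the per-control log2 ratio M = log2 S_i - log2 S_j is
plotted against the average log2 signal A = (log2 S_i + log2 S_j)/2 — the
MA-plot form of a Bland-Altman difference plot.  The Latin square design
fixes each control's nominal fold change between the pools, so deviations of
M from log2(fold) measure ratio-detection accuracy.

On hybridisation platforms the fitted Langmuir model predicts the whole
(A, M) trajectory for a given fold change: additive background compresses
ratios toward 0 at low signal and saturation compresses them at high signal,
so target ratios are met only in the interior linear region.  Counting
platforms do not saturate; the expected M is flat at log2(fold) with Poisson
shot noise funnelling the points at low counts.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .design import DesignTable, abundance_profile, pairwise_ratio
from .dose_response import LangmuirFit
from .linearity import LinearRegion
from .signals import SignalTable, collapse_replicates

__all__ = [
    "bland_altman",
    "expected_ratio_curve",
    "rnaseq_expected_ratio",
    "ratio_recovery_summary",
]


def bland_altman(
    signals: SignalTable,
    design: DesignTable,
    pool_i: int,
    pool_j: int,
    log_average: bool = True,
) -> pd.DataFrame:
    """Per-control (A, M) ratio points for one pool pair.

    Only controls with signal in both pools contribute.  ``log_average=True``
    (default) uses the MA convention A = mean of log2 signals; False gives
    the literal Bland-Altman abscissa, log2 of the mean linear signal.
    """
    collapsed = collapse_replicates(signals)
    wide = collapsed.pivot(index="control_id", columns="pool", values="mean_log2")
    if pool_i not in wide.columns or pool_j not in wide.columns:
        missing = [p for p in (pool_i, pool_j) if p not in wide.columns]
        raise ValueError(f"no signal for pool(s) {missing}")
    wide = wide.dropna(subset=[pool_i, pool_j])
    rows = []
    for control_id, row in wide.iterrows():
        if control_id not in design:
            continue
        rec = design.record(control_id)
        if rec.subpool == "omitted":
            continue
        s_i, s_j = float(row[pool_i]), float(row[pool_j])
        m = s_i - s_j
        if log_average:
            a = (s_i + s_j) / 2
        else:
            a = math.log2((2.0**s_i + 2.0**s_j) / 2)
        nominal = float(math.log2(pairwise_ratio(design, rec.subpool, pool_i, pool_j)))
        rows.append(
            {"control_id": control_id, "subpool": rec.subpool,
             "a_value": a, "m_value": m, "nominal_log2_ratio": nominal}
        )
    return pd.DataFrame(
        rows, columns=["control_id", "subpool", "a_value", "m_value", "nominal_log2_ratio"]
    )


def expected_ratio_curve(
    fit: LangmuirFit,
    fold: float,
    log2_c_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Model-derived (A, M) trajectory for a nominal fold change (arrays).

    Traces M(C) = log2 I(f C) - log2 I(C) and A(C) = (log2 I(f C) +
    log2 I(C))/2 parametrically over abundance; returned sorted by A.  M -> 0
    at both extremes (background and saturation compression) and approaches
    log2 f only in the interior.
    """
    if log2_c_grid is None:
        log2_c_grid = np.arange(-8.0, 30.0 + 0.01, 0.01)
    c = np.exp2(np.asarray(log2_c_grid, dtype=float))
    hi = fit.predict_log2(fold * c)
    lo = fit.predict_log2(c)
    frame = pd.DataFrame(
        {"a_value": (hi + lo) / 2, "m_value": hi - lo, "log2_abundance": log2_c_grid}
    )
    return frame.sort_values("a_value", ignore_index=True)


def rnaseq_expected_ratio(fold: float) -> float:
    """Counting platforms do not saturate: expected M is log2(fold) everywhere."""
    return math.log2(fold)


def ratio_recovery_summary(
    points: pd.DataFrame,
    centroids: pd.DataFrame | None = None,
    region: LinearRegion | None = None,
) -> pd.DataFrame:
    """Per-fold ratio recovery, split by linear-region membership.

    For each nominal fold change: the median observed M and the median
    absolute error |M - log2 fold|, separately for controls whose centroid
    abundance lies inside vs outside the region.  With no region (counting
    platforms) all points count as inside.
    """
    pts = points.copy()
    if region is None or centroids is None:
        pts["in_region"] = True
    else:
        abund = centroids.set_index("control_id")["mean_log2_abundance"]
        pts["in_region"] = [
            bool(region.contains(float(abund[c]))) if c in abund.index else False
            for c in pts["control_id"]
        ]
    pts["abs_error"] = (pts["m_value"] - pts["nominal_log2_ratio"]).abs()
    grouped = (
        pts.groupby(["nominal_log2_ratio", "in_region"])
        .agg(
            n=("m_value", "size"),
            median_m=("m_value", "median"),
            median_abs_error=("abs_error", "median"),
        )
        .reset_index()
    )
    return grouped.sort_values(["nominal_log2_ratio", "in_region"], ignore_index=True)
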