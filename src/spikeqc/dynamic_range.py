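"""Dynamic-range coverage summaries.

For each of the four pool samples the minimum and maximum log2 signal over
the detected members of a subset (the spike-in controls, or optionally the
endogenous background transcripts) are taken; the summary reports their mean
± sample SD across the samples.  The range is the difference of the means and
its uncertainty combines the min and max SDs in quadrature:

    range = max_mean - min_mean,   range_sd = sqrt(min_sd^2 + max_sd^2)

On hybridisation platforms the omitted control's signal level is reported
alongside as the effective background floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import OMITTED_CONTROL, DesignTable
from .signals import SignalTable, collapse_replicates

__all__ = ["RangeSummary", "range_summary", "combine_range"]


@dataclass(frozen=True)
class RangeSummary:
    subset: str
    min_mean: float
    min_sd: float
    max_mean: float
    max_sd: float
    range_mean: float
    range_sd: float
    omitted_mean: float | None = None
    omitted_sd: float | None = None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def combine_range(
    min_mean: float, min_sd: float, max_mean: float, max_sd: float
) -> tuple[float, float]:
    """Range of a signal window and its quadrature uncertainty."""
    return max_mean - min_mean, math.sqrt(min_sd**2 + max_sd**2)


def _sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0


def range_summary(
    signals: SignalTable,
    subset: str = "ERCC",
    members: list[str] | None = None,
    design: DesignTable | None = None,
    omitted_id: str = OMITTED_CONTROL,
) -> RangeSummary:
    """Per-sample signal extrema for a subset, summarised across samples.

    ``members`` restricts the rows considered (defaults to the design's
    analysis-set controls when a design is given, else every control in the
    table, excluding the omitted control).  Extrema are taken per pool over
    the controls actually present there (detected-only by construction).
    """
    collapsed = collapse_replicates(signals)
    if members is None:
        if design is not None:
            members = [r.control_id for r in design.records if r.subpool != "omitted"]
        else:
            members = [c for c in collapsed["control_id"].unique() if c != omitted_id]
    rows = collapsed[collapsed["control_id"].isin(members)]
    if rows.empty:
        raise ValueError(f"subset {subset!r} has no signal rows")
    per_pool = rows.groupby("pool")["mean_log2"]
    mins = per_pool.min().to_numpy(dtype=float)
    maxs = per_pool.max().to_numpy(dtype=float)
    range_mean, range_sd = combine_range(
        float(np.mean(mins)), _sd(mins), float(np.mean(maxs)), _sd(maxs)
    )
    omitted_rows = signals.control(omitted_id)
    if signals.platform == "array" and not omitted_rows.empty:
        per_pool_bg = omitted_rows.groupby("pool")["log2_signal"].mean().to_numpy(dtype=float)
        omitted_mean, omitted_sd = float(np.mean(per_pool_bg)), _sd(per_pool_bg)
    else:
        omitted_mean = omitted_sd = None
    return RangeSummary(
        subset=subset,
        min_mean=float(np.mean(mins)), min_sd=_sd(mins),
        max_mean=float(np.mean(maxs)), max_sd=_sd(maxs),
        range_mean=range_mean, range_sd=range_sd,
        omitted_mean=omitted_mean, omitted_sd=omitted_sd,
    )
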