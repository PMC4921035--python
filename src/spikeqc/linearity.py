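"""Per-control linearity assessment and linear-region demarcation.

Each titrated control is measured at four abundances (one per pool), so its
dose-response can be summarised by a log2-log2 least-squares slope (m = 1 is
the ideal proportional response) and by whether its signal is strictly
monotone in the mixing proportions 10 % < 15 % < 25 % < 40 %.  Monotonicity
is screened with Spearman's rho computed by the classical formula

    rho = 1 - 6 * sum(d^2) / (n * (n^2 - 1))

with midranks on ties; any tie therefore gives rho < 1 and counts as
non-monotonic.  The constant 1-to-1 subpool has a single abundance and is not
screened.

For hybridisation platforms the fitted Langmuir model also predicts the slope
at every abundance, m(C) = dlog2 I / dlog2 C; the two inflection points of
this expected-slope curve demarcate the linear region of the dynamic range.
Non-monotonic controls inside the region are flagged as outliers; those below
it only delimit the detection floor and are listed separately.  On counting
platforms there is no saturation model and every non-monotonic control is
flagged.

A control that is non-monotonic because its pools were mixed from the wrong
subpool (the ERCC-00113 pattern) can be diagnosed by re-scoring it under each
candidate subpool's proportion schedule and picking the assignment with the
best rank agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .design import (
    TITRATED_SUBPOOLS,
    DesignTable,
    abundance_profile,
)
from .dose_response import LangmuirFit, LinearFit
from .signals import SignalTable, collapse_replicates

__all__ = [
    "SlopeEstimate",
    "MonotonicityResult",
    "LinearRegion",
    "RegionUndefinedError",
    "SubpoolSuggestion",
    "control_slope",
    "slope_table",
    "spearman_formula",
    "spearman_rho",
    "monotonicity_table",
    "expected_slope",
    "linear_region",
    "flag_nonmonotonic_outliers",
    "best_fit_subpool",
]


@dataclass(frozen=True)
class SlopeEstimate:
    control_id: str
    slope: float | None
    defined: bool


@dataclass(frozen=True)
class MonotonicityResult:
    control_id: str
    rho: float
    monotonic: bool


@dataclass(frozen=True)
class LinearRegion:
    """Log2-abundance bounds of the expected linear response."""

    lower_log2_abundance: float
    upper_log2_abundance: float

    def contains(self, log2_abundance: float) -> bool:
        return self.lower_log2_abundance <= log2_abundance <= self.upper_log2_abundance


class RegionUndefinedError(RuntimeError):
    """The expected-slope curve has no two inflection points (e.g. bg = 0)."""


@dataclass(frozen=True)
class SubpoolSuggestion:
    control_id: str
    original_subpool: str
    suggested_subpool: str
    rho_by_subpool: dict[str, float]
    residual_by_subpool: dict[str, float]
    tie: bool = False


def _pool_means(signals: SignalTable, control_id: str) -> dict[int, float]:
    collapsed = collapse_replicates(signals)
    rows = collapsed[collapsed["control_id"] == control_id]
    return dict(zip(rows["pool"].astype(int), rows["mean_log2"].astype(float)))


def control_slope(
    signals: SignalTable, design: DesignTable, control_id: str
) -> SlopeEstimate:
    """OLS slope of log2 signal vs log2 nominal abundance over the pools.

    Undefined (``defined=False``) for constant-proportion (subpool A)
    controls, which sit at a single abundance.
    """
    rec = design.record(control_id)
    means = _pool_means(signals, control_id)
    abundances = abundance_profile(design, control_id)
    pools = [p for p in design.square.pools if p in means]
    log2_a = np.log2([abundances[p] for p in pools])
    if len(set(log2_a)) < 2:
        return SlopeEstimate(control_id=control_id, slope=None, defined=False)
    log2_s = np.array([means[p] for p in pools])
    slope = float(np.polyfit(log2_a, log2_s, 1)[0])
    return SlopeEstimate(control_id=control_id, slope=slope, defined=True)


def slope_table(signals: SignalTable, design: DesignTable) -> pd.DataFrame:
    rows = []
    for rec in design.records:
        if rec.subpool == "omitted":
            continue
        est = control_slope(signals, design, rec.control_id)
        rows.append(
            {"control_id": rec.control_id, "subpool": rec.subpool,
             "slope": est.slope, "slope_defined": est.defined}
        )
    return pd.DataFrame(rows)


def spearman_formula(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman's rho via 1 - 6*sum(d^2)/(n(n^2-1)), midranks on ties."""
    rx = rankdata(np.asarray(x, dtype=float))
    ry = rankdata(np.asarray(y, dtype=float))
    n = len(rx)
    d2 = float(np.sum((rx - ry) ** 2))
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))


def spearman_rho(
    signals: SignalTable, design: DesignTable, control_id: str
) -> MonotonicityResult:
    """Rank agreement between a titrated control's signal and its proportions.

    Monotone iff rho equals 1 exactly; ties in signal yield rho < 1.
    """
    rec = design.record(control_id)
    if rec.subpool not in TITRATED_SUBPOOLS:
        raise ValueError(
            f"{control_id} is in subpool {rec.subpool!r}; monotonicity is "
            "defined only for titrated (B-E) controls"
        )
    means = _pool_means(signals, control_id)
    pools = [p for p in design.square.pools if p in means]
    props = [design.square.proportion(rec.subpool, p) for p in pools]
    sigs = [means[p] for p in pools]
    rho = spearman_formula(np.array(props), np.array(sigs))
    return MonotonicityResult(control_id=control_id, rho=rho, monotonic=rho == 1.0)


def monotonicity_table(signals: SignalTable, design: DesignTable) -> pd.DataFrame:
    rows = []
    for rec in design.records:
        if rec.subpool not in TITRATED_SUBPOOLS:
            continue
        if len(_pool_means(signals, rec.control_id)) < len(design.square.pools):
            continue  # partial/undetected: not screened
        res = spearman_rho(signals, design, rec.control_id)
        rows.append(
            {"control_id": rec.control_id, "subpool": rec.subpool,
             "rho": res.rho, "monotonic": res.monotonic}
        )
    return pd.DataFrame(rows, columns=["control_id", "subpool", "rho", "monotonic"])


def expected_slope(fit: LangmuirFit, log2_c) -> np.ndarray:
    """Expected log-log slope m(C) = dlog2 I/dlog2 C of the Langmuir model.

    Analytic form: m = (C / I) * I_max * K_d / (K_d + C)^2 with I the model
    intensity; m -> 1 in the proportional regime (bg = 0, C << K_d) and
    m -> 0 in saturation.
    """
    c = np.exp2(np.asarray(log2_c, dtype=float))
    intensity = fit.predict_linear(c)
    return (c / intensity) * fit.i_max * fit.k_d / (fit.k_d + c) ** 2


def _sign_changes(values: np.ndarray) -> list[int]:
    sign = np.sign(values)
    nz = sign != 0
    idx = []
    prev = None
    for i, s in enumerate(sign):
        if s == 0:
            continue
        if prev is not None and s != sign[prev]:
            idx.append(i)
        prev = i
    return idx


def _refine(fit: LangmuirFit, lo: float, hi: float, step: float) -> float:
    grid = np.arange(lo, hi + step, step)
    m = expected_slope(fit, grid)
    d2 = np.diff(m, 2)
    changes = _sign_changes(d2)
    if not changes:
        return (lo + hi) / 2
    i = changes[0]
    return float(grid[i + 1])


def linear_region(
    fit: LangmuirFit,
    design: DesignTable | None = None,
    log2_c_range: tuple[float, float] | None = None,
    coarse_step: float = 0.01,
    fine_step: float = 0.001,
) -> LinearRegion:
    """Demarcate the linear region from the expected-slope curve.

    Scans m(log2 C) on a grid over the design's abundance ladder extended one
    decade on each side, finds the sign changes of its second difference (the
    inflection points), refining each location to ``fine_step``.  With bg = 0
    the low-abundance inflection does not exist and the region is undefined.
    """
    if log2_c_range is None:
        if design is not None:
            values = [
                a
                for rec in design.records
                if rec.subpool != "omitted"
                for a in abundance_profile(design, rec.control_id).values()
            ]
            lo, hi = math.log2(min(values)), math.log2(max(values))
        else:
            lo, hi = 0.0, 22.0
        decade = math.log2(10)
        log2_c_range = (lo - decade, hi + decade)
    grid = np.arange(log2_c_range[0], log2_c_range[1] + coarse_step, coarse_step)
    m = expected_slope(fit, grid)
    d2 = np.diff(m, 2)
    changes = _sign_changes(d2)
    if len(changes) < 2:
        raise RegionUndefinedError(
            f"expected-slope curve has {len(changes)} inflection point(s) on "
            f"log2 C in [{log2_c_range[0]:.2f}, {log2_c_range[1]:.2f}]; "
            "the linear region is undefined (bg = 0 removes the lower bound)"
        )
    lower_i, upper_i = changes[0], changes[-1]
    lower = _refine(fit, grid[lower_i - 1], grid[lower_i + 2], fine_step)
    upper = _refine(fit, grid[upper_i - 1], grid[upper_i + 2], fine_step)
    return LinearRegion(lower_log2_abundance=lower, upper_log2_abundance=upper)


def flag_nonmonotonic_outliers(
    monotonicity: pd.DataFrame,
    centroids: pd.DataFrame,
    region: LinearRegion | None,
    platform: str,
    design: DesignTable | None = None,
    rule: str = "centroid",
) -> pd.DataFrame:
    """Classify non-monotonic controls relative to the linear region.

    Arrays: a rho < 1 control whose abundance lies inside the region is an
    outlier (class ``non_monotonic``); one outside it is listed as
    ``sub_range`` — performance cannot be assessed there beyond delimiting
    the usable range.  RNA-Seq: every rho < 1 control is an outlier.  ``rule``
    places a control by its centroid abundance (default) or by any of its
    four pool abundances ("any-point").
    """
    cent = centroids.set_index("control_id")
    rows = []
    for rec in monotonicity.itertuples(index=False):
        if rec.monotonic:
            cls = "none"
        elif platform == "rnaseq" or region is None:
            cls = "non_monotonic"
        else:
            if rule == "centroid":
                inside = region.contains(float(cent.loc[rec.control_id, "mean_log2_abundance"]))
            elif rule == "any-point":
                if design is None:
                    raise ValueError("any-point rule needs the design table")
                inside = any(
                    region.contains(math.log2(a))
                    for a in abundance_profile(design, rec.control_id).values()
                )
            else:
                raise ValueError(f"unknown region rule {rule!r}")
            cls = "non_monotonic" if inside else "sub_range"
        rows.append({"control_id": rec.control_id, "rho": rec.rho, "outlier_class": cls})
    return pd.DataFrame(rows, columns=["control_id", "rho", "outlier_class"])


def best_fit_subpool(
    signals: SignalTable,
    design: DesignTable,
    control_id: str,
    fit: LangmuirFit | LinearFit | None = None,
) -> SubpoolSuggestion:
    """Diagnose a likely subpool mis-assignment for a non-monotonic control.

    Re-scores the control's four pool signals under each titrated subpool's
    proportion schedule: rank agreement (rho) first, and the sum of squared
    log2 residuals against the platform fit (or, lacking one, against a
    per-candidate unit-slope offset) as tie-breaker.  All-equal signals are
    uninformative: the original assignment is returned with ``tie=True``.
    """
    rec = design.record(control_id)
    means = _pool_means(signals, control_id)
    pools = [p for p in design.square.pools if p in means]
    sigs = np.array([means[p] for p in pools])
    rho_by: dict[str, float] = {}
    res_by: dict[str, float] = {}
    for sub in TITRATED_SUBPOOLS:
        props = np.array([design.square.proportion(sub, p) for p in pools], dtype=float)
        rho_by[sub] = spearman_formula(props, sigs)
        log2_c = np.log2(rec.base_abundance * props / 10.0)
        if fit is not None:
            pred = np.asarray(fit.predict_log2_from_log2(log2_c), dtype=float)
        else:
            offsets = sigs - log2_c
            pred = log2_c + float(np.mean(offsets))
        res_by[sub] = float(np.sum((sigs - pred) ** 2))
    if np.allclose(sigs, sigs[0]):
        return SubpoolSuggestion(
            control_id=control_id, original_subpool=rec.subpool,
            suggested_subpool=rec.subpool, rho_by_subpool=rho_by,
            residual_by_subpool=res_by, tie=True,
        )
    best = max(TITRATED_SUBPOOLS, key=lambda s: (rho_by[s], -res_by[s]))
    best_key = (rho_by[best], -res_by[best])
    tie = sum(1 for s in TITRATED_SUBPOOLS if (rho_by[s], -res_by[s]) == best_key) > 1
    if tie:
        best = rec.subpool if rec.subpool in TITRATED_SUBPOOLS else best
    return SubpoolSuggestion(
        control_id=control_id, original_subpool=rec.subpool,
        suggested_subpool=best, rho_by_subpool=rho_by,
        residual_by_subpool=res_by, tie=tie,
    )
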