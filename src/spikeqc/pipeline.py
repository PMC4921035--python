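"""End-to-end assessment run: design -> signals -> fits -> flags -> report.

The composite testing scheme evaluates three performance characteristics in
one pass: linear performance of individual controls (slope and monotonicity),
signal response of the whole dynamic-range pool (dose-response fit with
outlier flags), and ratio detection between pool pairs (Bland-Altman panels
against model-expected curves), plus the dynamic-range coverage summary.
:func:`run_assessment` orchestrates the modules and optionally writes the
full report bundle as TSV/YAML files; outputs are a pure function of config
and inputs, so reruns are byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import design as design_mod
from .design import DesignTable, apply_exclusions, enumerate_pool_pairs, load_design
from .dose_response import (
    LangmuirFit,
    LinearFit,
    compute_centroids,
    estimate_background,
    estimate_imax,
    fit_langmuir,
    fit_linear_unit_slope,
    flag_response_outliers,
)
from .dynamic_range import RangeSummary, range_summary
from .linearity import (
    LinearRegion,
    RegionUndefinedError,
    flag_nonmonotonic_outliers,
    linear_region,
    monotonicity_table,
    slope_table,
)
from .ratios import bland_altman, ratio_recovery_summary
from .signals import SignalTable, detection_table, read_signals

__all__ = ["RunConfig", "AssessmentResult", "run_assessment", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for context."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class RunConfig:
    """Configuration of one assessment run."""

    platform: str
    signals_path: str | Path | None = None
    signals: SignalTable | None = None
    design_path: str | Path | None = None
    background_path: str | Path | None = None
    rpkm_floor: float = 0.01
    ci_level: float = 0.99
    band: str = "prediction"
    region_rule: str = "centroid"
    drop_non_srm: bool = False
    bg_override: float | None = None
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.platform not in ("array", "rnaseq"):
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.signals is None and self.signals_path is None:
            raise ValueError("either signals or signals_path is required")


@dataclass
class AssessmentResult:
    design: DesignTable
    detection: pd.DataFrame
    centroids: pd.DataFrame
    fit: LangmuirFit | LinearFit
    region: LinearRegion | None
    per_control: pd.DataFrame
    ratio_tables: dict[tuple[int, int], pd.DataFrame]
    ratio_summary: pd.DataFrame
    ranges: list[RangeSummary]
    log: list[str] = field(default_factory=list)

    @property
    def outlier_table(self) -> pd.DataFrame:
        """Outliers grouped by criterion (response-curve / non-monotonic / both)."""
        flagged = self.per_control[
            self.per_control["outlier_class"].isin(
                ["response_curve", "non_monotonic", "both"]
            )
        ]
        cols = ["control_id", "subpool", "log2_base_abundance", "rho", "residual",
                "outlier_class"]
        return flagged[cols].reset_index(drop=True)


def _merge_class(is_response: bool, nonmono_class: str) -> str:
    if is_response and nonmono_class == "non_monotonic":
        return "both"
    if is_response:
        return "response_curve"
    return nonmono_class


def run_assessment(config: RunConfig) -> AssessmentResult:
    """Run the full composite assessment; write the report bundle if asked.

    Stages: design load + exclusions; signal load and detection flags;
    centroid fit (Langmuir for arrays, unit-slope for sequencing) with
    99 % response-curve outlier flags; slope/monotonicity screen with
    linear-region placement; the six pairwise Bland-Altman tables with a
    ratio-recovery summary; and the dynamic-range coverage summary.
    """
    log: list[str] = []

    def stage(name):
        class _Ctx:
            def __enter__(self_inner):
                return None

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, exc) from exc
                return False

        return _Ctx()

    with stage("design"):
        raw_design = load_design(config.design_path)
        design = apply_exclusions(raw_design, drop_non_srm=config.drop_non_srm)
        log.append(
            f"design: {len(raw_design.records)} controls, analysis set "
            f"{len(design.records)} after excluding "
            f"{len(design.excluded)} (antisense/omitted"
            + ("/non-SRM" if config.drop_non_srm else "")
            + ")"
        )
        for rec in design.records:
            orig = raw_design.record(rec.control_id)
            if orig.subpool != rec.subpool:
                log.append(
                    f"design: {rec.control_id} analysed under subpool "
                    f"{rec.subpool} (labelled {orig.subpool})"
                )

    with stage("signals"):
        if config.signals is not None:
            signals = config.signals
        else:
            signals = read_signals(
                config.signals_path, config.platform, rpkm_floor=config.rpkm_floor
            )
        detection = detection_table(signals, design)
        n_det = (detection["status"] == "detected").sum()
        log.append(
            f"signals: {len(signals.data)} rows; detection "
            f"{n_det} detected / {(detection['status'] == 'partial').sum()} partial / "
            f"{(detection['status'] == 'undetected').sum()} undetected"
        )

    with stage("dose_response"):
        centroids = compute_centroids(signals, design)
        if config.platform == "array":
            i_max = estimate_imax(signals, design)
            bg = estimate_background(signals, override=config.bg_override)
            fit = fit_langmuir(centroids, i_max, bg, ci_level=config.ci_level)
            log.append(
                f"fit: Langmuir K_d={fit.k_d:.6g} (I_max={i_max:.6g}, bg={bg:.6g}), "
                f"residual SD {fit.residual_sd:.4f} over {fit.n_centroids} centroids"
            )
        else:
            fit = fit_linear_unit_slope(centroids, ci_level=config.ci_level)
            log.append(
                f"fit: unit-slope intercept {fit.intercept:.4f}, residual SD "
                f"{fit.residual_sd:.4f} over {fit.n_centroids} centroids"
            )
        response = flag_response_outliers(fit, centroids, band=config.band)

    with stage("linearity"):
        region: LinearRegion | None = None
        if config.platform == "array":
            try:
                region = linear_region(fit, design=design)
                log.append(
                    f"linear region: log2 abundance in "
                    f"[{region.lower_log2_abundance:.3f}, {region.upper_log2_abundance:.3f}]"
                )
            except RegionUndefinedError as exc:
                log.append(f"linear region undefined: {exc}")
        slopes = slope_table(signals, design)
        mono = monotonicity_table(signals, design)
        nonmono = flag_nonmonotonic_outliers(
            mono, centroids, region, config.platform,
            design=design, rule=config.region_rule,
        )

    with stage("report_merge"):
        per = detection.merge(
            centroids[["control_id", "mean_log2_abundance", "mean_log2_signal"]],
            on="control_id", how="left",
        )
        per = per.merge(
            response[["control_id", "fitted_log2", "residual", "is_outlier"]],
            on="control_id", how="left",
        )
        per = per.merge(slopes[["control_id", "slope"]], on="control_id", how="left")
        per = per.merge(mono[["control_id", "rho", "monotonic"]], on="control_id", how="left")
        per = per.merge(
            nonmono[["control_id", "outlier_class"]].rename(
                columns={"outlier_class": "nonmono_class"}
            ),
            on="control_id", how="left",
        )
        per["log2_base_abundance"] = [
            math.log2(design.record(c).base_abundance)
            if design.record(c).base_abundance > 0 else float("nan")
            for c in per["control_id"]
        ]
        if region is not None:
            per["in_linear_region"] = [
                region.contains(a) if pd.notna(a) else False
                for a in per["mean_log2_abundance"]
            ]
        else:
            per["in_linear_region"] = pd.NA
        per["outlier_class"] = [
            _merge_class(bool(o) if pd.notna(o) else False,
                         n if isinstance(n, str) else "none")
            for o, n in zip(per["is_outlier"], per["nonmono_class"])
        ]
        per = per.drop(columns=["nonmono_class"])

    with stage("ratios"):
        ratio_tables: dict[tuple[int, int], pd.DataFrame] = {}
        for pool_i, pool_j, _folds in enumerate_pool_pairs(design):
            ratio_tables[(pool_i, pool_j)] = bland_altman(signals, design, pool_i, pool_j)
        all_points = pd.concat(ratio_tables.values(), ignore_index=True)
        ratio_summary = ratio_recovery_summary(all_points, centroids, region)

    with stage("dynamic_range"):
        ranges = [range_summary(signals, subset="ERCC", design=design)]
        if config.background_path is not None:
            bkgd_signals = read_signals(
                config.background_path, config.platform, rpkm_floor=config.rpkm_floor
            )
            members = list(bkgd_signals.data["control_id"].unique())
            ranges.append(
                range_summary(bkgd_signals, subset="background", members=members)
            )

    result = AssessmentResult(
        design=design, detection=detection, centroids=centroids, fit=fit,
        region=region, per_control=per, ratio_tables=ratio_tables,
        ratio_summary=ratio_summary, ranges=ranges, log=log,
    )
    if config.outdir is not None:
        _write_bundle(result, config)
    return result


def _fit_sidecar(result: AssessmentResult, config: RunConfig) -> dict:
    fit = result.fit
    if isinstance(fit, LangmuirFit):
        payload = {
            "model": "langmuir",
            "i_max": fit.i_max, "k_d": fit.k_d, "bg": fit.bg,
        }
    else:
        payload = {"model": "unit_slope_linear", "intercept": fit.intercept, "slope": fit.slope}
    payload.update(
        {
            "residual_sd": fit.residual_sd,
            "n_centroids": fit.n_centroids,
            "ci_level": fit.ci_level,
            "band": config.band,
            "linear_region": (
                None
                if result.region is None
                else {
                    "lower_log2_abundance": result.region.lower_log2_abundance,
                    "upper_log2_abundance": result.region.upper_log2_abundance,
                }
            ),
        }
    )
    return payload


def _write_bundle(result: AssessmentResult, config: RunConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        def emit(frame: pd.DataFrame, name: str) -> None:
            path = outdir / name
            frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
            written.append(path)

        emit(result.per_control, "per_control.tsv")
        emit(result.outlier_table, "outliers.tsv")
        emit(result.ratio_summary, "ratio_summary.tsv")
        for (pool_i, pool_j), frame in result.ratio_tables.items():
            emit(frame, f"ratios_{pool_i}_vs_{pool_j}.tsv")
        ranges_frame = pd.concat([r.frame() for r in result.ranges], ignore_index=True)
        emit(ranges_frame, "range_summary.tsv")
        sidecar = outdir / "fit.yaml"
        sidecar.write_text(yaml.safe_dump(_fit_sidecar(result, config), sort_keys=True))
        written.append(sidecar)
        log_path = outdir / "assessment.log"
        log_path.write_text("\n".join(result.log) + "\n")
        written.append(log_path)
    except BaseException:
        for path in written:
            path.unlink(missing_ok=True)
        raise
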