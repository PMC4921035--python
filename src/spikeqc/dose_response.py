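"""Dose-response model fitting and response-curve outlier flagging.

Each detected control is collapsed to a centroid: the average over the four
pools of its log2 nominal abundance and of its log2 signal.  The centroid
cloud is then fit with the platform-appropriate model:

* hybridisation arrays — the Langmuir isotherm

      I = I_max * C / (K_d + C) + bg

  where ``I_max`` (saturation intensity) is anchored experimentally to the
  average linear signal of the most abundant control in each pool, ``bg``
  (additive background) to the average signal of the omitted control
  ERCC-00073, and only the dissociation constant ``K_d`` is fit, by least
  squares on log2 residuals;

* RNA-Seq — a unit-slope line in log2-log2 space with a fitted intercept
  (counting has no saturation, and signal is proportional to abundance).

Controls whose centroid falls outside a 99 % interval around the fitted curve
are flagged as response-curve outliers.  The interval is a residual band,
Student-t at the chosen level with df = n - 1 times the residual SD
(prediction-style by default; a narrower mean-curve band is available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import OMITTED_CONTROL, DesignTable, abundance_profile
from .signals import SignalTable, collapse_replicates, detection_status

__all__ = [
    "LangmuirFit",
    "LinearFit",
    "FitError",
    "compute_centroids",
    "estimate_imax",
    "estimate_background",
    "fit_langmuir",
    "fit_linear_unit_slope",
    "flag_response_outliers",
    "langmuir_intensity",
]


class FitError(RuntimeError):
    """Raised when an anchor or model fit cannot be computed."""


def langmuir_intensity(
    c: np.ndarray | float, i_max: float, k_d: float, bg: float
) -> np.ndarray | float:
    """Langmuir isotherm intensity at relative abundance ``c`` (linear scale)."""
    c = np.asarray(c, dtype=float)
    out = i_max * c / (k_d + c) + bg
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class LangmuirFit:
    """Fitted saturation model for a hybridisation platform."""

    i_max: float
    k_d: float
    bg: float
    residual_sd: float
    n_centroids: int
    ci_level: float = 0.99

    def predict_linear(self, c):
        return langmuir_intensity(c, self.i_max, self.k_d, self.bg)

    def predict_log2(self, c):
        return np.log2(self.predict_linear(c))

    def predict_log2_from_log2(self, log2_c):
        return self.predict_log2(np.exp2(np.asarray(log2_c, dtype=float)))


@dataclass(frozen=True)
class LinearFit:
    """Unit-slope log2 fit for a counting (RNA-Seq) platform."""

    intercept: float
    residual_sd: float
    n_centroids: int
    ci_level: float = 0.99
    slope: float = 1.0

    def predict_log2_from_log2(self, log2_c):
        return np.asarray(log2_c, dtype=float) * self.slope + self.intercept


def compute_centroids(signals: SignalTable, design: DesignTable) -> pd.DataFrame:
    """Centroid (mean log2 abundance, mean log2 signal) per detected control.

    ``design`` should already be the analysis set (exclusions applied);
    partially detected and undetected controls yield no centroid.
    """
    collapsed = collapse_replicates(signals).set_index(["control_id", "pool"])
    pools = design.square.pools
    rows = []
    for rec in design.records:
        if detection_status(signals, rec.control_id, pools).status != "detected":
            continue
        abundances = abundance_profile(design, rec.control_id)
        log2_a = np.log2([abundances[p] for p in pools])
        log2_s = [collapsed.loc[(rec.control_id, p), "mean_log2"] for p in pools]
        rows.append(
            {
                "control_id": rec.control_id,
                "subpool": rec.subpool,
                "mean_log2_abundance": float(np.mean(log2_a)),
                "mean_log2_signal": float(np.mean(log2_s)),
            }
        )
    return pd.DataFrame(rows, columns=["control_id", "subpool", "mean_log2_abundance", "mean_log2_signal"])


def estimate_imax(
    signals: SignalTable, design: DesignTable, space: str = "linear"
) -> float:
    """Saturation anchor: per pool, take the detected control with the highest
    nominal abundance, convert its mean log2 signal to linear intensity, and
    average the four values (in linear space by default)."""
    collapsed = collapse_replicates(signals).set_index(["control_id", "pool"])
    pools = design.square.pools
    tops = []
    for pool in pools:
        candidates = [
            (abundance_profile(design, rec.control_id)[pool], rec.control_id)
            for rec in design.records
            if rec.subpool != "omitted"
            and detection_status(signals, rec.control_id, pools).status == "detected"
        ]
        if not candidates:
            raise FitError(f"pool {pool}: no detected control to anchor I_max")
        _, top_id = max(candidates)
        tops.append(float(collapsed.loc[(top_id, pool), "mean_log2"]))
    if space == "linear":
        return float(np.mean(np.exp2(tops)))
    if space == "log":
        return float(np.exp2(np.mean(tops)))
    raise ValueError(f"unknown averaging space {space!r}")


def estimate_background(
    signals: SignalTable,
    omitted_id: str = OMITTED_CONTROL,
    override: float | None = None,
    space: str = "linear",
) -> float:
    """Background anchor from the omitted control's signal (arrays).

    RNA-Seq has no additive background term: returns 0 (undetected handling
    plays that role instead).  ``override`` short-circuits estimation.
    """
    if override is not None:
        return float(override)
    if signals.platform == "rnaseq":
        return 0.0
    rows = signals.control(omitted_id)
    if rows.empty:
        raise FitError(
            f"no {omitted_id} rows to anchor the background; "
            "pass an explicit background override"
        )
    log2_vals = rows["log2_signal"].to_numpy(dtype=float)
    if space == "linear":
        return float(np.mean(np.exp2(log2_vals)))
    if space == "log":
        return float(np.exp2(np.mean(log2_vals)))
    raise ValueError(f"unknown averaging space {space!r}")


def _langmuir_sse(log10_kd: float, log2_a: np.ndarray, log2_s: np.ndarray,
                  i_max: float, bg: float) -> float:
    pred = np.log2(langmuir_intensity(np.exp2(log2_a), i_max, 10.0**log10_kd, bg))
    return float(np.sum((log2_s - pred) ** 2))


def fit_langmuir(
    centroids: pd.DataFrame,
    i_max: float,
    bg: float,
    ci_level: float = 0.99,
    log10_kd_bounds: tuple[float, float] = (-4.0, 10.0),
) -> LangmuirFit:
    """Fit K_d of the Langmuir isotherm with I_max and bg held at their anchors.

    Minimises the sum of squared log2 residuals over centroids; the residual
    SD uses df = n - 1 (one fitted parameter).
    """
    if len(centroids) < 3:
        raise FitError("need at least 3 centroids to fit the isotherm")
    log2_a = centroids["mean_log2_abundance"].to_numpy(dtype=float)
    log2_s = centroids["mean_log2_signal"].to_numpy(dtype=float)
    result = optimize.minimize_scalar(
        _langmuir_sse,
        bounds=log10_kd_bounds,
        args=(log2_a, log2_s, i_max, bg),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if not result.success:
        raise FitError(
            f"K_d optimisation failed over log10 K_d in {log10_kd_bounds}: {result.message}"
        )
    k_d = 10.0 ** float(result.x)
    sse = float(result.fun)
    residual_sd = math.sqrt(sse / (len(centroids) - 1))
    return LangmuirFit(
        i_max=float(i_max), k_d=k_d, bg=float(bg),
        residual_sd=residual_sd, n_centroids=len(centroids), ci_level=ci_level,
    )


def fit_linear_unit_slope(centroids: pd.DataFrame, ci_level: float = 0.99) -> LinearFit:
    """Unit-slope fit: intercept is the mean log2 signal-to-abundance offset."""
    if len(centroids) < 2:
        raise FitError("need at least 2 centroids for the unit-slope fit")
    offsets = (
        centroids["mean_log2_signal"] - centroids["mean_log2_abundance"]
    ).to_numpy(dtype=float)
    intercept = float(np.mean(offsets))
    residual_sd = float(
        math.sqrt(np.sum((offsets - intercept) ** 2) / (len(offsets) - 1))
    )
    return LinearFit(
        intercept=intercept, residual_sd=residual_sd,
        n_centroids=len(centroids), ci_level=ci_level,
    )


def outlier_threshold(fit: LangmuirFit | LinearFit, band: str = "prediction") -> float:
    """Half-width of the residual interval used for outlier flagging."""
    df = fit.n_centroids - 1
    t_crit = float(stats.t.ppf(0.5 + fit.ci_level / 2, df))
    width = t_crit * fit.residual_sd
    if band == "prediction":
        return width
    if band == "mean":
        return width / math.sqrt(fit.n_centroids)
    raise ValueError(f"unknown band {band!r}")


def flag_response_outliers(
    fit: LangmuirFit | LinearFit,
    centroids: pd.DataFrame,
    band: str = "prediction",
) -> pd.DataFrame:
    """Flag centroids outside the fit's 99 % interval.

    Returns one row per centroid: control_id, fitted_log2, residual (signed,
    log2 units) and is_outlier.
    """
    fitted = fit.predict_log2_from_log2(
        centroids["mean_log2_abundance"].to_numpy(dtype=float)
    )
    residual = centroids["mean_log2_signal"].to_numpy(dtype=float) - fitted
    half_width = outlier_threshold(fit, band=band)
    return pd.DataFrame(
        {
            "control_id": centroids["control_id"].to_numpy(),
            "fitted_log2": fitted,
            "residual": residual,
            "is_outlier": np.abs(residual) > half_width,
        }
    )
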