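"""Centroids, anchors, Langmuir and unit-slope fits, response outliers."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikeqc import ArraySimConfig, AnomalySpec, simulate_microarray
from spikeqc.design import abundance_profile
from spikeqc.dose_response import (
    FitError,
    compute_centroids,
    estimate_background,
    estimate_imax,
    fit_langmuir,
    fit_linear_unit_slope,
    flag_response_outliers,
    langmuir_intensity,
)
from spikeqc.signals import SignalTable


def _table(rows, platform="array"):
    frame = pd.DataFrame(rows, columns=["control_id", "pool", "replicate", "log2_signal"])
    return SignalTable(data=frame, platform=platform)


def _identity_signals(analysis_design):
    """Signals exactly equal to log2 nominal abundance."""
    rows = []
    for rec in analysis_design.records:
        for pool, a in abundance_profile(analysis_design, rec.control_id).items():
            rows.append((rec.control_id, pool, 1, math.log2(a)))
    return _table(rows)


def grid_search_kd(centroids, i_max, bg, lo=-2.0, hi=8.0, step=0.001):
    """Independent dense grid-search oracle for the dissociation constant."""
    log2_a = centroids["mean_log2_abundance"].to_numpy()
    log2_s = centroids["mean_log2_signal"].to_numpy()
    grid = np.arange(lo, hi + step, step)
    kd = 10.0 ** grid[:, None]
    pred = np.log2(i_max * np.exp2(log2_a)[None, :] / (kd + np.exp2(log2_a)[None, :]) + bg)
    sse = ((log2_s[None, :] - pred) ** 2).sum(axis=1)
    return 10.0 ** grid[int(np.argmin(sse))]


class TestCentroids:
    def test_titrated_centroid_hand_value(self, analysis_design, noiseless_array_signals):
        control = next(
            r.control_id for r in analysis_design.records
            if r.subpool == "B" and r.base_abundance == 16
        )
        cent = compute_centroids(noiseless_array_signals, analysis_design)
        row = cent[cent["control_id"] == control].iloc[0]
        expected = (4 + math.log2(24) + math.log2(40) + 6) / 4
        assert row["mean_log2_abundance"] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(4.977, abs=5e-4)

    def test_constant_subpool_centroid_is_exact(self, analysis_design, noiseless_array_signals):
        control = next(
            r.control_id for r in analysis_design.records
            if r.subpool == "A" and r.base_abundance == 1024
        )
        cent = compute_centroids(noiseless_array_signals, analysis_design)
        row = cent[cent["control_id"] == control].iloc[0]
        assert row["mean_log2_abundance"] == 10.0

    def test_identity_signals_lie_on_identity_line(self, analysis_design, design):
        cent = compute_centroids(_identity_signals(analysis_design), analysis_design)
        assert np.allclose(cent["mean_log2_signal"], cent["mean_log2_abundance"])

    def test_only_detected_controls(self, analysis_design, noiseless_array_signals):
        dropped = noiseless_array_signals.data[
            noiseless_array_signals.data["control_id"] != "ERCC-00002"
        ]
        partial = dropped[
            ~((dropped["control_id"] == "ERCC-00013") & (dropped["pool"] == 12))
        ]
        table = SignalTable(data=partial.reset_index(drop=True), platform="array")
        cent = compute_centroids(table, analysis_design)
        assert "ERCC-00002" not in set(cent["control_id"])
        assert "ERCC-00013" not in set(cent["control_id"])


class TestAnchors:
    def test_imax_all_equal_tops(self, analysis_design):
        rows = []
        for rec in analysis_design.records:
            for pool in (12, 13, 14, 15):
                log2_a = math.log2(abundance_profile(analysis_design, rec.control_id)[pool])
                rows.append((rec.control_id, pool, 1, 14.0 if log2_a > 20 else log2_a))
        # the most abundant control per pool carries log2 signal 14
        table = _table(rows)
        assert estimate_imax(table, analysis_design) == pytest.approx(2**14)

    def test_imax_linear_average(self, analysis_design):
        # top-of-ladder controls at log2 {14, 14, 15, 15} across the four pools
        tops = {12: 14.0, 13: 14.0, 14: 15.0, 15: 15.0}
        rows = []
        for rec in analysis_design.records:
            profile = abundance_profile(analysis_design, rec.control_id)
            for pool, a in profile.items():
                is_top = a == max(
                    abundance_profile(analysis_design, r.control_id)[pool]
                    for r in analysis_design.records
                )
                rows.append((rec.control_id, pool, 1, tops[pool] if is_top else 5.0))
        assert estimate_imax(_table(rows), analysis_design) == pytest.approx(24576.0)

    def test_imax_anchor_reaches_deep_saturation(self, design, analysis_design):
        config = ArraySimConfig(noise_sd=0.0, seed=0)
        signals = simulate_microarray(design, config, AnomalySpec())
        anchor = estimate_imax(signals, analysis_design)
        # deep-saturation intensity at the top of the ladder, within 1 %
        assert anchor == pytest.approx(config.i_max + config.bg, rel=0.01)
        assert anchor <= config.i_max + config.bg

    def test_background_from_omitted_control(self):
        rows = [("ERCC-00073", p, 1, 5.81) for p in (12, 13, 14, 15)]
        assert estimate_background(_table(rows)) == pytest.approx(2**5.81)

    def test_background_zero_for_rnaseq(self):
        assert estimate_background(_table([], platform="rnaseq")) == 0.0

    def test_background_override(self):
        assert estimate_background(_table([]), override=0.0) == 0.0

    def test_background_missing_rows_instructs_override(self):
        with pytest.raises(FitError, match="override"):
            estimate_background(_table([("X", 12, 1, 5.0)]))


class TestLangmuirFit:
    def test_noiseless_recovery_with_true_anchors(self, design, analysis_design):
        """K_d is recovered to 0.1 % on noiseless data.  Titrated centroids
        carry a small curvature (Jensen) gap — the mean of log2 I over four
        abundances is not log2 I at their geometric mean — so the residual SD
        is small but not zero; single-abundance (subpool A) centroids sit on
        the curve exactly."""
        config = ArraySimConfig(noise_sd=0.0, seed=0)
        signals = simulate_microarray(design, config, AnomalySpec())
        cent = compute_centroids(signals, analysis_design)
        fit = fit_langmuir(cent, config.i_max, config.bg)
        assert fit.k_d == pytest.approx(config.k_d, rel=1e-3)
        assert fit.residual_sd < 0.05
        cent_a = cent[cent["subpool"] == "A"]
        fit_a = fit_langmuir(cent_a, config.i_max, config.bg)
        assert fit_a.k_d == pytest.approx(config.k_d, rel=1e-6)
        assert fit_a.residual_sd == pytest.approx(0.0, abs=1e-6)

    def test_noiseless_recovery_with_estimated_anchors(self, design, analysis_design):
        """Anchoring I_max at the deep-saturation signal (which includes bg)
        costs well under 1 % in the recovered dissociation constant."""
        config = ArraySimConfig(noise_sd=0.0, seed=0)
        signals = simulate_microarray(design, config, AnomalySpec())
        cent = compute_centroids(signals, analysis_design)
        fit = fit_langmuir(cent, estimate_imax(signals, analysis_design),
                           estimate_background(signals))
        assert fit.k_d == pytest.approx(config.k_d, rel=0.01)
        assert fit.residual_sd < 0.05

    def test_matches_grid_oracle(self, design, analysis_design):
        signals = simulate_microarray(design, ArraySimConfig(seed=11), AnomalySpec())
        cent = compute_centroids(signals, analysis_design)
        i_max = estimate_imax(signals, analysis_design)
        bg = estimate_background(signals)
        fit = fit_langmuir(cent, i_max, bg)
        oracle = grid_search_kd(cent, i_max, bg)
        assert abs(math.log10(fit.k_d) - math.log10(oracle)) <= 0.001

    def test_midpoint_and_saturation_limits(self):
        i_max, k_d = 2**14, 1e4
        assert langmuir_intensity(k_d, i_max, k_d, 0.0) == pytest.approx(i_max / 2)
        assert langmuir_intensity(1e12, i_max, k_d, 5.0) == pytest.approx(i_max + 5.0, rel=1e-6)

    def test_fitted_curve_monotone_on_ladder(self, design, analysis_design):
        signals = simulate_microarray(design, ArraySimConfig(seed=3), AnomalySpec())
        cent = compute_centroids(signals, analysis_design)
        fit = fit_langmuir(cent, estimate_imax(signals, analysis_design),
                           estimate_background(signals))
        ladder = np.exp2(np.arange(0.0, 22.0, 0.25))
        values = fit.predict_log2(ladder)
        assert np.all(np.diff(values) > 0)

    def test_noisy_recovery_within_ten_percent(self, design, analysis_design):
        errors = []
        for seed in range(20):
            signals = simulate_microarray(design, ArraySimConfig(seed=seed), AnomalySpec())
            cent = compute_centroids(signals, analysis_design)
            fit = fit_langmuir(cent, estimate_imax(signals, analysis_design),
                               estimate_background(signals))
            errors.append(abs(fit.k_d - 1e4) / 1e4)
        assert np.median(errors) < 0.10

    def test_too_few_centroids_raises(self):
        cent = pd.DataFrame(
            {"control_id": ["X"], "mean_log2_abundance": [5.0], "mean_log2_signal": [5.0]}
        )
        with pytest.raises(FitError):
            fit_langmuir(cent, 2**14, 32.0)


class TestUnitSlopeFit:
    @staticmethod
    def _centroids(abund, signal):
        return pd.DataFrame(
            {"control_id": [f"C{i}" for i in range(len(abund))],
             "mean_log2_abundance": abund, "mean_log2_signal": signal}
        )

    def test_perfect_offset(self):
        abund = np.arange(0.0, 10.0)
        fit = fit_linear_unit_slope(self._centroids(abund, abund + 3.0))
        assert fit.intercept == pytest.approx(3.0)
        assert fit.residual_sd == pytest.approx(0.0)

    def test_two_point_residual_sd(self):
        fit = fit_linear_unit_slope(self._centroids([4.0, 8.0], [5.0, 7.0]))
        assert fit.intercept == pytest.approx(0.0)
        assert fit.residual_sd == pytest.approx(math.sqrt(2))

    @given(shift=st.floats(-20, 20, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_translation_equivariance(self, shift):
        abund = np.linspace(0, 20, 11)
        rng = np.random.default_rng(0)
        signal = abund + rng.normal(0, 0.3, size=abund.size)
        base = fit_linear_unit_slope(self._centroids(abund, signal))
        shifted = fit_linear_unit_slope(self._centroids(abund, signal + shift))
        assert shifted.intercept == pytest.approx(base.intercept + shift, abs=1e-9)
        assert shifted.residual_sd == pytest.approx(base.residual_sd, abs=1e-9)

    def test_equals_closed_form_mean_offset(self):
        rng = np.random.default_rng(1)
        abund = np.linspace(-5, 15, 40)
        signal = abund - 3.8 + rng.normal(0, 0.2, size=abund.size)
        fit = fit_linear_unit_slope(self._centroids(abund, signal))
        assert fit.intercept == np.mean(signal - abund)


class TestOutlierFlags:
    def test_no_outliers_when_residuals_zero(self, design, analysis_design):
        signals = simulate_microarray(design, ArraySimConfig(noise_sd=0.0, seed=0), AnomalySpec())
        cent = compute_centroids(signals, analysis_design)
        fit = fit_langmuir(cent, estimate_imax(signals, analysis_design),
                           estimate_background(signals))
        flags = flag_response_outliers(fit, cent)
        assert not flags["is_outlier"].any()

    def test_single_offset_control_flagged(self, design, analysis_design):
        offset_id = "ERCC-00051"  # mid-ladder subpool C control
        signals = simulate_microarray(
            design, ArraySimConfig(seed=5),
            AnomalySpec(offset_controls={offset_id: 2.0}),
        )
        cent = compute_centroids(signals, analysis_design)
        fit = fit_langmuir(cent, estimate_imax(signals, analysis_design),
                           estimate_background(signals))
        flags = flag_response_outliers(fit, cent)
        flagged = set(flags.loc[flags["is_outlier"], "control_id"])
        assert flagged == {offset_id}

    def test_mean_band_narrower_than_prediction(self, design, analysis_design):
        signals = simulate_microarray(design, ArraySimConfig(seed=2), AnomalySpec())
        cent = compute_centroids(signals, analysis_design)
        fit = fit_langmuir(cent, estimate_imax(signals, analysis_design),
                           estimate_background(signals))
        pred = flag_response_outliers(fit, cent, band="prediction")
        mean = flag_response_outliers(fit, cent, band="mean")
        assert mean["is_outlier"].sum() >= pred["is_outlier"].sum()
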