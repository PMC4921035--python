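"""Synthetic signal-table generator for the Latin square spike-in design.

Emulates the statistical structure of the two platform families so the whole
assessment pipeline is testable without any platform download:

* hybridisation arrays — signals follow the Langmuir isotherm
  I = I_max C/(K_d + C) + bg over the nominal abundance ladder, with
  additive Gaussian noise on the log2 scale (multiplicative in intensity).
  The omitted control and the seven antisense controls (which cannot
  hybridise sense-strand probes) emit background-level signal;

* RNA-Seq — per-control read counts are Poisson with mean proportional to
  depth x molar abundance x transcript length, normalised within each pool;
  counts are reported as RPKM with a reporting floor (default 0.01) below
  which a value is missing, so the lowest ladder rungs come out partially
  detected or undetected at realistic depths.  Antisense controls yield no
  reads against a sense-strand reference.

An :class:`AnomalySpec` injects the failure modes the assessment is meant to
catch: a control mixed from the wrong subpool (the ERCC-00113 pattern),
forced dropouts, and per-control log2 signal offsets mimicking concentration
errors.  Every table is a deterministic function of the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import DesignTable
from .signals import SignalTable

__all__ = [
    "ArraySimConfig",
    "RnaseqSimConfig",
    "AnomalySpec",
    "study_anomalies",
    "default_lengths",
    "simulate_microarray",
    "simulate_rnaseq",
]


@dataclass(frozen=True)
class ArraySimConfig:
    """Langmuir forward-model parameters for a simulated hybridisation run.

    Defaults put the dissociation constant mid-ladder (K_d = 10^4), a 14-bit
    saturation intensity and a background floor of 2^5, with 0.1 log2-units
    of multiplicative noise — a spread comparable to the platforms the
    design was built to exercise.  ``spike_fraction`` (percent wt/wt of
    spike-in pool per total RNA, 0.3 by default) is carried as metadata; it
    rescales effective concentration uniformly and is absorbed by K_d.
    """

    k_d: float = 1.0e4
    i_max: float = 2.0**14
    bg: float = 2.0**5
    noise_sd: float = 0.1
    spike_fraction: float = 0.3
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_d <= 0 or self.i_max <= 0 or self.bg < 0 or self.noise_sd < 0:
            raise ValueError("k_d, i_max must be positive; bg, noise_sd non-negative")


@dataclass(frozen=True)
class RnaseqSimConfig:
    """Poisson counting parameters for a simulated sequencing run.

    ``depth`` is the expected number of spike-in-aligned reads per sample
    (default 10^6, the order implied by a ~0.3 % wt/wt spike into a
    tens-of-millions-read library).  ``lengths`` maps control to transcript
    length in nt; when omitted a deterministic spread over 250-2000 nt
    (typical of the control catalogue) is used.
    """

    depth: float = 1.0e6
    lengths: Mapping[str, int] | None = None
    floor: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0 or self.floor < 0:
            raise ValueError("depth must be positive and floor non-negative")


@dataclass(frozen=True)
class AnomalySpec:
    """Failure modes injected into a simulated run."""

    misassigned: Mapping[str, str] = field(default_factory=dict)
    dropouts: Sequence[str] = ()
    offset_controls: Mapping[str, float] = field(default_factory=dict)

    def validate(self, design: DesignTable) -> None:
        for cid in [*self.misassigned, *self.dropouts, *self.offset_controls]:
            if cid not in design:
                raise ValueError(f"anomaly targets unknown control {cid!r}")


def study_anomalies() -> AnomalySpec:
    """The anomaly observed in the original pool preparation: ERCC-00113 was
    labelled subpool E but behaved as a member of subpool C."""
    return AnomalySpec(misassigned={"ERCC-00113": "C"})


def default_lengths(design: DesignTable) -> dict[str, int]:
    """Deterministic per-control transcript lengths spread over 250-2000 nt."""
    ids = sorted(design.control_ids)
    return {cid: 250 + (i * 97) % 1751 for i, cid in enumerate(ids)}


def _true_subpool(rec, anomalies: AnomalySpec) -> str:
    # As-prepared membership: an explicit anomaly wins; otherwise a control
    # with a known reassignment (ERCC-00113) really sits in that subpool.
    if rec.control_id in anomalies.misassigned:
        return anomalies.misassigned[rec.control_id]
    return rec.reassigned_subpool or rec.subpool


def simulate_microarray(
    design: DesignTable,
    config: ArraySimConfig | None = None,
    anomalies: AnomalySpec | None = None,
) -> SignalTable:
    """Simulate a four-pool hybridisation signal table from the design."""
    config = config or ArraySimConfig()
    anomalies = anomalies or AnomalySpec()
    anomalies.validate(design)
    rng = np.random.default_rng(config.seed)
    pools = design.square.pools
    rows = []
    for rec in design.records:
        if rec.control_id in anomalies.dropouts:
            continue
        offset = float(anomalies.offset_controls.get(rec.control_id, 0.0))
        for pool in pools:
            if rec.subpool == "omitted" or rec.antisense:
                mean_log2 = np.log2(config.bg)
            else:
                sub = _true_subpool(rec, anomalies)
                c = rec.base_abundance * design.square.proportion(sub, pool) / 10.0
                intensity = config.i_max * c / (config.k_d + c) + config.bg
                mean_log2 = np.log2(intensity) + offset
            for rep in range(1, config.n_replicates + 1):
                noise = rng.normal(0.0, config.noise_sd) if config.noise_sd else 0.0
                rows.append(
                    {"control_id": rec.control_id, "pool": pool,
                     "replicate": rep, "log2_signal": float(mean_log2 + noise)}
                )
    frame = pd.DataFrame(rows, columns=["control_id", "pool", "replicate", "log2_signal"])
    return SignalTable(data=frame, platform="array", spike_fraction=config.spike_fraction)


def simulate_rnaseq(
    design: DesignTable,
    config: RnaseqSimConfig | None = None,
    anomalies: AnomalySpec | None = None,
) -> SignalTable:
    """Simulate a four-pool RPKM signal table with Poisson shot noise.

    Controls whose RPKM falls at or below the reporting floor in a pool are
    absent from that pool; all-zero controls come out undetected, exercising
    the detection-status logic downstream.
    """
    config = config or RnaseqSimConfig()
    anomalies = anomalies or AnomalySpec()
    anomalies.validate(design)
    lengths = dict(config.lengths) if config.lengths else default_lengths(design)
    rng = np.random.default_rng(config.seed)
    pools = design.square.pools
    spiked = [
        rec for rec in design.records
        if rec.subpool != "omitted"
        and not rec.antisense
        and rec.control_id not in anomalies.dropouts
    ]
    def pool_weights(pool):
        return np.array(
            [
                rec.base_abundance
                * design.square.proportion(_true_subpool(rec, anomalies), pool)
                / 10.0
                * lengths[rec.control_id]
                * 2.0 ** float(anomalies.offset_controls.get(rec.control_id, 0.0))
                for rec in spiked
            ]
        )

    # Normalise by the cross-pool mean total: the sequenced library is
    # dominated by the constant background, so the read scale per unit of
    # spike mass is the same in every sample and pool-to-pool composition
    # differences show up as slightly different spike read totals.
    mean_total = np.mean([pool_weights(p).sum() for p in pools])
    rows = []
    for pool in pools:
        lam = config.depth * pool_weights(pool) / mean_total
        counts = rng.poisson(lam)
        for rec, count in zip(spiked, counts):
            if count == 0:
                continue
            rpkm = count / ((lengths[rec.control_id] / 1000.0) * (config.depth / 1.0e6))
            if rpkm <= config.floor:
                continue
            rows.append(
                {"control_id": rec.control_id, "pool": pool,
                 "replicate": 1, "log2_signal": float(np.log2(rpkm))}
            )
    frame = pd.DataFrame(rows, columns=["control_id", "pool", "replicate", "log2_signal"])
    return SignalTable(
        data=frame, platform="rnaseq", spike_fraction=0.3, rpkm_floor=config.floor
    )
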