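"""Signal-table I/O and detection-status bookkeeping.

A signal table is the long-format record of one platform's measurements of the
four spike-in pools: one row per (control, pool, replicate) with the measured
signal.  Array signals are log2 fluorescence intensities; sequencing signals
arrive as linear FPKM/RPKM and are log2-transformed on load, after values at
or below the reporting floor (default 0.01) are discarded as missing.  A
control present in all four pools is "detected", in some pools "partial", in
none "undetected"; partially detected and undetected controls are excluded
from model fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .design import POOLS, DesignTable

__all__ = [
    "SignalTable",
    "SignalTableError",
    "DetectionStatus",
    "read_signals",
    "write_signals",
    "detection_status",
    "detection_table",
    "collapse_replicates",
]

PlatformClass = Literal["array", "rnaseq"]

_COLUMNS = ["control_id", "pool", "replicate", "signal"]


class SignalTableError(ValueError):
    """Raised for malformed signal files."""


@dataclass(frozen=True)
class DetectionStatus:
    control_id: str
    status: Literal["detected", "partial", "undetected"]
    pools_present: tuple[int, ...] = ()


@dataclass
class SignalTable:
    """Per-(control, pool, replicate) log2 signals for one platform.

    ``data`` columns: control_id (str), pool (int), replicate (int),
    log2_signal (float, always finite).  ``platform`` is ``"array"`` or
    ``"rnaseq"``; ``spike_fraction`` (percent wt/wt of spike-in pool per total
    RNA) is carried as metadata only.
    """

    data: pd.DataFrame
    platform: PlatformClass
    spike_fraction: float | None = None
    rpkm_floor: float = 0.01

    def __post_init__(self) -> None:
        missing = [c for c in ("control_id", "pool", "replicate", "log2_signal") if c not in self.data.columns]
        if missing:
            raise SignalTableError(f"signal data lacks columns {missing}")
        if len(self.data) and not np.isfinite(self.data["log2_signal"]).all():
            raise SignalTableError("non-finite log2 signal present")

    @property
    def pools(self) -> tuple[int, ...]:
        return tuple(sorted(self.data["pool"].unique()))

    def control(self, control_id: str) -> pd.DataFrame:
        return self.data[self.data["control_id"] == control_id]

    def pools_present(self, control_id: str) -> tuple[int, ...]:
        return tuple(sorted(self.control(control_id)["pool"].unique()))


def _read_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        return pd.DataFrame(columns=_COLUMNS)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    try:
        frame = pd.read_csv(path, sep=sep, na_values=["NA"], keep_default_na=True)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=_COLUMNS)
    return frame


def read_signals(
    path: str | Path,
    platform: PlatformClass,
    rpkm_floor: float = 0.01,
    spike_fraction: float | None = None,
) -> SignalTable:
    """Read a long-format signal file (TSV or CSV).

    Required columns: control_id, pool, replicate, signal.  Array signals are
    taken as log2 intensities; rnaseq signals are linear FPKM/RPKM, values at
    or below ``rpkm_floor`` (and zeros, which carry no log2 value) are treated
    as missing, and the remainder are log2-transformed.
    """
    if platform not in ("array", "rnaseq"):
        raise ValueError(f"unknown platform class {platform!r}")
    frame = _read_frame(path)
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise SignalTableError(f"{path}: missing columns {missing}")
    frame = frame.loc[:, _COLUMNS].copy()
    numeric = pd.to_numeric(frame["signal"], errors="coerce")
    nonnum = numeric.isna() & frame["signal"].notna()
    if nonnum.any():
        row = frame.loc[nonnum].iloc[0]
        raise SignalTableError(
            f"{path}: non-numeric signal {row['signal']!r} for "
            f"({row['control_id']}, pool {row['pool']}, rep {row['replicate']})"
        )
    frame["signal"] = numeric
    frame = frame.dropna(subset=["signal"])
    if platform == "rnaseq":
        frame = frame[frame["signal"] > rpkm_floor].copy()
        frame["log2_signal"] = np.log2(frame["signal"].to_numpy(dtype=float))
    else:
        frame["log2_signal"] = frame["signal"].astype(float)
    frame = frame.drop(columns=["signal"])
    frame["pool"] = frame["pool"].astype(int)
    frame["replicate"] = frame["replicate"].astype(int)
    dupes = frame.duplicated(subset=["control_id", "pool", "replicate"], keep=False)
    if dupes.any():
        key = frame.loc[dupes].iloc[0]
        raise SignalTableError(
            f"{path}: duplicate key ({key['control_id']}, pool {key['pool']}, "
            f"rep {key['replicate']})"
        )
    frame = frame.reset_index(drop=True)
    return SignalTable(
        data=frame, platform=platform, spike_fraction=spike_fraction, rpkm_floor=rpkm_floor
    )


def write_signals(table: SignalTable, path: str | Path) -> None:
    """Write a signal table in the same long-format dialect read_signals expects.

    Array tables emit the stored log2 intensities; rnaseq tables emit linear
    FPKM/RPKM (2**log2_signal) so a written file round-trips through
    :func:`read_signals` bit-exactly for finite values.
    """
    path = Path(path)
    out = table.data.copy()
    if table.platform == "rnaseq":
        out["signal"] = np.exp2(out["log2_signal"].to_numpy(dtype=float))
    else:
        out["signal"] = out["log2_signal"]
    out = out[["control_id", "pool", "replicate", "signal"]]
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(sep.join(_COLUMNS) + "\n")
        for row in out.itertuples(index=False):
            fh.write(sep.join([row.control_id, str(row.pool), str(row.replicate), repr(float(row.signal))]) + "\n")


def detection_status(
    table: SignalTable, control_id: str, pools: Iterable[int] = POOLS
) -> DetectionStatus:
    """Classify a control as detected / partial / undetected across the pools."""
    pools = tuple(pools)
    present = tuple(p for p in table.pools_present(control_id) if p in pools)
    if len(present) == len(pools):
        status = "detected"
    elif present:
        status = "partial"
    else:
        status = "undetected"
    return DetectionStatus(control_id=control_id, status=status, pools_present=present)


def detection_table(table: SignalTable, design: DesignTable) -> pd.DataFrame:
    """Detection status for every control in the design's analysis set."""
    rows = [
        {
            "control_id": rec.control_id,
            "subpool": rec.subpool,
            "status": detection_status(table, rec.control_id, design.square.pools).status,
        }
        for rec in design.records
    ]
    return pd.DataFrame(rows)


def collapse_replicates(table: SignalTable) -> pd.DataFrame:
    """Per-(control, pool) mean and sample SD of log2 signal.

    SD is 0 where only one replicate is present.
    """
    grouped = table.data.groupby(["control_id", "pool"], sort=True)["log2_signal"]
    out = grouped.agg(mean_log2="mean", sd_log2="std", n_replicates="size").reset_index()
    out["sd_log2"] = out["sd_log2"].fillna(0.0)
    return out
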