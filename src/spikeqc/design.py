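"""The modified Latin square pool design for ERCC spike-in control pools.

Five subpools (A–E) of ERCC controls, each spanning a 2^20 ladder of relative
abundance, are mixed by volume into four pools (12–15).  Subpools B–E rotate
through the mixing proportions 10/15/25/40 % in a Latin square; subpool A is
held at a constant 10 % (the "modification"), giving a 1-to-1 component in
every comparison.  The six pairwise pool comparisons therefore realise known
fold changes of 4, 2.7, 2.5, 1.7, 1.6 and 1.5 (and their reciprocals) on top
of the within-subpool abundance ladder.

The packaged design table records, for every control, its subpool, its base
relative abundance on the subpool ladder, and the exclusion flags used by the
analysis: seven controls were synthesised as antisense RNA (no signal on
sense-probe assays), one control (ERCC-00073) is omitted from all pools and
serves as a background probe, ERCC-00114 is not part of SRM 2374, and
ERCC-00113 behaves as a member of subpool C rather than its labelled subpool
(a pool-preparation error).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from fractions import Fraction
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "POOLS",
    "SUBPOOLS",
    "TITRATED_SUBPOOLS",
    "OMITTED_CONTROL",
    "ControlRecord",
    "LatinSquare",
    "DesignTable",
    "DesignError",
    "load_design",
    "nominal_abundance",
    "abundance_profile",
    "pairwise_ratio",
    "round_ratio",
    "enumerate_pool_pairs",
    "apply_exclusions",
    "nominal_matrix",
]

POOLS: tuple[int, ...] = (12, 13, 14, 15)
SUBPOOLS: tuple[str, ...] = ("A", "B", "C", "D", "E")
TITRATED_SUBPOOLS: tuple[str, ...] = ("B", "C", "D", "E")
OMITTED_CONTROL = "ERCC-00073"

# Cyclic Latin square over pools 12-15; subpool A is the constant modification.
_PROPORTIONS: dict[str, dict[int, int]] = {
    "A": {12: 10, 13: 10, 14: 10, 15: 10},
    "B": {12: 10, 13: 15, 14: 25, 15: 40},
    "C": {12: 15, 13: 25, 14: 40, 15: 10},
    "D": {12: 25, 13: 40, 14: 10, 15: 15},
    "E": {12: 40, 13: 10, 14: 15, 15: 25},
}

#: Ladder of base relative abundances shared by the subpools: 2^0..2^16 plus
#: 2^18 and 2^20 (19 rungs spanning a 2^20 dynamic range).
LADDER: tuple[int, ...] = tuple(2**k for k in list(range(17)) + [18, 20])


class DesignError(ValueError):
    """Raised when the design table fails validation."""


@dataclass(frozen=True)
class ControlRecord:
    """One ERCC control's place in the pool design."""

    control_id: str
    subpool: str  # "A".."E" or "omitted"
    base_abundance: float
    antisense: bool = False
    non_srm: bool = False
    reassigned_subpool: str | None = None

    @property
    def titrated(self) -> bool:
        return self.subpool in TITRATED_SUBPOOLS


@dataclass(frozen=True)
class LatinSquare:
    """Mixing proportions (percent by volume) of each subpool in each pool."""

    pools: tuple[int, ...] = POOLS
    proportions: Mapping[str, Mapping[int, int]] = field(
        default_factory=lambda: _PROPORTIONS
    )

    def proportion(self, subpool: str, pool: int) -> int:
        try:
            return self.proportions[subpool][pool]
        except KeyError as exc:
            raise KeyError(f"no proportion for subpool {subpool!r}, pool {pool!r}") from exc

    def validate(self) -> None:
        for pool in self.pools:
            total = sum(self.proportions[s][pool] for s in SUBPOOLS)
            if total != 100:
                raise DesignError(f"pool {pool} proportions sum to {total}, not 100")
        for sub in TITRATED_SUBPOOLS:
            values = sorted(self.proportions[sub][p] for p in self.pools)
            if values != [10, 15, 25, 40]:
                raise DesignError(f"subpool {sub} proportions {values} are not a Latin row")
        if any(self.proportions["A"][p] != 10 for p in self.pools):
            raise DesignError("subpool A must be a constant 10 % component")


@dataclass(frozen=True)
class DesignTable:
    """Validated pool design: control records plus the mixing square."""

    records: tuple[ControlRecord, ...]
    square: LatinSquare = field(default_factory=LatinSquare)
    #: Records removed by :func:`apply_exclusions` (kept for background use).
    excluded: tuple[ControlRecord, ...] = ()

    def __post_init__(self) -> None:
        ids = [r.control_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise DesignError("duplicate control_id in design records")

    def record(self, control_id: str) -> ControlRecord:
        for rec in self.records:
            if rec.control_id == control_id:
                return rec
        raise KeyError(f"unknown control {control_id!r}")

    def __contains__(self, control_id: str) -> bool:
        return any(r.control_id == control_id for r in self.records)

    @property
    def control_ids(self) -> tuple[str, ...]:
        return tuple(r.control_id for r in self.records)

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])

    def validate(self) -> None:
        self.square.validate()
        omitted = [r for r in self.records if r.subpool == "omitted"]
        if len(omitted) != 1 or omitted[0].control_id != OMITTED_CONTROL:
            raise DesignError("exactly one omitted control (ERCC-00073) is required")
        n_anti = sum(r.antisense for r in self.records)
        if n_anti != 7:
            raise DesignError(f"expected 7 antisense controls, found {n_anti}")
        for rec in self.records:
            if rec.subpool == "omitted":
                continue
            if rec.subpool not in SUBPOOLS:
                raise DesignError(f"{rec.control_id}: unknown subpool {rec.subpool!r}")
            if not rec.non_srm and rec.base_abundance not in LADDER:
                raise DesignError(
                    f"{rec.control_id}: base abundance {rec.base_abundance} "
                    "is not on the subpool ladder"
                )
        for sub in SUBPOOLS:
            bases = [r.base_abundance for r in self.records if r.subpool == sub and not r.non_srm]
            if bases and max(bases) / min(bases) != 2**20:
                raise DesignError(f"subpool {sub} ladder does not span 2^20")


def _parse_bool(text: str, row: int, column: str) -> bool:
    lowered = text.strip().lower()
    if lowered in {"true", "1", "yes"}:
        return True
    if lowered in {"false", "0", "no", ""}:
        return False
    raise DesignError(f"row {row}: cannot parse {column}={text!r} as boolean")


def load_design(path: str | Path | None = None) -> DesignTable:
    """Load and validate the pool design.

    By default the packaged design table is used; ``path`` may point to an
    alternative CSV with the same header
    (``control_id,subpool,base_abundance,antisense,non_srm,reassigned_subpool``).
    """
    if path is None:
        source = resources.files("spikeqc.data").joinpath("design.csv")
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    reader = csv.DictReader(text.splitlines())
    required = {"control_id", "subpool", "base_abundance", "antisense", "non_srm"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        raise DesignError(f"design file must have columns {sorted(required)}")
    records = []
    for i, row in enumerate(reader, start=2):
        try:
            base = float(row["base_abundance"])
        except ValueError:
            raise DesignError(
                f"row {i} ({row.get('control_id')}): non-numeric base abundance "
                f"{row['base_abundance']!r}"
            ) from None
        records.append(
            ControlRecord(
                control_id=row["control_id"].strip(),
                subpool=row["subpool"].strip(),
                base_abundance=base,
                antisense=_parse_bool(row["antisense"], i, "antisense"),
                non_srm=_parse_bool(row["non_srm"], i, "non_srm"),
                reassigned_subpool=(row.get("reassigned_subpool") or "").strip() or None,
            )
        )
    table = DesignTable(records=tuple(records))
    table.validate()
    return table


def nominal_abundance(table: DesignTable, control_id: str, pool: int) -> float:
    """Nominal relative abundance of a control in a pool.

    This is the subpool base abundance scaled by the pool's mixing proportion,
    normalised so the 10 % proportion reproduces the base value.
    """
    rec = table.record(control_id)
    if rec.subpool == "omitted":
        raise KeyError(f"{control_id} is omitted from all pools")
    return rec.base_abundance * table.square.proportion(rec.subpool, pool) / 10


def abundance_profile(table: DesignTable, control_id: str) -> dict[int, float]:
    """Nominal abundance of one control in each of the four pools."""
    return {p: nominal_abundance(table, control_id, p) for p in table.square.pools}


def pairwise_ratio(
    table: DesignTable, subpool: str, pool_i: int, pool_j: int
) -> Fraction:
    """Exact nominal fold change of a subpool between two pools.

    Ratios are kept as exact rationals; use :func:`round_ratio` for the
    one-decimal reporting convention (40/15 -> 2.7).
    """
    if pool_i == pool_j:
        raise ValueError("pool_i and pool_j must differ")
    return Fraction(
        table.square.proportion(subpool, pool_i),
        table.square.proportion(subpool, pool_j),
    )


def round_ratio(ratio: Fraction | float) -> float:
    return round(float(ratio), 1)


def enumerate_pool_pairs(
    table: DesignTable,
) -> list[tuple[int, int, frozenset[float]]]:
    """All six unordered pool pairs with their titrated fold changes.

    Fold changes are reported rounded to one decimal and as the "up" direction
    (>= 1); each pair carries four titrated folds (one per subpool B-E) plus
    the implicit 1-to-1 component from subpool A.
    """
    pairs = []
    for pool_i, pool_j in combinations(table.square.pools, 2):
        folds = frozenset(
            round_ratio(max(r, 1 / r))
            for sub in TITRATED_SUBPOOLS
            for r in [pairwise_ratio(table, sub, pool_i, pool_j)]
        )
        pairs.append((pool_i, pool_j, folds))
    return pairs


def apply_exclusions(table: DesignTable, drop_non_srm: bool = False) -> DesignTable:
    """Reduce the design to the analysis set.

    Removes antisense controls (sense-probe assays cannot detect them) and the
    omitted control (needed only for background estimation); both are retained
    on ``excluded``.  Controls with a reassigned subpool (the ERCC-00113 case)
    are re-labelled so downstream analysis uses the corrected membership.
    Idempotent.
    """
    kept: list[ControlRecord] = []
    dropped: list[ControlRecord] = list(table.excluded)
    for rec in table.records:
        if rec.antisense or rec.subpool == "omitted" or (drop_non_srm and rec.non_srm):
            dropped.append(rec)
            continue
        if rec.reassigned_subpool and rec.subpool != rec.reassigned_subpool:
            rec = replace(rec, subpool=rec.reassigned_subpool)
        kept.append(rec)
    return DesignTable(records=tuple(kept), square=table.square, excluded=tuple(dropped))


def nominal_matrix(table: DesignTable) -> pd.DataFrame:
    """Controls x pools matrix of nominal abundances (omitted control excluded)."""
    rows = {}
    for rec in table.records:
        if rec.subpool == "omitted":
            continue
        rows[rec.control_id] = abundance_profile(table, rec.control_id)
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "control_id"
    frame.columns = [f"pool_{p}" for p in frame.columns]
    return frame.sort_index()
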