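"""Tabular I/O for food-composition tables and dietary records, plus unit handling.

Food-composition tables arrive with heterogeneous per-nutrient units (g, mg,
µg, IU, ...).  Everything downstream works in grams, so amounts are converted
on ingest through a :class:`UnitMap`.  International units and other non-mass
units have no universal gram equivalent and therefore require an explicit
per-nutrient override; they are never converted silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "UnitError",
    "UnitMap",
    "FoodCompositionTable",
    "DietRecordSet",
    "to_grams",
    "read_food_composition",
    "write_food_composition",
    "read_diet_records",
    "write_diet_records",
]

#: metric mass units resolvable without configuration
DEFAULT_UNIT_FACTORS: dict[str, float] = {
    "g": 1.0,
    "gram": 1.0,
    "grams": 1.0,
    "kg": 1e3,
    "mg": 1e-3,
    "ug": 1e-6,
    "µg": 1e-6,
    "mcg": 1e-6,
    "ng": 1e-9,
}


class UnitError(ValueError):
    """Raised when a unit cannot be resolved to a gram factor."""


@dataclass(frozen=True)
class UnitMap:
    """Mapping from unit strings to multiplicative gram factors.

    Parameters
    ----------
    factors
        unit string -> grams per one unit.  All factors must be positive.
    nutrient_overrides
        nutrient_id -> {unit -> factor}; consulted before ``factors`` so that
        e.g. ``IU`` can mean different masses for vitamin A and vitamin D.
    """

    factors: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_UNIT_FACTORS)
    )
    nutrient_overrides: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for unit, fac in self.factors.items():
            if not np.isfinite(fac) or fac <= 0:
                raise ValueError(f"unit factor for {unit!r} must be > 0, got {fac}")
        for nid, table in self.nutrient_overrides.items():
            for unit, fac in table.items():
                if not np.isfinite(fac) or fac <= 0:
                    raise ValueError(
                        f"override factor for nutrient {nid!r}, unit {unit!r} "
                        f"must be > 0, got {fac}"
                    )

    def factor(self, unit: str, nutrient_id: Optional[str] = None) -> float:
        """Gram factor for ``unit``, honouring per-nutrient overrides."""
        if nutrient_id is not None:
            override = self.nutrient_overrides.get(nutrient_id, {})
            if unit in override:
                return float(override[unit])
        if unit in self.factors:
            return float(self.factors[unit])
        raise UnitError(
            f"cannot convert unit {unit!r}"
            + (f" for nutrient {nutrient_id!r}" if nutrient_id is not None else "")
            + "; add it to the unit map (non-mass units such as IU need a "
            "per-nutrient override)"
        )

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "UnitMap":
        """Load a unit map from YAML/JSON (keys ``factors``, ``nutrient_overrides``)."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        factors = dict(DEFAULT_UNIT_FACTORS)
        factors.update(raw.get("factors", {}))
        return cls(factors=factors, nutrient_overrides=raw.get("nutrient_overrides", {}))


def to_grams(
    amount: float,
    unit: str,
    unit_map: Optional[UnitMap] = None,
    nutrient_id: Optional[str] = None,
) -> float:
    """Convert ``amount`` expressed in ``unit`` to grams.

    >>> to_grams(500, "mg")
    0.5
    """
    if unit_map is None:
        unit_map = UnitMap()
    if amount < 0:
        raise ValueError(f"amount must be non-negative, got {amount}")
    return float(amount) * unit_map.factor(unit, nutrient_id=nutrient_id)


@dataclass
class FoodCompositionTable:
    """Long-format food composition: one row per (food, nutrient), amounts in grams.

    ``data`` columns: food_id, food_group, nutrient_id, amount (grams per
    serving).  (food_id, nutrient_id) pairs are unique after aggregation.
    """

    data: pd.DataFrame

    REQUIRED = ("food_id", "food_group", "nutrient_id", "amount")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"composition table missing columns: {missing}")
        if len(self.data) == 0:
            raise ValueError("composition table is empty")
        if (self.data["amount"] < 0).any():
            raise ValueError("composition amounts must be non-negative")
        if self.data.duplicated(["food_id", "nutrient_id"]).any():
            raise ValueError("duplicate (food_id, nutrient_id) pairs after aggregation")

    @property
    def foods(self) -> list[str]:
        return sorted(self.data["food_id"].unique())

    @property
    def nutrients(self) -> list[str]:
        return sorted(self.data["nutrient_id"].unique())

    def food_groups(self) -> dict[str, str]:
        return dict(
            self.data.drop_duplicates("food_id")[["food_id", "food_group"]].values
        )


@dataclass
class DietRecordSet:
    """Longitudinal dietary records: (subject, timepoint, food, grams).

    A *record* is one (subject_id, timepoint) diet assessment.  The food
    profile of a record is its relative-abundance vector over consumed foods
    (grams normalised to sum to one), i.e. a point on the simplex.
    """

    data: pd.DataFrame

    REQUIRED = ("subject_id", "timepoint", "food_id", "grams")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"diet records missing columns: {missing}")
        if (self.data["grams"] < 0).any():
            raise ValueError("grams must be non-negative")

    @property
    def subjects(self) -> list[str]:
        return sorted(self.data["subject_id"].unique())

    @property
    def record_ids(self) -> list[tuple]:
        """Sorted (subject_id, timepoint) keys of all records."""
        return sorted(
            self.data.groupby(["subject_id", "timepoint"], sort=True).groups.keys()
        )

    @property
    def foods(self) -> list[str]:
        return sorted(self.data["food_id"].unique())

    def abundances(self) -> pd.DataFrame:
        """Record x food relative-abundance matrix (rows sum to one).

        Index is a (subject_id, timepoint) MultiIndex; columns are food ids.
        """
        wide = self.data.pivot_table(
            index=["subject_id", "timepoint"],
            columns="food_id",
            values="grams",
            aggfunc="sum",
            fill_value=0.0,
        )
        totals = wide.sum(axis=1)
        if (totals <= 0).any():
            raise ValueError("record with zero total grams present")
        return wide.div(totals, axis=0)

    def to_matrix(self, food_ids: Optional[list[str]] = None):
        """Relative abundances as ``(record_keys, food_ids, F)`` with F row-simplex.

        ``food_ids`` widens/reorders columns to an external food pool (e.g. a
        network's food list); foods never consumed get zero columns.
        """
        ab = self.abundances()
        if food_ids is not None:
            unknown = set(ab.columns) - set(food_ids)
            if unknown:
                raise KeyError(f"records contain foods absent from pool: {sorted(unknown)[:5]}")
            ab = ab.reindex(columns=food_ids, fill_value=0.0)
        return list(ab.index), list(ab.columns), ab.to_numpy(dtype=float)


def _numeric_column(df: pd.DataFrame, col: str, path: Union[str, Path]) -> pd.Series:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        # +2: header line plus 1-based indexing
        line = int(bad.idxmax()) + 2
        raise ValueError(
            f"{path}: unparseable numeric in column {col!r} at line {line}: "
            f"{df[col][bad.idxmax()]!r}"
        )
    if vals.isna().any():
        line = int(vals.isna().idxmax()) + 2
        raise ValueError(f"{path}: missing value in column {col!r} at line {line}")
    return vals.astype(float)


def read_food_composition(
    path: Union[str, Path],
    unit_map: Optional[UnitMap] = None,
    delimiter: str = ",",
) -> FoodCompositionTable:
    """Read a composition CSV (food_id,food_group,nutrient_id,amount,unit) in grams.

    Amounts are converted via ``unit_map``; duplicate (food, nutrient) rows are
    summed with a logged warning.  Negative or unparseable amounts raise with
    the offending line number.
    """
    if unit_map is None:
        unit_map = UnitMap()
    df = pd.read_csv(path, sep=delimiter, dtype=str, encoding="utf-8")
    required = ["food_id", "food_group", "nutrient_id", "amount", "unit"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df = df.reset_index(drop=True)
    amounts = _numeric_column(df, "amount", path)
    neg = amounts < 0
    if neg.any():
        line = int(neg.idxmax()) + 2
        raise ValueError(f"{path}: negative amount at line {line}")
    grams = np.empty(len(df))
    for idx, (amt, unit, nid) in enumerate(
        zip(amounts, df["unit"], df["nutrient_id"])
    ):
        try:
            grams[idx] = amt * unit_map.factor(str(unit), nutrient_id=str(nid))
        except UnitError as err:
            raise UnitError(f"{path}: line {idx + 2}: {err}") from None
    out = df[["food_id", "food_group", "nutrient_id"]].copy()
    out["amount"] = grams
    n_dup = out.duplicated(["food_id", "nutrient_id"]).sum()
    if n_dup:
        logger.warning(
            "%s: summed %d duplicate (food, nutrient) rows", path, int(n_dup)
        )
        out = (
            out.groupby(["food_id", "nutrient_id"], as_index=False, sort=False)
            .agg(food_group=("food_group", "first"), amount=("amount", "sum"))
        )[["food_id", "food_group", "nutrient_id", "amount"]]
    logger.info(
        "%s: %d rows, %d foods, %d nutrients",
        path,
        len(out),
        out["food_id"].nunique(),
        out["nutrient_id"].nunique(),
    )
    return FoodCompositionTable(out.reset_index(drop=True))


def write_food_composition(
    table: FoodCompositionTable, path: Union[str, Path], delimiter: str = ","
) -> None:
    """Write a composition table back to CSV (amounts in grams, unit column 'g')."""
    out = table.data.copy()
    out["unit"] = "g"
    out.to_csv(path, sep=delimiter, index=False, float_format="%.17g", encoding="utf-8")


def read_diet_records(
    path: Union[str, Path],
    net=None,
    on_unknown: str = "error",
    delimiter: str = ",",
) -> DietRecordSet:
    """Read dietary records (subject_id,timepoint,food_id,grams).

    Records whose total intake is zero are dropped with a warning.  When a
    food-nutrient network ``net`` is supplied, food ids are checked against its
    pool; ``on_unknown`` is ``"error"`` or ``"warn"``.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, encoding="utf-8")
    required = ["subject_id", "timepoint", "food_id", "grams"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df = df.reset_index(drop=True)
    grams = _numeric_column(df, "grams", path)
    neg = grams < 0
    if neg.any():
        line = int(neg.idxmax()) + 2
        raise ValueError(f"{path}: negative grams at line {line}")
    df = df[["subject_id", "timepoint", "food_id"]].copy()
    df["grams"] = grams

    totals = df.groupby(["subject_id", "timepoint"])["grams"].transform("sum")
    empty = totals <= 0
    if empty.any():
        dropped = df.loc[empty, ["subject_id", "timepoint"]].drop_duplicates()
        logger.warning(
            "%s: dropped %d zero-intake record(s)", path, len(dropped)
        )
        df = df[~empty].reset_index(drop=True)
    if len(df) == 0:
        raise ValueError(f"{path}: no non-empty records")

    if net is not None:
        unknown = sorted(set(df["food_id"]) - set(net.foods))
        if unknown:
            msg = f"{path}: {len(unknown)} food id(s) not in network: {unknown[:5]}"
            if on_unknown == "error":
                raise KeyError(msg)
            logger.warning(msg)
    return DietRecordSet(df)


def write_diet_records(
    records: DietRecordSet, path: Union[str, Path], delimiter: str = ","
) -> None:
    records.data.to_csv(
        path, sep=delimiter, index=False, float_format="%.17g", encoding="utf-8"
    )
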