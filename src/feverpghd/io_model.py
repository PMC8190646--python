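"""Record schemas, CSV readers/writers, ingredient normalization and
child-level eligibility filters.

The pipeline consumes three tabular streams:

* ``children.csv``      — ``child_id,sex,birth_date,weight_kg``
* ``temperatures.csv``  — ``child_id,timestamp,temp_c``
* ``antipyretics.csv``  — ``child_id,timestamp,ingredient,dose_mg``

All timestamps are ISO-8601; temperatures are degrees Celsius. Rows that
fail validation are counted per reason and reported, never silently dropped.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

# The three antipyretic ingredients tracked by the analysis.
ACE = "ACE"  # acetaminophen (paracetamol)
IBU = "IBU"  # ibuprofen
DEX = "DEX"  # dexibuprofen (the active S(+) enantiomer of ibuprofen)
INGREDIENTS = (ACE, IBU, DEX)

# Sanity bounds for a body-temperature reading; outside -> row rejected.
TEMP_MIN_C = 30.0
TEMP_MAX_C = 43.0

# Child eligibility bounds (closed intervals).
WEIGHT_MIN_KG = 2.0
WEIGHT_MAX_KG = 50.0
AGE_MIN_DAYS = 0
AGE_MAX_DAYS = 7000
FEVER_THRESHOLD_C = 38.0

_GENERIC_NAMES: dict[str, str] = {
    "ace": ACE,
    "acetaminophen": ACE,
    "paracetamol": ACE,
    "ibu": IBU,
    "ibuprofen": IBU,
    "dex": DEX,
    "dexibuprofen": DEX,
}


class SchemaError(ValueError):
    """A required column is missing from an input CSV."""


class UnknownIngredientError(ValueError):
    """An ingredient name could not be mapped to ACE, IBU or DEX."""

    def __init__(self, raw_name: str):
        self.raw_name = raw_name
        super().__init__(
            f"unknown ingredient {raw_name!r}: not one of "
            f"{INGREDIENTS} and not in the brand-name table"
        )


@dataclass(frozen=True)
class ChildProfile:
    child_id: str
    sex: str  # "male" | "female"
    birth_date: date
    weight_kg: float

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not self.weight_kg > 0:
            raise ValueError(f"weight_kg must be > 0, got {self.weight_kg}")


@dataclass(frozen=True)
class TemperatureRecord:
    child_id: str
    time: datetime
    temp_c: float

    def __post_init__(self):
        if not (TEMP_MIN_C <= self.temp_c <= TEMP_MAX_C):
            raise ValueError(
                f"temp_c {self.temp_c} outside sanity bounds "
                f"[{TEMP_MIN_C}, {TEMP_MAX_C}]"
            )


@dataclass(frozen=True)
class AntipyreticRecord:
    child_id: str
    time: datetime
    ingredient: str
    dose_mg: float | None = None

    def __post_init__(self):
        if self.ingredient not in INGREDIENTS:
            raise ValueError(f"ingredient must be one of {INGREDIENTS}")


@dataclass
class ReadReport:
    """Row-level accounting for one :func:`read_cohort` call."""

    n_rows: dict[str, int] = field(default_factory=dict)
    n_rejected: dict[str, int] = field(default_factory=dict)
    reasons: Counter = field(default_factory=Counter)
    n_duplicate_temps: int = 0


@dataclass
class Cohort:
    """Validated, per-child time-sorted record streams.

    ``children`` has one row per child (unique ``child_id``);
    ``temperatures`` and ``antipyretics`` are sorted by (child_id, time),
    ties broken by input order (stable sort). Every record's child_id
    appears in ``children``.
    """

    children: pd.DataFrame
    temperatures: pd.DataFrame
    antipyretics: pd.DataFrame
    read_report: ReadReport = field(default_factory=ReadReport)

    @property
    def n_children(self) -> int:
        return len(self.children)

    def child_ids(self) -> list[str]:
        return self.children["child_id"].tolist()

    def temps_for(self, child_id: str) -> pd.DataFrame:
        return self.temperatures[self.temperatures["child_id"] == child_id]

    def meds_for(self, child_id: str) -> pd.DataFrame:
        return self.antipyretics[self.antipyretics["child_id"] == child_id]


def load_brand_table(path: str | Path) -> dict[str, str]:
    """Load an editable YAML brand-name table mapping names to ACE/IBU/DEX.

    The generic names are always available; the file adds brand names, e.g.::

        tylenol: ACE
        brufen: IBU
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    table: dict[str, str] = {}
    for k, v in raw.items():
        v = str(v).upper()
        if v not in INGREDIENTS:
            raise ValueError(f"brand table maps {k!r} to unknown ingredient {v!r}")
        table[str(k).strip().lower()] = v
    return table


def normalize_ingredient(
    raw_name: str, brand_table: Mapping[str, str] | None = None
) -> str:
    """Map an ingredient or brand name (case-insensitive) to ACE/IBU/DEX.

    Unknown names raise :class:`UnknownIngredientError` — the pipeline never
    guesses which drug a brand is.
    """
    if not raw_name or not str(raw_name).strip():
        raise UnknownIngredientError(raw_name)
    key = str(raw_name).strip().lower()
    if key in _GENERIC_NAMES:
        return _GENERIC_NAMES[key]
    if brand_table:
        hit = brand_table.get(key)
        if hit in INGREDIENTS:
            return hit
    raise UnknownIngredientError(raw_name)


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def _sort_records(df: pd.DataFrame) -> pd.DataFrame:
    # stable sort: ties at identical (child_id, time) keep input order
    return df.sort_values(["child_id", "time"], kind="stable").reset_index(drop=True)


def read_cohort(
    children_path: str | Path,
    temps_path: str | Path,
    meds_path: str | Path,
    brand_table: Mapping[str, str] | None = None,
) -> Cohort:
    """Read and validate the three CSV streams into a :class:`Cohort`.

    Malformed rows (unparseable timestamp/temperature/date, out-of-bounds
    temperature, unknown ingredient, unknown child_id) are counted in the
    returned cohort's ``read_report`` and logged. Duplicate (child, time)
    temperature rows keep the last occurrence.
    """
    report = ReadReport()

    children_raw = pd.read_csv(children_path, dtype={"child_id": str})
    _require_columns(children_raw, ["child_id", "sex", "birth_date", "weight_kg"],
                     "children")
    report.n_rows["children"] = len(children_raw)

    sex = children_raw["sex"].astype(str).str.strip().str.lower()
    sex = sex.replace({"m": "male", "f": "female"})
    birth = pd.to_datetime(children_raw["birth_date"], errors="coerce",
                           format="ISO8601")
    weight = pd.to_numeric(children_raw["weight_kg"], errors="coerce")
    ok = sex.isin(["male", "female"]) & birth.notna() & (weight > 0)
    ok &= ~children_raw["child_id"].duplicated(keep="first")
    _count_rejects(report, "children", ~ok, {
        "bad_sex": ~sex.isin(["male", "female"]),
        "bad_birth_date": birth.isna(),
        "bad_weight": ~(weight > 0),
        "duplicate_child_id": children_raw["child_id"].duplicated(keep="first"),
    })
    children = pd.DataFrame({
        "child_id": children_raw["child_id"],
        "sex": sex,
        "birth_date": birth,
        "weight_kg": weight,
    })[ok].reset_index(drop=True)
    known_ids = set(children["child_id"])

    temps_raw = pd.read_csv(temps_path, dtype={"child_id": str})
    _require_columns(temps_raw, ["child_id", "timestamp", "temp_c"], "temperatures")
    report.n_rows["temperatures"] = len(temps_raw)
    if len(temps_raw):
        t = pd.to_datetime(temps_raw["timestamp"], errors="coerce", format="ISO8601")
        temp = pd.to_numeric(temps_raw["temp_c"], errors="coerce")
        in_bounds = (temp >= TEMP_MIN_C) & (temp <= TEMP_MAX_C)
        known = temps_raw["child_id"].isin(known_ids)
        ok = t.notna() & temp.notna() & in_bounds & known
        _count_rejects(report, "temperatures", ~ok, {
            "bad_timestamp": t.isna(),
            "bad_temperature": temp.isna() | (t.notna() & ~in_bounds.fillna(False)),
            "unknown_child": ~known,
        })
        temperatures = pd.DataFrame({
            "child_id": temps_raw["child_id"], "time": t, "temp_c": temp,
        })[ok]
        temperatures = _sort_records(temperatures)
        dup = temperatures.duplicated(["child_id", "time"], keep="last")
        report.n_duplicate_temps = int(dup.sum())
        if report.n_duplicate_temps:
            logger.info("dropping %d duplicate (child, time) temperature rows "
                        "(keeping last)", report.n_duplicate_temps)
            temperatures = temperatures[~dup].reset_index(drop=True)
    else:
        report.n_rejected["temperatures"] = 0
        temperatures = _empty_temps()

    meds_raw = pd.read_csv(meds_path, dtype={"child_id": str})
    _require_columns(meds_raw, ["child_id", "timestamp", "ingredient"], "antipyretics")
    report.n_rows["antipyretics"] = len(meds_raw)
    if len(meds_raw):
        t = pd.to_datetime(meds_raw["timestamp"], errors="coerce", format="ISO8601")
        ing = meds_raw["ingredient"].map(
            lambda s: _try_normalize(s, brand_table))
        dose = (pd.to_numeric(meds_raw["dose_mg"], errors="coerce")
                if "dose_mg" in meds_raw.columns
                else pd.Series(np.nan, index=meds_raw.index))
        known = meds_raw["child_id"].isin(known_ids)
        ok = t.notna() & ing.notna() & known
        _count_rejects(report, "antipyretics", ~ok, {
            "bad_timestamp": t.isna(),
            "unknown_ingredient": ing.isna(),
            "unknown_child": ~known,
        })
        antipyretics = pd.DataFrame({
            "child_id": meds_raw["child_id"], "time": t,
            "ingredient": ing, "dose_mg": dose,
        })[ok]
        antipyretics = _sort_records(antipyretics)
    else:
        report.n_rejected["antipyretics"] = 0
        antipyretics = _empty_meds()

    total_rej = sum(report.n_rejected.values())
    if total_rej:
        logger.warning("rejected %d malformed rows: %s", total_rej,
                       dict(report.reasons))
    return Cohort(children, temperatures, antipyretics, report)


def _try_normalize(raw, brand_table) -> str | None:
    try:
        return normalize_ingredient(raw, brand_table)
    except UnknownIngredientError:
        return None


def _count_rejects(report: ReadReport, what: str, bad: pd.Series,
                   reasons: dict[str, pd.Series]) -> None:
    report.n_rejected[what] = int(bad.sum())
    for name, mask in reasons.items():
        n = int((bad & mask.fillna(True)).sum())
        if n:
            report.reasons[f"{what}:{name}"] += n


def _empty_temps() -> pd.DataFrame:
    return pd.DataFrame({"child_id": pd.Series(dtype=str),
                         "time": pd.Series(dtype="datetime64[ns]"),
                         "temp_c": pd.Series(dtype=float)})


def _empty_meds() -> pd.DataFrame:
    return pd.DataFrame({"child_id": pd.Series(dtype=str),
                         "time": pd.Series(dtype="datetime64[ns]"),
                         "ingredient": pd.Series(dtype=str),
                         "dose_mg": pd.Series(dtype=float)})


@dataclass
class FilterReport:
    """Exclusion accounting for :func:`filter_children`.

    ``overlapping`` counts each criterion independently (a child failing two
    criteria appears in both); ``first_reason`` assigns each excluded child
    to the first criterion it fails, in the order weight, age, no
    antipyretic record, no fever record — so first_reason counts plus
    retained children sum exactly to the input children.
    """

    n_input: int = 0
    n_retained: int = 0
    overlapping: dict[str, int] = field(default_factory=dict)
    first_reason: dict[str, int] = field(default_factory=dict)


_CRITERIA = ("weight", "age", "no_antipyretic", "no_fever")


def filter_children(
    cohort: Cohort, fever_threshold_c: float = FEVER_THRESHOLD_C
) -> tuple[Cohort, FilterReport]:
    """Apply the child-level eligibility screen.

    Retains children with weight in [2, 50] kg, age at first record in
    [0, 7000] days, at least one antipyretic record, and at least one
    temperature record >= 38.0 C. Records of excluded children are dropped.
    Idempotent: filtering a filtered cohort changes nothing.
    """
    ch = cohort.children
    report = FilterReport(n_input=len(ch))
    if not len(ch):
        report.overlapping = {c: 0 for c in _CRITERIA}
        report.first_reason = {c: 0 for c in _CRITERIA}
        return cohort, report

    first_temp = cohort.temperatures.groupby("child_id")["time"].min()
    first_med = cohort.antipyretics.groupby("child_id")["time"].min()
    first_record = pd.concat([first_temp, first_med], axis=1).min(axis=1)
    first_record = ch["child_id"].map(first_record)

    age_days = (first_record - ch["birth_date"]).dt.total_seconds() / 86400.0
    # children with no records at all have undefined age; they are excluded
    # anyway by the record criteria, so treat their age as passing
    age_bad = age_days.notna() & ((age_days < AGE_MIN_DAYS) | (age_days > AGE_MAX_DAYS))
    weight_bad = (ch["weight_kg"] < WEIGHT_MIN_KG) | (ch["weight_kg"] > WEIGHT_MAX_KG)

    has_med = ch["child_id"].isin(set(cohort.antipyretics["child_id"]))
    febrile = cohort.temperatures[
        cohort.temperatures["temp_c"] >= fever_threshold_c]
    has_fever = ch["child_id"].isin(set(febrile["child_id"]))

    bad = {
        "weight": weight_bad,
        "age": age_bad,
        "no_antipyretic": ~has_med,
        "no_fever": ~has_fever,
    }
    excluded = weight_bad | age_bad | ~has_med | ~has_fever
    report.overlapping = {c: int(m.sum()) for c, m in bad.items()}
    assigned = pd.Series(False, index=ch.index)
    for c in _CRITERIA:
        first = bad[c] & ~assigned
        report.first_reason[c] = int(first.sum())
        assigned |= bad[c]
    report.n_retained = int((~excluded).sum())

    kept = ch[~excluded].reset_index(drop=True)
    kept_ids = set(kept["child_id"])
    temps = cohort.temperatures[
        cohort.temperatures["child_id"].isin(kept_ids)].reset_index(drop=True)
    meds = cohort.antipyretics[
        cohort.antipyretics["child_id"].isin(kept_ids)].reset_index(drop=True)
    return Cohort(kept, temps, meds, cohort.read_report), report


_TS_FMT = "%Y-%m-%dT%H:%M:%S"


def write_cohort(
    cohort: Cohort,
    children_path: str | Path,
    temps_path: str | Path,
    meds_path: str | Path,
) -> None:
    """Write the three canonical CSVs (UTF-8, header, newline-terminated).

    Canonical formatting is deterministic, so read -> write -> read -> write
    produces byte-identical files.
    """
    ch = cohort.children.copy()
    ch["birth_date"] = ch["birth_date"].dt.strftime("%Y-%m-%d")
    ch["weight_kg"] = ch["weight_kg"].map(lambda v: f"{v:.2f}")
    ch.to_csv(children_path, index=False, lineterminator="\n", encoding="utf-8")

    te = cohort.temperatures.copy()
    te["time"] = te["time"].dt.strftime(_TS_FMT)
    te["temp_c"] = te["temp_c"].map(lambda v: f"{v:.2f}")
    te = te.rename(columns={"time": "timestamp"})
    te.to_csv(temps_path, index=False, lineterminator="\n", encoding="utf-8")

    me = cohort.antipyretics.copy()
    me["time"] = me["time"].dt.strftime(_TS_FMT)
    me["dose_mg"] = me["dose_mg"].map(
        lambda v: "" if pd.isna(v) else f"{v:.1f}")
    me = me.rename(columns={"time": "timestamp"})
    me.to_csv(meds_path, index=False, lineterminator="\n", encoding="utf-8")
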