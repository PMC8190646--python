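"""72-hour antipyretic case construction and classification.

A *case* is the analysis unit: all antipyretic doses in the 72 hours
following a child's first (not-yet-assigned) administration. Windows are
half-open ``[start, start + 72 h)`` and built greedily left-to-right, so a
child's doses partition into non-overlapping cases. A case is *single* when
its window contains exactly one distinct ingredient and *combination*
otherwise; the baseline temperature is the (imputed) temperature at the
first administration and defines the case's onset-temperature bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .episode_builder import TemperatureSeries, to_hours
from .io_model import ACE, DEX, IBU

WINDOW_H = 72.0
BASELINE_TOLERANCE_H = 1.0

SINGLE = "single"
COMBINATION = "combination"

#: canonical ingredient order for pattern labels
_PATTERN_ORDER = {ACE: 0, IBU: 1, DEX: 2}

ONSET_BINS = ("<37", "[37,38)", "[38,39)", "[39,40)", ">=40")


@dataclass
class FeverCase:
    """One 72-hour dosing window with its classification and baseline."""

    case_id: str
    child_id: str
    window_start_h: float            # float hours (internal clock)
    dose_times_h: np.ndarray         # sorted, within [start, start+72)
    ingredients: tuple[str, ...]     # per dose, aligned with dose_times_h
    window_h: float = WINDOW_H
    baseline_temp_c: float | None = None
    baseline_missing: bool = True
    group: str = ""
    pattern: str = ""
    onset_bin: str | None = None
    episodes: list = field(default_factory=list)

    @property
    def window_end_h(self) -> float:
        return self.window_start_h + self.window_h

    @property
    def n_doses(self) -> int:
        return len(self.dose_times_h)

    @property
    def ingredient_set(self) -> frozenset:
        return frozenset(self.ingredients)


def classify_case(case: FeverCase) -> tuple[str, str]:
    """Return (group, pattern) from the case's distinct ingredients.

    Pattern labels use the canonical ACE < IBU < DEX ordering, e.g. a case
    containing DEX and ACE doses in any order is ``combination / ACE-DEX``.
    """
    distinct = sorted(case.ingredient_set, key=_PATTERN_ORDER.__getitem__)
    if not distinct:
        raise ValueError("a case must contain at least one dose")
    group = SINGLE if len(distinct) == 1 else COMBINATION
    return group, "-".join(distinct)


def baseline_temperature(
    case: FeverCase,
    series: TemperatureSeries,
    tolerance_h: float = BASELINE_TOLERANCE_H,
) -> tuple[float | None, bool]:
    """Temperature at the first administration of the case.

    Interpolated when the window start lies inside the series' observation
    span; otherwise the nearest reading within ``tolerance_h``. Returns
    ``(baseline, missing_flag)``; cases flagged missing are excluded from
    AUC analyses downstream.
    """
    t0 = case.window_start_h
    if series.contains(t0):
        return float(series.interpolate(t0)), False
    gaps = np.abs(series.t_h - t0)
    k = int(np.argmin(gaps))
    if gaps[k] <= tolerance_h:
        return float(series.temp_c[k]), False
    return None, True


def onset_bin(baseline_temp_c: float) -> str:
    """Half-open onset-temperature bin of a baseline reading."""
    if baseline_temp_c < 37.0:
        return "<37"
    if baseline_temp_c < 38.0:
        return "[37,38)"
    if baseline_temp_c < 39.0:
        return "[38,39)"
    if baseline_temp_c < 40.0:
        return "[39,40)"
    return ">=40"


def eligible_for_auc(case: FeverCase, threshold_c: float) -> bool:
    """True iff the case has a baseline at or above the analysis threshold.

    The two standard threshold populations (38.0 and 39.0 C) nest: a case
    eligible at 39 is always eligible at 38.
    """
    if case.baseline_missing or case.baseline_temp_c is None:
        return False
    return case.baseline_temp_c >= threshold_c


def build_cases(
    child_id: str,
    dose_times_h: Sequence[float] | np.ndarray,
    ingredients: Sequence[str],
    series: TemperatureSeries | None = None,
    window_h: float = WINDOW_H,
    baseline_tolerance_h: float = BASELINE_TOLERANCE_H,
    case_prefix: str = "",
) -> list[FeverCase]:
    """Greedy left-to-right 72-hour windowing of one child's doses.

    The earliest unassigned dose opens a case; every dose strictly inside
    ``[start, start + window_h)`` joins it; the next unassigned dose opens
    the next case. When ``series`` is given, baselines, groups, patterns and
    onset bins are attached.
    """
    t = np.asarray(dose_times_h, dtype=float)
    ing = list(ingredients)
    if len(t) != len(ing):
        raise ValueError("dose times and ingredients must align")
    order = np.argsort(t, kind="stable")
    t = t[order]
    ing = [ing[k] for k in order]

    cases: list[FeverCase] = []
    i = 0
    n = len(t)
    while i < n:
        start = t[i]
        # half-open window: a dose at exactly start + window_h opens a new case
        j = int(np.searchsorted(t, start + window_h, side="left"))
        case = FeverCase(
            case_id=f"{case_prefix}{child_id}-c{len(cases)}",
            child_id=child_id,
            window_start_h=float(start),
            dose_times_h=t[i:j].copy(),
            ingredients=tuple(ing[i:j]),
            window_h=window_h,
        )
        case.group, case.pattern = classify_case(case)
        if series is not None:
            case.baseline_temp_c, case.baseline_missing = baseline_temperature(
                case, series, baseline_tolerance_h)
            if not case.baseline_missing:
                case.onset_bin = onset_bin(case.baseline_temp_c)
        cases.append(case)
        i = j
    return cases


def build_cases_from_frames(
    meds: pd.DataFrame,
    temps: pd.DataFrame,
    window_h: float = WINDOW_H,
    baseline_tolerance_h: float = BASELINE_TOLERANCE_H,
) -> tuple[list[FeverCase], dict[str, TemperatureSeries]]:
    """Build cases for every child in a cohort's record frames.

    Children without a single temperature record still yield cases (flagged
    baseline-missing). Returns the cases plus the per-child series used, so
    downstream AUC computation reuses the same interpolants.
    """
    series_by_child: dict[str, TemperatureSeries] = {}
    for cid, grp in temps.groupby("child_id", sort=True):
        series_by_child[cid] = TemperatureSeries.from_frame(cid, grp)

    all_cases: list[FeverCase] = []
    for cid, grp in meds.groupby("child_id", sort=True):
        t_h = to_hours(grp["time"].to_numpy())
        cases = build_cases(
            cid, t_h, grp["ingredient"].tolist(),
            series=series_by_child.get(cid),
            window_h=window_h,
            baseline_tolerance_h=baseline_tolerance_h,
        )
        all_cases.extend(cases)
    return all_cases, series_by_child


def attach_episodes(cases: Iterable[FeverCase], episodes_by_child: dict) -> None:
    """Link each case to the fever episodes overlapping its window."""
    for case in cases:
        eps = episodes_by_child.get(case.child_id, [])
        linked = []
        for ep, (on_h, off_h) in eps:
            if off_h is None:
                overlaps = on_h < case.window_end_h
            else:
                overlaps = on_h < case.window_end_h and off_h > case.window_start_h
            if overlaps:
                linked.append(ep)
        case.episodes = linked


def cases_to_frame(cases: Sequence[FeverCase]) -> pd.DataFrame:
    """Flatten cases to the ``cases.csv`` schema."""
    from .episode_builder import from_hours

    starts = from_hours([c.window_start_h for c in cases]) if cases else []
    return pd.DataFrame({
        "case_id": [c.case_id for c in cases],
        "child_id": [c.child_id for c in cases],
        "window_start": starts,
        "group": [c.group for c in cases],
        "pattern": [c.pattern for c in cases],
        "baseline_temp_c": [c.baseline_temp_c for c in cases],
        "onset_bin": [c.onset_bin for c in cases],
        "n_doses": [c.n_doses for c in cases],
        "baseline_missing_flag": [c.baseline_missing for c in cases],
    })
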