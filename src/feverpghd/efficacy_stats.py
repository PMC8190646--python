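"""Fever-exposure statistics: baseline-anchored AUC, delta-fever curves, and
single-vs-combination group comparisons.

The efficacy statistic is the area under the temperature *change* curve
(AUC, C*h): with baseline B the temperature at the first administration,
``delta(t) = T(t) - B`` is evaluated on an hourly grid over the case window
and integrated by the trapezoidal rule over a fixed horizon (6, 8, 10 or
12 h). Negative AUC means net defervescence; a more negative AUC means less
total fever exposure. Groups are compared by pooled-variance Student t,
chi-square for frequencies, and Cohen d standardized mean differences;
"Total" columns are exact two-component mixture moments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .case_builder import COMBINATION, SINGLE, FeverCase, eligible_for_auc
from .episode_builder import TemperatureSeries

STANDARD_HORIZONS = (6, 8, 10, 12)
STANDARD_THRESHOLDS = (38.0, 39.0)


@dataclass(frozen=True)
class AUCResult:
    """Trapezoidal integral of delta-fever for one case and one horizon."""

    case_id: str
    horizon_h: int
    auc_c_h: float
    truncated: bool


@dataclass(frozen=True)
class GroupComparison:
    """Two-group summary for one variable, plus the mixture total."""

    variable: str
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    t_statistic: float
    p_value: float
    cohens_d: float
    total_mean: float
    total_sd: float


# ---------------------------------------------------------------------------
# AUC and delta curves
# ---------------------------------------------------------------------------

def delta_grid(
    case: FeverCase, series: TemperatureSeries, horizon_h: int
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Hourly delta-fever grid for a case: (offsets_h, delta_c, truncated).

    delta at offset 0 is exactly 0 by construction (the baseline *is* the
    temperature at the window start). Offsets where the series has ended are
    dropped and the grid flagged truncated.
    """
    if case.baseline_missing or case.baseline_temp_c is None:
        raise ValueError(f"case {case.case_id}: baseline missing")
    t0 = case.window_start_h
    if series.contains(t0):
        offsets, temps, truncated = series.hourly_grid(t0, horizon_h)
        delta = temps - case.baseline_temp_c
        delta[0] = 0.0
        return offsets, delta, truncated
    # baseline came from the nearest-reading fallback; anchor the grid at the
    # window start anyway, keeping only in-span offsets (offset 0 is 0 by
    # definition of the baseline)
    lo, hi = series.domain
    offsets = np.arange(horizon_h + 1, dtype=float)
    ok = (t0 + offsets >= lo) & (t0 + offsets <= hi)
    truncated = not bool(ok.all())
    kept = offsets[ok]
    delta = np.asarray(series.interpolate(t0 + kept)) - case.baseline_temp_c
    if len(kept) == 0 or kept[0] != 0.0:
        kept = np.concatenate([[0.0], kept])
        delta = np.concatenate([[0.0], np.atleast_1d(delta)])
    else:
        delta[0] = 0.0
    return kept, delta, truncated


def auc_from_baseline(
    case: FeverCase, series: TemperatureSeries, horizon_h: int
) -> AUCResult:
    """Trapezoidal AUC of delta-fever over [0, horizon] hours, in C*h."""
    if horizon_h not in STANDARD_HORIZONS:
        warnings.warn(
            f"horizon {horizon_h} h is outside the standard set "
            f"{STANDARD_HORIZONS}", stacklevel=2)
    offsets, delta, truncated = delta_grid(case, series, horizon_h)
    auc = float(np.trapezoid(delta, offsets)) if len(offsets) > 1 else 0.0
    return AUCResult(case.case_id, horizon_h, auc, truncated)


def compute_aucs(
    cases: Sequence[FeverCase],
    series_by_child: Mapping[str, TemperatureSeries],
    thresholds: Sequence[float] = STANDARD_THRESHOLDS,
    horizons: Sequence[int] = STANDARD_HORIZONS,
) -> pd.DataFrame:
    """Per-case AUC at every horizon for each threshold population.

    One grid evaluation per case (at the longest horizon) serves all
    horizons, so horizon additivity AUC(0->12) = AUC(0->6) + AUC(6->12)
    holds exactly. Columns: case_id, group, pattern, threshold_c, horizon_h,
    auc_c_h, truncated_flag.
    """
    max_h = max(horizons)
    rows = []
    for case in cases:
        series = series_by_child.get(case.child_id)
        if series is None or case.baseline_missing:
            continue
        offsets, delta, _ = delta_grid(case, series, max_h)
        reached = offsets[-1] if len(offsets) else 0.0
        for thr in thresholds:
            if not eligible_for_auc(case, thr):
                continue
            for h in horizons:
                m = offsets <= h + 1e-12
                auc = (float(np.trapezoid(delta[m], offsets[m]))
                       if m.sum() > 1 else 0.0)
                rows.append((case.case_id, case.group, case.pattern, thr,
                             h, auc, reached < h - 1e-12))
    return pd.DataFrame(rows, columns=[
        "case_id", "group", "pattern", "threshold_c", "horizon_h",
        "auc_c_h", "truncated_flag"])


def delta_curve(
    cases: Sequence[FeverCase],
    series_by_child: Mapping[str, TemperatureSeries],
    stratifier: str = "group",
    horizon_h: int = 24,
    threshold_c: float = 38.0,
) -> pd.DataFrame:
    """Mean delta-fever per hourly offset, stratified by group or pattern.

    A case contributes to an offset while its series still covers it, so n
    is non-increasing in offset. Empty strata are omitted with a warning.
    Columns: stratum, offset_h, mean_delta_c, n.
    """
    if stratifier not in ("group", "pattern"):
        raise ValueError("stratifier must be 'group' or 'pattern'")
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    for case in cases:
        series = series_by_child.get(case.child_id)
        if series is None or not eligible_for_auc(case, threshold_c):
            continue
        offsets, delta, _ = delta_grid(case, series, horizon_h)
        key = getattr(case, stratifier)
        if key not in sums:
            sums[key] = np.zeros(horizon_h + 1)
            counts[key] = np.zeros(horizon_h + 1, dtype=int)
        idx = offsets.astype(int)
        sums[key][idx] += delta
        counts[key][idx] += 1
    rows = []
    for key in sorted(sums):
        n = counts[key]
        if n.sum() == 0:
            warnings.warn(f"stratum {key!r} is empty; omitted", stacklevel=2)
            continue
        with np.errstate(invalid="ignore"):
            mean = np.where(n > 0, sums[key] / np.maximum(n, 1), np.nan)
        for o in range(horizon_h + 1):
            if n[o] > 0:
                rows.append((key, o, float(mean[o]), int(n[o])))
    return pd.DataFrame(rows, columns=["stratum", "offset_h",
                                       "mean_delta_c", "n"])


# ---------------------------------------------------------------------------
# Two-group statistics (summary-statistic forms)
# ---------------------------------------------------------------------------

def student_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Two-sample pooled-variance Student t with n1 + n2 - 2 df.

    Returns (t, two-sided p). Zero pooled variance gives t = 0, p = 1 when
    the means agree and a signed infinite t (p = 0) when they differ.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if pooled_var == 0.0:
        if mean1 == mean2:
            return 0.0, 1.0
        return math.copysign(math.inf, mean1 - mean2), 0.0
    se = math.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    t = (mean1 - mean2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, p


def student_t_from_samples(x1, x2) -> tuple[float, float]:
    """Pooled-variance Student t from raw samples."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return student_t(float(x1.mean()), float(x1.std(ddof=1)), len(x1),
                     float(x2.mean()), float(x2.std(ddof=1)), len(x2))


def chi_square(table) -> tuple[float, float]:
    """Pearson chi-square on a 2 x k contingency table, no continuity
    correction, (2-1)(k-1) df."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] != 2 or obs.shape[1] < 2:
        raise ValueError("expected a 2 x k table with k >= 2")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    res = stats.chi2_contingency(obs, correction=False)
    return float(res.statistic), float(res.pvalue)


def cohens_d(
    mean1: float, sd1: float, mean2: float, sd2: float,
    n1: int | None = None, n2: int | None = None,
    variant: str = "equal",
) -> float:
    """Standardized mean difference |mean1 - mean2| / s, reported as a
    magnitude (interpretation bands: 0.2 small, 0.5 medium, 0.8 large).

    ``variant='equal'`` (default) pools with equal weights,
    s = sqrt((sd1^2 + sd2^2)/2); ``variant='pooled'`` uses the n-weighted
    pooled SD and requires n1, n2.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("both standard deviations are zero")
    if variant == "equal":
        s = math.sqrt((sd1**2 + sd2**2) / 2.0)
    elif variant == "pooled":
        if n1 is None or n2 is None:
            raise ValueError("variant='pooled' requires n1 and n2")
        s = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return abs(mean1 - mean2) / s


def mixture_total(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Exact mean and SD of the two groups pooled as one sample.

    total_var = sum_i w_i (sd_i^2 + mean_i^2) - total_mean^2 with
    w_i = n_i / (n1 + n2). With n2 = 0 this is (mean1, sd1).
    """
    n = n1 + n2
    if n < 1:
        raise ValueError("n1 + n2 must be >= 1")
    if n2 == 0:
        return mean1, sd1
    if n1 == 0:
        return mean2, sd2
    w1, w2 = n1 / n, n2 / n
    m = w1 * mean1 + w2 * mean2
    var = w1 * (sd1**2 + mean1**2) + w2 * (sd2**2 + mean2**2) - m**2
    return m, math.sqrt(max(var, 0.0))


def compare_groups(
    variable: str, x1, x2, d_variant: str = "equal"
) -> GroupComparison:
    """Full two-group comparison of a numeric variable from raw samples."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    m1, s1, n1 = float(x1.mean()), float(x1.std(ddof=1)), len(x1)
    m2, s2, n2 = float(x2.mean()), float(x2.std(ddof=1)), len(x2)
    t, p = student_t(m1, s1, n1, m2, s2, n2)
    d = cohens_d(m1, s1, m2, s2, n1, n2, variant=d_variant)
    tm, ts = mixture_total(m1, s1, n1, m2, s2, n2)
    return GroupComparison(variable, m1, s1, n1, m2, s2, n2, t, p, d, tm, ts)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def case_table(
    cases: Sequence[FeverCase],
    series_by_child: Mapping[str, TemperatureSeries],
    children: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-case analysis frame feeding the descriptive report.

    max_temp_c is the maximum observed reading inside the 72-h window;
    duration_resolved_h is the duration of the first resolved fever episode
    linked to the case (NaN when none).
    """
    sex_map = age_ref = None
    if children is not None and len(children):
        from .episode_builder import to_hours

        sex_map = dict(zip(children["child_id"], children["sex"]))
        age_ref = dict(zip(children["child_id"],
                           to_hours(children["birth_date"])))
    rows = []
    for c in cases:
        series = series_by_child.get(c.child_id)
        max_t = np.nan
        if series is not None:
            m = (series.t_h >= c.window_start_h) & (series.t_h < c.window_end_h)
            if m.any():
                max_t = float(series.temp_c[m].max())
        dur = next((e.duration_h for e in c.episodes if e.duration_h is not None),
                   np.nan)
        age_days = np.nan
        if age_ref is not None and c.child_id in age_ref:
            age_days = (c.window_start_h - age_ref[c.child_id]) / 24.0
        rows.append((c.case_id, c.child_id, c.group, c.pattern,
                     sex_map.get(c.child_id) if sex_map else None,
                     age_days, c.baseline_temp_c, c.onset_bin, max_t, dur,
                     c.n_doses, c.baseline_missing))
    return pd.DataFrame(rows, columns=[
        "case_id", "child_id", "group", "pattern", "sex", "age_days",
        "baseline_temp_c", "onset_bin", "max_temp_c", "duration_resolved_h",
        "n_doses", "baseline_missing"])


_BIN_ORDER = ("<37", "[37,38)", "[38,39)", "[39,40)", ">=40")


def table1_report(case_frame: pd.DataFrame, d_variant: str = "equal") -> dict:
    """Descriptive single-vs-combination comparison (Table-1 style).

    Numeric rows carry (mean, sd, n) per group, pooled-t p, Cohen d and the
    mixture total; the sex row and each onset-bin row carry counts,
    percentages and a chi-square p. Values are unrounded; render with
    :func:`render_table` for 2-dp presentation.
    """
    s = case_frame[case_frame["group"] == SINGLE]
    c = case_frame[case_frame["group"] == COMBINATION]
    out: dict = {"n_single": len(s), "n_combination": len(c),
                 "n_total": len(case_frame), "numeric": {}, "categorical": {}}

    for var, col in [("age_days", "age_days"),
                     ("baseline_temp_c", "baseline_temp_c"),
                     ("max_temp_c", "max_temp_c"),
                     ("duration_resolved_h", "duration_resolved_h")]:
        x1 = s[col].dropna().to_numpy()
        x2 = c[col].dropna().to_numpy()
        if len(x1) >= 2 and len(x2) >= 2:
            cmp = compare_groups(var, x1, x2, d_variant)
            out["numeric"][var] = cmp.__dict__.copy()

    if case_frame["sex"].notna().any() and len(s) and len(c):
        tab = np.array([
            [(s["sex"] == "male").sum(), (s["sex"] == "female").sum()],
            [(c["sex"] == "male").sum(), (c["sex"] == "female").sum()],
        ])
        row = {"single_male": int(tab[0, 0]), "combination_male": int(tab[1, 0]),
               "single_pct": 100.0 * tab[0, 0] / max(len(s), 1),
               "combination_pct": 100.0 * tab[1, 0] / max(len(c), 1)}
        if (tab.sum(axis=0) > 0).all():
            chi, p = chi_square(tab)
            row.update(chi_square_stat=chi, p_value=p)
        out["categorical"]["sex_male"] = row

    bins = {}
    for b in _BIN_ORDER:
        ns = int((s["onset_bin"] == b).sum())
        nc = int((c["onset_bin"] == b).sum())
        tot = ns + nc
        if tot == 0:
            continue
        bins[b] = {"single": ns, "combination": nc, "total": tot,
                   "single_pct": 100.0 * ns / tot,
                   "combination_pct": 100.0 * nc / tot}
    out["onset_bins"] = bins
    return out


def table2_report(
    auc_frame: pd.DataFrame,
    d_variant: str = "equal",
    include_truncated: bool = False,
) -> dict:
    """AUC group comparison per threshold and horizon (Table-2 style).

    Truncated cases are excluded (and counted) by default. Each cell carries
    per-group mean/SD/n, pooled-t p, Cohen d, and the mixture total.
    """
    out: dict = {}
    n_trunc = int(auc_frame["truncated_flag"].sum())
    out["n_truncated_excluded"] = 0 if include_truncated else n_trunc
    if not len(auc_frame):
        return out
    df = (auc_frame if include_truncated
          else auc_frame[~auc_frame["truncated_flag"].astype(bool)])
    for thr, sub in df.groupby("threshold_c"):
        block = {}
        for h, hh in sub.groupby("horizon_h"):
            x1 = hh.loc[hh["group"] == SINGLE, "auc_c_h"].to_numpy()
            x2 = hh.loc[hh["group"] == COMBINATION, "auc_c_h"].to_numpy()
            if len(x1) >= 2 and len(x2) >= 2:
                cmp = compare_groups(f"auc_{int(h)}h", x1, x2, d_variant)
                block[int(h)] = cmp.__dict__.copy()
        out[f">={thr:g}"] = block
    return out


def render_table(report: dict, decimals: int = 2) -> str:
    """Render a report dict as a plain-text table with 2-dp rounding."""
    lines = []
    for section, content in report.items():
        if not isinstance(content, dict):
            lines.append(f"{section}: {content}")
            continue
        lines.append(f"[{section}]")
        for key, row in content.items():
            if isinstance(row, dict):
                cells = ", ".join(
                    f"{k}={v:.{decimals}f}" if isinstance(v, float)
                    else f"{k}={v}" for k, v in row.items())
                lines.append(f"  {key}: {cells}")
            else:
                lines.append(f"  {key}: {row}")
    return "\n".join(lines) + "\n"
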