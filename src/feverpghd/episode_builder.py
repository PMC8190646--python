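"""Fever-episode segmentation and linear temperature imputation.

A child's temperature log is an irregular time series. Between two
neighboring readings the temperature is assumed to progress linearly, so the
series defines a piecewise-linear interpolant over its observation span.
A fever episode is a maximal interval on which that interpolant is at or
above the fever threshold (default 38.0 C); when the threshold crossing
falls between two readings the onset/offset is placed at the interpolated
crossing time. An episode still at or above threshold at the last reading is
left open (no offset, no duration).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD_C = 38.0

#: epoch against which all internal float-hour clocks are measured
_EPOCH = np.datetime64("2015-01-01T00:00:00")


def to_hours(times) -> np.ndarray:
    """Convert datetimes to float hours since the internal epoch."""
    arr = pd.to_datetime(pd.Series(times)).to_numpy(dtype="datetime64[s]")
    return (arr - _EPOCH) / np.timedelta64(3600, "s")


def from_hours(hours) -> pd.DatetimeIndex:
    """Inverse of :func:`to_hours` (second resolution)."""
    secs = np.round(np.asarray(hours, dtype=float) * 3600.0).astype("int64")
    return pd.DatetimeIndex(_EPOCH + secs.astype("timedelta64[s]"))


class ExtrapolationError(ValueError):
    """A query time falls outside the series' observation span."""


@dataclass(frozen=True)
class FeverEpisode:
    """One contiguous interval with interpolated temperature >= threshold.

    ``offset_time``/``duration_h`` are ``None`` for an episode unresolved at
    the end of the data (the series ends while still febrile).
    ``max_temp_c`` is the maximum *observed* reading within the episode.
    """

    child_id: str
    onset_time: datetime
    offset_time: datetime | None
    duration_h: float | None
    max_temp_c: float

    @property
    def resolved(self) -> bool:
        return self.offset_time is not None


class TemperatureSeries:
    """Per-child sorted (time, temp) pairs with a linear interpolant.

    Duplicate timestamps are resolved by keeping the last reading. The
    interpolation domain is [first reading, last reading]; no extrapolation
    is ever performed.
    """

    def __init__(self, child_id: str, times, temps_c: Sequence[float]):
        arr = np.asarray(times)
        if arr.dtype.kind in "Mm" or (
            arr.dtype == object and len(arr)
            and isinstance(arr.flat[0], (datetime, pd.Timestamp, str))
        ):
            t = to_hours(times)
        else:
            t = arr.astype(float)
        y = np.asarray(temps_c, dtype=float)
        if t.shape != y.shape:
            raise ValueError("times and temps must have equal length")
        if len(t) == 0:
            raise ValueError("a TemperatureSeries needs at least one reading")
        order = np.argsort(t, kind="stable")
        t, y = t[order], y[order]
        # keep the last reading at any duplicated timestamp
        keep = np.ones(len(t), dtype=bool)
        keep[:-1] = t[1:] > t[:-1]
        self.child_id = child_id
        self.t_h = t[keep]
        self.temp_c = y[keep]

    @classmethod
    def from_frame(cls, child_id: str, frame: pd.DataFrame) -> "TemperatureSeries":
        return cls(child_id, frame["time"].to_numpy(), frame["temp_c"].to_numpy())

    def __len__(self) -> int:
        return len(self.t_h)

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.t_h[0]), float(self.t_h[-1])

    def contains(self, t_h: float) -> bool:
        return self.t_h[0] <= t_h <= self.t_h[-1]

    def interpolate(self, t_h) -> np.ndarray | float:
        """Linearly imputed temperature at ``t_h`` (float hours).

        Exact reading when ``t_h`` coincides with a record; raises
        :class:`ExtrapolationError` outside the observation span.
        """
        t = np.asarray(t_h, dtype=float)
        if np.any(t < self.t_h[0]) or np.any(t > self.t_h[-1]):
            raise ExtrapolationError(
                f"query time outside observation span "
                f"[{self.t_h[0]:.3f}, {self.t_h[-1]:.3f}] h")
        out = np.interp(t, self.t_h, self.temp_c)
        return float(out) if np.isscalar(t_h) else out

    def hourly_grid(
        self, anchor_h: float, horizon_h: int
    ) -> tuple[np.ndarray, np.ndarray, bool]:
        """Temperatures at anchor + 0,1,...,horizon hours.

        Returns ``(offsets_h, temps, truncated)``; the grid is truncated
        where the series ends before ``anchor + horizon`` and ``truncated``
        is set. ``anchor_h`` must lie inside the observation span.
        """
        if not self.contains(anchor_h):
            raise ExtrapolationError(
                f"anchor {anchor_h:.3f} h outside observation span")
        offsets = np.arange(horizon_h + 1, dtype=float)
        end = self.t_h[-1]
        in_domain = anchor_h + offsets <= end + 1e-12
        truncated = not bool(in_domain.all())
        offsets = offsets[in_domain]
        temps = self.interpolate(np.minimum(anchor_h + offsets, end))
        return offsets, np.atleast_1d(temps), truncated


def interpolate_temperature(series: TemperatureSeries, t_h: float) -> float:
    """Module-level convenience wrapper around ``series.interpolate``."""
    return float(series.interpolate(t_h))


def _crossing(t0: float, y0: float, t1: float, y1: float, thr: float) -> float:
    """Time at which the segment (t0,y0)-(t1,y1) crosses ``thr``."""
    return t0 + (thr - y0) * (t1 - t0) / (y1 - y0)


def detect_episodes(
    series: TemperatureSeries,
    threshold_c: float = DEFAULT_THRESHOLD_C,
    max_gap_h: float | None = None,
) -> list[FeverEpisode]:
    """Segment a series into maximal intervals with interpolant >= threshold.

    Onset is the (interpolated) time the temperature reaches the threshold;
    offset the time it falls below. Ties at exactly the threshold count as
    febrile. Consecutive episodes are separated by a genuinely sub-threshold
    excursion; no refractory merging is applied.

    ``max_gap_h`` (off by default) refuses to impute across reading gaps
    longer than the given span: the series is split at such gaps and each
    segment segmented independently, so an episode still febrile at a
    segment's last reading is left unresolved.
    """
    if max_gap_h is not None:
        gaps = np.diff(series.t_h)
        cuts = np.flatnonzero(gaps > max_gap_h) + 1
        if len(cuts):
            episodes: list[FeverEpisode] = []
            for lo, hi in zip(np.r_[0, cuts], np.r_[cuts, len(series.t_h)]):
                seg = TemperatureSeries(
                    series.child_id, series.t_h[lo:hi], series.temp_c[lo:hi])
                episodes.extend(detect_episodes(seg, threshold_c))
            return episodes
    t, y = series.t_h, series.temp_c
    feb = y >= threshold_c
    episodes: list[FeverEpisode] = []
    n = len(t)
    i = 0
    while i < n:
        if not feb[i]:
            i += 1
            continue
        # onset: interpolated crossing on the inbound segment, or the first
        # reading if the series starts febrile
        if i == 0:
            onset = t[0]
        else:
            onset = _crossing(t[i - 1], y[i - 1], t[i], y[i], threshold_c)
        j = i
        while j + 1 < n and feb[j + 1]:
            j += 1
        max_temp = float(np.max(y[i:j + 1]))
        if j == n - 1:
            episodes.append(FeverEpisode(
                series.child_id, _dt(onset), None, None, max_temp))
            break
        offset = _crossing(t[j], y[j], t[j + 1], y[j + 1], threshold_c)
        episodes.append(FeverEpisode(
            series.child_id, _dt(onset), _dt(offset),
            float(offset - onset), max_temp))
        i = j + 1
    return episodes


def _dt(t_h: float) -> datetime:
    return from_hours([t_h])[0].to_pydatetime()


def episodes_to_frame(episodes: Sequence[FeverEpisode]) -> pd.DataFrame:
    """Flatten episodes to the ``episodes.csv`` schema."""
    return pd.DataFrame({
        "child_id": [e.child_id for e in episodes],
        "onset_time": [e.onset_time for e in episodes],
        "offset_time": [e.offset_time for e in episodes],
        "duration_h": [e.duration_h for e in episodes],
        "max_temp_c": [e.max_temp_c for e in episodes],
    })
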