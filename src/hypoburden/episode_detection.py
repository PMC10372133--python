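"""Threshold-excursion and alarm-episode detection on MAP/HPI traces.

Hypotensive (MAP below threshold) and hypertensive (MAP above threshold)
excursions are delimited by linearly interpolated threshold crossings
between adjacent samples; a value exactly at the threshold counts as the
non-excursion side (the clinical definitions are strict inequalities).
A span qualifies as an *event* only when its interpolated duration is
strictly greater than the minimum-duration rule (default: 1 min).  Shorter
spans are still returned by :func:`threshold_spans` so that area bookkeeping
can include them.

Alarm episodes on the risk-index channel use a two-sided hysteresis on the
sample grid: the index must sit at/above the trigger for at least 60 s of
consecutive samples to open an alarm, and below the trigger for at least
60 s to close it, so two high spells separated by a shorter dip merge into
one alarm.

Recording gaps (inter-sample intervals > 1.5x the nominal interval) split
the trace: no excursion is interpolated across a gap and gaps contribute
neither time nor area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Literal, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import MissingChannelError, ValidationError
from .timeseries_io import GAP_FACTOR, MapSeries

Direction = Literal["below", "above"]

#: Minimum excursion duration for an event, seconds ("for > 1 min", strict).
DEFAULT_MIN_DURATION_S = 60.0

#: Risk-index alarm trigger and the onset/offset persistence requirement.
ALARM_TRIGGER = 85.0
ALARM_PERSISTENCE_S = 60.0


@dataclass
class Episode:
    """A contiguous excursion of MAP beyond a threshold."""

    start_s: float
    end_s: float
    direction: Direction
    threshold_mmHg: float
    nadir_or_peak_mmHg: float
    area_mmHg_min: float

    @property
    def duration_min(self) -> float:
        return (self.end_s - self.start_s) / 60.0

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class AlarmEpisode:
    """A sustained high-risk-index spell (trigger-with-hysteresis)."""

    start_s: float
    end_s: float
    peak_index: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _chunk_bounds(t: np.ndarray, nominal_interval_s: float, gap_factor: float) -> List[Tuple[int, int]]:
    """Index ranges [i, j] of maximal gap-free runs of samples."""
    dt = np.diff(t)
    gap_idx = np.flatnonzero(dt > gap_factor * nominal_interval_s)
    bounds = []
    start = 0
    for g in gap_idx:
        bounds.append((start, int(g)))
        start = int(g) + 1
    bounds.append((start, len(t) - 1))
    return [(i, j) for i, j in bounds if j > i]


def _spans_from_deficit(t: np.ndarray, d: np.ndarray) -> List[Tuple[float, float, int, int, float]]:
    """Maximal runs where the deficit d > 0, with interpolated boundaries.

    Returns tuples ``(start_s, end_s, i_first, i_last, area_units_s)`` where
    area integrates the piecewise-linear deficit over [start, end] exactly.
    """
    active = d > 0
    spans: List[Tuple[float, float, int, int, float]] = []
    n = len(t)
    i = 0
    while i < n:
        if not active[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and active[j + 1]:
            j += 1
        if i == 0:
            start = float(t[0])
            lead = 0.0
        else:
            # d[i-1] <= 0 < d[i]; linear crossing of zero deficit
            start = float(t[i - 1] + (t[i] - t[i - 1]) * (-d[i - 1]) / (d[i] - d[i - 1]))
            lead = 0.5 * (t[i] - start) * d[i]
        if j == n - 1:
            end = float(t[-1])
            tail = 0.0
        else:
            end = float(t[j] + (t[j + 1] - t[j]) * d[j] / (d[j] - d[j + 1]))
            tail = 0.5 * (end - t[j]) * d[j]
        core = float(np.trapezoid(d[i : j + 1], t[i : j + 1])) if j > i else 0.0
        spans.append((start, end, i, j, lead + core + tail))
        i = j + 1
    return spans


def threshold_spans(
    series: MapSeries,
    threshold_mmHg: float,
    direction: Direction,
    gap_factor: float = GAP_FACTOR,
) -> List[Episode]:
    """All maximal threshold excursions, regardless of duration.

    Crossing times are linearly interpolated; spans never straddle a
    recording gap.  The per-span area is the exact integral of the
    piecewise-linear deficit, in mmHg*min.
    """
    if len(series) < 2:
        raise ValidationError(f"{series.patient_id}: need at least 2 samples")
    if direction not in ("below", "above"):
        raise ValueError(f"direction must be 'below' or 'above', got {direction!r}")
    sign = 1.0 if direction == "below" else -1.0
    d_all = sign * (threshold_mmHg - series.map_mmHg)
    episodes: List[Episode] = []
    for i0, i1 in _chunk_bounds(series.t, series.nominal_interval_s, gap_factor):
        t = series.t[i0 : i1 + 1]
        d = d_all[i0 : i1 + 1]
        m = series.map_mmHg[i0 : i1 + 1]
        for start, end, i, j, area_s in _spans_from_deficit(t, d):
            extreme = float(m[i : j + 1].min() if direction == "below" else m[i : j + 1].max())
            episodes.append(
                Episode(
                    start_s=start,
                    end_s=end,
                    direction=direction,
                    threshold_mmHg=threshold_mmHg,
                    nadir_or_peak_mmHg=extreme,
                    area_mmHg_min=area_s / 60.0,
                )
            )
    return episodes


def _merge_spans(episodes: List[Episode], merge_gap_s: float) -> List[Episode]:
    if merge_gap_s <= 0 or len(episodes) < 2:
        return episodes
    merged = [episodes[0]]
    for ep in episodes[1:]:
        prev = merged[-1]
        if ep.start_s - prev.end_s < merge_gap_s:
            better = (
                min(prev.nadir_or_peak_mmHg, ep.nadir_or_peak_mmHg)
                if ep.direction == "below"
                else max(prev.nadir_or_peak_mmHg, ep.nadir_or_peak_mmHg)
            )
            merged[-1] = Episode(
                start_s=prev.start_s,
                end_s=ep.end_s,
                direction=ep.direction,
                threshold_mmHg=ep.threshold_mmHg,
                nadir_or_peak_mmHg=better,
                area_mmHg_min=prev.area_mmHg_min + ep.area_mmHg_min,
            )
        else:
            merged.append(ep)
    return merged


def detect_episodes(
    series: MapSeries,
    threshold_mmHg: float,
    direction: Direction,
    min_duration_s: float = DEFAULT_MIN_DURATION_S,
    merge_gap_s: float = 0.0,
    gap_factor: float = GAP_FACTOR,
) -> List[Episode]:
    """Qualifying threshold excursions (duration strictly > ``min_duration_s``).

    ``merge_gap_s`` > 0 merges excursions separated by less than that much
    recovered time before the duration filter is applied (off by default:
    event starts and ends are defined purely by threshold crossing).
    """
    if min_duration_s < 0:
        raise ValueError("min_duration_s must be non-negative")
    spans = threshold_spans(series, threshold_mmHg, direction, gap_factor)
    spans = _merge_spans(spans, merge_gap_s)
    return [ep for ep in spans if ep.duration_s > min_duration_s]


def detect_alarms(
    series: MapSeries,
    trigger: float = ALARM_TRIGGER,
    min_on_s: float = ALARM_PERSISTENCE_S,
    min_off_s: float = ALARM_PERSISTENCE_S,
) -> List[AlarmEpisode]:
    """Risk-index alarms: >= ``min_on_s`` at/above trigger to open, and a
    normalized spell of >= ``min_off_s`` below trigger to close.

    The index is only defined at sample times, so the hysteresis runs on the
    sample grid: with the nominal 20-s interval, 60 s corresponds to three
    consecutive samples.  The alarm spans from the first sample of the
    opening run to the last at-or-above-trigger sample before closure.
    """
    if "hpi" not in series.channels:
        raise MissingChannelError("hpi", f"patient {series.patient_id}")
    hpi = series.channels["hpi"]
    t = series.t
    k_on = max(1, math.ceil(min_on_s / series.nominal_interval_s))
    k_off = max(1, math.ceil(min_off_s / series.nominal_interval_s))

    high = hpi >= trigger
    # run-length encode
    runs: List[Tuple[bool, int, int]] = []
    i = 0
    n = len(high)
    while i < n:
        j = i
        while j + 1 < n and high[j + 1] == high[i]:
            j += 1
        runs.append((bool(high[i]), i, j))
        i = j + 1

    alarms: List[AlarmEpisode] = []
    open_start: float | None = None
    last_on: int | None = None
    for is_high, i0, i1 in runs:
        length = i1 - i0 + 1
        if is_high:
            if open_start is None and length >= k_on:
                open_start = float(t[i0])
            if open_start is not None:
                last_on = i1
        else:
            if open_start is not None and length >= k_off:
                assert last_on is not None
                seg = hpi[np.searchsorted(t, open_start) : last_on + 1]
                alarms.append(AlarmEpisode(open_start, float(t[last_on]), float(seg.max())))
                open_start = None
                last_on = None
    if open_start is not None and last_on is not None:
        seg = hpi[np.searchsorted(t, open_start) : last_on + 1]
        alarms.append(AlarmEpisode(open_start, float(t[last_on]), float(seg.max())))
    return alarms


def episodes_to_frame(episodes: Sequence[Episode], patient_id: str = "") -> pd.DataFrame:
    """Serialize an episode list to a flat table (one row per episode)."""
    return pd.DataFrame(
        [
            {
                "patient_id": patient_id,
                "threshold_mmHg": ep.threshold_mmHg,
                "direction": ep.direction,
                "start_s": ep.start_s,
                "end_s": ep.end_s,
                "duration_min": ep.duration_min,
                "nadir_or_peak_mmHg": ep.nadir_or_peak_mmHg,
                "area_mmHg_min": ep.area_mmHg_min,
            }
            for ep in episodes
        ],
        columns=[
            "patient_id",
            "threshold_mmHg",
            "direction",
            "start_s",
            "end_s",
            "duration_min",
            "nadir_or_peak_mmHg",
            "area_mmHg_min",
        ],
    )
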