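"""Per-patient hypotension/hypertension burden statistics.

The central quantity is the time-weighted average (TWA) of MAP beyond a
threshold::

    TWA = AUC / monitoring time
    AUC = integral of the MAP deficit beyond the threshold (mmHg * min)

computed by the trapezoid rule on the piecewise-linear trace, with episode
boundaries located by interpolated threshold crossings.  The AUC integrates
*all* time beyond the threshold, including excursions too short to qualify
as events; event counts and summed event durations apply the >1-min rule.
The TWA denominator is the elapsed window time minus recording gaps longer
than ``max_gap_s`` (short gaps stay in the denominator but contribute no
area, matching a first-to-last-measurement definition of monitoring time).

Burdens can be evaluated over the full monitoring window or over the first
20 minutes after induction of general anesthesia, where post-induction
hypotension concentrates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .episode_detection import (
    DEFAULT_MIN_DURATION_S,
    Direction,
    _spans_from_deficit,
)
from .errors import ValidationError
from .timeseries_io import (
    DEFAULT_MAX_GAP_S,
    GAP_FACTOR,
    MapSeries,
    PatientRecord,
)

#: Length of the post-induction analysis window, seconds.
INDUCTION_WINDOW_S = 1200.0

#: Trial thresholds: hypotension, severe hypotension, hypertension, severe
#: hypertension.
DEFAULT_THRESHOLDS: Tuple[Tuple[float, Direction], ...] = (
    (65.0, "below"),
    (50.0, "below"),
    (110.0, "above"),
    (130.0, "above"),
)


@dataclass
class BurdenSummary:
    """Burden metrics for one patient at one threshold over one window."""

    patient_id: str
    threshold_mmHg: float
    direction: Direction
    window: str
    window_min: float
    n_events: int
    total_duration_min: float
    pct_time: float
    auc_mmHg_min: float
    twa_mmHg: float


def induction_window(record: PatientRecord) -> Tuple[float, float]:
    """The first 20 min after induction, truncated at end of monitoring.

    Returned in absolute trace time (seconds).
    """
    if record.induction_time_s is None:
        raise ValidationError(f"{record.patient_id}: induction_time_s is not set")
    t0 = float(record.series.t[0])
    a = t0 + record.induction_time_s
    b = min(a + INDUCTION_WINDOW_S, float(record.series.t[-1]))
    if b <= a:
        raise ValidationError(
            f"{record.patient_id}: induction window [{a}, {b}] is empty"
        )
    return a, b


def _clip_to_window(
    t: np.ndarray,
    m: np.ndarray,
    a: float,
    b: float,
    gap_seg: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Restrict (t, m) to [a, b], interpolating boundary values.

    ``gap_seg[k]`` flags the original segment [t[k], t[k+1]] as a recording
    gap; the returned per-segment flags inherit from the segment each new
    interval falls inside, so a window edge inside a gap does not turn the
    gap into monitored time.
    """
    i0 = int(np.searchsorted(t, a, side="right"))
    i1 = int(np.searchsorted(t, b, side="left"))
    new_t = np.concatenate(([a], t[i0:i1], [b]))
    new_m = np.interp(new_t, t, m)
    seg_of = np.clip(np.searchsorted(t, new_t[:-1], side="right") - 1, 0, len(gap_seg) - 1)
    return new_t, new_m, gap_seg[seg_of]


def compute_burden(
    series: MapSeries,
    threshold_mmHg: float,
    direction: Direction,
    window: Optional[Tuple[float, float]] = None,
    window_label: Optional[str] = None,
    min_duration_s: float = DEFAULT_MIN_DURATION_S,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
    gap_factor: float = GAP_FACTOR,
    auc_qualifying_only: bool = False,
) -> BurdenSummary:
    """Burden metrics at one threshold over ``window`` (default: full trace).

    ``auc_qualifying_only=False`` (default) integrates every excursion into
    the AUC while counting only >``min_duration_s`` excursions as events;
    setting it restricts the AUC to qualifying events as well.
    """
    t, m = series.t, series.map_mmHg
    t_first, t_last = float(t[0]), float(t[-1])
    if window is None:
        a, b = t_first, t_last
        label = window_label or "full"
    else:
        a, b = float(window[0]), float(window[1])
        label = window_label or "custom"
    if b <= a:
        raise ValidationError(f"{series.patient_id}: empty window [{a}, {b}]")
    if a < t_first - 1e-9 or b > t_last + 1e-9:
        raise ValidationError(
            f"{series.patient_id}: window [{a}, {b}] outside the monitoring "
            f"span [{t_first}, {t_last}]"
        )

    dt = np.diff(t)
    gap_seg = dt > gap_factor * series.nominal_interval_s
    wt, wm, wgap = _clip_to_window(t, m, a, b, gap_seg)

    # denominator: elapsed window time minus long gaps (judged on the gap's
    # full length, subtracting only the part inside the window)
    window_s = b - a
    for k in np.flatnonzero(gap_seg):
        if dt[k] > max_gap_s:
            window_s -= max(0.0, min(b, t[k + 1]) - max(a, t[k]))
    if window_s <= 0:
        raise ValidationError(f"{series.patient_id}: window [{a}, {b}] is all gap")

    sign = 1.0 if direction == "below" else -1.0
    d = sign * (threshold_mmHg - wm)

    # split at gap segments; detect spans chunk-wise
    spans: List[Tuple[float, float, float]] = []  # (start, end, area_mmHg_s)
    # wgap[k] flags interval between wt[k] and wt[k+1]; chunks are the runs
    # between flagged intervals
    chunk_edges: List[Tuple[int, int]] = []
    start = 0
    for k in np.flatnonzero(wgap):
        chunk_edges.append((start, int(k)))
        start = int(k) + 1
    chunk_edges.append((start, len(wt) - 1))
    for i0, i1 in chunk_edges:
        if i1 <= i0:
            continue
        for s0, s1, _, _, area_s in _spans_from_deficit(wt[i0 : i1 + 1], d[i0 : i1 + 1]):
            spans.append((s0, s1, area_s))

    qualifying = [(s0, s1, ar) for s0, s1, ar in spans if (s1 - s0) > min_duration_s]
    auc_spans = qualifying if auc_qualifying_only else spans
    auc_mmHg_min = sum(ar for _, _, ar in auc_spans) / 60.0
    time_beyond_s = sum(s1 - s0 for s0, s1, _ in spans)
    window_min = window_s / 60.0

    return BurdenSummary(
        patient_id=series.patient_id,
        threshold_mmHg=threshold_mmHg,
        direction=direction,
        window=label,
        window_min=window_min,
        n_events=len(qualifying),
        total_duration_min=sum(s1 - s0 for s0, s1, _ in qualifying) / 60.0,
        pct_time=100.0 * time_beyond_s / window_s,
        auc_mmHg_min=auc_mmHg_min,
        twa_mmHg=auc_mmHg_min / window_min,
    )


def _normalize_thresholds(
    thresholds: Optional[Sequence[Union[float, Tuple[float, Direction]]]],
) -> List[Tuple[float, Direction]]:
    if thresholds is None:
        return list(DEFAULT_THRESHOLDS)
    out: List[Tuple[float, Direction]] = []
    for item in thresholds:
        if isinstance(item, (tuple, list)):
            th, direction = item
            out.append((float(th), direction))
        else:
            # bare numbers: hypotension thresholds sit well below typical MAP,
            # hypertension thresholds well above
            out.append((float(item), "below" if float(item) < 90.0 else "above"))
    return out


def cohort_burden_table(
    records: Sequence[PatientRecord],
    thresholds: Optional[Sequence[Union[float, Tuple[float, Direction]]]] = None,
    windows: Sequence[str] = ("full", "induction20"),
    min_duration_s: float = DEFAULT_MIN_DURATION_S,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
) -> pd.DataFrame:
    """One row per patient x threshold x window, in deterministic order."""
    if not records:
        raise ValidationError("cohort_burden_table needs at least one record")
    th_list = _normalize_thresholds(thresholds)
    rows = []
    for rec in sorted(records, key=lambda r: r.patient_id):
        for th, direction in th_list:
            for wname in windows:
                if wname == "full":
                    window = None
                elif wname == "induction20":
                    window = induction_window(rec)
                else:
                    raise ValueError(f"unknown window {wname!r}")
                summ = compute_burden(
                    rec.series,
                    th,
                    direction,
                    window=window,
                    window_label=wname,
                    min_duration_s=min_duration_s,
                    max_gap_s=max_gap_s,
                )
                rows.append(
                    {
                        "patient_id": rec.patient_id,
                        "arm": rec.arm,
                        "threshold_mmHg": th,
                        "direction": direction,
                        "window": wname,
                        "window_min": summ.window_min,
                        "n_events": summ.n_events,
                        "total_duration_min": summ.total_duration_min,
                        "pct_time": summ.pct_time,
                        "auc_mmHg_min": summ.auc_mmHg_min,
                        "twa_mmHg": summ.twa_mmHg,
                    }
                )
    return pd.DataFrame(rows)
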