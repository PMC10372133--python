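"""Deterministic rule engines for the two hemodynamic management arms.

The intervention arm reacts to the predictive risk index: once the index
reaches its trigger (>= 85), a secondary screen classifies the impending
instability by mechanism — hypovolemia (fluid-responsive, SVV high),
depressed contractility (dP/dt_max low), or vasoplegia (dynamic arterial
elastance Ea_dyn = PPV/SVV low) — and maps it to fluids, an inotrope, a
vasopressor, or fluids plus vasopressor.  Only the SVV cutoff (13%) is a
protocol constant; the dP/dt_max and Ea_dyn bounds are configurable
implementation defaults, exposed through :class:`RuleThresholds`.

The control arm is conventional stroke-volume-index optimization: an
initial fluid loading of up to 500 ml establishes a maximal-SVI reference;
thereafter 250-ml fluid challenges are repeated only when SVI falls > 10%
from the reference or SVV exceeds 13%, and a vasopressor is given —
independently — whenever MAP drops below 65 mmHg.  The control protocol
never schedules an inotrope.

Both engines are pure functions of the hemodynamic state they are given.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple, Union

from .episode_detection import AlarmEpisode, Episode
from .errors import MissingChannelError
from .timeseries_io import PatientRecord

ACTIONS = (
    "none",
    "fluid_bolus_250",
    "fluid_up_to_500_initial",
    "fluid_plus_vasopressor",
    "vasopressor",
    "inotrope",
)

NOREPINEPHRINE_START = ("norepinephrine", 0.1, "mcg/kg/min")
DOBUTAMINE_START = ("dobutamine", 2.5, "mcg/kg/min")


@dataclass(frozen=True)
class RuleThresholds:
    """Cutoffs for the decision tables.

    ``svv_high_pct`` is the stated protocol value; ``dpdt_low_mmHg_s`` and
    ``eadyn_low`` are implementation defaults for the secondary screen and
    should be tuned to local practice.
    """

    hpi_trigger: float = 85.0
    svv_high_pct: float = 13.0
    dpdt_low_mmHg_s: float = 400.0
    eadyn_low: float = 0.9
    map_low_mmHg: float = 65.0
    svi_drop_frac: float = 0.10
    initial_fluid_cap_ml: float = 500.0


DEFAULT_THRESHOLDS = RuleThresholds()


@dataclass(frozen=True)
class HemoState:
    """A snapshot of the monitored hemodynamic variables."""

    map_mmHg: float
    hpi: Optional[float] = None
    svv_pct: Optional[float] = None
    svi_ml_m2: Optional[float] = None
    svi_reference_ml_m2: Optional[float] = None
    dpdt_mmHg_s: Optional[float] = None
    eadyn_unitless: Optional[float] = None
    cumulative_initial_fluid_ml: float = 0.0
    initial_optimization_complete: bool = True


@dataclass(frozen=True)
class Recommendation:
    """The engine's suggested intervention for one state snapshot."""

    action: str
    drug_default: Optional[Tuple[str, float, str]] = None  # (drug, dose, unit)
    rationale_tag: Optional[str] = None


_NONE = Recommendation(action="none")


def recommend_hpi_arm(
    state: HemoState, thresholds: RuleThresholds = DEFAULT_THRESHOLDS
) -> Recommendation:
    """Intervention-arm engine: trigger on the risk index, then classify.

    Branch order: hypovolemia -> low contractility -> vasoplegia.  A
    fluid-responsive state that is simultaneously vasoplegic gets fluids
    plus vasopressor.  With the index high but no mechanism flagged, the
    engine falls back to pressure support alone.
    """
    if state.hpi is None:
        raise MissingChannelError("hpi", "intervention-arm engine")
    if state.hpi < thresholds.hpi_trigger:
        return _NONE
    if state.svv_pct is None:
        raise MissingChannelError("svv_pct", "secondary screen")
    if state.svv_pct > thresholds.svv_high_pct:
        vasoplegic = (
            state.eadyn_unitless is not None
            and state.eadyn_unitless < thresholds.eadyn_low
        )
        if vasoplegic:
            return Recommendation(
                "fluid_plus_vasopressor", NOREPINEPHRINE_START, "hypovolemia"
            )
        return Recommendation("fluid_bolus_250", None, "hypovolemia")
    if state.dpdt_mmHg_s is None:
        raise MissingChannelError("dpdt_mmHg_s", "secondary screen")
    if state.dpdt_mmHg_s < thresholds.dpdt_low_mmHg_s:
        return Recommendation("inotrope", DOBUTAMINE_START, "low_contractility")
    if state.eadyn_unitless is None:
        raise MissingChannelError("eadyn_unitless", "secondary screen")
    if state.eadyn_unitless < thresholds.eadyn_low:
        return Recommendation("vasopressor", NOREPINEPHRINE_START, "vasoplegia")
    return Recommendation("vasopressor", NOREPINEPHRINE_START, "pressure_only")


def recommend_control_arm(
    state: HemoState, thresholds: RuleThresholds = DEFAULT_THRESHOLDS
) -> Recommendation:
    """Control-arm engine: SVI optimization plus MAP rescue, no inotrope."""
    if not state.initial_optimization_complete:
        if state.cumulative_initial_fluid_ml < thresholds.initial_fluid_cap_ml:
            return Recommendation("fluid_up_to_500_initial", None, "hypovolemia")
    if state.svi_ml_m2 is None:
        raise MissingChannelError("svi_ml_m2", "control-arm engine")
    if state.svi_reference_ml_m2 is None:
        raise MissingChannelError("svi_reference_ml_m2", "control-arm engine")
    svi_low = state.svi_ml_m2 < (1.0 - thresholds.svi_drop_frac) * state.svi_reference_ml_m2
    svv_high = state.svv_pct is not None and state.svv_pct > thresholds.svv_high_pct
    needs_fluid = svi_low or svv_high
    needs_pressor = state.map_mmHg < thresholds.map_low_mmHg
    if needs_fluid and needs_pressor:
        return Recommendation("fluid_plus_vasopressor", NOREPINEPHRINE_START, "hypovolemia")
    if needs_fluid:
        return Recommendation("fluid_bolus_250", None, "hypovolemia")
    if needs_pressor:
        return Recommendation("vasopressor", NOREPINEPHRINE_START, "pressure_only")
    return _NONE


@dataclass(frozen=True)
class SviOptimizationState:
    """Running maximal-SVI reference and whether optimization has plateaued."""

    reference_ml_m2: float
    optimization_complete: bool


def update_svi_reference(
    history: Sequence[Tuple[float, float]],
    challenge_times: Optional[Sequence[float]] = None,
    rise_frac: float = 0.10,
    sustain_s: float = 600.0,
) -> SviOptimizationState:
    """Maximal-SVI tracking during initial fluid optimization.

    ``history`` is an ordered list of ``(time_s, svi)`` observations.  The
    reference is the running maximum.  Optimization is declared complete
    when the most recent fluid challenge failed to produce a rise of at
    least ``rise_frac`` over the pre-challenge SVI sustained for more than
    ``sustain_s`` (10 min).  With no challenges yet, optimization is still
    in progress.
    """
    if not history:
        raise ValueError("history must contain at least one observation")
    times = [float(t) for t, _ in history]
    svis = [float(v) for _, v in history]
    reference = max(svis)
    if not challenge_times:
        return SviOptimizationState(reference, False)
    tc = max(challenge_times)
    pre = [v for t, v in zip(times, svis) if t <= tc]
    if not pre:
        raise ValueError("no SVI observation at or before the last fluid challenge")
    target = (1.0 + rise_frac) * pre[-1]
    # longest contiguous run of post-challenge samples at/above target
    run_start: Optional[float] = None
    run_end: Optional[float] = None
    sustained = False
    for t, v in zip(times, svis):
        if t <= tc:
            continue
        if v >= target:
            if run_start is None:
                run_start = t
            run_end = t
            if run_end - run_start > sustain_s:
                sustained = True
        else:
            run_start = None
            run_end = None
    return SviOptimizationState(reference, optimization_complete=not sustained)


OnsetLike = Union[Episode, AlarmEpisode, float]


def _onset_time(item: OnsetLike) -> float:
    if isinstance(item, (Episode, AlarmEpisode)):
        return item.start_s
    return float(item)


def treatment_latencies(
    record: PatientRecord,
    episodes_or_alarms: Sequence[OnsetLike],
) -> List[float]:
    """Onset-to-first-treatment delays, one per treated event.

    For each alarm (intervention arm) or hypotensive-episode onset (control
    arm), the latency is the delay to the first treatment at or after the
    onset and before the next onset; events with no treatment in their
    window contribute nothing.
    """
    onsets = sorted(_onset_time(x) for x in episodes_or_alarms)
    tx_times = [ev.time_s for ev in record.treatments]  # already sorted
    latencies: List[float] = []
    for k, onset in enumerate(onsets):
        nxt = onsets[k + 1] if k + 1 < len(onsets) else float("inf")
        for t in tx_times:
            if onset <= t < nxt:
                latencies.append(t - onset)
                break
    return latencies
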