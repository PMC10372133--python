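"""Synthetic two-arm cohorts with trial-like hypotension structure.

Real per-patient monitor exports from hemodynamic-management trials are
rarely public, so this module generates cohorts whose *pipeline-computed*
summaries — per-arm medians of TWA-MAP<65, hypotensive-event counts and
durations, monitoring times, and alarm/onset-to-treatment latencies —
land inside the interquartile bands reported for a 30-per-arm trial of
predictive-index-guided versus conventional goal-directed management.

Each patient's trace is a noisy baseline plateau with superimposed
raised-cosine hypotensive dips (smooth, integrable in closed form, so
burden oracles have exact references) and occasional hypertensive bumps.
Intervention-arm records carry a simulated risk-index channel built from a
logistic transform of the forward-looking minimum of the latent MAP
trajectory: the index crosses its alarm trigger a configurable lead time
before each dip, which is the qualitative behaviour of a hypotension
predictor without any claim of modelling the proprietary algorithm.
Treatment events are placed at alarm onset (intervention arm) or
hypotension onset (control arm) plus a sampled log-normal latency.

All randomness flows from one seed; per-patient substreams are derived by
stable hashing of the patient id, so cohorts are reproducible sample-for-
sample and insensitive to generation order.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .episode_detection import detect_alarms, detect_episodes
from .errors import ConfigError
from .protocol_engine import HemoState, recommend_hpi_arm
from .timeseries_io import (
    ARM_CONTROL,
    ARM_HPI,
    MapSeries,
    PatientRecord,
    TreatmentEvent,
)

HYPO_THRESHOLD = 65.0
MECHANISMS = ("hypovolemia", "vasoplegia", "low_contractility")


@dataclass(frozen=True)
class LogNormalSpec:
    """Log-normal distribution parameterized by median and log-scale SD."""

    median: float
    sigma: float

    def sample(self, rng: np.random.Generator, size=None):
        return self.median * np.exp(self.sigma * rng.standard_normal(size))


@dataclass(frozen=True)
class GammaSpec:
    shape: float
    scale: float

    def sample(self, rng: np.random.Generator, size=None):
        return rng.gamma(self.shape, self.scale, size)


@dataclass(frozen=True)
class NegBinSpec:
    """Over-dispersed count distribution (mean / dispersion r)."""

    mean: float
    dispersion: float

    def sample(self, rng: np.random.Generator) -> int:
        if self.mean <= 0:
            return 0
        r = self.dispersion
        p = r / (r + self.mean)
        return int(rng.negative_binomial(r, p))


@dataclass(frozen=True)
class InductionDipSpec:
    """An additional dip inside the first 20 min after induction."""

    prob: float
    depth_mult: float = 1.3
    duration_mult: float = 1.3


@dataclass(frozen=True)
class ArmProfile:
    """Generative parameters for one randomization arm."""

    n_patients: int
    monitoring_min: LogNormalSpec
    baseline_map: Tuple[float, float]  # (mean, sd) of the plateau, mmHg
    episodes_per_patient: NegBinSpec
    episode_depth_mmHg: GammaSpec  # nadir depth below 65
    episode_duration_min: LogNormalSpec  # time below 65 per episode
    induction_dip: InductionDipSpec
    hypertension_rate: float  # mean excursions above 110 per patient
    treatment_latency_s: LogNormalSpec
    alarm_lead_s: float = 120.0
    false_alarms_per_h: float = 0.2
    has_hpi_channel: bool = False
    treat_prob: float = 0.9
    mechanism_probs: Tuple[float, float, float] = (0.45, 0.35, 0.20)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        for name in ("hypertension_rate", "alarm_lead_s", "false_alarms_per_h"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")


@dataclass(frozen=True)
class CohortConfig:
    profiles: Dict[str, ArmProfile]
    sampling_interval_s: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        missing = [a for a in (ARM_HPI, ARM_CONTROL) if a not in self.profiles]
        if missing:
            raise ConfigError(f"missing arm profile(s): {missing}")
        if self.sampling_interval_s <= 0:
            raise ConfigError("sampling_interval_s must be positive")


def default_trial_profiles(seed: int = 0) -> CohortConfig:
    """Trial-like defaults for a 30 + 30 cohort.

    Dip depth/duration/count parameters were derived from the closed-form
    raised-cosine area so that pipeline medians of TWA-MAP<65 (~0.14 vs
    ~0.77 mmHg), events per patient (~2 vs ~7), total event duration (~7 vs
    ~35 min) and monitoring time (~253 vs ~325 min) match the two arms.
    """
    hpi = ArmProfile(
        n_patients=30,
        monitoring_min=LogNormalSpec(253.0, 0.354),
        baseline_map=(78.0, 3.0),
        episodes_per_patient=NegBinSpec(2.2, 1.4),
        episode_depth_mmHg=GammaSpec(3.0, 4.2),
        episode_duration_min=LogNormalSpec(2.6, 0.5),
        induction_dip=InductionDipSpec(prob=0.67, depth_mult=1.2, duration_mult=1.2),
        hypertension_rate=0.7,
        treatment_latency_s=LogNormalSpec(60.0, 1.44),
        alarm_lead_s=120.0,
        false_alarms_per_h=0.2,
        has_hpi_channel=True,
    )
    control = ArmProfile(
        n_patients=30,
        monitoring_min=LogNormalSpec(325.0, 0.419),
        baseline_map=(78.0, 3.0),
        episodes_per_patient=NegBinSpec(7.0, 3.0),
        episode_depth_mmHg=GammaSpec(3.0, 4.2),
        episode_duration_min=LogNormalSpec(4.4, 0.5),
        induction_dip=InductionDipSpec(prob=0.94, depth_mult=1.3, duration_mult=1.4),
        hypertension_rate=0.13,
        treatment_latency_s=LogNormalSpec(190.0, 1.27),
        has_hpi_channel=False,
    )
    return CohortConfig(profiles={ARM_HPI: hpi, ARM_CONTROL: control}, seed=seed)


# ---------------------------------------------------------------------------
# trace construction
# ---------------------------------------------------------------------------

@dataclass
class _Dip:
    start_s: float  # start of the raised-cosine window
    width_s: float
    amplitude: float  # plateau-to-nadir drop
    mechanism: str
    induction: bool = False

    @property
    def end_s(self) -> float:
        return self.start_s + self.width_s

    @property
    def center_s(self) -> float:
        return self.start_s + 0.5 * self.width_s


def _cosine_window_width(baseline_gap: float, depth: float, below_time_s: float) -> float:
    """Width of a raised-cosine dip whose below-threshold time is given.

    The dip drops ``baseline_gap + depth`` from the plateau; the trace is
    below threshold for the fraction of the window where the cosine exceeds
    the plateau-to-threshold gap.
    """
    b = baseline_gap
    amp = b + depth
    r = min(max(b / amp, 1e-6), 1.0 - 1e-6)
    theta_c = math.acos(1.0 - 2.0 * r)
    frac_below = 1.0 - theta_c / math.pi
    return below_time_s / frac_below


def _ar1(rng: np.random.Generator, n: int, sd: float, tau_s: float, dt: float) -> np.ndarray:
    """Stationary AR(1) wander with marginal SD ``sd`` and time constant tau."""
    phi = math.exp(-dt / tau_s)
    innov_sd = sd * math.sqrt(1.0 - phi * phi)
    x = np.empty(n)
    x[0] = sd * rng.standard_normal()
    eps = innov_sd * rng.standard_normal(n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def _forward_min(x: np.ndarray, k: int) -> np.ndarray:
    """fm[i] = min(x[i : i + k]) with a shrinking window at the tail."""
    k = min(max(k, 1), len(x))
    head = np.lib.stride_tricks.sliding_window_view(x, k).min(axis=1)
    tail = np.minimum.accumulate(x[::-1])[::-1][len(head):]
    return np.concatenate([head, tail])


def _place_dips(
    rng: np.random.Generator,
    dips_spec: List[Tuple[float, float, str, bool]],  # (amp, width_s, mech, induction)
    total_s: float,
    induction_s: float,
    margin_s: float = 120.0,
) -> List[_Dip]:
    placed: List[_Dip] = []
    for amp, width, mech, is_induction in dips_spec:
        lo, hi = 60.0, max(61.0, total_s - width - 60.0)
        if is_induction:
            lo = induction_s
            hi = max(lo + 1.0, min(induction_s + 1200.0 - width, total_s - width - 60.0))
        ok = None
        for _ in range(60):
            start = rng.uniform(lo, hi)
            if all(
                start + width + margin_s < d.start_s or start > d.end_s + margin_s
                for d in placed
            ):
                ok = start
                break
        if ok is None:
            continue  # trace too crowded; drop the dip
        placed.append(_Dip(ok, width, amp, mech, is_induction))
    return sorted(placed, key=lambda d: d.start_s)


def _cosine_bump(t: np.ndarray, start: float, width: float, amp: float) -> np.ndarray:
    """Raised-cosine pulse of height ``amp`` on [start, start + width]."""
    out = np.zeros_like(t)
    mask = (t >= start) & (t <= start + width)
    out[mask] = amp * 0.5 * (1.0 - np.cos(2.0 * math.pi * (t[mask] - start) / width))
    return out


def _patient_rng(seed: int, patient_id: str) -> np.random.Generator:
    h = zlib.crc32(patient_id.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, h]))


def _simulate_patient(
    patient_id: str,
    arm: str,
    profile: ArmProfile,
    dt: float,
    seed: int,
    engine_blunting: Optional[float] = None,
) -> PatientRecord:
    rng = _patient_rng(seed, patient_id)

    total_s = float(np.clip(profile.monitoring_min.sample(rng) * 60.0, 5400.0, 48_000.0))
    n = int(total_s // dt) + 1
    t = np.arange(n) * dt
    total_s = float(t[-1])
    induction_s = float(rng.uniform(240.0, 600.0))

    b_mean, b_sd = profile.baseline_map
    plateau = float(np.clip(rng.normal(b_mean, b_sd), 70.0, 95.0))
    wander = _ar1(rng, n, sd=2.0, tau_s=600.0, dt=dt)
    baseline_gap = plateau - HYPO_THRESHOLD

    # draw dips
    n_dips = profile.episodes_per_patient.sample(rng)
    has_induction_dip = rng.random() < profile.induction_dip.prob
    spec: List[Tuple[float, float, str, bool]] = []
    for k in range(n_dips + int(has_induction_dip)):
        is_ind = has_induction_dip and k == 0
        depth = float(profile.episode_depth_mmHg.sample(rng))
        below_min = float(profile.episode_duration_min.sample(rng))
        if is_ind:
            depth *= profile.induction_dip.depth_mult
            below_min *= profile.induction_dip.duration_mult
        depth = min(max(depth, 1.0), HYPO_THRESHOLD - 35.0)  # keep nadir above 35
        below_min = min(max(below_min, 0.4), 45.0)
        mech = MECHANISMS[rng.choice(3, p=list(profile.mechanism_probs))]
        spec.append((depth, below_min, mech, is_ind))

    if engine_blunting is not None and profile.has_hpi_channel:
        # closed-loop mode: each dip whose alarm draws an intervention from
        # the rule engine is blunted before it reaches the trace
        blunted = []
        for depth, below_min, mech, is_ind in spec:
            state = _state_for_mechanism(mech, rng)
            rec = recommend_hpi_arm(state)
            if rec.action != "none":
                depth *= engine_blunting
                below_min *= 0.7
            blunted.append((depth, below_min, mech, is_ind))
        spec = blunted

    dip_geom = [
        (
            baseline_gap + depth,
            _cosine_window_width(baseline_gap, depth, below_min * 60.0),
            mech,
            is_ind,
        )
        for depth, below_min, mech, is_ind in spec
    ]
    dips = _place_dips(rng, dip_geom, total_s, induction_s)

    latent = plateau + wander
    for d in dips:
        latent -= _cosine_bump(t, d.start_s, d.width_s, d.amplitude)

    # hypertensive bumps
    n_bumps = rng.poisson(profile.hypertension_rate)
    for _ in range(n_bumps):
        amp = (110.0 - plateau) + rng.gamma(2.0, 8.0)
        width = float(np.clip(180.0 * math.exp(0.5 * rng.standard_normal()), 90.0, 900.0))
        for _ in range(40):
            start = rng.uniform(60.0, max(61.0, total_s - width - 60.0))
            if all(start + width < d.start_s - 60.0 or start > d.end_s + 60.0 for d in dips):
                latent += _cosine_bump(t, start, width, amp)
                break

    measured = np.clip(latent + rng.normal(0.0, 0.8, n), 30.0, 240.0)

    channels = _make_channels(rng, t, dips, profile, latent)
    series = MapSeries(patient_id, t, measured, channels, nominal_interval_s=dt)

    treatments = _make_treatments(rng, series, dips, profile, total_s)

    return PatientRecord(
        series=series,
        arm=arm,
        induction_time_s=induction_s,
        weight_kg=float(np.clip(60.0 * math.exp(0.12 * rng.standard_normal()), 40.0, 120.0)),
        treatments=treatments,
        metadata={"age": int(np.clip(rng.normal(58, 11), 25, 85))},
    )


def _state_for_mechanism(mech: str, rng: np.random.Generator) -> HemoState:
    """Plausible secondary-screen snapshot for a dip of known mechanism."""
    svv = 17.0 if mech == "hypovolemia" else 8.0
    dpdt = 300.0 if mech == "low_contractility" else 700.0
    eadyn = 0.6 if mech == "vasoplegia" else 1.1
    return HemoState(
        map_mmHg=68.0,
        hpi=90.0 + 5.0 * rng.random(),
        svv_pct=svv,
        dpdt_mmHg_s=dpdt,
        eadyn_unitless=eadyn,
    )


def _make_channels(
    rng: np.random.Generator,
    t: np.ndarray,
    dips: List[_Dip],
    profile: ArmProfile,
    latent: np.ndarray,
) -> Dict[str, np.ndarray]:
    dt = t[1] - t[0] if len(t) > 1 else 20.0
    n = len(t)
    lead = profile.alarm_lead_s

    svv = 8.0 + _ar1(rng, n, 1.2, 900.0, dt)
    svi = 38.0 + _ar1(rng, n, 2.5, 900.0, dt)
    dpdt = 700.0 + _ar1(rng, n, 50.0, 900.0, dt)
    eadyn = 1.1 + _ar1(rng, n, 0.08, 900.0, dt)
    for d in dips:
        w0, w1 = d.start_s - lead, d.end_s
        width = w1 - w0
        if d.mechanism == "hypovolemia":
            svv += _cosine_bump(t, w0, width, 9.0)
            svi -= _cosine_bump(t, w0, width, 9.0)
        elif d.mechanism == "low_contractility":
            dpdt -= _cosine_bump(t, w0, width, 420.0)
        else:
            eadyn -= _cosine_bump(t, w0, width, 0.55)
    channels = {
        "svv_pct": np.clip(svv, 0.5, 40.0),
        "svi_ml_m2": np.clip(svi, 10.0, 80.0),
        "dpdt_mmHg_s": np.clip(dpdt, 100.0, 2000.0),
        "eadyn_unitless": np.clip(eadyn, 0.2, 3.0),
    }

    if profile.has_hpi_channel:
        k = int(round(lead / dt)) + 1
        fm = _forward_min(latent, k)
        hpi = 100.0 / (1.0 + np.exp((fm - 66.5) / 1.5))
        hpi += rng.normal(0.0, 1.5, n)
        n_false = rng.poisson(profile.false_alarms_per_h * (t[-1] - t[0]) / 3600.0)
        for _ in range(n_false):
            j = int(rng.integers(0, max(1, n - 5)))
            if fm[j] > HYPO_THRESHOLD + 3:  # only away from real dips
                hpi[j : j + 4] = rng.uniform(86.0, 95.0)
        channels["hpi"] = np.clip(hpi, 0.0, 100.0)
    return channels


_CONTROL_TX = (
    ("fluid_bolus", 250.0, "ml", 0.40),
    ("norepinephrine", 0.1, "mcg/kg/min", 0.30),
    ("ephedrine", 5.0, "mg", 0.15),
    ("etilefrine", 2.0, "mg", 0.15),
)

_MECH_TX = {
    "hypovolemia": ("fluid_bolus", 250.0, "ml"),
    "vasoplegia": ("norepinephrine", 0.1, "mcg/kg/min"),
    "low_contractility": ("dobutamine", 2.5, "mcg/kg/min"),
}


def _make_treatments(
    rng: np.random.Generator,
    series: MapSeries,
    dips: List[_Dip],
    profile: ArmProfile,
    total_s: float,
) -> List[TreatmentEvent]:
    events: List[TreatmentEvent] = []
    if profile.has_hpi_channel:
        onsets = [a.start_s for a in detect_alarms(series)]
        for onset in onsets:
            if rng.random() > profile.treat_prob:
                continue
            latency = float(profile.treatment_latency_s.sample(rng))
            t_tx = onset + latency
            if t_tx > total_s:
                continue
            near = [d for d in dips if onset - 60.0 <= d.start_s <= onset + 900.0]
            if near:
                kind, dose, unit = _MECH_TX[near[0].mechanism]
            else:
                kind, dose, unit = "norepinephrine", 0.1, "mcg/kg/min"
            events.append(TreatmentEvent(t_tx, kind, dose, unit))
    else:
        episodes = detect_episodes(series, HYPO_THRESHOLD, "below")
        for ep in episodes:
            if rng.random() > profile.treat_prob:
                continue
            latency = float(profile.treatment_latency_s.sample(rng))
            t_tx = ep.start_s + latency
            if t_tx > total_s:
                continue
            u = rng.random()
            acc = 0.0
            for kind, dose, unit, p in _CONTROL_TX:
                acc += p
                if u <= acc:
                    events.append(TreatmentEvent(t_tx, kind, dose, unit))
                    break
    return sorted(events, key=lambda ev: ev.time_s)


def generate_cohort(
    config: CohortConfig,
    seed: Optional[int] = None,
    engine_blunting: Optional[float] = None,
) -> List[PatientRecord]:
    """Generate one cohort; deterministic for a given config and seed.

    ``engine_blunting`` enables closed-loop mode: intervention-arm dips
    whose alarms draw a recommendation from the rule engine have their
    depth multiplied by the factor (and duration by 0.7) before the trace
    is rendered, emulating timely treatment.
    """
    use_seed = config.seed if seed is None else seed
    records: List[PatientRecord] = []
    for arm in (ARM_HPI, ARM_CONTROL):
        profile = config.profiles[arm]
        prefix = "H" if arm == ARM_HPI else "C"
        for i in range(profile.n_patients):
            pid = f"{prefix}{i + 1:03d}"
            records.append(
                _simulate_patient(
                    pid,
                    arm,
                    profile,
                    config.sampling_interval_s,
                    use_seed,
                    engine_blunting=engine_blunting if arm == ARM_HPI else None,
                )
            )
    return records


# ---------------------------------------------------------------------------
# YAML-friendly (de)serialization
# ---------------------------------------------------------------------------

def config_to_dict(config: CohortConfig) -> dict:
    return asdict(config)


def config_from_dict(data: dict) -> CohortConfig:
    profiles = {}
    for arm, p in data["profiles"].items():
        p = dict(p)
        p["monitoring_min"] = LogNormalSpec(**p["monitoring_min"])
        p["episodes_per_patient"] = NegBinSpec(**p["episodes_per_patient"])
        p["episode_depth_mmHg"] = GammaSpec(**p["episode_depth_mmHg"])
        p["episode_duration_min"] = LogNormalSpec(**p["episode_duration_min"])
        p["induction_dip"] = InductionDipSpec(**p["induction_dip"])
        p["treatment_latency_s"] = LogNormalSpec(**p["treatment_latency_s"])
        p["baseline_map"] = tuple(p["baseline_map"])
        p["mechanism_probs"] = tuple(p.get("mechanism_probs", (0.45, 0.35, 0.20)))
        profiles[arm] = ArmProfile(**p)
    return CohortConfig(
        profiles=profiles,
        sampling_interval_s=data.get("sampling_interval_s", 20.0),
        seed=data.get("seed", 0),
    )
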