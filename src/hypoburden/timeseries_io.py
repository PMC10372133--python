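"""Per-patient hemodynamic time series: containers, validation and CSV I/O.

A monitored patient is represented by a :class:`MapSeries` (mean arterial
pressure sampled nominally every 20 s, plus optional monitor channels such
as the hypotension-risk index, stroke volume variation, or dP/dt_max) and a
:class:`PatientRecord` that attaches the randomization arm, the time of
anesthesia induction, body weight and the intraoperative treatment log.

Cohorts live on disk as plain CSV: one ``<patient_id>.csv`` per patient
(columns ``time_s, map_mmHg`` plus optional channels), one metadata table
and one treatment log.  ``read_cohort``/``write_cohort`` round-trip these
files exactly (floats are written with full repr precision).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError

ARM_HPI = "HPI"
ARM_CONTROL = "Control"
ARM_LABELS = (ARM_HPI, ARM_CONTROL)

#: Nominal monitor reporting interval (the platforms update displayed
#: parameters every 20 s).
NOMINAL_INTERVAL_S = 20.0

#: A between-sample interval longer than this multiple of the nominal
#: interval is recorded as a recording gap.
GAP_FACTOR = 1.5

#: Gaps longer than this are excluded from the monitoring-time denominator;
#: shorter gaps stay inside monitoring time (which is defined first-to-last
#: measurement) but contribute no area and no time-below-threshold.
DEFAULT_MAX_GAP_S = 300.0

#: Channels understood by the readers; anything else in a series file is
#: preserved verbatim as an additional channel.
KNOWN_CHANNELS = (
    "hpi",
    "svv_pct",
    "svi_ml_m2",
    "dpdt_mmHg_s",
    "eadyn_unitless",
    "sbp_mmHg",
    "dbp_mmHg",
    "hr_bpm",
    "artifact",
)

TREATMENT_KINDS = (
    "fluid_bolus",
    "colloid",
    "norepinephrine",
    "ephedrine",
    "etilefrine",
    "dobutamine",
    "rbc_transfusion",
)

MAP_VALID_RANGE = (10.0, 250.0)


@dataclass
class MapSeries:
    """One patient's sampled arterial-pressure trace.

    Parameters
    ----------
    patient_id
        Opaque identifier; also the series file stem on disk.
    t
        Sample times in seconds since monitoring start, strictly increasing.
    map_mmHg
        Mean arterial pressure at each sample, in (10, 250) mmHg.
    channels
        Optional per-sample channels keyed by name, each the same length
        as ``t``.
    nominal_interval_s
        Expected sampling interval; used only to classify gaps.
    """

    patient_id: str
    t: np.ndarray
    map_mmHg: np.ndarray
    channels: Dict[str, np.ndarray] = field(default_factory=dict)
    nominal_interval_s: float = NOMINAL_INTERVAL_S

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.map_mmHg = np.asarray(self.map_mmHg, dtype=float)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        self.validate()

    def validate(self) -> None:
        if self.t.ndim != 1 or self.map_mmHg.ndim != 1:
            raise ValidationError(f"{self.patient_id}: t and map_mmHg must be 1-D")
        if len(self.t) != len(self.map_mmHg):
            raise ValidationError(
                f"{self.patient_id}: t has {len(self.t)} samples but "
                f"map_mmHg has {len(self.map_mmHg)}"
            )
        if len(self.t) < 2:
            raise ValidationError(f"{self.patient_id}: need at least 2 samples")
        if self.t[0] < 0:
            raise ValidationError(f"{self.patient_id}: negative start time {self.t[0]}")
        dt = np.diff(self.t)
        bad = np.flatnonzero(dt <= 0)
        if bad.size:
            i = int(bad[0]) + 1
            raise ValidationError(
                f"{self.patient_id}: timestamps not strictly increasing at index {i} "
                f"(t[{i - 1}]={self.t[i - 1]}, t[{i}]={self.t[i]})"
            )
        lo, hi = MAP_VALID_RANGE
        out = np.flatnonzero((self.map_mmHg <= lo) | (self.map_mmHg >= hi))
        if out.size:
            i = int(out[0])
            raise ValidationError(
                f"{self.patient_id}: MAP value {self.map_mmHg[i]} mmHg at index {i} "
                f"outside the valid range ({lo}, {hi})"
            )
        for name, vals in self.channels.items():
            if len(vals) != len(self.t):
                raise ValidationError(
                    f"{self.patient_id}: channel {name!r} has {len(vals)} samples, "
                    f"expected {len(self.t)}"
                )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def monitoring_time_s(self) -> float:
        """Elapsed time between first and last measurement, in seconds."""
        return float(self.t[-1] - self.t[0])

    def gap_segments(self, gap_factor: float = GAP_FACTOR) -> List[Tuple[float, float]]:
        """Recording gaps: inter-sample intervals > ``gap_factor`` x nominal."""
        dt = np.diff(self.t)
        idx = np.flatnonzero(dt > gap_factor * self.nominal_interval_s)
        return [(float(self.t[i]), float(self.t[i + 1])) for i in idx]

    def effective_monitoring_time_s(
        self,
        max_gap_s: float = DEFAULT_MAX_GAP_S,
        gap_factor: float = GAP_FACTOR,
    ) -> float:
        """Monitoring time with gaps longer than ``max_gap_s`` excluded."""
        total = self.monitoring_time_s
        for a, b in self.gap_segments(gap_factor):
            if b - a > max_gap_s:
                total -= b - a
        return total


@dataclass
class TreatmentEvent:
    """A single intraoperative intervention from the treatment log."""

    time_s: float
    kind: str
    dose: float
    unit: str

    def __post_init__(self) -> None:
        if self.kind not in TREATMENT_KINDS:
            raise ValidationError(
                f"unknown treatment kind {self.kind!r}; expected one of {TREATMENT_KINDS}"
            )
        if self.dose <= 0:
            raise ValidationError(f"treatment dose must be positive, got {self.dose}")


@dataclass
class PatientRecord:
    """A monitored patient: trace, arm assignment and treatment history."""

    series: MapSeries
    arm: str
    induction_time_s: float
    weight_kg: float
    treatments: List[TreatmentEvent] = field(default_factory=list)
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arm not in ARM_LABELS:
            raise ValidationError(
                f"{self.patient_id}: arm must be one of {ARM_LABELS}, got {self.arm!r}"
            )
        if not (0 <= self.induction_time_s < self.series.monitoring_time_s):
            raise ValidationError(
                f"{self.patient_id}: induction_time_s={self.induction_time_s} outside "
                f"the monitoring window [0, {self.series.monitoring_time_s})"
            )
        if self.weight_kg <= 0:
            raise ValidationError(f"{self.patient_id}: non-positive weight {self.weight_kg}")
        self.treatments = sorted(self.treatments, key=lambda ev: ev.time_s)
        span = self.series.monitoring_time_s
        for ev in self.treatments:
            if not (0 <= ev.time_s <= span):
                raise ValidationError(
                    f"{self.patient_id}: treatment at {ev.time_s} s outside the "
                    f"monitoring window [0, {span}]"
                )

    @property
    def patient_id(self) -> str:
        return self.series.patient_id


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _series_from_frame(patient_id: str, df: pd.DataFrame, path: str) -> MapSeries:
    for col in ("time_s", "map_mmHg"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    channels = {
        c: df[c].to_numpy(dtype=float)
        for c in df.columns
        if c not in ("time_s", "map_mmHg")
    }
    try:
        return MapSeries(
            patient_id=patient_id,
            t=df["time_s"].to_numpy(dtype=float),
            map_mmHg=df["map_mmHg"].to_numpy(dtype=float),
            channels=channels,
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def read_series(path: str | Path, patient_id: Optional[str] = None) -> MapSeries:
    """Read a single patient series CSV."""
    path = Path(path)
    pid = patient_id if patient_id is not None else path.stem
    return _series_from_frame(pid, pd.read_csv(path), str(path))


def read_cohort(
    series_dir: str | Path,
    metadata_path: str | Path,
    treatments_path: Optional[str | Path] = None,
) -> List[PatientRecord]:
    """Load a cohort from per-patient CSV files plus a metadata table.

    ``metadata_path`` must contain columns ``patient_id, arm,
    induction_time_s, weight_kg``; any extra columns are carried into
    ``PatientRecord.metadata``.  If ``treatments_path`` is omitted, a file
    named ``treatments.csv`` next to the metadata is used when present.
    """
    series_dir = Path(series_dir)
    meta = pd.read_csv(metadata_path)
    required = {"patient_id", "arm", "induction_time_s", "weight_kg"}
    missing = required - set(meta.columns)
    if missing:
        raise ValidationError(f"{metadata_path}: missing metadata columns {sorted(missing)}")

    if treatments_path is None:
        candidate = Path(metadata_path).with_name("treatments.csv")
        treatments_path = candidate if candidate.exists() else None
    tx_by_patient: Dict[str, List[TreatmentEvent]] = {}
    if treatments_path is not None:
        tx = pd.read_csv(treatments_path)
        for row in tx.itertuples(index=False):
            tx_by_patient.setdefault(str(row.patient_id), []).append(
                TreatmentEvent(
                    time_s=float(row.time_s),
                    kind=str(row.kind),
                    dose=float(row.dose),
                    unit=str(row.unit),
                )
            )

    records: List[PatientRecord] = []
    extra_cols = [c for c in meta.columns if c not in required]
    for i, row in meta.iterrows():
        pid = str(row["patient_id"])
        arm = str(row["arm"])
        if arm not in ARM_LABELS:
            raise ValidationError(
                f"{metadata_path}: row {i} (patient {pid}): unknown arm label {arm!r}"
            )
        series_path = series_dir / f"{pid}.csv"
        if not series_path.exists():
            raise ValidationError(
                f"{metadata_path}: row {i} (patient {pid}): no series file {series_path}"
            )
        series = read_series(series_path, pid)
        records.append(
            PatientRecord(
                series=series,
                arm=arm,
                induction_time_s=float(row["induction_time_s"]),
                weight_kg=float(row["weight_kg"]),
                treatments=tx_by_patient.get(pid, []),
                metadata={c: row[c] for c in extra_cols},
            )
        )
    return records


def write_cohort(records: Sequence[PatientRecord], out_dir: str | Path) -> Path:
    """Write a cohort as ``<out_dir>/series/*.csv`` + metadata + treatment log.

    Returns ``out_dir``.  ``read_cohort`` on the result reproduces the input
    records (floats round-trip through repr).
    """
    out_dir = Path(out_dir)
    series_dir = out_dir / "series"
    os.makedirs(series_dir, exist_ok=True)

    meta_rows = []
    tx_rows = []
    for rec in records:
        s = rec.series
        cols: Dict[str, np.ndarray] = {"time_s": s.t, "map_mmHg": s.map_mmHg}
        cols.update(s.channels)
        pd.DataFrame(cols).to_csv(series_dir / f"{s.patient_id}.csv", index=False)
        meta_rows.append(
            {
                "patient_id": s.patient_id,
                "arm": rec.arm,
                "induction_time_s": rec.induction_time_s,
                "weight_kg": rec.weight_kg,
                **rec.metadata,
            }
        )
        for ev in rec.treatments:
            tx_rows.append(
                {
                    "patient_id": s.patient_id,
                    "time_s": ev.time_s,
                    "kind": ev.kind,
                    "dose": ev.dose,
                    "unit": ev.unit,
                }
            )
    meta_cols = ["patient_id", "arm", "induction_time_s", "weight_kg"]
    pd.DataFrame(meta_rows, columns=None if meta_rows else meta_cols).to_csv(
        out_dir / "metadata.csv", index=False
    )
    pd.DataFrame(tx_rows, columns=["patient_id", "time_s", "kind", "dose", "unit"]).to_csv(
        out_dir / "treatments.csv", index=False
    )
    return out_dir


def load_cohort_dir(cohort_dir: str | Path) -> List[PatientRecord]:
    """Convenience loader for the layout produced by :func:`write_cohort`."""
    cohort_dir = Path(cohort_dir)
    return read_cohort(cohort_dir / "series", cohort_dir / "metadata.csv")
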