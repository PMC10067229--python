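"""NOD / SOD / POD outcome stratification from the clinical course.

Patients are classified post hoc into three strata:

* **POD** (progressive organ dysfunction): de novo kidney, liver or
  respiratory dysfunction — an organ system not dysfunctional on the
  admission-day assessment becoming dysfunctional within the horizon — or ICU
  admission or death within 72 h of ED admission.
* **SOD** (stable organ dysfunction): dysfunction present on the admission-day
  assessment, with no new organ system and no ICU/death trigger.
* **NOD**: no organ dysfunction at all.

Organ criteria (daily assessments, worst vitals of the day):

* AKI by creatinine: rise >= 25.6 µmol/L above baseline, or >= 150% of
  baseline. (25.6 is used verbatim; the canonical KDIGO 26.5 µmol/L is
  available via ``aki_rise_umol_l``.)
* Liver: bilirubin > 35.2 µmol/L AND any of ALP/ASAT/ALAT > 2x the upper
  limit of normal.
* Respiratory: mechanical ventilation, PaO2 < 8.0 kPa, PaCO2 > 6.5 kPa,
  SpO2 < 90% on ambient air, or SpO2 < 95% on >= 2 L/min oxygen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "GroupLabel",
    "PatientRecord",
    "StratificationThresholds",
    "assess_aki",
    "assess_liver",
    "assess_respiratory",
    "classify_outcome",
    "classify_cohort",
]


class Group(str, Enum):
    NOD = "NOD"
    SOD = "SOD"
    POD = "POD"


@dataclass(frozen=True)
class StratificationThresholds:
    aki_rise_umol_l: float = 25.6
    aki_relative: float = 1.5
    bilirubin_umol_l: float = 35.2
    enzyme_uln_factor: float = 2.0
    pao2_kpa: float = 8.0
    paco2_kpa: float = 6.5
    spo2_ambient_pct: float = 90.0
    spo2_oxygen_pct: float = 95.0
    oxygen_flow_l_min: float = 2.0
    icu_death_horizon_h: float = 72.0
    de_novo_horizon_h: float = 72.0


@dataclass
class GroupLabel:
    label: Group
    trigger: str | None = None  # which criterion fired (POD only)
    trigger_day: int | None = None

    def __post_init__(self) -> None:
        if (self.label is Group.POD) != (self.trigger is not None):
            raise ValueError("POD labels require a trigger; non-POD labels must not carry one")


@dataclass
class PatientRecord:
    """Clinical course of one patient.

    ``days`` holds one row per hospital day (day 0 = admission day) with
    columns: day, creatinine (µmol/L), bilirubin (µmol/L), alp_uln, asat_uln,
    alat_uln (multiples of the upper limit of normal), pao2 (kPa, worst),
    paco2 (kPa, worst), spo2 (%, worst), o2_flow (L/min concurrent with the
    worst SpO2), ventilated (bool). Missing measurements are NaN.
    """

    patient_id: str
    days: pd.DataFrame
    baseline_creatinine: float
    icu_admission_time_h: float | None = None
    death_time_h: float | None = None
    # comparator-score inputs, measured at ED arrival
    respiratory_rate: float = np.nan
    systolic_bp: float = np.nan
    gcs: float = np.nan
    sepsis_severity: float = np.nan
    admission_time: float = 0.0
    dropout_time_h: float = 48.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.days) == 0:
            raise ValueError(f"patient {self.patient_id}: no clinical data at all")
        if self.baseline_creatinine is not None and self.baseline_creatinine <= 0:
            raise ValueError("baseline creatinine must be positive")

    def day_row(self, day: int) -> pd.Series | None:
        rows = self.days[self.days["day"] == day]
        return rows.iloc[0] if len(rows) else None


def _num(row: pd.Series, key: str) -> float:
    val = row.get(key, np.nan)
    return float(val) if val is not None and np.isfinite(val) else np.nan


def assess_aki(
    record: PatientRecord, day: int, thresholds: StratificationThresholds | None = None
) -> bool:
    """True iff that day's creatinine meets the rise-based AKI criterion."""
    th = thresholds or StratificationThresholds()
    row = record.day_row(day)
    if row is None:
        return False
    cr = _num(row, "creatinine")
    if not np.isfinite(cr):
        return False
    base = record.baseline_creatinine
    return bool(cr - base >= th.aki_rise_umol_l or cr >= th.aki_relative * base)


def assess_liver(
    record: PatientRecord, day: int, thresholds: StratificationThresholds | None = None
) -> bool:
    """Bilirubin above threshold AND any cholestatic/transaminase enzyme > 2x ULN."""
    th = thresholds or StratificationThresholds()
    row = record.day_row(day)
    if row is None:
        return False
    bili = _num(row, "bilirubin")
    if not (np.isfinite(bili) and bili > th.bilirubin_umol_l):
        return False
    enzymes = [_num(row, k) for k in ("alp_uln", "asat_uln", "alat_uln")]
    return any(np.isfinite(e) and e > th.enzyme_uln_factor for e in enzymes)


def assess_respiratory(
    record: PatientRecord, day: int, thresholds: StratificationThresholds | None = None
) -> bool:
    """Ventilation, hypoxaemia, hypercapnia, or low SpO2 for the oxygen context."""
    th = thresholds or StratificationThresholds()
    row = record.day_row(day)
    if row is None:
        return False
    if bool(row.get("ventilated", False)):
        return True
    pao2, paco2 = _num(row, "pao2"), _num(row, "paco2")
    if np.isfinite(pao2) and pao2 < th.pao2_kpa:
        return True
    if np.isfinite(paco2) and paco2 > th.paco2_kpa:
        return True
    spo2, flow = _num(row, "spo2"), _num(row, "o2_flow")
    if np.isfinite(spo2):
        on_oxygen = np.isfinite(flow) and flow >= th.oxygen_flow_l_min
        ambient = (not np.isfinite(flow)) or flow == 0.0
        if on_oxygen and spo2 < th.spo2_oxygen_pct:
            return True
        if ambient and spo2 < th.spo2_ambient_pct:
            return True
    return False


_ORGANS = {
    "aki": assess_aki,
    "liver": assess_liver,
    "respiratory": assess_respiratory,
}


def classify_outcome(
    record: PatientRecord, thresholds: StratificationThresholds | None = None
) -> GroupLabel:
    """Classify one patient into NOD / SOD / POD.

    POD iff an organ system clean on the admission-day assessment becomes
    dysfunctional within the de novo horizon, or ICU admission or death occurs
    within 72 h. Otherwise SOD iff any organ system is dysfunctional on the
    admission day; otherwise NOD. The first firing POD criterion is recorded
    as the trigger.
    """
    th = thresholds or StratificationThresholds()
    if record.day_row(0) is None:
        raise ValueError(f"patient {record.patient_id}: no admission-day assessment")

    baseline_status = {name: fn(record, 0, th) for name, fn in _ORGANS.items()}

    if record.icu_admission_time_h is not None and record.icu_admission_time_h <= th.icu_death_horizon_h:
        return GroupLabel(Group.POD, trigger="icu_admission", trigger_day=int(record.icu_admission_time_h // 24))
    if record.death_time_h is not None and record.death_time_h <= th.icu_death_horizon_h:
        return GroupLabel(Group.POD, trigger="death", trigger_day=int(record.death_time_h // 24))

    max_day = int(th.de_novo_horizon_h // 24)
    observed_days = sorted(int(d) for d in record.days["day"] if 0 < d <= max_day)
    for day in observed_days:
        for name, fn in _ORGANS.items():
            if not baseline_status[name] and fn(record, day, th):
                return GroupLabel(Group.POD, trigger=f"de_novo_{name}", trigger_day=day)

    if any(baseline_status.values()):
        return GroupLabel(Group.SOD)
    return GroupLabel(Group.NOD)


def classify_cohort(
    records: list[PatientRecord], thresholds: StratificationThresholds | None = None
) -> pd.DataFrame:
    """Label table: one row per patient with label, trigger and trigger day."""
    rows = []
    for rec in records:
        lab = classify_outcome(rec, thresholds)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "label": lab.label.value,
                "trigger": lab.trigger,
                "trigger_day": lab.trigger_day,
            }
        )
    return pd.DataFrame(rows)
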