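"""Synthetic cohort generator: ECG waveforms, tachograms and clinical courses.

Beat times follow an integral-pulse-frequency-modulation (IPFM) style scheme:
the instantaneous NN interval is a baseline mean plus sinusoidal (or
band-limited-noise) modulations in the four HRV bands (ULF/VLF/LF/HF), so
injected band powers are controllable and known. Ectopic beats are injected
as a shortened interval followed by a compensatory lengthened one, missed
beats as merged (doubled) intervals — the two artifact classes the ADARRI
correction targets. An ECG trace is rendered by placing a biphasic QRS-like
template (with optional P/T bumps, Gaussian noise and baseline wander) at
each beat time, sampled at 500 Hz by default.

Clinical courses are constructed to classify deterministically to an intended
NOD/SOD/POD label, with POD realising exactly one randomly chosen trigger.
Per-group multiplicative effects on the mean NN interval and on modulation
amplitudes emulate the depressed heart-rate-variability trajectories of
deteriorating patients; attrition follows a censoring schedule whose expected
cohort sizes at 0/12/24/48 h match 168/105/69/25.

All randomness flows from a single root seed through per-patient spawned
streams; identical configs and seeds give identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocessing import ECGRecord, NNSeries
from .stratification import Group, PatientRecord, StratificationThresholds

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CohortDataset",
    "simulate_nn_series",
    "render_ecg",
    "simulate_patient_course",
    "simulate_cohort",
    "DEFAULT_GROUP_SIZES",
    "ATTRITION_SCHEDULE",
]

#: Study-scale group sizes (NOD, SOD, POD).
DEFAULT_GROUP_SIZES = {"NOD": 119, "SOD": 38, "POD": 11}

#: (hours, surviving fraction) knots of the censoring schedule; expected
#: record counts at 0/12/24/48 h then match 168/105/69/25.
ATTRITION_SCHEDULE = ((0.0, 1.0), (12.0, 105 / 168), (24.0, 69 / 168), (48.0, 25 / 168))

_BANDS = ("ULF", "VLF", "LF", "HF")
_BAND_RANGES = {
    "ULF": (0.0, 0.003),
    "VLF": (0.0033, 0.04),
    "LF": (0.04, 0.15),
    "HF": (0.15, 0.4),
}


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults describe the emulated study conditions.

    Amplitudes/frequencies are per band (ULF/VLF/LF/HF). ``group_effects``
    maps group name to multiplicative shifts ``(mean_nn_scale,
    amplitude_scale)`` applied to the per-patient generative parameters.
    """

    mean_nn: float = 850.0  # ms; ~70 bpm resting sepsis-ward heart rate
    mean_nn_sd: float = 70.0  # ms between-patient spread
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: {"ULF": 25.0, "VLF": 30.0, "LF": 25.0, "HF": 20.0}
    )
    band_freqs: dict[str, float] = field(
        default_factory=lambda: {"ULF": 0.002, "VLF": 0.02, "LF": 0.1, "HF": 0.3}
    )
    modulation: str = "sinusoid"  # or "bandnoise"
    ectopic_rate: float = 0.005  # per beat
    missed_beat_rate: float = 0.002  # per beat
    record_duration: float = 48 * 3600.0  # s
    sampling_rate: float = 500.0  # Hz
    ecg_noise_sd: float = 0.05  # mV (R amplitude 1 mV)
    baseline_wander_mv: float = 0.05
    baseline_wander_hz: float = 0.25
    dropout_times: list[float] | None = None  # h; None -> drawn from schedule
    group_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "NOD": (1.0, 1.0),
            "SOD": (0.97, 0.85),
            "POD": (0.85, 0.5),
        }
    )
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_nn <= 0:
            raise ValueError(f"mean_nn must be positive, got {self.mean_nn}")
        if self.record_duration <= 0:
            raise ValueError(f"record_duration must be positive, got {self.record_duration}")
        for name, rate in (("ectopic_rate", self.ectopic_rate), ("missed_beat_rate", self.missed_beat_rate)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {rate}")
        for band, f in self.band_freqs.items():
            lo, hi = _BAND_RANGES[band]
            if not lo <= f < hi:
                raise ValueError(f"{band} centre frequency {f} Hz outside its band [{lo}, {hi})")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be nonnegative")


@dataclass
class GroundTruth:
    """What the generator actually did, for oracle comparisons downstream."""

    true_peak_times: np.ndarray  # s, artifact-free
    true_nn: np.ndarray  # ms, artifact-free
    injected_artifact_indices: np.ndarray  # positions in the OUTPUT series
    intended_group: str | None = None
    params: dict = field(default_factory=dict)


def _modulation(config: SimulationConfig, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Summed band modulations of the instantaneous NN interval, in ms."""
    out = np.zeros_like(t)
    if config.modulation == "sinusoid":
        for band in _BANDS:
            a = config.band_amplitudes.get(band, 0.0)
            if a == 0.0:
                continue
            phase = rng.uniform(0.0, 2.0 * np.pi)
            out += a * np.sin(2.0 * np.pi * config.band_freqs[band] * t + phase)
    elif config.modulation == "bandnoise":
        # band-limited noise: sum of a few random-phase sinusoids per band
        for band in _BANDS:
            a = config.band_amplitudes.get(band, 0.0)
            if a == 0.0:
                continue
            lo, hi = _BAND_RANGES[band]
            lo = max(lo, 1e-4)
            n_comp = 8
            freqs = rng.uniform(lo, hi, n_comp)
            phases = rng.uniform(0.0, 2.0 * np.pi, n_comp)
            out += (a / np.sqrt(n_comp)) * np.sum(
                np.sin(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]), axis=0
            )
    else:
        raise ValueError(f"unknown modulation scheme {config.modulation!r}")
    return out


def simulate_nn_series(
    config: SimulationConfig, seed: int | np.random.Generator | None = None
) -> tuple[NNSeries, GroundTruth]:
    """Generate a beat-interval series with known band content and artifacts.

    Beat times are built iteratively: the next interval equals ``mean_nn``
    plus the summed band modulations evaluated at the current beat time.
    Ectopic and missed beats are then injected at the configured per-beat
    rates and their output positions recorded in the ground truth.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed if seed is None else seed
    )
    # fixed per-record phases
    mod_rng = np.random.default_rng(rng.integers(0, 2**31))
    art_rng = np.random.default_rng(rng.integers(0, 2**31))

    duration = config.record_duration
    min_interval = max(config.mean_nn - sum(config.band_amplitudes.values()), 100.0)
    est_beats = int(duration * 1000.0 / min_interval) + 16
    # evaluate modulation on a fine uniform grid once, then walk beat times through it
    grid_dt = 0.25
    grid = np.arange(0.0, duration + 2.0 * config.mean_nn / 1000.0 + grid_dt, grid_dt)
    mod = _modulation(config, grid, mod_rng)

    intervals_ms = np.empty(est_beats)
    n = 0
    t = 0.0
    while n < est_beats:
        m = mod[int(t / grid_dt)]
        interval_ms = config.mean_nn + m
        if interval_ms <= 0:
            raise ValueError("modulation amplitudes exceed mean_nn: nonpositive interval")
        if t + interval_ms / 1000.0 > duration:
            break  # recording stops at the record end; no interval crosses it
        intervals_ms[n] = interval_ms
        t += interval_ms / 1000.0
        n += 1
    true_nn = intervals_ms[:n].copy()
    peak_times = np.concatenate([[0.0], np.cumsum(true_nn) / 1000.0])

    nn = true_nn.copy()
    end_times = peak_times[1:].copy()
    artifact = np.zeros(len(nn), dtype=bool)

    # ectopics: shorten interval j, lengthen j+1 compensatorily
    u = art_rng.random(len(nn))
    ect = np.flatnonzero(u < config.ectopic_rate)
    for j in ect:
        if j + 1 >= len(nn) or artifact[j] or artifact[j + 1]:
            continue
        total = nn[j] + nn[j + 1]
        short = 0.5 * nn[j]
        nn[j] = short
        nn[j + 1] = total - short
        end_times[j] = end_times[j] - short / 1000.0  # premature beat arrives early
        artifact[j] = artifact[j + 1] = True

    # missed beats: merge interval j with j+1 (doubled interval)
    u2 = art_rng.random(len(nn))
    missed = [
        j
        for j in np.flatnonzero(u2 < config.missed_beat_rate)
        if j + 1 < len(nn) and not artifact[j] and not artifact[j + 1]
    ]
    keep = np.ones(len(nn), dtype=bool)
    for j in missed:
        nn[j + 1] = nn[j] + nn[j + 1]
        artifact[j + 1] = True
        keep[j] = False
    nn, end_times, artifact = nn[keep], end_times[keep], artifact[keep]

    series = NNSeries(nn, end_times)
    truth = GroundTruth(
        true_peak_times=peak_times,
        true_nn=true_nn,
        injected_artifact_indices=np.flatnonzero(artifact),
        params={"mean_nn": config.mean_nn, "band_amplitudes": dict(config.band_amplitudes)},
    )
    return series, truth


# -- ECG rendering ----------------------------------------------------------

# QRS-complex template components: (time offset s, amplitude mV, width s)
_WAVE_COMPONENTS = (
    (-0.035, -0.12, 0.010),  # Q
    (0.0, 1.0, 0.012),  # R
    (0.035, -0.20, 0.010),  # S
    (-0.180, 0.12, 0.030),  # P
    (0.280, 0.28, 0.060),  # T
)


def render_ecg(
    peak_times: np.ndarray,
    config: SimulationConfig,
    duration: float | None = None,
    seed: int | np.random.Generator | None = None,
    patient_id: str | None = None,
) -> ECGRecord:
    """Render a voltage trace with a QRS-like template at each peak time.

    The R wave is a narrow 1 mV Gaussian flanked by Q/S dips plus low, wide
    P and T bumps; Gaussian noise of ``ecg_noise_sd`` mV and sinusoidal
    baseline wander are added on top. The sample-grid argmax near each beat
    stays within one sample of the requested peak time.
    """
    peak_times = np.asarray(peak_times, dtype=float)
    if peak_times.size > 1 and np.any(np.diff(peak_times) <= 0):
        raise ValueError("peak times must be strictly increasing")
    fs = config.sampling_rate
    if duration is None:
        duration = config.record_duration if peak_times.size == 0 else float(peak_times[-1] + 1.0)
    n = int(round(duration * fs))
    x = np.zeros(n)
    t_axis = np.arange(n) / fs
    for tp in peak_times:
        for off, amp, width in _WAVE_COMPONENTS:
            c = tp + off
            lo = max(0, int((c - 5 * width) * fs))
            hi = min(n, int((c + 5 * width) * fs) + 1)
            if hi <= lo:
                continue
            tt = t_axis[lo:hi]
            x[lo:hi] += amp * np.exp(-0.5 * ((tt - c) / width) ** 2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed if seed is None else seed
    )
    if config.ecg_noise_sd > 0:
        x += rng.normal(0.0, config.ecg_noise_sd, n)
    if config.baseline_wander_mv > 0:
        x += config.baseline_wander_mv * np.sin(
            2.0 * np.pi * config.baseline_wander_hz * t_axis + rng.uniform(0, 2 * np.pi)
        )
    return ECGRecord(x, sampling_rate=fs, t0=0.0, patient_id=patient_id)


# -- clinical courses -------------------------------------------------------

_NORMALS = {
    "creatinine": (80.0, 10.0),
    "bilirubin": (12.0, 4.0),
    "alp_uln": (0.7, 0.15),
    "asat_uln": (0.8, 0.2),
    "alat_uln": (0.8, 0.2),
    "pao2": (12.0, 1.0),
    "paco2": (5.0, 0.4),
    "spo2": (97.0, 1.0),
}

_POD_TRIGGERS = ("de_novo_aki", "de_novo_liver", "de_novo_respiratory", "icu_admission", "death")
_SOD_ORGANS = ("aki", "liver", "respiratory")


def _normal_day(rng: np.random.Generator, day: int) -> dict:
    row = {"day": day, "o2_flow": 0.0, "ventilated": False}
    for key, (mu, sd) in _NORMALS.items():
        row[key] = float(np.clip(rng.normal(mu, sd), 0.01, None))
    row["spo2"] = float(np.clip(row["spo2"], 90.5, 100.0))
    row["pao2"] = max(row["pao2"], 8.5)
    row["paco2"] = min(row["paco2"], 6.3)
    row["alp_uln"] = min(row["alp_uln"], 1.9)
    row["asat_uln"] = min(row["asat_uln"], 1.9)
    row["alat_uln"] = min(row["alat_uln"], 1.9)
    row["bilirubin"] = min(row["bilirubin"], 34.0)
    return row


def _apply_organ_dysfunction(row: dict, organ: str, rng: np.random.Generator, baseline_cr: float) -> None:
    if organ == "aki":
        row["creatinine"] = baseline_cr + 25.6 + rng.uniform(5.0, 60.0)
    elif organ == "liver":
        row["bilirubin"] = 35.2 + rng.uniform(5.0, 40.0)
        row["alat_uln"] = 2.0 + rng.uniform(0.5, 3.0)
    elif organ == "respiratory":
        choice = rng.integers(0, 3)
        if choice == 0:
            row["pao2"] = rng.uniform(5.5, 7.8)
        elif choice == 1:
            row["spo2"] = rng.uniform(82.0, 89.0)
            row["o2_flow"] = 0.0
        else:
            row["spo2"] = rng.uniform(88.0, 94.0)
            row["o2_flow"] = rng.uniform(2.0, 6.0)
    else:  # pragma: no cover
        raise ValueError(organ)


def simulate_patient_course(
    intended_group: Group | str,
    seed: int | np.random.Generator,
    patient_id: str = "P000",
    n_days: int = 4,
) -> PatientRecord:
    """Daily labs/vitals that classify deterministically to the intended group.

    POD realises exactly one randomly chosen trigger (de novo AKI, liver or
    respiratory dysfunction, ICU admission, or death within 72 h); SOD has one
    organ dysfunctional from day 0 with no de novo organ and no ICU/death
    trigger; NOD stays inside all thresholds on every day. Comparator inputs
    (respiratory rate, systolic BP, GCS, an external severity score) are drawn
    with group-dependent shifts so the comparator scores are mildly
    informative, as in real triage data.
    """
    group = Group(intended_group)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    baseline_cr = float(rng.normal(80.0, 10.0))
    days = [_normal_day(rng, d) for d in range(n_days)]
    for row in days:
        row["creatinine"] = float(np.clip(rng.normal(baseline_cr, 5.0), 1.0, baseline_cr + 20.0))
        row["creatinine"] = min(row["creatinine"], 1.45 * baseline_cr)

    icu_time: float | None = None
    death_time: float | None = None
    if group is Group.SOD:
        organ = _SOD_ORGANS[rng.integers(0, len(_SOD_ORGANS))]
        for row in days:  # present from day 0, stable
            _apply_organ_dysfunction(row, organ, rng, baseline_cr)
    elif group is Group.POD:
        trigger = _POD_TRIGGERS[rng.integers(0, len(_POD_TRIGGERS))]
        if trigger == "icu_admission":
            icu_time = float(rng.uniform(4.0, 72.0))
        elif trigger == "death":
            death_time = float(rng.uniform(8.0, 72.0))
        else:
            organ = trigger.removeprefix("de_novo_")
            onset = int(rng.integers(1, min(n_days, 4)))  # within the 72 h horizon
            for row in days[onset:]:
                _apply_organ_dysfunction(row, organ, rng, baseline_cr)

    shift = {"NOD": 0.0, "SOD": 0.4, "POD": 1.0}[group.value]
    rr = float(np.clip(rng.normal(19.0 + 7.0 * shift, 4.0), 8.0, 45.0))
    sbp = float(np.clip(rng.normal(130.0 - 22.0 * shift, 15.0), 60.0, 220.0))
    gcs = 15.0 if rng.random() > 0.3 * shift else float(rng.integers(10, 15))
    severity = float(rng.normal(2.0 * shift, 1.0))
    return PatientRecord(
        patient_id=patient_id,
        days=pd.DataFrame(days),
        baseline_creatinine=baseline_cr,
        icu_admission_time_h=icu_time,
        death_time_h=death_time,
        respiratory_rate=rr,
        systolic_bp=sbp,
        gcs=gcs,
        sepsis_severity=severity,
        meta={"intended_group": group.value},
    )


# -- cohort -----------------------------------------------------------------


def _draw_dropout(rng: np.random.Generator) -> float:
    """Censoring time in hours from the piecewise-linear attrition schedule."""
    u = rng.random()  # u = surviving fraction at the drawn time
    hours = np.array([k[0] for k in ATTRITION_SCHEDULE])
    surv = np.array([k[1] for k in ATTRITION_SCHEDULE])
    if u <= surv[-1]:
        return float(hours[-1])
    # invert the decreasing piecewise-linear survival curve
    return float(np.interp(u, surv[::-1], hours[::-1]))


@dataclass
class SyntheticPatient:
    patient_id: str
    intended_group: str
    nn: NNSeries
    truth: GroundTruth
    course: PatientRecord
    dropout_time_h: float
    ecg: ECGRecord | None = None


@dataclass
class CohortDataset:
    patients: list[SyntheticPatient]
    config: SimulationConfig

    def __len__(self) -> int:
        return len(self.patients)

    def ground_truth_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "intended_group": p.intended_group,
                    "dropout_time_h": p.dropout_time_h,
                    "true_mean_nn": float(np.mean(p.truth.true_nn)),
                    "n_beats": len(p.truth.true_nn),
                    "n_injected_artifacts": len(p.truth.injected_artifact_indices),
                }
            )
        return pd.DataFrame(rows)


def simulate_cohort(config: SimulationConfig, render: bool = False) -> CohortDataset:
    """One tachogram (optionally an ECG) + clinical course per synthetic patient.

    Group effects multiply each patient's drawn mean NN and band amplitudes;
    records are truncated at the patient's censoring time. ``render=True``
    additionally rasterises the 500 Hz ECG (slow for long records).
    """
    total = sum(config.group_sizes.values())
    if total == 0:
        raise ValueError("zero total patients requested")
    root = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in root.spawn(total)]
    patients: list[SyntheticPatient] = []
    i = 0
    for group in ("NOD", "SOD", "POD"):
        nn_scale, amp_scale = config.group_effects.get(group, (1.0, 1.0))
        for _ in range(config.group_sizes.get(group, 0)):
            rng = streams[i]
            pid = f"P{i:03d}"
            if config.dropout_times is not None:
                dropout = float(config.dropout_times[i % len(config.dropout_times)])
            else:
                dropout = _draw_dropout(rng)
            duration = min(config.record_duration, dropout * 3600.0)
            patient_mean = max(300.0, rng.normal(config.mean_nn, config.mean_nn_sd)) * nn_scale
            amps = {b: a * amp_scale for b, a in config.band_amplitudes.items()}
            pconf = replace(
                config,
                mean_nn=patient_mean,
                band_amplitudes=amps,
                record_duration=max(duration, 1.0),
            )
            nn, truth = simulate_nn_series(pconf, seed=rng)
            truth.intended_group = group
            nn.patient_id = pid
            course = simulate_patient_course(group, rng, patient_id=pid)
            course.dropout_time_h = dropout
            ecg = None
            if render:
                ecg = render_ecg(
                    truth.true_peak_times, pconf, duration=pconf.record_duration,
                    seed=rng, patient_id=pid,
                )
            patients.append(
                SyntheticPatient(pid, group, nn, truth, course, dropout, ecg)
            )
            i += 1
    return CohortDataset(patients, config)
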