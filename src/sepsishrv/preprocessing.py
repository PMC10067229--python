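"""ECG → artifact-corrected NN-interval tachogram → quality-filtered 5-min windows.

The stages mirror standard HRV practice for continuous bedside ECG:

1. QRS detection with the Pan-Tompkins pipeline (band-pass, derivative,
   squaring, moving-window integration, adaptive dual thresholds with
   refractory period and search-back).
2. NN-interval computation from successive R-peak times.
3. Artifact flagging from the absolute difference of adjacent RR intervals
   (ADARRI): ectopic and missed beats produce interval jumps far outside the
   physiological successive-difference distribution. Flagged intervals are
   excluded, never interpolated.
4. Segmentation into consecutive non-overlapping 5-minute windows aligned to
   ED admission; a window is kept only if it holds at least 20% of the 300
   beats minimally expected in 5 minutes (i.e. >= 60 clean intervals).

All times are seconds from ED admission; intervals are milliseconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "ECGRecord",
    "RPeakSeries",
    "NNSeries",
    "Window5Min",
    "PanTompkinsParams",
    "detect_r_peaks",
    "compute_nn_intervals",
    "correct_artifacts",
    "segment_windows",
    "WINDOW_LENGTH_S",
    "MIN_BEATS_PER_WINDOW",
]

WINDOW_LENGTH_S = 300.0
#: 20% of the 300 beats minimally expected in a 5-minute window.
MIN_BEATS_PER_WINDOW = 60


@dataclass
class ECGRecord:
    """Uniformly sampled single-lead voltage trace.

    Parameters
    ----------
    samples : ndarray
        Voltage in mV.
    sampling_rate : float
        Samples per second (Hz); must be positive.
    t0 : float
        Time of the first sample relative to ED admission, in seconds.
    patient_id : str, optional
    """

    samples: np.ndarray
    sampling_rate: float
    t0: float = 0.0
    patient_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.sampling_rate


@dataclass
class RPeakSeries:
    """Admission-aligned R-peak times (seconds), strictly increasing."""

    peak_times: np.ndarray
    patient_id: str | None = None

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if self.peak_times.size > 1 and np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peak_times)


@dataclass
class NNSeries:
    """Beat-to-beat intervals (ms) with end-times (s) and per-interval artifact flags."""

    values: np.ndarray
    end_times: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]
    patient_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.end_times = np.asarray(self.end_times, dtype=float)
        if self.flags is None:
            self.flags = np.zeros(self.values.shape, dtype=bool)
        else:
            self.flags = np.asarray(self.flags, dtype=bool)
        if self.values.shape != self.end_times.shape or self.values.shape != self.flags.shape:
            raise ValueError("values, end_times and flags must have identical shapes")
        if np.any(self.values <= 0):
            raise ValueError("NN intervals must be positive")
        if self.end_times.size > 1 and np.any(np.diff(self.end_times) <= 0):
            raise ValueError("end times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())

    def clean(self) -> tuple[np.ndarray, np.ndarray]:
        """Unflagged (values, end_times)."""
        keep = ~self.flags
        return self.values[keep], self.end_times[keep]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"end_time_s": self.end_times, "nn_ms": self.values, "artifact": self.flags}
        )


@dataclass
class Window5Min:
    """One candidate 5-minute window of the cleaned tachogram.

    ``values``/``times`` hold only the unflagged member intervals; ``retained``
    records whether the window passed the beat-count quality rule.
    """

    start: float
    end: float
    values: np.ndarray
    times: np.ndarray
    retained: bool
    patient_id: str | None = None

    @property
    def n_beats(self) -> int:
        return len(self.values)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class PanTompkinsParams:
    """Tunables of the QRS detector (canonical 1985 values)."""

    band_low_hz: float = 5.0
    band_high_hz: float = 15.0
    integration_window_s: float = 0.150
    refractory_s: float = 0.200
    searchback_factor: float = 1.66
    searchback_threshold_fraction: float = 0.5
    refine_window_s: float = 0.150


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-sample vertex of the parabola through (i-1, i, i+1). Returns offset in samples."""
    if i <= 0 or i >= len(y) - 1:
        return 0.0
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return 0.0
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(np.clip(delta, -0.5, 0.5))


def detect_r_peaks(ecg: ECGRecord, params: PanTompkinsParams | None = None) -> RPeakSeries:
    """Detect R-peaks with the Pan-Tompkins algorithm.

    Stages: zero-phase 5–15 Hz band-pass, derivative, squaring, 150 ms
    moving-window integration, adaptive signal/noise thresholds with a 200 ms
    refractory period and search-back at half threshold when an expected beat
    is overdue. Accepted detections are refined to the local maximum of the
    band-passed signal with parabolic sub-sample interpolation, and returned
    as admission-aligned times.

    Raises
    ------
    ValueError
        If the sampling rate is below 100 Hz or the record is empty.
    """
    params = params or PanTompkinsParams()
    if ecg.sampling_rate < 100:
        raise ValueError(
            f"sampling rate {ecg.sampling_rate} Hz too low for QRS detection (need >= 100 Hz)"
        )
    if len(ecg.samples) == 0:
        raise ValueError("empty ECG record")
    x = ecg.samples
    fs = ecg.sampling_rate
    if np.ptp(x) == 0:
        warnings.warn("all-constant ECG signal: no peaks detectable", stacklevel=2)
        return RPeakSeries(np.empty(0), patient_id=ecg.patient_id)

    sos = signal.butter(
        2, [params.band_low_hz, params.band_high_hz], btype="bandpass", fs=fs, output="sos"
    )
    bp = signal.sosfiltfilt(sos, x)
    deriv = np.gradient(bp) * fs
    squared = deriv * deriv
    win = max(1, int(round(params.integration_window_s * fs)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(params.refractory_s * fs))
    cand_idx, _ = signal.find_peaks(mwi, distance=max(1, refractory))
    if cand_idx.size == 0:
        return RPeakSeries(np.empty(0), patient_id=ecg.patient_id)

    # Adaptive thresholding over candidate integration-waveform peaks.
    init = mwi[: min(len(mwi), int(2 * fs))]
    spki = float(np.max(init)) * 0.5 if init.size else float(mwi[cand_idx[0]])
    npki = float(np.mean(init)) * 0.5 if init.size else 0.0
    accepted: list[int] = []
    rr_history: list[float] = []
    noise_buffer: list[int] = []

    def threshold() -> float:
        return npki + 0.25 * (spki - npki)

    for idx in cand_idx:
        peak = mwi[idx]
        thr = threshold()
        is_signal = peak > thr
        if is_signal:
            accepted.append(int(idx))
            spki = 0.125 * peak + 0.875 * spki
            if len(accepted) >= 2:
                rr_history.append(accepted[-1] - accepted[-2])
        else:
            noise_buffer.append(int(idx))
            npki = 0.125 * peak + 0.875 * npki
        # search-back when the gap since the last accepted beat is too long
        if accepted and rr_history:
            mean_rr_samp = float(np.mean(rr_history[-8:]))
            if (idx - accepted[-1]) > params.searchback_factor * mean_rr_samp:
                half_thr = params.searchback_threshold_fraction * threshold()
                back = [
                    j
                    for j in noise_buffer
                    if accepted[-1] + refractory < j < idx - refractory and mwi[j] > half_thr
                ]
                if back:
                    j = max(back, key=lambda k: mwi[k])
                    accepted.append(j)
                    accepted.sort()
                    spki = 0.25 * mwi[j] + 0.75 * spki
                    noise_buffer = [b for b in noise_buffer if b > idx]

    if not accepted:
        return RPeakSeries(np.empty(0), patient_id=ecg.patient_id)

    # Refine each detection to the local band-passed maximum.
    half = int(round(params.refine_window_s * fs))
    refined: list[float] = []
    for idx in accepted:
        lo = max(0, idx - half)
        hi = min(len(bp), idx + half + 1)
        local = int(lo + np.argmax(bp[lo:hi]))
        refined.append(local + _parabolic_refine(bp, local))

    # Enforce the refractory period on refined times (refinement can merge
    # neighbouring integration peaks onto the same R wave).
    times: list[float] = []
    for t in sorted(refined):
        if not times or (t - times[-1]) / fs >= params.refractory_s:
            times.append(t)
        elif mwi[int(round(t))] > mwi[int(round(times[-1]))]:
            times[-1] = t
    peak_times = ecg.t0 + np.asarray(times) / fs
    return RPeakSeries(peak_times, patient_id=ecg.patient_id)


def compute_nn_intervals(peaks: RPeakSeries) -> NNSeries:
    """Successive R-peak differences in ms; interval i ends at peak i+1.

    Fewer than two peaks yield an empty series.
    """
    t = peaks.peak_times
    if len(t) < 2:
        return NNSeries(np.empty(0), np.empty(0), patient_id=peaks.patient_id)
    return NNSeries(np.diff(t) * 1000.0, t[1:], patient_id=peaks.patient_id)


def correct_artifacts(
    nn: NNSeries,
    k_iqr: float = 4.0,
    min_threshold_ms: float = 100.0,
    local_window: int = 11,
) -> NNSeries:
    """Flag artifact intervals by the ADARRI criterion.

    ADARRI for interval *i* is the absolute difference to its predecessor,
    ``|RR_i - RR_{i-1}|``. The decision threshold is a robust limit of the
    record's own ADARRI distribution, ``median + k_iqr * IQR`` (floored at
    ``min_threshold_ms``, since physiological successive differences below
    ~100 ms should never be treated as artifacts). An interval is flagged when
    it participates in an over-threshold jump *and* deviates from the local
    running median of the tachogram by more than the threshold — the second
    gate keeps the first clean interval after an artifact (whose backward
    difference is necessarily large) unflagged.

    Flagged intervals are excluded from all downstream computation; nothing is
    interpolated. Returns a new series; ``n_flagged`` reports the count.
    """
    if len(nn) == 0:
        raise ValueError("cannot correct an empty NN series")
    rr = nn.values
    if len(rr) < 3:
        return NNSeries(rr.copy(), nn.end_times.copy(), nn.flags.copy(), nn.patient_id)
    d = np.abs(np.diff(rr))
    q1, med, q3 = np.percentile(d, [25, 50, 75])
    thr = max(med + k_iqr * (q3 - q1), min_threshold_ms)

    jump = d > thr  # jump[j] is between intervals j and j+1
    participates = np.zeros(len(rr), dtype=bool)
    participates[:-1] |= jump
    participates[1:] |= jump

    local_med = (
        pd.Series(rr).rolling(local_window, center=True, min_periods=1).median().to_numpy()
    )
    deviant = np.abs(rr - local_med) > thr
    flags = participates & deviant
    if flags.all():
        warnings.warn("every interval flagged as artifact; no clean data retained", stacklevel=2)
    return NNSeries(rr.copy(), nn.end_times.copy(), flags | nn.flags, nn.patient_id)


def segment_windows(nn: NNSeries, record_duration: float) -> list[Window5Min]:
    """Split the cleaned tachogram into consecutive 5-minute windows.

    Windows are half-open ``[k*300, (k+1)*300)`` seconds from ED admission; an
    interval belongs to the window containing its end-time. A window is
    retained iff it holds at least ``MIN_BEATS_PER_WINDOW`` (60) unflagged
    intervals — 20% of the 300 beats minimally expected in five minutes.
    """
    if record_duration < 0:
        raise ValueError("record duration must be nonnegative")
    n_windows = int(np.ceil(record_duration / WINDOW_LENGTH_S)) if record_duration > 0 else 0
    values, times = nn.clean() if len(nn) else (np.empty(0), np.empty(0))
    windows: list[Window5Min] = []
    for k in range(n_windows):
        start = k * WINDOW_LENGTH_S
        end = start + WINDOW_LENGTH_S
        sel = (times >= start) & (times < end)
        v, t = values[sel], times[sel]
        windows.append(
            Window5Min(
                start=start,
                end=end,
                values=v,
                times=t,
                retained=len(v) >= MIN_BEATS_PER_WINDOW,
                patient_id=nn.patient_id,
            )
        )
    return windows
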