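"""The 17 per-window HRV features.

Time domain: AVNN, SDNN, RMSSD, NN50, pNN50, CV. Nonlinear: SampEn, Poincaré
SD1/SD2. Frequency domain, from a Lomb-Scargle periodogram of the unevenly
timed tachogram: ULF (< 0.003 Hz), VLF (0.0033–0.04 Hz), LF (0.04–0.15 Hz),
HF (0.15–0.4 Hz), TotalPower (defined as LF + HF), LFnorm = LF/(LF+HF),
HFnorm = HF/(LF+HF) and the LF/HF ratio.

Notes
-----
* TotalPower here is LF + HF by definition, not the full-band integral; the
  conventional full-band power is additionally reported as ``FullBandPower``
  under a distinct name to avoid ambiguity.
* Inside a 5-minute window the lowest resolvable frequency is 1/300 Hz
  (~0.0033 Hz); the ULF band and most of the VLF band lie below it. Their
  values are still computed, but every feature row carries a
  ``spectral_reliable`` flag that is False when a requested band extends
  below the window's resolution.
* Missing values propagate as NaN, never as zero.
* All sample standard deviations use the n-1 denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import interpolate
from scipy import signal as sps
from scipy.spatial import cKDTree

from .preprocessing import Window5Min

__all__ = [
    "SpectralBands",
    "FEATURE_NAMES",
    "time_domain_features",
    "poincare_features",
    "sample_entropy",
    "spectral_features",
    "feature_vector",
]

#: The 17 per-window features, in canonical order.
FEATURE_NAMES = [
    "AVNN",
    "SDNN",
    "RMSSD",
    "NN50",
    "pNN50",
    "CV",
    "SampEn",
    "SD1",
    "SD2",
    "ULF",
    "VLF",
    "LF",
    "HF",
    "TotalPower",
    "LFnorm",
    "HFnorm",
    "LFHFratio",
]


@dataclass(frozen=True)
class SpectralBands:
    """Frequency-band edges in Hz.

    The published edges leave 0.003–0.0033 Hz unassigned between ULF and VLF;
    it is deliberately assigned to neither band.
    """

    ulf: tuple[float, float] = (0.0, 0.003)
    vlf: tuple[float, float] = (0.0033, 0.04)
    lf: tuple[float, float] = (0.04, 0.15)
    hf: tuple[float, float] = (0.15, 0.4)

    def __post_init__(self) -> None:
        edges = [*self.ulf, *self.vlf, *self.lf, *self.hf]
        if any(b < a for a, b in zip(edges[::2], edges[1::2])):
            raise ValueError("band edges must be increasing within each band")
        for (_, hi), (lo, _) in zip(
            [self.ulf, self.vlf, self.lf], [self.vlf, self.lf, self.hf]
        ):
            if lo < hi:
                raise ValueError("bands must not overlap")


def _as_values(window: Window5Min | np.ndarray) -> np.ndarray:
    if isinstance(window, Window5Min):
        return np.asarray(window.values, dtype=float)
    return np.asarray(window, dtype=float)


def time_domain_features(window: Window5Min | np.ndarray) -> dict[str, float]:
    """AVNN, SDNN, RMSSD, NN50, pNN50, CV of the window's clean intervals.

    NN50 counts successive differences strictly greater than 50 ms; pNN50 is
    NN50 normalised by the n-1 successive differences.
    """
    v = _as_values(window)
    if len(v) < 2:
        return {k: np.nan for k in ("AVNN", "SDNN", "RMSSD", "NN50", "pNN50", "CV")}
    diffs = np.diff(v)
    avnn = float(np.mean(v))
    sdnn = float(np.std(v, ddof=1))
    nn50 = int(np.sum(np.abs(diffs) > 50.0))
    return {
        "AVNN": avnn,
        "SDNN": sdnn,
        "RMSSD": float(np.sqrt(np.mean(diffs**2))),
        "NN50": float(nn50),
        "pNN50": 100.0 * nn50 / len(diffs),
        "CV": sdnn / avnn if avnn > 0 else np.nan,
    }


def poincare_features(window: Window5Min | np.ndarray) -> tuple[float, float]:
    """Poincaré-plot axes: SD1 = SDSD/sqrt(2); SD2 = sqrt(2*SDNN^2 - SD1^2).

    SD2 is floored at zero against roundoff.
    """
    v = _as_values(window)
    if len(v) < 3:
        return (np.nan, np.nan)
    sdsd = float(np.std(np.diff(v), ddof=1))
    sdnn = float(np.std(v, ddof=1))
    sd1 = sdsd / np.sqrt(2.0)
    sd2 = float(np.sqrt(max(2.0 * sdnn**2 - sd1**2, 0.0)))
    return (sd1, sd2)


def sample_entropy(values: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy: -ln(A/B) with Chebyshev distance, self-matches excluded.

    A counts template pairs of length m+1 within tolerance r, B of length m.
    Default r is 0.2 times the sample SD of the window. Returns NaN (with a
    warning) when no templates match at either length.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n <= m + 1:
        return np.nan
    if r is None:
        sd = float(np.std(x, ddof=1))
        r = 0.2 * sd
        if r == 0.0:
            return 0.0  # constant series: all templates match at both lengths
    if r <= 0:
        raise ValueError("tolerance r must be positive")

    def _pairs(mm: int) -> int:
        # count template pairs i<j with Chebyshev distance <= r; both lengths
        # use the same n-m templates so a constant series gives A = B exactly
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)[: n - m]
        tree = cKDTree(emb)
        return int(tree.count_neighbors(tree, r, p=np.inf) - len(emb)) // 2

    b = _pairs(m)
    a = _pairs(m + 1)
    if b == 0 or a == 0:
        warnings.warn("sample entropy undefined: no matching templates", stacklevel=2)
        return np.nan
    return float(-np.log(a / b))


def _lombscargle_psd(
    times: np.ndarray, values: np.ndarray, fmax: float, oversample: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided PSD estimate (ms^2/Hz) on a regular frequency grid.

    The raw Lomb-Scargle periodogram of a sinusoid of amplitude A peaks at
    N*A^2/4 with a main lobe of equivalent width 1/T; scaling by 2T/N makes
    the integral of the density over the lobe equal the sinusoid's variance
    A^2/2, so band powers integrate to ms^2.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float) - float(np.mean(values))
    span = t[-1] - t[0]
    if span <= 0:
        raise ValueError("window must span positive time")
    df = 1.0 / (oversample * span)
    freqs = np.arange(df, fmax + 0.5 * df, df)
    pgram = sps.lombscargle(t, y, 2.0 * np.pi * freqs)
    psd = pgram * 2.0 * span / len(t)
    return freqs, psd


def _welch_psd(
    times: np.ndarray, values: np.ndarray, fs_resample: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline resampling at ``fs_resample`` Hz followed by Welch."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    spline = interpolate.CubicSpline(t, y)
    tt = np.arange(t[0], t[-1], 1.0 / fs_resample)
    yy = spline(tt) - np.mean(spline(tt))
    nperseg = min(len(yy), 256)
    freqs, psd = sps.welch(yy, fs=fs_resample, nperseg=nperseg, detrend="constant")
    return freqs, psd


def spectral_features(
    window: Window5Min,
    bands: SpectralBands | None = None,
    method: str = "lombscargle",
) -> dict[str, float]:
    """Band powers and derived ratios for one window.

    Returns ULF, VLF, LF, HF (ms^2), TotalPower = LF + HF exactly, LFnorm,
    HFnorm, LFHFratio, the conventional full-band integral ``FullBandPower``,
    and a ``spectral_reliable`` flag (0/1) that is 0 when any requested band
    extends below the window's resolvable frequency 1/span.
    """
    bands = bands or SpectralBands()
    keys = ["ULF", "VLF", "LF", "HF", "TotalPower", "LFnorm", "HFnorm", "LFHFratio"]
    out: dict[str, float] = {k: np.nan for k in keys}
    out["FullBandPower"] = np.nan
    out["spectral_reliable"] = 0.0
    v = np.asarray(window.values, dtype=float)
    t = np.asarray(window.times, dtype=float)
    if len(v) < 4:
        warnings.warn("too few intervals for spectral estimation", stacklevel=2)
        return out
    fmax = bands.hf[1]
    if method == "lombscargle":
        freqs, psd = _lombscargle_psd(t, v, fmax=fmax)
    elif method == "welch":
        freqs, psd = _welch_psd(t, v)
    else:
        raise ValueError(f"unknown spectral method {method!r}")
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0

    def band_power(lo: float, hi: float) -> float:
        sel = (freqs >= lo) & (freqs < hi)
        return float(np.sum(psd[sel]) * df)

    ulf = band_power(*bands.ulf)
    vlf = band_power(*bands.vlf)
    lf = band_power(*bands.lf)
    hf = band_power(*bands.hf)
    out.update(ULF=ulf, VLF=vlf, LF=lf, HF=hf, TotalPower=lf + hf)
    out["FullBandPower"] = band_power(0.0, fmax)
    f_resolve = 1.0 / (t[-1] - t[0])
    out["spectral_reliable"] = float(bands.ulf[0] >= f_resolve and bands.vlf[0] >= f_resolve)
    if lf + hf > 0:
        out["LFnorm"] = lf / (lf + hf)
        out["HFnorm"] = hf / (lf + hf)
    if hf > 0:
        out["LFHFratio"] = lf / hf
    return out


def feature_vector(
    window: Window5Min,
    bands: SpectralBands | None = None,
    sampen_m: int = 2,
    sampen_r_factor: float = 0.2,
    spectral_method: str = "lombscargle",
) -> dict[str, float]:
    """Assemble the full 17-feature vector for one retained window.

    Undefined components propagate as NaN. The returned mapping also carries
    ``window_start`` and the spectral-reliability flag.
    """
    td = time_domain_features(window)
    sd1, sd2 = poincare_features(window)
    sdnn = td["SDNN"]
    r = sampen_r_factor * sdnn if np.isfinite(sdnn) and sdnn > 0 else None
    if np.isfinite(sdnn) and sdnn == 0:
        sampen = 0.0
    else:
        sampen = sample_entropy(window.values, m=sampen_m, r=r) if len(window.values) else np.nan
    spec = spectral_features(window, bands=bands, method=spectral_method)
    vec: dict[str, float] = {}
    vec.update(td)
    vec["SampEn"] = sampen
    vec["SD1"], vec["SD2"] = sd1, sd2
    vec.update(spec)
    vec["window_start"] = window.start
    return vec
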