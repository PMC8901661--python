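"""Acoustic feature extraction for cropped calls.

Ten parameters, grouped in four categories:

===========  ==========================================================
Duration     Dur (s)
Amplitude    AmpVar (dB/s), AmpModRate (1/s), AmpModExtent (dB)
Spectrum     Q25, Q50, Q75, FPeak (Hz)
Tonality     Harmonicity (dB), WienEntropy (dimensionless, <= 0)
===========  ==========================================================

Q50 (the spectral center of gravity) doubles as the call-type criterion:
a call is typed HF when its Q50 exceeds an age-class-specific cutoff
(piglets call higher, so the cutoff drops with age), LF otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "IntensityContour",
    "AverageSpectrum",
    "FeatureConfig",
    "duration",
    "intensity_contour",
    "amplitude_features",
    "average_spectrum",
    "spectral_features",
    "harmonicity",
    "classify_call_type",
    "extract_features",
    "extract_table",
    "FEATURE_COLUMNS",
    "CATEGORY_MAP",
    "Q50_CUTOFFS_HZ",
]

#: LF/HF cutoff on Q50 per age class (Hz); HF iff Q50 strictly above the cutoff
Q50_CUTOFFS_HZ = {1: 2414.0, 2: 2153.0, 3: 896.0}

#: feature-table column order (missing values written as empty fields)
FEATURE_COLUMNS = [
    "call_id", "pig_id", "team_id", "age_class", "context", "valence",
    "Dur", "AmpVar", "AmpModRate", "AmpModExtent",
    "Q25", "Q50", "Q75", "FPeak", "Harmonicity", "WienEntropy", "call_type",
]

#: parameter -> category, used by the PCA-based screening step
CATEGORY_MAP = {
    "Dur": "Duration",
    "AmpVar": "Amplitude modulation",
    "AmpModRate": "Amplitude modulation",
    "AmpModExtent": "Amplitude modulation",
    "Q25": "Spectrum",
    "Q50": "Spectrum",
    "Q75": "Spectrum",
    "FPeak": "Spectrum",
    "Harmonicity": "Tonality/noise",
    "WienEntropy": "Tonality/noise",
}

PARAMETERS = [c for c in FEATURE_COLUMNS if c in CATEGORY_MAP]


@dataclass
class FeatureConfig:
    """Analysis settings (frame sizes resolve AM up to ~50 Hz)."""

    frame_len: float = 0.010  # s, intensity frame length
    frame_step: float = 0.001  # s, intensity frame step
    db_floor: float = -70.0  # dB re full scale, silence floor
    am_prominence_db: float = 2.0  # peak prominence defining a real AM cycle
    am_lowpass_hz: float = 50.0  # contour lowpass before AM peak-picking
    n_fft: int = 2048
    power_floor_frac: float = 1e-12  # relative floor for the entropy log
    pitch_floor: float = 60.0  # Hz, lowest admissible periodicity
    pitch_ceiling: float = 2000.0  # Hz
    hnr_clamp: tuple = (-10.0, 40.0)  # dB


@dataclass
class IntensityContour:
    times: np.ndarray  # s, frame centers
    levels: np.ndarray  # dB re full scale
    frame_step: float  # s


@dataclass
class AverageSpectrum:
    freqs: np.ndarray  # Hz, increasing
    power: np.ndarray  # linear power per bin, >= 0


def duration(call) -> float:
    """Call duration: number of samples over the sample rate."""
    if call.waveform.size == 0:
        raise ValueError("empty waveform")
    return call.waveform.size / call.sample_rate


def intensity_contour(call, frame_len=None, frame_step=None, db_floor=None,
                      cfg: FeatureConfig | None = None) -> IntensityContour:
    """Per-frame RMS level in dB re full scale, floored at ``db_floor``.

    Frames are half-open windows [start, start + frame_len) advanced by
    ``frame_step``; the last frame is the last one fully inside the call.
    """
    cfg = cfg or FeatureConfig()
    frame_len = cfg.frame_len if frame_len is None else frame_len
    frame_step = cfg.frame_step if frame_step is None else frame_step
    db_floor = cfg.db_floor if db_floor is None else db_floor
    x = np.asarray(call.waveform, float)
    sr = call.sample_rate
    flen = max(1, int(round(frame_len * sr)))
    fstep = max(1, int(round(frame_step * sr)))
    if x.size < flen:
        raise ValueError("call shorter than one frame")
    n_frames = 1 + (x.size - flen) // fstep
    idx = np.arange(flen)[None, :] + fstep * np.arange(n_frames)[:, None]
    rms = np.sqrt(np.mean(x[idx] ** 2, axis=1))
    levels = 20.0 * np.log10(np.maximum(rms, 10 ** (db_floor / 20.0)))
    times = (np.arange(n_frames) * fstep + flen / 2) / sr
    return IntensityContour(times=times, levels=levels, frame_step=fstep / sr)


def amplitude_features(contour: IntensityContour, dur: float,
                       prominence_db: float | None = None,
                       cfg: FeatureConfig | None = None):
    """AmpVar, AmpModRate, AmpModExtent from an intensity contour.

    The contour is first zero-phase low-passed below ``am_lowpass_hz``:
    amplitude modulation of interest sits well below 50 Hz, while the raw
    frame-RMS contour also carries ripple at the fundamental and from
    band-noise fading, which is not amplitude modulation.  (Contours too
    short or too coarsely sampled to filter are used as is.)  AmpVar is the
    cumulative absolute level change of the smoothed contour divided by the
    call duration.  An AM cycle is a contour peak with prominence at or above the
    configured threshold; the cycle's extent is the peak level minus the
    mean of the adjacent trough levels (contour minima between neighbouring
    peaks, call edges included).  With no qualifying cycle, AmpModRate and
    AmpModExtent are missing (NaN) rather than zero.
    """
    cfg = cfg or FeatureConfig()
    prom = cfg.am_prominence_db if prominence_db is None else prominence_db
    levels = np.asarray(contour.levels, float)
    if levels.size < 2:
        raise ValueError("need at least 2 frames")
    fs = 1.0 / contour.frame_step
    if levels.size > 21 and fs > 3.0 * cfg.am_lowpass_hz:
        sos = signal.butter(4, cfg.am_lowpass_hz, fs=fs, output="sos")
        smooth = signal.sosfiltfilt(sos, levels)
    else:  # contour too short/coarse for filtering; use it as is
        smooth = levels
    amp_var = float(np.sum(np.abs(np.diff(smooth))) / dur)
    peaks, _ = signal.find_peaks(smooth, prominence=prom)
    if peaks.size == 0:
        return amp_var, float("nan"), float("nan")
    extents = []
    bounds = np.concatenate(([0], peaks, [smooth.size - 1]))
    for j, pk in enumerate(peaks):
        left = smooth[bounds[j]: pk + 1].min()
        right = smooth[pk: bounds[j + 2] + 1].min()
        extents.append(smooth[pk] - 0.5 * (left + right))
    return amp_var, float(peaks.size / dur), float(np.mean(extents))


def average_spectrum(call, n_fft=None, cfg: FeatureConfig | None = None) -> AverageSpectrum:
    """Average power spectrum of the call (Welch mean of frame periodograms;
    a single whole-call periodogram for calls shorter than one segment)."""
    cfg = cfg or FeatureConfig()
    n_fft = cfg.n_fft if n_fft is None else n_fft
    x = np.asarray(call.waveform, float)
    if not np.any(x):
        raise ValueError("all-zero waveform")
    nperseg = min(n_fft, x.size)
    freqs, power = signal.welch(x, fs=call.sample_rate, window="hann",
                                nperseg=nperseg, noverlap=nperseg // 2, nfft=n_fft)
    return AverageSpectrum(freqs=freqs, power=power)


def spectral_features(spec: AverageSpectrum, power_floor_frac=None,
                      cfg: FeatureConfig | None = None):
    """(Q25, Q50, Q75, FPeak, WienEntropy) from an average spectrum.

    Qx is the smallest frequency where cumulative power reaches x% of the
    total; FPeak the frequency of the (first) maximum bin.  Wiener entropy
    is ln(geometric mean / arithmetic mean) of the floored power bins: 0
    for a flat spectrum, more negative the more peaked (tonal) it is.
    """
    cfg = cfg or FeatureConfig()
    floor_frac = cfg.power_floor_frac if power_floor_frac is None else power_floor_frac
    p = np.asarray(spec.power, float)
    f = np.asarray(spec.freqs, float)
    total = p.sum()
    if total <= 0:
        raise ValueError("zero total power")
    cum = np.cumsum(p)
    q25, q50, q75 = (float(f[np.searchsorted(cum, frac * total)]) for frac in (0.25, 0.50, 0.75))
    fpeak = float(f[np.argmax(p)])
    pf = np.maximum(p, floor_frac * p.max())
    entropy = float(np.mean(np.log(pf)) - np.log(np.mean(pf)))
    return q25, q50, q75, fpeak, min(entropy, 0.0)


def harmonicity(call, pitch_floor=None, pitch_ceiling=None,
                cfg: FeatureConfig | None = None) -> float:
    """Harmonic-to-noise ratio in dB from the normalized autocorrelation.

    r is the autocorrelation maximum over lags spanning the pitch search
    range; HNR = 10 log10(r / (1 - r)), clamped.  A perfectly periodic
    signal gives the clamp ceiling; broadband noise lands near the floor.
    """
    cfg = cfg or FeatureConfig()
    floor = cfg.pitch_floor if pitch_floor is None else pitch_floor
    ceiling = cfg.pitch_ceiling if pitch_ceiling is None else pitch_ceiling
    x = np.asarray(call.waveform, float)
    sr = call.sample_rate
    if x.size < 2 * sr / floor:
        raise ValueError("call too short for the pitch floor")
    x = x - x.mean()
    n = x.size
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    ac = np.fft.irfft(np.abs(np.fft.rfft(x, nfft)) ** 2)[:n]
    if ac[0] <= 0:
        return cfg.hnr_clamp[0]
    ac = ac / ac[0]
    lo = max(1, int(np.floor(sr / ceiling)))
    hi = min(n - 1, int(np.ceil(sr / floor)))
    if hi <= lo:
        raise ValueError("call too short for the pitch range")
    lags = np.arange(lo, hi + 1)
    # unbiased estimate: undo the 1 - lag/n taper of the raw autocorrelation
    r = float(np.max(ac[lo: hi + 1] * n / (n - lags)))
    r = min(r, 1.0 - 1e-12)
    if r <= 0:
        return cfg.hnr_clamp[0]
    hnr = 10.0 * np.log10(r / (1.0 - r))
    return float(np.clip(hnr, *cfg.hnr_clamp))


def classify_call_type(q50: float, age_class: int) -> str:
    """HF iff Q50 strictly exceeds the age-class cutoff; a value exactly at
    the cutoff is LF."""
    if q50 <= 0:
        raise ValueError("q50 must be > 0")
    try:
        cutoff = Q50_CUTOFFS_HZ[int(age_class)]
    except (KeyError, ValueError):
        raise ValueError(f"unknown age_class {age_class!r}") from None
    return "HF" if q50 > cutoff else "LF"


def extract_features(call, cfg: FeatureConfig | None = None) -> dict:
    """All ten parameters plus the call type for one call."""
    cfg = cfg or FeatureConfig()
    dur = duration(call)
    contour = intensity_contour(call, cfg=cfg)
    amp_var, am_rate, am_extent = amplitude_features(contour, dur, cfg=cfg)
    spec = average_spectrum(call, cfg=cfg)
    q25, q50, q75, fpeak, entropy = spectral_features(spec, cfg=cfg)
    hnr = harmonicity(call, cfg=cfg)
    row = {
        "call_id": call.call_id,
        "pig_id": call.pig_id,
        "team_id": call.team_id,
        "age_class": call.age_class,
        "context": call.context,
        "valence": call.valence,
        "Dur": dur,
        "AmpVar": amp_var,
        "AmpModRate": am_rate,
        "AmpModExtent": am_extent,
        "Q25": q25,
        "Q50": q50,
        "Q75": q75,
        "FPeak": fpeak,
        "Harmonicity": hnr,
        "WienEntropy": entropy,
    }
    row["call_type"] = classify_call_type(q50, call.age_class)
    return row


def extract_table(calls, cfg: FeatureConfig | None = None) -> pd.DataFrame:
    """Feature table for a list of calls, in the canonical column order."""
    cfg = cfg or FeatureConfig()
    rows = []
    for call in calls:
        try:
            rows.append(extract_features(call, cfg))
        except ValueError as exc:
            warnings.warn(f"skipping {call.call_id}: {exc}")
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
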