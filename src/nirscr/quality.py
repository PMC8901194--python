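"""Screening and confound metrics: raw signal strength, short-channel
quality, Mayer-wave amplitude.

All band powers are Welch estimates (Hann window, 60 s segments, 50 %
overlap) integrated over the band.  The short-channel quality index follows
the cardiac-content idea: a short channel is usable when its oxyhemoglobin
series carries a clear pulse, quantified as the dB ratio of cardiac-band
(0.6-2 Hz) power to background (2-4 Hz) power, with a 12 dB pass threshold.
Mayer-wave amplitude is the 0.07-0.14 Hz band power normalized by the
cardiac band power, median across long channels — a scale-free, subject-level
measure of how strongly ~0.1 Hz systemic oscillations contaminate the data.
Both spectral metrics require the *unfiltered* hemoglobin series (the 0.35 Hz
low-pass would destroy the pulse band).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import HemoSeries, RawRecording

__all__ = [
    "QualityReport",
    "signal_strength",
    "short_channel_quality",
    "mayer_wave_amplitude",
    "quality_report",
    "SCREENING_INTENSITY_V",
    "SCREENING_SNR_DB",
    "SHORT_QUALITY_DB",
]

SCREENING_INTENSITY_V = 0.06
SCREENING_SNR_DB = 40.0
SHORT_QUALITY_DB = 12.0

CARDIAC_BAND_HZ = (0.6, 2.0)
BACKGROUND_BAND_HZ = (2.0, 4.0)
MAYER_BAND_HZ = (0.07, 0.14)


def _band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    nperseg = min(x.size, int(round(60.0 * fs)))
    f, pxx = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                       noverlap=nperseg // 2, detrend="constant")
    sel = (f >= band[0]) & (f < band[1])
    if not sel.any():
        return 0.0
    return float(pxx[sel].sum() * (f[1] - f[0]))


def signal_strength(
    rec: RawRecording, window: tuple[float, float] = (0.0, 120.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean raw intensity (V) and SNR (dB) over a rest window.

    SNR = 20 log10(mean/sd) per channel and wavelength, then averaged over
    wavelengths.  A noiseless constant gives +inf with a warning.
    """
    i0 = int(np.floor(window[0] * rec.fs))
    i1 = int(np.ceil(window[1] * rec.fs))
    if not (0 <= i0 < i1 <= rec.n_samples):
        raise ValueError("window outside recording")
    seg = rec.intensities[i0:i1]
    mean = seg.mean(axis=0)                    # [c, w]
    sd = seg.std(axis=0)
    degenerate = sd <= np.abs(mean) * 1e-12    # numerically constant signal
    with np.errstate(divide="ignore"):
        snr = 20.0 * np.log10(np.where(degenerate, np.inf, mean / np.where(degenerate, 1.0, sd)))
    if np.isinf(snr).any():
        warnings.warn("zero variance in rest window; SNR reported as +inf")
    return mean.mean(axis=1), snr.mean(axis=1)


def short_channel_quality(hemo: HemoSeries, channel: int) -> tuple[float, bool]:
    """Cardiac-content quality (dB) of one short channel; pass iff >= 12 dB."""
    if hemo.montage.channels[channel].role != "short":
        raise ValueError(f"channel {channel} is not a short channel")
    if hemo.n_samples / hemo.fs < 60.0:
        raise ValueError("need at least 60 s of data")
    x = hemo.o2hb[:, channel]
    p_card = _band_power(x, hemo.fs, CARDIAC_BAND_HZ)
    p_back = _band_power(x, hemo.fs, BACKGROUND_BAND_HZ)
    if p_back == 0:
        return np.inf, True
    q = 10.0 * np.log10(p_card / p_back)
    return float(q), bool(q >= SHORT_QUALITY_DB)


def mayer_wave_amplitude(hemo: HemoSeries) -> float:
    """Median over long channels of O2Hb band power 0.07-0.14 Hz / 0.6-2 Hz."""
    ratios = []
    for ci in hemo.montage.long_indices:
        x = hemo.o2hb[:, ci]
        p_mw = _band_power(x, hemo.fs, MAYER_BAND_HZ)
        p_card = _band_power(x, hemo.fs, CARDIAC_BAND_HZ)
        if p_card == 0:
            raise ValueError("cardiac band power is zero; series must retain the pulse")
        ratios.append(p_mw / p_card)
    return float(np.median(ratios))


@dataclass
class QualityReport:
    mean_intensity_v: np.ndarray      # per channel
    snr_db: np.ndarray                # per channel
    short_quality_db: dict[int, float]
    short_pass: dict[int, bool]
    mayer_amplitude: float
    screening_pass: bool              # subject-level mean intensity >= 0.06 V

    @property
    def short_pass_rate(self) -> float:
        return float(np.mean(list(self.short_pass.values())))


def quality_report(
    rec: RawRecording,
    hemo_unfiltered: HemoSeries,
    rest_window: tuple[float, float] = (0.0, 120.0),
    intensity_threshold_v: float = SCREENING_INTENSITY_V,
) -> QualityReport:
    mean_v, snr_db = signal_strength(rec, rest_window)
    short_q, short_p = {}, {}
    for ci in rec.montage.short_indices:
        q, ok = short_channel_quality(hemo_unfiltered, int(ci))
        short_q[int(ci)], short_p[int(ci)] = q, ok
    mw = mayer_wave_amplitude(hemo_unfiltered)
    long_idx = rec.montage.long_indices
    screening = bool(mean_v[long_idx].mean() >= intensity_threshold_v)
    return QualityReport(mean_v, snr_db, short_q, short_p, mw, screening)
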