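"""Synthetic fNIRS study generator with known ground truth.

Emulates a test-retest motor-execution study: 15 subjects x 2 sessions x
2 runs, an 8-optode bilateral motor-cortex montage (16 long + 8 short
channels, 8 ROIs), and a block design of 30 hand-grasping trials (15 left /
15 right) of 16 s with 15-24 s inter-stimulus intervals, framed by 120 s
leading and 60 s trailing rest.

Each recording is built generatively:

* a cortical hemodynamic response per ROI — lateralized double-gamma
  responses (contralateral M1 strongest), oxyhemoglobin positive and
  deoxyhemoglobin negative at -0.4x the O2Hb amplitude;
* one shared superficial (scalp) signal per hemisphere — a narrow-band
  Mayer-wave oscillation near 0.1 Hz with slowly wandering amplitude,
  cardiac pulsation near 1-1.3 Hz, a linear drift and 1/f background;
  short channels see only this signal (with channel-specific gains), long
  channels see cortex plus a configurable superficial share;
* channel-specific 1/f "brain noise" that no regression can remove;
* the forward modified Beer-Lambert model converts hemoglobin to optical
  intensities at the four montage wavelengths, scaled to the subject's raw
  signal strength (short channels receive more light), plus white detector
  noise in volts.

Subjects split into "strong" and "weak" responders: weak responders have
either a raw intensity below the 0.06 V screening threshold (detector noise
then dominates the hemoglobin estimates) or a near-absent response paired
with large Mayer waves.  All draws flow from one integer seed, so a study is
bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .hrf import canonical_hrf, condition_regressor  # noqa: F401  (re-export)
from .io import CONDITIONS, EventBlock, Montage, RawRecording, build_default_montage
from .preprocess import MbllParams, forward_mbll

__all__ = [
    "SimConfig",
    "SubjectProfile",
    "Study",
    "make_protocol",
    "simulate_recording",
    "simulate_rest_recording",
    "simulate_study",
    "default_profiles",
    "canonical_hrf",
]

#: relative spatial activation pattern: condition -> roi_id -> weight.
#: ROI 1 is left M1 (contralateral to the right hand), ROI 5 right M1;
#: premotor neighbours activate weakly, ipsilateral M1 weaker still.
ACTIVATION_PATTERN: dict[str, dict[int, float]] = {
    "right": {1: 1.00, 2: 0.45, 3: 0.45, 4: 0.10, 5: 0.20, 6: 0.05, 7: 0.05, 8: 0.05},
    "left": {5: 0.80, 6: 0.38, 7: 0.38, 8: 0.08, 1: 0.16, 2: 0.04, 3: 0.04, 4: 0.04},
}


@dataclass
class SimConfig:
    """Study protocol and noise-model parameters (defaults = study conditions)."""

    n_subjects: int = 15
    n_sessions: int = 2
    runs_per_session: int = 2
    n_trials: int = 30
    trial_duration_s: float = 16.0
    isi_range_s: tuple[float, float] = (15.0, 24.0)
    baseline_start_s: float = 120.0
    baseline_end_s: float = 60.0
    fs: float = 8.98
    # noise / physiology
    white_noise_sd_v: float = 6e-4       # detector noise; 0.06 V <-> 40 dB SNR
    mayer_freq_range_hz: tuple[float, float] = (0.095, 0.11)
    mayer_amp_uM: float = 0.26            # superficial O2Hb, scaled by mw_amplitude
    cardiac_freq_range_hz: tuple[float, float] = (1.0, 1.3)
    cardiac_amp_uM: float = 0.7
    drift_uM_per_min: float = 0.2
    superficial_pink_uM: float = 0.23
    cortical_noise_uM: float = 0.03      # per-channel 1/f background (broadband sd)
    background_band_hz: tuple[float, float] = (0.03, 1.2)
    superficial_share: float = 0.4       # scalp contribution reaching long channels
    short_gain_range: tuple[float, float] = (0.8, 1.2)
    short_intensity_factor: float = 30.0  # shorts sit much closer -> more light
    short_noise_uM: float = 0.03
    hhb_ratio: float = -0.4              # task HHb = ratio x task O2Hb
    hhb_superficial_factor: float = 0.25
    hhb_noise_factor: float = 0.4
    session_effect_sd: float = 0.12      # lognormal sd of per-session amplitude factor
    run_effect_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.isi_range_s[0] > self.isi_range_s[1]:
            raise ValueError("isi_range_s must be ordered")
        for name in ("trial_duration_s", "baseline_start_s", "baseline_end_s", "fs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def noise_free(self) -> "SimConfig":
        """Copy with every stochastic signal component switched off."""
        return replace(
            self,
            white_noise_sd_v=0.0, mayer_amp_uM=0.0, cardiac_amp_uM=0.0,
            drift_uM_per_min=0.0, superficial_pink_uM=0.0,
            cortical_noise_uM=0.0, short_noise_uM=0.0, superficial_share=0.0,
        )


@dataclass
class SubjectProfile:
    subject_id: int
    responder: str                        # 'strong' | 'weak'
    amplitude_uM: float                   # contralateral-M1 O2Hb peak, right hand
    mw_amplitude: float = 1.0             # Mayer-wave scale (1 = mid)
    raw_mean_intensity_v: float = 0.12
    session_effect: tuple[float, ...] = (1.0, 1.0)

    def __post_init__(self):
        if self.raw_mean_intensity_v <= 0:
            raise ValueError("raw_mean_intensity_v must be > 0")

    def roi_amplitudes(self, condition: str) -> dict[int, float]:
        return {roi: self.amplitude_uM * w
                for roi, w in ACTIVATION_PATTERN[condition].items()}


@dataclass
class Study:
    cfg: SimConfig
    profiles: list[SubjectProfile]
    records: list[dict] = field(default_factory=list)  # subject/session/run/recording/truth

    def recordings(self):
        yield from self.records

    def manifest(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "subject": p.subject_id,
                    "responder": p.responder,
                    "amplitude_uM": p.amplitude_uM,
                    "mw_amplitude": p.mw_amplitude,
                    "raw_mean_intensity_v": p.raw_mean_intensity_v,
                    "session_effect_1": p.session_effect[0],
                    "session_effect_2": p.session_effect[1],
                }
                for p in self.profiles
            ]
        )


# ---------------------------------------------------------------------------
# protocol


def make_protocol(cfg: SimConfig, rng: np.random.Generator) -> tuple[EventBlock, ...]:
    """Randomized block-design event list: balanced left/right trial order,
    uniform inter-stimulus intervals, 120 s leading rest."""
    half = cfg.n_trials // 2
    labels = ["left"] * half + ["right"] * (cfg.n_trials - half)
    order = rng.permutation(cfg.n_trials)
    t = cfg.baseline_start_s
    events = []
    for i in order:
        events.append(EventBlock(labels[i], t, cfg.trial_duration_s))
        t += cfg.trial_duration_s + rng.uniform(*cfg.isi_range_s)
    return tuple(events)


def protocol_duration_s(cfg: SimConfig, events) -> float:
    return max(e.offset for e in events) + cfg.baseline_end_s


# ---------------------------------------------------------------------------
# signal components


def _pink_noise(n: int, rng: np.random.Generator,
                fs: float | None = None, f_max: float | None = None) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise (flat below the lowest resolvable f).

    With ``f_max`` the spectrum is additionally cut off above that frequency
    (slow hemodynamic fluctuations roll off well before the cardiac band).
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs if fs else 1.0)
    f[0] = f[1]
    spec /= np.sqrt(f / f[1])
    if f_max is not None:
        spec[f > f_max] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _background_noise(n: int, rng: np.random.Generator, fs: float,
                      band: tuple[float, float] = (0.03, 1.2)) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise restricted to ``band`` (Hz).

    Models spontaneous cortical hemodynamic background (low-frequency
    oscillations, residual respiration); very slow drifts are generated
    separately as part of the shared superficial signal.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    f[0] = f[1]
    shape = np.where((f >= band[0]) & (f <= band[1]), 1.0 / np.sqrt(f), 0.0)
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _smooth(x: np.ndarray, fs: float, tau_s: float) -> np.ndarray:
    """Moving-average smoothing used for slow amplitude modulation."""
    w = max(1, int(round(tau_s * fs)))
    kernel = np.ones(w) / w
    return np.convolve(np.pad(x, w, mode="edge"), kernel, mode="same")[w:-w]


def _superficial_pair(
    n: int, cfg: SimConfig, profile: SubjectProfile, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One hemisphere's superficial (scalp) O2Hb/HHb traces in uM."""
    t = np.arange(n) / cfg.fs
    # Mayer wave: narrow-band oscillation with slowly wandering amplitude
    f_mw = rng.uniform(*cfg.mayer_freq_range_hz)
    mod = 1.0 + 0.3 * _smooth(rng.standard_normal(n), cfg.fs, 20.0)
    mayer = (
        profile.mw_amplitude * cfg.mayer_amp_uM
        * np.clip(mod, 0.0, None)
        * np.sin(2 * np.pi * f_mw * t + rng.uniform(0, 2 * np.pi))
    )
    f_hr = rng.uniform(*cfg.cardiac_freq_range_hz)
    cardiac = cfg.cardiac_amp_uM * (1.0 + 0.1 * _smooth(rng.standard_normal(n), cfg.fs, 10.0)) \
        * np.sin(2 * np.pi * f_hr * t + rng.uniform(0, 2 * np.pi))
    drift = rng.uniform(-1, 1) * cfg.drift_uM_per_min / 60.0 * t
    pink = cfg.superficial_pink_uM * _pink_noise(n, rng, cfg.fs, f_max=0.5)
    o2hb = mayer + cardiac + drift + pink
    hhb = cfg.hhb_superficial_factor * o2hb
    return o2hb, hhb


# ---------------------------------------------------------------------------
# recording synthesis


def _subject_statics(profile: SubjectProfile, cfg: SimConfig, montage: Montage) -> dict:
    """Optode-placement-dependent quantities, fixed across a subject's runs.

    Superficial-share jitter per long channel, short-channel superficial
    gains and per-channel/wavelength light coupling all derive from how the
    optodes sit on this subject's head, so they are drawn once per subject.
    """
    rng = np.random.default_rng([cfg.seed, profile.subject_id, 555])
    n_ch = montage.n_channels
    n_wl = len(montage.wavelengths)
    share_gain = np.empty(n_ch)
    i0 = np.empty((n_ch, n_wl))
    for ci, ch in enumerate(montage.channels):
        if ch.role == "long":
            share_gain[ci] = cfg.superficial_share * rng.uniform(0.7, 1.3)
            base = profile.raw_mean_intensity_v
        else:
            share_gain[ci] = rng.uniform(*cfg.short_gain_range)
            base = profile.raw_mean_intensity_v * cfg.short_intensity_factor
        i0[ci] = base * np.exp(rng.normal(0.0, 0.15, n_wl))
    return {"share_gain": share_gain, "i0": i0}


def simulate_recording(
    profile: SubjectProfile,
    cfg: SimConfig,
    session: int = 1,
    run: int = 1,
    rng: np.random.Generator | None = None,
    montage: Montage | None = None,
) -> tuple[RawRecording, dict]:
    """Generate one run and its ground truth.

    Ground truth holds the effective per-ROI amplitudes (after session/run
    factors), the noiseless cortical O2Hb trace per ROI and the superficial
    traces per hemisphere.
    """
    if rng is None:
        rng = np.random.default_rng(
            [cfg.seed, profile.subject_id, session, run]
        )
    montage = montage or build_default_montage()
    events = make_protocol(cfg, rng)
    n = int(np.ceil(protocol_duration_s(cfg, events) * cfg.fs))
    sess_fac = profile.session_effect[session - 1]
    run_fac = float(np.exp(rng.normal(0.0, cfg.run_effect_sd)))

    regs = {c: condition_regressor(events, c, n, cfg.fs, "canonical",
                                   cfg.trial_duration_s) for c in CONDITIONS}
    amplitudes = {
        c: {roi: a * sess_fac * run_fac for roi, a in profile.roi_amplitudes(c).items()}
        for c in CONDITIONS
    }
    roi_ids = sorted(montage.roi_map)
    cortical = {
        roi: sum(amplitudes[c].get(roi, 0.0) * regs[c] for c in CONDITIONS)
        for roi in roi_ids
    }
    superficial = [_superficial_pair(n, cfg, profile, rng) for _ in range(2)]
    statics = _subject_statics(profile, cfg, montage)

    n_ch = montage.n_channels
    o2hb = np.zeros((n, n_ch))
    hhb = np.zeros((n, n_ch))
    for ci, ch in enumerate(montage.channels):
        hemi = 0 if ch.source_id < 4 else 1
        sup_o, sup_h = superficial[hemi]
        gain = statics["share_gain"][ci]
        if ch.role == "long":
            noise_o = cfg.cortical_noise_uM * _background_noise(n, rng, cfg.fs, cfg.background_band_hz)
            noise_h = cfg.hhb_noise_factor * cfg.cortical_noise_uM \
                * _background_noise(n, rng, cfg.fs, cfg.background_band_hz)
            o2hb[:, ci] = cortical[ch.roi_id] + gain * sup_o + noise_o
            hhb[:, ci] = (cfg.hhb_ratio * cortical[ch.roi_id]
                          + gain * sup_h + noise_h)
        else:
            o2hb[:, ci] = gain * sup_o + cfg.short_noise_uM * _pink_noise(n, rng)
            hhb[:, ci] = gain * sup_h + cfg.hhb_noise_factor * cfg.short_noise_uM \
                * _pink_noise(n, rng)

    params = MbllParams(wavelengths=montage.wavelengths)
    od = forward_mbll(o2hb, hhb, montage, params)
    intensities = statics["i0"][None, :, :] * 10.0 ** (-od)
    if cfg.white_noise_sd_v > 0:
        intensities = intensities + rng.normal(
            0.0, cfg.white_noise_sd_v, intensities.shape
        )
        intensities = np.maximum(intensities, 1e-9)

    meta = {"subject": profile.subject_id, "session": session, "run": run}
    rec = RawRecording(intensities, cfg.fs, montage, events, meta)
    truth = {
        "amplitudes": amplitudes,
        "cortical_o2hb": cortical,
        "superficial_o2hb": np.stack([s[0] for s in superficial], axis=1),
        "superficial_hhb": np.stack([s[1] for s in superficial], axis=1),
        "session_factor": sess_fac,
        "run_factor": run_fac,
        "profile": profile,
    }
    return rec, truth


def simulate_rest_recording(
    profile: SubjectProfile,
    cfg: SimConfig,
    duration_s: float = 1400.0,
    rng: np.random.Generator | None = None,
    montage: Montage | None = None,
) -> RawRecording:
    """Task-free recording (event list empty) with the full noise model.

    Same superficial physiology, channel noise and forward optics as
    :func:`simulate_recording`, but no cortical task response — the substrate
    for deriving baseline-null activation thresholds.
    """
    if rng is None:
        rng = np.random.default_rng([cfg.seed, profile.subject_id, 7777])
    montage = montage or build_default_montage()
    n = int(np.ceil(duration_s * cfg.fs))
    superficial = [_superficial_pair(n, cfg, profile, rng) for _ in range(2)]
    statics = _subject_statics(profile, cfg, montage)
    n_ch = montage.n_channels
    o2hb = np.zeros((n, n_ch))
    hhb = np.zeros((n, n_ch))
    for ci, ch in enumerate(montage.channels):
        hemi = 0 if ch.source_id < 4 else 1
        sup_o, sup_h = superficial[hemi]
        gain = statics["share_gain"][ci]
        if ch.role == "long":
            o2hb[:, ci] = gain * sup_o \
                + cfg.cortical_noise_uM * _background_noise(n, rng, cfg.fs, cfg.background_band_hz)
            hhb[:, ci] = gain * sup_h \
                + cfg.hhb_noise_factor * cfg.cortical_noise_uM \
                * _background_noise(n, rng, cfg.fs, cfg.background_band_hz)
        else:
            o2hb[:, ci] = gain * sup_o + cfg.short_noise_uM * _pink_noise(n, rng)
            hhb[:, ci] = gain * sup_h + cfg.hhb_noise_factor * cfg.short_noise_uM \
                * _pink_noise(n, rng)
    params = MbllParams(wavelengths=montage.wavelengths)
    od = forward_mbll(o2hb, hhb, montage, params)
    intensities = statics["i0"][None, :, :] * 10.0 ** (-od)
    if cfg.white_noise_sd_v > 0:
        intensities = np.maximum(
            intensities + rng.normal(0.0, cfg.white_noise_sd_v, intensities.shape),
            1e-9,
        )
    meta = {"subject": profile.subject_id, "session": 0, "run": 0}
    return RawRecording(intensities, cfg.fs, montage, (), meta)


def default_profiles(cfg: SimConfig, rng: np.random.Generator | None = None) -> list[SubjectProfile]:
    """Fifteen subjects: nine strong responders, six weak.

    Five weak responders have raw intensities below the 0.06 V screening
    threshold; the sixth has good optics but a near-absent response and
    large Mayer waves.
    """
    rng = rng or np.random.default_rng(cfg.seed + 101)
    profiles: list[SubjectProfile] = []
    weak_low_intensity = {6, 7, 8, 14, 15}
    weak_high_mw = {5}
    for sid in range(1, cfg.n_subjects + 1):
        sess = tuple(np.exp(rng.normal(0.0, cfg.session_effect_sd, cfg.n_sessions)))
        if sid in weak_low_intensity:
            profiles.append(SubjectProfile(
                sid, "weak",
                amplitude_uM=float(np.clip(rng.normal(0.09, 0.012), 0.06, 0.12)),
                mw_amplitude=float(np.exp(rng.normal(0.0, 0.3))),
                raw_mean_intensity_v=float(rng.uniform(0.02, 0.045)),
                session_effect=sess,
            ))
        elif sid in weak_high_mw:
            profiles.append(SubjectProfile(
                sid, "weak", amplitude_uM=0.04, mw_amplitude=2.5,
                raw_mean_intensity_v=0.15, session_effect=sess,
            ))
        else:
            profiles.append(SubjectProfile(
                sid, "strong",
                amplitude_uM=float(np.clip(rng.normal(0.40, 0.05), 0.30, 0.52)),
                mw_amplitude=float(np.exp(rng.normal(-0.2, 0.35))),
                raw_mean_intensity_v=float(np.exp(rng.normal(np.log(0.22), 0.3))),
                session_effect=sess,
            ))
    return profiles


def simulate_study(
    cfg: SimConfig,
    profiles: list[SubjectProfile] | None = None,
) -> Study:
    """Full study: every profile x session x run, deterministically seeded."""
    profiles = profiles if profiles is not None else default_profiles(cfg)
    if not profiles:
        raise ValueError("profiles must be non-empty")
    study = Study(cfg, profiles)
    montage = build_default_montage()
    for p in profiles:
        for session in range(1, cfg.n_sessions + 1):
            for run in range(1, cfg.runs_per_session + 1):
                rec, truth = simulate_recording(p, cfg, session, run, montage=montage)
                study.records.append({
                    "subject": p.subject_id, "session": session, "run": run,
                    "recording": rec, "truth": truth,
                })
    return study
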