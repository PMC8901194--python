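"""Canonical hemodynamic response function and task regressors.

The canonical kernel is the standard double-gamma: a positive gamma density
peaking at 6 s minus a 1/6-scaled undershoot gamma peaking at 16 s, truncated
at 32 s and peak-normalized to 1.  Two shape-correction kernels accompany it:
a temporal derivative (finite difference with respect to a 1 s onset shift)
and a dispersion derivative (finite difference with respect to the peak
dispersion parameter).  Task regressors are the convolution of a condition
boxcar with the canonical kernel, scaled so a single isolated trial peaks at
1 — the fitted coefficient of the canonical column is then directly the
per-trial peak response amplitude in uM.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as gamma_dist

__all__ = ["canonical_hrf", "condition_regressor", "hrf_basis"]

PEAK_DELAY_S = 6.0
UNDERSHOOT_DELAY_S = 16.0
UNDERSHOOT_RATIO = 1.0 / 6.0
SUPPORT_S = 32.0
_ONSET_SHIFT_S = 1.0
_DISPERSION_STEP = 0.01


def _double_gamma(t: np.ndarray, dispersion: float = 1.0, shift: float = 0.0) -> np.ndarray:
    """Un-normalized double-gamma evaluated at times ``t`` (s).

    Gamma densities are parameterized by their mode: shape = delay/disp + 1,
    scale = disp, so the positive lobe peaks at ``PEAK_DELAY_S`` and the
    undershoot at ``UNDERSHOOT_DELAY_S`` when ``dispersion`` is 1.
    """
    ts = np.asarray(t, float) - shift
    pos = gamma_dist.pdf(ts, PEAK_DELAY_S / dispersion + 1.0, scale=dispersion)
    neg = gamma_dist.pdf(ts, UNDERSHOOT_DELAY_S / dispersion + 1.0, scale=dispersion)
    h = pos - UNDERSHOOT_RATIO * neg
    h[ts < 0] = 0.0
    return h


def _check_uniform(t_grid: np.ndarray) -> float:
    t = np.asarray(t_grid, float)
    if t.size < 2:
        raise ValueError("t_grid needs at least 2 points")
    dt = np.diff(t)
    if t[0] != 0 or np.any(np.abs(dt - dt[0]) > 1e-9 * dt[0]):
        raise ValueError("t_grid must be uniform and start at 0")
    return float(dt[0])


def canonical_hrf(t_grid: np.ndarray, kind: str = "canonical") -> np.ndarray:
    """Evaluate an HRF basis kernel on a uniform time grid starting at 0.

    ``kind`` is one of ``canonical``, ``temporal_derivative`` or
    ``dispersion_derivative``.  The canonical kernel is peak-normalized to 1;
    the derivatives are scaled by the same factor so the basis stays mutually
    consistent.
    """
    _check_uniform(t_grid)
    t = np.asarray(t_grid, float)
    base = _double_gamma(t)
    scale = 1.0 / np.max(_double_gamma(np.linspace(0, SUPPORT_S, 4001)))
    if kind == "canonical":
        out = base * scale
    elif kind == "temporal_derivative":
        out = (base - _double_gamma(t, shift=_ONSET_SHIFT_S)) / _ONSET_SHIFT_S * scale
    elif kind == "dispersion_derivative":
        out = (
            (base - _double_gamma(t, dispersion=1.0 + _DISPERSION_STEP))
            / _DISPERSION_STEP
            * scale
        )
    else:
        raise ValueError(f"unknown kernel kind {kind!r}")
    out = out.copy()
    out[t > SUPPORT_S] = 0.0
    return out


def hrf_basis(fs: float) -> dict[str, np.ndarray]:
    """The three kernels sampled at ``fs`` over the 32 s support."""
    t = np.arange(0, SUPPORT_S + 1.0 / fs, 1.0 / fs)
    return {k: canonical_hrf(t, k) for k in
            ("canonical", "temporal_derivative", "dispersion_derivative")}


def _boxcar(events, condition: str, n_samples: int, fs: float) -> np.ndarray:
    box = np.zeros(n_samples)
    for e in events:
        if e.condition != condition:
            continue
        i0 = int(np.ceil(e.onset * fs - 1e-9))
        i1 = int(np.ceil(e.offset * fs - 1e-9))
        box[i0:min(i1, n_samples)] = 1.0
    return box


def _single_trial_peak(duration_s: float, fs: float, kernel: np.ndarray) -> float:
    n_box = max(1, int(round(duration_s * fs)))
    resp = np.convolve(np.ones(n_box), kernel)
    return float(np.max(resp))


def condition_regressor(
    events,
    condition: str,
    n_samples: int,
    fs: float,
    kind: str = "canonical",
    trial_duration_s: float | None = None,
) -> np.ndarray:
    """Boxcar (x) HRF-kernel regressor for one condition.

    Normalized by the peak of an isolated single-trial canonical response so
    the canonical column carries amplitude units.  ``trial_duration_s``
    defaults to the duration of the first matching event.
    """
    kernel = hrf_basis(fs)[kind]
    box = _boxcar(events, condition, n_samples, fs)
    if trial_duration_s is None:
        durs = [e.duration for e in events if e.condition == condition]
        trial_duration_s = durs[0] if durs else 16.0
    peak = _single_trial_peak(trial_duration_s, fs, hrf_basis(fs)["canonical"])
    return np.convolve(box, kernel)[:n_samples] / peak
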