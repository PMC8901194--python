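"""Pseudo-online left-vs-right hand-grasping classification.

The causal processing chain mirrors what an online BCI could run sample by
sample:

1. forward-only band-pass: Chebyshev-II order-2 high-pass at 0.005 Hz
   followed by Butterworth order-4 low-pass at 0.35 Hz (no future samples);
2. sample-wise adaptive short-channel regression: for every long channel, a
   normalized-LMS filter estimates non-negative weights on the short-channel
   streams and subtracts their combination;
3. per-trial features over the full 16 s window, per long channel: amplitude
   (window mean minus value at onset), slope (least-squares line), and the
   mean of the CBSI-combined trace x = (dO2Hb - sigma*dHHb)/2 with
   sigma = sd(dO2Hb)/sd(dHHb) computed within the window;
4. a linear SVM with L1 penalty (joint feature selection), its regularization
   chosen by stratified 5-fold cross-validation on the training run only;
   features are standardized with training statistics.

Training uses run 1, evaluation run 2 of the same session; accuracy over the
30 test trials is compared against a significance line (70 % display
default; the exact one-sided binomial threshold is also available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .io import EventBlock, HemoSeries

__all__ = [
    "TrialDataset",
    "ClassifierResult",
    "causal_filter",
    "adaptive_scr",
    "extract_features",
    "build_trial_dataset",
    "train_classifier",
    "evaluate_session",
    "significance_line",
    "SIGNIFICANCE_LINE_PCT",
]

#: conventional display threshold (1 % significance above chance on 30 trials)
SIGNIFICANCE_LINE_PCT = 70.0


def causal_filter(
    series: HemoSeries,
    highpass_hz: float = 0.005,
    lowpass_hz: float = 0.35,
    cheby_stop_db: float = 20.0,
) -> HemoSeries:
    """Forward-only (causal) band-pass of both chromophores."""
    nyq = series.fs / 2
    if not (0 < highpass_hz < nyq and 0 < lowpass_hz < nyq):
        raise ValueError("cutoffs must lie below Nyquist")
    sos_hp = sps.cheby2(2, cheby_stop_db, highpass_hz, "highpass",
                        fs=series.fs, output="sos")
    sos_lp = sps.butter(4, lowpass_hz, "lowpass", fs=series.fs, output="sos")
    def run(x):
        return sps.sosfilt(sos_lp, sps.sosfilt(sos_hp, x, axis=0), axis=0)
    return series.copy_with(o2hb=run(series.o2hb), hhb=run(series.hhb))


def adaptive_scr(
    long: np.ndarray,
    shorts: np.ndarray,
    step: float = 0.005,
    eps: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample-wise non-negative short-channel regression (normalized LMS).

    ``long`` is ``[n]`` or ``[n, n_long]``; ``shorts`` is ``[n, n_short]``.
    Per sample the prediction error ``e = long - w^T shorts`` is the output,
    weights move along the normalized gradient and are projected onto
    ``w >= 0``.  Returns ``(regressed, weight_trace)`` with the trace shaped
    ``[n, n_long, n_short]`` (squeezed when ``long`` is 1-D).
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    one_d = long.ndim == 1
    y = np.atleast_2d(np.asarray(long, float).T).T  # [n, n_long]
    s = np.asarray(shorts, float)
    if s.shape[0] != y.shape[0]:
        raise ValueError("streams must be aligned")
    n, n_long = y.shape
    m = s.shape[1]
    w = np.zeros((n_long, m))
    out = np.empty_like(y)
    trace = np.empty((n, n_long, m))
    for t in range(n):
        st = s[t]
        e = y[t] - w @ st
        out[t] = e
        w += step * np.outer(e, st) / (eps + st @ st)
        np.clip(w, 0.0, None, out=w)
        trace[t] = w
    if one_d:
        return out[:, 0], trace[:, 0, :]
    return out, trace


def apply_adaptive_scr(series: HemoSeries, step: float = 0.005) -> HemoSeries:
    """Adaptive SCR of every long channel on all short channels, per chromophore."""
    short_idx = series.montage.short_indices
    long_idx = series.montage.long_indices
    o2hb = series.o2hb.copy()
    hhb = series.hhb.copy()
    o2hb[:, long_idx], _ = adaptive_scr(series.o2hb[:, long_idx],
                                        series.o2hb[:, short_idx], step)
    hhb[:, long_idx], _ = adaptive_scr(series.hhb[:, long_idx],
                                       series.hhb[:, short_idx], step)
    return series.copy_with(o2hb=o2hb, hhb=hhb, tag="SCR")


# ---------------------------------------------------------------------------
# features


@dataclass
class TrialDataset:
    features: np.ndarray               # [n_trials, n_features]
    labels: np.ndarray                 # 'left' / 'right'
    feature_names: tuple[str, ...]
    source_tag: str = "SCR"            # SS_only | LS_only | SCR

    def __post_init__(self):
        if not np.isfinite(self.features).all():
            raise ValueError("features must be finite")
        if self.features.shape[0] != self.labels.size:
            raise ValueError("label/feature count mismatch")


def extract_features(
    series: HemoSeries, trial: EventBlock, channels: np.ndarray | None = None
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Amplitude, slope and CBSI features for one trial window.

    Per channel: amplitude and slope of each chromophore over the 16 s
    window, plus the mean of the CBSI-combined trace.  The CBSI combination
    exploits the anti-correlation of dO2Hb and dHHb to suppress common-mode
    artifacts.
    """
    i0 = int(np.round(trial.onset * series.fs))
    i1 = int(np.round(trial.offset * series.fs))
    if i1 > series.n_samples:
        raise ValueError("trial window extends past the recording")
    channels = channels if channels is not None else series.montage.long_indices
    t = np.arange(i1 - i0) / series.fs
    feats, names = [], []
    for ci in channels:
        win = {c: series.chromophore(c)[i0:i1, ci] for c in ("o2hb", "hhb")}
        for chrom, x in win.items():
            amp = float(x.mean() - x[0])
            slope = float(np.polyfit(t, x, 1)[0]) if x.size > 1 else 0.0
            feats += [amp, slope]
            names += [f"ch{ci}_{chrom}_amplitude", f"ch{ci}_{chrom}_slope"]
        sd_h = win["hhb"].std()
        sigma = win["o2hb"].std() / sd_h if sd_h > 0 else 0.0
        cbsi = (win["o2hb"] - sigma * win["hhb"]) / 2.0
        feats.append(float(cbsi.mean() - cbsi[0]))
        names.append(f"ch{ci}_cbsi")
    return np.array(feats), tuple(names)


def build_trial_dataset(series: HemoSeries, source_tag: str = "SCR") -> TrialDataset:
    """Features for every task trial of a processed recording.

    ``source_tag`` selects the channels: ``SS_only`` uses the short channels
    (a negative control — they carry no cortical signal), otherwise the long
    channels of the given series (``LS_only`` for unregressed input, ``SCR``
    after adaptive regression).
    """
    channels = (series.montage.short_indices if source_tag == "SS_only"
                else series.montage.long_indices)
    rows, labels, names = [], [], None
    for e in series.events:
        if e.condition not in ("left", "right"):
            continue
        f, names = extract_features(series, e, channels)
        rows.append(f)
        labels.append(e.condition)
    return TrialDataset(np.array(rows), np.array(labels), names, source_tag)


# ---------------------------------------------------------------------------
# classifier


def train_classifier(
    train: TrialDataset,
    c_grid: np.ndarray | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> Pipeline:
    """L1-regularized linear SVM; C chosen by stratified CV on training data."""
    if train.features.shape[0] < 10:
        raise ValueError("need at least 10 training trials")
    if np.unique(train.labels).size < 2:
        raise ValueError("both classes must be present")
    c_grid = c_grid if c_grid is not None else np.logspace(-3, 2, 10)
    svm = LinearSVC(penalty="l1", dual=False, max_iter=20000, random_state=seed)
    pipe = Pipeline([("scale", StandardScaler()), ("svm", svm)])
    cv = StratifiedKFold(n_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, {"svm__C": c_grid}, cv=cv, scoring="accuracy")
    search.fit(train.features, train.labels)
    return search.best_estimator_


@dataclass
class ClassifierResult:
    predictions: np.ndarray
    accuracy_pct: float
    n_trials: int
    selected_features: int
    regularization_c: float
    significant: bool
    significance_line_pct: float = SIGNIFICANCE_LINE_PCT


def evaluate_session(
    model: Pipeline,
    test: TrialDataset,
    train_names: tuple[str, ...] | None = None,
    line_pct: float = SIGNIFICANCE_LINE_PCT,
) -> ClassifierResult:
    """Accuracy of a run-1-trained model on the run-2 trials."""
    if train_names is not None and tuple(train_names) != tuple(test.feature_names):
        raise ValueError("feature-name mismatch between train and test datasets")
    pred = model.predict(test.features)
    acc = 100.0 * float(np.mean(pred == test.labels))
    coefs = model.named_steps["svm"].coef_.ravel()
    return ClassifierResult(
        pred, acc, test.labels.size,
        int(np.sum(np.abs(coefs) > 1e-12)),
        float(model.named_steps["svm"].C),
        bool(acc >= line_pct), line_pct,
    )


def significance_line(n_trials: int, alpha: float = 0.01) -> float:
    """Smallest accuracy (%) whose one-sided binomial tail at p=0.5 is <= alpha."""
    if n_trials < 1 or not (0 < alpha < 1):
        raise ValueError("need n_trials >= 1 and 0 < alpha < 1")
    k = np.arange(n_trials + 1)
    tail = stats.binom.sf(k - 1, n_trials, 0.5)  # P(X >= k)
    ok = np.flatnonzero(tail <= alpha)
    k_min = int(ok[0]) if ok.size else n_trials + 1
    return 100.0 * min(k_min, n_trials) / n_trials if ok.size else 100.0
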