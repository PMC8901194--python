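import numpy as np
import pytest
from scipy import signal as sps

from nirscr import (EventBlock, HemoSeries, TrialDataset, adaptive_scr,
                    causal_filter, evaluate_session, extract_features,
                    significance_line, train_classifier)
from nirscr.bci import build_trial_dataset

FS = 8.98


def _series(montage, arr, events=()):
    return HemoSeries(arr, arr.copy(), FS, montage, events)


# ---------------------------------------------------------------------------
# causal filtering


def test_filter_is_causal(montage):
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, (3000, 24))
    full = causal_filter(_series(montage, x))
    truncated = causal_filter(_series(montage, x[:2000]))
    np.testing.assert_allclose(full.o2hb[:2000], truncated.o2hb, atol=1e-12)


def test_step_input_returns_toward_zero(montage):
    # Chebyshev-II stop band sits at -20 dB, so "toward zero" means down to
    # ~10% of the step, not exactly zero
    x = np.ones((20000, 24))
    out = causal_filter(_series(montage, x))
    assert abs(out.o2hb[-1, 0]) < 0.15 * abs(out.o2hb[:, 0]).max()


def test_tone_attenuation_matches_analytic_magnitude(montage):
    t = np.arange(0, 600, 1 / FS)
    for freq, tol_db in ((1.0, 3.0), (0.05, 3.0)):
        x = np.tile(np.sin(2 * np.pi * freq * t)[:, None], (1, 24))
        out = causal_filter(_series(montage, x))
        steady = out.o2hb[len(t) // 2:, 0]
        measured = np.sqrt(2) * steady.std()
        b, a = sps.butter(4, 0.35, "lowpass", fs=FS)
        _, h_lp = sps.freqz(b, a, worN=[freq], fs=FS)
        sos_hp = sps.cheby2(2, 20.0, 0.005, "highpass", fs=FS, output="sos")
        _, h_hp = sps.sosfreqz(sos_hp, worN=[freq], fs=FS)
        expected = abs(h_lp[0]) * abs(h_hp[0])
        assert 20 * np.log10(measured / expected) == pytest.approx(0.0, abs=tol_db)


def test_passband_tone_within_3db(montage):
    t = np.arange(0, 600, 1 / FS)
    x = np.tile(np.sin(2 * np.pi * 0.05 * t)[:, None], (1, 24))
    out = causal_filter(_series(montage, x))
    steady = out.o2hb[len(t) // 2:, 0]
    assert 20 * np.log10(np.sqrt(2) * steady.std()) > -3.0


def test_cutoff_beyond_nyquist_rejected(montage):
    x = np.zeros((100, 24))
    with pytest.raises(ValueError, match="Nyquist"):
        causal_filter(_series(montage, x), lowpass_hz=5.0)


# ---------------------------------------------------------------------------
# adaptive short-channel regression


def test_weight_converges_to_batch_solution():
    t = np.arange(0, 120, 1 / FS)
    short = np.sin(2 * np.pi * 0.3 * t)[:, None]
    long = 0.5 * short[:, 0]
    out, trace = adaptive_scr(long, short, step=0.01)
    assert trace[-1, 0] == pytest.approx(0.5, abs=0.02)
    # batch oracle on the same window
    from scipy.optimize import nnls

    w_batch, _ = nnls(short, long)
    assert trace[-1, 0] == pytest.approx(w_batch[0], abs=0.02)


def test_uncorrelated_streams_leave_weights_near_zero():
    # no gradient to follow: the weights hover at the constraint boundary
    # with a scale set by the adaptation step
    rng = np.random.default_rng(1)
    n = int(600 * FS)
    out, trace = adaptive_scr(rng.normal(0, 1, n), rng.normal(0, 1, (n, 2)),
                              step=5e-4)
    last = trace[-int(60 * FS):]
    assert np.all(np.abs(last) < 0.05)


def test_anticorrelated_weight_pinned_at_zero():
    t = np.arange(0, 120, 1 / FS)
    short = np.sin(2 * np.pi * 0.3 * t)[:, None]
    out, trace = adaptive_scr(-0.7 * short[:, 0], short, step=0.01)
    assert np.all(trace[:, 0] >= 0.0)
    assert trace[-1, 0] == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(out, -0.7 * short[:, 0], atol=1e-9)


def test_invalid_step_rejected():
    with pytest.raises(ValueError, match="step"):
        adaptive_scr(np.zeros(10), np.zeros((10, 1)), step=0.0)


def test_end_to_end_causality_of_adaptive_stage():
    rng = np.random.default_rng(2)
    n = 2000
    long = rng.normal(0, 1, n)
    shorts = rng.normal(0, 1, (n, 3))
    full, _ = adaptive_scr(long, shorts)
    part, _ = adaptive_scr(long[:1500], shorts[:1500])
    np.testing.assert_allclose(full[:1500], part, atol=1e-12)


# ---------------------------------------------------------------------------
# features


def test_flat_signal_gives_zero_features(montage):
    arr = np.zeros((int(60 * FS), 24))
    series = _series(montage, arr)
    feats, names = extract_features(series, EventBlock("left", 10.0, 16.0))
    assert np.allclose(feats, 0.0)
    assert len(feats) == 16 * 5   # amp+slope per chromophore + cbsi, per channel


def test_linear_ramp_slope_and_amplitude():
    from nirscr import build_default_montage

    montage = build_default_montage()
    t = np.arange(0, 60, 1 / FS)
    a = 0.37
    arr = np.tile((a * t)[:, None], (1, 24))
    series = HemoSeries(arr, -arr, FS, montage)
    feats, names = extract_features(series, EventBlock("left", 10.0, 16.0))
    i_slope = names.index("ch0_o2hb_slope")
    i_amp = names.index("ch0_o2hb_amplitude")
    assert feats[i_slope] == pytest.approx(a, abs=1e-9)
    # mean of a ramp over [0, T) minus its start = a*(T-dt)/2 ~ a*8 s
    assert feats[i_amp] == pytest.approx(a * 8.0, rel=0.02)


def test_cbsi_recovers_o2hb_under_perfect_anticorrelation(montage):
    rng = np.random.default_rng(3)
    n = int(60 * FS)
    x = rng.normal(0, 1, (n, 24))
    k = 2.5
    series = HemoSeries(x, -x / k, FS, montage)
    trial = EventBlock("left", 10.0, 16.0)
    feats, names = extract_features(series, trial)
    i0, i1 = int(round(10 * FS)), int(round(26 * FS))
    win = x[i0:i1, 0]
    expected = (win.mean() - win[0])
    assert feats[names.index("ch0_cbsi")] == pytest.approx(expected, abs=1e-9)


def test_window_past_end_rejected(montage):
    arr = np.zeros((100, 24))
    with pytest.raises(ValueError, match="past"):
        extract_features(_series(montage, arr), EventBlock("left", 10.0, 16.0))


def test_trial_dataset_source_channels(montage):
    n = int(200 * FS)
    arr = np.random.default_rng(4).normal(0, 1, (n, 24))
    events = tuple(EventBlock(c, 20.0 + 40 * i, 16.0)
                   for i, c in enumerate(["left", "right", "left", "right"]))
    series = _series(montage, arr, events)
    ls = build_trial_dataset(series, "LS_only")
    ss = build_trial_dataset(series, "SS_only")
    assert ls.features.shape == (4, 16 * 5)
    assert ss.features.shape == (4, 8 * 5)
    assert all(n.startswith("ch16") or not n.startswith("ch0_")
               for n in ss.feature_names[:5])


# ---------------------------------------------------------------------------
# classifier


def _toy_dataset(n=30, seed=0, informative=True):
    rng = np.random.default_rng(seed)
    labels = np.array(["left", "right"] * (n // 2))
    X = rng.normal(0, 1, (n, 6))
    if informative:
        X[:, 0] += np.where(labels == "right", 3.0, -3.0)
        X[:, 1] += np.where(labels == "right", 3.0, -3.0)
    return TrialDataset(X, labels, tuple(f"f{i}" for i in range(6)), "SCR")


def test_separable_toy_problem_perfect_and_sparse():
    train = _toy_dataset()
    model = train_classifier(train, seed=0)
    assert np.mean(model.predict(train.features) == train.labels) == 1.0
    coefs = model.named_steps["svm"].coef_.ravel()
    assert np.sum(np.abs(coefs) > 1e-12) <= 3


def test_single_class_and_tiny_datasets_rejected():
    ds = _toy_dataset()
    one_class = TrialDataset(ds.features, np.array(["left"] * 30),
                             ds.feature_names, "SCR")
    with pytest.raises(ValueError, match="class"):
        train_classifier(one_class)
    tiny = TrialDataset(ds.features[:6], ds.labels[:6], ds.feature_names, "SCR")
    with pytest.raises(ValueError, match="10"):
        train_classifier(tiny)


def test_evaluation_checks_feature_names():
    train = _toy_dataset(seed=1)
    test = _toy_dataset(seed=2)
    model = train_classifier(train, seed=0)
    renamed = TrialDataset(test.features, test.labels,
                           tuple(f"g{i}" for i in range(6)), "SCR")
    with pytest.raises(ValueError, match="mismatch"):
        evaluate_session(model, renamed, train.feature_names)
    res = evaluate_session(model, test, train.feature_names)
    assert res.accuracy_pct >= 90.0
    assert res.significant


# ---------------------------------------------------------------------------
# significance line


def _binomial_line_oracle(n, alpha):
    from math import comb

    for k in range(n + 1):
        tail = sum(comb(n, j) for j in range(k, n + 1)) / 2**n
        if tail <= alpha:
            return 100.0 * k / n
    return 100.0


@pytest.mark.parametrize("n,alpha", [(10, 0.5), (30, 0.01), (30, 0.05), (100, 0.001)])
def test_significance_line_matches_exact_enumeration(n, alpha):
    assert significance_line(n, alpha) == pytest.approx(
        _binomial_line_oracle(n, alpha)
    )


def test_significance_line_limits():
    assert significance_line(30, 1e-12) == 100.0
    assert significance_line(30, 0.01) == pytest.approx(100 * 22 / 30)
    with pytest.raises(ValueError):
        significance_line(0, 0.05)
    with pytest.raises(ValueError):
        significance_line(10, 1.5)
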