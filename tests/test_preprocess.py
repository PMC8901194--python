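import numpy as np
import pytest

from nirscr import (HemoSeries, MbllParams, RawRecording, bandpass_fir,
                    build_default_montage, forward_mbll, intensity_to_od,
                    od_to_hemoglobin, remove_motion_spline)
from nirscr.preprocess import OpticalDensity

FS = 8.98


def _flat_recording(montage, value=0.1, n=3000):
    return RawRecording(np.full((n, 24, 4), value), FS, montage)


# ---------------------------------------------------------------------------
# optical density


def test_constant_intensity_gives_zero_od(montage):
    od = intensity_to_od(_flat_recording(montage), (0.0, 60.0))
    assert np.allclose(od.od, 0.0)


def test_tenfold_drop_gives_od_one(montage):
    rec = _flat_recording(montage)
    data = rec.intensities.copy()
    data[2000:] /= 10.0
    rec2 = RawRecording(data, FS, montage)
    od = intensity_to_od(rec2, (0.0, 60.0))
    assert od.od[2500, 0, 0] == pytest.approx(1.0, abs=1e-12)


def test_od_matches_elementwise_formula(montage):
    rng = np.random.default_rng(0)
    data = 0.1 * np.exp(rng.normal(0, 0.01, (3000, 24, 4)))
    rec = RawRecording(data, FS, montage)
    od = intensity_to_od(rec, (0.0, 60.0))
    ref = data[: int(np.ceil(60 * FS))].mean(axis=0)
    brute = -np.log10(data / ref)   # direct formula, elementwise
    np.testing.assert_allclose(od.od, brute, atol=1e-9)


def test_nonpositive_intensity_names_location(montage):
    rec = _flat_recording(montage)
    rec.intensities[10, 3, 2] = -1e-6
    with pytest.raises(ValueError, match="channel 3"):
        intensity_to_od(rec, (0.0, 60.0))


def test_reference_window_must_lie_inside_recording(montage):
    rec = _flat_recording(montage)
    with pytest.raises(ValueError, match="window"):
        intensity_to_od(rec, (0.0, 1e4))


# ---------------------------------------------------------------------------
# MBLL inversion


def test_zero_od_maps_to_zero_concentration(montage):
    params = MbllParams()
    od = OpticalDensity(np.zeros((100, 24, 4)), FS, np.full((24, 4), 0.1), montage)
    hemo = od_to_hemoglobin(od, params)
    assert np.allclose(hemo.o2hb, 0) and np.allclose(hemo.hhb, 0)
    assert hemo.tag == "NR"


def test_paper_scale_amplitudes_round_trip(montage):
    params = MbllParams()
    o2 = np.full((10, 24), 0.26)
    hh = np.full((10, 24), -0.12)
    od = forward_mbll(o2, hh, montage, params)
    hemo = od_to_hemoglobin(
        OpticalDensity(od, FS, np.full((24, 4), 0.1), montage), params
    )
    np.testing.assert_allclose(hemo.o2hb, 0.26, atol=1e-9)
    np.testing.assert_allclose(hemo.hhb, -0.12, atol=1e-9)


def test_random_round_trip_against_dense_lstsq(montage):
    rng = np.random.default_rng(1)
    params = MbllParams()
    o2 = rng.normal(0, 1, (200, 24))
    hh = rng.normal(0, 1, (200, 24))
    od = forward_mbll(o2, hh, montage, params)
    hemo = od_to_hemoglobin(
        OpticalDensity(od, FS, np.full((24, 4), 0.1), montage), params
    )
    assert np.max(np.abs(hemo.o2hb - o2)) < 1e-8
    assert np.max(np.abs(hemo.hhb - hh)) < 1e-8
    # independent oracle: dense per-sample least squares on one channel
    A = params.design(3.0)
    sol = np.linalg.lstsq(A, od[0, 0, :], rcond=None)[0]
    assert sol[0] == pytest.approx(hemo.o2hb[0, 0], abs=1e-10)


def test_rank_deficient_extinction_rejected():
    bad = np.array([[1.0, 2.0]] * 4)
    with pytest.raises(ValueError, match="rank"):
        MbllParams(extinction=bad)


# ---------------------------------------------------------------------------
# band-pass


def _tone_series(montage, freq, n_s=1200.0, amp=1.0):
    t = np.arange(0, n_s, 1 / FS)
    x = amp * np.sin(2 * np.pi * freq * t)
    arr = np.tile(x[:, None], (1, 24))
    return HemoSeries(arr, arr, FS, montage), t


def _fft_amplitude(x, freq):
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(x.size, 1 / FS)
    return np.abs(spec[np.argmin(np.abs(f - freq))]) * 2 / x.size


def test_stopband_tone_attenuated_40db(montage):
    series, _ = _tone_series(montage, 1.0)
    out = bandpass_fir(series)
    ratio = _fft_amplitude(out.o2hb[:, 0], 1.0) / _fft_amplitude(series.o2hb[:, 0], 1.0)
    assert 20 * np.log10(ratio) < -40


def test_passband_tone_preserved_without_phase_shift(montage):
    series, t = _tone_series(montage, 0.1)
    out = bandpass_fir(series)
    mid = slice(2000, 8000)   # away from edge transients
    ratio = _fft_amplitude(out.o2hb[mid, 0], 0.1) / _fft_amplitude(series.o2hb[mid, 0], 0.1)
    assert abs(20 * np.log10(ratio)) < 1.0
    # zero-phase: cross-correlation peak at zero lag
    a, b = series.o2hb[mid, 0], out.o2hb[mid, 0]
    lags = np.arange(-20, 21)
    xc = [np.dot(a[20:-20], b[20 + k:len(b) - 20 + k]) for k in lags]
    lag = lags[int(np.argmax(xc))]
    assert abs(lag / FS * 0.1 * 360) < 1.0  # degrees of a 0.1 Hz cycle


def test_dc_offset_removed(montage):
    arr = np.full((6000, 24), 5.0)
    series = HemoSeries(arr, arr, FS, montage)
    out = bandpass_fir(series)
    assert abs(out.o2hb[:, 0].mean()) < 1e-3 * 5.0


def test_order_too_long_raises(montage):
    arr = np.zeros((1500, 24))
    with pytest.raises(ValueError, match="order"):
        bandpass_fir(HemoSeries(arr, arr, FS, montage), order=1000)


def test_pipeline_is_linear_in_input(montage):
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, (4000, 24))
    s1 = HemoSeries(x, x, FS, montage)
    s2 = HemoSeries(3.5 * x, 3.5 * x, FS, montage)
    np.testing.assert_allclose(
        bandpass_fir(s2).o2hb, 3.5 * bandpass_fir(s1).o2hb, atol=1e-9
    )


# ---------------------------------------------------------------------------
# motion correction


def test_artifact_free_sinusoid_unchanged():
    t = np.arange(0, 300, 1 / FS)
    x = 0.5 * np.sin(2 * np.pi * 0.1 * t)
    corrected, mask = remove_motion_spline(x, FS)
    assert not mask.any()
    np.testing.assert_array_equal(corrected, x)


def test_constant_signal_unchanged():
    x = np.full(2000, 1.23)
    corrected, mask = remove_motion_spline(x, FS)
    assert not mask.any()
    np.testing.assert_array_equal(corrected, x)


def test_step_artifact_suppressed():
    rng = np.random.default_rng(0)
    t = np.arange(0, 300, 1 / FS)
    clean = 0.5 * np.sin(2 * np.pi * 0.1 * t) + rng.normal(0, 0.05, t.size)
    step = 10 * clean.std()
    art = clean.copy()
    art[1300:] += step
    corrected, mask = remove_motion_spline(art, FS)
    assert mask.any()
    assert np.abs(np.diff(corrected)).max() < 0.1 * step


def test_spike_artifact_suppressed():
    rng = np.random.default_rng(1)
    clean = rng.normal(0, 0.05, 2700)
    art = clean.copy()
    art[1000:1010] += 2.0
    corrected, mask = remove_motion_spline(art, FS)
    assert mask[1000:1010].all()
    assert np.abs(corrected[1000:1010]).max() < 0.5


def test_too_short_series_rejected():
    with pytest.raises(ValueError, match="window"):
        remove_motion_spline(np.zeros(5), FS, window_s=1.0)
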