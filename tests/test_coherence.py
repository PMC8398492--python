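"""Morlet CWT, smoothing operator, wavelet coherence, scalogram rendering."""

import numpy as np
import pytest

from boldwct import (
    CoherenceConfig,
    CohortSpec,
    cwt_morlet,
    generate_cohort,
    images_per_class,
    morlet_fourier_factor,
    pairwise_scalograms,
    render_scalogram,
    scalogram_count,
    smooth_cross_spectrum,
    unique_pair_count,
    wavelet_coherence,
)
from boldwct.coherence import CoherenceError, CoherenceMap, CwtResult, _smooth

TR = 2.0


# -------------------------------------------------------------------- CWT

def test_zero_signal_zero_coefficients():
    w = cwt_morlet(np.zeros(145), TR)
    assert np.all(w.coefficients == 0)


def test_cwt_linearity():
    x = np.random.default_rng(0).normal(size=145)
    w1 = cwt_morlet(x, TR)
    w2 = cwt_morlet(2 * x, TR)
    np.testing.assert_allclose(w2.coefficients, 2 * w1.coefficients, atol=1e-10)


def test_sinusoid_peak_scale_matches_period():
    """|CWT| of a 40 s sinusoid peaks (mid-series) at the scale whose Fourier
    period is ~40 s; checked on a dense grid against the analytic mapping."""
    t = np.arange(145) * TR
    x = np.sin(2 * np.pi * t / 40.0)
    w = cwt_morlet(x, TR, CoherenceConfig(voices_per_octave=32))
    mid = np.abs(w.coefficients[:, 55:90]).mean(axis=1)
    peak_period = w.periods[mid.argmax()]
    assert abs(peak_period - 40.0) / 40.0 < 0.05


def test_cwt_agrees_with_pywavelets_oracle():
    """Independent implementation check: PyWavelets' complex-Morlet CWT finds
    the same dominant period for a noisy 40 s oscillation."""
    pywt = pytest.importorskip("pywt")
    t = np.arange(145) * TR
    rng = np.random.default_rng(3)
    x = np.sin(2 * np.pi * t / 40.0) + 0.2 * rng.normal(size=145)

    mine = cwt_morlet(x, TR, CoherenceConfig(voices_per_octave=32))
    e_mine = np.abs(mine.coefficients[:, 55:90]).mean(axis=1)
    period_mine = mine.periods[e_mine.argmax()]

    center_hz = 6.0 / (2 * np.pi)
    scales = np.geomspace(2, 40, 150)
    coefs, freqs = pywt.cwt(x, scales, f"cmor1.0-{center_hz:.6f}", sampling_period=TR)
    e_ref = np.abs(coefs[:, 55:90]).mean(axis=1)
    period_ref = 1.0 / freqs[e_ref.argmax()]
    assert abs(period_mine - period_ref) / period_ref < 0.07


def test_period_scale_ratio_constant_and_near_1_03():
    w = cwt_morlet(np.random.default_rng(1).normal(size=145), TR)
    ratios = w.periods / w.scales
    np.testing.assert_allclose(ratios, ratios[0], rtol=1e-12)
    assert round(ratios[0], 2) == 1.03
    assert ratios[0] == pytest.approx(morlet_fourier_factor(6.0))


def test_cwt_input_validation():
    with pytest.raises(CoherenceError):
        cwt_morlet(np.ones(8), TR)
    with pytest.raises(CoherenceError, match="period"):
        cwt_morlet(np.ones(32), TR, CoherenceConfig(period_range_seconds=(1.0, 20.0)))


def test_coi_shape_and_edges():
    w = cwt_morlet(np.random.default_rng(2).normal(size=100), TR)
    assert w.coi.shape == (100,)
    assert w.coi[0] == 0 and w.coi[50] == w.coi.max()


# -------------------------------------------------------------- smoothing

def _dummy_cwt(matrix):
    n_scales, n = matrix.shape
    periods = 4.0 * 2 ** (np.arange(n_scales) / 12)
    scales = periods / morlet_fourier_factor()
    return CwtResult(
        coefficients=matrix.astype(complex),
        scales=scales,
        periods=periods,
        times=np.arange(n) * TR,
        coi=np.zeros(n),
        tr_seconds=TR,
        omega0=6.0,
    )


def test_smoothing_preserves_constant():
    ones = _dummy_cwt(np.ones((20, 64)))
    out = smooth_cross_spectrum(ones, ones, CoherenceConfig())
    np.testing.assert_allclose(out, np.ones((20, 64)), atol=1e-9)


def test_smoothing_commutes_with_complex_scaling():
    rng = np.random.default_rng(4)
    m = rng.normal(size=(20, 64))
    a, b = _dummy_cwt(np.ones((20, 64))), _dummy_cwt(m)
    c = 2.0 - 3.0j
    s1 = smooth_cross_spectrum(a, _dummy_cwt(m * 0 + m), CoherenceConfig())
    # scale y by c: conj(x) * (c y) = c (conj(x) y)
    cb = _dummy_cwt(m)
    cb.coefficients = cb.coefficients * c
    s2 = smooth_cross_spectrum(a, cb, CoherenceConfig())
    np.testing.assert_allclose(s2, c * s1, atol=1e-9)


def test_smoothing_impulse_mass_preserved():
    impulse = np.zeros((30, 128))
    impulse[15, 64] = 1.0
    cfg = CoherenceConfig()
    out = _smooth(impulse, _dummy_cwt(impulse).scales, TR, cfg)
    assert out.sum() == pytest.approx(1.0, abs=1e-6)
    assert out[15, 64] == out.max()


def test_smoothing_grid_mismatch_errors():
    a = _dummy_cwt(np.ones((20, 64)))
    b = _dummy_cwt(np.ones((21, 64))[:20])
    b.scales = b.scales * 1.5
    with pytest.raises(CoherenceError, match="grid"):
        smooth_cross_spectrum(a, b, CoherenceConfig())


# -------------------------------------------------------------- coherence

def test_self_coherence_is_one():
    x = np.random.default_rng(0).normal(size=145)
    m = wavelet_coherence(x, x, TR)
    np.testing.assert_allclose(m.values, 1.0, atol=1e-6)


def test_coherence_bounded_and_symmetric(binary_signals):
    x, y = binary_signals
    mxy = wavelet_coherence(x, y, TR)
    myx = wavelet_coherence(y, x, TR)
    assert mxy.values.min() >= 0.0 and mxy.values.max() <= 1.0
    np.testing.assert_allclose(mxy.values, myx.values, atol=1e-9)


def test_unsmoothed_coherence_degenerates_to_one():
    rng = np.random.default_rng(9)
    cfg = CoherenceConfig(smoothing_enabled=False)
    m = wavelet_coherence(rng.normal(size=145), rng.normal(size=145), TR, cfg)
    np.testing.assert_allclose(m.values, 1.0, atol=1e-9)


def test_constant_signal_rejected():
    with pytest.raises(CoherenceError, match="constant"):
        wavelet_coherence(np.ones(145), np.random.default_rng(0).normal(size=145), TR)


def test_shared_oscillation_raises_band_coherence():
    """Signals sharing a 40 s component: mean coherence inside the 30-55 s
    band exceeds the outside mean in 20/20 seeded replicates."""
    t = np.arange(145) * TR
    for seed in range(20):
        rng = np.random.default_rng(seed)
        phase = rng.uniform(0, 2 * np.pi)
        x = np.sin(2 * np.pi * t / 40 + phase) + 0.5 * rng.normal(size=145)
        y = np.sin(2 * np.pi * t / 40 + phase + 1.0) + 0.5 * rng.normal(size=145)
        m = wavelet_coherence(x, y, TR)
        band = (m.periods >= 30) & (m.periods <= 55)
        assert m.values[band].mean() > m.values[~band].mean()


def test_time_shift_covariance_in_interior():
    rng = np.random.default_rng(1)
    x, y = rng.normal(size=145), rng.normal(size=145)
    k = 5
    m0 = wavelet_coherence(x, y, TR)
    m1 = wavelet_coherence(np.roll(x, k), np.roll(y, k), TR)
    rows = m0.periods <= 12.0
    cols = np.arange(45, 100)
    np.testing.assert_allclose(
        m1.values[np.ix_(rows, cols + k)], m0.values[np.ix_(rows, cols)], atol=0.05
    )


def test_coi_mask_marks_long_periods_at_edges(binary_signals):
    x, y = binary_signals
    m = wavelet_coherence(x, y, TR)
    assert m.coi_mask[:, 0].all()  # every period unreliable at the first sample
    assert not m.coi_mask[0, len(m.times) // 2]  # shortest period fine mid-series


# -------------------------------------------------------------- rendering

def _toy_map(values):
    n_scales, n = values.shape
    periods = 4.0 * 2 ** (np.arange(n_scales) / 12)
    return CoherenceMap(values=values, periods=periods,
                        times=np.arange(n) * TR, coi=np.zeros(n))


def test_render_shape_and_dtype():
    img = render_scalogram(_toy_map(np.random.default_rng(0).uniform(size=(30, 64))))
    assert img.pixels.shape == (224, 224, 3)
    assert img.pixels.dtype == np.uint8


def test_render_constant_maps_are_uniform_extremes():
    import matplotlib

    low = render_scalogram(_toy_map(np.zeros((20, 64)))).pixels
    high = render_scalogram(_toy_map(np.ones((20, 64)))).pixels
    palette = matplotlib.colormaps["viridis"]
    assert (low == low[0, 0]).all() and (high == high[0, 0]).all()
    np.testing.assert_array_equal(
        low[0, 0], (np.array(palette(0.0)[:3]) * 255 + 0.5).astype(np.uint8)
    )
    np.testing.assert_array_equal(
        high[0, 0], (np.array(palette(1.0)[:3]) * 255 + 0.5).astype(np.uint8)
    )


def test_render_byte_deterministic(binary_signals):
    x, y = binary_signals
    m = wavelet_coherence(x, y, TR)
    a = render_scalogram(m).pixels
    b = render_scalogram(m).pixels
    assert a.tobytes() == b.tobytes()


def test_render_custom_size():
    cfg = CoherenceConfig(image_size=(32, 48))
    img = render_scalogram(_toy_map(np.random.default_rng(1).uniform(size=(20, 64))), cfg)
    assert img.pixels.shape == (32, 48, 3)


# ---------------------------------------------------------- pairwise sets

def test_one_seed_node_yields_n_minus_one_images():
    spec = CohortSpec(n_per_group=1, groups=("ASD",), n_nodes=116,
                      n_timepoints=145, rng_seed=0,
                      power_effects={"ASD": 1.0}, coupling_effects={"ASD": 0.5})
    rec = generate_cohort(spec).recordings[0]
    cfg = CoherenceConfig(image_size=(32, 32))
    images = pairwise_scalograms(rec, [5], cfg)
    assert len(images) == 115
    assert all(img.partner_node != 5 for img in images)
    assert {img.group for img in images} == {"ASD"}


def test_seed_node_out_of_range(small_cohort):
    with pytest.raises(CoherenceError, match="out of range"):
        pairwise_scalograms(small_cohort.recordings[0], [99])


def test_image_count_bookkeeping():
    assert scalogram_count(116, 1) == 115
    assert unique_pair_count(116) == 6670
    assert images_per_class(36, 116, 1) == 4140
    assert images_per_class(36, 116, 2) == 8280
    assert images_per_class(36, 116, 3) == 12420
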