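"""Oracle tests for the 17-feature battery.

Each nontrivial feature is checked against an independent brute-force
implementation on many small random instances, plus closed-form cases.
"""

import math

import numpy as np
import pytest

from eggsense.features import (
    FeatureConfig,
    Spectrum,
    autocorr_zero_crossing,
    categorize_sampent,
    crest_factor,
    dominant_frequency,
    EggFeatureExtractor,
    estimate_psd,
    extract_features,
    magnitude_df,
    median_frequency,
    poincare,
    rms,
    sampen_cap,
    sample_entropy,
    sample_entropy_psd,
    sdv,
    spectral_entropy,
)
from eggsense.io import FEATURE_COLUMNS

FS = 2.0


from oracles import autocorr_brute, sampen_brute, sampen_counts_brute


def _spec(psd):
    """Spectrum whose bins exactly span the 1-10 cpm analysis band."""
    psd = np.asarray(psd, float)
    freqs = np.linspace(1.0, 10.0, len(psd))
    return Spectrum(freqs_cpm=freqs, psd=psd, band_cpm=(1.0, 10.0))


# ------------------------------------------------------------------- PSD

def test_psd_argmax_at_planted_frequency():
    t = np.arange(840) / FS
    spec = estimate_psd(np.sin(2 * np.pi * 3 / 60 * t), FS)
    assert dominant_frequency(spec) == pytest.approx(3.0, abs=spec.resolution_cpm)


def test_psd_parseval(rng):
    """Total estimated power is calibrated against the signal variance.

    The windowed periodogram of a single realisation fluctuates by a few
    percent, so single inputs are held loosely and the ensemble ratio
    tightly.
    """
    ratios = []
    for _ in range(100):
        x = rng.normal(size=512) * rng.uniform(1, 100)
        spec = estimate_psd(x, FS)
        df_hz = (spec.freqs_cpm[1] - spec.freqs_cpm[0]) / 60.0
        ratio = np.sum(spec.psd) * df_hz / np.var(x)
        assert ratio == pytest.approx(1.0, rel=0.3)
        ratios.append(ratio)
    assert np.mean(ratios) == pytest.approx(1.0, rel=0.05)


def test_psd_white_noise_flat_in_band():
    rng = np.random.default_rng(3)
    acc = None
    n_rel = 500
    for _ in range(n_rel):
        spec = estimate_psd(rng.standard_normal(840), FS)
        acc = spec.psd if acc is None else acc + spec.psd
    spec = Spectrum(spec.freqs_cpm, acc / n_rel)
    inband = spec.inband_psd
    assert np.max(np.abs(inband / inband.mean() - 1)) < 0.2


def test_psd_too_short_rejected():
    with pytest.raises(ValueError):
        estimate_psd(np.zeros(32), FS)


def test_welch_option_runs():
    rng = np.random.default_rng(0)
    spec = estimate_psd(rng.normal(size=840), FS, FeatureConfig(psd_method="welch"))
    assert spec.psd.size > 0


# ------------------------------------------------------------- amplitude

def test_rms_cases():
    t = np.arange(840) / FS
    assert rms(100 * np.sin(2 * np.pi * 3 / 60 * t)) == pytest.approx(100 / np.sqrt(2), abs=0.1)
    assert rms(np.zeros(10)) == 0.0
    assert rms(np.full(10, -4.2)) == pytest.approx(4.2)
    with pytest.raises(ValueError):
        rms(np.array([]))


# ------------------------------------------------------ spectral scalars

def test_median_frequency_conventions():
    one_hot = np.zeros(19)
    one_hot[4] = 5.0  # bin at 3 cpm with f0=1, df=0.5
    assert median_frequency(_spec(one_hot)) == pytest.approx(3.0)
    flat = _spec(np.ones(19))  # 1..10 cpm
    assert abs(median_frequency(flat) - 5.5) <= 0.5
    two = np.zeros(19)
    two[2] = two[14] = 1.0  # 2 and 8 cpm equal bins
    assert median_frequency(_spec(two)) == pytest.approx(2.0)


def test_dominant_frequency_tie_and_magnitude_scaling():
    two = np.zeros(19)
    two[4] = two[10] = 3.0  # equal peaks at 3 and 6 cpm
    assert dominant_frequency(_spec(two)) == pytest.approx(3.0)
    t = np.arange(840) / FS
    m1 = magnitude_df(estimate_psd(np.sin(2 * np.pi * 3 / 60 * t), FS))
    m2 = magnitude_df(estimate_psd(2 * np.sin(2 * np.pi * 3 / 60 * t), FS))
    assert m2 / m1 == pytest.approx(4.0, rel=1e-6)


def test_crest_factor_cases(rng):
    assert crest_factor(_spec(np.ones(25))) == pytest.approx(1.0)
    n = 16
    one_hot = np.zeros(n)
    one_hot[3] = 7.0
    assert crest_factor(_spec(one_hot)) == pytest.approx(math.sqrt(n))
    split = np.zeros(n)
    split[3] = split[8] = 7.0
    assert crest_factor(_spec(split)) < crest_factor(_spec(one_hot))
    # brute-force oracle on random spectra
    for _ in range(200):
        p = rng.uniform(0.01, 1.0, size=rng.integers(4, 32))
        assert crest_factor(_spec(p)) == pytest.approx(
            p.max() / np.sqrt(np.mean(p**2)), rel=1e-12
        )


def test_sdv_cases(rng):
    assert sdv(_spec(np.ones(20))) == pytest.approx(100.0)
    n = 10
    one_hot = np.zeros(n)
    one_hot[0] = 1.0
    assert sdv(_spec(one_hot)) == pytest.approx(100.0 / n)
    tri = np.concatenate([np.arange(1, 11), np.arange(10, 0, -1)]).astype(float)
    expected = 100.0 * np.sum(tri > 0.25 * tri.max()) / tri.size
    assert sdv(_spec(tri)) == pytest.approx(expected)
    for _ in range(200):
        p = rng.uniform(0, 1, size=rng.integers(4, 32))
        p[rng.integers(p.size)] = 1.0
        assert sdv(_spec(p)) == pytest.approx(
            100.0 * np.count_nonzero(p > 0.25 * p.max()) / p.size
        )


# -------------------------------------------------------- sample entropy

def test_sample_entropy_constant_series_is_zero():
    assert sample_entropy(np.ones(30), 2, 0.5) == 0.0


def test_sample_entropy_worked_example():
    x = np.array([1, 2, 3, 2, 1, 2, 3, 2, 1, 2], dtype=float)
    assert sample_entropy(x, 2, 0.5) == pytest.approx(sampen_brute(x, 2, 0.5), rel=1e-12)


def test_sample_entropy_oracle_equivalence(rng):
    """Matches exhaustive pair enumeration on 200 random small instances."""
    for _ in range(200):
        n = int(rng.integers(10, 50))
        x = rng.normal(size=n)
        m = int(rng.integers(1, 5))
        r = float(rng.uniform(0.05, 1.5))
        assert sample_entropy(x, m, r) == pytest.approx(sampen_brute(x, m, r), rel=1e-12)


def test_sample_entropy_match_counts_monotone_in_r(rng):
    for _ in range(20):
        x = rng.normal(size=30)
        prev_a = prev_b = -1
        for r in np.linspace(0.05, 3.0, 10):
            a, b = sampen_counts_brute(x, 2, r)
            assert a >= prev_a and b >= prev_b
            prev_a, prev_b = a, b
        assert sample_entropy(x, 2, 10.0) == pytest.approx(0.0, abs=1e-12)


def test_sample_entropy_cap_and_errors():
    x = np.array([0, 100, 1, 101, 2, 102, 3, 103, 4, 104], float)
    n, m = len(x), 2
    assert sample_entropy(x, m, 1e-6) == pytest.approx(sampen_cap(n, m))
    with pytest.raises(ValueError):
        sample_entropy(np.ones(4), 2, 0.5)
    with pytest.raises(ValueError):
        sample_entropy(np.ones(30), 2, 0.0)


def test_sample_entropy_psd_cases(rng):
    assert sample_entropy_psd(_spec(np.ones(20)), 2, 0.5) == 0.0
    p = rng.uniform(0, 1, size=20)
    spec = _spec(p)
    r = 0.15 * np.std(p)
    assert sample_entropy_psd(spec, 2, r) == pytest.approx(
        sampen_brute(spec.inband_psd, 2, r), rel=1e-12
    )
    # scale invariance when the tolerance reference scales along
    assert sample_entropy_psd(_spec(5.0 * p), 2, 5.0 * r) == pytest.approx(
        sample_entropy_psd(spec, 2, r), rel=1e-12
    )


# ------------------------------------------------------ spectral entropy

def test_spectral_entropy_bounds_and_closed_form():
    n = 24
    one_hot = np.zeros(n)
    one_hot[5] = 3.0
    assert spectral_entropy(_spec(one_hot)) == pytest.approx(0.0)
    assert spectral_entropy(_spec(np.ones(n))) == pytest.approx(1.0)
    assert spectral_entropy(_spec(np.ones(n)), normalize=False) == pytest.approx(math.log(n))
    two = np.zeros(n)
    two[1] = two[7] = 2.0
    assert spectral_entropy(_spec(two)) == pytest.approx(math.log(2) / math.log(n))


# --------------------------------------------------------- autocorr, SD

def test_autocorr_sinusoid_quarter_period():
    t = np.arange(840) / FS
    x = np.sin(2 * np.pi * 3 / 60 * t)  # period 20 s
    assert autocorr_zero_crossing(x, FS) == pytest.approx(5.0, abs=0.5)


def test_autocorr_white_noise_short():
    meds = [autocorr_zero_crossing(np.random.default_rng(s).normal(size=840), FS)
            for s in range(50)]
    assert np.median(meds) <= 1.0


def test_autocorr_oracle_equivalence(rng):
    for _ in range(200):
        x = rng.normal(size=30)
        assert autocorr_zero_crossing(x, FS) == pytest.approx(autocorr_brute(x, FS))
    with pytest.raises(ValueError):
        autocorr_zero_crossing(np.ones(30), FS)


def test_poincare_identities(rng):
    sd1, _, _ = poincare(np.arange(50, dtype=float))
    assert sd1 == pytest.approx(0.0, abs=1e-9)
    for _ in range(20):
        x = rng.normal(size=300) * rng.uniform(1, 50)
        sd1, sd2, sdegg = poincare(x)
        assert sdegg == pytest.approx(np.std(x, ddof=1), rel=0.01)
        assert sd1**2 + sd2**2 == pytest.approx(2 * np.var(x, ddof=1), rel=0.01)
    x = rng.normal(0, 3.0, size=20_000)
    sd1, sd2, _ = poincare(x)
    assert sd1 == pytest.approx(3.0, rel=0.05)
    assert sd2 == pytest.approx(3.0, rel=0.05)
    with pytest.raises(ValueError):
        poincare(np.ones(2))


# ------------------------------------------------------------- assembly

def test_extract_features_complete_and_deterministic(rng):
    x = rng.normal(size=840)
    a = extract_features(x)
    b = extract_features(x)
    assert list(a) == FEATURE_COLUMNS and a == b


def test_amplitude_scaling_covariance(rng):
    x = rng.normal(size=840)
    base = extract_features(x)
    scaled = extract_features(5.0 * x)
    for name in ("RMS", "SD1", "SD2", "SDEGG"):
        assert scaled[name] == pytest.approx(5.0 * base[name], rel=1e-9)
    for name in ("DF", "median", "SpectEnt", "SDV", "CS", "Autocorr",
                 "SampEntT_m2", "SampEntT_m3", "SampEntT_m4",
                 "SampEntP_m2", "SampEntP_m3", "SampEntP_m4"):
        assert scaled[name] == pytest.approx(base[name], rel=1e-9)


def test_extractor_transformer_reference_semantics(rng):
    X = rng.normal(size=(5, 840))
    ext = EggFeatureExtractor().fit(X)
    own = ext.transform(X)
    plain = np.array([[extract_features(row)[c] for c in FEATURE_COLUMNS] for row in X])
    np.testing.assert_allclose(own, plain, rtol=1e-12)
    with pytest.raises(ValueError):
        ext.transform(X[:3])
    assert list(ext.get_feature_names_out()) == FEATURE_COLUMNS


@pytest.mark.parametrize("value,expected", [(9.99, "low"), (10.01, "high")])
def test_categorize_sampent(value, expected):
    assert categorize_sampent(value) == expected


def test_cap_value_is_high_category():
    assert categorize_sampent(sampen_cap(840, 2)) == "high"
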