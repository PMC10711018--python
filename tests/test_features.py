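"""Windowing, the four feature families and the 176-feature assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spirodesat.dtw import dtw_distance
from spirodesat.errors import FeatureUndefinedError
from spirodesat.features import (WindowingConfig, coherence_mean,
                                 detect_peaks, extract_feature_vector,
                                 make_windows, variability_features,
                                 window_starts)
from spirodesat.registry import (FAMILY_SIZES, FEATURE_NAMES, REGISTRY,
                                 TABLE_ALIASES, registry_json)
from spirodesat.segmentation import Interval

from oracles import dtw_oracle, kendall_tau_oracle

FS = 15.0


# ---------------------------------------------------------------- windowing

def test_window_stride_follows_printed_formula():
    """L = 42000 gives stride (42000-2000)/20 = 2000: starts 0..38000."""
    starts = window_starts(42_000)
    assert np.array_equal(starts, np.arange(0, 40_000, 2000))


def test_degenerate_segment_gives_twenty_identical_windows():
    starts = window_starts(2000)
    assert np.array_equal(starts, np.zeros(20, dtype=int))


def test_long_segment_windows_are_spread_to_the_end():
    L = 500_000
    starts = window_starts(L)
    assert starts[0] == 0
    assert starts[-1] == L - 2000
    assert len(starts) == 20
    assert np.all(np.diff(starts) > 0)


def test_window_duration_is_about_133_seconds():
    assert WindowingConfig().window_samples / FS == pytest.approx(133.3,
                                                                  abs=0.05)


def test_make_windows_shape_and_bounds():
    series = np.arange(50_000, dtype=float)
    seg = Interval(1000, 31_000)
    wins = make_windows(seg, series)
    assert wins.shape == (20, 2000)
    assert wins.min() >= seg.start
    assert wins.max() < seg.end


def test_too_short_segment_raises():
    with pytest.raises(FeatureUndefinedError):
        window_starts(1500)


# ------------------------------------------------------------------- peaks

def test_sinusoid_peak_count_and_intervals():
    """A 0.25 Hz cosine over 2000 samples at 15 Hz has 33 interior maxima
    spaced 60 samples apart (brute-force verified count = floor(T * f))."""
    t = np.arange(2000) / FS
    window = np.cos(2 * np.pi * 0.25 * t)
    idx, values = detect_peaks(window, FS)
    assert len(idx) == 33
    assert np.all(np.diff(idx) == 60)
    assert np.all(values > 0.99)


def test_monotone_ramp_has_no_peaks():
    idx, _ = detect_peaks(np.linspace(0, 1, 2000), FS)
    assert len(idx) == 0


def test_breath_train_peak_interval_matches_rate(noise_free_profile):
    from spirodesat.simulate import generate_breath_train

    _, _, vol = generate_breath_train(noise_free_profile, "supine", 300.0,
                                      np.random.default_rng(0))
    idx, _ = detect_peaks(vol[:2000], FS)
    assert np.allclose(np.diff(idx), 5 * FS)  # 12 breaths/min -> 5 s


# -------------------------------------------------------------- variability

def test_periodic_peaks_have_zero_variability():
    values = np.full(10, 7.0)
    intervals = np.full(9, 75.0)
    f = variability_features(values, intervals, FS)
    assert f["piv_sdnn"] == 0.0
    assert f["piv_rmssd"] == 0.0
    assert f["piv_pnnxx"] == 0.0
    assert f["pvv_sd"] == 0.0


def test_rmssd_hand_computation():
    """Intervals [4, 6, 4, 6] s: successive diffs +-2 s, RMS = 2 s."""
    intervals_s = np.array([4.0, 6.0, 4.0, 6.0])
    f = variability_features(np.ones(5), intervals_s * FS, FS)
    assert f["piv_rmssd"] == pytest.approx(2.0 * FS)


def test_pvv_sd_equals_sample_standard_deviation():
    rng = np.random.default_rng(3)
    values = rng.normal(10, 2, 30)
    f = variability_features(values, np.full(29, 70.0), FS)
    assert f["pvv_sd"] == pytest.approx(values.std(ddof=1), rel=1e-12)


def test_variability_requires_three_peaks():
    with pytest.raises(FeatureUndefinedError):
        variability_features(np.array([1.0, 2.0]), np.array([5.0]), FS)


# ------------------------------------------------------------- correlations

def test_identity_pair_correlations():
    rng = np.random.default_rng(1)
    w = rng.normal(size=2000)
    from spirodesat.features import _pair_metrics

    m = _pair_metrics(w, w, FS)
    assert m["pcc"] == pytest.approx(1.0)
    assert m["scc"] == pytest.approx(1.0)
    assert m["kc"] == pytest.approx(1.0)
    assert m["coherence"] == pytest.approx(1.0, abs=1e-10)
    assert m["dtw"] == 0.0


def test_negated_pair_pcc():
    rng = np.random.default_rng(2)
    w = rng.normal(size=500)
    from spirodesat.features import _corr_triplet

    pcc, _, _ = _corr_triplet(w, -w)
    assert pcc == pytest.approx(-1.0)


def test_zero_variance_window_maps_rank_correlations_to_zero():
    from spirodesat.features import _corr_triplet

    assert _corr_triplet(np.full(100, 2.0), np.arange(100.0)) == (0, 0, 0)


def test_coherence_affine_invariance_and_noise_floor():
    rng = np.random.default_rng(4)
    a = rng.normal(size=2000)
    assert coherence_mean(a, 2 * a + 1, FS) == pytest.approx(1.0, abs=1e-10)
    b = rng.normal(size=2000)
    assert coherence_mean(a, b, FS) < 0.3


def test_coherence_rejects_short_input():
    with pytest.raises(ValueError):
        coherence_mean(np.ones(100), np.ones(100), FS)


def test_kendall_matches_bruteforce_oracle():
    from scipy.stats import kendalltau

    rng = np.random.default_rng(5)
    for n in (10, 57, 200):
        x, y = rng.normal(size=n), rng.normal(size=n)
        assert kendalltau(x, y).statistic == pytest.approx(
            kendall_tau_oracle(x, y), abs=1e-9)


def test_dtw_examples_and_oracle():
    assert dtw_distance(np.zeros(3), np.ones(3)) == pytest.approx(1.0)
    rng = np.random.default_rng(6)
    for na, nb in ((10, 10), (50, 80), (200, 200)):
        a, b = rng.normal(size=na), rng.normal(size=nb)
        assert dtw_distance(a, b) == pytest.approx(dtw_oracle(a, b),
                                                   abs=1e-9)
        assert dtw_distance(a, b) == dtw_distance(b, a)
    assert dtw_distance(np.arange(5.0), np.arange(5.0)) == 0.0


def test_dtw_rejects_empty_series():
    with pytest.raises(ValueError):
        dtw_distance(np.array([]), np.ones(3))


# ---------------------------------------------------------------- assembly

def test_registry_partition_and_aliases():
    assert len(REGISTRY) == 176
    assert FAMILY_SIZES == {"demographics": 4, "signal_property": 44,
                            "correlation": 20, "variability": 108}
    for alias, name in TABLE_ALIASES.items():
        assert name in FEATURE_NAMES, alias
    assert len(registry_json()) > 1000


def test_feature_vector_length_partition_and_bounds(fast_extraction):
    _, _, vector = fast_extraction
    assert len(vector) == 176
    assert list(vector.index) == list(FEATURE_NAMES)
    counts = {}
    for spec in REGISTRY:
        counts[spec.family] = counts.get(spec.family, 0) + 1
    assert counts == FAMILY_SIZES
    # bounds: rank/linear correlations in [-1, 1], coherence in [0, 1],
    # DTW and dispersion features non-negative
    for name in vector.index:
        v = vector[name]
        if name.endswith((".pcc", ".scc", ".kc")):
            assert -1.0 <= v <= 1.0, name
        if name.endswith(".coherence"):
            assert 0.0 <= v <= 1.0, name
        if name.endswith((".dtw", ".std", "_sdnn", "_sd", "_rmssd")):
            assert v >= 0.0, name


def test_noise_free_supine_pip_mean_equals_plateau(noise_free_profile):
    from spirodesat.features import build_window_set, signal_property_features
    from spirodesat.segmentation import segment_record
    from spirodesat.simulate import generate_case

    rec = generate_case(noise_free_profile, np.random.default_rng(7))
    ws = build_window_set(rec, segment_record(rec))
    f = signal_property_features(ws)
    assert f["supine.PIP.mean"] == pytest.approx(
        noise_free_profile.pip_supine_cmH2O)
    assert f["supine.PIP.std"] == pytest.approx(0.0, abs=1e-9)
    assert f["supine.PIP.z_outlier"] == 0.0


def test_extraction_is_deterministic(fast_extraction):
    record, segments, vector = fast_extraction
    again = extract_feature_vector(record, segments)
    assert np.array_equal(vector.to_numpy(), again.to_numpy())


@given(st.floats(min_value=0.1, max_value=50.0),
       st.floats(min_value=-100.0, max_value=100.0))
@settings(max_examples=10, deadline=None, derandomize=True)
def test_scale_invariant_metrics_under_affine_rescaling(scale, offset):
    """Correlation and coherence are unchanged when a channel is rescaled
    affinely; DTW scales with the amplitude."""
    from spirodesat.features import _pair_metrics

    rng = np.random.default_rng(8)
    a = rng.normal(size=600)
    b = np.roll(a, 3) + 0.2 * rng.normal(size=600)
    m0 = _pair_metrics(a, b, FS)
    m1 = _pair_metrics(a * scale + offset, b, FS)
    assert m1["pcc"] == pytest.approx(m0["pcc"], abs=1e-9)
    assert m1["scc"] == pytest.approx(m0["scc"], abs=1e-9)
    assert m1["kc"] == pytest.approx(m0["kc"], abs=1e-9)
    assert m1["coherence"] == pytest.approx(m0["coherence"], abs=1e-9)
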