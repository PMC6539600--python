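"""Unit and property tests for the SDH texture-feature core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tremorsdh import sdh
from tremorsdh.sdh import (
    FEATURE_NAMES,
    HistogramPair,
    contrast,
    features_for_signal,
    homogeneity,
    quantize,
    sum_diff_vectors,
    texture_features,
    window_histograms,
)

from sdh_oracle import oracle_features, oracle_sum_diff


def make_hist(diff_hist: dict, sum_hist: dict | None = None, N: int = 1):
    sum_hist = sum_hist if sum_hist is not None else {0: 1.0}
    return HistogramPair(
        sum_values=np.array(sorted(sum_hist)),
        sum_masses=np.array([sum_hist[j] for j in sorted(sum_hist)]),
        diff_values=np.array(sorted(diff_hist)),
        diff_masses=np.array([diff_hist[k] for k in sorted(diff_hist)]),
        window_size=N,
    )


class TestQuantize:
    def test_exact_linear_map(self):
        q = quantize([0.0, 2.5, 5.0], bin_width=2.5)
        assert q.levels.tolist() == [0, 1, 2]
        assert q.offset == 0.0

    def test_constant_series_all_zero(self):
        assert quantize([3.3] * 5, 0.1).levels.tolist() == [0] * 5

    def test_dequantization_error_bounded(self, rng):
        x = rng.uniform(0, 10, size=100)
        q = quantize(x, bin_width=0.1)
        assert np.max(np.abs(q.dequantize() - x)) <= 0.05 + 1e-12

    @pytest.mark.parametrize(
        "signal,bw,err",
        [([], 0.1, "non-empty"), ([1.0, np.nan], 0.1, "finite"), ([1.0], -1.0, "positive")],
    )
    def test_invalid_inputs(self, signal, bw, err):
        with pytest.raises(ValueError, match=err):
            quantize(signal, bw)


class TestSumDiffVectors:
    def test_enumeration_example(self):
        pair = sum_diff_vectors(np.array([1, 2, 4, 2, 1]), M=1)
        assert pair.sum_vector.tolist() == [3, 6, 6, 3]
        assert pair.diff_vector.tolist() == [1, 2, -2, -1]

    def test_alternating_signal(self):
        pair = sum_diff_vectors(np.array([0, 1, 0, 1, 0, 1]), M=1)
        assert pair.diff_vector.tolist() == [1, -1, 1, -1, 1]

    def test_constant_signal_any_displacement(self):
        for M in (1, 2, 3):
            pair = sum_diff_vectors(np.full(8, 4), M=M)
            assert (pair.diff_vector == 0).all()
            assert (pair.sum_vector == 8).all()
            assert len(pair) == 8 - M

    def test_displacement_out_of_range(self):
        with pytest.raises(ValueError, match="displacement"):
            sum_diff_vectors(np.arange(5), M=5)


class TestWindowHistograms:
    def test_counting_example(self):
        pair = sum_diff_vectors(np.array([1, 2, 4, 2, 1]), M=1)
        (h,) = window_histograms(pair, N=4)
        assert h.diff_hist == {-2: 0.25, -1: 0.25, 1: 0.25, 2: 0.25}
        assert h.sum_masses.sum() == pytest.approx(1.0, abs=1e-12)
        assert h.diff_masses.sum() == pytest.approx(1.0, abs=1e-12)

    def test_full_length_window_is_single(self):
        pair = sum_diff_vectors(np.arange(10), M=1)
        assert len(window_histograms(pair, N=len(pair))) == 1

    def test_window_count_formula(self, rng):
        levels = rng.integers(0, 5, size=452)
        pair = sum_diff_vectors(levels, M=1)  # length 451
        assert len(window_histograms(pair, N=149)) == 303
        assert len(window_histograms(pair, N=149, stride=10)) == (451 - 149) // 10 + 1

    def test_oversized_window_rejected(self):
        pair = sum_diff_vectors(np.arange(10), M=1)
        with pytest.raises(ValueError, match="window size"):
            window_histograms(pair, N=10)


class TestHeadlineFeatures:
    def test_contrast_examples(self):
        assert contrast(make_hist({0: 1.0})) == 0.0
        assert contrast(make_hist({-2: 0.25, -1: 0.25, 1: 0.25, 2: 0.25})) == pytest.approx(2.5)
        assert contrast(make_hist({1: 0.6, -1: 0.4})) == pytest.approx(1.0)

    def test_homogeneity_examples(self):
        assert homogeneity(make_hist({0: 1.0})) == 1.0
        h = make_hist({-2: 0.25, -1: 0.25, 1: 0.25, 2: 0.25})
        assert homogeneity(h, "abs") == pytest.approx(5 / 12)
        assert homogeneity(make_hist({1: 0.6, -1: 0.4}), "abs") == pytest.approx(0.5)

    def test_homogeneity_squared_kernel(self):
        h = make_hist({-2: 0.25, -1: 0.25, 1: 0.25, 2: 0.25})
        assert homogeneity(h, "squared") == pytest.approx(0.5 * (1 / 5 + 1 / 2))

    def test_unknown_kernel(self):
        with pytest.raises(ValueError, match="kernel"):
            homogeneity(make_hist({0: 1.0}), "cubic")


class TestTextureFeatures:
    def test_constant_signal_degenerate_values(self):
        pair = sum_diff_vectors(np.full(10, 7), M=1)
        (h,) = window_histograms(pair, N=9)
        f = texture_features(h)
        assert f.mean == 7.0
        assert f.variance == 0.0
        assert f.energy == 1.0
        assert f.entropy == 0.0
        assert f.contrast == 0.0
        assert f.homogeneity == 1.0
        assert f.cluster_shade == 0.0

    def test_three_point_ramp(self):
        pair = sum_diff_vectors(np.array([1, 2, 3]), M=1)
        (h,) = window_histograms(pair, N=2)
        f = texture_features(h)
        assert h.sum_hist == {3: 0.5, 5: 0.5}
        assert h.diff_hist == {1: 1.0}
        assert f.mean == pytest.approx(2.0)
        assert f.contrast == pytest.approx(1.0)
        assert f.homogeneity == pytest.approx(0.5)

    def test_symmetric_sum_histogram_has_zero_shade(self):
        # V = [0, 2, 0, 2, ...]: sums all equal, trivially symmetric about 2 mu
        pair = sum_diff_vectors(np.array([0, 2] * 5), M=1)
        (h,) = window_histograms(pair, N=len(pair))
        assert texture_features(h).cluster_shade == pytest.approx(0.0, abs=1e-12)


class TestOracleEquivalence:
    """The vectorized pipeline must agree with brute-force multiset evaluation."""

    @pytest.mark.parametrize("kernel", ["abs", "squared"])
    def test_random_signals_match_oracle(self, kernel, rng):
        for trial in range(120):
            n = int(rng.integers(5, 50))
            M = int(rng.integers(1, min(4, n)))
            levels = rng.integers(-6, 7, size=n)
            max_n = n - M
            N = int(rng.integers(1, max_n + 1))
            stride = int(rng.integers(1, 4))
            table = sdh._sliding_features(
                sum_diff_vectors(levels, M), N, stride, kernel
            )
            for w, start in enumerate(range(0, max_n - N + 1, stride)):
                expect = oracle_features(levels, M, start, N, kernel)
                for i, name in enumerate(FEATURE_NAMES):
                    assert table[w, i] == pytest.approx(
                        expect[name], abs=1e-10, rel=1e-10
                    ), f"{name} mismatch (trial {trial}, window {w})"

    def test_histogram_path_matches_oracle(self, rng):
        levels = rng.integers(0, 10, size=40)
        pair = sum_diff_vectors(levels, M=1)
        hists = window_histograms(pair, N=11, stride=3)
        for w, h in enumerate(hists):
            expect = oracle_features(levels, 1, 3 * w, 11)
            got = texture_features(h).as_dict()
            for name in FEATURE_NAMES:
                assert got[name] == pytest.approx(expect[name], abs=1e-10, rel=1e-10)


@given(
    levels=st.lists(st.integers(-20, 20), min_size=3, max_size=40),
    M=st.integers(1, 2),
)
@settings(max_examples=100, derandomize=True, deadline=None)
def test_histogram_normalization_and_moment_identity(levels, M):
    """Masses sum to one and contrast == 2 (variance - correlation), always."""
    if M >= len(levels):
        M = len(levels) - 1
    pair = sum_diff_vectors(np.array(levels), M=M)
    N = max(1, len(pair) // 2)
    for h in window_histograms(pair, N=N):
        assert abs(h.sum_masses.sum() - 1.0) < 1e-12
        assert abs(h.diff_masses.sum() - 1.0) < 1e-12
        f = texture_features(h)
        # variance = (S + C)/2 and correlation = (S - C)/2, so their
        # difference is exactly the contrast C
        assert f.contrast == pytest.approx(f.variance - f.correlation, abs=1e-9)
        assert 0 < f.energy <= 1 + 1e-12
        assert f.entropy >= -1e-12
        assert f.contrast >= 0
        assert 0 < f.homogeneity <= 1 + 1e-12
        assert f.variance >= -1e-12


class TestAnalyticAndInvarianceProperties:
    def test_sinusoid_contrast_closed_form(self):
        # contrast * bin_width^2 -> 2 A^2 sin^2(pi f / fs) for fine quantization
        A, f, fs, bw = 5.0, 5.0, 40.0, 0.01
        x = A * np.sin(2 * np.pi * f * np.arange(4000) / fs)
        pair = sum_diff_vectors(quantize(x, bw), M=1)
        (h,) = window_histograms(pair, N=len(pair))
        predicted = 2 * A**2 * np.sin(np.pi * f / fs) ** 2
        assert contrast(h) * bw**2 == pytest.approx(predicted, rel=0.05)

    def test_shift_invariance_of_difference_features(self, rng):
        # shift by a bin multiple so the quantization grid stays aligned
        x = rng.normal(0, 1, size=300)
        fa = features_for_signal(x, N=100)
        fb = features_for_signal(x + 173 * 0.1, N=100)
        assert np.allclose(fa["contrast"], fb["contrast"], atol=1e-9)
        assert np.allclose(fa["homogeneity"], fb["homogeneity"], atol=1e-9)

    def test_amplitude_scale_monotonicity(self):
        t = np.arange(600) / 40.0
        base = np.sin(2 * np.pi * 5.0 * t)
        f1 = features_for_signal(1.0 * base, N=149, bin_width=0.1)
        f2 = features_for_signal(2.0 * base, N=149, bin_width=0.1)
        assert (f2["contrast"].to_numpy() > f1["contrast"].to_numpy()).all()
        assert (f2["homogeneity"].to_numpy() < f1["homogeneity"].to_numpy()).all()


class TestRecordingPipeline:
    def test_row_count_for_default_window(self, small_recordings):
        table = sdh.features_for_recording(small_recordings[0], N=149)
        assert len(table) == 451  # floor((600 - 1 - 149)/1) + 1

    def test_too_long_window_rejected(self, small_recordings):
        with pytest.raises(ValueError, match="too short"):
            sdh.features_for_recording(small_recordings[0], N=600)

    def test_multichannel_feature_row_width(self, small_recordings):
        table = sdh.features_for_recording(
            small_recordings[0],
            channels=["palm_pos_x", "palm_pos_y", "palm_pos_z"],
            N=599,
        )
        assert len(table) == 1
        assert len([c for c in table.columns if c != "window_index"]) == 27

    def test_feature_table_sidecar(self, small_recordings, tmp_path):
        table = sdh.features_for_recording(small_recordings[0], N=590)
        out = sdh.save_feature_table(table, tmp_path / "f.csv", {"N": 590, "M": 1})
        assert out.exists()
        assert (tmp_path / "f.json").exists()
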