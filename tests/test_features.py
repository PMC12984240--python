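"""Center-symmetric rank-transition feature extraction.

Includes a literal brute-force re-implementation of the seven extraction
steps (explicit Python loops, no shared code) used as the independent
oracle for the vectorized extractor.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from tensorcsbp import extract_feature_matrix, extract_features, transition_matrix
from tensorcsbp.features import (
    FeatureExtractionError,
    build_transformed_signals,
    center_symmetric_differences,
    make_windows,
    rank_transform,
)
from tensorcsbp.io import EEGRecording, SegmentSet


def brute_force_features(sig: np.ndarray) -> np.ndarray:
    """Literal step-by-step extraction: windows, differences, descending
    argsort per window, pair counting, row-major flatten, concatenate."""
    L, nc = sig.shape
    seqs = [[], [], [], []]
    for i in range(L - 7):  # step 1: overlapping 8-sample windows
        win = sig[i : i + 8]
        for k in range(1, 5):  # step 2: D_k = V_k - V_{9-k}
            D = win[k - 1] - win[8 - k]
            # step 3: descending order, ties to smaller channel index
            order = sorted(range(nc), key=lambda c: (-D[c], c))
            seqs[k - 1].extend(c + 1 for c in order)  # step 4: concatenate
    FF = []
    for k in range(4):  # step 5: count adjacent pairs
        tm = [[0] * nc for _ in range(nc)]
        s = seqs[k]
        for a in range(len(s) - 1):
            tm[s[a] - 1][s[a + 1] - 1] += 1
        FF.extend(v for row in tm for v in row)  # steps 6-7: flatten, merge
    return np.array(FF)


class TestWindows:
    def test_single_window_at_boundary(self, rng):
        sig = rng.normal(size=(8, 3))
        w = make_windows(sig)
        assert w.shape == (1, 8, 3)
        np.testing.assert_array_equal(w[0], sig)

    def test_step_one_overlap(self, rng):
        sig = rng.normal(size=(9, 2))
        w = make_windows(sig)
        assert w.shape == (2, 8, 2)
        np.testing.assert_array_equal(w[0], sig[:8])
        np.testing.assert_array_equal(w[1], sig[1:])

    def test_paper_scale_window_count(self):
        assert make_windows(np.zeros((3840, 2))).shape[0] == 3833

    def test_too_short_names_minimum(self):
        with pytest.raises(FeatureExtractionError, match="at least 8"):
            make_windows(np.zeros((7, 2)))


class TestDifferences:
    def test_constant_window_gives_zero(self):
        win = np.ones((8, 3))
        np.testing.assert_array_equal(
            center_symmetric_differences(win), np.zeros((4, 3))
        )

    def test_time_reversal_negates(self, rng):
        win = rng.normal(size=(8, 4))
        d = center_symmetric_differences(win)
        d_rev = center_symmetric_differences(win[::-1])
        np.testing.assert_allclose(d_rev, -d)

    def test_worked_example(self, worked_signal):
        # V3 - V6 = (2,0) - (0,3) = (2,-3); V4 - V5 = (0,2) - (3,0) = (-3,2)
        d = center_symmetric_differences(worked_signal[:8])
        np.testing.assert_array_equal(
            d, [[1, -4], [-4, 1], [2, -3], [-3, 2]]
        )


class TestRankTransform:
    @pytest.mark.parametrize(
        "vec,expected",
        [
            ([1, -4], [1, 2]),
            ([-3, 2], [2, 1]),
            ([0, 0, 0, 0], [1, 2, 3, 4]),  # ties break to smaller channel
            ([5, 5, 7], [3, 1, 2]),
        ],
    )
    def test_descending_with_stable_ties(self, vec, expected):
        np.testing.assert_array_equal(rank_transform(np.array(vec)), expected)

    def test_nan_rejected(self):
        with pytest.raises(FeatureExtractionError, match="NaN"):
            rank_transform(np.array([1.0, np.nan]))


class TestTransformedSignals:
    def test_constant_signal_repeats_identity(self):
        T = build_transformed_signals(np.ones((10, 2)))
        np.testing.assert_array_equal(T, [[1, 2] * 3] * 4)

    def test_worked_example(self, worked_signal):
        T = build_transformed_signals(worked_signal)
        np.testing.assert_array_equal(
            T, [[1, 2, 2, 1], [2, 1, 1, 2], [1, 2, 2, 1], [2, 1, 1, 2]]
        )

    def test_affine_invariance(self, rng):
        sig = rng.normal(size=(25, 4))
        np.testing.assert_array_equal(
            build_transformed_signals(sig),
            build_transformed_signals(3.7 * sig + 100.0),
        )

    @given(
        hnp.arrays(
            float,
            st.tuples(st.integers(8, 20), st.integers(2, 5)),
            elements=st.floats(-100, 100),
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_every_block_is_a_permutation(self, sig):
        L, nc = sig.shape
        T = build_transformed_signals(sig)
        assert T.shape == (4, nc * (L - 7))
        blocks = T.reshape(4, -1, nc)
        expected = np.arange(1, nc + 1)
        assert (np.sort(blocks, axis=2) == expected).all()


class TestTransitionMatrix:
    def test_enumerated_pairs(self):
        np.testing.assert_array_equal(
            transition_matrix(np.array([1, 2, 2, 1]), 2), [[0, 1], [1, 1]]
        )
        np.testing.assert_array_equal(
            transition_matrix(np.array([1, 2, 1, 2, 1, 2]), 2), [[0, 3], [2, 0]]
        )

    def test_length_one_gives_zero_matrix(self):
        np.testing.assert_array_equal(transition_matrix(np.array([2]), 3), np.zeros((3, 3)))

    def test_out_of_range_symbol_names_position(self):
        with pytest.raises(FeatureExtractionError, match="position 2"):
            transition_matrix(np.array([1, 2, 5]), 2)


class TestExtractFeatures:
    @pytest.mark.parametrize("nc,expected", [(32, 4096), (14, 784), (2, 16)])
    def test_feature_length_is_4nc_squared(self, rng, nc, expected):
        assert len(extract_features(rng.normal(size=(20, nc)))) == expected

    def test_worked_example_flattening(self, worked_signal):
        np.testing.assert_array_equal(
            extract_features(worked_signal),
            [0, 1, 1, 1, 1, 1, 1, 0, 0, 1, 1, 1, 1, 1, 1, 0],
        )

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(60):
            nc = rng.integers(2, 5)
            L = rng.integers(8, 31)
            sig = rng.normal(size=(L, nc))
            np.testing.assert_array_equal(
                extract_features(sig), brute_force_features(sig)
            )

    def test_oracle_agrees_on_heavily_tied_inputs(self, rng):
        # integer-valued signals force rank ties, stressing the tie-break
        for _ in range(20):
            sig = rng.integers(0, 3, size=(rng.integers(8, 20), 3)).astype(float)
            np.testing.assert_array_equal(
                extract_features(sig), brute_force_features(sig)
            )

    def test_conservation_of_counts(self, rng):
        sig = rng.normal(size=(30, 5))
        ff = extract_features(sig).reshape(4, 25)
        expected = 5 * (30 - 7) - 1
        assert (ff.sum(axis=1) == expected).all()

    def test_scale_offset_invariance(self, rng):
        sig = rng.normal(size=(40, 6))
        base = extract_features(sig)
        np.testing.assert_array_equal(base, extract_features(0.001 * sig - 42.0))
        np.testing.assert_array_equal(base, extract_features(1e6 * sig + 7.0))


class TestFeatureMatrix:
    def _segments(self, arrays, fs=10):
        names = [f"c{i}" for i in range(arrays[0].shape[1])]
        return SegmentSet(
            segments=[
                EEGRecording(a, fs=fs, channel_names=names) for a in arrays
            ],
            labels=[None] * len(arrays),
        )

    def test_identical_segments_identical_rows(self, rng):
        a = rng.normal(size=(12, 3))
        X = extract_feature_matrix(self._segments([a, a.copy()]))
        np.testing.assert_array_equal(X[0], X[1])

    def test_shape_and_row_sums(self, rng):
        arrays = [rng.normal(size=(20, 14)) for _ in range(10)]
        X = extract_feature_matrix(self._segments(arrays))
        assert X.shape == (10, 784)
        assert (X.sum(axis=1) == 4 * (14 * (20 - 7) - 1)).all()

    def test_failing_segment_reports_index(self, rng):
        arrays = [rng.normal(size=(12, 3))]
        segs = self._segments(arrays)
        segs.segments[0].samples[3, 1] = np.nan
        with pytest.raises(FeatureExtractionError, match="segment 0"):
            extract_feature_matrix(segs)
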