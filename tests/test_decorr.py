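"""Decorrelation metric: formula, pairing, masking, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from octaflow.containers import OCTVolume, ScanPattern
from octaflow.decorr import (
    build_octa_volume,
    consecutive_pair_decorrelations,
    estimate_noise_threshold,
    octa_bframe,
    pairwise_decorrelation,
)
from octaflow.exceptions import PatternError


# amplitudes are detector counts; exclude values tiny enough that
# squaring them underflows, where scale invariance genuinely breaks
_amplitude = st.one_of(st.just(0.0), st.floats(1e-6, 1e6))


class TestPairwise:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (3.0, 1.0, 0.4),  # (3-1)^2 / (9+1)
            (1.0, 0.0, 1.0),  # maximal decorrelation
            (0.0, 0.0, 0.0),  # zero-denominator convention
            (2.0, 2.0, 0.0),  # identical amplitudes
        ],
    )
    def test_pointwise_formula(self, a, b, expected):
        out = pairwise_decorrelation(np.array([[a]]), np.array([[b]]))
        assert out[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_identical_frames_give_zero(self, rng):
        frame = rng.random((16, 16))
        assert np.all(pairwise_decorrelation(frame, frame) == 0)

    def test_shape_mismatch_and_negatives_rejected(self):
        with pytest.raises(ValueError, match="shapes differ"):
            pairwise_decorrelation(np.ones((2, 2)), np.ones((3, 2)))
        with pytest.raises(ValueError, match="nonnegative"):
            pairwise_decorrelation(-np.ones((2, 2)), np.ones((2, 2)))

    @settings(deadline=None, max_examples=50)
    @given(
        frames=hnp.arrays(
            np.float64,
            st.tuples(st.integers(1, 6), st.integers(1, 6)),
            elements=_amplitude,
        ).flatmap(
            lambda a: st.tuples(
                st.just(a),
                hnp.arrays(np.float64, a.shape, elements=_amplitude),
            )
        ),
        scale=st.floats(1e-3, 1e3),
    )
    def test_symmetry_bounds_and_scale_invariance(self, frames, scale):
        a, b = frames
        d = pairwise_decorrelation(a, b)
        assert np.all((d >= 0) & (d <= 1))
        np.testing.assert_array_equal(d, pairwise_decorrelation(b, a))
        np.testing.assert_allclose(
            d, pairwise_decorrelation(scale * a, scale * b), rtol=1e-9, atol=1e-12
        )


class TestBFrame:
    def test_three_repeats_average_exactly_two_pair_images(self, rng):
        stack = rng.random((3, 8, 8))
        pairs = consecutive_pair_decorrelations(stack)
        assert pairs.shape[0] == 2
        np.testing.assert_allclose(octa_bframe(stack), pairs.mean(axis=0))

    def test_identical_repeats_give_zero(self, rng):
        frame = rng.random((8, 8))
        assert np.all(octa_bframe(np.stack([frame] * 3)) == 0)

    def test_two_repeats_equal_single_pair(self, rng):
        stack = rng.random((2, 8, 8))
        np.testing.assert_array_equal(
            octa_bframe(stack), pairwise_decorrelation(stack[0], stack[1])
        )

    def test_single_repeat_rejected(self):
        with pytest.raises(PatternError):
            octa_bframe(np.ones((1, 4, 4)))


def _noise_volume(sigma, shape, rng):
    """Amplitude volume of pure detector noise (clipped at zero)."""
    return np.clip(sigma * rng.standard_normal(shape), 0, None)


class TestBuildVolume:
    def test_output_shape_matches_pattern(self, rng):
        pat = ScanPattern(16, 6, 3, 1.5, (0.16, 0.06), "t")
        amp = rng.random((6, 3, 20, 16))
        octa = build_octa_volume(
            OCTVolume(amplitude=amp, pattern=pat, axial_pitch_um=10.0),
            mask_threshold=0.0,
        )
        assert octa.decorrelation.shape == (6, 20, 16)
        assert octa.structural.shape == (6, 20, 16)

    def test_noise_free_static_volume_is_zero_below_surface(self):
        frame = np.zeros((5, 30, 16))
        frame[:, 10:, :] = 1.3  # tissue from z=10
        amp = np.repeat(frame[:, None], 3, axis=1)
        pat = ScanPattern(16, 5, 3, 1.5, (0.16, 0.05), "t")
        octa = build_octa_volume(
            OCTVolume(amplitude=amp, pattern=pat, axial_pitch_um=10.0)
        )
        assert np.all(octa.decorrelation == 0)

    def test_auto_mask_leaves_at_most_the_oracle_tail_fraction(self, rng):
        """On a pure-noise volume the auto mask (mean + k sigma of the
        noise region) must leave unmasked no more than the fraction
        predicted by directly computing the tail of the repeat-mean
        noise-amplitude distribution."""
        sigma, k = 0.05, 3.0
        shape = (8, 3, 60, 32)
        amp = _noise_volume(sigma, shape, rng)
        pat = ScanPattern(32, 8, 3, 1.5, (0.32, 0.08), "t")
        octa = build_octa_volume(
            OCTVolume(amplitude=amp, pattern=pat, axial_pitch_um=10.0),
            mask_threshold="auto",
            mask_k=k,
        )
        unmasked = np.mean(octa.decorrelation > 0)

        # direct tail computation: distribution of the repeat-mean of 3
        # clipped-normal amplitudes, thresholded at mean + k sd
        draws = np.clip(
            sigma * np.random.default_rng(0).standard_normal((3, 200_000)), 0, None
        ).mean(axis=0)
        thr = draws.mean() + k * draws.std()
        tail = np.mean(draws > thr)
        assert unmasked <= tail * 1.5 + 3.0 / amp[:, 0].size

    def test_global_gain_invariance_of_decorrelation(self, rng):
        pat = ScanPattern(16, 4, 3, 1.5, (0.16, 0.04), "t")
        amp = rng.random((4, 3, 20, 16)) + 0.1
        base = build_octa_volume(
            OCTVolume(amplitude=amp, pattern=pat, axial_pitch_um=10.0),
            mask_threshold=0.0,
        )
        scaled = build_octa_volume(
            OCTVolume(amplitude=4.0 * amp, pattern=pat, axial_pitch_um=10.0),
            mask_threshold=0.0,
        )
        np.testing.assert_array_equal(base.decorrelation, scaled.decorrelation)

    def test_threshold_estimate_uses_only_top_rows(self, rng):
        structural = np.full((4, 30, 8), 10.0)
        structural[:, :8, :] = rng.normal(0.02, 0.01, (4, 8, 8)).clip(0)
        thr = estimate_noise_threshold(structural, k=3.0, noise_rows=8)
        assert float(thr.max()) < 0.2
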