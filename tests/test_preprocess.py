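"""Normalization, averaging, blurring, Phansalkar thresholding, ROI."""

import dataclasses
import math

import numpy as np
import pytest

from icspectrum import preprocess as pp
from icspectrum import SceneConfig, render_frames, render_mask
from icspectrum.preprocess import EnFaceImage, ThresholdParams

PITCH = 3.0 / 1024


class TestNormalize:
    def test_eight_bit_rescale(self, rng):
        raw = rng.integers(0, 256, size=(32, 32))
        raw.flat[0], raw.flat[1] = 0, 255
        img = pp.normalize_intensity(raw, PITCH)
        np.testing.assert_allclose(img.data, raw / 255.0)

    def test_constant_image_maps_to_zero(self):
        img = pp.normalize_intensity(np.full((8, 8), 7.0), PITCH)
        assert (img.data == 0).all()

    def test_idempotent_on_unit_range(self, rng):
        x = rng.random((16, 16))
        x.flat[0], x.flat[1] = 0.0, 1.0
        img = pp.normalize_intensity(x, PITCH)
        np.testing.assert_array_equal(img.data, x)

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError):
            pp.normalize_intensity(np.empty((0, 0)), PITCH)


class TestAverageFrames:
    def test_identical_frames_pass_through(self, rng):
        x = rng.random((16, 16))
        frames = [EnFaceImage(x, PITCH) for _ in range(3)]
        avg = pp.average_frames(frames)
        np.testing.assert_allclose(avg.data, x)
        assert avg.provenance == "averaged"

    def test_two_frame_mean(self):
        a = EnFaceImage(np.zeros((4, 4)), PITCH)
        b = EnFaceImage(np.ones((4, 4)), PITCH)
        assert (pp.average_frames([a, b]).data == 0.5).all()

    def test_shape_mismatch_raises(self):
        a = EnFaceImage(np.zeros((4, 4)), PITCH)
        b = EnFaceImage(np.zeros((5, 5)), PITCH)
        with pytest.raises(ValueError, match="shape"):
            pp.average_frames([a, b])

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            pp.average_frames([EnFaceImage(np.zeros((4, 4)), PITCH)])

    def test_blanked_segment_mean_is_two_thirds(self, small_eye):
        """A stroke blanked in one of three frames averages to 2/3 intensity."""
        stack = small_eye["stack"]  # noise-free, all frames identical
        frames = stack.frames.copy()
        vessel = frames[0] > 0.5
        frames[0][vessel] = 0.0  # blank every stroke in the first frame only
        imgs = [EnFaceImage(f, stack.pitch_mm) for f in frames]
        avg = pp.average_frames(imgs)
        np.testing.assert_allclose(avg.data[vessel], 2.0 / 3.0)

    def test_commutes_with_normalize_for_normalized_frames(self, rng):
        x = [rng.random((8, 8)) for _ in range(3)]
        for arr in x:
            arr.flat[0], arr.flat[1] = 0.0, 1.0
        direct = pp.average_frames([EnFaceImage(a, PITCH) for a in x])
        pre = pp.average_frames(
            [pp.normalize_intensity(a, PITCH) for a in x]
        )
        np.testing.assert_allclose(direct.data, pre.data)


class TestGaussianBlur:
    def test_constant_image_unchanged(self):
        img = EnFaceImage(np.full((32, 32), 0.3), PITCH)
        np.testing.assert_allclose(pp.gaussian_blur(img, 2.0).data, 0.3)

    def test_impulse_response_is_normalized(self):
        x = np.zeros((65, 65))
        x[32, 32] = 1.0
        out = pp.gaussian_blur(EnFaceImage(x, PITCH), 2.0)
        assert out.data.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_bruteforce_convolution(self, rng):
        x = rng.random((32, 32))
        sigma = 2.0
        out = pp.gaussian_blur(EnFaceImage(x, PITCH), sigma).data
        # separable brute-force convolution with reflect padding
        radius = int(3.0 * sigma + 0.5)
        k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
        k /= k.sum()
        # numpy's "symmetric" equals scipy.ndimage's "reflect" (edge repeated)
        padded = np.pad(x, radius, mode="symmetric")
        tmp = np.zeros_like(padded)
        for i in range(padded.shape[0]):
            tmp[i] = np.convolve(padded[i], k, mode="same")
        ref = np.zeros_like(padded)
        for j in range(padded.shape[1]):
            ref[:, j] = np.convolve(tmp[:, j], k, mode="same")
        ref = ref[radius:-radius, radius:-radius]
        assert np.abs(out - ref).max() < 1e-6

    def test_negative_radius_raises(self):
        with pytest.raises(ValueError):
            pp.gaussian_blur(EnFaceImage(np.zeros((8, 8)), PITCH), -1.0)


def _brute_phansalkar(data, params):
    R = params.window_radius_px
    H, W = data.shape
    t = np.zeros_like(data)
    for y in range(H):
        for x in range(W):
            vals = []
            for dy in range(-R, R + 1):
                for dx in range(-R, R + 1):
                    if dy * dy + dx * dx <= R * R and 0 <= y + dy < H and 0 <= x + dx < W:
                        vals.append(data[y + dy, x + dx])
            v = np.asarray(vals)
            m, s = v.mean(), v.std()
            t[y, x] = m * (
                1 + params.p * math.exp(-params.q * m) + params.k * (s / params.r - 1)
            )
    return t


class TestPhansalkar:
    def test_uniform_image_closed_form(self):
        """At intensity 0.5 the threshold is 0.5*(1 + 2e^-5 - 0.25) ~ 0.3817."""
        img = EnFaceImage(np.full((40, 40), 0.5), PITCH)
        t = pp.phansalkar_surface(img, ThresholdParams())
        expected = 0.5 * (1 + 2 * math.exp(-5) - 0.25)
        np.testing.assert_allclose(t, expected, atol=1e-12)
        assert pp.phansalkar_threshold(img).vessel.all()

    @pytest.mark.parametrize("level", [0.1, 0.5, 0.9])
    def test_uniform_image_reduces_formula(self, level):
        img = EnFaceImage(np.full((40, 40), level), PITCH)
        t = pp.phansalkar_surface(img, ThresholdParams())
        expected = level * (1 + 2 * math.exp(-10 * level) - 0.25)
        np.testing.assert_allclose(t, expected, atol=1e-12)

    def test_identical_to_bruteforce_window_scan(self, rng):
        data = rng.random((64, 64))
        params = ThresholdParams(window_radius_px=5)
        img = EnFaceImage(data, PITCH)
        t_fast = pp.phansalkar_surface(img, params)
        t_ref = _brute_phansalkar(data, params)
        assert np.array_equal(data > t_fast, data > t_ref)
        assert np.abs(t_fast - t_ref).max() < 1e-10

    def test_window_larger_than_image_raises(self):
        img = EnFaceImage(np.zeros((8, 8)), PITCH)
        with pytest.raises(ValueError, match="window"):
            pp.phansalkar_threshold(img, ThresholdParams(window_radius_px=10))

    def test_padding_invariance_away_from_border(self, rng):
        """Window-clipped statistics make interior output padding-independent."""
        data = rng.random((48, 48))
        params = ThresholdParams(window_radius_px=4)
        inner = pp.phansalkar_threshold(EnFaceImage(data, PITCH), params).vessel
        padded = np.pad(data, 8, mode="constant", constant_values=1.0)
        outer = pp.phansalkar_threshold(EnFaceImage(padded, PITCH), params).vessel
        core = np.s_[12:-12, 12:-12]
        np.testing.assert_array_equal(
            inner[4:-4, 4:-4][8:-8, 8:-8], outer[core][8:-8, 8:-8]
        )


class TestCircularROI:
    def test_reference_geometry(self):
        img = EnFaceImage(np.zeros((1024, 1024)), PITCH)
        roi = pp.make_circular_roi(img, 2.0)
        assert roi.radius_px == pytest.approx(1024 / 3)
        count = roi.mask(img.shape).sum()
        assert count == pytest.approx(math.pi * roi.radius_px**2, rel=0.005)

    def test_inscribed_circle_touches_edges(self):
        img = EnFaceImage(np.zeros((256, 256)), 3.0 / 256)
        roi = pp.make_circular_roi(img, 3.0)
        assert roi.radius_px == pytest.approx(128)

    def test_oversized_roi_raises(self):
        img = EnFaceImage(np.zeros((256, 256)), 3.0 / 256)
        with pytest.raises(ValueError, match="exceeds"):
            pp.make_circular_roi(img, 4.0)


class TestTransientLossMap:
    def test_identical_maps_yield_empty(self):
        m = pp.BinaryVesselMap(np.eye(8, dtype=bool), PITCH)
        assert not pp.transient_loss_map(m, m).any()

    def test_extra_segment_flagged_exactly(self):
        base = np.zeros((8, 8), dtype=bool)
        single = pp.BinaryVesselMap(base.copy(), PITCH)
        extra = base.copy()
        extra[3, 2:6] = True
        averaged = pp.BinaryVesselMap(extra, PITCH)
        flagged = pp.transient_loss_map(single, averaged)
        np.testing.assert_array_equal(flagged, extra)

    def test_shape_mismatch_raises(self):
        a = pp.BinaryVesselMap(np.zeros((4, 4), dtype=bool), PITCH)
        b = pp.BinaryVesselMap(np.zeros((5, 5), dtype=bool), PITCH)
        with pytest.raises(ValueError):
            pp.transient_loss_map(a, b)

    def test_flagged_fraction_grows_with_transient_rate(self, small_eye):
        """More transient loss means more averaged-only vessel pixels."""
        fractions = []
        for rate in (0.0, 0.1, 0.2):
            scene = dataclasses.replace(
                small_eye["scene"], transient_rate=rate, rng_seed=33
            )
            stack = render_frames(small_eye["graph"], scene)
            imgs = [EnFaceImage(f, stack.pitch_mm) for f in stack.frames]
            single = pp.phansalkar_threshold(imgs[0])
            averaged = pp.phansalkar_threshold(pp.average_frames(imgs))
            fractions.append(pp.transient_loss_map(single, averaged).mean())
        assert fractions[0] <= fractions[1] < fractions[2]
        assert fractions[2] > 0


def test_binarization_recovers_strokes_on_clean_scene(small_eye):
    """Thresholding a noise-free scene reproduces the stroke mask.

    Without blur the recovery is exact; with denoising enabled the halo
    widens strokes by about a pixel, so vessel recall stays >= 0.99 while
    the dice coefficient drops but stays bounded.
    """
    scene = small_eye["scene"]
    truth = render_mask(small_eye["graph"], scene)
    img = EnFaceImage(small_eye["stack"].frames[0], scene.pitch_mm)
    exact = pp.phansalkar_threshold(img).vessel
    assert np.array_equal(exact, truth)

    blurred = pp.gaussian_blur(img, 2.0 * scene.grid_px / 1024)
    det = pp.phansalkar_threshold(blurred).vessel
    recall = (det & truth).sum() / truth.sum()
    dice = 2 * (det & truth).sum() / (det.sum() + truth.sum())
    assert recall >= 0.99
    assert dice >= 0.85
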