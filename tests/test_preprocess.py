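import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from holospm.simulate import Hologram
from holospm.preprocess import (COARSE_BRANCH, FINE_BRANCH, PreprocParams,
                                apply_frequency_filter, build_frequency_mask,
                                enhance_contrast, ensemble_background,
                                run_preproc_chain, segment_image,
                                shift_intensity, subtract_background)
from holospm.metrics import mean_spatial_frequency


def unit_holo(arr, **kw):
    return Hologram(intensity=np.asarray(arr, float), scale="unit", **kw)


class TestEnsembleBackground:
    def test_identical_frames_average_to_themselves(self, rng):
        frame = unit_holo(rng.random((16, 16)))
        out = ensemble_background([frame] * 10)
        assert np.allclose(out.intensity, frame.intensity)

    def test_constant_frames_average(self):
        frames = [unit_holo(np.full((8, 8), 0.2)),
                  unit_holo(np.full((8, 8), 0.4))]
        assert np.allclose(ensemble_background(frames).intensity, 0.3)

    def test_noise_averages_out(self, rng):
        """CLT: the 500-frame ensemble is within 5 sd/sqrt(500) of truth."""
        sd = 0.05
        frames = [unit_holo(0.5 + rng.normal(0, sd, (32, 32)))
                  for _ in range(500)]
        out = ensemble_background(frames)
        assert np.max(np.abs(out.intensity - 0.5)) < 5 * sd / np.sqrt(500)

    def test_empty_and_mismatched_rejected(self):
        with pytest.raises(ValueError):
            ensemble_background([])
        with pytest.raises(ValueError):
            ensemble_background([unit_holo(np.zeros((4, 4))),
                                 unit_holo(np.zeros((8, 8)))])


class TestSubtractBackground:
    def test_frame_equals_background_gives_midscale(self, rng):
        frame = unit_holo(rng.random((16, 16)))
        out = subtract_background(frame, frame)
        assert np.allclose(out.intensity, 0.5)

    def test_zero_background_shifts_by_midscale(self):
        frame = unit_holo(np.full((8, 8), 0.3))
        out = subtract_background(frame, unit_holo(np.zeros((8, 8))))
        assert np.allclose(out.intensity, 0.8)

    def test_removes_fixed_background_from_gradient(self, rng):
        """Gradient after subtracting a known background matches the
        signal-only gradient within 10%."""
        from holospm.metrics import mean_intensity_gradient
        from scipy.ndimage import gaussian_filter
        signal = 0.2 * rng.standard_normal((64, 64))
        background = gaussian_filter(rng.standard_normal((64, 64)), 8)
        mixed = unit_holo(np.clip(0.5 + signal + background, 0, 1))
        recovered = subtract_background(mixed, unit_holo(background + 0.5))
        g_rec = mean_intensity_gradient(recovered.intensity)
        g_sig = mean_intensity_gradient(np.clip(0.5 + signal, 0, 1))
        assert abs(g_rec - g_sig) / g_sig < 0.10


class TestFrequencyMask:
    def test_lowpass_is_one_at_origin(self):
        mask = build_frequency_mask((64, 64), 10, "lowpass")
        assert mask.values[32, 32] == 1.0

    def test_lowpass_value_at_radius_2r(self):
        r = 10
        mask = build_frequency_mask((128, 128), r, "lowpass")
        assert mask.values[64, 64 + 2 * r] == pytest.approx(np.exp(-1))

    @given(r=st.floats(1.0, 60.0), side=st.sampled_from([32, 65, 70, 128]))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_lowpass_plus_highpass_is_one(self, r, side):
        lo = build_frequency_mask((side, side), r, "lowpass").values
        hi = build_frequency_mask((side, side), r, "highpass").values
        assert np.allclose(lo + hi, 1.0)

    def test_symmetric_under_frequency_negation(self):
        # odd side: the centered grid is exactly symmetric
        mask = build_frequency_mask((65, 65), 7, "lowpass").values
        assert np.allclose(mask, mask[::-1, ::-1])

    def test_nonpositive_r_rejected(self):
        with pytest.raises(ValueError):
            build_frequency_mask((8, 8), 0.0, "lowpass")


class TestApplyFrequencyFilter:
    def test_lowpass_preserves_constant(self):
        img = unit_holo(np.full((64, 64), 0.7))
        out = apply_frequency_filter(img, PreprocParams(filter_size=5,
                                                        filter_mode="lowpass"))
        assert np.allclose(out.intensity, 0.7, atol=1e-9)

    def test_highpass_removes_dc(self, rng):
        img = unit_holo(rng.random((64, 64)))
        out = apply_frequency_filter(
            img, PreprocParams(filter_size=5, filter_mode="highpass"),
            rescale=False)
        assert abs(out.intensity.mean()) < 1e-9

    def test_band_reconstruction(self, rng):
        """lowpass(img) + highpass(img) = img exactly, before rescaling."""
        img = unit_holo(rng.random((70, 70)))
        lo = apply_frequency_filter(img, PreprocParams(filter_size=12,
                                    filter_mode="lowpass"), rescale=False)
        hi = apply_frequency_filter(img, PreprocParams(filter_size=12,
                                    filter_mode="highpass"), rescale=False)
        assert np.allclose(lo.intensity + hi.intensity, img.intensity,
                           atol=1e-9)

    def test_sinusoid_attenuated_by_mask_value(self):
        """A pure sinusoid at integer bin k is scaled by exactly LPF(k)."""
        n, k, r = 128, 9, 15.0
        x = np.arange(n)
        img = unit_holo(0.5 + 0.3 * np.cos(2 * np.pi * k * x / n)[None, :]
                        * np.ones((n, 1)))
        out = apply_frequency_filter(img, PreprocParams(filter_size=r,
                                     filter_mode="lowpass"), rescale=False)
        expected = np.exp(-k**2 / (4 * r**2))
        in_amp = np.abs(np.fft.fft2(img.intensity - 0.5))[0, k]
        out_amp = np.abs(np.fft.fft2(out.intensity - 0.5))[0, k]
        assert out_amp / in_amp == pytest.approx(expected, rel=1e-9)

    def test_huge_r_lowpass_is_identity(self, rng):
        img = unit_holo(rng.random((32, 32)))
        out = apply_frequency_filter(img, PreprocParams(filter_size=1e5,
                                     filter_mode="lowpass"), rescale=False)
        assert np.allclose(out.intensity, img.intensity, atol=1e-6)

    def test_lowpass_converges_to_input_with_r(self, rng):
        img = unit_holo(rng.random((64, 64)))
        dists = []
        for r in (5, 10, 20, 40, 80):
            out = apply_frequency_filter(img, PreprocParams(
                filter_size=r, filter_mode="lowpass"), rescale=False)
            dists.append(np.linalg.norm(out.intensity - img.intensity))
        assert all(a > b for a, b in zip(dists, dists[1:]))


class TestShiftAndContrast:
    def test_shift_cases(self):
        img = Hologram(intensity=np.array([[100.0, 250.0, 5.0]]),
                       scale="uint8")
        out = shift_intensity(img, 50)
        assert out.intensity.tolist() == [[150.0, 255.0, 55.0]]
        assert np.array_equal(shift_intensity(img, 0).intensity,
                              img.intensity)

    def test_contrast_identity_and_collapse(self, rng):
        img = Hologram(intensity=rng.integers(0, 255, (8, 8)).astype(float),
                       scale="uint8")
        assert np.allclose(enhance_contrast(img, 1.0).intensity,
                           img.intensity)
        assert np.allclose(enhance_contrast(img, 0.0).intensity,
                           img.intensity.mean())

    def test_contrast_saturates_extremes(self):
        img = Hologram(intensity=np.array([[100.0, 200.0]]), scale="uint8")
        out = enhance_contrast(img, 7.0)
        assert out.intensity.tolist() == [[0.0, 255.0]]


class TestSegmentImage:
    def test_700px_frame_yields_100_segments(self):
        frame = Hologram(intensity=np.zeros((700, 700)), scale="uint8")
        assert len(segment_image(frame, 70)) == 100

    def test_hundred_frames_yield_10000_segments(self):
        frame = Hologram(intensity=np.zeros((700, 700)), scale="uint8")
        total = sum(len(segment_image(frame, 70)) for _ in range(100))
        assert total == 10_000

    def test_rectangular_frame(self):
        frame = Hologram(intensity=np.zeros((140, 70)), scale="unit")
        assert len(segment_image(frame, 70)) == 2

    def test_non_divisible_rejected(self):
        frame = Hologram(intensity=np.zeros((100, 100)), scale="unit")
        with pytest.raises(ValueError):
            segment_image(frame, 70)

    @given(tiles=st.sampled_from([(2, 7), (4, 35), (1, 70)]))
    @settings(max_examples=3, deadline=None, derandomize=True)
    def test_restitching_reproduces_frame(self, tiles):
        n_tiles, tile = tiles
        rng = np.random.default_rng(1)
        arr = rng.random((n_tiles * tile, n_tiles * tile))
        seg = segment_image(unit_holo(arr), tile)
        stitched = np.zeros_like(arr)
        for s in seg.segments:
            i, j = s.grid_position
            stitched[i * tile:(i + 1) * tile,
                     j * tile:(j + 1) * tile] = s.pixels
        assert np.allclose(stitched, arr)

    def test_labels_inherited(self):
        frame = unit_holo(np.zeros((140, 140)), labels=(2.0, 1.0))
        seg = segment_image(frame, 70)
        assert all(s.labels == (2.0, 1.0) for s in seg.segments)


class TestPreprocChain:
    def test_fine_branch_has_higher_spatial_frequency(self, fine_stacks_small):
        frames = fine_stacks_small[8.0]
        fine = run_preproc_chain(frames, branch="fine")
        coarse = run_preproc_chain(frames, branch="coarse")
        msf = lambda seg: np.mean([mean_spatial_frequency(s.pixels)
                                   for s in seg.segments])
        assert msf(fine) > msf(coarse)

    def test_segment_count_scales_with_frames(self, fine_stacks_small):
        frames = fine_stacks_small[1.0]
        seg = run_preproc_chain(frames, branch="fine")
        assert len(seg) == len(frames) * 4  # 140 px -> 2x2 tiles of 70

    def test_neutral_chain_returns_subtracted_tiles(self, rng):
        frames = [unit_holo(rng.random((140, 140))) for _ in range(3)]
        params = PreprocParams(filter_size=1.0, filter_mode="none",
                               shift=0.0, contrast=1.0, tile_size=70)
        seg = run_preproc_chain(frames, params=params)
        bg = ensemble_background(frames)
        manual = segment_image(
            enhance_contrast(shift_intensity(
                subtract_background(frames[0], bg), 0.0), 1.0), 70)
        assert np.allclose(seg.segments[0].pixels, manual.segments[0].pixels)

    def test_branch_defaults_match_workflows(self):
        assert (FINE_BRANCH.filter_mode, FINE_BRANCH.shift,
                FINE_BRANCH.contrast, FINE_BRANCH.filter_size) == (
                    "highpass", 50.0, 7.0, 20.0)
        assert (COARSE_BRANCH.filter_mode, COARSE_BRANCH.shift,
                COARSE_BRANCH.contrast, COARSE_BRANCH.filter_size) == (
                    "lowpass", 0.0, 5.0, 20.0)
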