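"""Temporal filtering, DFT reconstruction, MTF maps, masks, normalisation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fddcs.errors import ConfigurationError, DegenerateInputError, MaskError
from fddcs.reconstruction import (
    MaskGeometry,
    build_masks,
    mtf_map,
    normalize_s1,
    reconstruct,
    reconstruct_and_normalize,
    temporal_filter,
)
from fddcs.scenarios import scaled_mask_geometry, small_dynamic_scenario
from fddcs.simulator import simulate


class TestTemporalFilter:
    def test_definitions_on_three_frames(self):
        a, b, c = (np.full((4, 4), v, dtype=float) for v in (1.0, 2.0, 4.0))
        stack = np.stack([a, b, c])
        dc = temporal_filter(stack, "dc_pair")
        assert dc.n_frames == 2
        np.testing.assert_array_equal(dc.frames[0], a - b)
        np.testing.assert_array_equal(dc.frames[1], b - c)
        ff = temporal_filter(stack, "first_frame")
        np.testing.assert_array_equal(ff.frames[0], b - a)
        np.testing.assert_array_equal(ff.frames[1], c - a)
        sf = temporal_filter(stack, "single_frame")
        np.testing.assert_array_equal(sf.frames, stack)

    def test_constant_stack_gives_zero_holograms(self):
        stack = np.ones((5, 8, 8))
        assert not temporal_filter(stack, "dc_pair").frames.any()
        assert not temporal_filter(stack, "first_frame").frames.any()

    @pytest.mark.parametrize("mode,n_min", [("dc_pair", 2), ("first_frame", 2), ("single_frame", 1)])
    def test_too_few_frames_rejected(self, mode, n_min):
        with pytest.raises(ConfigurationError):
            temporal_filter(np.ones((n_min - 1, 4, 4)), mode)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigurationError):
            temporal_filter(np.ones((3, 4, 4)), "boxcar")


class TestReconstruct:
    def test_zero_hologram_reconstructs_to_zero(self):
        assert not reconstruct(np.zeros((2, 8, 8))).any()

    def test_cosine_closed_form(self):
        n, q = 32, 5
        x = np.arange(n)
        hc = np.cos(2 * np.pi * q * x / n)[:, None] * np.ones(n)[None, :]
        hr = reconstruct(hc[None])[0]
        half = n // 2
        # energy only at (+-q, 0) in shifted coordinates, each n^4 / 4
        expected = np.zeros((n, n))
        expected[half + q, half] = n**4 / 4
        expected[half - q, half] = n**4 / 4
        np.testing.assert_allclose(hr, expected, atol=1e-6 * n**4)

    @given(arrays(np.float64, (64, 64), elements=st.floats(-100, 100, allow_nan=False)))
    def test_parseval_identity(self, hc):
        hr = reconstruct(hc[None])[0]
        lhs = hr.sum()
        rhs = 64 * 64 * np.sum(hc**2)
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-6)

    def test_non_finite_rejected(self):
        bad = np.ones((1, 8, 8))
        bad[0, 3, 3] = np.nan
        with pytest.raises(ConfigurationError):
            reconstruct(bad)


class TestMTFMap:
    def test_unity_at_origin_for_any_alpha(self):
        for alpha in (0.0, 0.3, 0.72, 1.0):
            m = mtf_map(alpha, 32)
            assert m.values[16, 16] == pytest.approx(1.0)

    def test_alpha_zero_is_identity(self):
        np.testing.assert_array_equal(mtf_map(0.0, 16).values, np.ones((16, 16)))

    def test_reference_values_at_alpha_072(self):
        m = mtf_map(0.72, 512)
        # u = -0.5 on the shifted grid is index 0
        assert m.values[0, 256] == pytest.approx(0.6401, abs=2e-4)
        assert m.values[0, 0] == pytest.approx(0.4097, abs=2e-4)

    def test_rotational_symmetry_and_positivity(self):
        v = mtf_map(0.9, 64).values
        assert (v > 0).all()
        inner = v[1:, 1:]  # indices with an exact mirror partner on an even grid
        np.testing.assert_allclose(inner, inner[::-1, :], rtol=1e-12)
        np.testing.assert_allclose(inner, inner.T, rtol=1e-12)

    def test_alpha_out_of_range(self):
        with pytest.raises(ConfigurationError):
            mtf_map(1.2, 16)


class TestMasks:
    def test_radius_zero_single_pixel(self):
        geo = MaskGeometry(plus_center=(5, 5), radius=0.0, shot_center=(5, -5), shot_radius=0.0)
        ms = build_masks(geo, 32)
        assert ms.n_pixels == 1
        assert ms.shot_flat.size == 1

    def test_minus_mask_is_point_reflection(self):
        geo = MaskGeometry(plus_center=(6, 4), radius=2.5, shot_center=(6, -6), shot_radius=2.0)
        ms = build_masks(geo, 32)
        n, half = 32, 16
        px = np.stack(np.divmod(ms.plus_flat, n), axis=1) - half
        mx = np.stack(np.divmod(ms.minus_flat, n), axis=1) - half
        np.testing.assert_array_equal(mx, -px)

    def test_radius_80_closed_disc_has_20081_pixels(self):
        # brute-force lattice enumeration
        y, x = np.mgrid[-90:91, -90:91]
        count = int((x**2 + y**2 <= 80**2).sum())
        ms = build_masks(scaled_mask_geometry(512), 512)
        assert ms.n_pixels == count == 20081

    def test_overlap_rejected(self):
        geo = MaskGeometry(plus_center=(5, 5), radius=3.0, shot_center=(5, -2), shot_radius=4.0)
        with pytest.raises(MaskError, match="overlap"):
            build_masks(geo, 32)

    def test_dc_pixel_rejected(self):
        geo = MaskGeometry(plus_center=(1, 1), radius=2.0, shot_center=(10, -10), shot_radius=1.0)
        with pytest.raises(MaskError, match="DC"):
            build_masks(geo, 32)

    def test_out_of_bounds_rejected(self):
        geo = MaskGeometry(plus_center=(15, 15), radius=3.0, shot_center=(10, -10), shot_radius=1.0)
        with pytest.raises(MaskError):
            build_masks(geo, 32)


class TestNormalizeS1:
    def test_constant_hr_gives_zero_s1(self, small_masks):
        hr = np.full((3, 64, 64), 7.5)
        res = normalize_s1(hr, small_masks)
        np.testing.assert_allclose(res.s1_bar, 0.0, atol=1e-12)

    def test_doubled_plus_mask_gives_unit_s1(self, small_masks):
        hr = np.full((1, 64, 64), 3.0)
        flat = hr[0].ravel()
        flat[small_masks.plus_flat] = 6.0
        flat[small_masks.minus_flat] = 6.0
        res = normalize_s1(hr, small_masks)
        assert res.s1_bar[0] == pytest.approx(1.0)

    def test_zero_stack_is_degenerate(self, small_masks):
        with pytest.raises(DegenerateInputError):
            normalize_s1(np.zeros((2, 64, 64)), small_masks)

    def test_static_noiseless_dc_pair_is_degenerate(self, small_masks):
        """A static sample with noise off cancels exactly under DC-pair
        filtering, leaving no shot-noise energy to normalise against."""
        cfg = small_dynamic_scenario(3, n_frames=4, detuning_hz=0.0)
        cfg.correlation_time_s = np.inf
        cfg.shot_noise = False
        cfg.read_noise_e = 0.0
        stack = simulate(cfg).stacks[0.0]
        holo = temporal_filter(stack.frames, "dc_pair")
        assert not holo.frames.any()
        with pytest.raises(DegenerateInputError):
            reconstruct_and_normalize(holo, small_masks)

    def test_twin_mask_symmetry(self, dynamic_rec):
        np.testing.assert_allclose(dynamic_rec.s_plus, dynamic_rec.s_minus, rtol=1e-10)

    def test_streaming_matches_materialized(self, dynamic_stack, small_masks):
        holo = temporal_filter(dynamic_stack.frames[:10], "dc_pair")
        a = reconstruct_and_normalize(holo, small_masks)
        b = normalize_s1(reconstruct(holo), small_masks)
        np.testing.assert_allclose(a.s1_bar, b.s1_bar, rtol=1e-12)
        np.testing.assert_allclose(a.s1_pixels, b.s1_pixels, rtol=1e-12)

    def test_stack_mean_nbar_mode(self, dynamic_stack, small_masks):
        holo = temporal_filter(dynamic_stack.frames[:10], "dc_pair")
        pooled = reconstruct_and_normalize(holo, small_masks, nbar_mode="stack_mean")
        per = reconstruct_and_normalize(holo, small_masks, nbar_mode="per_frame")
        assert pooled.s1_bar.mean() == pytest.approx(per.s1_bar.mean(), rel=0.02)
        with pytest.raises(ConfigurationError):
            reconstruct_and_normalize(holo, small_masks, nbar_mode="median")

    def test_mtf_correction_divides_per_pixel(self, dynamic_stack, small_masks):
        from fddcs.reconstruction import mtf_map

        holo = temporal_filter(dynamic_stack.frames[:6], "dc_pair")
        plain = reconstruct_and_normalize(holo, small_masks)
        corr = reconstruct_and_normalize(holo, small_masks, mtf=mtf_map(0.72, 64))
        m = mtf_map(0.72, 64).values.ravel()[small_masks.plus_flat]
        np.testing.assert_allclose(corr.s1_pixels, plain.s1_pixels / m[:, None], rtol=1e-10)
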