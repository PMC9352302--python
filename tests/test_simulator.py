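"""Field synthesis statistics, detector model, clutter and hop injection."""

import warnings

import numpy as np
import pytest

from fddcs.errors import AliasingError, ConfigurationError
from fddcs.scenarios import small_dynamic_scenario
from fddcs.simulator import (
    SimulationConfig,
    _pixel_weights,
    detector_integrate,
    inject_global_clutter,
    inject_mode_hops,
    make_field_stack,
    simulate,
)


def _noiseless(cfg):
    cfg.shot_noise = False
    cfg.read_noise_e = 0.0
    cfg.quantise = False
    return cfg


class TestFieldStatistics:
    def test_static_sample_has_identical_substeps(self):
        cfg = small_dynamic_scenario(1, n_frames=2, detuning_hz=0.0)
        cfg.correlation_time_s = np.inf
        fields = make_field_stack(cfg).materialize()
        np.testing.assert_array_equal(fields[0][0], fields[0][1])
        np.testing.assert_array_equal(fields[0][0], fields[1][0])

    def test_mode_lag1_autocorrelation_matches_g1(self):
        """Track the single synthesised mode through the carrier DFT bin: its
        lag-1 autocorrelation over 10^4 substeps must equal exp(-dt/tauc)."""
        cfg = small_dynamic_scenario(4, n_frames=1, grid_size=16, detuning_hz=0.0)
        cfg.carrier_offset = (4, 4)
        cfg.aperture_radius_freq = 0.5  # a single mode
        cfg.correlation_time_s = 2e-3
        cfg.exposure_time_s = 0.1
        cfg.frame_period_s = 0.1
        cfg.substeps_per_exposure = 10_000
        field = next(make_field_stack(cfg).iter_frames(0.0))
        mode = np.fft.fft2(field, axes=(1, 2))[:, 4, 4]
        x = mode - mode.mean()
        rho = np.real(np.vdot(x[:-1], x[1:])) / np.real(np.vdot(x[:-1], x[:-1]))
        expected = np.exp(-(cfg.substep_dt) / cfg.correlation_time_s)
        se = np.sqrt((1 - expected**2) / x.size)
        assert abs(rho - expected) < 3 * se

    def test_spatial_autocovariance_matches_aperture(self):
        """The intensity autocovariance of one frame must follow |mu_E|^2,
        the squared magnitude of the Fourier transform of the mode disc."""
        cfg = small_dynamic_scenario(5, n_frames=40, grid_size=64, detuning_hz=0.0)
        cfg.substeps_per_exposure = 2
        cfg.correlation_time_s = 1e-3  # frames decorrelate between exposures
        fs = make_field_stack(cfg)
        flat, n_modes = fs._mode_layout()
        acs = []
        for f, frame in zip(range(40), fs.iter_frames(0.0)):
            intensity = np.abs(frame[0]) ** 2
            d = intensity - intensity.mean()
            ac = np.fft.ifft2(np.abs(np.fft.fft2(d)) ** 2).real
            acs.append(ac / ac[0, 0])
        ac = np.mean(acs, axis=0)
        # brute-force theory from the mode layout
        kx = flat // 64
        ky = flat % 64
        theory = np.zeros((6, 6))
        for dx in range(6):
            for dy in range(6):
                mu = np.exp(2j * np.pi * (kx * dx + ky * dy) / 64).mean()
                theory[dx, dy] = abs(mu) ** 2
        # compare where the aperture autocorrelation carries structure; the
        # far tail of the estimate is limited by its own sampling floor
        core = theory > 0.05
        np.testing.assert_allclose(ac[:6, :6][core], theory[core], atol=0.06)

    def test_speckle_contrast_near_unity(self):
        cfg = small_dynamic_scenario(6, n_frames=1, grid_size=128, detuning_hz=0.0)
        cfg.substeps_per_exposure = 1
        cfg.correlation_time_s = 5e-3
        frame = next(make_field_stack(cfg).iter_frames(0.0))[0]
        intensity = np.abs(frame) ** 2
        assert intensity.std() / intensity.mean() == pytest.approx(1.0, abs=0.05)

    def test_bit_for_bit_reproducibility(self):
        cfg = small_dynamic_scenario(7, n_frames=6)
        a = simulate(cfg).stacks[200.0].frames
        b = simulate(cfg).stacks[200.0].frames
        np.testing.assert_array_equal(a, b)


class TestConfigValidation:
    def test_twin_band_overlap_with_dc_rejected(self):
        cfg = small_dynamic_scenario(1)
        cfg.carrier_offset = (10, 10)
        cfg.aperture_radius_freq = 10.0
        with pytest.raises(ConfigurationError, match="overlap"):
            make_field_stack(cfg)

    def test_band_outside_quadrant_rejected(self):
        cfg = small_dynamic_scenario(1)
        cfg.carrier_offset = (30, 30)
        cfg.aperture_radius_freq = 10.0
        with pytest.raises(ConfigurationError, match="Nyquist"):
            make_field_stack(cfg)

    def test_unresolved_beat_rejected(self):
        cfg = small_dynamic_scenario(1, detuning_hz=5000.0)
        with pytest.raises(AliasingError, match="beat"):
            make_field_stack(cfg)

    def test_too_short_correlation_time_rejected(self):
        cfg = small_dynamic_scenario(1)
        cfg.correlation_time_s = 1e-5
        with pytest.raises(AliasingError, match="correlation"):
            make_field_stack(cfg)


class TestDetector:
    def test_reference_only_noiseless_is_exact_constant(self):
        cfg = _noiseless(small_dynamic_scenario(2, n_frames=3, detuning_hz=0.0))
        cfg.sample_to_reference_ratio = 0.0
        cfg.quantise = True  # keep the ADC: counts = floor(R / gain)
        cfg.fill_factor = 1.0
        stack = detector_integrate(make_field_stack(cfg), cfg, 0.0)
        expected = int(cfg.reference_photoelectrons_per_pixel / cfg.quantisation_gain_e)
        assert (stack.frames == expected).all()

    def test_poisson_variance_matches_mean(self):
        cfg = small_dynamic_scenario(3, n_frames=8, grid_size=128, detuning_hz=0.0)
        cfg.sample_to_reference_ratio = 0.0
        cfg.read_noise_e = 0.0
        cfg.quantise = False
        stack = detector_integrate(make_field_stack(cfg), cfg, 0.0)
        pe = stack.frames  # photoelectrons / gain, unquantised
        counts_e = pe * cfg.quantisation_gain_e
        mean, var = counts_e.mean(), counts_e.var()
        n = counts_e.size  # ~1.3e5 samples
        assert var == pytest.approx(mean, rel=4 / np.sqrt(n) * 2)

    def test_fill_factor_attenuates_carrier_per_mtf(self):
        """Two runs sharing the field seed and differing only in fill factor:
        the per-bin hologram energy ratio at the carrier equals the discrete
        pixel-window response, which matches the analytic MTF closely."""
        spectra = {}
        for alpha in (0.9, 0.0):
            cfg = small_dynamic_scenario(6, n_frames=2, grid_size=32, detuning_hz=0.0)
            cfg.carrier_offset = (10, 10)
            cfg.aperture_radius_freq = 5.0
            cfg.oversample_factor = 5
            cfg.pixel_integration = "oversample"
            cfg.fill_factor = alpha
            cfg.substeps_per_exposure = 1
            cfg.correlation_time_s = 5e-3
            _noiseless(cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                st = detector_integrate(make_field_stack(cfg), cfg, 0.0)
            spectra[alpha] = np.abs(np.fft.fft2(st.frames[0] - st.frames[1])) ** 2
        ratio = spectra[0.9][10, 10] / spectra[0.0][10, 10]
        u = 10 / 32
        w = _pixel_weights(5, 0.9)
        offsets = (np.arange(5) + 0.5) / 5 - 0.5
        discrete = float(np.sum(w * np.cos(2 * np.pi * u * offsets))) ** 2
        assert ratio == pytest.approx(discrete**2, rel=1e-9)
        assert ratio == pytest.approx((np.sinc(0.9 * u) ** 2) ** 2, rel=0.05)

    def test_fourier_and_oversample_paths_agree(self):
        """The Fourier-domain pixel integration is the continuum limit of the
        oversampled spatial average.  The two paths differ by a fixed
        sub-pixel registration offset, so the comparison is made on the
        reconstruction intensities, which are translation invariant."""
        hr = {}
        for mode, os in (("fourier", 1), ("oversample", 15)):
            cfg = small_dynamic_scenario(9, n_frames=2, grid_size=32, detuning_hz=0.0)
            cfg.carrier_offset = (10, 10)
            cfg.aperture_radius_freq = 4.0
            cfg.pixel_integration = mode
            cfg.oversample_factor = os
            cfg.fill_factor = 0.72
            cfg.substeps_per_exposure = 1
            cfg.correlation_time_s = 5e-3
            _noiseless(cfg)
            frames = detector_integrate(make_field_stack(cfg), cfg, 0.0).frames
            hr[mode] = np.abs(np.fft.fft2(frames[0] - frames[1])) ** 2
        band = hr["fourier"] > 1e-6 * hr["fourier"].max()
        ratio = hr["oversample"][band] / hr["fourier"][band]
        np.testing.assert_allclose(ratio, 1.0, atol=0.02)

    def test_pixel_weights_cover_active_area(self):
        w = _pixel_weights(5, 0.72)
        assert w.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(w, w[::-1])  # centred window

    def test_saturation_warning(self):
        cfg = small_dynamic_scenario(3, n_frames=2, detuning_hz=0.0)
        cfg.bit_depth = 8
        with pytest.warns(UserWarning, match="saturated"):
            detector_integrate(make_field_stack(cfg), cfg, 0.0)


class TestClutterInjection:
    def test_zero_waveform_is_identity(self, dynamic_stack):
        out = inject_global_clutter(dynamic_stack, np.zeros(dynamic_stack.n_frames))
        np.testing.assert_array_equal(out.frames, dynamic_stack.frames)

    def test_large_waveform_rejected(self, dynamic_stack):
        with pytest.raises(ConfigurationError, match="< 1"):
            inject_global_clutter(dynamic_stack, np.ones(dynamic_stack.n_frames))

    def test_wrong_length_rejected(self, dynamic_stack):
        with pytest.raises(ConfigurationError, match="length"):
            inject_global_clutter(dynamic_stack, np.zeros(3))

    def test_beat_note_elevates_one_singular_value(self):
        """A global scale modulation is a rank-one perturbation (one spatial
        pattern, one temporal profile): after DC-pair filtering a beat note
        elevates exactly one singular value above the speckle floor, while a
        slow drift sits inside the DC-pair stopband and leaves the spectrum
        unchanged."""
        from fddcs.reconstruction import temporal_filter
        from fddcs.svd_filter import singular_spectrum, stack_to_matrix

        cfg = small_dynamic_scenario(8, n_frames=60)
        cfg.sample_to_reference_ratio = 0.001
        base = simulate(cfg).stacks[200.0]
        t = np.arange(cfg.n_frames)

        def spectrum(frames):
            return singular_spectrum(stack_to_matrix(temporal_filter(frames, "dc_pair").frames))

        sv_clean = spectrum(base.frames)
        beat = inject_global_clutter(base, 0.05 * np.sin(2 * np.pi * 0.2 * t))
        sv_beat = spectrum(beat.frames)
        assert sv_beat[0] / sv_clean[0] > 2.0
        assert sv_beat[1] / sv_clean[1] < 1.3
        drift = inject_global_clutter(base, 0.1 * (t / t.size - 0.5))
        sv_drift = spectrum(drift.frames)
        np.testing.assert_allclose(sv_drift[:5], sv_clean[:5], rtol=0.15)


class TestModeHops:
    def test_no_hops_identity(self):
        cfg = small_dynamic_scenario(10, n_frames=8)
        fs = make_field_stack(cfg)
        assert inject_mode_hops(fs, []) is fs

    def test_hop_out_of_range_rejected(self):
        cfg = small_dynamic_scenario(10, n_frames=8)
        with pytest.raises(ConfigurationError):
            inject_mode_hops(make_field_stack(cfg), [8])

    def test_pre_hop_frames_unchanged(self):
        cfg = small_dynamic_scenario(10, n_frames=10)
        clean = detector_integrate(make_field_stack(cfg), cfg, 0.0)
        hopped = detector_integrate(inject_mode_hops(make_field_stack(cfg), [6]), cfg, 0.0)
        np.testing.assert_array_equal(clean.frames[:6], hopped.frames[:6])
        assert not np.array_equal(clean.frames[6], hopped.frames[6])
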