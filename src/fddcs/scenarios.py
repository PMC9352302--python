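"""Named study conditions: instrument geometry and simulation presets.

The reference geometry is a 785 nm source observed at 76.84 mm through a
5.0 mm circular collection aperture on a 3.45 um-pitch sensor: one speckle
then covers 15.57 camera pixels, and the radius-80 signal mask of a 512 x 512
reconstruction (20081 pixels) detects ~1290 speckles in parallel.

Mask layout scales with the grid: the carrier sits at 170/512 of the grid
along each axis and the aperture/mask radius is 80/512 of the grid, which
keeps the twin heterodyne bands, the sample autocorrelation band and the
quiet shot-noise corners disjoint at every size.
"""

from __future__ import annotations

import numpy as np

from .reconstruction import MaskGeometry, build_masks
from .simulator import SimulationConfig
from .snr_analysis import SpeckleGeometry, speckle_area

__all__ = [
    "REFERENCE_GEOMETRY",
    "REFERENCE_SPECKLE_PX",
    "scaled_mask_geometry",
    "snr_gain_scenario",
    "flat_field_scenario",
    "tauc_recovery_scenario",
    "small_dynamic_scenario",
    "mode_hop_scenario",
]

REFERENCE_GEOMETRY = SpeckleGeometry.circular_aperture(
    wavelength_m=785e-9,
    distance_m=76.84e-3,
    aperture_diameter_m=5.0e-3,
    pixel_pitch_m=3.45e-6,
)

#: speckle area in camera pixels for the reference geometry (~15.57)
REFERENCE_SPECKLE_PX = speckle_area(REFERENCE_GEOMETRY)

_CARRIER_FRAC = 170 / 512
_RADIUS_FRAC = 80 / 512


def scaled_mask_geometry(grid_size: int, shot_radius: float | None = None) -> MaskGeometry:
    """Twin-mask / shot-mask layout scaled from the 512-pixel reference."""
    c = int(round(_CARRIER_FRAC * grid_size))
    r = float(int(round(_RADIUS_FRAC * grid_size)))
    return MaskGeometry(
        plus_center=(c, c),
        radius=r,
        shot_center=(c, -c),
        shot_radius=r if shot_radius is None else shot_radius,
    )


def _carrier(grid_size: int) -> tuple[int, int]:
    c = int(round(_CARRIER_FRAC * grid_size))
    return (c, c)


def _radius(grid_size: int) -> float:
    return float(int(round(_RADIUS_FRAC * grid_size)))


def snr_gain_scenario(seed: int, n_frames: int = 501, grid_size: int = 512) -> SimulationConfig:
    """Phantom acquisition for the SNR-gain study.

    One detuning of 1 kHz with the correlation time at the matched point
    ``w tau_c = 1`` of the Lorentzian; 200 Hz frame rate with a 0.2 ms
    exposure; reference ~5000 photoelectrons per pixel per frame with a
    0.2 % sensor-mean sample beam (per-pixel S1 values then sit in the tens
    to low hundreds); read noise 2.45 e-, quantisation interval 5.73 e-,
    12-bit ADC.  Speckle counts follow the geometric bookkeeping of
    :data:`REFERENCE_SPECKLE_PX`: the full radius-80 mask of a 512-pixel grid
    (20081 px) detects ~1290 speckles.
    """
    return SimulationConfig(
        grid_size=grid_size,
        carrier_offset=_carrier(grid_size),
        aperture_radius_freq=_radius(grid_size),
        correlation_time_s=1.0 / (2 * np.pi * 1000.0),
        detuning_list_hz=(1000.0,),
        exposure_time_s=0.2e-3,
        frame_period_s=5e-3,
        substeps_per_exposure=4,
        reference_photoelectrons_per_pixel=5000.0,
        sample_to_reference_ratio=0.002,
        fill_factor=0.72,
        read_noise_e=2.45,
        quantisation_gain_e=5.73,
        bit_depth=12,
        n_frames=n_frames,
        rng_seed=seed,
        speckle_area_px=1.0,
        pixel_integration="fourier",
    )


def flat_field_scenario(
    seed: int, n_frames: int = 500, grid_size: int = 128, oversample: int = 5
) -> SimulationConfig:
    """Flat-field acquisition for fill-factor calibration.

    The detector integrates over the active pixel area on an oversampled
    grid (5 x 5 sub-samples per pixel by default) so the fill-factor
    attenuation enters through actual spatial integration, not through the
    analytic MTF being fitted.
    """
    return SimulationConfig(
        grid_size=grid_size,
        oversample_factor=oversample,
        carrier_offset=_carrier(grid_size),
        aperture_radius_freq=_radius(grid_size),
        correlation_time_s=1e-3,
        detuning_list_hz=(0.0,),
        exposure_time_s=1e-3,
        frame_period_s=1e-3,
        substeps_per_exposure=2,
        reference_photoelectrons_per_pixel=5000.0,
        sample_to_reference_ratio=0.02,
        fill_factor=0.72,
        n_frames=n_frames,
        rng_seed=seed,
        speckle_area_px=1.0,
        pixel_integration="oversample",
    )


def tauc_recovery_scenario(
    seed: int,
    tauc_s: float = 1e-3,
    n_frames: int = 500,
    grid_size: int = 64,
    detunings_hz: tuple[float, ...] = (0.0, 50.0, 100.0, 200.0, 400.0, 800.0),
) -> SimulationConfig:
    """Multi-detuning acquisition for correlation-time recovery.

    The 5 ms exposure spans five correlation times so the sampled PSD is
    close to the true Lorentzian (the residual triangular-window bias is
    removed by fitting the exposure-windowed model).
    """
    return SimulationConfig(
        grid_size=grid_size,
        carrier_offset=_carrier(grid_size),
        aperture_radius_freq=_radius(grid_size),
        correlation_time_s=tauc_s,
        detuning_list_hz=detunings_hz,
        exposure_time_s=5e-3,
        frame_period_s=10e-3,
        substeps_per_exposure=32,
        reference_photoelectrons_per_pixel=5000.0,
        sample_to_reference_ratio=0.02,
        fill_factor=0.0,
        n_frames=n_frames,
        rng_seed=seed,
        pixel_integration="fourier",
    )


def small_dynamic_scenario(
    seed: int,
    n_frames: int = 60,
    grid_size: int = 64,
    detuning_hz: float = 200.0,
    **overrides,
) -> SimulationConfig:
    """Small generic dynamic-speckle acquisition for unit tests."""
    cfg = SimulationConfig(
        grid_size=grid_size,
        carrier_offset=_carrier(grid_size),
        aperture_radius_freq=_radius(grid_size),
        correlation_time_s=1e-3,
        detuning_list_hz=(detuning_hz,),
        exposure_time_s=1e-3,
        frame_period_s=2e-3,
        substeps_per_exposure=2,
        reference_photoelectrons_per_pixel=5000.0,
        sample_to_reference_ratio=0.02,
        fill_factor=0.0,
        n_frames=n_frames,
        rng_seed=seed,
        pixel_integration="fourier",
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def mode_hop_scenario(seed: int, n_frames: int = 250, grid_size: int = 64) -> SimulationConfig:
    """Fast-decorrelating acquisition used for mode-hop signature studies."""
    return small_dynamic_scenario(
        seed,
        n_frames=n_frames,
        grid_size=grid_size,
        detuning_hz=0.0,
        correlation_time_s=1e-3,
        frame_period_s=5e-3,
        substeps_per_exposure=4,
    )
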