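"""Miniature named scenarios with machine-readable expectations.

Each fixture is a small (64 x 64, <= 50 frames) synthetic acquisition built
for a specific property: flat-field fill factor, mode hopping, injected beat
clutter, shot-noise-only, or a known correlation time.  The expectation
dictionary states what a correct analysis should find, so test suites and
demos can consume fixtures without re-deriving the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .scenarios import scaled_mask_geometry, small_dynamic_scenario
from .simulator import FrameStack, GroundTruth, SimulationConfig, simulate

__all__ = ["Fixture", "fixture_generator", "FIXTURE_SCENARIOS"]

FIXTURE_SCENARIOS = (
    "flat_field_alpha",
    "mode_hop",
    "beat_clutter",
    "shot_noise_only",
    "known_tauc",
)


@dataclass
class Fixture:
    stacks: dict[float, FrameStack]
    ground_truth: GroundTruth
    config: SimulationConfig
    expectations: dict


def fixture_generator(scenario: str, seed: int) -> Fixture:
    """Generate one miniature scenario stack plus its expectation record."""
    if scenario == "flat_field_alpha":
        cfg = small_dynamic_scenario(
            seed, n_frames=50, detuning_hz=0.0,
            oversample_factor=5, pixel_integration="oversample",
            fill_factor=0.72, frame_period_s=1e-3,
        )
        result = simulate(cfg)
        expect = {"alpha_true": 0.72, "alpha_tolerance": 0.15, "note": "few frames: loose tolerance"}
    elif scenario == "mode_hop":
        cfg = small_dynamic_scenario(
            seed, n_frames=50, detuning_hz=0.0, frame_period_s=5e-3,
            substeps_per_exposure=4,
        )
        hop = 25
        result = simulate(cfg, hop_frames=[hop])
        expect = {
            "hop_frame": hop,
            "dc_pair_outlier_pairs": [hop - 1, hop],
            "signature": "negative-going S1 outlier under dc_pair; intensity step under first_frame",
        }
    elif scenario == "beat_clutter":
        cfg = small_dynamic_scenario(seed, n_frames=50, detuning_hz=0.0)
        t = np.arange(cfg.n_frames)
        waveform = 0.05 * np.sin(2 * np.pi * 0.19 * t)
        result = simulate(cfg, clutter_waveform=waveform)
        expect = {
            "waveform_amplitude": 0.05,
            "declutter_nc": 2,
            "raw_correlation_min": 0.9,
            # the residual correlation floor is ~1/sqrt(n_frames); at full
            # length (hundreds of frames) it drops below 0.05
            "max_abs_residual_correlation": 3.0 / np.sqrt(cfg.n_frames),
        }
    elif scenario == "shot_noise_only":
        cfg = small_dynamic_scenario(seed, n_frames=50, sample_to_reference_ratio=0.0)
        result = simulate(cfg)
        expect = {"s1_bar_abs_limit": "3 standard errors of the mask mean", "s1_true": 0.0}
    elif scenario == "known_tauc":
        cfg = small_dynamic_scenario(
            seed, n_frames=50,
            correlation_time_s=1e-3,
            detuning_list_hz=(0.0, 100.0, 300.0, 800.0),
            exposure_time_s=4e-3, frame_period_s=8e-3, substeps_per_exposure=32,
            detuning_hz=None,
        )
        result = simulate(cfg)
        expect = {"tauc_true_s": 1e-3, "tauc_tolerance_rel": 0.15, "note": "few frames: loose tolerance"}
    else:
        raise ConfigurationError(f"unknown fixture scenario {scenario!r}")
    return Fixture(
        stacks=result.stacks,
        ground_truth=result.ground_truth,
        config=cfg,
        expectations=expect,
    )
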