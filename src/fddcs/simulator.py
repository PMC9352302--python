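"""Synthetic off-axis heterodyne dynamic-speckle hologram stacks.

The simulator emulates a lensless Fourier-geometry interferometer: a dynamic
speckle field from the sample interferes on the camera with a strong,
frequency-shifted, spatially uniform reference beam.  Rather than propagating
light from a physical collection aperture, the sample field is synthesised
directly in the camera's spatial-frequency domain — circular-complex-Gaussian
modes on a disc of radius ``aperture_radius_freq`` centred at
``carrier_offset`` — which reproduces the reconstruction statistics of the
off-axis geometry exactly.  Each mode evolves in time as a first-order
autoregressive process whose autocorrelation matches the configured field
autocorrelation g1 sampled at the substep interval.

Detection integrates the beat over a finite exposure (several substeps per
exposure), averages the intensity over the active fraction of each pixel
(fill factor), and applies Poisson shot noise, Gaussian read noise and ADC
quantisation.

Optionally the reconstruction-plane speckle field can be given a coherence
area larger than one bin (``speckle_area_px``): each resolvable speckle then
occupies that many reconstruction pixels, so a signal mask of ``M`` pixels
detects ``M / speckle_area_px`` speckles — the quantity that the square-root
SNR scaling law counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import AliasingError, ConfigurationError

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "FieldStack",
    "FrameStack",
    "SimulationResult",
    "register_g1_model",
    "make_field_stack",
    "detector_integrate",
    "inject_mode_hops",
    "inject_global_clutter",
    "simulate",
]

# ---------------------------------------------------------------------------
# g1 models

_G1_MODELS: dict[str, Callable[[np.ndarray, float], np.ndarray]] = {}


def register_g1_model(name: str, g1: Callable[[np.ndarray, float], np.ndarray]) -> None:
    """Register a field-autocorrelation model ``g1(tau, correlation_time)``.

    The built-in ``"exponential"`` model is ``exp(-|tau| / tau_c)``; plug-ins
    are mapped to per-step AR coefficients ``g1(dt) / g1(0)`` (exact for the
    exponential model, a first-order surrogate otherwise).
    """
    _G1_MODELS[name] = g1


register_g1_model("exponential", lambda tau, tc: np.exp(-np.abs(tau) / tc))


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class SimulationConfig:
    """Instrument and phantom description for one simulated acquisition.

    Times are seconds, photon quantities are photoelectrons.
    ``reference_photoelectrons_per_pixel`` is the expected reference count per
    pixel integrated over one exposure; ``sample_to_reference_ratio`` scales
    the sensor-mean sample intensity relative to the reference.
    """

    grid_size: int = 512
    oversample_factor: int = 1
    carrier_offset: tuple[int, int] = (170, 170)
    aperture_radius_freq: float = 80.0
    g1_model: str = "exponential"
    correlation_time_s: float = 1e-3
    detuning_list_hz: tuple[float, ...] = (1000.0,)
    exposure_time_s: float = 1e-3
    frame_period_s: Optional[float] = None
    substeps_per_exposure: int = 8
    reference_photoelectrons_per_pixel: float = 5000.0
    sample_to_reference_ratio: float = 0.02
    fill_factor: float = 0.72
    read_noise_e: float = 2.45
    quantisation_gain_e: float = 5.73
    bit_depth: int = 12
    n_frames: int = 501
    rng_seed: int = 0
    speckle_area_px: float = 1.0
    pixel_integration: str = "fourier"  # "fourier" (exact, band-limited) or "oversample"
    shot_noise: bool = True
    quantise: bool = True
    hop_reference_step: float = 1.01

    @property
    def frame_period(self) -> float:
        return self.exposure_time_s if self.frame_period_s is None else self.frame_period_s

    @property
    def substep_dt(self) -> float:
        return self.exposure_time_s / self.substeps_per_exposure

    def validate(self) -> None:
        n = self.grid_size
        cx, cy = self.carrier_offset
        r = self.aperture_radius_freq
        if self.oversample_factor < 1:
            raise ConfigurationError("oversample_factor must be >= 1")
        if not 0.0 <= self.fill_factor <= 1.0:
            raise ConfigurationError("fill_factor must be in [0, 1]")
        for name in ("exposure_time_s", "reference_photoelectrons_per_pixel", "quantisation_gain_e"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.correlation_time_s <= 0:
            raise ConfigurationError("correlation_time_s must be > 0 (use np.inf for static)")
        if self.frame_period < self.exposure_time_s:
            raise ConfigurationError("frame_period_s must be >= exposure_time_s")
        if self.g1_model not in _G1_MODELS:
            raise ConfigurationError(f"unknown g1 model {self.g1_model!r}")
        half = n // 2
        if max(abs(cx), abs(cy)) + r > half - 1:
            raise ConfigurationError("carrier offset plus aperture radius leaves the Nyquist quadrant")
        if np.hypot(cx, cy) <= 2 * r:
            raise ConfigurationError(
                "twin heterodyne bands overlap each other or the DC/autocorrelation term"
            )
        if self.pixel_integration not in ("fourier", "oversample"):
            raise ConfigurationError("pixel_integration must be 'fourier' or 'oversample'")
        if self.pixel_integration == "fourier" and self.oversample_factor != 1:
            raise ConfigurationError("the Fourier pixel-integration path runs on the camera grid")
        # temporal resolution: heterodyne beat within an exposure, and field decorrelation
        max_dw = 2 * np.pi * max((abs(f) for f in self.detuning_list_hz), default=0.0)
        if max_dw * self.exposure_time_s / self.substeps_per_exposure > np.pi / 4:
            raise AliasingError(
                "heterodyne beat is unresolved within the exposure: "
                "increase substeps_per_exposure or shorten the exposure"
            )
        if np.isfinite(self.correlation_time_s) and self.correlation_time_s < 2 * self.substep_dt:
            raise AliasingError(
                "correlation time shorter than twice the substep interval aliases the dynamics"
            )

    def envelope_sigma(self) -> Optional[float]:
        """Std dev (camera px) of the Gaussian field envelope implementing
        ``speckle_area_px``; ``None`` means a uniform envelope (one-bin speckles)."""
        if self.speckle_area_px <= 1.0:
            return None
        return _envelope_sigma(self.grid_size, self.speckle_area_px)


def _coherence_area(n: int, sigma: float) -> float:
    """Reconstruction-plane coherence area (bins) of a disc-band speckle field
    whose camera-plane amplitude envelope is exp(-|x|^2 / (4 sigma^2))."""
    x = np.arange(n) - n / 2 + 0.5
    h2 = np.exp(-(x**2) / (2 * sigma**2))
    s2 = h2.sum() ** 2        # separable: sum of |h|^2 over the plane, squared
    s4 = (h2**2).sum() ** 2
    return n**2 * s4 / s2**2


def _envelope_sigma(n: int, area_px: float) -> float:
    lo, hi = 2.0, 50.0 * n
    if _coherence_area(n, lo) < area_px:
        raise ConfigurationError(f"speckle_area_px={area_px} too large for grid size {n}")
    return brentq(lambda s: _coherence_area(n, s) - area_px, lo, hi, xtol=1e-6)


@dataclass
class GroundTruth:
    """What the generator actually put into a stack, for recovery tests."""

    correlation_time_s: float
    fill_factor: float
    speckle_area_px: float
    hop_frames: tuple[int, ...] = ()
    clutter_waveform: Optional[np.ndarray] = None
    n_frames: int = 0

    def expected_speckle_count(self, n_mask_pixels: int) -> float:
        return n_mask_pixels / self.speckle_area_px


# ---------------------------------------------------------------------------
# Field synthesis


@dataclass
class FieldStack:
    """Lazily evaluated time-resolved sample field on the camera grid.

    Frames are generated on demand (one exposure at a time) so that
    paper-scale stacks never hold the full complex field in memory.  All
    randomness derives from ``config.rng_seed``; identical configurations
    reproduce identical fields bit for bit.
    """

    config: SimulationConfig
    hop_frames: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.config.validate()
        for f in self.hop_frames:
            if not 0 < f < self.config.n_frames:
                raise ConfigurationError(f"hop frame {f} outside 1..{self.config.n_frames - 1}")

    @property
    def fine_grid_size(self) -> int:
        return self.config.grid_size * self.config.oversample_factor

    def reference_scale(self) -> np.ndarray:
        """Per-frame multiplicative reference-power factor (mode hops shift
        the laser to a mode with slightly different output power)."""
        scale = np.ones(self.config.n_frames)
        for f in self.hop_frames:
            scale[f:] *= self.config.hop_reference_step
        return scale

    def _mode_layout(self) -> tuple[np.ndarray, int]:
        cfg = self.config
        nf = self.fine_grid_size
        cx, cy = cfg.carrier_offset
        r = cfg.aperture_radius_freq
        rr = int(np.floor(r))
        xs = np.arange(cx - rr, cx + rr + 1)
        ys = np.arange(cy - rr, cy + rr + 1)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        keep = (gx - cx) ** 2 + (gy - cy) ** 2 <= r**2
        # frequencies in cycles per camera frame are grid-size independent,
        # so mode bins keep their signed indices on the oversampled grid
        flat = (gx[keep] % nf) * nf + (gy[keep] % nf)
        return flat, int(keep.sum())

    def _envelope(self) -> Optional[np.ndarray]:
        sigma = self.config.envelope_sigma()
        if sigma is None:
            return None
        nf = self.fine_grid_size
        os = self.config.oversample_factor
        x = ((np.arange(nf) + 0.5) / os) - self.config.grid_size / 2
        h = np.exp(-(x**2) / (4 * sigma**2))
        return np.outer(h, h)

    def iter_frames(self, detuning_hz: float, stream: int = 0) -> Iterator[np.ndarray]:
        """Yield, per frame, the complex sample field at each substep,
        shape ``(substeps, n_fine, n_fine)``, in units such that the mean of
        ``|E|^2`` over the sensor is the sample photoelectron rate per camera
        pixel per substep."""
        cfg = self.config
        nf = self.fine_grid_size
        rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 7, stream]))
        flat, n_modes = self._mode_layout()
        env = self._envelope()
        g1 = _G1_MODELS[cfg.g1_model]

        def ar_coeff(dt: float) -> float:
            if not np.isfinite(cfg.correlation_time_s):
                return 1.0
            g0 = float(g1(np.asarray(0.0), cfg.correlation_time_s))
            return float(np.clip(g1(np.asarray(dt), cfg.correlation_time_s) / g0, 0.0, 1.0))

        dt = cfg.substep_dt
        rho_step = ar_coeff(dt)
        rho_gap = ar_coeff(cfg.frame_period - cfg.exposure_time_s + dt)
        innov_step = np.sqrt(max(0.0, 1.0 - rho_step**2))
        innov_gap = np.sqrt(max(0.0, 1.0 - rho_gap**2))

        def draw_modes() -> np.ndarray:
            return (rng.standard_normal(n_modes) + 1j * rng.standard_normal(n_modes)) / np.sqrt(2)

        # scale so that the sensor-mean of |E|^2 equals the target rate
        var_e0 = n_modes / nf**4  # per-pixel variance of ifft2 of unit modes
        mean_env2 = 1.0 if env is None else float((env**2).mean())
        target = cfg.sample_to_reference_ratio * cfg.reference_photoelectrons_per_pixel / cfg.substeps_per_exposure
        amp = np.sqrt(target / (var_e0 * mean_env2)) if target > 0 else 0.0

        modes = draw_modes()
        hops = set(self.hop_frames)
        grid = np.zeros((nf, nf), dtype=np.complex128)
        for f in range(cfg.n_frames):
            if f in hops:
                # new laser mode: fresh speckle state with an independent phase
                modes = draw_modes()
            washed = f in hops
            out = np.empty((cfg.substeps_per_exposure, nf, nf), dtype=np.complex128)
            for j in range(cfg.substeps_per_exposure):
                if f > 0 or j > 0:
                    rho, innov = (rho_gap, innov_gap) if j == 0 else (rho_step, innov_step)
                    modes = rho * modes + innov * draw_modes()
                grid.ravel()[flat] = modes
                e = np.fft.ifft2(grid)
                if env is not None:
                    e *= env
                if washed:
                    # during the hop exposure the reference and sample arms
                    # lose mutual coherence: independent global phase history
                    e = e * np.exp(2j * np.pi * rng.random())
                out[j] = amp * e
            yield out

    def materialize(self, detuning_hz: float = 0.0) -> np.ndarray:
        """Full field stack (n_frames, substeps, n, n); small grids only."""
        return np.stack(list(self.iter_frames(detuning_hz)))


def make_field_stack(config: SimulationConfig) -> FieldStack:
    """Validate the configuration and return a (lazy) sample-field stack."""
    return FieldStack(config=config)


def inject_mode_hops(field_stack: FieldStack, hop_frames: Sequence[int]) -> FieldStack:
    """Return a field stack in which the laser mode hops before each listed frame.

    A hop redraws every mode (new speckle state, independent global phase),
    destroys reference–sample mutual coherence for the remainder of the hop
    frame's exposure, and steps the reference power by ``hop_reference_step``.
    With no hop frames the stack is returned unchanged.
    """
    if not hop_frames:
        return field_stack
    hops = tuple(sorted(set(int(f) for f in hop_frames)))
    return replace(field_stack, hop_frames=hops)


# ---------------------------------------------------------------------------
# Detection


@dataclass
class FrameStack:
    """Raw camera frames in detector counts, plus acquisition metadata."""

    frames: np.ndarray  # (n_frames, N, N), uint16 when quantised
    detuning_hz: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_size(self) -> int:
        return self.frames.shape[1]


def _pixel_weights(os: int, alpha: float) -> np.ndarray:
    """Area weights of the ``os`` sub-samples covered by the active width
    ``alpha * os``, centred in the pixel; fractional boundary sub-samples are
    weighted by their covered fraction."""
    a = alpha * os
    lo, hi = (os - a) / 2, (os + a) / 2
    edges_lo = np.arange(os)
    w = np.clip(np.minimum(hi, edges_lo + 1) - np.maximum(lo, edges_lo), 0.0, 1.0)
    return w / w.sum()


def _integrate_pixels(intensity: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    n, os = cfg.grid_size, cfg.oversample_factor
    if cfg.pixel_integration == "fourier":
        if cfg.fill_factor == 0.0:
            return intensity
        u = np.fft.fftfreq(n)
        tx = np.sinc(cfg.fill_factor * u)
        spec = np.fft.rfft2(intensity)
        spec *= tx[:, None]
        spec *= np.sinc(cfg.fill_factor * np.fft.rfftfreq(n))[None, :]
        return np.fft.irfft2(spec, s=(n, n))
    if cfg.fill_factor == 0.0:
        warnings.warn("fill_factor = 0: degenerate point sampling at pixel centres")
        mid = os // 2
        return intensity[mid::os, mid::os]
    w = _pixel_weights(os, cfg.fill_factor)
    shaped = intensity.reshape(n, os, n, os)
    return np.einsum("iajb,a,b->ij", shaped, w, w, optimize=True)


def detector_integrate(
    field_stack: FieldStack,
    config: Optional[SimulationConfig] = None,
    detuning_hz: float = 0.0,
    stream: int = 0,
) -> FrameStack:
    """Expose, pixel-integrate, and digitise a field stack into camera counts.

    Per substep the intensity is ``|R exp(i dw t) + E|^2`` with a uniform
    reference amplitude ``R``; intensities are summed over the exposure,
    averaged over the active pixel area, converted to photoelectrons, Poisson
    sampled, read noise added, divided by the quantisation gain, floored and
    clipped to the bit depth.
    """
    cfg = config or field_stack.config
    n = cfg.grid_size
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 13, stream]))
    r_amp0 = np.sqrt(cfg.reference_photoelectrons_per_pixel / cfg.substeps_per_exposure)
    dw = 2 * np.pi * detuning_hz
    ref_scale = field_stack.reference_scale()
    max_count = 2**cfg.bit_depth - 1

    frames = np.empty(
        (cfg.n_frames, n, n), dtype=np.uint16 if cfg.quantise else np.float64
    )
    saturated = 0
    for f, substeps in enumerate(field_stack.iter_frames(detuning_hz, stream=stream)):
        r_amp = r_amp0 * np.sqrt(ref_scale[f])
        acc = np.zeros((field_stack.fine_grid_size,) * 2)
        for j, e in enumerate(substeps):
            t = f * cfg.frame_period + (j + 0.5) * cfg.substep_dt
            ref = r_amp * np.exp(1j * dw * t)
            acc += np.abs(ref + e) ** 2
        pe = _integrate_pixels(acc, cfg)
        if cfg.shot_noise:
            pe = rng.poisson(np.clip(pe, 0, None)).astype(np.float64)
        if cfg.read_noise_e > 0:
            pe = pe + rng.normal(0.0, cfg.read_noise_e, size=pe.shape)
        counts = pe / cfg.quantisation_gain_e
        if cfg.quantise:
            counts = np.clip(np.floor(counts), 0, max_count)
            saturated += int((counts == max_count).sum())
            frames[f] = counts.astype(np.uint16)
        else:
            frames[f] = counts
    if saturated > 0.01 * frames.size:
        warnings.warn(
            f"{saturated / frames.size:.1%} of pixels saturated the {cfg.bit_depth}-bit ADC"
        )
    meta = {
        "seed": cfg.rng_seed,
        "alpha": cfg.fill_factor,
        "tauc": cfg.correlation_time_s,
        "detuning": detuning_hz,
        "gain": cfg.quantisation_gain_e,
        "read_noise": cfg.read_noise_e,
        "exposure": cfg.exposure_time_s,
        "frame_period": cfg.frame_period,
        "hop_frames": ",".join(str(h) for h in field_stack.hop_frames),
    }
    return FrameStack(frames=frames, detuning_hz=detuning_hz, metadata=meta)


def inject_global_clutter(frame_stack: FrameStack, waveform: np.ndarray) -> FrameStack:
    """Multiply each frame by ``1 + waveform[t]`` (laser power modulation).

    Models spatiotemporally correlated clutter such as beat notes or slow
    drifts of the source power.  ``|waveform| >= 1`` would produce negative
    intensities and is rejected.
    """
    w = np.asarray(waveform, dtype=np.float64)
    if w.shape != (frame_stack.n_frames,):
        raise ConfigurationError("waveform length must equal the number of frames")
    if np.any(np.abs(w) >= 1.0):
        raise ConfigurationError("clutter waveform magnitude must be < 1")
    if not np.any(w):
        return frame_stack
    scaled = frame_stack.frames.astype(np.float64) * (1.0 + w)[:, None, None]
    if frame_stack.frames.dtype == np.uint16:
        scaled = np.clip(np.rint(scaled), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    meta = dict(frame_stack.metadata)
    meta["clutter"] = "global"
    return FrameStack(frames=scaled, detuning_hz=frame_stack.detuning_hz, metadata=meta)


# ---------------------------------------------------------------------------
# One-call front end


@dataclass
class SimulationResult:
    stacks: dict[float, FrameStack]
    ground_truth: GroundTruth


def simulate(
    config: SimulationConfig,
    hop_frames: Sequence[int] = (),
    clutter_waveform: Optional[np.ndarray] = None,
) -> SimulationResult:
    """Simulate one frame stack per configured detuning frequency."""
    fields = inject_mode_hops(make_field_stack(config), hop_frames)
    stacks: dict[float, FrameStack] = {}
    for i, det in enumerate(config.detuning_list_hz):
        stack = detector_integrate(fields, config, detuning_hz=det, stream=i)
        if clutter_waveform is not None:
            stack = inject_global_clutter(stack, clutter_waveform)
        stacks[det] = stack
    truth = GroundTruth(
        correlation_time_s=config.correlation_time_s,
        fill_factor=config.fill_factor,
        speckle_area_px=config.speckle_area_px,
        hop_frames=tuple(fields.hop_frames),
        clutter_waveform=None if clutter_waveform is None else np.asarray(clutter_waveform),
        n_frames=config.n_frames,
    )
    return SimulationResult(stacks=stacks, ground_truth=truth)
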