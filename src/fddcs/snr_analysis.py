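"""SNR, SNR gain, and speckle-count analysis of S1 measurements.

The SNR of a series of per-frame S1 averages is the ratio of its mean to its
sample standard deviation.  For a speckle-averaging detector free of
instrumental noise, the SNR grows as the square root of the number of
independent speckles inside the signal mask; the number of speckles is the
mask pixel count divided by the speckle area

    S = (lambda z)^2 / A_aperture

expressed in camera pixels.  The SNR gain of a multispeckle measurement is
its SNR divided by the SNR of a single-speckle measurement processed the same
way at the same detuning frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, UndefinedSNRError
from .reconstruction import MaskSet, ReconstructionResult

__all__ = [
    "SpeckleGeometry",
    "SNRCurve",
    "GainCurve",
    "snr",
    "speckle_area",
    "mask_radius_sweep",
    "snr_gain",
    "loglog_slope",
]


@dataclass
class SpeckleGeometry:
    """Optical geometry that sets the speckle area on the sensor."""

    wavelength_m: float
    distance_m: float
    aperture_area_m2: float
    pixel_pitch_m: float

    def __post_init__(self) -> None:
        for name in ("wavelength_m", "distance_m", "aperture_area_m2", "pixel_pitch_m"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    @classmethod
    def circular_aperture(
        cls, wavelength_m: float, distance_m: float, aperture_diameter_m: float, pixel_pitch_m: float
    ) -> "SpeckleGeometry":
        area = np.pi * (aperture_diameter_m / 2) ** 2
        return cls(wavelength_m, distance_m, area, pixel_pitch_m)

    @property
    def speckle_area_m2(self) -> float:
        return (self.wavelength_m * self.distance_m) ** 2 / self.aperture_area_m2


def speckle_area(geometry: SpeckleGeometry) -> float:
    """Speckle area on the sensor in camera pixels: (lambda z)^2 / (A * dx^2)."""
    return geometry.speckle_area_m2 / geometry.pixel_pitch_m**2


def snr(series: Sequence[float]) -> float:
    """Mean over sample standard deviation (N-1 denominator) of an S1 series."""
    x = np.asarray(series, dtype=np.float64)
    if x.size < 3:
        raise UndefinedSNRError(f"need at least 3 repeats, got {x.size}")
    s = x.std(ddof=1)
    if s == 0:
        raise UndefinedSNRError("zero spread: SNR undefined")
    return float(x.mean() / s)


@dataclass
class SNRCurve:
    """SNR versus concentric mask radius (NaN where SNR is undefined)."""

    radii: np.ndarray
    n_pixels: np.ndarray
    n_speckles: np.ndarray
    snr: np.ndarray
    n_repeats: int
    detuning_hz: Optional[float] = None


@dataclass
class GainCurve:
    """SNR gain relative to a single-speckle measurement."""

    radii: np.ndarray
    n_speckles: np.ndarray
    gain: np.ndarray
    snr_single: float
    reference_radius: float
    reference_pixels: int
    normalized_reference: bool


def _s1_matrix(data: ReconstructionResult | np.ndarray) -> tuple[np.ndarray, MaskSet | None]:
    if isinstance(data, ReconstructionResult):
        return data.s1_pixels, data.mask_set
    return np.asarray(data, dtype=np.float64), None


def mask_radius_sweep(
    data: ReconstructionResult | np.ndarray,
    radii: Sequence[float],
    speckle_px: float,
    mask_set: Optional[MaskSet] = None,
    detuning_hz: Optional[float] = None,
) -> SNRCurve:
    """Recompute per-frame S1 averages over concentric reduced masks.

    ``data`` is a reconstruction result (or its (n_px, n_frames) S1 matrix
    with ``mask_set`` given).  Reduced masks are concentric with the full
    heterodyne mask; for each radius the per-frame S1 average over the
    reduced mask gives one SNR value and a real-valued speckle count
    ``n_pixels / speckle_px``.
    """
    s1, ms = _s1_matrix(data)
    ms = ms or mask_set
    if ms is None:
        raise ConfigurationError("a MaskSet is required to order pixels radially")
    radii = np.asarray(sorted(float(r) for r in radii))
    if radii.size == 0 or np.any(np.diff(radii) <= 0):
        raise ConfigurationError("radii must be strictly increasing and non-empty")
    if radii[-1] > ms.geometry.radius:
        raise ConfigurationError("requested radius exceeds the recorded mask")
    order, dist = ms.plus_radial_order()
    # prefix sums over radially ordered pixels -> every concentric sub-mask mean
    csum = np.cumsum(s1[order, :], axis=0)
    counts = np.searchsorted(dist, radii, side="right")
    out_snr = np.full(radii.size, np.nan)
    n_frames = s1.shape[1]
    for i, c in enumerate(counts):
        if c == 0:
            continue
        series = csum[c - 1, :] / c
        try:
            out_snr[i] = snr(series)
        except UndefinedSNRError:
            out_snr[i] = np.nan
    return SNRCurve(
        radii=radii,
        n_pixels=counts,
        n_speckles=counts / speckle_px,
        snr=out_snr,
        n_repeats=n_frames,
        detuning_hz=detuning_hz,
    )


def snr_gain(
    curve: SNRCurve,
    speckle_px: float,
    normalize_reference: bool = True,
    max_reference_speckles: Optional[float] = None,
) -> GainCurve:
    """SNR gain of every mask radius relative to single-speckle detection.

    The reference is the smallest concentric mask whose pixel count reaches
    one speckle area.  Because lattice discs cannot hit one speckle area
    exactly (the smallest disc at or above 15.57 px holds 21 px), the
    reference SNR is by default rescaled to exactly one speckle using the
    square-root speckle-statistics law, i.e.
    ``snr_single = snr_ref / sqrt(n_speckles_ref)``.  Passing
    ``max_reference_speckles`` pools every mask containing at most that many
    speckles into the reference (each scaled to one speckle and averaged),
    which reduces the Monte-Carlo noise of the single-speckle estimate.  Set
    ``normalize_reference=False`` for the plain ratio against the smallest
    reference mask (whose own gain is then 1 by construction).
    """
    valid = (curve.n_pixels >= speckle_px) & np.isfinite(curve.snr)
    if not np.any(valid):
        raise ConfigurationError("no mask radius reaches one speckle area: missing reference")
    ref = int(np.argmax(valid))
    if not normalize_reference:
        snr_single = float(curve.snr[ref])
    elif max_reference_speckles is not None:
        pool = valid & (curve.n_speckles <= max_reference_speckles)
        if not np.any(pool):
            raise ConfigurationError("no mask small enough for the reference pool")
        snr_single = float(np.mean(curve.snr[pool] / np.sqrt(curve.n_speckles[pool])))
    else:
        snr_single = float(curve.snr[ref]) / np.sqrt(float(curve.n_speckles[ref]))
    return GainCurve(
        radii=curve.radii,
        n_speckles=curve.n_speckles,
        gain=curve.snr / snr_single,
        snr_single=snr_single,
        reference_radius=float(curve.radii[ref]),
        reference_pixels=int(curve.n_pixels[ref]),
        normalized_reference=normalize_reference,
    )


def loglog_slope(curve: SNRCurve, min_speckles: float = 1.0) -> float:
    """Slope of log SNR versus log N_speckles (0.5 for ideal speckle averaging)."""
    keep = np.isfinite(curve.snr) & (curve.snr > 0) & (curve.n_speckles >= min_speckles)
    if keep.sum() < 3:
        raise ConfigurationError("need at least 3 valid points for a slope")
    return float(np.polyfit(np.log(curve.n_speckles[keep]), np.log(curve.snr[keep]), 1)[0])
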