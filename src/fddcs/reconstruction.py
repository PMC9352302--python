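"""Holographic reconstruction of shot-noise-normalised power spectral densities.

A camera-plane hologram ``H_C`` is formed from raw interferogram frames by a
temporal filter (successive-pair difference, first-frame subtraction, or no
filter at all).  The image-plane intensity hologram is the squared magnitude of
its unnormalised 2-D DFT,

    H_R = |F_2D(H_C)|^2 ,

with the zero-frequency bin shifted to the grid centre.  Off-axis recombination
separates the two heterodyne twin images (a conjugate pair) from the DC and
sample-autocorrelation terms, so a circular mask over each twin image and a
third mask in a quiet corner (pure shot noise) turn ``H_R`` into a normalised,
unitless PSD sample:

    S1 = H_R / N_bar - 1 ,

optionally divided per pixel by the camera MTF ``|sinc(a u) sinc(a v)|^2``
(fill factor ``a``) before averaging over each twin mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

from .errors import ConfigurationError, DegenerateInputError, MaskError

__all__ = [
    "HologramStack",
    "MaskGeometry",
    "MaskSet",
    "MTFMap",
    "ReconstructionResult",
    "temporal_filter",
    "reconstruct",
    "mtf_map",
    "build_masks",
    "normalize_s1",
    "reconstruct_and_normalize",
]

FILTER_MODES = ("dc_pair", "first_frame", "single_frame")


@dataclass
class HologramStack:
    """Temporally filtered camera-plane holograms (signed, real)."""

    frames: np.ndarray  # (n_holograms, N, N)
    filter_mode: str
    source_indices: list[tuple[int, ...]] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_size(self) -> int:
        return self.frames.shape[1]


def temporal_filter(frames: np.ndarray, mode: str) -> HologramStack:
    """High-pass filter a raw frame stack in time.

    ``dc_pair``      H_C[n] = I_n - I_{n+1}   (sliding successive pairs, N-1 out)
    ``first_frame``  H_C[n] = I_{n+1} - I_1   (N-1 outputs)
    ``single_frame`` H_C[n] = I_n             (no filtering, N outputs)
    """
    if mode not in FILTER_MODES:
        raise ConfigurationError(f"unknown temporal filter mode {mode!r}")
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ConfigurationError("frame stack must be 3-D (n_frames, ny, nx)")
    n = frames.shape[0]
    need = 1 if mode == "single_frame" else 2
    if n < need:
        raise ConfigurationError(f"{mode} needs at least {need} frames, got {n}")
    work = frames.astype(np.float64, copy=False)
    if mode == "dc_pair":
        out = work[:-1] - work[1:]
        src = [(i, i + 1) for i in range(n - 1)]
    elif mode == "first_frame":
        out = work[1:] - work[0]
        src = [(i + 1, 0) for i in range(n - 1)]
    else:
        out = work.copy()
        src = [(i,) for i in range(n)]
    return HologramStack(frames=out, filter_mode=mode, source_indices=src)


def _reconstruct_frame(hc: np.ndarray) -> np.ndarray:
    """|unnormalised 2-D DFT|^2 of one hologram, zero frequency at the centre."""
    return np.fft.fftshift(np.abs(np.fft.fft2(hc)) ** 2)


def reconstruct(holograms: HologramStack | np.ndarray) -> np.ndarray:
    """Reconstruct intensity holograms H_R = |F_2D(H_C)|^2 for a whole stack.

    Uses the forward unnormalised transform, so Parseval's identity reads
    ``H_R.sum() == N_pix * (H_C ** 2).sum()`` per frame.
    """
    frames = holograms.frames if isinstance(holograms, HologramStack) else np.asarray(holograms)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[1] != frames.shape[2]:
        raise ConfigurationError("holograms must be square")
    if not np.all(np.isfinite(frames)):
        raise ConfigurationError("holograms contain non-finite values")
    return np.stack([_reconstruct_frame(f) for f in frames])


# ---------------------------------------------------------------------------
# MTF


@dataclass
class MTFMap:
    """Camera MTF sampled on the shifted reconstruction grid.

    ``values[i, j] = |sinc(a*u) sinc(a*v)|^2`` with ``(u, v)`` running linearly
    over [-0.5, 0.5) across the grid (units of pixel pitch times spatial
    frequency).  Equal to 1 at the origin; strictly positive everywhere for
    fill factors in [0, 1].
    """

    values: np.ndarray
    alpha: float
    pixel_pitch: tuple[float, float] = (1.0, 1.0)

    @property
    def grid_size(self) -> int:
        return self.values.shape[0]


def mtf_map(alpha: float, grid_size: int, pixel_pitch: tuple[float, float] = (1.0, 1.0)) -> MTFMap:
    """Build the pixel fill-factor MTF map for an ``grid_size``-pixel sensor."""
    if not 0.0 <= alpha <= 1.0:
        raise ConfigurationError(f"fill factor must be in [0, 1], got {alpha}")
    n = int(grid_size)
    u = _shifted_coords(n) / n  # in [-0.5, 0.5)
    m1d = np.sinc(alpha * u) ** 2
    return MTFMap(values=np.outer(m1d, m1d), alpha=float(alpha), pixel_pitch=pixel_pitch)


def _shifted_coords(n: int) -> np.ndarray:
    """Shifted-frequency integer coordinates along one axis (DC at index n//2)."""
    return np.arange(n) - n // 2


# ---------------------------------------------------------------------------
# Masks


@dataclass
class MaskGeometry:
    """Circular mask layout in shifted frequency coordinates.

    ``plus_center`` locates the +detuning twin image; the -detuning mask is its
    exact point reflection through the origin.  ``shot_center`` must sit in a
    quiet corner that receives neither heterodyne nor sample-autocorrelation
    energy.
    """

    plus_center: tuple[int, int]
    radius: float
    shot_center: tuple[int, int]
    shot_radius: float


@dataclass
class MaskSet:
    """Pixel-index sets for the two heterodyne masks and the shot-noise mask.

    Discs are closed (``x^2 + y^2 <= r^2``) on the integer lattice: a radius-80
    disc then contains exactly 20081 pixels, the signal-mask size quoted for a
    512 x 512 sensor.  ``minus_flat[i]`` is the conjugate-symmetric partner of
    ``plus_flat[i]``.
    """

    grid_size: int
    geometry: MaskGeometry
    plus_flat: np.ndarray      # flat indices into the shifted N*N grid
    minus_flat: np.ndarray     # point-reflected partners, same order
    shot_flat: np.ndarray
    plus_offsets: np.ndarray   # (n_px, 2) integer offsets from the plus centre

    @property
    def n_pixels(self) -> int:
        return self.plus_flat.size

    def plus_radial_order(self) -> tuple[np.ndarray, np.ndarray]:
        """Indices of plus-mask pixels sorted by distance from the mask centre.

        Returns (order, radius) so that concentric sub-masks are prefixes.
        """
        r = np.hypot(self.plus_offsets[:, 0], self.plus_offsets[:, 1])
        order = np.argsort(r, kind="stable")
        return order, r[order]


def _disc_pixels(center: tuple[int, int], radius: float, n: int) -> np.ndarray:
    """(n_px, 2) shifted coordinates of a closed lattice disc."""
    cx, cy = center
    rr = int(np.floor(radius))
    xs = np.arange(cx - rr, cx + rr + 1)
    ys = np.arange(cy - rr, cy + rr + 1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    keep = (gx - cx) ** 2 + (gy - cy) ** 2 <= radius**2
    return np.stack([gx[keep], gy[keep]], axis=1)


def _to_flat(coords: np.ndarray, n: int) -> np.ndarray:
    half = n // 2
    ix = coords[:, 0] + half
    iy = coords[:, 1] + half
    return ix * n + iy


def build_masks(geometry: MaskGeometry, grid_size: int) -> MaskSet:
    """Construct the twin heterodyne masks and the shot-noise mask.

    The minus mask is generated by exact point reflection of the plus mask, so
    the two are a conjugate pair bin by bin.  Raises :class:`MaskError` if any
    mask leaves the grid, touches the DC pixel, or if the three masks overlap.
    """
    n = int(grid_size)
    half = n // 2
    plus = _disc_pixels(geometry.plus_center, geometry.radius, n)
    minus = -plus  # exact point reflection through the origin
    shot = _disc_pixels(geometry.shot_center, geometry.shot_radius, n)

    problems = []
    for name, coords in (("plus", plus), ("minus", minus), ("shot", shot)):
        # reflection of coordinate -half does not exist on an even grid, so
        # require all coordinates within [-half + 1, half - 1]
        if np.any(np.abs(coords) > half - 1):
            problems.append(f"{name} mask leaves the usable grid")
        if np.any((coords[:, 0] == 0) & (coords[:, 1] == 0)):
            problems.append(f"{name} mask contains the DC pixel")
    flats = {
        "plus": _to_flat(plus, n) if not problems else None,
        "minus": _to_flat(minus, n) if not problems else None,
        "shot": _to_flat(shot, n) if not problems else None,
    }
    if not problems:
        for a, b in (("plus", "minus"), ("plus", "shot"), ("minus", "shot")):
            if np.intersect1d(flats[a], flats[b]).size:
                problems.append(f"{a} and {b} masks overlap")
    if problems:
        raise MaskError("; ".join(problems))

    offsets = plus - np.asarray(geometry.plus_center)
    return MaskSet(
        grid_size=n,
        geometry=geometry,
        plus_flat=flats["plus"],
        minus_flat=flats["minus"],
        shot_flat=flats["shot"],
        plus_offsets=offsets,
    )


# ---------------------------------------------------------------------------
# Normalisation


@dataclass
class ReconstructionResult:
    """Per-frame PSD scalars and per-pixel S1 values over the signal masks.

    ``s1_pixels`` has shape (n_mask_pixels, n_frames): column ``t`` holds the
    (optionally MTF-corrected) S1 values of the plus mask for hologram ``t``,
    in the pixel order of ``mask_set.plus_flat``.  For real holograms the
    minus-mask values are the bin-exact mirror of these.
    """

    s_plus: np.ndarray
    s_minus: np.ndarray
    n_bar: np.ndarray
    s1_bar: np.ndarray
    s1_pixels: np.ndarray
    mask_set: MaskSet
    mtf_applied: bool
    hr_frames: Optional[np.ndarray] = None

    @property
    def n_frames(self) -> int:
        return self.s1_bar.size


def _mask_mtf(mtf: Optional[MTFMap], flat: np.ndarray, n: int) -> np.ndarray:
    if mtf is None:
        return np.ones(flat.size)
    if mtf.grid_size != n:
        raise ConfigurationError("MTF map grid size does not match holograms")
    vals = mtf.values.ravel()[flat]
    if np.any(vals <= 0):
        raise ConfigurationError("MTF is non-positive inside a signal mask")
    return vals


def _normalize_frames(
    hr_iter: Iterable[np.ndarray],
    masks: MaskSet,
    mtf: Optional[MTFMap],
    nbar_mode: str = "per_frame",
) -> ReconstructionResult:
    if nbar_mode not in ("per_frame", "stack_mean"):
        raise ConfigurationError("nbar_mode must be 'per_frame' or 'stack_mean'")
    n = masks.grid_size
    mtf_plus = _mask_mtf(mtf, masks.plus_flat, n)
    mtf_minus = _mask_mtf(mtf, masks.minus_flat, n)

    plus_cols, minus_cols, n_bar = [], [], []
    for t, hr in enumerate(hr_iter):
        flat = hr.ravel()
        nb = float(flat[masks.shot_flat].mean())
        if nb <= 0:
            raise DegenerateInputError(
                f"shot-noise mask mean is {nb} in frame {t}: degenerate input "
                "(no photon noise energy to normalise against)"
            )
        n_bar.append(nb)
        plus_cols.append(flat[masks.plus_flat])
        minus_cols.append(flat[masks.minus_flat])

    n_bar = np.asarray(n_bar)
    plus_vals = np.stack(plus_cols, axis=1)    # (n_px, n_frames)
    minus_vals = np.stack(minus_cols, axis=1)
    # For a stationary acquisition the shot-noise floor is constant, so its
    # estimate may be pooled over frames; the per-frame estimate (the default)
    # carries a common-mode relative noise of 1/sqrt(n_shot_pixels) per frame.
    norm = n_bar if nbar_mode == "per_frame" else np.full_like(n_bar, n_bar.mean())
    s1_plus = (plus_vals / norm - 1.0) / mtf_plus[:, None]
    s1_minus = (minus_vals / norm - 1.0) / mtf_minus[:, None]
    return ReconstructionResult(
        s_plus=plus_vals.mean(axis=0),
        s_minus=minus_vals.mean(axis=0),
        n_bar=n_bar,
        s1_bar=0.5 * (s1_plus.mean(axis=0) + s1_minus.mean(axis=0)),
        s1_pixels=s1_plus,
        mask_set=masks,
        mtf_applied=mtf is not None,
    )


def normalize_s1(
    hr: np.ndarray,
    masks: MaskSet,
    mtf: Optional[MTFMap] = None,
    keep_frames: bool = False,
    nbar_mode: str = "per_frame",
) -> ReconstructionResult:
    """Shot-noise normalise reconstructed holograms into S1 values.

    For each frame, ``N_bar`` is the mean of H_R over the shot-noise mask and
    each signal-mask pixel becomes ``(H_R / N_bar - 1)``, divided per pixel by
    the MTF when a map is supplied (the shot-noise normalisation itself is not
    MTF corrected, since pixel integration does not attenuate the homodyne
    shot-noise floor).  ``s1_bar`` is the mean of the two twin-mask averages.
    """
    hr = np.asarray(hr)
    if hr.ndim == 2:
        hr = hr[None]
    result = _normalize_frames(hr, masks, mtf, nbar_mode=nbar_mode)
    if keep_frames:
        result.hr_frames = hr
    return result


def reconstruct_and_normalize(
    holograms: HologramStack | np.ndarray,
    masks: MaskSet,
    mtf: Optional[MTFMap] = None,
    keep_frames: bool = False,
    nbar_mode: str = "per_frame",
) -> ReconstructionResult:
    """Reconstruct and normalise a hologram stack one frame at a time.

    Equivalent to ``normalize_s1(reconstruct(stack), ...)`` but never holds the
    full H_R stack in memory, which matters at the 512 x 512 x 500 scale.
    """
    frames = holograms.frames if isinstance(holograms, HologramStack) else np.asarray(holograms)
    if keep_frames:
        hr = reconstruct(frames)
        return normalize_s1(hr, masks, mtf, keep_frames=True, nbar_mode=nbar_mode)

    def frame_iter() -> Iterator[np.ndarray]:
        for f in frames:
            if not np.all(np.isfinite(f)):
                raise ConfigurationError("holograms contain non-finite values")
            yield _reconstruct_frame(f)

    return _normalize_frames(frame_iter(), masks, mtf, nbar_mode=nbar_mode)
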