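"""Multispeckle denoising by column sorting, temporal median filtering, unsorting.

Masked per-pixel S1 values from a series of reconstructed holograms are
reshaped into a space-time matrix ``R`` (mask pixels x frames).  Each column
represents the same S1 distribution, independently randomised by the spatial
sampling of speckle and contaminated by detector noise.  Sorting each column
into ascending order removes the random spatial arrangement; a ``[1 x n]``
median filter along the time axis then suppresses the frame-to-frame noise of
each order statistic; finally each column's sort is exactly reversed, which
restores the native spatial arrangement of the speckle ranks bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter, rank_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigurationError
from .reconstruction import MaskSet
from .svd_filter import SpaceTimeMatrix

__all__ = [
    "DenoiseConfig",
    "build_R",
    "sort_median_unsort",
    "restore_mask",
    "MultispeckleDenoiser",
]

_EDGE_MODES = {"replicate": "nearest", "reflect": "reflect", "wrap": "wrap"}


@dataclass
class DenoiseConfig:
    """Time-axis window width ``n``, edge policy, and even-window convention.

    The neighbourhood is ``[1 x n]`` — one pixel in space, ``n`` frames in
    time.  For even ``n`` the median is the mean of the two central order
    statistics by default (``even_mode="mean"``), or the lower one
    (``even_mode="lower"``).
    """

    window: int = 3
    edge: str = "replicate"
    even_mode: str = "mean"


def build_R(s1_pixels: np.ndarray, mask: MaskSet | np.ndarray | None = None) -> SpaceTimeMatrix:
    """Assemble the S1 space-time matrix ``R`` (mask pixels x frames).

    Accepts either an already-masked (n_px, n_frames) matrix, or a stack of
    full S1 frames (n_frames, N, N) together with a mask.  Values are copied
    bit-exactly; forming ``R`` does not alter the S1 data.
    """
    arr = np.asarray(s1_pixels, dtype=np.float64)
    if arr.ndim == 2:
        values = arr.copy()
        mask_flat = mask.plus_flat if isinstance(mask, MaskSet) else (
            None if mask is None else np.asarray(mask)
        )
    elif arr.ndim == 3:
        if mask is None:
            raise ConfigurationError("a mask is required to reshape full S1 frames")
        mask_flat = mask.plus_flat if isinstance(mask, MaskSet) else np.asarray(mask)
        nt, nx, ny = arr.shape
        values = arr.reshape(nt, nx * ny)[:, mask_flat].T.copy()
    else:
        raise ConfigurationError("expected (n_px, n_frames) or (n_frames, N, N) input")
    return SpaceTimeMatrix(values=values, mask_flat=mask_flat, provenance="reconstructed_R")


def _time_median(rows: np.ndarray, cfg: DenoiseConfig) -> np.ndarray:
    mode = _EDGE_MODES.get(cfg.edge)
    if mode is None:
        raise ConfigurationError(f"unknown edge policy {cfg.edge!r}")
    n = cfg.window
    if n % 2 == 1 or cfg.even_mode == "lower":
        if n % 2 == 1:
            return median_filter(rows, size=(1, n), mode=mode)
        # even window, lower median: rank n//2 - 1 of n
        return rank_filter(rows, rank=n // 2 - 1, size=(1, n), mode=mode)
    lo = rank_filter(rows, rank=n // 2 - 1, size=(1, n), mode=mode)
    hi = rank_filter(rows, rank=n // 2, size=(1, n), mode=mode)
    return 0.5 * (lo + hi)


def sort_median_unsort(
    R: SpaceTimeMatrix | np.ndarray, config: DenoiseConfig | None = None, **kwargs
) -> SpaceTimeMatrix:
    """Denoise ``R``: sort each column, median-filter along time, unsort.

    With ``window = 1`` this is the identity.  Ties are broken by the stable
    order of the original indices; the recorded permutation guarantees an
    exact unsort regardless of ties.
    """
    cfg = config or DenoiseConfig(**kwargs)
    mat = R if isinstance(R, SpaceTimeMatrix) else SpaceTimeMatrix(np.asarray(R, dtype=np.float64))
    x = mat.values
    if cfg.window < 1:
        raise ConfigurationError("window must be >= 1")
    if cfg.window > mat.n_time:
        raise ConfigurationError(f"window {cfg.window} exceeds {mat.n_time} frames")
    if cfg.window == 1:
        out = x.copy()
    else:
        perm = np.argsort(x, axis=0, kind="stable")
        sorted_x = np.take_along_axis(x, perm, axis=0)
        filtered = _time_median(sorted_x, cfg)
        out = np.empty_like(filtered)
        np.put_along_axis(out, perm, filtered, axis=0)
    return SpaceTimeMatrix(
        values=out, spatial_shape=mat.spatial_shape, mask_flat=mat.mask_flat,
        provenance=mat.provenance,
    )


def restore_mask(R: SpaceTimeMatrix, mask: MaskSet | np.ndarray, frame_shape: tuple[int, int]) -> np.ndarray:
    """Scatter ``R`` columns back into full frames (exact inverse of build_R)."""
    mask_flat = mask.plus_flat if isinstance(mask, MaskSet) else np.asarray(mask)
    if mask_flat.size != R.n_space:
        raise ConfigurationError("mask size does not match the space dimension of R")
    nx, ny = frame_shape
    frames = np.zeros((R.n_time, nx * ny))
    frames[:, mask_flat] = R.values.T
    return frames.reshape(R.n_time, nx, ny)


class MultispeckleDenoiser(BaseEstimator, TransformerMixin):
    """Sort-median-unsort denoiser with a scikit-learn transformer surface.

    Parameters mirror :class:`DenoiseConfig`.  ``transform`` accepts the
    (n_px, n_frames) S1 matrix and returns the denoised matrix; the column
    means (per-frame S1 averages) are recomputed downstream from the restored
    mask values.
    """

    def __init__(self, window: int = 3, edge: str = "replicate", even_mode: str = "mean"):
        self.window = window
        self.edge = edge
        self.even_mode = even_mode

    def fit(self, X, y=None):
        self.config_ = DenoiseConfig(window=self.window, edge=self.edge, even_mode=self.even_mode)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "config_"):
            self.fit(X)
        return sort_median_unsort(X, self.config_).values
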