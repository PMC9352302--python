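"""Space-time SVD filtering of hologram stacks.

A series of ``n_t`` holograms of ``n_x x n_y`` pixels is reshaped into a
space-time matrix ``Q`` (``n_x n_y x n_t``).  Its largest singular values
carry the most spatiotemporally correlated content — clutter such as laser
power modulation, beat notes or mode hops — whereas dynamic speckle has
inherently weak spatiotemporal correlation.  Zeroing the first ``n_c``
singular values and rebuilding ``Q`` therefore declutters the stack while
leaving the speckle signal essentially untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigurationError

__all__ = [
    "SpaceTimeMatrix",
    "stack_to_matrix",
    "matrix_to_stack",
    "singular_spectrum",
    "svd_declutter",
    "suggest_nc",
    "SVDClutterFilter",
]


@dataclass
class SpaceTimeMatrix:
    """2-D space x time reshaping of a stack, with its inverse map.

    ``values[:, t]`` is frame ``t`` flattened in row-major order (grid
    provenance) or its masked pixel values (mask provenance).
    """

    values: np.ndarray                     # (n_space, n_time)
    spatial_shape: Optional[tuple[int, int]] = None
    mask_flat: Optional[np.ndarray] = None
    provenance: str = "camera_plane_Q"

    @property
    def n_space(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]


def stack_to_matrix(stack: np.ndarray) -> SpaceTimeMatrix:
    """Reshape a frame stack (n_t, n_x, n_y) into an (n_x n_y, n_t) matrix."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ConfigurationError("expected a (n_frames, n_x, n_y) stack")
    nt, nx, ny = stack.shape
    values = stack.reshape(nt, nx * ny).T.astype(np.float64, copy=True)
    return SpaceTimeMatrix(values=values, spatial_shape=(nx, ny))


def matrix_to_stack(matrix: SpaceTimeMatrix) -> np.ndarray:
    """Inverse of :func:`stack_to_matrix`; round-trip is the identity."""
    if matrix.spatial_shape is None:
        raise ConfigurationError("matrix has mask provenance, not a full grid")
    nx, ny = matrix.spatial_shape
    return matrix.values.T.reshape(matrix.n_time, nx, ny)


def _gram_svd(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Singular values and right singular vectors via the time-side Gram matrix."""
    g = x.T @ x
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    svals = np.sqrt(np.clip(evals[order], 0.0, None))
    return svals, evecs[:, order]


def singular_spectrum(matrix: SpaceTimeMatrix | np.ndarray, method: str = "auto") -> np.ndarray:
    """All ``n_time`` singular values of the space-time matrix, non-increasing.

    For tall matrices the values are computed from the ``n_time x n_time``
    Gram matrix, which matches a full decomposition to high relative accuracy
    at a fraction of the cost.
    """
    x = matrix.values if isinstance(matrix, SpaceTimeMatrix) else np.asarray(matrix, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ConfigurationError("space-time matrix contains non-finite values")
    if method == "auto":
        method = "gram" if x.shape[0] >= 4 * x.shape[1] else "full"
    if method == "gram":
        return _gram_svd(x)[0]
    if method == "full":
        return np.linalg.svd(x, compute_uv=False)
    raise ConfigurationError(f"unknown method {method!r}")


def svd_declutter(matrix: SpaceTimeMatrix | np.ndarray, nc: int) -> SpaceTimeMatrix:
    """Zero the ``nc`` largest singular values and rebuild the matrix.

    The result is the projection of the data onto the orthogonal complement of
    the ``nc`` strongest spatiotemporal components; applying the filter twice
    with the same ``nc`` is idempotent up to re-decomposition round-off.
    Downstream reconstruction should use single-frame holography, since the
    SVD step has already removed the temporally static content.
    """
    mat = matrix if isinstance(matrix, SpaceTimeMatrix) else SpaceTimeMatrix(np.asarray(matrix, dtype=np.float64))
    if not 0 <= nc < mat.n_time:
        raise ConfigurationError(f"nc must be in [0, n_time), got {nc} with n_time={mat.n_time}")
    if nc == 0:
        filtered = mat.values.copy()
    else:
        _, v = _gram_svd(mat.values)
        vc = v[:, :nc]
        filtered = mat.values - (mat.values @ vc) @ vc.T
    return SpaceTimeMatrix(
        values=filtered,
        spatial_shape=mat.spatial_shape,
        mask_flat=mat.mask_flat,
        provenance=mat.provenance,
    )


def suggest_nc(singular_values: np.ndarray, factor: float = 1.25) -> int:
    """Count leading singular values elevated above the speckle floor.

    A log-linear baseline is fitted to the tail half of the spectrum and
    extrapolated to the head; the suggested cutoff is the length of the
    initial run of values exceeding ``factor`` times the baseline (0 when no
    elevation is detected).  Advisory only — inspect the spectrum before
    filtering real data.
    """
    sv = np.asarray(singular_values, dtype=np.float64)
    if sv.size < 20:
        raise ConfigurationError("need at least 20 singular values")
    idx = np.arange(sv.size)
    tail = idx[sv.size // 2 :]
    positive = sv[tail] > 0
    if positive.sum() < 2:
        return 0
    coeffs = np.polyfit(tail[positive], np.log(sv[tail][positive]), 1)
    baseline = np.exp(np.polyval(coeffs, idx))
    elevated = sv > factor * baseline
    nc = 0
    while nc < sv.size and elevated[nc]:
        nc += 1
    return nc


class SVDClutterFilter(BaseEstimator, TransformerMixin):
    """Spatiotemporal clutter filter with a scikit-learn transformer surface.

    Parameters
    ----------
    n_components : int or "auto"
        Number of leading singular values to zero.  ``"auto"`` selects the
        count of elevated values via :func:`suggest_nc`.
    factor : float
        Elevation threshold used when ``n_components="auto"``.

    Attributes
    ----------
    singular_values_ : ndarray
        Full singular spectrum of the fitted matrix.
    n_components_ : int
        The cutoff actually applied.
    """

    def __init__(self, n_components: int | str = 10, factor: float = 1.25):
        self.n_components = n_components
        self.factor = factor

    def fit(self, X, y=None):
        mat = X if isinstance(X, SpaceTimeMatrix) else SpaceTimeMatrix(np.asarray(X, dtype=np.float64))
        self.singular_values_ = singular_spectrum(mat)
        if self.n_components == "auto":
            self.n_components_ = suggest_nc(self.singular_values_, self.factor)
        else:
            self.n_components_ = int(self.n_components)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "n_components_"):
            raise RuntimeError("SVDClutterFilter is not fitted")
        mat = X if isinstance(X, SpaceTimeMatrix) else SpaceTimeMatrix(np.asarray(X, dtype=np.float64))
        return svd_declutter(mat, self.n_components_).values
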