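"""Fitting flow parameters to sampled power spectral densities.

By the Wiener-Khinchin theorem the first-order PSD of the scattered field is
the Fourier transform of the field autocorrelation g1(tau).  For the
single-exponential model ``g1(tau) = exp(-|tau|/tau_c)`` the PSD is the
Lorentzian ``s1(w) = 2 tau_c / (1 + w^2 tau_c^2)``.  A camera of finite
exposure T samples a triangularly windowed version of s1; the closed-form
windowed response is available so that exposure-limited spectra can be fitted
without bias.

The mapping from the fitted correlation time to an effective Brownian
diffusion coefficient depends on the semi-infinite correlation-diffusion
model of the measurement geometry, which is deliberately kept behind a
plug-in proportionality here; any reported Db is labelled as a placeholder
scale of 1/tau_c.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import ConfigurationError, FitError

__all__ = [
    "Spectrum",
    "FitResult",
    "model_psd",
    "windowed_lorentzian_psd",
    "fit_db",
    "SpectrumModel",
]


@dataclass
class Spectrum:
    """S1 repeats per detuning frequency."""

    detunings_hz: np.ndarray
    repeats: list[np.ndarray]

    def __post_init__(self) -> None:
        self.detunings_hz = np.asarray(self.detunings_hz, dtype=np.float64)
        if len(self.repeats) != self.detunings_hz.size:
            raise ConfigurationError("one repeat list per detuning required")
        self.repeats = [np.asarray(r, dtype=np.float64) for r in self.repeats]

    @property
    def omega(self) -> np.ndarray:
        return 2 * np.pi * self.detunings_hz

    @property
    def means(self) -> np.ndarray:
        return np.array([r.mean() for r in self.repeats])

    @property
    def stds(self) -> np.ndarray:
        return np.array([r.std(ddof=1) if r.size > 1 else 0.0 for r in self.repeats])


@dataclass
class FitResult:
    """Fitted correlation time / flow parameter with amplitude and residuals."""

    tauc_s: float
    amplitude: float
    residual_norm: float
    model: str
    db: Optional[float] = None
    db_note: str = "Db = scale / tau_c placeholder; supply the analytic FD-DCS model for absolute flow"
    n_detunings: int = 0


def model_psd(
    omega: np.ndarray,
    tauc_s: float,
    model: str = "exponential_g1",
    g1: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    quad_tol: float = 1e-8,
) -> np.ndarray:
    """Unit-amplitude PSD ``s1(w)`` of the field fluctuations.

    ``exponential_g1`` uses the closed-form Lorentzian; ``plugin`` evaluates
    the Fourier transform of a supplied ``g1`` (symmetrically extended,
    ``g1(-tau) = g1(tau)``) by adaptive quadrature.
    """
    omega = np.asarray(omega, dtype=np.float64)
    if tauc_s <= 0:
        raise ConfigurationError("correlation time must be positive")
    if model == "exponential_g1":
        return 2 * tauc_s / (1 + (omega * tauc_s) ** 2)
    if model == "plugin":
        if g1 is None:
            raise ConfigurationError("plugin model requires a g1 callable")
        out = np.empty(omega.shape)
        for i, w in np.ndenumerate(omega):
            # s1(w) = 2 * Int_0^inf g1(tau) cos(w tau) dtau
            upper = 60 * tauc_s
            val, err = quad(
                g1, 0, upper, weight="cos", wvar=float(w),
                epsabs=1e-14, epsrel=quad_tol, limit=500,
            )
            if abs(err) > max(1e-6 * abs(val), 1e-13):
                raise FitError(f"PSD quadrature did not converge at omega={w}")
            out[i] = 2 * val
        return out
    raise ConfigurationError(f"unknown PSD model {model!r}")


def windowed_lorentzian_psd(omega: np.ndarray, tauc_s: float, exposure_time_s: float) -> np.ndarray:
    """Exposure-windowed Lorentzian PSD (exact closed form).

    A camera exposure of length T measures
    ``(2/T) Re Int_0^T (T - tau) g1(tau) exp(-i w tau) dtau`` which tends to
    the true ``s1(w)`` as ``T / tau_c -> inf``.
    """
    omega = np.asarray(omega, dtype=np.float64)
    t = float(exposure_time_s)
    a = 1.0 / tauc_s + 1j * omega
    integral = t / a - (1.0 - np.exp(-a * t)) / a**2
    return (2.0 / t) * integral.real


def _design(omega: np.ndarray, tauc: float, model: str, exposure: Optional[float], g1) -> np.ndarray:
    if exposure is not None and model == "exponential_g1":
        return windowed_lorentzian_psd(omega, tauc, exposure)
    return model_psd(omega, tauc, model=model, g1=g1)


def fit_db(
    spectrum: Spectrum,
    model: str = "exponential_g1",
    exposure_time_s: Optional[float] = None,
    weighted: bool = False,
    db_scale: Optional[float] = None,
    g1: Optional[Callable] = None,
) -> FitResult:
    """Least-squares fit of (amplitude, tau_c) to per-detuning mean S1 values.

    The amplitude is profiled out analytically, leaving a 1-D search over
    ``log tau_c`` started from five log-spaced initial values (the best kept),
    so the result is deterministic given the inputs.  Weights, when enabled,
    are inverse per-detuning variances of the S1 repeats.
    """
    if spectrum.detunings_hz.size < 2:
        raise ConfigurationError("need at least 2 detuning frequencies to fit")
    y = spectrum.means
    if np.any(~np.isfinite(y)):
        raise ConfigurationError("non-finite spectrum means")
    omega = spectrum.omega
    if weighted:
        s = spectrum.stds
        w = 1.0 / np.clip(s, max(s[s > 0].min() if np.any(s > 0) else 1.0, 1e-30), None) ** 2
    else:
        w = np.ones_like(y)

    def cost(log_tauc: float) -> tuple[float, float]:
        tauc = float(np.exp(log_tauc))
        m = _design(omega, tauc, model, exposure_time_s, g1)
        denom = float(np.sum(w * m * m))
        amp = float(np.sum(w * m * y) / denom) if denom > 0 else 0.0
        resid = y - amp * m
        return float(np.sum(w * resid**2)), amp

    w_ref = max(float(np.max(np.abs(omega))), 1e-3)
    starts = np.log(np.logspace(-2, 2, 5) / w_ref)
    best = None
    for s0 in starts:
        res = minimize_scalar(
            lambda lt: cost(lt)[0],
            bounds=(s0 - 6, s0 + 6),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("correlation-time fit failed to converge from all starts")
    tauc = float(np.exp(best.x))
    sq, amp = cost(best.x)
    return FitResult(
        tauc_s=tauc,
        amplitude=amp,
        residual_norm=float(np.sqrt(sq)),
        model=model + ("", "+window")[exposure_time_s is not None],
        db=None if db_scale is None else db_scale / tauc,
        n_detunings=int(omega.size),
    )


class SpectrumModel(BaseEstimator, RegressorMixin):
    """PSD model fit with a scikit-learn estimator surface.

    ``fit(X, y)`` takes detuning frequencies in Hz (shape ``(n,)`` or
    ``(n, 1)``) and mean S1 values; fitted attributes are ``tauc_``,
    ``amplitude_`` and ``residual_``.  ``predict`` evaluates the fitted model.
    """

    def __init__(
        self,
        model: str = "exponential_g1",
        exposure_time_s: Optional[float] = None,
        weighted: bool = False,
        db_scale: Optional[float] = None,
    ):
        self.model = model
        self.exposure_time_s = exposure_time_s
        self.weighted = weighted
        self.db_scale = db_scale

    @staticmethod
    def _as_hz(X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return X.ravel()

    def fit(self, X, y):
        hz = self._as_hz(X)
        spec = Spectrum(detunings_hz=hz, repeats=[np.atleast_1d(v) for v in np.asarray(y, dtype=np.float64)])
        res = fit_db(
            spec,
            model=self.model,
            exposure_time_s=self.exposure_time_s,
            weighted=self.weighted,
            db_scale=self.db_scale,
        )
        self.tauc_ = res.tauc_s
        self.amplitude_ = res.amplitude
        self.residual_ = res.residual_norm
        self.db_ = res.db
        self.result_ = res
        return self

    def predict(self, X) -> np.ndarray:
        hz = self._as_hz(X)
        m = _design(2 * np.pi * hz, self.tauc_, self.model, self.exposure_time_s, None)
        return self.amplitude_ * m
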