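"""First-order first-moment (FOFM) propagation law.

Implements the GUM law of propagation of uncertainty: the variance of a
scalar output y = f(x) is approximated to first order as

    u^2(y) = sum_i (df/dx_i)^2 u^2(x_i)                      (uncorrelated)
    u^2(y) = g^T V g,  g_i = df/dx_i                         (correlated)

plus a central-difference numeric gradient used to verify the analytic
partial derivatives of every bio-optical algorithm in this package.
"""

from __future__ import annotations

import warnings
from typing import Callable

import numpy as np

from .spectra import SpectralCovariance, Spectrum

__all__ = [
    "propagate_uncorrelated",
    "propagate_covariance",
    "numeric_gradient",
    "NonNegativeClipWarning",
]


class NonNegativeClipWarning(UserWarning):
    """A tiny negative quadratic form g^T V g was clipped to zero."""


def propagate_uncorrelated(gradient, u) -> float:
    """Standard uncertainty of the output for uncorrelated inputs.

    ``gradient`` holds the partial derivatives df/dx_i and ``u`` the
    1-sigma input uncertainties; returns sqrt(sum g_i^2 u_i^2) >= 0.
    """
    g = np.asarray(gradient, dtype=float)
    uv = np.asarray(u, dtype=float)
    if g.shape != uv.shape:
        raise ValueError(f"length mismatch: gradient {g.shape}, u {uv.shape}")
    if not (np.all(np.isfinite(g)) and np.all(np.isfinite(uv))):
        raise ValueError("non-finite gradient or uncertainty entries")
    if np.any(uv < 0):
        raise ValueError("uncertainties must be non-negative")
    return float(np.sqrt(np.sum((g * uv) ** 2)))


def propagate_covariance(gradient, cov: SpectralCovariance | np.ndarray) -> float:
    """Standard uncertainty of the output given a full input covariance.

    Computes sqrt(g^T V g).  For a PSD V the quadratic form is
    analytically non-negative; a tiny negative value arising from
    floating-point roundoff is clipped to zero with a warning.
    """
    g = np.asarray(gradient, dtype=float)
    V = cov.matrix if isinstance(cov, SpectralCovariance) else np.asarray(cov, float)
    if V.shape != (g.size, g.size):
        raise ValueError(f"dimension mismatch: gradient {g.size}, V {V.shape}")
    if not isinstance(cov, SpectralCovariance):
        scale = np.max(np.abs(V)) or 1.0
        if np.max(np.abs(V - V.T)) > 1e-12 * scale:
            raise ValueError("covariance matrix is not symmetric")
    var = float(g @ V @ g)
    if var < 0:
        warnings.warn(
            f"negative variance {var:g} from roundoff clipped to 0",
            NonNegativeClipWarning,
        )
        var = 0.0
    return float(np.sqrt(var))


def numeric_gradient(
    f: Callable[[Spectrum], float],
    s: Spectrum,
    eps_rel: float = 1e-5,
    eps_abs: float = 1e-9,
) -> np.ndarray:
    """Central-difference gradient of a scalar spectrum functional.

    The per-band step is ``h_i = max(eps_rel * |x_i|, eps_abs)``.  Used
    throughout the test-suite as the independent oracle for analytic
    gradients.
    """
    x = s.values
    g = np.empty_like(x)
    for i in range(x.size):
        h = max(eps_rel * abs(x[i]), eps_abs)
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        fp = f(s.with_values(xp))
        fm = f(s.with_values(xm))
        if not (np.isfinite(fp) and np.isfinite(fm)):
            raise ValueError(
                f"function non-finite when perturbing band "
                f"{s.wavelengths[i]:g} nm"
            )
        g[i] = (fp - fm) / (2.0 * h)
    return g
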