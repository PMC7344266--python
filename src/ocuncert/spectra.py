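"""Core spectral data types, band matching, and table I/O.

All wavelengths are in nanometres. The canonical multiband working grid
is the sixteen 10 nm-wide visible bands used throughout this package:
412, 425, 443, 460, 475, 490, 510, 532, 555, 583, 617, 640, 655, 665,
678 and 710 nm.  Remote-sensing reflectance (Rrs) and sub-surface
reflectance (rrs) carry units of sr^-1; normalized water-leaving radiance
(nLw) mW cm^-2 um^-1 sr^-1; absorption and backscattering m^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectralCovariance",
    "BandSet",
    "MULTIBAND_16",
    "DEFAULT_BAND_TOL",
    "MissingBandError",
    "nearest_band",
    "subsample_to_bands",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_covariance_csv",
    "write_covariance_csv",
]

#: Default tolerance (nm) when resolving a nominal band centre on a grid.
DEFAULT_BAND_TOL = 3.0


class MissingBandError(KeyError):
    """Raised when a requested band centre cannot be resolved on a grid."""


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class Spectrum:
    """A wavelength grid plus the values of one spectral quantity.

    Parameters
    ----------
    wavelengths:
        Strictly increasing, positive wavelengths in nm.
    values:
        Finite values, one per wavelength, in the units implied by
        ``quantity``.
    quantity:
        Free-form role tag, e.g. ``"Rrs"``, ``"rrs"``, ``"u(Rrs)"``,
        ``"nLw"``, ``"a"``, ``"bb"``.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    quantity: str = "Rrs"

    def __post_init__(self):
        object.__setattr__(self, "wavelengths", _as_float_array(self.wavelengths))
        object.__setattr__(self, "values", _as_float_array(self.values))
        w, v = self.wavelengths, self.values
        if w.ndim != 1 or v.ndim != 1:
            raise ValueError("wavelengths and values must be one-dimensional")
        if w.size == 0:
            raise ValueError("empty spectrum")
        if v.shape != w.shape:
            raise ValueError(
                f"length mismatch: {w.size} wavelengths vs {v.size} values"
            )
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("wavelengths must be finite and positive")
        if np.any(np.diff(w) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("spectrum values must be finite")

    def __len__(self) -> int:
        return self.wavelengths.size

    def with_values(self, values, quantity: str | None = None) -> "Spectrum":
        """Return a new spectrum on the same grid with different values."""
        return Spectrum(self.wavelengths, values,
                        self.quantity if quantity is None else quantity)

    def band_value(self, center: float, tol: float = DEFAULT_BAND_TOL) -> float:
        """Value at the band nearest ``center`` (within ``tol`` nm)."""
        return float(self.values[nearest_band(self, center, tol)])


@dataclass(frozen=True)
class SpectralCovariance:
    """Symmetric PSD covariance matrix over a wavelength grid.

    Units are the product of the two bands' units (sr^-2 for an Rrs
    covariance).  Symmetry is enforced to 1e-12 relative tolerance and
    eigenvalues must be >= -1e-10 x the largest diagonal entry.
    """

    wavelengths: np.ndarray
    matrix: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "wavelengths", _as_float_array(self.wavelengths))
        object.__setattr__(self, "matrix", _as_float_array(self.matrix))
        w, m = self.wavelengths, self.matrix
        n = w.size
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} does not match {n} bands")
        if np.any(np.diff(w) <= 0) or np.any(w <= 0):
            raise ValueError("wavelengths must be positive, strictly increasing")
        if not np.all(np.isfinite(m)):
            raise ValueError("covariance entries must be finite")
        scale = np.max(np.abs(m)) or 1.0
        if np.max(np.abs(m - m.T)) > 1e-12 * scale:
            raise ValueError("covariance matrix is not symmetric")
        if np.any(np.diag(m) < 0):
            raise ValueError("covariance diagonal must be non-negative")
        eigmin = float(np.linalg.eigvalsh(0.5 * (m + m.T)).min())
        tol = 1e-10 * max(float(np.max(np.diag(m))), 1e-300)
        if eigmin < -tol:
            raise ValueError(
                f"covariance not positive semi-definite (min eigenvalue {eigmin:g})"
            )

    def __len__(self) -> int:
        return self.wavelengths.size

    @property
    def diagonal_u(self) -> np.ndarray:
        """Per-band standard uncertainties sqrt(diag)."""
        return np.sqrt(np.diag(self.matrix))

    def subset(self, centers: Sequence[float],
               tol: float = DEFAULT_BAND_TOL) -> "SpectralCovariance":
        """Covariance restricted to the bands nearest the given centres."""
        probe = Spectrum(self.wavelengths, np.zeros(len(self)), "probe")
        idx = np.array([nearest_band(probe, c, tol) for c in centers])
        return SpectralCovariance(self.wavelengths[idx],
                                  self.matrix[np.ix_(idx, idx)])


@dataclass(frozen=True)
class BandSet:
    """Multiband grid: boxcar bands of common width centred on ``centers``."""

    centers: np.ndarray
    width: float = 10.0

    def __post_init__(self):
        object.__setattr__(self, "centers", _as_float_array(self.centers))
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("band centers must be strictly increasing")
        if not self.width > 0:
            raise ValueError("band width must be positive")

    def __len__(self) -> int:
        return self.centers.size


#: The sixteen-band visible grid used by default throughout the package.
MULTIBAND_16 = BandSet(
    centers=np.array([412., 425., 443., 460., 475., 490., 510., 532.,
                      555., 583., 617., 640., 655., 665., 678., 710.]),
    width=10.0,
)


def nearest_band(s: Spectrum, target: float, tol: float = DEFAULT_BAND_TOL) -> int:
    """Index of the wavelength in ``s`` closest to ``target``.

    Raises :class:`MissingBandError` if no wavelength lies within
    ``tol`` nm of the target.
    """
    i = int(np.argmin(np.abs(s.wavelengths - target)))
    if abs(s.wavelengths[i] - target) > tol:
        raise MissingBandError(
            f"no band within {tol} nm of {target} nm "
            f"(grid spans {s.wavelengths[0]:g}-{s.wavelengths[-1]:g} nm)"
        )
    return i


def subsample_to_bands(hyper: Spectrum, bands: BandSet = MULTIBAND_16) -> Spectrum:
    """Boxcar-average a hyperspectral spectrum onto a multiband grid.

    Each output value is the unweighted mean of the source values whose
    wavelengths fall in the closed interval [c - w/2, c + w/2]. A band
    interval containing no source wavelengths is an error.
    """
    half = bands.width / 2.0
    out = np.empty(len(bands))
    for k, c in enumerate(bands.centers):
        mask = (hyper.wavelengths >= c - half) & (hyper.wavelengths <= c + half)
        if not mask.any():
            raise MissingBandError(
                f"no source wavelengths in band {c:g} +/- {half:g} nm"
            )
        out[k] = hyper.values[mask].mean()
    return Spectrum(bands.centers, out, hyper.quantity)


# ---------------------------------------------------------------------------
# Delimited-table I/O.  Spectra tables: one row per spectrum, header row of
# band-centre wavelengths.  Covariance: square CSV with wavelength header
# row and index column.
# ---------------------------------------------------------------------------

def write_spectra_csv(path, spectra: Sequence[Spectrum]) -> None:
    if not spectra:
        raise ValueError("no spectra to write")
    grid = spectra[0].wavelengths
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths, grid):
            raise ValueError("all spectra must share one wavelength grid")
    df = pd.DataFrame([s.values for s in spectra],
                      columns=[f"{w:g}" for w in grid])
    df.to_csv(path, index=False)


def read_spectra_csv(path, quantity: str = "Rrs") -> list[Spectrum]:
    df = pd.read_csv(path)
    wl = np.array([float(c) for c in df.columns])
    return [Spectrum(wl, row, quantity) for row in df.to_numpy(dtype=float)]


def write_covariance_csv(path, cov: SpectralCovariance) -> None:
    labels = [f"{w:g}" for w in cov.wavelengths]
    pd.DataFrame(cov.matrix, index=labels, columns=labels).to_csv(path)


def read_covariance_csv(path) -> SpectralCovariance:
    df = pd.read_csv(path, index_col=0)
    wl = np.array([float(c) for c in df.columns])
    return SpectralCovariance(wl, df.to_numpy(dtype=float))
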