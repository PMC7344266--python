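"""Per-band Rrs uncertainty models and covariance construction.

Three regimes are supported:

* spectrally flat relative uncertainty (e.g. the classic 5% mission goal),
  treated as uncorrelated;
* a spectrally dependent relative-uncertainty surface tabulated against
  chlorophyll concentration and wavelength (bilinear interpolation, with
  linear extrapolation above the top chlorophyll level);
* a user-supplied correlation/covariance matrix.

Relative uncertainties are applied to |Rrs| so rare negative bands still
yield non-negative standard uncertainties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import SpectralCovariance, Spectrum

__all__ = [
    "FlatRelativeUncertainty",
    "RelativeUncertaintySurface",
    "flat_u",
    "surface_u",
    "build_covariance",
    "synthetic_demo_surface",
]


@dataclass(frozen=True)
class FlatRelativeUncertainty:
    """A single spectrally flat relative uncertainty fraction (e.g. 0.05)."""

    rel: float

    def __post_init__(self):
        if not (np.isfinite(self.rel) and self.rel >= 0):
            raise ValueError("relative uncertainty must be finite and >= 0")


@dataclass(frozen=True)
class RelativeUncertaintySurface:
    """Tabulated relative uncertainty of Rrs vs chlorophyll and wavelength.

    ``rel_values[i, j]`` is the relative fraction at ``chl_levels[i]``
    (mg m^-3) and ``wavelengths[j]`` (nm).
    """

    chl_levels: np.ndarray
    wavelengths: np.ndarray
    rel_values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "chl_levels", np.asarray(self.chl_levels, float))
        object.__setattr__(self, "wavelengths", np.asarray(self.wavelengths, float))
        object.__setattr__(self, "rel_values", np.asarray(self.rel_values, float))
        c, w, r = self.chl_levels, self.wavelengths, self.rel_values
        if r.shape != (c.size, w.size):
            raise ValueError(
                f"rel_values shape {r.shape} inconsistent with "
                f"{c.size} chl levels x {w.size} wavelengths"
            )
        if np.any(np.diff(c) <= 0) or np.any(np.diff(w) <= 0):
            raise ValueError("chl levels and wavelengths must be ascending")
        if np.any(r < 0) or not np.all(np.isfinite(r)):
            raise ValueError("relative uncertainties must be finite and >= 0")

    def rel_at(self, wavelength, chl: float) -> np.ndarray:
        """Relative fraction at given wavelength(s) for one chl value.

        Linear in wavelength within the tabulated range (no wavelength
        extrapolation); linear in chl between levels, linearly
        EXTRApolated from the last two levels above the grid top, and
        clamped to the lowest level below the grid bottom.
        """
        wl = np.atleast_1d(np.asarray(wavelength, float))
        if wl.min() < self.wavelengths[0] or wl.max() > self.wavelengths[-1]:
            raise ValueError(
                f"wavelength outside tabulated range "
                f"[{self.wavelengths[0]:g}, {self.wavelengths[-1]:g}] nm"
            )
        c = self.chl_levels
        if chl <= c[0]:
            row = self.rel_values[0]
        elif chl >= c[-1] and c.size >= 2:
            # linear extrapolation from the last two tabulated levels
            t = (chl - c[-2]) / (c[-1] - c[-2])
            row = self.rel_values[-2] + t * (self.rel_values[-1] - self.rel_values[-2])
        else:
            i = int(np.searchsorted(c, chl, side="right")) - 1
            i = min(max(i, 0), c.size - 2)
            t = (chl - c[i]) / (c[i + 1] - c[i])
            row = self.rel_values[i] + t * (self.rel_values[i + 1] - self.rel_values[i])
        out = np.interp(wl, self.wavelengths, row)
        return out if np.ndim(wavelength) else out

    @classmethod
    def from_csv(cls, path) -> "RelativeUncertaintySurface":
        """Read a surface table: first row wavelengths, first column chl."""
        df = pd.read_csv(path, index_col=0)
        return cls(
            chl_levels=df.index.to_numpy(dtype=float),
            wavelengths=np.array([float(c) for c in df.columns]),
            rel_values=df.to_numpy(dtype=float),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.rel_values,
            index=[f"{c:g}" for c in self.chl_levels],
            columns=[f"{w:g}" for w in self.wavelengths],
        ).to_csv(path)


def flat_u(s: Spectrum, f: FlatRelativeUncertainty) -> Spectrum:
    """Per-band u(Rrs_i) = rel * |Rrs_i| (spectrally flat, uncorrelated)."""
    return s.with_values(f.rel * np.abs(s.values), quantity=f"u({s.quantity})")


def surface_u(t: RelativeUncertaintySurface, s: Spectrum, chl: float) -> Spectrum:
    """Spectrally dependent u(Rrs_i) = rel(lambda_i, chl) * |Rrs_i|.

    ``chl`` is the chlorophyll concentration used to index the surface;
    in the standard workflow it comes from the blended chlorophyll
    algorithm applied to the same spectrum.
    """
    rel = t.rel_at(s.wavelengths, chl)
    return s.with_values(rel * np.abs(s.values), quantity=f"u({s.quantity})")


def build_covariance(u: Spectrum, corr: np.ndarray | None = None) -> SpectralCovariance:
    """Covariance matrix V_ij = corr_ij * u_i * u_j.

    With ``corr`` omitted the result is the diagonal matrix diag(u_i^2)
    (the uncorrelated case).  ``corr`` must be symmetric with unit
    diagonal and entries in [-1, 1].
    """
    uv = u.values
    if np.any(uv < 0):
        raise ValueError("uncertainty vector must be non-negative")
    if corr is None:
        return SpectralCovariance(u.wavelengths, np.diag(uv**2))
    C = np.asarray(corr, dtype=float)
    if C.shape != (uv.size, uv.size):
        raise ValueError(f"correlation shape {C.shape} does not match {uv.size} bands")
    if np.max(np.abs(C - C.T)) > 1e-12:
        raise ValueError("correlation matrix is not symmetric")
    if np.any(np.abs(C) > 1 + 1e-12):
        raise ValueError("correlation entries must lie in [-1, 1]")
    if np.max(np.abs(np.diag(C) - 1.0)) > 1e-12:
        raise ValueError("correlation matrix must have unit diagonal")
    return SpectralCovariance(u.wavelengths, C * np.outer(uv, uv))


def synthetic_demo_surface() -> RelativeUncertaintySurface:
    """Small SYNTHETIC illustrative uncertainty surface (not sensor data).

    Mimics the qualitative behaviour reported for heritage sensors —
    relative uncertainty growing toward the red and with chlorophyll —
    for tests and CLI examples only.
    """
    wl = np.array([400., 450., 500., 550., 600., 650., 700., 720.])
    chl = np.array([0.03, 0.1, 0.2])
    base = 0.03 + 0.10 * (wl - 400.0) / 320.0          # 3% blue -> 13% red
    factor = np.array([1.0, 1.3, 1.7])[:, None]
    return RelativeUncertaintySurface(chl, wl, factor * base[None, :])
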