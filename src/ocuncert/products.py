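"""Forward ocean-color (OC-suite) algorithms with analytic gradients.

Each algorithm returns its derived value together with the analytic
gradient with respect to the input reflectance (or radiance) vector, on
the full input grid, so that the FOFM engine can propagate per-band
uncertainties or a full spectral covariance.

Products:

* ``chl_br``  — chlorophyll from the maximum blue-green band ratio
  (OCx polynomial, mg m^-3);
* ``chl_lh``  — chlorophyll from a three-band line height / color index
  (mg m^-3);
* ``chl_blend`` — the standard blended chlorophyll product switching
  smoothly between the two;
* ``kd490``   — diffuse attenuation coefficient at 490 nm (m^-1);
* ``poc``     — particulate organic carbon from a blue-to-green
  reflectance-ratio power law (mg m^-3);
* ``nflh``    — normalized fluorescence line height from nLw
  (mW cm^-2 um^-1 sr^-1).

Default polynomial coefficients follow the heritage NASA OC4 / CI /
KD2S parameterisations; they are configuration, not results, and every
uncertainty statement in this package is either coefficient-independent
or uses the published POC coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .spectra import DEFAULT_BAND_TOL, Spectrum, nearest_band

__all__ = [
    "AlgorithmDomainError",
    "ProductResult",
    "OCxCoefficients",
    "LineHeightChlCoefficients",
    "BlendWindow",
    "Kd490Coefficients",
    "PocCoefficients",
    "NflhBands",
    "chl_br",
    "chl_lh",
    "chl_blend",
    "kd490",
    "poc",
    "nflh",
    "nflh_from_rrs",
    "rrs_to_nlw",
    "DEFAULT_F0",
]

_LN10 = math.log(10.0)


class AlgorithmDomainError(ValueError):
    """Input spectrum outside the domain of a bio-optical algorithm."""


@dataclass(frozen=True)
class ProductResult:
    """A derived geophysical value with its gradient and provenance flags."""

    name: str
    value: float
    gradient: np.ndarray
    branch: str | None = None
    active_band: float | None = None
    warnings: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Coefficient containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OCxCoefficients:
    """Maximum-band-ratio chlorophyll polynomial (OC4-style)."""

    blue_bands: tuple[float, ...] = (443.0, 490.0, 510.0)
    green_band: float = 555.0
    poly: tuple[float, ...] = (0.3272, -2.9940, 2.7218, -1.2259, -0.5683)

    def __post_init__(self):
        if len(self.poly) != 5:
            raise ValueError("OCx polynomial must have 5 coefficients")


@dataclass(frozen=True)
class LineHeightChlCoefficients:
    """Color-index chlorophyll: linear baseline under the green band."""

    ci_bands: tuple[float, float, float] = (443.0, 555.0, 670.0)
    b0: float = -0.4909
    b1: float = 191.6590

    def __post_init__(self):
        b, g, r = self.ci_bands
        if not b < g < r:
            raise ValueError("CI bands must satisfy blue < green < red")


@dataclass(frozen=True)
class BlendWindow:
    """Chlorophyll interval over which line-height and band-ratio blend."""

    t_low: float = 0.15
    t_high: float = 0.20

    def __post_init__(self):
        if not 0 < self.t_low < self.t_high:
            raise ValueError("require 0 < t_low < t_high")


@dataclass(frozen=True)
class Kd490Coefficients:
    """Blue-green-ratio diffuse-attenuation polynomial with pure-water floor.

    The heritage default is the two-band form (490/555); supplying
    several blue bands activates the same maximum-ratio selection used
    by the band-ratio chlorophyll."""

    blue_bands: tuple[float, ...] = (490.0,)
    green_band: float = 555.0
    poly: tuple[float, ...] = (-0.8515, -1.8263, 1.8714, -2.4414, -1.0690)
    floor: float = 0.0166

    def __post_init__(self):
        if len(self.poly) != 5:
            raise ValueError("Kd490 polynomial must have 5 coefficients")


@dataclass(frozen=True)
class PocCoefficients:
    """Power-law POC from the blue-to-green reflectance ratio.

    POC = a_poc * (Rrs(blue)/Rrs(green))^b_poc with published defaults
    a_poc = 203.2 mg m^-3, b_poc = -1.034.
    """

    a_poc: float = 203.2
    b_poc: float = -1.034
    blue: float = 443.0
    green: float = 555.0

    def __post_init__(self):
        if not self.a_poc > 0:
            raise ValueError("a_poc must be positive")


@dataclass(frozen=True)
class NflhBands:
    """Fluorescence line-height band triplet (left, peak, right).

    Heritage default (667, 678, 748); the sixteen-band visible grid used
    in this package instead supplies (665, 678, 710).
    """

    left: float = 667.0
    peak: float = 678.0
    right: float = 748.0

    def __post_init__(self):
        if not self.left < self.peak < self.right:
            raise ValueError("require left < peak < right")

    @classmethod
    def for_multiband16(cls) -> "NflhBands":
        return cls(665.0, 678.0, 710.0)


# ---------------------------------------------------------------------------
# Maximum band-ratio machinery shared by chl_br and kd490
# ---------------------------------------------------------------------------

def _max_ratio_poly(
    s: Spectrum,
    blue_bands: tuple[float, ...],
    green_band: float,
    poly: tuple[float, ...],
    tol: float,
    name: str,
):
    """value = 10^(sum a_k chi^k), chi = log10(max_blue Rrs_b / Rrs_g).

    Gradient is nonzero only on the active (maximum) blue band and the
    green band.  A tie between blue bands is broken toward the shortest
    wavelength and flagged (the derivative is discontinuous there).
    """
    ig = nearest_band(s, green_band, tol)
    Rg = s.values[ig]
    if Rg <= 0:
        raise AlgorithmDomainError(f"{name}: non-positive green band Rrs")
    idx_blue = [nearest_band(s, b, tol) for b in blue_bands]
    blue_vals = s.values[np.array(idx_blue)]
    k = int(np.argmax(blue_vals))          # argmax returns first (shortest) at ties
    Rb = blue_vals[k]
    ib = idx_blue[k]
    if Rb <= 0:
        raise AlgorithmDomainError(f"{name}: non-positive maximum band ratio")
    warn: tuple[str, ...] = ()
    if np.sum(blue_vals == Rb) > 1:
        warn = ("max-band-ratio tie: gradient discontinuous, "
                "shortest wavelength chosen",)
    chi = math.log10(Rb / Rg)
    p = np.polyval(poly[::-1], chi)
    dp = np.polyval(np.polyder(np.array(poly[::-1])), chi)
    value = 10.0 ** p
    g = np.zeros(len(s))
    # d(10^p)/dR = 10^p * ln10 * dp/dchi * dchi/dR ; dchi/dRb = 1/(ln10 Rb)
    g[ib] = value * dp / Rb
    g[ig] = -value * dp / Rg
    return value, g, float(s.wavelengths[ib]), warn


def chl_br(s: Spectrum, c: OCxCoefficients = OCxCoefficients(),
           tol: float = DEFAULT_BAND_TOL) -> ProductResult:
    """Band-ratio chlorophyll (OCx maximum blue-green ratio), mg m^-3."""
    value, g, active, warn = _max_ratio_poly(
        s, c.blue_bands, c.green_band, c.poly, tol, "chl_br")
    return ProductResult("chl_br", value, g, branch="BR",
                         active_band=active, warnings=warn)


def chl_lh(s: Spectrum, c: LineHeightChlCoefficients = LineHeightChlCoefficients(),
           tol: float = DEFAULT_BAND_TOL) -> ProductResult:
    """Line-height (color index) chlorophyll, mg m^-3.

    CI = Rrs_g - [Rrs_b + w (Rrs_r - Rrs_b)], w = (lg-lb)/(lr-lb);
    Chl = 10^(b0 + b1 CI).
    """
    lb, lg, lr = c.ci_bands
    ib, ig, ir = (nearest_band(s, x, tol) for x in (lb, lg, lr))
    # weight from the actual grid wavelengths, not the nominal names
    wb, wg, wr = s.wavelengths[ib], s.wavelengths[ig], s.wavelengths[ir]
    w = (wg - wb) / (wr - wb)
    ci = s.values[ig] - (s.values[ib] + w * (s.values[ir] - s.values[ib]))
    value = 10.0 ** (c.b0 + c.b1 * ci)
    dvdci = _LN10 * c.b1 * value
    g = np.zeros(len(s))
    g[ib] = -dvdci * (1.0 - w)
    g[ig] = dvdci
    g[ir] = -dvdci * w
    return ProductResult("chl_lh", value, g, branch="LH")


def chl_blend(
    s: Spectrum,
    ocx: OCxCoefficients = OCxCoefficients(),
    lh: LineHeightChlCoefficients = LineHeightChlCoefficients(),
    window: BlendWindow = BlendWindow(),
    tol: float = DEFAULT_BAND_TOL,
) -> ProductResult:
    """Blended chlorophyll: line height below the window, band ratio above.

    Inside the window the value is the convex combination
    alpha*Chl_BR + (1-alpha)*Chl_LH with alpha driven by Chl_LH; the
    gradient includes the d(alpha)/dRrs cross terms, so it is the full
    first-order derivative of the blended value.
    """
    r_lh = chl_lh(s, lh, tol)
    if r_lh.value <= window.t_low:
        return ProductResult("chl", r_lh.value, r_lh.gradient, branch="LH")
    r_br = chl_br(s, ocx, tol)
    if r_lh.value >= window.t_high:
        return ProductResult("chl", r_br.value, r_br.gradient, branch="BR",
                             active_band=r_br.active_band,
                             warnings=r_br.warnings)
    span = window.t_high - window.t_low
    alpha = (r_lh.value - window.t_low) / span
    value = alpha * r_br.value + (1.0 - alpha) * r_lh.value
    dalpha = r_lh.gradient / span
    g = (alpha * r_br.gradient + (1.0 - alpha) * r_lh.gradient
         + (r_br.value - r_lh.value) * dalpha)
    return ProductResult("chl", value, g, branch="blended",
                         active_band=r_br.active_band,
                         warnings=r_br.warnings)


def kd490(s: Spectrum, c: Kd490Coefficients = Kd490Coefficients(),
          tol: float = DEFAULT_BAND_TOL) -> ProductResult:
    """Diffuse attenuation coefficient at 490 nm, m^-1.

    Kd = floor + 10^(sum c_k chi^k) with the same maximum blue-green
    ratio construction as the band-ratio chlorophyll.
    """
    v, g, active, warn = _max_ratio_poly(
        s, c.blue_bands, c.green_band, c.poly, tol, "kd490")
    return ProductResult("kd490", c.floor + v, g,
                         active_band=active, warnings=warn)


def poc(s: Spectrum, c: PocCoefficients = PocCoefficients(),
        tol: float = DEFAULT_BAND_TOL) -> ProductResult:
    """Particulate organic carbon, mg m^-3.

    POC = a (Rb/Rg)^b; gradient (b*POC/Rb, -b*POC/Rg) on the two bands.
    """
    ib = nearest_band(s, c.blue, tol)
    ig = nearest_band(s, c.green, tol)
    Rb, Rg = s.values[ib], s.values[ig]
    if Rb <= 0 or Rg <= 0:
        raise AlgorithmDomainError("poc: non-positive reflectance band")
    value = c.a_poc * (Rb / Rg) ** c.b_poc
    g = np.zeros(len(s))
    g[ib] = c.b_poc * value / Rb
    g[ig] = -c.b_poc * value / Rg
    return ProductResult("poc", value, g)


def nflh(nlw: Spectrum, b: NflhBands = NflhBands(),
         tol: float = DEFAULT_BAND_TOL) -> ProductResult:
    """Normalized fluorescence line height, mW cm^-2 um^-1 sr^-1.

    Peak nLw above the linear baseline between the left and right bands.
    The model is linear, so the gradient is the constant coefficient
    vector and FOFM is exact.
    """
    il = nearest_band(nlw, b.left, tol)
    ip = nearest_band(nlw, b.peak, tol)
    ir = nearest_band(nlw, b.right, tol)
    wl, wp, wr = nlw.wavelengths[il], nlw.wavelengths[ip], nlw.wavelengths[ir]
    w = (wp - wl) / (wr - wl)
    value = nlw.values[ip] - (nlw.values[il]
                              + w * (nlw.values[ir] - nlw.values[il]))
    g = np.zeros(len(nlw))
    g[il] = -(1.0 - w)
    g[ip] = 1.0
    g[ir] = -w
    return ProductResult("nflh", value, g)


# ---------------------------------------------------------------------------
# Rrs -> nLw helper
# ---------------------------------------------------------------------------

#: Approximate band-averaged mean extraterrestrial solar irradiance
#: (mW cm^-2 um^-1) on the sixteen-band grid, after standard solar
#: reference spectra.  Configuration values: update per sensor as needed.
DEFAULT_F0: dict[float, float] = {
    412.0: 170.79, 425.0: 170.23, 443.0: 189.45, 460.0: 206.07,
    475.0: 203.70, 490.0: 193.66, 510.0: 192.85, 532.0: 188.57,
    555.0: 185.33, 583.0: 181.68, 617.0: 172.96, 640.0: 166.00,
    655.0: 161.28, 665.0: 158.43, 678.0: 154.63, 710.0: 143.90,
}


def nflh_from_rrs(s: Spectrum, b: NflhBands | None = None,
                  f0: dict[float, float] | None = None,
                  tol: float = DEFAULT_BAND_TOL) -> ProductResult:
    """nflh computed from an Rrs spectrum (nLw = F0 * Rrs internally).

    The gradient is returned with respect to Rrs (the conversion is
    linear and diagonal, so the chain rule is exact): d nflh/dRrs_i =
    F0_i * d nflh/dnLw_i.  Convenient when a whole batch is driven from
    Rrs tables with a single uncertainty model.
    """
    if b is None:
        b = NflhBands.for_multiband16()
    nlw = rrs_to_nlw(s, f0, tol)
    res = nflh(nlw, b, tol)
    scale = np.where(s.values != 0, nlw.values / s.values, 0.0)
    # F0 per band even where Rrs == 0
    if np.any(s.values == 0):
        table = DEFAULT_F0 if f0 is None else f0
        probe = Spectrum(np.asarray(sorted(table)), np.zeros(len(table)), "F0")
        for i in np.flatnonzero(s.values == 0):
            scale[i] = table[float(
                probe.wavelengths[nearest_band(probe, s.wavelengths[i], tol)])]
    return ProductResult("nflh", res.value, res.gradient * scale)


def rrs_to_nlw(s: Spectrum, f0: dict[float, float] | None = None,
               tol: float = DEFAULT_BAND_TOL) -> Spectrum:
    """Convert Rrs (sr^-1) to nLw (mW cm^-2 um^-1 sr^-1): nLw = F0 * Rrs.

    ``f0`` maps nominal band centres to mean extraterrestrial solar
    irradiance; bands absent from the table raise a missing-band error.
    Because the conversion is linear and diagonal, perturbing nLw is
    equivalent to perturbing Rrs scaled by F0 — the Monte-Carlo engine
    and FOFM gradients both operate on the quantity actually perturbed.
    """
    table = DEFAULT_F0 if f0 is None else f0
    probe = Spectrum(np.asarray(sorted(table)), np.zeros(len(table)), "F0")
    scale = np.array([table[float(probe.wavelengths[nearest_band(probe, w, tol)])]
                      for w in s.wavelengths])
    return Spectrum(s.wavelengths, scale * s.values, "nLw")
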