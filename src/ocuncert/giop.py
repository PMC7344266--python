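"""Default-configuration GIOP: forward reflectance model, inversion,
and Jacobian-based parameter/IOP uncertainties.

The Generalized Inherent Optical Properties (GIOP) model describes the
sub-surface remote-sensing reflectance rrs (sr^-1) as a quadratic in
u = bb/(a + bb):

    rrs_i = g1 u_i + g2 u_i^2

with total absorption and backscattering decomposed as

    a_i  = aw_i + x_phi * aphi*_i + x_dg * exp(-S_dg (lambda_i - 443))
    bb_i = bbw_i + x_bp * (443 / lambda_i)^gamma

The three amplitudes x_phi (chlorophyll-like, mg m^-3), x_dg
(detrital+dissolved absorption at 443 nm, m^-1) and x_bp (particulate
backscattering at 443 nm, m^-1) are retrieved by non-linear least
squares with an unweighted cost function; the power-law exponent gamma
is fixed beforehand from an rrs band ratio, not fitted.

Parameter uncertainty follows the Gauss-Markov sandwich

    E_x = (J^T J)^-1 J^T V J (J^T J)^-1

where J is the Jacobian of the forward model and V is either the
radiometric rrs covariance (data uncertainty) or the diagonal matrix of
squared fit residuals (model-misfit uncertainty).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .spectra import (DEFAULT_BAND_TOL, MULTIBAND_16, SpectralCovariance,
                      Spectrum, nearest_band)

__all__ = [
    "GIOPConfig",
    "GIOPState",
    "IOPValue",
    "IOPResult",
    "DEFAULT_BBP_GAMMA_COV",
    "rrs_from_Rrs",
    "Rrs_from_rrs",
    "drrs_dRrs",
    "gamma_from_rrs",
    "giop_forward",
    "giop_jacobian",
    "giop_invert",
    "param_covariance",
    "misfit_uncertainty",
    "derived_iops",
    "bbp_shift",
]

#: Default covariance between bbp at the reference band and gamma
#: (m^-1 nm^-1), as estimated for heritage-sensor retrievals.
DEFAULT_BBP_GAMMA_COV = -1.64e-6

_REF_WL = 443.0

# Bundled pure-water absorption (m^-1) on the sixteen-band grid,
# after standard clear-water laboratory determinations (approximate
# band-centre values; configuration, not results).
_AW_16 = {
    412.0: 0.00455, 425.0: 0.00503, 443.0: 0.00706, 460.0: 0.00909,
    475.0: 0.01140, 490.0: 0.01500, 510.0: 0.03250, 532.0: 0.04440,
    555.0: 0.05960, 583.0: 0.09270, 617.0: 0.27550, 640.0: 0.32920,
    655.0: 0.38010, 665.0: 0.42430, 678.0: 0.46220, 710.0: 0.84110,
}

# Chl-specific phytoplankton absorption shape normalized to 443 nm,
# times a 0.055 m^2 mg^-1 amplitude (Bricaud-style mean shape).
_APHI_SHAPE_16 = {
    412.0: 0.70, 425.0: 0.80, 443.0: 1.00, 460.0: 0.92, 475.0: 0.80,
    490.0: 0.67, 510.0: 0.44, 532.0: 0.29, 555.0: 0.18, 583.0: 0.11,
    617.0: 0.12, 640.0: 0.15, 655.0: 0.22, 665.0: 0.30, 678.0: 0.37,
    710.0: 0.04,
}
_APHI_STAR_443 = 0.055


def _default_aw() -> Spectrum:
    wl = np.array(sorted(_AW_16))
    return Spectrum(wl, [_AW_16[w] for w in wl], "aw")


def _default_bbw() -> Spectrum:
    # Power-law pure-seawater backscattering, bbw(443) = 1.22e-3 m^-1
    wl = np.array(sorted(_AW_16))
    return Spectrum(wl, 1.22e-3 * (443.0 / wl) ** 4.32, "bbw")


def _default_aphi_star() -> Spectrum:
    wl = np.array(sorted(_APHI_SHAPE_16))
    vals = _APHI_STAR_443 * np.array([_APHI_SHAPE_16[w] for w in wl])
    return Spectrum(wl, vals, "aphi*")


@dataclass(frozen=True)
class GammaRule:
    """gamma = p0 * (1 - p1 * exp(-p2 * rrs(blue)/rrs(green))).

    The QAA-style spectral-slope rule used by the default GIOP
    configuration.  Setting p1 = 0 makes gamma the constant p0.
    """

    p0: float = 2.0
    p1: float = 1.2
    p2: float = 0.9
    blue: float = 443.0
    green: float = 555.0


@dataclass(frozen=True)
class GIOPConfig:
    """Configuration of the GIOP forward model and its inversion."""

    fit_bands: tuple[float, ...] = (412., 425., 443., 460., 475., 490.,
                                    510., 532., 555., 583., 617., 640., 655.)
    g1: float = 0.0949          # sr^-1
    g2: float = 0.0794          # sr^-1
    s_dg: float = 0.018         # nm^-1, detrital/dissolved spectral slope
    aphi_star: Spectrum = field(default_factory=_default_aphi_star)
    aw: Spectrum = field(default_factory=_default_aw)
    bbw: Spectrum = field(default_factory=_default_bbw)
    gamma_rule: GammaRule = field(default_factory=GammaRule)
    x0: tuple[float, float, float] = (0.1, 0.01, 1e-3)
    ftol: float = 1e-10
    xtol: float = 1e-10
    max_nfev: int = 200

    def __post_init__(self):
        if not (self.g1 > 0 and self.g2 >= 0 and self.s_dg > 0):
            raise ValueError("require g1 > 0, g2 >= 0, s_dg > 0")
        for table, name in ((self.aw, "aw"), (self.bbw, "bbw"),
                            (self.aphi_star, "aphi_star")):
            for b in self.fit_bands:
                nearest_band(table, b, DEFAULT_BAND_TOL)

    def _tables_on_fit_bands(self):
        """(wavelengths, aw, bbw, aphi*) resolved on the fit-band grid."""
        wl = np.array([
            self.aw.wavelengths[nearest_band(self.aw, b)] for b in self.fit_bands
        ])
        aw = np.array([self.aw.band_value(b) for b in self.fit_bands])
        bbw = np.array([self.bbw.band_value(b) for b in self.fit_bands])
        ap = np.array([self.aphi_star.band_value(b) for b in self.fit_bands])
        return wl, aw, bbw, ap

    @property
    def aphi_star_443(self) -> float:
        return self.aphi_star.band_value(_REF_WL)


@dataclass
class GIOPState:
    """Result of a GIOP inversion on one spectrum."""

    x: np.ndarray                  # (x_phi, x_dg, x_bp)
    gamma: float
    wavelengths: np.ndarray        # fit-band grid
    rrs_obs: np.ndarray
    rrs_mod: np.ndarray
    residuals: np.ndarray          # rrs_obs - rrs_mod, sr^-1
    jacobian: np.ndarray           # d rrs_mod / d x, (n_bands, 3)
    Rrs_obs: np.ndarray            # above-water Rrs on fit bands
    success: bool
    message: str = ""
    cost: float = float("nan")

    @property
    def x_phi(self) -> float:
        return float(self.x[0])

    @property
    def x_dg(self) -> float:
        return float(self.x[1])

    @property
    def x_bp(self) -> float:
        return float(self.x[2])


@dataclass(frozen=True)
class IOPValue:
    """A derived IOP with data- and misfit-uncertainty components (m^-1)."""

    value: float
    u_data: float = float("nan")
    u_misfit: float = float("nan")


@dataclass(frozen=True)
class IOPResult:
    """IOPs at 443 nm: total non-water, phytoplankton, detrital+dissolved
    absorption and particulate backscattering."""

    a_nw: IOPValue
    a_phi: IOPValue
    a_dg: IOPValue
    b_bp: IOPValue


# ---------------------------------------------------------------------------
# Air-water interface transform
# ---------------------------------------------------------------------------

def rrs_from_Rrs(R: Spectrum) -> Spectrum:
    """Sub-surface rrs from above-water Rrs: rrs = Rrs/(0.52 + 1.7 Rrs)."""
    return R.with_values(R.values / (0.52 + 1.7 * R.values), "rrs")


def Rrs_from_rrs(r: Spectrum) -> Spectrum:
    """Inverse transform: Rrs = 0.52 rrs / (1 - 1.7 rrs)."""
    return r.with_values(0.52 * r.values / (1.0 - 1.7 * r.values), "Rrs")


def drrs_dRrs(Rrs_values: np.ndarray) -> np.ndarray:
    """Exact derivative of the interface transform, 0.52/(0.52+1.7 Rrs)^2."""
    return 0.52 / (0.52 + 1.7 * np.asarray(Rrs_values, float)) ** 2


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def gamma_from_rrs(rrs: Spectrum, rule: GammaRule = GammaRule(),
                   tol: float = DEFAULT_BAND_TOL) -> float:
    """Particulate-backscattering spectral slope from an rrs band ratio."""
    rb = rrs.band_value(rule.blue, tol)
    rg = rrs.band_value(rule.green, tol)
    if rb <= 0 or rg <= 0:
        raise ValueError("gamma rule requires positive rrs at both bands")
    return rule.p0 * (1.0 - rule.p1 * math.exp(-rule.p2 * rb / rg))


def _forward_arrays(x, cfg: GIOPConfig, gamma: float):
    wl, aw, bbw, ap = cfg._tables_on_fit_bands()
    x_phi, x_dg, x_bp = float(x[0]), float(x[1]), float(x[2])
    a = aw + x_phi * ap + x_dg * np.exp(-cfg.s_dg * (wl - _REF_WL))
    bb = bbw + x_bp * (_REF_WL / wl) ** gamma
    t = a + bb
    if np.any(t <= 0):
        raise ValueError("non-positive total a + bb in GIOP forward model")
    u = bb / t
    rrs = cfg.g1 * u + cfg.g2 * u**2
    return wl, a, bb, u, rrs


def giop_forward(x, cfg: GIOPConfig = GIOPConfig(), gamma: float = 1.0) -> Spectrum:
    """Model sub-surface reflectance rrs_mod on the fit bands."""
    wl, _, _, _, rrs = _forward_arrays(x, cfg, gamma)
    return Spectrum(wl, rrs, "rrs")


def giop_jacobian(x, cfg: GIOPConfig = GIOPConfig(), gamma: float = 1.0) -> np.ndarray:
    """Analytic Jacobian d rrs_mod,i / d x_k, shape (n_bands, 3)."""
    wl, a, bb, u, _ = _forward_arrays(x, cfg, gamma)
    _, aw, bbw, ap = cfg._tables_on_fit_bands()
    t = a + bb
    drrs_du = cfg.g1 + 2.0 * cfg.g2 * u
    du_da = -u / t                       # = -bb/t^2
    du_dbb = (1.0 - u) / t               # =  a/t^2
    da_dphi = ap
    da_ddg = np.exp(-cfg.s_dg * (wl - _REF_WL))
    dbb_dbp = (_REF_WL / wl) ** gamma
    J = np.empty((wl.size, 3))
    J[:, 0] = drrs_du * du_da * da_dphi
    J[:, 1] = drrs_du * du_da * da_ddg
    J[:, 2] = drrs_du * du_dbb * dbb_dbp
    return J


# ---------------------------------------------------------------------------
# Inversion
# ---------------------------------------------------------------------------

def giop_invert(R: Spectrum, cfg: GIOPConfig = GIOPConfig(),
                tol: float = DEFAULT_BAND_TOL) -> GIOPState:
    """Retrieve (x_phi, x_dg, x_bp) from an above-water Rrs spectrum.

    gamma is fixed from the observed rrs ratio before fitting.  The cost
    function is the unweighted sum of squared rrs residuals, minimised
    by a Levenberg-Marquardt-type trust-region scheme with x >= 0
    bounds.  Non-convergence or a degenerate (non-positive) observation
    is returned as a flagged state rather than an exception, mirroring
    per-pixel product-failure masking in satellite processing.
    """
    idx = [nearest_band(R, b, tol) for b in cfg.fit_bands]
    wl = R.wavelengths[np.array(idx)]
    Rfit = R.values[np.array(idx)]
    rrs_obs = Rfit / (0.52 + 1.7 * Rfit)
    n = wl.size

    def failed(msg: str) -> GIOPState:
        return GIOPState(
            x=np.full(3, np.nan), gamma=float("nan"), wavelengths=wl,
            rrs_obs=rrs_obs, rrs_mod=np.full(n, np.nan),
            residuals=np.full(n, np.nan), jacobian=np.full((n, 3), np.nan),
            Rrs_obs=Rfit, success=False, message=msg,
        )

    if np.max(rrs_obs) <= 0:
        return failed("non-positive rrs observation")
    try:
        gamma = gamma_from_rrs(Spectrum(wl, rrs_obs, "rrs"), cfg.gamma_rule, tol)
    except ValueError as exc:
        return failed(f"gamma rule failed: {exc}")

    def resid(x):
        return giop_forward(x, cfg, gamma).values - rrs_obs

    def jac(x):
        return giop_jacobian(x, cfg, gamma)

    try:
        sol = least_squares(
            resid, x0=np.asarray(cfg.x0, float), jac=jac,
            bounds=(0.0, np.inf), method="trf",
            ftol=cfg.ftol, xtol=cfg.xtol, gtol=None, max_nfev=cfg.max_nfev,
        )
    except Exception as exc:          # pragma: no cover - defensive
        return failed(f"optimizer error: {exc}")
    if not sol.success:
        return failed(f"non-convergence: {sol.message}")
    rrs_mod = giop_forward(sol.x, cfg, gamma).values
    return GIOPState(
        x=sol.x, gamma=gamma, wavelengths=wl, rrs_obs=rrs_obs,
        rrs_mod=rrs_mod, residuals=rrs_obs - rrs_mod,
        jacobian=giop_jacobian(sol.x, cfg, gamma), Rrs_obs=Rfit,
        success=True, message=sol.message, cost=float(sol.cost),
    )


# ---------------------------------------------------------------------------
# Parameter uncertainty
# ---------------------------------------------------------------------------

def param_covariance(J: np.ndarray, V) -> np.ndarray:
    """Parameter error covariance via the Gauss-Markov sandwich.

    E_x = (J^T J)^-1 J^T V J (J^T J)^-1.  For a square invertible J this
    reduces to J^-1 V (J^T)^-1.  ``V`` may be a SpectralCovariance or a
    plain (n, n) array over the same bands as J's rows.
    """
    J = np.asarray(J, float)
    Vm = V.matrix if isinstance(V, SpectralCovariance) else np.asarray(V, float)
    n, p = J.shape
    if Vm.shape != (n, n):
        raise ValueError(f"V shape {Vm.shape} does not match {n} bands")
    s = np.linalg.svd(J, compute_uv=False)
    if s[-1] <= 0 or s[0] / s[-1] > 1e12:
        raise np.linalg.LinAlgError(
            f"Jacobian rank-deficient (condition number "
            f"{s[0] / max(s[-1], 1e-300):.3g})"
        )
    JtJ_inv = np.linalg.inv(J.T @ J)
    A = JtJ_inv @ J.T              # pseudo-inverse of J
    return A @ Vm @ A.T


def misfit_uncertainty(state: GIOPState, cfg: GIOPConfig | None = None) -> np.ndarray:
    """Per-parameter model-misfit uncertainty.

    Sets the residual covariance to diag(eps_rrs,i^2) — attributing the
    optimal-fit residual entirely to model imperfection — and returns
    sqrt(diag(E_x)) for (x_phi, x_dg, x_bp).
    """
    if not state.success:
        raise ValueError("misfit uncertainty requires a converged state")
    E_rrs = np.diag(state.residuals**2)
    Ex = param_covariance(state.jacobian, E_rrs)
    return np.sqrt(np.clip(np.diag(Ex), 0.0, None))


def _rrs_covariance_on_fit_bands(state: GIOPState, V_Rrs) -> np.ndarray:
    """Chain an Rrs uncertainty description into rrs space on fit bands."""
    wl = state.wavelengths
    D = drrs_dRrs(state.Rrs_obs)
    if isinstance(V_Rrs, SpectralCovariance):
        sub = V_Rrs.subset(wl) if len(V_Rrs) != wl.size or \
            not np.allclose(V_Rrs.wavelengths, wl) else V_Rrs
        return (D[:, None] * sub.matrix) * D[None, :]
    if isinstance(V_Rrs, Spectrum):       # per-band u(Rrs), uncorrelated
        u = np.array([V_Rrs.band_value(w) for w in wl])
        return np.diag((D * u) ** 2)
    raise TypeError("V_Rrs must be a SpectralCovariance or a u(Rrs) Spectrum")


def derived_iops(state: GIOPState, cfg: GIOPConfig, V_Rrs=None,
                 include_misfit: bool = True) -> IOPResult:
    """IOPs at 443 nm with data and model-misfit uncertainties.

    a_phi,443 = x_phi * aphi*(443); a_dg,443 = x_dg; b_bp,443 = x_bp;
    a_nw,443 = a_phi,443 + a_dg,443.  Data uncertainties propagate the
    radiometric covariance (chained through the air-water interface
    transform) into parameter space; the a_nw uncertainty includes the
    x_phi - x_dg covariance term.
    """
    if not state.success:
        raise ValueError("derived IOPs require a converged state")
    astar = cfg.aphi_star_443
    a_phi = state.x_phi * astar
    a_dg = state.x_dg
    b_bp = state.x_bp

    def combine(Ex: np.ndarray) -> tuple[float, float, float, float]:
        u_phi = astar * math.sqrt(max(Ex[0, 0], 0.0))
        u_dg = math.sqrt(max(Ex[1, 1], 0.0))
        u_bp = math.sqrt(max(Ex[2, 2], 0.0))
        var_nw = astar**2 * Ex[0, 0] + Ex[1, 1] + 2.0 * astar * Ex[0, 1]
        return math.sqrt(max(var_nw, 0.0)), u_phi, u_dg, u_bp

    u_nw_d = u_phi_d = u_dg_d = u_bp_d = float("nan")
    if V_Rrs is not None:
        Vrrs = _rrs_covariance_on_fit_bands(state, V_Rrs)
        u_nw_d, u_phi_d, u_dg_d, u_bp_d = combine(
            param_covariance(state.jacobian, Vrrs))
    u_nw_m = u_phi_m = u_dg_m = u_bp_m = float("nan")
    if include_misfit:
        Ex_m = param_covariance(state.jacobian, np.diag(state.residuals**2))
        u_nw_m, u_phi_m, u_dg_m, u_bp_m = combine(Ex_m)

    return IOPResult(
        a_nw=IOPValue(a_phi + a_dg, u_nw_d, u_nw_m),
        a_phi=IOPValue(a_phi, u_phi_d, u_phi_m),
        a_dg=IOPValue(a_dg, u_dg_d, u_dg_m),
        b_bp=IOPValue(b_bp, u_bp_d, u_bp_m),
    )


def bbp_shift(
    bbp_ref: float,
    gamma: float,
    wavelength: float,
    ref_wavelength: float = _REF_WL,
    u_bbp: float = 0.0,
    u_gamma: float = 0.0,
    cov: float = 0.0,
) -> tuple[float, float]:
    """Shift particulate backscattering to another wavelength.

    value = bbp_ref * (ref/lambda)^gamma; the uncertainty combines
    u(bbp_ref), u(gamma) and their covariance:

        u^2 = d1^2 u^2(bbp) + d2^2 u^2(gamma) + 2 d1 d2 cov

    with d1 = (ref/lambda)^gamma and d2 = value * ln(ref/lambda).
    """
    if wavelength <= 0 or ref_wavelength <= 0:
        raise ValueError("wavelengths must be positive")
    if bbp_ref < 0:
        raise ValueError("bbp must be non-negative")
    ratio = ref_wavelength / wavelength
    d1 = ratio**gamma
    value = bbp_ref * d1
    d2 = value * math.log(ratio)
    var = d1**2 * u_bbp**2 + d2**2 * u_gamma**2 + 2.0 * d1 * d2 * cov
    return value, math.sqrt(max(var, 0.0))
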