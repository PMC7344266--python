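import math

import numpy as np
import pytest

from ocuncert import (GIOPConfig, Rrs_from_rrs, Spectrum, bbp_shift,
                      build_covariance, derived_iops, flat_u,
                      FlatRelativeUncertainty, gamma_from_rrs, giop_forward,
                      giop_invert, giop_jacobian, misfit_uncertainty,
                      numeric_gradient, param_covariance, rrs_from_Rrs)
from ocuncert.giop import GammaRule, drrs_dRrs


class TestInterfaceTransform:
    def test_zero_maps_to_zero(self):
        r = rrs_from_Rrs(Spectrum([443.0], [0.0]))
        assert r.values[0] == 0.0

    def test_known_value(self):
        r = rrs_from_Rrs(Spectrum([443.0], [0.01]))
        assert r.values[0] == pytest.approx(0.01 / 0.537, rel=1e-9)
        assert r.values[0] == pytest.approx(0.0186220, abs=1e-6)

    def test_roundtrip_identity(self):
        x = np.linspace(0.0, 0.05, 40)
        wl = np.linspace(400.0, 700.0, 40)
        back = Rrs_from_rrs(rrs_from_Rrs(Spectrum(wl, x)))
        assert np.allclose(back.values, x, atol=1e-12)

    def test_derivative_matches_numeric(self):
        s = Spectrum([443.0, 555.0], [0.01, 0.004])
        g = numeric_gradient(
            lambda sp: float(np.sum(rrs_from_Rrs(sp).values)), s)
        assert np.allclose(g, drrs_dRrs(s.values), rtol=1e-7)


class TestForwardModel:
    def test_linear_when_quadratic_term_off(self, unit_giop):
        from dataclasses import replace
        cfg = replace(unit_giop, g2=0.0)
        rrs = giop_forward((0.05, 0.0, 0.0), cfg, gamma=1.0)
        wl = np.array(cfg.fit_bands)
        a = 0.01 + 0.05
        bb = 0.001
        assert np.allclose(rrs.values, cfg.g1 * bb / (a + bb), rtol=1e-12)

    def test_known_quadratic_value(self):
        # a = 0.1, bb = 0.01 -> u = 1/11; rrs = g1 u + g2 u^2
        u = 1.0 / 11.0
        expected = 0.0949 * u + 0.0794 * u * u
        assert expected == pytest.approx(0.0092835, abs=1e-6)
        wl = np.array([443.0])
        cfg = GIOPConfig(
            fit_bands=(443.0,),
            aphi_star=Spectrum(wl, [1.0], "aphi*"),
            aw=Spectrum(wl, [0.05], "aw"),
            bbw=Spectrum(wl, [0.004], "bbw"),
            gamma_rule=GammaRule(p0=1.0, p1=0.0, blue=443.0, green=443.0),
        )
        rrs = giop_forward((0.05, 0.0, 0.006), cfg, gamma=1.0)
        assert rrs.values[0] == pytest.approx(expected, rel=1e-10)

    def test_water_only_floor_is_positive(self, giop16):
        rrs = giop_forward((0.0, 0.0, 0.0), giop16, gamma=1.0)
        assert np.all(rrs.values > 0)


class TestGammaRule:
    def test_degenerate_rule_returns_constant(self, unit_giop):
        s = Spectrum([443.0, 555.0], [0.01, 0.004], "rrs")
        assert gamma_from_rrs(s, GammaRule(p0=1.7, p1=0.0)) == pytest.approx(1.7)

    def test_monotone_in_band_ratio(self):
        rule = GammaRule()
        ratios = np.linspace(0.2, 8.0, 200)
        gammas = [gamma_from_rrs(
            Spectrum([443.0, 555.0], [r * 0.004, 0.004], "rrs"), rule)
            for r in ratios]
        assert np.all(np.diff(gammas) > 0)

    def test_pure_function(self, one_spectrum):
        r = rrs_from_Rrs(one_spectrum)
        assert gamma_from_rrs(r) == gamma_from_rrs(r)

    def test_nonpositive_band_rejected(self):
        with pytest.raises(ValueError):
            gamma_from_rrs(Spectrum([443.0, 555.0], [-0.01, 0.004], "rrs"))


class TestJacobian:
    def test_reference_band_dg_column(self, unit_giop):
        """At 443 nm the detrital exponential factor is exactly 1, so the
        x_dg column equals the x_phi column there (unit aphi*)."""
        J = giop_jacobian((0.05, 0.01, 0.002), unit_giop, gamma=1.0)
        i443 = 0
        assert J[i443, 0] == pytest.approx(J[i443, 1], rel=1e-12)

    def test_columns_match_central_differences(self, giop16):
        x0 = np.array([0.3, 0.01, 0.002])
        gamma = 1.2
        wl = giop_forward(x0, giop16, gamma).wavelengths
        for k in range(3):
            def f(xk, k=k):
                x = x0.copy()
                x[k] = xk
                return giop_forward(x, giop16, gamma).values
            h = 1e-6 * max(abs(x0[k]), 1e-3)
            num = (f(x0[k] + h) - f(x0[k] - h)) / (2 * h)
            J = giop_jacobian(x0, giop16, gamma)
            assert np.allclose(J[:, k], num, rtol=1e-5)

    def test_linear_in_reflectance_coefficients(self, unit_giop):
        from dataclasses import replace
        x = (0.05, 0.01, 0.002)
        J1 = giop_jacobian(x, unit_giop, gamma=1.0)
        J2 = giop_jacobian(x, replace(unit_giop, g1=2 * unit_giop.g1,
                                      g2=2 * unit_giop.g2), gamma=1.0)
        assert np.allclose(J2, 2.0 * J1, rtol=1e-12)


class TestInversion:
    def test_noiseless_roundtrip_recovers_parameters(self, giop16,
                                                     synthetic_spectra):
        spectra, truth = synthetic_spectra
        for s, (_, row) in zip(spectra[:8], truth.iterrows()):
            state = giop_invert(s, giop16)
            assert state.success
            x_true = row[["x_phi", "x_dg", "x_bp"]].to_numpy()
            assert np.allclose(state.x, x_true, rtol=1e-4)
            assert np.max(np.abs(state.residuals)) < 1e-9

    def test_all_negative_input_flagged_not_raised(self, giop16):
        wl = np.array(giop16.fit_bands)
        s = Spectrum(wl, np.full(wl.size, -0.001))
        state = giop_invert(s, giop16)
        assert not state.success
        assert np.isnan(state.x).all()


class TestParamCovariance:
    def test_single_band_single_parameter(self):
        Ex = param_covariance(np.array([[2.0]]), np.array([[9.0]]))
        assert math.sqrt(Ex[0, 0]) == pytest.approx(3.0 / 2.0)

    def test_two_band_averaging(self):
        J = np.array([[1.0], [1.0]])
        Ex = param_covariance(J, 4.0 * np.eye(2))
        assert math.sqrt(Ex[0, 0]) == pytest.approx(2.0 / math.sqrt(2.0))

    def test_homogeneous_in_covariance_scale(self, giop16, one_spectrum):
        state = giop_invert(one_spectrum, giop16)
        V = np.diag(np.full(len(state.wavelengths), 1e-8))
        E1 = param_covariance(state.jacobian, V)
        E2 = param_covariance(state.jacobian, 4.0 * V)
        assert np.allclose(E2, 4.0 * E1, rtol=1e-10)

    def test_white_noise_reduces_to_classic_form(self, giop16, one_spectrum):
        state = giop_invert(one_spectrum, giop16)
        J = state.jacobian
        sigma2 = 1e-8
        Ex = param_covariance(J, sigma2 * np.eye(J.shape[0]))
        assert np.allclose(Ex, sigma2 * np.linalg.inv(J.T @ J), rtol=1e-10)

    def test_rank_deficient_jacobian_reports_condition(self):
        J = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(np.linalg.LinAlgError, match="condition"):
            param_covariance(J, np.eye(3))

    def test_psd_covariance_gives_nonnegative_variances(self, giop16,
                                                        one_spectrum):
        state = giop_invert(one_spectrum, giop16)
        rng = np.random.default_rng(5)
        n = len(state.wavelengths)
        A = rng.standard_normal((n, n)) * 1e-4
        Ex = param_covariance(state.jacobian, A @ A.T)
        assert np.all(np.diag(Ex) >= 0)


class TestMisfit:
    def test_noiseless_misfit_is_negligible(self, giop16, one_spectrum):
        state = giop_invert(one_spectrum, giop16)
        u = misfit_uncertainty(state)
        assert np.all(u < 1e-8 * np.abs(state.x))

    def test_doubling_residuals_doubles_misfit(self, giop16, one_spectrum):
        state = giop_invert(one_spectrum, giop16)
        state.residuals = state.residuals + 1e-5   # synthetic misfit
        u1 = misfit_uncertainty(state)
        state.residuals = 2.0 * state.residuals
        u2 = misfit_uncertainty(state)
        assert np.allclose(u2, 2.0 * u1, rtol=1e-12)

    def test_misfit_below_data_u_for_model_consistent_spectra(
            self, giop16, synthetic_spectra):
        """When radiometric uncertainty dominates the residual, the misfit
        component is much smaller than the data component."""
        spectra, _ = synthetic_spectra
        for s in spectra[:5]:
            state = giop_invert(s, giop16)
            u = flat_u(s, FlatRelativeUncertainty(0.05))
            iops = derived_iops(state, giop16, V_Rrs=u)
            assert iops.b_bp.u_misfit < iops.b_bp.u_data
            assert iops.a_dg.u_misfit < iops.a_dg.u_data


class TestDerivedIops:
    def test_additivity_of_nonwater_absorption(self, giop16, one_spectrum):
        state = giop_invert(one_spectrum, giop16)
        u = flat_u(one_spectrum, FlatRelativeUncertainty(0.05))
        iops = derived_iops(state, giop16, V_Rrs=u)
        assert iops.a_nw.value == pytest.approx(
            iops.a_phi.value + iops.a_dg.value, abs=1e-14)

    def test_unit_shape_passes_xphi_uncertainty_through(self, unit_giop):
        rrs = giop_forward((0.05, 0.01, 0.002), unit_giop, gamma=1.0)
        R = Rrs_from_rrs(rrs)
        state = giop_invert(R, unit_giop)
        assert state.success
        u = flat_u(R, FlatRelativeUncertainty(0.05))
        iops = derived_iops(state, unit_giop, V_Rrs=u)
        # aphi*(443) = 1 -> u(a_phi,443) = u(x_phi)
        Vr = np.diag((drrs_dRrs(state.Rrs_obs) * u.values) ** 2)
        Ex = param_covariance(state.jacobian, Vr)
        assert iops.a_phi.u_data == pytest.approx(math.sqrt(Ex[0, 0]), rel=1e-10)

    def test_quadrature_with_zero_cross_covariance(self):
        # with E_x diagonal the a_nw variance is the quadrature sum
        from ocuncert.giop import IOPValue
        Ex = np.diag([4.0, 9.0, 1.0])
        astar = 1.0
        var_nw = astar**2 * Ex[0, 0] + Ex[1, 1] + 2 * astar * Ex[0, 1]
        assert math.sqrt(var_nw) == pytest.approx(math.hypot(2.0, 3.0))

    def test_fofm_u_within_mc_envelope(self, giop16, synthetic_spectra):
        """FOFM parameter uncertainties agree with a Monte-Carlo estimate on
        a synthetic spectrum to within MC sampling scatter."""
        from ocuncert import mc_uncertainty
        s = synthetic_spectra[0][2]
        u = flat_u(s, FlatRelativeUncertainty(0.01))
        state = giop_invert(s, giop16)
        iops = derived_iops(state, giop16, V_Rrs=u)

        def model(sp):
            st = giop_invert(sp, giop16)
            if not st.success:
                raise ValueError("inversion failed")
            return st.x_bp

        mc = mc_uncertainty(model, s, u, n_iter=300, seed=99)
        assert iops.b_bp.u_data == pytest.approx(mc.sigma, rel=0.35)


class TestBbpShift:
    def test_gamma_zero_is_identity(self):
        v, u = bbp_shift(1e-3, 0.0, 470.0, ref_wavelength=440.0,
                         u_bbp=2e-4)
        assert v == pytest.approx(1e-3)
        assert u == pytest.approx(2e-4)

    def test_known_shift(self):
        v, _ = bbp_shift(1e-3, 1.0, 470.0, ref_wavelength=440.0)
        assert v == pytest.approx(440.0 / 470.0 * 1e-3, rel=1e-12)
        assert v == pytest.approx(9.3617e-4, abs=1e-8)

    def test_covariance_term_enters_variance(self):
        from ocuncert import DEFAULT_BBP_GAMMA_COV
        assert DEFAULT_BBP_GAMMA_COV == pytest.approx(-1.64e-6)
        b, g, lam = 1e-3, 1.0, 470.0
        ratio = 440.0 / 470.0
        d1 = ratio**g
        d2 = b * d1 * math.log(ratio)
        u_b, u_g, cov = 2e-4, 0.1, -1e-9
        expected = math.sqrt(d1**2 * u_b**2 + d2**2 * u_g**2
                             + 2 * d1 * d2 * cov)
        _, u = bbp_shift(b, g, lam, ref_wavelength=440.0,
                         u_bbp=u_b, u_gamma=u_g, cov=cov)
        assert u == pytest.approx(expected, rel=1e-12)
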