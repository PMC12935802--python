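import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hawkdove as hd
from hawkdove.stability import det_quadratic_coefficients


@pytest.fixture
def rd_params(baseline_matrix, kappa):
    return hd.LocalPDEParams(matrix=baseline_matrix, kappa=kappa, D_u=4.93, D_v=0.1)


L = 40.0


class TestSensitivityConstants:
    def test_exponential_closed_form_values(self, baseline_matrix, kappa):
        cs = hd.sensitivity_constants(baseline_matrix, kappa)
        assert cs.c1 == pytest.approx(-0.0025)
        assert cs.c2 == pytest.approx(0.005)
        assert cs.c3 == pytest.approx(-0.001)
        assert cs.c4 == pytest.approx(0.002)

    def test_exponential_rule_is_w_independent(self, baseline_matrix, kappa):
        a = hd.sensitivity_constants(baseline_matrix, kappa, w_u=0.0, w_v=0.0)
        b = hd.sensitivity_constants(baseline_matrix, kappa, w_u=3.0, w_v=7.0)
        assert a == b

    @given(V=st.floats(0.5, 20.0), ratio=st.floats(1.05, 8.0))
    @settings(max_examples=30, deadline=None)
    def test_sign_pattern_for_any_contest_game(self, V, ratio):
        cs = hd.sensitivity_constants(hd.build_cv_matrix(V, ratio * V), 0.001)
        assert cs.c1 < 0 and cs.c2 > 0 and cs.c3 < 0 and cs.c4 > 0

    def test_matches_numerical_payoff_partials(self, baseline_matrix, kappa, equilibrium):
        h = 1e-3
        u0, v0 = equilibrium.u0, equilibrium.v0
        num = (hd.payoffs(u0 + h, v0, baseline_matrix)[0]
               - hd.payoffs(u0 - h, v0, baseline_matrix)[0]) / (2 * h)
        assert hd.sensitivity_constants(baseline_matrix, kappa).c1 == pytest.approx(num, rel=1e-6)

    def test_affine_rule_divides_by_equilibrium_weight(self, baseline_matrix, kappa):
        cs_exp = hd.sensitivity_constants(baseline_matrix, kappa)
        cs_aff = hd.sensitivity_constants(baseline_matrix, kappa, rule="affine", w_u=1.5, w_v=0.0)
        assert cs_aff.c1 == pytest.approx(cs_exp.c1 / (1 + 1.5 * 2 / 3))

    def test_affine_rule_rejects_nonpositive_weight(self, baseline_matrix, kappa):
        # equilibrium payoff is 2/3, so w_v = -3 gives 1 + w*p = -1
        with pytest.raises(ValueError):
            hd.sensitivity_constants(baseline_matrix, kappa, rule="affine", w_v=-3.0)


class TestDispersionMatrixA:
    def test_mode_zero_is_reaction_jacobian(self, baseline_matrix, kappa):
        params = hd.LocalPDEParams(
            matrix=baseline_matrix, kappa=kappa, D_u=2.0, D_v=0.3, w_u=0.4, w_v=1.2
        )
        pt = hd.A_matrix(0, params, L)
        assert np.allclose(pt.matrix, hd.reaction_jacobian(baseline_matrix, kappa).as_matrix())

    def test_zero_sensitivity_reduces_to_reaction_diffusion(self, rd_params):
        taxis = hd.LocalPDEParams(
            matrix=rd_params.matrix, kappa=rd_params.kappa,
            D_u=rd_params.D_u, D_v=rd_params.D_v, w_u=0.0, w_v=0.0,
        )
        for m in (1, 7, 19):
            assert np.allclose(
                hd.A_matrix(m, taxis, L).matrix, hd.A_rd_matrix(m, rd_params, L).matrix
            )

    def test_single_unstable_mode_just_above_threshold(self, rd_params):
        pts = [hd.A_rd_matrix(m, rd_params, L) for m in range(1, 40)]
        unstable = [p.m for p in pts if p.sigma > 0]
        assert unstable == [12]
        assert max(pts, key=lambda p: p.sigma).m == 12

    def test_determinant_matches_quadratic_coefficients(self, baseline_matrix, kappa):
        """det(A(m)) assembled from the matrix equals the quartic-in-wavenumber
        polynomial built from (alpha, beta, gamma)."""
        params = hd.LocalPDEParams(
            matrix=baseline_matrix, kappa=kappa, D_u=4.2, D_v=0.1, w_u=0.05, w_v=0.9
        )
        alpha, beta, gamma = det_quadratic_coefficients(params)
        for m in range(0, 30):
            pt = hd.A_matrix(m, params, L)
            poly = alpha * pt.q**2 + beta * pt.q + gamma
            assert pt.det == pytest.approx(poly, abs=1e-10, rel=1e-10)


class TestTuringThresholds:
    def test_wavenumber_cutoff(self, rd_params):
        assert hd.turing_cutoff_mc(rd_params, L) == pytest.approx(18.98, abs=0.005)

    def test_cutoff_scales_linearly_with_length(self, rd_params):
        assert hd.turing_cutoff_mc(rd_params, 2 * L) == pytest.approx(
            2 * hd.turing_cutoff_mc(rd_params, L)
        )

    def test_no_turing_when_dove_self_activation_vanishes(self, kappa):
        m = hd.build_cv_matrix(4.0, 8.0)  # C = 2V: b2 = 0
        params = hd.LocalPDEParams(matrix=m, kappa=kappa, D_u=5.0, D_v=0.1)
        assert hd.turing_cutoff_mc(params, L) is None
        assert hd.critical_Du_min(params, L) is None
        assert hd.critical_diffusivity_ratio(m, kappa) is None

    def test_critical_diffusivity_minimum(self, rd_params):
        val, argmin = hd.critical_Du_min(rd_params, L)
        assert argmin == 12
        assert val == pytest.approx(4.917, abs=5e-4)

    def test_critical_diffusivity_grows_toward_cutoff(self, rd_params):
        """D_u*(m) rises steeply as m approaches the cutoff (denominator -> 0)
        and is undefined beyond it."""
        assert hd.critical_Du(18, rd_params, L) > 3 * hd.critical_Du(12, rd_params, L)
        with pytest.raises(ValueError):
            hd.critical_Du(19, rd_params, L)  # m_c ~ 18.98

    def test_brute_force_determinant_scan_agrees(self, rd_params):
        """Independent oracle: scan det(A_RD) signs over a (D_u, m) grid."""
        du_grid = np.arange(4.0, 7.0, 1e-3)
        onset = None
        for du in du_grid:
            p = hd.LocalPDEParams(matrix=rd_params.matrix, kappa=rd_params.kappa,
                                  D_u=du, D_v=rd_params.D_v)
            dets = [hd.A_rd_matrix(m, p, L).det for m in range(1, 19)]
            if min(dets) < 0:
                onset = (du, 1 + int(np.argmin(dets)))
                break
        val, argmin = hd.critical_Du_min(rd_params, L)
        assert onset is not None
        assert abs(onset[0] - val) < 2e-3
        assert onset[1] == argmin

    def test_diffusivity_ratio_is_49(self, baseline_matrix, kappa):
        assert hd.critical_diffusivity_ratio(baseline_matrix, kappa) == pytest.approx(49.0)

    def test_ratio_roots_identity(self, baseline_matrix, kappa):
        """Both roots of the marginal quadratic (b2 d + a1)^2 = 4 d det are
        recovered and multiply to (a1/b2)^2; for this game they are 1 and 49."""
        jac = hd.reaction_jacobian(baseline_matrix, kappa)
        roots = np.sort(np.roots(
            [jac.b2**2, 2 * jac.a1 * jac.b2 - 4 * jac.det, jac.a1**2]).real)
        assert roots[0] * roots[1] == pytest.approx((jac.a1 / jac.b2) ** 2)
        assert roots == pytest.approx([1.0, 49.0])
        assert hd.critical_diffusivity_ratio(baseline_matrix, kappa) == pytest.approx(roots[1])

    def test_ratio_independent_of_kappa(self, baseline_matrix):
        assert hd.critical_diffusivity_ratio(baseline_matrix, 1e-3) == pytest.approx(
            hd.critical_diffusivity_ratio(baseline_matrix, 5e-2)
        )


class TestPayoffThresholds:
    def test_closed_forms_for_contest_game(self, baseline_matrix, kappa):
        """General coefficient route reproduces the V,C closed forms."""
        V, C = 4.0, 6.0
        for Du, Dv, wu in [(4.2, 0.1, 0.05), (0.1, 0.1, 0.2), (2.0, 0.5, 0.0)]:
            params = hd.LocalPDEParams(matrix=baseline_matrix, kappa=kappa,
                                       D_u=Du, D_v=Dv, w_u=wu)
            ts = hd.payoff_thresholds(params)
            wv_i = (C**2 * (Du + Dv) + Du * V * wu * (C - V) * (C + V)) / (Dv * V**2 * (C - V))
            wv_ii = (C**2 + V * wu * (C - V) * (C + V)) / (V**2 * (C - V))
            wv_iiia = (C * (Du * (C - 2 * V) + Dv * (C + 2 * V))
                       + Du * V * wu * (C - V) * (C + V)) / (Dv * V**2 * (C - V))
            assert ts.wv_I == pytest.approx(wv_i)
            assert ts.wv_II == pytest.approx(wv_ii)
            assert ts.wv_IIIa == pytest.approx(wv_iiia)

    def test_simple_alpha_threshold(self, baseline_matrix, kappa):
        # equal diffusivities, w_u = 0: wv_II = C^2 / (V^2 (C-V)) = 36/32
        params = hd.LocalPDEParams(matrix=baseline_matrix, kappa=kappa, D_u=0.1, D_v=0.1)
        assert hd.payoff_thresholds(params).wv_II == pytest.approx(36.0 / 32.0)

    def test_mixed_regime_onset(self, baseline_matrix, kappa):
        params = hd.LocalPDEParams(matrix=baseline_matrix, kappa=kappa,
                                   D_u=4.2, D_v=0.1, w_u=0.05)
        ts = hd.payoff_thresholds(params)
        assert ts.route == "det_finite_band"
        assert ts.wv_star == pytest.approx(0.848, abs=2e-3)
        assert ts.wv_III < ts.wv_II < ts.wv_I
        onset = hd.integer_mode_det_onset(params, L)
        assert onset is not None
        w_int, m_int = onset
        assert w_int == pytest.approx(0.848, abs=5e-4)
        assert w_int >= ts.wv_star

    def test_onset_sensitivity_actually_destabilizes(self, baseline_matrix, kappa):
        """Just below the onset no mode is unstable; just above, some mode is."""
        base = dict(matrix=baseline_matrix, kappa=kappa, D_u=4.2, D_v=0.1, w_u=0.05)
        ts = hd.payoff_thresholds(hd.LocalPDEParams(**base))
        onset_int, _ = hd.integer_mode_det_onset(hd.LocalPDEParams(**base), L)
        below = hd.classify_instability(hd.LocalPDEParams(**base, w_v=0.995 * ts.wv_star), L)
        above = hd.classify_instability(hd.LocalPDEParams(**base, w_v=1.01 * onset_int), L)
        assert below.label == "stable"
        assert above.label == "finite_band" and len(above.unstable_modes) > 0

    @given(
        wu=st.floats(0.0, 0.5),
        dd=st.floats(0.05, 2.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_no_finite_band_with_equal_diffusivities(self, wu, dd, baseline_matrix):
        """For D_u = D_v the finite-band window never opens: the beta<0
        threshold coincides with the trace threshold and exceeds the
        alpha<0 threshold, so the determinant route is always short-wave."""
        params = hd.LocalPDEParams(matrix=baseline_matrix, kappa=0.001,
                                   D_u=dd, D_v=dd, w_u=wu)
        ts = hd.payoff_thresholds(params)
        assert ts.wv_IIIa == pytest.approx(ts.wv_I, rel=1e-9)
        assert ts.wv_IIIa > ts.wv_II
        assert ts.route in ("det_shortwave",)
        for wv in (0.5 * ts.wv_II, 1.05 * ts.wv_II, 3.0 * ts.wv_II, 10 * ts.wv_II):
            cls = hd.classify_instability(
                hd.LocalPDEParams(matrix=baseline_matrix, kappa=0.001,
                                  D_u=dd, D_v=dd, w_u=wu, w_v=wv), L)
            assert cls.label != "finite_band"


class TestClassifier:
    def test_turing_band_is_finite(self, baseline_matrix, kappa):
        params = hd.LocalPDEParams(matrix=baseline_matrix, kappa=kappa, D_u=10.0, D_v=0.1)
        cls = hd.classify_instability(params, L)
        assert cls.label == "finite_band" and not cls.unbounded
        assert cls.fastest_mode in cls.unstable_modes

    def test_stable_below_all_thresholds(self, baseline_matrix, kappa):
        params = hd.LocalPDEParams(matrix=baseline_matrix, kappa=kappa, D_u=1.0, D_v=0.1)
        cls = hd.classify_instability(params, L)
        assert cls.label == "stable" and cls.unstable_modes == ()

    def test_trace_route_is_shortwave(self, baseline_matrix, kappa):
        params = hd.LocalPDEParams(matrix=baseline_matrix, kappa=kappa,
                                   D_u=0.1, D_v=0.1, w_u=0.0, w_v=100.0)
        ts = hd.payoff_thresholds(params)
        assert params.w_v > ts.wv_I
        cls = hd.classify_instability(params, L)
        assert cls.label.startswith("shortwave") and cls.unbounded


class TestDispersionMatrixB:
    def test_small_radius_limit_matches_local_entries(self, baseline_matrix, kappa):
        """As rho -> 0 the sensing factor sin(k rho)/rho -> k and B(m)
        approaches the local dispersion matrix at wavenumber 2 m pi / l."""
        params_loc = hd.LocalPDEParams(matrix=baseline_matrix, kappa=kappa,
                                       D_u=0.1, D_v=0.1, w_u=1.0, w_v=10.0)
        m = 5
        # local matrix at q = (2 m pi / l)^2 equals A at doubled mode index
        a_pt = hd.A_matrix(2 * m, params_loc, L)
        for rho, tol in [(1e-3, 1e-4), (1e-5, 1e-8)]:
            b_pt = hd.B_matrix(m, hd.NonlocalParams(
                matrix=baseline_matrix, kappa=kappa, D_u=0.1, D_v=0.1,
                w_u=1.0, w_v=10.0, rho=rho), L)
            assert np.allclose(b_pt.matrix, a_pt.matrix, rtol=tol, atol=tol)

    def test_mode_zero_is_reaction_jacobian(self, baseline_matrix, kappa):
        params = hd.NonlocalParams(matrix=baseline_matrix, kappa=kappa,
                                   D_u=0.1, D_v=0.1, w_u=1.0, w_v=10.0, rho=0.01)
        assert np.allclose(hd.B_matrix(0, params, L).matrix,
                           hd.reaction_jacobian(baseline_matrix, kappa).as_matrix())

    def test_sensing_factor_vanishes_at_resonant_modes(self, baseline_matrix, kappa):
        """When 2 m rho / l is an integer the taxis contribution is exactly
        zero and B(m) equals the reaction-diffusion matrix."""
        rho = 2.0
        params = hd.NonlocalParams(matrix=baseline_matrix, kappa=kappa,
                                   D_u=0.1, D_v=0.1, w_u=1.0, w_v=10.0, rho=rho)
        rd = hd.LocalPDEParams(matrix=baseline_matrix, kappa=kappa, D_u=0.1, D_v=0.1)
        for m in (10, 20, 30):  # 2*m*rho/l = m/10 integer
            assert (2 * m * rho / L) == int(2 * m * rho / L)
            b = hd.B_matrix(m, params, L)
            a = hd.A_rd_matrix(2 * m, rd, L)
            assert np.allclose(b.matrix, a.matrix, atol=1e-10)

    def test_band_is_finite_and_certified(self, baseline_matrix, kappa):
        params = hd.NonlocalParams(matrix=baseline_matrix, kappa=kappa,
                                   D_u=0.1, D_v=0.1, w_u=1.0, w_v=10.0, rho=0.01)
        band = hd.nonlocal_band(params, L)
        assert band.label == "finite_band" and not band.unbounded
        assert len(band.unstable_modes) > 0
        hi = max(band.unstable_modes)
        # beyond the band both instability conditions fail
        for m in (hi + 1, hi + 50, hi + 500):
            pt = hd.B_matrix(m, params, L)
            assert pt.trace < 0 and pt.det > 0
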