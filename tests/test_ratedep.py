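import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from nablock import ratedep
from nablock.gating import DrugParams, steady_state
from nablock.ratedep import (
    BindingEnv,
    RestitutionCurve,
    SquareWaveAP,
    b_inf,
    b_star,
    b_star_at_bcl,
    b_star_from_env,
    b_transient,
    binding_env,
    critical_slope,
    critical_slope_from_env,
    db_star_dbcl,
    db_star_dV,
    eq6_bracket,
    iterate_pacing_map,
    ode_pace,
    rate_scaling_pair,
    scan_b_star,
    tau_b,
)

IDEAL_20 = BindingEnv(tau_ap=1.0 / 6.7e-3, tau_di=1.0 / 1.7e-3,
                      binf_ap=5.0 / 6.7, binf_di=0.0, apd=300.0, di=450.0)


class TestTauBAndBInf:
    def test_drug_free_values(self, truth):
        d0 = DrugParams(concentration=0.0)
        assert float(tau_b(-85.0, truth, d0)) == pytest.approx(1 / 1.7e-3,
                                                               rel=1e-12)
        assert float(b_inf(-85.0, truth, d0)) == 0.0

    def test_fully_inactivated_20uM(self, truth, drug20):
        # at +20 mV, 1 - h_inf is 1 to ~1e-8: tau_b -> 1/6.7e-3, b_inf -> 5/6.7
        assert float(tau_b(20.0, truth, drug20)) == pytest.approx(
            1.0 / 6.7e-3, rel=1e-6)
        assert float(b_inf(20.0, truth, drug20)) == pytest.approx(
            5.0 / 6.7, rel=1e-6)

    def test_fully_inactivated_5uM(self, truth):
        d5 = DrugParams().with_concentration_uM(5.0)
        assert float(tau_b(20.0, truth, d5)) == pytest.approx(
            1.0 / 2.95e-3, rel=1e-6)
        assert float(b_inf(20.0, truth, d5)) == pytest.approx(
            1.25 / 2.95, rel=1e-6)

    def test_tau_b_bounded_by_unbinding_time(self, truth, drug20):
        V = np.linspace(-120, 40, 30)
        assert np.all(tau_b(V, truth, drug20) <= 1.0 / drug20.k_off + 1e-9)


class TestBTransient:
    def test_continuity_at_zero(self):
        assert b_transient(0.0, "AP", 0.3, IDEAL_20) == 0.3

    def test_asymptote(self):
        assert b_transient(1e9, "AP", 0.3, IDEAL_20) == pytest.approx(
            IDEAL_20.binf_ap)
        assert b_transient(1e9, "DI", 0.3, IDEAL_20) == pytest.approx(
            IDEAL_20.binf_di)

    def test_bad_phase(self):
        with pytest.raises(ValueError):
            b_transient(1.0, "XX", 0.3, IDEAL_20)

    def test_full_cycle_composition_vs_ode(self, truth, drug20):
        # independent scalar-ODE oracle with h pinned per phase
        sq = SquareWaveAP(APD=250.0, DI=350.0)
        env = binding_env(sq, truth, drug20)
        h_ap = float(steady_state(sq.V_AP, truth)[1])
        h_di = float(steady_state(sq.V_DI, truth)[1])
        kon_c = drug20.k_on * drug20.concentration

        def rhs(t, y):
            h = h_ap if (t % sq.BCL) < sq.APD else h_di
            return kon_c * (1 - h) * (1 - y[0]) - drug20.k_off * y[0]

        b0 = 0.12
        t_eval = np.linspace(0, sq.BCL, 601)
        sol = solve_ivp(rhs, (0, sq.BCL), [b0], rtol=1e-11, atol=1e-13,
                        t_eval=t_eval, max_step=5.0, method="LSODA")
        expect = np.where(
            t_eval < sq.APD,
            b_transient(t_eval, "AP", b0, env),
            b_transient(t_eval - sq.APD, "DI",
                        float(b_transient(sq.APD, "AP", b0, env)), env))
        assert np.max(np.abs(sol.y[0] - expect)) < 1e-6


class TestBStar:
    def test_idealized_example(self):
        # frozen from an independent computation via the iterated pacing map
        assert b_star_from_env(IDEAL_20) == pytest.approx(0.32073215, abs=1e-6)

    def test_limits(self, truth, drug20):
        near0 = b_star(SquareWaveAP(APD=1e-6, DI=450.0), truth, drug20)
        assert near0 == pytest.approx(float(b_inf(-85.0, truth, drug20)),
                                      abs=1e-6)
        near1 = b_star(SquareWaveAP(APD=300.0, DI=1e-6), truth, drug20)
        assert near1 == pytest.approx(float(b_inf(20.0, truth, drug20)),
                                      abs=1e-6)

    def test_zero_without_drug(self, truth):
        d0 = DrugParams(concentration=0.0)
        assert b_star(SquareWaveAP(), truth, d0) == 0.0

    def test_convex_combination_bounds(self, truth, drug20):
        for apd, di in [(50, 60), (300, 450), (500, 100)]:
            sq = SquareWaveAP(APD=apd, DI=di)
            env = binding_env(sq, truth, drug20)
            bs = b_star(sq, truth, drug20)
            assert min(env.binf_ap, env.binf_di) <= bs <= max(env.binf_ap,
                                                              env.binf_di)

    def test_monotone_in_concentration(self, truth):
        sq = SquareWaveAP()
        vals = [b_star(sq, truth, DrugParams().with_concentration_uM(c))
                for c in (0.0, 5.0, 10.0, 20.0, 40.0)]
        assert np.all(np.diff(vals) > 0)

    def test_degenerate_waveform_rejected(self, truth, drug20, default_restitution):
        with pytest.raises(ValueError):
            SquareWaveAP(APD=0.0, DI=100.0)
        with pytest.raises(ValueError):
            # BCL below the restitution domain
            b_star_at_bcl(100.0, default_restitution, truth, drug20)

    @settings(max_examples=200, deadline=None)
    @given(a=st.floats(1e-6, 0.999), d=st.floats(1e-6, 0.999))
    def test_weight_identity(self, a, d):
        w_di = (1 - d) / (1 - a * d)
        w_ap = (1 - a) * d / (1 - a * d)
        assert w_di + w_ap == pytest.approx(1.0, abs=1e-12)


class TestPacingMap:
    def test_fixed_point_is_stationary(self, truth, drug20):
        sq = SquareWaveAP(APD=220.0, DI=380.0)
        bs = b_star(sq, truth, drug20)
        seq = iterate_pacing_map(sq, truth, drug20, b0=bs, n_cycles=10)
        assert np.max(np.abs(seq - bs)) < 1e-14

    def test_geometric_contraction_bound(self, truth, drug20):
        sq = SquareWaveAP(APD=220.0, DI=380.0)
        env = binding_env(sq, truth, drug20)
        bs = b_star(sq, truth, drug20)
        seq = iterate_pacing_map(sq, truth, drug20, b0=0.0, n_cycles=40)
        n = np.arange(seq.size)
        assert np.all(np.abs(seq - bs) <= abs(seq[0] - bs)
                      * (env.A * env.D) ** n + 1e-14)

    def test_monotone_after_first_cycle(self, truth, drug20):
        seq = iterate_pacing_map(SquareWaveAP(), truth, drug20, b0=0.0,
                                 n_cycles=30)
        assert np.all(np.diff(seq[1:]) >= -1e-15)

    def test_matches_pinned_ode_pacing(self, truth, drug20):
        sq = SquareWaveAP(APD=300.0, DI=450.0)
        bs = b_star(sq, truth, drug20)
        ode = ode_pace(sq, truth, drug20, b0=bs, n_cycles=8)
        assert abs(ode[-1] - bs) < 1e-4

    def test_free_h_pacing_is_close_but_not_identical(self, truth, drug20):
        # relaxing the pinned-h approximation shifts the fixed point slightly
        sq = SquareWaveAP(APD=300.0, DI=450.0)
        bs = b_star(sq, truth, drug20)
        ode = ode_pace(sq, truth, drug20, b0=bs, n_cycles=25, pin_h=False,
                       rtol=1e-8, atol=1e-10)
        assert abs(ode[-1] - bs) < 0.02


class TestDerivativeAndCriticalSlope:
    def test_flat_restitution_negative_derivative(self, truth, drug20):
        flat = RestitutionCurve.flat(250.0, (300.0, 1000.0))
        for bcl in (350.0, 600.0, 900.0):
            assert db_star_dbcl(bcl, flat, truth, drug20) < 0.0

    def test_matches_finite_difference(self, truth, drug20,
                                       default_restitution, fd4):
        for bcl in (350.0, 500.0, 700.0, 900.0):
            fd = fd4(lambda x: b_star_at_bcl(x, default_restitution, truth,
                                             drug20), bcl, 1.0)
            an = db_star_dbcl(bcl, default_restitution, truth, drug20)
            assert abs(fd - an) / abs(an) < 1e-6

    def test_zero_when_asymptotes_equal(self, truth, drug20):
        # both potentials deep: b_inf(V_AP) ~= b_inf(V_DI) ~= 0
        flat = RestitutionCurve.flat(250.0, (300.0, 1000.0))
        # both potentials deep: asymptotes nearly coincide, prefactor ~ 0
        assert abs(db_star_dbcl(600.0, flat, truth, drug20,
                                v_ap=-115.0, v_di=-120.0)) < 1e-6
        # exactly equal asymptotes: the prefactor vanishes identically
        env = BindingEnv(tau_ap=200.0, tau_di=400.0, binf_ap=0.3,
                         binf_di=0.3, apd=250.0, di=350.0)
        prefactor = (env.binf_ap - env.binf_di) / (1 - env.A * env.D) ** 2
        assert prefactor * eq6_bracket(env, 0.2) == 0.0

    def test_critical_slope_is_bracket_root(self, truth, drug20,
                                            default_restitution):
        for bcl in (400.0, 700.0):
            s = critical_slope(bcl, default_restitution, truth, drug20)
            sq = ratedep._square_at_bcl(bcl, default_restitution, 20.0, -85.0)
            env = binding_env(sq, truth, drug20)
            assert 0.0 < s < 1.0
            assert abs(eq6_bracket(env, s)) < 1e-10

    @settings(max_examples=1000, deadline=None)
    @given(apd=st.floats(10.0, 600.0), di=st.floats(10.0, 600.0),
           tau_ap=st.floats(50.0, 800.0), tau_di=st.floats(50.0, 800.0))
    def test_root_property_random_tuples(self, apd, di, tau_ap, tau_di):
        env = BindingEnv(tau_ap=tau_ap, tau_di=tau_di, binf_ap=0.7,
                         binf_di=0.1, apd=apd, di=di)
        s = critical_slope_from_env(env)
        scale = max(abs(eq6_bracket(env, 0.0)), abs(eq6_bracket(env, 1.0)))
        assert abs(eq6_bracket(env, s)) <= 1e-10 * max(scale, 1e-30)

    def test_long_apd_limit_slope_to_one(self):
        env = BindingEnv(tau_ap=150.0, tau_di=500.0, binf_ap=0.7, binf_di=0.1,
                         apd=6000.0, di=300.0)
        assert critical_slope_from_env(env) == pytest.approx(1.0, abs=1e-10)

    def test_short_di_limit_slope_to_one(self):
        env = BindingEnv(tau_ap=150.0, tau_di=500.0, binf_ap=0.7, binf_di=0.1,
                         apd=300.0, di=1e-9)
        s = critical_slope_from_env(env)
        assert s == pytest.approx(1.0, abs=1e-9)
        assert abs(eq6_bracket(env, s)) < 1e-12


class TestScans:
    def test_flat_restitution_b_star_nonincreasing_in_bcl(self, truth, drug20):
        flat = RestitutionCurve.flat(250.0, (300.0, 1000.0))
        scan = scan_b_star(np.arange(300.0, 1001.0, 50.0), flat, truth, drug20)
        assert np.all(np.diff(scan["b_star"]) < 0)

    def test_v_ap_insensitivity(self, fitted, drug20, default_restitution):
        grid = np.arange(300.0, 1001.0, 50.0)
        a = scan_b_star(grid, default_restitution, fitted, drug20, v_ap=20.0)
        b = scan_b_star(grid, default_restitution, fitted, drug20, v_ap=-20.0)
        assert np.max(np.abs(a["b_star"] - b["b_star"])) < 0.01

    def test_raising_v_di_increases_block(self, fitted, drug20,
                                          default_restitution):
        grid = np.arange(300.0, 1001.0, 50.0)
        a = scan_b_star(grid, default_restitution, fitted, drug20, v_di=-85.0)
        b = scan_b_star(grid, default_restitution, fitted, drug20, v_di=-75.0)
        assert np.all(b["b_star"] > a["b_star"])

    def test_steeper_restitution_lowers_block_at_short_bcl(
            self, fitted, drug20, default_restitution, steep_restitution):
        for bcl in (300.0, 350.0, 400.0):
            assert (b_star_at_bcl(bcl, steep_restitution, fitted, drug20)
                    < b_star_at_bcl(bcl, default_restitution, fitted, drug20))

    def test_domain_errors_collected_not_fatal(self, truth, drug20,
                                               default_restitution):
        scan = scan_b_star([200.0, 500.0], default_restitution, truth, drug20)
        assert 0 in scan["errors"]
        assert np.isnan(scan["b_star"][0]) and np.isfinite(scan["b_star"][1])

    def test_dv_di_sensitivity_positive(self, fitted, drug20,
                                        default_restitution):
        assert db_star_dV(600.0, default_restitution, fitted, drug20,
                          which="V_DI") > 0

    def test_dv_ap_sensitivity_negligible(self, fitted, drug20,
                                          default_restitution):
        assert abs(db_star_dV(600.0, default_restitution, fitted, drug20,
                              which="V_AP")) < 1e-4


class TestRateScaling:
    def test_identity_at_sigma_one(self, truth, drug20):
        l, r = rate_scaling_pair(1.0, SquareWaveAP(), truth, drug20)
        assert l == r

    @pytest.mark.parametrize("sigma", [0.5, 0.75, 2.0])
    def test_equivalence_on_bcl_grid(self, sigma, truth, drug20,
                                     default_restitution):
        for bcl in np.arange(300.0, 1001.0, 100.0):
            apd = float(default_restitution(bcl))
            sq = SquareWaveAP(APD=apd, DI=bcl - apd)
            l, r = rate_scaling_pair(sigma, sq, truth, drug20)
            assert abs(l - r) < 1e-12

    def test_scaled_restitution_matches_paper_form(self, default_restitution):
        # APD = f(sigma * BCL) / sigma on the rescaled domain
        s = default_restitution.scaled(0.75)
        assert float(s(600.0)) == pytest.approx(
            float(default_restitution(450.0)) / 0.75, rel=1e-12)


class TestRestitutionCurve:
    def test_rejects_apd_above_bcl(self):
        with pytest.raises(ValueError):
            RestitutionCurve.flat(400.0, (300.0, 1000.0))

    def test_rejects_decreasing(self):
        with pytest.raises(ValueError):
            RestitutionCurve(lambda b: 500.0 - 0.3 * np.asarray(b),
                             lambda b: np.full_like(np.asarray(b, float), -0.3),
                             (600.0, 1000.0))

    def test_tabulated_interpolation_and_derivative(self, default_restitution,
                                                    fd4):
        grid = np.linspace(300.0, 1000.0, 15)
        table = RestitutionCurve.from_table(grid, default_restitution(grid))
        mid = np.linspace(320.0, 980.0, 23)
        assert np.max(np.abs(table(mid) - default_restitution(mid))) < 0.5
        for bcl in (400.0, 700.0):
            # the interpolant is only C1 at knots: difference away from them
            assert float(table.derivative(bcl)) == pytest.approx(
                fd4(lambda x: float(table(x)), bcl, 0.05), abs=1e-6)
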