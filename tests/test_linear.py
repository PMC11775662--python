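import math
import warnings

import numpy as np
import pytest
from scipy.signal import lti

import mcpid as m
from mcpid.linear import (
    AggregatedGains,
    aggregate_gains,
    check_equilibrium_condition,
    check_stability,
    closed_loop_tf,
    dominant_pole_bound,
    poles,
    predict_metrics_from_poles,
    root_contour,
    static_gain,
    tune_fastest,
)
from mcpid.model import reduced_rhs
from mcpid.params import ARCHITECTURES

from conftest import conditioned_gains, random_params


class TestAggregateGains:
    def test_direct_evaluation_of_integral_gain(self):
        # gamma=0.02, beta_u=beta_x=1, beta_I=2e-4, M=4:
        # kappa_I = 2e-4 / 0.08^2 = 0.03125
        p = m.nominal_params(gamma=0.02, beta_u=1.0, beta_x=1.0)
        g = m.ControlGains(beta_P=0.01, beta_I=2e-4, beta_D=0.0)
        k = aggregate_gains(p, g, ARCHITECTURES["PI" ])
        # PI has M=3; use PID for M=4
        k4 = aggregate_gains(p, g, ARCHITECTURES["PID"])
        assert k4.kappa_I == pytest.approx(2e-4 / 0.08**2, rel=1e-12)
        assert k4.Gamma == pytest.approx(4 * 0.02)
        assert k.Gamma == pytest.approx(3 * 0.02)

    def test_zero_gain_gives_zero_kappa(self, params):
        g = m.ControlGains(beta_P=0.1)
        k = aggregate_gains(params, g, ARCHITECTURES["PID"])
        assert k.kappa_I == 0.0 and k.kappa_D == 0.0 and k.kappa_P > 0

    def test_division_by_zero_guard(self, params):
        g = m.ControlGains(beta_P=0.1)
        with pytest.raises(ZeroDivisionError):
            aggregate_gains(params.with_(mu=0.0), g, ARCHITECTURES["P"])


class TestStaticGain:
    def test_unity_with_integral_action(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            p = random_params(rng)
            k = AggregatedGains(kappa_P=rng.uniform(0.01, 5),
                                kappa_I=rng.uniform(1e-4, 1),
                                kappa_D=rng.uniform(0, 50),
                                Gamma=4 * p.gamma)
            assert static_gain(closed_loop_tf(k, p)) == pytest.approx(1.0, abs=1e-12)

    def test_p_formula_and_special_values(self, params):
        tb = params.theta * params.beta_c
        kP = params.gamma**2 / tb  # theta*beta_c*kappa_P = gamma^2
        k = AggregatedGains(kappa_P=kP, Gamma=2 * params.gamma)
        assert static_gain(closed_loop_tf(k, params)) == pytest.approx(1.5, rel=1e-12)
        k0 = AggregatedGains(Gamma=2 * params.gamma)
        assert static_gain(closed_loop_tf(k0, params)) == 0.0


class TestEquilibriumCondition:
    def test_unitary_tuning_solves_equality(self, params):
        p = params
        c = p.gamma_a * p.mu / (p.beta_a * p.beta_m * p.theta)
        kP = p.gamma**2 / (2 * p.beta_c * p.theta)
        k = AggregatedGains(kappa_P=kP, Gamma=2 * p.gamma)
        lhs, ok = check_equilibrium_condition(k, p, ARCHITECTURES["P"])
        assert lhs == pytest.approx(0.0, abs=1e-12 * c)
        assert ok

    def test_zero_gains_satisfy_existence(self, params):
        k = AggregatedGains(Gamma=3 * params.gamma)
        lhs, ok = check_equilibrium_condition(k, params, ARCHITECTURES["PI"])
        assert lhs < 0 and ok

    def test_equality_implies_unity_static_gain(self):
        """Whenever the P/PD tuning identity holds, the closed-loop static
        gain is exactly one."""
        rng = np.random.default_rng(1)
        for lab in ("P", "PD"):
            arch = ARCHITECTURES[lab]
            for _ in range(10):
                p = random_params(rng)
                g = conditioned_gains(p, arch, rng)
                k = aggregate_gains(p, g, arch)
                lhs, ok = check_equilibrium_condition(k, p, arch)
                assert ok
                assert static_gain(closed_loop_tf(k, p)) == pytest.approx(
                    1.0, rel=1e-9)


class TestStability:
    def test_no_integral_always_stable(self, params):
        k = AggregatedGains(kappa_P=2.0, kappa_D=30.0, Gamma=3 * params.gamma)
        rep = check_stability(k, params)
        assert rep.routh
        ps = poles(closed_loop_tf(k, params))
        assert ps.poles.real.max() < 0

    def test_routh_boundary_gives_imaginary_pair(self, params):
        tb = params.theta * params.beta_c
        kP, kD = 1.0, 10.0
        a2 = 2 * params.gamma + tb * kD
        a1 = params.gamma**2 + tb * kP
        kI = a2 * a1 / tb  # exactly on the boundary a2*a1 = a0
        k = AggregatedGains(kappa_P=kP, kappa_I=kI, kappa_D=kD,
                            Gamma=4 * params.gamma)
        ps = poles(closed_loop_tf(k, params))
        pair = ps.poles[np.abs(ps.poles.imag) > 0]
        assert pair.size == 2
        np.testing.assert_allclose(pair.real, 0.0, atol=1e-12)

    def test_derivative_widens_stable_integral_range(self, params):
        """For fixed kappa_P, the admissible kappa_I interval of the PID
        strictly contains that of the PI."""
        tb = params.theta * params.beta_c
        kP = 1.0
        bound_pi = (2 * params.gamma) * (params.gamma**2 + tb * kP) / tb
        bound_pid = (2 * params.gamma + tb * 20.0) * (params.gamma**2 + tb * kP) / tb
        assert bound_pid > bound_pi
        kI_mid = 0.5 * (bound_pi + bound_pid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep_pi = check_stability(
                AggregatedGains(kP, kI_mid, 0.0, 3 * params.gamma), params)
            rep_pid = check_stability(
                AggregatedGains(kP, kI_mid, 20.0, 4 * params.gamma), params)
        assert not rep_pi.routh and rep_pid.routh

    def test_simplified_condition_vs_routh_documented_disagreement(self, params, gains):
        """The simplified inequality omits a 1/(theta*beta_c) factor; at the
        nominal PID point it rejects a loop that Routh-Hurwitz (and the
        actual pole locations) show to be stable."""
        k = aggregate_gains(params, gains, ARCHITECTURES["PID"])
        with pytest.warns(UserWarning):
            rep = check_stability(k, params)
        assert rep.routh and not rep.printed and not rep.agree
        assert poles(closed_loop_tf(k, params)).poles.real.max() < 0


class TestPolesAndContours:
    def test_p_contour_dominant_on_vertical_line(self, params):
        """P architecture: complex dominant poles sit on Re(s) = -gamma."""
        tb = params.theta * params.beta_c
        base = AggregatedGains(Gamma=2 * params.gamma)
        grid = np.geomspace(0.5, 50.0, 40) * params.gamma**2 / tb
        rc = root_contour(params, ARCHITECTURES["P"], base, "kappa_P", grid)
        for ps in rc.pole_sets:
            assert ps.poles.size == 2
            if np.abs(ps.dominant.imag) > 0:
                assert ps.dominant.real == pytest.approx(-params.gamma, rel=1e-9)

    def test_single_point_grid(self, params):
        base = AggregatedGains(kappa_P=1.0, Gamma=2 * params.gamma)
        rc = root_contour(params, ARCHITECTURES["P"], base, "kappa_P", [1.0])
        assert rc.branches.shape[0] == 1

    def test_branch_continuity(self, params):
        """On a refined grid, consecutive points on a branch move by less
        than the separation between distinct branches (P architecture:
        branches are the conjugate pair, always separated)."""
        tb = params.theta * params.beta_c
        base = AggregatedGains(Gamma=2 * params.gamma)
        grid = np.geomspace(0.5, 50.0, 200) * params.gamma**2 / tb
        rc = root_contour(params, ARCHITECTURES["P"], base, "kappa_P", grid)
        steps = np.abs(np.diff(rc.branches, axis=0))
        for k in range(1, len(grid)):
            row = rc.branches[k]
            sep = np.min(np.abs(row[:, None] - row[None, :])
                         + np.diag([np.inf] * row.size))
            assert steps[k - 1].max() < sep

    def test_grid_validation(self, params):
        base = AggregatedGains(Gamma=2 * params.gamma)
        with pytest.raises(ValueError):
            root_contour(params, ARCHITECTURES["P"], base, "kappa_P", [2.0, 1.0])
        with pytest.raises(ValueError):
            root_contour(params, ARCHITECTURES["P"], base, "kappa_Q", [1.0])


class TestDominantPoleBounds:
    def test_limit_values(self, params):
        g = params.gamma
        assert dominant_pole_bound(ARCHITECTURES["P"],
                                   AggregatedGains(), params) == -g
        # kappa_P = 0: PD bound continuously matches the P bound
        assert dominant_pole_bound(ARCHITECTURES["PD"],
                                   AggregatedGains(), params) == pytest.approx(-g)
        assert dominant_pole_bound(ARCHITECTURES["PI"],
                                   AggregatedGains(), params) == pytest.approx(
            -2 * g / 3)
        # kappa_D = 0: PID bound equals the PI bound
        assert dominant_pole_bound(ARCHITECTURES["PID"],
                                   AggregatedGains(), params) == pytest.approx(
            -2 * g / 3)

    def test_contours_respect_bounds(self, params):
        """No dominant pole along a swept contour crosses its bound."""
        tb = params.theta * params.beta_c
        g = params.gamma
        cases = []
        grid_p = np.geomspace(0.1, 100.0, 50) * g**2 / tb
        cases.append(("P", AggregatedGains(Gamma=2 * g), "kappa_P", grid_p))
        kP = 1.0
        a1 = g**2 + tb * kP
        cases.append(("PD", AggregatedGains(kappa_P=kP, Gamma=3 * g),
                      "kappa_D", np.geomspace(0.01, 100.0, 50)))
        cases.append(("PI", AggregatedGains(kappa_P=kP, Gamma=3 * g),
                      "kappa_I", np.geomspace(1e-4, 0.99, 50) * 2 * g * a1 / tb))
        kD = 15.0
        a2 = 2 * g + tb * kD
        cases.append(("PID",
                      AggregatedGains(kappa_P=kP, kappa_D=kD, Gamma=4 * g),
                      "kappa_I", np.geomspace(1e-4, 0.99, 50) * a2 * a1 / tb))
        for lab, base, swept, grid in cases:
            arch = ARCHITECTURES[lab]
            rc = root_contour(params, arch, base, swept, grid)
            for gval, ps in zip(rc.grid, rc.pole_sets):
                k = base.replace(**{swept: float(gval)})
                bound = dominant_pole_bound(arch, k, params)
                assert ps.dominant.real >= bound - 1e-9, (lab, gval)


class TestTuneFastest:
    def test_pd_coincident_pole_matches_closed_form(self, params):
        """The tuned kappa_D solves (2g + tb*kD)^2 = 4(g^2 + tb*kP)."""
        tb = params.theta * params.beta_c
        kP = 1.0
        res = tune_fastest(ARCHITECTURES["PD"], params,
                           AggregatedGains(kappa_P=kP, Gamma=3 * params.gamma))
        want = (2 * math.sqrt(params.gamma**2 + tb * kP) - 2 * params.gamma) / tb
        assert res.coincident
        assert res.gain == pytest.approx(want, rel=1e-10)
        r1, r2 = res.pole_set.poles
        assert r1.imag == 0 and r2.imag == 0
        assert abs(r1 - r2) <= 1e-6 * abs(r1)

    def test_pi_triple_coincidence_at_matched_kappa_p(self, params):
        """With kappa_P chosen so a1 = a2^2/3, the tuned kappa_I places a
        triple real pole at -2*gamma/3 with kappa_I = 8*gamma^3/(27*tb)."""
        tb = params.theta * params.beta_c
        g = params.gamma
        kP = (4 * g**2 / 3 - g**2) / tb
        res = tune_fastest(ARCHITECTURES["PI"], params,
                           AggregatedGains(kappa_P=kP, Gamma=3 * g))
        assert res.coincident
        assert res.gain == pytest.approx(8 * g**3 / (27 * tb), rel=1e-6)
        np.testing.assert_allclose(res.pole_set.poles.real, -2 * g / 3, rtol=1e-4)
        # triple roots have cube-root conditioning; allow that slack
        np.testing.assert_allclose(res.pole_set.poles.imag, 0.0, atol=1e-6)

    def test_perturbing_tuned_gain_is_locally_worse(self, params):
        """±10% around the tuned gain either slows the dominant pole or
        splits it into a less-damped complex pair."""
        tb = params.theta * params.beta_c
        base = AggregatedGains(kappa_P=1.0, kappa_D=5.0, Gamma=4 * params.gamma)
        res = tune_fastest(ARCHITECTURES["PID"], params, base)
        a0 = res.pole_set.dominant.real
        for f in (0.9, 1.1):
            k = base.replace(kappa_I=res.gain * f)
            ps = poles(closed_loop_tf(k, params))
            worse_speed = ps.dominant.real > a0 + 1e-12
            split = abs(ps.dominant.imag) > 0
            assert worse_speed or split

    def test_p_architecture_rejected(self, params):
        with pytest.raises(ValueError):
            tune_fastest(ARCHITECTURES["P"], params, AggregatedGains())


class TestPredictMetrics:
    def test_single_real_pole(self, params):
        from mcpid.linear import PoleSet

        ps = PoleSet(np.array([-params.gamma]))
        ts, xi = predict_metrics_from_poles(ps, chi=0.10)
        assert ts == pytest.approx(math.log(10) / params.gamma)
        assert xi == 1.0

    def test_nonsettling_rejected(self):
        from mcpid.linear import PoleSet

        with pytest.raises(ValueError):
            predict_metrics_from_poles(PoleSet(np.array([0.001 + 0j])))

    def test_estimate_matches_simulated_step_response(self, params):
        """For well-separated poles the |ln chi|/|Re| estimate agrees with
        the measured 10% settling time of the linearized step response."""
        from mcpid.metrics import settling_time

        tb = params.theta * params.beta_c
        k = AggregatedGains(kappa_P=0.2, kappa_I=2e-3, Gamma=3 * params.gamma)
        tf = closed_loop_tf(k, params).minimal()
        ps = poles(closed_loop_tf(k, params))
        doms = np.sort(ps.poles.real)[::-1]
        assert doms[0] / doms[1] <= 1 / 3 or doms[1] <= 3 * doms[0]
        t = np.linspace(0, 12000, 12001)
        _, y = lti(list(tf.num), list(tf.den)).step(T=t)
        ts_meas, settled = settling_time(t, y, y[-1], 0.10)
        ts_est, _ = predict_metrics_from_poles(ps, 0.10)
        assert settled
        assert ts_meas == pytest.approx(ts_est, rel=0.25)


class TestStepResponseShaping:
    def test_pd_overshoot_nonincreasing_in_derivative_gain(self, params):
        """Raising kappa_D damps the PD step response monotonically."""
        from mcpid.metrics import overshoot

        t = np.linspace(0, 4000, 8001)
        last = np.inf
        for kD in (0.0, 2.0, 5.0, 12.0, 30.0):
            k = AggregatedGains(kappa_P=1.0, kappa_D=kD, Gamma=3 * params.gamma)
            tf = closed_loop_tf(k, params).minimal()
            _, y = lti(list(tf.num), list(tf.den)).step(T=t)
            o = overshoot(y, y[-1])
            assert o <= last + 1e-6
            last = o

    def test_pi_speed_overshoot_tradeoff(self, params):
        """Past the coincident-pole point, faster settling costs overshoot."""
        from mcpid.metrics import overshoot, settling_time

        tb = params.theta * params.beta_c
        g = params.gamma
        kP = (4 * g**2 / 3 - g**2) / tb
        base = AggregatedGains(kappa_P=kP, Gamma=3 * g)
        kI_star = 8 * g**3 / (27 * tb)
        t = np.linspace(0, 20000, 20001)
        os = []
        for f in (1.0, 2.0, 4.0):
            tf = closed_loop_tf(base.replace(kappa_I=kI_star * f), params).minimal()
            _, y = lti(list(tf.num), list(tf.den)).step(T=t)
            os.append(overshoot(y, y[-1]))
        assert os[0] <= os[1] <= os[2]


class TestLinearizationConsistency:
    def _cstep_jacobian(self, f, x0, h=1e-30):
        n = x0.size
        J = np.empty((n, n))
        for j in range(n):
            x = x0.astype(complex)
            x[j] += 1j * h
            J[:, j] = np.imag(f(x)) / h
        return J

    @pytest.mark.parametrize("lab", ["P", "PD", "PI", "PID"])
    def test_jacobian_eigenvalues_match_denominator_roots(self, lab):
        """The reduced model linearized at its equilibrium reproduces the
        closed-loop characteristic polynomial for every architecture."""
        rng = np.random.default_rng(42)
        arch = ARCHITECTURES[lab]
        for _ in range(50):
            p = random_params(rng)
            g = conditioned_gains(p, arch, rng)
            eqr = m.equilibrium(p, g, arch)
            if arch.has_integral:
                x0 = np.array([eqr.state["X1"], eqr.state["Xc"],
                               eqr.state["zeta"]])
            else:
                x0 = np.array([eqr.state["X1"], eqr.state["Xc"]])
            J = self._cstep_jacobian(
                lambda x: reduced_rhs(x, 0.0, p, g, arch), x0)
            eigs = np.sort_complex(np.linalg.eigvals(J))
            tf = closed_loop_tf(aggregate_gains(p, g, arch), p).minimal()
            rts = np.sort_complex(np.roots(tf.den))
            np.testing.assert_allclose(eigs, rts, rtol=1e-6,
                                       atol=1e-9 * np.abs(rts).max())


class TestTransferFunctionCrossCheck:
    def test_frequency_response_matches_linearized_state_space(self):
        """Independent oracle for numerator AND denominator: the transfer
        function evaluated at complex frequencies equals C(sI-J)^{-1}B of
        the reduced model linearized (complex-step) at the set point."""
        rng = np.random.default_rng(7)
        for lab in ("PD", "PI", "PID"):
            arch = ARCHITECTURES[lab]
            for _ in range(5):
                p = random_params(rng)
                g = conditioned_gains(p, arch, rng)
                eqr = m.equilibrium(p, g, arch)
                x0 = [eqr.state["X1"], eqr.state["Xc"]]
                if arch.has_integral:
                    x0.append(eqr.state["zeta"])
                x0 = np.asarray(x0, dtype=float)
                h = 1e-30
                n = x0.size
                J = np.empty((n, n))
                for j in range(n):
                    x = x0.astype(complex)
                    x[j] += 1j * h
                    J[:, j] = np.imag(reduced_rhs(x, 0.0, p, g, arch)) / h
                # input channel: mu*Yd deviation (central difference in Yd)
                dY = 1e-6 * p.Yd
                f_hi = reduced_rhs(x0, 0.0, p.with_(Yd=p.Yd + dY), g, arch)
                f_lo = reduced_rhs(x0, 0.0, p.with_(Yd=p.Yd - dY), g, arch)
                B = (f_hi - f_lo) / (2 * dY * p.mu)
                Gamma = arch.Gamma(p)
                C = np.zeros(n)
                C[1] = p.theta * p.beta_x / Gamma
                tf = closed_loop_tf(aggregate_gains(p, g, arch), p)
                for s in (0.013j, 0.002 + 0.005j, 0.05 + 0.0j):
                    ss_val = C @ np.linalg.solve(
                        s * np.eye(n) - J, B.astype(complex))
                    assert ss_val == pytest.approx(tf(s), rel=1e-8), (lab, s)
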