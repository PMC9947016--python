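"""Closed forms, the TD right-hand side, and the in vitro simulator."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import cardiotd as ct
from cardiotd.model import TDState, td_rhs


class TestDegradationClosedForm:
    @pytest.mark.parametrize(
        "c0,kdeg,t,expected",
        [
            (1.0, 0.022, 0.0, 1.0),
            (10.0, 0.0, 100.0, 10.0),
            (0.5, 0.022, 24.0, 0.5 * np.exp(-0.022 * 24)),
            (1.0, 0.022, 72.0, np.exp(-0.022 * 72)),
        ],
    )
    def test_closed_form(self, c0, kdeg, t, expected):
        assert ct.conc_at(c0, kdeg, t) == pytest.approx(expected, rel=1e-12)

    def test_vectorized_and_domain(self):
        t = np.array([0.0, 12.0, 24.0])
        np.testing.assert_allclose(ct.conc_at(2.0, 0.05, t), 2.0 * np.exp(-0.05 * t))
        for bad in [(-1, 0.1, 1), (1, -0.1, 1), (1, 0.1, -1)]:
            with pytest.raises(ValueError):
                ct.conc_at(*bad)

    def test_matches_co_integrated_ode(self, deg):
        """Closed-form medium concentrations agree with integrating the
        degradation ODEs to <= 1e-8 relative over 0-72 h."""
        t = np.linspace(0, 72, 145)
        for c0, k in [(0.5, deg.kdeg_dox), (100.0, deg.kdeg_dex)]:
            sol = solve_ivp(lambda tt, y: [-k * y[0]], (0, 72), [c0],
                            t_eval=t, rtol=1e-12, atol=1e-14)
            np.testing.assert_allclose(ct.conc_at(c0, k, t), sol.y[0], rtol=1e-8)


class TestHillFunctions:
    def test_dox_kill_zero_halfmax_saturation(self, td):
        assert ct.dox_kill_rate(0.0, td) == 0.0
        assert ct.dox_kill_rate(td.kc50_dox, td) == pytest.approx(td.kmax_dox / 2, rel=1e-12)
        assert ct.dox_kill_rate(1e6, td) == pytest.approx(td.kmax_dox, rel=1e-4)

    def test_dex_inhibition_zero_halfmax_saturation(self, td):
        assert ct.dex_inhibition_rate(0.0, td) == 0.0
        assert ct.dex_inhibition_rate(td.ic50_dexi, td) == pytest.approx(
            td.imax_dexi / 2, rel=1e-12)
        assert ct.dex_inhibition_rate(1e6, td) == pytest.approx(td.imax_dexi, rel=1e-4)

    def test_monotone_in_concentration(self, td):
        c = np.linspace(0, 50, 200)
        assert np.all(np.diff(ct.dox_kill_rate(c, td)) > 0)
        assert np.all(np.diff(ct.dex_inhibition_rate(c, td)) > 0)


class TestControlGrowth:
    def test_baseline_and_growth(self, td):
        assert ct.control_viability(0.0, td) == pytest.approx(101.0)
        assert ct.control_viability(72.0, td) == pytest.approx(101 * np.exp(0.0115 * 72),
                                                               rel=1e-12)

    def test_zero_growth_is_flat(self):
        p = ct.DEFAULT_TD.replace(kg=1e-300)
        assert ct.control_viability(500.0, p) == pytest.approx(p.r0)


def _eq4_rhs(y, c_dox, p):
    """Independently coded single-agent DOX right-hand side (kill Hill,
    3 transit compartments, linear growth inhibition)."""
    r, k1, k2, k3 = y
    ktr = p.ktr_dox  # the transit rate constant, i.e. 1/(mean transit time)
    kdox = p.kmax_dox * c_dox / (p.kc50_dox + c_dox)
    return np.array([
        (1 - p.s_dox * c_dox) * p.kg * r - k3 * r,
        ktr * (kdox - k1),
        ktr * (k1 - k2),
        ktr * (k2 - k3),
    ])


def _eq5_rhs(y, c_dex, p):
    """Independently coded single-agent DEX right-hand side (growth
    inhibition only)."""
    r = y[0]
    return np.array([(1 - p.s_dex * c_dex) * p.kg * r, 0.0, 0.0, 0.0])


class TestTDRightHandSide:
    def test_control_derivative(self, td):
        dy = td_rhs(TDState(r=101.0), 0.0, 0.0, td)
        assert dy[0] == pytest.approx(td.kg * 101.0, rel=1e-12)  # = 1.1615
        np.testing.assert_array_equal(dy[1:], 0.0)

    def test_combination_chain_input_is_difference_of_hills(self, td):
        dy = td_rhs(TDState(r=50.0), td.kc50_dox, td.ic50_dexi, td)
        expected_input = td.kmax_dox / 2 - td.imax_dexi / 2  # 0.03485 - 0.03125
        assert dy[1] / td.ktr_dox == pytest.approx(expected_input, rel=1e-12)
        assert expected_input == pytest.approx(0.0036, abs=1e-6)

    def test_reduces_to_single_agent_dox_bitwise(self, td):
        """With C_DEX = 0 the combination RHS equals an independently coded
        single-agent DOX RHS exactly, over random states and parameters."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = ct.TDParams(
                kg=rng.uniform(0.001, 0.05), r0=rng.uniform(80, 120),
                s_dox=rng.uniform(0.01, 0.5), s_dex=rng.uniform(0.001, 0.05),
                kmax_dox=rng.uniform(0.01, 0.2), kc50_dox=rng.uniform(0.05, 5),
                ktr_dox=rng.uniform(0.05, 0.5), imax_dexi=rng.uniform(0.01, 0.2),
                ic50_dexi=rng.uniform(5, 100),
            )
            y = rng.uniform(0, 100, size=4)
            c = rng.uniform(0, 10)
            np.testing.assert_array_equal(td_rhs(y, c, 0.0, p), _eq4_rhs(y, c, p))

    def test_reduces_to_single_agent_dex(self, td):
        rng = np.random.default_rng(7)
        for _ in range(200):
            r = rng.uniform(1, 200)
            c = rng.uniform(0, 100)
            y = np.array([r, 0.0, 0.0, 0.0])
            got = td_rhs(y, 0.0, c, td)
            want = _eq5_rhs(y, c, td)
            assert got[0] == pytest.approx(want[0], rel=1e-12)
            # literal equation feeds -K_DEXi into the chain; clamped mode is 0
            assert got[1] == pytest.approx(-td.ktr_dox * ct.dex_inhibition_rate(c, td))
            clamped = td_rhs(y, 0.0, c, td, clamp_net_kill=True)
            np.testing.assert_array_equal(clamped[1:], 0.0)

    def test_transit_chain_fixed_point(self, td):
        """For constant drug input every transit compartment converges to the
        chain input, on a timescale set by 1/ktr."""
        c_dox = 1.0
        target = ct.dox_kill_rate(c_dox, td)
        for ktr in (0.126, 0.5):
            p = td.replace(ktr_dox=ktr)
            sol = solve_ivp(
                lambda t, y: td_rhs(y, c_dox, 0.0, p), (0, 40 / ktr),
                [100.0, 0, 0, 0], rtol=1e-10, atol=1e-12)
            np.testing.assert_allclose(sol.y[1:, -1], target, rtol=1e-4)

    def test_negative_concentration_rejected(self, td):
        with pytest.raises(ValueError):
            td_rhs(TDState(r=100.0), -1.0, 0.0, td)


class TestInVitroSimulator:
    def test_control_matches_closed_form(self, td, deg, default_times):
        cond = ct.InVitroCondition(0.0, 0.0)
        v = ct.simulate_invitro(cond, td, deg)
        np.testing.assert_allclose(v, ct.control_viability(default_times, td), rtol=1e-6)

    def test_dox_reduces_viability(self, td, deg):
        v = ct.simulate_invitro(ct.InVitroCondition(0.5, 0.0), td, deg)
        ctrl = ct.control_viability(72.0, td)
        assert v[-1] < ctrl

    def test_dex_protection_is_dose_dependent(self, td, deg):
        """At fixed DOX, a higher DEX level lowers the kill-chain input at
        every time (K_DEXi is monotone in C_DEX) and yields higher viability
        once the delayed kill dominates (48-72 h)."""
        t = np.linspace(0.0, 72.0, 300)
        c_dox = ct.conc_at(0.5, deg.kdeg_dox, t)
        u = {}
        for dex in (5.0, 100.0):
            c_dex = ct.conc_at(dex, deg.kdeg_dex, t)
            u[dex] = ct.dox_kill_rate(c_dox, td) - ct.dex_inhibition_rate(c_dex, td)
        assert np.all(u[100.0] < u[5.0])
        lo = ct.simulate_invitro(ct.InVitroCondition(0.5, 5.0), td, deg)
        hi = ct.simulate_invitro(ct.InVitroCondition(0.5, 100.0), td, deg)
        assert hi[-1] > lo[-1] and hi[-2] > lo[-2]

    def test_single_agent_dex_has_no_kill_chain(self, td, deg):
        """A DEX-only condition follows the growth-inhibition-only model: its
        viability is below control but above zero-slope growth would allow."""
        times = np.linspace(0, 72, 25)
        v = ct.simulate_invitro(ct.InVitroCondition(0.0, 100.0), td, deg,
                                out_times=times)
        ctrl = ct.control_viability(times, td)
        assert np.all(v[1:] < ctrl[1:])
        # independent quadrature oracle: R = R0 exp(kg*t - s*kg*AUC_dex(t))
        aucs = 100.0 * (1 - np.exp(-deg.kdeg_dex * times)) / deg.kdeg_dex
        oracle = td.r0 * np.exp(td.kg * times - td.s_dex * td.kg * aucs)
        np.testing.assert_allclose(v, oracle, rtol=1e-6)

    def test_timepoint_validation(self):
        with pytest.raises(ValueError):
            ct.InVitroCondition(0.5, 0.0, timepoints=(12.0, 24.0))
        with pytest.raises(ValueError):
            ct.InVitroCondition(0.5, 0.0, timepoints=(0.0, 48.0, 24.0))
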