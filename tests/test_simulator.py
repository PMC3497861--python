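"""Quasi-steady two-compartment solver, stepping, and the emptying oracle."""

import math

import numpy as np
import pytest
from scipy import optimize

from lungbench import (
    AIR,
    HELIOX,
    Chamber,
    CircuitLossModel,
    LungSystem,
    VentilatorSettings,
    advance,
    apparent_time_constant,
    build_point_system,
    make_resistor,
    mixture_density,
    reference_area,
    run_expiration,
    simulate,
    single_chamber_emptying_closed_form,
    solve_expiratory_flows,
    solve_inspiratory_split,
    units,
)


def _system(k_left, k_right, c=0.05, v_left=0.0, v_right=0.0, gas=HELIOX,
            k_cct=5.0, k_fs=1.2, clamp=False):
    return LungSystem(
        left=Chamber(compliance=c, resistor=make_resistor(k_left), sensor_loss_k=k_fs,
                     volume=v_left),
        right=Chamber(compliance=c, resistor=make_resistor(k_right), sensor_loss_k=k_fs,
                      volume=v_right),
        gas=gas,
        circuit=CircuitLossModel(form="inertial", k=k_cct),
        clamp_expiratory_inflow=clamp,
    )


class TestInspiratorySplit:
    def test_identical_chambers_split_exactly_in_half(self):
        q_l, q_r = solve_inspiratory_split(_system("Rp5", "Rp5"), 1.0)
        assert q_l == pytest.approx(0.5, rel=1e-12)
        assert q_l + q_r == pytest.approx(1.0, rel=1e-12)

    def test_zero_recoil_split_follows_sqrt_of_loss_ratio(self):
        """Empty chambers, no sensor loss: Q_l/Q_r = sqrt(k_r/k_l)."""
        sys_ = _system("Rp5", "Rp50", k_fs=0.0)
        q_l, q_r = solve_inspiratory_split(sys_, 1.0)
        assert q_l / q_r == pytest.approx(math.sqrt(132.9 / 3.3), rel=1e-9)

    def test_zero_flow_equal_pressures_gives_zero(self):
        sys_ = _system("Rp5", "Rp50", v_left=0.2, v_right=0.2)
        assert solve_inspiratory_split(sys_, 0.0) == (0.0, 0.0)

    def test_flows_sum_to_total_exactly(self):
        sys_ = _system("Rp5", "Rp50", v_left=0.3, v_right=0.1)
        q_l, q_r = solve_inspiratory_split(sys_, 0.8)
        assert q_l + q_r == pytest.approx(0.8, abs=1e-14)

    def test_common_airway_pressure_balance(self):
        """Recoil plus branch loss is equal on both sides at the solution."""
        sys_ = _system("Rp5", "Rp20", v_left=0.25, v_right=0.05)
        q_l, q_r = solve_inspiratory_split(sys_, 1.0)
        rho = mixture_density(sys_.gas)
        a = sys_.area

        def branch_paw(ch, q_lps):
            q = units.lps_to_m3s(q_lps)
            loss = (ch.resistor.k + ch.sensor_loss_k) / 2 * rho * (q / a) * abs(q / a)
            return units.cmh2o_to_pa(ch.pressure) + loss

        assert branch_paw(sys_.left, q_l) == pytest.approx(branch_paw(sys_.right, q_r), rel=1e-8)


class TestExpiratoryFlows:
    def test_decoupled_chambers_match_closed_form(self):
        """With no circuit loss each flow is A*sqrt(2 P/(rho k'))."""
        sys_ = _system("Rp5", "Rp50", v_left=0.3, v_right=0.2, k_cct=0.0)
        q_l, q_r = solve_expiratory_flows(sys_)
        rho = mixture_density(sys_.gas)
        a = sys_.area
        for ch, q in ((sys_.left, q_l), (sys_.right, q_r)):
            expected = a * math.sqrt(
                2 * units.cmh2o_to_pa(ch.pressure) / (rho * (ch.resistor.k + ch.sensor_loss_k))
            )
            assert units.lps_to_m3s(q) == pytest.approx(expected, rel=1e-10)

    def test_symmetric_state_gives_equal_flows(self):
        sys_ = _system("Rp20", "Rp20", v_left=0.25, v_right=0.25)
        q_l, q_r = solve_expiratory_flows(sys_)
        assert q_l == pytest.approx(q_r, rel=1e-10)
        assert q_l > 0

    def test_both_chambers_empty_gives_zero(self):
        assert solve_expiratory_flows(_system("Rp5", "Rp50")) == (0.0, 0.0)

    def test_matches_independent_scipy_solution(self):
        """Dual route: the hand-rolled bracketed Newton agrees with
        scipy.optimize.root applied directly to the two pressure balances."""
        sys_ = _system("Rp5", "Rp50", v_left=0.4, v_right=0.15, k_cct=5.0)
        q_l, q_r = solve_expiratory_flows(sys_)
        rho = mixture_density(sys_.gas)
        a2 = sys_.area**2
        a_l = (3.3 + 1.2) * rho / (2 * a2)
        a_r = (132.9 + 1.2) * rho / (2 * a2)
        b = 5.0 * rho / (2 * a2)
        p_l = units.cmh2o_to_pa(sys_.left.pressure)
        p_r = units.cmh2o_to_pa(sys_.right.pressure)

        def residual(q):
            ql, qr = q
            s = ql + qr
            return [
                p_l - a_l * ql * abs(ql) - b * s * abs(s),
                p_r - a_r * qr * abs(qr) - b * s * abs(s),
            ]

        sol = optimize.root(residual, [units.lps_to_m3s(q_l) * 1.2, units.lps_to_m3s(q_r) * 0.8])
        assert sol.success
        assert units.lps_to_m3s(q_l) == pytest.approx(sol.x[0], rel=1e-8)
        assert units.lps_to_m3s(q_r) == pytest.approx(sol.x[1], rel=1e-8)

    def test_pendelluft_inflow_into_empty_chamber(self):
        """An empty chamber behind a shared circuit receives reverse flow when
        the other chamber's discharge raises the common pressure above zero."""
        sys_ = _system("Rp5", "Rp50", v_left=0.5, v_right=0.0, k_cct=5.0)
        q_l, q_r = solve_expiratory_flows(sys_)
        assert q_l > 0
        assert q_r < 0

    def test_clamp_suppresses_pendelluft(self):
        sys_ = _system("Rp5", "Rp50", v_left=0.5, v_right=0.0, k_cct=5.0, clamp=True)
        q_l, q_r = solve_expiratory_flows(sys_)
        assert q_l > 0
        assert q_r == 0.0


class TestAdvance:
    def test_one_inspiratory_step_splits_volume_evenly(self):
        sys_ = _system("Rp5", "Rp5")
        settings = VentilatorSettings(tidal_volume=1.0, rate=20)
        rec = advance(sys_, settings, dt=1e-3)
        assert rec.phase == "I"
        # VT/t_i = 1 l/s total -> each chamber gains q*dt/2 = 0.5 ml
        assert sys_.left.volume == pytest.approx(0.5e-3, rel=1e-9)
        assert sys_.right.volume == pytest.approx(sys_.left.volume, rel=1e-12)
        assert rec.q_left == pytest.approx(-0.5, rel=1e-9)  # out-positive convention

    def test_empty_chamber_stays_clamped_at_zero(self):
        sys_ = _system("Rp5", "Rp50", v_left=0.0, v_right=0.0, clamp=True)
        sys_.time = 1.5  # inside expiration for the 20/min pattern
        settings = VentilatorSettings(tidal_volume=1.0, rate=20)
        advance(sys_, settings, dt=1e-3)
        assert sys_.left.volume == 0.0
        assert sys_.right.volume == 0.0

    def test_first_order_convergence_in_dt(self):
        """Richardson: halving dt halves the end-expiratory volume error."""
        settings = VentilatorSettings(tidal_volume=1.0, rate=20)
        eev = []
        for dt in (2e-3, 1e-3, 5e-4):
            res = simulate(build_point_system("air", 0.05, "Rp50"), settings,
                           n_breaths=1, dt=dt)
            eev.append(res.breaths[-1].end_expiratory_right)
        ratio = (eev[0] - eev[1]) / (eev[1] - eev[2])
        assert 1.5 < ratio < 2.7


class TestSimulate:
    def test_symmetric_system_has_equal_time_constants(self, pattern_20):
        res = simulate(build_point_system("heliox", 0.05, "Rp5"), pattern_20,
                       n_breaths=4, dt=1e-3)
        for breath in range(len(res.breaths)):
            tau_l = apparent_time_constant(res.breath_summary("left", breath)).tau
            tau_r = apparent_time_constant(res.breath_summary("right", breath)).tau
            assert tau_l == pytest.approx(tau_r, rel=1e-6)

    def test_mass_conservation_at_steady_cycle(self, pattern_20):
        res = simulate(build_point_system("heliox", 0.05, "Rp20"), pattern_20,
                       n_breaths=6, dt=1e-3)
        assert res.steady
        b = res.breaths[-1]
        exhaled = b.v_exhaled_left + b.v_exhaled_right
        assert exhaled == pytest.approx(pattern_20.tidal_volume, rel=5e-3)

    def test_volume_traces_never_negative(self, pattern_20):
        res = simulate(build_point_system("air", 0.02, "Rp50"), pattern_20,
                       n_breaths=3, dt=1e-3)
        assert (res.v_left >= 0).all()
        assert (res.v_right >= 0).all()

    def test_tau_right_monotone_in_obstruction_at_figure_conditions(self, pattern_20):
        """At the compliance shown in the bench figures (0.05 l/cmH2O) the
        obstructed-chamber time constant rises with the loss coefficient."""
        taus = []
        for rp in ("Rp5", "Rp20", "Rp50"):
            res = simulate(build_point_system("heliox", 0.05, rp), pattern_20,
                           n_breaths=8, dt=2e-3, stop_at_steady=True)
            taus.append(apparent_time_constant(res.breath_summary("right")).tau)
        assert taus[0] < taus[1] < taus[2]

    def test_trace_dataframe_columns(self, pattern_6):
        res = simulate(build_point_system("air", 0.05, "Rp5"), pattern_6,
                       n_breaths=1, dt=5e-3)
        df = res.to_dataframe()
        assert list(df.columns) == [
            "time_s", "phase", "q_left_lps", "q_right_lps", "q_total_lps",
            "v_left_l", "v_right_l", "p_left_cmh2o", "p_right_cmh2o",
        ]


class TestSingleChamberOracle:
    def _single_chamber_system(self, c, k, gas, v0):
        # degenerate left chamber (negligible compliance, zero volume) so the
        # system reduces to one compartment; circuit loss folded into k
        return LungSystem(
            left=Chamber(compliance=1e-9, resistor=make_resistor("Rp5"),
                         sensor_loss_k=0.0, volume=0.0),
            right=Chamber(compliance=c, resistor=make_resistor(k),
                          sensor_loss_k=0.0, volume=v0),
            gas=gas,
            circuit=CircuitLossModel(form="inertial", k=0.0),
            clamp_expiratory_inflow=True,
        )

    def test_closed_form_reference_value(self):
        t_empty, _ = single_chamber_emptying_closed_form(
            0.05, 132.9, reference_area(), HELIOX, 0.3335
        )
        assert t_empty == pytest.approx(1.5947, rel=1e-3)

    def test_sqrt_scaling_in_volume_and_density(self):
        area = reference_area()
        t1, _ = single_chamber_emptying_closed_form(0.05, 132.9, area, HELIOX, 0.3335)
        t4, _ = single_chamber_emptying_closed_form(0.05, 132.9, area, HELIOX, 4 * 0.3335)
        assert t4 == pytest.approx(2 * t1, rel=1e-12)
        quad_rho = HELIOX.at(pressure=4 * 101325.0)
        t_rho, _ = single_chamber_emptying_closed_form(0.05, 132.9, area, quad_rho, 0.3335)
        assert t_rho == pytest.approx(2 * t1, rel=1e-12)

    def test_simulated_trace_matches_closed_form(self):
        t_empty, oracle = single_chamber_emptying_closed_form(
            0.05, 132.9, reference_area(), HELIOX, 0.3335, dt=1e-3
        )
        sys_ = self._single_chamber_system(0.05, 132.9, HELIOX, 0.3335)
        res = run_expiration(sys_, duration=t_empty, dt=1e-3)
        n = min(len(res.q_right), len(oracle.flows))
        rms = np.sqrt(np.mean((res.q_right[:n] - oracle.flows[:n]) ** 2))
        assert rms / oracle.flows.max() < 5e-3

    def test_flow_decays_linearly(self):
        _, oracle = single_chamber_emptying_closed_form(
            0.05, 132.9, reference_area(), AIR, 0.3335, dt=1e-3
        )
        q = oracle.flows[oracle.flows > 0]
        second_diff = np.diff(q, 2)
        assert np.max(np.abs(second_diff)) < 1e-9 * q[0]
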