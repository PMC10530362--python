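"""Master-equation simulator: exactness, conservation, steady-state oracle
agreement with the closed forms, and the gate-blocker interaction signatures
(tail currents, trapping residual, pore-site competition)."""

import dataclasses

import numpy as np
import pytest

import azoblock as az
from azoblock import kinetics as kin


def _segment(V=-70.0, agonist=100.0, C=0.0, duration=1.0):
    blockers = {"blocker": C} if C > 0 else {}
    return kin.Segment(duration, voltage=V, agonist=agonist, blockers=blockers)


TAIL_PROTOCOL = kin.Protocol([
    kin.Segment(2.0, voltage=-70.0, agonist=100.0),
    kin.Segment(3.0, voltage=-70.0, agonist=100.0, blockers={"blocker": 300.0}),
    kin.Segment(2.0, voltage=-70.0),
])


class TestSchemeConstruction:
    def test_foot_in_door_cannot_close_while_blocked(self, gating, block_rates, qaq_nmda):
        s = kin.build_block_scheme("foot_in_door", gating, block_rates, qaq_nmda)
        assert not s.has_transition("OpenBlocked", "ClosedBlocked")
        assert "ClosedBlocked" not in s.states

    def test_trapping_closes_over_the_blocker(self, gating, block_rates, qaq_nmda):
        s = kin.build_block_scheme("trapping", gating, block_rates, qaq_nmda)
        assert s.has_transition("OpenBlocked", "ClosedBlocked")
        assert s.has_transition("ClosedBlocked", "OpenBlocked")

    def test_unknown_mode_rejected(self, gating, block_rates, qaq_nmda):
        with pytest.raises(kin.SchemeError, match="unknown mode"):
            kin.build_block_scheme("sideways", gating, block_rates, qaq_nmda)

    def test_permeant_mode_needs_permeation_term(self, gating, block_rates, qaq_nmda):
        with pytest.raises(kin.SchemeError, match="K_p"):
            kin.build_block_scheme("permeant", gating, block_rates, qaq_nmda)

    def test_rate_matrix_rows_sum_to_zero(self, gating, block_rates, qaq_cp_ampa):
        s = kin.build_block_scheme("permeant", gating, block_rates, qaq_cp_ampa)
        Q = s.rate_matrix(_segment(C=30.0))
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        off = Q[~np.eye(len(s.states), dtype=bool)]
        assert np.all(off >= 0)


class TestSimulate:
    def test_zero_rates_freeze_occupancy(self):
        s = kin.KineticScheme(
            states=("Closed", "Open"),
            transitions=(kin.Transition("Closed", "Open", kin.RateLaw(0.0)),),
            conductance={"Closed": 0.0, "Open": 1.0},
        )
        p0 = np.array([0.3, 0.7])
        tc = kin.simulate(s, kin.Protocol([_segment(duration=2.0)]), dt=0.01, p0=p0)
        np.testing.assert_allclose(
            tc.occupancy, np.broadcast_to(p0, tc.occupancy.shape), atol=1e-15
        )

    def test_two_state_relaxation_matches_analytic_solution(self):
        a, b = 12.0, 5.0
        s = kin.KineticScheme(
            states=("Closed", "Open"),
            transitions=(
                kin.Transition("Closed", "Open", kin.RateLaw(a)),
                kin.Transition("Open", "Closed", kin.RateLaw(b)),
            ),
            conductance={"Closed": 0.0, "Open": 1.0},
        )
        tc = kin.simulate(s, kin.Protocol([_segment(duration=1.0)]), dt=1e-3)
        p_inf = a / (a + b)
        expected = p_inf * (1 - np.exp(-(a + b) * tc.time))
        np.testing.assert_allclose(tc.occupancy_of("Open"), expected, atol=1e-8)

    def test_terminal_state_insensitive_to_dt(self, gating, block_rates, qaq_nmda):
        s = kin.build_block_scheme("foot_in_door", gating, block_rates, qaq_nmda)
        tc1 = kin.simulate(s, TAIL_PROTOCOL, dt=2e-3)
        tc2 = kin.simulate(s, TAIL_PROTOCOL, dt=1e-3)
        assert np.abs(tc1.occupancy[-1] - tc2.occupancy[-1]).max() < 1e-6

    def test_probability_conserved_and_nonnegative(self, gating, block_rates, qaq_cp_ampa):
        s = kin.build_block_scheme("trapping", gating, block_rates, qaq_cp_ampa)
        tc = kin.simulate(s, TAIL_PROTOCOL, dt=1e-3)
        np.testing.assert_allclose(tc.occupancy.sum(axis=1), 1.0, atol=1e-9)
        assert tc.occupancy.min() >= -1e-12

    def test_dt_larger_than_segment_rejected(self, gating, block_rates, qaq_nmda):
        s = kin.build_block_scheme("foot_in_door", gating, block_rates, qaq_nmda)
        with pytest.raises(kin.SchemeError, match="dt"):
            kin.simulate(s, TAIL_PROTOCOL, dt=5.0)

    def test_inward_current_is_negative(self, gating, block_rates, qaq_nmda):
        s = kin.build_block_scheme("foot_in_door", gating, block_rates, qaq_nmda)
        tc = kin.simulate(s, kin.Protocol([_segment(duration=1.0)]), dt=1e-3)
        assert tc.current[-1] < 0  # V = -70 mV below E_rev = 0


class TestSteadyState:
    def test_without_blocker_only_gating_states_occupied(self, gating, block_rates, qaq_nmda):
        s = kin.build_block_scheme("trapping", gating, block_rates, qaq_nmda)
        # reach the blocker-free stationary distribution dynamically: the
        # blocked states are then transient and empty
        proto = kin.Protocol([_segment(duration=5.0)])
        tc = kin.simulate(s, proto, dt=1e-3)
        assert tc.occupancy_of("OpenBlocked")[-1] < 1e-12
        assert tc.occupancy_of("ClosedBlocked")[-1] < 1e-12
        assert tc.occupancy_of("Open")[-1] == pytest.approx(2.0 / 3.0, abs=1e-9)

    def test_matches_long_simulation(self, gating, block_rates, qaq_cp_ampa):
        s = kin.build_block_scheme("permeant", gating, block_rates, qaq_cp_ampa)
        seg = _segment(C=30.0, duration=5.0)
        ss = kin.steady_state(s, seg)
        tc = kin.simulate(s, kin.Protocol([seg]), dt=1e-3)
        assert np.abs(tc.occupancy[-1] - ss).max() < 1e-7

    def test_permeant_unblocked_fraction_equals_closed_form(
        self, gating, block_rates, qaq_cp_ampa, thermo
    ):
        s = kin.build_block_scheme("permeant", gating, block_rates, qaq_cp_ampa)
        for V in (-140.0, -70.0, 0.0, 20.0):
            for C in (1.0, 30.0, 500.0):
                seg = _segment(V=V, C=C)
                got = kin.unblocked_fraction(s, kin.steady_state(s, seg), seg)
                want = float(az.ratio_eq2(C, V, qaq_cp_ampa, thermo))
                assert got == pytest.approx(want, abs=1e-6)

    def test_allosteric_site_reproduces_two_site_model(
        self, gating, block_rates, qaq_cp_ampa, thermo
    ):
        s = kin.build_block_scheme("allosteric", gating, block_rates, qaq_cp_ampa)
        seg = _segment(V=-70.0, C=30.0)
        got = kin.unblocked_fraction(s, kin.steady_state(s, seg), seg)
        assert got == pytest.approx(float(az.ratio_eq3(30.0, -70.0, qaq_cp_ampa, thermo)),
                                    abs=1e-9)

    def test_rate_scale_invariance(self, qaq_cp_ampa):
        seg = _segment(C=30.0)
        s1 = kin.build_block_scheme("permeant", kin.GatingRates(), kin.BlockRates(),
                                    qaq_cp_ampa)
        s2 = kin.build_block_scheme(
            "permeant",
            kin.GatingRates(opening_per_uM=1.0, closing=50.0),
            kin.BlockRates(kon_per_uM=1.4),
            qaq_cp_ampa,
        )
        np.testing.assert_allclose(kin.steady_state(s1, seg), kin.steady_state(s2, seg),
                                   atol=1e-10)

    def test_reducible_conditions_flagged_with_closed_classes(
        self, gating, block_rates, qaq_nmda
    ):
        s = kin.build_block_scheme("trapping", gating, block_rates, qaq_nmda)
        with pytest.raises(kin.ReducibleSchemeError) as exc:
            kin.steady_state(s, _segment(agonist=0.0))  # nothing can reopen
        assert exc.value.closed_classes  # absorbing-class report present

    def test_detailed_balance_without_permeation(self, gating, block_rates, qaq_nmda,
                                                 qaq_cp_ampa):
        s = kin.build_block_scheme("trapping", gating, block_rates, qaq_nmda)
        assert kin.detailed_balance_violation(s, _segment(C=30.0)) < 1e-9
        s_perm = kin.build_block_scheme("permeant", gating, block_rates, qaq_cp_ampa)
        assert kin.detailed_balance_violation(s_perm, _segment(C=30.0)) > 1e-3


class TestTailCurrents:
    def test_agonist_alone_decays_without_tail(self, gating, block_rates, qaq_nmda):
        s = kin.build_block_scheme("foot_in_door", gating, block_rates, qaq_nmda)
        proto = kin.Protocol([_segment(duration=2.0), _segment(agonist=0.0, duration=2.0)])
        tc = kin.simulate(s, proto, dt=1e-3)
        assert kin.tail_current_index(tc, 2.0) <= 1.0

    def test_foot_in_door_overshoots_after_washout(self, gating, block_rates, qaq_nmda):
        s = kin.build_block_scheme("foot_in_door", gating, block_rates, qaq_nmda)
        tc = kin.simulate(s, TAIL_PROTOCOL, dt=1e-3)
        assert kin.tail_current_index(tc, 5.0) > 1.5

    def test_slow_trapping_blocker_shows_no_tail(self, gating):
        slow_params, slow_rates = kin.slow_trapping_reference()
        s = kin.build_block_scheme("trapping", gating, slow_rates, slow_params)
        proto = kin.Protocol([
            _segment(duration=2.0),
            kin.Segment(8.0, voltage=-70.0, agonist=100.0, blockers={"blocker": 2.0}),
            kin.Segment(4.0, voltage=-70.0),
        ])
        tc = kin.simulate(s, proto, dt=1e-3)
        assert kin.tail_current_index(tc, 10.0) <= 1.0 + 1e-6

    def test_fast_kinetics_blur_the_mode_distinction(self, gating, block_rates, qaq_nmda):
        # with binding faster than gating (k_on C >> closing rate) even a
        # trapping scheme overshoots transiently: the tail-current
        # diagnostic discriminates modes only for slow-unbinding blockers
        s = kin.build_block_scheme("trapping", gating, block_rates, qaq_nmda)
        tc = kin.simulate(s, TAIL_PROTOCOL, dt=1e-3)
        assert kin.tail_current_index(tc, 5.0) > 1.0

    def test_washout_time_outside_window_rejected(self, gating, block_rates, qaq_nmda):
        s = kin.build_block_scheme("foot_in_door", gating, block_rates, qaq_nmda)
        tc = kin.simulate(s, TAIL_PROTOCOL, dt=1e-3)
        with pytest.raises(ValueError, match="washout"):
            kin.tail_current_index(tc, 10.0)


class TestTrappingResidual:
    def test_trapped_blocker_survives_agonist_free_wash(self, gating):
        slow_params, slow_rates = kin.slow_trapping_reference()
        s = kin.build_block_scheme("trapping", gating, slow_rates, slow_params)
        res = kin.double_pulse_residual(s, concentration=2.0, pulse_s=4.0, wash_s=2.0)
        assert res > 0.3

    def test_foot_in_door_blocker_fully_washes_out(self, gating, block_rates, qaq_nmda):
        s = kin.build_block_scheme("foot_in_door", gating, block_rates, qaq_nmda)
        res = kin.double_pulse_residual(s, concentration=30.0)
        assert abs(res) <= 1e-6

    def test_near_irreversible_blocker_retained_indefinitely(self, gating):
        # k_off -> 0: blocked occupancy persists after agonist removal
        p = az.BlockParams(K_b=1e-8, delta_b=0.5, z=2)
        s = kin.build_block_scheme("trapping", gating, kin.BlockRates(0.5), p)
        proto = kin.Protocol([
            kin.Segment(5.0, voltage=-70.0, agonist=100.0, blockers={"blocker": 2.0}),
            kin.Segment(20.0, voltage=-70.0),
        ])
        tc = kin.simulate(s, proto, dt=5e-3)
        blocked_at_wash = (tc.occupancy_of("OpenBlocked") +
                           tc.occupancy_of("ClosedBlocked"))[tc.time <= 5.0][-1]
        blocked_end = (tc.occupancy_of("OpenBlocked") +
                       tc.occupancy_of("ClosedBlocked"))[-1]
        assert blocked_end == pytest.approx(blocked_at_wash, rel=1e-4)


class TestCompetition:
    @pytest.fixture(scope="class")
    def slow(self):
        return kin.slow_trapping_reference()

    def test_pore_partner_accelerates_recovery(self, gating, block_rates, qaq_nmda, slow):
        slow_params, slow_rates = slow
        tau_alone = kin.competition_recovery_tau(gating, slow_params, slow_rates,
                                                 partner="none", dt=5e-3)
        tau_pore = kin.competition_recovery_tau(
            gating, slow_params, slow_rates, partner="pore",
            partner_params=qaq_nmda, partner_block=block_rates, dt=5e-3,
        )
        assert tau_alone / tau_pore >= 2.0

    def test_independent_allosteric_partner_changes_nothing(self, gating, slow):
        slow_params, slow_rates = slow
        tau_alone = kin.competition_recovery_tau(gating, slow_params, slow_rates,
                                                 partner="none", dt=5e-3)
        allo = az.BlockParams(K_b=1.0, delta_b=0.0, K_vin=20.0, z=1)
        tau_allo = kin.competition_recovery_tau(
            gating, slow_params, slow_rates, partner="allosteric",
            partner_params=allo, partner_conc=200.0, dt=5e-3,
        )
        assert abs(tau_allo - tau_alone) / tau_alone < 0.05

    def test_fast_unbinding_limits_recovery_to_solution_exchange(self, gating, qaq_nmda):
        # a slow blocker with k_off made huge recovers within the first
        # samples of the washout segment
        fast_escape = dataclasses.replace(qaq_nmda, K_b=1e5)
        tau = kin.competition_recovery_tau(gating, fast_escape, kin.BlockRates(0.7),
                                           partner="none", dt=5e-3)
        assert tau < 0.5
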