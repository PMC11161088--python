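import math

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.optimize import brentq

from rosdyn import (
    CompartmentState,
    DetachmentSchedule,
    ModelDomainError,
    equilibrium_points,
    equilibrium_total_length,
    integrate,
    critical_time,
    nondimensionalize,
    sweep_critical_time,
    time_to_equilibrium,
)


def linear_crossing_time(params, gamma, state0, lc, horizon=2000.0):
    """Matrix-exponential oracle for the δ=0 regime.

    With addition halted the (Lg, Lm) subsystem is linear; the total length
    is monotone non-increasing, so the first crossing of Lc is the unique
    root of a closed-form expression.
    """
    A = np.array([[-params.alpha_g, 0.0], [params.alpha_g, -gamma * params.alpha_s]])
    y0 = np.array([state0.Lg, state0.Lm])

    def lt(t):
        return float(np.sum(expm(A * t) @ y0))

    if lt(0.0) <= lc:
        return 0.0
    if lt(horizon) > lc:
        return None
    return brentq(lambda t: lt(t) - lc, 0.0, horizon, xtol=1e-12)


class TestIntegrate:
    def test_normal_renewal_reaches_equilibrium_length(self, params, normal, single_disc):
        traj = integrate(single_disc, params, normal, horizon=30.0)
        assert traj.Lt[-1] == pytest.approx(equilibrium_total_length(params, 1, 1), rel=5e-3)

    def test_total_length_is_sum_of_outer_compartments(self, params, normal, adult_state):
        traj = integrate(adult_state, params, normal, horizon=10.0)
        assert np.allclose(traj.Lt, traj.Lg + traj.Lm)

    def test_output_frame_columns(self, params, normal, adult_state):
        frame = integrate(adult_state, params, normal, horizon=1.0).to_frame()
        assert list(frame.columns) == [
            "t_days", "Lg_um", "Lm_um", "Ls_um", "Lt_um", "G_discs", "M_discs", "S_discs",
        ]
        assert frame.M_discs.iloc[0] == pytest.approx(627, abs=0.51)

    def test_integration_splits_at_reattachment(self, params, adult_state):
        """Detachment shortens the ROS; reattachment regrows it."""
        sched = DetachmentSchedule(delta0=0.0, gamma0=0.625, Ta=30.0)
        traj = integrate(adult_state, params, sched, horizon=60.0)
        before = traj.Lt[traj.times <= 30.0]
        assert np.all(np.diff(before) < 0)
        assert traj.dense(40.0)[:2].sum() > traj.dense(30.0)[:2].sum()

    def test_bad_inputs(self, params, normal):
        with pytest.raises(ModelDomainError):
            integrate(CompartmentState(0.0, 0.0, 1.0), params, normal, horizon=1.0)
        with pytest.raises(ValueError):
            integrate(CompartmentState(1.0, 1.0, 0.0), params, normal, horizon=-1.0)
        with pytest.raises(ValueError):
            integrate(CompartmentState(1.0, 1.0, 0.0), params, normal, horizon=1.0,
                      grid=np.array([0.0, 2.0]))


class TestTimeToEquilibrium:
    def test_zero_when_starting_at_equilibrium(self, params, nd, normal):
        e1 = equilibrium_points(nd, 1.0, 1.0).point("E1").state * params.Lmax
        t = time_to_equilibrium(CompartmentState.from_array(e1), params, normal, horizon=50.0)
        assert t == 0.0

    def test_matches_independent_band_scan(self, params, normal, single_disc):
        """Cross-check against a brute-force scan of a finely sampled trajectory."""
        t = time_to_equilibrium(single_disc, params, normal, band=0.02, horizon=60.0)
        lt_star = equilibrium_total_length(params, 1, 1)
        grid = np.linspace(0.0, 60.0, 60_001)
        traj = integrate(single_disc, params, normal, horizon=60.0, grid=grid)
        outside = np.nonzero(np.abs(traj.Lt - lt_star) / lt_star > 0.02)[0]
        assert t == pytest.approx(grid[outside[-1]], abs=2e-3)

    def test_agrees_with_reduced_model_entry_time(self, params, normal, single_disc):
        """A one-variable reduction (u = Lt², valid for Lg ≪ Lm) predicts the
        band-entry time of normal renewal to within a day."""
        band = 0.02
        u0 = single_disc.total_length ** 2
        u_star = params.mu0 * params.Lmax / params.alpha_s
        t_reduced = math.log((u_star - u0) / (u_star * (1 - (1 - band) ** 2))) / (
            2 * params.alpha_s
        )
        t = time_to_equilibrium(single_disc, params, normal, band=band, horizon=60.0)
        assert abs(t - t_reduced) < 1.0

    def test_tighter_band_takes_longer(self, params, normal, single_disc):
        t2 = time_to_equilibrium(single_disc, params, normal, band=0.02, horizon=60.0)
        t1 = time_to_equilibrium(single_disc, params, normal, band=0.01, horizon=60.0)
        assert t1 > t2

    def test_requires_finite_equilibrium(self, params, adult_state):
        with pytest.raises(ModelDomainError):
            time_to_equilibrium(
                adult_state, params, DetachmentSchedule(delta0=0.0, gamma0=1.0), horizon=10.0
            )


class TestCriticalTime:
    def test_already_below_threshold(self, params, normal, adult_state):
        ev = critical_time(adult_state, params, normal, Lc=25.0)
        assert ev.crossed and ev.Tc == 0.0

    def test_frozen_regime_never_crosses(self, params, adult_state):
        sched = DetachmentSchedule(delta0=0.0, gamma0=0.0)
        ev = critical_time(adult_state, params, sched, Lc=10.0, horizon=200.0)
        assert ev.status == "never"

    def test_growth_regime_never_crosses(self, params, adult_state):
        sched = DetachmentSchedule(delta0=0.0136, gamma0=0.0)
        ev = critical_time(adult_state, params, sched, Lc=10.0, horizon=200.0)
        assert ev.status == "never"

    def test_short_horizon_is_reported_undecided(self, params, adult_state):
        sched = DetachmentSchedule(delta0=0.0, gamma0=0.05)
        ev = critical_time(adult_state, params, sched, Lc=10.0, horizon=5.0)
        assert ev.status == "undecided"
        assert ev.Tc is None

    def test_reattachment_can_rescue_the_cell(self, params, adult_state):
        # brief detachment: the length never reaches Lc and regrows after Ta
        sched = DetachmentSchedule(delta0=0.0, gamma0=0.625, Ta=2.0)
        ev = critical_time(adult_state, params, sched, Lc=15.0, horizon=100.0)
        assert ev.status == "never"

    @pytest.mark.parametrize("gamma,lc", [(0.3, 15.0), (0.625, 10.0), (1.2, 5.0)])
    def test_matches_matrix_exponential_oracle(self, params, adult_state, gamma, lc):
        """Event-detected crossing equals the linear-system closed form to 1e-3 day."""
        sched = DetachmentSchedule(delta0=0.0, gamma0=gamma)
        ev = critical_time(adult_state, params, sched, Lc=lc)
        t_oracle = linear_crossing_time(params, gamma, adult_state, lc)
        assert ev.crossed
        assert ev.Tc == pytest.approx(t_oracle, abs=1e-3)

    def test_event_location_accuracy(self, params, adult_state):
        sched = DetachmentSchedule(delta0=0.0, gamma0=0.625)
        ev = critical_time(adult_state, params, sched, Lc=10.0)
        assert abs(ev.terminal_state.total_length - 10.0) < 1e-6

    def test_tolerance_refinement_convergence(self, params, adult_state):
        sched = DetachmentSchedule(delta0=0.0, gamma0=0.625)
        t1 = critical_time(adult_state, params, sched, Lc=10.0, rtol=1e-9).Tc
        t2 = critical_time(adult_state, params, sched, Lc=10.0, rtol=1e-10, atol=1e-13).Tc
        assert abs(t1 - t2) < 1e-3

    def test_smaller_critical_length_gives_later_crossing(self, params, adult_state):
        sched = DetachmentSchedule(delta0=0.0, gamma0=0.625)
        tc = {
            lc: critical_time(adult_state, params, sched, Lc=lc).Tc for lc in (5.0, 10.0, 15.0)
        }
        assert tc[5.0] > tc[10.0] > tc[15.0]

    def test_invalid_critical_length(self, params, adult_state, normal):
        with pytest.raises(ValueError):
            critical_time(adult_state, params, normal, Lc=0.0)


class TestSweep:
    @pytest.fixture
    def halted(self):
        return DetachmentSchedule(delta0=0.0, gamma0=1.0)

    def test_removal_rate_sweep_is_strictly_decreasing(self, params, adult_state, halted):
        values = np.linspace(0.25, 2.0, 8)
        table = sweep_critical_time("gamma", values, adult_state, params, halted, Lc=10.0)
        assert (table.status == "crossed").all()
        assert np.all(np.diff(table.Tc) < 0)

    def test_disposal_rate_does_not_affect_critical_time(self, params, adult_state, halted):
        values = np.linspace(0.05, 1.0, 8)
        table = sweep_critical_time("mu_s", values, adult_state, params, halted, Lc=10.0)
        assert np.ptp(table.Tc.to_numpy()) < 1e-6

    def test_single_value_equals_direct_call(self, params, adult_state, halted):
        table = sweep_critical_time("gamma", [0.625], adult_state, params, halted, Lc=10.0)
        direct = critical_time(adult_state, params,
                               DetachmentSchedule(delta0=0.0, gamma0=0.625), Lc=10.0)
        assert table.Tc.iloc[0] == pytest.approx(direct.Tc, abs=1e-9)

    def test_uncrossed_values_are_flagged(self, params, adult_state, halted):
        table = sweep_critical_time("gamma", [0.0, 1.0], adult_state, params, halted, Lc=10.0)
        assert list(table.status) == ["never", "crossed"]
        assert math.isnan(table.Tc.iloc[0])

    def test_requires_halted_addition_and_values(self, params, adult_state, normal, halted):
        with pytest.raises(ValueError):
            sweep_critical_time("gamma", [1.0], adult_state, params, normal, Lc=10.0)
        with pytest.raises(ValueError):
            sweep_critical_time("gamma", [], adult_state, params, halted, Lc=10.0)
        with pytest.raises(ValueError):
            sweep_critical_time("mu0", [1.0], adult_state, params, halted, Lc=10.0)
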