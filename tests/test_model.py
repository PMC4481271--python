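"""Daily switched maps: one-step arithmetic, simulation, protocol switching."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import iasfit as F
from iasfit.model import TreatmentSchedule


def make_params(x0=(1.0, 0.0, 0.0),
                d_on=(1.0, 0.0, 1.0, 0.0, 0.0, 1.0),
                d_off=(1.0, 0.0, 1.0, 1.0)) -> F.CombinedParameters:
    return F.CombinedParameters(x0, d_on, d_off)


class TestStep:
    @pytest.mark.parametrize("state,m,expected", [
        # identity coefficients leave the state unchanged
        ((1, 0, 0), 1, (1.0, 0.0, 0.0)),
        # on-treatment map: leakage from x1 into both resistant pools
        ((1, 2, 0), 1, (0.9, 2.05, 0.08)),
        # off-treatment map: reversion from x2 back into x1
        ((1, 2, 3), 0, (1.2, 1.8, 3.0)),
    ])
    def test_one_day_arithmetic(self, state, m, expected):
        if m == 1 and expected == (1.0, 0.0, 0.0):
            p = make_params()
        else:
            p = make_params(d_on=(0.9, 0.05, 1.0, 0.02, 0.03, 1.01),
                            d_off=(1.1, 0.05, 0.9, 1.0))
        out = F.step(state, p, m)
        assert np.allclose([out.x1, out.x2, out.x3], expected)

    def test_rejects_non_binary_flag(self):
        with pytest.raises(ValueError, match="flag"):
            F.step((1, 0, 0), make_params(), 2)


class TestSimulate:
    def test_zero_horizon_returns_only_initial_state(self):
        traj = F.simulate(make_params(x0=(2, 3, 4)),
                          TreatmentSchedule.all_on(1), 0)
        assert traj.states.shape == (1, 3)
        assert np.allclose(traj.states[0], [2, 3, 4])
        assert traj.psa[0] == 9

    def test_scalar_geometric_growth(self):
        p = make_params(d_on=(1.2, 0.0, 1.0, 0.0, 0.0, 1.0))
        traj = F.simulate(p, TreatmentSchedule.all_on(10), 10)
        assert np.allclose(traj.psa, 1.2 ** np.arange(11))

    def test_schedule_gap_inside_horizon_is_an_error(self):
        sched = TreatmentSchedule(((0, 5, 1),))
        with pytest.raises(ValueError, match="gap|ends"):
            F.simulate(make_params(), sched, 10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_repeated_python_step(self, seed):
        """The compiled simulator agrees with the one-day reference map."""
        rng = np.random.default_rng(seed)
        p = F.CombinedParameters(rng.uniform(0, 20, 3),
                                 rng.uniform(0, 1.3, 6),
                                 rng.uniform(0, 1.3, 4))
        sched = TreatmentSchedule(((0, 7, 1), (7, 12, 0), (12, 20, 1)))
        traj = F.simulate(p, sched, 20)
        x = F.TumorState(*p.x0)
        for t in range(20):
            assert np.allclose(traj.states[t], x.to_array(), rtol=1e-12)
            x = F.step(x, p, sched.flag_at(t))
        assert np.allclose(traj.states[20], x.to_array(), rtol=1e-12)

    def test_psa_is_component_sum(self, feasible_params):
        traj = F.simulate_cas(feasible_params, 50)
        assert np.allclose(traj.psa, traj.states.sum(axis=1))

    def test_to_frame_tidy_export(self, feasible_params):
        df = F.simulate_cas(feasible_params, 5).to_frame()
        assert list(df.columns) == ["day", "x1", "x2", "x3", "psa", "m"]
        assert len(df) == 6
        assert (df["m"] == 1).all()


class TestModelProperties:
    @given(st.integers(0, 2 ** 32 - 1))
    def test_non_negativity(self, seed):
        """Non-negative coefficients map non-negative states forward."""
        rng = np.random.default_rng(seed)
        p = F.CombinedParameters(rng.uniform(0, 10, 3),
                                 rng.uniform(0, 1.3, 6),
                                 rng.uniform(0, 1.3, 4))
        sched = TreatmentSchedule(((0, 10, 1), (10, 30, 0)))
        assert np.all(F.simulate(p, sched, 30).states >= 0)

    @given(st.integers(0, 2 ** 32 - 1),
           st.floats(0.1, 50.0, allow_nan=False))
    def test_linearity_in_initial_state(self, seed, alpha):
        """Scaling the initial burden scales the whole PSA course."""
        rng = np.random.default_rng(seed)
        x0 = rng.uniform(0.1, 10, 3)
        d_on = rng.uniform(0, 1.2, 6)
        d_off = rng.uniform(0, 1.2, 4)
        sched = TreatmentSchedule(((0, 15, 1), (15, 25, 0)))
        base = F.simulate(F.CombinedParameters(x0, d_on, d_off), sched, 25)
        scaled = F.simulate(F.CombinedParameters(alpha * x0, d_on, d_off),
                            sched, 25)
        assert np.allclose(scaled.psa, alpha * base.psa, rtol=1e-9)

    @given(st.integers(0, 2 ** 32 - 1))
    def test_column_stochastic_matrices_conserve_psa(self, seed):
        """Unit column sums move burden between pools without creating it."""
        rng = np.random.default_rng(seed)
        a, b = rng.uniform(0, 0.3, 2)
        c = rng.uniform(0, 0.3)
        # on: columns (1-a-b, a, b), (0, 1-c, c), (0, 0, 1)
        d_on = (1 - a - b, a, 1 - c, b, c, 1.0)
        r = rng.uniform(0, 0.3)
        d_off = (1.0, r, 1 - r, 1.0)
        p = F.CombinedParameters(rng.uniform(0, 10, 3), d_on, d_off)
        sched = TreatmentSchedule(((0, 10, 1), (10, 20, 0)))
        psa = F.simulate(p, sched, 20).psa
        assert np.allclose(psa, psa[0], rtol=1e-10)


class TestSimulateIAS:
    def test_never_reaching_low_threshold_stays_on(self):
        """Growth under treatment never triggers the stop rule: one segment."""
        p = make_params(x0=(5, 0, 0), d_on=(1.01, 0.0, 1.0, 0.0, 0.0, 1.0))
        proto = F.IASProtocol(min_on_days=10, psa_low=1.0, psa_high=10.0,
                              horizon=200)
        _, sched = F.simulate_ias(p, proto)
        assert sched.segments == ((0, 200, 1),)

    def test_alternating_segments_for_cycling_dynamics(self):
        """Shrink on treatment, regrow off: strictly alternating segments."""
        p = make_params(x0=(8, 0, 0), d_on=(0.97, 0.0, 1.0, 0.0, 0.0, 1.0),
                        d_off=(1.03, 0.0, 1.0, 1.0))
        proto = F.IASProtocol(min_on_days=30, psa_low=1.0, psa_high=10.0,
                              horizon=1500)
        _, sched = F.simulate_ias(p, proto)
        flags = [m for _, _, m in sched.segments]
        assert len(flags) >= 4
        assert all(a != b for a, b in zip(flags, flags[1:]))
        assert flags[0] == 1

    def test_resimulating_returned_schedule_reproduces_trajectory(
            self, feasible_params):
        proto = F.IASProtocol(horizon=1200)
        traj, sched = F.simulate_ias(feasible_params, proto)
        again = F.simulate(feasible_params, sched, 1200)
        assert np.array_equal(traj.states, again.states)

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            F.IASProtocol(psa_low=10.0, psa_high=1.0)
        with pytest.raises(ValueError):
            F.IASProtocol(min_on_days=0)


class TestTreatmentSchedule:
    def test_must_start_at_zero_and_be_contiguous(self):
        with pytest.raises(ValueError):
            TreatmentSchedule(((1, 5, 1),))
        with pytest.raises(ValueError):
            TreatmentSchedule(((0, 5, 1), (6, 8, 0)))
        with pytest.raises(ValueError):
            TreatmentSchedule(((0, 5, 2),))

    def test_flags_round_trip(self):
        sched = TreatmentSchedule(((0, 3, 1), (3, 7, 0), (7, 9, 1)))
        flags = sched.flags(9)
        assert TreatmentSchedule.from_flags(flags).segments == sched.segments
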