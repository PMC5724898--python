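"""Steady states, simulation, exact adaptation and compensation symmetries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hyp

import strident as st
from strident.dc import SimulationError, rhs_value
from strident.signals import InputSignal, Pulse


@pytest.fixture(scope="module")
def decay_model():
    return st.define_model(
        {
            "name": "decay",
            "states": ["x"],
            "params": ["p"],
            "inputs": ["v"],
            "constants": {"u0": 2},
            "dynamics": {"x": "u0 + v - p*x"},
            "defaults": {"p": 0.5},
        }
    )


class TestSteadyState:
    def test_closed_form(self, decay_model):
        x = st.find_steady_state(decay_model)
        assert x == pytest.approx([4.0], abs=1e-10)  # u0 / p

    def test_residual_postcondition(self, betaIG, betaIG_steady):
        res = rhs_value(betaIG, betaIG_steady, betaIG.param_values())
        assert np.max(np.abs(res)) < 1e-10

    def test_glucose_baseline_independent_of_si_and_p(self, betaIG):
        """The beta-cell rate balance pins G* regardless of si and p."""
        ref = st.find_steady_state(betaIG)
        for si in (5e-5, 5e-3):
            for p in (0.003, 0.3):
                ss = st.find_steady_state(betaIG, {"si": si, "p": p})
                assert ss[0] == pytest.approx(ref[0], rel=1e-8)

    def test_insulin_scales_inversely_with_si(self, betaIG):
        ss1 = st.find_steady_state(betaIG, {"si": 5e-4})
        ss2 = st.find_steady_state(betaIG, {"si": 5e-5})
        assert ss2[1] / ss1[1] == pytest.approx(10.0, rel=1e-6)


class TestSignals:
    def test_meal_train_counts(self):
        sig = st.meal_pulse_input(n_pulses=3, spacing=360.0)
        assert sig.n_pulses == 3
        assert sig(0.0) == 0.0

    def test_zero_pulses(self):
        sig = st.meal_pulse_input(n_pulses=0)
        t = np.linspace(0, 1000, 100)
        assert np.all(sig(t) == 0.0)

    @pytest.mark.parametrize("shape", ["square", "smooth"])
    def test_pulse_quadrature(self, shape):
        from scipy.integrate import quad

        p = Pulse(onset=10.0, amplitude=0.7, width=25.0, shape=shape)
        area, _ = quad(p, 9.0, 40.0, limit=200)
        assert area == pytest.approx(0.7 * 25.0, rel=1e-6)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            InputSignal([Pulse(10, 1, 30), Pulse(20, 1, 30)])

    def test_onset_at_zero_rejected(self):
        with pytest.raises(ValueError, match="onset"):
            Pulse(0.0, 1.0, 10.0)


class TestSimulate:
    def test_equilibrium_preserved(self, betaIG, betaIG_steady):
        traj = st.simulate(
            betaIG, x0=betaIG_steady, t_span=(0.0, 5000.0)
        )
        rel = np.abs(traj.states - betaIG_steady) / betaIG_steady
        assert float(rel.max()) < 1e-8

    def test_state_continuous_at_switch(self, betaIG, betaIG_steady):
        traj = st.simulate(
            betaIG,
            x0=betaIG_steady,
            t_span=(0.0, 2000.0),
            t_eval=np.linspace(0, 2000, 4001),
            switches=[(1000.0, {"si": 0.00025})],
        )
        i = int(np.searchsorted(traj.t, 1000.0))
        jump = np.abs(traj.states[i] - traj.states[i - 1]) / betaIG_steady
        assert float(jump.max()) < 1e-2  # continuous state, only f changes
        # and the glucose level departs from baseline afterwards
        assert traj.state("G")[-1] > betaIG_steady[0] * 1.05

    def test_decreasing_span_rejected(self, betaIG):
        with pytest.raises(SimulationError):
            st.simulate(betaIG, x0=[5, 10, 300], t_span=(10.0, 0.0))

    def test_positivity_violation_detected(self):
        m = st.define_model(
            {
                "states": ["x"],
                "dynamics": {"x": "-1"},
                "constraints": ["x > 0"],
            }
        )
        with pytest.raises(SimulationError, match="positivity"):
            st.simulate(m, x0=[0.5], t_span=(0.0, 2.0))

    def test_trajectory_export(self, betaIG, betaIG_steady):
        traj = st.simulate(betaIG, x0=betaIG_steady, t_span=(0.0, 10.0),
                           t_eval=np.linspace(0, 10, 11))
        df = traj.to_dataframe()
        assert list(df.columns)[:4] == ["t", "G", "I", "beta"]
        assert len(df) == 11


class TestExactAdaptation:
    def test_identity_switch_is_trivially_adapted(self, betaIG):
        res = st.check_exact_adaptation(
            betaIG, "G", "si", 5e-4, 5e-4, horizon=1e4
        )
        assert res.adapted
        assert res.output_rel_deviation < 1e-9

    def test_glucose_adapts_insulin_doubles(self, betaIG):
        res = st.check_exact_adaptation(betaIG, "G", "si", 5e-4, 2.5e-4)
        assert res.adapted and res.settled
        assert res.output_rel_deviation < 1e-3
        assert res.state_ratios["I"] == pytest.approx(2.0, rel=1e-2)
        assert res.state_ratios["beta"] == pytest.approx(2.0, rel=1e-2)

    def test_insulin_output_does_not_adapt(self, betaIG):
        res = st.check_exact_adaptation(betaIG, "I", "si", 5e-4, 2.5e-4)
        assert not res.adapted
        assert res.output_rel_deviation == pytest.approx(1.0, rel=0.05)


class TestDCInvariance:
    def test_requires_two_distinct_signals(self, hormone):
        sig = st.meal_pulse_input(n_pulses=2, spacing=5.0, width=1.0)
        with pytest.raises(ValueError):
            st.check_dc_invariance(hormone, "x", "s", 1.0, 0.5, [sig])

    @pytest.fixture()
    def hormone_signals(self):
        return [
            st.meal_pulse_input(n_pulses=2, spacing=20.0, amplitude=0.4,
                                width=4.0, first_onset=5.0),
            st.meal_pulse_input(n_pulses=3, spacing=15.0, amplitude=0.8,
                                width=3.0, first_onset=5.0),
        ]

    def test_hormone_circuit_has_dc_in_both_gains(self, hormone, hormone_signals):
        for param in ("s", "p"):
            v = st.check_dc_invariance(
                hormone, "x", param, 1.0, 0.5, hormone_signals,
                t_span=(0.0, 80.0),
                adaptation_kwargs={"horizon": 2000.0},
            )
            assert v.has_dc, (param, v.max_rel_deviation)

    def test_verdict_symmetric_in_k1_k2(self, hormone, hormone_signals):
        kw = dict(
            input_signals=hormone_signals,
            t_span=(0.0, 80.0),
            adaptation_kwargs={"horizon": 2000.0},
        )
        a = st.check_dc_invariance(hormone, "x", "s", 1.0, 0.5, **kw)
        b = st.check_dc_invariance(hormone, "x", "s", 0.5, 1.0, **kw)
        assert a.has_dc == b.has_dc
        assert a.max_rel_deviation == pytest.approx(
            b.max_rel_deviation, rel=1e-3
        )

    def test_hormone_y_output_has_no_dc(self, hormone, hormone_signals):
        v = st.check_dc_invariance(
            hormone, "y", "s", 1.0, 0.5, hormone_signals,
            t_span=(0.0, 80.0),
            adaptation_kwargs={"horizon": 2000.0},
        )
        assert not v.has_dc


class TestScalingSymmetry:
    def test_identity_scaling(self, betaIG):
        rep = st.scaling_symmetry_experiment(
            betaIG, k=1.0, mode="param_state", switch_time=None,
            t_span=(0.0, 1000.0), n_grid=501,
        )
        assert max(rep.max_rel_deviation.values()) < 1e-9

    def test_param_param_preserves_G_and_beta_only(self, betaIG):
        rep = st.scaling_symmetry_experiment(
            betaIG, k=2.0, mode="param_param", switch_time=None,
            t_span=(0.0, 1440.0), n_grid=721,
        )
        assert rep.max_rel_deviation["G"] < 1e-6
        assert rep.max_rel_deviation["beta"] < 1e-6
        assert rep.max_rel_deviation["I"] > 0.1
        assert rep.max_scaled_deviation["I"] < 1e-6

    def test_invalid_k_rejected(self, betaIG):
        with pytest.raises(ValueError):
            st.scaling_symmetry_experiment(betaIG, k=-1.0)

    @settings(max_examples=6, deadline=None, derandomize=True)
    @given(
        k=hyp.floats(0.3, 4.0),
        n_pulses=hyp.integers(0, 3),
        amplitude=hyp.floats(0.1, 1.0),
    )
    def test_glucose_invariance_is_exact_for_any_k_and_schedule(
        self, k, n_pulses, amplitude
    ):
        """The compensation symmetry holds for every k and input schedule."""
        betaIG = st.load_circuit("betaIG")
        sig = st.meal_pulse_input(
            n_pulses=n_pulses, spacing=300.0, amplitude=amplitude, width=30.0
        )
        rep = st.scaling_symmetry_experiment(
            betaIG, k=k, mode="param_state", input_signal=sig,
            switch_time=1000.0, t_span=(0.0, 2000.0), n_grid=401,
        )
        assert rep.max_rel_deviation["G"] < 1e-6

    def test_verdict_robust_to_tighter_tolerance(self, betaIG):
        """Halving integration tolerances does not change the outcome."""
        kw = dict(
            k=3.0, mode="param_state", switch_time=500.0,
            t_span=(0.0, 1000.0), n_grid=501,
        )
        a = st.scaling_symmetry_experiment(betaIG, rtol=1e-10, atol=1e-12, **kw)
        b = st.scaling_symmetry_experiment(betaIG, rtol=5e-11, atol=5e-13, **kw)
        assert (a.max_rel_deviation["G"] < 1e-6) == (
            b.max_rel_deviation["G"] < 1e-6
        )
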