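"""Fermentation simulator: kinetics, sensor maps, faults, determinism."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fermaug.core import CHANNELS, channel_index
from fermaug.simulate import (
    FaultSpec,
    SimulatorParams,
    default_fault_plan,
    inject_fault,
    kinetic_rhs,
    simulate_experiment,
    simulate_study,
)


class TestKineticRHS:
    @pytest.mark.parametrize(
        "state",
        [
            (0.0, 100.0, 20.0),   # no biomass -> no reaction
            (5.0, 0.0, 20.0),     # substrate exhausted
        ],
    )
    def test_degenerate_states_give_zero_rates(self, state):
        params = SimulatorParams(maintenance=0.0)
        assert kinetic_rhs(state, 0.0, params) == (0.0, 0.0, 0.0)

    def test_full_product_inhibition_stops_everything(self):
        params = SimulatorParams(maintenance=0.0)
        rates = kinetic_rhs((5.0, 100.0, params.P_max), 0.0, params)
        assert rates == (0.0, 0.0, 0.0)

    def test_negative_state_rejected(self):
        with pytest.raises(ValueError, match="negative state"):
            kinetic_rhs((-1.0, 100.0, 0.0), 0.0, SimulatorParams())

    def test_stoichiometry_links_rates(self):
        params = SimulatorParams()
        dX, dS, dP = kinetic_rhs((8.0, 200.0, 30.0), 0.0, params)
        assert dX > 0 and dS < 0 and dP > 0
        assert dP == pytest.approx(-params.Y_ps * dS, rel=1e-12)


class TestSimulateExperiment:
    def test_default_run_matches_study_conditions(self, noise_free_params):
        series = simulate_experiment(noise_free_params, seed=0)
        ethanol = series.channel("ethanol")
        temp = series.channel("temperature")
        assert abs(ethanol[-1] - 108.0) <= 5.0
        assert temp[-1] == 28.0

    def test_noise_free_monotonicity_and_cascade(self, noise_free_params):
        series = simulate_experiment(noise_free_params, seed=3)
        assert np.all(np.diff(series.channel("ethanol")) >= 0)
        assert np.all(np.diff(series.channel("substrate")) <= 0)
        temp = series.channel("temperature")
        assert set(np.unique(temp)) <= set(noise_free_params.cascade_levels)
        assert np.all(np.diff(temp) <= 0)

    def test_no_inoculum_means_no_reaction(self, noise_free_params):
        params = SimulatorParams(**{**noise_free_params.__dict__, "X0": 0.0})
        params.noise_sd = {k: 0.0 for k in params.noise_sd}
        series = simulate_experiment(params, seed=0)
        assert np.all(series.channel("ethanol") == 0.0)
        assert np.all(series.channel("substrate") == params.S0)

    def test_substrate_ethanol_conservation_without_maintenance(self, noise_free_params):
        params = SimulatorParams(**{**noise_free_params.__dict__, "maintenance": 0.0})
        params.noise_sd = {k: 0.0 for k in params.noise_sd}
        series = simulate_experiment(params, seed=5)
        S = series.channel("substrate")
        P = series.channel("ethanol")
        residual = params.Y_ps * (params.S0 - S) - P
        assert np.max(np.abs(residual)) <= 1e-6 * params.S0

    def test_monod_growth_matches_independent_integrator(self):
        # disable inhibition and maintenance: pure Monod growth; compare the
        # fixed-step integrator against an adaptive high-accuracy solver
        params = SimulatorParams(P_max=1e12, maintenance=0.0, S0=400.0)
        params.noise_sd = {k: 0.0 for k in params.noise_sd}
        params.between_experiment_cv = 0.0
        series = simulate_experiment(params, seed=0)

        def rhs(t, y):
            X, S, P = y
            dX = params.mu_max * S / (params.K_s + S) * X if S > 0 else 0.0
            dS = -dX / params.Y_xs if S > 0 else 0.0
            return [dX, dS, -params.Y_ps * dS]

        ref = solve_ivp(rhs, (0, params.duration_h), [params.X0, params.S0, 0.0],
                        t_eval=series.time, rtol=1e-10, atol=1e-10)
        np.testing.assert_allclose(series.channel("cells"), ref.y[0], rtol=1e-2)

    def test_deterministic_for_fixed_seed(self, default_params):
        a = simulate_experiment(default_params, seed=9)
        b = simulate_experiment(default_params, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_aeration_window_flagged(self, noise_free_params):
        series = simulate_experiment(noise_free_params, seed=0)
        start = series.meta["aeration_start_h"]
        assert start is not None
        # air goes on roughly over the last 3.5 h of the cycle
        assert noise_free_params.duration_h - start == pytest.approx(3.5, abs=1.0)


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_points": 1},
            {"duration_h": 0.0},
            {"mu_max": -0.1},
            {"cascade_levels": (34.0, 31.0, 28.0)},
            {"cascade_thresholds": (40.0, 30.0, 95.0)},
            {"cascade_thresholds": (40.0, 70.0)},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulatorParams(**kwargs)


class TestFaults:
    def test_missing_channel_masks_only_that_channel(self, small_study):
        fault = FaultSpec("missing_channel", "redox", experiment_index=0)
        out = inject_fault(small_study[0], fault)
        assert np.isnan(out.channel("redox")).all()
        for name in CHANNELS:
            if name != "redox":
                np.testing.assert_array_equal(out.channel(name),
                                              small_study[0].channel(name))

    def test_offset_roundtrip_restores_values(self, small_study):
        plus = FaultSpec("offset_channel", "capacitance", 0, offset=3.7)
        minus = FaultSpec("offset_channel", "capacitance", 0, offset=-3.7)
        out = inject_fault(inject_fault(small_study[0], plus), minus)
        np.testing.assert_allclose(out.channel("capacitance"),
                                   small_study[0].channel("capacitance"), atol=1e-12)

    def test_offset_shifts_channel_mean_exactly(self, small_study):
        delta = 4.25
        fault = FaultSpec("offset_channel", "capacitance", 0, offset=delta)
        out = inject_fault(small_study[0], fault)
        shift = out.channel("capacitance").mean() - small_study[0].channel("capacitance").mean()
        assert shift == pytest.approx(delta, abs=1e-10)

    def test_invalid_fault_specs_rejected(self):
        with pytest.raises(ValueError, match="unknown fault kind"):
            FaultSpec("drop_channel", "redox", 0)
        with pytest.raises(ValueError, match="probe channels"):
            FaultSpec("missing_channel", "ethanol", 0)
        with pytest.raises(ValueError):
            FaultSpec("offset_channel", "capacitance", 0, offset=np.inf)


class TestSimulateStudy:
    def test_default_plan_places_the_two_sensor_problems(self, study11):
        missing_redox = [np.isnan(s.channel("redox")).all() for s in study11]
        assert sum(missing_redox) == 1
        offset = [any(f["kind"] == "offset_channel" for f in s.meta["faults"])
                  for s in study11]
        assert sum(offset) == 1
        assert missing_redox.index(True) != offset.index(True)
        assert len(study11) == 11
        assert all(s.provenance == "original" for s in study11)

    def test_empty_plan_gives_fault_free_series(self, default_params):
        study = simulate_study(default_params, 2, fault_plan=[], seed=0)
        assert len(study) == 2
        assert not any(np.isnan(s.values).any() for s in study)

    def test_same_seed_is_bit_identical(self, default_params):
        a = simulate_study(default_params, 3, fault_plan=[], seed=5)
        b = simulate_study(default_params, 3, fault_plan=[], seed=5)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.values, sb.values)

    def test_adding_experiments_preserves_earlier_ones(self, default_params):
        a = simulate_study(default_params, 3, fault_plan=[], seed=5)
        b = simulate_study(default_params, 5, fault_plan=[], seed=5)
        for sa, sb in zip(a, b[:3]):
            np.testing.assert_array_equal(sa.values, sb.values)

    def test_fault_index_out_of_range_rejected(self, default_params):
        plan = [FaultSpec("missing_channel", "redox", experiment_index=7)]
        with pytest.raises(IndexError):
            simulate_study(default_params, 3, fault_plan=plan, seed=0)

    def test_between_experiment_cv_propagates_to_final_ethanol(self, default_params):
        study = simulate_study(default_params, 20, fault_plan=[], seed=10)
        finals = np.array([s.channel("ethanol")[-1] for s in study])
        cv = finals.std(ddof=1) / finals.mean()
        target = default_params.between_experiment_cv
        assert target / 3 <= cv <= target * 3

    def test_default_fault_plan_uses_distinct_indices(self):
        plan = default_fault_plan(11)
        assert len({f.experiment_index for f in plan}) == 2
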