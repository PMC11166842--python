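"""Dosing schedules, time-course integration and observed-scale mapping."""

import numpy as np
import pytest

from cb1lag import (
    DoseEvent,
    DoseSchedule,
    co_addition_schedule,
    model_lag,
    observe_trace,
    preincubation_schedule,
    simulate_timecourse,
    species_fractions,
)


class TestScheduleValidation:
    def test_events_must_be_sorted(self):
        with pytest.raises(ValueError, match="sorted"):
            DoseSchedule(
                (DoseEvent(5.0, "B", 0.1), DoseEvent(0.0, "A", 1.0)), horizon=20.0
            )

    def test_horizon_covers_events(self):
        with pytest.raises(ValueError, match="horizon"):
            DoseSchedule((DoseEvent(25.0, "B", 0.1),), horizon=20.0)

    def test_unknown_ligand_and_negative_conc(self):
        with pytest.raises(ValueError):
            DoseEvent(0.0, "X", 1.0)
        with pytest.raises(ValueError):
            DoseEvent(0.0, "A", -1.0)

    def test_t_B_reads_first_modulator_event(self):
        sch = preincubation_schedule(1.0, 0.1, delay=15.0)
        assert sch.t_B == 15.0
        assert co_addition_schedule(1.0, 0.0).t_B is None


class TestSimulateTimecourse:
    def test_forskolin_only_rises_to_plateau_below_receptor_free(self, ref_params):
        """Constitutive receptor inhibits: the forskolin plateau sits below
        the receptor-free steady state of 1."""
        traj = simulate_timecourse(ref_params, co_addition_schedule(0.0, 0.0, horizon=20.0))
        post = traj.times >= 0.0
        C = traj.C[post]
        assert np.all(np.diff(C) >= -1e-12)
        assert C[-1] < 1.0
        # half-suppressed production: heading towards ~Imax/2 territory
        assert C[-1] < ref_params.system.k_in / ref_params.system.k_out

    def test_agonist_alone_occupancy_at_15_min(self, ref_params):
        """1 uM agonist with printed pKd/k_int leaves AR near 10% of R0 at
        15 min, crossing below 10% just after 15 min."""
        traj = simulate_timecourse(ref_params, co_addition_schedule(1.0, 0.0, horizon=20.0))
        ar15 = np.interp(15.0, traj.times, traj.species["AR"])
        assert ar15 == pytest.approx(0.105, abs=0.01)
        crossed = traj.times[(traj.times > 1.0) & (traj.species["AR"] < 0.10)]
        assert crossed[0] == pytest.approx(15.4, abs=0.5)
        assert crossed[0] >= 15.0

    def test_initial_condition_and_pre_read(self, ref_params):
        traj = simulate_timecourse(ref_params, co_addition_schedule(1.0, 0.1))
        assert traj.times[0] == pytest.approx(-5.0)
        i0 = np.searchsorted(traj.times, 0.0)
        pre = slice(0, i0)
        assert np.allclose(traj.species["AR"][pre], 0.0)
        assert np.allclose(traj.C[pre], 0.0)
        assert traj.species["R"][0] == pytest.approx(1.0)

    def test_grid_refinement_stability(self, ref_params):
        sch = co_addition_schedule(1.0, 0.3, horizon=20.0)
        coarse = simulate_timecourse(ref_params, sch, grid_step=0.2)
        fine = simulate_timecourse(ref_params, sch, grid_step=0.1)
        on_coarse = np.interp(coarse.times, fine.times, fine.C)
        scale = max(np.max(np.abs(coarse.C)), 1e-3)
        assert np.max(np.abs(coarse.C - on_coarse)) / scale < 1e-3

    def test_conservation_along_trajectory(self, ref_params):
        for model in ("reduced", "full"):
            traj = simulate_timecourse(
                ref_params, co_addition_schedule(1.0, 0.3, horizon=20.0), model=model
            )
            total = sum(
                traj.species[s] for s in ("R", "AR", "ARB_T", "ARB", "RB", "R_lost")
            )
            assert np.max(np.abs(total - 1.0)) < 1e-6

    def test_non_negativity(self, ref_params):
        for b in (0.0, 0.1, 1.0, 10.0):
            traj = simulate_timecourse(ref_params, co_addition_schedule(1.0, b, horizon=20.0))
            for name, series in traj.species.items():
                assert series.min() >= -1e-9, name


class TestSpeciesFractions:
    def test_initial_composition(self, ref_params):
        traj = simulate_timecourse(ref_params, co_addition_schedule(1.0, 0.3))
        frac = species_fractions(traj)
        first = frac.iloc[0]
        assert first["R"] == pytest.approx(1.0)
        assert first[["AR", "ARB_T", "ARB", "RB", "R_lost"]].abs().max() < 1e-12

    def test_agonist_alone_has_two_species(self, ref_params):
        traj = simulate_timecourse(ref_params, co_addition_schedule(1.0, 0.0, horizon=10.0))
        frac = species_fractions(traj)
        assert np.allclose(frac[["ARB_T", "ARB", "RB"]].to_numpy(), 0.0, atol=1e-12)
        post = frac[frac["time_min"] > 0.5]
        assert (post["R"] > 0).all() and (post["AR"] > 0).all()

    def test_ternary_species_appear_with_modulator(self, ref_params):
        traj = simulate_timecourse(ref_params, co_addition_schedule(1.0, 0.3, horizon=20.0))
        late = species_fractions(traj).iloc[-1]
        assert late["ARB_T"] > 0 and late["ARB"] > 0 and late["RB"] > 0


class TestObserveTrace:
    def test_identity_mapping(self, ref_params):
        traj = simulate_timecourse(ref_params, co_addition_schedule(0.0, 0.0, horizon=10.0))
        trace = observe_trace(traj)
        assert np.allclose(trace.values, traj.C)

    def test_affine_mapping(self, ref_params):
        traj = simulate_timecourse(ref_params, co_addition_schedule(0.0, 0.0, horizon=10.0))
        trace = observe_trace(traj, baseline=0.2, fsk_efficacy=0.5)
        assert np.allclose(trace.values, 0.2 + 0.5 * traj.C)

    def test_baseline_shift_is_constant_offset(self, ref_params):
        traj = simulate_timecourse(ref_params, co_addition_schedule(1.0, 0.1, horizon=10.0))
        a = observe_trace(traj, baseline=0.0)
        b = observe_trace(traj, baseline=0.3)
        assert np.allclose(b.values - a.values, 0.3)

    def test_nonpositive_efficacy_rejected(self, ref_params):
        traj = simulate_timecourse(ref_params, co_addition_schedule(0.0, 0.0, horizon=5.0))
        with pytest.raises(ValueError):
            observe_trace(traj, fsk_efficacy=0.0)


class TestScheduleEffects:
    @pytest.mark.parametrize("org", [0.1, 0.316, 1.0])
    def test_preincubation_shortens_lag(self, ref_params, org):
        """Letting the agonist internalise receptor for 15 min before the
        modulator arrives shortens the disinhibition lag."""
        co = co_addition_schedule(1.0, org, horizon=35.0)
        pre = preincubation_schedule(1.0, org, delay=15.0, horizon=35.0)
        lag_co = model_lag(
            observe_trace(simulate_timecourse(ref_params, co)),
            observe_trace(simulate_timecourse(ref_params, co.without(["B"]))),
        )
        lag_pre = model_lag(
            observe_trace(simulate_timecourse(ref_params, pre)),
            observe_trace(simulate_timecourse(ref_params, pre.without(["B"]))),
            t_B=15.0,
        )
        assert lag_pre.separated and lag_co.separated
        assert lag_pre.T_d < lag_co.T_d

    def test_lag_non_increasing_in_modulator_concentration(self, ref_params):
        lags = []
        ref = observe_trace(
            simulate_timecourse(ref_params, co_addition_schedule(1.0, 0.0, horizon=30.0))
        )
        for org in (0.1, 0.316, 1.0, 10.0):
            tr = observe_trace(
                simulate_timecourse(ref_params, co_addition_schedule(1.0, org, horizon=30.0))
            )
            lags.append(model_lag(tr, ref).T_d)
        assert all(b <= a + 1e-9 for a, b in zip(lags, lags[1:]))

    def test_high_modulator_shows_inverse_agonism(self, ref_params):
        """At 10 uM modulator the late-time response exceeds forskolin alone
        (blockade of constitutive activity)."""
        org = observe_trace(
            simulate_timecourse(ref_params, co_addition_schedule(1.0, 10.0, horizon=20.0))
        )
        fsk = observe_trace(
            simulate_timecourse(ref_params, co_addition_schedule(0.0, 0.0, horizon=20.0))
        )
        tail = org.times > 15.0
        assert np.all(org.values[tail] > fsk.values[tail])
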