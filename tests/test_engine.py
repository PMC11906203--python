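"""Engine: mass balance, equilibrium, oracle equivalence, mechanics."""

import numpy as np
import pytest

from breathsim.circuit import (
    CompliantLung,
    LinearElement,
    SeriesAirway,
    StorageCompartment,
    polyfill_preset,
)
from breathsim.engine import (
    BreathingPattern,
    MetabolicSource,
    SimConfig,
    SimulationError,
    breath_recurrence_steady_state,
    detect_equilibrium,
    run_simulation,
    simulate_pressure_driven,
    summarize,
)
from breathsim.gas import AMBIENT_AIR

VT = 35.0
Q_PER_BREATH = 0.044 * VT  # default CO2 bolus per breath, mL


class TestDetectEquilibrium:
    def test_constant_trace_converges_immediately(self):
        assert detect_equilibrium(np.full(3, 0.04), tol=1e-4, consecutive=1) == 2

    def test_constant_trace_default_window(self):
        assert detect_equilibrium(np.full(10, 0.04), tol=1e-4) == 6

    def test_growing_trace_not_converged(self):
        trace = 0.01 + 0.001 * np.arange(50)
        assert detect_equilibrium(trace, tol=1e-4) == -1

    def test_too_short(self):
        with pytest.raises(ValueError, match="2 breaths"):
            detect_equilibrium(np.array([0.04]), tol=1e-4)

    def test_default_run_converges_quickly(self):
        res = run_simulation(SimConfig())
        eq = detect_equilibrium(res.breath_end_f_co2, 1e-4)
        assert 0 < eq <= 200


class TestMassBalance:
    def test_zero_resistance_zero_pressure(self):
        cfg = SimConfig(airway=SeriesAirway((LinearElement(0.0),)))
        res = run_simulation(cfg)
        assert np.all(res.pressure == 0.0)

    def test_fresh_air_exhaled_co2(self):
        """No storage: mean exhaled CO2 = ambient + injection per breath / V_T."""
        res = run_simulation(SimConfig())
        mean_exhaled = res.breath_exhaled_co2[-1] / VT
        assert mean_exhaled == pytest.approx(0.0004 + Q_PER_BREATH / VT, abs=2e-6)

    def test_volume_stays_in_bounds_and_flow_consistent(self):
        res = run_simulation(SimConfig())
        assert res.volume.min() >= 30.0 - 1e-9
        assert res.volume.max() <= 65.0 + 1e-9
        dt = res.t[1] - res.t[0]
        q_num = np.gradient(res.volume, dt)
        # prescribed analytic flow vs numerical dV/dt
        assert np.allclose(q_num[2:-2], res.flow[2:-2], atol=0.02 * np.abs(res.flow).max())

    def test_steady_state_co2_conservation(self):
        """Injected CO2 equals net CO2 vented to ambient within 0.5%."""
        cfg = SimConfig(storage=polyfill_preset(4), post_equilibrium_breaths=50)
        res = run_simulation(cfg)
        assert summarize(res).converged
        inj = res.breath_injected_co2[-50:].sum()
        ven = res.breath_net_vented_co2[-50:].sum()
        assert ven == pytest.approx(inj, rel=5e-3)

    def test_o2_moves_opposite_to_co2(self):
        """More storage -> higher equilibrium CO2 and lower O2."""
        runs = [
            run_simulation(SimConfig(storage=polyfill_preset(n))) for n in (0, 2, 8)
        ]
        co2 = [r.breath_end_f_co2[-1] for r in runs]
        o2 = [r.breath_end_f_o2[-1] for r in runs]
        assert co2[0] < co2[1] < co2[2]
        assert o2[0] > o2[1] > o2[2]

    def test_unbounded_rebreathing_flagged(self):
        """beta = 1, a = 1, storage >= V_T: no CO2 export, no equilibrium."""
        storage = StorageCompartment(
            storage_volume=50.0, entrainment_fraction=1.0, washout_retention=1.0
        )
        res = run_simulation(SimConfig(storage=storage, max_breaths=50))
        summary = summarize(res)
        assert not summary.converged
        assert np.all(np.diff(res.breath_end_f_co2) > 0)

    def test_invalid_state_names_step(self):
        # absurd injection rate drives the CO2 fraction past 1 mid-run
        src = MetabolicSource(co2_injection=1e5, o2_uptake=0.0)
        with pytest.raises(SimulationError, match="breath"):
            run_simulation(SimConfig(source=src, max_breaths=10))


class TestRecurrenceOracle:
    def test_fresh_air_limit_exact(self):
        lung_f, storage_f = breath_recurrence_steady_state(None)
        assert lung_f == pytest.approx(0.0004 + Q_PER_BREATH / VT, rel=1e-14)
        assert storage_f == AMBIENT_AIR.f_co2

    def test_beta_one_a_one_unbounded(self):
        storage = StorageCompartment(
            storage_volume=50.0, entrainment_fraction=1.0, washout_retention=1.0
        )
        with pytest.raises(SimulationError, match="without bound"):
            breath_recurrence_steady_state(storage)

    def test_fixed_point_matches_iterated_map(self):
        """Linear-solve fixed point vs brute-force iteration of the map."""
        storage = StorageCompartment(
            storage_volume=50.0, entrainment_fraction=0.5, washout_retention=0.5
        )
        lung_f, storage_f = breath_recurrence_steady_state(storage)

        # independent iteration of the same per-breath stages
        v_min, v_max, vs, beta, a = 30.0, 65.0, 50.0, 0.5, 0.5
        c_a, q = 0.0004, Q_PER_BREATH
        b = min(beta * VT, vs)
        L = S = c_a
        for _ in range(2000):
            L = (v_min * L + b * S + (VT - b) * c_a) / v_max + q / v_max
            s_refill = ((vs - b) * S + b * L) / vs
            e = np.exp(-(VT - b) / vs)
            S = a * (L + (s_refill - L) * e) + (1 - a) * c_a
        assert lung_f == pytest.approx(L, rel=1e-10)
        assert storage_f == pytest.approx(S, rel=1e-10)

    @pytest.mark.parametrize("layers", [1, 2, 4, 8])
    def test_engine_matches_recurrence(self, layers):
        """Engine equilibrium CO2 vs analytic fixed point, <= 0.05 vol%."""
        storage = polyfill_preset(layers)
        cfg = SimConfig(storage=storage, injection_mode="per_breath")
        res = run_simulation(cfg)
        lung_f, _ = breath_recurrence_steady_state(storage)
        assert abs(100 * res.breath_end_f_co2[-1] - 100 * lung_f) <= 0.05

    def test_engine_matches_recurrence_no_storage(self):
        res = run_simulation(SimConfig(injection_mode="per_breath"))
        lung_f, _ = breath_recurrence_steady_state(None)
        assert abs(100 * res.breath_end_f_co2[-1] - 100 * lung_f) <= 0.05


class TestMechanics:
    def test_dissociation_resistance_vs_co2(self):
        """Resistance changes work, not equilibrium CO2 (no storage)."""
        open_run = summarize(run_simulation(SimConfig()))
        narrow = summarize(
            run_simulation(SimConfig(airway=SeriesAirway.tube_with_orifice(1.07)))
        )
        assert abs(open_run.co2_volpct - narrow.co2_volpct) <= 0.1
        assert narrow.wob_j_per_min > 10 * open_run.wob_j_per_min

    def test_peak_negative_pressure_orders_with_diameter(self):
        peaks = [
            summarize(
                run_simulation(SimConfig(airway=SeriesAirway.tube_with_orifice(d)))
            ).peak_negative_pressure_mbar
            for d in (4.03, 2.64, 1.07)
        ]
        assert peaks[0] < peaks[1] < peaks[2]

    def test_open_tube_wob_matches_linear_formula(self):
        """Engine WOB for the laminar tube vs pi R omega V_T^2 / 8."""
        from breathsim.circuit import tube_resistance

        summary = summarize(run_simulation(SimConfig()))
        r = tube_resistance(300.0, 5.0)
        omega = 2 * np.pi * 44 / 60
        expected = np.pi * r * omega * VT**2 / 8 * 1e-4
        assert summary.work_per_breath_j == pytest.approx(expected, rel=0.01)

    def test_tidal_volume_mismatch_rejected(self):
        with pytest.raises(ValueError, match="tidal volume mismatch"):
            SimConfig(pattern=BreathingPattern(tidal_volume=30.0))

    def test_pressure_driven_mode_follows_compliance(self):
        """Slow sinusoidal drive: volume amplitude ~ compliance x pressure."""
        cfg = SimConfig(lung=CompliantLung(compliance=0.7))
        amp = 10.0  # mbar
        omega = cfg.pattern.omega

        res = simulate_pressure_driven(lambda t: amp * np.sin(omega * t), cfg, n_breaths=4)
        # resistive drop across the open tube is small, so V tracks -C p_drive
        last = slice(-cfg.steps_per_breath, None)
        v_amp = 0.5 * (res.volume[last].max() - res.volume[last].min())
        assert v_amp == pytest.approx(0.7 * amp, rel=0.05)
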