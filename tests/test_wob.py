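"""Work-of-breathing: loop areas vs closed forms, segmentation, scaling."""

import math

import numpy as np
import pytest

from breathsim.engine import SimConfig, run_simulation
from breathsim.fixtures import FixtureSpec, generate_fixture
from breathsim.wob import (
    MBAR_ML_TO_J,
    PVRecord,
    SegmentationError,
    analyze_record,
    segment_breaths,
    work_negative_side,
    work_per_minute,
    work_positive_side,
)


def mean_cycle_work(rec):
    return float(np.mean([c.work_j for c in analyze_record(rec)]))


class TestClosedFormAgreement:
    @pytest.mark.parametrize(
        "kind, amplitude",
        [("ellipse", 10.0), ("linear_resistance", 0.01), ("orifice", 0.02)],
    )
    def test_trapezoid_matches_closed_form(self, kind, amplitude):
        """Loop area vs the analytic half-ellipse / resistive-work integrals."""
        rec, expected = generate_fixture(
            FixtureSpec(kind=kind, amplitude=amplitude, samples_per_cycle=400)
        )
        assert mean_cycle_work(rec) == pytest.approx(expected, rel=0.01)

    def test_ellipse_expected_value(self):
        # half-ellipse: (pi * 10 mbar * 17.5 mL / 2) * 1e-4 J
        _, expected = generate_fixture(FixtureSpec(kind="ellipse", amplitude=10.0))
        assert expected == pytest.approx(math.pi * 10.0 * 17.5 / 2.0 * 1e-4, rel=1e-12)

    def test_linear_resistance_expected_value(self):
        # W = pi R omega V_T^2 / 8 * 1e-4 at R = 0.01, V_T = 35, 44/min
        _, expected = generate_fixture(
            FixtureSpec(kind="linear_resistance", amplitude=0.01)
        )
        omega = 2 * math.pi * 44 / 60
        assert expected == pytest.approx(math.pi * 0.01 * omega * 35**2 / 8 * 1e-4, rel=1e-12)
        assert expected == pytest.approx(2.2165e-3, rel=1e-4)

    def test_flat_pressure_zero_work(self):
        rec, expected = generate_fixture(FixtureSpec(kind="flat"))
        assert expected == 0.0
        assert mean_cycle_work(rec) == 0.0

    def test_trapezoid_convergence(self):
        """Quadrupling sampling density moves the area by < 0.1%."""
        spec_lo = FixtureSpec(kind="linear_resistance", amplitude=0.01, samples_per_cycle=200)
        spec_hi = FixtureSpec(kind="linear_resistance", amplitude=0.01, samples_per_cycle=800)
        w_lo = mean_cycle_work(generate_fixture(spec_lo)[0])
        w_hi = mean_cycle_work(generate_fixture(spec_hi)[0])
        assert abs(w_lo - w_hi) / w_hi < 1e-3

    def test_resampling_invariance(self):
        """The same loop sampled on different uniform grids gives the same work."""
        w = {
            n: mean_cycle_work(
                generate_fixture(
                    FixtureSpec(kind="orifice", amplitude=0.02, samples_per_cycle=n)
                )[0]
            )
            for n in (250, 1000)
        }
        assert w[250] == pytest.approx(w[1000], rel=0.005)


class TestSegmentation:
    def test_ten_periods_give_nine_cycles(self):
        rec, _ = generate_fixture(FixtureSpec(kind="flat", n_cycles=10))
        assert len(segment_breaths(rec)) == 9

    def test_constant_volume_rejected(self):
        t = np.linspace(0, 10, 500)
        rec = PVRecord(t=t, p=np.sin(t), v=np.full_like(t, 47.5))
        with pytest.raises(SegmentationError, match="constant"):
            segment_breaths(rec)

    def test_single_period_rejected(self):
        rec, _ = generate_fixture(FixtureSpec(kind="flat", n_cycles=1))
        with pytest.raises(SegmentationError, match="minima"):
            segment_breaths(rec)

    def test_engine_round_trip_period(self):
        """Cycles segmented from an engine trace recover 60/44 s per breath."""
        cfg = SimConfig(max_breaths=20, equilibrium_tol=1e-12)  # run all 20
        res = run_simulation(cfg)
        rec = PVRecord(t=res.t, p=res.pressure, v=res.volume)
        cycles = segment_breaths(rec)
        dt = res.t[1] - res.t[0]
        period = 60.0 / 44.0
        for a, b in cycles:
            assert abs((res.t[b] - res.t[a]) - period) <= dt + 1e-12

    def test_trapezoid_waveform_segments(self):
        """Flat volume holds (plateau minima) still segment cleanly."""
        from breathsim.engine import BreathingPattern

        cfg = SimConfig(
            pattern=BreathingPattern(waveform="trapezoid"),
            max_breaths=10,
            equilibrium_tol=1e-12,
        )
        res = run_simulation(cfg)
        rec = PVRecord(t=res.t, p=res.pressure, v=res.volume)
        cycles = segment_breaths(rec)
        assert 7 <= len(cycles) <= 10


class TestWorkProperties:
    def test_work_nonnegative_and_positive_side_split(self):
        rec, _ = generate_fixture(FixtureSpec(kind="linear_resistance", amplitude=0.01))
        for cyc in segment_breaths(rec):
            assert work_negative_side(rec, cyc) >= 0.0
            # resistive loop: exhalation does equal work against positive pressure
            assert work_positive_side(rec, cyc) == pytest.approx(
                work_negative_side(rec, cyc), rel=0.02
            )

    def test_unit_conversion_constant(self):
        assert MBAR_ML_TO_J == 1e-4

    @pytest.mark.parametrize(
        "w, rate, expected",
        [(0.0, 44.0, 0.0), (2.2165e-3, 44.0, 9.7526e-2), (0.5, 0.0, 0.0)],
    )
    def test_work_per_minute(self, w, rate, expected):
        assert work_per_minute(w, rate) == pytest.approx(expected, rel=1e-4)

    def test_work_per_minute_rejects_negative(self):
        with pytest.raises(ValueError):
            work_per_minute(-1.0, 44.0)
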