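"""Breath-by-breath simulation of the mechanical breathing model.

The engine prescribes the lung-volume trajectory V(t) (the bench model
moves a fixed tidal volume at a fixed frequency regardless of resistance),
derives the flow Q = dV/dt, and computes the circuit pressure as
p = -ΔP_airway(Q): negative while inhaling, positive while exhaling.

Species transport per time step:

* inhalation — the inhaled stream is a beta-weighted blend of stored
  bedding gas and fresh ambient air (capped by the stored amount
  available); the lung is well-mixed;
* exhalation — lung gas leaves at lung composition; it first refills the
  storage compartment's freed space, then overflows through the full,
  well-mixed compartment, venting the mixed excess to ambient;
* metabolism — CO2 is metered into the lung and O2 removed, continuously
  by default (``injection_mode='continuous'``) or as a single per-breath
  bolus at end-inhalation (``'per_breath'``, the assumption under which
  the analytic recurrence below is exact);
* at each breath boundary the storage composition's excess over ambient
  is multiplied by the washout retention a.

Because the volume trajectory is prescribed, the pressure/flow mechanics
and the gas transport decouple: resistance changes affect work of
breathing but not equilibrium CO2, and storage changes affect CO2 but not
work — the dissociation between the two suffocation mechanisms that the
model exists to exhibit.

:func:`breath_recurrence_steady_state` reduces the same per-breath mass
balance to an affine 2-state map (lung composition, storage composition)
and solves for its fixed point in closed form; it serves as an
independent oracle for the time-stepping engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .circuit import CompliantLung, SeriesAirway, StorageCompartment
from .gas import AMBIENT_AIR, DRY_AIR_760, GasMixture, fraction_to_partial_pressure

__all__ = [
    "BreathingPattern",
    "MetabolicSource",
    "SimConfig",
    "SimResult",
    "EquilibriumSummary",
    "SimulationError",
    "run_simulation",
    "detect_equilibrium",
    "breath_recurrence_steady_state",
    "simulate_pressure_driven",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = ("t_s", "V_mL", "p_mbar", "Q_mL_s", "lung_fCO2", "lung_fO2", "storage_fCO2")

#: Exhaled-breath CO2 target used to calibrate the default metering rate.
EXHALED_CO2_TARGET = 0.044
DEFAULT_RQ = 0.8


class SimulationError(RuntimeError):
    """Raised when the numerics produce a physically invalid state."""


@dataclass(frozen=True)
class BreathingPattern:
    """Prescribed lung-volume driver.

    Defaults emulate a sleeping infant: 44 breaths/min, 35 mL tidal
    volume.  ``waveform`` is ``'sinusoid'`` (closed-form work integrals
    exist) or ``'trapezoid'`` (constant-flow ramps with end-of-stroke
    holds, ``rise_fraction`` of each half-period spent moving).
    """

    rate: float = 44.0  # breaths/min
    tidal_volume: float = 35.0  # mL
    waveform: str = "sinusoid"
    rise_fraction: float = 0.7  # trapezoid only: moving fraction of each half-stroke

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"breathing rate must be positive, got {self.rate!r}")
        if self.tidal_volume <= 0:
            raise ValueError(f"tidal volume must be positive, got {self.tidal_volume!r}")
        if self.waveform not in ("sinusoid", "trapezoid"):
            raise ValueError(
                f"waveform must be 'sinusoid' or 'trapezoid', got {self.waveform!r}"
            )
        if not 0.0 < self.rise_fraction <= 1.0:
            raise ValueError(
                f"rise_fraction must be in (0, 1], got {self.rise_fraction!r}"
            )

    @property
    def period(self) -> float:
        """Breath period, s."""
        return 60.0 / self.rate

    @property
    def omega(self) -> float:
        """Angular frequency, rad/s."""
        return 2.0 * math.pi / self.period

    def volume(self, t: np.ndarray, v_min: float) -> np.ndarray:
        """V(t) starting at end-expiration (V = v_min at t = 0)."""
        t = np.asarray(t, dtype=float)
        vt = self.tidal_volume
        if self.waveform == "sinusoid":
            return v_min + vt / 2.0 * (1.0 - np.cos(self.omega * t))
        # trapezoid: ramp up over rise_fraction of the first half-period,
        # hold at v_max, ramp down symmetrically, hold at v_min
        half = self.period / 2.0
        move = self.rise_fraction * half
        tau = np.mod(t, self.period)
        v = np.empty_like(tau)
        up = tau < half
        v[up] = v_min + vt * np.clip(tau[up] / move, 0.0, 1.0)
        v[~up] = v_min + vt * (1.0 - np.clip((tau[~up] - half) / move, 0.0, 1.0))
        return v


@dataclass(frozen=True)
class MetabolicSource:
    """CO2 injection into / O2 uptake from the lung gas, mL/min.

    The default injection rate is calibrated so that, breathing fresh air
    with no storage, the exhaled CO2 fraction equals the 4.4 vol%
    exhaled-breath benchmark: injection = 0.044 × V_T × rate
    (≈ 67.8 mL/min at the defaults).  O2 uptake = injection / RQ with
    RQ = 0.8.
    """

    co2_injection: float  # mL/min
    o2_uptake: float  # mL/min

    def __post_init__(self) -> None:
        if self.co2_injection < 0 or self.o2_uptake < 0:
            raise ValueError(
                f"metabolic rates must be >= 0, got co2_injection="
                f"{self.co2_injection!r}, o2_uptake={self.o2_uptake!r}"
            )

    @staticmethod
    def default_for(pattern: BreathingPattern, rq: float = DEFAULT_RQ) -> "MetabolicSource":
        inj = EXHALED_CO2_TARGET * pattern.tidal_volume * pattern.rate
        return MetabolicSource(co2_injection=inj, o2_uptake=inj / rq)


@dataclass(frozen=True)
class SimConfig:
    """Complete description of one simulation run."""

    lung: CompliantLung = field(default_factory=CompliantLung)
    airway: SeriesAirway = field(default_factory=SeriesAirway.open_tube)
    storage: StorageCompartment | None = None
    pattern: BreathingPattern = field(default_factory=BreathingPattern)
    source: MetabolicSource | None = None  # None -> calibrated default
    ambient: GasMixture = AMBIENT_AIR
    steps_per_breath: int = 256
    max_breaths: int = 1000
    equilibrium_tol: float = 1e-4  # |d f_co2| per breath
    post_equilibrium_breaths: int = 10
    injection_mode: str = "continuous"  # or "per_breath"

    def __post_init__(self) -> None:
        if self.pattern.tidal_volume != self.lung.tidal_volume:
            raise ValueError(
                f"tidal volume mismatch: pattern moves {self.pattern.tidal_volume!r} mL "
                f"but lung excursion v_max - v_min = {self.lung.tidal_volume!r} mL"
            )
        if self.steps_per_breath < 200:
            raise ValueError(
                f"steps_per_breath must be >= 200 for area/transport accuracy, "
                f"got {self.steps_per_breath!r}"
            )
        if self.max_breaths < 2:
            raise ValueError(f"max_breaths must be >= 2, got {self.max_breaths!r}")
        if self.equilibrium_tol <= 0:
            raise ValueError(
                f"equilibrium_tol must be positive, got {self.equilibrium_tol!r}"
            )
        if self.injection_mode not in ("continuous", "per_breath"):
            raise ValueError(
                f"injection_mode must be 'continuous' or 'per_breath', "
                f"got {self.injection_mode!r}"
            )

    @property
    def resolved_source(self) -> MetabolicSource:
        return self.source if self.source is not None else MetabolicSource.default_for(self.pattern)


@dataclass
class SimResult:
    """Uniform-grid time series plus per-breath diagnostics of one run."""

    t: np.ndarray  # s
    volume: np.ndarray  # mL
    pressure: np.ndarray  # mbar, circuit pressure relative to ambient
    flow: np.ndarray  # mL/s, positive into lung
    lung_f_co2: np.ndarray
    lung_f_o2: np.ndarray
    storage_f_co2: np.ndarray
    breath_bounds: np.ndarray  # sample index of each breath start
    # per-breath diagnostics (one entry per completed breath)
    breath_end_f_co2: np.ndarray  # lung CO2 fraction at end of exhalation
    breath_end_f_o2: np.ndarray
    breath_exhaled_co2: np.ndarray  # mL of CO2 exhaled through the airway
    breath_injected_co2: np.ndarray  # mL of CO2 metered in
    breath_net_vented_co2: np.ndarray  # mL net CO2 exported to ambient
    config: SimConfig = None  # type: ignore[assignment]

    @property
    def n_breaths(self) -> int:
        return len(self.breath_end_f_co2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "V_mL": self.volume,
                "p_mbar": self.pressure,
                "Q_mL_s": self.flow,
                "lung_fCO2": self.lung_f_co2,
                "lung_fO2": self.lung_f_o2,
                "storage_fCO2": self.storage_f_co2,
            }
        )


@dataclass(frozen=True)
class EquilibriumSummary:
    """Per-run equilibrium metrics."""

    co2_volpct: float  # equilibrium lung CO2 at end-exhalation, vol%
    o2_volpct: float
    etco2_mmhg: float  # end-tidal CO2, dry convention at 760 mm Hg
    wob_j_per_min: float  # inspiratory negative-side work x breathing rate
    work_per_breath_j: float
    peak_negative_pressure_mbar: float  # magnitude of the deepest suction
    breaths_to_equilibrium: int  # -1 if not converged
    converged: bool


def detect_equilibrium(
    f_co2_trace: np.ndarray, tol: float, consecutive: int = 5
) -> int:
    """First breath index at which the trace has settled, or -1.

    Settled means |Δf_co2| per breath stays below ``tol`` for
    ``consecutive`` successive breaths; the returned index is the last
    breath of the first such run (1-based breath count).
    """
    trace = np.asarray(f_co2_trace, dtype=float)
    if trace.size < 2:
        raise ValueError("need at least 2 breaths to assess equilibrium")
    small = np.abs(np.diff(trace)) < tol
    run = 0
    for i, ok in enumerate(small):
        run = run + 1 if ok else 0
        if run >= consecutive:
            return i + 2  # diff i covers breaths i+1 -> i+2 (1-based)
    return -1


def _breath_profile(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time, volume and flow samples for one breath period.

    Returns n+1 points covering [0, T]; flow is the exact analytic
    derivative for the sinusoid and the ramp slope for the trapezoid.
    """
    n = cfg.steps_per_breath
    t = np.linspace(0.0, cfg.pattern.period, n + 1)
    v = cfg.pattern.volume(t, cfg.lung.v_min)
    if cfg.pattern.waveform == "sinusoid":
        q = cfg.pattern.tidal_volume / 2.0 * cfg.pattern.omega * np.sin(cfg.pattern.omega * t)
    else:
        q = np.gradient(v, t)
    return t, v, q


def run_simulation(config: SimConfig) -> SimResult:
    """Run the prescribed-volume simulation to equilibrium (or max_breaths).

    Stops ``post_equilibrium_breaths`` after equilibrium is detected so
    that steady-state fluxes can be audited, or at ``max_breaths``.
    """
    cfg = config
    src = cfg.resolved_source
    amb = cfg.ambient
    t1, v1, q1 = _breath_profile(cfg)
    n = cfg.steps_per_breath
    dt = cfg.pattern.period / n
    dv = np.diff(v1)

    # airway chain including the storage material's intrinsic drag
    airway = cfg.airway
    if cfg.storage is not None and cfg.storage.intrinsic_resistance > 0:
        from .circuit import LinearElement

        airway = SeriesAirway(airway.elements + (LinearElement(cfg.storage.intrinsic_resistance),))
    p1 = np.array([-airway.dp(q) for q in q1])

    # lung state as species volumes (mL); balance gas implicit
    co2 = amb.f_co2 * v1[0]
    o2 = amb.f_o2 * v1[0]

    has_storage = cfg.storage is not None and cfg.storage.storage_volume > 0
    if has_storage:
        vs_cap = cfg.storage.storage_volume
        beta = cfg.storage.effective_entrainment
        retain = cfg.storage.washout_retention
        s_amount = vs_cap  # compartment starts full of its initial gas
        s_co2 = cfg.storage.initial_gas.f_co2 * vs_cap
        s_o2 = cfg.storage.initial_gas.f_o2 * vs_cap
    else:
        beta = 0.0

    inj_dt = src.co2_injection * dt / 60.0  # continuous-mode per-step bolus
    upt_dt = src.o2_uptake * dt / 60.0
    inj_breath = src.co2_injection / cfg.pattern.rate  # per-breath totals
    upt_breath = src.o2_uptake / cfg.pattern.rate
    per_breath_mode = cfg.injection_mode == "per_breath"
    end_inhale_step = int(np.argmax(v1))  # step index after which V peaks

    max_b = cfg.max_breaths
    total_steps = max_b * n + 1
    out_fco2 = np.empty(total_steps)
    out_fo2 = np.empty(total_steps)
    out_sco2 = np.empty(total_steps)
    out_fco2[0] = co2 / v1[0]
    out_fo2[0] = o2 / v1[0]
    out_sco2[0] = (s_co2 / s_amount) if has_storage else amb.f_co2

    end_fco2: list[float] = []
    end_fo2: list[float] = []
    b_exhaled: list[float] = []
    b_injected: list[float] = []
    b_vented: list[float] = []

    breaths_done = 0
    stop_after = None

    for b in range(max_b):
        base = b * n
        co2_in_amb = 0.0  # ambient CO2 drawn in this breath
        co2_out_amb = 0.0  # CO2 vented to ambient this breath
        exhaled_co2 = 0.0
        injected = 0.0
        for k in range(n):
            vol_pre = v1[k]
            d = dv[k]
            if d >= 0.0:  # inhalation
                draw = 0.0
                if has_storage and beta > 0.0:
                    draw = min(beta * d, s_amount)
                    if draw > 0.0:
                        c_s = s_co2 / s_amount
                        c_so = s_o2 / s_amount
                        co2 += draw * c_s
                        o2 += draw * c_so
                        s_co2 -= draw * c_s
                        s_o2 -= draw * c_so
                        s_amount -= draw
                fresh = d - draw
                co2 += fresh * amb.f_co2
                o2 += fresh * amb.f_o2
                co2_in_amb += fresh * amb.f_co2
            else:  # exhalation: gas leaves at lung composition
                de = -d
                f_c = co2 / vol_pre
                f_o = o2 / vol_pre
                out_c = de * f_c
                out_o = de * f_o
                co2 -= out_c
                o2 -= out_o
                exhaled_co2 += out_c
                if has_storage:
                    space = vs_cap - s_amount
                    fill = de if de <= space else space
                    if fill > 0.0:
                        s_co2 += fill * f_c
                        s_o2 += fill * f_o
                        s_amount += fill
                    over = de - fill
                    if over > 0.0:
                        # well-mixed overflow: mix in, vent the same volume
                        s_co2 += over * f_c
                        s_o2 += over * f_o
                        tot = s_amount + over
                        vent_c = over * s_co2 / tot
                        vent_o = over * s_o2 / tot
                        s_co2 -= vent_c
                        s_o2 -= vent_o
                        co2_out_amb += vent_c
                else:
                    co2_out_amb += out_c

            # O2 uptake is limited to the O2 present: the sink cannot
            # drive the lung O2 fraction below zero
            if per_breath_mode:
                if k == end_inhale_step - 1:
                    co2 += inj_breath
                    o2 -= min(upt_breath, o2)
                    injected += inj_breath
            else:
                co2 += inj_dt
                o2 -= min(upt_dt, o2)
                injected += inj_dt

            vol_post = v1[k + 1]
            idx = base + k + 1
            f_c = co2 / vol_post
            f_o = o2 / vol_post
            if not (0.0 <= f_c <= 1.0) or not math.isfinite(f_c):
                raise SimulationError(
                    f"lung CO2 fraction {f_c!r} invalid at breath {b + 1}, step {k + 1}"
                )
            if f_o < 0.0 or not math.isfinite(f_o):
                raise SimulationError(
                    f"lung O2 exhausted (fraction {f_o!r}) at breath {b + 1}, step {k + 1}"
                )
            out_fco2[idx] = f_c
            out_fo2[idx] = f_o
            out_sco2[idx] = (s_co2 / s_amount) if has_storage else amb.f_co2

        # breath boundary: inter-breath washout of the storage compartment
        if has_storage and retain < 1.0:
            c_s = s_co2 / s_amount
            c_so = s_o2 / s_amount
            exch = (1.0 - retain) * s_amount
            co2_out_amb += exch * c_s
            co2_in_amb += exch * amb.f_co2
            s_co2 = s_amount * (amb.f_co2 + retain * (c_s - amb.f_co2))
            s_o2 = s_amount * (amb.f_o2 + retain * (c_so - amb.f_o2))
            out_sco2[base + n] = s_co2 / s_amount

        breaths_done = b + 1
        end_fco2.append(out_fco2[base + n])
        end_fo2.append(out_fo2[base + n])
        b_exhaled.append(exhaled_co2)
        b_injected.append(injected)
        b_vented.append(co2_out_amb - co2_in_amb)

        if stop_after is None and breaths_done >= 2 + 5:
            eq = detect_equilibrium(np.array(end_fco2), cfg.equilibrium_tol)
            if eq > 0:
                stop_after = min(max_b, eq + cfg.post_equilibrium_breaths)
        if stop_after is not None and breaths_done >= stop_after:
            break

    m = breaths_done * n + 1
    t_all = np.arange(m) * dt
    v_all = np.empty(m)
    v_all[0] = v1[0]
    p_all = np.empty(m)
    p_all[0] = p1[0]
    q_all = np.empty(m)
    q_all[0] = q1[0]
    for b in range(breaths_done):
        sl = slice(b * n + 1, (b + 1) * n + 1)
        v_all[sl] = v1[1:]
        p_all[sl] = p1[1:]
        q_all[sl] = q1[1:]

    return SimResult(
        t=t_all,
        volume=v_all,
        pressure=p_all,
        flow=q_all,
        lung_f_co2=out_fco2[:m],
        lung_f_o2=out_fo2[:m],
        storage_f_co2=out_sco2[:m],
        breath_bounds=np.arange(breaths_done) * n,
        breath_end_f_co2=np.array(end_fco2),
        breath_end_f_o2=np.array(end_fo2),
        breath_exhaled_co2=np.array(b_exhaled),
        breath_injected_co2=np.array(b_injected),
        breath_net_vented_co2=np.array(b_vented),
        config=cfg,
    )


def summarize(result: SimResult) -> EquilibriumSummary:
    """Equilibrium metrics of a finished run (work from the p-v profile)."""
    from .wob import work_negative_side_arrays

    cfg = result.config
    n = cfg.steps_per_breath
    # pressure/volume profile is identical every breath; use the first
    w_breath = work_negative_side_arrays(
        result.pressure[: n + 1], result.volume[: n + 1]
    )
    eq = detect_equilibrium(result.breath_end_f_co2, cfg.equilibrium_tol) if result.n_breaths >= 2 else -1
    converged = eq > 0
    f_co2 = float(result.breath_end_f_co2[-1])
    f_o2 = float(result.breath_end_f_o2[-1])
    return EquilibriumSummary(
        co2_volpct=100.0 * f_co2,
        o2_volpct=100.0 * f_o2,
        etco2_mmhg=fraction_to_partial_pressure(f_co2, DRY_AIR_760),
        wob_j_per_min=w_breath * cfg.pattern.rate,
        work_per_breath_j=w_breath,
        peak_negative_pressure_mbar=float(-result.pressure.min()),
        breaths_to_equilibrium=eq,
        converged=converged,
    )


def breath_recurrence_steady_state(
    storage: StorageCompartment | None,
    pattern: BreathingPattern | None = None,
    source: MetabolicSource | None = None,
    ambient: GasMixture = AMBIENT_AIR,
    lung: CompliantLung | None = None,
) -> tuple[float, float]:
    """Steady-state (lung, storage) CO2 fractions of the per-breath map.

    Analytic reduction of the engine's mass balance under the per-breath
    injection assumption.  One breath maps the state (L, S) — lung CO2
    fraction at the start of inhalation, storage CO2 fraction with the
    compartment full — through four affine stages:

    1. inhale V_T, of which b = min(beta V_T, V_s) comes from storage at
       composition S and the rest is ambient;
    2. inject the per-breath CO2 bolus q into the lung at v_max;
    3. exhale V_T at (constant) lung composition: refill the freed space
       b, then pass the remaining V_T - b through the full compartment as
       a well-mixed overflow, an exponential relaxation by
       exp(-(V_T - b)/V_s);
    4. inter-breath washout: storage excess over ambient times a.

    The map is affine, x' = A x + d; the steady state is the solution of
    (I - A) x = d.  With beta = 1 and a = 1 (and V_s >= V_T) the map is
    row-stochastic — no CO2 leaves the system — and no fixed point
    exists: a ``SimulationError`` reports the unbounded regime.

    Returns
    -------
    (lung_f_co2, storage_f_co2) at steady state.  For no storage the
    storage entry is the ambient CO2 fraction.
    """
    pattern = pattern or BreathingPattern()
    lung = lung or CompliantLung()
    src = source or MetabolicSource.default_for(pattern)
    vt = pattern.tidal_volume
    v_min, v_max = lung.v_min, lung.v_max
    c_a = ambient.f_co2
    q = src.co2_injection / pattern.rate  # mL CO2 per breath

    if storage is None or storage.storage_volume == 0 or storage.effective_entrainment == 0:
        # fresh-air limit: L* = ambient + q / V_T
        return c_a + q / vt, c_a

    vs = storage.storage_volume
    beta = storage.effective_entrainment
    a = storage.washout_retention
    b = min(beta * vt, vs)

    # L' = A11 L + A12 S + d1
    a11 = v_min / v_max
    a12 = b / v_max
    d1 = ((vt - b) * c_a + q) / v_max
    # storage: refill then CSTR overflow, then washout
    e = math.exp(-(vt - b) / vs)
    g = (1.0 - e) + e * b / vs  # weight of exhaled composition L'
    h = e * (vs - b) / vs  # weight of prior storage composition
    a21 = a * g * a11
    a22 = a * (g * a12 + h)
    d2 = a * g * d1 + (1.0 - a) * c_a

    A = np.array([[a11, a12], [a21, a22]])
    d = np.array([d1, d2])
    eigmax = max(abs(np.linalg.eigvals(A)))
    if eigmax >= 1.0 - 1e-12:
        raise SimulationError(
            "no steady state: per-breath map is non-contractive "
            f"(spectral radius {eigmax:.6f}); with beta = {beta} and "
            f"a = {a} no CO2 leaves the system and lung CO2 grows without bound"
        )
    sol = np.linalg.solve(np.eye(2) - A, d)
    return float(sol[0]), float(sol[1])


def simulate_pressure_driven(
    drive_pressure: Callable[[float], float],
    config: SimConfig,
    n_breaths: int = 5,
) -> SimResult:
    """Pressure-driven alternative: the driver applies a pleural-side
    pressure and the lung volume follows compliance and airway resistance.

    Quasi-static force balance at each instant:
    (V - V_rest)/C = -ΔP_airway(dV/dt) - p_drive(t), integrated with an
    implicit per-step root solve for the flow.  ``V_rest`` is taken as
    the mid-excursion volume.  Gas transport is not modelled in this mode
    (mechanics only); the returned composition channels are held at
    ambient.  Exposed for completeness; the replication harness drives
    volume, matching the bench apparatus.
    """
    from scipy.optimize import brentq

    cfg = config
    n = cfg.steps_per_breath
    dt = cfg.pattern.period / n
    steps = n_breaths * n + 1
    v_rest = 0.5 * (cfg.lung.v_min + cfg.lung.v_max)
    c = cfg.lung.compliance

    t = np.arange(steps) * dt
    v = np.empty(steps)
    q = np.empty(steps)
    p = np.empty(steps)
    v[0] = v_rest
    q[0] = 0.0
    p[0] = 0.0
    for i in range(1, steps):
        ti = t[i]
        v_prev = v[i - 1]

        def residual(flow: float) -> float:
            v_new = v_prev + flow * dt
            return (v_new - v_rest) / c + cfg.airway.dp(flow) + drive_pressure(ti)

        qi = brentq(residual, -1e4, 1e4)
        v[i] = v_prev + qi * dt
        q[i] = qi
        p[i] = -cfg.airway.dp(qi)

    amb = cfg.ambient
    const = np.full(steps, amb.f_co2)
    return SimResult(
        t=t,
        volume=v,
        pressure=p,
        flow=q,
        lung_f_co2=const,
        lung_f_o2=np.full(steps, amb.f_o2),
        storage_f_co2=const,
        breath_bounds=np.arange(n_breaths) * n,
        breath_end_f_co2=np.full(n_breaths, amb.f_co2),
        breath_end_f_o2=np.full(n_breaths, amb.f_o2),
        breath_exhaled_co2=np.zeros(n_breaths),
        breath_injected_co2=np.zeros(n_breaths),
        breath_net_vented_co2=np.zeros(n_breaths),
        config=cfg,
    )
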