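"""Synthetic pressure-volume fixtures with closed-form expected work.

Every fixture is deterministic (seedless) and carries the analytically
expected negative-side work per cycle, so the trapezoidal loop-area
computation can be validated against an independent closed form:

``ellipse``
    p = -a sin(theta), V = V0 - b cos(theta): negative-side area is the
    half-ellipse, (pi a b / 2) x 1e-4 J.
``linear_resistance``
    sinusoidal volume through a linear resistance R: p = -R Q and
    W = (pi R omega V_T^2 / 8) x 1e-4 J.
``orifice``
    sinusoidal volume through a quadratic law p = -k Q|Q|:
    W = (k Q_peak^3 4 / (3 omega)) x 1e-4 J.
``flat``
    sinusoidal volume at zero pressure: W = 0.

The oscillatory fixtures start mid-volume (sine phase) so every volume
minimum lies strictly inside the record and ``n_cycles`` sampled periods
segment into ``n_cycles - 1`` complete min-to-min cycles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .wob import MBAR_ML_TO_J, PVRecord

__all__ = ["FixtureSpec", "generate_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("ellipse", "linear_resistance", "orifice", "flat")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic p-v record.

    ``amplitude`` is the pressure semi-axis a (mbar) for the ellipse, the
    linear resistance R (mbar·s/mL) for ``linear_resistance``, and the
    quadratic coefficient k (mbar/(mL/s)^2) for ``orifice``; it is unused
    for ``flat``.
    """

    kind: str = "linear_resistance"
    amplitude: float = 0.01
    tidal_volume: float = 35.0  # mL (ellipse: volume semi-axis b = V_T / 2)
    rate: float = 44.0  # cycles/min
    v_mid: float = 47.5  # mL, mid-cycle volume
    samples_per_cycle: int = 400
    n_cycles: int = 10

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(
                f"unknown fixture kind {self.kind!r}; choose from {FIXTURE_KINDS}"
            )
        if self.tidal_volume <= 0 or self.rate <= 0:
            raise ValueError("tidal_volume and rate must be positive")
        if self.samples_per_cycle < 50:
            raise ValueError(
                f"need >= 50 samples per cycle, got {self.samples_per_cycle!r}"
            )
        if self.n_cycles < 1:
            raise ValueError(f"need >= 1 cycle, got {self.n_cycles!r}")


def generate_fixture(spec: FixtureSpec) -> tuple[PVRecord, float]:
    """Build the record and return it with its expected work per cycle (J)."""
    period = 60.0 / spec.rate
    omega = 2.0 * math.pi / period
    n = spec.samples_per_cycle * spec.n_cycles
    t = np.arange(n) * (period / spec.samples_per_cycle)
    b = spec.tidal_volume / 2.0
    v = spec.v_mid + b * np.sin(omega * t)
    q = b * omega * np.cos(omega * t)

    if spec.kind == "ellipse":
        a = spec.amplitude
        # quarter-phase pressure: negative exactly while volume rises
        p = -a * np.cos(omega * t)
        expected = math.pi * a * b / 2.0 * MBAR_ML_TO_J
    elif spec.kind == "linear_resistance":
        r = spec.amplitude
        p = -r * q
        expected = math.pi * r * omega * spec.tidal_volume**2 / 8.0 * MBAR_ML_TO_J
    elif spec.kind == "orifice":
        k = spec.amplitude
        p = -k * q * np.abs(q)
        q_peak = b * omega
        expected = k * q_peak**3 * 4.0 / (3.0 * omega) * MBAR_ML_TO_J
    else:  # flat
        p = np.zeros_like(t)
        expected = 0.0

    return PVRecord(t=t, p=p, v=v), expected
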