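"""Physical elements of the breathing circuit.

The circuit is a compliant lung breathing through a series airway made of
an open-ended tube (laminar, Poiseuille law) and optionally a sharp-edged
orifice (quadratic law), with an optional bedding gas-storage compartment
wrapped around the airway opening.

Unit conventions used throughout the package:

========  =========================
volume    mL
flow Q    mL/s (positive into lung)
pressure  mbar
R_lin     mbar·s/mL
========  =========================

with 1 mbar = 100 Pa and 1 m^3 = 1e6 mL, so a Poiseuille resistance
computed in SI (Pa·s/m^3) converts to mbar·s/mL by a factor 1e-8.
Air is treated as incompressible; pressure excursions are small relative
to atmospheric for all but the narrowest orifice (documented limitation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .gas import AMBIENT_AIR, GasMixture

__all__ = [
    "CompliantLung",
    "TubeElement",
    "OrificeElement",
    "SeriesAirway",
    "StorageCompartment",
    "tube_resistance",
    "orifice_dp",
    "series_dp",
    "polyfill_preset",
    "ORIFICE_DIAMETERS_MM",
]

#: Orifice internal diameters (mm) of the resistance ladder, largest first.
ORIFICE_DIAMETERS_MM = (4.03, 3.25, 2.64, 1.93, 1.07)

_PA_S_M3_TO_MBAR_S_ML = 1e-8  # (1/100 Pa per mbar) * (1e-6 m^3 per mL)


def tube_resistance(
    length_mm: float, diameter_mm: float, viscosity: float = 1.81e-5
) -> float:
    """Laminar (Poiseuille) resistance of a circular tube, in mbar·s/mL.

    R = 8 mu L / (pi r^4), converted from Pa·s/m^3.  The default
    open-ended tube (300 mm long, 5 mm bore) gives 3.54e-3 mbar·s/mL.
    """
    if length_mm <= 0 or diameter_mm <= 0 or viscosity <= 0:
        raise ValueError(
            f"tube geometry must be positive: length={length_mm!r} mm, "
            f"diameter={diameter_mm!r} mm, viscosity={viscosity!r} Pa·s"
        )
    r_m = diameter_mm * 1e-3 / 2.0
    r_si = 8.0 * viscosity * (length_mm * 1e-3) / (math.pi * r_m**4)
    return r_si * _PA_S_M3_TO_MBAR_S_ML


@dataclass(frozen=True)
class TubeElement:
    """Open-ended tube with a linear pressure-drop law ΔP = R_lin · Q."""

    length_mm: float = 300.0
    inner_diameter_mm: float = 5.0
    air_viscosity: float = 1.81e-5  # Pa·s at room temperature

    def __post_init__(self) -> None:
        self.resistance  # validates geometry

    @property
    def resistance(self) -> float:
        """Linear resistance, mbar·s/mL."""
        return tube_resistance(
            self.length_mm, self.inner_diameter_mm, self.air_viscosity
        )

    def dp(self, q_ml_s: float) -> float:
        return self.resistance * q_ml_s


def orifice_dp(
    q_ml_s: float,
    diameter_mm: float,
    discharge_coefficient: float = 0.6,
    air_density: float = 1.2,
) -> float:
    """Quadratic pressure drop across a sharp-edged orifice, in mbar.

    ΔP = rho Q|Q| / (2 C_d^2 A^2), sign-preserving.  At 80.6 mL/s the
    4.03 mm orifice drops ~0.67 mbar and the 1.07 mm orifice ~134 mbar —
    the d^-4 scaling of the quadratic law.
    """
    if diameter_mm <= 0:
        raise ValueError(f"orifice diameter must be positive, got {diameter_mm!r}")
    if not 0.0 < discharge_coefficient <= 1.0:
        raise ValueError(
            f"discharge coefficient must be in (0, 1], got {discharge_coefficient!r}"
        )
    area_m2 = math.pi * (diameter_mm * 1e-3 / 2.0) ** 2
    q_si = q_ml_s * 1e-6
    dp_pa = air_density * q_si * abs(q_si) / (2.0 * discharge_coefficient**2 * area_m2**2)
    return dp_pa / 100.0


@dataclass(frozen=True)
class OrificeElement:
    """Sharp-edged orifice with quadratic law ΔP = rho Q|Q| / (2 C_d^2 A^2)."""

    diameter_mm: float
    discharge_coefficient: float = 0.6
    air_density: float = 1.2  # kg/m^3

    def __post_init__(self) -> None:
        self.dp(0.0)  # validates geometry / coefficient

    def dp(self, q_ml_s: float) -> float:
        return orifice_dp(
            q_ml_s, self.diameter_mm, self.discharge_coefficient, self.air_density
        )


@dataclass(frozen=True)
class LinearElement:
    """Generic linear resistance (used for the polyfill's intrinsic drag)."""

    resistance: float  # mbar·s/mL

    def __post_init__(self) -> None:
        if self.resistance < 0:
            raise ValueError(f"resistance must be >= 0, got {self.resistance!r}")

    def dp(self, q_ml_s: float) -> float:
        return self.resistance * q_ml_s


@dataclass(frozen=True)
class SeriesAirway:
    """Ordered chain of airway elements; ΔP_total(Q) = Σ ΔP_element(Q).

    The total law is odd and strictly increasing in Q because every
    element's law is.
    """

    elements: tuple

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("airway must contain at least one element")

    def dp(self, q_ml_s: float) -> float:
        return sum(e.dp(q_ml_s) for e in self.elements)

    @staticmethod
    def open_tube(tube: TubeElement | None = None) -> "SeriesAirway":
        return SeriesAirway((tube or TubeElement(),))

    @staticmethod
    def tube_with_orifice(
        diameter_mm: float, tube: TubeElement | None = None
    ) -> "SeriesAirway":
        return SeriesAirway((tube or TubeElement(), OrificeElement(diameter_mm)))


def series_dp(q_ml_s: float, airway: SeriesAirway) -> float:
    """Total pressure drop across a series airway, mbar."""
    return airway.dp(q_ml_s)


@dataclass(frozen=True)
class CompliantLung:
    """Compliant bellows lung reciprocating between fixed volumes.

    Compliance 0.7 mL/mbar with a 30–65 mL excursion (tidal volume 35 mL)
    emulates an infant lung.  The volume excursion is prescribed by the
    breathing pattern in the volume-driven mode; compliance enters only in
    the pressure-driven mode.
    """

    compliance: float = 0.7  # mL/mbar
    v_min: float = 30.0  # mL
    v_max: float = 65.0  # mL

    def __post_init__(self) -> None:
        if self.compliance <= 0:
            raise ValueError(f"compliance must be positive, got {self.compliance!r}")
        if not self.v_min < self.v_max:
            raise ValueError(
                f"require v_min < v_max, got {self.v_min!r} >= {self.v_max!r}"
            )

    @property
    def tidal_volume(self) -> float:
        return self.v_max - self.v_min


# Polyfill calibration: the bench study quantifies layers of material, not
# storage volume, so layers map linearly onto the compartment parameters.
# These constants are free calibration choices (see docs/methods.md).
POLYFILL_STORAGE_ML_PER_LAYER = 12.0
POLYFILL_ENTRAINMENT_PER_LAYER = 0.12
POLYFILL_RESISTANCE_PER_LAYER = 5e-5  # mbar·s/mL
POLYFILL_WASHOUT_RETENTION = 0.6
WRAPPED_EQUIVALENT_LAYERS = 8


@dataclass(frozen=True)
class StorageCompartment:
    """Bedding gas-storage compartment around the airway opening.

    The compartment holds up to ``storage_volume`` mL of gas.  During
    inhalation a fraction ``entrainment_fraction`` (beta) of the inhaled
    flow is drawn from the stored gas (capped by the amount available);
    during exhalation the exhaled stream first refills the freed space and
    then overflows through the well-mixed compartment, venting the mixed
    excess to ambient.  Between breaths the compartment's composition
    excess over ambient decays by the factor ``washout_retention`` (a),
    emulating inter-breath dissipation through the material.

    ``intrinsic_resistance`` is the (small, linear) airflow resistance the
    material itself adds to the circuit.
    """

    storage_volume: float  # mL
    entrainment_fraction: float  # beta in [0, 1]
    washout_retention: float = POLYFILL_WASHOUT_RETENTION  # a in [0, 1]
    intrinsic_resistance: float = 0.0  # mbar·s/mL
    initial_gas: GasMixture = field(default=AMBIENT_AIR)

    def __post_init__(self) -> None:
        if self.storage_volume < 0:
            raise ValueError(
                f"storage_volume must be >= 0, got {self.storage_volume!r}"
            )
        for name in ("entrainment_fraction", "washout_retention"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if self.intrinsic_resistance < 0:
            raise ValueError(
                f"intrinsic_resistance must be >= 0, got {self.intrinsic_resistance!r}"
            )

    @property
    def effective_entrainment(self) -> float:
        """beta forced to 0 when there is nothing to store."""
        return self.entrainment_fraction if self.storage_volume > 0 else 0.0


def polyfill_preset(layers: float) -> StorageCompartment | None:
    """Storage compartment for ``layers`` layers of polyfill (0 -> no storage).

    The 'wrapped in polyfill' condition of the combination grid is the
    8-layer-equivalent preset, approaching full rebreathing (beta -> 1).
    """
    if layers < 0:
        raise ValueError(f"layer count must be >= 0, got {layers!r}")
    if layers == 0:
        return None
    return StorageCompartment(
        storage_volume=POLYFILL_STORAGE_ML_PER_LAYER * layers,
        entrainment_fraction=min(1.0, POLYFILL_ENTRAINMENT_PER_LAYER * layers),
        washout_retention=POLYFILL_WASHOUT_RETENTION,
        intrinsic_resistance=POLYFILL_RESISTANCE_PER_LAYER * layers,
    )
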