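"""Gas mixture bookkeeping for the breathing-circuit model.

A gas parcel is described by its CO2 and O2 volume fractions; everything
else (nitrogen plus trace species) is lumped into a balance fraction.
Fractions — not percentages — are the internal representation throughout
the package; formatting to vol% happens only at reporting time.

Partial pressures are derived from fractions under an explicit
:class:`PressureConvention`. Two conventions are in common use:

* dry gas at the full barometric pressure (default, 760 mm Hg), and
* BTPS, in which the 47 mm Hg water-vapor pressure at body temperature is
  subtracted from the total before multiplying by the fraction.

Published fresh-air values (pO2 160 mm Hg at 21 vol%, pCO2 0.3 mm Hg at
0.04 vol%) follow the dry convention; published exhaled-breath values do
not fall cleanly on either convention, so both are exposed and none is
hard-coded into reported concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "GasMixture",
    "PressureConvention",
    "DRY_AIR_760",
    "BTPS_760",
    "AMBIENT_AIR",
    "fraction_to_partial_pressure",
    "partial_pressure_to_fraction",
    "mix",
]

_FRACTION_SUM_TOL = 1e-9


@dataclass(frozen=True)
class GasMixture:
    """Composition of a well-mixed gas volume, as volume fractions.

    Parameters
    ----------
    f_co2, f_o2 : float
        CO2 and O2 volume fractions in [0, 1].
    f_bal : float, optional
        Balance (N2 + trace) fraction.  If omitted it is inferred as
        ``1 - f_co2 - f_o2``; if given, the three fractions must sum to 1
        within 1e-9.
    """

    f_co2: float
    f_o2: float
    f_bal: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.f_bal is None:
            object.__setattr__(self, "f_bal", 1.0 - self.f_co2 - self.f_o2)
        for name in ("f_co2", "f_o2", "f_bal"):
            f = getattr(self, name)
            if not (-_FRACTION_SUM_TOL <= f <= 1.0 + _FRACTION_SUM_TOL):
                raise ValueError(f"{name}={f!r} outside [0, 1]")
        total = self.f_co2 + self.f_o2 + self.f_bal
        if abs(total - 1.0) > _FRACTION_SUM_TOL:
            raise ValueError(f"fractions sum to {total!r}, not 1 within 1e-9")

    def co2_volpct(self) -> float:
        """CO2 concentration in vol% (reporting convenience)."""
        return 100.0 * self.f_co2

    def o2_volpct(self) -> float:
        """O2 concentration in vol% (reporting convenience)."""
        return 100.0 * self.f_o2


@dataclass(frozen=True)
class PressureConvention:
    """Total-pressure convention for fraction <-> partial-pressure conversion.

    ``water_vapor_correction`` is subtracted from ``total_pressure`` before
    multiplying by the volume fraction: 0 for dry gas, 47 mm Hg for gas
    saturated at body temperature (BTPS).
    """

    total_pressure: float = 760.0  # mm Hg
    water_vapor_correction: float = 0.0  # mm Hg

    def __post_init__(self) -> None:
        if not self.total_pressure > self.water_vapor_correction >= 0.0:
            raise ValueError(
                "require total_pressure > water_vapor_correction >= 0, got "
                f"{self.total_pressure!r} and {self.water_vapor_correction!r}"
            )

    @property
    def effective_pressure(self) -> float:
        return self.total_pressure - self.water_vapor_correction


DRY_AIR_760 = PressureConvention(760.0, 0.0)
BTPS_760 = PressureConvention(760.0, 47.0)

#: Fresh ambient air: 0.04 vol% CO2, 21 vol% O2.
AMBIENT_AIR = GasMixture(f_co2=0.0004, f_o2=0.21)


def fraction_to_partial_pressure(
    f: float, conv: PressureConvention = DRY_AIR_760
) -> float:
    """Partial pressure (mm Hg) of a species at volume fraction ``f``.

    Under the dry convention at 760 mm Hg, fresh-air O2 (f = 0.21) gives
    159.6 mm Hg and fresh-air CO2 (f = 0.0004) gives 0.304 mm Hg — the
    values conventionally rounded to 160 and 0.3 mm Hg.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"volume fraction {f!r} outside [0, 1]")
    return f * conv.effective_pressure


def partial_pressure_to_fraction(
    p: float, conv: PressureConvention = DRY_AIR_760
) -> float:
    """Volume fraction of a species at partial pressure ``p`` mm Hg."""
    if not 0.0 <= p <= conv.effective_pressure:
        raise ValueError(
            f"partial pressure {p!r} outside [0, {conv.effective_pressure}]"
        )
    return p / conv.effective_pressure


def mix(a: GasMixture, vol_a: float, b: GasMixture, vol_b: float) -> GasMixture:
    """Conservatively mix two gas parcels (volume-weighted mean fractions).

    Raises
    ------
    ValueError
        If either volume is negative or both are zero.
    """
    if vol_a < 0.0 or vol_b < 0.0:
        raise ValueError(f"negative parcel volume: {vol_a!r}, {vol_b!r}")
    total = vol_a + vol_b
    if total == 0.0:
        raise ValueError("cannot mix two zero-volume parcels")
    w = vol_a / total
    return GasMixture(
        f_co2=w * a.f_co2 + (1.0 - w) * b.f_co2,
        f_o2=w * a.f_o2 + (1.0 - w) * b.f_o2,
        f_bal=w * a.f_bal + (1.0 - w) * b.f_bal,
    )
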