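"""Pressure drops across the airway elements at peak inspiratory flow.

The sinusoidal 35 mL / 44 bpm pattern peaks at ~80.6 mL/s.  The open
300 mm x 5 mm tube is laminar (linear law); each orifice follows the
quadratic sharp-edged law, so the drop scales with d^-4.
"""

from breathsim.circuit import ORIFICE_DIAMETERS_MM, SeriesAirway, orifice_dp, tube_resistance
from breathsim.engine import BreathingPattern

pattern = BreathingPattern()
q_peak = pattern.tidal_volume / 2 * pattern.omega
print(f"peak inspiratory flow: {q_peak:.1f} mL/s at {pattern.rate:.0f} breaths/min")

r_tube = tube_resistance(300.0, 5.0)
print(f"open tube: R = {r_tube:.3e} mbar.s/mL -> dP = {r_tube * q_peak:.3f} mbar")

print("orifice ladder (tube + orifice in series):")
for d in ORIFICE_DIAMETERS_MM:
    chain = SeriesAirway.tube_with_orifice(d)
    print(f"  {d:5.2f} mm: dP at peak flow = {chain.dp(q_peak):9.3f} mbar "
          f"(orifice alone {orifice_dp(q_peak, d):9.3f})")
print("each halving of the diameter multiplies the drop ~16x: the suction")
print("needed to keep the tidal volume fixed rises steeply as the path narrows")
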