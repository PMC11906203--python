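"""Gas fractions and partial pressures under the two conventions.

Converts the fresh-air and exhaled-breath benchmark compositions between
volume fraction and partial pressure, dry (760 mm Hg) vs BTPS (760 - 47).
"""

from breathsim import (
    BTPS_760,
    DRY_AIR_760,
    GasMixture,
    fraction_to_partial_pressure,
    mix,
)

print("fresh air, dry convention:")
print(f"  O2  21 vol%   -> {fraction_to_partial_pressure(0.21, DRY_AIR_760):7.1f} mm Hg")
print(f"  CO2 0.04 vol% -> {fraction_to_partial_pressure(0.0004, DRY_AIR_760):7.3f} mm Hg")

print("exhaled breath (4.4 vol% CO2, 16.4 vol% O2):")
for name, conv in [("dry", DRY_AIR_760), ("BTPS", BTPS_760)]:
    pco2 = fraction_to_partial_pressure(0.044, conv)
    po2 = fraction_to_partial_pressure(0.164, conv)
    print(f"  {name:4s}: pCO2 {pco2:5.1f} mm Hg, pO2 {po2:6.1f} mm Hg")

exhaled = GasMixture(f_co2=0.044, f_o2=0.164)
fresh = GasMixture(f_co2=0.0004, f_o2=0.21)
half = mix(exhaled, 35.0, fresh, 35.0)
print(f"equal-volume mix of exhaled and fresh air: CO2 {half.co2_volpct():.2f} vol%")
print("(the partial pressures scale linearly with the fraction; the dry")
print(" convention reproduces the textbook fresh-air values 160 / 0.3 mm Hg)")
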