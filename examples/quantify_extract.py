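"""Quantify anthocyanin content and antioxidant activity from raw readings.

Builds a pH-differential absorbance quadruple, converts it to mg of
cyanidin-3-O-glucoside equivalents per g dry weight, then calibrates a DPPH
response against Trolox standards and inverts it.
"""

from thermokin import (
    AbsorbanceQuadruple,
    PhDifferentialParams,
    fit_trolox_calibration,
    tac_ph_differential,
    trolox_equivalents,
)

# one measurement: A520/A700 at pH 1.0 and 4.5, with a constant 0.05 haze
quad = AbsorbanceQuadruple(a520_ph1=0.319, a700_ph1=0.050,
                           a520_ph45=0.050, a700_ph45=0.050)
params = PhDifferentialParams(dilution_factor=10, final_volume=10, dry_mass=100)
res = tac_ph_differential(quad, params)
print(f"net absorbance        : {res.net_abs:.3f}")
print(f"TAC                   : {res.tac_mg_per_g:.3f} mg C3G/g DW")
# the net absorbance isolates monomeric pigment; TAC scales it by the
# Beer-Lambert constants, the dilution and the dry-mass basis

standards = [(c, 0.090 * c + 0.020) for c in (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)]
curve = fit_trolox_calibration(standards)
print(f"Trolox calibration    : slope {curve.slope:.3f}, intercept "
      f"{curve.intercept:.3f}, r^2 {curve.r_squared:.3f}")

activity, below = trolox_equivalents(0.514, curve)
print(f"antioxidant activity  : {activity:.2f} mmol Trolox equivalents"
      f"{' (below calibration range)' if below else ''}")
# a response of 0.514 sits mid-curve: (0.514 - 0.020) / 0.090 = 5.49 mmol
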