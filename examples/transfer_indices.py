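"""Soil→plant transfer indices from a tiny hand-made survey.

Builds one plant/soil pair plus a BCR extraction row, then computes
the BCR fraction profile, BAC, BC and the qualitative BAC class.
"""

from pterisk import (
    Element,
    bioaccumulation,
    bioconcentration,
    classify_bac,
    fraction_profile,
)

# a copper-rich soil: BCR steps in mg/kg against a 60 mg/kg pseudo-total
prof = fraction_profile(s1=2.7, s2=5.5, s3=2.6, pseudo_total=60.0,
                        element=Element.CU)
print(f"labile pool : {prof.labile_conc:.1f} mg/kg = {prof.labile_pct:.1f}% "
      f"(residual {prof.pct_residual:.1f}%)")

c_plant = 16.9  # leaf Cu, mg/kg
bac = bioaccumulation(c_plant, 60.0)
bc = bioconcentration(c_plant, prof.labile_conc)
print(f"BAC = {bac:.2f} ({classify_bac(bac).value})")
print(f"BC  = {bc:.2f}  (plant vs the labile pool only)")

print(
    "\nBAC relates the leaf concentration to the total soil pool, BC to\n"
    "the plant-available (labile) pool; BC >= BAC whenever the labile\n"
    "pool is part of the total, and a BAC >= 1 marks strong accumulation."
)
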