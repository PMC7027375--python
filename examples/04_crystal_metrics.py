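"""Crystal-content bookkeeping: cell volume, Matthews coefficient, solvent
content and displacement-parameter conversion.

Uses a monoclinic P2₁ cell typical of peptide-MHC crystals (one complex per
asymmetric unit, two per cell).
"""

import math

from pepgroove import CrystalCell, b_eq_from_aniso, cell_volume, matthews

cell = CrystalCell(51.0, 81.9, 65.4, 90.0, 108.9, 90.0, z_value=2)
vol = cell_volume(cell)
print(f"cell volume: {vol:,.0f} ų (= abc·sinβ = "
      f"{51.0 * 81.9 * 65.4 * math.sin(math.radians(108.9)):,.0f})")

mass = 46_150.0  # Da, a class-I heavy chain + light chain + nonamer
res = matthews(cell, z=2, mass=mass)
print(f"V_M = {res.v_m:.2f} ų/Da -> solvent content {100 * res.solvent_fraction:.1f} %")

u = (0.01, 0.01, 0.01, 0.0, 0.0, 0.0)
print(f"B_eq for U = diag(0.01) Ų: {b_eq_from_aniso(u):.4f} Ų (= 8π²·0.01)")
# V_M near 2.8 ų/Da and ~56 % solvent are the textbook values for a
# monoclinic class-I crystal; the 1.23 constant assumes a protein partial
# specific volume of 0.74 cm³/g.
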