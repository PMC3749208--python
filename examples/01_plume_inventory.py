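"""Geometry and hydrogen-sulfide inventory of a shelf-wide sulfidic plume.

A plume covering 5500 km2 of shelf with a mean sulfidic thickness of 80 m
and an average H2S concentration of 1.5 µM is converted into a water volume,
a molar inventory and a total mass of H2S (molar mass 34.08 g/mol).
"""

import omzplume as oz

budget = oz.plume_budget(
    area_km2=5500.0,
    thickness_m=80.0,
    mean_concentration_umol_l=1.5,
    molar_mass_g_mol=34.08,
)

print(f"plume volume:     {budget.volume_km3:.0f} km^3")
print(f"H2S inventory:    {budget.inventory_mol:.3g} mol")
print(f"H2S mass:         {budget.mass_tons:.3g} t")
print()
print("The volume is the sulfide-containing water mass; the mass is the "
      "standing stock of toxic H2S a detoxifying microbial community "
      "would have to oxidize.")
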