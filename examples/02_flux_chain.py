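"""From a density profile to sulfide and nitrite fluxes across a reaction layer.

Builds a noise-free water column in which H2S rises at +0.22 µM/m and NO2-
falls at -0.53 µM/m between 25 and 29 m, with a density gradient whose
stability (Brunt-Väisälä N^2) yields a turbulent diffusivity of 2e-5 m2/s.
Fick's law then gives the opposing diffusive fluxes, and spreading each flux
over the 4-m overlap layer gives the volumetric turnover rates.
"""

import omzplume as oz

constants = oz.PhysicalConstants()
rho0 = 1026.0
density_slope = (constants.gamma * constants.epsilon / 2e-5) * rho0 / constants.g

profile = oz.simulate_profile(
    oz.ProfileSpec(
        breakpoints={
            "density": [(25.0, rho0), (29.0, rho0 + 4 * density_slope)],
            "h2s": [(25.0, 0.0), (29.0, 0.88)],
            "no2": [(25.0, 2.12), (29.0, 0.0)],
        },
        grid_spacing=0.5,
    )
)

bins = oz.stability_and_diffusivity(profile, constants)
ez = bins.iloc[0]["ez"]
h2s_grad = oz.column_gradient(profile, "h2s", 25.0, 29.0)
no2_grad = oz.column_gradient(profile, "no2", 25.0, 29.0)
h2s_flux = oz.fick_flux(ez, h2s_grad, constants)
no2_flux = oz.fick_flux(ez, no2_grad, constants)

print(f"N^2:                 {bins.iloc[0]['n2']:.3g} s^-2")
print(f"Ez:                  {ez:.3g} m^2 s^-1")
print(f"H2S gradient:        {h2s_grad:+.2f} µM/m  ->  flux {h2s_flux:+.2f} mmol m^-2 d^-1")
print(f"NO2- gradient:       {no2_grad:+.2f} µM/m  ->  flux {no2_flux:+.2f} mmol m^-2 d^-1")
print(f"H2S oxidation rate:  {oz.layer_rate(h2s_flux, 4.0):.0f} nmol l^-1 d^-1 over 4 m")
print(f"NO2- removal rate:   {abs(oz.layer_rate(no2_flux, 4.0)):.0f} nmol N l^-1 d^-1 over 4 m")
print()
print("The upward H2S flux meets a larger downward NO2- flux in the 4-m "
      "overlap layer: nitrite supply is sufficient to oxidize the rising "
      "sulfide (sulfur-driven autotrophic denitrification).")
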