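"""Small solution-characterization conversions around the binding model."""

from lnsaxs.speciation import (
    concentration_from_absorbance,
    hydrodynamic_diameter,
    zeta_from_mobility,
)

# Stokes-Einstein: diffusion coefficient -> hydrodynamic diameter
d_nm = hydrodynamic_diameter(5.34e-10, temperature=298.15, viscosity=8.9e-4)
print(f"D = 5.34e-10 m^2/s  ->  d_H = {d_nm:.2f} nm  (monomeric complex scale)")

# Henry / Smoluchowski: electrophoretic mobility -> zeta potential
zeta = zeta_from_mobility(1e-8, viscosity=8.9e-4, permittivity=6.95e-10)
print(f"mu = 1e-8 m^2/(V s) ->  zeta = {zeta:+.1f} mV  (thin-double-layer limit)")

# Beer-Lambert at 280 nm with the peptide's extinction coefficient
c = concentration_from_absorbance(0.065, path_cm=1.0, epsilon=8250.0)
print(f"A280 = 0.065        ->  c = {c * 1e6:.2f} uM  (vs 8 uM nominal, within 2%)")
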