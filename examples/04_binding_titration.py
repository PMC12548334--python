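"""Binding speciation: titration of the lanthanide-binding peptide with Tb.

Reproduces the free-peptide / free-metal picture behind aggregate
formation: below a 1:1 metal:peptide ratio almost all added Tb is chelated
(undersaturated); above it, free Tb accumulates and neutralizes the
complexes' negative charge, which is what drives condensation.
"""

import numpy as np

from lnsaxs.speciation import DEFAULT_K_ASSOC, solve_competitive, BindingSystem, titration_curve

P0 = 100e-6  # 100 uM peptide
tab = titration_curve(P0, DEFAULT_K_ASSOC["Tb"], np.array([0.0, 0.5, 0.9, 1.0, 1.1, 2.0, 5.0]))
shown = tab.copy()
for col in ("free_peptide", "free_metal", "complexed"):
    shown[col] = shown[col] * 1e6  # mol/L -> uM for display
print(shown.to_string(index=False, float_format=lambda x: f"{x:8.3f}"))
print("(concentrations in uM)")

# competitive selectivity in the dilute-excess regime
k = DEFAULT_K_ASSOC
sys_ = BindingSystem(1e-10, (("Tb", 1e-9, k["Tb"]), ("La", 1e-9, k["La"])))
st = solve_competitive(sys_)
print(f"\ndilute 10x excess Tb+La: bound Tb / bound La = "
      f"{st.complexed['Tb'] / st.complexed['La']:.2f} "
      f"(affinity ratio {k['Tb'] / k['La']:.0f})")
# in the dilute monomeric regime selectivity follows the association
# constants; in the aggregated regime secondary binding erodes it
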