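"""Two-edge selectivity: separation factor from independent Tb and Lu fits.

One sample containing both elements is measured below the Tb L3 edge
(7.514 keV) and the Lu L3 edge (9.244 keV); each scan isolates its own
element's content.  The ratio of per-peptide ion numbers is the separation
factor of the peptide for Tb over Lu.
"""

import warnings

from lnsaxs.studies import two_edge_ratio_study

warnings.filterwarnings("ignore")

ratio = two_edge_ratio_study(n_a=1.7, n_b=1.0, seed=11, noise_rel=0.01)
print(f"constructed Tb:Lu per-peptide ratio = 1.7")
print(f"recovered separation factor        = {ratio:.3f}")
# agreement within a few percent shows two independent single-edge fits
# reproduce a relative elemental composition without any cross-calibration
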