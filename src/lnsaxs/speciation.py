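"""Metal–peptide binding equilibria and small solution-observable conversions.

The lanthanide-binding-tag peptide P chelates a trivalent lanthanide M in a
1:1 complex, P + M <=> PM, with association constant K = [PM]/([P][M]) in
L/mol.  Single-metal speciation has a closed-form quadratic solution; with
several metals competing for one peptide the coupled equilibria are solved
by safeguarded root bracketing on the free-peptide concentration (the total
bound metal is monotone in free peptide, so the residual has exactly one
root).

Also here: the Stokes–Einstein diffusion-to-diameter conversion, Henry's
equation for zeta potential in the thin-double-layer (Smoluchowski) limit,
and Beer–Lambert absorbance-to-concentration — the standard conversions a
solution characterization workflow needs around the binding model.

Concentrations are handled in mol/L throughout.  The shipped default
association constants (:data:`DEFAULT_K_ASSOC`) set the Tb:Lu and Tb:La
affinity ratios to 1.6 and 35 with an absolute scale typical for an
engineered lanthanide-binding tag; they are a documented convenience for
synthetic work, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "BindingSystem",
    "SpeciationState",
    "solve_binding_1to1",
    "titration_curve",
    "solve_competitive",
    "hydrodynamic_diameter",
    "zeta_from_mobility",
    "concentration_from_absorbance",
    "DEFAULT_K_ASSOC",
]

BOLTZMANN = 1.380649e-23  # J/K

#: non-authoritative default association constants (L/mol): the Tb/Lu and
#: Tb/La ratios (1.6 and 35) are the physically meaningful part.
DEFAULT_K_ASSOC = {
    "Tb": 1.8e7,
    "Lu": 1.8e7 / 1.6,
    "La": 1.8e7 / 35.0,
}


@dataclass(frozen=True)
class BindingSystem:
    """Totals and affinities for competitive 1:1 binding.

    metals: list of (label, total mol/L, association constant L/mol).
    """

    peptide_total: float
    metals: tuple[tuple[str, float, float], ...]
    temperature: float = 298.15

    def __post_init__(self):
        if self.peptide_total < 0:
            raise ValueError("peptide_total must be >= 0")
        if not self.metals:
            raise ValueError("at least one metal required")
        object.__setattr__(self, "metals", tuple(tuple(m) for m in self.metals))
        for label, total, k in self.metals:
            if total < 0:
                raise ValueError(f"negative total for {label}")
            if k <= 0:
                raise ValueError(f"association constant for {label} must be > 0")


@dataclass(frozen=True)
class SpeciationState:
    """Equilibrium concentrations (mol/L) of all species."""

    free_peptide: float
    free_metal: dict[str, float] = field(default_factory=dict)
    complexed: dict[str, float] = field(default_factory=dict)

    @property
    def total_complexed(self) -> float:
        return sum(self.complexed.values())


def solve_binding_1to1(
    peptide_total: float, metal_total: float, k_assoc: float, label: str = "M"
) -> SpeciationState:
    """Closed-form 1:1 equilibrium P + M <=> PM.

    [PM] is the smaller root of
    ``K x^2 - (K P0 + K M0 + 1) x + K P0 M0 = 0``; evaluated in the
    numerically stable form that avoids cancellation for strong binding.
    """
    if peptide_total < 0 or metal_total < 0:
        raise ValueError("totals must be >= 0")
    if k_assoc <= 0:
        raise ValueError("association constant must be > 0")
    b = peptide_total + metal_total + 1.0 / k_assoc
    c = peptide_total * metal_total
    # smaller root of x^2 - b x + c, stable form
    disc = np.sqrt(b * b - 4.0 * c)
    complexed = 2.0 * c / (b + disc)
    return SpeciationState(
        free_peptide=peptide_total - complexed,
        free_metal={label: metal_total - complexed},
        complexed={label: complexed},
    )


def titration_curve(
    peptide_total: float,
    k_assoc: float,
    ratio_grid,
    label: str = "M",
) -> pd.DataFrame:
    """Speciation along an added-metal/peptide ratio grid.

    Returns a DataFrame with columns ratio, free_peptide, free_metal,
    complexed, regime — the regime label being 'undersaturated' below a
    metal:peptide ratio of 1 and 'oversaturated' above it (past 1:1
    stoichiometry, excess free ions accumulate and drive aggregation).
    """
    ratios = np.asarray(ratio_grid, dtype=float)
    if np.any(ratios < 0):
        raise ValueError("ratio_grid must be >= 0")
    rows = []
    for r in ratios:
        st = solve_binding_1to1(peptide_total, r * peptide_total, k_assoc, label)
        regime = "undersaturated" if r < 1 else ("stoichiometric" if r == 1 else "oversaturated")
        rows.append(
            (r, st.free_peptide, st.free_metal[label], st.complexed[label], regime)
        )
    return pd.DataFrame(
        rows, columns=["ratio", "free_peptide", "free_metal", "complexed", "regime"]
    )


def solve_competitive(system: BindingSystem, max_iter: int = 200) -> SpeciationState:
    """Coupled competitive 1:1 equilibria for several metals on one peptide.

    With free peptide p, each metal's bound amount is
    ``K_i p M_i / (1 + K_i p)``, so the peptide mass balance

        p + sum_i K_i p M_i / (1 + K_i p) = P0

    has a strictly increasing left side in p and a unique root in
    ``[0, P0]``, found by Brent bracketing.  Mass balances of the returned
    state hold to better than 1e-12 relative.
    """
    p0 = system.peptide_total
    ks = np.array([k for _, _, k in system.metals])
    totals = np.array([t for _, t, _ in system.metals])
    labels = [l for l, _, _ in system.metals]

    if p0 == 0:
        return SpeciationState(0.0, dict(zip(labels, totals)), {l: 0.0 for l in labels})

    def residual(p):
        return p + np.sum(ks * p * totals / (1.0 + ks * p)) - p0

    if residual(p0) <= 0:  # no metal: root at p0
        p_free = p0
    else:
        p_free = brentq(residual, 0.0, p0, xtol=1e-300, rtol=1e-15, maxiter=max_iter)
    bound = ks * p_free * totals / (1.0 + ks * p_free)
    state = SpeciationState(
        free_peptide=float(p_free),
        free_metal={l: float(t - b) for l, t, b in zip(labels, totals, bound)},
        complexed={l: float(b) for l, b in zip(labels, bound)},
    )
    # verify mass balances before returning
    scale = max(p0, 1e-300)
    if abs(state.free_peptide + state.total_complexed - p0) > 1e-10 * scale:
        raise RuntimeError("competitive solver failed peptide mass balance")
    return state


def hydrodynamic_diameter(
    diffusion_coeff: float, temperature: float = 298.15, viscosity: float = 8.9e-4
) -> float:
    """Stokes–Einstein hydrodynamic diameter in nm.

    ``d = k_B T / (3 pi eta D)`` with D in m^2/s, T in K, eta in Pa*s.
    """
    if diffusion_coeff <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("diffusion coefficient, temperature, viscosity must be > 0")
    d_m = BOLTZMANN * temperature / (3.0 * np.pi * viscosity * diffusion_coeff)
    return d_m * 1e9


def zeta_from_mobility(
    mobility: float,
    viscosity: float = 8.9e-4,
    permittivity: float = 6.95e-10,
    henry_factor: float = 1.5,
) -> float:
    """Zeta potential (mV) from electrophoretic mobility via Henry's equation.

    ``zeta = 3 mu eta / (2 eps F(ka))``; the default Henry factor
    F(ka) = 1.5 is the thin-double-layer Smoluchowski limit, where the
    expression reduces to ``mu eta / eps``.  mobility in m^2/(V s),
    viscosity in Pa*s, permittivity in F/m.
    """
    if viscosity <= 0 or permittivity <= 0 or henry_factor <= 0:
        raise ValueError("viscosity, permittivity, henry_factor must be > 0")
    zeta_v = 3.0 * mobility * viscosity / (2.0 * permittivity * henry_factor)
    return zeta_v * 1e3


def concentration_from_absorbance(
    absorbance: float, path_cm: float = 1.0, epsilon: float = 8250.0
) -> float:
    """Beer–Lambert concentration (mol/L) from absorbance.

    Default molar extinction coefficient 8250 1/(M cm) is the 280 nm value
    for the single-tryptophan lanthanide-binding-tag peptide.
    """
    if path_cm <= 0 or epsilon <= 0:
        raise ValueError("path length and extinction coefficient must be > 0")
    if absorbance < 0:
        raise ValueError("absorbance must be >= 0")
    return absorbance / (epsilon * path_cm)
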