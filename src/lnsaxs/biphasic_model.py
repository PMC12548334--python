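"""Forward model: biphasic uniform spheres with log-normal polydispersity.

The aggregates are modelled as dilute spheres whose interior is a
homogeneous (interpenetrating, not core–shell) mixture of

1. a peptide–cation phase — peptide formula units each carrying
   ``phase1_rmoles`` resonant lanthanide ions — with volume fraction
   ``phase1_volfrac``,
2. a LnCl3-rich aqueous phase with volume fraction ``phase2_volfrac``,
3. solvent filling the remaining ``1 - vf1 - vf2`` of the sphere.

Two energy-independent contrasts follow: the excess electron density of the
interior over the solvent, ``delta_rho0`` (electrons/A^3), and the resonant
atom number density ``rho_res`` (atoms/A^3).  With the uniform-sphere shape
factor Phi(qR) and the polydispersity average <.> over a log-normal radius
distribution, the three scattering terms share one shape integral:

    S(Q) = norm * (r_e delta_rho0)^2 <V^2 Phi^2>
    C(Q) = norm * r_e^2 delta_rho0 rho_res <V^2 Phi^2>
    R(Q) = norm * (r_e rho_res)^2 <V^2 Phi^2>

so C^2 = S * R identically, and the measurable intensity at energy E is
``I = S + 2 f' C + (f'^2 + f''^2) R``.  ``norm`` is the aggregate number
density (1/cm^3); intensities come out in absolute units (1/cm).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .scatter_factors import (
    R_E_CM,
    DispersionTable,
    MaterialComposition,
    dispersion_at,
    electron_density,
    formula_unit_density,
)
from .stuhrmann import ScatteringTerms

__all__ = [
    "BiphasicParameters",
    "PhaseCompositions",
    "sphere_amplitude",
    "effective_contrasts",
    "model_terms",
    "model_intensity",
    "guinier_radius",
    "default_phase_compositions",
    "PEPTIDE_FORMULA",
]

#: lanthanide-binding-tag peptide, fully deprotonated form
PEPTIDE_FORMULA = "C103H149N23O36"

#: Gauss–Legendre nodes used for the log-normal radius average
_QUAD_NODES = 101
_QUAD_SPAN_SIGMA = 5.0


@dataclass(frozen=True)
class BiphasicParameters:
    """The eight fit parameters of the biphasic sphere model.

    norm            aggregate number density, 1/cm^3
    phase1_density  mass density of the peptide–cation phase, g/cm^3
    phase1_volfrac  volume fraction of phase 1 inside the sphere
    phase1_rmoles   lanthanide ions per peptide in phase 1
    phase2_density  mass density of the LnCl3-rich phase, g/cm^3
    phase2_volfrac  volume fraction of phase 2 inside the sphere
    mean_radius     median of the log-normal radius distribution, Angstrom
    rsig            standard deviation of ln R (0 = monodisperse)
    """

    norm: float
    phase1_density: float
    phase1_volfrac: float
    phase1_rmoles: float
    phase2_density: float
    phase2_volfrac: float
    mean_radius: float
    rsig: float

    def __post_init__(self):
        if self.norm < 0:
            raise ValueError("norm must be >= 0")
        if self.phase1_density <= 0 or self.phase2_density <= 0:
            raise ValueError("phase densities must be > 0")
        if not (0 <= self.phase1_volfrac <= 1) or not (0 <= self.phase2_volfrac <= 1):
            raise ValueError("volume fractions must lie in [0, 1]")
        if self.phase1_volfrac + self.phase2_volfrac > 1 + 1e-12:
            raise ValueError("phase volume fractions must sum to <= 1")
        if self.phase1_rmoles < 0:
            raise ValueError("phase1_rmoles must be >= 0")
        if self.mean_radius <= 0:
            raise ValueError("mean_radius must be > 0")
        if self.rsig < 0:
            raise ValueError("rsig must be >= 0")

    def replace(self, **kw) -> "BiphasicParameters":
        return replace(self, **kw)

    # mapping to the XModFit-style parameter names used in config files
    _XMODFIT = {
        "norm": "norm",
        "phase1_density": "Phase1_Density",
        "phase1_volfrac": "Phase1_volFrac",
        "phase1_rmoles": "Phase1_rmoles",
        "phase2_density": "Phase2_Density",
        "phase2_volfrac": "Phase2_volFrac",
        "mean_radius": "Phase1_R",
        "rsig": "Rsig",
    }

    def to_xmodfit_dict(self) -> dict[str, float]:
        return {ext: getattr(self, f) for f, ext in self._XMODFIT.items()}

    @classmethod
    def from_xmodfit_dict(cls, d: dict) -> "BiphasicParameters":
        inv = {ext: f for f, ext in cls._XMODFIT.items()}
        return cls(**{inv[k]: float(v) for k, v in d.items() if k in inv})


@dataclass(frozen=True)
class PhaseCompositions:
    """Material compositions of the two solute phases and the solvent.

    The peptide formula's resonant-element count is overridden by
    ``phase1_rmoles`` at evaluation time; the solvent must not contain the
    resonant element.
    """

    peptide: MaterialComposition
    phase2: MaterialComposition
    solvent: MaterialComposition

    def __post_init__(self):
        if self.peptide.resonant_element is None:
            raise ValueError("peptide composition must declare the resonant element")
        if self.solvent.resonant_element is not None or any(
            sym == self.peptide.resonant_element for sym in self.solvent.formula
        ):
            raise ValueError("solvent must not contain the resonant element")


def default_phase_compositions(
    element: str = "Tb",
    *,
    phase1_density: float = 1.35,
    phase2_density: float = 1.5,
    phase2_waters: int = 12,
) -> PhaseCompositions:
    """Peptide + LnCl3·nH2O + water compositions for a given lanthanide.

    The hydration number of the salt-rich phase is not strongly constrained
    by scattering (it mostly rescales phase-2 electron density against its
    fitted mass density) and defaults to 12 waters per LnCl3.
    """
    peptide = MaterialComposition(
        PEPTIDE_FORMULA + element + "0", phase1_density, element
    )
    phase2 = MaterialComposition(
        {element: 1.0, "Cl": 3.0, "H": 2.0 * phase2_waters, "O": float(phase2_waters)},
        phase2_density,
        element,
    )
    solvent = MaterialComposition("H2O", 1.0, None)
    return PhaseCompositions(peptide, phase2, solvent)


def sphere_amplitude(q, radius):
    """Uniform-sphere shape factor Phi(x) = 3 (sin x - x cos x) / x^3, x = qR.

    Phi(0) = 1 by the limit; |Phi| <= 1 everywhere.  Evaluated with a series
    expansion for small x to avoid cancellation.
    """
    if np.any(np.asarray(radius) <= 0):
        raise ValueError("radius must be > 0")
    scalar = np.isscalar(q) or np.ndim(q) == 0
    x = np.abs(np.atleast_1d(np.asarray(q, dtype=float)) * float(radius))
    out = np.empty_like(x)
    small = x < 1e-2
    xs = x[small]
    # 3(sin x - x cos x)/x^3 = 1 - x^2/10 + x^4/280 - ...
    out[small] = 1.0 - xs**2 / 10.0 + xs**4 / 280.0
    xl = x[~small]
    out[~small] = 3.0 * (np.sin(xl) - xl * np.cos(xl)) / xl**3
    if scalar:
        return float(out[0])
    return out.reshape(np.shape(q))


def effective_contrasts(
    params: BiphasicParameters,
    comps: PhaseCompositions,
) -> tuple[float, float]:
    """Volume-fraction-weighted (delta_rho0, rho_res) of the sphere interior.

    delta_rho0 (electrons/A^3) is the interior electron density minus the
    solvent's; rho_res (atoms/A^3) is the resonant-element number density.
    Both are energy independent: the resonant atom's full Z sits in
    delta_rho0 and only the f'/f'' part is carried by rho_res downstream.
    """
    vf1, vf2 = params.phase1_volfrac, params.phase2_volfrac
    if vf1 + vf2 > 1 + 1e-12:
        raise ValueError("phase volume fractions sum to more than 1")
    pep = replace(
        comps.peptide.with_resonant_count(params.phase1_rmoles),
        mass_density=params.phase1_density,
    )
    ph2 = replace(comps.phase2, mass_density=params.phase2_density)
    rho_solv = electron_density(comps.solvent)
    delta_rho0 = vf1 * (electron_density(pep) - rho_solv) + vf2 * (
        electron_density(ph2) - rho_solv
    )
    rho_res = vf1 * formula_unit_density(pep) * params.phase1_rmoles + vf2 * (
        formula_unit_density(ph2) * ph2.formula.get(ph2.resonant_element or "", 0.0)
    )
    return float(delta_rho0), float(rho_res)


def _lognormal_nodes(params: BiphasicParameters) -> tuple[np.ndarray, np.ndarray]:
    """Radii and normalized weights of the log-normal quadrature."""
    if params.rsig < 1e-8:
        return np.array([params.mean_radius]), np.array([1.0])
    from numpy.polynomial.legendre import leggauss

    u, w = leggauss(_QUAD_NODES)
    half = _QUAD_SPAN_SIGMA * params.rsig
    t = u * half  # ln(R / median)
    pdf = np.exp(-0.5 * (t / params.rsig) ** 2)
    weights = w * half * pdf
    weights /= weights.sum()  # renormalize the truncated Gaussian mass
    return params.mean_radius * np.exp(t), weights


def _shape_integral(params: BiphasicParameters, q_grid: np.ndarray) -> np.ndarray:
    """<V(R)^2 Phi(qR)^2> over the radius distribution, V in cm^3."""
    radii, weights = _lognormal_nodes(params)
    vol_cm3 = (4.0 / 3.0) * np.pi * radii**3 * 1e-24  # A^3 -> cm^3
    x = np.outer(q_grid, radii)
    phi = sphere_amplitude(x, 1.0)
    return phi**2 @ (weights * vol_cm3**2)


def model_terms(
    params: BiphasicParameters,
    comps: PhaseCompositions,
    table: DispersionTable,
    q_grid: np.ndarray,
) -> ScatteringTerms:
    """Forward-compute the (S, C, R) term vectors in 1/cm.

    All three terms share the polydispersity-averaged shape integral, so the
    output satisfies C^2 = S*R exactly.  ``table`` fixes which element is
    resonant (its f'/f'' enter only at intensity assembly).
    """
    q_grid = np.asarray(q_grid, dtype=float)
    if comps.peptide.resonant_element != table.element:
        raise ValueError("compositions and dispersion table disagree on the element")
    delta_rho0, rho_res = effective_contrasts(params, comps)
    shape = _shape_integral(params, q_grid)  # cm^6
    # contrasts to scattering-length densities in 1/cm^2
    sld0 = delta_rho0 * 1e24 * R_E_CM
    sld_res = rho_res * 1e24 * R_E_CM
    return ScatteringTerms(
        q_grid=q_grid,
        saxs_term=params.norm * sld0**2 * shape,
        cross_term=params.norm * sld0 * sld_res * shape,
        resonant_term=params.norm * sld_res**2 * shape,
    )


def model_intensity(
    params: BiphasicParameters,
    comps: PhaseCompositions,
    table: DispersionTable,
    q_grid: np.ndarray,
    energy: float,
) -> np.ndarray:
    """Absolute intensity I(Q) in 1/cm at one photon energy.

    Assembles ``S + 2 f' C + (f'^2 + f''^2) R`` from :func:`model_terms` and
    the dispersion table at ``energy`` (keV).
    """
    terms = model_terms(params, comps, table, q_grid)
    fp, fpp = dispersion_at(table, energy)
    return (
        terms.saxs_term
        + 2.0 * fp * terms.cross_term
        + (fp**2 + fpp**2) * terms.resonant_term
    )


def guinier_radius(params: BiphasicParameters) -> float:
    """Intensity-weighted radius of gyration in Angstrom.

    Monodisperse limit sqrt(3/5) R; for rsig > 0 the low-Q expansion of the
    averaged intensity gives Rg^2 = (3/5) <R^8>/<R^6> over the log-normal
    distribution (heavier spheres dominate as V^2 ~ R^6).
    """
    radii, weights = _lognormal_nodes(params)
    r6 = weights @ radii**6
    r8 = weights @ radii**8
    return float(np.sqrt(0.6 * r8 / r6))
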