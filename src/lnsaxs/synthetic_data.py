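"""Synthetic multi-energy anomalous SAXS datasets with known ground truth.

Emulates the measurement protocol the analysis modules expect: a 20-energy
scan in the 100 eV window just below a lanthanide L3 edge (Tb 7.514 keV or
Lu 9.244 keV), absolute-scale 1-D profiles on a logarithmic Q grid, and
Gaussian counting-statistics-style noise ``sigma = rel * I + floor``
appropriate for reduced, background-subtracted data.  Energies are spaced
uniformly in f' (denser in energy near the edge), which maximizes the
leverage of the anomalous signal for a fixed number of exposures.

Every random draw flows through one ``numpy`` generator seeded by the
config, so datasets are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .biphasic_model import (
    BiphasicParameters,
    PhaseCompositions,
    default_phase_compositions,
    model_terms,
)
from .scatter_factors import DispersionTable, dispersion_at, lu_l3_table, tb_l3_table
from .speciation import titration_curve
from .stuhrmann import EnergyScanDataset, reconstruct_intensity

__all__ = [
    "SyntheticConfig",
    "default_truth",
    "default_q_grid",
    "edge_scan_energies",
    "generate_asaxs",
    "generate_two_edge_sample",
    "generate_titration_fixture",
    "two_edge_configs",
]


def default_truth() -> BiphasicParameters:
    """Ground-truth parameters of the default synthetic sample.

    An 800 uM peptide / few-mM lanthanide condensate: ~2.25 ions per peptide
    bound in the peptide phase, a trace cation-rich phase bringing the total
    to ~2.4, 400 A median radius with moderate polydispersity, and an
    aggregate number density giving forward scattering of order 1 1/cm.
    """
    return BiphasicParameters(
        norm=1.0e12,
        phase1_density=1.35,
        phase1_volfrac=0.08,
        phase1_rmoles=2.25,
        phase2_density=1.5,
        phase2_volfrac=0.002,
        mean_radius=400.0,
        rsig=0.2,
    )


def default_q_grid(
    q_min: float = 0.003, q_max: float = 0.3, n: int = 200
) -> np.ndarray:
    """Logarithmic Q grid (1/A) typical of a 3.6 m pinhole SAXS geometry."""
    return np.geomspace(q_min, q_max, n)


def edge_scan_energies(
    table: DispersionTable,
    n_energies: int = 20,
    span_kev: float = 0.100,
    min_gap_kev: float = 0.002,
) -> np.ndarray:
    """Scan energies below the edge, spaced uniformly in f'.

    Covers ``[edge - span, edge - min_gap]`` with points whose f' values are
    equally spaced, so the set is denser in energy close to the edge where
    f' varies fastest.
    """
    e_hi = min(table.edge_energy - min_gap_kev, table.energy_range[1])
    e_lo = max(table.edge_energy - span_kev, table.energy_range[0])
    if not e_lo < e_hi:
        raise ValueError("requested scan window lies outside the dispersion table")
    dense = np.linspace(e_lo, e_hi, 4001)
    fp, _ = dispersion_at(table, dense)
    targets = np.linspace(fp[0], fp[-1], n_energies)
    # f' is monotone decreasing toward the edge for these tables
    energies = np.interp(targets, fp[::-1], dense[::-1])
    return np.sort(energies)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full specification of one synthetic ASAXS measurement."""

    truth: BiphasicParameters = field(default_factory=default_truth)
    comps: PhaseCompositions | None = None  # default: Tb peptide system
    table: DispersionTable | None = None  # default: synthetic Tb L3 table
    element: str = "Tb"
    n_energies: int = 20
    span_kev: float = 0.100
    q_grid: np.ndarray = field(default_factory=default_q_grid)
    noise_rel: float = 0.01
    noise_floor: float = 1e-5  # 1/cm
    seed: int = 0

    def __post_init__(self):
        if self.noise_rel < 0 or self.noise_floor < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.n_energies < 3:
            raise ValueError("need at least 3 energies")

    def resolve(self) -> tuple[PhaseCompositions, DispersionTable]:
        table = self.table
        if table is None:
            table = {"Tb": tb_l3_table, "Lu": lu_l3_table}[self.element]()
        comps = self.comps
        if comps is None:
            comps = default_phase_compositions(
                table.element,
                phase1_density=self.truth.phase1_density,
                phase2_density=self.truth.phase2_density,
            )
        return comps, table


def generate_asaxs(config: SyntheticConfig) -> EnergyScanDataset:
    """Forward-model intensities plus seeded Gaussian noise.

    ``sigma = noise_rel * I_true + noise_floor`` is both the perturbation
    scale and the uncertainty reported in the dataset (the noise model is
    told truthfully to the analysis).  ``noise_rel = 0`` with zero floor
    returns the exact forward model.
    """
    comps, table = config.resolve()
    energies = edge_scan_energies(table, config.n_energies, config.span_kev)
    if np.any(energies >= table.edge_energy):
        raise ValueError("scan energies must stay below the absorption edge")
    q = np.asarray(config.q_grid, dtype=float)
    # one terms evaluation serves all energies (I = S + 2f'C + (f'^2+f''^2)R)
    terms = model_terms(config.truth, comps, table, q)
    fp, fpp = dispersion_at(table, energies)
    intensity = reconstruct_intensity(terms, fp, fpp)
    sigma = config.noise_rel * np.abs(intensity) + config.noise_floor
    rng = np.random.default_rng(config.seed)
    noisy = intensity + rng.standard_normal(intensity.shape) * sigma
    if np.all(sigma == 0):
        sigma = np.full_like(intensity, 1e-30)  # exact data; nominal weights
    return EnergyScanDataset(
        q_grid=q,
        energies=energies,
        intensity=noisy,
        sigma=sigma,
        resonant_element=table.element,
        dispersion=table,
    )


def generate_two_edge_sample(
    config_a: SyntheticConfig,
    config_b: SyntheticConfig,
) -> tuple[EnergyScanDataset, EnergyScanDataset]:
    """One physical sample measured below two different absorption edges.

    The two configs must share the geometric truth (radius, width, volume
    fractions, norm); per-element ion numbers (phase1_rmoles) may differ.
    Seeds should differ if independent noise realizations are wanted.
    """
    ta, tb = config_a.truth, config_b.truth
    for name in ("norm", "phase1_volfrac", "phase2_volfrac", "mean_radius", "rsig"):
        if getattr(ta, name) != getattr(tb, name):
            raise ValueError(f"two-edge sample: geometric truth differs in {name}")
    qa = np.asarray(config_a.q_grid, dtype=float)
    qb = np.asarray(config_b.q_grid, dtype=float)
    if qa.shape != qb.shape or not np.allclose(qa, qb):
        raise ValueError("two-edge sample: q_grids must match")
    return generate_asaxs(config_a), generate_asaxs(config_b)


def generate_titration_fixture(
    k_assoc: float,
    peptide_total: float,
    ratios,
    noise_rel: float = 0.0,
    seed: int = 0,
):
    """Speciation titration table with optional multiplicative noise.

    Returns the exact :func:`lnsaxs.speciation.titration_curve` table with
    the concentration columns perturbed by ``(1 + noise_rel * z)``,
    z ~ N(0,1), seeded.  Used to exercise curve-reading utilities and regime
    labelling against a known truth.
    """
    tab = titration_curve(peptide_total, k_assoc, ratios)
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        for col in ("free_peptide", "free_metal", "complexed"):
            tab[col] = tab[col] * (
                1.0 + noise_rel * rng.standard_normal(len(tab))
            )
    return tab


def two_edge_configs(
    n_tb: float = 1.7,
    n_lu: float = 1.0,
    seed: int = 0,
    noise_rel: float = 0.01,
    truth: BiphasicParameters | None = None,
) -> tuple[SyntheticConfig, SyntheticConfig]:
    """Convenience pair of configs for a Tb/Lu two-edge selectivity study.

    The same geometry is measured below both edges; only the per-peptide ion
    numbers differ.  The cation-rich phase is switched off so the element
    ratio equals n_tb/n_lu by construction.
    """
    base = truth if truth is not None else default_truth()
    base = replace(base, phase2_volfrac=0.0)
    cfg_tb = SyntheticConfig(
        truth=replace(base, phase1_rmoles=n_tb),
        element="Tb",
        seed=seed,
        noise_rel=noise_rel,
    )
    cfg_lu = SyntheticConfig(
        truth=replace(base, phase1_rmoles=n_lu),
        element="Lu",
        seed=seed + 1,
        noise_rel=noise_rel,
    )
    return cfg_tb, cfg_lu
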