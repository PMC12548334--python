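"""Anomalous dispersion tables and composition-to-scattering-density arithmetic.

X-ray scattering from an atom near one of its absorption edges carries an
energy-dependent correction to the atomic form factor,

    f(E) = Z + f'(E) + i f''(E),

where ``f'`` (real, strongly negative just below the edge) and ``f''``
(imaginary, non-negative) are the anomalous dispersion corrections.  This
module provides

* :class:`DispersionTable` — tabulated ``(E, f', f'')`` for one element near
  one edge, with linear interpolation and a hard no-extrapolation policy;
* :class:`MaterialComposition` — a chemical formula plus mass density, from
  which electron densities (electrons/A^3) and resonant-atom number densities
  (atoms/A^3) are derived.

Densities stay in electrons/A^3 throughout; the classical electron radius is
applied only when intensities are assembled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "DispersionTable",
    "MaterialComposition",
    "dispersion_at",
    "electron_density",
    "resonant_split_density",
    "parse_formula",
    "atomic_number",
    "atomic_weight",
    "molar_mass",
    "electrons_per_formula",
    "synthetic_edge_table",
    "tb_l3_table",
    "lu_l3_table",
    "TB_L3_EDGE_KEV",
    "LU_L3_EDGE_KEV",
]

TB_L3_EDGE_KEV = 7.514
LU_L3_EDGE_KEV = 9.244

AVOGADRO = 6.02214076e23  # 1/mol
#: classical electron radius in Angstrom (Thomson scattering length)
R_E_ANGSTROM = 2.8179403262e-5
R_E_CM = R_E_ANGSTROM * 1e-8

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


class UnknownElementError(ValueError):
    """Raised for element symbols gemmi does not recognise."""


class DispersionRangeError(ValueError):
    """Raised when an energy falls outside a dispersion table's support."""


def atomic_number(symbol: str) -> int:
    el = gemmi.Element(symbol)
    if el.atomic_number == 0:
        raise UnknownElementError(f"unknown element symbol {symbol!r}")
    return el.atomic_number


def atomic_weight(symbol: str) -> float:
    el = gemmi.Element(symbol)
    if el.atomic_number == 0:
        raise UnknownElementError(f"unknown element symbol {symbol!r}")
    return el.weight


def parse_formula(formula: str) -> dict[str, float]:
    """Parse ``'C103H149N23O36Tb2.25'`` into ``{symbol: count}``.

    Counts may be non-integer (fractional site occupancy of the resonant
    element).  An omitted count means 1.
    """
    if not formula or not formula.strip():
        raise ValueError("empty chemical formula")
    pos = 0
    counts: dict[str, float] = {}
    for m in _FORMULA_TOKEN.finditer(formula.strip()):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
        if not m.group(0):
            break
        pos = m.end()
        sym = m.group(1)
        atomic_number(sym)  # validates the symbol
        n = float(m.group(2)) if m.group(2) else 1.0
        counts[sym] = counts.get(sym, 0.0) + n
    if pos != len(formula.strip()):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


@dataclass(frozen=True)
class DispersionTable:
    """Tabulated anomalous corrections f'(E), f''(E) for one element.

    Parameters
    ----------
    element:
        Element symbol the table belongs to.
    edge_energy:
        Absorption-edge energy in keV (metadata; rows normally sit below it).
    rows:
        ``(Ne, 3)`` array of ``(energy_keV, f_prime, f_doubleprime)``,
        strictly increasing in energy, with ``f'' >= 0``.
    """

    element: str
    edge_energy: float
    rows: np.ndarray

    def __post_init__(self):
        rows = np.asarray(self.rows, dtype=float)
        if rows.ndim != 2 or rows.shape[1] != 3 or rows.shape[0] < 2:
            raise ValueError("dispersion table needs >= 2 rows of (E, f', f'')")
        if np.any(np.diff(rows[:, 0]) <= 0):
            raise ValueError("dispersion table energies must be strictly increasing")
        if np.any(rows[:, 2] < 0):
            raise ValueError("f'' must be non-negative")
        atomic_number(self.element)
        object.__setattr__(self, "rows", rows)

    @property
    def energies(self) -> np.ndarray:
        return self.rows[:, 0]

    @property
    def energy_range(self) -> tuple[float, float]:
        return float(self.rows[0, 0]), float(self.rows[-1, 0])

    @classmethod
    def from_file(cls, path, element: str, edge_energy: float) -> "DispersionTable":
        """Read a whitespace-delimited 3-column table (``#`` comments allowed)."""
        rows = np.loadtxt(path, comments="#", ndmin=2)
        if rows.shape[1] < 3:
            raise ValueError(f"{path}: expected 3 columns (energy_keV f' f'')")
        return cls(element=element, edge_energy=edge_energy, rows=rows[:, :3])

    def to_file(self, path) -> None:
        header = (
            f"dispersion table for {self.element}, edge {self.edge_energy} keV\n"
            "energy_keV  f_prime(e)  f_doubleprime(e)"
        )
        np.savetxt(path, self.rows, header=header, fmt="%.8g")


def dispersion_at(table: DispersionTable, energy) -> tuple[float, float]:
    """Linearly interpolated ``(f', f'')`` at ``energy`` (keV).

    Exact at tabulated points.  Energies outside the tabulated range raise
    :class:`DispersionRangeError`: dispersion curves are steep near an edge
    and extrapolating them is unsafe.
    """
    e = np.asarray(energy, dtype=float)
    lo, hi = table.energy_range
    if np.any(e < lo) or np.any(e > hi):
        raise DispersionRangeError(
            f"energy {energy} keV outside table range [{lo}, {hi}] keV "
            f"for {table.element}"
        )
    fp = np.interp(e, table.rows[:, 0], table.rows[:, 1])
    fpp = np.interp(e, table.rows[:, 0], table.rows[:, 2])
    if e.ndim == 0:
        return float(fp), float(fpp)
    return fp, fpp


@dataclass(frozen=True)
class MaterialComposition:
    """A material defined by a chemical formula and a mass density.

    ``formula`` maps element symbol to stoichiometric count per formula unit;
    counts may be non-integer.  ``resonant_element``, if set, marks which
    element's anomalous corrections apply.
    """

    formula: dict[str, float] = field(default_factory=dict)
    mass_density: float = 1.0  # g/cm^3
    resonant_element: str | None = None

    def __post_init__(self):
        if isinstance(self.formula, str):
            object.__setattr__(self, "formula", parse_formula(self.formula))
        if not self.formula:
            raise ValueError("empty chemical formula")
        for sym, n in self.formula.items():
            atomic_number(sym)
            if n < 0:
                raise ValueError(f"negative count for {sym}")
        if self.mass_density <= 0:
            raise ValueError("mass_density must be > 0")
        if self.resonant_element is not None:
            atomic_number(self.resonant_element)

    def with_resonant_count(self, count: float) -> "MaterialComposition":
        """Copy with the resonant element's stoichiometry replaced."""
        if self.resonant_element is None:
            raise ValueError("composition has no resonant element")
        f = dict(self.formula)
        f[self.resonant_element] = float(count)
        return MaterialComposition(f, self.mass_density, self.resonant_element)


def molar_mass(comp: MaterialComposition) -> float:
    """Molar mass of one formula unit in g/mol."""
    return sum(n * atomic_weight(sym) for sym, n in comp.formula.items())


def electrons_per_formula(comp: MaterialComposition) -> float:
    return sum(n * atomic_number(sym) for sym, n in comp.formula.items())


def formula_unit_density(comp: MaterialComposition) -> float:
    """Number density of formula units in 1/A^3."""
    return comp.mass_density * AVOGADRO / molar_mass(comp) * 1e-24


def electron_density(comp: MaterialComposition) -> float:
    """Energy-independent electron density in electrons/A^3.

    Full Z of every atom, including the resonant one, is counted here; the
    anomalous part is carried separately by :func:`resonant_split_density`.
    """
    return formula_unit_density(comp) * electrons_per_formula(comp)


def resonant_split_density(
    comp: MaterialComposition, table: DispersionTable, energy: float
) -> tuple[float, float, float, float]:
    """Split the effective scattering density into resonant and non-resonant parts.

    Returns ``(nonresonant_density, resonant_number_density, f', f'')`` where
    the non-resonant part (electrons/A^3) uses full Z of all atoms and the
    resonant number density (atoms/A^3) multiplies ``f' + i f''`` at
    ``energy``, so the total effective density is::

        rho(E) = nonresonant + resonant_number_density * (f'(E) + i f''(E))
    """
    if comp.resonant_element is None:
        raise ValueError("composition declares no resonant element")
    if comp.resonant_element != table.element:
        raise ValueError(
            f"composition resonant element {comp.resonant_element!r} does not "
            f"match dispersion table element {table.element!r}"
        )
    fp, fpp = dispersion_at(table, energy)
    n_res = formula_unit_density(comp) * comp.formula.get(comp.resonant_element, 0.0)
    return electron_density(comp), n_res, fp, fpp


# ---------------------------------------------------------------------------
# Synthetic edge tables
# ---------------------------------------------------------------------------

def synthetic_edge_table(
    element: str,
    edge_kev: float,
    *,
    f_prime_far: float = -6.0,
    amplitude: float = 2.2,
    f_dp_far: float = 3.3,
    f_dp_slope: float = 0.5,
    span_ev: float = 300.0,
    closest_ev: float = 1.0,
    n_rows: int = 80,
) -> DispersionTable:
    """Synthetic dispersion table for the region below an L3 edge.

    This is NOT a measured or Cromer–Liberman tabulation: it is a smooth
    stand-in with the right qualitative shape, for synthetic-data work when no
    tabulation file is supplied.  Below an edge ``f'`` diverges logarithmically,

        f'(E) = f_prime_far - amplitude * ln(span_ev / (E_edge - E)),

    reaching roughly -6 electrons 300 eV below the edge and about -19
    electrons 1 eV below it (typical magnitudes for a lanthanide L3 edge),
    while ``f''`` drifts gently upward toward the edge.  Rows are log-spaced
    in distance from the edge so interpolation stays accurate where the curve
    is steep.  Real analyses should load a beamline or tabulated file via
    :meth:`DispersionTable.from_file`.
    """
    d_ev = np.geomspace(closest_ev, span_ev, n_rows)[::-1]  # distance below edge
    e_kev = edge_kev - d_ev * 1e-3
    f_prime = f_prime_far - amplitude * np.log(span_ev / d_ev)
    f_dp = f_dp_far + f_dp_slope * (1.0 - d_ev / span_ev)
    return DispersionTable(element, edge_kev, np.column_stack([e_kev, f_prime, f_dp]))


def tb_l3_table() -> DispersionTable:
    """Synthetic f'/f'' table for Tb below its L3 edge (7.514 keV)."""
    return synthetic_edge_table("Tb", TB_L3_EDGE_KEV)


def lu_l3_table() -> DispersionTable:
    """Synthetic f'/f'' table for Lu below its L3 edge (9.244 keV)."""
    return synthetic_edge_table("Lu", LU_L3_EDGE_KEV, f_dp_far=3.6)
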