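"""Simultaneous fit of the biphasic sphere model to decomposed scattering terms.

The fit minimizes a chi-squared built from all three decomposed term vectors
(S, C, R) at once.  When the decomposition supplies the full per-Q 3x3
covariance of the estimates, residuals are whitened with its Cholesky
factor; because the decomposition is a linear sufficient reduction of the
raw multi-energy intensity matrix, this chi-squared equals the chi-squared
against the raw data up to an additive constant, and Delta-chi2 = 1 profile
intervals retain their nominal one-parameter coverage.  With only diagonal
per-term sigmas (e.g. terms loaded from a 7-column text file) the weights
fall back to 1/sigma^2 and intervals are approximate.

Parameter uncertainties come from chi-squared mapping: one parameter is
stepped along a grid, the remaining free parameters are re-optimized at
each step, and the Delta-chi2 <= 1 region is the reported interval.

Derived quantities close the loop to chemistry: ions per peptide, molar
metal concentration per phase, and the two-edge element ratio (separation
factor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .biphasic_model import (
    BiphasicParameters,
    PhaseCompositions,
    model_terms,
)
from .scatter_factors import DispersionTable, formula_unit_density
from .stuhrmann import ScatteringTerms

__all__ = [
    "FitResult",
    "DerivedQuantities",
    "Chi2Profile",
    "fit_biphasic",
    "chi2_map",
    "ions_per_peptide",
    "phase_metal_concentrations",
    "element_ratio",
    "DEFAULT_BOUNDS",
    "PARAM_NAMES",
]

PARAM_NAMES = (
    "norm",
    "phase1_density",
    "phase1_volfrac",
    "phase1_rmoles",
    "phase2_density",
    "phase2_volfrac",
    "mean_radius",
    "rsig",
)

#: default box constraints; generous but physical
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "norm": (0.0, np.inf),
    "phase1_density": (0.8, 2.5),
    "phase1_volfrac": (0.0, 1.0),
    "phase1_rmoles": (0.0, 30.0),
    "phase2_density": (0.8, 3.0),
    "phase2_volfrac": (0.0, 1.0),
    "mean_radius": (10.0, 5000.0),
    "rsig": (0.0, 1.5),
}

HESSIAN_CONDITION_LIMIT = 1e8


@dataclass
class FitResult:
    """Outcome of a biphasic-model fit to decomposed terms."""

    best_params: BiphasicParameters
    chi2: float
    dof: int
    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)
    stderr: dict[str, float] = field(default_factory=dict)
    free_names: tuple[str, ...] = ()
    n_eval: int = 0
    success: bool = True
    message: str = ""
    identifiability_warning: str | None = None

    @property
    def reduced_chi2(self) -> float:
        return self.chi2 / self.dof if self.dof > 0 else np.nan


@dataclass
class DerivedQuantities:
    """Chemically meaningful numbers computed from a converged fit."""

    ions_per_peptide: float
    phase_molarity: dict[str, float]  # in-phase mol/L of the resonant element
    aggregate_molarity: dict[str, float]  # volume-fraction-weighted mol/L


def _slice_terms(terms: ScatteringTerms, mask: np.ndarray) -> ScatteringTerms:
    return ScatteringTerms(
        q_grid=terms.q_grid[mask],
        saxs_term=terms.saxs_term[mask],
        cross_term=terms.cross_term[mask],
        resonant_term=terms.resonant_term[mask],
        term_sigma=None if terms.term_sigma is None else terms.term_sigma[:, mask],
        term_cov=None if terms.term_cov is None else terms.term_cov[mask],
    )


def _whitener(terms: ScatteringTerms) -> np.ndarray | None:
    """Per-Q lower Cholesky factors of the term covariance, if available."""
    if terms.term_cov is not None:
        return np.linalg.cholesky(terms.term_cov)  # (Nq, 3, 3)
    return None


def _residuals_factory(terms, comps, table, fixed_template):
    data = terms.stacked()  # (3, Nq)
    q = terms.q_grid
    chol = _whitener(terms)
    inv_chol = np.linalg.inv(chol) if chol is not None else None
    if chol is None:
        if terms.term_sigma is None:
            raise ValueError("terms carry no uncertainties; cannot weight the fit")
        sig = np.asarray(terms.term_sigma, dtype=float)
        if np.any(sig <= 0):
            raise ValueError("term_sigma must be strictly positive")

    def residuals(lmpars):
        p = fixed_template.replace(**{n: lmpars[n].value for n in PARAM_NAMES})
        model = model_terms(p, comps, table, q).stacked()
        diff = data - model  # (3, Nq)
        if inv_chol is not None:
            # whiten with L^-1 per Q (Sigma = L L^T)
            return np.einsum("qij,jq->iq", inv_chol, diff).ravel()
        return (diff / sig).ravel()

    return residuals


def _make_lmfit_params(initial, bounds, fixed_set):
    lmpars = lmfit.Parameters()
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    for name in PARAM_NAMES:
        lo, hi = bounds[name]
        val = getattr(initial, name)
        if not (lo <= val <= hi):
            raise ValueError(f"initial {name}={val} outside bounds [{lo}, {hi}]")
        lmpars.add(name, value=val, min=lo, max=hi, vary=name not in fixed_set)
    return lmpars


def fit_biphasic(
    terms: ScatteringTerms,
    initial: BiphasicParameters,
    comps: PhaseCompositions,
    table: DispersionTable,
    bounds: dict[str, tuple[float, float]] | None = None,
    fixed: set[str] | frozenset[str] = frozenset(
        {"phase1_density", "phase1_volfrac", "phase2_density", "phase2_volfrac"}
    ),
    n_starts: int = 1,
    seed: int = 0,
    staged: bool = True,
) -> FitResult:
    """Trust-region bounded least-squares fit of the biphasic model.

    Parameters named in ``fixed`` are held at their ``initial`` values.  The
    default fixes the phase densities and volume fractions: the term
    amplitudes determine only two independent combinations (C^2 = S*R), so
    the full 8-parameter set is degenerate — norm trades against volume
    fraction and density.  With geometry (mean_radius, rsig), norm and
    phase1_rmoles free, the problem is well posed: the curve shape pins the
    size distribution, the SAXS amplitude pins norm, and the cross/SAXS
    amplitude ratio pins the resonant ion content.

    The chi-squared landscape ripples in ``mean_radius`` with period
    ~pi/q_max (the sphere form factor oscillates), so a distant start can
    trap in a local minimum.  With ``staged=True`` (default) the fit first
    runs on truncated Q ranges — Q <= 8/R then Q <= 25/R, where the
    landscape is smooth — and uses each stage's optimum to start the next;
    the reported result always comes from the full Q range.  ``n_starts >
    1`` additionally tries that many seeded multiplicative perturbations of
    the (refined) start and keeps the lowest chi-squared; deterministic
    given ``initial`` and ``seed``.

    Raises on non-finite residuals at the initial point and on data that are
    identically zero (non-informative).  A correlation-matrix condition
    number beyond 1e8 attaches an identifiability warning to the result
    instead of failing.
    """
    if not np.any(terms.saxs_term) and not np.any(terms.resonant_term):
        raise ValueError("all-zero scattering terms: nothing to fit")
    fixed = frozenset(fixed)
    unknown = fixed - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter(s) in fixed set: {sorted(unknown)}")
    residuals = _residuals_factory(terms, comps, table, initial)
    lmpars = _make_lmfit_params(initial, bounds, fixed)
    r0 = residuals(lmpars)
    if not np.all(np.isfinite(r0)):
        raise ValueError("non-finite residuals at the initial point")

    eff_bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    nfree = sum(1 for n in PARAM_NAMES if n not in fixed)

    start = initial
    if staged and "mean_radius" not in fixed:
        for qr_max in (8.0, 25.0):
            mask = terms.q_grid <= qr_max / start.mean_radius
            if mask.sum() < max(3 * nfree, 10) or mask.all():
                continue
            sub = _slice_terms(terms, mask)
            sub_res = _residuals_factory(sub, comps, table, initial)
            lmp = _make_lmfit_params(start, bounds, fixed)
            trial = lmfit.Minimizer(sub_res, lmp).least_squares(
                x_scale="jac", ftol=1e-10, xtol=1e-10, gtol=1e-10
            )
            start = initial.replace(
                **{n: trial.params[n].value for n in PARAM_NAMES}
            )

    starts = [start]
    if n_starts > 1:
        rng = np.random.default_rng(seed)
        free = [n for n in PARAM_NAMES if n not in fixed]
        for _ in range(n_starts - 1):
            kw = {}
            for name in free:
                v = getattr(start, name)
                lo, hi = eff_bounds[name]
                base = v if v > 0 else 0.1 * (hi if np.isfinite(hi) else 1.0)
                kw[name] = float(np.clip(base * 2.0 ** rng.uniform(-1, 1), lo, hi))
            if "phase1_volfrac" in kw or "phase2_volfrac" in kw:
                vf1 = kw.get("phase1_volfrac", start.phase1_volfrac)
                vf2 = kw.get("phase2_volfrac", start.phase2_volfrac)
                if vf1 + vf2 > 1:
                    continue
            starts.append(start.replace(**kw))

    out = None
    for s in starts:
        lmp = _make_lmfit_params(s, bounds, fixed)
        mini = lmfit.Minimizer(residuals, lmp, scale_covar=False)
        trial = mini.least_squares(x_scale="jac", ftol=1e-12, xtol=1e-12, gtol=1e-12)
        if out is None or np.sum(np.asarray(trial.residual) ** 2) < np.sum(
            np.asarray(out.residual) ** 2
        ):
            out = trial

    best = initial.replace(**{n: out.params[n].value for n in PARAM_NAMES})
    chi2 = float(np.sum(np.asarray(out.residual) ** 2))
    dof = r0.size - nfree

    stderr = {}
    ident = None
    if out.covar is not None:
        var_names = list(out.var_names)
        for n in var_names:
            i = var_names.index(n)
            stderr[n] = float(np.sqrt(max(out.covar[i, i], 0.0)))
        try:
            d = np.sqrt(np.diag(out.covar))
            corr = out.covar / np.outer(d, d)
            cond = np.linalg.cond(corr)
            if cond > HESSIAN_CONDITION_LIMIT:
                ident = (
                    f"Hessian condition number {cond:.3g} exceeds "
                    f"{HESSIAN_CONDITION_LIMIT:.0e}: parameters are partially "
                    "degenerate (norm vs volume fractions); fix more of them"
                )
                warnings.warn(ident, stacklevel=2)
        except np.linalg.LinAlgError:
            pass

    return FitResult(
        best_params=best,
        chi2=chi2,
        dof=dof,
        stderr=stderr,
        free_names=tuple(n for n in PARAM_NAMES if n not in fixed),
        n_eval=int(out.nfev),
        success=bool(out.success),
        message=str(out.message),
        identifiability_warning=ident,
    )


@dataclass
class Chi2Profile:
    """Chi-squared profile of one parameter with its Delta-chi2=1 interval."""

    param_name: str
    grid: np.ndarray
    chi2: np.ndarray
    chi2_min: float
    interval: tuple[float, float]
    one_sided: bool = False

    def as_table(self) -> np.ndarray:
        return np.column_stack([self.grid, self.chi2])


def _crossings(grid, dchi2, target=1.0):
    """Interpolated parameter values where the profile crosses Delta-chi2=target."""
    xs = []
    for i in range(len(grid) - 1):
        a, b = dchi2[i] - target, dchi2[i + 1] - target
        if a == 0:
            xs.append(grid[i])
        elif a * b < 0:
            xs.append(grid[i] + (grid[i + 1] - grid[i]) * (-a) / (b - a))
    if dchi2[-1] == target:
        xs.append(grid[-1])
    return xs


def chi2_map(
    result: FitResult,
    terms: ScatteringTerms,
    comps: PhaseCompositions,
    table: DispersionTable,
    param_name: str,
    grid: np.ndarray | None = None,
    n_points: int = 41,
    span_stderr: float = 4.0,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> Chi2Profile:
    """Profile chi-squared along one parameter, re-optimizing the others.

    ``grid`` defaults to ``n_points`` values spanning +/- ``span_stderr``
    approximate standard errors around the best fit (clipped to bounds).
    The Delta-chi2 <= 1 region, interpolated between grid points, is the
    one-parameter confidence interval.  If the grid fails to bracket the
    rise on one side, a warning is issued and the interval is one-sided
    (clamped at the grid end).
    """
    if param_name not in result.free_names:
        raise ValueError(f"{param_name!r} was not free in the fit; cannot profile")
    best_val = getattr(result.best_params, param_name)
    eff_bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    lo_b, hi_b = eff_bounds[param_name]
    if grid is None:
        se = result.stderr.get(param_name) or abs(best_val) * 0.1 or 0.1
        grid = np.linspace(
            max(lo_b, best_val - span_stderr * se),
            min(hi_b, best_val + span_stderr * se),
            n_points,
        )
    grid = np.asarray(grid, dtype=float)

    others_fixed = set(PARAM_NAMES) - set(result.free_names)
    fixed_now = others_fixed | {param_name}
    chi2s = np.empty_like(grid)
    # march outward from the best fit on each side, warm-starting every
    # re-optimization from its inward neighbour
    left = [i for i in range(grid.size) if grid[i] <= best_val]
    right = [i for i in range(grid.size) if grid[i] > best_val]
    for side in (left, right):
        start = result.best_params
        for i in sorted(side, key=lambda i: abs(grid[i] - best_val)):
            sub = fit_biphasic(
                terms,
                start.replace(**{param_name: grid[i]}),
                comps,
                table,
                bounds=bounds,
                fixed=fixed_now,
            )
            chi2s[i] = sub.chi2
            start = sub.best_params

    chi2_min = min(float(np.min(chi2s)), result.chi2)
    dchi2 = chi2s - chi2_min
    xs = _crossings(grid, dchi2)
    one_sided = False
    lows = [x for x in xs if x < best_val]
    highs = [x for x in xs if x > best_val]
    lo = max(lows) if lows else grid[0]
    hi = min(highs) if highs else grid[-1]
    if not lows or not highs:
        one_sided = True
        warnings.warn(
            f"chi2 profile for {param_name} does not bracket Delta-chi2=1 on "
            "both sides; interval is one-sided",
            stacklevel=2,
        )
    return Chi2Profile(param_name, grid, chi2s, chi2_min, (float(lo), float(hi)), one_sided)


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def _phase_number_densities(params: BiphasicParameters, comps: PhaseCompositions):
    """Resonant-ion and peptide number densities (1/A^3) inside each phase."""
    from dataclasses import replace as _rep

    pep = _rep(
        comps.peptide.with_resonant_count(params.phase1_rmoles),
        mass_density=params.phase1_density,
    )
    ph2 = _rep(comps.phase2, mass_density=params.phase2_density)
    n_pep = formula_unit_density(pep)
    n_res1 = n_pep * params.phase1_rmoles
    n_res2 = formula_unit_density(ph2) * ph2.formula.get(
        ph2.resonant_element or "", 0.0
    )
    return n_pep, n_res1, n_res2


def ions_per_peptide(result: FitResult, comps: PhaseCompositions) -> float:
    """Total resonant ions per peptide inside the aggregate.

    phase1_rmoles counts the ions bound within the peptide–cation phase; the
    cation-rich phase contributes additional ions that are divided by the
    same peptide inventory:

        N = rmoles + (vf2 * n_res,2) / (vf1 * n_pep,1)
    """
    p = result.best_params
    n_pep, _, n_res2 = _phase_number_densities(p, comps)
    pep_amount = p.phase1_volfrac * n_pep
    if pep_amount <= 0:
        raise ZeroDivisionError("no peptide in the aggregate (vf1 * n_pep = 0)")
    return float(p.phase1_rmoles + p.phase2_volfrac * n_res2 / pep_amount)


#: 1/A^3 -> mol/L
_NUMDENS_TO_MOLAR = 1e27 / 6.02214076e23


def phase_metal_concentrations(
    result: FitResult, comps: PhaseCompositions
) -> DerivedQuantities:
    """Molar concentration of the resonant element in each phase.

    ``phase_molarity`` is the concentration within the phase material;
    ``aggregate_molarity`` scales each by its volume fraction, i.e. the
    contribution to the sphere-interior average — linear in the fitted
    volume fractions.
    """
    p = result.best_params
    _, n_res1, n_res2 = _phase_number_densities(p, comps)
    phase_molarity = {
        "phase1": n_res1 * _NUMDENS_TO_MOLAR,
        "phase2": n_res2 * _NUMDENS_TO_MOLAR,
    }
    aggregate_molarity = {
        "phase1": phase_molarity["phase1"] * p.phase1_volfrac,
        "phase2": phase_molarity["phase2"] * p.phase2_volfrac,
    }
    return DerivedQuantities(
        ions_per_peptide=ions_per_peptide(result, comps),
        phase_molarity=phase_molarity,
        aggregate_molarity=aggregate_molarity,
    )


def element_ratio(
    result_a: FitResult,
    result_b: FitResult,
    comps_a: PhaseCompositions,
    comps_b: PhaseCompositions | None = None,
) -> float:
    """Separation factor: per-peptide ion content of element A over element B.

    Both fits must describe the same sample measured below two different
    absorption edges; each result yields its element's ions-per-peptide and
    the ratio is A/B.  The ratio's uncertainty, when propagated from the two
    chi-squared intervals, treats the two fits as independent.
    """
    comps_b = comps_b if comps_b is not None else comps_a
    n_a = ions_per_peptide(result_a, comps_a)
    n_b = ions_per_peptide(result_b, comps_b)
    if n_b == 0:
        raise ZeroDivisionError("element B has zero ions per peptide")
    return n_a / n_b
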