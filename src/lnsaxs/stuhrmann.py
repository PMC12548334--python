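"""Stuhrmann decomposition of multi-energy SAXS intensities.

A scattering intensity measured at several photon energies below the
absorption edge of a resonant element can be written per momentum transfer Q
as

    I(Q, E) = S(Q) + 2 f'(E) C(Q) + (f'(E)^2 + f''(E)^2) R(Q)

with S the energy-independent SAXS term, C the cross term (linear in the
anomalous correction f') and R the resonant term (the scattering of the
resonant element alone).  With measurements at Ne >= 3 energies this is an
overdetermined linear system per Q, solved here by weighted least squares
with weights 1/sigma^2.

The three terms are amplitudes of one underlying pair of density profiles,
so they obey a Cauchy–Schwarz inequality C^2 <= S * R — with equality when
the resonant element shares the spatial profile of the non-resonant
contrast.  :func:`validate_cauchy_schwarz` checks estimated terms against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scatter_factors import DispersionTable, dispersion_at

__all__ = [
    "EnergyScanDataset",
    "ScatteringTerms",
    "DegenerateDesignError",
    "decompose",
    "design_matrix",
    "validate_cauchy_schwarz",
    "linearity_diagnostic",
    "reconstruct_intensity",
]

#: condition number above which the energy design is declared degenerate
CONDITION_LIMIT = 1e8


class DegenerateDesignError(ValueError):
    """The set of measurement energies cannot separate S, C and R."""


@dataclass
class EnergyScanDataset:
    """A multi-energy SAXS measurement on a common Q grid.

    intensity and sigma are (Ne, Nq) matrices in absolute units (1/cm);
    q_grid is ascending in 1/Angstrom; energies in keV, all below the
    resonant element's edge.
    """

    q_grid: np.ndarray
    energies: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    resonant_element: str
    dispersion: DispersionTable

    def __post_init__(self):
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        nq, ne = self.q_grid.size, self.energies.size
        if np.any(self.q_grid <= 0) or np.any(np.diff(self.q_grid) <= 0):
            raise ValueError("q_grid must be positive and strictly ascending")
        if self.intensity.shape != (ne, nq) or self.sigma.shape != (ne, nq):
            raise ValueError(
                f"intensity/sigma must have shape (Ne, Nq) = ({ne}, {nq})"
            )
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")
        if self.resonant_element != self.dispersion.element:
            raise ValueError("dataset resonant element does not match dispersion table")
        if np.any(self.energies >= self.dispersion.edge_energy):
            raise ValueError("all energies must lie below the absorption edge")

    @property
    def n_energies(self) -> int:
        return self.energies.size

    @property
    def n_q(self) -> int:
        return self.q_grid.size

    def anomalous_factors(self) -> tuple[np.ndarray, np.ndarray]:
        fp, fpp = dispersion_at(self.dispersion, self.energies)
        return np.atleast_1d(fp), np.atleast_1d(fpp)


@dataclass
class ScatteringTerms:
    """Per-Q (S, C, R) triple, optionally with uncertainties and covariance.

    term_sigma is a (3, Nq) array of 1-sigma uncertainties on (S, C, R);
    term_cov, when present, is the full (Nq, 3, 3) covariance from the
    weighted least-squares decomposition (the three estimates at one Q are
    strongly correlated, and downstream fits should whiten with it).
    """

    q_grid: np.ndarray
    saxs_term: np.ndarray
    cross_term: np.ndarray
    resonant_term: np.ndarray
    term_sigma: np.ndarray | None = None
    term_cov: np.ndarray | None = None

    def __post_init__(self):
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        self.saxs_term = np.asarray(self.saxs_term, dtype=float)
        self.cross_term = np.asarray(self.cross_term, dtype=float)
        self.resonant_term = np.asarray(self.resonant_term, dtype=float)
        nq = self.q_grid.size
        for v in (self.saxs_term, self.cross_term, self.resonant_term):
            if v.shape != (nq,):
                raise ValueError("term vectors must match q_grid length")

    def stacked(self) -> np.ndarray:
        """(3, Nq) array in (S, C, R) order."""
        return np.vstack([self.saxs_term, self.cross_term, self.resonant_term])


def design_matrix(f_prime: np.ndarray, f_doubleprime: np.ndarray) -> np.ndarray:
    """(Ne, 3) design [1, 2 f', f'^2 + f''^2] of the three-term model."""
    fp = np.asarray(f_prime, dtype=float)
    fpp = np.asarray(f_doubleprime, dtype=float)
    return np.column_stack([np.ones_like(fp), 2.0 * fp, fp**2 + fpp**2])


def _check_design(a: np.ndarray) -> None:
    # scale columns to comparable magnitude before conditioning: the raw
    # columns differ by ~f'^2 in size, which is not the degeneracy of interest
    norms = np.linalg.norm(a, axis=0)
    if np.any(norms == 0):
        raise DegenerateDesignError("design matrix has a zero column")
    cond = np.linalg.cond(a / norms)
    if cond > CONDITION_LIMIT:
        raise DegenerateDesignError(
            f"energy design matrix is degenerate (condition number {cond:.3g} "
            f"> {CONDITION_LIMIT:.0e}); energies must span distinct f' values"
        )


def decompose(dataset: EnergyScanDataset) -> ScatteringTerms:
    """Weighted least-squares Stuhrmann decomposition, independently per Q.

    Solves, at every Q, the linear model
    ``I(E) = S + 2 f'(E) C + (f'(E)^2 + f''(E)^2) R`` with weights
    ``1/sigma^2``.  Returns the three term vectors with propagated
    uncertainties and the full per-Q covariance.

    Raises
    ------
    DegenerateDesignError
        If fewer than 3 energies are given or all energies share (nearly)
        one f' value so S, C, R cannot be separated.
    """
    if dataset.n_energies < 3:
        raise DegenerateDesignError("need at least 3 energies to decompose")
    fp, fpp = dataset.anomalous_factors()
    a = design_matrix(fp, fpp)  # (Ne, 3)
    _check_design(a)

    w = 1.0 / dataset.sigma**2  # (Ne, Nq)
    wq = w.T  # (Nq, Ne)
    # normal equations per Q: M x = b with M = A^T W A, b = A^T W y
    m = np.einsum("qe,ei,ej->qij", wq, a, a)
    b = np.einsum("qe,ei,qe->qi", wq, a, dataset.intensity.T)
    try:
        terms = np.linalg.solve(m, b[..., None])[..., 0]  # (Nq, 3)
        cov = np.linalg.inv(m)  # (Nq, 3, 3)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise DegenerateDesignError(f"singular normal equations: {exc}") from exc
    sigma = np.sqrt(np.einsum("qii->qi", cov)).T  # (3, Nq)
    return ScatteringTerms(
        q_grid=dataset.q_grid,
        saxs_term=terms[:, 0],
        cross_term=terms[:, 1],
        resonant_term=terms[:, 2],
        term_sigma=sigma,
        term_cov=cov,
    )


def decompose_nonnegative(dataset: EnergyScanDataset) -> ScatteringTerms:
    """Variant of :func:`decompose` constraining S >= 0 and R >= 0.

    Solved per Q by non-negative least squares on the weighted system with
    the cross term left free (split into +/- parts).  No covariance is
    attached: at an active constraint the Gaussian error model does not
    apply.  The unconstrained :func:`decompose` is the default; estimates
    that go negative from noise are information, and clipping them biases
    downstream fits.
    """
    from scipy.optimize import nnls

    if dataset.n_energies < 3:
        raise DegenerateDesignError("need at least 3 energies to decompose")
    fp, fpp = dataset.anomalous_factors()
    a = design_matrix(fp, fpp)
    _check_design(a)
    # columns: S, C+, C-, R with C = C+ - C-
    a4 = np.column_stack([a[:, 0], a[:, 1], -a[:, 1], a[:, 2]])
    out = np.empty((dataset.n_q, 3))
    for j in range(dataset.n_q):
        wsr = 1.0 / dataset.sigma[:, j]
        x, _ = nnls(a4 * wsr[:, None], dataset.intensity[:, j] * wsr)
        out[j] = x[0], x[1] - x[2], x[3]
    return ScatteringTerms(dataset.q_grid, out[:, 0], out[:, 1], out[:, 2])


def reconstruct_intensity(
    terms: ScatteringTerms, f_prime: np.ndarray, f_doubleprime: np.ndarray
) -> np.ndarray:
    """Reassemble the (Ne, Nq) intensity matrix from decomposed terms."""
    a = design_matrix(f_prime, f_doubleprime)
    return a @ terms.stacked()


@dataclass
class CauchySchwarzReport:
    """Outcome of the C^2 <= S*R validity check."""

    n_q: int
    n_violations: int
    worst_ratio: float  # max over Q of C^2 / (S*R); <= 1 means satisfied
    violating_indices: np.ndarray

    @property
    def ok(self) -> bool:
        return self.n_violations == 0


def validate_cauchy_schwarz(
    terms: ScatteringTerms, tolerance: float = 0.0, n_sigma: float = 3.0
) -> CauchySchwarzReport:
    """Check C(Q)^2 <= (1 + tolerance) * S(Q) * R(Q) at every Q.

    For terms estimated from noisy data a nonzero relative ``tolerance``
    absorbs estimation scatter, and — when the decomposition covariance is
    available — an excess is only flagged if it is statistically
    significant: the per-Q resonant-term estimate is strongly
    anti-correlated with the cross term and individually very noisy, so the
    raw inequality fails by chance on a large fraction of points.  The
    significance gate propagates the (S, C, R) covariance through
    ``C^2 - (1+tolerance) S R`` and requires an ``n_sigma`` excess.  Exact
    terms (no covariance) are checked directly.  Q points where S*R <= 0
    count as violations whenever C is nonzero there (subject to the same
    significance gate).
    """
    c2 = terms.cross_term**2
    sr = terms.saxs_term * terms.resonant_term
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sr > 0, c2 / sr, np.where(c2 > 0, np.inf, 0.0))
    excess = c2 - (1.0 + tolerance) * sr
    bad = excess > 0
    if terms.term_cov is not None:
        s, c, r = terms.saxs_term, terms.cross_term, terms.resonant_term
        grad = np.stack(
            [-(1.0 + tolerance) * r, 2.0 * c, -(1.0 + tolerance) * s], axis=1
        )  # (Nq, 3)
        var = np.einsum("qi,qij,qj->q", grad, terms.term_cov, grad)
        bad &= excess > n_sigma * np.sqrt(np.maximum(var, 0.0))
    return CauchySchwarzReport(
        n_q=terms.q_grid.size,
        n_violations=int(np.count_nonzero(bad)),
        worst_ratio=float(np.max(ratio)) if ratio.size else 0.0,
        violating_indices=np.flatnonzero(bad),
    )


def linearity_diagnostic(
    dataset: EnergyScanDataset, q_index: int
) -> tuple[float, float, float]:
    """Quantify how linear I(Q_fixed, E) is in f'(E).

    Fits a weighted quadratic ``I = a + b f' + c f'^2`` at the given Q index
    and returns ``(slope, intercept, curvature)`` where slope = b (equals
    2C when the resonant term is negligible), intercept = a, and the
    curvature statistic is the size of the quadratic contribution over the
    measured f' span relative to the intercept:
    ``c * span^2 / |a|`` with ``span = (max f' - min f') / 2``.

    Zero resonant term gives (up to f'' variation) zero curvature; its sign
    follows the sign of R.
    """
    if dataset.n_energies < 3:
        raise ValueError("need at least 3 energies for the quadratic diagnostic")
    fp, _ = dataset.anomalous_factors()
    if np.ptp(fp) == 0:
        raise ValueError("f' is constant over the scan; no linearity to assess")
    y = dataset.intensity[:, q_index]
    w = 1.0 / dataset.sigma[:, q_index]
    coeffs = np.polynomial.polynomial.polyfit(fp, y, deg=2, w=w)
    a0, b1, c2 = coeffs
    span = np.ptp(fp) / 2.0
    curvature = c2 * span**2 / max(abs(a0), np.finfo(float).tiny)
    return float(b1), float(a0), float(curvature)
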