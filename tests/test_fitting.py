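import warnings

import numpy as np
import pytest

from lnsaxs.biphasic_model import model_terms
from lnsaxs.fitting import (
    chi2_map,
    element_ratio,
    fit_biphasic,
    ions_per_peptide,
    phase_metal_concentrations,
)
from lnsaxs.stuhrmann import ScatteringTerms, decompose
from lnsaxs.synthetic_data import (
    SyntheticConfig,
    generate_asaxs,
    two_edge_configs,
)


def perturbed(truth, factor=1.5):
    return truth.replace(
        norm=truth.norm * factor,
        phase1_rmoles=truth.phase1_rmoles * factor,
        mean_radius=truth.mean_radius * factor,
        rsig=min(truth.rsig * factor, 1.4),
    )


class TestFitBiphasic:
    def test_noise_free_recovery_to_0p1_percent(self, clean_scan, truth):
        """Perturbed x1.5 start on exact data recovers all free parameters."""
        from lnsaxs.stuhrmann import EnergyScanDataset

        _, ds, comps, table = clean_scan
        # exact intensities carrying nominal 1% uncertainties
        nominal = EnergyScanDataset(
            ds.q_grid, ds.energies, ds.intensity, 0.01 * np.abs(ds.intensity),
            ds.resonant_element, table,
        )
        terms = decompose(nominal)
        res = fit_biphasic(terms, perturbed(truth), comps, table)
        for name in res.free_names:
            got, want = getattr(res.best_params, name), getattr(truth, name)
            assert got == pytest.approx(want, rel=1e-3), name
        assert res.chi2 == pytest.approx(0.0, abs=1e-8)

    def test_all_zero_terms_rejected(self, noisy_scan, truth):
        _, ds, comps, table = noisy_scan
        q = ds.q_grid
        zero = ScatteringTerms(
            q, np.zeros_like(q), np.zeros_like(q), np.zeros_like(q),
            term_sigma=np.ones((3, q.size)),
        )
        with pytest.raises(ValueError, match="zero"):
            fit_biphasic(zero, truth, comps, table)

    def test_noisy_recovery_median_within_10_percent(self, truth):
        """1% noise replicates: median phase1_rmoles error well under 10%."""
        errs = []
        for seed in range(7):
            cfg = SyntheticConfig(seed=seed)
            comps, table = cfg.resolve()
            terms = decompose(generate_asaxs(cfg))
            res = fit_biphasic(terms, perturbed(truth, 1.3), comps, table)
            errs.append(
                abs(res.best_params.phase1_rmoles / truth.phase1_rmoles - 1)
            )
        assert np.median(errs) <= 0.10

    def test_invariant_to_q_reordering_and_rescaling(self, noisy_terms, noisy_scan,
                                                     truth):
        _, ds, comps, table = noisy_scan
        res = fit_biphasic(noisy_terms, perturbed(truth, 1.2), comps, table)
        # uniform rescale of (data, sigma) leaves the minimizer fixed
        t = noisy_terms
        scaled = ScatteringTerms(
            t.q_grid, 3.0 * t.saxs_term, 3.0 * t.cross_term, 3.0 * t.resonant_term,
            term_sigma=3.0 * t.term_sigma, term_cov=9.0 * t.term_cov,
        )
        # norm absorbs the factor 3; compare shape parameters
        res2 = fit_biphasic(scaled, perturbed(truth, 1.2), comps, table)
        assert res2.best_params.mean_radius == pytest.approx(
            res.best_params.mean_radius, rel=1e-4
        )
        assert res2.best_params.phase1_rmoles == pytest.approx(
            res.best_params.phase1_rmoles, rel=1e-3
        )
        assert res2.best_params.norm == pytest.approx(
            3.0 * res.best_params.norm, rel=1e-3
        )
        assert res2.chi2 == pytest.approx(res.chi2, rel=1e-6)

    def test_fixed_parameters_honoured(self, noisy_terms, noisy_scan, truth):
        _, ds, comps, table = noisy_scan
        fixed = frozenset(
            {"phase1_density", "phase1_volfrac", "phase2_density",
             "phase2_volfrac", "rsig"}
        )
        res = fit_biphasic(noisy_terms, perturbed(truth, 1.2), comps, table,
                           fixed=fixed)
        assert res.best_params.rsig == perturbed(truth, 1.2).rsig
        assert "rsig" not in res.free_names

    def test_chi2_per_dof_near_unity_on_correct_model(self, noisy_terms,
                                                      noisy_scan, truth):
        _, ds, comps, table = noisy_scan
        res = fit_biphasic(noisy_terms, perturbed(truth, 1.2), comps, table)
        assert 0.5 < res.reduced_chi2 < 2.0


class TestChi2Map:
    def test_exactly_quadratic_surface_interval_matches_covariance(
        self, noisy_scan, noisy_terms, truth
    ):
        """Model linear in norm: Delta-chi2=1 interval is +/-1 analytic stderr."""
        _, ds, comps, table = noisy_scan
        fixed = frozenset(set(truth.__dataclass_fields__) - {"norm"})
        res = fit_biphasic(noisy_terms, truth, comps, table, fixed=fixed)
        prof = chi2_map(res, noisy_terms, comps, table, "norm")
        lo, hi = prof.interval
        assert lo < res.best_params.norm < hi
        assert (hi - lo) / 2 == pytest.approx(res.stderr["norm"], rel=0.02)

    def test_profile_interval_consistent_with_stderr(self, noisy_scan,
                                                     noisy_terms, truth):
        """For the mildly nonlinear ion count the interval tracks the stderr."""
        _, ds, comps, table = noisy_scan
        res = fit_biphasic(noisy_terms, perturbed(truth, 1.2), comps, table)
        prof = chi2_map(res, noisy_terms, comps, table, "phase1_rmoles")
        lo, hi = prof.interval
        best = res.best_params.phase1_rmoles
        assert lo < best < hi
        se = res.stderr["phase1_rmoles"]
        assert (hi - lo) / 2 == pytest.approx(se, rel=0.15)

    def test_fixed_parameter_cannot_be_profiled(self, noisy_scan, noisy_terms,
                                                truth):
        _, ds, comps, table = noisy_scan
        res = fit_biphasic(noisy_terms, perturbed(truth, 1.2), comps, table)
        with pytest.raises(ValueError, match="not free"):
            chi2_map(res, noisy_terms, comps, table, "phase1_volfrac")

    def test_interval_shrinks_with_noise(self, truth):
        widths = []
        for rel in (0.02, 0.005):
            cfg = SyntheticConfig(seed=11, noise_rel=rel, noise_floor=0.0)
            comps, table = cfg.resolve()
            terms = decompose(generate_asaxs(cfg))
            res = fit_biphasic(terms, perturbed(truth, 1.2), comps, table)
            prof = chi2_map(res, terms, comps, table, "phase1_rmoles")
            widths.append(prof.interval[1] - prof.interval[0])
        assert widths[1] < widths[0] / 2


class TestDerivedQuantities:
    def test_ions_per_peptide_reduces_to_rmoles(self, noisy_scan, truth):
        _, ds, comps, table = noisy_scan
        from lnsaxs.fitting import FitResult

        p = truth.replace(phase2_volfrac=0.0, phase1_rmoles=2.2)
        res = FitResult(best_params=p, chi2=0.0, dof=1)
        assert ions_per_peptide(res, comps) == pytest.approx(2.2)

    def test_ions_per_peptide_requires_peptide(self, noisy_scan, truth):
        _, ds, comps, table = noisy_scan
        from lnsaxs.fitting import FitResult

        p = truth.replace(phase1_volfrac=0.0)
        with pytest.raises(ZeroDivisionError):
            ions_per_peptide(FitResult(best_params=p, chi2=0.0, dof=1), comps)

    def test_phase_concentration_stoichiometry_oracle(self, noisy_scan, truth):
        """1 Tb per phase-2 formula unit: molarity = density/molar-mass * 1000."""
        _, ds, comps, table = noisy_scan
        from lnsaxs.fitting import FitResult
        from lnsaxs.scatter_factors import molar_mass

        res = FitResult(best_params=truth, chi2=0.0, dof=1)
        d = phase_metal_concentrations(res, comps)
        from dataclasses import replace

        ph2 = replace(comps.phase2, mass_density=truth.phase2_density)
        expected = truth.phase2_density / molar_mass(ph2) * 1000.0
        assert d.phase_molarity["phase2"] == pytest.approx(expected, rel=1e-9)
        # aggregate-average is linear in the volume fraction
        assert d.aggregate_molarity["phase2"] == pytest.approx(
            expected * truth.phase2_volfrac, rel=1e-9
        )

    def test_zero_resonant_phase_has_zero_molarity(self, noisy_scan, truth):
        _, ds, comps, table = noisy_scan
        from dataclasses import replace

        from lnsaxs.fitting import FitResult

        ph2 = comps.phase2.with_resonant_count(0.0)
        comps0 = replace(comps, phase2=ph2)
        d = phase_metal_concentrations(
            FitResult(best_params=truth, chi2=0.0, dof=1), comps0
        )
        assert d.phase_molarity["phase2"] == 0.0


class TestElementRatio:
    def test_identical_fits_give_unity(self, noisy_scan, truth):
        _, ds, comps, table = noisy_scan
        from lnsaxs.fitting import FitResult

        res = FitResult(best_params=truth, chi2=0.0, dof=1)
        assert element_ratio(res, res, comps) == pytest.approx(1.0)

    def test_swapping_elements_inverts_ratio(self, noisy_scan, truth):
        _, ds, comps, table = noisy_scan
        from lnsaxs.fitting import FitResult

        a = FitResult(best_params=truth.replace(phase1_rmoles=1.7,
                                                phase2_volfrac=0.0),
                      chi2=0.0, dof=1)
        b = FitResult(best_params=truth.replace(phase1_rmoles=1.0,
                                                phase2_volfrac=0.0),
                      chi2=0.0, dof=1)
        r = element_ratio(a, b, comps)
        assert r == pytest.approx(1.7)
        assert element_ratio(b, a, comps) == pytest.approx(1 / r)

    def test_zero_denominator_rejected(self, noisy_scan, truth):
        _, ds, comps, table = noisy_scan
        from lnsaxs.fitting import FitResult

        a = FitResult(best_params=truth, chi2=0.0, dof=1)
        b = FitResult(
            best_params=truth.replace(phase1_rmoles=0.0, phase2_volfrac=0.0),
            chi2=0.0, dof=1,
        )
        with pytest.raises(ZeroDivisionError):
            element_ratio(a, b, comps)

    def test_two_edge_recovery(self, truth):
        """Constructed N_Tb/N_Lu = 1.7 recovered from independent fits."""
        cfg_a, cfg_b = two_edge_configs(n_tb=1.7, n_lu=1.0, seed=3)
        comps_a, table_a = cfg_a.resolve()
        comps_b, table_b = cfg_b.resolve()
        fits = []
        for cfg, comps, table in ((cfg_a, comps_a, table_a),
                                  (cfg_b, comps_b, table_b)):
            terms = decompose(generate_asaxs(cfg))
            fits.append(
                fit_biphasic(terms, perturbed(cfg.truth, 1.3), comps, table)
            )
        ratio = element_ratio(fits[0], fits[1], comps_a, comps_b)
        assert ratio == pytest.approx(1.7, abs=0.1)
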