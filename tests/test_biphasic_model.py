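import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lnsaxs.biphasic_model import (
    BiphasicParameters,
    default_phase_compositions,
    effective_contrasts,
    guinier_radius,
    model_intensity,
    model_terms,
    sphere_amplitude,
)
from lnsaxs.scatter_factors import (
    R_E_CM,
    MaterialComposition,
    electron_density,
    tb_l3_table,
)


class TestSphereAmplitude:
    def test_forward_scattering_limit(self):
        assert sphere_amplitude(0.0, 123.0) == 1.0

    def test_closed_form_at_pi(self):
        # x = pi: sin(pi)=0, cos(pi)=-1 -> Phi = 3/pi^2
        assert sphere_amplitude(np.pi, 1.0) == pytest.approx(3 / np.pi**2, rel=1e-12)

    @given(x=st.floats(min_value=1e-6, max_value=200.0))
    @settings(max_examples=100, deadline=None)
    def test_even_and_bounded(self, x):
        v = sphere_amplitude(x, 1.0)
        assert abs(v) <= 1.0
        assert v == sphere_amplitude(-x, 1.0)

    def test_series_matches_direct_formula_at_crossover(self):
        x = np.array([0.009, 0.0099, 0.0101, 0.011])
        direct = 3 * (np.sin(x) - x * np.cos(x)) / x**3
        np.testing.assert_allclose(sphere_amplitude(x, 1.0), direct, rtol=1e-10)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            sphere_amplitude(0.1, 0.0)


@pytest.fixture(scope="module")
def comps():
    return default_phase_compositions("Tb")


@pytest.fixture(scope="module")
def table():
    return tb_l3_table()


def params(**kw):
    base = dict(
        norm=1e12,
        phase1_density=1.35,
        phase1_volfrac=0.08,
        phase1_rmoles=2.25,
        phase2_density=1.5,
        phase2_volfrac=0.002,
        mean_radius=400.0,
        rsig=0.2,
    )
    base.update(kw)
    return BiphasicParameters(**base)


class TestEffectiveContrasts:
    def test_pure_solvent_sphere_has_no_contrast(self, comps):
        d, r = effective_contrasts(
            params(phase1_volfrac=0.0, phase2_volfrac=0.0), comps
        )
        assert d == 0.0 and r == 0.0

    def test_no_resonant_content(self, comps):
        _, r = effective_contrasts(
            params(phase1_rmoles=0.0, phase2_volfrac=0.0), comps
        )
        assert r == 0.0

    def test_against_hand_stoichiometry(self, comps):
        """Independent arithmetic: single phase of known composition."""
        p = params(phase1_volfrac=0.1, phase2_volfrac=0.0, phase1_rmoles=2.0,
                   phase1_density=1.2)
        d, r = effective_contrasts(p, comps)
        pep = MaterialComposition(
            {"C": 103, "H": 149, "N": 23, "O": 36, "Tb": 2.0}, 1.2, "Tb"
        )
        water = MaterialComposition("H2O", 1.0)
        assert d == pytest.approx(
            0.1 * (electron_density(pep) - electron_density(water)), rel=1e-12
        )
        m = sum(n * w for n, w in [(103, 12.011), (149, 1.008), (23, 14.007),
                                    (36, 15.999), (2.0, 158.925)])
        n_pep = 1.2 * 6.02214076e23 / m * 1e-24
        assert r == pytest.approx(0.1 * n_pep * 2.0, rel=1e-3)

    def test_overfull_volume_fractions_rejected(self, comps):
        with pytest.raises(ValueError):
            params(phase1_volfrac=0.7, phase2_volfrac=0.5)


class TestModelTerms:
    def test_no_resonant_content_kills_cross_and_resonant(self, comps, table,
                                                          small_q_grid):
        p = params(phase1_rmoles=0.0, phase2_volfrac=0.0)
        t = model_terms(p, comps, table, small_q_grid)
        assert np.all(t.cross_term == 0) and np.all(t.resonant_term == 0)
        assert np.all(t.saxs_term > 0)

    def test_linearity_in_norm(self, comps, table, small_q_grid):
        t1 = model_terms(params(), comps, table, small_q_grid)
        t2 = model_terms(params(norm=2e12), comps, table, small_q_grid)
        for a, b in [(t1.saxs_term, t2.saxs_term), (t1.cross_term, t2.cross_term),
                     (t1.resonant_term, t2.resonant_term)]:
            np.testing.assert_allclose(b, 2 * a, rtol=1e-12)

    def test_monodisperse_limit_matches_closed_form(self, comps, table,
                                                    small_q_grid):
        """rsig -> 0 equals norm * V^2 (r_e drho)^2 Phi(qR)^2 exactly."""
        p = params(rsig=0.0)
        t = model_terms(p, comps, table, small_q_grid)
        drho, _ = effective_contrasts(p, comps)
        v = 4 / 3 * np.pi * p.mean_radius**3 * 1e-24
        phi = sphere_amplitude(small_q_grid * p.mean_radius, 1.0)
        expected = p.norm * (drho * 1e24 * R_E_CM) ** 2 * v**2 * phi**2
        np.testing.assert_allclose(t.saxs_term, expected, rtol=1e-6)

    def test_cauchy_schwarz_equality(self, comps, table, small_q_grid):
        t = model_terms(params(), comps, table, small_q_grid)
        np.testing.assert_allclose(
            t.cross_term**2, t.saxs_term * t.resonant_term, rtol=1e-10
        )

    def test_forward_intensity_scales_as_r6(self, comps, table):
        """Doubling R at rsig=0 multiplies I(Q->0) by 64 (V^2 ~ R^6)."""
        q = np.array([1e-5])
        lo = model_terms(params(rsig=0.0, mean_radius=100.0), comps, table, q)
        hi = model_terms(params(rsig=0.0, mean_radius=200.0), comps, table, q)
        assert hi.saxs_term[0] / lo.saxs_term[0] == pytest.approx(64.0, rel=1e-6)

    def test_negative_rsig_rejected(self):
        with pytest.raises(ValueError):
            params(rsig=-0.1)


class TestModelIntensity:
    def test_zero_dispersion_gives_saxs_term(self, comps, small_q_grid):
        from lnsaxs.scatter_factors import DispersionTable

        flat = DispersionTable(
            "Tb", 7.514, np.array([(7.0, 0.0, 0.0), (7.5, 0.0, 0.0)])
        )
        p = params()
        i = model_intensity(p, comps, flat, small_q_grid, 7.3)
        t = model_terms(p, comps, flat, small_q_grid)
        np.testing.assert_allclose(i, t.saxs_term, rtol=1e-12)

    def test_intensity_ordering_follows_direct_substitution(self, comps, table,
                                                            small_q_grid):
        """With C > 0 and f' negative, intensity drops toward the edge."""
        p = params()
        t = model_terms(p, comps, table, small_q_grid)
        for e in (7.30, 7.50):
            from lnsaxs.scatter_factors import dispersion_at

            fp, fpp = dispersion_at(table, e)
            direct = t.saxs_term + 2 * fp * t.cross_term + (fp**2 + fpp**2) * t.resonant_term
            np.testing.assert_allclose(
                model_intensity(p, comps, table, small_q_grid, e), direct, rtol=1e-12
            )
        near = model_intensity(p, comps, table, small_q_grid, 7.50)
        far = model_intensity(p, comps, table, small_q_grid, 7.30)
        assert np.all(near < far)

    def test_intensity_positive(self, comps, table, small_q_grid):
        i = model_intensity(params(), comps, table, small_q_grid, 7.45)
        assert np.all(i > 0)


class TestGuinier:
    def test_monodisperse_closed_form(self):
        assert guinier_radius(params(rsig=0.0, mean_radius=100.0)) == pytest.approx(
            np.sqrt(3 / 5) * 100.0, rel=1e-9
        )

    def test_monotone_in_rsig(self):
        rgs = [guinier_radius(params(rsig=s)) for s in (0.0, 0.1, 0.2, 0.3)]
        assert all(a < b for a, b in zip(rgs, rgs[1:]))

    def test_low_q_slope_matches_guinier_expansion(self, comps, table):
        """ln S vs Q^2 slope equals -Rg^2/3 within 1% for Q*Rg < 1."""
        p = params(rsig=0.15)
        rg = guinier_radius(p)
        q = np.linspace(0.2 / rg, 0.9 / rg, 30)
        s = model_terms(p, comps, table, q).saxs_term
        slope = np.polyfit(q**2, np.log(s), 1)[0]
        assert slope == pytest.approx(-rg**2 / 3, rel=0.01)
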