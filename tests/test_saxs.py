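import numpy as np
import pytest

from openring import (FormFactorTable, SAXSProfile, chi_square_fit,
                      debye_profile, guinier_fit, kratky_curve,
                      make_bead_protomer, porod_exponent, read_profile,
                      simulate_profile, write_profile)
from openring.synthetic import _bead_set
from .conftest import random_transform


UNIT_FF = FormFactorTable.unit()


def bead_cloud(n, extent, seed):
    return make_bead_protomer(n, extent=extent, seed=seed)


class TestDebye:
    def test_single_atom_unit_form_factor(self):
        atoms = _bead_set(np.zeros((1, 3)), "A", "point")
        q = np.linspace(0.0, 0.5, 20)
        prof = debye_profile(atoms, q, ff=UNIT_FF)
        assert np.allclose(prof.I, 1.0)

    def test_two_atom_closed_form(self):
        d = 10.0
        atoms = _bead_set(np.array([[0, 0, 0], [d, 0, 0.0]]), "A", "pair")
        q = np.linspace(0.01, 0.5, 50)
        prof = debye_profile(atoms, q, ff=UNIT_FF, bin_width=0.0)
        expected = 2 + 2 * np.sin(q * d) / (q * d)
        assert np.allclose(prof.I, expected, atol=1e-12)

    def test_forward_scattering_is_squared_f_sum(self):
        atoms = bead_cloud(120, 30.0, seed=6)
        f = UNIT_FF.lookup(atoms.elements)
        q = np.array([0.0, 0.01, 0.3])
        for bw in (0.0, 0.1):
            prof = debye_profile(atoms, q, ff=UNIT_FF, bin_width=bw)
            assert prof.I[0] == pytest.approx(float(f.sum()) ** 2, rel=1e-12)

    def test_binned_matches_brute_force_500_beads(self):
        """Histogram-binned Debye vs the exact double sum: < 1e-4 relative."""
        atoms = bead_cloud(500, 45.0, seed=7)
        q = np.linspace(0.0, 0.5, 101)
        exact = debye_profile(atoms, q, ff=UNIT_FF, bin_width=0.0)
        binned = debye_profile(atoms, q, ff=UNIT_FF, bin_width=0.1)
        rel = np.abs(binned.I - exact.I) / np.abs(exact.I)
        assert rel.max() < 1e-4

    def test_binning_error_shrinks_with_bin_width(self):
        atoms = bead_cloud(200, 35.0, seed=8)
        q = np.linspace(0.0, 0.5, 51)
        exact = debye_profile(atoms, q, ff=UNIT_FF, bin_width=0.0).I
        errs = []
        for bw in (0.4, 0.2, 0.1, 0.05):
            binned = debye_profile(atoms, q, ff=UNIT_FF, bin_width=bw).I
            errs.append(np.abs(binned - exact).max())
        assert errs == sorted(errs, reverse=True)

    def test_rotational_translational_invariance(self):
        atoms = bead_cloud(150, 30.0, seed=9)
        q = np.linspace(0.0, 0.5, 40)
        base = debye_profile(atoms, q, ff=UNIT_FF, bin_width=0.0).I
        rng = np.random.default_rng(10)
        for _ in range(3):
            t = random_transform(rng)
            moved = atoms.with_coords(t.apply(atoms.coords))
            I = debye_profile(moved, q, ff=UNIT_FF, bin_width=0.0).I
            assert np.abs(I - base).max() / base.max() < 1e-10

    def test_doubling_f_quadruples_intensity(self):
        atoms = bead_cloud(80, 25.0, seed=11)
        q = np.linspace(0.0, 0.4, 30)
        one = debye_profile(atoms, q, ff=FormFactorTable({"RES": 1.0}))
        two = debye_profile(atoms, q, ff=FormFactorTable({"RES": 2.0}))
        assert np.allclose(two.I, 4.0 * one.I, rtol=1e-12)

    def test_unknown_element_lists_offenders(self):
        atoms = _bead_set(np.zeros((1, 3)), "A", "point")
        atoms.elements[0] = "QQ"
        with pytest.raises(KeyError, match="QQ"):
            debye_profile(atoms, np.array([0.1]))


class TestChiSquare:
    def test_identical_profiles(self):
        q = np.linspace(0.01, 0.4, 60)
        I = np.exp(-(q * 25) ** 2 / 3)
        exp = SAXSProfile(q, I, np.full_like(q, 1.0))
        fit = chi_square_fit(SAXSProfile(q, I), exp)
        assert fit.scale == pytest.approx(1.0, abs=1e-12)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_scaled_experiment_absorbed(self):
        q = np.linspace(0.01, 0.4, 60)
        I = 1e5 * np.exp(-(q * 25) ** 2 / 3)
        exp = SAXSProfile(q, 2.0 * I, 0.01 * I)
        fit = chi_square_fit(SAXSProfile(q, I), exp)
        assert fit.scale == pytest.approx(2.0, rel=1e-9)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-9)

    def test_chi2_invariant_to_model_rescale(self, truth40, qgrid,
                                             noisy_profile40):
        model = debye_profile(truth40.assembly, qgrid)
        scaled = SAXSProfile(model.q, 7.5 * model.I)
        f1 = chi_square_fit(model, noisy_profile40)
        f2 = chi_square_fit(scaled, noisy_profile40)
        assert f1.chi2 == pytest.approx(f2.chi2, rel=1e-9)

    def test_expected_chi2_near_one_under_matched_noise(self, truth40, qgrid):
        model = debye_profile(truth40.assembly, qgrid)
        chi2s = []
        for s in range(50):
            noisy = simulate_profile(truth40.assembly, qgrid, 0.02, 0.0,
                                     seed=1000 + s)
            chi2s.append(chi_square_fit(model, noisy).chi2)
        assert np.mean(chi2s) == pytest.approx(1.0, abs=3 / np.sqrt(50))

    def test_non_overlapping_ranges_rejected(self):
        m = SAXSProfile(np.linspace(0.01, 0.1, 10), np.ones(10))
        e = SAXSProfile(np.linspace(0.2, 0.3, 10), np.ones(10), np.ones(10))
        with pytest.raises(ValueError, match="range"):
            chi_square_fit(m, e)

    def test_sigma_required(self):
        q = np.linspace(0.01, 0.1, 10)
        with pytest.raises(ValueError, match="uncertain"):
            chi_square_fit(SAXSProfile(q, np.ones(10)),
                           SAXSProfile(q, np.ones(10)))


class TestGuinier:
    def test_exact_gaussian_recovers_rg(self):
        rg = 30.0
        q = np.linspace(0.001, 0.04, 80)
        prof = SAXSProfile(q, 5.0 * np.exp(-(q * rg) ** 2 / 3))
        stats = guinier_fit(prof)
        assert stats.Rg == pytest.approx(rg, abs=1e-6)
        assert stats.I0 == pytest.approx(5.0, rel=1e-6)

    def test_bead_sphere_rg(self):
        # homogeneous sphere radius 10: Rg = sqrt(3/5) * 10
        rng = np.random.default_rng(0)
        pts = []
        while len(pts) < 3000:
            c = rng.uniform(-1, 1, (9000, 3))
            pts.extend(c[(c ** 2).sum(axis=1) <= 1][:3000 - len(pts)])
        beads = _bead_set(np.array(pts) * 10.0, "A", "sphere")
        prof = debye_profile(beads, np.linspace(0.002, 0.12, 60), ff=UNIT_FF)
        stats = guinier_fit(prof)
        assert stats.Rg == pytest.approx(10.0 * np.sqrt(3 / 5), rel=0.02)

    def test_noisy_rg_bias_below_one_percent(self, truth40, qgrid):
        clean = debye_profile(truth40.assembly, qgrid)
        true_rg = guinier_fit(clean).Rg
        rgs = []
        for s in range(40):
            noisy = simulate_profile(truth40.assembly, qgrid, 0.01, 0.0,
                                     seed=2000 + s)
            rgs.append(guinier_fit(noisy).Rg)
        assert abs(np.mean(rgs) - true_rg) / true_rg < 0.01

    def test_rising_intensity_rejected(self):
        q = np.linspace(0.01, 0.1, 30)
        with pytest.raises(ValueError, match="Guinier"):
            guinier_fit(SAXSProfile(q, np.exp(+(q * 20) ** 2)))


class TestKratkyPorod:
    def test_power_laws_recovered_exactly(self):
        q = np.linspace(0.05, 0.5, 100)
        for exponent in (4.0, 2.0):
            prof = SAXSProfile(q, q ** (-exponent))
            assert porod_exponent(prof, (0.05, 0.5)) == pytest.approx(
                exponent, abs=1e-9)

    def test_solid_sphere_porod_limit(self):
        # dense bead sphere: slope -> -4 below the incoherent crossover,
        # fitted over ~2 oscillation periods (u in [3, 9])
        rng = np.random.default_rng(0)
        pts = []
        while len(pts) < 5000:
            c = rng.uniform(-1, 1, (9000, 3))
            pts.extend(c[(c ** 2).sum(axis=1) <= 1][:5000 - len(pts)])
        beads = _bead_set(np.array(pts) * 10.0, "A", "sphere")
        q = np.linspace(0.05, 1.0, 400)
        prof = debye_profile(beads, q, ff=UNIT_FF, bin_width=0.02)
        assert porod_exponent(prof, (0.3, 0.9)) == pytest.approx(4.0, abs=0.3)

    def test_kratky_curve_shape(self):
        q = np.linspace(0.01, 0.3, 50)
        prof = SAXSProfile(q, np.exp(-(q * 20) ** 2 / 3))
        curve = kratky_curve(prof)
        assert curve.shape == (50, 2)
        assert np.allclose(curve[:, 1], q ** 2 * prof.I)

    def test_too_few_points_in_range(self):
        q = np.linspace(0.01, 0.5, 50)
        prof = SAXSProfile(q, q ** -4.0)
        with pytest.raises(ValueError, match="point"):
            porod_exponent(prof, (0.49, 0.5))


class TestProfileIO:
    def test_three_column_round_trip(self, tmp_path, noisy_profile40):
        path = tmp_path / "profile.dat"
        write_profile(noisy_profile40, path)
        back = read_profile(path)
        assert np.allclose(back.q, noisy_profile40.q)
        assert np.allclose(back.I, noisy_profile40.I)
        assert np.allclose(back.sigma, noisy_profile40.sigma)

    def test_comments_and_validation(self, tmp_path):
        path = tmp_path / "p.dat"
        path.write_text("# q I sigma\n0.01 5.0 0.1\n0.02 4.5 0.1\n")
        prof = read_profile(path)
        assert len(prof) == 2
        with pytest.raises(ValueError, match="increasing"):
            SAXSProfile(np.array([0.2, 0.1]), np.ones(2))
        with pytest.raises(ValueError, match="sigma"):
            SAXSProfile(np.array([0.1, 0.2]), np.ones(2), np.array([1.0, 0.0]))
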