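import numpy as np
import pytest

from synidp import scattering as sc
from synidp.scattering import (
    ChainEnsemble,
    PEVParams,
    ScatteringProfile,
    cd_random_coil_check,
    debye_chain,
    fit_pev,
    kratky_classify,
    pev_intensity,
    porod_exponent,
    rod_form_factor,
    simulate_chain_scattering,
    tcep_length_model,
)
from synidp.workbench import make_fixtures

Q_GRID = np.geomspace(0.012, 0.6, 200)


class TestFormFactors:
    def test_debye_normalization_and_value(self):
        prof = debye_chain(np.array([1e-6, 1.0 / 42.0]), 42.0)
        assert prof.I[0] == pytest.approx(1.0, abs=1e-9)
        # x = (q Rg)^2 = 1 -> I = 2/e
        assert prof.I[1] == pytest.approx(2.0 / np.e, rel=1e-9)

    def test_rod_normalization_and_value(self):
        prof = rod_form_factor(np.array([1e-8, np.pi / 300.0]), 300.0)
        assert prof.I[0] == pytest.approx(1.0, abs=1e-6)
        assert prof.I[1] == pytest.approx(0.7737, abs=2e-4)  # qL = pi

    def test_positive_everywhere(self):
        for prof in (debye_chain(Q_GRID, 42.0), rod_form_factor(Q_GRID, 300.0),
                     pev_intensity(Q_GRID, PEVParams(rg=42.0, nu=0.6))):
            assert np.all(prof.I > 0)

    def test_pev_reduces_to_debye_at_half(self):
        pev = pev_intensity(Q_GRID, PEVParams(rg=42.0, nu=0.5))
        deb = debye_chain(Q_GRID, 42.0)
        assert np.max(np.abs(pev.I - deb.I) / deb.I) < 1e-6

    def test_pev_high_q_slope_is_inverse_nu(self):
        for nu in (0.5, 0.6, 0.9):
            rg = 60.0
            q = np.geomspace(5.0 / rg, 12.0 / rg, 60)
            prof = pev_intensity(q, PEVParams(rg=rg, nu=nu))
            m, _ = porod_exponent(prof, (q[0], q[-1]))
            assert m == pytest.approx(1.0 / nu, rel=0.1)

    def test_pev_scale_background(self):
        prof = pev_intensity(np.array([1e-6]), PEVParams(rg=42.0, nu=0.6,
                                                         scale=7.0,
                                                         background=0.5))
        assert prof.I[0] == pytest.approx(7.5, rel=1e-6)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            debye_chain(Q_GRID, -1.0)
        with pytest.raises(ValueError):
            PEVParams(rg=42.0, nu=0.2)


class TestPorodExponent:
    def test_exact_power_law(self):
        q = np.geomspace(0.01, 0.5, 80)
        prof = ScatteringProfile(q=q, I=q ** -3.0)
        m, err = porod_exponent(prof, (0.03, 0.2))
        assert m == pytest.approx(3.0, abs=1e-9)

    def test_debye_asymptote_rounds_to_two(self):
        rg = 42.0
        m, _ = porod_exponent(debye_chain(np.geomspace(1e-3, 0.5, 600), rg),
                              (4.0 / rg, 10.0 / rg))
        assert round(m) == 2

    def test_rod_asymptote_rounds_to_one(self):
        L = 300.0
        m, _ = porod_exponent(rod_form_factor(np.geomspace(1e-3, 0.5, 600), L),
                              (10.0 / L, 60.0 / L))
        assert round(m) == 1

    def test_empty_window(self):
        with pytest.raises(ValueError):
            porod_exponent(debye_chain(Q_GRID, 42.0), (10.0, 11.0))


class TestEnsembleScattering:
    def test_two_bead_closed_form(self):
        r = 5.0
        ens = ChainEnsemble(model="rigid_rod", n_beads=2, bond_length=r,
                            n_conformers=1)
        q = np.array([0.1, 0.3, 1.0])
        prof, _ = simulate_chain_scattering(ens, q)
        expected = (1.0 + np.sin(q * r) / (q * r)) / 2.0
        assert prof.I == pytest.approx(expected, rel=1e-12)

    def test_random_walk_matches_debye(self):
        ens = ChainEnsemble(model="random_walk", n_beads=120, bond_length=3.8,
                            n_conformers=250, seed=3)
        rg_ideal = 3.8 * np.sqrt(120 / 6.0)
        q = np.linspace(0.2 / rg_ideal, 3.0 / rg_ideal, 25)
        prof, rg = simulate_chain_scattering(ens, q)
        analytic = debye_chain(q, rg)
        assert np.max(np.abs(prof.I - analytic.I) / analytic.I) < 0.08

    def test_rod_matches_rod_form(self):
        n = 300
        ens = ChainEnsemble(model="rigid_rod", n_beads=n, bond_length=1.0,
                            n_conformers=1)
        L = (n - 1) * 1.0
        q = np.linspace(0.01, 0.2, 25)
        prof, _ = simulate_chain_scattering(ens, q)
        analytic = rod_form_factor(q, L)
        assert np.max(np.abs(prof.I - analytic.I) / analytic.I) < 0.02

    def test_seeded_reproducibility(self):
        ens = ChainEnsemble(n_beads=30, n_conformers=5, seed=11)
        a, _ = simulate_chain_scattering(ens, Q_GRID[:10])
        b, _ = simulate_chain_scattering(ens, Q_GRID[:10])
        assert np.array_equal(a.I, b.I)


class TestPEVFit:
    def test_noiseless_self_consistency(self):
        truth = PEVParams(rg=42.0, nu=0.588)
        prof = pev_intensity(Q_GRID, truth)
        fit = fit_pev(prof, seed=0)
        assert fit.rg == pytest.approx(truth.rg, rel=1e-3)
        assert fit.nu == pytest.approx(truth.nu, abs=1e-3)
        assert fit.converged

    @pytest.mark.parametrize("seed", range(10))
    def test_recovery_under_noise(self, seed):
        """2% noise on the experimental q range: Rg within 10%, nu within
        0.05, across a seed sweep."""
        fx = make_fixtures("scattering",
                           {"model": "pev", "rg": 42.0, "nu": 0.588,
                            "noise": 0.02}, seed=seed)
        fit = fit_pev(fx["profile"], seed=seed)
        assert fit.rg == pytest.approx(42.0, rel=0.10)
        assert fit.nu == pytest.approx(0.588, abs=0.05)

    def test_rg_within_reported_uncertainty_band(self):
        """Synthetic curve at Rg = 4.2 nm refits within +/-0.5 nm."""
        fx = make_fixtures("scattering", {"model": "pev", "rg": 42.0,
                                          "nu": 0.55, "noise": 0.02}, seed=1)
        fit = fit_pev(fx["profile"], seed=1)
        assert abs(fit.rg - 42.0) < 5.0

    def test_porod_consistency_with_fitted_nu(self):
        truth = PEVParams(rg=50.0, nu=0.6)
        q = np.geomspace(0.012, 0.6, 300)
        prof = pev_intensity(q, truth)
        fit = fit_pev(prof, seed=2)
        m, _ = porod_exponent(prof, (5.0 / truth.rg, 11.0 / truth.rg))
        assert m == pytest.approx(1.0 / fit.nu, rel=0.10)


class TestKratky:
    def test_debye_is_flexible_disordered(self):
        assert kratky_classify(debye_chain(Q_GRID, 42.0)) == "flexible_disordered"

    def test_rod_is_extended(self):
        assert kratky_classify(rod_form_factor(Q_GRID, 300.0)) == "extended"

    def test_sphere_is_compact(self):
        x = Q_GRID * 30.0
        sphere = (3 * (np.sin(x) - x * np.cos(x)) / x ** 3) ** 2
        prof = ScatteringProfile(q=Q_GRID, I=np.maximum(sphere, 1e-14))
        assert kratky_classify(prof) == "compact"

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            kratky_classify(debye_chain(Q_GRID[:5], 42.0))


class TestProfileIO:
    def test_three_column_roundtrip(self, tmp_path):
        prof = pev_intensity(Q_GRID[:20], PEVParams(rg=40.0, nu=0.6))
        prof.sigma = 0.02 * prof.I
        path = tmp_path / "prof.dat"
        sc.save_profile(prof, path)
        back = sc.load_profile(path)
        assert back.q == pytest.approx(prof.q)
        assert back.sigma == pytest.approx(prof.sigma)

    def test_validation(self):
        with pytest.raises(ValueError):
            ScatteringProfile(q=np.array([0.2, 0.1]), I=np.array([1.0, 1.0]))


class TestTcep:
    def test_full_conversion_mean(self):
        out = tcep_length_model(500, 1.0)
        assert out["mean_dp"] == 500.0
        assert out["dispersity"] == pytest.approx(1.002)
        assert out["pmf"].sum() == pytest.approx(1.0, abs=1e-7)

    def test_zero_conversion_degenerate(self):
        out = tcep_length_model(500, 0.0)
        assert out["mean_dp"] == 0.0
        assert out["pmf"][0] == 1.0

    def test_poisson_moment_identity(self):
        out = tcep_length_model(200, 0.5)
        k, pmf = out["k"], out["pmf"]
        mean = (k * pmf).sum()
        var = ((k - mean) ** 2 * pmf).sum()
        # Poisson: dispersity = Mw/Mn = 1 + var/mean^2 = 1 + 1/mean
        assert 1 + var / mean ** 2 == pytest.approx(out["dispersity"], abs=1e-6)


class TestCircularDichroism:
    def test_random_coil_fixture(self):
        fx = make_fixtures("cd", {"shape": "coil"})
        out = cd_random_coil_check(fx["wavelength_nm"], fx["ellipticity"])
        assert out["random_coil"]
        assert 195 <= out["min_position_nm"] <= 200
        assert 212 <= out["max_position_nm"] <= 218

    @pytest.mark.parametrize("shape", ["zero", "helix"])
    def test_non_coil_shapes_rejected(self, shape):
        fx = make_fixtures("cd", {"shape": shape})
        assert not cd_random_coil_check(fx["wavelength_nm"],
                                        fx["ellipticity"])["random_coil"]

    def test_insufficient_coverage(self):
        wl = np.arange(200.0, 240.0)
        with pytest.raises(ValueError):
            cd_random_coil_check(wl, np.zeros_like(wl))
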