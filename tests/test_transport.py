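import math

import numpy as np
import pytest
from scipy.special import erf

from chiralprop import (
    ConcentrationProfile,
    characteristic_length,
    ee_vs_time,
    enrichment_from_ee,
    evolve_bounded,
    fit_propulsion_velocity,
    gaussian_pair_profile,
    split_ee,
    steady_state_profile,
)
from chiralprop.params import ParameterError
from chiralprop.transport import read_profile_csv, write_profile_csv


def wide_grid(v, d, t, n=4001, pad_sigma=8.0):
    """Grid wide enough that Gaussian tails are negligible."""
    width = pad_sigma * math.sqrt(2 * d * t) + abs(v) * 100 * t
    return np.linspace(-width, width, n)


class TestEeVsTime:
    def test_molecule_i_prediction(self):
        # 25 nm/s against its measured diffusion for a 45-h exposure
        assert 100 * ee_vs_time(25e-9, 8.3e-6, 45 * 3600) == pytest.approx(19.0, rel=0.05)

    def test_molecule_ii_prediction(self):
        assert 100 * ee_vs_time(45e-9, 1.4e-5, 46 * 3600) == pytest.approx(27.0, rel=0.03)

    def test_zero_time_gives_zero(self):
        assert ee_vs_time(25e-9, 8.3e-6, 0.0) == 0.0

    def test_capped_at_unity(self):
        assert ee_vs_time(1e-3, 1e-8, 1e6) == 1.0

    def test_sqrt_time_scaling(self):
        t = np.array([1e3, 1e4, 1e5, 1e6])
        ee = np.array([ee_vs_time(25e-9, 8.3e-6, ti) for ti in t])
        slope = np.polyfit(np.log(t), np.log(ee), 1)[0]
        assert slope == pytest.approx(0.5, abs=1e-6)

    def test_invalid_diffusion(self):
        with pytest.raises(ParameterError):
            ee_vs_time(25e-9, 0.0, 10.0)


class TestGaussianPair:
    def test_coincident_at_time_zero(self):
        grid = np.linspace(-1, 1, 801)
        p = gaussian_pair_profile(25e-9, 8.3e-6, 0.0, 0.0, grid)
        assert np.allclose(p.c_s, p.c_r)
        lead, trail = split_ee(p, 0.0)
        assert lead == pytest.approx(0.0, abs=1e-9)

    def test_mirror_symmetry_about_centre(self):
        v, d, t = 25e-9, 8.3e-6, 45 * 3600
        grid = wide_grid(v, d, t)
        p = gaussian_pair_profile(v, d, t, 0.0, grid)
        assert np.allclose(p.c_s, p.c_r[::-1], rtol=1e-9)

    def test_unit_mass_each_species(self):
        grid = wide_grid(25e-9, 8.3e-6, 3600)
        p = gaussian_pair_profile(25e-9, 8.3e-6, 3600, 0.0, grid)
        s, r = p.mass()
        assert s == pytest.approx(1.0, rel=1e-9)
        assert r == pytest.approx(1.0, rel=1e-9)


class TestSplitEe:
    def test_centre_split_matches_drift_formula(self):
        # numerical Gaussian-split integration vs the sqrt-time formula,
        # within one ee point up to ee ~ 0.3
        for v, d, t in [(25e-9, 8.3e-6, 45 * 3600), (45e-9, 1.4e-5, 46 * 3600),
                        (35e-9, 8.3e-6, 30 * 3600)]:
            grid = wide_grid(v, d, t)
            p = gaussian_pair_profile(v, d, t, 0.0, grid)
            lead, trail = split_ee(p, 0.0)
            ee_pred = 100 * ee_vs_time(v, d, t)
            assert ee_pred <= 31.0
            assert abs(lead - ee_pred) < 1.0
            assert abs(trail + ee_pred) < 1.0

    def test_centre_split_matches_erf_exactly(self):
        v, d, t = 25e-9, 8.3e-6, 45 * 3600
        grid = wide_grid(v, d, t)
        lead, _ = split_ee(gaussian_pair_profile(v, d, t, 0.0, grid), 0.0)
        exact = 100 * erf(v * 100 / 2 * math.sqrt(t / d))
        assert lead == pytest.approx(exact, abs=0.05)

    def test_off_centre_cut_is_more_enriched(self):
        v, d, t = 25e-9, 8.3e-6, 45 * 3600
        grid = wide_grid(v, d, t)
        p = gaussian_pair_profile(v, d, t, 0.0, grid)
        centre, _ = split_ee(p, 0.0)
        sigma = math.sqrt(2 * d * t)
        edge, _ = split_ee(p, 1.5 * sigma)
        assert abs(edge) > abs(centre)

    def test_no_drift_gives_zero_both_sides(self):
        grid = np.linspace(-2, 2, 401)
        p = gaussian_pair_profile(0.0, 8.3e-6, 3600, 0.0, grid)
        lead, trail = split_ee(p, 0.0)
        assert lead == pytest.approx(0.0, abs=1e-12)
        assert trail == pytest.approx(0.0, abs=1e-12)

    def test_empty_side_rejected(self):
        grid = np.linspace(0, 2, 201)
        p = gaussian_pair_profile(0.0, 8.3e-6, 10.0, 1.0, grid)
        with pytest.raises(ValueError, match="outside|empty"):
            split_ee(p, 5.0)


class TestEvolveBounded:
    def setup_profile(self, active=(-5.0, 5.0)):
        grid = np.linspace(-8, 8, 801)
        return gaussian_pair_profile(0.0, 8.3e-6, 2 * 3600, 0.0, grid, active_region=active)

    def test_pure_diffusion_variance_growth(self):
        p0 = self.setup_profile()
        d = 8.3e-6
        dt = 0.25 * p0.dx**2 / d
        n = 1500
        p1 = evolve_bounded(p0, 0.0, d, dt, n)
        var0 = np.trapezoid(p0.grid**2 * p0.c_s, p0.grid) / p0.mass()[0]
        var1 = np.trapezoid(p1.grid**2 * p1.c_s, p1.grid) / p1.mass()[0]
        assert var1 - var0 == pytest.approx(2 * d * n * dt, rel=0.01)

    def test_mass_conserved(self):
        p0 = self.setup_profile()
        d = 8.3e-6
        dt = 0.25 * p0.dx**2 / d
        p1 = evolve_bounded(p0, 30e-9, d, dt, 2000)
        assert p1.mass()[0] == pytest.approx(p0.mass()[0], rel=1e-6)
        assert p1.mass()[1] == pytest.approx(p0.mass()[1], rel=1e-6)

    def test_matches_free_gaussian_at_short_times(self):
        # wide active region, slug far from walls: FD solution ~ analytic pair
        d = 8.3e-6
        v = 45e-9
        t0, t1 = 2 * 3600, 4 * 3600
        grid = np.linspace(-8, 8, 1601)
        p0 = gaussian_pair_profile(v, d, t0, 0.0, grid, active_region=(-8, 8))
        dt = 0.25 * p0.dx**2 / d
        n = int(round((t1 - t0) / dt))
        p_fd = evolve_bounded(p0, v, d, (t1 - t0) / n, n)
        p_exact = gaussian_pair_profile(v, d, t1, 0.0, grid)
        assert np.max(np.abs(p_fd.c_s - p_exact.c_s)) < 0.01 * p_exact.c_s.max()
        lead_fd, _ = split_ee(p_fd, 0.0)
        lead_exact, _ = split_ee(p_exact, 0.0)
        assert lead_fd == pytest.approx(lead_exact, abs=0.3)

    def test_bounded_ee_does_not_exceed_unbounded(self):
        # long exposure: material outside the 10-cm active area stops drifting
        d = 1.4e-5
        v = 45e-9
        grid = np.linspace(-12, 12, 1201)
        p0 = gaussian_pair_profile(0.0, d, 60.0, 0.0, grid, active_region=(-5, 5))
        dt = 0.4 * p0.dx**2 / d
        t_total = 60 * 3600
        n = int(t_total / dt)
        p1 = evolve_bounded(p0, v, d, dt, n)
        lead, _ = split_ee(p1, 0.0)
        assert abs(lead) <= 100 * ee_vs_time(v, d, t_total)

    def test_cfl_violation_rejected(self):
        p0 = self.setup_profile()
        with pytest.raises(ParameterError, match="unstable"):
            evolve_bounded(p0, 0.0, 8.3e-6, 1e6, 1)


class TestSteadyState:
    def test_spatial_mean_is_average_concentration(self):
        grid = np.linspace(0, 10, 2001)
        v = 8.3e-6 / 3.0 / 100.0  # D/v = 3 cm
        p = steady_state_profile(v, 8.3e-6, 10.0, 2.5, grid)
        assert np.trapezoid(p.c_s, grid) / 10.0 == pytest.approx(2.5, rel=1e-6)
        assert np.trapezoid(p.c_r, grid) / 10.0 == pytest.approx(2.5, rel=1e-6)

    def test_zero_flux_everywhere(self):
        grid = np.linspace(0, 10, 4001)
        d = 8.3e-6
        v = d / 3.0 / 100.0
        p = steady_state_profile(v, d, 10.0, 1.0, grid)
        # central-difference flux on interior points
        dcdx = (p.c_s[2:] - p.c_s[:-2]) / (2 * p.dx)
        flux = v * 100 * p.c_s[1:-1] - d * dcdx
        assert np.max(np.abs(flux)) < 1e-4 * (v * 100 * p.c_s.max())

    def test_opposite_enantiomer_profile_is_mirrored(self):
        grid = np.linspace(0, 10, 1001)
        p = steady_state_profile(30e-9, 8.3e-6, 10.0, 1.0, grid)
        assert np.allclose(p.c_r, p.c_s[::-1], rtol=1e-9)

    def test_zero_velocity_limit_uniform(self):
        grid = np.linspace(0, 10, 101)
        p = steady_state_profile(0.0, 8.3e-6, 10.0, 1.7, grid)
        assert np.allclose(p.c_s, 1.7)


class TestCharacteristicLength:
    def test_molecule_i_reference_values(self):
        # D/v from the measured diffusion coefficient and predicted velocity
        assert characteristic_length(8.3e-6, 25e-9) == pytest.approx(3.4, rel=0.07)

    def test_molecule_ii_reference_values(self):
        assert characteristic_length(1.4e-5, 45e-9) == pytest.approx(3.0, rel=0.07)

    def test_halves_when_velocity_doubles(self):
        assert characteristic_length(8.3e-6, 50e-9) == pytest.approx(
            characteristic_length(8.3e-6, 25e-9) / 2, rel=1e-12)

    def test_zero_velocity_is_infinite(self):
        assert characteristic_length(8.3e-6, 0.0) == math.inf


class TestEnrichment:
    @pytest.mark.parametrize("ee, expected", [(61.0, 80.5), (0.0, 50.0), (100.0, 100.0),
                                              (-61.0, 80.5)])
    def test_conversion(self, ee, expected):
        assert enrichment_from_ee(ee) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            enrichment_from_ee(120.0)


class TestVelocityFit:
    def test_recovers_velocity_from_noisy_ee_series(self, rng):
        # emulates fitting an enrichment-vs-exposure curve: 5% multiplicative
        # noise on ee(t) generated at 50 nm/s
        v_true, d = 50e-9, 1.4e-5
        t = np.linspace(1, 46, 12) * 3600.0
        ee = np.array([ee_vs_time(v_true, d, ti) for ti in t])
        ee_noisy = ee * (1 + 0.05 * rng.standard_normal(len(t)))
        v_hat, stderr = fit_propulsion_velocity(t, ee_noisy, d)
        assert v_hat == pytest.approx(v_true, rel=0.10)
        assert stderr > 0

    def test_exact_data_recovered_exactly(self):
        v_true, d = 25e-9, 8.3e-6
        t = np.linspace(1, 45, 8) * 3600.0
        ee = [ee_vs_time(v_true, d, ti) for ti in t]
        v_hat, stderr = fit_propulsion_velocity(t, ee, d)
        assert v_hat == pytest.approx(v_true, rel=1e-12)
        assert stderr == pytest.approx(0.0, abs=1e-15)


class TestProfileIO:
    def test_csv_round_trip(self, tmp_path):
        grid = np.linspace(-2, 2, 101)
        p = gaussian_pair_profile(25e-9, 8.3e-6, 3600, 0.0, grid, active_region=(-1, 1))
        path = tmp_path / "profile.csv"
        write_profile_csv(p, path)
        back = read_profile_csv(path, active_region=(-1, 1))
        assert np.allclose(back.c_s, p.c_s, rtol=1e-12)
        assert np.allclose(back.grid, p.grid, rtol=1e-12)

    def test_profile_validation(self):
        with pytest.raises(ValueError, match="uniform"):
            ConcentrationProfile(np.array([0.0, 1.0, 3.0]), np.ones(3), np.ones(3))
        with pytest.raises(ValueError):
            ConcentrationProfile(np.array([0.0, 1.0]), -np.ones(2), np.ones(2))
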