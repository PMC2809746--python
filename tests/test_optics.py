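"""Photon statistics: molecule counts, PSF kernel, image formation, noise."""

import numpy as np
import pytest

from synbow.neuropil import SizeDistribution, VolumeSpec, rasterize_synapse_map
from synbow.optics import (
    MICROMOLAR_TO_PER_UM3,
    OperatingPoint,
    PhotonField,
    PSFSpec,
    background_photon_stats,
    downsample_optical,
    make_psf_kernel,
    molecule_count_stats,
    optical_grid,
    photon_field,
    sample_realization,
    synapse_photon_contributions,
)

from conftest import point_synapse


def _single_source_field(vol, area=0.05, op=None, center=None):
    op = op or OperatingPoint()
    syn = point_synapse(center or np.asarray(vol.extents_um) / 2, area=area)
    surface = rasterize_synapse_map([syn], vol)
    return syn, surface, op


class TestMoleculeStats:
    def test_zero_surface_gives_zero_stats(self, small_volume, op_default):
        _, surface, _ = _single_source_field(small_volume)
        surface.values[:] = 0
        mean, var = molecule_count_stats(surface, op_default)
        assert not mean.any() and not var.any()

    def test_conditional_mean_is_concentration_times_area(self):
        """0.05 µm² at 750 µm⁻² binds 37.5 molecules on average."""
        vol = VolumeSpec((1, 1, 1), (0.5, 0.5, 0.5))
        _, surface, op = _single_source_field(vol, area=0.05,
                                              center=(0.25, 0.25, 0.25))
        mean, var = molecule_count_stats(surface, op, mode="conditional")
        assert mean.sum() == pytest.approx(37.5)
        assert var.sum() == pytest.approx(37.5)  # pure Poisson

    def test_negative_surface_rejected(self, small_volume, op_default):
        _, surface, _ = _single_source_field(small_volume)
        surface.values.flat[0] = -1.0
        with pytest.raises(ValueError):
            molecule_count_stats(surface, op_default)

    def test_marginal_variance_matches_bernoulli_poisson_monte_carlo(self):
        """Marginal mode adds the Brainbow term f(1−f)c²s²; check against a
        direct Bernoulli(f) × Poisson(c·s) simulation."""
        rng = np.random.default_rng(0)
        f, c, s = 0.5, 750.0, 0.05
        n = 100_000
        expressed = rng.random(n) < f
        draws = np.where(expressed, rng.poisson(c * s, size=n), 0)
        vol = VolumeSpec((1, 1, 1), (0.5, 0.5, 0.5))
        _, surface, op = _single_source_field(vol, area=s,
                                              center=(0.25, 0.25, 0.25))
        mean, var = molecule_count_stats(surface, op, mode="marginal")
        mc_mean, mc_var = draws.mean(), draws.var(ddof=1)
        se_mean = draws.std(ddof=1) / np.sqrt(n)
        se_var = mc_var * np.sqrt(2.0 / (n - 1)) * 3  # loose normal-theory SE
        assert abs(mean.sum() - mc_mean) < 3 * se_mean
        assert abs(var.sum() - mc_var) < max(3 * se_var, 0.05 * mc_var)
        assert var.sum() > mean.sum()  # over-dispersed


class TestPSFKernel:
    def test_unit_sum_and_symmetry(self, small_volume):
        k = make_psf_kernel(PSFSpec(0.2, 0.5), small_volume)
        assert k.sum() == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(k, k[::-1, ::-1, ::-1])

    def test_isotropic_resolution_gives_spherical_kernel(self):
        vol = VolumeSpec((2, 2, 2), (0.05, 0.05, 0.05))
        k = make_psf_kernel(PSFSpec(0.3, 0.3), vol)
        c = np.array(k.shape) // 2
        np.testing.assert_allclose(k[:, c[1], c[2]], k[c[0], c[1], :],
                                   rtol=1e-10)

    def test_discretized_fwhm_matches_resolution(self):
        d = 0.2
        vol = VolumeSpec((4, 4, 4), (d / 4, d / 4, d / 4))
        k = make_psf_kernel(PSFSpec(d, d), vol)
        c = np.array(k.shape) // 2
        profile = k[:, c[1], c[2]]
        x = (np.arange(len(profile)) - c[0]) * d / 4
        half = profile.max() / 2
        # interpolate the half-max crossing
        fine_x = np.linspace(x[0], x[-1], 2001)
        fine = np.interp(fine_x, x, profile)
        width = fine_x[fine >= half][-1] - fine_x[fine >= half][0]
        assert width == pytest.approx(d, rel=0.05)

    def test_too_tight_truncation_rejected(self):
        with pytest.raises(ValueError):
            PSFSpec(0.2, 0.2, truncation_sigma=1.5)

    def test_undersampled_grid_warns(self):
        vol = VolumeSpec((2, 2, 2), (0.2, 0.2, 0.2))
        with pytest.warns(UserWarning, match="undersamples"):
            make_psf_kernel(PSFSpec(0.2, 0.2), vol)


class TestPhotonField:
    def test_zero_photon_budget_gives_dark_image(self, small_volume):
        _, surface, _ = _single_source_field(small_volume)
        op = OperatingPoint(h_photons=0.0)
        mean, var = molecule_count_stats(surface, op)
        k = make_psf_kernel(PSFSpec(0.2, 0.2), small_volume)
        fld = photon_field(mean, var, k, op, small_volume)
        assert not fld.mean.any() and not fld.variance.any()

    def test_total_photons_conserved(self, small_volume, op_default):
        """Unit-sum kernel: total photons = h × total molecules."""
        _, surface, op = _single_source_field(small_volume)
        mean, var = molecule_count_stats(surface, op)
        k = make_psf_kernel(PSFSpec(0.2, 0.2), small_volume)
        fld = photon_field(mean, var, k, op, small_volume)
        assert fld.mean.sum() == pytest.approx(
            op.h_photons * mean.sum(), rel=1e-3)

    def test_point_source_peak_value(self):
        """50 molecules in one voxel, h=1000: peak voxel mean = 50·h·K(0)."""
        vol = VolumeSpec((2, 2, 2), (0.05, 0.05, 0.05))
        op = OperatingPoint()
        mol = np.zeros(vol.shape)
        mol[20, 20, 20] = 50.0
        k = make_psf_kernel(PSFSpec(0.2, 0.2), vol)
        fld = photon_field(mol, mol.copy(), k, op, vol)
        k0 = k.max()
        assert fld.mean.max() == pytest.approx(50 * 1000 * k0, rel=1e-6)

    def test_mismatched_grid_rejected(self, small_volume, op_default):
        k = make_psf_kernel(PSFSpec(0.2, 0.2), small_volume)
        with pytest.raises(ValueError):
            photon_field(np.zeros((4, 4, 4)), np.zeros((4, 4, 4)), k,
                         op_default, small_volume)

    def test_linearity_of_mean_fields(self, small_volume, op_default):
        rng = np.random.default_rng(3)
        k = make_psf_kernel(PSFSpec(0.2, 0.2), small_volume)
        for _ in range(3):
            c1, c2 = rng.random((2, 3)) * [2.5, 2.5, 1.5] + 0.25
            s1 = rasterize_synapse_map([point_synapse(c1, 0.05)], small_volume)
            s2 = rasterize_synapse_map(
                [point_synapse(c2, 0.08, sid=1)], small_volume)
            both = rasterize_synapse_map(
                [point_synapse(c1, 0.05), point_synapse(c2, 0.08, sid=1)],
                small_volume)
            f1 = photon_field(*molecule_count_stats(s1, op_default), k,
                              op_default, small_volume)
            f2 = photon_field(*molecule_count_stats(s2, op_default), k,
                              op_default, small_volume)
            fb = photon_field(*molecule_count_stats(both, op_default), k,
                              op_default, small_volume)
            np.testing.assert_allclose(fb.mean, f1.mean + f2.mean, atol=1e-9)

    def test_overdispersion_wherever_signal(self, small_volume, op_default):
        _, surface, op = _single_source_field(small_volume)
        mean, var = molecule_count_stats(surface, op)
        k = make_psf_kernel(PSFSpec(0.2, 0.2), small_volume)
        fld = photon_field(mean, var, k, op, small_volume)
        sig = fld.mean > 1e-6
        assert np.all(fld.variance[sig] >= fld.mean[sig])


class TestOpticalDownsampling:
    def test_idlm_optical_voxel_is_50nm(self):
        vol = VolumeSpec((4, 4, 2), (0.05, 0.05, 0.05))
        grid = optical_grid(vol, PSFSpec(0.2, 0.2))
        assert grid.voxel_size_um == (0.05, 0.05, 0.05)
        grid_sim = optical_grid(vol, PSFSpec(0.1, 0.1))
        assert grid_sim.voxel_size_um == (0.025, 0.025, 0.025)

    def test_total_mean_conserved(self, small_volume, op_default):
        _, surface, op = _single_source_field(small_volume)
        mean, var = molecule_count_stats(surface, op)
        k = make_psf_kernel(PSFSpec(0.4, 0.4), small_volume)
        fld = photon_field(mean, var, k, op, small_volume)
        down = downsample_optical(fld, PSFSpec(0.4, 0.4))
        assert down.mean.sum() == pytest.approx(fld.mean.sum(), rel=1e-12)
        assert down.variance.sum() == pytest.approx(fld.variance.sum(),
                                                    rel=1e-12)

    def test_anisotropic_per_axis_factors(self):
        vol = VolumeSpec((4, 4, 4), (0.008, 0.008, 0.05))
        fld = PhotonField(0, vol, np.ones(vol.shape), np.ones(vol.shape))
        down = downsample_optical(fld, PSFSpec(0.2, 0.8), per_axis=True)
        # d_xy/4 = 50 nm (factor ~6 on 8 nm), d_z/4 = 200 nm (factor 4)
        assert down.grid.voxel_size_um[2] == pytest.approx(0.2)
        assert down.mean.sum() == pytest.approx(fld.mean.sum())

    def test_finer_target_than_source_rejected(self):
        vol = VolumeSpec((2, 2, 2), (0.1, 0.1, 0.1))
        fld = PhotonField(0, vol, np.zeros(vol.shape), np.zeros(vol.shape))
        with pytest.raises(ValueError):
            downsample_optical(fld, PSFSpec(0.1, 0.1))


class TestRealization:
    def test_zero_variance_returns_mean(self):
        vol = VolumeSpec((1, 1, 1), (0.25, 0.25, 0.25))
        mean = np.full(vol.shape, 7.0)
        fld = PhotonField(0, vol, mean, np.zeros_like(mean))
        img = sample_realization(fld, 0)
        np.testing.assert_array_equal(img, mean)

    def test_normal_sampling_statistics(self):
        vol = VolumeSpec((23.2, 21.6, 20.0), (1.0, 1.0, 1.0))  # ~1e4 voxels
        n = np.prod(vol.shape)
        mean = np.full(vol.shape, 100.0)
        var = np.full(vol.shape, 150.0)
        img = sample_realization(PhotonField(0, vol, mean, var), 5)
        assert img.mean() == pytest.approx(100.0, abs=4 * np.sqrt(150 / n))
        assert img.var(ddof=1) == pytest.approx(150.0, rel=0.05)
        assert img.min() >= 0.0

    def test_poisson_mode(self):
        vol = VolumeSpec((10, 10, 10), (1.0, 1.0, 1.0))
        mean = np.full(vol.shape, 4.0)
        img = sample_realization(
            PhotonField(0, vol, mean, mean.copy()), 1, mode="poisson")
        assert np.all(img == np.round(img))
        assert img.mean() == pytest.approx(4.0, rel=0.1)


class TestAnalyticContributions:
    def test_contributions_match_grid_convolution(self, op_default):
        """The sparse analytic route and the rasterize-convolve route agree
        on total photons and on the blurred profile."""
        vol = VolumeSpec((2, 2, 2), (0.025, 0.025, 0.025))
        psf = PSFSpec(0.2, 0.2)
        # centred on a voxel center so the raster route's snap-to-voxel does
        # not introduce a systematic half-voxel offset
        syn = point_synapse((1.0125, 1.0125, 1.0125), area=0.05)
        contribs = synapse_photon_contributions([syn], vol, psf, op_default)
        dense = np.zeros(vol.shape)
        np.add.at(dense.ravel(), contribs[0].voxels, contribs[0].mean)
        surface = rasterize_synapse_map([syn], vol)
        mean, var = molecule_count_stats(surface, op_default)
        k = make_psf_kernel(psf, vol)
        fld = photon_field(mean, var, k, op_default, vol)
        total = op_default.h_photons * op_default.c_per_um2 * 0.05
        assert dense.sum() == pytest.approx(total, rel=1e-3)
        assert fld.mean.sum() == pytest.approx(total, rel=1e-3)
        # profiles agree in relative RMS over the signal region (the grid
        # route quantizes surface mass to voxel centers, so pointwise
        # differences concentrate on steep Gaussian flanks)
        m = fld.mean > fld.mean.max() * 0.05
        rms = np.sqrt(np.mean((dense[m] - fld.mean[m]) ** 2))
        assert rms < 0.05 * fld.mean[m].mean()
        # peak position agrees
        assert np.unravel_index(dense.argmax(), dense.shape) == \
            np.unravel_index(fld.mean.argmax(), fld.mean.shape)

    def test_double_poisson_normal_approximation_against_monte_carlo(self):
        """Full Bernoulli(f) × Poisson(molecules) × Poisson(photons) MC on a
        3-synapse toy volume matches the Normal-model mean/variance maps."""
        vol = VolumeSpec((2, 2, 1), (0.1, 0.1, 0.1))
        psf = PSFSpec(0.3, 0.3)
        op = OperatingPoint(f=0.5, c_per_um2=750, b_uM=0.0, h_photons=50)
        syns = [point_synapse((0.7, 1.0, 0.5), 0.04, sid=0),
                point_synapse((1.0, 1.0, 0.5), 0.05, sid=1),
                point_synapse((1.3, 1.1, 0.5), 0.03, sid=2)]
        analytic = np.zeros(vol.shape)
        analytic_var = np.zeros(vol.shape)
        rng = np.random.default_rng(17)
        n_rep = 10_000
        mc = np.zeros((n_rep,) + vol.shape)
        marg = synapse_photon_contributions(
            syns, vol, psf, op, n_points=1, marginal=True,
            min_mean_photons=0.0)
        for s, c in zip(syns, marg):
            np.add.at(analytic.ravel(), c.voxels, c.mean)
            np.add.at(analytic_var.ravel(), c.voxels, c.variance)
            # photon fraction per voxel from the conditional mean
            cond = synapse_photon_contributions(
                [s], vol, psf, op, n_points=1, min_mean_photons=0.0)[0]
            lam_mol = op.c_per_um2 * s.area
            frac = cond.mean / (op.h_photons * lam_mol)
            expressed = rng.random(n_rep) < op.f
            mols = rng.poisson(lam_mol, size=n_rep) * expressed
            lam_phot = np.outer(mols, op.h_photons * frac)
            draws = rng.poisson(lam_phot)
            np.add.at(mc.reshape(n_rep, -1), (slice(None), cond.voxels), draws)
        mc_mean = mc.mean(axis=0)
        mc_var = mc.var(axis=0, ddof=1)
        se_mean = mc.std(axis=0, ddof=1) / np.sqrt(n_rep) + 1e-9
        hot = analytic > analytic.max() * 0.05
        assert np.all(np.abs(mc_mean - analytic)[hot] < 4 * se_mean[hot])
        # variance agreement (looser: SE of a variance estimate)
        se_var = mc_var * np.sqrt(2.0 / n_rep) + 1e-9
        assert np.all(np.abs(mc_var - analytic_var)[hot]
                      < 5 * se_var[hot] + 0.02 * analytic_var[hot])


def test_background_stats_use_avogadro_conversion(op_default):
    vol = VolumeSpec((1, 1, 1), (0.05, 0.05, 0.05))
    bg_mean, bg_var = background_photon_stats(op_default, vol)
    expected = 1000 * 0.1 * MICROMOLAR_TO_PER_UM3 * 0.05**3
    assert bg_mean == pytest.approx(expected)
    assert bg_var == pytest.approx(expected)
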