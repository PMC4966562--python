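"""Filtering and filtered-backprojection: kernels, oracles, 4D behaviour."""

import numpy as np
import pytest
from skimage.data import shepp_logan_phantom
from skimage.transform import iradon, radon, resize

import cbct4d as c
from cbct4d.errors import EmptyPhaseBinError
from cbct4d.reconstruction import ramp_kernel


class TestRampFilter:
    def test_impulse_yields_ramlak_kernel(self):
        n = 64
        data = np.zeros((1, 1, n))
        data[0, 0, n // 2] = 1.0
        projs = c.ProjectionSet(data=data, timestamps=np.zeros(1),
                                angles=np.zeros(1), mode="parallel")
        out = c.filter_projections(projs).data[0, 0]
        # closed-form kernel at unit pitch, centered on the impulse
        h = ramp_kernel(n, 1.0)
        expected = h[n - 1 - n // 2:2 * n - 1 - n // 2]
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_linearity(self, rng):
        a = rng.normal(size=(3, 4, 128))
        b = rng.normal(size=(3, 4, 128))
        mk = lambda d: c.ProjectionSet(data=d, timestamps=np.zeros(3),
                                       angles=np.zeros(3), mode="parallel")
        fa = c.filter_projections(mk(a)).data
        fb = c.filter_projections(mk(b)).data
        fab = c.filter_projections(mk(a + b)).data
        np.testing.assert_allclose(fab, fa + fb, atol=1e-9)

    def test_constant_row_filtered_to_zero(self):
        data = np.full((1, 1, 256), 3.0)
        projs = c.ProjectionSet(data=data, timestamps=np.zeros(1),
                                angles=np.zeros(1), mode="parallel")
        out = c.filter_projections(projs).data[0, 0]
        # ramp kills DC away from the edges
        assert np.abs(out[64:192]).max() < 1e-2 * np.abs(out).max()

    def test_hann_window_suppresses_high_frequencies(self, rng):
        data = rng.normal(size=(1, 1, 256))
        projs = c.ProjectionSet(data=data, timestamps=np.zeros(1),
                                angles=np.zeros(1), mode="parallel")
        ramp = c.filter_projections(projs, window="ramp").data
        hann = c.filter_projections(projs, window="hann").data
        assert np.abs(hann).sum() < np.abs(ramp).sum()

    def test_empty_set_rejected(self):
        projs = c.ProjectionSet(data=np.zeros((0, 1, 8)),
                                timestamps=np.zeros(0), angles=np.zeros(0))
        with pytest.raises(ValueError):
            c.filter_projections(projs)


class TestParallelFbpOracle:
    def test_matches_textbook_fbp_on_shepp_logan(self):
        """Dual-route check: our FBP vs an independent implementation."""
        img = resize(shepp_logan_phantom(), (128, 128), anti_aliasing=True)
        angles = np.arange(180.0)
        sino = radon(img, theta=angles)  # (n_s, n_angles)
        n_s = sino.shape[0]
        # skimage centers both sinogram and image on index n//2
        ss = np.arange(n_s) - n_s // 2
        ours = c.reconstruct_parallel2d(sino.T, angles, ss, (128, 128), 1.0,
                                        center=(-0.5, -0.5))
        theirs_xy = iradon(sino, theta=angles, filter_name="ramp",
                           interpolation="linear", circle=True)
        xs = (np.arange(128) - 63.5)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        inside = X ** 2 + Y ** 2 < 55 ** 2
        rms = np.sqrt(np.mean((ours - theirs_xy)[inside] ** 2))
        assert rms < 0.01 * np.ptp(theirs_xy[inside])

    def test_water_cylinder_parallel(self, water_cylinder):
        ss = (np.arange(200) - 99.5) * 0.1
        angles = np.arange(0.0, 180.0, 1.0)
        sino = c.parallel_sinogram(water_cylinder, angles, ss,
                                   sampling_step=0.05)
        img = c.reconstruct_parallel2d(sino, angles, ss, (100, 100), 0.2)
        xs = (np.arange(100) - 49.5) * 0.2
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        core = X ** 2 + Y ** 2 < 4 ** 2
        assert img[core].mean() == pytest.approx(c.MU_WATER, rel=0.02)


class TestFdk:
    def test_water_cylinder_amplitude(self, water_cone_scan):
        grid = c.GridSpec.centered((64, 64, 8), (0.25, 0.25, 0.4))
        vol = c.reconstruct(water_cone_scan, grid)
        xs, ys, _ = grid.axis_centers()
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        core = X ** 2 + Y ** 2 < 4 ** 2
        assert vol.values[:, :, 4][core].mean() == pytest.approx(
            c.MU_WATER, rel=0.02)

    def test_zero_projections_reconstruct_to_zero(self, water_cone_scan):
        from dataclasses import replace
        zeros = replace(water_cone_scan,
                        data=np.zeros_like(water_cone_scan.data))
        grid = c.GridSpec.centered((16, 16, 4), (0.5, 0.5, 0.5))
        vol = c.reconstruct(zeros, grid)
        assert np.allclose(vol.values, 0.0)

    def test_empty_projection_set_rejected(self, water_cone_scan):
        with pytest.raises(ValueError):
            c.reconstruct(water_cone_scan.subset([]),
                          c.GridSpec.centered((8, 8, 2), (1, 1, 1)))

    def test_pipeline_linearity_in_mu(self, water_cylinder, small_detector):
        """Scaling the phantom's attenuation scales the reconstruction."""
        denser = c.DigitalPhantom(
            housing_radius=8.0,
            modules=[c.PhantomModule("u", (-6.0, 6.0), background_hu=1000.0)])
        proto = c.AcquisitionProtocol(gantry_speed=6.0, frame_rate=0.5,
                                      detector=small_detector)
        grid = c.GridSpec.centered((32, 32, 4), (0.4, 0.4, 0.5))
        v1 = c.reconstruct(c.forward_project(water_cylinder, None, proto,
                                             sampling_step=0.1), grid)
        v2 = c.reconstruct(c.forward_project(denser, None, proto,
                                             sampling_step=0.1), grid)
        # mu doubles from 0 HU to +1000 HU
        np.testing.assert_allclose(v2.values, 2.0 * v1.values, atol=2e-3)


class TestHuCalibration:
    def test_anchor_values(self, water_cone_scan):
        grid = c.GridSpec.centered((8, 8, 2), (1, 1, 1))
        vol = c.reconstruct(water_cone_scan.subset(np.arange(10)), grid)
        hu = c.calibrate_hu(vol)
        np.testing.assert_allclose(
            hu.values, 1000 * (vol.values - c.MU_WATER) / c.MU_WATER)

    def test_round_trip_with_hu_to_mu(self, rng):
        mu = rng.uniform(0, 0.4, size=(4, 4, 4))
        vol = c.VoxelVolume(values=mu, spacing=(1, 1, 1), origin=(0, 0, 0))
        back = c.hu_to_mu(c.calibrate_hu(vol).values)
        np.testing.assert_allclose(back, mu, atol=1e-9)

    def test_invalid_mu_water(self, rng):
        vol = c.VoxelVolume(values=rng.uniform(size=(2, 2, 2)),
                            spacing=(1, 1, 1), origin=(0, 0, 0))
        with pytest.raises(c.ConfigurationError):
            c.calibrate_hu(vol, mu_water=0.0)


class TestReconstruct4d:
    def test_bins_share_grid_and_empty_bin_named(self, water_cone_scan):
        grid = c.GridSpec.centered((16, 16, 4), (1, 1, 1))
        bins = [water_cone_scan.subset(np.arange(i, 90, 9))
                for i in range(9)]
        vols = c.reconstruct_4d(bins, grid)
        assert len(vols) == 9
        assert all(v.values.shape == (16, 16, 4) for v in vols)
        bins[4] = water_cone_scan.subset([])
        with pytest.raises(EmptyPhaseBinError, match="bin 4"):
            c.reconstruct_4d(bins, grid)

    def test_static_phantom_phases_agree(self, water_cone_scan):
        grid = c.GridSpec.centered((24, 24, 4), (0.5, 0.5, 0.5))
        bins = [water_cone_scan.subset(np.arange(i, 90, 3))
                for i in range(3)]
        vols = c.reconstruct_4d(bins, grid)
        for v in vols[1:]:
            diff = v.values - vols[0].values
            assert np.sqrt(np.mean(diff ** 2)) < 10.0  # HU, noiseless

    def test_sparse_bin_has_more_artifact_than_average(self, water_cone_scan):
        """Fewer angles per bin -> streaks: higher error vs the full recon."""
        grid = c.GridSpec.centered((24, 24, 2), (0.5, 0.5, 0.5))
        full = c.reconstruct(water_cone_scan, grid)
        sparse = c.reconstruct(water_cone_scan.subset(np.arange(0, 90, 10)),
                               grid)
        truth = c.voxelize(
            c.DigitalPhantom(housing_radius=8.0,
                             modules=[c.PhantomModule("u", (-6.0, 6.0))]),
            grid)
        full_err = np.sqrt(np.mean(
            (c.calibrate_hu(full).values - truth.values) ** 2))
        sparse_err = np.sqrt(np.mean(
            (c.calibrate_hu(sparse).values - truth.values) ** 2))
        assert sparse_err > full_err


class TestNifti:
    def test_round_trip(self, tmp_path, rng):
        vol = c.VoxelVolume(values=rng.normal(size=(8, 6, 4)),
                            spacing=(0.25, 0.25, 0.1),
                            origin=(-1.0, -0.75, -0.2),
                            provenance={"phase_bin": 3})
        path = tmp_path / "vol.nii.gz"
        vol.save_nifti(path)
        back = c.VoxelVolume.load_nifti(path)
        np.testing.assert_allclose(back.values, vol.values, atol=1e-5)
        np.testing.assert_allclose(back.spacing, vol.spacing)
        np.testing.assert_allclose(back.origin, vol.origin)
        assert back.provenance["phase_bin"] == 3
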