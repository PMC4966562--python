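"""Image-quality metrics: MTF, CNR, UI, HU sensitivity, excursion, mAs norm."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import gaussian_filter

import cbct4d as c
from cbct4d.errors import InsertDetectionError, MtfFitError
from cbct4d.metrics import F_MAX_SIGMA_RATIO


def bar_phantom(frequencies, n_cycles=4, bar_length=2.0):
    groups = [c.BarGroupSpec(frequency=f, n_cycles=n_cycles,
                             center=(0.0, 0.0, 0.0), bar_hu=500.0,
                             background_hu=0.0, orientation=0.0,
                             bar_length=bar_length, bar_height=2.0)
              for f in frequencies]
    # one group per phantom instance keeps groups from overlapping
    return [c.DigitalPhantom(housing_radius=6.0, modules=[
        c.PhantomModule("bars", (-2.0, 2.0), bar_groups=[g])])
        for g in groups]


def gaussian_square_wave_ctf(f, sigma_cm, n_terms=25):
    """Closed-form square-wave (bar-pattern) response of a Gaussian PSF.

    Fourier series of the square wave filtered by MTF(f)=exp(-2 pi^2 s^2 f^2):
    CTF(f) = (4/pi) sum_k (-1)^((k-1)/2) MTF(k f)/k over odd k.
    """
    total = 0.0
    for i, k in enumerate(range(1, 2 * n_terms, 2)):
        total += (-1) ** i * math.exp(
            -2 * math.pi ** 2 * sigma_cm ** 2 * (k * f) ** 2) / k
    return 4.0 / math.pi * total


class TestMtfRaw:
    def test_unblurred_bars_give_full_modulation(self):
        phantoms = bar_phantom([1.0, 2.0])
        for ph, f in zip(phantoms, [1.0, 2.0]):
            grid = c.GridSpec.centered((240, 120, 3), (0.025, 0.025, 0.5))
            vol = c.voxelize(ph, grid)
            freqs, raws, _ = c.mtf_raw(vol, ph.modules[0].bar_groups)
            assert freqs[0] == f
            assert raws[0] == pytest.approx(1.0, abs=0.02)

    def test_uniform_volume_has_zero_modulation(self):
        vol = c.VoxelVolume(values=np.zeros((64, 64, 3)),
                            spacing=(0.05, 0.05, 0.5),
                            origin=(-1.6, -1.6, -0.5))
        group = c.BarGroupSpec(frequency=2.0, n_cycles=2,
                               center=(0.0, 0.0, 0.0), bar_length=0.5,
                               bar_height=0.5)
        _, raws, _ = c.mtf_raw(vol, [group])
        assert raws[0] == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_blur_matches_closed_form_ctf(self):
        """Blurred bar modulation follows the analytic square-wave CTF."""
        sigma_cm = 0.08
        spacing = 0.02
        freqs = [1.0, 2.0, 3.0, 4.0]
        for ph, f in zip(bar_phantom(freqs, n_cycles=6), freqs):
            grid = c.GridSpec.centered((360, 160, 3), (spacing, spacing, 0.5))
            vol = c.voxelize(ph, grid)
            blurred = gaussian_filter(vol.values,
                                      (sigma_cm / spacing,
                                       sigma_cm / spacing, 0))
            vol = c.VoxelVolume(values=blurred, spacing=vol.spacing,
                                origin=vol.origin)
            _, raws, _ = c.mtf_raw(vol, ph.modules[0].bar_groups)
            expected = gaussian_square_wave_ctf(f, sigma_cm)
            assert raws[0] == pytest.approx(expected, rel=0.05)

    def test_unresolvable_group_excluded(self):
        vol = c.VoxelVolume(values=np.zeros((32, 32, 3)),
                            spacing=(0.2, 0.2, 0.5), origin=(-3.1, -3.1, -0.5))
        groups = [c.BarGroupSpec(frequency=f, n_cycles=2,
                                 center=(0.0, 0.0, 0.0), bar_length=0.5,
                                 bar_height=0.5) for f in (1.0, 8.0)]
        freqs, _, excluded = c.mtf_raw(vol, groups)
        assert list(freqs) == [1.0]
        assert excluded == [8.0]


class TestMtfFit:
    def test_recovers_exact_gaussian(self):
        f = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.exp(-f ** 2 / (2 * 2.5 ** 2))
        sigma, r2 = c.fit_mtf_gaussian(f, y)
        assert sigma == pytest.approx(2.5, abs=1e-6)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_mean_recovery_under_noise(self, rng):
        f = np.linspace(0.5, 6.0, 10)
        truth = 2.0
        sigmas = []
        for _ in range(100):
            y = np.exp(-f ** 2 / (2 * truth ** 2)) * (
                1 + rng.normal(0, 0.02, f.size))
            sigmas.append(c.fit_mtf_gaussian(f, y)[0])
        assert np.mean(sigmas) == pytest.approx(truth, rel=0.02)

    def test_too_few_points_rejected(self):
        with pytest.raises(MtfFitError):
            c.fit_mtf_gaussian([1.0], [0.9])


class TestFmax:
    def test_ten_percent_crossing(self):
        assert c.f_max_10pct(2.0) == pytest.approx(4.292, abs=1e-3)
        # MTF evaluated at f_max is exactly 10%
        sigma = 1.7
        f = c.f_max_10pct(sigma)
        assert math.exp(-f ** 2 / (2 * sigma ** 2)) == pytest.approx(0.1)

    @settings(deadline=None, max_examples=50)
    @given(sigma=st.floats(min_value=0.1, max_value=20.0))
    def test_linear_in_sigma(self, sigma):
        assert c.f_max_10pct(sigma) / sigma == pytest.approx(
            F_MAX_SIGMA_RATIO)
        assert c.f_max_10pct(2 * sigma) == pytest.approx(
            2 * c.f_max_10pct(sigma))


def flat_volume(shape=(64, 64, 10), spacing=(0.2, 0.2, 0.2), value=0.0):
    origin = tuple(-(n - 1) / 2 * s for n, s in zip(shape, spacing))
    return c.VoxelVolume(values=np.full(shape, value, dtype=float),
                         spacing=spacing, origin=origin)


class TestCnr:
    def test_direct_formula(self, rng):
        vol = flat_volume()
        sig = c.RoiSpec("disk", (0.0, 0.0), (1.0,), (0, 10))
        bg = c.RoiSpec("annulus", (0.0, 0.0), (2.0, 3.0), (0, 10))
        vol.values[...] = rng.normal(30.0, 5.0, vol.values.shape)
        vol.values[sig.mask_inplane(vol)] = 40.0
        mean, se = c.cnr(vol, sig, bg)
        expected = []
        for iz in range(10):
            sl = vol.values[:, :, iz]
            expected.append(abs(40.0 - sl[bg.mask_inplane(vol)].mean())
                            / sl[bg.mask_inplane(vol)].std(ddof=1))
        assert mean == pytest.approx(np.mean(expected))
        assert se == pytest.approx(np.std(expected, ddof=1) / math.sqrt(10))

    def test_equal_statistics_give_near_zero(self, rng):
        vol = flat_volume()
        vol.values[...] = rng.normal(0, 5.0, vol.values.shape)
        sig = c.RoiSpec("disk", (0.0, 0.0), (1.0,), (0, 10))
        bg = c.RoiSpec("annulus", (0.0, 0.0), (2.0, 3.0), (0, 10))
        mean, _ = c.cnr(vol, sig, bg)
        assert mean < 0.5

    def test_zero_background_sd_rejected(self):
        vol = flat_volume()
        with pytest.raises(ValueError):
            c.cnr(vol, c.RoiSpec("disk", (0, 0), (1.0,), (0, 10)),
                  c.RoiSpec("annulus", (0, 0), (2.0, 3.0), (0, 10)))

    def test_overlapping_rois_rejected(self):
        vol = flat_volume()
        with pytest.raises(ValueError):
            c.cnr(vol, c.RoiSpec("disk", (0, 0), (2.5,), (0, 10)),
                  c.RoiSpec("annulus", (0, 0), (2.0, 3.0), (0, 10)))

    def test_cnr_scales_with_sqrt_projection_count(self, rng):
        """Poisson-noise sweep: CNR ~ sqrt(N) at fixed mAs/projection."""
        ph = c.DigitalPhantom(housing_radius=8.0, modules=[
            c.PhantomModule("lc", (-1.0, 1.0), inserts=[
                c.InsertSpec("insert", (3.0, 0.0, 0.0), 0.75, 2.0, 30.0)])])
        ss = (np.arange(160) - 79.5) * 0.11
        sig = c.RoiSpec("disk", (3.0, 0.0), (0.6,), (0, 1))
        bg = c.RoiSpec("annulus", (3.0, 0.0), (0.95, 2.2), (0, 1))
        counts = [450, 225, 150, 113, 90, 75]
        sinos = {}
        normalized = []
        for n in counts:
            angles = np.arange(n) * 360.0 / n
            if n not in sinos:
                sinos[n] = c.parallel_sinogram(ph, angles, ss,
                                               sampling_step=0.05)
            vals = []
            for seed in range(1, 9):
                projs = c.ProjectionSet(
                    data=sinos[n][:, None, :], timestamps=np.arange(n) * 1.0,
                    angles=angles, mode="parallel")
                noisy = c.apply_noise(projs, photons_per_mas=2e4, seed=seed)
                img = c.reconstruct_parallel2d(noisy.data[:, 0, :], angles,
                                               ss, (128, 128), 0.12)
                vol = c.VoxelVolume(values=1000 * (img[..., None]
                                                   - c.MU_WATER) / c.MU_WATER,
                                    spacing=(0.12, 0.12, 1.0),
                                    origin=(-7.62, -7.62, 0.0))
                vals.append(c.cnr(vol, sig, bg)[0])
            normalized.append(np.mean(vals) / math.sqrt(n))
        normalized = np.asarray(normalized)
        assert np.all(np.abs(normalized / normalized.mean() - 1) < 0.10)
        # and raw CNR is monotone non-increasing with gantry speed
        raw = normalized * np.sqrt(counts)
        assert np.all(np.diff(raw) < 0)


class TestUniformity:
    def _rois(self):
        center = c.RoiSpec("disk", (0.0, 0.0), (0.5,), (0, 10))
        periph = [c.RoiSpec("disk", (xy), (0.5,), (0, 10))
                  for xy in [(5, 0), (-5, 0), (0, 5), (0, -5)]]
        return center, periph

    def test_known_roi_means(self):
        vol = flat_volume(shape=(80, 80, 10), spacing=(0.2, 0.2, 0.2))
        center, periph = self._rois()
        for roi, val in zip([center] + periph, [10, 12, 9, 11, 10]):
            vol.values[roi.mask_inplane(vol)] = val
        mean, se = c.uniformity_index(vol, center, periph)
        assert mean == pytest.approx(3.0)
        assert se == pytest.approx(0.0)

    def test_constant_volume_is_perfectly_uniform(self):
        vol = flat_volume(shape=(80, 80, 10), value=7.0)
        center, periph = self._rois()
        mean, _ = c.uniformity_index(vol, center, periph)
        assert mean == 0.0

    def test_roi_outside_volume_rejected(self):
        vol = flat_volume(shape=(16, 16, 10), spacing=(0.2, 0.2, 0.2))
        center, periph = self._rois()
        with pytest.raises(ValueError):
            c.uniformity_index(vol, center, periph)


class TestHuSensitivity:
    def _inserts(self):
        return {"a": c.RoiSpec("disk", (2.0, 0.0), (0.5,), (0, 10)),
                "b": c.RoiSpec("disk", (-2.0, 0.0), (0.5,), (0, 10))}

    def test_identical_volumes_have_zero_difference(self, rng):
        vol = flat_volume()
        vol.values[...] = rng.normal(0, 10, vol.values.shape)
        df = c.hu_sensitivity(vol, vol, self._inserts())
        assert np.allclose(df["difference_hu"], 0.0)

    def test_uniform_offset_is_recovered(self, rng):
        vol = flat_volume()
        vol.values[...] = rng.normal(0, 10, vol.values.shape)
        shifted = c.VoxelVolume(values=vol.values + 50.0,
                                spacing=vol.spacing, origin=vol.origin)
        df = c.hu_sensitivity(shifted, vol, self._inserts())
        assert np.allclose(df["difference_hu"], 50.0)

    def test_grid_mismatch_rejected(self):
        a = flat_volume()
        b = flat_volume(spacing=(0.25, 0.2, 0.2))
        with pytest.raises(ValueError):
            c.hu_sensitivity(a, b, self._inserts())


def air_column_volume(z_position, nz=80, dz=0.1):
    """Water volume with a 4 cm air cylinder whose center sits at z_position."""
    vol = flat_volume(shape=(32, 32, nz), spacing=(0.2, 0.2, dz))
    xs, ys, zs = vol.axis_centers()
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    disk = X ** 2 + Y ** 2 <= 0.6 ** 2
    inside_z = np.abs(zs - z_position) <= 2.0
    for iz in np.nonzero(inside_z)[0]:
        sl = vol.values[:, :, iz]
        sl[disk] = -1000.0
    return vol


class TestExcursion:
    roi = c.RoiSpec("box", (0.0, 0.0), (0.8, 0.8), None)

    def test_three_cm_travel_measured_exactly(self):
        vols = [air_column_volume(-1.5), air_column_volume(1.5)]
        res = c.measure_excursion(vols, self.roi)
        assert res.excursion == pytest.approx(3.0, abs=1e-9)
        assert res.percent_difference == pytest.approx(0.0, abs=1e-6)

    def test_static_volumes_have_zero_excursion(self):
        vols = [air_column_volume(0.0) for _ in range(3)]
        res = c.measure_excursion(vols, self.roi)
        assert res.excursion == 0.0

    def test_missing_insert_raises_with_phase_index(self):
        vols = [air_column_volume(0.0), flat_volume(shape=(32, 32, 80),
                                                    spacing=(0.2, 0.2, 0.1))]
        with pytest.raises(InsertDetectionError, match="phase 1"):
            c.measure_excursion(vols, self.roi)


class TestRmse:
    def test_perfect_measurements(self):
        assert c.rmse_excursion([3.0] * 6) == 0.0

    def test_single_deviation(self):
        vals = [3.0] * 5 + [3.06]
        assert c.rmse_excursion(vals) == pytest.approx(0.06 / math.sqrt(6))

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(min_value=0, max_value=6), min_size=1,
                    max_size=12))
    def test_matches_brute_force_oracle(self, vals):
        brute = math.sqrt(sum((v - 3.0) ** 2 for v in vals) / len(vals))
        assert c.rmse_excursion(vals) == pytest.approx(brute, abs=1e-12)


class TestSqrtMasNormalization:
    def test_reference_value(self):
        assert c.normalize_sqrt_mas(4.80, 5716.0) == pytest.approx(0.0635,
                                                                   abs=2e-4)

    def test_unit_mas_is_identity(self):
        assert c.normalize_sqrt_mas(2.5, 1.0) == 2.5

    def test_quadrupling_mas_halves_value(self):
        assert c.normalize_sqrt_mas(1.0, 400.0) == pytest.approx(
            0.5 * c.normalize_sqrt_mas(1.0, 100.0))

    def test_nonpositive_mas_rejected(self):
        with pytest.raises(ValueError):
            c.normalize_sqrt_mas(1.0, 0.0)
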