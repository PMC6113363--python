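import numpy as np
import pytest

from srclem import profiling as pf
from srclem import synthetic_data as sd
from srclem.profiling import ProfilingError
from srclem.synthetic_data import CHANNELS


def _symmetric_blob_stack(nz=8, n=161, sigma_nm=480.0, ps=40.0):
    """Rotationally symmetric 3D blob centered on a grid point."""
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    c = (n - 1) / 2.0
    s = sigma_nm / ps
    blob = np.exp(-((yy - c) ** 2 + (xx - c) ** 2) / (2 * s * s))
    zprof = np.exp(-((np.arange(nz) - 3.0) ** 2) / 4.0)
    return zprof[:, None, None] * blob[None], (c * ps, c * ps)


class TestDetectCores:
    def test_five_cores_recovered_within_one_pixel(self):
        cluster = sd.ClusterSpec(n_podosomes=5, field_size_xy=(12000, 12000),
                                 ventral_filament_density=0.0)
        optics = sd.OpticsSpec(bead_count=0, noise_scale=0.0)
        scene = sd.generate_scene(cluster, optics, sd.SEMSpec(), seed=10)
        stack = sd.render_lm_stack(scene, optics)
        cores = pf.detect_cores(stack[CHANNELS.index("actin")],
                                optics.lm_pixel_xy)
        assert len(cores) == 5
        truth = np.array([p.center_xy for p in scene.podosomes])
        for c in cores:
            d = np.linalg.norm(truth - np.asarray(c.center_xy), axis=1).min()
            assert d <= optics.lm_pixel_xy

    def test_blank_stack_yields_nothing(self):
        assert pf.detect_cores(np.zeros((4, 32, 32)), 40.0) == []

    def test_close_cores_merge_into_single_detection(self):
        """Two cores 400 nm apart with min_separation 700 nm cannot be
        resolved and collapse to one detection (documented limitation)."""
        p0 = sd.PodosomeSpec(center_xy=(3000.0, 3200.0))
        p1 = sd.PodosomeSpec(center_xy=(3400.0, 3200.0))
        scene = sd.GroundTruthScene(
            podosomes=[p0, p1], beads=np.zeros((0, 2)),
            affine_true=sd.AffineTransform2D.identity(),
            filament_segments=[], rings=[], field_size_xy=(6400.0, 6400.0),
            seed=0)
        optics = sd.OpticsSpec(bead_count=0)
        stack = sd.render_lm_stack(scene, optics)
        cores = pf.detect_cores(stack[CHANNELS.index("actin")],
                                optics.lm_pixel_xy, min_separation=700.0)
        assert len(cores) == 1

    def test_nonpositive_pixel_size_rejected(self):
        with pytest.raises(ProfilingError):
            pf.detect_cores(np.zeros((2, 8, 8)), 0.0)


class TestRadialView:
    def test_stack_of_ones_gives_view_of_ones(self):
        view = pf.radial_view(np.ones((5, 101, 101)), (2000.0, 2000.0),
                              40.0, 150.0)
        np.testing.assert_allclose(view.data, 1.0)

    def test_default_width_and_angles(self):
        view = pf.radial_view(np.ones((3, 101, 101)), (2000.0, 2000.0),
                              40.0, 150.0)
        assert view.data.shape == (3, int(3000 / 40) + 1)
        assert view.n_angles == 36
        assert view.angle_step == 10.0

    def test_symmetric_podosome_matches_single_angle_slice(self):
        """For a rotationally symmetric input, averaging over 36 angles
        reproduces the angle-0 slice to better than 1e-3 relative error."""
        stack, center = _symmetric_blob_stack()
        v36 = pf.radial_view(stack, center, 40.0, 150.0, n_angles=36)
        v1 = pf.radial_view(stack, center, 40.0, 150.0, n_angles=1)
        rel = np.linalg.norm(v36.data - v1.data) / np.linalg.norm(v1.data)
        assert rel < 1e-3

    def test_angle_count_invariance(self):
        stack, center = _symmetric_blob_stack()
        v36 = pf.radial_view(stack, center, 40.0, 150.0, n_angles=36)
        v360 = pf.radial_view(stack, center, 40.0, 150.0, n_angles=360)
        rel = np.linalg.norm(v36.data - v360.data) / np.linalg.norm(v360.data)
        assert rel < 1e-3

    def test_center_near_border_rejected_with_margin_named(self):
        with pytest.raises(ProfilingError, match="margin"):
            pf.radial_view(np.ones((3, 101, 101)), (400.0, 2000.0), 40.0, 150.0)


class TestProfileExtraction:
    def _asym_view(self):
        data = np.arange(40.0).reshape(4, 10)
        r = (np.arange(10) - 4.5) * 40.0
        return pf.RadialOrthogonalView(data=data, r_coords=r, r_step=40.0,
                                       z_step=150.0, n_angles=36,
                                       line_length=360.0)

    def test_xy_profile_is_the_requested_row(self):
        view = self._asym_view()
        np.testing.assert_array_equal(pf.extract_xy_profile(view, 2),
                                      view.data[2])
        with pytest.raises(ProfilingError):
            pf.extract_xy_profile(view, 4)

    def test_xy_profile_peaks_at_bright_column(self):
        r = (np.arange(76) - 37.5) * 40.0
        data = np.zeros((4, 76))
        col = int(np.argmin(np.abs(r - 360.0)))
        data[:, col] = 5.0
        view = pf.RadialOrthogonalView(data=data, r_coords=r, r_step=40.0,
                                       z_step=150.0, n_angles=36,
                                       line_length=3000.0)
        prof = pf.extract_xy_profile(view, 1)
        assert r[int(np.argmax(prof))] == pytest.approx(360.0, abs=20.0)

    def test_z_profile_side_policies_agree_on_symmetric_view(self):
        r = (np.arange(75) - 37.0) * 40.0
        data = np.exp(-np.abs(r)[None, :] / 500.0) * np.ones((4, 1))
        view = pf.RadialOrthogonalView(data=data, r_coords=r, r_step=40.0,
                                       z_step=150.0, n_angles=36,
                                       line_length=3000.0)
        for off in (0.0, 200.0, 360.0):
            left = pf.extract_z_profile(view, off, "left")
            right = pf.extract_z_profile(view, off, "right")
            both = pf.extract_z_profile(view, off, "mean_of_both")
            np.testing.assert_allclose(left, right)
            np.testing.assert_allclose(both, left)

    def test_core_profile_peaks_at_mid_height(self, single_podosome):
        scene, stack, optics = single_podosome
        p = scene.podosomes[0]
        view = pf.radial_view(stack[CHANNELS.index("actin")] - optics.background,
                              p.center_xy, optics.lm_pixel_xy,
                              optics.lm_z_step)
        prof = pf.extract_z_profile(view, 0.0)
        z_peak = int(np.argmax(prof)) * optics.lm_z_step
        assert z_peak == pytest.approx(p.core_height / 2.0,
                                       abs=optics.lm_z_step)

    def test_zyxin_peaks_above_vinculin(self, single_podosome):
        """200 nm zyxin z-profile peaks higher in z than the 360 nm
        vinculin profile (the axial layering of ring and cap)."""
        scene, stack, optics = single_podosome
        p = scene.podosomes[0]
        kw = dict(pixel_size=optics.lm_pixel_xy, z_step=optics.lm_z_step)
        vin = pf.radial_view(stack[CHANNELS.index("vinculin")], p.center_xy, **kw)
        zyx = pf.radial_view(stack[CHANNELS.index("zyxin")], p.center_xy, **kw)
        z_vin = int(np.argmax(pf.extract_z_profile(vin, 360.0)))
        z_zyx = int(np.argmax(pf.extract_z_profile(zyx, 200.0)))
        assert z_zyx > z_vin

    def test_offset_beyond_view_rejected(self):
        view = self._asym_view()
        with pytest.raises(ProfilingError):
            pf.extract_z_profile(view, 5000.0)


class TestNormalization:
    def _ps(self, xy, zp=None):
        r = (np.arange(len(next(iter(xy.values())))) - 1.0) * 40.0
        return pf.ProfileSet(xy_profiles=xy, z_profiles=zp or {},
                             r_coords=r, z_step=150.0)

    def test_endpoints_map_to_zero_and_one(self):
        ps = self._ps({0: np.array([10.0, 30.0, 50.0])})
        out = pf.normalize_profiles(ps)
        np.testing.assert_allclose(out.xy_profiles[0], [0.0, 0.5, 1.0])
        assert out.normalization == (10.0, 50.0)

    def test_global_extrema_span_all_z_sections(self):
        """Sections with ranges [0, 1] and [0, 10]: the weaker section's
        peak maps to 0.1, not 1.0."""
        ps = self._ps({0: np.array([0.0, 1.0, 0.0]),
                       1: np.array([0.0, 10.0, 0.0])})
        out = pf.normalize_profiles(ps)
        assert out.xy_profiles[0].max() == pytest.approx(0.1)
        assert out.xy_profiles[1].max() == pytest.approx(1.0)

    def test_constant_profiles_flagged_degenerate(self):
        ps = self._ps({0: np.full(3, 7.0), 1: np.full(3, 7.0)})
        out = pf.normalize_profiles(ps)
        assert out.degenerate
        np.testing.assert_array_equal(out.xy_profiles[0], 0.0)

    def test_normalization_is_idempotent(self):
        ps = self._ps({0: np.array([2.0, 8.0, 4.0])})
        once = pf.normalize_profiles(ps)
        twice = pf.normalize_profiles(once)
        np.testing.assert_allclose(twice.xy_profiles[0], once.xy_profiles[0])

    def test_all_nan_rejected(self):
        ps = self._ps({0: np.full(3, np.nan)})
        with pytest.raises(ProfilingError):
            pf.normalize_profiles(ps)


class TestAggregate:
    def _ps(self, values):
        return pf.ProfileSet(xy_profiles={0: np.asarray(values, dtype=float)},
                             z_profiles={}, r_coords=np.arange(3) * 40.0,
                             z_step=150.0)

    def test_identical_podosomes_have_zero_sem(self):
        sets = [self._ps([1.0, 2.0, 3.0])] * 5
        agg = pf.aggregate(sets)
        np.testing.assert_allclose(agg.mean.xy_profiles[0], [1, 2, 3])
        np.testing.assert_allclose(agg.sem.xy_profiles[0], 0.0)
        assert agg.n == 5

    def test_zero_one_pair_gives_sem_half(self):
        """sd({0, 1}) = 0.7071 (ddof=1), SEM = sd/sqrt(2) = 0.5."""
        agg = pf.aggregate([self._ps([0.0, 0.0, 0.0]),
                            self._ps([1.0, 1.0, 1.0])])
        np.testing.assert_allclose(agg.mean.xy_profiles[0], 0.5)
        np.testing.assert_allclose(agg.sem.xy_profiles[0], 0.5)

    def test_mixed_grids_rejected(self):
        a = self._ps([1.0, 2.0, 3.0])
        b = pf.ProfileSet(xy_profiles={0: np.zeros(4)}, z_profiles={},
                          r_coords=np.arange(4) * 40.0, z_step=150.0)
        with pytest.raises(ProfilingError):
            pf.aggregate([a, b])

    def test_vinculin_ring_wider_than_zyxin_across_podosomes(self):
        """Across simulated podosomes the mean vinculin x-y peak radius
        exceeds the mean zyxin peak radius."""
        vin_r, zyx_r = [], []
        for seed in range(8):
            cluster = sd.ClusterSpec(n_podosomes=1, field_size_xy=(7000, 7000))
            optics = sd.OpticsSpec(bead_count=0, noise_scale=1.0)
            scene = sd.generate_scene(cluster, optics, sd.SEMSpec(), seed=seed)
            stack = sd.render_lm_stack(scene, optics)
            p = scene.podosomes[0]
            kw = dict(pixel_size=optics.lm_pixel_xy, z_step=optics.lm_z_step)
            vin = pf.radial_view(stack[CHANNELS.index("vinculin")],
                                 p.center_xy, **kw)
            zyx = pf.radial_view(stack[CHANNELS.index("zyxin")],
                                 p.center_xy, **kw)
            zi_v = int(round(p.vinculin_ring_z / optics.lm_z_step))
            zi_z = int(round(p.zyxin_cap_z / optics.lm_z_step))
            prof_v = pf.extract_xy_profile(vin, zi_v)
            prof_z = pf.extract_xy_profile(zyx, zi_z)
            vin_r.append(abs(vin.r_coords[int(np.argmax(prof_v))]))
            zyx_r.append(abs(zyx.r_coords[int(np.argmax(prof_z))]))
        assert np.mean(vin_r) > np.mean(zyx_r)


class TestNormalizeToControl:
    def _ps(self, values, channel="actin"):
        return pf.ProfileSet(xy_profiles={}, z_profiles={
            0.0: np.asarray(values, dtype=float)},
            r_coords=np.arange(3) * 40.0, z_step=150.0, channel=channel)

    def test_treated_equal_control_gives_unity(self):
        c = self._ps([2.0, 4.0, 8.0])
        ratio, valid = pf.normalize_to_control(self._ps([2.0, 4.0, 8.0]), c)
        np.testing.assert_allclose(ratio.z_profiles[0.0], 1.0)
        assert valid.z_profiles[0.0].all()

    def test_half_control_gives_half(self):
        c = self._ps([2.0, 4.0, 8.0])
        t = self._ps([1.0, 2.0, 4.0])
        ratio, _ = pf.normalize_to_control(t, c)
        np.testing.assert_allclose(ratio.z_profiles[0.0], 0.5)

    def test_near_zero_control_flagged(self):
        c = self._ps([0.0, 4.0, 8.0])
        t = self._ps([1.0, 2.0, 4.0])
        ratio, valid = pf.normalize_to_control(t, c)
        assert not valid.z_profiles[0.0][0]
        assert np.isnan(ratio.z_profiles[0.0][0])

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ProfilingError, match="channel"):
            pf.normalize_to_control(self._ps([1.0, 1.0, 1.0], "actin"),
                                    self._ps([1.0, 1.0, 1.0], "zyxin"))
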