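"""Reslicing, per-plane deconvolution, fusion and the FBP baseline."""

import numpy as np
import pytest
from scipy.signal import fftconvolve

from mvbf import (DeconvSpec, Phantom, RotationAxis, SectionPlane, ViewStack,
                  ValidationError, deconvolve_plane, fbp_baseline, fuse_plane,
                  fwhm, make_phantom, reconstruct_volume, reslice_to_planes,
                  rotate_plane, simulate_dataset, design,
                  AcquisitionGeometry)
from mvbf._transform import rotate_plane_values


def stack_from(arr, angle=0.0, axial_step=1.0, pixel_size=1.0):
    return ViewStack(intensity=np.asarray(arr, dtype=float), angle=angle,
                     axial_step=axial_step, pixel_size=pixel_size)


class TestReslice:
    def test_isotropic_stack_reslices_by_transposition(self):
        rng = np.random.default_rng(0)
        vol = rng.random((6, 4, 7))
        planes = reslice_to_planes(stack_from(vol))
        assert len(planes) == 4
        for y, p in enumerate(planes):
            assert np.array_equal(p.values, vol[:, y, :])
            assert p.y_index == y

    def test_double_step_interpolates_linear_content_exactly(self):
        z = np.arange(5, dtype=float)
        vol = np.tile(z[:, None, None], (1, 2, 3))  # linear along z
        planes = reslice_to_planes(stack_from(vol, axial_step=2.0))
        assert planes[0].values.shape == (9, 3)
        assert np.allclose(planes[0].values[:, 0], np.arange(9) / 2.0)

    def test_reslice_preserves_y_ordering(self):
        vol = np.stack([np.full((3, 2), y) for y in range(5)], axis=1)
        planes = reslice_to_planes(stack_from(vol))
        restacked = np.stack([p.values for p in planes], axis=1)
        assert np.array_equal(restacked, vol)

    def test_too_few_z_samples_rejected(self):
        with pytest.raises(ValidationError):
            reslice_to_planes(stack_from(np.ones((2, 2, 4)), axial_step=0.1))


class TestRotatePlane:
    def test_zero_and_full_turn_are_identity(self):
        rng = np.random.default_rng(1)
        p = SectionPlane(values=rng.random((11, 11)), y_index=0, angle=0.0)
        for ang in (0.0, 360.0):
            out = rotate_plane(p, ang, (5.0, 5.0))
            assert np.allclose(out.values, p.values)

    def test_quarter_turn_matches_permutation_oracle(self):
        vals = np.zeros((5, 5))
        vals[0, 4] = 1.0   # (z=0, x=4) -> (z=4, x=4) under x-toward-z
        vals[2, 0] = 2.0   # (z=2, x=0) -> (z=0, x=2)
        p = SectionPlane(values=vals, y_index=0, angle=0.0)
        out = rotate_plane(p, 90.0, (2.0, 2.0), fill=0.0)
        expected = np.zeros((5, 5))
        expected[4, 4] = 1.0
        expected[0, 2] = 2.0
        assert np.allclose(out.values, expected)

    def test_default_fill_is_border_median(self):
        vals = np.full((9, 9), 3.0)
        vals[4, 4] = 0.0
        out = rotate_plane(SectionPlane(values=vals, y_index=0, angle=0.0),
                           45.0, (4.0, 4.0))
        assert out.values[0, 0] == pytest.approx(3.0)


class TestDeconvolvePlane:
    @staticmethod
    def delta_psf(n=9):
        d = np.zeros((n, n))
        d[n // 2, n // 2] = 1.0
        return d

    def test_delta_psf_is_identity_for_both_methods(self):
        rng = np.random.default_rng(2)
        vals = np.ones((21, 21))
        vals[4:-4, 4:-4] -= 0.3 * rng.random((13, 13))  # dark interior
        plane = SectionPlane(values=vals, y_index=0, angle=0.0)
        w = deconvolve_plane(plane, self.delta_psf(),
                             DeconvSpec(method="wiener", wiener_k=1e-9))
        rl = deconvolve_plane(plane, self.delta_psf(),
                              DeconvSpec(method="richardson_lucy",
                                         rl_iterations=5))
        assert np.allclose(w.values, plane.values, atol=1e-6)
        assert np.allclose(rl.values, plane.values, atol=1e-6)

    def test_wiener_round_trip_restores_blurred_plane(self, psf2d_na05):
        from scipy import ndimage
        rng = np.random.default_rng(3)
        truth = ndimage.gaussian_filter(rng.random((129, 129)), 2.0)
        truth = (truth - truth.min()) / (truth.max() - truth.min())
        window = np.zeros((129, 129))
        window[45:-45, 45:-45] = 1.0
        signal = 0.3 * truth * ndimage.gaussian_filter(window, 4.0)
        blurred = fftconvolve(signal, psf2d_na05, mode="same")
        plane = SectionPlane(values=1.0 - blurred, y_index=0, angle=0.0)
        out = deconvolve_plane(plane, psf2d_na05,
                               DeconvSpec(method="wiener", wiener_k=1e-6))
        err = ((1.0 - out.values) - signal)[20:-20, 20:-20]
        assert np.sqrt((err**2).mean()) / 0.3 < 0.02

    def test_richardson_lucy_preserves_flux_and_positivity(self, psf2d_na05):
        rng = np.random.default_rng(4)
        sig = np.zeros((65, 65))
        sig[28:37, 28:37] = 0.3 * rng.random((9, 9))
        blurred = fftconvolve(sig, psf2d_na05, mode="same")
        plane = SectionPlane(values=1.0 - blurred, y_index=0, angle=0.0)
        out = deconvolve_plane(plane, psf2d_na05,
                               DeconvSpec(method="richardson_lucy",
                                          rl_iterations=20))
        restored = 1.0 - out.values
        assert restored.min() >= -1e-12
        assert restored.sum() == pytest.approx(blurred.sum(), rel=0.01)

    def test_unnormalised_psf_rejected(self):
        plane = SectionPlane(values=np.ones((9, 9)), y_index=0, angle=0.0)
        with pytest.raises(ValidationError):
            deconvolve_plane(plane, np.ones((3, 3)),
                             DeconvSpec(method="wiener"))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            DeconvSpec(method="wiener", wiener_k=0.0)
        with pytest.raises(ValidationError):
            DeconvSpec(method="richardson_lucy", rl_iterations=0)


class TestFusePlane:
    def test_single_view_identity(self):
        rng = np.random.default_rng(5)
        p = SectionPlane(values=rng.random((9, 9)), y_index=2, angle=0.0)
        out = fuse_plane([p], (4.0, 4.0))
        assert np.array_equal(out.values, p.values)
        assert out.y_index == 2

    def test_constant_planes_fuse_to_same_constant(self):
        planes = [SectionPlane(values=np.full((9, 9), 1.5), y_index=0,
                               angle=a) for a in (0.0, 45.0, 170.0)]
        out = fuse_plane(planes, (4.0, 4.0), fill=1.5)
        assert np.allclose(out.values, 1.5)

    def test_two_opposite_views_match_explicit_oracle(
            self, point_dataset_factory):
        ds = point_dataset_factory([(6, 2)], axis=(48.0, 48.0), n_views=2)
        planes = [reslice_to_planes(v)[0] for v in ds.views]
        fused = fuse_plane(planes, (48.0, 48.0))
        oracle = (rotate_plane_values(planes[0].values, 0.0, (48.0, 48.0),
                                      fill=1.0)
                  + rotate_plane_values(planes[1].values, 180.0, (48.0, 48.0),
                                        fill=1.0)) / 2.0
        # identical up to the border-median fill estimate (~background)
        assert np.allclose(fused.values, oracle, atol=1e-3)

    def test_view_order_does_not_change_the_result(self, point_dataset_factory):
        ds = point_dataset_factory([(6, 2), (-9, 5)], axis=(48.0, 48.0),
                                   n_views=6)
        planes = [reslice_to_planes(v)[0] for v in ds.views]
        a = fuse_plane(planes, (48.0, 48.0))
        b = fuse_plane(planes[::-1], (48.0, 48.0))
        assert np.array_equal(a.values, b.values)

    def test_mixed_sections_rejected(self):
        p0 = SectionPlane(values=np.ones((5, 5)), y_index=0, angle=0.0)
        p1 = SectionPlane(values=np.ones((5, 5)), y_index=1, angle=90.0)
        with pytest.raises(ValidationError):
            fuse_plane([p0, p1], (2.0, 2.0))


class TestReconstructVolume:
    def test_single_zero_degree_view_reproduces_resliced_stack(
            self, point_dataset_factory):
        ds = point_dataset_factory([(6, 2)], axis=(48.0, 48.0), n_views=1)
        vol = reconstruct_volume(ds, RotationAxis(48.0, 48.0))
        resliced = np.stack([p.values for p in
                             reslice_to_planes(ds.views[0])])
        assert np.allclose(vol.values, resliced)

    def test_fused_point_returns_to_phantom_position(
            self, point_dataset_factory):
        """End-to-end sign convention check: simulate off-axis point,
        reconstruct, centroid lands back on the phantom position."""
        ds = point_dataset_factory([(8, 3)], axis=(48.0, 48.0), n_views=12)
        vol = reconstruct_volume(ds, RotationAxis(48.0, 48.0))
        img = vol.values[0]
        pk = np.unravel_index(np.argmin(img), img.shape)
        w = img.max() - img
        zz, xx = np.mgrid[pk[0]-4:pk[0]+5, pk[1]-4:pk[1]+5]
        ww = w[pk[0]-4:pk[0]+5, pk[1]-4:pk[1]+5]
        cz = (ww * zz).sum() / ww.sum()
        cx = (ww * xx).sum() / ww.sum()
        assert abs(cz - (48 + 3)) <= 0.5
        assert abs(cx - (48 + 8)) <= 0.5

    def test_angular_offset_invariance_for_symmetric_phantom(
            self, na05_params, psf_na05):
        """A rotationally symmetric phantom reconstructs identically from an
        angle set and from the same set shifted by half a step."""
        ph = make_phantom("tube", (65, 1, 65),
                          {"inner_radius": 5, "outer_radius": 8,
                           "amplitude": 0.3}, voxel_size=(0.25,) * 3)
        axis = (32.0, 32.0)
        def recon(offset):
            angles = tuple((a + offset) % 360
                           for a in design.make_angle_list(8))
            geo = AcquisitionGeometry(angles=angles, axial_step=0.25,
                                      num_z_steps=65)
            ds = simulate_dataset(ph, psf_na05, na05_params, geo, axis)
            order = np.argsort(angles)
            ds.views = [ds.views[i] for i in order]
            ds.geometry = AcquisitionGeometry(
                angles=tuple(np.array(angles)[order]), axial_step=0.25,
                num_z_steps=65)
            return reconstruct_volume(ds, RotationAxis(*axis)).values
        a, b = recon(0.0), recon(22.5)
        assert np.abs(a - b)[:, 10:-10, 10:-10].max() < 0.02


class TestFbpBaseline:
    def test_zero_attenuation_gives_zero_volume(self, point_dataset_factory):
        ds = point_dataset_factory([(6, 2)], axis=(48.0, 48.0), n_views=8,
                                   amplitude=0.0)
        vol = fbp_baseline(ds, RotationAxis(48.0, 48.0))
        assert np.abs(vol.values).max() < 1e-9

    def test_thin_sample_point_recovered_near_true_position(
            self, point_dataset_factory):
        """A point within the depth of field reconstructs at the correct
        location (centroid error < 1 px)."""
        ds = point_dataset_factory([(8, 3)], axis=(48.0, 48.0), n_views=24)
        vol = fbp_baseline(ds, RotationAxis(48.0, 48.0))
        plane = vol.values[0]
        c = plane.shape[0] // 2  # axis sits at the grid centre
        pk = np.unravel_index(np.argmax(plane), plane.shape)
        assert abs(pk[0] - (c + 3)) <= 1
        assert abs(pk[1] - (c + 8)) <= 1


class TestFwhm:
    def test_gaussian_width_closed_form(self):
        z, x = np.mgrid[-30:31, -30:31]
        sigma = 4.0
        img = np.exp(-(z**2 + x**2) / (2 * sigma**2))
        measured = fwhm(img, (30.0, 30.0), (0, 1), background=0.0)
        assert measured == pytest.approx(2.3548 * sigma, rel=0.02)

    def test_direction_invariance_for_radial_spot(self):
        z, x = np.mgrid[-30:31, -30:31]
        img = np.exp(-(z**2 + x**2) / 18.0)
        a = fwhm(img, (30.0, 30.0), (0, 1), background=0.0)
        b = fwhm(img, (30.0, 30.0), (1, 1), background=0.0)
        assert a == pytest.approx(b, rel=0.02)

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_dense_profile_oracle(self, seed):
        from scipy import ndimage
        rng = np.random.default_rng(seed)
        z, x = np.mgrid[0:41, 0:41]
        cz, cx = rng.uniform(15, 25, 2)
        sz, sx = rng.uniform(2, 5, 2)
        img = np.exp(-((z - cz)**2 / (2 * sz**2) + (x - cx)**2 / (2 * sx**2)))
        img += 0.05 * ndimage.gaussian_filter(rng.random((41, 41)), 4.0)
        measured = fwhm(img, (cz, cx), (0, 1), background=0.0)
        # brute-force: sample the same profile at 0.01 px and threshold
        t = np.arange(0, 40, 0.01)
        half = ndimage.map_coordinates(img, [[cz], [cx]], order=1)[0] / 2.0
        widths = []
        for sign in (1, -1):
            xs = cx + sign * t
            ok = (xs >= 0) & (xs <= 40)
            prof = ndimage.map_coordinates(
                img, [np.full(ok.sum(), cz), xs[ok]], order=1)
            widths.append(t[ok][np.flatnonzero(prof < half)[0]])
        assert measured == pytest.approx(sum(widths), abs=0.2)

    def test_flat_profile_raises(self):
        with pytest.raises(ValidationError):
            fwhm(np.ones((9, 9)), (4.0, 4.0), (0, 1), background=0.0)
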