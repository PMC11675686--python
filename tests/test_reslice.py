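"""Geometric pre-processing: resampling, frames, extraction, centering."""

import numpy as np
import pytest

from flvae.phantom import PhantomSpec, make_phantom_volume
from flvae.reslice import (Centerline, DegenerateCenterlineError,
                           EmptySegmentationError, apply_mask_and_center,
                           compute_frames, extract_cross_sections,
                           normalize_intensity, resample_centerline)
from flvae.types import CrossSection, SliceLabel


def straight_line(length=10.0, n=5):
    z = np.linspace(0.0, length, n)
    return np.column_stack([np.zeros(n), np.zeros(n), z])


class TestResample:
    def test_straight_segment_point_count(self):
        cl = resample_centerline(straight_line(10.0), step_mm=1.0)
        assert len(cl) == 11

    def test_uniform_spacing_except_last(self):
        pts = np.array([[0, 0, 0], [3, 0, 0], [3, 4, 0], [3, 4, 2.5]])
        cl = resample_centerline(pts, step_mm=1.0)
        gaps = np.linalg.norm(np.diff(cl.points, axis=0), axis=1)
        assert np.all(np.abs(gaps[:-1] - 1.0) < 1e-9)
        assert gaps[-1] <= 1.0 + 1e-9

    def test_endpoints_preserved(self):
        pts = np.array([[0, 0, 0], [1, 2, 2], [5, 5, 5.0]])
        cl = resample_centerline(pts, step_mm=0.7)
        np.testing.assert_allclose(cl.points[0], pts[0], atol=1e-12)
        np.testing.assert_allclose(cl.points[-1], pts[-1], atol=1e-12)

    def test_identical_points_rejected(self):
        with pytest.raises(DegenerateCenterlineError):
            resample_centerline(np.array([[1, 1, 1], [1, 1, 1.0]]), 1.0)

    def test_resampling_is_idempotent(self):
        """Resampling an already-resampled centerline at the same step moves
        no point by more than 1e-9 mm."""
        rng = np.random.default_rng(0)
        pts = np.cumsum(rng.uniform(0.5, 1.5, size=(20, 3)), axis=0)
        cl1 = resample_centerline(pts, step_mm=0.8)
        cl2 = resample_centerline(cl1, step_mm=0.8)
        assert len(cl1) == len(cl2)
        assert np.max(np.linalg.norm(cl1.points - cl2.points, axis=1)) < 1e-9


class TestFrames:
    def test_straight_line_frames_constant(self):
        cl = resample_centerline(straight_line(), 1.0)
        fr = compute_frames(cl)
        for arr in (fr.tangent, fr.normal_u, fr.normal_v):
            assert np.allclose(arr, arr[0])

    def test_orthonormal_right_handed(self):
        rng = np.random.default_rng(3)
        pts = np.cumsum(rng.uniform(0.2, 1.0, size=(30, 3)), axis=0)
        fr = compute_frames(resample_centerline(pts, 0.5))
        for t, u, v in zip(fr.tangent, fr.normal_u, fr.normal_v):
            m = np.stack([t, u, v])
            np.testing.assert_allclose(m @ m.T, np.eye(3), atol=1e-6)
            assert np.linalg.det(m) > 0.999

    def test_quarter_circle_matches_closed_form(self):
        """On a planar quarter-circle arc the tangent rotates 90 degrees, the
        in-plane normal rotates with it, and the out-of-plane normal stays
        fixed (within 1e-3)."""
        R = 20.0
        phi = np.linspace(0.0, np.pi / 2, 2001)
        pts = np.column_stack([R * np.cos(phi), R * np.sin(phi), np.zeros_like(phi)])
        cl = Centerline.from_points(pts)
        fr = compute_frames(cl)
        # closed form: tangent (-sin, cos, 0); radial (-cos, -sin, 0); +/-z fixed
        t_exact = np.column_stack([-np.sin(phi), np.cos(phi), np.zeros_like(phi)])
        assert np.max(np.linalg.norm(fr.tangent - t_exact, axis=1)) < 1e-3
        # out-of-plane component of each normal must stay what it started as
        for nrm in (fr.normal_u, fr.normal_v):
            assert np.max(np.abs(nrm[:, 2] - nrm[0, 2])) < 1e-3
        # in-plane part co-rotates: its angle tracks phi
        inplane = fr.normal_u if abs(fr.normal_u[0, 2]) < 0.5 else fr.normal_v
        ang = np.unwrap(np.arctan2(inplane[:, 1], inplane[:, 0]))
        dphi = ang - ang[0]
        assert np.max(np.abs(dphi - phi)) < 1e-3

    def test_tangent_follows_direction(self):
        cl = resample_centerline(straight_line(), 1.0)
        fr = compute_frames(cl)
        assert np.all(np.sum(fr.tangent * np.array([0, 0, 1.0]), axis=1) > 0)


@pytest.fixture(scope="module")
def cylinder():
    spec = PhantomSpec(noise_sd=0.0, tl_radius_mm=(10.0, 10.0),
                       curvature_amplitude_mm=0.0)
    vp = make_phantom_volume(spec, 40, seed=4, label=SliceLabel.NO_FL)
    cl = resample_centerline(vp.centerline_truth, 1.0)
    fr = compute_frames(cl)
    secs = extract_cross_sections(vp.intensities, vp.spacing_mm, cl, fr,
                                  fov_mm=40.0, grid_n=64,
                                  lumen_mask=vp.lumen_mask,
                                  thrombus_mask=vp.thrombus_mask,
                                  subject_id="cyl")
    return vp, secs


class TestExtract:

    def test_lumen_area_matches_disk(self, cylinder):
        """Radius-10mm straight cylinder, 40mm FOV: segmented lumen area per
        interior slice within 5% of pi * 100 mm^2."""
        _, secs = cylinder
        expected = np.pi * 100.0
        for s in secs[2:-2]:
            area = s.lumen_mask.sum() * s.pixel_spacing_mm ** 2
            assert abs(area - expected) / expected < 0.05

    def test_images_are_64x64_in_unit_range(self, cylinder):
        _, secs = cylinder
        for s in secs:
            assert s.pixels.shape == (64, 64)
            assert 0.0 <= s.pixels.min() and s.pixels.max() <= 1.0

    def test_out_of_bounds_fills_zero(self):
        vol = np.ones((10, 10, 10))
        cl = Centerline.from_points([[0, 0, 0], [0, 0, 9.0]])
        fr = compute_frames(cl)
        secs = extract_cross_sections(vol, (1, 1, 1), cl, fr, fov_mm=40.0)
        corner = secs[0]
        assert corner.pixels.min() == 0.0  # out-of-volume region filled
        assert corner.pixels.max() == 1.0  # in-volume region sampled

    def test_arclength_recorded(self, cylinder):
        _, secs = cylinder
        arc = [s.arclength_mm for s in secs]
        assert arc[0] == 0.0 and np.all(np.diff(arc) > 0)


class TestMaskAndCenter:
    def _disk_image(self, center, radius=8, n=64):
        yy, xx = np.mgrid[:n, :n]
        mask = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2
        pix = np.where(mask, 0.8, 0.3)
        return CrossSection(pixels=pix, lumen_mask=mask)

    def test_offcenter_disk_centroid_recentred(self):
        cs = self._disk_image((20.0, 40.0))
        out = apply_mask_and_center(cs)
        r, c = np.nonzero(out.lumen_mask)
        assert abs(r.mean() - 31.5) <= 0.5 and abs(c.mean() - 31.5) <= 0.5

    def test_outside_mask_zeroed(self):
        cs = self._disk_image((31.5, 31.5))
        out = apply_mask_and_center(cs)
        assert np.all(out.pixels[~out.lumen_mask] == 0.0)

    def test_already_centered_unchanged(self):
        cs = self._disk_image((31.5, 31.5))
        out = apply_mask_and_center(cs)
        np.testing.assert_array_equal(out.pixels[out.lumen_mask],
                                      cs.pixels[cs.lumen_mask])
        np.testing.assert_array_equal(out.lumen_mask, cs.lumen_mask)

    def test_idempotent(self):
        cs = self._disk_image((12.0, 50.0))
        once = apply_mask_and_center(cs)
        twice = apply_mask_and_center(once)
        np.testing.assert_array_equal(once.pixels, twice.pixels)

    def test_empty_mask_error_names_slice(self):
        cs = CrossSection(pixels=np.zeros((64, 64)), subject_id="s7", slice_index=3)
        cs.lumen_mask = np.zeros((64, 64), dtype=bool)
        with pytest.raises(EmptySegmentationError, match=r"s7.*3"):
            apply_mask_and_center(cs)


class TestNormalize:
    @pytest.mark.parametrize("value,expected", [(100.0, 0.0), (300.0, 1.0),
                                                (200.0, 0.5), (50.0, 0.0),
                                                (400.0, 1.0)])
    def test_affine_window(self, value, expected):
        out = normalize_intensity(np.array([[value]]), 100.0, 300.0)
        assert out[0, 0] == pytest.approx(expected)

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            normalize_intensity(np.zeros((2, 2)), 1.0, 1.0)
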