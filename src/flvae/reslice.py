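"""Geometric pre-processing: from a 3D volume to centered 64x64 sections.

Mirrors the curved-MPR workflow used clinically: resample the aortic
centerline to uniform arc length, attach a rotation-minimizing orthonormal
frame at every point (so the in-plane axes do not spin about the tangent),
sample the volume on the perpendicular plane at each point by trilinear
interpolation, apply the segmentation mask, auto-center on the mask
centroid, and window-normalize intensities into [0, 1].

Conventions (fixed throughout the package): 0-based pixel-center indexing,
grid center of an n x n image at ((n-1)/2, (n-1)/2); world coordinates in mm
with voxel centers at index * spacing; rotation-minimizing transport via the
double-reflection method, which is immune to the normal-flipping of Frenet
frames at inflection points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .types import CrossSection

__all__ = [
    "Centerline", "FrameField", "DegenerateCenterlineError",
    "EmptySegmentationError", "resample_centerline", "compute_frames",
    "extract_cross_sections", "apply_mask_and_center", "normalize_intensity",
]


class DegenerateCenterlineError(ValueError):
    """Fewer than two distinct centerline points."""


class EmptySegmentationError(ValueError):
    """A slice's segmentation mask contains no pixels."""


@dataclass
class Centerline:
    """Ordered 3D polyline (mm) with cumulative arc length."""

    points: np.ndarray
    cumulative_arclength: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        self.cumulative_arclength = np.asarray(self.cumulative_arclength,
                                               dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise DegenerateCenterlineError("need >= 2 points of dimension 3")
        if len(self.cumulative_arclength) != len(self.points):
            raise ValueError("arclength array must match point count")
        if self.cumulative_arclength[0] != 0.0 or \
                np.any(np.diff(self.cumulative_arclength) <= 0):
            raise ValueError("cumulative arclength must start at 0 and strictly increase")

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def from_points(cls, points) -> "Centerline":
        points = _dedupe(np.asarray(points, dtype=np.float64))
        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
        return cls(points, np.concatenate([[0.0], np.cumsum(seg)]))


@dataclass
class FrameField:
    """Right-handed orthonormal triads (tangent, normal_u, normal_v), one per
    centerline point, with minimal rotation about the tangent between
    consecutive points."""

    tangent: np.ndarray
    normal_u: np.ndarray
    normal_v: np.ndarray

    def __len__(self) -> int:
        return len(self.tangent)


def _dedupe(points: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    if points.ndim != 2 or points.shape[1] != 3:
        raise DegenerateCenterlineError("points must be an (N, 3) array")
    keep = [0]
    for i in range(1, len(points)):
        if np.linalg.norm(points[i] - points[keep[-1]]) > tol:
            keep.append(i)
    pts = points[keep]
    if len(pts) < 2:
        raise DegenerateCenterlineError("fewer than 2 distinct centerline points")
    return pts


def resample_centerline(points, step_mm: float) -> Centerline:
    """Resample a polyline at uniform arc-length spacing ``step_mm``.

    Output points lie exactly on the piecewise-linear input path; both
    endpoints are preserved, so the final spacing may be shorter than
    ``step_mm``.  Passing an existing :class:`Centerline` reuses its stored
    cumulative arc length as the path parameterization, which makes
    resampling at the same step an exact fixed point.
    """
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    if isinstance(points, Centerline):
        pts, cum = points.points, points.cumulative_arclength
    else:
        pts = _dedupe(np.asarray(points, dtype=np.float64))
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    targets = np.arange(0.0, total, step_mm)
    if total - targets[-1] > 1e-9:
        targets = np.concatenate([targets, [total]])
    else:
        targets[-1] = total
    out = np.column_stack([np.interp(targets, cum, pts[:, i]) for i in range(3)])
    return Centerline(out, targets.copy())


def _tangents(points: np.ndarray) -> np.ndarray:
    """Unit tangents by central differences, one-sided at the endpoints."""
    t = np.empty_like(points)
    t[1:-1] = points[2:] - points[:-2]
    t[0] = points[1] - points[0]
    t[-1] = points[-1] - points[-2]
    return t / np.linalg.norm(t, axis=1, keepdims=True)


def compute_frames(centerline: Centerline) -> FrameField:
    """Rotation-minimizing frames along the centerline (double reflection).

    The initial in-plane axis is the coordinate axis least aligned with the
    first tangent, projected orthogonal to it; each subsequent frame is the
    previous one transported with no rotation about the tangent beyond what
    curvature forces.
    """
    pts = centerline.points
    t = _tangents(pts)
    n = len(pts)
    u = np.empty_like(t)
    v = np.empty_like(t)
    ref = np.eye(3)[np.argmin(np.abs(t[0]))]
    u0 = ref - np.dot(ref, t[0]) * t[0]
    u[0] = u0 / np.linalg.norm(u0)
    v[0] = np.cross(t[0], u[0])
    for i in range(n - 1):
        r1 = pts[i + 1] - pts[i]
        c1 = np.dot(r1, r1)
        if c1 < 1e-24:
            uL, tL = u[i], t[i]
        else:
            uL = u[i] - (2.0 / c1) * np.dot(r1, u[i]) * r1
            tL = t[i] - (2.0 / c1) * np.dot(r1, t[i]) * r1
        r2 = t[i + 1] - tL
        c2 = np.dot(r2, r2)
        un = uL if c2 < 1e-24 else uL - (2.0 / c2) * np.dot(r2, uL) * r2
        un = un - np.dot(un, t[i + 1]) * t[i + 1]
        u[i + 1] = un / np.linalg.norm(un)
        v[i + 1] = np.cross(t[i + 1], u[i + 1])
    return FrameField(tangent=t, normal_u=u, normal_v=v)


def extract_cross_sections(volume: np.ndarray, spacing_mm, centerline: Centerline,
                           frames: FrameField, fov_mm: float, grid_n: int = 64,
                           lumen_mask: Optional[np.ndarray] = None,
                           thrombus_mask: Optional[np.ndarray] = None,
                           subject_id: str = "") -> List[CrossSection]:
    """Sample perpendicular planes along the centerline.

    One ``grid_n x grid_n`` image per centerline point, trilinear-interpolated
    on the plane spanned by (normal_u, normal_v) centered at the point, with
    ``pixel_spacing_mm = fov_mm / grid_n``; samples outside the volume are
    filled with 0.  Mask volumes, when given, are resliced with
    nearest-neighbor interpolation on the same planes.  Image rows follow
    normal_v, columns normal_u.
    """
    if fov_mm <= 0:
        raise ValueError("fov_mm must be positive")
    if grid_n < 2:
        raise ValueError("grid_n must be >= 2")
    if len(centerline) == 0 or len(centerline) != len(frames):
        raise ValueError("centerline and frames must be nonempty and congruent")
    volume = np.asarray(volume, dtype=np.float64)
    spacing = np.asarray(spacing_mm, dtype=np.float64)
    ps = fov_mm / grid_n
    off = (np.arange(grid_n) - (grid_n - 1) / 2.0) * ps
    # world-coordinate sampling points: (n_slices, grid_n, grid_n, 3)
    P = (centerline.points[:, None, None, :]
         + frames.normal_v[:, None, None, :] * off[None, :, None, None]
         + frames.normal_u[:, None, None, :] * off[None, None, :, None])
    idx = (P / spacing).transpose(3, 0, 1, 2)  # voxel-index coordinates
    vals = map_coordinates(volume, idx, order=1, mode="constant", cval=0.0)
    vals = np.clip(vals, 0.0, 1.0)
    masks = {}
    for name, m in (("lumen", lumen_mask), ("thrombus", thrombus_mask)):
        if m is not None:
            masks[name] = map_coordinates(np.asarray(m, dtype=np.uint8), idx,
                                          order=0, mode="constant", cval=0).astype(bool)
    out = []
    for i in range(len(centerline)):
        out.append(CrossSection(
            pixels=vals[i], pixel_spacing_mm=ps,
            lumen_mask=masks["lumen"][i] if "lumen" in masks else None,
            thrombus_mask=masks["thrombus"][i] if "thrombus" in masks else None,
            subject_id=subject_id, slice_index=i,
            arclength_mm=float(centerline.cumulative_arclength[i])))
    return out


def _int_shift(arr: np.ndarray, dr: int, dc: int, fill=0) -> np.ndarray:
    """Shift a 2D array by whole pixels, filling vacated cells."""
    out = np.full_like(arr, fill)
    n0, n1 = arr.shape
    r0, r1 = max(0, dr), min(n0, n0 + dr)
    c0, c1 = max(0, dc), min(n1, n1 + dc)
    out[r0:r1, c0:c1] = arr[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
    return out


def apply_mask_and_center(image: CrossSection,
                          mask: Optional[np.ndarray] = None) -> CrossSection:
    """Zero everything outside the mask and center the mask centroid.

    ``mask`` defaults to the section's own vessel mask (lumen | thrombus).
    The image is translated by an integer pixel shift (no interpolation blur)
    so the mask centroid lands within half a pixel of the grid center
    ((n-1)/2, (n-1)/2); masks are shifted identically.  Idempotent.
    """
    if mask is None:
        mask = image.vessel_mask()
    if mask is None or not np.any(mask):
        raise EmptySegmentationError(
            f"empty segmentation mask (subject {image.subject_id!r}, "
            f"slice {image.slice_index})")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.pixels.shape:
        raise ValueError("mask incongruent with image")
    rows, cols = np.nonzero(mask)
    cr, cc = rows.mean(), cols.mean()
    n0, n1 = mask.shape
    dr = int(np.rint((n0 - 1) / 2.0 - cr))
    dc = int(np.rint((n1 - 1) / 2.0 - cc))
    pix = np.where(mask, image.pixels, 0.0)
    shift2 = lambda a: _int_shift(a, dr, dc)
    return CrossSection(
        pixels=shift2(pix), pixel_spacing_mm=image.pixel_spacing_mm,
        lumen_mask=None if image.lumen_mask is None else shift2(image.lumen_mask),
        thrombus_mask=None if image.thrombus_mask is None else shift2(image.thrombus_mask),
        subject_id=image.subject_id, slice_index=image.slice_index,
        arclength_mm=image.arclength_mm)


def normalize_intensity(image, window_lo: float, window_hi: float):
    """Affine window map: ``window_lo`` -> 0, ``window_hi`` -> 1, clamped.

    Accepts a bare array or a :class:`CrossSection` (returned as the same
    kind).
    """
    if window_lo >= window_hi:
        raise ValueError("window_lo must be strictly less than window_hi")
    if isinstance(image, CrossSection):
        pix = normalize_intensity(image.pixels, window_lo, window_hi)
        return CrossSection(pixels=pix, pixel_spacing_mm=image.pixel_spacing_mm,
                            lumen_mask=image.lumen_mask,
                            thrombus_mask=image.thrombus_mask,
                            subject_id=image.subject_id,
                            slice_index=image.slice_index,
                            arclength_mm=image.arclength_mm)
    arr = np.asarray(image, dtype=np.float64)
    return np.clip((arr - window_lo) / (window_hi - window_lo), 0.0, 1.0)
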