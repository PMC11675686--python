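"""Synthetic aortic phantoms: cross-sections, cohorts, and 3D tube volumes.

The generator emulates the appearance of contrast-enhanced CT cross-sections
of a dissected aorta after stent-graft repair: a hyperintense patent lumen,
thrombus that is isointense relative to surrounding tissue (mid-gray), a thin
dissection septum between true and false lumen, and larger overall diameters
in dissected than in non-dissected vessels.  Geometry is deliberately simple
and closed-form checkable: true and false lumen are two half-disks of
independent radii joined along a straight septum stripe, and thrombus fills
an angular fraction of the false-lumen half-disk (so the thrombosed area
fraction equals the angular fraction).

Every generated object carries ground-truth masks, which makes the whole
downstream pipeline (reslicing, VAE training, scoring) testable without any
patient data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import CrossSection, SliceLabel, VolumePhantom

GRID = 64


class PhantomBoundsError(ValueError):
    """The requested tube does not fit inside the volume grid."""


def _check_range(name, r, lo_ok=0.0):
    r = (float(r[0]), float(r[1]))
    if not r[0] <= r[1]:
        raise ValueError(f"{name}: range must satisfy low <= high, got {r}")
    if r[0] < lo_ok and lo_ok == 0.0:
        raise ValueError(f"{name}: must be nonnegative, got {r}")
    return r


@dataclass
class PhantomSpec:
    """Parameter ranges for the synthetic vessel generator (units: mm and
    window-normalized intensity in [0, 1])."""

    voxel_spacing_mm: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    tl_radius_mm: Tuple[float, float] = (8.0, 12.0)
    fl_radius_mm: Tuple[float, float] = (10.0, 16.0)
    septum_thickness_mm: float = 2.0
    thrombus_fraction: Tuple[float, float] = (0.9, 1.0)
    intensity_lumen: Tuple[float, float] = (0.75, 0.95)
    intensity_thrombus: Tuple[float, float] = (0.40, 0.55)
    intensity_background: Tuple[float, float] = (0.20, 0.35)
    noise_sd: float = 0.03
    curvature_amplitude_mm: float = 8.0

    def __post_init__(self) -> None:
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)
        if len(self.voxel_spacing_mm) != 3 or any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel_spacing_mm must be a positive 3-vector")
        self.tl_radius_mm = _check_range("tl_radius_mm", self.tl_radius_mm)
        self.fl_radius_mm = _check_range("fl_radius_mm", self.fl_radius_mm)
        if self.tl_radius_mm[0] <= 0 or self.fl_radius_mm[0] <= 0:
            raise ValueError("radius ranges must be positive")
        if self.septum_thickness_mm <= 0:
            raise ValueError("septum_thickness_mm must be positive")
        self.thrombus_fraction = _check_range("thrombus_fraction", self.thrombus_fraction)
        if not (0.0 <= self.thrombus_fraction[0] and self.thrombus_fraction[1] <= 1.0):
            raise ValueError("thrombus_fraction must lie within [0, 1]")
        for name in ("intensity_lumen", "intensity_thrombus", "intensity_background"):
            setattr(self, name, _check_range(name, getattr(self, name)))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.curvature_amplitude_mm < 0:
            raise ValueError("curvature_amplitude_mm must be nonnegative")
        m = lambda r: 0.5 * (r[0] + r[1])
        if not (m(self.intensity_lumen) > m(self.intensity_thrombus)
                >= m(self.intensity_background)):
            raise ValueError(
                "intensity ordering violated: require mean lumen > mean thrombus "
                ">= mean background")


def _upper_half(r: Tuple[float, float]) -> Tuple[float, float]:
    return (0.5 * (r[0] + r[1]), r[1])


def _sample_fraction(spec: PhantomSpec, label: SliceLabel, rng) -> float:
    """Fraction of the false-lumen area filled by thrombus, per label."""
    if label is SliceLabel.THROMBOSED_FL:
        return float(rng.uniform(*spec.thrombus_fraction))
    if label is SliceLabel.PARTIAL_FL:
        hi = spec.thrombus_fraction[1]
        return float(rng.uniform(0.2 * hi, 0.8 * hi))
    return 0.0


def _draw_section(shape, spacing, center, r_tl, r_fl, theta, frac, thickness,
                  label: SliceLabel):
    """Rasterize one vessel cross-section in world (mm) coordinates.

    Returns boolean (lumen, thrombus, septum) grids of ``shape``; axis 0/1
    world coordinates are index * spacing (pixel-center convention).
    ``theta`` orients the septum normal (pointing into the true lumen).
    """
    n0, n1 = shape
    x0 = np.arange(n0) * spacing[0]
    x1 = np.arange(n1) * spacing[1]
    X0, X1 = np.meshgrid(x0, x1, indexing="ij")
    p0, p1 = X0 - center[0], X1 - center[1]
    rr = np.hypot(p0, p1)
    lumen = np.zeros(shape, dtype=bool)
    thromb = np.zeros(shape, dtype=bool)
    septum = np.zeros(shape, dtype=bool)
    if label is SliceLabel.NO_FL:
        lumen[rr <= r_tl] = True
        return lumen, thromb, septum
    nvec = (np.cos(theta), np.sin(theta))      # septum normal, toward TL
    svec = (-np.sin(theta), np.cos(theta))     # along the septum
    d = p0 * nvec[0] + p1 * nvec[1]
    s = p0 * svec[0] + p1 * svec[1]
    half_t = 0.5 * thickness
    tl = (d >= half_t) & (rr <= r_tl)
    fl = (d <= -half_t) & (rr <= r_fl)
    septum = (np.abs(d) < half_t) & (rr <= max(r_tl, r_fl))
    # angular coordinate inside the FL half-disk, 0..pi from one septum end
    alpha = np.arctan2(-d, s)
    thromb = fl & (alpha < frac * np.pi)
    lumen = tl | (fl & ~thromb)
    return lumen, thromb, septum


def _sample_geometry(spec: PhantomSpec, label: SliceLabel, rng):
    """Radii, septum angle and thrombus fraction for one vessel instance."""
    if label is SliceLabel.NO_FL:
        r_tl = float(rng.uniform(*spec.tl_radius_mm))
        r_fl = 0.0
    else:
        # dissected aortas present with larger diameters: sample upper halves
        r_tl = float(rng.uniform(*_upper_half(spec.tl_radius_mm)))
        r_fl = float(rng.uniform(*_upper_half(spec.fl_radius_mm)))
    theta = float(rng.uniform(0.0, 2.0 * np.pi))
    frac = _sample_fraction(spec, label, rng)
    return r_tl, r_fl, theta, frac


def _sample_intensities(spec: PhantomSpec, rng):
    return (float(rng.uniform(*spec.intensity_lumen)),
            float(rng.uniform(*spec.intensity_thrombus)),
            float(rng.uniform(*spec.intensity_background)))


def make_phantom_slice(spec: PhantomSpec, label: SliceLabel, rng,
                       subject_id: str = "", slice_index: int = 0) -> CrossSection:
    """Generate one 64x64 cross-section with ground-truth masks.

    ``rng`` is a seeded :class:`numpy.random.Generator`.  The vessel center is
    jittered a few pixels off the grid center so that auto-centering has work
    to do downstream.
    """
    if not isinstance(label, SliceLabel):
        label = SliceLabel(label)
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    dx, dy = spec.voxel_spacing_mm[0], spec.voxel_spacing_mm[1]
    r_tl, r_fl, theta, frac = _sample_geometry(spec, label, rng)
    jitter = rng.uniform(-3.0, 3.0, size=2)
    center = ((GRID - 1) / 2 * dx + jitter[0] * dx,
              (GRID - 1) / 2 * dy + jitter[1] * dy)
    lumen, thromb, _ = _draw_section((GRID, GRID), (dx, dy), center, r_tl, r_fl,
                                     theta, frac, spec.septum_thickness_mm, label)
    i_lum, i_thr, i_bg = _sample_intensities(spec, rng)
    pixels = np.full((GRID, GRID), i_bg)
    pixels[lumen] = i_lum
    pixels[thromb] = i_thr
    if spec.noise_sd > 0:
        pixels = pixels + rng.normal(0.0, spec.noise_sd, size=pixels.shape)
    pixels = np.clip(pixels, 0.0, 1.0)
    return CrossSection(pixels=pixels, pixel_spacing_mm=dx, lumen_mask=lumen,
                        thrombus_mask=thromb, subject_id=subject_id,
                        slice_index=slice_index)


def make_phantom_cohort(spec: PhantomSpec, class_counts: Dict[SliceLabel, int],
                        seed: int, subject_id: str = "cohort"):
    """Generate a labeled stack of cross-sections, reproducible from ``seed``.

    Returns ``(slices, table)`` where ``table`` has one row per image with
    columns subject_id, slice_index, label.  Labels are generated in enum
    order, so the table, not the order, carries the ground truth.
    """
    counts = {SliceLabel(k): int(v) for k, v in class_counts.items()}
    if any(v < 0 for v in counts.values()):
        raise ValueError("class counts must be nonnegative")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty cohort: all class counts are zero")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF]))
    slices: List[CrossSection] = []
    rows = []
    idx = 0
    for label in SliceLabel:
        for _ in range(counts.get(label, 0)):
            slices.append(make_phantom_slice(spec, label, rng,
                                             subject_id=subject_id, slice_index=idx))
            rows.append((subject_id, idx, label.value))
            idx += 1
    table = pd.DataFrame(rows, columns=["subject_id", "slice_index", "label"])
    return slices, table


def make_phantom_volume(spec: PhantomSpec, n_slices: int, seed: int,
                        label: SliceLabel = SliceLabel.NO_FL,
                        shape: Optional[Tuple[int, int]] = None) -> VolumePhantom:
    """Build a 3D volume containing one (optionally curved) vessel tube.

    The tube runs along the z axis; with ``curvature_amplitude_mm`` > 0 its
    center follows a single-period sinusoid in x (closed-form tangents for
    frame tests).  Geometry and intensities are sampled once per volume so
    the tube is coherent along its length.  ``shape`` optionally forces the
    in-plane grid; if the tube would leave the grid a
    :class:`PhantomBoundsError` names the first offending slice.
    """
    if n_slices < 2:
        raise ValueError("n_slices must be >= 2")
    if not isinstance(label, SliceLabel):
        label = SliceLabel(label)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xB0]))
    dx, dy, dz = spec.voxel_spacing_mm
    r_tl, r_fl, theta, frac = _sample_geometry(spec, label, rng)
    amp = spec.curvature_amplitude_mm
    max_r = max(r_tl, r_fl)
    if shape is None:
        half = max_r + amp + 4.0 * max(dx, dy)
        n0 = 2 * int(np.ceil(half / dx)) + 1
        n1 = 2 * int(np.ceil(2 * (max_r + 4.0 * dy) / dy / 2)) + 1
        shape = (n0, n1)
    n0, n1 = shape
    cx0, cy0 = (n0 - 1) / 2 * dx, (n1 - 1) / 2 * dy
    length = (n_slices - 1) * dz

    vol = np.zeros((n0, n1, n_slices))
    lumen = np.zeros_like(vol, dtype=bool)
    thromb = np.zeros_like(vol, dtype=bool)
    i_lum, i_thr, i_bg = _sample_intensities(spec, rng)
    centerline = np.zeros((n_slices, 3))
    nvec = (np.cos(theta), np.sin(theta))
    for k in range(n_slices):
        z = k * dz
        cx = cx0 + (amp * np.sin(2.0 * np.pi * z / length) if amp > 0 else 0.0)
        reach = max_r + max(dx, dy)
        if cx - reach < 0 or cx + reach > (n0 - 1) * dx \
                or cy0 - reach < 0 or cy0 + reach > (n1 - 1) * dy:
            raise PhantomBoundsError(
                f"tube exits volume bounds at slice {k} (center x = {cx:.1f} mm)")
        lum_k, thr_k, _ = _draw_section((n0, n1), (dx, dy), (cx, cy0), r_tl, r_fl,
                                        theta, frac, spec.septum_thickness_mm, label)
        sl = np.full((n0, n1), i_bg)
        sl[lum_k] = i_lum
        sl[thr_k] = i_thr
        vol[:, :, k] = sl
        lumen[:, :, k] = lum_k
        thromb[:, :, k] = thr_k
        if label is SliceLabel.NO_FL:
            cl_xy = (cx, cy0)
        else:
            # centerline tracks the patent true lumen, not the septum
            off = 0.5 * spec.septum_thickness_mm + 0.45 * r_tl
            cl_xy = (cx + off * nvec[0], cy0 + off * nvec[1])
        centerline[k] = (cl_xy[0], cl_xy[1], z)
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape)
    vol = np.clip(vol, 0.0, 1.0)
    return VolumePhantom(intensities=vol, spacing_mm=np.array([dx, dy, dz]),
                         centerline_truth=centerline, lumen_mask=lumen,
                         thrombus_mask=thromb, label=label)
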