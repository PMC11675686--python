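"""File-format plumbing: NIfTI volumes and stacks, centerline text, tables.

Volumes use a diagonal affine built from the voxel spacing (world mm =
index * spacing, matching the package-wide convention).  Cross-section
stacks are stored as 64 x 64 x n_slices NIfTI images together with a CSV
manifest (subject_id, slice_index, arclength_mm).  Centerlines are
whitespace-delimited ``x y z`` text in mm, one point per line.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .types import CrossSection, VolumePhantom, SliceLabel


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_nifti(array: np.ndarray, spacing, path) -> None:
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float32), _affine(spacing))
    nib.save(img, str(path))


def load_nifti(path) -> Tuple[np.ndarray, np.ndarray]:
    """Returns (array, spacing_mm[3])."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=np.float64)
    return data, spacing


def save_centerline(points: np.ndarray, path) -> None:
    np.savetxt(str(path), np.asarray(points, dtype=np.float64), fmt="%.6f")


def load_centerline(path) -> np.ndarray:
    pts = np.loadtxt(str(path), dtype=np.float64)
    return np.atleast_2d(pts)


def save_volume_phantom(vp: VolumePhantom, stem: Path) -> List[Path]:
    """Write intensities, masks and centerline beside each other; returns the
    paths written.  ``stem`` is a path prefix without extension."""
    stem = Path(stem)
    paths = [stem.with_suffix(".nii"), Path(f"{stem}_lumen.nii"),
             Path(f"{stem}_thrombus.nii"), Path(f"{stem}_centerline.txt")]
    save_nifti(vp.intensities, vp.spacing_mm, paths[0])
    save_nifti(vp.lumen_mask.astype(np.uint8), vp.spacing_mm, paths[1])
    save_nifti(vp.thrombus_mask.astype(np.uint8), vp.spacing_mm, paths[2])
    save_centerline(vp.centerline_truth, paths[3])
    return paths


def load_volume_phantom(stem: Path, label: SliceLabel = SliceLabel.NO_FL) -> VolumePhantom:
    stem = Path(stem)
    vol, spacing = load_nifti(stem.with_suffix(".nii"))
    lumen, _ = load_nifti(f"{stem}_lumen.nii")
    thromb, _ = load_nifti(f"{stem}_thrombus.nii")
    cl = load_centerline(f"{stem}_centerline.txt")
    return VolumePhantom(intensities=vol, spacing_mm=spacing, centerline_truth=cl,
                         lumen_mask=lumen > 0.5, thrombus_mask=thromb > 0.5,
                         label=label)


def save_stack(sections: Sequence[CrossSection], stem: Path) -> List[Path]:
    """Write a cross-section stack as NIfTI plus its CSV manifest."""
    stem = Path(stem)
    if not sections:
        raise ValueError("cannot save an empty stack")
    ps = sections[0].pixel_spacing_mm
    arr = np.stack([s.pixels for s in sections], axis=-1)
    paths = [stem.with_suffix(".nii"), Path(f"{stem}_manifest.csv")]
    save_nifti(arr, (ps, ps, 1.0), paths[0])
    pd.DataFrame({
        "subject_id": [s.subject_id for s in sections],
        "slice_index": [s.slice_index for s in sections],
        "arclength_mm": [s.arclength_mm for s in sections],
    }).to_csv(paths[1], index=False)
    return paths


def load_stack(stem: Path) -> List[CrossSection]:
    stem = Path(stem)
    arr, spacing = load_nifti(stem.with_suffix(".nii"))
    manifest = pd.read_csv(f"{stem}_manifest.csv")
    if arr.shape[2] != len(manifest):
        raise ValueError(f"stack {stem}: manifest rows != slices")
    out = []
    for i, row in manifest.iterrows():
        out.append(CrossSection(pixels=np.clip(arr[:, :, i], 0.0, 1.0),
                                pixel_spacing_mm=float(spacing[0]),
                                subject_id=str(row["subject_id"]),
                                slice_index=int(row["slice_index"]),
                                arclength_mm=float(row["arclength_mm"])))
    return out
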