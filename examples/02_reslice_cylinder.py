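"""Reslice a curved synthetic tube perpendicular to its centerline.

Builds a curved vessel volume, resamples its centerline at 1 mm arc-length
steps, attaches rotation-minimizing frames, and extracts centered 64x64
cross-sections.  For a constant-radius tube the segmented lumen area of each
interior slice should match the analytic disk area pi*r^2.
"""

import numpy as np

from flvae import (PhantomSpec, SliceLabel, apply_mask_and_center,
                   compute_frames, extract_cross_sections, make_phantom_volume,
                   resample_centerline)

# mild bend: the phantom rasterizes the tube in axial planes, so strong
# curvature would make truly-perpendicular cuts elliptical by cos(tilt)
spec = PhantomSpec(noise_sd=0.0, tl_radius_mm=(10.0, 10.0),
                   curvature_amplitude_mm=2.0)
vp = make_phantom_volume(spec, 60, seed=4, label=SliceLabel.NO_FL)
cl = resample_centerline(vp.centerline_truth, step_mm=1.0)
frames = compute_frames(cl)
secs = extract_cross_sections(vp.intensities, vp.spacing_mm, cl, frames,
                              fov_mm=40.0, grid_n=64, lumen_mask=vp.lumen_mask)

areas = [s.lumen_mask.sum() * s.pixel_spacing_mm ** 2 for s in secs[3:-3]]
print(f"volume shape {vp.intensities.shape}, centerline length "
      f"{cl.cumulative_arclength[-1]:.1f} mm, {len(secs)} slices")
print(f"lumen area per slice: {np.mean(areas):.1f} +/- {np.std(areas):.1f} mm^2 "
      f"(analytic disk: {np.pi * 100:.1f} mm^2)")

centered = apply_mask_and_center(secs[len(secs) // 2])
r, c = np.nonzero(centered.vessel_mask())
print(f"centered mid-slice centroid: ({r.mean():.2f}, {c.mean():.2f}) "
      "(grid center is (31.50, 31.50))")
# Interior slice areas sit within a few percent of the analytic value even
# though the tube is curved: the frames keep each cut perpendicular.
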