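"""Latent-space partitioning and thrombus scoring.

A trained encoder maps every cross-section to a posterior mean in the 2D
latent space.  On a well-trained cohort the latent cloud is bipolar: slices
containing thrombus cluster on one side, thrombus-free slices on the other.
The partition is a straight line at coordinate ``x0`` on one latent axis;
the per-slice thrombus score is

    ts = (x - x0) / (xmin - x0)   for x inside the thrombus subspace,
    ts = 0                         otherwise,

where ``xmin`` is the extreme latent coordinate on the thrombus side among
the reference (fitting) cohort, so ts runs from 0 at the boundary to 1 at the
most thrombus-like image seen.  Averaging over all slices of one subject
gives that subject's total thrombus score.

Latent axes of a VAE carry no intrinsic meaning, so nothing transfers
between training runs: the partition is always fit per trained model.  In
``auto`` mode the boundary is the midpoint of a deterministic 1D 2-means on
the chosen axis, and the cluster whose members have the larger segmented
foreground area is taken as the thrombus side (dissected aortas are larger);
``fixed`` mode reproduces the classical convention of a hand-picked boundary
(default x0 = -0.8, thrombus below).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .types import CrossSection, LatentPoint
from .vae import VAEParams, encode_batch

__all__ = [
    "LatentPartition", "SliceScore", "DatasetScore", "embed_dataset",
    "fit_partition", "thrombus_score", "dataset_score", "score_track",
    "foreground_area", "select_axis",
]

THROMBUS_BELOW = "thrombus_below_x0"
THROMBUS_ABOVE = "thrombus_above_x0"


@dataclass(frozen=True)
class LatentPartition:
    """Straight-line split of the latent space into thrombus / no-thrombus
    subspaces along one axis."""

    x0: float = -0.8
    xmin: Optional[float] = None
    orientation: str = THROMBUS_BELOW
    degenerate: bool = False
    axis: int = 0
    model_fingerprint: str = ""

    def __post_init__(self) -> None:
        if self.orientation not in (THROMBUS_BELOW, THROMBUS_ABOVE):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.degenerate:
            if self.xmin is not None:
                raise ValueError("degenerate partition must not carry xmin")
        else:
            if self.xmin is None:
                raise ValueError("non-degenerate partition requires xmin")
            if self.orientation == THROMBUS_BELOW and not self.xmin < self.x0:
                raise ValueError("thrombus_below_x0 requires xmin < x0")
            if self.orientation == THROMBUS_ABOVE and not self.xmin > self.x0:
                raise ValueError("thrombus_above_x0 requires xmin > x0")

    def on_thrombus_side(self, x: float) -> bool:
        if self.orientation == THROMBUS_BELOW:
            return x < self.x0
        return x > self.x0

    def to_json(self) -> str:
        d = {"x0": self.x0, "xmin": self.xmin, "orientation": self.orientation,
             "degenerate": self.degenerate, "axis": self.axis,
             "model_fingerprint": self.model_fingerprint}
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "LatentPartition":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class SliceScore:
    ts: float
    subject_id: str = ""
    slice_index: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.ts) or not 0.0 <= self.ts <= 1.0:
            raise ValueError(f"slice score must lie in [0, 1], got {self.ts}")


@dataclass
class DatasetScore:
    """Per-subject result: all slice scores and their arithmetic mean."""

    mean_ts: float
    n_slices: int
    per_slice: List[SliceScore]


def embed_dataset(params: VAEParams, images: Sequence) -> List[LatentPoint]:
    """Encode every image to its latent posterior, order-preserving."""
    images = list(images)
    if not images:
        raise ValueError("embed_dataset requires a nonempty image list")
    mu, lv = encode_batch(params, images)
    return [LatentPoint(mu=mu[i], logvar=lv[i]) for i in range(len(images))]


def foreground_area(image: CrossSection, threshold: float = 1e-6) -> float:
    """Segmented foreground area in pixels (masked images are 0 outside)."""
    m = image.vessel_mask()
    if m is not None:
        return float(m.sum())
    return float((image.pixels > threshold).sum())


def _kmeans_1d(x: np.ndarray):
    """Deterministic 1D 2-means: extreme-point init, ties toward the lower
    center; returns (lo_center, hi_center, assignment-to-hi bool array)."""
    c_lo, c_hi = float(x.min()), float(x.max())
    if c_lo == c_hi:
        return c_lo, c_hi, np.zeros(len(x), dtype=bool)
    for _ in range(200):
        hi = (x - c_lo) ** 2 > (x - c_hi) ** 2  # ties -> lower center
        if not hi.any() or hi.all():
            break
        n_lo, n_hi = float(x[~hi].mean()), float(x[hi].mean())
        if n_lo == c_lo and n_hi == c_hi:
            break
        c_lo, c_hi = n_lo, n_hi
    return c_lo, c_hi, hi


def select_axis(points: Sequence[LatentPoint]) -> int:
    """Pick the latent axis with the cleanest bimodal split.

    For each axis, run the deterministic 1D 2-means and rank axes by the
    between-cluster center distance in units of pooled within-cluster spread.
    """
    mu = np.array([p.mu for p in points])
    best_axis, best_sep = 0, -np.inf
    for ax in range(mu.shape[1]):
        x = mu[:, ax]
        c_lo, c_hi, hi = _kmeans_1d(x)
        if not hi.any() or hi.all():
            sep = 0.0
        else:
            within = np.sqrt((np.var(x[hi]) * hi.sum()
                              + np.var(x[~hi]) * (~hi).sum()) / len(x))
            sep = (c_hi - c_lo) / max(within, 1e-12)
        if sep > best_sep:
            best_axis, best_sep = ax, sep
    return best_axis


def fit_partition(points: Sequence[LatentPoint], mode: str = "fixed",
                  x0_fixed: float = -0.8,
                  foreground_areas: Optional[Sequence[float]] = None,
                  axis: int = 0, orientation: Optional[str] = None,
                  model_fingerprint: str = "") -> LatentPartition:
    """Fit the latent split from a reference cohort of latent points.

    ``mode='fixed'``: boundary at ``x0_fixed``, thrombus below (the classical
    convention).  ``mode='auto'``: boundary at the midpoint of the two 1D
    2-means centers on the chosen axis; the thrombus side is the cluster with
    the larger mean ``foreground_areas`` (falling back to thrombus-below when
    areas are not supplied), unless ``orientation`` overrides it.  ``xmin``
    is the extreme coordinate on the thrombus side among the supplied points;
    with no point on the thrombus side the partition is degenerate and scores
    everything 0.
    """
    points = list(points)
    if not points:
        raise ValueError("fit_partition requires a nonempty point list")
    x = np.array([float(p.mu[axis]) for p in points])
    if mode == "fixed":
        x0 = float(x0_fixed)
        orient = orientation or THROMBUS_BELOW
    elif mode == "auto":
        c_lo, c_hi, hi = _kmeans_1d(x)
        x0 = 0.5 * (c_lo + c_hi)
        if orientation is not None:
            orient = orientation
        elif foreground_areas is not None:
            areas = np.asarray(foreground_areas, dtype=float)
            if len(areas) != len(points):
                raise ValueError("foreground_areas must match points")
            if not hi.any() or hi.all():
                orient = THROMBUS_BELOW
            else:
                orient = THROMBUS_ABOVE if areas[hi].mean() > areas[~hi].mean() \
                    else THROMBUS_BELOW
        else:
            orient = THROMBUS_BELOW
    else:
        raise ValueError("mode must be 'fixed' or 'auto'")
    side = x < x0 if orient == THROMBUS_BELOW else x > x0
    if not side.any():
        return LatentPartition(x0=x0, xmin=None, orientation=orient,
                               degenerate=True, axis=axis,
                               model_fingerprint=model_fingerprint)
    xmin = float(x[side].min() if orient == THROMBUS_BELOW else x[side].max())
    return LatentPartition(x0=x0, xmin=xmin, orientation=orient, degenerate=False,
                           axis=axis, model_fingerprint=model_fingerprint)


def thrombus_score(point: LatentPoint, partition: LatentPartition,
                   subject_id: str = "", slice_index: int = 0) -> SliceScore:
    """Per-slice thrombus score ts in [0, 1].

    ts = (x - x0) / (xmin - x0) inside the thrombus subspace, 0 otherwise;
    values beyond the reference extreme clamp to 1 (new data may exceed the
    fitting cohort's range).
    """
    x = float(point.mu[partition.axis])
    if not np.isfinite(x):
        raise ValueError("non-finite latent coordinate")
    if partition.degenerate or not partition.on_thrombus_side(x):
        ts = 0.0
    else:
        ts = (x - partition.x0) / (partition.xmin - partition.x0)
        ts = min(max(ts, 0.0), 1.0)
    return SliceScore(ts=ts, subject_id=subject_id, slice_index=slice_index)


def dataset_score(scores: Sequence[SliceScore]) -> DatasetScore:
    """Arithmetic mean of one subject's slice scores (order-invariant)."""
    scores = list(scores)
    if not scores:
        raise ValueError("dataset_score requires a nonempty score list")
    subjects = {s.subject_id for s in scores}
    if len(subjects) > 1:
        raise ValueError(f"dataset_score mixes subjects: {sorted(subjects)}")
    # sort before summing so the mean is exactly permutation-invariant
    vals = np.sort(np.array([s.ts for s in scores], dtype=np.float64))
    return DatasetScore(mean_ts=float(vals.mean()), n_slices=len(scores),
                        per_slice=scores)


def score_track(per_slice: Sequence[SliceScore], colormap_bins: int = 10):
    """Discretize slice scores into colormap bins for the per-slice track.

    Returns ``(bin_indices, legend)`` with ``bin = floor(ts * bins)`` capped
    at ``bins - 1`` and ``legend[b] = (lo, hi)`` score interval of bin b.
    """
    per_slice = list(per_slice)
    if not per_slice:
        raise ValueError("score_track requires a nonempty score list")
    if colormap_bins < 2:
        raise ValueError("colormap_bins must be >= 2")
    b = colormap_bins
    idx = np.minimum((np.array([s.ts for s in per_slice]) * b).astype(int), b - 1)
    legend = {i: (i / b, (i + 1) / b) for i in range(b)}
    return idx, legend


def scores_frame(points: Sequence[LatentPoint], partition: LatentPartition,
                 images: Sequence[CrossSection],
                 colormap_bins: int = 10) -> pd.DataFrame:
    """Per-slice score table: subject_id, slice_index, arclength_mm, x, y,
    ts, bin — one row per image, aligned with ``points``."""
    rows = []
    scores = []
    for p, im in zip(points, images):
        s = thrombus_score(p, partition, subject_id=im.subject_id,
                           slice_index=im.slice_index)
        scores.append(s)
        rows.append((im.subject_id, im.slice_index, im.arclength_mm,
                     float(p.mu[0]), float(p.mu[1]) if len(p.mu) > 1 else np.nan,
                     s.ts))
    df = pd.DataFrame(rows, columns=["subject_id", "slice_index", "arclength_mm",
                                     "x", "y", "ts"])
    bins, _ = score_track(scores, colormap_bins)
    df["bin"] = bins
    return df
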