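"""Shared domain containers used across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np


class SliceLabel(Enum):
    """False-lumen status of one aortic cross-section.

    The four clinical categories: no false lumen at all (no residual
    dissection), a fully patent false lumen, a partially thrombosed false
    lumen, and a fully thrombosed false lumen.
    """

    NO_FL = "NO_FL"
    PATENT_FL = "PATENT_FL"
    PARTIAL_FL = "PARTIAL_FL"
    THROMBOSED_FL = "THROMBOSED_FL"

    @property
    def has_fl(self) -> bool:
        return self is not SliceLabel.NO_FL

    @property
    def has_thrombus(self) -> bool:
        return self in (SliceLabel.PARTIAL_FL, SliceLabel.THROMBOSED_FL)


@dataclass
class CrossSection:
    """One 64x64 normalized aortic cross-section, the unit of VAE input.

    ``pixels`` holds window-normalized intensities in [0, 1]. Masks, when
    present, are boolean grids congruent with ``pixels``: ``lumen_mask`` marks
    patent (contrast-enhanced) lumen, ``thrombus_mask`` marks thrombosed
    false-lumen tissue; the two never overlap.
    """

    pixels: np.ndarray
    pixel_spacing_mm: float = 1.0
    lumen_mask: Optional[np.ndarray] = None
    thrombus_mask: Optional[np.ndarray] = None
    subject_id: str = ""
    slice_index: int = 0
    arclength_mm: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D grid")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"pixels must lie in [0,1], got range [{lo}, {hi}]")
        for name in ("lumen_mask", "thrombus_mask"):
            m = getattr(self, name)
            if m is not None:
                m = np.asarray(m, dtype=bool)
                if m.shape != self.pixels.shape:
                    raise ValueError(f"{name} shape {m.shape} != pixels {self.pixels.shape}")
                setattr(self, name, m)
        if self.lumen_mask is not None and self.thrombus_mask is not None:
            if np.any(self.lumen_mask & self.thrombus_mask):
                raise ValueError("lumen_mask and thrombus_mask overlap")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def vessel_mask(self) -> Optional[np.ndarray]:
        """Union of lumen and thrombus masks (the segmented aorta)."""
        if self.lumen_mask is None and self.thrombus_mask is None:
            return None
        m = np.zeros(self.pixels.shape, dtype=bool)
        if self.lumen_mask is not None:
            m |= self.lumen_mask
        if self.thrombus_mask is not None:
            m |= self.thrombus_mask
        return m


@dataclass(frozen=True)
class LatentPoint:
    """Gaussian posterior assigned to one image by the encoder: mean and
    log-variance, each a ``latent_dim`` vector (2 for the canonical model)."""

    mu: np.ndarray
    logvar: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=np.float64))
        object.__setattr__(self, "logvar", np.asarray(self.logvar, dtype=np.float64))
        if not (np.all(np.isfinite(self.mu)) and np.all(np.isfinite(self.logvar))):
            raise ValueError("latent point components must be finite")
        if self.mu.shape != self.logvar.shape:
            raise ValueError("mu and logvar must have matching shapes")


@dataclass
class VolumePhantom:
    """Synthetic 3D intensity volume with ground truth.

    Array axes are (x, y, z); world coordinates in mm are index * spacing.
    ``centerline_truth`` is an ordered (N, 3) point list in mm running through
    the patent true lumen.
    """

    intensities: np.ndarray
    spacing_mm: np.ndarray
    centerline_truth: np.ndarray
    lumen_mask: np.ndarray
    thrombus_mask: np.ndarray
    label: SliceLabel = SliceLabel.PATENT_FL

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=np.float64)
        self.centerline_truth = np.asarray(self.centerline_truth, dtype=np.float64)
        self.lumen_mask = np.asarray(self.lumen_mask, dtype=bool)
        self.thrombus_mask = np.asarray(self.thrombus_mask, dtype=bool)
        if self.lumen_mask.shape != self.intensities.shape:
            raise ValueError("lumen_mask incongruent with intensities")
        if self.thrombus_mask.shape != self.intensities.shape:
            raise ValueError("thrombus_mask incongruent with intensities")
        if np.any(self.lumen_mask & self.thrombus_mask):
            raise ValueError("lumen and thrombus masks overlap")
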