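"""Binary masks and the morphological clean-up applied to them.

Corrected 8-bit channels become thresholded masks (default range
10-255, inclusive at both ends).  The islet channel sum is then cleaned
in a fixed order: small foreground specks are removed, and background
enclaves (unstained nuclei inside endocrine tissue) are filled.
Foreground uses 8-connectivity and background 4-connectivity, the
standard complementary pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi

from .errors import DimensionError, ValidationError

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass
class BinaryMask:
    """A thresholded foreground grid carrying the spatial calibration."""

    grid: np.ndarray
    um_per_px: float
    role_tag: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.dtype != bool:
            self.grid = self.grid.astype(bool)
        if self.grid.ndim != 2:
            raise DimensionError("mask grid must be 2-D")
        if not self.um_per_px > 0:
            raise ValidationError("um_per_px must be positive")

    @property
    def area_px(self) -> int:
        return int(self.grid.sum())

    @property
    def area_um2(self) -> float:
        return self.area_px * self.um_per_px**2

    def with_grid(self, grid: np.ndarray) -> "BinaryMask":
        return BinaryMask(grid, self.um_per_px, self.role_tag)


@dataclass(frozen=True)
class MaskConfig:
    """Thresholding and clean-up parameters.

    ``min_size`` is a pixel *radius*: connected foreground components
    with area below ``pi * min_size**2`` are treated as noise.  It
    should approximate the lymphocyte radius at the image scale.
    """

    thresh_lo: int = 10
    thresh_hi: int = 255
    min_size: float = 5.0

    def __post_init__(self) -> None:
        if not (0 <= self.thresh_lo <= self.thresh_hi <= 255):
            raise ValidationError("thresholds must satisfy 0 <= lo <= hi <= 255")
        if self.min_size < 0:
            raise ValidationError("min_size must be non-negative")

    @property
    def min_area_px(self) -> float:
        return math.pi * self.min_size**2


def threshold_mask(
    channel: np.ndarray,
    cfg: MaskConfig,
    um_per_px: float,
    role_tag: str = "",
) -> BinaryMask:
    """Mark pixels whose 8-bit intensity lies in [thresh_lo, thresh_hi]."""
    channel = np.asarray(channel)
    if channel.dtype != np.uint8:
        raise TypeError(f"threshold_mask needs an 8-bit channel, got {channel.dtype}")
    grid = (channel >= cfg.thresh_lo) & (channel <= cfg.thresh_hi)
    return BinaryMask(grid, um_per_px, role_tag)


def remove_small(mask: BinaryMask, min_size: float) -> BinaryMask:
    """Drop 8-connected components with area below ``pi * min_size**2``."""
    if min_size < 0:
        raise ValidationError("min_size must be non-negative")
    cutoff = math.pi * min_size**2
    labels, n = ndi.label(mask.grid, structure=_EIGHT_CONNECTED)
    if n == 0:
        return mask.with_grid(mask.grid.copy())
    sizes = np.bincount(labels.ravel())
    keep = sizes >= cutoff
    keep[0] = False
    return mask.with_grid(keep[labels])


def fill_enclaves(mask: BinaryMask) -> BinaryMask:
    """Convert background enclaves (holes) to foreground.

    A background component (4-connectivity) that does not reach the
    image border is entirely surrounded by foreground — typically an
    unstained nucleus inside endocrine tissue — and is filled.
    """
    return mask.with_grid(ndi.binary_fill_holes(mask.grid))


def combine(a: BinaryMask, b: BinaryMask, mode: str) -> BinaryMask:
    """Pixelwise union, intersection or difference of two masks.

    Union realizes the binary "addition" of thresholded channels and
    intersection the "multiplication" by the islet-area mask.
    """
    if a.grid.shape != b.grid.shape:
        raise DimensionError(f"mask dimensions differ: {a.grid.shape} vs {b.grid.shape}")
    if a.um_per_px != b.um_per_px:
        raise DimensionError("mask calibrations differ")
    if mode == "union":
        grid = a.grid | b.grid
    elif mode == "intersection":
        grid = a.grid & b.grid
    elif mode == "difference":
        grid = a.grid & ~b.grid
    else:
        raise ValidationError(f"unknown combine mode {mode!r}")
    return BinaryMask(grid, a.um_per_px, a.role_tag)


def mask_area(mask: BinaryMask) -> tuple[int, float]:
    """Return ``(area_px, area_um2)`` with area_um2 = px count * um_per_px**2."""
    return mask.area_px, mask.area_um2
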