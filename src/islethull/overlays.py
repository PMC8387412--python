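"""Validation overlays for rapid human quality control.

Two images are rendered per analyzed islet: the islet-area mask
alpha-blended in white over the false-colour channel merge, and the
islet area plus thresholded CD4/CD8 masks on black.  A glance at the
pair tells the analyst whether the background ROI was drawn well; a bad
islet is fixed by correcting its manifest rows and re-running.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import DimensionError
from .image_io import CalibratedImage, convert_to_8bit
from .masking import BinaryMask

#: Default false-colour map (RGB 0-255 per marker role).
DEFAULT_COLORS = {
    "insulin": (255, 0, 0),
    "glucagon": (255, 0, 255),
    "cd4": (255, 255, 0),
    "cd8": (0, 255, 255),
    "dapi": (0, 0, 255),
}


@dataclass(frozen=True)
class OverlayStyle:
    colors: dict = field(default_factory=lambda: dict(DEFAULT_COLORS))
    overlay_color: tuple = (255, 255, 255)
    alpha: float = 0.35
    cd4_color: tuple = (255, 255, 0)
    cd8_color: tuple = (0, 255, 255)


@dataclass
class OverlayPair:
    hull_on_merge: np.ndarray
    hull_on_masks: np.ndarray


def false_color_merge(image: CalibratedImage, style: OverlayStyle | None = None) -> np.ndarray:
    """Additively merge channels into an RGB image using the colour map."""
    style = style or OverlayStyle()
    img8 = convert_to_8bit(image)
    h, w = img8.shape
    acc = np.zeros((h, w, 3), dtype=np.float64)
    for role, ch in img8.channels.items():
        color = np.asarray(style.colors.get(role, (255, 255, 255)), dtype=np.float64)
        acc += ch[:, :, None].astype(np.float64) / 255.0 * color
    return np.floor(np.clip(acc, 0, 255) + 0.5).astype(np.uint8)


def _blend(rgb: np.ndarray, mask: np.ndarray, color: tuple, alpha: float) -> np.ndarray:
    out = rgb.astype(np.float64)
    col = np.asarray(color, dtype=np.float64)
    out[mask] = (1.0 - alpha) * out[mask] + alpha * col
    return np.floor(np.clip(out, 0, 255) + 0.5).astype(np.uint8)


def render_validation_pair(
    image: CalibratedImage,
    islet_mask: BinaryMask,
    cd4: BinaryMask,
    cd8: BinaryMask,
    style: OverlayStyle | None = None,
) -> OverlayPair:
    """Render the two per-islet validation images.

    Deterministic for fixed inputs and style: no randomness, all
    blending in float64 with half-up rounding back to uint8.
    """
    style = style or OverlayStyle()
    for m in (islet_mask, cd4, cd8):
        if m.grid.shape != image.shape:
            raise DimensionError(
                f"mask shape {m.grid.shape} does not match image shape {image.shape}"
            )
    merge = false_color_merge(image, style)
    hull_on_merge = _blend(merge, islet_mask.grid, style.overlay_color, style.alpha)

    black = np.zeros((*image.shape, 3), dtype=np.uint8)
    on_masks = _blend(black, islet_mask.grid, style.overlay_color, style.alpha)
    on_masks = _blend(on_masks, cd4.grid, style.cd4_color, 1.0)
    on_masks = _blend(on_masks, cd8.grid, style.cd8_color, 1.0)
    return OverlayPair(hull_on_merge=hull_on_merge, hull_on_masks=on_masks)


def save_overlay_pair(pair: OverlayPair, out_dir: str | Path, stem: str) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p1 = out_dir / f"{stem}_hull_on_merge.png"
    p2 = out_dir / f"{stem}_hull_on_masks.png"
    iio.imwrite(p1, pair.hull_on_merge)
    iio.imwrite(p2, pair.hull_on_masks)
    return p1, p2
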