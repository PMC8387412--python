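"""Calibrated image loading, bit-depth conversion, crops and manifests.

All coordinates are 0-based pixels with origin at the top-left corner,
``x`` = column and ``y`` = row; rectangles are half-open.  Processing is
done in pixels throughout; the micrometre calibration is applied only
when areas are reported.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

from .background import RoiSpec
from .errors import (
    BoundsError,
    ConfigurationError,
    DimensionError,
    ValidationError,
)

#: Marker roles understood by the pipeline.  Insulin (beta cells) and
#: glucagon (alpha cells) are mandatory for islet-area analysis; CD4 and
#: CD8 carry the T-cell signal; DAPI is display-only.
ROLES = ("insulin", "glucagon", "cd4", "cd8", "dapi")
MANDATORY_ROLES = ("insulin", "glucagon")


@dataclass
class CalibratedImage:
    """A named multi-channel intensity stack with spatial calibration.

    ``channels`` maps a marker role to a 2-D intensity grid; all grids
    share identical dimensions and intensities lie within the bit depth.
    """

    channels: dict[str, np.ndarray]
    bit_depth: int
    um_per_px: float
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ConfigurationError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not self.um_per_px > 0:
            raise ConfigurationError("um_per_px must be positive")
        if not self.channels:
            raise ConfigurationError("image has no channels")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise DimensionError(f"channel dimensions differ: {sorted(shapes)}")
        for role, ch in self.channels.items():
            if role not in ROLES:
                raise ConfigurationError(f"unknown marker role {role!r}")
            if ch.ndim != 2:
                raise DimensionError(f"channel {role!r} is not 2-D")
            if ch.size and float(np.max(ch)) > 2**self.bit_depth - 1:
                raise ValidationError(
                    f"channel {role!r} exceeds the {self.bit_depth}-bit range"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass(frozen=True)
class CropSpec:
    """Half-open pixel rectangle ``(x0, y0, width, height)``, origin top-left."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValidationError("crop width and height must be >= 1")
        if self.x0 < 0 or self.y0 < 0:
            raise BoundsError("crop origin must be non-negative")

    def validate_within(self, grid_shape: tuple[int, int]) -> None:
        h, w = grid_shape
        if self.x0 + self.width > w or self.y0 + self.height > h:
            raise BoundsError(
                f"crop {self} exceeds image bounds {w}x{h} (width x height)"
            )

    def apply(self, grid: np.ndarray) -> np.ndarray:
        self.validate_within(grid.shape)
        return grid[self.y0 : self.y0 + self.height, self.x0 : self.x0 + self.width].copy()


@dataclass
class ManifestEntry:
    """One islet to analyze: its anonymized label, source image and crop."""

    anonymized_id: str
    source_id: str
    mouse_id: str = ""
    group: str = ""
    crop: CropSpec | None = None
    rois: list[RoiSpec] = field(default_factory=list)


@dataclass
class IsletManifest:
    """Blinded, seed-determined processing order over a set of islets."""

    entries: list[ManifestEntry]
    seed: int


def _dtype_bit_depth(dtype: np.dtype) -> int:
    if dtype == np.uint8:
        return 8
    if dtype == np.uint16:
        return 16
    raise ConfigurationError(f"unsupported image dtype {dtype}; expected uint8/uint16")


def load_channels(
    paths: str | Path | Sequence[str | Path],
    channel_map: Mapping[str, int],
    um_per_px: float,
    source_id: str = "",
) -> CalibratedImage:
    """Load a multi-page TIFF (or one single-channel TIFF per role).

    ``channel_map`` maps each marker role to a page index (multi-page
    input) or to an index into ``paths`` (per-channel input).  Insulin
    and glucagon are mandatory.
    """
    for role in MANDATORY_ROLES:
        if role not in channel_map:
            raise ConfigurationError(f"channel map must include {role!r}")
    for role in channel_map:
        if role not in ROLES:
            raise ConfigurationError(f"unknown marker role {role!r}")

    if isinstance(paths, (str, Path)):
        stack = tifffile.imread(paths)
        if stack.ndim == 2:
            stack = stack[None]
        pages = list(stack)
    else:
        pages = [tifffile.imread(p) for p in paths]

    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise DimensionError(f"channel pages differ in size: {sorted(shapes)}")

    channels = {}
    for role, idx in channel_map.items():
        if idx < 0 or idx >= len(pages):
            raise ConfigurationError(f"channel index {idx} for {role!r} out of range")
        channels[role] = np.asarray(pages[idx])
    bit_depth = _dtype_bit_depth(next(iter(channels.values())).dtype)
    if not isinstance(paths, (str, Path)):
        source_id = source_id or str(paths[0])
    else:
        source_id = source_id or str(paths)
    return CalibratedImage(channels, bit_depth, um_per_px, source_id)


def save_channels(image: CalibratedImage, path: str | Path, channel_order: Sequence[str]) -> None:
    """Write the image as a multi-page grayscale TIFF in ``channel_order``."""
    missing = [r for r in channel_order if r not in image.channels]
    if missing:
        raise ConfigurationError(f"image lacks channels {missing}")
    stack = np.stack([image.channels[r] for r in channel_order])
    tifffile.imwrite(path, stack, photometric="minisblack")


def convert_to_8bit(image: CalibratedImage) -> CalibratedImage:
    """Linearly rescale each channel from [0, channel max] to [0, 255].

    Rounding is half-up.  An 8-bit input is returned unchanged and an
    all-zero channel stays all-zero, so the conversion is idempotent.
    The per-channel-max convention preserves relative intensities after
    background subtraction has zeroed the background.
    """
    if image.bit_depth == 8:
        return image
    out = {}
    for role, ch in image.channels.items():
        mx = float(ch.max()) if ch.size else 0.0
        if mx == 0.0:
            out[role] = np.zeros_like(ch, dtype=np.uint8)
        else:
            out[role] = np.floor(ch.astype(np.float64) / mx * 255.0 + 0.5).astype(np.uint8)
    return CalibratedImage(out, 8, image.um_per_px, image.source_id)


def fisher_yates(items: list, rng: np.random.Generator) -> list:
    """Return a new list shuffled with the Fisher-Yates algorithm."""
    out = list(items)
    for i in range(len(out) - 1, 0, -1):
        j = int(rng.integers(0, i + 1))
        out[i], out[j] = out[j], out[i]
    return out


def randomize_order(ids: Sequence[str], seed: int) -> IsletManifest:
    """Produce a blinded, seed-determined processing order over ``ids``.

    The permutation is generated by a seeded Fisher-Yates shuffle so
    that the analyst encounters islets in an order uncorrelated with
    treatment group; the seed is recorded in the manifest.
    """
    ids = list(ids)
    if not ids:
        raise ValidationError("ids must be non-empty")
    if len(set(ids)) != len(ids):
        raise ValidationError("ids must be unique")
    order = fisher_yates(ids, np.random.default_rng(seed))
    entries = [
        ManifestEntry(anonymized_id=f"islet_{i:04d}", source_id=sid)
        for i, sid in enumerate(order)
    ]
    return IsletManifest(entries=entries, seed=int(seed))


def split_islets(image: CalibratedImage, crops: Sequence[CropSpec]) -> list[CalibratedImage]:
    """Duplicate and crop the image once per islet rectangle.

    Images containing several islets are duplicated before analysis so
    each islet can be assessed independently; every channel is cropped
    identically and the calibration is preserved.
    """
    out = []
    for crop in crops:
        channels = {role: crop.apply(ch) for role, ch in image.channels.items()}
        out.append(
            CalibratedImage(channels, image.bit_depth, image.um_per_px, image.source_id)
        )
    return out


# ---------------------------------------------------------------------------
# Plain-text manifests

MANIFEST_COLUMNS = [
    "anonymized_id",
    "source_id",
    "mouse_id",
    "group",
    "crop_x0",
    "crop_y0",
    "crop_w",
    "crop_h",
]
ROI_COLUMNS = ["anonymized_id", "role", "shape", "params"]


def write_manifest(manifest: IsletManifest, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["# seed", manifest.seed])
        w.writerow(MANIFEST_COLUMNS)
        for e in manifest.entries:
            crop = e.crop
            w.writerow(
                [
                    e.anonymized_id,
                    e.source_id,
                    e.mouse_id,
                    e.group,
                    *( [crop.x0, crop.y0, crop.width, crop.height] if crop else ["", "", "", ""] ),
                ]
            )


def read_manifest(path: str | Path) -> IsletManifest:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 2 or rows[0][0] != "# seed":
        raise ValidationError(f"{path} is not an islet manifest")
    seed = int(rows[0][1])
    entries = []
    for row in rows[2:]:
        if not row:
            continue
        aid, sid, mid, grp, x0, y0, w, h = row
        crop = CropSpec(int(x0), int(y0), int(w), int(h)) if x0 != "" else None
        entries.append(ManifestEntry(aid, sid, mouse_id=mid, group=grp, crop=crop))
    return IsletManifest(entries=entries, seed=seed)


def _roi_params_to_str(roi: RoiSpec) -> str:
    if roi.shape == "polygon":
        return ";".join(f"{x}:{y}" for x, y in roi.params)
    return ";".join(str(v) for v in roi.params)


def _roi_params_from_str(shape: str, s: str) -> tuple:
    if shape == "polygon":
        return tuple(tuple(float(v) for v in p.split(":")) for p in s.split(";"))
    vals = tuple(float(v) for v in s.split(";"))
    if shape == "rectangle":
        vals = tuple(int(v) for v in vals)
    return vals


def write_rois(rois: Sequence[RoiSpec], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(ROI_COLUMNS)
        for roi in rois:
            w.writerow([roi.islet_id, roi.role, roi.shape, _roi_params_to_str(roi)])


def read_rois(path: str | Path) -> list[RoiSpec]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            out.append(
                RoiSpec(
                    role=row["role"],
                    shape=row["shape"],
                    params=_roi_params_from_str(row["shape"], row["params"]),
                    islet_id=row["anonymized_id"],
                )
            )
    return out


def attach_rois(manifest: IsletManifest, rois: Sequence[RoiSpec]) -> None:
    """Attach ROI rows to their manifest entries by anonymized id."""
    by_id: dict[str, list[RoiSpec]] = {}
    for roi in rois:
        by_id.setdefault(roi.islet_id, []).append(roi)
    for e in manifest.entries:
        e.rois = by_id.get(e.anonymized_id, [])
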