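"""Synthetic multi-channel islet images with exact ground truth.

The generator emulates the geometry the analysis pipeline is built for:
a roughly elliptical islet with an insulin-positive beta-cell core and
a glucagon-positive alpha-cell rim encircling the perimeter, T-cell
infiltrate as lymphocyte-scale disks placed inside the islet
(insulitis) and/or in an annulus around it (peri-insulitis),
approximately Gaussian background intensity per channel, and optional
linear spectral bleed-through between channels (by default insulin into
CD4, mimicking Cy3 / AF594 overlap).  Disks rather than textured cells
keep the ground-truth areas exact, which is what the recovery tests
measure.

Background ROIs are emitted at a guaranteed signal-free image corner so
automated runs exercise the real ROI code path without a human choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage as ndi
from skimage.morphology import disk as disk_footprint

from .background import RoiSpec
from .errors import SimulationError, ValidationError
from .image_io import (
    CalibratedImage,
    CropSpec,
    IsletManifest,
    randomize_order,
    save_channels,
    write_manifest,
    write_rois,
)
from .masking import BinaryMask

#: Channel page order used for all simulated TIFFs.
CHANNELS = ("insulin", "glucagon", "cd4", "cd8")

#: Width of the peri-islet annulus (px) in which outside blobs land.
OUT_BAND = 40
#: Minimum clearance (px) between an outside blob and the islet edge.
OUT_MARGIN = 3
#: Side of the square background ROI placed at the image corner.
ROI_SIZE = 40


@dataclass(frozen=True)
class SynthParams:
    """Study conditions for one simulated islet.

    Semi-axes are in pixels; infiltration fractions are target T-cell
    areas as a fraction of the islet (ellipse) area per marker;
    intensities are on the 16-bit scale.  ``bleed`` maps
    ``(source, destination)`` role pairs to mixing coefficients (the
    diagonal is implicitly 1).
    """

    semi_axis_a: float = 90.0
    semi_axis_b: float = 80.0
    orientation_deg: float = 0.0
    rim_width: float = 6.0
    core_fill: float = 0.9
    hole_radius: float = 3.0
    cd4_in_frac: float = 0.0
    cd4_out_frac: float = 0.0
    cd8_in_frac: float = 0.0
    cd8_out_frac: float = 0.0
    cell_radius: float = 7.0
    bg_mu: float = 400.0
    bg_sigma: float = 75.0
    bleed: tuple = (("insulin", "cd4", 0.05),)
    foreground_intensity: tuple = (
        ("insulin", 1500.0),
        ("glucagon", 1500.0),
        ("cd4", 1500.0),
        ("cd8", 1500.0),
    )
    um_per_px: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.semi_axis_a > self.rim_width >= 0):
            raise ValidationError("semi-axes must exceed rim_width >= 0")
        if not (self.semi_axis_b > self.rim_width):
            raise ValidationError("semi-axes must exceed rim_width >= 0")
        for f in (self.cd4_in_frac, self.cd4_out_frac, self.cd8_in_frac, self.cd8_out_frac):
            if f < 0:
                raise ValidationError("infiltration fractions must be non-negative")
        if self.bg_sigma < 0:
            raise ValidationError("bg_sigma must be non-negative")
        if not (0 < self.core_fill <= 1):
            raise ValidationError("core_fill must lie in (0, 1]")

    @property
    def frame(self) -> int:
        reach = max(self.semi_axis_a, self.semi_axis_b) + OUT_BAND + self.cell_radius + 6
        return 2 * int(math.ceil(reach)) + 2 * (ROI_SIZE + 8)

    def noise_free(self) -> "SynthParams":
        """The same geometry with zero background noise and no bleed."""
        return replace(self, bg_mu=0.0, bg_sigma=0.0, bleed=())


@dataclass
class GroundTruth:
    """Simulator sidecar: true masks and areas for recovery tests."""

    islet_mask: BinaryMask
    insulin_mask: BinaryMask
    cd4_in: BinaryMask
    cd4_out: BinaryMask
    cd8_in: BinaryMask
    cd8_out: BinaryMask

    @property
    def areas_um2(self) -> dict[str, float]:
        t_in = self.cd4_in.with_grid(self.cd4_in.grid | self.cd8_in.grid)
        t_out = self.cd4_out.with_grid(self.cd4_out.grid | self.cd8_out.grid)
        return {
            "islet_area": self.islet_mask.area_um2,
            "insulin_area": self.insulin_mask.area_um2,
            "cd4_in": self.cd4_in.area_um2,
            "cd4_out": self.cd4_out.area_um2,
            "cd8_in": self.cd8_in.area_um2,
            "cd8_out": self.cd8_out.area_um2,
            "t_in": t_in.area_um2,
            "t_out": t_out.area_um2,
        }


def _ellipse_mask(frame: int, a: float, b: float, theta_deg: float) -> np.ndarray:
    cx = cy = frame / 2.0
    yy, xx = np.mgrid[0:frame, 0:frame]
    dx = xx + 0.5 - cx
    dy = yy + 0.5 - cy
    t = math.radians(theta_deg)
    u = dx * math.cos(t) + dy * math.sin(t)
    v = -dx * math.sin(t) + dy * math.cos(t)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _place_blobs(
    allowed: np.ndarray,
    target_px: float,
    radius: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stamp disks of ``radius`` at centres drawn uniformly from ``allowed``
    until the accumulated foreground area reaches ``target_px`` (within
    one blob).  Overlapping blobs are permitted; area counts the union."""
    frame = allowed.shape[0]
    out = np.zeros_like(allowed)
    if target_px <= 0:
        return out
    idx = np.flatnonzero(allowed)
    if idx.size == 0:
        raise SimulationError("no feasible blob positions for requested infiltration")
    r_int = int(math.ceil(radius))
    dy, dx = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    stamp = dy**2 + dx**2 <= radius**2
    attempts = 0
    while out.sum() < target_px:
        attempts += 1
        if attempts > 10_000:
            raise SimulationError("infeasible packing: target infiltration too high")
        k = int(idx[rng.integers(0, idx.size)])
        r, c = divmod(k, frame)
        out[r - r_int : r + r_int + 1, c - r_int : c + r_int + 1] |= stamp
    return out


def background_rois(p: SynthParams, islet_id: str = "") -> list[RoiSpec]:
    """Background ROIs at the signal-free top-left corner, one per channel."""
    return [
        RoiSpec(role=role, shape="rectangle", params=(4, 4, ROI_SIZE, ROI_SIZE), islet_id=islet_id)
        for role in CHANNELS
    ]


def simulate_islet(
    p: SynthParams, rng: np.random.Generator | None = None
) -> tuple[CalibratedImage, GroundTruth]:
    """Render one synthetic islet image and its exact ground truth.

    A fixed seed yields bitwise-identical output.
    """
    rng = rng if rng is not None else np.random.default_rng(p.seed)
    frame = p.frame
    a, b = p.semi_axis_a, p.semi_axis_b

    islet = _ellipse_mask(frame, a, b, p.orientation_deg)
    core = _ellipse_mask(frame, a - p.rim_width, b - p.rim_width, p.orientation_deg)
    rim = islet & ~core

    # Punch unstained-nuclei holes into the insulin core until roughly
    # (1 - core_fill) of it is background.
    insulin = core.copy()
    if p.core_fill < 1.0:
        core_px = int(core.sum())
        hole_area = math.pi * p.hole_radius**2
        n_holes = int(round((1.0 - p.core_fill) * core_px / hole_area))
        idx = np.flatnonzero(core)
        r_int = int(math.ceil(p.hole_radius))
        dy, dx = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
        stamp = dy**2 + dx**2 <= p.hole_radius**2
        # hole centres sit inside the core, which is far from the frame
        # edge by construction, so no boundary clipping is needed
        for k in rng.integers(0, idx.size, size=n_holes):
            r, c = divmod(int(idx[k]), frame)
            insulin[r - r_int : r + r_int + 1, c - r_int : c + r_int + 1] &= ~stamp

    islet_area_px = float(islet.sum())
    selem_in = disk_footprint(int(math.ceil(p.cell_radius)) + 1)
    allowed_in = ndi.binary_erosion(islet, structure=selem_in)
    selem_out = disk_footprint(int(math.ceil(p.cell_radius)) + OUT_MARGIN)
    cx = cy = frame / 2.0
    yy, xx = np.mgrid[0:frame, 0:frame]
    ring = (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2 <= (max(a, b) + OUT_BAND) ** 2
    allowed_out = ring & ~ndi.binary_dilation(islet, structure=selem_out)

    cd4_in = _place_blobs(allowed_in, p.cd4_in_frac * islet_area_px, p.cell_radius, rng)
    cd4_out = _place_blobs(allowed_out, p.cd4_out_frac * islet_area_px, p.cell_radius, rng)
    cd8_in = _place_blobs(allowed_in, p.cd8_in_frac * islet_area_px, p.cell_radius, rng)
    cd8_out = _place_blobs(allowed_out, p.cd8_out_frac * islet_area_px, p.cell_radius, rng)

    fg = dict(p.foreground_intensity)
    clean = {
        "insulin": insulin.astype(np.float64) * fg["insulin"],
        "glucagon": rim.astype(np.float64) * fg["glucagon"],
        "cd4": (cd4_in | cd4_out).astype(np.float64) * fg["cd4"],
        "cd8": (cd8_in | cd8_out).astype(np.float64) * fg["cd8"],
    }
    mixed = {role: clean[role].copy() for role in CHANNELS}
    for src, dst, coef in p.bleed:
        mixed[dst] += coef * clean[src]
    channels = {}
    for role in CHANNELS:
        ch = mixed[role]
        if p.bg_sigma > 0 or p.bg_mu > 0:
            ch = ch + rng.normal(p.bg_mu, p.bg_sigma, ch.shape)
        channels[role] = np.floor(np.clip(ch, 0, 65535) + 0.5).astype(np.uint16)

    image = CalibratedImage(channels, 16, p.um_per_px)
    scale = p.um_per_px

    def bm(grid, tag):
        return BinaryMask(grid, scale, tag)

    truth = GroundTruth(
        islet_mask=bm(islet, "islet"),
        insulin_mask=bm(insulin, "insulin"),
        cd4_in=bm(cd4_in, "cd4_in"),
        cd4_out=bm(cd4_out, "cd4_out"),
        cd8_in=bm(cd8_in, "cd8_in"),
        cd8_out=bm(cd8_out, "cd8_out"),
    )
    return image, truth


#: Per-preset parameter distributions (uniform ranges).  Young mice have
#: sparse, predominantly peri-islet infiltrate; adult non-diabetics the
#: heaviest mixed infiltrate; adult diabetics smaller islets with
#: depleted insulin cores; RAG knockouts no lymphocytes at all.
PRESETS = {
    "young": dict(
        a=(55, 80), b_ratio=(0.8, 1.0), core_fill=0.9,
        cd4_in=(0.0, 0.004), cd4_out=(0.01, 0.03),
        cd8_in=(0.0, 0.004), cd8_out=(0.005, 0.02),
    ),
    "adult_nondiabetic": dict(
        a=(60, 90), b_ratio=(0.8, 1.0), core_fill=0.85,
        cd4_in=(0.03, 0.08), cd4_out=(0.01, 0.04),
        cd8_in=(0.02, 0.06), cd8_out=(0.01, 0.03),
    ),
    "adult_diabetic": dict(
        a=(38, 58), b_ratio=(0.8, 1.0), core_fill=0.5,
        cd4_in=(0.02, 0.05), cd4_out=(0.01, 0.03),
        cd8_in=(0.01, 0.04), cd8_out=(0.005, 0.02),
    ),
    "rag_ko": dict(
        a=(55, 80), b_ratio=(0.8, 1.0), core_fill=0.9,
        cd4_in=(0.0, 0.0), cd4_out=(0.0, 0.0),
        cd8_in=(0.0, 0.0), cd8_out=(0.0, 0.0),
    ),
}


def draw_params(preset: str, rng: np.random.Generator, noise_free: bool = False, seed: int = 0) -> SynthParams:
    """Draw one islet's parameters from a preset's distributions."""
    if preset not in PRESETS:
        raise ValidationError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    d = PRESETS[preset]
    a = float(rng.uniform(*d["a"]))
    b = a * float(rng.uniform(*d["b_ratio"]))
    p = SynthParams(
        semi_axis_a=a,
        semi_axis_b=b,
        orientation_deg=float(rng.uniform(0, 180)),
        core_fill=d["core_fill"],
        cd4_in_frac=float(rng.uniform(*d["cd4_in"])),
        cd4_out_frac=float(rng.uniform(*d["cd4_out"])),
        cd8_in_frac=float(rng.uniform(*d["cd8_in"])),
        cd8_out_frac=float(rng.uniform(*d["cd8_out"])),
        seed=seed,
    )
    return p.noise_free() if noise_free else p


GROUND_TRUTH_COLUMNS = [
    "source_id", "mouse_id", "group",
    "islet_area", "insulin_area",
    "cd4_in", "cd4_out", "cd8_in", "cd8_out", "t_in", "t_out",
]


def simulate_cohort(
    preset: str,
    n_mice: int,
    islets_per_mouse: int,
    seed: int,
    out_dir: str | Path,
    noise_free: bool = False,
) -> IsletManifest:
    """Write a full synthetic dataset: TIFFs, manifests, ROIs, ground truth.

    The directory tree is a drop-in input for the analyzer: images/,
    manifest.csv (blinded order, seeded), rois.csv, ground_truth.csv and
    config.yaml.  The same seed reproduces identical trees.
    """
    if n_mice < 1 or islets_per_mouse < 1:
        raise ValidationError("n_mice and islets_per_mouse must be >= 1")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)

    rows = []
    rois = []
    infos = {}
    um_per_px = None
    for mi in range(n_mice):
        mouse_id = f"{preset}_m{mi}"
        for ii in range(islets_per_mouse):
            rng = np.random.default_rng([seed, mi, ii])
            p = draw_params(preset, rng, noise_free=noise_free)
            image, truth = simulate_islet(p, rng)
            um_per_px = p.um_per_px
            source_id = f"{mouse_id}_islet{ii}"
            save_channels(image, out_dir / "images" / f"{source_id}.tif", CHANNELS)
            areas = truth.areas_um2
            rows.append(
                dict(source_id=source_id, mouse_id=mouse_id, group=preset, **{
                    k: areas[k] for k in GROUND_TRUTH_COLUMNS[3:]
                })
            )
            infos[source_id] = (mouse_id, p)

    manifest = randomize_order([r["source_id"] for r in rows], seed)
    for e in manifest.entries:
        mouse_id, p = infos[e.source_id]
        e.mouse_id = mouse_id
        e.group = preset
        e.crop = CropSpec(0, 0, p.frame, p.frame)
        rois.extend(background_rois(p, islet_id=e.anonymized_id))

    write_manifest(manifest, out_dir / "manifest.csv")
    write_rois(rois, out_dir / "rois.csv")

    import pandas as pd

    pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS).to_csv(
        out_dir / "ground_truth.csv", index=False
    )
    config = {
        "channel_map": {role: i for i, role in enumerate(CHANNELS)},
        "um_per_px": um_per_px,
        "seed": seed,
        "preset": preset,
        "noise_free": noise_free,
        "n_mice": n_mice,
        "islets_per_mouse": islets_per_mouse,
    }
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return manifest
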