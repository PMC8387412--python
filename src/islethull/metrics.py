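"""Per-islet and per-mouse quantities derived from the masks.

Insulitis is T-cell signal inside the hull-defined islet border,
peri-insulitis is T-cell signal outside it.  The combined T signal is
the union of the CD4 and CD8 masks so overlapping pixels count once;
the pixel-set partition guarantees t_in + t_out = t_total exactly.

Measured T-cell area at or below the limit of detection (default
20 um**2) is attributed to spectral bleed-through rather than true
infiltrate and flagged, with the raw value preserved.  Undefined ratios
(zero denominators) are reported as missing values rather than zeros so
that "no insulin left" — real late-stage biology — is distinguishable
from a measured zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import MetricsError, ValidationError
from .masking import BinaryMask, combine, fill_enclaves


@dataclass(frozen=True)
class MetricsConfig:
    """Reporting thresholds: detection limit and insulitis break point."""

    lod_um2: float = 20.0
    insulitis_breakpoint: float = 0.5

    def __post_init__(self) -> None:
        if self.lod_um2 < 0:
            raise ValidationError("lod_um2 must be non-negative")
        if not (0 < self.insulitis_breakpoint < 1):
            raise ValidationError("insulitis_breakpoint must lie in (0, 1)")


@dataclass
class IsletMetrics:
    """One output row: areas (um**2), proportions and flags for an islet."""

    islet_id: str
    mouse_id: str
    group: str
    islet_area: float
    insulin_area: float
    cd4_in: float
    cd4_out: float
    cd8_in: float
    cd8_out: float
    t_in: float
    t_out: float
    t_total: float
    prop_insulin: float
    prop_t: float
    insulitis_fraction: float
    t_insulin_ratio: float
    below_lod_cd4: bool
    below_lod_cd8: bool
    below_lod_t: bool
    qual_score: int


def apply_lod(area_um2: float, cfg: MetricsConfig) -> tuple[float, bool]:
    """Flag an area at or below the limit of detection (inclusive).

    The raw value is always preserved alongside the flag.
    """
    if area_um2 < 0:
        raise ValidationError("area must be non-negative")
    return area_um2, area_um2 <= cfg.lod_um2


def beta_cell_area(insulin_mask: BinaryMask) -> float:
    """Beta-cell area (um**2): insulin mask with background enclaves filled.

    Insulin staining is cytoplasmic, so unstained nuclei punch holes in
    the raw mask that do not reflect lost beta-cell mass.
    """
    return fill_enclaves(insulin_mask).area_um2


def compute_islet_metrics(
    islet_mask: BinaryMask,
    insulin_mask: BinaryMask,
    cd4_mask: BinaryMask,
    cd8_mask: BinaryMask,
    cfg: MetricsConfig,
    islet_id: str = "",
    mouse_id: str = "",
    group: str = "",
) -> IsletMetrics:
    """Quantify T-cell infiltration relative to the islet border.

    Insulitis = area(T & islet); peri-insulitis = area(T) - area(T & islet),
    with T = CD4 | CD8.  Ratios with zero denominators are NaN.
    """
    for m in (insulin_mask, cd4_mask, cd8_mask):
        combine(islet_mask, m, "union")  # raises on dim/calibration mismatch
    if islet_mask.area_px == 0:
        raise MetricsError("islet-area mask is empty")
    scale = islet_mask.um_per_px**2

    t_mask = combine(cd4_mask, cd8_mask, "union")
    t_in_px = int((t_mask.grid & islet_mask.grid).sum())
    t_out_px = int((t_mask.grid & ~islet_mask.grid).sum())
    cd4_in_px = int((cd4_mask.grid & islet_mask.grid).sum())
    cd8_in_px = int((cd8_mask.grid & islet_mask.grid).sum())

    islet_area = islet_mask.area_um2
    insulin_area = beta_cell_area(insulin_mask)
    t_in = t_in_px * scale
    t_out = t_out_px * scale
    t_total = t_in + t_out
    cd4_total = cd4_mask.area_um2
    cd8_total = cd8_mask.area_um2

    prop_insulin = insulin_area / islet_area
    prop_t = t_in / islet_area
    insulitis_fraction = t_in / t_total if t_total > 0 else math.nan
    t_insulin_ratio = t_total / insulin_area if insulin_area > 0 else math.nan

    _, lod_cd4 = apply_lod(cd4_total, cfg)
    _, lod_cd8 = apply_lod(cd8_total, cfg)
    _, lod_t = apply_lod(t_total, cfg)

    m = IsletMetrics(
        islet_id=islet_id,
        mouse_id=mouse_id,
        group=group,
        islet_area=islet_area,
        insulin_area=insulin_area,
        cd4_in=cd4_in_px * scale,
        cd4_out=cd4_total - cd4_in_px * scale,
        cd8_in=cd8_in_px * scale,
        cd8_out=cd8_total - cd8_in_px * scale,
        t_in=t_in,
        t_out=t_out,
        t_total=t_total,
        prop_insulin=prop_insulin,
        prop_t=prop_t,
        insulitis_fraction=insulitis_fraction,
        t_insulin_ratio=t_insulin_ratio,
        below_lod_cd4=lod_cd4,
        below_lod_cd8=lod_cd8,
        below_lod_t=lod_t,
        qual_score=0,
    )
    m.qual_score = qualitative_score(m, cfg)
    return m


def qualitative_score(m: IsletMetrics, cfg: MetricsConfig) -> int:
    """Bin an islet onto the conventional 0-4 insulitis scoring scale.

    0 no insulitis; 1 peri-insulitis only; 2 under 25% of islet mass
    infiltrated; 3 from 25% to under 75%; 4 at least 75%.  The limit of
    detection, not strict zero, separates scores 0 and 1 so that
    bleed-through-level signal does not masquerade as infiltration.
    """
    if m.t_total <= cfg.lod_um2:
        return 0
    if m.t_in <= cfg.lod_um2:
        return 1
    if m.prop_t < 0.25:
        return 2
    if m.prop_t < 0.75:
        return 3
    return 4


def classify_dominance(m: IsletMetrics, cfg: MetricsConfig) -> str:
    """Label inflammation as insulitis- or peri-insulitis-dominant.

    More than the break point (default 50%) of total T signal inside
    the islet border means insulitis dominates.
    """
    if math.isnan(m.insulitis_fraction):
        return "undefined"
    if m.insulitis_fraction > cfg.insulitis_breakpoint:
        return "insulitis-dominant"
    return "peri-insulitis-dominant"


_MEDIAN_FIELDS = [
    "islet_area",
    "insulin_area",
    "t_in",
    "t_out",
    "t_total",
    "prop_insulin",
    "prop_t",
    "insulitis_fraction",
    "t_insulin_ratio",
]


@dataclass
class MouseSummary:
    """Per-mouse aggregate: summed islet area, count and metric medians."""

    mouse_id: str
    group: str
    total_islet_area: float
    islet_count: int
    medians: dict = field(default_factory=dict)


def aggregate_mouse(metrics: Sequence[IsletMetrics]) -> MouseSummary:
    """Sum islet areas and take per-metric medians for one mouse."""
    if not metrics:
        raise MetricsError("cannot aggregate an empty islet list")
    mouse_ids = {m.mouse_id for m in metrics}
    if len(mouse_ids) != 1:
        raise ValidationError(f"mixed mouse ids in aggregate: {sorted(mouse_ids)}")
    medians = {}
    for f in _MEDIAN_FIELDS:
        vals = np.array([getattr(m, f) for m in metrics], dtype=float)
        with np.errstate(all="ignore"):
            med = np.nanmedian(vals) if not np.all(np.isnan(vals)) else math.nan
        medians[f] = float(med)
    return MouseSummary(
        mouse_id=metrics[0].mouse_id,
        group=metrics[0].group,
        total_islet_area=float(sum(m.islet_area for m in metrics)),
        islet_count=len(metrics),
        medians=medians,
    )


REPORT_COLUMNS = [
    "islet_id",
    "mouse_id",
    "group",
    "islet_area",
    "insulin_area",
    "cd4_in",
    "cd4_out",
    "cd8_in",
    "cd8_out",
    "t_in",
    "t_out",
    "t_total",
    "prop_insulin",
    "prop_t",
    "insulitis_fraction",
    "t_insulin_ratio",
    "below_lod_cd4",
    "below_lod_cd8",
    "below_lod_t",
    "qual_score",
]


def metrics_frame(metrics: Sequence[IsletMetrics]) -> pd.DataFrame:
    return pd.DataFrame([asdict(m) for m in metrics], columns=REPORT_COLUMNS)


def write_report(metrics: Sequence[IsletMetrics], path: str | Path) -> None:
    """Write one CSV row per islet; undefined ratios serialize as empty cells."""
    metrics_frame(metrics).to_csv(path, index=False)


def read_report(path: str | Path) -> list[IsletMetrics]:
    df = pd.read_csv(path, dtype={"islet_id": str, "mouse_id": str, "group": str})
    out = []
    for _, row in df.iterrows():
        d = {c: row[c] for c in REPORT_COLUMNS}
        for c in ("islet_id", "mouse_id", "group"):
            d[c] = "" if pd.isna(d[c]) else str(d[c])
        for c in ("below_lod_cd4", "below_lod_cd8", "below_lod_t"):
            d[c] = bool(d[c])
        d["qual_score"] = int(d["qual_score"])
        out.append(IsletMetrics(**d))
    return out


def summarize_by_mouse(metrics: Sequence[IsletMetrics]) -> pd.DataFrame:
    """Aggregate a per-islet list into one summary row per mouse."""
    by_mouse: dict[str, list[IsletMetrics]] = {}
    for m in metrics:
        by_mouse.setdefault(m.mouse_id, []).append(m)
    rows = []
    for mouse_id in sorted(by_mouse):
        s = aggregate_mouse(by_mouse[mouse_id])
        row = {
            "mouse_id": s.mouse_id,
            "group": s.group,
            "total_islet_area": s.total_islet_area,
            "islet_count": s.islet_count,
        }
        row.update({f"median_{k}": v for k, v in s.medians.items()})
        rows.append(row)
    return pd.DataFrame(rows)
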