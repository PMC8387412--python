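"""End-to-end analysis: manifest in, per-islet metrics and overlays out.

Per islet the stages run in a fixed order: per-channel background
ROI statistics and subtraction on the native bit depth, crop to the
islet, conversion to 8 bit, thresholding, small-object removal on the
T-cell channels, hull-based islet-area construction, metric
computation, and the two validation overlays.  Failures on one islet
(e.g. endocrine masks vanishing during clean-up) are logged and the run
continues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .background import roi_stats, rois_by_role, subtract_background
from .errors import ConfigurationError, IsletHullError
from .image_io import (
    CalibratedImage,
    IsletManifest,
    ManifestEntry,
    attach_rois,
    convert_to_8bit,
    load_channels,
    read_manifest,
    read_rois,
    split_islets,
)
from .masking import MaskConfig, remove_small, threshold_mask
from .hull import islet_area_mask
from .metrics import IsletMetrics, MetricsConfig, compute_islet_metrics, write_report
from .overlays import OverlayStyle, render_validation_pair, save_overlay_pair

T_ROLES = ("cd4", "cd8")


@dataclass
class RunConfig:
    """Resolved analysis configuration; written next to every run's output."""

    channel_map: dict
    um_per_px: float
    mask: MaskConfig = field(default_factory=MaskConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    seed: int = 0
    overlay_alpha: float = 0.35

    def __post_init__(self) -> None:
        if not self.channel_map:
            raise ConfigurationError("channel_map is required")
        for role in ("insulin", "glucagon"):
            if role not in self.channel_map:
                raise ConfigurationError(f"channel_map must include {role!r}")
        if not self.um_per_px > 0:
            raise ConfigurationError("um_per_px must be positive")
        if not (0 < self.overlay_alpha <= 1):
            raise ConfigurationError("overlay_alpha must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        mask = MaskConfig(**raw.get("mask", {}))
        metrics = MetricsConfig(**raw.get("metrics", {}))
        return cls(
            channel_map={k: int(v) for k, v in raw["channel_map"].items()},
            um_per_px=float(raw["um_per_px"]),
            mask=mask,
            metrics=metrics,
            seed=int(raw.get("seed", 0)),
            overlay_alpha=float(raw.get("overlay_alpha", 0.35)),
        )

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "channel_map": dict(self.channel_map),
            "um_per_px": self.um_per_px,
            "mask": asdict(self.mask),
            "metrics": asdict(self.metrics),
            "seed": self.seed,
            "overlay_alpha": self.overlay_alpha,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def analyze_islet(
    image: CalibratedImage,
    entry: ManifestEntry,
    cfg: RunConfig,
) -> tuple[IsletMetrics | None, dict, "object | None"]:
    """Run the full per-islet analysis.

    Returns ``(metrics, log_record, overlay_pair)``; ``metrics`` and the
    overlays are ``None`` when the islet is skipped, with the reason in
    the log record.
    """
    record: dict = {"anonymized_id": entry.anonymized_id, "source_id": entry.source_id}
    try:
        rois = rois_by_role(entry.rois)
        corrected = {}
        for role, ch in image.channels.items():
            if role not in rois:
                raise ConfigurationError(f"no background ROI for channel {role!r}")
            stats = roi_stats(ch, rois[role])
            record[f"{role}_mu"] = stats.mu
            record[f"{role}_sigma"] = stats.sigma
            record[f"{role}_s"] = stats.s_value
            corrected[role] = subtract_background(ch, stats.s_value)
        corrected_img = CalibratedImage(
            corrected, image.bit_depth, image.um_per_px, image.source_id
        )
        if entry.crop is not None:
            corrected_img = split_islets(corrected_img, [entry.crop])[0]
        img8 = convert_to_8bit(corrected_img)

        masks = {
            role: threshold_mask(ch, cfg.mask, img8.um_per_px, role_tag=role)
            for role, ch in img8.channels.items()
        }
        for role in T_ROLES:
            if role in masks:
                masks[role] = remove_small(masks[role], cfg.mask.min_size)
        islet_mask, hull = islet_area_mask(masks["insulin"], masks["glucagon"], cfg.mask)
        record["hull_vertices"] = int(len(hull.vertices))

        empty = masks["insulin"].with_grid(np.zeros(islet_mask.grid.shape, dtype=bool))
        cd4 = masks.get("cd4", empty)
        cd8 = masks.get("cd8", empty)
        m = compute_islet_metrics(
            islet_mask,
            masks["insulin"],
            cd4,
            cd8,
            cfg.metrics,
            islet_id=entry.anonymized_id,
            mouse_id=entry.mouse_id,
            group=entry.group,
        )
        style = OverlayStyle(alpha=cfg.overlay_alpha)
        pair = render_validation_pair(img8, islet_mask, cd4, cd8, style)
        record["status"] = "ok"
        return m, record, pair
    except IsletHullError as exc:
        record["status"] = "skipped"
        record["reason"] = f"{type(exc).__name__}: {exc}"
        return None, record, None


def analyze_cohort(
    data_dir: str | Path,
    out_dir: str | Path,
    cfg: RunConfig,
    write_overlays: bool = True,
) -> pd.DataFrame:
    """Analyze every islet of a dataset directory in its blinded order.

    Expects ``images/``, ``manifest.csv`` and ``rois.csv`` under
    ``data_dir``; writes ``metrics.csv``, ``log.jsonl``, the resolved
    config and (optionally) overlay PNGs under ``out_dir``.
    """
    data_dir = Path(data_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(data_dir / "manifest.csv")
    attach_rois(manifest, read_rois(data_dir / "rois.csv"))

    results: list[IsletMetrics] = []
    records: list[dict] = []
    for entry in manifest.entries:
        path = data_dir / "images" / f"{entry.source_id}.tif"
        try:
            image = load_channels(path, cfg.channel_map, cfg.um_per_px, entry.source_id)
        except (OSError, IsletHullError) as exc:
            records.append(
                {
                    "anonymized_id": entry.anonymized_id,
                    "source_id": entry.source_id,
                    "status": "skipped",
                    "reason": f"unreadable image: {exc}",
                }
            )
            continue
        m, record, pair = analyze_islet(image, entry, cfg)
        records.append(record)
        if m is not None:
            results.append(m)
        if pair is not None and write_overlays:
            save_overlay_pair(pair, out_dir / "overlays", entry.anonymized_id)

    write_report(results, out_dir / "metrics.csv")
    with open(out_dir / "log.jsonl", "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    cfg.to_yaml(out_dir / "resolved_config.yaml")
    from .metrics import metrics_frame

    return metrics_frame(results)
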