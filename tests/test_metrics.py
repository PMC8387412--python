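"""Per-islet quantities, LOD flags, scoring and per-mouse aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from islethull.errors import DimensionError, MetricsError, ValidationError
from islethull.masking import BinaryMask
from islethull.metrics import (
    IsletMetrics,
    MetricsConfig,
    REPORT_COLUMNS,
    aggregate_mouse,
    apply_lod,
    beta_cell_area,
    classify_dominance,
    compute_islet_metrics,
    metrics_frame,
    qualitative_score,
    read_report,
    summarize_by_mouse,
    write_report,
)
from conftest import disk_grid, mask_of


def _metrics(**over) -> IsletMetrics:
    base = dict(
        islet_id="i0", mouse_id="m0", group="g", islet_area=400.0,
        insulin_area=100.0, cd4_in=0.0, cd4_out=0.0, cd8_in=0.0, cd8_out=0.0,
        t_in=0.0, t_out=0.0, t_total=0.0, prop_insulin=0.25, prop_t=0.0,
        insulitis_fraction=math.nan, t_insulin_ratio=0.0,
        below_lod_cd4=True, below_lod_cd8=True, below_lod_t=True, qual_score=0,
    )
    base.update(over)
    return IsletMetrics(**base)


def _hand_scenario():
    """Hand-countable masks on a 40x40 grid at 1 um/px.

    islet: 20x20 square (400 px).  insulin: 10x10 block inside with a 2x2
    nuclear hole (raw 96 px, filled 100 px).  cd4: 4x4 inside + 4x4
    outside (16 px each).  cd8: 4x4 inside overlapping cd4 by 2x4 = 8 px.
    T union: inside 16+16-8 = 24 px, outside 16 px.
    """
    islet = np.zeros((40, 40), bool)
    islet[10:30, 10:30] = True
    insulin = np.zeros((40, 40), bool)
    insulin[15:25, 15:25] = True
    insulin[18:20, 18:20] = False
    cd4 = np.zeros((40, 40), bool)
    cd4[12:16, 12:16] = True   # inside
    cd4[2:6, 2:6] = True       # outside
    cd8 = np.zeros((40, 40), bool)
    cd8[12:16, 14:18] = True   # inside, overlaps cd4 on cols 14:16
    return tuple(mask_of(g) for g in (islet, insulin, cd4, cd8))


class TestComputeIsletMetrics:
    def test_hand_computed_row(self):
        islet, insulin, cd4, cd8 = _hand_scenario()
        m = compute_islet_metrics(islet, insulin, cd4, cd8, MetricsConfig(),
                                  islet_id="i1", mouse_id="m1", group="adult")
        assert m.islet_area == pytest.approx(400.0)
        assert m.insulin_area == pytest.approx(100.0)  # hole filled back
        assert m.cd4_in == pytest.approx(16.0)
        assert m.cd4_out == pytest.approx(16.0)
        assert m.cd8_in == pytest.approx(16.0)
        assert m.cd8_out == pytest.approx(0.0)
        assert m.t_in == pytest.approx(24.0)
        assert m.t_out == pytest.approx(16.0)
        assert m.t_total == pytest.approx(40.0)
        assert m.prop_insulin == pytest.approx(0.25)
        assert m.prop_t == pytest.approx(24 / 400)
        assert m.insulitis_fraction == pytest.approx(24 / 40)
        assert m.t_insulin_ratio == pytest.approx(40 / 100)
        assert not m.below_lod_cd4          # 32 um**2 > 20
        assert m.below_lod_cd8              # 16 um**2 <= 20
        assert not m.below_lod_t
        assert m.qual_score == 2            # prop_t = 6% < 25%
        assert classify_dominance(m, MetricsConfig()) == "insulitis-dominant"

    def test_no_t_cells_gives_nan_fraction_and_score_zero(self):
        islet, insulin, _, _ = _hand_scenario()
        empty = mask_of(np.zeros((40, 40), bool))
        m = compute_islet_metrics(islet, insulin, empty, empty, MetricsConfig())
        assert m.t_total == 0.0
        assert math.isnan(m.insulitis_fraction)
        assert m.qual_score == 0
        assert classify_dominance(m, MetricsConfig()) == "undefined"

    def test_no_insulin_gives_nan_ratio_not_zero(self):
        islet, _, cd4, cd8 = _hand_scenario()
        empty = mask_of(np.zeros((40, 40), bool))
        m = compute_islet_metrics(islet, empty, cd4, cd8, MetricsConfig())
        assert m.insulin_area == 0.0
        assert math.isnan(m.t_insulin_ratio)

    def test_empty_islet_mask_rejected(self):
        empty = mask_of(np.zeros((40, 40), bool))
        with pytest.raises(MetricsError):
            compute_islet_metrics(empty, empty, empty, empty, MetricsConfig())

    def test_mismatched_grids_rejected(self):
        islet, insulin, cd4, cd8 = _hand_scenario()
        bad = mask_of(np.zeros((30, 30), bool))
        with pytest.raises(DimensionError):
            compute_islet_metrics(islet, insulin, bad, cd8, MetricsConfig())

    @given(st.integers(0, 2**32 - 1))
    def test_conservation_is_exact_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        um = float(rng.choice([0.25, 0.5, 1.0, 1.3]))
        islet = BinaryMask(rng.random((30, 30)) < 0.6, um)
        if islet.area_px == 0:
            return
        insulin = BinaryMask(rng.random((30, 30)) < 0.3, um)
        cd4 = BinaryMask(rng.random((30, 30)) < 0.2, um)
        cd8 = BinaryMask(rng.random((30, 30)) < 0.2, um)
        m = compute_islet_metrics(islet, insulin, cd4, cd8, MetricsConfig())
        # exact float identity, not approx: t_total is defined as the sum
        assert m.t_in + m.t_out == m.t_total
        union_px = int((cd4.grid | cd8.grid).sum())
        assert m.t_total == pytest.approx(union_px * um**2)


class TestLodAndScoring:
    def test_lod_boundary_is_inclusive(self):
        cfg = MetricsConfig()
        assert apply_lod(20.0, cfg) == (20.0, True)
        assert apply_lod(20.0001, cfg) == (20.0001, False)
        assert apply_lod(0.0, cfg) == (0.0, True)

    def test_negative_area_rejected(self):
        with pytest.raises(ValidationError):
            apply_lod(-1.0, MetricsConfig())

    @pytest.mark.parametrize(
        "t_total,t_in,prop_t,expected",
        [
            (0.0, 0.0, 0.0, 0),      # nothing detected
            (20.0, 20.0, 0.05, 0),   # at LOD still counts as nothing
            (30.0, 10.0, 0.025, 1),  # peri only: inside at/below LOD
            (30.0, 25.0, 0.0625, 2), # detectable inside, < 25% of islet
            (120.0, 100.0, 0.25, 3), # 25% boundary belongs to score 3
            (200.0, 180.0, 0.45, 3),
            (400.0, 300.0, 0.75, 4), # 75% boundary belongs to score 4
            (400.0, 390.0, 0.975, 4),
        ],
    )
    def test_score_bins(self, t_total, t_in, prop_t, expected):
        m = _metrics(t_total=t_total, t_in=t_in, prop_t=prop_t)
        assert qualitative_score(m, MetricsConfig()) == expected

    def test_dominance_breakpoint_is_strict(self):
        cfg = MetricsConfig()
        at = _metrics(insulitis_fraction=0.5)
        above = _metrics(insulitis_fraction=0.5000001)
        assert classify_dominance(at, cfg) == "peri-insulitis-dominant"
        assert classify_dominance(above, cfg) == "insulitis-dominant"

    def test_bad_config_rejected(self):
        with pytest.raises(ValidationError):
            MetricsConfig(lod_um2=-1)
        with pytest.raises(ValidationError):
            MetricsConfig(insulitis_breakpoint=1.0)


class TestBetaCellArea:
    def test_annulus_counts_as_full_disk(self):
        ring = disk_grid(10, 30) & ~disk_grid(6, 30)
        full = disk_grid(10, 30)
        assert beta_cell_area(mask_of(ring)) == float(full.sum())

    def test_solid_mask_unchanged(self):
        m = mask_of(disk_grid(8), um_per_px=0.5)
        assert beta_cell_area(m) == m.area_um2


class TestAggregation:
    def _mouse_rows(self):
        return [
            _metrics(islet_id="a", islet_area=100.0, t_total=10.0,
                     insulitis_fraction=0.2),
            _metrics(islet_id="b", islet_area=300.0, t_total=30.0,
                     insulitis_fraction=0.6),
            _metrics(islet_id="c", islet_area=200.0, t_total=50.0,
                     insulitis_fraction=math.nan),
        ]

    def test_medians_and_totals(self):
        s = aggregate_mouse(self._mouse_rows())
        assert s.islet_count == 3
        assert s.total_islet_area == pytest.approx(600.0)
        assert s.medians["islet_area"] == pytest.approx(200.0)
        assert s.medians["t_total"] == pytest.approx(30.0)
        # NaN entries are excluded from the median, not propagated
        assert s.medians["insulitis_fraction"] == pytest.approx(0.4)

    def test_all_nan_metric_stays_nan(self):
        rows = [_metrics(insulitis_fraction=math.nan) for _ in range(3)]
        s = aggregate_mouse(rows)
        assert math.isnan(s.medians["insulitis_fraction"])

    def test_mixed_mice_and_empty_rejected(self):
        rows = self._mouse_rows()
        rows[1].mouse_id = "other"
        with pytest.raises(ValidationError):
            aggregate_mouse(rows)
        with pytest.raises(MetricsError):
            aggregate_mouse([])

    def test_summarize_by_mouse_one_row_per_mouse(self):
        rows = [_metrics(islet_id=f"i{i}", mouse_id=f"m{i % 2}") for i in range(6)]
        df = summarize_by_mouse(rows)
        assert list(df["mouse_id"]) == ["m0", "m1"]
        assert list(df["islet_count"]) == [3, 3]
        assert "median_t_total" in df.columns


class TestReportFiles:
    def test_round_trip_preserves_values_and_flags(self, tmp_path):
        islet, insulin, cd4, cd8 = _hand_scenario()
        m = compute_islet_metrics(islet, insulin, cd4, cd8, MetricsConfig(),
                                  islet_id="i1", mouse_id="m1", group="adult")
        path = tmp_path / "metrics.csv"
        write_report([m], path)
        (back,) = read_report(path)
        for col in REPORT_COLUMNS:
            a, b = getattr(m, col), getattr(back, col)
            if isinstance(a, float):
                assert b == pytest.approx(a, nan_ok=True)
            else:
                assert a == b

    def test_nan_serializes_as_empty_cell(self, tmp_path):
        m = _metrics(insulitis_fraction=math.nan, t_insulin_ratio=math.nan)
        path = tmp_path / "metrics.csv"
        write_report([m], path)
        header, row = path.read_text().strip().split("\n")
        cells = dict(zip(header.split(","), row.split(",")))
        assert cells["insulitis_fraction"] == ""
        assert cells["t_insulin_ratio"] == ""
        (back,) = read_report(path)
        assert math.isnan(back.insulitis_fraction)

    def test_frame_column_order_is_stable(self):
        df = metrics_frame([_metrics()])
        assert list(df.columns) == REPORT_COLUMNS
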