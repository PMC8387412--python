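# Methods

This document specifies the exact computational model implemented by
`islethull`: every convention that affects a reported number, the
default parameters with units and rationale, the synthetic-data model
used for validation, and known limitations.

## 1. Image model

An islet observation is a set of co-registered single-channel grayscale
images (`CalibratedImage`) with a shared bit depth (8 or 16), a shared
pixel size `um_per_px` (µm per pixel edge), and channel *roles*:
`insulin`, `glucagon`, `cd4`, `cd8` and optionally `dapi`.  `insulin`
and `glucagon` are mandatory because they define the islet border; the
T-cell channels are optional and treated as empty when absent.

Areas are reported in µm²: `area_um2 = pixel_count * um_per_px**2`.

## 2. Background subtraction

For each channel, a user-supplied background ROI (rectangle, circle or
polygon; at least 25 px) is sampled on the **native bit depth**, before
any conversion.  With ROI mean `mu` and **population** standard
deviation `sigma` (`ddof = 0`), the subtraction value is

```
S = mu + 3 * sigma
```

Every pixel at or below `S` becomes 0; pixels above it become
`round_half_up(value - S)`, cast back to the input dtype.  For Gaussian
background the expected capture rate is Φ(3) ≈ 99.87%, which is the
rationale for the 3-sigma multiplier: essentially all background is
removed while bright, specific staining survives.

ROI pixel membership uses pixel centers: the pixel at row `r`,
column `c` has center `(c + 0.5, r + 0.5)`.

## 3. 8-bit conversion and thresholding

Each background-subtracted channel is linearly rescaled from
`[0, channel_max]` to `[0, 255]` with half-up rounding
(`floor(x * 255 / max + 0.5)`).  An all-zero channel stays zero and an
8-bit input is returned unchanged, so the conversion is idempotent.
Per-channel maxima (rather than a global maximum) preserve relative
intensities after the background has been zeroed.

Binary masks are produced by an inclusive threshold of `[10, 255]` on
the 8-bit data.  The lower bound of 10 rejects residual sub-background
ripple while keeping dim genuine staining; it is configurable
(`MaskConfig.thresh_lo/hi`).

## 4. Mask clean-up

- **Small-object removal** (`remove_small`): 8-connected components
  with pixel area `< pi * min_size**2` are dropped; `min_size`
  (default 5 px) is the minimum plausible lymphocyte radius at the
  default pixel size (5 px · 0.5 µm/px = 2.5 µm radius, i.e. a 5 µm
  cell).  In the pipeline this runs on the CD4/CD8 channels, where
  isolated supra-threshold noise pixels would otherwise count as
  infiltrate.
- **Enclave filling** (`fill_enclaves`): background regions not
  4-connected to the image border are filled.  Applied to the insulin
  mask when reporting beta-cell area, because insulin staining is
  cytoplasmic and unstained nuclei punch biologically meaningless
  holes.

## 5. Convex hull and islet area

Pixels are treated as unit squares.  The hull of a mask is the convex
hull of all four **corners** of every boundary pixel (interior pixels
are excluded first by erosion purely as an optimization; this does not
change the hull).  Vertices are stored counter-clockwise; collinear
vertices are dropped (cross-product tolerance 1e-9).  Area is the
shoelace formula; perimeter the vertex-to-vertex arc length.

Rasterizing a hull back to a mask (`fill_hull`) includes a pixel iff
its **center** lies inside or on the hull (half-plane cross products
`>= -1e-9`).

The islet-area mask is built in the fixed order:

```
union(insulin, glucagon) -> remove_small -> fill_enclaves
   -> convex hull -> fill_hull
```

raising `IsletNotFoundError` when nothing survives clean-up.

**Corner-hull / center-fill convention.**  Because the hull is taken
over pixel corners but rasterized through pixel centers, the filled
hull of an already convex pixel shape is a slight *superset* of it
(a sub-pixel boundary ring; ≈ +4% area for a radius-20 disk, ≈ +1.6%
for radius 80, vanishing as sizes grow; exactly zero for
axis-aligned rectangles).  The operation is therefore idempotent only
up to this rasterization tolerance, which at realistic islet sizes
(≥ 50 px radius) stays within ≈ 2% per application.  The alternative
(hull over centers) would instead *clip* true signal at the border; the
superset convention was chosen so the border never cuts through
stained pixels.

## 6. Validation geometry

For a shape with area `A_E` and perimeter `P_E`, and its hull with
`A_CH`, `P_CH`:

```
C_Area      = A_E  / A_CH      (<= 1, = 1 iff convex)
C_Perimeter = P_CH / P_E       (<= 1, = 1 iff convex)
```

For polygon outlines both are computed from exact polygon area and
perimeter, and equal 1 for convex polygons within 1e-9.  For rasterized
masks, `A_E` is the pixel count and `P_E` the iso-contour perimeter
(below), so values can exceed the analytic ratio by a small
rasterization epsilon (tested bound: 2%).

**Mask perimeter** is measured by marching-squares contour tracing at
iso-level 0.5 on the hole-filled mask (so it is an outer-boundary
perimeter).  Exact conventions: a 10×10 pixel square yields
`36 + 2*sqrt(2)` (corners are chamfered), a single pixel `2*sqrt(2)`.
This convention **overestimates smooth curves**: the traced perimeter
of a pixel disk exceeds `2*pi*r` by ≈ 5–7%, decreasing toward an
asymptote of ≈ 5.4% — consequently `C_Perimeter` of large disks tends
to ≈ 0.949, not 1.  Tests assert this behavior rather than pretending
convergence to 1.

**Interior angles** are computed per vertex of a simple polygon
(self-intersection is rejected), orientation-independent, with the
convex classification requiring every angle < 180°.  A regular pentagon
yields 108° everywhere.

## 7. Metrics

With `T = CD4 ∪ CD8` (union, so double-stained pixels count once) and
the islet mask `I`:

```
t_in    = area(T ∩ I)          # insulitis
t_out   = area(T) - t_in       # peri-insulitis
t_total = t_in + t_out         # exact float identity by construction
```

Further quantities per islet: filled insulin (beta-cell) area,
`prop_insulin = insulin_area / islet_area`,
`prop_t = t_in / islet_area`,
`insulitis_fraction = t_in / t_total`,
`t_insulin_ratio = t_total / insulin_area`.  Ratios with zero
denominators are **NaN** (empty CSV cells), never zero, so "no insulin
left" is distinguishable from "measured zero".

**Limit of detection (LOD).**  Measured T areas at or below
`lod_um2` (default 20 µm², inclusive) are flagged as below-LOD —
attributed to spectral bleed-through rather than infiltration — with
the raw value preserved.  20 µm² is a nuclear-scale cross-section
(π · 2.5² ≈ 19.6 µm²), whereas a single genuine lymphocyte at the
default pixel size measures ≈ 150 px · 0.25 µm²/px ≈ 37 µm² — so one
real cell still scores positive while sub-cellular speckle does not.

**Qualitative score** (0–4): 0 if `t_total <= LOD`; 1 if only
peri-insulitis (`t_in <= LOD`); otherwise 2, 3, 4 for
`prop_t` in `[0, 0.25)`, `[0.25, 0.75)`, `[0.75, ∞)`.

**Dominance**: insulitis-dominant iff
`insulitis_fraction > 0.5` (strictly), else peri-insulitis-dominant;
undefined when the fraction is NaN.

Per-mouse aggregation: islet count, summed islet area, and NaN-aware
medians of the per-islet metrics.

## 8. Blinded manifests

`randomize_order` shuffles source image IDs with a hand-rolled,
seed-reproducible Fisher–Yates shuffle and assigns opaque
`islet_NNNN` IDs; the analysis runs and reports in this order so the
analyst never sees group labels next to images.  The shuffle seed is
recorded in the manifest header.  Uniformity is tested by chi-square
over 48,000 shuffles.

## 9. Synthetic islet model

The generator exists to validate the pipeline against exact ground
truth, not to be photorealistic.  Geometry (per islet, pixels):

| parameter | default | meaning |
|---|---|---|
| `semi_axis_a`, `semi_axis_b` | 90, 80 | islet ellipse semi-axes |
| `orientation_deg` | 0 | ellipse rotation |
| `rim_width` | 6 | glucagon (alpha-cell) mantle thickness |
| `core_fill` | 0.9 | insulin-positive fraction of the core; holes of radius `hole_radius` = 3 are punched for the remainder |
| `cd4/cd8_in/out_frac` | 0 | target T area as a fraction of islet area |
| `cell_radius` | 7 | T cells are disks of this radius (≈ 7 µm cell at 0.5 µm/px) |
| `bg_mu`, `bg_sigma` | 400, 75 | Gaussian background (16-bit counts) |
| `foreground_intensity` | 1500 | stain intensity per channel |
| `bleed` | insulin→cd4 @ 0.05 | linear spectral mixing before noise |
| `um_per_px` | 0.5 | pixel size |

"Inside" T cells are placed with centers in the islet eroded by
`cell_radius + 1` (so they lie fully inside); "outside" cells in an
annulus 3 px clear of the islet out to 40 px beyond it.  Disks are
stamped until the union area reaches the target, so ground truth is
exact to within one cell footprint.  Infeasible packing requests raise
`SimulationError` rather than looping forever.

Intensity calibration: with `S ≈ 400 + 3·75 = 625` and bleed
`0.05 · 1500 = 75` counts, bleed-through sits inside the background
band and is removed by subtraction, while true signal
(1500 + background) survives — this is what makes the
zero-infiltration (RAG-KO analog) preset a genuine false-positive
control rather than a tautology.  These values were fixed before the
validation thresholds were frozen.

Each image carries four signal-free 40×40 corner ROIs (one per
channel) at `(4, 4)`, so automated runs exercise the real
ROI-statistics code path.

Cohort presets (`young`, `adult_nondiabetic`, `adult_diabetic`,
`rag_ko`) draw per-islet parameters from uniform ranges: young mice
have sparse, peri-islet-dominated infiltrate; adult non-diabetics the
heaviest mixed infiltrate; adult diabetics smaller islets with depleted
cores (`core_fill = 0.5`); RAG knockouts no lymphocytes at all.  Cohort
RNG streams are `default_rng([seed, mouse_index, islet_index])`, so
every islet is reproducible independently.  `simulate_cohort` writes a
complete analyzable tree: `images/*.tif` (multi-page 16-bit grayscale),
`manifest.csv` (blinded order), `rois.csv`, `ground_truth.csv`,
`config.yaml`.

Problem sizes used in the validation suite (3 mice × 10 islets per
cohort, 50 recovery seeds, 100-mask oracle sweeps) are this package's
own choice: large enough for stable statistics, small enough that the
entire suite runs in well under five minutes on a laptop.

## 10. Determinism

All randomness flows through `numpy.random.default_rng` with explicit
seeds; overlay blending is float64 with half-up rounding; CSV/JSON/YAML
writers sort keys or use fixed column orders.  Identical seeds and
configs reproduce bitwise-identical TIFFs, CSVs and PNGs (tested by
hashing two full simulate + analyze runs).

## 11. Limitations

- The islet border is a *convex* proxy; genuinely concave islets (e.g.
  horseshoe sections) are over-covered by construction, inflating
  islet area and converting some peri-insulitis into insulitis.  The
  convexity ratios exist precisely to quantify how non-convex a mask
  was before trusting its hull.
- Intensity-threshold masking has no illumination-gradient correction;
  the background model is a single global `S` per channel per islet.
- The mask perimeter convention overestimates smooth boundaries by up
  to ≈ 7% (section 6); perimeters and `C_Perimeter` values are
  comparable within this package but not across tools with different
  contour conventions.
- The simulator uses flat-intensity shapes and linear bleed; it
  validates geometry and bookkeeping, not segmentation robustness on
  textured tissue.
- Touching or overlapping islets are not separated; one manifest entry
  is assumed to contain one islet (crop accordingly).
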