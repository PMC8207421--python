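# Methods

## Model and assumptions

scrubmap treats scrub mapping as a deterministic raster pipeline over a
photogrammetric DSM/DTM pair in a projected, meter-unit CRS:

AGM(x) = max(0, DSM(x) − DTM(x))

on the DSM grid, followed by interval classification, connected-component
delineation and area accounting. The central assumptions are:

- **Height identifies scrub.** Woody shrub vegetation is the stuff between
  grassland and woodland, conventionally about 1–5 m tall. The method cannot
  distinguish scrub from other objects in that band (tall ruderal vegetation,
  low buildings, vehicles); those must be handled by ground-verified band
  bounds and exclusion polygons, which the API makes explicit.
- **The DSM/DTM pair is trustworthy.** Reconstruction artifacts appear as
  negative AGM values (DTM above DSM, typical at data edges); these clamp to
  0 by default and can be inspected with `clamp_negative=False`.
- **Areas are pixel-counting areas.** A stand's area is member-pixel count ×
  pixel area; polygons are exact pixel-edge traces so vector and raster
  areas agree to float precision, with no smoothing.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| height bands | ground [0,1), scrub [1,5), tall [5,∞) | m | conventional scrub height definition; presets `daneway` (scrub [1.5,5.75)) and `flatholm` (scrub [1,5)) reflect site-verified bounds, `subbands` splits scrub at 3 m into low/tall management classes |
| interval convention | lower-inclusive, upper-exclusive | — | guarantees a partition: every height in exactly one band, band areas + nodata = extent area |
| min_area_m2 | 0.5 | m² | minimum mapping unit; the test is **inclusive** (a 0.5 m² component survives) and applies to whole-component area after labeling |
| connectivity | 8 | — | diagonally touching canopies are one bush on the ground; 4 available |
| resampling | bilinear | — | elevation is continuous; nearest available for categorical uses |
| grid cell side | 50 | m | within-site assessment scale; configurable (any cell ≥ one pixel) |
| removal strategy | largest_first | — | meets a prescription with the fewest interventions; `smallest_first` preserves large habitat blocks. Whole stands only — no partial-stand removal |

## Numerical and geometric choices

- **Pixel-center membership** decides boundary clipping and grid-cell
  assignment: simple, deterministic, standard raster semantics; no
  partial-pixel weighting.
- **Conservative nodata in interpolation:** any stencil cell with nonzero
  weight that is nodata or outside the source extent makes the output pixel
  nodata, so alignment never fabricates heights at data edges. Alignment of
  a raster onto its own grid is exactly the identity for both methods.
- **Classification boundaries:** a value exactly at a band boundary belongs
  to the upper band (lower-inclusive). Values at or above a *bounded* final
  band's upper bound raise an error rather than being silently lumped —
  unexpectedly tall surfaces must be consciously handled with an unbounded
  final band or an exclusion polygon.
- **Deterministic component numbering:** components are renumbered in
  row-major order of their first cell, so stand ids are reproducible across
  runs and platforms.
- **Exact polygonization:** per-row pixel runs are unioned as
  integer-coordinate boxes in pixel space (an exact operation) and then
  affine-mapped to world coordinates; enclosed non-member cells become
  interior rings, and 8-connected components that touch only diagonally
  become MultiPolygons.
- **Removal-plan feasibility** is enforced in percentage space — the greedy
  loop stops on the same comparison the invariant is stated in
  (residual_cover_pct ≤ target_pct) — avoiding one-ulp edge cases from the
  area/percentage round trip. Ties in stand area break by id.
- **Percentages** are kept at full precision internally; rounding (2 d.p.)
  happens only in the human-readable report layer.
- **GeoTIFF support** is the subset photogrammetric exports use: single-band
  float32, north-up transforms, EPSG-coded CRS, GDAL nodata tag. Rotated
  transforms and unreferenced rasters are rejected. Geographic (degree) CRSs
  are a hard error for any area computation. Printed resolution metadata is
  never trusted; pixel size always comes from the file's transform.

## Synthetic scenes: what they emulate and what they do not

`generate_terrain` produces a band-limited random surface (spectrally
Gaussian-smoothed white noise, periodic boundary), centered and rescaled so
max |elevation − base| equals the relief amplitude exactly. `render_scene`
adds canopy objects by maximum (crowns shade, they do not stack) plus
additive Gaussian noise on the DSM only; the DTM stays clean so recovery
tests remain sharp against analytic truth.

Canopy objects are ellipsoidal caps — height h at the center falling to 0 at
the footprint ellipse with semi-axes (a, b) — or flat-topped rectangles for
buildings. The cap has closed-form areas: the full footprint is πab, and the
region at or above a threshold t is the concentric sub-ellipse of area
πab(1 − (t/h)²). A height-thresholding pipeline can only ever see that
sub-ellipse, so recovery is judged against the **detectable footprint**
(area above the scrub band's lower bound), with the full footprint also
recorded in truth tables. Overlapping same-class footprints are unioned in
truth, because touching crowns are indistinguishable to the pipeline.

`preset_reserve` is the standing test scene: 200 m × 200 m at 0.25 m ground
sample distance, undulating terrain (3 m relief, 30 m correlation length),
30 mutually disjoint scrub canopies (heights 1.5–4.5 m, semi-axes 1.2–3 m,
≥1.5 m apart), a block of three trees (6.5–10 m) and one 4 m flat-topped
building — deliberately inside the scrub height band, reproducing the
classic confusion case — with a boundary that excludes the tree block and
the building compound. DSM noise sd is 0.05 m, a plausible reconstruction
noise level for low-altitude UAV photogrammetry at this GSD.

What passing these tests shows: the arithmetic, labeling, polygonization and
planning layers are correct, and recovery is robust to discretization and
modest surface noise. What they do not show: performance on real
photogrammetric error fields (doming, vegetation-penetration failure of the
DTM, rolling-shutter artifacts), species confusion, or seasonal change —
real surveys still need ground verification of the band bounds.

Problem sizes in the default test run and acceptance script (an 800 × 800
scene per seed, 10 seeds; 200 random ≤30×30 labeling rasters; 100 random
removal problems with exhaustive enumeration up to 12 stands) were chosen so
the full check completes in seconds while still exercising every code path
at realistic pixel counts.

## Known limitations

- No reprojection: DSM, DTM and boundary must share one projected CRS.
- Geographic/projected CRS detection uses the GeoTIFF model-type key plus an
  EPSG range heuristic (4000–4999 = geographic), not a full CRS database.
- Single-epoch analysis only; no change detection between survey dates.
- No spectral information: the scrub band is purely height-based.
- The removal planner optimizes intervention count (largest-first) or block
  preservation (smallest-first) greedily; it does not do multi-objective
  optimization over other habitat constraints.
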