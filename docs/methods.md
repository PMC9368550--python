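# Methods

This note documents the models implemented in `ecocrit`, the choices made
where the underlying methodology leaves the design open, what the
synthetic-landscape generator does and does not emulate, and the numerical
conventions that matter for reproducing results.

## Criticality model

A cell's ecological critical index is the product `ECI = MESLI × LESSI`.

**MESLI.** Each ecosystem-service layer is min–max normalised over the
study-area cells of its own period (`(x − min)/(max − min)`) and the
normalised layers are summed, giving a range of `[0, n_services]`.
Normalisation is per period, not pooled across periods: the definition is
stated per observation set, and pooling would couple periods through their
extremes.  This is switchable in principle but is the package default.
Cells with missing data in any layer propagate NaN and are excluded from
the threshold histogram and the ECA mask.

**Landscape metrics and LESSI.** Patches are maximal connected same-class
cell sets (8-connectivity by default, the FRAGSTATS convention;
4-connectivity available).  Patch area is `cells × cell_size²`; patch
perimeter counts exposed cell edges *including* edges on the raster or
unit border, so a square patch filling its unit has shape index exactly 1.
Edge density, by contrast, counts only inter-class edges interior to the
unit: clipping patches at unit borders and discounting border edges keeps
each unit's score independent of its neighbours.  Class-level PD and ED
are summed over classes by default (ED therefore counts each inter-class
edge once per adjoining class; a mosaic variant counting each edge once is
available).  The reference area A for PD, ED and D is the unit's total
geometric area, including any nodata cells.

AWMSI, F and D use the standard raster formulas

```
AWMSI = Σ_j (0.25 p_j / √a_j)(a_j / Σa)
F     = Σ_j (2 ln(0.25 p_j) / ln a_j)(a_j / Σa)
D     = 1 − Σ_j (a_j / A)²
```

For a single 1-km² patch `ln a = 0`; this removable singularity is assigned
the minimum fractal dimension 1, and per-patch F is clipped to [1, 2] (the
admissible range for a plane curve) to guard degenerate sub-km geometries.

The raw metrics are not commensurable inside `LESSI = 1 − [(PD + ED) ×
2.5V]` — PD is km⁻², ED km·km⁻², and AWMSI/F/D are not in [0, 1] — so each
component is min–max rescaled across the units of one period before
entering `V = 0.5·AWMSI′ + 0.3·F′ + 0.2·D′`, and the bracket
`(PD′ + ED′) × 2.5V` is divided by its cross-unit maximum.  This guarantees
`LESSI ∈ [0, 1]` with 1 for the structurally most intact unit and 0 for the
most fragmented one, which is what a multiplicative index factor requires.
`2.5V` is read as the scalar product, not an exponent.  LESSI is computed
per county-style unit by default; a moving-window variant
(`lessi_moving_window`) is provided for cell-centred analysis.

## Threshold extraction

The ECA threshold is read off the ECI frequency distribution: a histogram
over `[min, max]` with equal-width bins, counts smoothed by a centred
moving average (window truncated and renormalised at the ends), and peaks
defined as strict local maxima of the smoothed curve with plateaus
collapsed to their centre bin.  T is the centre of the highest-ECI (last)
peak bin; `ECA = {ECI > T}` strictly.  If no interior maximum exists the
global maximum bin is used and a warning logged.  Defaults are 100 bins
and a 5-bin window for the operation itself; the pipeline preset uses 50
bins, the Scott-rule bin-width magnitude for the default scenario's ~65k
ECI values, fixed rather than data-driven so that bin edges — and hence
the threshold — are stable and comparable across periods.

## Evolution typing

Expansion is `¬ECA(t1) ∧ ECA(t2)`, degradation the converse, retained the
conjunction.  Buffers are rasterised as centre-distance disks: with 1-km
cells and the default 1-km radius each cell's buffer is its 4-neighbour
cross.  Two changed cells share a patch iff a chain of pairwise-overlapping
buffers connects them, implemented as 4-connected components of the
buffer-dilated mask restricted to changed cells (4-connectivity is exact
here: overlapping disks always share a cell, while disks touching only
diagonally do not).  Patches are mode-pure.

`LEI = 100·A0/(AE − AP)` with the buffer zone including the patch itself,
so the denominator is the buffer ring and LEI cannot exceed 100; an empty
ring yields LEI = 0.  For expansion patches the reference ECA is the
earlier mask ("original" ECA).  For degradation the mirror reading uses
the *retained* ECA (present at both dates): a lost patch surrounded by
surviving ECA disintegrated from within.  A switch to earlier-ECA
reference (minus the patch itself) is provided.  Type intervals are exactly
as printed: 0 → isolation/departed, (0, 50] → spread/atrophy, (50, 100] →
infilling/disintegration.

## Driver attribution

Training rows are analysis units × period pairs (the county scale at which
drivers are interpreted); a cell-level mode is deliberately out of scope of
the default.  The twelve predictors are unit means (DEM, slope,
temperature, GDP, population density, nightlight, and the two
distance-transform layers from impervious and cropland cells), the
precipitation total, and forest/grassland/cropland area shares.  Units
with fewer than five changed cells carry no meaningful dominant label and
are excluded per response; ties break toward degradation, then
lexicographically.

The classifier is a random forest of 500 Gini-impurity CART trees with
√m features per split, unlimited depth and a fixed seed; accuracy is the
out-of-bag percent correct (a stratified 70/30 holdout is switchable).
Percent contributions `P(r)` are the normalised mean-decrease-impurity
shares × 100 and sum to 100 exactly.  Grading uses geometric intervals:
class widths in geometric progression over `[min, max]`, with the
progression ratio searched over a symmetric grid (ratios and inverses) to
balance class counts; a fixed six-break reference preset
(0.5037 / 1.5381 / 3.7400 / 8.4272 / 18.4052 / 39.6460, upper bounds in
percent) is shipped for replication of published gradings.

## The synthetic generator

The generator's role is to produce inputs whose correct analysis is known
exactly, so each pipeline stage can be audited.  It emulates: a 7-class
land-cover mosaic grown from class seeds (nearest-seed assignment under a
smooth coordinate wobble) with deliberately heterogeneous seeding density
across units, giving the unit-level fragmentation gradient the LESSI
rescaling needs; four class-conditioned service surfaces plus smooth
Gaussian-field noise (correlation length 3 cells, sd 0.003 service units —
smooth surfaces, as interpolated service layers are); seven driver
surfaces with the expected physical couplings (slope from the DEM,
temperature anti-correlated with elevation via a lapse rate, a
precipitation gradient, and GDP/population/nightlight decaying away from
impervious cells); and a rectangular tiling of analysis units.

**Calibrated criticality strata.** Planted criticality is specified in ECI
units and back-solved to service values through each unit's LESSI (which
the generator computes with the same metrics code the pipeline uses).  The
resulting ECI distribution has four strata: background (class means ×
LESSI, ≤ ~1.1); a clearly sub-critical *margin* band on fringe rings 1–4
of critical areas (N(1.15, 0.03)); a near-critical *anchor* band on rings
5–13 (N(1.26, 0.05)) whose narrow mode forms the terminal histogram peak
and therefore pins the extracted threshold; and critical cells at
1.3 plus a right-skewed magnitude (truncated exponential, scale 0.9,
linearly tapered to zero at 1.0, so the tail is steep everywhere and
carries no spurious histogram peak).  Three calibration cells fix each
service layer's dynamic range and the top of the ECI range, making
normalisation exact and histogram bin edges identical across periods.
Bands are frozen at the initial critical geometry so a cell's stratum
changes only through a planted transition, never through a band
reassignment around a moved boundary.  Critical cover is hosted only in
units secure enough (LESSI ≥ (floor + tail)/0.97·n) for the compensation
to be feasible.

**Planted change.** Rules plant expansion or degradation per period pair
with exact geometry: *edge* sets are contiguous arcs on the critical
boundary (preferring cells with ≤ 2 critical neighbours), *isolated* sets
are compact blobs beyond the isolation distance (3 km) plus a clearance,
and *interior* sets are whole holes (expansion) or double-eroded cores
(degradation).  Small isolated "satellite" patches planted at generation
serve the departed type, and isolated patches carry no fringe bands so
their isolation is geometrically exact.  Each planted buffer-group's LEI
against the true masks is verified at generation and groups violating
their intended interval are dropped (planted-type fidelity); a rule whose
quota exceeds its candidate set fails loudly.  Host units are split into
expansion-prone and degradation-prone regimes, the planted driver
(precipitation by default) is shifted ±2 sd between regimes, and all
plantings respect the regime split so unit-level labels are constant
across period pairs — without this, county-level rows would mix labels
over static predictors and no classifier could separate them.

**What passing tests do and do not show.** The generator's distributional
geometry is deliberately favourable: strata are separated by several noise
standard deviations, the terminal peak is unambiguous, and planted changes
are geometrically clean.  Passing the recovery suites therefore shows the
pipeline's machinery is correct — the threshold rule finds the terminal
peak, masks, patches, LEI and types follow their definitions, and
attribution recovers a genuinely informative driver — not that real
landscapes, where strata overlap and thresholds are ambiguous, would be
recovered at these rates.  Real-data properties not emulated include
mixed-pixel service gradients, temporally varying noise, landcover change
coupled to service change, and spatial autocorrelation in the driver–
response relationship.

**Determinism.** All randomness derives from per-operation substreams
(`default_rng([seed, op])`) of one scenario seed: identical configurations
are bit-identical, and adding an operation never perturbs earlier draws.

## Problem sizes

Default scenario: 256 × 256 cells (1 km), 25 units, 4 periods, ~14 %
critical cover, ten change rules covering all six types.  The recovery
suites run 20 seeded scenarios end to end; threshold recovery uses 100
mixtures of 10⁵ samples; the attribution noise floor uses 20 replicates of
500 rows.  Oracle suites use 5×5–32×32 rasters where brute-force
enumeration is exact.

## Known limitations

* The LESSI rescaling is relative to the unit ensemble of one period:
  scores are comparable within a period, not across studies.
* Buffers are raster disks; vector-polygon buffering can differ at patch
  corners.
* The published accuracy-averaging convention for multi-response forest
  models is not replicated (the printed mean is not the arithmetic mean of
  the printed cells); accuracies are reported per response only.
* Multi-date (> 2 period) trajectory typing is out of scope; pairs are
  analysed independently.
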