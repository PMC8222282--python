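# Methods

This note documents the models, numerical choices, and limitations behind
`mvtip`. It is the package's own account of its procedures; every number
quoted here is computed by the test suite or the acceptance script.

## Segmentation model

The segmentation assumes a two-channel image of a roughly convex cell with
thin surface protrusions, sampled finely enough that a microvillus (MV) is
several pixels wide. The default pixel size is 12.5 nm — 50 nm acquisition
pixels divided by the 4× gel-expansion factor — and every physical
threshold is converted to pixels by nearest-integer rounding at that
pitch, so 300 nm ≙ 24 px. Structuring elements historically specified in
pixels (5 px disk closing, 10 px disk closing, 5 px square erosions, 3 px
square dilation, the ≥2000 px component filter) are interpreted as
physical sizes (62.5 nm, 125 nm, …, 312 500 nm²) and converted to
nearest-odd pixel widths, which reproduces the original element sizes
exactly at 12.5 nm/px while keeping the algorithm invariant to resampling.

Stages and their contracts:

1. **OutBG.** Per-channel masks at the first level of a 2-level multi-Otsu
   threshold are combined with an adaptive local-mean threshold of the
   channel sum; after hole filling, the largest 8-connected component is
   the cell and its complement is the outside background.
2. **InBG.** The inside-cell background (lumen/nucleus) must be a single
   connected low-signal region strictly inside the cell. A seed is taken
   from the largest dark interior component (dark = below the first
   2-level multi-Otsu level of the smoothed channel sum — plain Otsu
   fails when very bright tips dominate the histogram and would absorb
   the membrane into the "dark" class) after an opening that cuts thin
   dark corridors such as unstained MV interiors. The seed is grown with
   a morphological geodesic active contour (25 iterations, edge
   stopping), constrained to the dark region so it cannot cross the
   bright membrane, then dilated by 5 px with the dilation clipped at the
   membrane. If no interior seed exists (e.g. a solid bright disk), the
   fallback is an erosion of the cell mask by a 24 px disk, with a
   warning.
3. **SegBW.** Union of per-channel global-Otsu masks minus both
   backgrounds: the entire-cell analysis region.
4. **Tip detection.** SegBW is bridged (62.5 nm disk closing), small
   disconnected components are removed, and the cell-body mask is the
   SegBW overlap with the 300 nm dilation of InBG; the remainder is the
   MV mask. The MV mask is closed (125 nm disk), eroded (5 px square),
   and its convex hull eroded (5 px square); MV pixels outside the eroded
   hull form the tip mask, whose 8-connected components (after a 3 px
   bridge dilation) yield candidate tips as sub-pixel centroids.
5. **Length and filters.** MV length is the Euclidean distance from the
   tip to the nearest outer-edge pixel of InBG (Sobel magnitude > 0,
   outside the mask, no thinning). Tips of MV shorter than 50 nm or
   longer than 1.5 µm are discarded; of two surviving tips closer than
   50 nm, the shorter MV's tip is dropped (ties keep the lower index),
   iterated to a fixed point — the filter is idempotent.
6. **Zoning.** MV-tip area = MV pixels within 150 nm of an accepted tip;
   the next 75 nm band is excluded from the MV-column; the cell body
   likewise loses its 75 nm junction band. Zone labels partition the
   raster; sub-threshold pixels inside the cell carry the InBG label
   (inside-cell background semantics) while the raw masks are kept
   separately in `SegmentationMap.masks`.

**Validity regime of convex-hull tip detection.** A hull edge between two
detected tips at radius R dips below them by the sagitta
≈ R·(1 − cos(π/n_MV)). An MV whose tip lies deeper than that chord is
geometrically invisible to the hull. The method therefore requires the
spread of MV lengths to be smaller than the sagitta — on a 2 µm body with
20 MV the sagitta is ≈ 135 nm, so the default phantom draws lengths from
650–750 nm; a 200–800 nm spread is only resolvable on a much larger body
(the wide-range test uses a 12 µm body at 25 nm/px). Real MV length
distributions are broader, so on real cells the method reports the
hull-visible subset of tips; all downstream statistics are conditional on
the detected tips, exactly as in the original procedure.

## Colocalization statistics

RIS and SR′ are computed on raw intensities; intensity summaries use the
normalized channels (global-Otsu background subtraction, saturation at the
99th percentile of positive in-mask pixels, linear scaling to [0, 1]).
Channel means for the RIS normalization and the SR′ anchors are taken over
SegBW. Conventions for degenerate inputs: Pearson over a zero-variance
segment is 0; SR′ with a zero squared-deviation sum is 0 (its numerator is
then necessarily 0); RIS is NaN where X + Yₙ = 0; SR′ is clipped to
[−1, 1] against floating-point overshoot of the Cauchy–Schwarz bound;
medians of even-sized pixel sets are the mean of the central order
statistics (numpy convention). Distance profiles assign each SegBW pixel
its Euclidean distance to the nearest accepted tip (KD-tree over pixel
centers, sub-pixel tips) and bin from 0 in 12.5 nm steps; SR′ per bin is
evaluated against the whole SegBW pixel set.

## STORM pair correlation

Quality filters (precision 0–14 nm; z ± 400 nm; photons ≤ 20 000;
background ≤ 100; σ ∈ [0, 2.5] px; σx/σy ∈ [0.6, 1.5]) are independent
row predicates, so the retained set is order-independent; removals are
counted per criterion. The single photon and background numbers are
interpreted as upper bounds (a lone number alongside explicit ranges reads
most naturally as a cap); both are configurable. Registration renders each
channel as a count histogram at the 117 nm detector pixel,
cross-correlates by FFT, and refines the discrete peak with a bounded 2D
Gaussian fit on a 3 × 3 window (the correlation background of a point
pattern is a broad ramp; a wider fit window lets the ramp bias the center,
a 3 × 3 window keeps the error well under a quarter pixel). Tip
neighborhoods are 9 × 9 detector pixels = 1.053 µm squares; the analysis
volume for the target density is the exact union area of the (possibly
overlapping) squares times the 800 nm z extent of the z filter — the
reference volume is not otherwise defined, and this choice is isolated in
one parameter. g(r) uses shells [r, r + dr) with dr = 10 nm (the last
shell closes at r_max) so that a pair at exactly 50 nm is counted in the
shell whose left edge is 50 nm; no edge correction is applied, so g is
biased low for references within r_max of the window border — tests use
interior references.

## MIL

The membrane integration limit is the length of the longest contiguous run
of non-charged residues (charged = {K, R, E, D, H}) that overlaps the
annotated TM span; the charged residues bounding the run are the anchors,
residues of the run outside the TM span are the N-/C-side spacers, and the
predicted helix length is 1.5 Å per residue. When a charged residue lies
inside the TM span the run need only overlap (not contain) the span and
the record is flagged `charged_in_tm`; when a sequence terminus bounds the
run the record is flagged `unbounded` and the MIL is a lower bound, never
silently exact. TM coordinates are 1-based inclusive in all I/O. The
implementation is verified against an exhaustive charge-free-window oracle
on random sequences.

## Calcium traces

Each frame is binarized with a global Otsu threshold, holes are filled,
and the ROI is the largest 8-connected component; the trace is the mean
in-ROI intensity with I − I(0) deltas and an 11 s default frame interval.
The ROI is recomputed per frame with no tracking, so a cell leaving the
field, or a second cell growing past it in area, changes the ROI — a
deliberate match to the original per-frame procedure.

## Synthetic phantoms

The cell generator renders membrane-contour (line) density, not filled
area, mimicking surface labelling: a body circle plus n radial MV
(rectangles capped with half-disks, 100 nm wide), sampled as weighted arc
points, rasterized at pixel centers, blurred with a Gaussian PSF
(σ = 15 nm default, matching a 30–40 nm resolution), scaled by a photon
factor (40) and Poissonized. Channel A is multiplied by 6 within 50 nm of
each apex (tip enrichment) and by 2 on the MV contour (tip-resident
receptors are concentrated on MV generally); channel B is multiplied by
1 − 0.9 within 150 nm of each apex (CD45-like exclusion). One explicit
`numpy` Generator per call, seeded from the `seed` parameter; identical
parameters and seed give bit-identical outputs. MV angles are evenly
spaced with ±1.5° jitter — enough to break symmetry without creating
hull-invisible tips (see the validity regime above).

What the phantom does **not** emulate: cytosolic background staining,
gel-distortion or labelling stochasticity beyond Poisson noise, MV
curvature or branching, z-blur (planes are strictly 2D), and blinking
kinetics in the STORM tables. Passing tests therefore demonstrate the
correctness of the algorithms under the stated geometry and noise model,
not performance on real micrographs.

The STORM generator samples channel A uniformly on hemispherical tip caps
and channel B on cylindrical MV walls and the body circle with rejection
inside the 150 nm exclusion zone; surface label density is a free
parameter (no published value exists) with defaults of ~2×10⁻³ nm⁻²
chosen to give a few thousand molecules per cell. The correlation phantom
blends an independent uniform vector with the (complemented) first channel
so the endpoint mixes ±1 give exactly correlated/anticorrelated channels.
The calcium generator steps one blob's Poisson mean from baseline to
baseline + amplitude at a given frame beside a smaller distractor blob.

## Problem sizes

Default phantoms are single cells of ~440² px (2 µm body + 750 nm MV at
12.5 nm/px), segmented in ~2 s; the recovery and monotonicity checks use
5 seeds and a 5-point exclusion grid × 3 seeds respectively, and the g(r)
checks use ≤ 20 000 points — sizes chosen so the whole suite runs in a few
minutes on one CPU while keeping shot noise far below the tested effects.

## Known limitations

* The SR′ formula is reconstructed from its stated properties (cell-level
  identity with Pearson R′, −1 on the fully anticorrelated constant
  segment, sensitivity to RIS); it satisfies all of them and is isolated
  in one function (`mvtip.coloc.sr_prime`) so an authoritative variant
  could be swapped in.
* Tip recall degrades, by construction of the hull method, when MV length
  spread exceeds the hull sagitta; see the validity regime above.
* g(r) has no edge correction; values near the window border are biased.
* The active-contour InBG stage assumes a closed bright membrane; heavily
  fragmented membranes fall back to the eroded-cell mask.
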