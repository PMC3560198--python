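# Methods

## Analysis model

A muscle cross-section is modelled as a planar partition: a thin stained
membrane network (sarcolemma plus endomysial matrix) separating convex-ish
fibre cross-sections, with myonuclei either in a subsarcolemmal rim or
internal, and a brightfield double stain whose colour encodes the myosin
heavy chain isoform content of each fibre.

The pipeline is a fixed sequence of fully specified open operators:

1. **Membrane mask** — Gaussian smoothing (`gaussian_sigma_px`, default
   1 px), thresholding (Otsu by default; a fixed threshold in [0, 1] for
   calibrated acquisitions), morphological closing with a disc
   (`closing_radius_px`, default 2 px) to seal small staining gaps.
   Requesting Otsu on a constant image is an error, not a guess.
2. **Fibre extraction** — fibre interiors are the 4-connected components of
   the mask complement. Components with solidity below the QC minimum are
   interpreted as fibres merged through a staining gap and re-split by a
   distance-transform watershed; markers are distance maxima separated by at
   least √(min fibre area) in pixels, and equidistant pixels flood to the
   lower marker id so the result is deterministic. Labels are numbered in
   raster-scan order of each region's first pixel.
3. **Border exclusion** — any label touching the outermost row/column is
   removed (truncated cross-sections bias size statistics low). A
   user-supplied exclusion mask (a binary image covering folds, freezing
   artefacts, etc.) removes any fibre it intersects; this keeps the
   pipeline headless instead of requiring interactive region editing.
4. **Boundary reclaim** — each label is grown by `boundary_reclaim_px`
   (default 1.5 px) into unlabelled pixels by nearest-label expansion.
   Because the sarcolemma is shared between neighbours, the raw complement
   components stop half a membrane width short of the cell boundary;
   without this step the minimal Feret diameter is biased low by one
   membrane width (~1–2 µm at usual magnifications). Set the parameter to
   half the stained membrane width, or 0 to disable. Labels never overwrite
   each other, so the pixel partition survives.
5. **QC screen** — area within [`min_area_um2`, `max_area_um2`] (defaults
   50–10000 µm², bracketing physiological mouse fibres of roughly 10–80 µm
   diameter), solidity ≥ 0.7, ellipse aspect ratio ≤ 6. Each rejection
   reports its first failing criterion in the fixed order area → solidity →
   aspect, making the screen idempotent and auditable. The thresholds are
   deliberately user-facing configuration, as they must be tuned per
   species/muscle/stain.
6. **Nuclei** — threshold (Otsu/fixed), removal of objects below
   `min_nucleus_area_um2` (default 5 µm²), optional watershed splitting of
   touching nuclei. Each nucleus is assigned to the fibre with maximal
   pixel overlap (ties toward the smaller fibre id; no overlap → 
   unassigned, excluded from counts). Position is called from the Euclidean
   distance transform of the fibre region at the nucleus centroid:
   internal iff distance > `peripheral_band_um` (default 3 µm), equality
   counting as peripheral; a centroid just outside the region (possible
   for rim nuclei straddling the membrane) uses the nearest fibre pixel.
   A fibre is *internally nucleated* iff it has ≥ 1 internal nucleus — the
   outcome counts fibres, not nuclei. The band criterion is an explicit,
   calibration-aware substitute for the qualitative internal/subsarcolemmal
   distinction; the band value is recorded in the run metadata so it is
   always reportable.
7. **Typing** — optical density OD = −log₁₀ max(I, 10⁻⁶) per RGB channel;
   least-squares colour deconvolution with the two stain vectors plus their
   normalised cross product as residual channel (negative densities clipped
   to 0). Defaults: the published DAB absorbance vector (0.268, 0.570,
   0.776) for slow MHC and a measured blue-grey vector (0.735, 0.508,
   0.449) for the fast chromogen; both are config-overridable and should be
   re-estimated on single-stain control sections for a new staining
   protocol. A fibre's call uses the *median* density over its pixels
   (robust to nuclear counterstain speckle) against two OD thresholds
   (default 0.2/0.2): above both → hybrid, above one → that type, below
   both → unclassified. Thresholds live in OD units, so illumination must
   be white-balanced; low-level isoform co-expression below threshold is
   reported as the dominant type, not guessed.
8. **Morphometry** — Feret diameters are computed on the convex hull of
   the pixel *corner* points (each pixel contributes its four unit-square
   corners), so a one-pixel-wide structure has width 1 px rather than 0.
   The minimal width of a convex polygon is attained perpendicular to one
   of its edges, so the minimum over hull-edge normals is exact (rotating
   calipers); the maximal Feret diameter is the largest pairwise
   hull-vertex distance. Area is pixel count × (µm/px)². The variance
   coefficient uses the sample (n − 1) standard deviation — the common
   convention of morphometry software; with ~2000 fibres per section the
   choice is numerically irrelevant, but it is fixed and tested. The size
   histogram uses half-open 10-µm bins [low, high) over 0–100 µm with an
   overflow bin; percentages are relative to fibre count and sum to 100.

The whole analysis path contains no randomness: identical inputs give
byte-identical output tables.

### Section-level aggregation

Summaries are strictly per section (QC-passing fibres only). Group-level
aggregation across animals should average per-section summaries, never pool
fibres across animals; the comparison utilities operate on any such paired
or grouped series.

## Method-comparison statistics

Bland–Altman: differences are fixed as automated − manual, bias is their
mean, limits of agreement bias ± 1.96 × sample SD (the large-sample 95 %
bracket, matching the usual "approximately 95 %" usage rather than
t-based small-sample limits). The normality screen is the Lilliefors
variant of the one-sample Kolmogorov–Smirnov test (moments estimated from
the data, D evaluated on both sides of every ECDF step) with the
Dallal–Wilkinson (1986) p-value approximation — the same formula used by
R's `nortest::lillie.test`; the test suite cross-checks the statistic
against `statsmodels`. Group contrasts use the pooled-variance unpaired
Student's t-test.

## Synthetic sections

The generator's job is a field with *exact* ground truth, not
photorealism. Geometry: a Lloyd-relaxed (2 iterations) Voronoi
tessellation of uniformly random points, points mirrored across the field
edges so all cells are bounded; the point count is adjusted until exactly
`n_fibres` cells sit clear of the border (infeasible packings raise an
error). Each interior cell is shrunk about its centroid so its minimal
width draws from a lognormal law (default median 35 µm, σ(log) 0.30 at
0.5 µm/px — an adult-mouse-like distribution); shrink factors are capped
at 0.95 (and floored so interiors stay resolvable), which truncates the
upper tail of very large draws relative to the local cell size.

Channels: the membrane image paints each parent cell bright and carves out
the fibre interior (shrunk polygon eroded by the membrane half-width,
default width 3 px), so shared boundaries become ~membrane-width ridges
and the space freed by shrinking remains bright, like WGA-positive
endomysial/perimysial matrix; a configurable fraction of bright pixels is
deleted (staining-gap defects, default 5 %), then Gaussian blur (σ 0.7 px)
and clipped additive Gaussian noise (SD 0.05) are applied. Any enclosed
background pocket that is neither a planted interior nor connected to the
border is painted over during construction, so the ground truth is
consistent with the rendered image by construction. Nuclei are bright
ellipses (semi-axes ≈ 2.5 × 1.7 µm): internal nuclei are placed at pixels
deeper than twice the analysis band (plus 2 px) from the boundary,
peripheral nuclei within half a band of it — margins chosen so the band
classifier has no ambiguous cases; exactly round(n · pct_internal/100)
fibres receive an internal nucleus. The MHC channel renders per-type
optical densities (slow 0.8/0.05, fast 0.05/0.8, hybrid 0.5/0.5 along the
default stain vectors) through the Beer–Lambert forward model.

Cohort presets encode the qualitative disease contrast: control-like
sections (rare internal nuclei, 5 %; narrow sizes, σ 0.25, median 34 µm)
versus dystrophic-like sections (60 % internal; smaller median 26 µm with
wide spread σ 0.45). Cohort tests use 8 sections per group of 30 fibres
each (512² px), and the default recovery section 50 fibres (640² px) —
sizes chosen to exercise every stage while keeping a full suite run in a
few minutes on one core.

What the generator does *not* emulate — and hence what passing tests do
not demonstrate about real data: uneven illumination and staining
intensity gradients, folds and freezing artefacts, interstitial and
inflammatory nuclei outside fibres, necrotic/hypercontracted fibre
texture, chromogen co-localisation noise, and optically realistic point
spread. Thresholds that are auto-estimated here (Otsu) or defaulted (OD
thresholds, QC bounds, band width) require calibration on real control
sections.

## Numerical choices and degenerate inputs

- Collinear point sets get Feret width 0 and length = extent rather than a
  hull failure; empty regions, empty diameter lists, < 2 diameters for the
  VC, < 2 pairs for Bland–Altman, < 5 values for the KS test and < 2 per
  group for the t-test are errors, not NaNs.
- Equality cases are fixed: nucleus distance equal to the band →
  peripheral; histogram values on a bin edge → upper bin; a diameter at
  the histogram top → overflow bin; OD exactly at threshold → positive.
- Watershed tie-breaks, label numbering and nucleus-assignment ties are
  all deterministic (raster order / smaller id).
- Intensities are normalised to [0, 1] by dtype range on load; colour
  fluorescence exports collapse to grayscale by the per-pixel maximum
  channel, which preserves contrast of single-channel colour exports.

## Known limitations

- The internality criterion is a centroid-band rule; whole-nucleus
  containment or membrane-contact rules would classify borderline rim
  nuclei differently. The band default (3 µm) is a documented convention,
  not a measured constant.
- Typing accuracy depends entirely on stain-vector calibration; the
  defaults suit DAB plus a blue-grey chromogen under white-balanced
  illumination and are not universal.
- Optional translation registration handles integer-pixel stage drift
  only; rotational or non-rigid misregistration is out of scope.
- The nuclear counterstain double-check of nucleus identification used in
  manual workflows is not implemented; nuclei outside the fibre mask are
  counted as unassigned rather than classified as interstitial vs
  myonuclear.
- Fibrosis quantification and force measurements are outside this
  package's scope.
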