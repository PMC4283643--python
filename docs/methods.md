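# Methods

`cortexflat` implements a quantitative pipeline for mapping retrograde-tracer
connectivity on histological sections, exercised end-to-end on synthetic
NeuN-stained tissue with known ground truth. This note documents the models,
the defaults and why they were chosen, and what the synthetic benchmark does
and does not demonstrate.

## Pipeline model

A brain sectioned coronally at 50 µm is collected in three parallel staining
series; the NeuN series is every third cut section, and a flat map is built
for every other NeuN section, so exactly 1/6 of the cut sections are mapped
(`generate_brain` enforces divisibility by 6 so the fraction is exact). Each
mapped section passes through:

1. **Soma detection** (`segmentation`). The NeuN channel is smoothed
   (Gaussian, σ = 1 px), thresholded (Otsu by default, or an absolute
   value), split by a watershed on the Euclidean distance transform, and
   filtered by minimum area. Per label we record the intensity-weighted
   centroid (pixel-centre convention, 0-based, x right / y down) and, per
   channel, the integrated intensity (sum of pixel values within the
   segmented boundary), maximum and minimum pixel. The detector is a
   deliberately simple, fully specified stand-in for a general-purpose
   segmentation tool: it is a black box to the rest of the pipeline and can
   be swapped without touching downstream stages.
2. **Tracer classification** (`tracer`). A soma is tracer positive iff its
   tracer-channel integrated intensity strictly exceeds 250,000 **and** its
   maximum pixel strictly exceeds 150 on the 8-bit scale. Boundary equality
   is negative; both thresholds are configurable.
3. **Flat-map projection** (`flatmap`). A reference polyline through the
   layer IV/V boundary is resampled to uniform 1-px arc spacing and smoothed
   with a moving-window line regression (window 5 px = 1.15 µm at
   0.23 µm/px, step 1 px); each output vertex is the centre-point evaluation
   of a least-squares line over its window, with one-sided shrunken windows
   at the ends. Every positive soma is projected orthogonally onto the
   nearest polyline segment (clamped at the ends, ties broken toward the
   smaller arc position) and reported as a signed arc length from the
   cingulum-border anchor (negative medial, positive lateral toward the
   rhinal sulcus), in µm. Rows of the flat map are keyed by
   anterior–posterior position rather than section index so lost sections do
   not distort the map.
4. **ROI counting** (`roi`). Positive cells are assigned to hand-drawn
   (here generated) region polygons; boundary points count as inside, and
   overlapping polygons resolve deterministically in name-sorted order with
   a logged warning. Cells flagged contralateral are excluded. The ROI(s)
   containing the injection centre — one, or two when the deposit straddles
   a border — are zeroed on every section, then counts are normalised to
   proportions of the total over included ROIs. Proportions aggregate into
   cortical networks (medial, lateral, somatic, claustrum/entorhinal) or
   seven thalamic groups (motor, sensory, anterior/lateral/mediodorsal
   associative, intralaminar, midline); both maps ship as overridable
   defaults because published group memberships are not exhaustive.
   Thalamic counts may enter from a manual-counts CSV, since thalamic somata
   resist automated segmentation.
5. **Count calibration** (`tracer`). Automated counts systematically
   undercount. Per animal, manual counts (on a subset of sections) are
   regressed on automated counts by OLS; the x-intercept −b/a is where the
   line predicts zero manual cells, and `max(0, −x_intercept)` is added to
   every included ROI's automated count. The regression orientation (manual
   as response) is the only one in which a negative x-intercept implies an
   additive correction; a non-positive slope marks the model unusable, and a
   manual-counts-only path covers animals whose labelling is too dim for
   automated counting. Adjustment precedes injection zeroing.
6. **Statistics** (`stats`). Regional proportion profiles are compared with
   a one-way within-subject ANOVA (region as repeated factor) or a
   split-plot ANOVA with injection-placement group (medial/lateral or
   rostral/caudal) as the between factor. Sums of squares follow the
   classical weighted cell-means decomposition; with unequal group sizes the
   interaction df is (k−1)(g−1) over (N−g)(k−1) — e.g. (20, 140) for 21
   regions × 9 animals in two groups. No sphericity correction is applied by
   default (Greenhouse–Geisser sits behind a flag) and α = 0.05. Post-hoc
   paired t-tests use Bonferroni adjustment with an explicitly supplied
   family size, because comparison families differ per analysis. The
   decomposition is verified in the test suite against an independent
   loop-based oracle and against `pingouin` to 1e−9, for balanced and
   unbalanced designs.

## Synthetic data: what it emulates

`synth.generate_section` builds a curved cortical ribbon (a spline through
control points), partitions it into named ROI bands by arc-length
breakpoints, and plants somata at rejection-sampled positions (1000 retries
per cell, minimum pairwise separation, bounded and deterministic under a
seeded generator). Cells are isotropic radial Gaussians clipped at the cell
radius, additive with saturation at 255; channels are ordered (NeuN,
tracer-red, tracer-yellow), with Fluoro-Gold written into a dedicated third
channel rather than split across red+green, to avoid cross-channel
ambiguity. Background noise is zero-mean Gaussian clipped at 0.

Key defaults and their rationale (all in `SynthParams`):

- **pixel_size = 0.23 µm/px** — the 40× whole-slide acquisition scale; it
  makes the smoothing-window equivalences exact (5 px = 1.15 µm).
- **cell radius 45–54 px** (soma ≈ 10–12 µm radius at this scale). The
  integrated-intensity threshold of 250,000 is fixed in 8-bit units, so a
  positive soma needs ≥ ~1,000 px of footprint even at full saturation;
  realistic soma sizes at 40× satisfy this comfortably.
- **NeuN profile σ = r/1.8, tracer profile σ = r/3.** The segmentation
  footprint is NeuN-driven; making the NeuN profile wider than the tracer
  profile ensures the segmented boundary captures essentially all tracer
  mass, as a filled soma does.
- **tracer peak 215–250 (positives) / 20–60 (negatives)** — planted
  integrated intensities ≳ 300,000 for positives and ≲ 160,000 (including
  background) for negatives, i.e. ≥ 10% clearance on both sides of both
  thresholds, so classifier fidelity is a property of the rule rather than
  luck.
- **min_separation 120 px > 2 × max radius**, so somata never touch and
  detection counts are tiling-invariant.
- **80 cells/section, 60 tracer positive.** With threshold-consistent soma
  sizes, packing at the required separation bounds the per-section count;
  whole-brain analyses reach ≥ 500 positive cells by mapping 10 sections
  (60 cut sections). The ap-position grid is 0.05 mm per cut section.
- The injection site is rendered as an over-exposed deposit in the tracer
  channel at the centre of one ROI on the middle mapped section, mirroring
  how fluorescent deposits look; its ROI is zeroed during quantification.

Ground truth records each cell's centre, per-channel painted integrated
intensity (the analog sum over the painted footprint, verified against a
brute-force pixel loop), ROI membership and arc position, so every
downstream stage has an oracle.

**What the generator does not emulate:** staining artifacts, tissue tearing,
section-to-section deformation, anisotropic or overlapping somata, tracer
bleed-through, and realistic background texture. Passing the benchmark
therefore shows the pipeline's bookkeeping and numerics are correct under
its stated assumptions — not that the simple detector would match a
production segmentation tool on real tissue.

## Numerical choices and degenerate inputs

- Strict (">") threshold comparisons throughout the classifier.
- Projection beyond the line ends clamps rather than extrapolates; the
  degenerate zero-length line is an error.
- Nearest-point ties break toward the smaller arc position (first minimum).
- Smoothing windows exceeding the vertex count are clamped with a warning;
  window = 1 is the identity.
- Tile-overlap duplicates keep the detection farthest from its own tile
  border (the complete soma, not the cut fragment); the dedup radius should
  be of order the soma radius and below half the minimum separation.
- An all-saturated section yields one warned, unreliable region; an
  all-zero count vector is an explicit error, never NaN proportions.
- Higher-depth rasters are rescaled to 8-bit with a logged factor.
- Injection centres exactly on the medial/lateral boundary classify as
  medial; exactly on the rostral/caudal boundary as rostral (logged ties).
- Missing design cells are rejected, not imputed.

## Problem sizes

The shipped benchmark sizes are chosen to keep a full run on one CPU within
minutes: the end-to-end recovery uses a 60-cut-section brain (10 mapped
sections of 4000 × 2600 px, 600 planted positives, ~2–3 min); calibration
recovery uses 100 seeds × 3 offsets at 50 ROI pairs; the Monte-Carlo type-I
check uses 2000 null replicates of an 8-subject × 5-level design. The
calibration fixture's true counts span sparse (10–30) and dense (250–400)
ROIs, reflecting the order-of-magnitude spread of real regional counts,
which is what makes the x-intercept identifiable to ±0.5 at n = 50.

## Known limitations

- The split-plot decomposition uses weighted (cell-size) sums of squares;
  strongly unbalanced designs with real group effects would be better served
  by a mixed model, which is out of scope.
- The detector assumes bright, convex, non-touching somata; its Otsu default
  misbehaves on sparse dim sections (use an absolute threshold there).
- Proportions treat ROIs as a closed set: adding or removing an ROI from
  the inclusion list changes every proportion.
- The calibration offset is additive and per animal; it does not model
  count-dependent undercounting.
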