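# Methods

`grapemap` reimplements an image-to-genetics analysis chain for grapevine
cluster architecture: instance-segmentation berry masks are filtered and
measured, cluster-level digital traits are aggregated into genotype values
by mixed models, and those values are scanned for quantitative trait loci
in an F1 pseudo-testcross.  Because the original study's field images and
genotyping-by-sequencing data are not reproducible at a desk, the package
ships a synthetic-data module that emulates both data types with exact
ground truth; every downstream stage is validated against that truth.

## Synthetic clusters

A cluster is a set of elliptical berries packed inside an elliptical
envelope.  Berries attach in clumps (shoulders) whose centres follow a
jittered sunflower-spiral layout filling the envelope — this reproduces two
properties of real 2D cluster projections simultaneously: *local* overlap
between neighbouring berries (which drives occlusion) and *global*
looseness (sums of berry areas are much smaller than the hull, giving
compactness indices near the 0.15–0.25 range typical of wine grapes).
Berry outlines carry a smooth low-order radial irregularity
(`boundary_noise`, default 3% of the radius) because segmented berries are
not perfect ellipses; this also gives the shape-screen population a genuine
spread.

Key defaults (all configurable in `ClusterSimConfig`): 46 berries of mean
radius 8.4 mm (projected area ≈ 222 mm²), envelope semi-axes 110 × 220 mm,
packing tightness 0.65, three rachis-like artifacts, 0.25 mm/px.  Under
these settings the realized compactness averages ≈ 0.17 ± 0.01 and ~2–3% of
berries per view are missed through occlusion; raising `packing_tightness`
to 0.9 produces the ≈ 15–20% undercount regime used to exercise the count
correction.

Each camera angle is rendered by the painter's algorithm with its own
random depth order: a berry's visible mask is its ellipse minus all nearer
berries, and berries whose visible fraction falls below
`visible_min_fraction` (default 0.30) are treated as missed by the
segmenter.  Ground truth — berry count, union projected area, compactness =
union area / convex-hull area — comes from the un-occluded geometry.  The
two angles share one 2D geometry and differ only in depth order; no 3D
geometry is modelled, so view-to-view variation in berry *size* traits is
smaller than in real stereo pairs.

What passing tests on this generator do **not** show: robustness to
photometric effects (shadows, specularity), to segmentation masks that
merge two berries, or to rachis geometries more complex than elongated
capsules.

## Mask post-processing

Candidate masks pass four stages.  (1) ROI: masks are grouped into
connected components using a bounding-box gap of 12 median equivalent
diameters; the largest-area component defines the ROI.  (2) Geometric
rules, in fixed order (area low/high, perimeter low/high, aspect ratio):
area and perimeter bounds are relative to the per-image median candidate
([0.2, 3.0]×), aspect-ratio cap 2.5 — berries are near-circular, rachis
fragments elongated.  (3) IoU deduplication, greedy in descending area with
ties broken by mask id, threshold 0.4.  (4) A shape screen: normalized
elliptical Fourier descriptors (10 harmonics, 128 arc-length-resampled
boundary points), PCA keeping 90% of variance, and a chi-square(k) cutoff
at the 0.99 quantile on squared Mahalanobis distance in the kept subspace.

One numerical subtlety matters for the screen.  EFD normalization anchors
rotation and start point to the first harmonic; for near-circular shapes
that anchor is almost degenerate and the normalized coefficients carry an
arbitrary residual phase, which destroys the chi-square calibration of
Mahalanobis distances (observed false-flag rates of 5–8% at a nominal 1%).
The screen therefore runs PCA on phase-invariant features — the singular
values of each harmonic's 2×2 coefficient matrix plus its signed
determinant — which preserve the harmonic energy profile that separates
artifacts while being immune to the phase ambiguity.  With this feature
map, false-flag rates sit at ≈ 1% and rachis-like slivers land far beyond
the cutoff.

The EFD implementation itself resolves the joint half-turn ambiguity of
start point and orientation (which flips the sign of every even harmonic)
by forcing the dominant even-harmonic coefficient positive, making
descriptors reproducible to 1e-6 under arbitrary rotation, scaling and
start-point shifts.

## Morphometrics

Berry length/width are the major/minor axes of the second-moment
(equivalent) ellipse computed from exact polygon moments — rotation
invariant, and identical to `skimage.regionprops` definitions on rasters.
Compactness is the sum of mask areas over the convex hull of all mask
boundary points (vertex hull, not raster); cluster aspect ratio is the hull
extent along the first principal axis over the orthogonal extent (≥ 1).
The occlusion correction is an ordinary least-squares line `true =
intercept + slope × observed` fitted on calibration clusters, with the
observed regressor being the maximum count over the two angles; the raw
prediction is reported unclamped.  Views are averaged with equal weight (no
view-quality metadata exists to do better).

## Mixed models and heritability

Digital traits are first averaged over the imaged clusters per genotype ×
block (× year).  Single-season model: block fixed, genotype random.
Multi-season: year and block-within-year fixed; genotype and
genotype-by-year random.  Variance components are estimated by REML,
optimizing the restricted likelihood over log-variances (L-BFGS-B with a
Nelder-Mead polish; a component collapsing to zero is clamped at 1e-12 and
reported as a boundary case, not an error).  All solves use the Woodbury
identity in the random-effect dimension, so a 138 × 3 × 2 fit costs
milliseconds per likelihood evaluation.  The fixed design is reduced to a
full-rank basis by pivoted QR, which is what makes the nested
block-within-year coding well-posed.  Balanced-design estimates agree with
the closed-form ANOVA estimators to < 1e-6 (a standing test), and
single-year fits match `statsmodels` MixedLM; a spot check against lme4
agreed to four decimals.

Broad-sense heritability is reported as H² = V_g / (V_g + V_e) — the plain
ratio of the printed components.  Note this is *entry-mean* heritability
only when V_e is already the variance of genotype-mean deviations at the
design's replicate number; it is reported as the formula states, without
silently rescaling by replicate count.  BLUPs are centered genotype
deviations; a "general mean + BLUP" presentation is available.

## QTL mapping

Markers are backcross-coded per parental map (0/1/missing).  QC drops
markers with minor allele frequency ≤ 0.1 or > 10% missing calls, then
individuals with > 10% missing; markers at identical cM positions collapse
to bins whose representative call is the per-individual consensus (which
also imputes missing calls where co-binned markers are unanimous;
conflicting bins fall back to majority and are flagged).

Genotype probabilities on a 1-cM grid condition on the nearest informative
flanking markers through the two-state Markov chain with Haldane
recombination fractions (Kosambi available); missing genotypes are handled
here, never by dropping individuals.  The scan regresses the phenotype on
P(genotype = 1) at each position and reports LOD = (n/2)·log10(RSS₀/RSS₁);
at fully typed markers this equals marker regression exactly (standing test
vs an OLS oracle at 1e-8).  Genome-wide thresholds shuffle the phenotype
vector (seeded), take each permutation's genome-wide maximum LOD, and
return the 95th percentile with numpy's default (type-7) quantile rule;
permutations are evaluated as one matrix product per grid position, so
1,000 permutations cost well under a second at n = 138.

Multi-QTL search is forward selection on penalized LOD (pLOD = model LOD −
penalty × n_QTL, penalty defaulting to the single-scan permutation
threshold), with backward elimination after each addition and
coordinate-wise position refinement; candidate positions within 10 cM of a
model QTL on the same chromosome are excluded to avoid collinear twins.
The search is additive-only: interaction-aware penalties are deliberately
out of scope, and all reported peaks are main effects.  Support intervals
take the outermost grid positions within `drop` (default 1.5) LOD of the
peak, optionally expanded to flanking bin positions.  Variance explained is
reported both ways: model % = 100·(1 − 10^(−2·LOD_full/n)) and per-QTL
marker % as the drop-one loss in explained variance — the two definitions
differ in multi-QTL models and both are printed rather than guessing which
one a given report used.

## Simulated cross

Each parent's meiosis is a Markov chain along the chromosome; markers
segregate 1:1.  The default genome for simulation studies is five 100-cM
chromosomes with markers every 5 cM — dense enough that interval mapping
behaves as on a real binned GBS map while keeping hundreds of replicates
cheap; study-scale maps are a config change.  Phenotypes follow
y = μ + block + Σ a·g + G + GY + e with user-set variance components; a
planted QTL of additive effect a on a 1:1 marker contributes a²/4 to the
genetic variance.  `h2_target` solves for the polygenic variance that hits
a requested heritability after accounting for planted QTLs.

## Linking images to genetics

The pipeline's imaging stage renders clusters whose target compactness is
an affine map of the genotype's simulated trait value (population mean 0.18,
genetic spread 0.009 — the scale reported for this population).  The
envelope is scaled by √(reference/target compactness) and additionally by
√(n_berries/46) so that the berry-count draw does not leak into compactness.
Rendering adds ≈ 0.014 SD of cluster-to-cluster compactness noise, so — as
in the real study design — multiple clusters per genotype × block are needed
before a 12%-variance QTL is detectable.  With 3 blocks × 5 clusters per
genotype the planted compactness locus was recovered above the 5%
genome-wide threshold in 12 of 12 power-analysis replicates (LOD 2.9–6.2
against thresholds ≈ 2.3–2.6); per-replicate LOD varies mainly with the
sampling fluctuation of the realized QTL R² at n = 138, the same reason a
borderline locus can change LOD substantially between seasons.  The test
suite renders one camera angle per cluster: the simulator's two angles
share a single 2D geometry, so the second angle adds no compactness
information (it matters only for berry counting).

## Problem sizes used by the test suite

Simulation studies run at the study's design sizes where those matter for
the claim being tested: 138 progeny, 3 blocks, 2 years for variance
components; 84 calibration clusters for the count correction; 400 null
genomes × 300 permutations for type-I error; 100 replicates for power,
interval coverage and null model-size checks.  The repeated-replicate
genome is the five-chromosome default; single fits use study-scale maps.

## Known limitations

* 2D geometry only; no photometric rendering, so segmentation failure modes
  beyond occlusion are not represented.
* The shape screen assumes the candidate population is berry-dominated; on
  images where artifacts outnumber berries the PCA centre would drift.
* REML assumes independent identically distributed residuals; no spatial
  field-trend correction.
* Stepwise search is additive-only; epistatic models are out of scope.
* Compactness can exceed 1 if overlapping (un-deduplicated) masks are
  passed; the pipeline always deduplicates first.
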