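# Methods

This note documents the models and procedures implemented in `nucmorph`,
the defaults chosen where the underlying assays leave details open, and what
the synthetic-data tests do and do not demonstrate about real images.

## Synthetic microscopy model

Fields of nuclei are rendered as axis-aligned ellipsoids with per-axis
semi-axes drawn from a configurable distribution (constant, uniform, or
lognormal parameterised by median and coefficient of variation; default
lognormal, median 4.5 µm, CV 0.10 — a realistic spread for cultured
epithelial nuclei). Axis alignment keeps the analytic oracles exact: volume
`4/3·π·abc` and the Knud Thomsen surface approximation
`4π[((ab)^p+(ac)^p+(bc)^p)/3]^(1/p)`, `p = 1.6075` (relative error < 1.1%).

Placement is rejection sampling with a pairwise centre-distance constraint
and a hard cap of 10,000 attempts per nucleus; exceeding it raises an
explicit "field too crowded" error naming the offending parameters.
Simplicity and unbiased uniform layouts were preferred over dense-packing
algorithms. Nuclei keep a 1 µm gap to the field boundary by default
(`border_pad_um`), so border-exclusion filtering does not silently eat
ground-truth objects; set it to a negative value to study clipped nuclei.

Rendering paints voxels whose centres fall inside the ellipsoid at a
constant foreground level (200), over a constant background (10), adds
i.i.d. Gaussian noise (σ = 5) and clips to the bit depth (8-bit default).
Real microscopes add depth-dependent blur, shot noise and staining
heterogeneity; none of that is modelled (no PSF, no chromatin texture), so
passing tests certify the measurement chain's geometry and statistics, not
robustness to optical artefacts.

A `median_scale` m ≠ 1 produces a matched-pair two-population field: each
base shape is instantiated once unscaled and once with all semi-axes × m,
making the ground-truth median-volume ratio exactly m³ — useful for testing
the two-group pipeline against an exact effect size. A separate
`size_scale` multiplies every nucleus of a field and is how distinct
experimental conditions are built.

### Membrane channel and its two calibrations

The rim shell of a nucleus is defined on the rendered voxel mask by
Euclidean distance-to-surface ≤ `rim_width_um` (default 1 µm), i.e. by what
a line scan actually samples, not analytically. Three signal layouts are
offered:

- **uniform** (`rim_fraction=None`): constant intensity over the nucleus;
  the rim's share of total signal then equals the shell-volume fraction.
- **mass calibration**: fraction ρ of the nucleus's total signal is placed
  in the rim (uniformly per rim voxel), the rest uniformly in the interior.
  The rendered voxel-sum rim share equals ρ exactly by construction.
- **line-scan calibration**: zone intensity levels (rim / rest-of-margin /
  core) are solved per nucleus so that an ideal continuous line scan along
  the in-plane long axis, scored with the assay's 3 µm edge margin, reads
  exactly ρ.

The two calibrations are deliberately distinct because a 1D line scan
weights zones by their length along the axis while a 3D mass fraction
weights them by shell volume; for realistic nucleus sizes the two disagree
substantially (a sphere of r = 5 µm with a 1 µm rim holds nearly half its
volume in the shell). When the quantity of interest is "percent of signal
at the periphery as measured by a line scan", the line-scan calibration is
the appropriate ground truth and is the default in the line-scan pipeline;
the mass calibration is the appropriate ground truth for volumetric
integrals. Both are verified by brute force in the tests.

### Decay courses

Cycloheximide-chase analogues are `level = L0·exp(−k t)` at timepoints
{0, 6, 12} h with mean-one multiplicative lognormal noise of chosen CV and
3 replicates by default, matching common chase designs. Summaries report
per-timepoint mean ± SEM and per-timepoint Student's t tests between two
conditions; the pooled log-linear least-squares half-life `t½ = ln2/k̂` is
reported separately and labelled an extension beyond the per-timepoint view.

## Segmentation

Smoothing sigma is specified in µm and converted to voxels per axis, so
anisotropic stacks are smoothed isotropically in physical space. The
automatic threshold is Otsu's between-class-variance criterion; manual
per-image thresholding (the irreproducible but common practice) is retained
as a numeric mode, and the value used is always recorded in provenance.
The mask rule is inclusive (`intensity ≥ value`).

Connectivity defaults to face-only (6-connectivity in 3D, 4 in 2D) and is
configurable; the filter's minimum size (default 50 voxels) is inclusive —
an object of exactly 50 voxels survives. "Partial" nuclei are
operationalised as border-touching components (removed by default);
"aggregated" nuclei as components whose solidity falls below
`1 − max_solidity_deficit` (off by default, since aggregates are usually
curated by eye). Counts removed per rule are recorded.

## Morphometry

All physical quantities are computed in µm-space; anisotropic voxels are
fully supported. Two surface-area estimators are provided because voxelised
surfaces are genuinely ambiguous: exposed-face counting is exact for the
voxel polyhedron but overestimates smooth surfaces by up to ~50%
(staircase bias); the marching-cubes mesh on a lightly anti-aliased mask
(Gaussian, 1 voxel) tracks smooth-object areas to ~1% at 0.2 µm voxels and
is the default where analytic comparison matters. The estimator used is
recorded in the output. The "nuclear diameter" entering the crowding index
is the sphere/circle-equivalent diameter (not Feret), chosen for its direct
analytic link to the measured volume/area; it is configurable in the sense
that any per-nucleus diameter column can be supplied to
`crowding_indices`.

Cytoplasm-by-subtraction clamps small negative results (segmentation noise)
to zero with a warning and refuses grossly inconsistent inputs
(nuclear > 1.5 × total).

## Spatial statistics

"Internuclear distance" is the centroid-to-centroid length of 2D Delaunay
edges. The per-nucleus summary is the mean of incident edge lengths by
default (median available); hull-boundary nuclei carry biased long edges,
and no edge pruning is applied by default. Collinear point sets fall back
to a nearest-neighbour chain flagged `degenerate`. ROI boxes (default
eight 1,500 × 1,500 µm, half-open, 0-based µm coordinates) are sampled
uniformly by rejection: non-overlapping unless the attempt cap forces
overlap (warned), and never intersecting the exclusion mask — mask
avoidance is implemented as a hard constraint rather than a preference, the
stricter and reproducible reading.

## Line scans

The long axis is the principal axis of the mask's pixel coordinates, tie
broken toward the image x-axis for near-round masks (eigenvalue ratio
< 1.05); the segment is clipped to the mask and extended 2 µm per side so
both edges are sampled. Profiles use bilinear interpolation at 0.1 µm steps
(neither is dictated by common practice; both are configurable). Edge
positions come from the mask crossings along the same segment. The
peripheral fraction integrates by trapezoid with exact interpolation at the
margin cut points; signal outside the nuclear span is excluded from the
denominator (the numerator's edge anchoring makes the trans-nuclear span
the consistent reading), and a toggle is available via the profile's edge
coordinates. Nuclei whose span does not exceed twice the margin are
trivially 1 and flagged.

## Statistics layer

The normality gate runs Shapiro-Wilk per group on raw and log-transformed
values at α = 0.05; a group passes if either scale passes, and any group
failing both routes the comparison to the rank branch. Groups of n < 3
cannot be gated and force the rank branch with a note. The Mann-Whitney U
uses the exact null distribution when min(n) ≤ 8 and there are no ties,
otherwise the tie-corrected normal approximation without continuity
correction (which makes the two-group Kruskal-Wallis reduction exact).
Dunn's post hoc uses tie-corrected rank variance
`z = (R̄_i − R̄_j)/√((N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_i+1/n_j))`
with Holm adjustment by default (Bonferroni and unadjusted available);
the adjustment is always labelled in the output.

## Problem sizes and reproducibility

The test suite and the acceptance script run at desk scale by design:
single-nucleus benchmark renders at 0.2 µm voxels, multi-condition runs of
~200 nuclei/condition at 0.4 µm voxels and ~50 line-scanned nuclei per
condition at 0.25 µm, 1,000-replicate null simulations at n = 50/group.
These sizes recover median-volume ratios within a few percent and
peripheral fractions within ~0.01; tissue-scale studies (10⁵–10⁶ nuclei)
only shrink the statistical error further. All randomness flows from
explicit integer seeds through `numpy.random.SeedSequence`; identical
config + seed reproduces every output byte, and each run writes its fully
resolved configuration and per-stage object counts alongside the tables.

## Known limitations

- No PSF, shot noise, staining heterogeneity, or touching-nuclei
  declumping; the segmentation chain assumes separable nuclei, as the
  generator guarantees by construction.
- Ellipsoids only (optionally anisotropic, never rotated off-axis);
  irregular or lobulated nuclear shapes are untested territory.
- The 2D "optical density" planes are contrast-inverted fluorescence
  renders, not colour H&E; no stain deconvolution.
- The crowding index inherits Delaunay hull bias at tissue borders.
- Whole-slide pyramidal formats, GUI, survival analysis and expression
  analysis are out of scope.
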