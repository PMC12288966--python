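# nucmorph

Nuclear morphometry for fluorescence microscopy stacks and histology planes.

Cancer cells show striking changes in nuclear size and shape, and these
changes are routinely graded by pathologists. `nucmorph` packages the image
analysis needed to quantify such phenotypes reproducibly: 3D nuclear volume
and surface area from DAPI-like z-stacks, 2D nuclear cross-sectional area
(CSA) over randomly tiled regions of whole-tissue images, a Delaunay-based
crowding index that removes nuclear-size confounding from packing density,
line-scan quantification of nuclear-envelope protein enrichment at the
nuclear periphery (e.g. Emerin), blot densitometry and protein-decay
(cycloheximide-chase) summaries, and a normality-gated statistics layer. A
ground-truthed synthetic-microscopy generator makes every stage testable
against closed-form geometry without any external data.

## What it computes

**Morphometry.** Nuclei are detected by Gaussian smoothing, a global
threshold (Otsu's between-class-variance criterion or a manual value),
connected-component labelling, and filtering (minimum size, inclusive, 50
voxels by default; border-clipped objects removed; optional low-solidity
rejection of aggregates). Per nucleus:

- volume `V = n_vox · dx·dy·dz` (µm³) and surface area `S` (µm²; marching-cubes
  mesh by default, exposed-voxel-face counting as the deterministic alternative),
- CSA `A = n_px · dx·dy` (µm²) on 2D planes,
- equivalent diameter `D = (6V/π)^(1/3)` (3D) or `(4A/π)^(1/2)` (2D),
- cytoplasm volume by subtraction: `V_cyto = V_total − V_nuc`.

**Crowding.** For nucleus *i* with mean incident Delaunay edge length
`ℓ̄_i` (centroid-to-centroid, µm), the crowding index is `c_i = ℓ̄_i / D_i`.
It is exactly invariant under joint scaling of positions and sizes.

**Peripheral enrichment.** A line is drawn through the long axis of each
nucleus on the middle z-plane; the peripheral fraction is the share of the
trans-nuclear line signal within a fixed margin *d* (3 µm by convention) of
the two nuclear edges:
`f = (∫_{p_L}^{p_L+d} I + ∫_{p_R−d}^{p_R} I) / ∫_{p_L}^{p_R} I`.

**Statistics.** Groups are checked for normality and lognormality
(Shapiro-Wilk at α = 0.05). Passing data use Student's t test / one-way
ANOVA + Tukey HSD; otherwise Mann-Whitney U (exact null distribution for
small tie-free samples) / Kruskal-Wallis + Dunn's tie-corrected post hoc
with Holm adjustment. The selected branch and gate outcomes are always
recorded in the output.

## Worked example

Simulate two conditions whose nuclei differ by a linear size factor 0.85
(volume ratio 0.85³ ≈ 0.614, an oncogene-induced shrinkage analogue), run
the full volume pipeline and compare:

```python
from nucmorph import RunConfig, run_volume_pipeline

field = {"n_nuclei": 20, "radii_dist": {"name": "lognormal", "median_um": 4.5, "cv": 0.10},
         "min_spacing_um": 13.0, "extent_um": (90, 90, 16), "voxel_size_um": (0.4, 0.4, 0.4)}
cfg = RunConfig(mode="volume", seed=11, n_fields=2, conditions=[
    {"name": "minus_dox", "field": field},
    {"name": "plus_dox", "field": {**field, "size_scale": 0.85}},
], policy={"force_branch": "nonparametric"})
bundle = run_volume_pipeline(cfg)
c = bundle.comparison
print(bundle.per_nucleus.groupby("condition").volume_um3.median())
print(f"{c.test_name}: U = {c.statistic:.0f}, p = {c.p_value:.3g}")
```

prints

```
condition
minus_dox    361.024
plus_dox     245.376
Name: volume_um3, dtype: float64
Mann-Whitney U (asymptotic, tie-corrected): U = 1540, p = 1.04e-12
```

The recovered median-volume ratio 245.4/361.0 ≈ 0.680 at n = 40/40 nuclei
approaches the ground-truth 0.614 as n grows (the acceptance run below uses
200 nuclei per condition and recovers it within a few percent), and the rank
test cleanly separates the conditions.

The same analyses are available from the shell:

```bash
nucmorph simulate field --config spec.yaml --seed 3 --out sim/
nucmorph segment --in sim/stack.tif --min-size 50 --out nuclei.csv
nucmorph crowding --in nuclei.csv --out crowding.csv
nucmorph run --config run.yaml --out results/
```

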