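# Methods

## Overview

The package quantifies how much of an articular surface is occupied by
high-radiodensity subchondral bone, and tests whether that fraction differs
between locomotor (gait) groups once phylogeny is accounted for. It has two
halves: an imaging pipeline (volume → surface → mask → MIP → eight-bin
ratios) and an inference layer (descriptive tables, one-way ANOVA with
assumption checks and Tukey HSD, and a simulation-based phylogenetic ANOVA).
Because the original museum CT scans cannot be shipped, a phantom generator
provides volumes with exact ground truth, and the published per-species and
per-group summary statistics are packaged as fixtures.

## Imaging model and parameters

**Orthographic projection.** Specimens are assumed scanned with the bone's
long axis perpendicular to the scan plane, so the distal articular surface
(the tibial plafond) is quasi-horizontal in grid coordinates and the MIP can
be taken along a grid axis. No registration or virtual reorientation is
performed; this replaces the interactive fitting of projections onto 3D
renderings with a reproducible operation, at the cost of assuming correct
specimen alignment at scan time.

**Surface detection** (`detect_surface`). Per projected column, the surface
is the first voxel at or above `bone_threshold` (default 50 phantom units;
for real HU data a value near 200–300 would be typical — the threshold is a
required, data-dependent argument). A 3×3 median filter (on by default,
recorded on the result) suppresses single-voxel spikes in the depth field.

**Articular mask** (`articular_mask`). The medial malleolus carries a
steeply descending facet that bears little axial compression; it is excluded
operationally by surface inclination: central-difference gradients of the
depth field give a local slope, and columns steeper than
`max_inclination_deg` (default 45°, configurable — the anatomical criterion
being replaced states no angle) are dropped. Connected components smaller
than `min_component_px` (default 8) are removed; this keeps the mask
monotone in the threshold (relaxing the angle can only add pixels). An
optional `largest_only` switch restricts to the single largest component
when stray facets survive the cut.

**Projection depth.** The MIP runs from the detected surface to
`depth_mm` below it (default 3 mm), intended to span the subchondral plate.
Columns whose window is clipped by the volume boundary are flagged
per-pixel rather than silently truncated.

**8-bit windowing** (`rescale_to_8bit`). `v → round(255·(v−lo)/(hi−lo))`,
round-half-up, clamped to [0, 255]. The window is **fixed for a whole
study**, never fitted per specimen: per-specimen min–max stretching would
force every specimen to populate the top bin, whereas observed datasets
contain specimens whose top-bin ratio is exactly 0.000. Radiodensity units
are abstract (scanners differ in calibration); the shared window makes
specimens comparable on one absolute scale.

**Binning** (`bin_counts`). Eight equal-width bins on [0, 256): edges 0,
32, …, 256, half-open intervals with the last closed at 255, so the bin of
value v is `v // 32`. The two response variables are
`max_ratio = counts[7]/total` and `second_ratio = counts[6]/total`, with
`total` the number of masked pixels only. The choice of an absolute 0–255
span (rather than a sub-window of observed values) is recorded in run
provenance so alternatives can be swapped in.

## Phantom generator

`generate_epiphysis_phantom` builds a volume from a smooth height field
z(x, y) (plane plus optional curvature), a subchondral plate of
`plate_thickness` (default 3 mm) whose surface density is `plate_base_value`
(default 100) with circular patches raised to each patch's `peak_value`,
trabecular filler (default 60) beneath, and background (default 0) above.
An optional malleolus flange makes the surface descend toward the viewer
from a given row at `drop_depth_mm` per `width_mm` — a steep planar ramp
whose wall inclination is `atan(drop/width)`, so a 8 mm drop over 5 mm
(58°) is excluded by the 45° mask default while the plafond is kept.
Gaussian noise of `noise_sd` is added last; with a fixed spec and seed the
volume is bit-identical on regeneration. The generator returns the exact
surface depth, true articular mask (flange excluded) and noise-free surface
density, which downstream tests treat as ground truth.

The phantom emulates the features the pipeline depends on — a detectable
surface, a plate with localized dense patches, a steep excludable flange —
and deliberately not trabecular microarchitecture, beam hardening, partial
volume blur, or scanner noise spectra. Passing phantom tests therefore
demonstrates correctness of the computational chain, not robustness to
every artifact of real CT data.

`generate_ratio_dataset` draws per-specimen ratios from normal
distributions truncated to [0, 1] by rejection sampling (ratios are bounded
and observed group means sit near 0). Note truncation biases the sample
mean upward when sd is not small relative to the distance to the boundary;
tests compare against the closed-form truncated-normal moments.

## Statistical procedures

All printed standard deviations are treated as n−1 sample SDs. The ANOVA is
the standard between/within decomposition; `anova_from_summary` implements
it directly from (n, mean, sd) so that published summary tables can be
re-analysed, and `anova_oneway` on raw data reduces to it exactly (an
algebraic identity, tested to 10 significant digits against scipy).
Reconstructing F from tables printed to three decimals propagates that
rounding; reproductions are accepted within 2% relative error.

Normality is checked per group by a one-sample Kolmogorov–Smirnov test
against a normal with estimated mean/SD (the plain asymptotic p, which is
conservative when parameters are estimated), with a Lilliefors-corrected
option. Variance homogeneity uses Levene's test with group-mean centering.
Post-hoc comparisons use Tukey HSD with the Tukey–Kramer unequal-n standard
error; adjusted p-values come from scipy's studentized-range distribution
(numerically integrated CDF, absolute accuracy well below 1e-6 in the
relevant range). Because that CDF evaluation is expensive, bulk calibration
work uses the equivalent rejection rule `q > q_crit(α, k, df)`.

## Phylogenetic ANOVA

The analysis unit is one value per species (species means), since
within-species specimens are not independent draws with respect to the tree.
The observed F is the conventional one-way F on the species values. The
null distribution is generated by simulating Brownian motion on the dated
tree: each branch adds an independent Normal(0, rate·length) increment,
tips inherit the summed increments. The Monte-Carlo p is
`(1 + #{F_null ≥ F_obs}) / (1 + nsim)` — the add-one estimator, which is
never exactly zero and slightly conservative. `nsim` defaults to 10 000
(Monte-Carlo SE ≈ 0.005 at p ≈ 0.4).

The BM rate is fixed at 1: F is invariant to affine transformation of the
response, so the null F distribution does not depend on the rate (verified
exactly in tests — the same RNG seed yields the identical F sample at any
rate). Post-hoc pairwise t statistics (pooled within-group MSE) are
referred to their own null samples from the same BM replicates and
Holm-adjusted across the three pairs; Holm is the convention of the
established simulation-ANOVA implementations, which this module reproduces
independently (and against which it is cross-checked in the test suite via
Rscript when available).

On a star tree BM tip values are i.i.d. normal, so the simulation p must
converge to the parametric p — this is the main calibration property tested.
When groups cluster on the tree, the Brownian null inflates the F tail and
`p_phylo > p_param`, which is exactly the correction the method exists for.

## Fixtures and their provenance

The packaged species and gait-group tables transcribe published descriptive
statistics for 41 marsupial distal tibiae: 14 species — five bipedal
macropods (kangaroos and wallabies), four arboreal quadrupeds (tree
kangaroos, koala, brushtail possum), five terrestrial quadrupeds (wombats,
Tasmanian devil, thylacine). The dated tree distributed with the original
study is not publicly available, so `study_fixture_tree` ships a
**synthetic** ultrametric 14-tip tree: the topology follows the published
figure (bipeds monophyletic, *Dendrolagus* their sister within
Macropodidae, Phalangeridae next, then Vombatiformes, with Dasyuromorphia
as outgroup) and node ages are round-number approximations of molecular
divergence estimates for marsupials (root ≈ 60 Ma, Vombatiformes–
Phalangerida ≈ 50 Ma, crown Macropodidae ≈ 12 Ma). Quantities that depend
on exact branch lengths — the phylogenetic p-values — are therefore
reproduced only qualitatively (non-significance, p > 0.05), while quantities
that depend only on the species values (F ≈ 4.15 and 3.95 on df (2, 11))
reproduce to printed precision.

## Problem sizes and numerical choices

Default phantom grids are 48×40×40 voxels at 0.5 mm spacing (a realistic
epiphysis field of view at typical clinical-CT slice thickness); oracle
comparisons run on random volumes up to 32³. Simulation-based checks use
10 000 BM replicates and 2 000 null replicates for type-I calibration of
Levene and Tukey (acceptance band 5% ± 1.5%). Ties in binning are impossible
by construction (integer gray values, integer edges); round-half-up is used
in windowing so that the midpoint maps to 128. Degenerate inputs are defined
explicitly: an all-background volume yields an all-invalid surface (not an
error), an empty mask raises, zero within-group variance yields F = ∞ with
p = 0 (or F = 0, p = 1 when between-group variance is also zero), and
Levene is reported as unavailable when every group is internally constant.

## Known limitations

- The orthographic projection assumes pre-aligned specimens; obliquely
  scanned bones would need reorientation upstream.
- The inclination threshold is an operational proxy for an anatomical
  judgement; 45° is a default, not a measured property of malleoli.
- The projection depth (3 mm) is a reasonable subchondral-plate scale but
  not species-calibrated; thin-plated small taxa may need a smaller window.
- The fixture tree's branch lengths are approximate; conclusions that hinge
  on exact divergence times should re-run with a vetted chronogram.
- Truncated-normal ratio simulation reproduces group means/SDs only when
  the SD is small relative to the distance to the [0, 1] boundary.
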