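# osteomip

CT osteoabsorptiometry of subchondral bone: maximum-intensity-projection
(MIP) radiodensity maps of articular surfaces, eight-bin pixel-ratio
statistics, and gait-group inference with both conventional and
phylogenetically-controlled ANOVA.

## The scientific problem

The apparent density (radiodensity) of subchondral bone — the mineralized
layer just beneath articular cartilage — records the compressive loads a
joint habitually carries. Mapping where a joint surface is densest therefore
gives a non-invasive readout of limb use: a hopping biped that carries its
whole body weight on two hind limbs should show more extensive high-density
area in its distal tibia than a quadruped, and a compliant-gaited arboreal
quadruped less than a terrestrial one.

The analysis chain this package implements:

1. **MIP mapping.** A CT volume of a distal epiphysis is condensed along the
   line of sight into a 2D map whose each pixel is the maximum radiodensity
   in a column of voxels through the subchondral plate,
   `MIP(x, y) = max_z V(x, y, z)` over `z ∈ [surface, surface + d]`.
2. **Articular masking.** Surface regions that descend steeply (the facet on
   the medial malleolus) are excluded by a surface-inclination threshold:
   they bear little axial compression and would dilute the statistic.
3. **Eight-bin quantization.** The 8-bit MIP is binned into eight equal
   gray-value classes on a fixed absolute scale (edges 0, 32, …, 256). The
   response variables are the size-corrected pixel-count ratios
   `max/total` (top bin over all masked pixels) and `second/total`.
4. **Inference.** Gait groups — bipedal (B), arboreal quadrupedal (AQ),
   terrestrial quadrupedal (TQ) — are compared by one-way ANOVA with Tukey
   HSD, after Kolmogorov–Smirnov normality and Levene variance checks.
5. **Phylogenetic control.** Because gait groups coincide with clades (the
   bipeds are all macropods), species means are re-tested against a null F
   distribution generated by simulating Brownian-motion trait evolution on
   a dated phylogeny: `p_phylo = (1 + #{F_null ≥ F_obs}) / (1 + nsim)`.

Museum CT scans are not redistributable, so the package ships a **phantom
generator** producing epiphysis-like volumes with known ground truth (surface
depth, articular mask, surface density field) plus packaged summary tables
for 41 marsupial tibiae (14 species) and a synthetic dated tree, making
every stage testable end to end.

## Worked example

Phantom → MIP → ratios, with the ground truth alongside:

```python
from osteomip import *

spec = PhantomSpec(density_patches=(DensityPatch((20., 20.), 5.0, 250.0),),
                   noise_sd=0.0, seed=0)
vol, truth = generate_epiphysis_phantom(spec)

surf = detect_surface(vol, bone_threshold=50.0)
mask = articular_mask(surf)                      # 45 degree default
mip  = project_mip(vol, surf, mask, depth_mm=3.0)
mip8 = rescale_to_8bit(mip, 0.0, 255.0)          # fixed study-wide window
hist = bin_counts(mip8.values, mip8.mask.mask)
print("bin counts :", hist.counts.tolist())
mr, sr = ratio_statistics(hist)
print(f"max/total = {mr:.4f}   second/total = {sr:.4f}")
```

prints

```
bin counts : [0, 0, 0, 1283, 0, 0, 0, 317]
max/total = 0.1981   second/total = 0.0000
```

The plate (radiodensity 100) lands in bin 3 and the high-density patch
(radiodensity 250) in the top bin; the patch covers 317 of 1600 masked
pixels, so `max/total` = 0.1981 equals the true patch areal fraction
(0.1981). `second/total` is exactly 0 — possible only because the 8-bit
window is fixed across specimens rather than stretched per specimen.

Group inference is model-styled: build a model from a tidy DataFrame, `fit()`
returns a results object with a `summary()`:

```python
res = GaitAnova.from_dataframe(records, "max_ratio").fit()   # ANOVA + Tukey
print(res.summary())

tree = study_fixture_tree()
pres = PhylogeneticAnova.from_dataframe(tree, species_means, "max_mean").fit(
    nsim=10_000, seed=1)
print(pres.summary())        # F_obs, parametric p, phylogenetic p, post hoc
```

The `osteomip` CLI wraps the same stages: `phantom`, `mip`, `bin`, `stats`,
`panova`, `run` (full pipeline from a YAML config), and `paper-tables`, which
recomputes the published aggregates from the packaged tables:

```
$ osteomip paper-tables
                      quantity  observed  published  rel_error
       wallaby_pooled_max_mean    0.1837     0.1840     0.0016
      kangaroo_pooled_max_mean    0.2434     0.2430     0.0018
   dendrolagus_pooled_max_mean    0.0170     0.0170     0.0000
dendrolagus_pooled_second_mean    0.3005     0.3000     0.0017
      species_group_mean_B_max    0.1874     0.1870     0.0021
     species_group_mean_AQ_max    0.0505     0.0510     0.0098
     species_group_mean_TQ_max    0.0644     0.0640     0.0062
                   anova_F_max    5.9565     5.9200     0.0062
                anova_F_second    7.4747     7.4920     0.0023
                  panova_F_max    4.1524     4.1520     0.0001
               panova_F_second    3.9475     3.9480     0.0001
```

(The F statistics are reconstructed from summary tables printed to three
decimals, so they carry that rounding.)

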