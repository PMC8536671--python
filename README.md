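# coamap

Quantitative mapping of **corpora amylacea (CoA)** — spherical polyglucosan
inclusion bodies of the aged human brain — in calibrated fluorescence
micrographs of the hippocampal formation.

CoA appear as bright circular profiles against a dim autofluorescence
background. They concentrate in a narrow *high-density (HD) band* just
beneath the pial border and in periventricular regions, with a burden that
peaks at the fimbria pial surface and decays bilaterally along the pial
border. `coamap` implements the full measurement chain for this biology, for
neuropathology image analysts who need reproducible, testable numbers rather
than manual counts:

1. **Detection** — thresholding (Otsu or fixed level), 8-connected
   labelling, and exact calibrated measurement of each object (pixel-count
   area, equivalent diameter `d = 2·√(A/π)`), with a minimum detection size
   of 3 µm and an unbiased counting frame: objects intersecting the **left
   or bottom** image border are excluded, right/top-touching objects kept,
   so tiled fields count every object exactly once.
2. **Per-field parameters** — for each 1600 × 1200 px field of view
   (0.2 mm²): CoA count, area fraction (%), and mean/min/max equivalent
   diameters (missing when the field is empty).
3. **HD/LD zoning** — fields from the seven pial-surface regions
   (APS, FPS, PPS, SPS, MPS, LPS, CPS) are split at fixed depths below the
   pial border (100 µm fimbria, 70 µm prosubiculum, 40 µm elsewhere) into HD
   and LD zones; packing density (count/mm²), area fraction and diameters
   are reported per zone, and the HD-band thickness of a traced polygon is
   estimated as *enclosed area / centre-line length*.
4. **Staging** — each section is classified into CoA stages 0–4 from its
   regional per-FOV mean counts (half-open bands [0,10), [10,50), [50,500]
   in the fimbria pial surface) and deep-white-matter involvement flags, and
   a continuous burden score (Σ log1p regional counts + flag bonuses) orders
   sections into a ranked sequence from lowest to highest burden.
5. **Statistics** — Spearman correlation grids (region × parameter, per
   covariate: ranked sequence, age, BMI) with Benjamini–Hochberg FDR
   adjustment per grid; unpaired t-tests for HD vs LD comparisons; one-way
   ANOVA with a Levene gate choosing Fisher's LSD (equal variances) or
   Games–Howell (unequal variances, Welch t referred to the studentized
   range) post hoc comparisons.

Because matched autopsy image sets are not publicly available, the package
ships a first-class **synthetic-micrograph generator** that emulates the
assumed statistical structure with exact ground truth — Poisson counts in a
subpial HD band, hard-core disc placement, truncated-lognormal diameters
(median 9 µm, bounds 3–30 µm), a stage-dependent regional gradient centred
on the fimbria, and covariate effects (age shifts the diameter location
parameter; burden stage is independent of age) — so that every stage of the
pipeline is validated against known truth.

## Worked example

```python
import numpy as np
from coamap import (
    DEFAULT_CALIBRATION, Region, SimConfig, simulate_fov, detect,
    summarize_fov, ZonePartition, summarize_zones, assign_zones,
)

rng = np.random.default_rng(0)
cfg = SimConfig(stage=3, hd_intensity=500.0)
img, truth = simulate_fov(cfg, DEFAULT_CALIBRATION, Region.FPS, rng, fov_id="demo/FPS/0")
objects = detect(img)                      # binarize -> label -> filter
summary = summarize_fov(objects, DEFAULT_CALIBRATION, Region.FPS, fov_id=img.fov_id)
part = ZonePartition.straight_top_edge(Region.FPS, DEFAULT_CALIBRATION)
hd, ld = summarize_zones(assign_zones(objects, part), part)

print(f"true objects: {len(truth.objects)}, detected: {summary.count}")
print(f"area fraction: {summary.area_fraction_pct:.2f} %")
print(f"diameters (um): mean {summary.mean_diameter_um:.1f}, "
      f"min {summary.min_diameter_um:.1f}, max {summary.max_diameter_um:.1f}")
print(f"HD packing density: {hd.packing_density_per_mm2:.0f} /mm^2, "
      f"LD: {ld.packing_density_per_mm2:.0f} /mm^2")
```

prints

```
true objects: 30, detected: 29
area fraction: 1.11 %
diameters (um): mean 9.5, min 5.9, max 16.4
HD packing density: 523 /mm^2, LD: 13 /mm^2
```

The one undetected object intersected the left/bottom counting frame — by
design it is excluded, and the matching ground-truth oracle excludes it too.
The HD/LD packing-density ratio (~40× here in a single field; ~10× on
average at the generator's default intensity ratio) quantifies the subpial
concentration of CoA.

The full pipeline (simulate → detect → quantify → stage → stats) runs as

```sh
coamap run --config run.yaml --out results/run1 --seed 1
```

producing `objects.csv`, `fov_summaries.csv`, `zone_summaries.csv`,
`stages.csv`, `stats_grid.csv`, `hd_ld_tests.csv` and a `manifest.json` with
a SHA-256 digest of every table; identical config and seed reproduce every
output byte for byte. `coamap simulate / detect / quantify / stage / stats /
make-fixtures` expose the individual stages.

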