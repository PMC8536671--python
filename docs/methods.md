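# Methods

## Measurement model

A field of view (FOV) is a calibrated single-channel image; the default
geometry is 1600 × 1200 px covering 0.2 mm², giving a pixel side of
√(0.2·10⁶/1.92·10⁶) ≈ 0.32275 µm. Pixel (i, j) has its centre at
((j+0.5)·ps, (i+0.5)·ps) with the origin at the top-left corner and y
pointing down; in synthetic pial-surface fields the pial border is the top
edge, so y is depth below the pia.

Detection binarises the image (Otsu by default; the chosen method and level
are recorded so runs are reproducible), labels 8-connected components
(matching the topology of rasterised circular blobs), and measures each
component exactly: area = pixel count × pixel area, centroid = mean of
pixel centres, equivalent diameter d = 2·√(A/π). Two filter rules follow:

* **minimum detection size** — equivalent diameter ≥ 3.0 µm, inclusive.
  The bound is placed on the diameter (not the area) because all size
  results are reported as diameters; equivalent rather than Feret diameter
  is used throughout.
* **counting frame** — objects whose raster touches the left or bottom
  image border are excluded; right/top-touching objects are retained. Under
  tiling of a larger region into FOVs this counts each object exactly once,
  so summed counts per unit area are unbiased for the generating intensity
  (verified against a toroidally wrapped mosaic, where the construction is
  exact up to minimum-size interactions with cut slivers).

No watershed splitting of touching objects is attempted: no reliable
splitting rule exists for merged spherical profiles in a single plane, the
generator's hard-core separation keeps merges rare, and their effect is
measurable against ground truth. Z-stacks are not modelled; each FOV is a
single rendered plane.

### Per-FOV parameters and missing values

Count and area fraction are recorded as 0 for empty fields and enter all
analyses; diameters are recorded as missing for empty fields and are removed
pairwise in any statistic (this is what makes n vary between cells of the
correlation grids). The per-FOV minimum (maximum) diameter is the diameter
of the single smallest (largest) object in the field; regional values
average these across the region's fields.

## HD/LD zoning

The subpial high-density band is analysed at fixed depths: 100 µm (fimbria
pial surface), 70 µm (prosubiculum), 40 µm (all other pial regions). Zone
membership is decided by the object centroid's distance to the pial-border
polyline — deterministic and oracle-checkable, unlike an overlap-fraction
rule — with the boundary depth inclusive to HD (a relative tolerance of
1e-9 absorbs geometric rounding in the distance computation). Neuropil
fields have no pial border; their objects are LD by convention. Packing
density and area fraction are computed against the zone's own area; the
HD/LD fold change is the ratio of per-region means and is reported missing
when the LD mean is zero. The thickness of a traced HD polygon is estimated
as enclosed area / centre-line length, which is exact for constant-depth
bands.

## Staging and the burden sequence

Stage bands on the fimbria pial-surface per-FOV count are printed with
overlapping endpoints (0–10, 10–50, 50–500); they are resolved as half-open
intervals [0,10), [10,50), [50,500], boundary counts going to the higher
stage. The ladder is evaluated top-down: stage 4 requires ≥ 50 CoA/FOV and
parahippocampal/fusiform deep-white-matter involvement; stage 3 requires
≥ 50, prosubiculum–subiculum pial continuity (operationalised as nonzero
counts in both, the regions between them inclusive), and lateral-ventricle
deep-white-matter involvement; stage 2 requires ≥ 10 with prosubiculum and
subiculum involvement; stage 1 any fimbria pial CoA; else stage 0.
Deep-white-matter flags are inputs: the LV flag derives from LV neuropil
counts, while parahippocampal/fusiform involvement has no sampled region
label and is carried as a per-section annotation, keeping staging testable
independently of detection.

The burden score Σ_pial log1p(mean count) + 2·[LV flag] + 4·[PHG/fusiform
flag] replaces the manual lowest-to-highest ordering of sections by three
observers. The weights are a declared convention: the downstream analyses
use only the rank order, which any strictly monotone alternative preserves.
Ties are broken by section id, so ranking is permutation-invariant.

## Statistics

* **Spearman's rho** on average ranks, two-sided p from the t
  approximation t = r·√((n−2)/(1−r²)); cells with fewer than 3 complete
  pairs are missing. The approximation is adequate at the n ≥ 14 arising in
  the grids; an exact permutation p would differ only at smaller n.
* **FDR** — the adjustment method is Benjamini–Hochberg step-up, applied
  across one covariate's full region × parameter grid as a single family
  (missing cells shrink the family).
* **t-test** — unpaired, two-tailed, pooled variance, df = n₁+n₂−2. With
  zero pooled variance, p = 1 for equal means, p = 0 otherwise.
* **Levene gate** — Levene's test centred at the group mean (the common
  statistical-package default; Brown–Forsythe median-centring is available
  via an argument). All-constant groups yield p = 1 by convention.
* **Post hoc** — Levene p > α selects Fisher's LSD (pairwise t on the
  pooled within-group MSE with its df); otherwise Games–Howell: pairwise
  Welch t with Welch–Satterthwaite df, referred to the studentized-range
  distribution with the full group count via q = |t|·√2 (scipy's
  `studentized_range`, evaluated to ~1e-8; cross-checked against an
  independent implementation). At k = 2 Games–Howell reduces exactly to
  the Welch two-sample t-test.

## Synthetic generator

The generator emulates what the analysis assumes, not everything real
tissue contains:

* **Counts and positions** — per-zone counts are Poisson (intensity × zone
  area); positions are then placed sequentially, uniformly within the zone,
  rejecting candidates closer than the hard-core separation to any accepted
  centre, so the count distribution is preserved while overlap is
  suppressed. Placement failure after a bounded number of attempts raises
  an explicit error naming the region and intensity.
* **Diameters** — lognormal on the log scale with median 9 µm and
  σ = 0.3, truncated to [3, 30] µm. This reproduces the observed regime:
  mean ≈ 9.2–9.5 µm against a reported 9.1 µm population mean, per-field
  means spanning roughly 6–15 µm, and rare large profiles up to the 25–30 µm
  ceiling of mature CoA.
* **Intensity model** — background 500 ± 50 (Gaussian noise) with discs at
  5000, written as 16-bit; the validity contract requires the disc level to
  exceed background by > 5 noise SDs. No vessels, lipofuscin or
  Gomori-positive distractors are simulated — separating those from CoA was
  a manual morphological exclusion, out of scope here — so detection scores
  on synthetic data bound what thresholding can do under clean conditions,
  not performance on real tissue.
* **Stage tables** — expected per-FOV counts per region are fixed
  band-interior values (fimbria pial surface 4 / 30 / 120 / 150 at stages
  1–4, ≥ 1 count from any band edge) decaying monotonically with ordinal
  pial distance from the fimbria on both sides (alveus one way,
  prosubiculum → collateral sulcus the other), with the fimbria always
  dominant; neuropil regions follow the reported prevalence pattern
  (fimbria ≫ LV ≫ CA4, traces in CA3/CA1 at stage 4, never CA2/subiculum).
* **Hard-core separation** — default 12 µm (15 µm in the detection-fidelity
  study, whose diameters are bounded at 20 µm). Chosen so that sequential
  placement remains feasible at the stage-4 subpial packing (≈ 40% of the
  jamming coverage) while keeping touching-disc merges rare enough not to
  dominate detection error.
* **Cohorts** — ages uniform on 42–89 y, BMI uniform on 20–42 kg/m²,
  balanced sex; the stage assignment is balanced over 0–4 and shuffled,
  independent of age. The age effect shifts each subject's median diameter
  by 0.05 µm/yr; there is deliberately no age → density effect, so the
  correlation grids should flag density only for the burden sequence and
  diameters only for age.
* **Defaults** — 3 FOVs per sampled region (the per-region sampling effort
  is not externally fixed; 3 balances Poisson noise in regional means
  against cohort size) and 30 subjects.

## Problem sizes and numerical choices

The validation studies use 100 FOVs (detection), 50 random masks (filter
oracle), 200 tiled frames (counting-frame bias), 100 FOVs (zone ratio), 50
sections (stage recovery), 1000 p-vectors / 2000 null replicates
(statistics), and a 29-subject cohort (effect recovery) — sizes at which
the binomial/Poisson noise of each check is well inside its acceptance
band. Determinism: every stochastic component consumes a single
`numpy.random.Generator`; identical seeds give bit-identical images and
tables, and the pipeline manifest records config, seed, versions and
SHA-256 digests of all outputs.

## Known limitations

* Touching CoA merge into one object; no splitting is attempted.
* The analytic ground-truth area fraction (render-free mode) ignores disc
  clipping at field edges; the rasterised mode reports the exact union.
* Real curved pial borders are supported through the polyline interface,
  but the generator only renders straight top-edge borders.
* Stage recovery at 100% holds for band-interior intensities; real sections
  near band boundaries would be genuinely ambiguous under any rule.
* The statistics battery reproduces the analysis structure, not any
  specific published table values, which derive from unpublished per-patient
  data.
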