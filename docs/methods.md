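# Methods

## The analysis in brief

`carbonfish` maps two ecosystem services on a common latitude–longitude
grid — particulate organic carbon (POC) export out of the upper ocean, and
commercial fishing intensity — and quantifies their spatial overlap at two
scales: a global pixel-level dual upper-quartile statistic, and per-region
(FAO-style fishing area) means, ranks and correlation. Both services depend
on phytoplankton primary production, so co-location is the expected
signal; the overlap statistic measures how concentrated it is.

## Grid geometry and integration

All fields live on uniform, cell-edge-registered global grids (latitude
ascending from −90°, longitude from −180°, half-open cell membership with
the final edge closed). Cell areas use the exact spherical form
`A = R²·Δλ·(sin φ₂ − sin φ₁)` with a fixed spherical Earth of R = 6371 km:
the band areas telescope, so the grid total equals `4πR²` to floating-point
accuracy on any resolution, and areas are symmetric about the equator. No
geodetic (ellipsoidal) correction is applied — the outputs are fractions
and ratios for which spherical areas are amply accurate.

Regridding is restricted to exact nesting (target resolution an integer
multiple of the source) with area-weighted means of valid source cells;
no interpolation is ever attempted. This conserves the area integral of a
fully valid intensive field to ~1e−15 relative and keeps results
bit-reproducible. A target cell is invalid only when every source cell
inside it is invalid.

Global export totals integrate `E · area · 365` over valid cells and
convert mg → Gt (÷10¹⁸). The field's unit metadata is checked before
integration, so a fishing field cannot be integrated as carbon by mistake.

## Export algorithms

Export is `e-ratio × NPP` per cell. The registry holds three empirical
export-ratio parameterizations (`henson`, `laws`, `dunne`; formulas in the
README) plus `model`, a pass-through for an externally computed export
product. Coefficients are registry data rather than hard-coded logic
because the scientific claim rests on the *ensemble mean*, not any single
parameterization; users can register alternatives.

Numerical guards:

* every ratio is clipped to [0, 1] — the `laws` polynomial crosses zero
  near SST ≈ 54 °C, unreachable in practice but guarded;
* `dunne` clips to [0.04, 0.72] as published; at NPP = 0 its logarithm is
  undefined, so the ratio is pinned at the floor and the export member is 0
  (zero production ⇒ zero export regardless of ratio);
* `dunne` without a euphotic-depth field raises an error naming the
  missing driver.

The ensemble mean is the cell-wise arithmetic mean over *valid* members:
where a member has no data (e.g. the model product's mask), the remaining
members average. The mean field is valid wherever at least one member is.

## The dual upper-quartile overlap

The analysis domain is the set of cells with valid export. Fishing must be
observed on all of it — absence of vessel activity is a true zero, not a
gap, so fishing gaps inside the ocean are coerced to 0 upstream. Two
thresholds are computed independently: the q-quantile (default 0.75) of
export values and of fishing values over the domain, by linear
interpolation at position `1 + (n−1)q` of the sorted sample. The overlap
mask is `E > q_E AND F > q_F` with *strict* inequality: ties fall outside,
which is deterministic and conservative.

Thresholds are computed **unweighted** over cells by default — each valid
cell is one observation, matching a pixel-counting reading of a gridded
product — while the reported fractions are always **area-weighted**:

    area_fraction   = Σ_mask a / Σ_domain a
    export_fraction = Σ_mask E·a / Σ_domain E·a
    effort_fraction = Σ_mask F·a / Σ_domain F·a

Area-weighted thresholds are available behind a flag
(`area_weighted_thresholds=True`) for sensitivity checks; the default is
the documented convention. Per-algorithm sensitivity reruns the whole
mask-and-fractions analysis once per ensemble member and reports the
min–max envelope of the three fractions.

Two useful baselines: for independent fields the expected area fraction is
`(1−q)² = 6.25%` at q = 0.75, and any strictly increasing transform of
either field leaves the mask unchanged (quantiles are equivariant), so the
statistic depends only on the rank structure of the two maps.

## Regional statistics

Per-region means are area-weighted over valid cells. Ranks are descending
with 1 = highest; tied values share the minimum rank of the tied block (a
rule needed only for synthetic edge cases — reference data are distinct).
The anomaly screen flags regions above `mean + k·SD` of the across-region
fishing intensities, with the **sample** (n−1) standard deviation and
k = 2 by default; this is the variant that reproduces the published
regional screen, and it is invariant under positive affine transforms.
The export–fishing relationship is a Pearson correlation across regions
after excluding flagged ones, with a two-sided t-test p-value (df = n−2).
Rounding (2 dp means, integer percentages) happens only in the report
layer.

One caveat worth knowing: a printed regional table rounded to 2 dp can
contain ties that the unrounded data did not have, so ranks regenerated
from printed values can differ from printed ranks exactly at those ties.

## Catch dominance

Per region and categorization (gear or species group), shares are exact
tonnage fractions sorted descending, with ties broken by category code for
determinism. The dominant set is the shortest descending-order prefix whose
cumulative share reaches the threshold (default 50%); selection always uses
exact fractions, and rounding to integer percent happens only when
formatting, which avoids artifacts for regions sitting right at 50%.
Unknown-gear/unknown-fish codes (`UG`, `UF`) are ordinary categories.

## The synthetic generator

The generator stands in for a satellite-driven export climatology and a
vessel-tracking effort map. What it emulates:

* **Spatial autocorrelation.** Fields are seeded white noise convolved
  with a Gaussian kernel (σ = `correlation_length`, default 6°, truncated
  at ±3σ; periodic in longitude, clamped at the poles), then standardized.
  Convolution rather than spectral synthesis: simpler, grid-agnostic, and
  deterministic across platforms for a fixed seed.
* **Positivity and skew.** NPP and fishing are exponentiated Gaussian
  fields (log-normal). Defaults: log-NPP mean 5.7 (median ≈ 300
  mg C m⁻² day⁻¹, consistent with a ~50 Gt C yr⁻¹ global NPP), SD 0.7;
  log-fishing mean −1.8 (median ≈ 0.17 h km⁻² yr⁻¹, of the order of
  observed regional means), SD 1.5 (effort is far more skewed than
  productivity).
* **Tunable coupling.** log-fishing is `ρ·S + √(1−ρ²)·N⊥` where `S` is the
  standardized log-NPP driver and `N⊥` an independent smoothed field
  *empirically orthogonalized* against `S` over ocean cells. The realized
  log-space correlation therefore equals the configured ρ exactly (before
  coastal enhancement), not just in expectation — parameter recovery is
  structural, and Monte-Carlo checks measure the pipeline, not generator
  sampling noise. Default ρ = 0.6, a strong but imperfect coupling of the
  kind regional-scale correlations suggest.
* **Coastlines and coastal enhancement.** Land is thresholded smooth noise
  (default 29% land), so coastlines are irregular; both NPP and fishing
  are multiplied by `coastal_boost` (default 2) within one correlation
  length of land, reproducing the coastal co-concentration of both
  services.
* **Masking semantics.** Export drivers are invalid poleward of
  `ice_mask_poleward_of` (default 70°, an ice/cloud retrieval analogue) and
  on land; fishing is observed over the entire ocean, including under the
  ice line (those cells simply fall outside the export-defined analysis
  domain).
* **Regions and catch.** The ocean is partitioned into `n_regions`
  (default 19) by nearest seed point under great-circle distance — every
  region is non-empty by construction. Catch tonnage per region is
  log-normal, allocated across the gear × group vocabularies as the outer
  product of two Dirichlet draws; the concentration parameter moves the
  tables from single-category dominance (small values) to near-uniform
  shares (large values).

What it does **not** emulate: seasonal cycles, bathymetry and shelf
topography, exclusive-economic-zone geometry, vessel-level track structure,
or the latitudinal organization of real productivity (log-NPP is
latitude-free by design, which keeps the independence baseline of the
overlap statistic clean). Passing tests on synthetic worlds therefore
demonstrate the correctness and calibration of the *statistics*, not the
realism of any particular map.

## Problem sizes and numerical tolerances

The default validation suite runs the stochastic overlap checks at 4°
resolution (≈ 2,900 ocean cells per world; 200 worlds for the independence
baseline, 50 per coupling level for monotonicity) and the
coupling-recovery check at 2° (≈ 11,500 ocean cells), sizes at which every
check completes in seconds on one CPU. Determinism contracts are exact
(bit-identical reruns); conservation identities are asserted at 1e−6
(sphere area) and 1e−12 (regrid integral) relative error; the zero-variance
guard in the log-z transform treats a standard deviation below
`1e−12·(1+|mean|)` as zero to absorb floating-point accumulation noise.

## Known limitations

* Real FAO polygon boundaries are not bundled; regional analysis takes any
  gridded integer mask (rasterize official boundaries yourself) or a
  pre-aggregated per-region table.
* The overlap statistic is a quartile intersection only — no spatial
  autocorrelation correction or hotspot significance testing, by design.
* Sequestration is a single fraction applied to the export total, not a
  temperature-dependent transfer model.
* NetCDF output uses the classic (NetCDF-3) format via xarray's scipy
  engine.
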