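# Methods

This note documents the models, the synthetic study design, and the
numerical and design choices behind `mopane_es`. It is the package's own
account; every number quoted as an output here is computed by the test
suite or by `scripts/acceptance.py`, not asserted.

## The analysis in one paragraph

Charcoal production in Mopane woodlands removes large stems of a handful
of preferred species, so its footprint on other provisioning services
(firewood, construction wood, wild food, medicinal plants, grass) depends
on which species and stem sizes each service draws on. The pipeline
estimates, for each village landscape, the standing availability of six
services through *ecological production functions* — maps from woodland
structure (stem density, diameter distribution, species composition) to a
biophysical service quantity — and then brackets the charcoal history with
two counterfactuals: **no charcoal** (every observed cut stem of a
charcoal species modelled as intact) and **total charcoal** (every live
charcoal-suitable stem modelled as cut).

## Inventory metrics

- **DBH correction.** Diameters measured away from 1.3 m are corrected
  with a linear taper, `d(1.3) = d(pom) · (1 − τ·(1.3 − pom))`, τ
  configurable (default 0.02 per m), clamped at zero. This is the
  simplest invertible taper; the stump-to-DBH reconstruction used by the
  no-charcoal scenario is its exact inverse, so a stump measured at
  height *h* with diameter *d* projects to `d·(1 − τ·(1.3 − h))`.
- **Stem biomass.** Power-law allometry `agb = a·dbh^b` with defaults
  a = 2.65·10⁻⁵ Mg C, b = 2.601 (documented to Ryan et al. 2011, southern
  African dry woodland). Coefficients are configuration, not results.
- **Diversity.** Richness counts distinct species among live intact
  stems; evenness is Pielou's J on species AGB shares (the source table
  says only "evenness (index)"; J on AGB shares is our documented
  assumption), defined as 1 when richness ≤ 1.
- **Grass.** Mean over four 1 m² quadrats of fresh mass × oven-dry
  fraction, g·m⁻² → Mg·ha⁻¹ (×0.01). Recently burnt plots return NaN and
  are excluded from grass means rather than erroring.
- **Coarse woody debris.** Line-intersect estimator
  `V = π²/(8L)·Σdᵢ²·10⁴` (d, L in m; V in m³·ha⁻¹) over four 20 m
  transects, converted to carbon with a decay-class wood-density table
  (defaults 0.65…0.20 Mg·m⁻³ for classes 1–5) and carbon fraction 0.47.
- **Standard errors** are sample SD/√n over plots, suppressed when n < 4
  (the source's reporting rule for sparse cells); suppressed SEs
  propagate as zero and flag the estimate `se_complete = False`.

## Woodland typology

Plots are compared on relative AGB shares per species (rows sum to 1;
plots with no live stems are excluded and typed from their sampling
stratum). The legend is an average-linkage tree on Bray–Curtis
dissimilarities; the number of types is selected by the
Calinski–Harabasz criterion over seeded k-means partitions of the raw
abundance rows (25 restarts per k, ties toward smaller k). Clusters are
named by matching them to the legend's indicator species
(A. johnsonii → Androstachys forest, C. mopane → Mopane woodland,
Combretum spp. → Combretum woodland, B. albitrunca → Boscia woodland,
Aloe spp. → shrub Mopane) with a Hungarian assignment on mean indicator
shares.

For the village upscaling the pipeline fixes k to the land-cover legend
size (five woodland classes) and reports the CH-selected k alongside
(`typology.json`, manifest): on unbalanced designs with very small types
(three shrub Mopane plots in the default study) the CH optimum can merge
a small cluster, which would orphan a land-cover class in the
area-weighted totals. On the balanced recovery design (30 plots/type) CH
selects k = 5 for the large majority of generation seeds; a ~7% tail of
seeds selects 6 by splitting the most diffuse cluster, an intrinsic
property of the criterion under unequal cluster spreads.

## Production functions and upscaling

Each tree service is defined by a species set and a diameter band
(defaults: charcoal ≥ 10 cm; firewood 5–20 cm; construction 5–15 cm;
food and medicine ≥ 5 cm — the source's species-use supplement prints no
size criteria, so bands are loud configuration). Biomass services sum
allometric AGB of live intact linked stems in band per hectare; food and
medicine count such stems (stem density). Cut stems provide nothing.

Grass cannot be tied to species, so a maximum-potential envelope is
fitted: a quantile regression (default q = 0.9, linear; exponential form
available) of measured grass biomass on live stem density over unburnt
plots. Positive fitted slopes are clamped to a flat envelope (the
relationship is meant to be non-increasing — denser canopies shade out
grass); predictions are clamped non-negative and to the fitted density
range (extrapolation guard, logged).

Per-plot per-ha values are amalgamated within chronosequence classes
(post-boom, boom, pre-boom) per woodland type — pooling plots across the
villages of a class to raise sample sizes — and upscaled to each village:
`value = Σ_type area·fraction·mean`, `se = √Σ(area·fraction·se)²`
(independence between types), over a village landscape of π·5² km² =
78.54 km² = 7 854 ha by default. A nonzero land-cover fraction with no
parameter cell is a hard error listing the gaps.

## Scenarios

Both counterfactuals are selective harvests (non-charcoal species
untouched), applied per plot and pushed back through the amalgamation and
upscaling, keeping the current typology labels and grass envelope.
Percent changes use first-order (delta-method) propagation treating
current and counterfactual estimates as independent — a fidelity choice
mirroring the source analysis even though the two share plots; a
Monte-Carlo resampling alternative sits behind `use_monte_carlo_ci`. A
current value of zero yields an undefined percent (NaN) with the absolute
change reported. Cut stems created by total charcoal leave stumps but do
not increment the CWD pool (harvest-residue modelling is out of scope).

Structural guarantees, all tested: total charcoal drives charcoal
availability to exactly −100% wherever current availability is positive;
no scenario moves any tree service in the wrong direction; food/medicine
losses are bounded by their stem overlap with the charcoal function; and
no-charcoal-after-total-charcoal restores charcoal availability exactly
on plots without pre-existing stumps (the generator cuts stems with the
same taper the reconstruction inverts).

## Synthetic study design

The generator emulates the study: seven villages (A–G) in three
chronosequence classes, per-village post-exclusion plot counts
(23, 23, 20, 19, 23, 23, 23; 154 total), five woodland types with the
published structural means as parameters (stem density 1764/769/639/582/
103 ha⁻¹; AGB 31.7/11.8/12.8/5.4/7.31 Mg C·ha⁻¹; grass 0.06/0.66/1.06/
0.79/0.34 Mg·ha⁻¹; CWD 3.57/0.90/0.98/0.72/0.02 Mg C·ha⁻¹), and a
species–service linkage table with the published cardinalities (6
charcoal, 5 firewood sharing 3, 10 construction, 21 food, 39 medicine;
C. mopane in all five).

Choices where the sources are silent, made once and frozen:

- **Diameters** are per-type lognormals truncated at the 5 cm inventory
  threshold, with the location solved in closed form so that mean
  per-stem biomass × density reproduces the type's AGB. Spread
  parameters are σ = 0.50–0.55 for the stem-rich types and 0.20 for
  shrub Mopane: broad, comparable within-type compositional variances
  keep the clustering criterion from splitting a single diffuse type,
  and the tight shrub spread reflects that type's strong single-species
  dominance (published evenness 0.34). The shrub pool is C. mopane 0.65 /
  Aloe spp. 0.35 — mopane carries the biomass, Aloe is the indicator.
- **Cut stems**: a per-class fraction (0.35 post-boom, 0.15 boom, 0.05
  pre-boom, 0 for village G) of charcoal-suitable stems (charcoal species,
  ≥ 10 cm) is flagged cut, with stump diameter inflated from the DBH by
  the inverse taper — magnitudes are free parameters ordered by the
  chronosequence narrative; the published 89–99% post-boom gains are not
  reproducible without the microdata, and the defaults yield ~45%.
- **Grass** is drawn around the type mean (lognormal, CV ≈ 0.3, split
  over four quadrats with dry fractions U(0.35, 0.55)); CWD piece counts
  are Poisson with the rate solved so expected line-intersect carbon
  equals the type mean. A separate envelope-calibration generator draws
  (density, grass) pairs from a known decreasing linear envelope with
  Beta(5,1) utilisation noise (0.9-quantile ≈ 0.979 of potential), so a
  q = 0.9 fit recovers the slope almost exactly.
- **Survey counts** are binomial draws from class-level use
  probabilities; **trend labels** derive from the generator's own cut
  fractions. The published household and trend tables ship as package
  data and are used directly for the printed-data recomputation.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: spatial autocorrelation and landscape
pattern (land cover enters as a composition table), per-species size
distributions, coppicing/regrowth, measurement error in species
identification, and any dependence between the survey and the plots.

## Problem sizes and runtime

Default verification scales, chosen to keep the whole suite and the
acceptance script in seconds on one CPU: 154-plot study datasets for the
end-to-end paths; 200 plots/type for structural-mean recovery; 30
plots/type for typology recovery; 150 plots for the envelope; 10⁵ draws
for Monte-Carlo oracles (agreement with closed forms asserted at 5%).
The structural-recovery criterion (means within Monte-Carlo error at 200
plots/type) is asserted family-wise across the 15 type × metric cells
(per-cell |z| ≤ 2.93, a Bonferroni 95% statement; a per-cell 2-SE rule
would false-alarm on roughly half of all seeds with no bias present).

## Known limitations

- The source study's exact DBH-correction function, production-function
  equations and species size criteria are not publicly available; every
  stand-in here (linear taper, bands, envelope form) is isolated in
  configuration and flagged.
- Biomass services report standing stock (Mg C); no kiln-yield,
  dry-mass conversion or monetary valuation.
- The independence assumption in scenario CIs overstates uncertainty
  when current and counterfactual share plots; the Monte-Carlo flag
  inherits the same assumption (it resamples the two estimates
  independently) and differs only in distributional shape.
- Standing dead uncut stems provide no service and are not added to CWD;
  only fallen pieces on transects count as necromass.
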