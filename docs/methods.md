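# Methods

`nemafauna` implements the faunal-analysis toolkit used to read soil
condition off nematode communities, together with the co-occurrence-network
and multivariate statistics that typically accompany it in field studies,
and a seeded synthetic-data generator that reproduces the statistical
structure such studies assume. This note records the models, the defaults
and their rationale, the numerical choices, and what the synthetic tests do
and do not demonstrate.

## Community model and observation process

A sample is a map genus → abundance expressed as individuals per 100 g dry
soil: an extracted count `c` from `m` grams of dry soil becomes `c·100/m`.
Identification happens on a fixed-size subsample (typically 100 individuals)
whose genus counts allocate the per-100 g total proportionally, so genus
abundances are real-valued and sum exactly to the total. Absent genera are
zeros, not missing values — community tables are rectangular after
alignment. Every genus is classified by a trait table: trophic group
(bacterivore Ba, fungivore Fu, plant parasite Pp, omnivore/predator Op),
colonizer–persister value (c-p, an integer life-history score from 1 =
extreme opportunist to 5 = persister), and fresh body weight in µg.

The packaged 46-genus trait fixture (19 Ba, 6 Fu, 9 Pp, 12 Op) is reference
*data*, not code: trophic groups and c-p values follow the standard
Yeates/Bongers conventions, except for a few genera (`Filenchus` under Fu,
`Tylenchus` and `Psilenchus` under Pp) that are encoded as the community
they were curated for uses them. Fresh weights are plausible
literature-scale values; published studies rarely print the weights they
used, so absolute footprint magnitudes are comparable only within a fixed
trait table, never across tables. Users override the fixture by supplying
their own delimited file. Each genus carries one c-p value and one weight
(no intra-genus variation), matching the per-taxon footprint formula.

## Ecological indices

With `f(i)` the proportion of taxon `i` within its reference set and `v(i)`
its c-p value:

- **MI** (maturity index) = Σ v(i)·f(i) over free-living taxa (Ba, Fu, Op),
  on the full c-p 1–5 scale. An `include_cp1=False` switch gives the MI2–5
  variant; it is not the default.
- **PPI** = the same weighted mean restricted to plant-parasitic taxa.
- **WI** = (Ba+Fu)/Pp, **NCR** = Ba/(Ba+Fu), on trophic-group abundances.
- **EI** = 100·e/(e+b), **SI** = 100·s/(s+b), where e, b, s are weighted
  guild sums: enrichment e over Ba1 and Fu2, basal b over Ba2 and Fu2,
  structure s over Ba3–5, Fu3–5, omnivore c-p 3–5 and predator c-p 2–5.
  Note Fu2 deliberately contributes to **both** e and b, following the
  component definitions as commonly stated; users who prefer a disjoint
  enrichment component can pass their own `GuildWeights`.

Default guild weights are the canonical faunal-profile set — Ba1 = 3.2,
Ba2 = Fu2 = 0.8, c-p 3/4/5 = 1.8/3.2/5.0 — and are fully configurable,
since published analyses name the guilds more often than the weights.
Because this package merges omnivores and predators into one Op group, the
structure component takes Op c-p 3–5 at the c-p-class weights, and a c-p 2
taxon enters the structure component (at weight 0.8) only when its trait
record is flagged `predator`. This is a recorded design choice, not a claim
about any particular study's intent.

An index with a zero denominator (no free-living taxa for MI, no plant
parasites for PPI/WI, no microbial feeders for NCR, e+b = 0 for EI) is NaN —
an explicit missing value, never 0 — and must be dropped before ANOVA;
`one_way_anova` refuses NaN input rather than silently absorbing it.

## Metabolic footprints and the faunal profile

The footprint of taxon t is `N_t·(0.1·W_t/m_t + 0.273·W_t^0.75)` — a
respiration term scaled down by life-history rank plus a production term in
body mass to the 3/4 power. Footprints sum within trophic groups (BaF, FuF,
PpF, OpF) and over life-history classes: enrichment footprint Fe (c-p 1–2)
and structure footprint Fs (c-p 3–5). Both partitions reconstruct the total
footprint exactly; the conservation is tested to 1e-9 relative tolerance on
1,000 random communities. Fe/Fs include all taxa by default (the c-p
classes are defined without a trophic restriction); a `free_living_only`
switch exists.

The functional metabolic footprint is the area of the rhombus centred on
the faunal-profile point (SI, EI) with half-diagonals 0.5·Fs/k horizontal
and 0.5·Fe/k vertical; the four vertices are connected in convex order
(left, top, right, bottom) so the enclosed area equals the closed form
Fe·Fs/(2k²) — verified against the shoelace evaluation on 10,000 random
draws. k is a unit-conversion constant, default 1; axes auto-scale in the
plot, so k matters only for cross-study comparability. Quadrant labels read
off (EI, SI) alone: A (EI>50, SI≤50), B (both >50: enriched, structured,
mature food web), C (EI≤50, SI>50), D (both ≤50); a value of exactly 50
falls in the lower quadrant on that axis — ties are not otherwise defined
anywhere, so this boundary rule is the package's own.

## Co-occurrence networks

Spearman correlations between genera are computed across samples on
relative abundances (per-sample proportions), with two-sided p-values from
`scipy.stats.spearmanr`. Genera with zero variance across samples have no
defined rank correlation and are dropped with a warning. An edge joins two
genera when |r| > 0.6 and p < 0.05 (both thresholds configurable); the
absolute-value reading is the default because negative co-occurrences are
ecologically meaningful and commonly reported, with a signed-threshold
option. No multiple-testing correction is applied by default, matching
common practice for these descriptive networks; a Benjamini–Hochberg step
can be added by filtering the p matrix beforehand. Isolated nodes are
dropped by convention (option to keep).

Metrics: average degree 2E/N, density 2E/(N(N−1)), positive/negative edge
fractions, and two "connectivity" readings (density × 100 and the average
degree) reported side by side because the term has no single convention.
Hub ("controlling") taxa are ranked by degree within each trophic group,
ties broken by summed |r| then lexicographically. Per-treatment networks
subset samples by treatment label first; with only 3 replicates per
treatment a Spearman edge can barely reach p < 0.05 at |r| > 0.6, so the
module warns below 6 samples rather than refusing — the warning, not a
hard floor, is the design choice, since the subsetting itself is standard.

Planted-structure validation: tables with two equicorrelated blocks
(latent Gaussian one-factor blocks at pairwise ρ = 0.9, exponentiated so
ranks carry the structure exactly) at n = 12 samples give ≥ 90%
within-block edge recovery with ≤ 5% between-block false edges over 100
seeds; the false-edge rate sits near 4.4% because the |r| > 0.6 cut at
n = 12 is itself close to the 5% two-sided critical value (0.587).

## Statistics

- **ln(x+1)** precedes ANOVA on abundances; indices and footprints are
  tested untransformed.
- **One-way ANOVA** is computed from sums of squares directly (the group
  means and MS_within feed Duncan's test); it matches `scipy.stats.f_oneway`
  to machine precision in the tests.
- **Duncan's multiple range test**: means sorted descending; a stretch of p
  means is homogeneous when its range ≤ R_p = q(1−α_p; p, df)·√(MS_w/n)
  with protection level α_p = 1−(1−α)^(p−1); quantiles from
  `scipy.stats.studentized_range` (cached), harmonic-mean n for unequal
  groups. The protection rule (no pair inside a homogeneous stretch is
  declared different) is applied top-down, and letters are assigned from
  the maximal homogeneous stretches, guaranteeing the containment property.
  For two groups the decision provably coincides with Fisher's LSD
  (q(α;2,df) = √2·t(α/2;df)), which the tests exercise on 500 random
  datasets.
- **Bray–Curtis** is the default community dissimilarity (Euclidean
  available via `euclidean_distance`), cross-checked against
  `scipy.spatial.distance.braycurtis`.
- **PCoA**: Gower double-centering of −½D², symmetric eigendecomposition,
  coordinates from positive eigenvalues only. Negative eigenvalues (normal
  for the semimetric Bray–Curtis) are reported but excluded; explained
  fractions are over the positive part, with a Lingoes-correction option.
  On Euclidean distance matrices the configuration is recovered up to
  rotation/reflection to < 1e-8 (and eigenvalues match PCA exactly);
  cross-checked against scikit-bio's implementation in the tests.
- **Mantel**: Spearman (default) or Pearson correlation of lower-triangle
  distances; p = (1+#{r_perm ≥ r_obs})/(n_perm+1) under label permutations
  of one matrix, so the attainable floor is 1/(n_perm+1). Permutations are
  vectorised and fully seeded. Under independence at n = 12 the measured
  type-I rate at α = 0.05 is within Monte-Carlo error of 0.05 over 500
  simulated pairs.

## Synthetic scenarios

The default scenario emulates a 4-treatment × 3-replicate cover-crop field
design: CK (bare soil control), C2/C4/C8 (2/4/8 cover-crop species).
Genus abundances are negative-binomial (variance μ + μ²/θ, θ = 10 — field
nematode counts are overdispersed; a Poisson switch exists for
exact-variance tests) around baselines that spread realistic group totals
(Ba 200, Fu 80, Pp 70, Op 50 per 100 g) across the 46-genus pool with the
three dominant genera (*Aphelenchoides*, *Eucephalobus*, *Rhabditis*)
weighted 3×. Treatment multipliers plant the qualitative cover-crop
pattern: all cover treatments lift Ba by 1.3, fungivores ×1.6 under C4/C8,
plant parasites ×1.4 under C2/C8, omnivores mildly (+10%) under C4/C8.
Under these defaults, ANOVA on ln(x+1) fungivore abundance detects the
planted effect in ≈ 85% of seeds (measured over 200), and with all
multipliers at 1 the rejection rate sits at the nominal α.

Identification subsampling is a multinomial draw (default 100 individuals)
followed by proportional re-expansion. Soil covariates (SMC, pH, SOC,
NO₃-N, NH₄-N, TN, C/N, MBC, MBN, cover-crop and weed biomass) are baseline
+ treatment shift + coupling·z(trophic-group abundance) + Gaussian noise;
defaults couple MBC to bacterivores and SOC/NO₃-N/MBN to fungivores. All
streams derive from one scenario seed through `SeedSequence` spawning; no
global random state is used.

**What the generator does not emulate**: spatial autocorrelation between
plots, temporal dynamics, genus-level (rather than group-level) treatment
responses, taxonomic misidentification, and mechanistic soil chemistry —
covariate couplings are statistical, not causal. Passing tests therefore
demonstrate the correctness and calibration of the estimators under the
assumed sampling model, not their field performance.

**A measured limitation worth knowing**: at the default observation noise
(NB θ = 10 plus a 100-individual subsample) the community–environment
Mantel test at n = 12 has only ≈ 55–60% power, even in the limit of
noiseless, maximal covariate coupling — genus-level Bray–Curtis geometry is
dominated by sampling noise that group-level covariates cannot track. The
coupling-detection test therefore demonstrates the capability under a
low-observation-noise configuration (Poisson counts, 500-individual
subsample: ≈ 92% measured power). Field designs with 3 replicates per
treatment should expect the same limitation.

## Problem sizes used in the validation suite

Index/footprint oracle agreement: 1,000 random communities (tolerance 1e-12
relative; footprint conservation 1e-9). Rhombus-area identity: 10,000
draws. Network recovery: 100 seeds × 12 samples. Duncan/LSD agreement and
containment: 500 datasets each. PCoA inversion: 100 seeds × 10 points.
Mantel calibration: 500 pairs × 999 permutations. ANOVA power: 200 seeds.
These sizes keep the whole suite under a minute on one CPU while leaving
Monte-Carlo error well below the margins being tested.
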