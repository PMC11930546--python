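# Methods

## Constant-hazard survival model

Larval lifetimes are modelled as exponential with hazard *b* (deaths per
individual-day).  With *d* observed deaths and total exposure *E* (each
death contributes its time to death, each censored individual its full
observation time), the censored-exponential log-likelihood is
*d* log *b* − *bE*, maximised at the person-time estimator *b̂* = *d/E*.
A cohort under constant hazard halves at *H* = ln 2 / *b*, and the drift
index is *D* = *H·V* for a current velocity *V*.

Conventions and numerical choices:

* **Sign convention.**  *b* ≥ 0 throughout and *H* = ln 2 / *b*.  (The
  survival identity 0.5 = e^{−bH} is sometimes written with a negative
  rate; reported mortality rates are positive, so the positive-rate form
  is used.)
* **Confidence interval.**  Exact (Garwood) two-sided Poisson interval for
  the death count — lower qχ²(α/2, 2d)/2, upper qχ²(1−α/2, 2d+2)/2 —
  divided by exposure.  Zero deaths give a one-sided interval with lower
  bound 0.  The interval maps to half-life and distance through ln 2/*b*
  (order-reversed, the map being decreasing) and ×*V*.
* **Death-time attribution.**  A death is recorded at the inspection at
  which it is observed (no midpoint imputation).  On a 2-day inspection
  grid this overstates exposure by at most one inspection interval per
  death; at hazards near 0.02/day the induced bias in *b̂* is ~2–3%,
  well inside the estimator's sampling noise at cohort sizes of 30.
* **Pooling** sums deaths and exposures across replicates (never averages
  rates), which is again the MLE on the pooled data.
* **Reporting precision.**  Rates are displayed to 3 decimals; half-lives
  are truncated to whole days and displayed drift is (truncated half-life)
  × *V*, so displayed rows satisfy drift = 50 × half-life exactly.  Full
  precision is retained internally.
* **Default velocity** *V* = 50 km/day — the upper range of the seasonal
  north-flowing Davidson Current; configurable everywhere it appears.

The estimator is validated three ways: agreement with a generic numerical
maximiser of the censored-exponential likelihood (20 random data sets,
1e-6 relative tolerance); ≥90% empirical coverage of the true hazard by
the 95% CI over 500 simulated cohorts (30 larvae, hazard 0.02/day, 58-day
horizon, 2-day inspections); and mean hazard recovery within 10% over the
same cohorts.

## Population-genetic estimators

Genotypes are 0/1/2 alternate-allele copies with a missing sentinel;
missing genotypes are excluded site-wise from every estimator.

* **Site filter.**  Sites with more than 20% missing genotypes are
  removed (the same rule applied to the deposited ddRAD data before
  analysis); filtering is idempotent and leaves individuals untouched.
* **Diversity.**  H_O is the mean over sites of the heterozygote fraction.
  H_S and H_T use Nei/Nei–Chesser sample-size-corrected gene diversities
  with the harmonic-mean sample size across populations; F_IS = 1 −
  H_O/H_S (Nei convention).  A monomorphic panel yields H_S = H_T = 0 and
  an undefined (None) F_IS rather than an error.
* **F_ST.**  Per-site Weir–Cockerham (1984) variance components a, b, c
  with unequal sample sizes; the multi-locus estimate is the ratio of
  summed components Σa/Σ(a+b+c), not a mean of ratios.  Negative
  estimates are retained in computation and clamped to zero only in
  display tables.  Pairwise values are multi-locus θ on the two-population
  subset; significance comes from shuffling individuals between the pair
  (B = 999 by default, p = (1 + #{θ* ≥ θ})/(B + 1)).
* **Tajima's D.**  Computed on the pooled sample: π is summed over sites
  from each site's own allele counts (2·c_alt·c_ref/(n_s(n_s−1))); the
  normalising constants a₁…e₂ use a single conservative n = 2 × (minimum
  per-site count of genotyped diploids).  D is flagged undefined when no
  site segregates.
* **AMOVA.**  Four levels: between range (north/south of a split latitude,
  default 40.44°N at Cape Mendocino), between populations within range,
  between individuals within populations, within individuals.  Sums of
  squares use the squared-Euclidean allele-mismatch form on 0/1 allele
  copies, which is additive over unlinked sites and computable from group
  allele counts alone (hence phase-free).  Variance components solve the
  nested-ANOVA expected sums of squares; with missing data the expectation
  coefficients are computed per site from that site's group sizes and
  summed, which is exact when missingness is independent of genotype.
  Negative components are retained and percentages always sum to 100.
  Permutation tests per level: populations shuffled across regions;
  individuals shuffled across populations within regions; allele copies
  shuffled among individuals within populations (this last tests the
  within-individual component one-sided for deficiency, i.e. excess
  homozygosity).
* **Isolation by distance.**  OLS of pairwise F_ST on pairwise haversine
  great-circle distance (Earth radius 6371 km) over the unique population
  pairs, reporting slope, intercept, adjusted r² and the OLS t-test p.
  Pairs are not independent observations; an optional Mantel permutation
  p-value is provided for that reason.
* **PCA.**  SVD of the mean-imputed, column-centred genotype matrix with a
  deterministic sign convention (largest-magnitude loading positive).

Each non-trivial estimator is tested against an independent brute-force
oracle on toy matrices (literal transcriptions of the published component
formulas, distance-matrix sums of squares, normal equations) to 1e-9, and
against distributional references: the panmictic null (mean θ within
±0.02 of zero; permutation p-values uniform to Kolmogorov distance < 0.1)
and the island-model equilibrium (mean θ within 30% of 1/(1 + 4Nm)).

## Synthetic data

The generator works at the level of per-site allele frequencies (binomial
Wright–Fisher resampling of unlinked sites — appropriate for a
one-SNP-per-RAD-locus panel) rather than sequences; there is no linkage,
no selection, and no read-level error model, so passing tests demonstrate
estimator correctness and scenario-level signatures, not robustness to
RAD-specific artefacts.

* **Survival experiments.**  Exponential lifetimes per treatment hazard,
  observed on the inspection grid (death recorded at the first inspection
  ≥ the true death time, survivors censored at the horizon).  Defaults
  emulate the 58-day design: three treatments (12 °C dark, 20 °C dark,
  20 °C diel), two dishes of five larvae each, 2-day inspections, with
  per-treatment hazards 0.015/0.036/0.024 per day chosen to match the
  observed ordering (coldest slowest, 20 °C dark fastest) and a pooled
  rate near 0.022/day.
* **Invasion panels.**  8 demes × 7 sampled diploids, 926 sites, ancestral
  frequencies Beta(0.5, 0.5) (U-shaped, ascertainment-like), 10% missing
  genotypes (a fixed per-site count at random rows, so a ≤20% target
  never loses sites to the 20% filter).  *single_founder*: one bottleneck
  of 10 diploids, 40 generations of growth at ×1.35 per generation
  (roughly one generation per year since the early-1980s arrival), then a
  recent 5-generation split into demes of 50 exchanging migrants at rate
  0.2 with the common pool — multi-locus θ ≈ 0.02.  *independent_sources*:
  each deme founded independently by 10 diploids and drifting in
  isolation for 40 generations at size 50 — θ ≈ 0.36.  Sites monomorphic
  among observed genotypes are redrawn.  Deme coordinates follow the
  sampled coastline transect (Morro Bay → Sitka, ~3000 km).  No
  historical-realism claim attaches to these sizes and times; they are
  chosen so each scenario reproduces its qualitative signature at desk
  scale with wide margins.
* **Expansion signature.**  Founder bottleneck, growth ×1.35/generation
  (capped at 10 000), and each generation Poisson(0.3 × 2N) new mutations
  entering at frequency 1/(2N) with lost sites pruned.  The mutational
  influx 0.3 per allele copy per generation is a panel-scale dial, not a
  genomic mutation rate: it makes young rare alleles dominate a
  ddRAD-panel-sized set of segregating sites, giving Tajima's D ≈ −1 and
  D < 0 in ≥90% of seeded runs.  With growth 1 and injection enabled the
  same machinery relaxes to a neutral mutation–drift equilibrium at
  constant size (mean D ≈ 0), which anchors the sign convention.

Identical configs and seeds give byte-identical outputs; all seeds are
explicit and surfaced in the pipeline manifest.

## Problem sizes

The calibration experiment uses 500 cohorts; scenario discrimination uses
50 paired simulations at the full panel size (56 × 926) with B = 99
permutations for the between-range AMOVA test; the expansion signature
uses 50 runs.  These sizes keep the whole suite and the acceptance script
in the minutes range while leaving the pass margins (typically ≥98% where
90–95% is required) far from the thresholds.

## Known limitations

* The real study's numeric estimates (e.g. H_O = 0.04, F_IS = 0.89,
  D = −3.49 on the deposited panel) require the raw sequence reads and the
  upstream assembly pipeline; they are out of scope here.  The synthetic
  single-founder panels are near Hardy–Weinberg within demes, so they do
  not emulate the strong heterozygote deficit of the real data.
* Tajima's D uses a single pooled-sample n; site-wise constants averaging
  is not implemented.
* The AMOVA missing-data treatment assumes missingness independent of
  genotype (as the generator produces); informative missingness would
  bias the per-site expectation coefficients.
* The drift index is a fixed-velocity upper-bound heuristic, not an ocean
  circulation model.
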