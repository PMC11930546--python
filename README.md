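# invadrift

Tools for asking how a parasite with a short-lived, non-feeding larva managed
to colonise 3000 km of coastline.  The package re-implements, as a tested
library, the two bespoke analyses behind that question for the bopyrid isopod
*Orthione griffenis*, a parasite of mud shrimp that invaded the northeast
Pacific:

1. **Larval survival → drift dispersal.**  From interval-censored laboratory
   survival experiments on cryptoniscan larvae, estimate the constant
   mortality hazard *b* (deaths per individual-day) by the person-time MLE
   *b* = deaths / exposure, attach an exact (Garwood) Poisson confidence
   interval to the death count, and propagate to the cohort half-life
   *H* = ln 2 / *b* and the passive-drift dispersal index *D* = *H·V* at a
   prevailing coastal current velocity *V* (default 50 km/day, a strong
   Davidson Current).

2. **Population-genetic summaries of invasion history.**  From diploid
   biallelic SNP panels (VCF + population map): observed heterozygosity and
   Nei gene diversities (H_O, H_S, H_T, F_IS), Weir–Cockerham θ (per SNP,
   multi-locus, and pairwise with permutation significance), Tajima's D,
   hierarchical AMOVA with a north/south range level and permutation tests,
   isolation-by-distance regression on great-circle distances, and genotype
   PCA.

A seeded synthetic-data module generates both kinds of input: exponential
lifetimes observed on an inspection schedule, and Wright–Fisher
founder-invasion SNP panels under two contrasting demographies — a
**single founder** population spreading with high along-coast gene flow
(predicting F_ST ≈ 0 and no range subdivision) versus **independent
sources** founding each population separately (predicting strong
differentiation) — plus a post-bottleneck expansion generator whose
site-frequency spectra give negative Tajima's D.

## Worked example

Five larvae, two dying at day 7 and three at day 10:

```python
from invadrift import (SurvivalRecord, TreatmentLabel, estimate_mortality,
                       half_life, dispersal_distance)

t = TreatmentLabel(20.0, "dark")
records = [SurvivalRecord(f"i{k}", "r1", t, "died", d)
           for k, d in enumerate([7, 7, 10, 10, 10])]
est = estimate_mortality(records)
est.exposure, est.rate_b        # (44.0, 0.11363636363636363)
half_life(est.rate_b)           # 6.099695188927519 days
```

The exposure is 2×7 + 3×10 = 44 individual-days, so the hazard MLE is 5/44 ≈
0.114 per day and the cohort would halve in about 6.1 days.

A full simulated 58-day experiment (three treatments, two dishes of five
larvae, 2-day inspections) and its report:

```python
from invadrift import SurvivalSimConfig, simulate_survival, summarize_experiment
report = summarize_experiment(simulate_survival(SurvivalSimConfig(seed=1)))
print(report.to_display()[["treatment", "deaths", "rate_b",
                           "half_life_days", "drift_km"]].tail(1))
#   treatment  deaths  rate_b  half_life_days  drift_km
#      pooled      22   0.022              31    1550.0
```

At the pooled rate 0.022/day the half-life truncates to 31 whole days, i.e.
1550 km of passive drift at 50 km/day; the Poisson CI on the rate maps to a
(20, 49)-day half-life interval and (1000, 2450) km of drift.

On the genetic side:

```python
from invadrift import (DemographySimConfig, simulate_invasion_panel,
                       filter_sites_max_missing, wc_fst, diversity_summary)
panel, popmap = simulate_invasion_panel(DemographySimConfig(seed=1))
panel = filter_sites_max_missing(panel, 0.20)
wc_fst(panel, popmap).overall   # 0.0216  (single-founder history: ~no structure)
```

The same panel under `scenario="independent_sources"` gives multi-locus
θ ≈ 0.36 — the contrast that separates the two invasion hypotheses.

Everything is also reachable from the `invadrift` command line
(`simulate-survival`, `simulate-genotypes`, `fit-survival`, `popgen-stats`,
`pairwise-fst`, `amova`, `ibd`, `pca`, `run`).

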