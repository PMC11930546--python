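"""Synthetic survival experiments and founder-invasion SNP panels.

The study system is a parasitic isopod that invaded a ~3000 km stretch of
the northeast Pacific coast.  This module generates the two kinds of data
every analysis stage consumes:

* interval-censored larval survival experiments (exponential lifetimes
  observed on a fixed inspection schedule), and
* diploid biallelic SNP panels for eight coastal populations under two
  demographic scenarios — a **single founder** population that expanded and
  spread with high along-coast gene flow (predicting F_ST near zero and no
  north/south structure) versus **independent sources** in which each
  population was founded separately and drifted in isolation (predicting
  strong differentiation).

Simulation is per-site allele-frequency Wright-Fisher drift (binomial
resampling); sites are unlinked, matching a one-SNP-per-RAD-locus panel.
A third generator produces the post-bottleneck expansion signature — a
site-frequency spectrum enriched for rare alleles, hence negative
Tajima's D — by injecting new mutations into a growing population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .popgen import MISSING, GenotypePanel, PopulationMap
from .survival import SurvivalRecord, TreatmentLabel

__all__ = [
    "SurvivalSimConfig",
    "DemographySimConfig",
    "DEFAULT_TREATMENT_HAZARDS",
    "DEFAULT_DEME_SITES",
    "simulate_survival",
    "simulate_invasion_panel",
    "simulate_island_model_panel",
    "simulate_rare_allele_excess",
]

#: Per-treatment hazards (deaths per individual-day) for the default
#: 58-day design; chosen to match the observed per-treatment mortality
#: rates (12C dark lowest, 20C dark highest, pooled near 0.022).
DEFAULT_TREATMENT_HAZARDS: dict[TreatmentLabel, float] = {
    TreatmentLabel(12.0, "dark"): 0.015,
    TreatmentLabel(20.0, "dark"): 0.036,
    TreatmentLabel(20.0, "diel"): 0.024,
}

#: Eight sampling sites spanning Morro Bay, CA to Sitka, AK (~3000 km of
#: coastline), south to north: (name, latitude, longitude).
DEFAULT_DEME_SITES: list[tuple[str, float, float]] = [
    ("MorroBay", 35.37, -120.85),
    ("TomalesBay", 38.15, -122.90),
    ("HumboldtBay", 40.76, -124.22),
    ("SouthSlough", 43.30, -124.32),
    ("YaquinaBay", 44.62, -124.05),
    ("CalvertIsland", 51.65, -128.02),
    ("Ketchikan", 55.34, -131.65),
    ("Sitka", 57.05, -135.33),
]


@dataclass(frozen=True)
class SurvivalSimConfig:
    """Design of a simulated larval survival experiment.

    Defaults emulate the 58-day design: three treatments, two replicate
    dishes of five individuals each, inspections every ~2 days.
    """

    hazards: dict[TreatmentLabel, float] = field(
        default_factory=lambda: dict(DEFAULT_TREATMENT_HAZARDS)
    )
    replicates_per_treatment: int = 2
    individuals_per_replicate: int = 5
    horizon_days: float = 58.0
    inspection_interval_days: float = 2.0
    experiment_id: str = "sim-58d"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h < 0 for h in self.hazards.values()):
            raise ValueError("hazards must be >= 0")
        if not self.horizon_days > self.inspection_interval_days > 0:
            raise ValueError("require horizon > inspection interval > 0")
        if self.individuals_per_replicate <= 0 or self.replicates_per_treatment <= 0:
            raise ValueError("need at least one individual and one replicate")


def simulate_survival(config: SurvivalSimConfig) -> list[SurvivalRecord]:
    """Exponential lifetimes observed on the inspection schedule.

    A death is recorded at the first inspection at or after the true death
    time; individuals alive at the horizon are censored there.
    Deterministic for a fixed config + seed.
    """
    rng = np.random.default_rng(config.seed)
    records: list[SurvivalRecord] = []
    dt = config.inspection_interval_days
    for treatment in config.hazards:
        hazard = config.hazards[treatment]
        for rep in range(1, config.replicates_per_treatment + 1):
            rep_id = f"{treatment}-r{rep}"
            if hazard > 0:
                lifetimes = rng.exponential(1.0 / hazard, size=config.individuals_per_replicate)
            else:
                lifetimes = np.full(config.individuals_per_replicate, np.inf)
            for i, t in enumerate(lifetimes):
                if t >= config.horizon_days:
                    outcome, day = "censored", config.horizon_days
                else:
                    outcome = "died"
                    day = min(math.ceil(t / dt) * dt, config.horizon_days)
                records.append(
                    SurvivalRecord(
                        individual_id=f"{rep_id}-i{i + 1}",
                        replicate_id=rep_id,
                        treatment=treatment,
                        outcome=outcome,
                        event_day=float(day),
                        experiment_id=config.experiment_id,
                    )
                )
    return records


@dataclass(frozen=True)
class DemographySimConfig:
    """Founder-invasion demography for the SNP panel generator.

    ``single_founder``: one bottleneck of ``founder_count`` diploids drawn
    from the ancestral pool, exponential growth for ``generations``
    generations, then a recent split into ``n_demes`` populations exchanging
    migrants at rate ``migration_rate`` — near-panmixia along the coast.
    ``independent_sources``: every deme is founded independently from the
    ancestral pool and drifts in isolation.  Panel dimensions default to
    the deposited dataset's (8 populations x 7 diploids, 926 SNPs, with
    missing genotypes at ``missingness`` completely at random).
    """

    scenario: str = "single_founder"  # or "independent_sources"
    ancestral_size: int = 10_000
    founder_count: int = 10
    generations: int = 40
    growth_factor: float = 1.35
    n_demes: int = 8
    samples_per_deme: int = 7
    n_sites: int = 926
    missingness: float = 0.10
    migration_rate: float = 0.2
    deme_size: int = 50
    split_generations: int = 5
    beta_a: float = 0.5
    beta_b: float = 0.5
    mutation_injection: bool = False
    mutation_rate_per_copy: float = 0.3
    deme_sites: tuple = tuple(DEFAULT_DEME_SITES)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("single_founder", "independent_sources"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.founder_count > self.ancestral_size:
            raise ValueError("founder_count must be <= ancestral_size")
        if self.n_demes < 2:
            raise ValueError("need >= 2 demes")
        if not 0.0 <= self.missingness <= 0.2:
            raise ValueError("missingness must be in [0, 0.2]")


def _ancestral_frequencies(rng: np.random.Generator, config: DemographySimConfig) -> np.ndarray:
    """U-shaped (SNP-ascertainment-like) ancestral alt-allele frequencies."""
    return rng.beta(config.beta_a, config.beta_b, size=config.n_sites)


def _drift(rng: np.random.Generator, freq: np.ndarray, n_diploid: int) -> np.ndarray:
    """One Wright-Fisher generation: binomial resampling of 2N allele copies."""
    n2 = 2 * max(1, int(n_diploid))
    return rng.binomial(n2, freq) / n2


def _sample_genotypes(rng: np.random.Generator, freq: np.ndarray, n_ind: int) -> np.ndarray:
    """Draw diploid genotypes (alt-copy counts) from deme frequencies."""
    return rng.binomial(2, freq[None, :].repeat(n_ind, axis=0)).astype(np.int8)


def _apply_missingness(rng: np.random.Generator, g: np.ndarray, rate: float) -> np.ndarray:
    """Blank a fixed count round(rate * n) of genotypes per site, at random
    rows.  The per-site missing fraction then never exceeds the target, so a
    panel generated at <= 0.20 missingness survives the 20% site filter
    intact."""
    if rate > 0:
        g = g.copy()
        n_ind = g.shape[0]
        k = int(round(rate * n_ind))
        for j in range(g.shape[1]):
            rows = rng.choice(n_ind, size=k, replace=False)
            g[rows, j] = MISSING
    return g


def _deme_frequencies_single_founder(
    rng: np.random.Generator, config: DemographySimConfig
) -> np.ndarray:
    p = _ancestral_frequencies(rng, config)
    # founder bottleneck: one binomial draw of 2*K founder copies
    p = _drift(rng, p, config.founder_count)
    # expansion: growth by `growth_factor` per generation, capped at the
    # ancestral size; drift weakens as N grows
    n = float(config.founder_count)
    for _ in range(config.generations):
        n = min(n * config.growth_factor, float(config.ancestral_size))
        p = _drift(rng, p, int(round(n)))
    # recent range expansion: demes split from the common pool and exchange
    # migrants with it at a high rate for a few generations
    deme_p = np.tile(p, (config.n_demes, 1))
    for _ in range(config.split_generations):
        pool = deme_p.mean(axis=0)
        for d in range(config.n_demes):
            mixed = (1.0 - config.migration_rate) * deme_p[d] + config.migration_rate * pool
            deme_p[d] = _drift(rng, mixed, config.deme_size)
    return deme_p


def _deme_frequencies_independent(
    rng: np.random.Generator, config: DemographySimConfig
) -> np.ndarray:
    p = _ancestral_frequencies(rng, config)
    deme_p = np.empty((config.n_demes, config.n_sites))
    for d in range(config.n_demes):
        q = _drift(rng, p, config.founder_count)  # independent founder event
        for _ in range(config.generations):
            q = _drift(rng, q, config.deme_size)  # isolated drift
        deme_p[d] = q
    return deme_p


def _build_popmap(config: DemographySimConfig, ind_ids, pop_of_ind) -> PopulationMap:
    sites = list(config.deme_sites)
    if len(sites) < config.n_demes:
        # extend the transect by linear extrapolation if more demes requested
        lat0, lon0 = sites[-1][1], sites[-1][2]
        for k in range(len(sites), config.n_demes):
            sites.append((f"Deme{k + 1}", lat0 + 2.0 * (k - len(config.deme_sites) + 1), lon0))
    coords = {name: (lat, lon) for name, lat, lon in sites[: config.n_demes]}
    mapping = dict(zip(ind_ids, pop_of_ind))
    pm = PopulationMap(individual_to_population=mapping, population_coords=coords)
    pm.assign_regions_by_latitude()
    return pm


def simulate_invasion_panel(
    config: DemographySimConfig,
) -> tuple[GenotypePanel, PopulationMap]:
    """Generate a founder-invasion SNP panel and its population map.

    Sites monomorphic in the pooled sample are redrawn (up to 50 rounds) so
    the panel stays polymorphic; missing genotypes are applied completely
    at random at the configured rate.
    """
    rng = np.random.default_rng(config.seed)
    if config.samples_per_deme <= 0:
        raise ValueError("zero individuals requested")
    freq_fn = (
        _deme_frequencies_single_founder
        if config.scenario == "single_founder"
        else _deme_frequencies_independent
    )

    n_ind = config.n_demes * config.samples_per_deme
    deme_names = [name for name, _, _ in DEFAULT_DEME_SITES[: config.n_demes]] + [
        f"Deme{k + 1}" for k in range(len(DEFAULT_DEME_SITES), config.n_demes)
    ]
    pop_of_ind = np.repeat(np.arange(config.n_demes), config.samples_per_deme)
    ind_ids = [
        f"{deme_names[p]}-{i % config.samples_per_deme + 1:02d}"
        for i, p in enumerate(pop_of_ind)
    ]

    genotypes = np.empty((n_ind, config.n_sites), dtype=np.int8)
    need = np.ones(config.n_sites, dtype=bool)
    for _round in range(50):
        sub = replace(config, n_sites=int(need.sum()))
        deme_p = freq_fn(rng, sub)
        g_new = np.concatenate(
            [
                _sample_genotypes(rng, deme_p[d], config.samples_per_deme)
                for d in range(config.n_demes)
            ]
        )
        genotypes[:, need] = _apply_missingness(rng, g_new, config.missingness)
        # redraw sites monomorphic among the observed (non-missing) genotypes
        observed = genotypes != MISSING
        alt = np.where(observed, genotypes, 0).sum(axis=0)
        need = (alt == 0) | (alt == 2 * observed.sum(axis=0))
        if not need.any():
            break
    else:
        raise RuntimeError(
            f"{int(need.sum())} sites remained fixed after the redraw budget; "
            "increase diversity (founder_count/beta parameters)"
        )

    site_ids = [f"snp{j + 1:05d}" for j in range(config.n_sites)]
    panel = GenotypePanel(genotypes, ind_ids, site_ids)
    popmap = _build_popmap(config, ind_ids, [deme_names[p] for p in pop_of_ind])
    return panel, popmap


def simulate_island_model_panel(
    config: DemographySimConfig, equilibration_generations: int = 400
) -> tuple[GenotypePanel, PopulationMap]:
    """Finite-island-model panel run to drift-migration quasi-equilibrium.

    Each generation every deme receives a fraction ``migration_rate`` of its
    gene pool from the across-deme mean and drifts at ``deme_size``.  With
    several demes of size N and migration m, expected F_ST is approximately
    the island-model limit 1 / (1 + 4*N*m).
    """
    rng = np.random.default_rng(config.seed)
    p = _ancestral_frequencies(rng, config)
    deme_p = np.tile(p, (config.n_demes, 1))
    m = config.migration_rate
    for _ in range(equilibration_generations):
        pool = deme_p.mean(axis=0)
        deme_p = (1.0 - m) * deme_p + m * pool[None, :]
        for d in range(config.n_demes):
            deme_p[d] = _drift(rng, deme_p[d], config.deme_size)

    n_ind = config.n_demes * config.samples_per_deme
    pop_of_ind = np.repeat(np.arange(config.n_demes), config.samples_per_deme)
    deme_names = [f"Deme{d + 1}" for d in range(config.n_demes)]
    ind_ids = [f"{deme_names[p]}-{i % config.samples_per_deme + 1:02d}" for i, p in enumerate(pop_of_ind)]
    genotypes = np.concatenate(
        [_sample_genotypes(rng, deme_p[d], config.samples_per_deme) for d in range(config.n_demes)]
    )
    alt = genotypes.sum(axis=0)
    poly = (alt > 0) & (alt < 2 * n_ind)
    genotypes = genotypes[:, poly]
    site_ids = [f"snp{j + 1:05d}" for j in range(genotypes.shape[1])]
    panel = GenotypePanel(genotypes, ind_ids, site_ids)
    coords = {name: (35.0 + 2.0 * d, -125.0) for d, name in enumerate(deme_names)}
    pm = PopulationMap(dict(zip(ind_ids, [deme_names[p] for p in pop_of_ind])), coords)
    pm.assign_regions_by_latitude(35.0 + config.n_demes)
    return panel, pm


def simulate_rare_allele_excess(config: DemographySimConfig) -> GenotypePanel:
    """Pooled-sample panel with a post-bottleneck expansion SFS.

    A founder bottleneck is followed by ``generations`` generations of
    growth at ``growth_factor`` per generation (capped at
    ``ancestral_size``); each generation ``Poisson(mutation_rate_per_copy
    * 2N)`` new mutations enter at frequency 1/(2N) and lost sites are
    pruned.  The recent mutations are young and rare, enriching the
    site-frequency spectrum for singletons so that Tajima's D on the
    output is negative with high probability.  With ``growth_factor`` = 1
    and ``mutation_injection`` the generator instead relaxes to a neutral
    mutation-drift equilibrium at constant size ``founder_count``
    (no standing ancestral sites; D near 0 after a long burn-in).

    The mutational influx is a panel-scale dial, not a genomic mutation
    rate: it is chosen so a desk-scale forward simulation yields a
    ddRAD-panel-sized set of segregating sites dominated by young alleles.
    """
    if config.growth_factor <= 1.0 and not config.mutation_injection:
        raise ValueError(
            "growth_factor <= 1 with mutation injection disabled cannot "
            "produce a rare-allele excess"
        )
    rng = np.random.default_rng(config.seed)
    equilibrium = config.growth_factor <= 1.0
    if equilibrium:
        freqs = np.empty(0)
        n = float(config.founder_count)
        cap = float(config.founder_count)
    else:
        p = _drift(rng, _ancestral_frequencies(rng, config), config.founder_count)
        freqs = p[(p > 0) & (p < 1)]
        n = float(config.founder_count)
        cap = float(config.ancestral_size)
    for _ in range(config.generations):
        n = min(n * config.growth_factor, cap)
        n2 = 2 * int(round(n))
        freqs = rng.binomial(n2, freqs) / n2
        freqs = freqs[(freqs > 0) & (freqs < 1)]
        n_new = rng.poisson(config.mutation_rate_per_copy * n2)
        freqs = np.concatenate([freqs, np.full(n_new, 1.0 / n2)])

    freq = np.asarray(freqs)
    n_ind = config.n_demes * config.samples_per_deme
    genotypes = _sample_genotypes(rng, freq, n_ind)
    alt = genotypes.sum(axis=0)
    poly = np.flatnonzero((alt > 0) & (alt < 2 * n_ind))
    if len(poly) == 0:
        raise RuntimeError("no polymorphic site in the sample; increase diversity")
    if len(poly) > config.n_sites:
        poly = np.sort(rng.choice(poly, size=config.n_sites, replace=False))
    genotypes = genotypes[:, poly]
    genotypes = _apply_missingness(rng, genotypes, config.missingness)
    ind_ids = [f"ind{i + 1:03d}" for i in range(n_ind)]
    site_ids = [f"snp{j + 1:05d}" for j in range(genotypes.shape[1])]
    return GenotypePanel(genotypes, ind_ids, site_ids)
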