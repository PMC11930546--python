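"""Population-genetic summaries for diploid biallelic SNP panels.

Implements the statistics used to characterise the invasion history of a
range-expanding marine parasite from ddRAD SNP genotypes:

* gene-diversity summary H_O / H_S / H_T and F_IS (Nei's sample-size
  corrected estimators),
* Weir & Cockerham (1984) theta: per-SNP, multi-locus (ratio of summed
  variance components) and pairwise with permutation significance,
* Tajima's D on the pooled sample,
* hierarchical AMOVA (region / population / individual / allele copy)
  with level-appropriate permutation tests,
* isolation-by-distance regression of pairwise F_ST on great-circle km,
* genotype PCA.

Genotypes are coded 0/1/2 alternate-allele copies with ``MISSING`` (-1)
for no-calls; all estimators exclude missing genotypes site-wise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MISSING",
    "EARTH_RADIUS_KM",
    "DEFAULT_SPLIT_LATITUDE",
    "GenotypePanel",
    "PopulationMap",
    "DiversitySummary",
    "FstResult",
    "TajimaResult",
    "AmovaTable",
    "IbdResult",
    "filter_sites_max_missing",
    "diversity_summary",
    "wc_fst",
    "pairwise_fst",
    "tajimas_d",
    "amova",
    "great_circle_km",
    "ibd_regression",
    "pca_genotypes",
    "per_snp_fst_histogram",
]

MISSING = -1
EARTH_RADIUS_KM = 6371.0
#: Latitude of Cape Mendocino, CA: the default split between the northern
#: and southern halves of the sampled range.
DEFAULT_SPLIT_LATITUDE = 40.44


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypePanel:
    """Individuals x biallelic-SNP matrix of alternate-allele counts.

    ``genotypes[i, j]`` is 0, 1 or 2 alternate-allele copies for individual
    ``i`` at site ``j``, or ``MISSING``.
    """

    genotypes: np.ndarray
    individual_ids: list[str]
    site_ids: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotype matrix must be 2-D (individuals x sites)")
        n, s = self.genotypes.shape
        if n != len(self.individual_ids):
            raise ValueError("individual_ids length does not match matrix rows")
        if s != len(self.site_ids):
            raise ValueError("site_ids length does not match matrix columns")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid genotype codes at {int(bad.sum())} cells")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        if len(set(self.site_ids)) != s:
            raise ValueError("duplicate site ids")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def missing_fraction_per_site(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=0)

    def subset_individuals(self, indices: Sequence[int]) -> "GenotypePanel":
        idx = np.asarray(indices)
        return GenotypePanel(
            self.genotypes[idx],
            [self.individual_ids[i] for i in idx],
            list(self.site_ids),
        )


@dataclass
class PopulationMap:
    """individual -> population assignment plus population coordinates."""

    individual_to_population: dict[str, str]
    population_coords: dict[str, tuple[float, float]]  # name -> (lat, lon)
    regions: dict[str, str] = field(default_factory=dict)  # population -> region

    def __post_init__(self) -> None:
        for pop, (lat, lon) in self.population_coords.items():
            if not (-90 <= lat <= 90 and -180 <= lon <= 180):
                raise ValueError(f"coordinates out of range for {pop}: ({lat}, {lon})")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.individual_to_population.values():
            seen.setdefault(pop, None)
        return list(seen)

    def assign_regions_by_latitude(self, split_latitude: float = DEFAULT_SPLIT_LATITUDE) -> None:
        """Label populations 'north'/'south' of a latitude (Cape Mendocino
        by default)."""
        self.regions = {
            pop: ("north" if lat >= split_latitude else "south")
            for pop, (lat, lon) in self.population_coords.items()
        }

    def population_indices(self, panel: GenotypePanel) -> dict[str, np.ndarray]:
        """Row indices of the panel grouped by population, in panel order.

        Raises if any panel individual is unmapped.
        """
        groups: dict[str, list[int]] = {}
        for i, ind in enumerate(panel.individual_ids):
            if ind not in self.individual_to_population:
                raise KeyError(f"individual {ind!r} missing from population map")
            groups.setdefault(self.individual_to_population[ind], []).append(i)
        return {pop: np.asarray(ix) for pop, ix in groups.items()}


@dataclass(frozen=True)
class DiversitySummary:
    h_obs: float
    h_s: float
    h_t: float
    f_is: float | None  # None when H_S == 0 (monomorphic panel)


@dataclass
class FstResult:
    overall: float
    per_site: np.ndarray | None = None
    pairwise: pd.DataFrame | None = None
    pairwise_p: pd.DataFrame | None = None


@dataclass(frozen=True)
class TajimaResult:
    d: float | None  # None when S == 0
    s_segregating: int
    pi: float
    n_chromosomes: int


@dataclass
class AmovaTable:
    """Nested variance decomposition: region / population / individual levels.

    ``table`` rows: between range; between populations within range; within
    populations (= between individuals within populations); within
    individuals.  Percentages are components over their sum and close to 100.
    """

    table: pd.DataFrame


@dataclass
class IbdResult:
    slope: float
    intercept: float
    r_squared_adj: float
    p_value: float
    distance_km: pd.DataFrame
    mantel_p: float | None = None


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_sites_max_missing(
    panel: GenotypePanel, max_missing_fraction: float = 0.20
) -> GenotypePanel:
    """Drop sites whose missing-genotype fraction exceeds the threshold.

    Mirrors a VCFtools ``--max-missing`` style site filter; keeps sites with
    missing fraction <= ``max_missing_fraction``. Idempotent.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    if panel.n_sites == 0 or panel.n_individuals == 0:
        raise ValueError("empty panel")
    keep = panel.missing_fraction_per_site() <= max_missing_fraction
    return GenotypePanel(
        panel.genotypes[:, keep],
        list(panel.individual_ids),
        [s for s, k in zip(panel.site_ids, keep) if k],
    )


# ---------------------------------------------------------------------------
# per-population site summaries (shared by the estimators)
# ---------------------------------------------------------------------------

def _pop_site_stats(genotypes: np.ndarray, pops: Sequence[np.ndarray]):
    """Per population and site: sample size n (diploids), alt-allele
    frequency p, and heterozygote fraction h. Entries with n == 0 are nan."""
    r = len(pops)
    n_sites = genotypes.shape[1]
    n = np.zeros((r, n_sites))
    p = np.full((r, n_sites), np.nan)
    h = np.full((r, n_sites), np.nan)
    for k, idx in enumerate(pops):
        g = genotypes[idx]
        ok = g != MISSING
        nk = ok.sum(axis=0)
        n[k] = nk
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(nk > 0, np.where(ok, g, 0).sum(axis=0) / (2.0 * nk), np.nan)
            h[k] = np.where(nk > 0, ((g == 1) & ok).sum(axis=0) / nk, np.nan)
    return n, p, h


# ---------------------------------------------------------------------------
# diversity (H_O, H_S, H_T, F_IS)
# ---------------------------------------------------------------------------

def diversity_summary(panel: GenotypePanel, popmap: PopulationMap) -> DiversitySummary:
    """Observed heterozygosity and Nei gene diversities, averaged over sites.

    Per site with r populations of n_k genotyped diploids (harmonic mean
    n~), Nei & Chesser's sample-size-corrected estimators:

        Hs = n~/(n~-1) * (1 - mean_k sum_a p_ka^2 - Ho/(2 n~))
        Ht = 1 - sum_a pbar_a^2 + Hs/(r n~) - Ho/(2 r n~)

    with pbar the unweighted across-population mean frequency and Ho the
    unweighted mean within-population heterozygote fraction.  F_IS is the
    Nei convention 1 - H_O/H_S (None when H_S = 0).
    """
    pops = popmap.population_indices(panel)
    pop_idx = list(pops.values())
    if len(pop_idx) < 2 or any(len(ix) < 2 for ix in pop_idx):
        raise ValueError("need >= 2 populations with >= 2 individuals each")
    n, p, h = _pop_site_stats(panel.genotypes, pop_idx)
    usable = (n > 0).all(axis=0)
    if not usable.any():
        raise ValueError("no site has data in every population")
    n, p, h = n[:, usable], p[:, usable], h[:, usable]
    r = len(pop_idx)

    ho_site = h.mean(axis=0)
    n_harm = r / (1.0 / n).sum(axis=0)
    # sum_a p_a^2 = p^2 + (1-p)^2 for a biallelic site
    sum_p2 = (p**2 + (1.0 - p) ** 2).mean(axis=0)
    hs_site = n_harm / (n_harm - 1.0) * (1.0 - sum_p2 - ho_site / (2.0 * n_harm))
    pbar = p.mean(axis=0)
    ht_site = (
        1.0
        - (pbar**2 + (1.0 - pbar) ** 2)
        + hs_site / (r * n_harm)
        - ho_site / (2.0 * r * n_harm)
    )
    h_obs = float(ho_site.mean())
    h_s = float(hs_site.mean())
    h_t = float(ht_site.mean())
    f_is = None if h_s <= 0 else float(1.0 - h_obs / h_s)
    return DiversitySummary(h_obs=h_obs, h_s=h_s, h_t=h_t, f_is=f_is)


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------

def _wc_components(genotypes: np.ndarray, pops: Sequence[np.ndarray]):
    """Weir & Cockerham (1984) per-site variance components (a, b, c).

    a: among populations; b: among individuals within populations;
    c: within individuals.  Sites where fewer than two populations have
    data, or where the pooled mean sample size is 1, are nan.
    """
    n, p, h = _pop_site_stats(genotypes, pops)
    present = n > 0
    r = present.sum(axis=0).astype(float)  # populations with data, per site
    n_sum = n.sum(axis=0)
    valid = r >= 2

    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_sum / r
        nc = (n_sum - (n**2).sum(axis=0) / n_sum) / (r - 1.0)
        p0 = np.where(present, np.nan_to_num(p), 0.0)
        h0 = np.where(present, np.nan_to_num(h), 0.0)
        pbar = (n * p0).sum(axis=0) / n_sum
        s2 = (n * (p0 - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n * h0).sum(axis=0) / n_sum

        inner = pbar * (1.0 - pbar) - (r - 1.0) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0

    valid &= np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


def _multilocus_theta(genotypes: np.ndarray, pops: Sequence[np.ndarray]) -> float:
    a, b, c = _wc_components(genotypes, pops)
    ok = np.isfinite(a)
    denom = (a[ok] + b[ok] + c[ok]).sum()
    if denom == 0:
        return math.nan
    return float(a[ok].sum() / denom)


def wc_fst(panel: GenotypePanel, popmap: PopulationMap) -> FstResult:
    """Weir-Cockerham theta: per-site values and the multi-locus estimate.

    The multi-locus estimate is the ratio of summed components
    sum(a)/sum(a+b+c) across sites (not the mean of per-site ratios).
    Negative estimates are reported raw; clamp to 0 only for display.
    """
    pops = popmap.population_indices(panel)
    names = list(pops)
    if len(names) < 2:
        raise ValueError("need >= 2 populations")
    for pop, idx in pops.items():
        nonmiss = (panel.genotypes[idx] != MISSING).sum(axis=0)
        if (nonmiss < 2).all():
            raise ValueError(f"population {pop!r} has < 2 non-missing genotypes at every site")
    a, b, c = _wc_components(panel.genotypes, list(pops.values()))
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = a / (a + b + c)
    overall = _multilocus_theta(panel.genotypes, list(pops.values()))
    return FstResult(overall=overall, per_site=per_site)


def pairwise_fst(
    panel: GenotypePanel,
    popmap: PopulationMap,
    n_permutations: int = 999,
    seed: int | None = None,
) -> FstResult:
    """Pairwise multi-locus theta between populations with permutation p.

    For each pair, individuals are shuffled between the two populations
    ``n_permutations`` times; p = (1 + #{theta_perm >= theta_obs}) /
    (n_permutations + 1).
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    rng = np.random.default_rng(seed)
    pops = popmap.population_indices(panel)
    names = list(pops)
    theta = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    pvals = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            ia, ib = pops[names[i]], pops[names[j]]
            merged = np.concatenate([ia, ib])
            g = panel.genotypes[merged]
            na = len(ia)
            obs = _multilocus_theta(g, [np.arange(na), np.arange(na, len(merged))])
            if not math.isfinite(obs):
                continue
            exceed = 0
            order = np.arange(len(merged))
            for _ in range(n_permutations):
                rng.shuffle(order)
                t = _multilocus_theta(g, [order[:na], order[na:]])
                if math.isfinite(t) and t >= obs:
                    exceed += 1
            p = (exceed + 1.0) / (n_permutations + 1.0)
            theta.iloc[i, j] = theta.iloc[j, i] = obs
            pvals.iloc[i, j] = pvals.iloc[j, i] = p
    per_pair = theta.values[np.triu_indices(len(names), k=1)]
    overall = float(np.nanmean(per_pair)) if len(per_pair) else math.nan
    return FstResult(overall=overall, pairwise=theta, pairwise_p=pvals)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajimas_d(panel: GenotypePanel) -> TajimaResult:
    """Tajima's D on the pooled sample.

    pi is summed over sites from each site's own allele counts
    (2*c_alt*c_ref / (n_s*(n_s-1))); the normalising constants use
    n = 2 x (minimum per-site count of non-missing diploids), a
    conservative single-n treatment of missing data.  D is None (flagged)
    when no site segregates.
    """
    g = panel.genotypes
    ok = g != MISSING
    n_dip = ok.sum(axis=0)
    informative = n_dip >= 2
    if not informative.any():
        raise ValueError("no site with >= 2 genotyped individuals")
    n_dip = n_dip[informative]
    g = g[:, informative]
    ok = ok[:, informative]

    n = int(2 * n_dip.min())
    if n < 4:
        raise ValueError(f"need >= 4 chromosomes, got {n}")
    alt = np.where(ok, g, 0).sum(axis=0)
    tot = 2 * n_dip
    seg = (alt > 0) & (alt < tot)
    s = int(seg.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_site = 2.0 * alt * (tot - alt) / (tot * (tot - 1.0))
    pi = float(pi_site.sum())
    if s == 0:
        return TajimaResult(d=None, s_segregating=0, pi=pi, n_chromosomes=n)

    i = np.arange(1, n)
    a1 = (1.0 / i).sum()
    a2 = (1.0 / i**2).sum()
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    d = (pi - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1.0))
    return TajimaResult(d=float(d), s_segregating=s, pi=pi, n_chromosomes=n)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def _amova_group_ss(alt: np.ndarray, cop: np.ndarray) -> np.ndarray:
    """Per-site sum of squares among the allele copies of one group, from the
    group's alt-copy count and total copy count: c*(n-c)/n (squared-distance
    form of the SS for 0/1 allele copies)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        ss = np.where(cop > 0, alt * (cop - alt) / cop, 0.0)
    return ss


def _amova_components(
    ss_wi: float,
    ss_wp: float,
    ss_wr: float,
    ss_tot: float,
    n_ps: np.ndarray,
    region_of_pop: np.ndarray,
    n_reg: int,
):
    """Solve the nested ANOVA expectations for the variance components.

    ``n_ps`` is the (populations x sites) matrix of non-missing diploid
    counts.  Because the sums of squares are additive over unlinked sites,
    the expected-SS coefficients are computed per site (each individual
    contributes 2 allele copies where genotyped, 0 where missing) and
    summed across sites — exact under missingness that is independent of
    genotype.  Returns the components ordered [between-range,
    between-pop-within-range, between-ind-within-pop, within-ind].
    """
    present = n_ps > 0
    n_s = n_ps.sum(axis=0)  # genotyped individuals per site
    p_s = present.sum(axis=0)  # populations with data per site
    n_gs = np.zeros((n_reg, n_ps.shape[1]))
    for p, r in enumerate(region_of_pop):
        n_gs[r] += n_ps[p]
    r_s = (n_gs > 0).sum(axis=0)
    m_s = 2.0 * n_s
    with np.errstate(invalid="ignore", divide="ignore"):
        d_s = np.where(
            n_gs > 0,
            np.stack(
                [
                    ((2.0 * n_ps[region_of_pop == g]) ** 2).sum(axis=0)
                    for g in range(n_reg)
                ]
            )
            / np.where(n_gs > 0, 2.0 * n_gs, 1.0),
            0.0,
        ).sum(axis=0)
        e_s = np.where(m_s > 0, ((2.0 * n_ps) ** 2).sum(axis=0) / np.where(m_s > 0, m_s, 1.0), 0.0)
        f_s = np.where(m_s > 0, ((2.0 * n_gs) ** 2).sum(axis=0) / np.where(m_s > 0, m_s, 1.0), 0.0)

    c_wi = float(n_s.sum())  # = sum(M_s - N_s)
    c_ai = float((n_s - p_s).sum())
    c_ap = float((p_s - r_s).sum())
    c_ar = float(np.maximum(r_s - 1, 0).sum())
    c_ap_2 = float((m_s - d_s).sum())
    c_ar_2 = float((d_s - e_s).sum())
    c_ar_1 = float((m_s - f_s).sum())

    ss_ai = ss_wp - ss_wi
    ss_ap = ss_wr - ss_wp
    ss_ar = ss_tot - ss_wr

    sig4 = ss_wi / c_wi
    sig3 = (ss_ai - sig4 * c_ai) / (2.0 * c_ai)
    sig2 = (ss_ap - sig4 * c_ap - sig3 * 2.0 * c_ap) / c_ap_2
    sig1 = (ss_ar - sig4 * c_ar - sig3 * 2.0 * c_ar - sig2 * c_ar_2) / c_ar_1
    return np.array([sig1, sig2, sig3, sig4])


def _amova_ss_from_pop_aggregates(alt_pop, cop_pop, region_of_pop, n_reg):
    """Within-region and total SS, per site, from per-population aggregates."""
    alt_reg = np.zeros((n_reg, alt_pop.shape[1]))
    cop_reg = np.zeros((n_reg, alt_pop.shape[1]))
    for p, r in enumerate(region_of_pop):
        alt_reg[r] += alt_pop[p]
        cop_reg[r] += cop_pop[p]
    ss_wr = _amova_group_ss(alt_reg, cop_reg).sum()
    ss_tot = _amova_group_ss(alt_pop.sum(axis=0), cop_pop.sum(axis=0)).sum()
    return ss_wr, ss_tot


def amova(
    panel: GenotypePanel,
    popmap: PopulationMap,
    n_permutations: int = 999,
    seed: int | None = None,
    split_latitude: float = DEFAULT_SPLIT_LATITUDE,
) -> AmovaTable:
    """Four-level AMOVA: range / population / individual / allele copy.

    Sums of squares are the squared-Euclidean (allele-mismatch) form on
    0/1 allele copies, additive over unlinked sites and computable from
    per-group allele counts.  Variance components come from the nested
    ANOVA expected sums of squares with unequal group sizes; negative
    components are retained.  Permutation p-values: populations shuffled
    across regions (between-range), individuals shuffled across
    populations within regions (between populations), allele copies
    shuffled among individuals within populations (the two lowest rows;
    the within-individual component is tested one-sided for deficiency,
    i.e. excess homozygosity).
    """
    rng = np.random.default_rng(seed)
    pops = popmap.population_indices(panel)
    names = list(pops)
    if not popmap.regions:
        popmap.assign_regions_by_latitude(split_latitude)
    region_names = sorted({popmap.regions[p] for p in names})
    if len(region_names) < 2:
        raise ValueError("need >= 2 regions for the top level")
    region_of_pop = np.array([region_names.index(popmap.regions[p]) for p in names])
    counts = np.bincount(region_of_pop, minlength=len(region_names))
    if (counts < 2).any():
        singles = [region_names[i] for i in np.flatnonzero(counts < 2)]
        raise ValueError(f"region(s) {singles} contain a single population: top-level test degenerate")

    g = panel.genotypes
    ok = g != MISSING
    n_reg = len(region_names)
    n_pop = len(names)
    n_ind = panel.n_individuals

    pop_of_ind = np.empty(n_ind, dtype=int)
    for k, name in enumerate(names):
        pop_of_ind[pops[name]] = k

    alt_ind = np.where(ok, g, 0).astype(float)
    cop_ind = 2.0 * ok
    het_ind = (g == 1) & ok

    alt_pop = np.zeros((n_pop, panel.n_sites))
    cop_pop = np.zeros((n_pop, panel.n_sites))
    for k in range(n_pop):
        alt_pop[k] = alt_ind[pop_of_ind == k].sum(axis=0)
        cop_pop[k] = cop_ind[pop_of_ind == k].sum(axis=0)
    n_ps = cop_pop / 2.0

    ss_wi = het_ind.sum() / 2.0
    ss_wp = _amova_group_ss(alt_pop, cop_pop).sum()
    ss_wr, ss_tot = _amova_ss_from_pop_aggregates(alt_pop, cop_pop, region_of_pop, n_reg)

    df = np.array([n_reg - 1, n_pop - n_reg, n_ind - n_pop, n_ind])
    sig = _amova_components(ss_wi, ss_wp, ss_wr, ss_tot, n_ps, region_of_pop, n_reg)
    total = sig.sum()
    pct = sig / total * 100.0

    # --- permutation tests -------------------------------------------------
    exceed = np.zeros(4)
    # level 1: shuffle populations across regions (region sizes preserved)
    perm_regions = region_of_pop.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm_regions)
        ss_wr_p, _ = _amova_ss_from_pop_aggregates(alt_pop, cop_pop, perm_regions, n_reg)
        s_p = _amova_components(ss_wi, ss_wp, ss_wr_p, ss_tot, n_ps, perm_regions, n_reg)
        if s_p[0] >= sig[0]:
            exceed[0] += 1
    # level 2: shuffle individuals across populations within regions
    region_of_ind = region_of_pop[pop_of_ind]
    for _ in range(n_permutations):
        perm_pop_of_ind = pop_of_ind.copy()
        for r in range(n_reg):
            sel = np.flatnonzero(region_of_ind == r)
            perm_pop_of_ind[sel] = pop_of_ind[sel[rng.permutation(len(sel))]]
        alt_p = np.zeros_like(alt_pop)
        cop_p = np.zeros_like(cop_pop)
        for k in range(n_pop):
            rows = perm_pop_of_ind == k
            alt_p[k] = alt_ind[rows].sum(axis=0)
            cop_p[k] = cop_ind[rows].sum(axis=0)
        ss_wp_p = _amova_group_ss(alt_p, cop_p).sum()
        ss_wr_p, _ = _amova_ss_from_pop_aggregates(alt_p, cop_p, region_of_pop, n_reg)
        s_p = _amova_components(
            ss_wi, ss_wp_p, ss_wr_p, ss_tot, cop_p / 2.0, region_of_pop, n_reg
        )
        if s_p[1] >= sig[1]:
            exceed[1] += 1
    # level 3: shuffle allele copies among individuals within populations
    # (per site; within-pop allele counts, hence ss_wp, are unchanged)
    for _ in range(n_permutations):
        ss_wi_p = 0.0
        for k in range(n_pop):
            rows = np.flatnonzero(pop_of_ind == k)
            gk = g[rows]
            okk = gk != MISSING
            copies = np.empty((2 * len(rows), panel.n_sites), dtype=np.int8)
            copies[0::2] = np.where(okk, (gk >= 1).astype(np.int8), MISSING)
            copies[1::2] = np.where(okk, (gk == 2).astype(np.int8), MISSING)
            perm = rng.permuted(copies, axis=0)
            c1, c2 = perm[0::2], perm[1::2]
            het = (c1 != c2) & (c1 != MISSING) & (c2 != MISSING)
            ss_wi_p += het.sum() / 2.0
        s_p = _amova_components(
            ss_wi_p, ss_wp, ss_wr, ss_tot, n_ps, region_of_pop, n_reg
        )
        if s_p[2] >= sig[2]:
            exceed[2] += 1
        if s_p[3] <= sig[3]:
            exceed[3] += 1
    pvals = (exceed + 1.0) / (n_permutations + 1.0)

    table = pd.DataFrame(
        {
            "source": [
                "between range",
                "between populations within range",
                "within populations",
                "within individuals",
            ],
            "df": df.astype(int),
            "sigma2": sig,
            "pct_variation": pct,
            "p_value": pvals,
        }
    )
    return AmovaTable(table=table)


# ---------------------------------------------------------------------------
# geography, IBD, PCA, histogram
# ---------------------------------------------------------------------------

def great_circle_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine great-circle distance in km (Earth radius 6371 km)."""
    for lat in (lat1, lat2):
        if not -90 <= lat <= 90:
            raise ValueError(f"latitude out of range: {lat}")
    for lon in (lon1, lon2):
        if not -180 <= lon <= 180:
            raise ValueError(f"longitude out of range: {lon}")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def ibd_regression(
    fst: FstResult,
    popmap: PopulationMap,
    mantel_permutations: int = 0,
    seed: int | None = None,
) -> IbdResult:
    """Isolation by distance: OLS of pairwise F_ST on great-circle km.

    Fits over the unique population pairs and reports the slope, intercept,
    adjusted r-squared and the OLS t-test p-value.  Pairs are not
    independent observations; pass ``mantel_permutations`` > 0 for a Mantel
    permutation p-value as well.
    """
    if fst.pairwise is None:
        raise ValueError("pairwise F_ST matrix required (run pairwise_fst first)")
    names = list(fst.pairwise.index)
    if len(names) < 3:
        raise ValueError("need >= 3 populations")
    dist = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            la, lo = popmap.population_coords[a]
            lb, lb_lon = popmap.population_coords[b]
            d = great_circle_km(la, lo, lb, lb_lon)
            dist.loc[a, b] = dist.loc[b, a] = d
    iu = np.triu_indices(len(names), k=1)
    x = dist.values[iu]
    y = fst.pairwise.values[iu]
    keep = np.isfinite(y)
    x, y = x[keep], y[keep]
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: all pairwise distances equal")
    res = stats.linregress(x, y)
    n = len(x)
    r2 = res.rvalue**2
    r2_adj = 1.0 - (1.0 - r2) * (n - 1.0) / (n - 2.0)

    mantel_p = None
    if mantel_permutations > 0:
        rng = np.random.default_rng(seed)
        fmat = fst.pairwise.values.copy()
        obs = res.rvalue
        exceed = 0
        for _ in range(mantel_permutations):
            perm = rng.permutation(len(names))
            yp = fmat[np.ix_(perm, perm)][iu]
            kp = np.isfinite(yp)
            r = stats.pearsonr(dist.values[iu][kp], yp[kp]).statistic
            if abs(r) >= abs(obs):
                exceed += 1
        mantel_p = (exceed + 1.0) / (mantel_permutations + 1.0)

    return IbdResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared_adj=float(r2_adj),
        p_value=float(res.pvalue),
        distance_km=dist,
        mantel_p=mantel_p,
    )


def pca_genotypes(panel: GenotypePanel, n_components: int = 2):
    """PCA of the mean-imputed, column-centred genotype matrix.

    Returns ``(scores, pct_variance)``: a DataFrame of individual scores on
    PC1..PCk and the percent variance explained per component.  Sign
    convention: the largest-magnitude loading of each component is positive.
    """
    if n_components > min(panel.n_individuals, panel.n_sites):
        raise ValueError("n_components exceeds matrix rank bound")
    g = panel.genotypes.astype(float)
    miss = panel.genotypes == MISSING
    if miss.all(axis=0).any():
        raise ValueError("site with all genotypes missing; filter first")
    g[miss] = np.nan
    col_mean = np.nanmean(g, axis=0)
    g = np.where(np.isnan(g), col_mean, g)
    g -= g.mean(axis=0)
    u, sv, vt = np.linalg.svd(g, full_matrices=False)
    for k in range(len(sv)):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    scores = u[:, :n_components] * sv[:n_components]
    var = sv**2
    pct = var[:n_components] / var.sum() * 100.0 if var.sum() > 0 else np.zeros(n_components)
    df = pd.DataFrame(
        scores,
        index=panel.individual_ids,
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )
    return df, pct


def per_snp_fst_histogram(fst: FstResult, bin_width: float = 0.05):
    """Bin the per-SNP theta values into fixed-width bins over [min, 1].

    Returns ``(counts, bin_edges)``; the counts sum to the number of sites
    with a defined theta.
    """
    if fst.per_site is None:
        raise ValueError("per-site theta values required")
    vals = fst.per_site[np.isfinite(fst.per_site)]
    if len(vals) == 0:
        raise ValueError("no defined per-site theta values")
    lo = min(0.0, float(vals.min()))
    n_bins = max(1, int(math.ceil((1.0 - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], 1.0)
    counts, edges = np.histogram(vals, bins=edges)
    return counts, edges
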