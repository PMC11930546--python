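"""Population-genetic estimators against independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from invadrift import (
    MISSING,
    GenotypePanel,
    PopulationMap,
    diversity_summary,
    filter_sites_max_missing,
    great_circle_km,
    ibd_regression,
    pairwise_fst,
    pca_genotypes,
    per_snp_fst_histogram,
    tajimas_d,
    wc_fst,
)
from invadrift.popgen import FstResult

from conftest import make_panel


# ---------------------------------------------------------------------------
# independent oracles (pure-python loops, written from the published
# definitions, deliberately not sharing code with the implementation)
# ---------------------------------------------------------------------------

def oracle_wc_abc(genotypes, pops):
    """Literal per-site transcription of the 1984 a, b, c components."""
    out = []
    for j in range(genotypes.shape[1]):
        ns, ps, hs = [], [], []
        for rows in pops:
            vals = [genotypes[i, j] for i in rows if genotypes[i, j] != MISSING]
            if not vals:
                continue
            ns.append(len(vals))
            ps.append(sum(vals) / (2.0 * len(vals)))
            hs.append(sum(1 for v in vals if v == 1) / len(vals))
        r = len(ns)
        if r < 2:
            out.append((math.nan,) * 3)
            continue
        nbar = sum(ns) / r
        if nbar <= 1:
            out.append((math.nan,) * 3)
            continue
        nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1.0)
        pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1.0) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
        out.append((a, b, c))
    return out


def oracle_nei_diversity(genotypes, pops):
    """From-scratch per-site Nei/Nei-Chesser gene-diversity computation."""
    ho_sites, hs_sites, ht_sites = [], [], []
    for j in range(genotypes.shape[1]):
        ns, ps, hos = [], [], []
        for rows in pops:
            vals = [genotypes[i, j] for i in rows if genotypes[i, j] != MISSING]
            if not vals:
                break
            ns.append(len(vals))
            ps.append(sum(vals) / (2.0 * len(vals)))
            hos.append(sum(1 for v in vals if v == 1) / len(vals))
        else:
            r = len(ns)
            nharm = r / sum(1.0 / n for n in ns)
            ho = sum(hos) / r
            mean_sum_p2 = sum(p * p + (1 - p) * (1 - p) for p in ps) / r
            hs = nharm / (nharm - 1.0) * (1.0 - mean_sum_p2 - ho / (2.0 * nharm))
            pbar = sum(ps) / r
            ht = (
                1.0
                - (pbar**2 + (1 - pbar) ** 2)
                + hs / (r * nharm)
                - ho / (2.0 * r * nharm)
            )
            ho_sites.append(ho)
            hs_sites.append(hs)
            ht_sites.append(ht)
    return (
        sum(ho_sites) / len(ho_sites),
        sum(hs_sites) / len(hs_sites),
        sum(ht_sites) / len(ht_sites),
    )


def oracle_tajima(genotypes):
    """Independent evaluation of the 1989 constants on a complete matrix."""
    n = 2 * genotypes.shape[0]
    s = 0
    pi = 0.0
    for j in range(genotypes.shape[1]):
        c = int(genotypes[:, j].sum())
        if 0 < c < n:
            s += 1
        pi += 2.0 * c * (n - c) / (n * (n - 1.0))
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1.0))


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

class TestFilterMaxMissing:
    def test_threshold_arithmetic(self):
        g = np.zeros((10, 2), dtype=np.int8)
        g[:3, 1] = MISSING
        g[0, 0] = 1
        panel, _ = make_panel(g, [5, 5])
        kept = filter_sites_max_missing(panel, 0.20)
        assert kept.site_ids == ["s0"]  # 0.3 missing > 0.2

    def test_threshold_one_is_identity(self):
        g = np.zeros((4, 3), dtype=np.int8)
        g[0] = MISSING
        panel, _ = make_panel(g, [2, 2])
        assert filter_sites_max_missing(panel, 1.0).n_sites == 3

    def test_survivor_count_matches_recount(self):
        rng = np.random.default_rng(5)
        g = rng.integers(0, 3, size=(20, 50)).astype(np.int8)
        g[rng.random(g.shape) < 0.25] = MISSING
        panel, _ = make_panel(g, [10, 10])
        kept = filter_sites_max_missing(panel, 0.20)
        expected = sum(
            1
            for j in range(50)
            if sum(1 for i in range(20) if g[i, j] == MISSING) / 20 <= 0.20
        )
        assert kept.n_sites == expected

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        g = rng.integers(0, 3, size=(12, 30)).astype(np.int8)
        g[rng.random(g.shape) < 0.3] = MISSING
        panel, _ = make_panel(g, [6, 6])
        once = filter_sites_max_missing(panel, 0.2)
        twice = filter_sites_max_missing(once, 0.2)
        assert np.array_equal(once.genotypes, twice.genotypes)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            panel, _ = make_panel(np.zeros((4, 1), dtype=np.int8), [2, 2])
            empty = filter_sites_max_missing(
                GenotypePanel(np.zeros((4, 0), dtype=np.int8), panel.individual_ids, []),
                0.2,
            )


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

class TestDiversity:
    def test_all_heterozygous(self):
        g = np.ones((8, 1), dtype=np.int8)
        panel, popmap = make_panel(g, [4, 4])
        d = diversity_summary(panel, popmap)
        assert d.h_obs == pytest.approx(1.0)
        assert d.f_is < 0

    def test_fixed_alternate(self):
        g = np.full((8, 1), 2, dtype=np.int8)
        panel, popmap = make_panel(g, [4, 4])
        d = diversity_summary(panel, popmap)
        assert d.h_obs == 0.0
        assert d.h_s == pytest.approx(0.0, abs=1e-12)
        assert d.f_is is None

    def test_matches_independent_nei_oracle(self):
        rng = np.random.default_rng(21)
        g = rng.integers(0, 3, size=(12, 20)).astype(np.int8)
        g[rng.random(g.shape) < 0.1] = MISSING
        panel, popmap = make_panel(g, [4, 4, 4])
        pops = list(popmap.population_indices(panel).values())
        ho, hs, ht = oracle_nei_diversity(g, pops)
        d = diversity_summary(panel, popmap)
        assert d.h_obs == pytest.approx(ho, abs=1e-9)
        assert d.h_s == pytest.approx(hs, abs=1e-9)
        assert d.h_t == pytest.approx(ht, abs=1e-9)
        assert d.f_is == pytest.approx(1.0 - ho / hs, abs=1e-9)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

class TestWcFst:
    def test_complete_fixation_gives_one(self):
        g = np.concatenate([np.zeros((10, 1)), np.full((10, 1), 2)]).astype(np.int8)
        panel, popmap = make_panel(g, [10, 10])
        res = wc_fst(panel, popmap)
        assert res.per_site[0] == pytest.approx(1.0, abs=1e-12)
        assert res.overall == pytest.approx(1.0, abs=1e-12)

    def test_matches_component_oracle_on_toy(self, toy_panel_three_pops):
        panel, popmap = toy_panel_three_pops
        pops = list(popmap.population_indices(panel).values())
        oracle = oracle_wc_abc(panel.genotypes, pops)
        res = wc_fst(panel, popmap)
        num = den = 0.0
        for j, (a, b, c) in enumerate(oracle):
            if math.isnan(a):
                continue
            num += a
            den += a + b + c
            if a + b + c != 0:
                assert res.per_site[j] == pytest.approx(a / (a + b + c), abs=1e-9)
        assert res.overall == pytest.approx(num / den, abs=1e-9)

    def test_matches_oracle_with_missing_data(self):
        rng = np.random.default_rng(33)
        g = rng.integers(0, 3, size=(15, 8)).astype(np.int8)
        g[rng.random(g.shape) < 0.15] = MISSING
        panel, popmap = make_panel(g, [5, 5, 5])
        pops = list(popmap.population_indices(panel).values())
        oracle = oracle_wc_abc(panel.genotypes, pops)
        res = wc_fst(panel, popmap)
        for j, (a, b, c) in enumerate(oracle):
            if math.isnan(a) or a + b + c == 0:
                continue
            assert res.per_site[j] == pytest.approx(a / (a + b + c), abs=1e-9)

    def test_null_mean_near_zero(self):
        """Two halves of one panmictic sample: E[theta] ~ 0 over 200 draws."""
        rng = np.random.default_rng(100)
        vals = []
        for _ in range(200):
            freqs = rng.uniform(0.1, 0.9, size=40)
            g = rng.binomial(2, np.tile(freqs, (16, 1))).astype(np.int8)
            panel, popmap = make_panel(g, [8, 8])
            vals.append(wc_fst(panel, popmap).overall)
        assert abs(float(np.mean(vals))) < 0.02

    def test_per_site_theta_bounded_by_one(self):
        rng = np.random.default_rng(44)
        g = rng.integers(0, 3, size=(20, 100)).astype(np.int8)
        panel, popmap = make_panel(g, [10, 10])
        res = wc_fst(panel, popmap)
        finite = res.per_site[np.isfinite(res.per_site)]
        assert (finite <= 1.0 + 1e-12).all()

    def test_underpopulated_population_rejected(self):
        g = np.array([[1], [0], [MISSING]], dtype=np.int8)
        panel, popmap = make_panel(g, [2, 1])
        with pytest.raises(ValueError, match="pop1"):
            wc_fst(panel, popmap)


class TestPairwiseFst:
    def test_duplicated_population_null(self):
        rng = np.random.default_rng(8)
        freqs = rng.uniform(0.2, 0.8, size=60)
        g = rng.binomial(2, np.tile(freqs, (20, 1))).astype(np.int8)
        panel, popmap = make_panel(g, [10, 10])
        res = pairwise_fst(panel, popmap, n_permutations=99, seed=0)
        assert abs(res.pairwise.iloc[0, 1]) < 0.05
        assert res.pairwise_p.iloc[0, 1] > 0.05

    def test_fixed_differences_maximally_significant(self):
        g = np.concatenate([np.zeros((8, 20)), np.full((8, 20), 2)]).astype(np.int8)
        panel, popmap = make_panel(g, [8, 8])
        res = pairwise_fst(panel, popmap, n_permutations=99, seed=0)
        assert res.pairwise.iloc[0, 1] == pytest.approx(1.0)
        assert res.pairwise_p.iloc[0, 1] == pytest.approx(1.0 / 100.0)

    def test_matrix_symmetric(self):
        rng = np.random.default_rng(9)
        g = rng.integers(0, 3, size=(18, 30)).astype(np.int8)
        panel, popmap = make_panel(g, [6, 6, 6])
        res = pairwise_fst(panel, popmap, n_permutations=99, seed=1)
        m = res.pairwise.values
        assert np.allclose(m, m.T, equal_nan=True)
        assert np.isnan(np.diag(m)).all()

    def test_too_few_permutations_rejected(self, toy_panel_three_pops):
        panel, popmap = toy_panel_three_pops
        with pytest.raises(ValueError):
            pairwise_fst(panel, popmap, n_permutations=10)

    def test_null_pvalues_approximately_uniform(self):
        """Permutation p-values under panmixia: KS distance < 0.1."""
        rng = np.random.default_rng(1234)
        pvals = []
        for _ in range(200):
            freqs = rng.uniform(0.1, 0.9, size=40)
            g = rng.binomial(2, np.tile(freqs, (16, 1))).astype(np.int8)
            panel, popmap = make_panel(g, [8, 8])
            res = pairwise_fst(
                panel, popmap, n_permutations=199, seed=int(rng.integers(2**31))
            )
            pvals.append(res.pairwise_p.iloc[0, 1])
        pvals = np.sort(pvals)
        grid = np.arange(1, 201) / 200.0
        ks = np.max(np.abs(pvals - grid))
        assert ks < 0.1


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

class TestTajimasD:
    def test_singletons_give_negative_d(self):
        g = np.zeros((10, 12), dtype=np.int8)
        for j in range(12):
            g[j % 10, j] = 1
        panel = GenotypePanel(g, [f"i{k}" for k in range(10)], [f"s{j}" for j in range(12)])
        assert tajimas_d(panel).d < 0

    def test_constructed_zero(self):
        # n = 4 chromosomes: 8 singleton + 3 doubleton sites give pi = S/a1
        g = np.zeros((2, 11), dtype=np.int8)
        g[0, :8] = 1
        g[0, 8:] = 2
        panel = GenotypePanel(g, ["a", "b"], [f"s{j}" for j in range(11)])
        res = tajimas_d(panel)
        assert res.s_segregating == 11
        assert res.d == pytest.approx(0.0, abs=1e-12)

    def test_matches_constants_oracle(self):
        rng = np.random.default_rng(77)
        g = rng.integers(0, 3, size=(5, 5)).astype(np.int8)  # 10 chromosomes
        g[0, 0] = 1  # keep at least one segregating site
        panel = GenotypePanel(g, [f"i{k}" for k in range(5)], [f"s{j}" for j in range(5)])
        assert tajimas_d(panel).d == pytest.approx(oracle_tajima(g), abs=1e-9)

    def test_monomorphic_flagged(self):
        g = np.zeros((5, 3), dtype=np.int8)
        panel = GenotypePanel(g, [f"i{k}" for k in range(5)], ["s0", "s1", "s2"])
        res = tajimas_d(panel)
        assert res.d is None
        assert res.s_segregating == 0


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def _regioned_panel(g, pop_sizes, n_south):
    """Panel + map with the first ``n_south`` populations labelled south."""
    panel, popmap = make_panel(g, pop_sizes)
    names = popmap.populations
    popmap.regions = {
        n: ("south" if k < n_south else "north") for k, n in enumerate(names)
    }
    return panel, popmap


def oracle_amova_ss(g, pops, regions):
    """Sums of squares from explicit pseudo-haplotype distance matrices."""
    n, s = g.shape
    cop = np.empty((2 * n, s))
    cop[0::2] = g >= 1
    cop[1::2] = g == 2

    def ss(rows):
        x = cop[rows]
        d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
        return d2[np.triu_indices(len(rows), k=1)].sum() / len(rows)

    copy_rows = lambda inds: np.concatenate([[2 * i, 2 * i + 1] for i in inds])
    ss_tot = ss(np.arange(2 * n))
    ss_wp = sum(ss(copy_rows(p)) for p in pops)
    ss_wr = sum(ss(copy_rows(np.concatenate([pops[k] for k in reg]))) for reg in regions)
    ss_wi = sum(ss([2 * i, 2 * i + 1]) for i in range(n))
    return ss_tot, ss_wr, ss_wp, ss_wi


class TestAmova:
    def test_identical_regions_no_top_level_signal(self):
        rng = np.random.default_rng(17)
        one_pop = rng.integers(0, 3, size=(8, 60)).astype(np.int8)
        g = np.concatenate([one_pop] * 8)  # 8 identical populations, 2 regions
        panel, popmap = _regioned_panel(g, [8] * 8, n_south=4)
        from invadrift import amova

        res = amova(panel, popmap, n_permutations=99, seed=0)
        assert abs(res.table["pct_variation"].iloc[0]) < 3.0
        assert res.table["p_value"].iloc[0] > 0.05

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(18)
        g = rng.integers(0, 3, size=(16, 60)).astype(np.int8)
        g[rng.random(g.shape) < 0.1] = MISSING
        panel, popmap = _regioned_panel(g, [4, 4, 4, 4], n_south=2)
        from invadrift import amova

        res = amova(panel, popmap, n_permutations=99, seed=1)
        assert res.table["pct_variation"].sum() == pytest.approx(100.0, abs=0.01)
        assert res.table["df"].sum() == 2 * 16 - 1

    def test_components_match_distance_oracle(self):
        """Balanced complete-data toy: components solved from brute-force
        distance-matrix sums of squares via the balanced nested-ANOVA
        expectations equal the implementation's to 1e-9."""
        rng = np.random.default_rng(19)
        g = rng.integers(0, 3, size=(8, 6)).astype(np.int8)
        pops = [np.arange(0, 2), np.arange(2, 4), np.arange(4, 6), np.arange(6, 8)]
        regions = [[0, 1], [2, 3]]
        ss_tot, ss_wr, ss_wp, ss_wi = oracle_amova_ss(g, pops, regions)
        n_ind, n_pop, n_reg = 8, 4, 2
        c_per_pop, q_per_reg = 2, 2  # balanced design
        sig4 = ss_wi / n_ind
        ms_ai = (ss_wp - ss_wi) / (n_ind - n_pop)
        sig3 = (ms_ai - sig4) / 2.0
        ms_ap = (ss_wr - ss_wp) / (n_pop - n_reg)
        sig2 = (ms_ap - sig4 - 2.0 * sig3) / (2.0 * c_per_pop)
        ms_ar = (ss_tot - ss_wr) / (n_reg - 1)
        sig1 = (ms_ar - sig4 - 2.0 * sig3 - 2.0 * c_per_pop * sig2) / (
            2.0 * c_per_pop * q_per_reg
        )

        panel, popmap = _regioned_panel(g, [2, 2, 2, 2], n_south=2)
        from invadrift import amova

        res = amova(panel, popmap, n_permutations=99, seed=2)
        # the implementation reports per-site-average components; the
        # brute-force solve above works on site-summed SS
        expected = [sig1 / 6, sig2 / 6, sig3 / 6, sig4 / 6]
        for got, want in zip(res.table["sigma2"], expected):
            assert got == pytest.approx(want, abs=1e-9)

    def test_single_population_region_rejected(self):
        rng = np.random.default_rng(20)
        g = rng.integers(0, 3, size=(8, 10)).astype(np.int8)
        panel, popmap = _regioned_panel(g, [4, 4], n_south=1)
        from invadrift import amova

        with pytest.raises(ValueError, match="single population"):
            amova(panel, popmap, n_permutations=99, seed=0)


# ---------------------------------------------------------------------------
# geography / IBD / PCA / histogram
# ---------------------------------------------------------------------------

class TestGreatCircle:
    def test_identical_points(self):
        assert great_circle_km(44.6, -124.0, 44.6, -124.0) == 0.0

    def test_antipodal(self):
        assert great_circle_km(0, 0, 0, 180) == pytest.approx(math.pi * 6371, rel=1e-9)

    def test_quarter_circle(self):
        assert great_circle_km(0, 0, 0, 90) == pytest.approx(6371 * math.pi / 2, rel=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            great_circle_km(91, 0, 0, 0)


def _fst_result_from_matrix(mat, names):
    import pandas as pd

    df = pd.DataFrame(mat, index=names, columns=names, dtype=float)
    return FstResult(overall=float(np.nanmean(mat)), pairwise=df)


class TestIbd:
    def _popmap(self, names):
        coords = {n: (35.0 + 5.0 * k, -120.0) for k, n in enumerate(names)}
        return PopulationMap({}, coords)

    def test_perfect_linear_fit(self):
        names = ["a", "b", "c", "d"]
        pm = self._popmap(names)
        d = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                d[i, j] = great_circle_km(35 + 5 * i, -120, 35 + 5 * j, -120)
        fst = _fst_result_from_matrix(2e-5 * d + 0.01, names)
        res = ibd_regression(fst, pm)
        assert res.r_squared_adj == pytest.approx(1.0, abs=1e-9)
        assert res.slope == pytest.approx(2e-5, rel=1e-9)

    def test_constant_fst_zero_slope(self):
        names = ["a", "b", "c"]
        res = ibd_regression(_fst_result_from_matrix(np.full((3, 3), 0.02), names), self._popmap(names))
        assert res.slope == pytest.approx(0.0, abs=1e-15)

    def test_matches_normal_equations(self):
        names = ["a", "b", "c", "d", "e"]
        pm = self._popmap(names)
        rng = np.random.default_rng(55)
        mat = np.zeros((5, 5))
        iu = np.triu_indices(5, k=1)
        vals = rng.normal(0.02, 0.01, size=len(iu[0]))
        mat[iu] = vals
        mat = mat + mat.T
        fst = _fst_result_from_matrix(mat, names)
        res = ibd_regression(fst, pm)
        x = res.distance_km.values[iu]
        y = mat[iu]
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        intercept = y.mean() - slope * x.mean()
        assert res.slope == pytest.approx(slope, rel=1e-9)
        assert res.intercept == pytest.approx(intercept, rel=1e-9)

    def test_degenerate_distances_rejected(self):
        names = ["a", "b", "c"]
        coords = {n: (40.0, -120.0) for n in names}
        pm = PopulationMap({}, coords)
        with pytest.raises(ValueError, match="degenerate"):
            ibd_regression(_fst_result_from_matrix(np.ones((3, 3)) * 0.01, names), pm)


class TestPca:
    def test_two_clusters_separate_on_pc1(self):
        g = np.concatenate([np.zeros((5, 10)), np.full((5, 10), 2)]).astype(np.int8)
        panel, _ = make_panel(g, [5, 5])
        scores, pct = pca_genotypes(panel, 2)
        assert pct[0] > 99.0
        pc1 = scores["PC1"].to_numpy()
        assert len(np.unique(np.sign(pc1[:5]))) == 1
        assert (np.sign(pc1[:5]) != np.sign(pc1[5:])).all()

    def test_scores_centered(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, size=(12, 30)).astype(np.int8)
        panel, _ = make_panel(g, [6, 6])
        scores, _ = pca_genotypes(panel, 3)
        assert np.allclose(scores.mean(axis=0), 0.0, atol=1e-9)

    def test_truncated_reconstruction_is_optimal(self):
        rng = np.random.default_rng(4)
        g = rng.integers(0, 3, size=(10, 25)).astype(np.int8)
        panel, _ = make_panel(g, [5, 5])
        k = 3
        scores, _ = pca_genotypes(panel, k)
        x = g.astype(float)
        x -= x.mean(axis=0)
        # independent full decomposition: optimal rank-k residual energy
        evals = np.linalg.eigvalsh(x.T @ x)[::-1]
        opt_residual = evals[k:].sum()
        achieved = (x**2).sum() - (scores.values**2).sum()
        assert achieved == pytest.approx(opt_residual, rel=1e-9)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(5)
        g = rng.integers(0, 3, size=(8, 12)).astype(np.int8)
        panel, _ = make_panel(g, [4, 4])
        s1, _ = pca_genotypes(panel, 2)
        s2, _ = pca_genotypes(panel, 2)
        assert np.array_equal(s1.values, s2.values)


class TestHistogram:
    def test_all_zero_thetas_single_bin(self):
        fst = FstResult(overall=0.0, per_site=np.zeros(50))
        counts, edges = per_snp_fst_histogram(fst, bin_width=0.05)
        assert counts.sum() == 50
        assert (counts > 0).sum() == 1

    def test_totals_match_defined_sites(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(-0.1, 0.9, size=80)
        vals[::7] = np.nan
        fst = FstResult(overall=0.1, per_site=vals)
        counts, _ = per_snp_fst_histogram(fst)
        assert counts.sum() == np.isfinite(vals).sum()

    def test_counts_match_recount(self):
        rng = np.random.default_rng(12)
        vals = rng.uniform(0, 0.5, size=100)
        fst = FstResult(overall=0.1, per_site=vals)
        counts, edges = per_snp_fst_histogram(fst, bin_width=0.1)
        for k in range(len(counts)):
            lo, hi = edges[k], edges[k + 1]
            if k == len(counts) - 1:
                expected = ((vals >= lo) & (vals <= hi)).sum()
            else:
                expected = ((vals >= lo) & (vals < hi)).sum()
            assert counts[k] == expected
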