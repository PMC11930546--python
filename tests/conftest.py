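import numpy as np
import pytest

from invadrift import GenotypePanel, PopulationMap, SurvivalRecord, TreatmentLabel


@pytest.fixture
def worked_example_records():
    """Two individuals dying at day 7 and three at day 10 (all died)."""
    t = TreatmentLabel(20.0, "dark")
    days = [7, 7, 10, 10, 10]
    return [
        SurvivalRecord(f"i{k}", "r1", t, "died", float(d), experiment_id="ex")
        for k, d in enumerate(days)
    ]


def make_panel(genotypes, pop_sizes, coords=None, prefix="pop"):
    """Build a panel plus population map from a genotype matrix and a list of
    population sizes (rows are assigned to populations in order)."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n = genotypes.shape[0]
    assert sum(pop_sizes) == n
    ind_ids = [f"ind{i}" for i in range(n)]
    site_ids = [f"s{j}" for j in range(genotypes.shape[1])]
    panel = GenotypePanel(genotypes, ind_ids, site_ids)
    mapping = {}
    i = 0
    names = [f"{prefix}{k}" for k in range(len(pop_sizes))]
    for name, size in zip(names, pop_sizes):
        for _ in range(size):
            mapping[ind_ids[i]] = name
            i += 1
    if coords is None:
        coords = {name: (35.0 + 3.0 * k, -120.0 - k) for k, name in enumerate(names)}
    popmap = PopulationMap(mapping, coords)
    return panel, popmap


@pytest.fixture
def toy_panel_three_pops():
    """3 populations x 3 individuals, 5 sites, complete data, seeded."""
    rng = np.random.default_rng(42)
    g = rng.integers(0, 3, size=(9, 5))
    # ensure every site polymorphic
    g[0] = [0, 1, 2, 1, 0]
    g[4] = [2, 1, 0, 1, 2]
    return make_panel(g, [3, 3, 3])
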