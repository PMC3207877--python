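import numpy as np
import pytest

import envscan


@pytest.fixture(scope="session")
def small_selected_panel():
    """30 populations in 5 continents, 5 genes driven by helminth richness."""
    cfg = envscan.SimulationConfig(
        n_continents=5, pops_per_continent=6, n_snps=400, snps_per_gene=4,
        frac_genic=0.5, n_selected_genes=5, effect_size=0.3, seed=11,
    )
    return envscan.simulate_panel(cfg)


@pytest.fixture(scope="session")
def small_null_panel():
    """12 populations in 3 continents, no selection."""
    cfg = envscan.SimulationConfig(
        n_continents=3, pops_per_continent=4, n_snps=240, snps_per_gene=4,
        frac_genic=0.5, n_selected_genes=0, effect_size=0.0, seed=7,
    )
    return envscan.simulate_panel(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_distance_matrix(n, labels, rng):
    """A valid Euclidean distance matrix on random points."""
    from envscan.distances import DistanceMatrix
    x = rng.standard_normal((n, 3))
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix(list(labels), d)
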