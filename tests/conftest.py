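import numpy as np
import pytest

import gsdesign as g
from gsdesign.experiments import fit_full_model


@pytest.fixture(scope="session")
def small_bundle():
    """Desk-scale panel + trial shared by model and CV tests."""
    cfg = g.SimulationConfig(n_pops=3, n_lines_per_pop=60, n_markers=200,
                             n_chromosomes=5, divergence=0.3, n_cohorts=1,
                             selected_trait=None, seed=7)
    return g.simulate_bundle(cfg)


@pytest.fixture(scope="session")
def small_kinship(small_bundle):
    return g.build_kinship(small_bundle.G)


@pytest.fixture(scope="session")
def small_full_model(small_bundle, small_kinship):
    y = small_bundle.phenotypes["trait_quant"].to_numpy()
    return g.fit_one_step(y, small_bundle.layout, small_kinship)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_genotypes(rng, n_lines=8, n_markers=12, prefix=""):
    calls = rng.choice([-1.0, 1.0], size=(n_lines, n_markers))
    return g.GenotypeMatrix(
        np.array([f"{prefix}L{i}" for i in range(n_lines)]),
        np.array([f"{prefix}M{j}" for j in range(n_markers)]),
        calls,
    )
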