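import numpy as np
import pytest
from hypothesis import settings

import spacephylo as sp

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

TOY_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def toy_tree():
    """3-leaf ultrametric tree: d(A,B)=2, d(A,C)=d(B,C)=4, root age 2."""
    return sp.read_tree(TOY_NEWICK)


@pytest.fixture(scope="session")
def small_params():
    """A scaled-down study: 4 plots, modest richness, quick to simulate."""
    return sp.SimParams(
        n_species_pool=40,
        n_plots_forest=2,
        n_plots_grassland=2,
        richness_forest=(5, 15),
        richness_grassland=(5, 15),
        individuals_forest=(40, 80),
        individuals_grassland=(60, 100),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_params):
    return sp.simulate_study(small_params)


@pytest.fixture(scope="session")
def small_sdm(small_study):
    return sp.patristic_matrix(small_study.tree, list(small_study.tree.leaf_labels))


def random_trees(n_trees: int, max_leaves: int = 16, seed: int = 0):
    """Stream of small random Yule trees for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    for _ in range(n_trees):
        n = int(rng.integers(3, max_leaves + 1))
        age = float(rng.uniform(10, 200))
        yield sp.simulate_tree(n, age, rng)


def make_plot(coords, species, plot_id="P1", vegetation="forest", statuses=None,
              families=None, size=5.0):
    """Handmade plot from parallel coordinate/species lists."""
    statuses = statuses or ["indigenous"] * len(species)
    families = families or [None] * len(species)
    plants = tuple(
        sp.PlantRecord(
            individual_id=f"i{k}", species=s, status=st, family=f, x=float(x), y=float(y)
        )
        for k, ((x, y), s, st, f) in enumerate(zip(coords, species, statuses, families))
    )
    return sp.PlotData(plot_id=plot_id, vegetation=vegetation, width=size, height=size,
                       plants=plants)
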