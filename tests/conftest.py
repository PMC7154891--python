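import numpy as np
import pytest
from hypothesis import settings

import gcphylo as g
from gcphylo.likelihood import ModelParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_tree():
    return g.read_newick("((A:0.3,B:0.5):0.2,(C:0.1,D:0.4):0.6);")


@pytest.fixture(scope="session")
def small_alignment():
    return g.Alignment({"A": "ACG", "B": "ACT", "C": "GCG", "D": "ACG"})


@pytest.fixture(scope="session")
def two_clade_fit():
    """One 2-clade simulation + matching fit, shared across tests."""
    recipe = g.make_clade_recipe(
        {"lowgc": 0.3, "highgc": 0.7}, n_per_clade=3, n_sites=2000, seed=11
    )
    aln = g.simulate_alignment(recipe)
    model = g.NonHomogeneousGC(aln, recipe.tree, recipe.classes, scheme="M1")
    results = model.fit(seed=0)
    return recipe, aln, results


def random_params(rng, n_classes):
    return ModelParams(
        theta=rng.uniform(0.15, 0.85, n_classes),
        theta_root=float(rng.uniform(0.2, 0.8)),
        kappa=float(rng.uniform(0.5, 5.0)),
        alpha=float(rng.uniform(0.3, 3.0)),
    )
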