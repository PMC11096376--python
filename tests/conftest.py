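import numpy as np
import pytest

from migsem.cycle_data import derive_table
from migsem.phylo_cov import parse_newick, vcv_from_tree
from migsem.synthetic_data import simulate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """20-species bundle shared by the fast end-to-end tests."""
    return simulate_bundle(n_species=20, mean_records_per_species=8, seed=42)


@pytest.fixture(scope="session")
def small_derived(small_bundle):
    return derive_table(small_bundle.records, small_bundle.traits)


@pytest.fixture(scope="session")
def small_phylo(small_bundle):
    return vcv_from_tree(parse_newick(small_bundle.newick))


def random_tree_newick(rng: np.random.Generator, n_tips: int) -> str:
    """Random binary tree with random branch lengths (test oracle input)."""
    nodes = [f"T{i}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        la, lb = rng.uniform(0.1, 2.0, size=2)
        nodes.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return nodes[0] + ";"
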