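import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from accelscan.phylo import NeutralModel, SubstitutionModel, parse_newick
from accelscan.synth import make_rev_model, make_tree


@pytest.fixture
def jc():
    return SubstitutionModel.jukes_cantor()


@pytest.fixture
def jc_model(jc):
    tree = parse_newick("((A:0.12,B:0.3):0.07,(C:0.25,D:0.1):0.2);")
    return NeutralModel(tree, jc)


@pytest.fixture
def rev_model_factory():
    """Random REV model + random small tree, reproducible by seed."""

    def build(seed: int, n_leaves: int = 4) -> NeutralModel:
        rng = np.random.default_rng(seed)
        tree = make_tree(max(n_leaves, 4), seed, depth=rng.uniform(0.3, 1.0))
        if n_leaves < tree.n_leaves:
            keep = list(tree.leaf_names)[:n_leaves]
            tree = tree.prune_to(keep)
        return NeutralModel(tree, make_rev_model(seed + 10_000))

    return build


@pytest.fixture(scope="session")
def desk_model():
    """The 12-leaf desk-scale model used across the heavier tests."""
    tree = make_tree(12, 1)
    return NeutralModel(tree, make_rev_model(2))
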