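"""Shared fixtures: toy metabolic models and small trees, generated in-process."""

import numpy as np
import pandas as pd
import pytest

from ecometab import metabolism, synthetic


@pytest.fixture(scope="session")
def crossfeed_models():
    """Donor d1 -> receiver r1 (vitb1, obligate) plus prototroph control p1."""
    plans = [synthetic.CrossFeedPlan("d1", "r1", "vitb1")]
    return synthetic.gen_toy_models(["d1", "r1", "p1"], plans, seed=0)


@pytest.fixture(scope="session")
def prototroph_pair():
    """Two independent prototrophs with identical requirements."""
    models = synthetic.gen_toy_models(["pa", "pb"], [], seed=0)
    return [models["pa"], models["pb"]]


@pytest.fixture()
def cherry_newick():
    return "(a:0.2,b:0.3);"


@pytest.fixture(scope="session")
def random_tree_ids():
    ids = [f"g{i:02d}" for i in range(12)]
    trees = synthetic.gen_phylogeny(ids, {g: "Bacteria" for g in ids}, seed=7)
    return trees["Bacteria"], ids
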