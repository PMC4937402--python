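import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from milknet import FeatureTable, GroupAssignment, milk_study_preset

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

sys.path.insert(0, str(Path(__file__).parent))  # for reference_values


def make_signed_graph(n_pos: int, n_neg: int, seed: int = 0) -> nx.Graph:
    """A connected-ish random graph with the requested signed edge counts;
    every edge carries r/p/sign attributes."""
    rng = np.random.default_rng(seed)
    m = n_pos + n_neg
    # enough nodes that a simple graph with m edges exists
    n = max(3, int(np.ceil((1 + np.sqrt(1 + 8 * m)) / 2)) + 2)
    g = nx.gnm_random_graph(n, m, seed=seed)
    while g.number_of_edges() < m:  # pragma: no cover - gnm always hits m
        g.add_edge(*rng.integers(0, n, 2))
    signs = ["pos"] * n_pos + ["neg"] * n_neg
    for (a, b), sign in zip(g.edges, signs):
        r = float(rng.uniform(0.5, 0.99)) * (1 if sign == "pos" else -1)
        g.edges[a, b].update(r=r, p=0.01, sign=sign)
    return g


def sign_all_edges(g: nx.Graph, sign: str = "pos") -> nx.Graph:
    for a, b in g.edges:
        g.edges[a, b].update(r=0.9 if sign == "pos" else -0.9, p=0.01, sign=sign)
    return g


@pytest.fixture
def small_table() -> FeatureTable:
    df = pd.DataFrame(
        [[10, 20], [5, 0], [1, 3]],
        index=["OTU1", "OTU2", "OTU3"],
        columns=["S1", "S2"],
    )
    return FeatureTable(df, feature_kind="otu")


@pytest.fixture
def groups_pre_post() -> GroupAssignment:
    return GroupAssignment({"S1": "pre", "S2": "pre", "S3": "post", "S4": "post"})


@pytest.fixture(scope="session")
def milk_scenario() -> dict:
    return milk_study_preset(seed=42)
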