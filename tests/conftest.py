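import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pathextend import SeedSet


@pytest.fixture
def small_expr() -> pd.DataFrame:
    rng = np.random.default_rng(7)
    return pd.DataFrame(
        rng.gamma(2.0, 1.0, size=(6, 10)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{j}" for j in range(10)],
    )


@pytest.fixture
def clique_world() -> tuple[nx.Graph, dict]:
    """Ten disjoint 6-cliques, each uniquely sharing one GO term."""
    net = nx.Graph()
    annot = {}
    for c in range(10):
        genes = [f"c{c}_{i}" for i in range(6)]
        for i, a in enumerate(genes):
            annot[a] = {f"GO:{c + 1:07d}"}
            for b in genes[i + 1:]:
                net.add_edge(a, b)
    return net, annot


@pytest.fixture
def toy_seeds() -> SeedSet:
    labels = ("fatty_acid_synthesis", "lipid_trafficking")
    return SeedSet(
        subpathway={"s1": labels[0], "s2": labels[0], "s3": labels[1]},
        labels=labels,
    )
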