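import networkx as nx
import numpy as np
import pandas as pd
import pytest

from neri.netio import CONTROL, DISEASE, IntegratedNetwork


def make_network(edges, control=None, disease=None, n_samples=4, rng_seed=0):
    """IntegratedNetwork from an explicit edge list plus per-gene expression.

    ``control``/``disease`` map gene -> value list; genes without an entry
    get deterministic pseudo-random values so every gene is covered.
    """
    g = nx.Graph()
    g.add_edges_from(edges)
    genes = sorted(g.nodes)
    rng = np.random.default_rng(rng_seed)
    out = {}
    for cond, given in ((CONTROL, control or {}), (DISEASE, disease or {})):
        n = n_samples
        for v in given.values():
            n = len(v)
            break
        rows = {g_: (list(given[g_]) if g_ in given else rng.normal(size=n).tolist())
                for g_ in genes}
        prefix = "C" if cond == CONTROL else "D"
        out[cond] = pd.DataFrame.from_dict(rows, orient="index",
                                           columns=[f"{prefix}{i}" for i in range(n)])
    return IntegratedNetwork(graph=g, expression=out)


@pytest.fixture
def line_abc():
    """Path graph a-b-c with fixed expression in both conditions."""
    return make_network([("A", "B"), ("B", "C")], n_samples=5, rng_seed=1)
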