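import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from cernanet import ExpressionMatrix, InteractionSet

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """3 genes (one per biotype) x 6 samples, log2 scale."""
    values = pd.DataFrame(
        [[5.0, 5.2, 4.8, 3.0, 3.1, 2.9],
         [8.0, 8.1, 7.9, 9.5, 9.6, 9.4],
         [6.0, 6.1, 5.9, 4.5, 4.4, 4.6]],
        index=["ASCC3", "miR-4728-5p", "NOTCH2"],
        columns=["c1", "c2", "c3", "s1", "s2", "s3"])
    biotype = pd.Series({"ASCC3": "lncRNA", "miR-4728-5p": "miRNA",
                         "NOTCH2": "mRNA"})
    group = pd.Series({"c1": "control", "c2": "control", "c3": "control",
                       "s1": "stretch", "s2": "stretch", "s3": "stretch"})
    return ExpressionMatrix(values, biotype, group)


@pytest.fixture
def toy_interactions() -> InteractionSet:
    return InteractionSet.from_tuples([
        ("miR-4728-5p", "ASCC3", "lncRNA", "starbase"),
        ("miR-4728-5p", "NOTCH2", "mRNA", "starbase"),
    ])


def enumerate_hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Exhaustive-enumeration oracle for P(|S ∩ top-K| >= k), |S| = n.

    Counts every one of the C(N, n) equally likely draws directly;
    independent of any library tail function.
    """
    hits = 0
    top = set(range(K))
    for S in itertools.combinations(range(N), n):
        if len(top.intersection(S)) >= k:
            hits += 1
    return hits / math.comb(N, n)


def make_interactions_for_counts(N: int, K: int, n: int,
                                 k: int) -> tuple[InteractionSet, set]:
    """Interaction set realizing exact overlap counts for one (lnc, mrna).

    lnc interacts with miRNAs 0..K-1; mrna with k of those plus n-k
    outside; background is all N miRNAs (padded with a dummy target so
    unconnected miRNAs still appear in the set).
    """
    mirs = [f"b{i}" for i in range(N)]
    rows = [(mirs[i], "L", "lncRNA", "") for i in range(K)]
    mrna_mirs = mirs[:k] + mirs[K:K + (n - k)]
    rows += [(m, "M", "mRNA", "") for m in mrna_mirs]
    rows += [(m, "PAD", "mRNA", "") for m in mirs]
    return InteractionSet.from_tuples(rows), set(mirs)


def random_tripartite(rng: np.random.Generator):
    """Random valid tripartite ceRNA network for property tests."""
    import networkx as nx
    n_l = int(rng.integers(1, 5))
    n_u = int(rng.integers(1, 7))
    n_m = int(rng.integers(1, 8))
    g = nx.Graph()
    lncs = [f"l{i}" for i in range(n_l)]
    mirs = [f"u{i}" for i in range(n_u)]
    mrnas = [f"m{i}" for i in range(n_m)]
    for x in lncs:
        g.add_node(x, biotype="lncRNA")
    for x in mirs:
        g.add_node(x, biotype="miRNA")
    for x in mrnas:
        g.add_node(x, biotype="mRNA")
    for u in mirs:
        for t in lncs + mrnas:
            if rng.random() < 0.3:
                g.add_edge(u, t)
    return g
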