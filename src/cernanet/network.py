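"""Tripartite ceRNA network construction, hub ranking and ego subnetworks.

The network has three node classes (lncRNA, miRNA, mRNA) and edges only
between lncRNA-miRNA and miRNA-mRNA — the two legs of each sponge
relationship.  Node importance is plain degree (incident edge count);
hubs are the top-ranked nodes above a strict degree cutoff.  The ego
subnetwork of a lncRNA is the center, its miRNA partners, the mRNAs
adjacent to those miRNAs, and every network edge within that node set.
"""

from __future__ import annotations

import pandas as pd
import networkx as nx

from .core_io import BIOTYPE_ORDER


def validate_network(g: nx.Graph) -> None:
    """Raise unless the graph is a well-formed tripartite ceRNA network."""
    for n, data in g.nodes(data=True):
        if data.get("biotype") not in BIOTYPE_ORDER:
            raise ValueError(f"node {n!r} has invalid biotype "
                             f"{data.get('biotype')!r}")
    for u, v in g.edges():
        if u == v:
            raise ValueError(f"self-loop at {u!r}")
        bts = {g.nodes[u]["biotype"], g.nodes[v]["biotype"]}
        if bts not in ({"lncRNA", "miRNA"}, {"miRNA", "mRNA"}):
            raise ValueError(f"edge {u!r}-{v!r} violates the tripartite "
                             f"structure: {sorted(bts)}")


def build_network(pairs: pd.DataFrame) -> nx.Graph:
    """Assemble the network from a ceRNA pair table.

    Each pair contributes its lncRNA, mRNA and shared miRNAs as nodes and
    the edges (lncRNA, miRNA) and (miRNA, mRNA) for every shared miRNA;
    nodes and edges are shared between pairs.  A pair with an empty
    shared-miRNA set is an error.
    """
    g = nx.Graph()
    for _, row in pairs.iterrows():
        shared = [m for m in str(row["shared_mirnas"]).split(";") if m]
        if not shared:
            raise ValueError(f"pair ({row['lncrna']!r}, {row['mrna']!r}) "
                             "has an empty shared miRNA set")
        g.add_node(row["lncrna"], biotype="lncRNA")
        g.add_node(row["mrna"], biotype="mRNA")
        for mu in shared:
            g.add_node(mu, biotype="miRNA")
            g.add_edge(row["lncrna"], mu)
            g.add_edge(mu, row["mrna"])
    validate_network(g)
    return g


def _node_sort_key(g: nx.Graph):
    def key(item):
        node, degree = item
        return (-degree, BIOTYPE_ORDER[g.nodes[node]["biotype"]], node)
    return key


def node_degrees(network: nx.Graph) -> pd.DataFrame:
    """Per-node incident edge count, sorted by degree descending.

    Ties break by biotype (lncRNA < miRNA < mRNA) then lexicographically,
    so the table is deterministic.
    """
    items = sorted(network.degree(), key=_node_sort_key(network))
    rows = [(n, network.nodes[n]["biotype"], d) for n, d in items]
    return pd.DataFrame(rows, columns=["node_id", "biotype", "degree"])


def top_hubs(degrees: pd.DataFrame, k: int = 20,
             min_degree: int = 5) -> pd.DataFrame:
    """Top-k nodes with degree strictly greater than ``min_degree``.

    Ranking is degree descending with the biotype-then-lexicographic
    tie-break of :func:`node_degrees`.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    kept = degrees[degrees["degree"] > min_degree]
    kept = kept.sort_values(
        ["degree", "biotype", "node_id"],
        ascending=[False, True, True],
        key=lambda s: s.map(BIOTYPE_ORDER) if s.name == "biotype" else s,
        kind="stable")
    return kept.head(k).reset_index(drop=True)


def extract_subnetwork(network: nx.Graph, center: str) -> nx.Graph:
    """Ego subnetwork of a lncRNA: center, its miRNAs, their mRNAs.

    Edges are all network edges with both endpoints inside that node set,
    so no node lies at graph distance greater than 2 from the center.
    The operation is idempotent around the same center.
    """
    if center not in network:
        raise ValueError(f"center {center!r} not in network")
    if network.nodes[center]["biotype"] != "lncRNA":
        raise ValueError(f"center {center!r} is not a lncRNA")
    mirs = {n for n in network.neighbors(center)
            if network.nodes[n]["biotype"] == "miRNA"}
    mrnas = {m for mu in mirs for m in network.neighbors(mu)
             if network.nodes[m]["biotype"] == "mRNA"}
    keep = {center} | mirs | mrnas
    sub = nx.Graph()
    for n in keep:
        sub.add_node(n, biotype=network.nodes[n]["biotype"])
    for u, v in network.edges():
        if u in keep and v in keep:
            sub.add_edge(u, v)
    return sub


def network_summary(network: nx.Graph) -> dict[str, int]:
    """Node counts per biotype and the edge count."""
    counts = {"lncRNA": 0, "miRNA": 0, "mRNA": 0}
    for _, data in network.nodes(data=True):
        counts[data["biotype"]] += 1
    return {"n_lncrna": counts["lncRNA"], "n_mirna": counts["miRNA"],
            "n_mrna": counts["mRNA"], "n_edges": network.number_of_edges()}
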