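"""Signed interaction networks from significant residual correlations.

Nodes are the taxa incident to at least one significant edge (taxa that were
modelled but never flagged do not enter the graph — this is what makes
linkage density = edges / nodes the "average number of edges per node" over
network members). Edges carry the posterior median residual correlation and
its sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class NetworkStats:
    linkage_density: float
    nodes: int
    edges: int
    pct_positive: float
    group_counts: dict
    photosynthetic_microbes: int

    def to_dict(self) -> dict:
        return {
            "linkage_density": self.linkage_density,
            "nodes": self.nodes,
            "edges": self.edges,
            "pct_positive": self.pct_positive,
            "group_counts": dict(self.group_counts),
            "photosynthetic_microbes": self.photosynthetic_microbes,
        }


def build_network(edges: pd.DataFrame, annotations: pd.DataFrame) -> nx.Graph:
    """Undirected signed graph from an edge table.

    ``edges`` needs columns taxon_a, taxon_b, median_rho, sign (the output of
    ``jsdm.significant_edges``); ``annotations`` is a taxon-indexed frame with
    ``group`` and ``trophic`` columns. Self-loops are rejected, duplicate
    pairs are dropped with a warning, and only taxa with >= 1 edge become
    nodes.
    """
    g = nx.Graph()
    seen = set()
    for row in edges.itertuples(index=False):
        a, b = str(row.taxon_a), str(row.taxon_b)
        if a == b:
            raise ValueError(f"self-edge on taxon {a!r}")
        key = (min(a, b), max(a, b))
        if key in seen:
            logger.warning("build_network: duplicate edge %s-%s dropped", a, b)
            continue
        seen.add(key)
        for t in (a, b):
            if t not in annotations.index:
                raise ValueError(f"edge references unannotated taxon {t!r}")
        g.add_edge(a, b, weight=float(row.median_rho), sign=str(row.sign))
    for t in g.nodes:
        g.nodes[t]["group"] = str(annotations.loc[t, "group"])
        g.nodes[t]["trophic"] = str(annotations.loc[t, "trophic"])
    return g


def linkage_density(nodes: int, edges: int) -> float:
    """Network complexity: average number of edges per node (edges/nodes)."""
    if nodes < 0 or edges < 0:
        raise ValueError("counts must be non-negative")
    return edges / nodes if nodes else 0.0


def network_stats(g: nx.Graph) -> NetworkStats:
    """All headline statistics of one stage's network."""
    n, e = g.number_of_nodes(), g.number_of_edges()
    pos = sum(1 for _, _, d in g.edges(data=True) if d.get("sign") == "positive")
    groups = ["bacteria", "fungi", "small_eukaryote", "microfauna", "plant"]
    counts = {grp: 0 for grp in groups}
    counts["unknown"] = 0
    photo = 0
    for t, data in g.nodes(data=True):
        grp = data.get("group", "unknown")
        counts[grp if grp in counts else "unknown"] += 1
        if (data.get("trophic") == "photosynthetic" and grp != "plant"):
            photo += 1
    return NetworkStats(
        linkage_density=linkage_density(n, e),
        nodes=n,
        edges=e,
        pct_positive=(100.0 * pos / e) if e else 0.0,
        group_counts=counts,
        photosynthetic_microbes=photo,
    )


def cross_group_edge_count(g: nx.Graph, selector_a, selector_b) -> int:
    """Edges with one endpoint matching each predicate over (group, trophic).

    Symmetric in the two selectors. An edge whose endpoints both satisfy both
    selectors is counted once.
    """
    count = 0
    for a, b in g.edges():
        ga = (g.nodes[a].get("group"), g.nodes[a].get("trophic"))
        gb = (g.nodes[b].get("group"), g.nodes[b].get("trophic"))
        if (selector_a(*ga) and selector_b(*gb)) or (selector_a(*gb) and selector_b(*ga)):
            count += 1
    return count


def degree_ranking(g: nx.Graph) -> list:
    """Taxa sorted by degree descending, ties broken by taxon id."""
    return [t for t, _ in sorted(g.degree(), key=lambda kv: (-kv[1], kv[0]))]


def round_density(x: float, ndigits: int = 1) -> float:
    """Half-up rounding as printed in ecological tables (16.65 -> 16.7)."""
    from decimal import ROUND_HALF_UP, Decimal
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
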