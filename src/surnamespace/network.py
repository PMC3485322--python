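"""Thresholded surname networks and their local/global statistics.

The surname space is the undirected graph whose nodes are surnames and whose
edges are relatedness links with value at or above a threshold *d*.  Local
structure is summarized by the node degree k_i (how embedded a surname is in
its sub-space); global structure by the mean degree c = 2m/n and the density
ρ = 2m / (n(n-1)) — the fraction of possible links realized — which compare
the internal homogeneity of different parts of the space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import LookupError_, UndefinedStatisticError, ValidationError
from .relatedness import LinkRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkStats:
    """Global statistics of a surname (sub-)network.

    n nodes, m edges, mean degree c = 2m/n, density rho = 2m/(n(n-1)).
    ``rho`` is None for n < 2 where it is undefined.
    """

    n: int
    m: int
    c: float
    rho: float | None

    def rounded(self) -> dict[str, float | int | None]:
        """Conventional reporting precision: c to 1 decimal, rho to 3."""
        return {
            "n": self.n,
            "m": self.m,
            "c": round(self.c, 1),
            "rho": None if self.rho is None else round(self.rho, 3),
        }


def build_network(
    links: Iterable[LinkRecord],
    node_attrs: Mapping[str, Mapping[str, object]] | None = None,
    d: float = 0.0,
    include_isolated: Iterable[str] | None = None,
) -> nx.Graph:
    """Assemble the undirected surname network from relatedness links.

    Every link value must be >= ``d`` (a violated threshold is a contract
    error, not silently dropped), pairs must be unique, and self-loops are
    forbidden.  Nodes are exactly the surnames incident to a link, plus the
    surnames in ``include_isolated`` if given; by default isolated surnames
    are left out, matching the convention that only linked names are drawn.
    """
    g = nx.Graph(threshold=float(d))
    for rec in links:
        if rec.surname_i == rec.surname_j:
            raise ValidationError(f"self-loop on {rec.surname_i!r}")
        if rec.value < d:
            raise ValidationError(
                f"link ({rec.surname_i}, {rec.surname_j}) value {rec.value} below threshold {d}"
            )
        if g.has_edge(rec.surname_i, rec.surname_j):
            raise ValidationError(
                f"duplicate link ({rec.surname_i}, {rec.surname_j})"
            )
        g.add_edge(rec.surname_i, rec.surname_j, weight=float(rec.value))
    if include_isolated is not None:
        g.add_nodes_from(include_isolated)
    if node_attrs:
        for node in g.nodes:
            attrs = node_attrs.get(node)
            if attrs:
                g.nodes[node].update(attrs)
    logger.info("built network: n=%d, m=%d, d=%g", g.number_of_nodes(), g.number_of_edges(), d)
    return g


def degree(net: nx.Graph, surname: str) -> int:
    """Degree k_i: the number of relatedness links incident to the surname."""
    if surname not in net:
        raise LookupError_(f"surname {surname!r} not in network")
    return int(net.degree[surname])


def network_stats(net: nx.Graph, subset: Iterable[str] | None = None) -> NetworkStats:
    """(n, m, c, rho) of the network or of the subgraph induced by ``subset``."""
    g = net.subgraph(list(subset)) if subset is not None else net
    n = g.number_of_nodes()
    m = g.number_of_edges()
    if n == 0:
        raise UndefinedStatisticError("statistics undefined for an empty network")
    c = 2.0 * m / n
    rho = None if n < 2 else 2.0 * m / (n * (n - 1))
    return NetworkStats(n=n, m=m, c=c, rho=rho)


def degree_distribution(net: nx.Graph) -> dict[int, int]:
    """Histogram {degree: node count}; Σ degree·count = 2m."""
    if net.number_of_nodes() == 0:
        raise UndefinedStatisticError("degree distribution undefined for an empty network")
    hist: dict[int, int] = {}
    for _, k in net.degree:
        hist[k] = hist.get(k, 0) + 1
    return dict(sorted(hist.items()))


def hubs(
    net: nx.Graph,
    grouping: Mapping[str, str] | Callable[[str], str] | None = None,
    top_n: int | None = None,
    min_degree: int | None = None,
) -> dict[str, list[tuple[str, int]]]:
    """Per-group lists of high-degree (hub) surnames with their degrees.

    Hubs are the names most embedded in their part of the space — exemplars
    of a local population.  Groups come from node labels (e.g. max-LQ
    attribution regions or externally delineated communities); nodes without
    a label fall into "ungrouped".  Within each group, names are sorted by
    degree descending, ties lexicographic, then cut by ``top_n`` and/or
    ``min_degree``.
    """
    if top_n is not None and top_n <= 0:
        raise ValidationError("top_n must be positive")
    label: Callable[[str], str]
    if grouping is None:
        label = lambda s: "all"
    elif callable(grouping):
        label = grouping
    else:
        label = lambda s: grouping.get(s, "ungrouped")
    by_group: dict[str, list[tuple[str, int]]] = {}
    for node, k in net.degree:
        by_group.setdefault(label(node), []).append((node, int(k)))
    out: dict[str, list[tuple[str, int]]] = {}
    for grp in sorted(by_group):
        members = sorted(by_group[grp], key=lambda t: (-t[1], t[0]))
        if min_degree is not None:
            members = [t for t in members if t[1] >= min_degree]
        if top_n is not None:
            members = members[:top_n]
        out[grp] = members
    return out


def connected_components(net: nx.Graph) -> list[set[str]]:
    """Maximal connected components, largest first; ties by the smallest
    member label.  Isolated nodes come out as singleton components."""
    comps = [set(c) for c in nx.connected_components(net)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def degree_vs_frequency(
    net: nx.Graph, totals: Mapping[str, int]
) -> tuple[pd.DataFrame, float | None]:
    """Pair each node's degree with its bearer count and return the Spearman
    rank correlation (ties handled by the usual mid-rank convention).

    The interesting empirical finding is the *absence* of a relationship:
    frequent surnames are not automatically hubs.  Returns correlation None
    (flagged) when either variable is constant, where Spearman is undefined.
    """
    missing = [s for s in net.nodes if s not in totals]
    if missing:
        raise ValidationError(f"missing bearer totals for: {sorted(missing)[:5]}")
    nodes = sorted(net.nodes)
    df = pd.DataFrame(
        {
            "surname": nodes,
            "degree": [net.degree[s] for s in nodes],
            "bearers": [int(totals[s]) for s in nodes],
        }
    )
    if df["degree"].nunique() < 2 or df["bearers"].nunique() < 2:
        logger.warning("degree or frequency is constant; Spearman correlation undefined")
        return df, None
    rho = sps.spearmanr(df["degree"], df["bearers"]).statistic
    return df, float(rho)


def detect_communities_greedy(net: nx.Graph) -> list[set[str]]:
    """Exploratory greedy-modularity community detection.

    Offered as a convenience only: delineating surname communities is in
    practice a judgement call that automated detection handles poorly, so
    treat these partitions as a starting point, not a result.
    """
    comms = nx.algorithms.community.greedy_modularity_communities(net)
    return sorted((set(c) for c in comms), key=lambda c: (-len(c), min(c)))


def export_graph(net: nx.Graph, path: str | Path, fmt: str = "graphml") -> Path:
    """Write the network for external visualization (e.g. Cytoscape/Gephi).

    fmt="graphml"    node attributes and edge weights preserved; a read-back
                     recovers the identical graph;
    fmt="edgelist"   CSV surname_i,surname_j,weight (one row per edge);
    fmt="nodetable"  CSV surname,degree,<other node attributes>.
    """
    if net.number_of_nodes() == 0:
        raise ValidationError("refusing to export an empty network")
    path = Path(path)
    if fmt == "graphml":
        g = net.copy()
        for node in g.nodes:
            g.nodes[node]["degree"] = int(net.degree[node])
        nx.write_graphml(g, path, encoding="utf-8")
    elif fmt == "edgelist":
        rows = [
            {"surname_i": min(u, v), "surname_j": max(u, v), "weight": d.get("weight", 1.0)}
            for u, v, d in net.edges(data=True)
        ]
        pd.DataFrame(rows).sort_values(
            ["surname_i", "surname_j"], ignore_index=True, kind="mergesort"
        ).to_csv(path, index=False, encoding="utf-8")
    elif fmt == "nodetable":
        attr_keys = sorted({k for _, d in net.nodes(data=True) for k in d})
        rows = []
        for node in sorted(net.nodes):
            row: dict[str, object] = {"surname": node, "degree": int(net.degree[node])}
            for k in attr_keys:
                row[k] = net.nodes[node].get(k)
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")
    else:
        raise ValidationError(f"unknown export format {fmt!r}")
    return path


def read_graphml(path: str | Path) -> nx.Graph:
    """Read a network previously written by :func:`export_graph`."""
    return nx.read_graphml(Path(path))
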