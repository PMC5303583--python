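"""Normalized degree and betweenness centrality, overall and per gender stratum.

Both measures run on the binarized co-occurrence network: degree centrality
is the fraction of other nodes a problem is directly connected to,
degree/(n-1); betweenness is the share of shortest paths between other node
pairs passing through a problem, normalized by (n-1)(n-2)/2. Weights never
enter shortest paths by default — connections are counted, not summed — but
a weighted variant (distance = 1/weight) is available behind a flag.

Normalization uses the full taxonomy node count n even when some problems
were never reported in a stratum, so scores stay comparable across strata;
isolates score 0 on both measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import Cohort, STRATA, filter_stratum
from .network import CooccurrenceNetwork, build_network, to_networkx

__all__ = [
    "degree_centrality",
    "betweenness_centrality",
    "centrality_report",
    "CentralityTable",
]


def degree_centrality(net: CooccurrenceNetwork) -> dict[str, float]:
    """Distinct-neighbor count over (n - 1), per node."""
    if net.n_nodes < 2:
        raise ValueError("degree centrality needs at least 2 nodes")
    return nx.degree_centrality(to_networkx(net))


def betweenness_centrality(
    net: CooccurrenceNetwork, weighted: bool = False
) -> dict[str, float]:
    """Shortest-path betweenness over (n-1)(n-2)/2, per node.

    Pairs in different components contribute 0; normalization keeps the full
    n. With ``weighted=True`` shortest paths minimize summed 1/weight
    distances instead of hop counts.
    """
    if net.n_nodes < 3:
        raise ValueError("betweenness centrality needs at least 3 nodes")
    g = to_networkx(net)
    dist = None
    if weighted:
        for _, _, d in g.edges(data=True):
            d["inv_weight"] = 1.0 / d["weight"]
        dist = "inv_weight"
    return nx.betweenness_centrality(g, normalized=True, weight=dist)


@dataclass(frozen=True)
class CentralityTable:
    """Per-node degree/betweenness scores for total/male/female strata.

    ``table`` is indexed by node with columns ``(stratum)_degree`` and
    ``(stratum)_betweenness``; entries are NaN for strata with no cases, and
    betweenness is NaN for strata in which fewer than 3 nodes were reported.
    """

    table: pd.DataFrame
    level: str
    n_nodes: int


def _stratum_scores(net: CooccurrenceNetwork, n_cases: int) -> tuple[dict, dict]:
    nan = {v: np.nan for v in net.nodes}
    if n_cases == 0:
        return nan, nan
    deg = degree_centrality(net)
    reported = sum(1 for v in net.nodes if net.occurrence[v] > 0)
    btw = betweenness_centrality(net) if reported >= 3 else nan
    return deg, btw


def centrality_report(cohort: Cohort, level: str = "leaf") -> CentralityTable:
    """Build total/male/female networks at ``level`` and tabulate both measures."""
    nets = {"total": build_network(cohort, level)}
    sizes = {"total": len(cohort)}
    for gender in ("male", "female"):
        sub = filter_stratum(cohort, gender)
        nets[gender] = build_network(sub, level)
        sizes[gender] = len(sub)

    nodes = nets["total"].nodes
    data: dict[str, list[float]] = {}
    for stratum in STRATA:
        deg, btw = _stratum_scores(nets[stratum], sizes[stratum])
        data[f"{stratum}_degree"] = [deg[v] for v in nodes]
        data[f"{stratum}_betweenness"] = [btw[v] for v in nodes]
    table = pd.DataFrame(data, index=pd.Index(nodes, name="node"))
    table.insert(0, "class", [nets["total"].node_class[v] for v in nodes])
    return CentralityTable(table=table, level=level, n_nodes=len(nodes))
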