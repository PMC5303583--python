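"""Problem co-occurrence network: construction, density, binarization, export.

Nodes are problem categories (leaf subcategories or their 6 parent classes);
an edge links two problems reported together by at least one case, weighted
by the number of such cases. Whole-network density — realized node pairs over
possible pairs on the binarized network — doubles as the significance
cut-off for blockmodel densities.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from .cohort import Cohort

__all__ = [
    "CooccurrenceNetwork",
    "build_network",
    "binarize",
    "network_density",
    "to_networkx",
    "write_graphml",
    "write_gexf",
    "write_edgelist",
]

LEVELS = ("leaf", "class")


@dataclass(frozen=True)
class CooccurrenceNetwork:
    """Symmetric integer co-occurrence weights over a fixed node order.

    ``weight[i, j]`` = number of cases reporting both node i and node j
    (zero diagonal); ``occurrence[node]`` = number of cases reporting the
    node at all. Nodes never reported stay in the taxonomy-ordered node
    list (stable matrix shapes across strata) and are listed in
    ``unreported``.
    """

    nodes: tuple[str, ...]
    occurrence: dict[str, int]
    weight: np.ndarray
    level: str
    node_class: dict[str, str]  # leaf -> parent class (identity at class level)

    def __post_init__(self) -> None:
        w = np.asarray(self.weight)
        n = len(self.nodes)
        if w.shape != (n, n):
            raise ValueError("weight matrix shape must match node count")
        if not np.array_equal(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weight matrix must have zero diagonal")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        occ = np.array([self.occurrence[v] for v in self.nodes])
        if np.any(w > np.minimum.outer(occ, occ)):
            raise ValueError("weight[i, j] cannot exceed min(occurrence)")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def unreported(self) -> tuple[str, ...]:
        return tuple(v for v in self.nodes if self.occurrence[v] == 0)

    def index(self, node: str) -> int:
        return self.nodes.index(node)


def _case_nodes(case_problems: frozenset[str], level: str, cohort: Cohort) -> set[str]:
    if level == "leaf":
        return set(case_problems)
    # class level: map each leaf to its class and deduplicate
    return {cohort.taxonomy.class_of(l) for l in case_problems}


def build_network(cohort: Cohort, level: str = "leaf") -> CooccurrenceNetwork:
    """Count, over cases, the unordered pairs within each case's problem set.

    Single-problem cases contribute occurrence only; zero-problem cases
    contribute nothing. At class level each case's problems are first mapped
    leaf -> class and deduplicated, so a class pair counts once per case no
    matter how many leaf pairs induce it.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    tax = cohort.taxonomy
    nodes = tuple(tax.subcategories if level == "leaf" else tax.classes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    weight = np.zeros((n, n), dtype=int)
    occurrence = {v: 0 for v in nodes}
    for case in cohort.cases:
        items = sorted(_case_nodes(case.problems, level, cohort), key=idx.__getitem__)
        for v in items:
            occurrence[v] += 1
        for a, b in combinations(items, 2):
            weight[idx[a], idx[b]] += 1
            weight[idx[b], idx[a]] += 1
    node_class = (
        {v: tax.class_of(v) for v in nodes} if level == "leaf" else {v: v for v in nodes}
    )
    return CooccurrenceNetwork(nodes, occurrence, weight, level, node_class)


def binarize(net: CooccurrenceNetwork) -> np.ndarray:
    """0/1 adjacency: entry 1 iff the pair co-occurred at least once."""
    return (net.weight > 0).astype(int)


def network_density(net: CooccurrenceNetwork) -> float:
    """Distinct co-occurring pairs over all possible pairs, on the binarized net."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    edges = int(binarize(net).sum()) // 2
    return edges / (n * (n - 1) / 2)


def to_networkx(net: CooccurrenceNetwork, weighted: bool = True) -> nx.Graph:
    """Undirected networkx graph with occurrence/class node attributes."""
    g = nx.Graph()
    for v in net.nodes:
        g.add_node(v, occurrence=int(net.occurrence[v]), problem_class=net.node_class[v])
    w = net.weight
    for i, a in enumerate(net.nodes):
        for j in range(i + 1, net.n_nodes):
            if w[i, j] > 0:
                if weighted:
                    g.add_edge(a, net.nodes[j], weight=int(w[i, j]))
                else:
                    g.add_edge(a, net.nodes[j])
    return g


def write_graphml(net: CooccurrenceNetwork, path) -> None:
    nx.write_graphml(to_networkx(net), path)


def write_gexf(net: CooccurrenceNetwork, path) -> None:
    nx.write_gexf(to_networkx(net), path)


def write_edgelist(net: CooccurrenceNetwork, path, delimiter: str = ",") -> None:
    """Delimited source,target,weight rows in node order."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["source", "target", "weight"])
        w = net.weight
        for i, a in enumerate(net.nodes):
            for j in range(i + 1, net.n_nodes):
                if w[i, j] > 0:
                    writer.writerow([a, net.nodes[j], int(w[i, j])])
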