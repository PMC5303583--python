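"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the code paths they check: pair counting
by a literal double loop, centrality by exhaustive path enumeration, CONCOR
by an unoptimized pure-Python iterate-correlations loop.
"""

from __future__ import annotations

import numpy as np
import pytest

from precipnet import CaseRecord, Cohort, CooccurrenceNetwork, default_taxonomy


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture()
def micro_cohort(taxonomy):
    """Five hand-checkable cases: 0/1/2/3-problem mix, both genders."""
    cases = (
        CaseRecord("c1", "female", 34, "medicines",
                   frozenset({"family_conflicts", "depression"})),
        CaseRecord("c2", "male", 21, None, frozenset({"drug_addiction"})),
        CaseRecord("c3", "female", 40, "pesticides",
                   frozenset({"family_conflicts", "physical_illness", "depression"})),
        CaseRecord("c4", "male", 55, None, frozenset()),
        CaseRecord("c5", "female", 19, None, frozenset({"romantic_problems"})),
    )
    return Cohort(taxonomy, cases)


def random_cohort(rng: np.random.Generator, taxonomy, n_cases: int,
                  max_k: int = 5, p_gender_missing: float = 0.0) -> Cohort:
    """Uniform random multi-label cohort for property tests."""
    leaves = list(taxonomy.subcategories)
    cases = []
    for i in range(n_cases):
        k = int(rng.integers(0, max_k + 1))
        problems = frozenset(rng.choice(leaves, size=k, replace=False))
        if p_gender_missing and rng.random() < p_gender_missing:
            gender = None
        else:
            gender = "female" if rng.random() < 0.5 else "male"
        cases.append(CaseRecord(f"r{i}", gender, None, None, problems))
    return Cohort(taxonomy, tuple(cases))


def net_from_adjacency(adj: np.ndarray) -> CooccurrenceNetwork:
    """Wrap a 0/1 adjacency matrix as a co-occurrence network (unit weights)."""
    adj = np.asarray(adj, dtype=int)
    n = len(adj)
    nodes = tuple(f"n{i}" for i in range(n))
    occurrence = {f"n{i}": int(adj[i].max(initial=0)) for i in range(n)}
    return CooccurrenceNetwork(nodes, occurrence, adj, "leaf",
                               {v: "c" for v in nodes})


# ---------------------------------------------------------------- oracles --

def brute_pair_counts(cohort: Cohort, level: str = "leaf"):
    """Literal double loop over cases and unordered pairs."""
    tax = cohort.taxonomy
    counts: dict[frozenset, int] = {}
    occ: dict[str, int] = {}
    for case in cohort.cases:
        if level == "leaf":
            items = sorted(case.problems)
        else:
            items = sorted({tax.class_of(l) for l in case.problems})
        for v in items:
            occ[v] = occ.get(v, 0) + 1
        for i, a in enumerate(items):
            for b in items[i + 1:]:
                key = frozenset({a, b})
                counts[key] = counts.get(key, 0) + 1
    return counts, occ


def brute_degree(adj: np.ndarray) -> list[float]:
    """Neighbor-set sizes from a full scan, over n - 1."""
    n = len(adj)
    return [sum(1 for j in range(n) if j != i and adj[i][j] > 0) / (n - 1)
            for i in range(n)]


def brute_betweenness(adj: np.ndarray) -> list[float]:
    """Exhaustive simple-path enumeration; shortest-path shares per interior node."""
    adj = np.asarray(adj)
    n = len(adj)
    score = [0.0] * n
    for s in range(n):
        for t in range(s + 1, n):
            paths: list[list[int]] = []

            def dfs(v: int, path: list[int]) -> None:
                if v == t:
                    paths.append(list(path))
                    return
                for u in range(n):
                    if adj[v][u] and u not in path:
                        path.append(u)
                        dfs(u, path)
                        path.pop()

            dfs(s, [s])
            if not paths:
                continue
            shortest = min(len(p) for p in paths)
            sp = [p for p in paths if len(p) == shortest]
            for p in sp:
                for v in p[1:-1]:
                    score[v] += 1.0 / len(sp)
    norm = (n - 1) * (n - 2) / 2
    return [x / norm for x in score]


def _corr(x: list[float], y: list[float]) -> float:
    mx = sum(x) / len(x)
    my = sum(y) / len(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = (sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)) ** 0.5
    if den == 0:
        return 0.0
    return max(-1.0, min(1.0, num / den))


def concor_oracle_bipartition(profiles, tol: float = 1e-8,
                              max_iter: int = 200) -> frozenset:
    """Literal iterate-correlations loop; returns the two groups as frozensets."""
    P = [list(map(float, row)) for row in profiles]
    n = len(P)
    C = [[1.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            xs = [P[i][k] for k in range(n) if k not in (i, j)]
            ys = [P[j][k] for k in range(n) if k not in (i, j)]
            C[i][j] = C[j][i] = _corr(xs, ys)
    for _ in range(max_iter):
        if all(abs(abs(C[i][j]) - 1.0) < tol
               for i in range(n) for j in range(n) if i != j):
            break
        nxt = [[1.0] * n for _ in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                nxt[i][j] = nxt[j][i] = _corr([C[k][i] for k in range(n)],
                                              [C[k][j] for k in range(n)])
        C = nxt
    a = frozenset(j for j in range(n) if C[0][j] >= 0)
    b = frozenset(range(n)) - a
    return frozenset({a, b})


def brute_block_density(adj: np.ndarray, membership: list[int]) -> dict:
    """Edge counts per block pair by direct enumeration."""
    n = len(adj)
    blocks = sorted(set(membership))
    out = {}
    for b1 in blocks:
        m1 = [i for i in range(n) if membership[i] == b1]
        within = sum(1 for i in m1 for j in m1 if i < j and adj[i][j])
        possible = len(m1) * (len(m1) - 1) / 2
        out[(b1, b1)] = within / possible if possible else None
        for b2 in blocks:
            if b2 <= b1:
                continue
            m2 = [i for i in range(n) if membership[i] == b2]
            between = sum(1 for i in m1 for j in m2 if adj[i][j])
            out[(b1, b2)] = between / (len(m1) * len(m2))
    return out
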