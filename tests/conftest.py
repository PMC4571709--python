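"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own code paths (and
networkx where the library uses networkx), so tests compare two
independent routes to the same quantity.
"""

from __future__ import annotations

import numpy as np
import pytest

from trophoweb import FoodWeb


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def chain_web():
    """basal -> herbivore -> carnivore."""
    return FoodWeb([("a", "b"), ("b", "c")], name="chain")


@pytest.fixture
def triangle_webs():
    """Two disjoint 3-cycles (undirected triangles)."""
    return FoodWeb(
        [("a", "b"), ("b", "c"), ("c", "a"), ("d", "e"), ("e", "f"), ("f", "d")],
        name="triangles",
    )


def random_web(rng: np.random.Generator, S: int, p: float, ensure_links: int = 1) -> FoodWeb:
    """Random directed web (self-links allowed) with at least ensure_links links."""
    while True:
        links = [
            (f"n{i}", f"n{j}")
            for i in range(S)
            for j in range(S)
            if rng.random() < p
        ]
        web = FoodWeb(links, nodes=[f"n{i}" for i in range(S)])
        if web.L >= ensure_links:
            return web


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def set_partitions(items: list):
    """Enumerate all set partitions (Bell-number search)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield part + [[first]]


def modularity_by_hand(web: FoodWeb, assignment: dict) -> float:
    """Term-by-term evaluation of M on the undirected projection."""
    und = {tuple(sorted((u, v))) for u, v in web.links if u != v}
    L = len(und)
    deg = {n: 0 for n in web.nodes}
    for u, v in und:
        deg[u] += 1
        deg[v] += 1
    modules = set(assignment.values())
    total = 0.0
    for s in modules:
        mem = {n for n in assignment if assignment[n] == s}
        I_s = sum(1 for u, v in und if u in mem and v in mem)
        d_s = sum(deg[n] for n in mem)
        total += I_s / L - (d_s / (2 * L)) ** 2
    return total


def exhaustive_best_modularity(web: FoodWeb) -> float:
    best = -2.0
    for part in set_partitions(sorted(web.nodes)):
        assignment = {n: i + 1 for i, blk in enumerate(part) for n in blk}
        m = modularity_by_hand(web, assignment)
        best = max(best, m)
    return best


def floyd_warshall_mean_path(web: FoodWeb) -> float:
    """All-pairs brute force on the undirected projection, largest component."""
    nodes = sorted(web.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    INF = float("inf")
    dist = [[INF] * n for _ in range(n)]
    for i in range(n):
        dist[i][i] = 0
    for u, v in web.links:
        if u != v:
            dist[idx[u]][idx[v]] = 1
            dist[idx[v]][idx[u]] = 1
    for k in range(n):
        for i in range(n):
            dik = dist[i][k]
            if dik == INF:
                continue
            for j in range(n):
                if dik + dist[k][j] < dist[i][j]:
                    dist[i][j] = dik + dist[k][j]
    # largest connected component
    comps = []
    seen = set()
    for i in range(n):
        if i in seen:
            continue
        comp = {j for j in range(n) if dist[i][j] < INF}
        seen |= comp
        comps.append(comp)
    lcc = max(comps, key=len)
    pairs = [(i, j) for i in lcc for j in lcc if i != j]
    return sum(dist[i][j] for i, j in pairs) / len(pairs)


def triangle_clustering(web: FoodWeb) -> float:
    """Per-node triangle counting on the undirected projection; mean over nodes."""
    neigh = {n: set() for n in web.nodes}
    for u, v in web.links:
        if u != v:
            neigh[u].add(v)
            neigh[v].add(u)
    vals = []
    for n in web.nodes:
        k = len(neigh[n])
        if k < 2:
            vals.append(0.0)
            continue
        tri = sum(
            1
            for a in neigh[n]
            for b in neigh[n]
            if a < b and b in neigh[a]
        )
        vals.append(2 * tri / (k * (k - 1)))
    return sum(vals) / len(vals)


def nodes_in_cycles(web: FoodWeb) -> set:
    """Nodes on a directed cycle of length >= 2, by DFS path enumeration."""
    succ = {n: set() for n in web.nodes}
    for u, v in web.links:
        if u != v:
            succ[u].add(v)
    in_cycle = set()

    def dfs(start, current, visited):
        for nxt in succ[current]:
            if nxt == start and len(visited) >= 2:
                in_cycle.update(visited)
            elif nxt not in visited and nxt > start:
                dfs(start, nxt, visited | {nxt})

    for s in sorted(web.nodes):
        dfs(s, s, {s})
    return in_cycle
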