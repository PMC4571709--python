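"""Modularity, simulated-annealing module detection, and degree-preserving
null-model significance testing.

Modularity is computed on the undirected projection of the web with
self-links removed (mutual predation collapses to a single link):

    M = sum_s [ I_s / L - (d_s / 2L)^2 ]

where the sum runs over modules s, I_s is the number of links between
nodes in module s, L is the (undirected) link count and d_s the summed
degree of module s. A random partition has expected M of 0; a single
module gives exactly 0.

The partition search is stochastic optimization by simulated annealing:
single-node reassignments plus collective merge/split moves, accepted with
probability min(1, exp(dM/T)) on a geometric temperature ladder. The
significance of an empirical modularity is assessed against networks with
an identical degree sequence, produced by double-edge swaps.
"""

from __future__ import annotations

import logging
import math
import random
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core import FoodWeb, FoodWebError

logger = logging.getLogger(__name__)


@dataclass
class ModulePartition:
    """A node -> module assignment with its modularity value.

    Module ids are 1..N_M. ``I_s`` is the within-module link count and
    ``d_s`` the summed degree per module (undirected projection).
    """

    assignment: dict[str, int]
    M: float
    I_s: dict[int, int]
    d_s: dict[int, int]
    seed: int | None = None

    @property
    def N_M(self) -> int:
        return len(set(self.assignment.values()))

    def modules(self) -> dict[int, set[str]]:
        out: dict[int, set] = {}
        for node, mod in self.assignment.items():
            out.setdefault(mod, set()).add(node)
        return out


@dataclass
class NullEnsemble:
    """Modularity of degree-preserving randomized networks."""

    values: list[float]
    mean: float
    sd: float
    p_value: float
    n_replicates: int
    seed: int
    empirical_M: float


@dataclass
class AnnealSchedule:
    """Simulated-annealing schedule.

    ``t0=None`` calibrates the initial temperature from trial moves so the
    initial acceptance rate of unfavourable moves is about 0.8.
    """

    t0: float | None = None
    cooling: float = 0.95
    node_moves: int | None = None      # per temperature; default factor * S
    collective_moves: int | None = None
    node_moves_factor: float = 10.0
    collective_moves_factor: float = 0.5
    patience: int = 20                 # temperatures without improvement
    t_min_ratio: float = 1e-4

    @classmethod
    def preset(cls, name: str) -> "AnnealSchedule":
        if name == "full":
            # Guimera-Amaral-style S^2 node moves per temperature
            return cls(cooling=0.995, node_moves_factor=-1.0,
                       collective_moves_factor=1.0, patience=50)
        if name == "standard":
            return cls()
        if name == "fast":
            return cls(cooling=0.90, node_moves_factor=5.0,
                       collective_moves_factor=0.25, patience=10)
        raise ValueError(f"unknown schedule preset {name!r}")


def _undirected_arrays(web: FoodWeb):
    g = web.undirected()
    nodes = sorted(g.nodes, key=str)
    idx = {n: i for i, n in enumerate(nodes)}
    adj = [[idx[v] for v in g.neighbors(u)] for u in nodes]
    return nodes, adj, g.number_of_edges()


def modularity_value(web: FoodWeb, assignment: dict[str, int]) -> float:
    """Modularity M of a partition on the undirected projection."""
    g = web.undirected()
    missing = set(g.nodes) - set(assignment)
    if missing:
        raise FoodWebError(f"partition does not cover: {sorted(map(str, missing))}")
    L = g.number_of_edges()
    if L == 0:
        raise FoodWebError("modularity undefined for a web with no links")
    within: dict[int, int] = {}
    dsum: dict[int, int] = {}
    for u, v in g.edges:
        if assignment[u] == assignment[v]:
            within[assignment[u]] = within.get(assignment[u], 0) + 1
    for n in g.nodes:
        dsum[assignment[n]] = dsum.get(assignment[n], 0) + g.degree(n)
    return sum(
        within.get(s, 0) / L - (dsum[s] / (2 * L)) ** 2 for s in dsum
    )


def _partition_from_labels(nodes, labels, adj, L, seed=None) -> ModulePartition:
    # compact module ids to 1..N_M in order of first appearance
    remap: dict[int, int] = {}
    assignment: dict = {}
    for n, lab in zip(nodes, labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        assignment[n] = remap[lab]
    within: dict[int, int] = {}
    dsum: dict[int, int] = {}
    for i, n in enumerate(nodes):
        m = assignment[n]
        dsum[m] = dsum.get(m, 0) + len(adj[i])
        for j in adj[i]:
            if j > i and labels[j] == labels[i]:
                within[m] = within.get(m, 0) + 1
    M = sum(within.get(s, 0) / L - (dsum[s] / (2 * L)) ** 2 for s in dsum) if L else 0.0
    return ModulePartition(assignment=assignment, M=M, I_s=within, d_s=dsum, seed=seed)


def anneal_partition(
    web: FoodWeb,
    schedule: AnnealSchedule | str | None = None,
    seed: int | None = None,
    refine: bool = True,
) -> ModulePartition:
    """Find a high-modularity partition by simulated annealing.

    Starts from singleton modules; proposes single-node reassignments and
    module merges/splits; returns the best partition encountered, after a
    greedy refinement pass (``refine=False`` disables it).
    """
    if isinstance(schedule, str):
        schedule = AnnealSchedule.preset(schedule)
    elif schedule is None:
        schedule = AnnealSchedule()
    nodes, adj, L = _undirected_arrays(web)
    if L == 0:
        raise FoodWebError(f"cannot anneal {web.name!r}: no undirected links")
    n = len(nodes)
    rng = random.Random(seed)
    k = [len(a) for a in adj]
    active = [i for i in range(n) if k[i] > 0]

    labels = list(range(n))             # singleton start
    d = [k[i] for i in range(n)]        # degree sum per module label
    members: list[set[int]] = [{i} for i in range(n)]
    # current modularity
    inv2L = 1.0 / (2 * L)
    curM = -sum((di * inv2L) ** 2 for di in d if di)
    bestM = curM
    best_labels = labels[:]

    if schedule.node_moves is not None:
        node_moves = schedule.node_moves
    elif schedule.node_moves_factor < 0:
        node_moves = n * n
    else:
        node_moves = max(10, int(schedule.node_moves_factor * n))
    if schedule.collective_moves is not None:
        coll_moves = schedule.collective_moves
    else:
        coll_moves = max(2, int(schedule.collective_moves_factor * n))

    def node_move_delta(i, a, b):
        e_ia = e_ib = 0
        li = labels
        for j in adj[i]:
            lj = li[j]
            if lj == a:
                e_ia += 1
            elif lj == b:
                e_ib += 1
        return (e_ib - e_ia) / L - k[i] * (d[b] - d[a] + k[i]) * 2 * inv2L * inv2L

    def between_edges(a, b):
        small, other = (members[a], b) if len(members[a]) <= len(members[b]) else (members[b], a)
        e = 0
        for i in small:
            for j in adj[i]:
                if labels[j] == other:
                    e += 1
        return e

    # calibrate T0 so that typical unfavourable moves accept with p ~ 0.8
    if schedule.t0 is None:
        deltas = []
        for _ in range(min(200, 20 * n)):
            i = rng.choice(active)
            j = adj[i][rng.randrange(k[i])]
            if labels[j] != labels[i]:
                deltas.append(abs(node_move_delta(i, labels[i], labels[j])))
        scale = float(np.mean(deltas)) if deltas else 1.0 / L
        t0 = scale / -math.log(0.8) if scale > 0 else 1.0 / L
    else:
        t0 = schedule.t0
    t = t0
    t_min = t0 * schedule.t_min_ratio
    stall = 0

    def accept(dM):
        if dM > 1e-15:
            return True
        if dM > -1e-15:
            return rng.random() < 0.5
        return rng.random() < math.exp(dM / t)

    while t > t_min and stall < schedule.patience:
        improved = False
        for _ in range(node_moves):
            i = rng.choice(active)
            a = labels[i]
            if rng.random() < 0.05:
                # propose a fresh singleton module
                b = next((m for m in range(n) if not members[m]), None)
                if b is None:
                    continue
            else:
                j = adj[i][rng.randrange(k[i])]
                b = labels[j]
            if b == a:
                continue
            dM = node_move_delta(i, a, b)
            if accept(dM):
                labels[i] = b
                d[a] -= k[i]
                d[b] += k[i]
                members[a].discard(i)
                members[b].add(i)
                curM += dM
                if curM > bestM + 1e-12:
                    bestM = curM
                    best_labels = labels[:]
                    improved = True
        for c in range(coll_moves):
            nonempty = [m for m in range(n) if members[m]]
            if c % 2 == 0 and len(nonempty) >= 2:
                # merge two random modules
                a, b = rng.sample(nonempty, 2)
                e_ab = between_edges(a, b)
                dM = e_ab / L - d[a] * d[b] * 2 * inv2L * inv2L
                if accept(dM):
                    for i in list(members[a]):
                        labels[i] = b
                        members[b].add(i)
                    members[a].clear()
                    d[b] += d[a]
                    d[a] = 0
                    curM += dM
            else:
                # split a random module by random bisection
                big = [m for m in nonempty if len(members[m]) >= 2]
                if not big:
                    continue
                a = rng.choice(big)
                # grow a connected half from a random seed node, so the
                # proposed split follows the web's own link structure
                mem = members[a]
                target = max(1, len(mem) // 2)
                start = rng.choice(tuple(mem))
                half_set0 = {start}
                frontier = [start]
                while frontier and len(half_set0) < target:
                    u = frontier.pop(rng.randrange(len(frontier)))
                    for j in adj[u]:
                        if j in mem and j not in half_set0:
                            half_set0.add(j)
                            frontier.append(j)
                            if len(half_set0) >= target:
                                break
                half = list(half_set0)
                if len(half) == len(mem):
                    continue
                b = next((m for m in range(n) if not members[m]), None)
                if b is None:
                    continue
                half_set = set(half)
                e_ab = 0
                d_b = 0
                for i in half:
                    d_b += k[i]
                    for j in adj[i]:
                        if labels[j] == a and j not in half_set:
                            e_ab += 1
                d_a = d[a] - d_b
                dM = -(e_ab / L - d_a * d_b * 2 * inv2L * inv2L)
                if accept(dM):
                    for i in half:
                        labels[i] = b
                        members[a].discard(i)
                        members[b].add(i)
                    d[a] = d_a
                    d[b] = d_b
                    curM += dM
            if curM > bestM + 1e-12:
                bestM = curM
                best_labels = labels[:]
                improved = True
        stall = 0 if improved else stall + 1
        t *= schedule.cooling

    if refine:
        best_labels = _refine_labels(best_labels, adj, k, L, rng)
    return _partition_from_labels(nodes, best_labels, adj, L, seed=seed)


def _refine_labels(labels, adj, k, L, rng, max_rounds: int = 5):
    """Greedy post-annealing refinement: improving node moves, module
    merges, and BFS-grown splits with local polish, applied until no move
    raises M. Escapes the over-merged local optima a cooling schedule can
    leave behind."""
    n = len(labels)
    labels = labels[:]
    inv2L = 1.0 / (2 * L)

    def rebuild():
        members: dict[int, set[int]] = {}
        d: dict[int, int] = {}
        for i, lab in enumerate(labels):
            members.setdefault(lab, set()).add(i)
            d[lab] = d.get(lab, 0) + k[i]
        return members, d

    members, d = rebuild()

    def node_polish(restrict: set[int] | None = None):
        moved_any = False
        order = [i for i in range(n) if k[i] > 0 and (restrict is None or i in restrict)]
        for _ in range(20):
            moved = False
            for i in order:
                a = labels[i]
                counts: dict[int, int] = {}
                for j in adj[i]:
                    counts[labels[j]] = counts.get(labels[j], 0) + 1
                e_ia = counts.get(a, 0)
                best_dm, best_b = 0.0, None
                for b, e_ib in counts.items():
                    if b == a or (restrict is not None and not members[b] & restrict):
                        continue
                    dm = (e_ib - e_ia) / L - k[i] * (d[b] - d[a] + k[i]) * 2 * inv2L * inv2L
                    if dm > best_dm + 1e-12:
                        best_dm, best_b = dm, b
                if best_b is not None:
                    d[a] -= k[i]
                    d[best_b] += k[i]
                    members[a].discard(i)
                    if not members[a]:
                        del members[a], d[a]
                    members[best_b].add(i)
                    labels[i] = best_b
                    moved = moved_any = True
            if not moved:
                break
        return moved_any

    def between(a, b):
        small, other = (a, b) if len(members[a]) <= len(members[b]) else (b, a)
        return sum(1 for i in members[small] for j in adj[i] if labels[j] == other)

    def merge_sweep():
        merged_any = False
        while True:
            mods = list(members)
            best = (0.0, None)
            for ai in range(len(mods)):
                for bi in range(ai + 1, len(mods)):
                    a, b = mods[ai], mods[bi]
                    dm = between(a, b) / L - d[a] * d[b] * 2 * inv2L * inv2L
                    if dm > best[0] + 1e-12:
                        best = (dm, (a, b))
            if best[1] is None:
                return merged_any
            a, b = best[1]
            for i in members[a]:
                labels[i] = b
            members[b] |= members[a]
            d[b] += d[a]
            del members[a], d[a]
            merged_any = True

    def try_splits():
        improved = False
        for a in list(members):
            mem = members.get(a)
            if mem is None or len(mem) < 4:
                continue
            snapshot = {i: labels[i] for i in mem}
            m_before = _labels_m_of(mem)
            # grow a connected half from a random member
            target = len(mem) // 2
            start = rng.choice(tuple(mem))
            half = {start}
            frontier = [start]
            while frontier and len(half) < target:
                u = frontier.pop()
                for j in adj[u]:
                    if j in mem and j not in half:
                        half.add(j)
                        frontier.append(j)
                        if len(half) >= target:
                            break
            if len(half) == len(mem):
                continue
            b = _fresh_label()
            for i in half:
                labels[i] = b
            members[a] = mem - half
            members[b] = half
            d_b = sum(k[i] for i in half)
            d[b] = d_b
            d[a] -= d_b
            node_polish(restrict=set(snapshot))
            if _labels_m_of(set(snapshot)) > m_before + 1e-12:
                improved = True
            else:  # revert
                for i, lab in snapshot.items():
                    cur = labels[i]
                    members[cur].discard(i)
                    if not members[cur]:
                        del members[cur], d[cur]
                    else:
                        d[cur] -= k[i]
                    labels[i] = lab
                    members.setdefault(lab, set()).add(i)
                    d[lab] = d.get(lab, 0) + k[i]
        return improved

    def _fresh_label():
        lab = max(members) + 1
        while lab in members:
            lab += 1
        return lab

    def _labels_m_of(node_set: set[int]) -> float:
        # M contribution of the modules touching node_set
        mods = {labels[i] for i in node_set}
        m = 0.0
        for s in mods:
            within = sum(
                1 for i in members[s] for j in adj[i] if j > i and labels[j] == s
            )
            m += within / L - (d[s] * inv2L) ** 2
        return m

    for _ in range(max_rounds):
        changed = node_polish()
        changed |= merge_sweep()
        changed |= try_splits()
        if not changed:
            break
    return labels


def replicate_partitions(
    web: FoodWeb,
    n: int,
    seed: int | None = None,
    schedule: AnnealSchedule | str | None = None,
) -> tuple[list[ModulePartition], ModulePartition]:
    """n independent seeded annealing runs plus one designated replicate.

    The designated replicate (a randomly chosen run) supplies the module
    membership used for reporting; the full list feeds replicate-based
    confidence intervals.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) for s in ss.generate_state(n + 1)]
    parts = [
        anneal_partition(web, schedule=schedule, seed=child_seeds[i] % (2**31))
        for i in range(n)
    ]
    designated = parts[child_seeds[n] % n]
    return parts, designated


def randomize_degree_preserving(
    web: FoodWeb,
    swaps_per_link: int = 10,
    seed: int | None = None,
) -> FoodWeb:
    """Randomize links while preserving every node's (undirected) degree.

    Double-edge swaps on the undirected projection; no self-links or
    multi-links are introduced. The result is returned as a food web with
    one arbitrary direction per undirected link, suitable for modularity
    analysis (which projects back to undirected).
    """
    g = web.undirected()
    L = g.number_of_edges()
    if L < 2:
        warnings.warn(f"{web.name!r}: too few links to swap; returning input")
        return web.copy(name=f"{web.name}_null")
    nswap = swaps_per_link * L
    try:
        nx.double_edge_swap(g, nswap=nswap, max_tries=100 * nswap, seed=seed)
    except nx.NetworkXError as err:
        warnings.warn(f"{web.name!r}: degree-preserving swap not possible ({err})")
    out = FoodWeb.__new__(FoodWeb)
    out.name = f"{web.name}_null"
    out.graph = nx.DiGraph()
    out.graph.add_nodes_from(g.nodes(data=True))
    out.graph.add_edges_from(g.edges)
    return out


def null_modularity_test(
    web: FoodWeb,
    n: int = 1000,
    seed: int | None = None,
    schedule: AnnealSchedule | str | None = None,
    null_schedule: AnnealSchedule | str | None = None,
    empirical_M: float | None = None,
    swaps_per_link: int = 10,
) -> NullEnsemble:
    """Is the web more modular than degree-matched random networks?

    Each replicate randomizes the web with degree-preserving swaps and
    anneals a partition (a reduced schedule may be used for replicates).
    p = (1 + #{M_null >= M_emp}) / (n + 1), the small-sample-corrected
    one-sided permutation p-value.
    """
    ss = np.random.SeedSequence(seed)
    states = ss.generate_state(2 * n + 1)
    if empirical_M is None:
        empirical_M = anneal_partition(
            web, schedule=schedule, seed=int(states[2 * n]) % (2**31)
        ).M
    if null_schedule is None:
        null_schedule = schedule
    values = []
    for i in range(n):
        null_web = randomize_degree_preserving(
            web, swaps_per_link=swaps_per_link, seed=int(states[2 * i]) % (2**31)
        )
        part = anneal_partition(
            null_web, schedule=null_schedule, seed=int(states[2 * i + 1]) % (2**31)
        )
        values.append(part.M)
    arr = np.array(values)
    p = (1 + int((arr >= empirical_M).sum())) / (n + 1)
    return NullEnsemble(
        values=values,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if n > 1 else 0.0,
        p_value=p,
        n_replicates=n,
        seed=seed if seed is not None else -1,
        empirical_M=empirical_M,
    )
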