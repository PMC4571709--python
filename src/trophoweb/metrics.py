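"""Structural food-web metrics and degree-distribution analysis.

The metric suite covers species and link counts, linkage density,
connectance, cannibalism, loop participation, path length, clustering,
omnivory and short-weighted trophic levels — the standard descriptors of
topological food-web complexity — plus cumulative degree distributions with
an exponential-rate fit for comparing generality and vulnerability across
webs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np

from .core import FoodWeb, FoodWebError


@dataclass
class MetricsReport:
    """The per-web metric vector. ``modularity`` is filled by the
    modularity stage and is ``None`` until then."""

    S: int
    L: int
    LD: float
    C: float
    pctOmni: float
    pctCan: float
    pctLoops: float
    meanPath: float
    meanOmni: float
    meanSWTL: float
    meanClust: float
    modularity: float | None = None

    def to_dict(self, round_2dp: bool = False) -> dict:
        d = asdict(self)
        if round_2dp:
            for key, value in d.items():
                if isinstance(value, float):
                    d[key] = round(value, 2)
        return d


def linkage_density(web: FoodWeb) -> float:
    """Links per species, L/S."""
    return web.L / web.S


def connectance(web: FoodWeb) -> float:
    """Fraction of realized directed links, L/S^2 (self-links allowed)."""
    return web.L / web.S**2


def percent_cannibals(web: FoodWeb) -> float:
    """Percentage of species with a self-link."""
    return 100.0 * sum(1 for n in web.graph if web.graph.has_edge(n, n)) / web.S


def percent_in_loops(web: FoodWeb) -> float:
    """Percentage of species lying in a directed cycle of length >= 2.

    A node is "in a loop" when it belongs to a strongly connected component
    of size >= 2; cannibalistic self-links do not count as loops.
    """
    g = web.graph.copy()
    g.remove_edges_from(nx.selfloop_edges(g))
    in_loop = sum(len(c) for c in nx.strongly_connected_components(g) if len(c) >= 2)
    return 100.0 * in_loop / web.S


def mean_path_length(web: FoodWeb) -> float:
    """Mean shortest-path length on the undirected projection.

    Averaged over all ordered reachable pairs within the largest connected
    component; self-links are ignored.
    """
    g = web.undirected()
    if g.number_of_edges() == 0:
        raise FoodWebError(f"mean path length undefined: {web.name!r} has no links")
    lcc = g.subgraph(max(nx.connected_components(g), key=len))
    return nx.average_shortest_path_length(lcc)


def mean_clustering(web: FoodWeb) -> float:
    """Mean local clustering coefficient on the undirected projection.

    Nodes with fewer than two neighbours contribute 0.
    """
    g = web.undirected()
    return nx.average_clustering(g)


def trophic_levels(web: FoodWeb) -> dict[str, float]:
    """Short-weighted trophic level (SWTL) per node.

    SWTL is the average of (i) the shortest-chain trophic level, 1 plus the
    length of the shortest directed prey chain down to a basal node, and
    (ii) the prey-averaged trophic level TL_i = 1 + mean over prey j of
    TL_j with basal nodes fixed at 1 (linear system solved exactly).
    Self-links are excluded from a node's prey set.
    """
    g = web.graph.copy()
    g.remove_edges_from(nx.selfloop_edges(g))
    nodes = list(g.nodes)
    basal = [n for n in nodes if g.in_degree(n) == 0]
    if not basal:
        raise FoodWebError(f"{web.name!r} has no basal node (in-degree 0)")

    # shortest-chain TL: BFS along link direction (prey -> predator) from
    # all basal nodes at once.
    shortest = nx.multi_source_dijkstra_path_length(g, basal)
    unreachable = [n for n in nodes if n not in shortest]
    if unreachable:
        raise FoodWebError(
            f"no directed prey chain from a basal node to: {', '.join(map(str, sorted(unreachable)))}"
        )

    # prey-averaged TL: TL = 1 + D^-1 A TL  with A[i, j]=1 if j is prey of i
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    mat = np.eye(n)
    for i, node in enumerate(nodes):
        prey = list(g.predecessors(node))
        if prey:
            for p in prey:
                mat[i, idx[p]] -= 1.0 / len(prey)
    prey_avg = np.linalg.solve(mat, np.ones(n))

    return {
        node: (1.0 + shortest[node] + prey_avg[idx[node]]) / 2.0 for node in nodes
    }


def omnivory(web: FoodWeb, tl: dict[str, float] | None = None, span_threshold: float = 1.0) -> tuple[float, float]:
    """(pct_omni, mean_omni) from prey trophic-level spread.

    Per consumer the omnivory index is the population SD of its prey's
    SWTLs (self-links excluded). ``mean_omni`` averages the index over
    consumers with >= 2 prey; ``pct_omni`` is the percentage of species
    whose prey SWTLs span at least ``span_threshold`` trophic levels.
    """
    if tl is None:
        tl = trophic_levels(web)
    indices = []
    n_omnivores = 0
    for node in web.graph:
        prey = [p for p in web.graph.predecessors(node) if p != node]
        if not prey:
            continue
        prey_tl = np.array([tl[p] for p in prey])
        if len(prey) >= 2:
            indices.append(float(prey_tl.std()))  # population SD
        if prey_tl.max() - prey_tl.min() >= span_threshold:
            n_omnivores += 1
    mean_omni = float(np.mean(indices)) if indices else 0.0
    return 100.0 * n_omnivores / web.S, mean_omni


@dataclass
class DegreeSummary:
    """Degree sequences, cumulative survival points and exponential rate."""

    in_degrees: list[int]
    out_degrees: list[int]
    in_survival: list[tuple[int, float]]
    out_survival: list[tuple[int, float]]
    in_rate: float
    out_rate: float


def _survival(degrees: np.ndarray) -> list[tuple[int, float]]:
    ks = np.unique(degrees)
    n = len(degrees)
    return [(int(k), float((degrees >= k).sum()) / n) for k in ks]


def _exp_rate(degrees: np.ndarray, method: str = "mle") -> float:
    """Exponential rate lambda for degrees >= 1.

    ``mle``: lambda = 1/mean. ``regression``: negative slope of
    log-survival vs degree (for comparing distribution steepness).
    """
    degrees = degrees[degrees >= 1]
    if len(degrees) == 0 or degrees.mean() == 0:
        return float("nan")
    if method == "mle":
        return 1.0 / float(degrees.mean())
    if method == "regression":
        pts = _survival(degrees)
        ks = np.array([k for k, _ in pts], dtype=float)
        surv = np.array([s for _, s in pts])
        slope = np.polyfit(ks, np.log(surv), 1)[0]
        return -float(slope)
    raise ValueError(f"unknown rate-fit method {method!r}")


def degree_summary(web: FoodWeb, rate_method: str = "mle") -> DegreeSummary:
    """Cumulative in/out degree distributions with exponential-rate fits.

    In-degree is generality (number of prey), out-degree vulnerability
    (number of predators).
    """
    if web.L < 1:
        raise FoodWebError(f"{web.name!r} has no links")
    indeg = np.array([d for _, d in web.graph.in_degree()])
    outdeg = np.array([d for _, d in web.graph.out_degree()])
    return DegreeSummary(
        in_degrees=[int(d) for d in indeg],
        out_degrees=[int(d) for d in outdeg],
        in_survival=_survival(indeg),
        out_survival=_survival(outdeg),
        in_rate=_exp_rate(indeg, rate_method),
        out_rate=_exp_rate(outdeg, rate_method),
    )


def metrics_report(web: FoodWeb, modularity: float | None = None) -> MetricsReport:
    """Compute the full structural metric suite for one web."""
    tl = trophic_levels(web)
    pct_omni, mean_omni = omnivory(web, tl)
    return MetricsReport(
        S=web.S,
        L=web.L,
        LD=linkage_density(web),
        C=connectance(web),
        pctOmni=pct_omni,
        pctCan=percent_cannibals(web),
        pctLoops=percent_in_loops(web),
        meanPath=mean_path_length(web),
        meanOmni=mean_omni,
        meanSWTL=float(np.mean(list(tl.values()))),
        meanClust=mean_clustering(web),
        modularity=modularity,
    )
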