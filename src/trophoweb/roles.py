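"""Topological roles of species with respect to modularity.

Each species is placed in the z-PC plane: the standardized within-module
degree z = (k_is - mean_s) / SD_s measures how connected a species is
inside its own module relative to the other members, and the participation
coefficient PC = 1 - sum_t (k_it / k_i)^2 measures how evenly its links
spread across modules (0 when every link is internal). The plane is split
into four role regions at z = 2.5 and PC = 0.625:

    peripheral   z < 2.5, PC < 0.625   few links, mostly internal
    connector    z < 2.5, PC >= 0.625  ties modules together
    module_hub   z >= 2.5, PC < 0.625  many links inside its module
    network_hub  z >= 2.5, PC >= 0.625 super-generalist, high within- and
                                       between-module connectivity

Because module detection is stochastic, z and PC are summarized over many
annealing replicates (mean and percentile 95% CI); classification uses the
replicate means, and module membership is reported from one designated
replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FoodWeb, FoodWebError
from .modularity import ModulePartition

Z_THRESHOLD = 2.5
PC_THRESHOLD = 0.625


@dataclass
class RoleProfile:
    """Replicate-summarized topological role of one species."""

    node: str
    z_mean: float
    z_lo: float
    z_hi: float
    pc_mean: float
    pc_lo: float
    pc_hi: float
    role: str
    degree: int
    module: int


def _module_degrees(web: FoodWeb, partition: ModulePartition):
    """Per node: links into each module (undirected, self-links dropped)."""
    g = web.undirected()
    assign = partition.assignment
    missing = set(g.nodes) - set(assign)
    if missing:
        raise FoodWebError(f"partition does not cover: {sorted(map(str, missing))}")
    per_node: dict[str, dict[int, int]] = {}
    for u in g.nodes:
        counts: dict[int, int] = {}
        for v in g.neighbors(u):
            counts[assign[v]] = counts.get(assign[v], 0) + 1
        per_node[u] = counts
    return per_node


def within_module_z(web: FoodWeb, partition: ModulePartition, node: str | None = None):
    """Standardized within-module degree z.

    z_i = (k_is - mean_s) / SD_s where k_is counts node i's links to other
    members of its own module s and mean/SD (population form) are taken
    over all members of s. Modules where every member has the same k_is
    (SD = 0) give z = 0.

    Returns the full node -> z mapping, or a single value if ``node`` is
    given.
    """
    per_node = _module_degrees(web, partition)
    assign = partition.assignment
    if node is not None and node not in assign:
        raise FoodWebError(f"node {node!r} not in partition")
    kis = {u: per_node[u].get(assign[u], 0) for u in per_node}
    stats: dict[int, tuple[float, float]] = {}
    for mod, mem in partition.modules().items():
        vals = np.array([kis[u] for u in mem], dtype=float)
        stats[mod] = (float(vals.mean()), float(vals.std()))  # population SD
    z = {}
    for u in per_node:
        mean, sd = stats[assign[u]]
        z[u] = (kis[u] - mean) / sd if sd > 0 else 0.0
    return z[node] if node is not None else z


def participation_coefficient(
    web: FoodWeb,
    partition: ModulePartition,
    node: str | None = None,
    form: str = "quadratic",
):
    """Among-module connectivity PC.

    ``quadratic`` (default): PC = 1 - sum_t (k_it/k_i)^2, summed over all
    modules t including the node's own. ``ratio``: the simple fraction of
    links leaving the node's own module. Isolated nodes get PC = 0.
    """
    per_node = _module_degrees(web, partition)
    assign = partition.assignment
    pc = {}
    for u, counts in per_node.items():
        k = sum(counts.values())
        if k == 0:
            pc[u] = 0.0
        elif form == "quadratic":
            pc[u] = 1.0 - sum((kit / k) ** 2 for kit in counts.values())
        elif form == "ratio":
            pc[u] = 1.0 - counts.get(assign[u], 0) / k
        else:
            raise ValueError(f"unknown PC form {form!r}")
    return pc[node] if node is not None else pc


def classify_role(z: float, pc: float) -> str:
    """Four-region role classification at z = 2.5 and PC = 0.625
    (thresholds inclusive on the hub/connector side)."""
    if z >= Z_THRESHOLD:
        return "network_hub" if pc >= PC_THRESHOLD else "module_hub"
    return "connector" if pc >= PC_THRESHOLD else "peripheral"


def role_profiles(
    web: FoodWeb,
    partitions: list[ModulePartition],
    designated: ModulePartition | None = None,
    pc_form: str = "quadratic",
) -> list[RoleProfile]:
    """Summarize z and PC over annealing replicates.

    Per node: mean and percentile (2.5, 97.5) CI of z and PC across
    partitions; role classified from the means; module id taken from the
    designated partition (default: the first).
    """
    if not partitions:
        raise ValueError("at least one partition required")
    if designated is None:
        designated = partitions[0]
    nodes = sorted(web.nodes, key=str)
    zmat = np.empty((len(partitions), len(nodes)))
    pmat = np.empty((len(partitions), len(nodes)))
    for r, part in enumerate(partitions):
        z = within_module_z(web, part)
        pc = participation_coefficient(web, part, form=pc_form)
        zmat[r] = [z[n] for n in nodes]
        pmat[r] = [pc[n] for n in nodes]
    z_mean, p_mean = zmat.mean(axis=0), pmat.mean(axis=0)
    z_lo, z_hi = np.percentile(zmat, [2.5, 97.5], axis=0)
    p_lo, p_hi = np.percentile(pmat, [2.5, 97.5], axis=0)
    return [
        RoleProfile(
            node=n,
            z_mean=float(z_mean[i]),
            z_lo=float(z_lo[i]),
            z_hi=float(z_hi[i]),
            pc_mean=float(p_mean[i]),
            pc_lo=float(p_lo[i]),
            pc_hi=float(p_hi[i]),
            role=classify_role(float(z_mean[i]), float(p_mean[i])),
            degree=web.degree_of(n),
            module=designated.assignment[n],
        )
        for i, n in enumerate(nodes)
    ]
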