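"""Do food-web modules segregate by habitat and trophic level?

Discriminant-style permutation test: predictors are indicator-coded
habitat (B / P / BP) and short-weighted trophic level, the grouping is the
module assignment, and the separation statistic is the trace ratio of
between-group to total scatter on standardized predictors (a Pillai-type
statistic). Significance comes from permuting module labels:
p = (1 + #{stat_perm >= stat_obs}) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import HABITATS, FoodWebError
from .modularity import ModulePartition


@dataclass
class AssociationResult:
    statistic: float
    p_value: float
    n_permutations: int
    per_module: dict[int, dict]
    mode: str
    seed: int | None


def _design_matrix(nodes, habitat, swtl, mode):
    cols = []
    names = []
    if mode in ("joint", "habitat"):
        for code in HABITATS:
            cols.append(np.array([1.0 if habitat[n] == code else 0.0 for n in nodes]))
            names.append(f"habitat_{code}")
    if mode in ("joint", "trophic"):
        cols.append(np.array([float(swtl[n]) for n in nodes]))
        names.append("swtl")
    X = np.column_stack(cols)
    keep, kept_names = [], []
    dropped_constant = []
    for j, name in enumerate(names):
        sd = X[:, j].std()
        if sd == 0:
            dropped_constant.append(name)
        else:
            keep.append(j)
            kept_names.append(name)
    # indicator sets are collinear by construction; a level nobody uses is
    # simply dropped, but an all-constant *informative* predictor is an error
    if "swtl" in dropped_constant or len(keep) == 0 or (
        mode in ("joint", "habitat")
        and not any(nm.startswith("habitat_") for nm in kept_names)
        and mode != "trophic"
    ):
        raise FoodWebError(f"constant predictor(s): {', '.join(dropped_constant)}")
    X = X[:, keep]
    return (X - X.mean(axis=0)) / X.std(axis=0), kept_names


def _trace_ratio(X: np.ndarray, groups: np.ndarray) -> float:
    """tr(B)/tr(T): between-group over total scatter (columns centred)."""
    Xc = X - X.mean(axis=0)
    total = float((Xc**2).sum())
    between = 0.0
    for g in np.unique(groups):
        sel = Xc[groups == g]
        between += len(sel) * float((sel.mean(axis=0) ** 2).sum())
    return between / total if total > 0 else 0.0


def module_trait_association(
    partition: ModulePartition,
    habitat: dict[str, str],
    swtl: dict[str, float],
    n_perm: int = 999,
    seed: int | None = None,
    mode: str = "joint",
) -> AssociationResult:
    """Permutation test of module association with habitat and trophic level.

    ``mode``: ``joint`` (default, habitat indicators + SWTL in one model),
    ``habitat`` or ``trophic`` for single-trait tests.
    """
    nodes = sorted(partition.assignment, key=str)
    for n in nodes:
        if n not in habitat or habitat[n] not in HABITATS:
            raise FoodWebError(f"node {n!r}: missing or invalid habitat code")
        if n not in swtl or not np.isfinite(swtl[n]):
            raise FoodWebError(f"node {n!r}: missing or non-finite trophic level")
    groups = np.array([partition.assignment[n] for n in nodes])
    if len(np.unique(groups)) < 2:
        raise FoodWebError("association test requires at least 2 modules")
    X, _ = _design_matrix(nodes, habitat, swtl, mode)
    stat = _trace_ratio(X, groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _trace_ratio(X, rng.permutation(groups)) >= stat:
            count += 1
    p = (1 + count) / (n_perm + 1)

    per_module: dict[int, dict] = {}
    for g in np.unique(groups):
        mem = [n for n in nodes if partition.assignment[n] == g]
        frac = {
            code: sum(1 for n in mem if habitat[n] == code) / len(mem)
            for code in HABITATS
        }
        per_module[int(g)] = {
            "n": len(mem),
            "habitat_fractions": frac,
            "mean_swtl": float(np.mean([swtl[n] for n in mem])),
        }
    return AssociationResult(
        statistic=stat,
        p_value=p,
        n_permutations=n_perm,
        per_module=per_module,
        mode=mode,
        seed=seed,
    )
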