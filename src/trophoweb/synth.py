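"""Synthetic food webs with the statistical structure the analysis assumes.

Three generators:

* ``niche_model_web`` — the classic one-dimensional niche model, the
  standard ecological random-web baseline with a target connectance.
* ``planted_module_web`` — stochastic block structure with known module
  labels, the validation target for the annealer.
* ``synthetic_metaweb`` — a meta-web of ~230 trophospecies / ~2200 links
  shaped like a high-latitude shelf-sea web: habitat-structured modules
  (pelagic/benthic compartments), trophic ranks from basal taxa to top
  predators, two overlapping regional species pools (a species-rich
  "boreal-like" pool holding a few super-generalist fish, and a more
  specialized "arctic-like" pool), and a survey station table spread over
  two spatial blocks.

All generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import FoodWeb, SpeciesSet
from .spatial import Station, StationTable

GROUP_SIZES = {
    "detritus": 2,
    "basal": 8,
    "zooplankton": 43,
    "benthos": 79,
    "fish": 77,
    "seabird": 9,
    "mammal": 15,
}
# trophic rank used only for generation (prey come from strictly lower
# ranks, with optional fish-fish same-rank links)
GROUP_RANK = {
    "detritus": 0,
    "basal": 0,
    "zooplankton": 1,
    "benthos": 1,
    "fish": 2,
    "seabird": 3,
    "mammal": 3,
}


def niche_model_web(S: int, C: float, seed: int | None = None, max_retries: int = 100) -> FoodWeb:
    """Niche-model food web with S species and target connectance C.

    Each species i gets a niche value n_i ~ U(0,1), a feeding range
    r_i = x_i n_i with x_i ~ Beta(1, (1-2C)/(2C)) and a range centre
    c_i ~ U(r_i/2, min(n_i, 1-r_i/2)); i eats every j whose n_j falls in
    the range. The species with the smallest niche value is forced basal.
    Webs containing species with no links are regenerated (up to
    ``max_retries``).
    """
    if not 0 < C < 0.5:
        raise ValueError(f"connectance must be in (0, 0.5), got {C}")
    rng = np.random.default_rng(seed)
    beta = (1.0 - 2.0 * C) / (2.0 * C)
    for _ in range(max_retries):
        n = rng.uniform(0, 1, S)
        r = rng.beta(1.0, beta, S) * n
        r[np.argmin(n)] = 0.0
        c = rng.uniform(r / 2, np.minimum(n, 1 - r / 2))
        eats = (n[None, :] >= (c - r / 2)[:, None]) & (n[None, :] <= (c + r / 2)[:, None])
        names = [f"sp{i:03d}" for i in range(S)]
        links = [(names[j], names[i]) for i in range(S) for j in range(S) if eats[i, j]]
        web = FoodWeb(links, nodes=names, name=f"niche_S{S}_C{C}")
        if all(web.graph.degree(v) > 0 for v in web.graph):
            return web
    return web  # last attempt, possibly with isolated species


def planted_module_web(
    module_sizes: list[int],
    p_in: float,
    p_out: float,
    seed: int | None = None,
) -> tuple[FoodWeb, dict[str, int]]:
    """Directed web with planted modules; returns (web, ground-truth labels).

    Every ordered pair (i, j), i != j, is linked with probability ``p_in``
    inside a module and ``p_out`` between modules.
    """
    if len(module_sizes) < 2:
        raise ValueError("at least 2 modules required")
    if not p_in > p_out >= 0:
        raise ValueError("require p_in > p_out >= 0")
    rng = np.random.default_rng(seed)
    names, labels = [], {}
    for m, size in enumerate(module_sizes, start=1):
        for i in range(size):
            name = f"m{m}_{i:02d}"
            names.append(name)
            labels[name] = m
    links = []
    for u in names:
        for v in names:
            if u == v:
                continue
            p = p_in if labels[u] == labels[v] else p_out
            if rng.random() < p:
                links.append((u, v))
    web = FoodWeb(links, nodes=names, name="planted")
    return web, labels


@dataclass
class GeneratorConfig:
    """Defaults emulate the study system: a ~230-node meta-web, a
    species-rich region-1 pool with four super-generalist fish, and a
    more specialized, more modular region-2 pool."""

    group_sizes: dict = field(default_factory=lambda: dict(GROUP_SIZES))
    n_modules: int = 5                       # 2 pelagic + 3 benthic compartments
    mean_diet: float = 9.0                   # geometric diet-size mean (non-generalists)
    q_within_shared: float = 0.88            # own-module prey preference
    q_within_r1only: float = 0.82
    q_within_r2only: float = 0.92
    super_generalist_diets: tuple = (112, 88)   # network-hub candidates
    incomer_diets: tuple = (62, 50)             # additional wide-diet incomers
    q_within_generalist: float = 0.45           # super-generalists' own-module diet share
    p_region: tuple = (0.43, 0.30, 0.27)     # shared / region-1-only / region-2-only
    p_fish_habitat: tuple = (0.40, 0.35, 0.25)  # B / P / BP among fish
    p_cannibal_r1_fish: float = 0.20
    p_cannibal_shared_fish: float = 0.08
    p_cannibal_other: float = 0.02
    p_mutual_r1_fish: float = 0.04           # mutual-predation (loop) pairs, region-1 fish
    n_stations_per_block: int = 30
    p_station_detect: float = 0.3


@dataclass
class SyntheticMetaweb:
    meta: FoodWeb
    region1: SpeciesSet        # "boreal-like", holds the super-generalists
    region2: SpeciesSet        # "arctic-like"
    stations: StationTable
    generalists: SpeciesSet | None   # planted super-generalists (network-hub candidates)
    newcomers: SpeciesSet | None     # all wide-diet region-1 fish used by add_species
    module_labels: dict[str, int]


def synthetic_metaweb(
    config: GeneratorConfig | None = None,
    seed: int | None = None,
) -> SyntheticMetaweb:
    """Generate the meta-web, two regional species pools and a station table."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    nodes, group, habitat, rank, module, region = [], {}, {}, {}, {}, {}

    def add_node(name, g, h, m, reg):
        nodes.append(name)
        group[name] = g
        habitat[name] = h
        rank[name] = GROUP_RANK[g]
        module[name] = m
        region[name] = reg

    pelagic_modules = list(range(1, cfg.n_modules // 2 + 1))
    benthic_modules = list(range(cfg.n_modules // 2 + 1, cfg.n_modules + 1))

    # basal taxa & detritus: present in both regions, split across modules
    for i in range(cfg.group_sizes["detritus"]):
        add_node(f"detritus{i:02d}", "detritus", "B",
                 benthic_modules[i % len(benthic_modules)], "both")
    for i in range(cfg.group_sizes["basal"]):
        if i % 2 == 0:
            add_node(f"basal{i:02d}", "basal", "P",
                     pelagic_modules[(i // 2) % len(pelagic_modules)], "both")
        else:
            add_node(f"basal{i:02d}", "basal", "B",
                     benthic_modules[(i // 2) % len(benthic_modules)], "both")

    def pick_region():
        return "pending"   # resolved to exact regional proportions below

    for i in range(cfg.group_sizes["zooplankton"]):
        add_node(f"zoop{i:02d}", "zooplankton", "P",
                 int(rng.choice(pelagic_modules)), pick_region())
    for i in range(cfg.group_sizes["benthos"]):
        add_node(f"benthos{i:02d}", "benthos", "B",
                 int(rng.choice(benthic_modules)), pick_region())

    diets = list(cfg.super_generalist_diets) + list(cfg.incomer_diets)
    n_gen = len(diets)
    n_super = len(cfg.super_generalist_diets)
    generalist_names = [f"fish_gen{i}" for i in range(n_gen)]
    super_names = generalist_names[:n_super]
    for i, name in enumerate(generalist_names):
        add_node(name, "fish", "BP", int(rng.choice(pelagic_modules + benthic_modules)), "r1")
    for i in range(cfg.group_sizes["fish"] - n_gen):
        h = rng.choice(["B", "P", "BP"], p=cfg.p_fish_habitat)
        if h == "B":
            m = int(rng.choice(benthic_modules))
        elif h == "P":
            m = int(rng.choice(pelagic_modules))
        else:
            m = int(rng.choice(pelagic_modules + benthic_modules))
        add_node(f"fish{i:02d}", "fish", h, m, pick_region())
    for i in range(cfg.group_sizes["seabird"]):
        add_node(f"bird{i:02d}", "seabird", "P",
                 int(rng.choice(pelagic_modules)), pick_region())
    for i in range(cfg.group_sizes["mammal"]):
        add_node(f"mammal{i:02d}", "mammal", "BP",
                 int(rng.choice(pelagic_modules + benthic_modules)), pick_region())

    # resolve 'pending' nodes to exact regional proportions so the two
    # species pools have reproducible sizes (region 1 the richer pool)
    pending = [n for n in nodes if region[n] == "pending"]
    n_shared = round(cfg.p_region[0] * len(pending))
    n_r1 = round(cfg.p_region[1] * len(pending))
    order = rng.permutation(len(pending))
    for pos, idx in enumerate(order):
        if pos < n_shared:
            region[pending[idx]] = "both"
        elif pos < n_shared + n_r1:
            region[pending[idx]] = "r1"
        else:
            region[pending[idx]] = "r2"

    def covers(prey_region, consumer_region):
        return prey_region == "both" or prey_region == consumer_region

    lower = {
        name: [p for p in nodes if rank[p] < rank[name]] for name in nodes
    }
    links: set[tuple[str, str]] = set()
    for consumer in nodes:
        if rank[consumer] == 0 or consumer in generalist_names:
            continue
        reg = region[consumer]
        q = {"both": cfg.q_within_shared, "r1": cfg.q_within_r1only,
             "r2": cfg.q_within_r2only}[reg]
        candidates = lower[consumer]
        own = [p for p in candidates if module[p] == module[consumer]]
        other = [p for p in candidates if module[p] != module[consumer]]
        diet_size = min(1 + int(rng.geometric(1.0 / cfg.mean_diet)), len(candidates))
        n_own = min(int(rng.binomial(diet_size, q)), len(own))
        n_other = min(diet_size - n_own, len(other))
        diet = set()
        if n_own:
            diet.update(own[i] for i in rng.choice(len(own), size=n_own, replace=False))
        if n_other:
            diet.update(other[i] for i in rng.choice(len(other), size=n_other, replace=False))
        if not diet:
            pool = own or other
            diet.add(pool[rng.integers(len(pool))])
        # anchor: at least one prey available wherever the consumer occurs,
        # so regional sub-webs keep every species on a chain to a basal taxon
        if not any(covers(region[p], reg) for p in diet):
            anchors = [p for p in own if covers(region[p], reg)] or [
                p for p in candidates if covers(region[p], reg)
            ]
            diet.add(anchors[rng.integers(len(anchors))])
        links.update((p, consumer) for p in diet)

    # planted generalists: wide diets across modules and habitats. The
    # super-generalists keep a substantial own-module diet share (high z)
    # while still spreading widely (PC above the connector threshold);
    # the remaining incomers feed uniformly across modules.
    for name, breadth in zip(generalist_names, diets):
        candidates = [
            p for p in nodes
            if rank[p] <= 2 and p != name and p not in generalist_names
        ]
        if name in super_names:
            own = [p for p in candidates if module[p] == module[name]]
            n_own = min(int(round(cfg.q_within_generalist * breadth)), len(own))
            other = [p for p in candidates if module[p] != module[name]]
            n_other = min(breadth - n_own, len(other))
            chosen = [own[i] for i in rng.choice(len(own), size=n_own, replace=False)]
            chosen += [other[i] for i in rng.choice(len(other), size=n_other, replace=False)]
        else:
            take = min(breadth, len(candidates))
            chosen = [candidates[i] for i in rng.choice(len(candidates), size=take, replace=False)]
        links.update((p, name) for p in chosen)

    # cannibalism (self-links) and mutual predation (2-loops) among fish;
    # both are much more common in the region-1 pool
    fish = [n for n in nodes if group[n] == "fish"]
    for f in fish:
        if region[f] == "r1":
            p_can = cfg.p_cannibal_r1_fish
        elif region[f] == "both":
            p_can = cfg.p_cannibal_shared_fish
        else:
            p_can = cfg.p_cannibal_other
        if rng.random() < p_can:
            links.add((f, f))
    r1_fish = [f for f in fish if region[f] == "r1"]
    for i, f in enumerate(r1_fish):
        for g2 in r1_fish[i + 1:]:
            if rng.random() < cfg.p_mutual_r1_fish:
                links.add((f, g2))
                links.add((g2, f))

    meta = FoodWeb(sorted(links), nodes=nodes, habitat=habitat, group=group,
                   name="synthetic_metaweb")
    r1_members = [n for n in nodes if region[n] in ("both", "r1")]
    r2_members = [n for n in nodes if region[n] in ("both", "r2")]
    region1 = SpeciesSet("region1_boreal_like", r1_members)
    region2 = SpeciesSet("region2_arctic_like", r2_members)

    # survey stations: region-1 fish in a southern block, region-2 fish in a
    # northern block; each station detects each regional fish independently
    stations = []
    r1_fish_all = [f for f in fish if region[f] in ("both", "r1")]
    r2_fish_all = [f for f in fish if region[f] in ("both", "r2")]
    for b, (lat_lo, lat_hi, pool, tag) in enumerate(
        [(70.0, 73.0, r1_fish_all, "S"), (76.0, 79.0, r2_fish_all, "N")]
    ):
        for i in range(cfg.n_stations_per_block):
            lon = float(rng.uniform(20.0, 50.0))
            lat = float(rng.uniform(lat_lo, lat_hi))
            detected = {f for f in pool if rng.random() < cfg.p_station_detect}
            stations.append(Station(f"st_{tag}{i:03d}", lon, lat, detected))

    return SyntheticMetaweb(
        meta=meta,
        region1=region1,
        region2=region2,
        stations=StationTable(stations),
        generalists=SpeciesSet("planted_super_generalists", super_names) if super_names else None,
        newcomers=SpeciesSet("planted_newcomers", generalist_names) if generalist_names else None,
        module_labels=module,
    )
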