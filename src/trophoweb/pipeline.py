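"""End-to-end regional food-web comparison.

Builds the regional sub-webs from a meta-web (plus an updated region-2 web
with incoming species), computes the structural metric suite, modularity
with degree-preserving null tests, topological roles, and module-trait
associations, and assembles a comparison table with pairwise percentage
differences.

Percentage differences follow the reporting convention of topological
food-web comparisons: metrics are first rounded to their display precision
(counts exact, ratio metrics to 2 decimals, percentages to whole numbers),
then Diff(X-Y) = 100 * (m_X - m_Y) / m_X, rounded half-away-from-zero to a
whole percent, with the first-named web in the denominator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

from .core import FoodWeb, SpeciesSet, add_species, induced_subweb
from .metrics import metrics_report, trophic_levels
from .modularity import null_modularity_test, replicate_partitions
from .roles import role_profiles
from .association import module_trait_association

logger = logging.getLogger(__name__)

# display precision per metric (Table-style reports)
METRIC_DECIMALS = {
    "S": 0, "L": 0,
    "LD": 2, "C": 2,
    "pctOmni": 0, "pctCan": 0, "pctLoops": 0,
    "meanPath": 2, "meanOmni": 2, "meanSWTL": 2, "meanClust": 2,
    "modularity": 2,
}


def round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def display_round(metric: str, value: float) -> float:
    nd = METRIC_DECIMALS.get(metric, 2)
    return int(round(value)) if nd == 0 and metric in ("S", "L") else round(value, nd)


def percent_diff(x: float, y: float) -> int | None:
    """100 * (x - y) / x to whole percent; None when undefined (x = 0)."""
    if x is None or y is None or x == 0:
        return None
    return round_half_away(100.0 * (x - y) / x)


def diff_table(
    metrics_by_web: dict[str, dict[str, float]],
    pairs: list[tuple[str, str]],
) -> dict[str, dict[str, int | None]]:
    """Pairwise percentage differences from display-rounded metric values."""
    out: dict[str, dict[str, int | None]] = {}
    for x_name, y_name in pairs:
        col = f"{x_name}-{y_name}"
        out[col] = {}
        for metric in METRIC_DECIMALS:
            mx = metrics_by_web[x_name].get(metric)
            my = metrics_by_web[y_name].get(metric)
            if mx is None or my is None:
                out[col][metric] = None
                continue
            out[col][metric] = percent_diff(
                display_round(metric, mx), display_round(metric, my)
            )
    return out


@dataclass
class PipelineConfig:
    """Replicate counts, annealing schedules and seeds for a comparison run."""

    n_replicates: int = 20        # annealing replicates per web (role CIs)
    n_null: int = 50              # degree-preserving null networks per web
    n_perm: int = 999             # label permutations for the trait test
    schedule: str = "standard"    # headline annealing schedule preset
    null_schedule: str = "fast"   # reduced schedule for null replicates
    swaps_per_link: int = 5
    seed: int = 0


@dataclass
class ComparisonReport:
    """Everything the comparison computes, JSON-serializable."""

    webs: dict[str, dict] = field(default_factory=dict)
    diffs: dict[str, dict] = field(default_factory=dict)
    roles: dict[str, list] = field(default_factory=dict)
    associations: dict[str, dict] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def analyse_web(web: FoodWeb, config: PipelineConfig, seed: int) -> dict:
    """Metrics + modularity + null test + roles + association for one web."""
    logger.info("analysing %s (S=%d, L=%d), seed=%d", web.name, web.S, web.L, seed)
    report = metrics_report(web)
    parts, designated = replicate_partitions(
        web, config.n_replicates, seed=seed, schedule=config.schedule
    )
    best_m = max(p.M for p in parts)
    report.modularity = best_m
    null = null_modularity_test(
        web,
        n=config.n_null,
        seed=seed + 1,
        schedule=config.schedule,
        null_schedule=config.null_schedule,
        empirical_M=best_m,
        swaps_per_link=config.swaps_per_link,
    )
    profiles = role_profiles(web, parts, designated)
    tl = trophic_levels(web)
    habitat = {n: web.habitat_of(n) for n in web.nodes}
    association = None
    if all(habitat.values()) and designated.N_M >= 2:
        association = module_trait_association(
            designated, habitat, tl, n_perm=config.n_perm, seed=seed + 2
        )
    return {
        "metrics": report.to_dict(),
        "metrics_display": {
            k: display_round(k, v)
            for k, v in report.to_dict().items()
            if v is not None
        },
        "modularity": {
            "M": best_m,
            "designated_M": designated.M,
            "N_M": designated.N_M,
            "null_mean": null.mean,
            "null_sd": null.sd,
            "p_value": null.p_value,
            "n_replicates": config.n_replicates,
            "n_null": config.n_null,
            "seed": seed,
        },
        "assignment": designated.assignment,
        "roles": [asdict(p) for p in profiles],
        "association": None
        if association is None
        else {
            "statistic": association.statistic,
            "p_value": association.p_value,
            "n_permutations": association.n_permutations,
            "per_module": association.per_module,
        },
    }


def run_comparison(
    meta: FoodWeb,
    region1: SpeciesSet,
    region2: SpeciesSet,
    newcomers: SpeciesSet | None = None,
    config: PipelineConfig | None = None,
) -> ComparisonReport:
    """The full three-web comparison workflow.

    Induces the two regional sub-webs, forms the updated region-2 web by
    adding the newcomers, analyses each, and tabulates pairwise percentage
    differences (first-named web in the denominator).
    """
    config = config or PipelineConfig()
    webs = [induced_subweb(meta, region1), induced_subweb(meta, region2)]
    if newcomers is not None:
        webs.append(
            add_species(webs[1], meta, newcomers, name=f"{webs[1].name}_II")
        )
    report = ComparisonReport(config=asdict(config))
    metrics_by_web: dict[str, dict] = {}
    for i, web in enumerate(webs):
        result = analyse_web(web, config, seed=config.seed + 1000 * i)
        report.webs[web.name] = {
            k: result[k] for k in ("metrics", "metrics_display", "modularity", "assignment")
        }
        report.roles[web.name] = result["roles"]
        if result["association"] is not None:
            report.associations[web.name] = result["association"]
        metrics_by_web[web.name] = dict(result["metrics"])
    pairs = [(webs[0].name, webs[1].name)]
    if len(webs) == 3:
        pairs.append((webs[2].name, webs[1].name))
    report.diffs = diff_table(metrics_by_web, pairs)
    return report
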