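"""Food-web data model, file I/O, and meta-web -> sub-web construction.

A food web is a directed graph of trophospecies. Links run prey -> predator
(the direction of energy flow), so a node's in-degree is its number of prey
(generality) and its out-degree its number of predators (vulnerability).
Self-links encode cannibalism and are permitted.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

HABITATS = ("B", "P", "BP")
FUNCTIONAL_GROUPS = (
    "detritus",
    "basal",
    "zooplankton",
    "benthos",
    "fish",
    "seabird",
    "mammal",
)


class FoodWebError(ValueError):
    """Raised on malformed or inconsistent food-web inputs."""


class FoodWeb:
    """Directed food web of trophospecies.

    Parameters
    ----------
    links : iterable of (prey, predator) pairs. Duplicates collapse with a
        warning; direction is energy flow.
    nodes : optional extra node identifiers (isolated nodes are retained).
    habitat : per-node habitat code, one of ``B`` (benthic), ``P`` (pelagic),
        ``BP`` (benthopelagic).
    group : per-node functional group (detritus, basal, zooplankton,
        benthos, fish, seabird, mammal).
    name : label of the web (e.g. ``"boreal"``).
    """

    def __init__(
        self,
        links: Iterable[tuple[str, str]] = (),
        nodes: Iterable[str] = (),
        habitat: Mapping[str, str] | None = None,
        group: Mapping[str, str] | None = None,
        name: str = "web",
    ):
        self.name = name
        self.graph = nx.DiGraph()
        seen = set()
        for prey, predator in links:
            if (prey, predator) in seen:
                logger.warning("duplicate link (%s, %s) collapsed", prey, predator)
                continue
            seen.add((prey, predator))
            self.graph.add_edge(prey, predator)
        self.graph.add_nodes_from(nodes)
        for mapping, key, allowed in (
            (habitat or {}, "habitat", HABITATS),
            (group or {}, "group", FUNCTIONAL_GROUPS),
        ):
            for node, value in mapping.items():
                if value not in allowed:
                    raise FoodWebError(
                        f"unknown {key} code {value!r} for node {node!r}; "
                        f"allowed: {', '.join(allowed)}"
                    )
                if node not in self.graph:
                    self.graph.add_node(node)
                self.graph.nodes[node][key] = value

    # -- basic accessors -------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def links(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    @property
    def S(self) -> int:
        """Number of trophospecies."""
        return self.graph.number_of_nodes()

    @property
    def L(self) -> int:
        """Number of feeding links."""
        return self.graph.number_of_edges()

    def habitat_of(self, node: str) -> str | None:
        return self.graph.nodes[node].get("habitat")

    def group_of(self, node: str) -> str | None:
        return self.graph.nodes[node].get("group")

    def degree_of(self, node: str) -> int:
        """Total degree (prey + predators); a self-link counts once."""
        d = self.graph.in_degree(node) + self.graph.out_degree(node)
        if self.graph.has_edge(node, node):
            d -= 1
        return d

    def undirected(self, drop_self_links: bool = True) -> nx.Graph:
        """Undirected projection; mutual predation collapses to one link."""
        g = nx.Graph(self.graph)
        if drop_self_links:
            g.remove_edges_from(nx.selfloop_edges(g))
        return g

    def copy(self, name: str | None = None) -> "FoodWeb":
        web = FoodWeb.__new__(FoodWeb)
        web.name = name if name is not None else self.name
        web.graph = self.graph.copy()
        return web

    def __eq__(self, other) -> bool:
        if not isinstance(other, FoodWeb):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.links == other.links
            and all(
                self.graph.nodes[n] == other.graph.nodes[n] for n in self.graph
            )
        )

    def __repr__(self) -> str:
        return f"FoodWeb({self.name!r}, S={self.S}, L={self.L})"


@dataclass(frozen=True)
class SpeciesSet:
    """Named set of trophospecies identifiers (duplicates collapsed)."""

    web_name: str
    members: frozenset[str]

    def __init__(self, web_name: str, members: Iterable[str]):
        object.__setattr__(self, "web_name", web_name)
        object.__setattr__(self, "members", frozenset(members))
        if not self.members:
            raise FoodWebError(f"species set {web_name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_web(
    edge_list_path: str | Path,
    attributes_path: str | Path | None = None,
    name: str | None = None,
) -> FoodWeb:
    """Read a food web from an edge-list CSV (``prey,predator`` header).

    ``attributes_path`` is an optional CSV with header ``id,habitat,group``;
    nodes present only there are added as isolated nodes. Habitat and group
    codes are validated against the allowed vocabularies.
    """
    edge_list_path = Path(edge_list_path)
    links: list[tuple[str, str]] = []
    with edge_list_path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [c.strip().lower() for c in header[:2]] != ["prey", "predator"]:
            raise FoodWebError(
                f"{edge_list_path}: expected header 'prey,predator', got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2 or not row[0].strip() or not row[1].strip():
                raise FoodWebError(f"{edge_list_path}:{lineno}: malformed row {row!r}")
            links.append((row[0].strip(), row[1].strip()))

    habitat: dict[str, str] = {}
    group: dict[str, str] = {}
    extra_nodes: list[str] = []
    if attributes_path is not None:
        attributes_path = Path(attributes_path)
        with attributes_path.open(newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or [c.strip().lower() for c in header[:3]] != [
                "id",
                "habitat",
                "group",
            ]:
                raise FoodWebError(
                    f"{attributes_path}: expected header 'id,habitat,group', got {header!r}"
                )
            for lineno, row in enumerate(reader, start=2):
                if not row or all(not c.strip() for c in row):
                    continue
                if len(row) < 3 or not row[0].strip():
                    raise FoodWebError(
                        f"{attributes_path}:{lineno}: malformed row {row!r}"
                    )
                node = row[0].strip()
                extra_nodes.append(node)
                if row[1].strip():
                    habitat[node] = row[1].strip()
                if row[2].strip():
                    group[node] = row[2].strip()

    return FoodWeb(
        links,
        nodes=extra_nodes,
        habitat=habitat,
        group=group,
        name=name or edge_list_path.stem,
    )


def read_species_set(path: str | Path, web_name: str | None = None) -> SpeciesSet:
    """Read a species set from a plain-text file, one identifier per line."""
    path = Path(path)
    members = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    return SpeciesSet(web_name or path.stem, members)


def write_edge_list(web: FoodWeb, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["prey", "predator"])
        for prey, predator in sorted(web.links):
            writer.writerow([prey, predator])


def write_attributes(web: FoodWeb, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "habitat", "group"])
        for node in sorted(web.nodes):
            writer.writerow(
                [node, web.habitat_of(node) or "", web.group_of(node) or ""]
            )


def write_graphml(web: FoodWeb, path: str | Path) -> None:
    """Export the web (with node attributes) as GraphML."""
    g = web.graph.copy()
    g.graph["name"] = web.name
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path) -> FoodWeb:
    g = nx.read_graphml(str(path))
    web = FoodWeb.__new__(FoodWeb)
    web.graph = nx.DiGraph(g)
    web.name = g.graph.get("name", Path(path).stem)
    return web


def write_report(report: Mapping, path: str | Path) -> None:
    """Write a metrics/comparison report as JSON (full precision)."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Meta-web -> sub-web construction
# ---------------------------------------------------------------------------

def induced_subweb(meta: FoodWeb, subset: SpeciesSet) -> FoodWeb:
    """Sub-sample a regional web from the meta-web.

    Species co-occurring in a region and linked in the meta-web are assumed
    to interact there, so the sub-web is the induced subgraph on
    ``subset.members``. Isolated nodes are retained; attributes are copied.
    """
    unknown = sorted(subset.members - meta.nodes)
    if unknown:
        raise FoodWebError(
            f"species absent from meta-web {meta.name!r}: {', '.join(unknown)}"
        )
    web = FoodWeb.__new__(FoodWeb)
    web.name = subset.web_name
    web.graph = meta.graph.subgraph(subset.members).copy()
    return web


def add_species(web: FoodWeb, meta: FoodWeb, newcomers: SpeciesSet, name: str | None = None) -> FoodWeb:
    """Update a regional web with incoming species.

    The result is the meta-web induced on the union of the resident and
    newcomer species, i.e. every meta-web link among the union appears.
    """
    unknown = sorted(set(newcomers.members) - meta.nodes)
    if unknown:
        raise FoodWebError(
            f"newcomers absent from meta-web {meta.name!r}: {', '.join(unknown)}"
        )
    union = SpeciesSet(name or f"{web.name}+{newcomers.web_name}", web.nodes | set(newcomers.members))
    return induced_subweb(meta, union)


def shared_unique(a: FoodWeb, b: FoodWeb) -> tuple[int, int]:
    """(number of shared trophospecies, number unique to either web)."""
    shared = len(a.nodes & b.nodes)
    unique = len(a.nodes ^ b.nodes)
    return shared, unique


def drop_isolated(web: FoodWeb) -> FoodWeb:
    """Return a copy without degree-zero nodes (optional; default keeps them)."""
    out = web.copy()
    isolated = [n for n in out.graph if out.graph.degree(n) == 0]
    out.graph.remove_nodes_from(isolated)
    if isolated:
        warnings.warn(f"dropped {len(isolated)} isolated nodes from {web.name!r}")
    return out
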