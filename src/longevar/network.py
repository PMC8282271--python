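"""Seed-based subnetwork extraction from a protein-protein interaction
graph.

The background network is an undirected simple graph (self-interactions
ignored).  Given a set of seed genes, the subnetwork is the union of
ALL shortest paths between every pair of seeds whose distance does not
exceed an adaptive cutoff L*: the smallest path length at which every
seed joins the subnetwork, i.e. the maximum over seeds of the distance
to their nearest other seed.  A ``global-max`` mode using the largest
pairwise seed distance is available behind a flag.  Seeds disconnected
from all others are excluded with a warning rather than failing the
run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx

from .core import ValidationError

__all__ = [
    "build_graph",
    "seed_distances",
    "inclusion_cutoff",
    "extract_subnetwork",
    "SubnetworkResult",
]

logger = logging.getLogger(__name__)


def build_graph(edges) -> nx.Graph:
    """Undirected simple graph from a 2-column edge list.

    Self-loops are dropped; duplicate edges (in either orientation)
    merge.  An empty edge list yields an empty (valid) graph.
    """
    g = nx.Graph()
    for u, v in edges:
        if u == v:
            continue
        g.add_edge(u, v)
    return g


def seed_distances(graph: nx.Graph, seeds) -> dict[tuple[str, str], float]:
    """Unweighted shortest-path length for every unordered seed pair.

    Seeds absent from the graph are reported and excluded; unreachable
    pairs are marked ``inf``.  Raises if no seed is present at all.
    """
    seeds = list(dict.fromkeys(seeds))
    present = [s for s in seeds if s in graph]
    missing = [s for s in seeds if s not in graph]
    if missing:
        logger.warning("seed_distances: seeds not in graph, excluded: %s", missing)
    if not present:
        raise ValidationError("none of the seeds is present in the graph")
    out: dict[tuple[str, str], float] = {}
    for i, s in enumerate(present):
        lengths = nx.single_source_shortest_path_length(graph, s)
        for t in present[i + 1 :]:
            out[(s, t)] = float(lengths.get(t, math.inf))
    return out


def inclusion_cutoff(distances: dict[tuple[str, str], float], mode: str = "nearest") -> int:
    """Adaptive path-length cutoff L*.

    ``nearest`` (default): the smallest L such that every reachable
    seed is the endpoint of at least one seed pair at finite distance
    <= L — equivalently max over seeds of the distance to the nearest
    other reachable seed.  ``global-max``: the largest finite pairwise
    distance.  Seeds with no finite distance to any other seed are
    excluded (reported by :func:`extract_subnetwork`).
    """
    seeds = sorted({s for pair in distances for s in pair})
    if len(seeds) < 2:
        raise ValidationError("need at least two seeds to define a cutoff")
    finite = {p: d for p, d in distances.items() if math.isfinite(d)}
    reachable = {s for pair in finite for s in pair}
    if len(reachable) < 2:
        raise ValidationError("fewer than two seeds are mutually reachable")
    if mode == "global-max":
        return int(max(finite.values()))
    if mode != "nearest":
        raise ValueError(f"unknown cutoff mode {mode!r}")
    nearest = {
        s: min(d for pair, d in finite.items() if s in pair) for s in reachable
    }
    return int(max(nearest.values()))


@dataclass
class SubnetworkResult:
    seeds: list[str]
    nodes: list[str]
    edges: list[tuple[str, str]]
    distances: dict[tuple[str, str], float]
    cutoff: int
    excluded_seeds: list[str] = field(default_factory=list)


def extract_subnetwork(
    graph: nx.Graph, seeds, mode: str = "nearest"
) -> SubnetworkResult:
    """Union of all shortest paths between seed pairs with distance <= L*.

    Nodes and edges outside every retained path are excluded; output
    ordering is deterministic (sorted).
    """
    seeds = list(dict.fromkeys(seeds))
    dist = seed_distances(graph, seeds)
    finite = {p: d for p, d in dist.items() if math.isfinite(d)}
    reachable = {s for pair in finite for s in pair}
    excluded = [s for s in seeds if s not in reachable]
    if excluded:
        logger.warning("extract_subnetwork: excluded seeds: %s", excluded)
    cutoff = inclusion_cutoff(dist, mode=mode)

    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for (s, t), d in finite.items():
        if d > cutoff:
            continue
        for path in nx.all_shortest_paths(graph, s, t):
            nodes.update(path)
            for u, v in zip(path, path[1:]):
                edges.add((min(u, v), max(u, v)))
    return SubnetworkResult(
        seeds=[s for s in seeds if s in reachable],
        nodes=sorted(nodes),
        edges=sorted(edges),
        distances=dist,
        cutoff=cutoff,
        excluded_seeds=excluded,
    )


def write_graphml(result: SubnetworkResult, path) -> None:
    """Export the subnetwork in GraphML for interactive viewers."""
    g = nx.Graph()
    for n in result.nodes:
        g.add_node(n, seed=n in set(result.seeds))
    g.add_edges_from(result.edges)
    nx.write_graphml(g, path)
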