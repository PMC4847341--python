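"""Attributed dynamic network construction and edge scoring.

The dynamic network is one graph whose vertices carry per-time-point
activity levels and whose edges carry the intersection of their
endpoints' active time sets. Edges with an empty intersection, and
vertices with no activity record, are pruned at construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import networkx as nx

from .expression import PROB_LOW, ActivityTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StaticPPINetwork:
    """Undirected, unweighted protein interaction network."""

    vertices: frozenset[str]
    edges: frozenset[frozenset[str]]

    def __post_init__(self) -> None:
        for edge in self.edges:
            if len(edge) != 2:
                raise ValueError(f"bad edge {set(edge)!r}")
            if not edge <= self.vertices:
                raise ValueError(f"edge {set(edge)!r} has endpoint outside vertex set")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def load_ppi_edgelist(path: str | Path) -> StaticPPINetwork:
    """Read a two-column TSV edge list; extra columns are ignored.

    Protein IDs are uppercased. Self-loops are dropped and duplicate
    pairs (either orientation) collapsed, with counts logged.
    """
    vertices: set[str] = set()
    edges: set[frozenset[str]] = set()
    n_self = 0
    n_dup = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}, line {lineno}: expected >= 2 columns")
            a, b = fields[0].strip().upper(), fields[1].strip().upper()
            if not a or not b:
                raise ValueError(f"{path}, line {lineno}: empty protein ID")
            if a == b:
                n_self += 1
                continue
            vertices.update((a, b))
            edge = frozenset((a, b))
            if edge in edges:
                n_dup += 1
            edges.add(edge)
    if n_self:
        logger.info("%s: dropped %d self-loop(s)", path, n_self)
    if n_dup:
        logger.info("%s: collapsed %d duplicate pair(s)", path, n_dup)
    logger.info("%s: %d proteins, %d interactions", path, len(vertices), len(edges))
    return StaticPPINetwork(frozenset(vertices), frozenset(edges))


class DPPN:
    """Dynamic probabilistic protein network.

    Wraps an undirected :class:`networkx.Graph`; each node has an
    ``active`` attribute (dict: 1-based time point -> probability level)
    and each edge a ``times`` attribute (sorted tuple of shared active
    time points).
    """

    def __init__(self, graph: nx.Graph, n_timepoints: int) -> None:
        self.graph = graph
        self.n_timepoints = n_timepoints
        self._avg_degree: float | None = None

    # -- basic views ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def vertices(self) -> Iterator[str]:
        return iter(self.graph.nodes)

    def edges(self) -> Iterator[tuple[str, str]]:
        return iter(self.graph.edges)

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def neighbors(self, v: str) -> set[str]:
        return set(self.graph.neighbors(v))

    def level(self, v: str, timepoint: int) -> float:
        """Activity probability of ``v`` at ``timepoint`` (0 if inactive)."""
        return self.graph.nodes[v]["active"].get(timepoint, 0.0)

    def active_set(self, v: str) -> frozenset[int]:
        return frozenset(self.graph.nodes[v]["active"])

    def edge_times(self, u: str, v: str) -> tuple[int, ...]:
        return self.graph.edges[u, v]["times"]

    # -- scoring -------------------------------------------------------

    def average_degree(self) -> float:
        """Mean vertex degree over the pruned dynamic network."""
        if self.n_vertices == 0:
            raise ValueError("average degree undefined on empty network")
        if self._avg_degree is None:
            self._avg_degree = 2.0 * self.n_edges / self.n_vertices
        return self._avg_degree

    def topology_score(self, u: str, v: str) -> float:
        """Shared-neighborhood score of an edge.

        ``(|N_u ∩ N_v| + 1) / (max(avg, |N_u|) + max(avg, |N_v|))``
        where ``avg`` is the network's average degree; the max in the
        denominator penalises sparsely connected endpoints.
        """
        g = self.graph
        nu, nv = set(g.neighbors(u)), set(g.neighbors(v))
        avg = self.average_degree()
        common = len(nu & nv)
        return (common + 1.0) / (max(avg, len(nu)) + max(avg, len(nv)))

    def edge_weight(self, u: str, v: str, timepoint: int) -> float:
        """Topology score times both endpoint levels at ``timepoint``.

        Zero when the edge is absent or not active at that time point.
        """
        if not self.graph.has_edge(u, v):
            return 0.0
        if timepoint not in self.graph.edges[u, v]["times"]:
            return 0.0
        return self.topology_score(u, v) * self.level(u, timepoint) * self.level(v, timepoint)

    # -- derived reports ----------------------------------------------

    def snapshot(self, timepoint: int) -> nx.Graph:
        """Subgraph of vertices/edges active at one time point."""
        g = nx.Graph()
        for v, data in self.graph.nodes(data=True):
            if timepoint in data["active"]:
                g.add_node(v, level=data["active"][timepoint])
        for u, v, data in self.graph.edges(data=True):
            if timepoint in data["times"]:
                g.add_edge(u, v)
        return g

    def active_protein_counts(self, min_level: float = PROB_LOW) -> list[int]:
        """Per-time-point count of proteins with level >= ``min_level``."""
        counts = [0] * self.n_timepoints
        for _, data in self.graph.nodes(data=True):
            for t, level in data["active"].items():
                if level >= min_level:
                    counts[t - 1] += 1
        return counts

    # -- serialization -------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_timepoints": self.n_timepoints,
            "vertices": {
                v: {str(t): level for t, level in sorted(data["active"].items())}
                for v, data in sorted(self.graph.nodes(data=True))
            },
            "edges": [
                [u, v, list(data["times"])]
                for u, v, data in sorted(
                    self.graph.edges(data=True), key=lambda e: tuple(sorted(e[:2]))
                )
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "DPPN":
        with open(path) as fh:
            payload = json.load(fh)
        g = nx.Graph()
        for v, active in payload["vertices"].items():
            g.add_node(v, active={int(t): float(p) for t, p in active.items()})
        for u, v, times in payload["edges"]:
            g.add_edge(u, v, times=tuple(int(t) for t in times))
        return cls(g, int(payload["n_timepoints"]))


def build_dppn(network: StaticPPINetwork, activity: ActivityTable) -> DPPN:
    """Annotate and prune a static network with activity data.

    Vertices without an activity record or with an empty active set are
    excluded; an edge survives only if its endpoints share at least one
    active time point, and then carries exactly that intersection.
    """
    g = nx.Graph()
    n_unmapped = 0
    for v in sorted(network.vertices):
        active = activity.levels_of(v)
        if active:
            g.add_node(v, active=active)
        else:
            n_unmapped += 1
    n_empty = 0
    for edge in network.edges:
        u, v = sorted(edge)
        if u not in g or v not in g:
            continue
        shared = activity.active_set(u) & activity.active_set(v)
        if shared:
            g.add_edge(u, v, times=tuple(sorted(shared)))
        else:
            n_empty += 1
    if n_unmapped:
        logger.info("dropped %d vertex/vertices with no active time point", n_unmapped)
    if n_empty:
        logger.info("dropped %d edge(s) with empty shared active set", n_empty)
    if g.number_of_nodes() == 0:
        logger.warning("resulting dynamic network is empty")
    return DPPN(g, activity.n_timepoints)
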