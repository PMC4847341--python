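"""Two-phase core-attachment complex detection on a dynamic network.

Phase one selects cores: maximal cliques whose members share at least
one active time point are scored and greedily selected with overlap
resolution, then high-weight edges outside the chosen cliques are added
as two-member cores. Phase two attaches neighbor proteins whose average
connection weight to the core, at the core's assigned time point,
exceeds a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx

from .network import DPPN


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds controlling core selection and attachment."""

    core_thresh: float = 0.09
    extend_thresh: float = 0.05
    min_clique_size: int = 3
    overlap_thresh: float = 0.5

    def __post_init__(self) -> None:
        for name in ("core_thresh", "extend_thresh", "overlap_thresh"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.min_clique_size < 2:
            raise ValueError("min_clique_size must be >= 2")


@dataclass(frozen=True)
class ActiveCorrelatedClique:
    """A clique whose members share at least one active time point."""

    members: frozenset[str]
    common_active: frozenset[int]
    probability: float
    assigned_time: int
    score: float

    def __post_init__(self) -> None:
        if not self.common_active:
            raise ValueError("common active set must be nonempty")
        if self.assigned_time not in self.common_active:
            raise ValueError("assigned time must lie in the common active set")


@dataclass(frozen=True)
class ComplexCore:
    """A selected core: a non-overlapping clique or a high-weight edge."""

    members: frozenset[str]
    assigned_time: int
    origin: str  # "clique" or "edge"
    score: float

    def __post_init__(self) -> None:
        if self.origin == "edge" and len(self.members) != 2:
            raise ValueError("edge cores have exactly 2 members")
        if self.origin == "clique" and len(self.members) < 3:
            raise ValueError("clique cores have >= 3 members")
        if self.origin not in ("clique", "edge"):
            raise ValueError(f"unknown core origin {self.origin!r}")


@dataclass(frozen=True)
class PredictedComplex:
    core: ComplexCore
    attachments: frozenset[str]

    @property
    def members(self) -> frozenset[str]:
        return self.core.members | self.attachments

    @property
    def assigned_time(self) -> int:
        return self.core.assigned_time

    @property
    def score(self) -> float:
        return self.core.score


def _rank_key(members: frozenset[str], score: float):
    # Descending score, then larger member count, then lexicographic
    # member IDs — fully deterministic ordering.
    return (-score, -len(members), tuple(sorted(members)))


def enumerate_maximal_cliques(dppn: DPPN, min_size: int = 3) -> set[frozenset[str]]:
    """All maximal cliques with at least ``min_size`` vertices."""
    return {
        frozenset(c)
        for c in nx.find_cliques(dppn.graph)
        if len(c) >= min_size
    }


def clique_probability(
    dppn: DPPN, members: Iterable[str], common_active: Iterable[int]
) -> tuple[float, int]:
    """Best joint activity over shared time points.

    Returns ``(max over shared k of prod of member levels at k, argmax
    time)``; ties go to the earliest time point.
    """
    members = list(members)
    best_prob = -1.0
    best_time = -1
    for k in sorted(common_active):
        prob = 1.0
        for v in members:
            prob *= dppn.level(v, k)
        if prob > best_prob:
            best_prob, best_time = prob, k
    if best_time < 0:
        raise ValueError("empty common active set")
    return best_prob, best_time


def clique_score(dppn: DPPN, members: Iterable[str], probability: float) -> float:
    """Joint activity probability times the sum of edge topology scores."""
    total = 0.0
    for u, v in combinations(sorted(members), 2):
        if dppn.has_edge(u, v):
            total += dppn.topology_score(u, v)
    return probability * total


def _make_acc(dppn: DPPN, members: frozenset[str]) -> ActiveCorrelatedClique | None:
    """Build a scored active-correlated clique, or None if the members
    share no active time point."""
    common = None
    for v in members:
        s = dppn.active_set(v)
        common = s if common is None else common & s
        if not common:
            return None
    assert common is not None
    prob, t_c = clique_probability(dppn, members, common)
    return ActiveCorrelatedClique(
        members=members,
        common_active=frozenset(common),
        probability=prob,
        assigned_time=t_c,
        score=clique_score(dppn, members, prob),
    )


def to_active_correlated_cliques(
    dppn: DPPN, cliques: Iterable[frozenset[str]]
) -> list[ActiveCorrelatedClique]:
    """Keep cliques with a nonempty common active set, scored and ranked."""
    accs = [acc for members in cliques if (acc := _make_acc(dppn, members)) is not None]
    accs.sort(key=lambda c: _rank_key(c.members, c.score))
    return accs


def max_edge_weight(dppn: DPPN, u: str, v: str) -> tuple[float, int]:
    """Maximum weight of an edge over its active time points.

    Returns ``(weight, argmax time)``, earliest time on ties.
    """
    best_w = -1.0
    best_t = -1
    for k in dppn.edge_times(u, v):
        w = dppn.edge_weight(u, v, k)
        if w > best_w:
            best_w, best_t = w, k
    return best_w, best_t


def select_cores(
    dppn: DPPN,
    cliques: Iterable[frozenset[str]],
    config: DetectorConfig,
) -> list[ComplexCore]:
    """Greedy core selection with overlap resolution, plus edge cores.

    Clique phase: repeatedly promote the best-ranked candidate clique;
    any remaining candidate B overlapping the winner A by
    ``|A ∩ B| / |B| >= overlap_thresh`` is deleted, a smaller overlap
    prunes A's vertices out of B (B stays a clique, is re-scored, and is
    kept only if it still has ``min_clique_size`` members and a nonempty
    common active set). Edge phase: every edge not inside a selected
    clique core whose maximum time-indexed weight exceeds
    ``core_thresh`` becomes a two-member core at the argmax time.
    """
    candidates: dict[frozenset[str], ActiveCorrelatedClique] = {}
    for acc in to_active_correlated_cliques(dppn, cliques):
        prev = candidates.get(acc.members)
        if prev is None or _rank_key(acc.members, acc.score) < _rank_key(
            prev.members, prev.score
        ):
            candidates[acc.members] = acc

    cores: list[ComplexCore] = []
    while candidates:
        winner = min(
            candidates.values(), key=lambda c: _rank_key(c.members, c.score)
        )
        del candidates[winner.members]
        cores.append(
            ComplexCore(
                members=winner.members,
                assigned_time=winner.assigned_time,
                origin="clique",
                score=winner.score,
            )
        )
        survivors: dict[frozenset[str], ActiveCorrelatedClique] = {}
        for acc in candidates.values():
            shared = len(winner.members & acc.members)
            if shared == 0:
                kept: ActiveCorrelatedClique | None = acc
            elif shared / len(acc.members) >= config.overlap_thresh:
                kept = None
            else:
                pruned = acc.members - winner.members
                if len(pruned) < config.min_clique_size:
                    kept = None
                else:
                    kept = _make_acc(dppn, pruned)  # subset of a clique is a clique
            if kept is None:
                continue
            prev = survivors.get(kept.members)
            if prev is None or _rank_key(kept.members, kept.score) < _rank_key(
                prev.members, prev.score
            ):
                survivors[kept.members] = kept
        candidates = survivors

    covered: set[frozenset[str]] = set()
    for core in cores:
        for u, v in combinations(sorted(core.members), 2):
            covered.add(frozenset((u, v)))

    edge_cores = []
    for u, v in dppn.edges():
        if frozenset((u, v)) in covered:
            continue
        weight, t = max_edge_weight(dppn, u, v)
        if weight > config.core_thresh:
            edge_cores.append(
                ComplexCore(
                    members=frozenset((u, v)),
                    assigned_time=t,
                    origin="edge",
                    score=weight,
                )
            )
    edge_cores.sort(key=lambda c: _rank_key(c.members, c.score))
    return cores + edge_cores


def attach_score(dppn: DPPN, core: ComplexCore, candidate: str) -> float:
    """Average weight, at the core's time point, of the candidate's
    edges into the core (missing edges contribute zero)."""
    if candidate in core.members:
        raise ValueError("candidate already in core")
    t = core.assigned_time
    total = sum(dppn.edge_weight(v, candidate, t) for v in core.members)
    return total / len(core.members)


def expand_cores(
    dppn: DPPN,
    cores: Sequence[ComplexCore],
    config: DetectorConfig,
) -> list[PredictedComplex]:
    """Attach qualifying neighbors to each core in a single pass.

    A neighbor must be active at the core's time point and beat
    ``extend_thresh``; each candidate is scored against the frozen core,
    so attachment order is irrelevant and a protein may join several
    complexes. Complexes with identical member sets are deduplicated,
    keeping the best-ranked core.
    """
    results: list[PredictedComplex] = []
    for core in cores:
        t = core.assigned_time
        neighborhood: set[str] = set()
        for v in core.members:
            neighborhood |= dppn.neighbors(v)
        neighborhood -= core.members
        attachments = frozenset(
            w
            for w in neighborhood
            if dppn.level(w, t) > 0.0 and attach_score(dppn, core, w) > config.extend_thresh
        )
        results.append(PredictedComplex(core=core, attachments=attachments))

    by_members: dict[frozenset[str], PredictedComplex] = {}
    for pc in results:
        prev = by_members.get(pc.members)
        if prev is None or _rank_key(pc.core.members, pc.score) < _rank_key(
            prev.core.members, prev.score
        ):
            by_members[pc.members] = pc
    final = list(by_members.values())
    final.sort(key=lambda pc: _rank_key(pc.members, pc.score))
    return final


def identify_complexes(dppn: DPPN, config: DetectorConfig | None = None) -> list[PredictedComplex]:
    """Full two-phase pipeline: cliques -> cores -> attachment."""
    if config is None:
        config = DetectorConfig()
    if dppn.n_vertices == 0:
        return []
    cliques = enumerate_maximal_cliques(dppn, config.min_clique_size)
    cores = select_cores(dppn, cliques, config)
    return expand_cores(dppn, cores, config)
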