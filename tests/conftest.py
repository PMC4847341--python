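from itertools import combinations

import pytest

from dppnet.expression import ActivityTable
from dppnet.network import StaticPPINetwork, build_dppn


def make_dppn(levels, edges, n_timepoints=12):
    """Build a DPPN directly from {protein: {t: level}} and edge pairs."""
    activity = ActivityTable(levels, n_timepoints)
    vertices = set(activity.proteins)
    for u, v in edges:
        vertices.update((u, v))
    network = StaticPPINetwork(
        frozenset(vertices), frozenset(frozenset(e) for e in edges)
    )
    return build_dppn(network, activity)


def clique_edges(members):
    return list(combinations(sorted(members), 2))


@pytest.fixture
def triangle_dppn():
    """Standalone K3, all members at level 0.99 at T2 (and only T2)."""
    levels = {v: {2: 0.99} for v in ("A", "B", "C")}
    return make_dppn(levels, clique_edges(["A", "B", "C"]))
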