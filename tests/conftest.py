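"""Shared fixtures and brute-force oracles for the test suite.

The oracles here are deliberately naive (dictionaries of sets, full edge-set
algebra, dense linear solves) and independent of the package's storage
layout, so they can stand as ground truth against the compressed structure.
"""

from __future__ import annotations

import numpy as np
import pytest

from vcsrnet import EdgeList, FamilyParams, generate_family
from vcsrnet.core import VersionedCSR


def cumulative_adjacency(plan):
    """Cumulative adjacency-map oracle for a version-tree build plan.

    ``plan`` is ``[(parent_id, EdgeList), ...]`` with entry 0 the root.
    Returns one ``{vertex: {neighbor: weight}}`` dict per version.
    """
    maps: list[dict[int, dict[int, float]]] = []
    for parent, el in plan:
        adj: dict[int, dict[int, float]] = (
            {} if not maps else {v: dict(nbrs) for v, nbrs in maps[parent].items()}
        )
        for u, v, w in el.edges:
            adj.setdefault(u, {})[v] = w
            adj.setdefault(v, {})[u] = w
        maps.append(adj)
    return maps


def oracle_neighbors(adj_map, v):
    return sorted(adj_map.get(v, {}).items())


def labeled_pair_set(edges, registry):
    """Unordered global-index pair set of a labeled edge list."""
    out = set()
    for u, v, _ in edges:
        iu, iv = registry.index(u), registry.index(v)
        out.add((min(iu, iv), max(iu, iv)))
    return out


def sibling_family(seed, b=3, n_vertices=60, base_edges=120, child_edges=15):
    """A root version plus ``b`` sibling children, with the build plan."""
    rng = np.random.default_rng(seed)

    def sample(count, forbidden):
        chosen, local = [], set(forbidden)
        while len(chosen) < count:
            a, c = (int(x) for x in rng.integers(0, n_vertices, size=2))
            if a == c:
                continue
            key = (min(a, c), max(a, c))
            if key in local:
                continue
            local.add(key)
            chosen.append((key[0], key[1], round(float(rng.uniform(0.1, 2.0)), 3)))
        return EdgeList(chosen, n_vertices)

    root = sample(base_edges, set())
    g = VersionedCSR.from_edge_list(root)
    plan = [(0, root)]
    for _ in range(b):
        adds = sample(child_edges, root.pair_set())
        g.add_version(0, adds)
        plan.append((0, adds))
    return g, plan


@pytest.fixture(scope="session")
def small_family():
    """A k=3 layered family with its built tree (session-cached: read-only)."""
    from vcsrnet import build_version_tree

    inputs = generate_family(FamilyParams(k=3, seed=11))
    g, meta, registry = build_version_tree(inputs)
    return inputs, g, meta, registry


@pytest.fixture()
def path_graph():
    """P3 path 0-1-2 with unit weights."""
    return VersionedCSR.from_edge_list(
        EdgeList([(0, 1, 1.0), (1, 2, 1.0)], 3)
    )
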