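"""Query-time extraction and composition of stored network versions.

*Vertical* integration materializes the cumulative network of a single
version as a standard CSR matrix (optionally pruned to the component(s)
reachable from a seed set).  *Horizontal* integration combines sibling
versions — e.g. several tissues — by edge union or intersection.  Composition
exploits the overlap between siblings: one pass over the row descriptors
partitions the vertices into ``S_p`` (descriptors identical in every composed
version, gathered from a single version) and ``S_n`` (everything else,
gathered from each of the ``b`` versions), so the whole composition touches
the edge arrays O(bE) times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .builder import (
    KIND_DISEASE,
    KIND_LOCUS,
    KIND_PROTEIN,
    LAYER_ASSOCIATION,
    LAYER_ONTOLOGY,
    LAYER_TISSUE_EQTL,
    LAYER_TISSUE_PPI,
    VersionMeta,
    VertexRegistry,
)
from .core import GraphInputError, VersionedCSR

__all__ = [
    "PlainCSR",
    "QuerySpec",
    "extract_version",
    "partition_vertices",
    "compose_versions",
    "resolve_query",
]

#: valid layer-selection prefixes, outermost layer last
_LAYER_ORDER = ("GD", "GA", "GP", "GL")


@dataclass
class PlainCSR:
    """A single composed network in standard CSR form.

    ``matrix`` is a symmetric ``scipy.sparse.csr_matrix`` with sorted rows;
    ``vertex_ids[i]`` maps local row ``i`` back to the global registry index.
    """

    matrix: sparse.csr_matrix
    vertex_ids: np.ndarray

    @property
    def A(self) -> np.ndarray:  # noqa: N802 - field name from the CSR layout
        return self.matrix.data

    @property
    def JA(self) -> np.ndarray:  # noqa: N802
        return self.matrix.indices

    @property
    def IA(self) -> np.ndarray:  # noqa: N802
        return self.matrix.indptr

    @property
    def n_vertices(self) -> int:
        return self.matrix.shape[0]

    def edge_set(self) -> set[tuple[int, int]]:
        """Unordered global-index edge pairs (diagnostic/oracle helper)."""
        coo = self.matrix.tocoo()
        out = set()
        for i, j in zip(coo.row, coo.col):
            gi, gj = int(self.vertex_ids[i]), int(self.vertex_ids[j])
            out.add((gi, gj) if gi <= gj else (gj, gi))
        return out

    def local_index(self, global_idx: int) -> int:
        pos = np.searchsorted(self.vertex_ids, global_idx)
        if pos == len(self.vertex_ids) or self.vertex_ids[pos] != global_idx:
            raise GraphInputError(
                f"global vertex {global_idx} is not part of this network"
            )
        return int(pos)


@dataclass
class QuerySpec:
    """A user query: layer subset, tissue subset, compose mode and seeds.

    ``layers`` must be a prefix of ``GD -> GA -> GP -> GL`` (the selected
    network types must induce a path in the version tree).  ``tissues`` is
    required once ``GP`` or ``GL`` is selected; ``mode`` decides whether a
    tissue-specific edge must occur in at least one (union) or all
    (intersection) selected tissues.
    """

    layers: tuple[str, ...]
    tissues: tuple[str, ...] = ()
    mode: str = "union"
    seeds: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        layers = tuple(self.layers)
        if layers != _LAYER_ORDER[: len(layers)]:
            raise GraphInputError(
                f"layers {layers} do not induce a path; expected a prefix of "
                f"{_LAYER_ORDER}"
            )
        if self.mode not in ("union", "intersection"):
            raise GraphInputError(f"unknown mode {self.mode!r}")
        if len(layers) >= 3 and not self.tissues:
            raise GraphInputError("tissue-specific layers require a tissue set")
        object.__setattr__(self, "layers", layers)
        object.__setattr__(self, "tissues", tuple(self.tissues))
        object.__setattr__(self, "seeds", tuple(self.seeds))

    def to_dict(self) -> dict:
        return {
            "layers": list(self.layers),
            "tissues": list(self.tissues),
            "mode": self.mode,
            "seeds": list(self.seeds),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuerySpec":
        return cls(
            layers=tuple(d["layers"]),
            tissues=tuple(d.get("tissues", ())),
            mode=d.get("mode", "union"),
            seeds=tuple(d.get("seeds", ())),
        )


def _rows_to_csr(
    rows: Sequence[Sequence[tuple[int, float]]], n: int
) -> sparse.csr_matrix:
    indptr = np.zeros(n + 1, dtype=np.int64)
    for v, row in enumerate(rows):
        indptr[v + 1] = indptr[v] + len(row)
    indices = np.empty(indptr[-1], dtype=np.int64)
    data = np.empty(indptr[-1], dtype=np.float64)
    pos = 0
    for row in rows:
        for nbr, w in row:
            indices[pos] = nbr
            data[pos] = w
            pos += 1
    mat = sparse.csr_matrix((data, indices, indptr), shape=(n, n))
    mat.sort_indices()
    return mat


def _prune_to_seeds(net: PlainCSR, seed_rows: Sequence[int]) -> PlainCSR:
    """Restrict to vertices reachable (undirected) from any seed row."""
    n_comp, labels = connected_components(net.matrix, directed=False)
    wanted = {labels[s] for s in seed_rows}
    keep = np.flatnonzero(np.isin(labels, sorted(wanted)))
    sub = net.matrix[keep][:, keep].tocsr()
    sub.sort_indices()
    return PlainCSR(matrix=sub, vertex_ids=net.vertex_ids[keep])


def extract_version(
    g: VersionedCSR, version_id: int, seeds: Sequence[int] | None = None
) -> PlainCSR:
    """Materialize one stored version as a standard CSR network.

    Linear in the number of edges of the extracted version.  When ``seeds``
    (global vertex indices) are given, parts of the network unreachable from
    every seed are removed and ``vertex_ids`` records the surviving vertices.
    """
    n = g.n_vertices(version_id)
    rows = [g.neighbors(version_id, v) for v in range(n)]
    net = PlainCSR(matrix=_rows_to_csr(rows, n), vertex_ids=np.arange(n))
    if seeds is None:
        return net
    for s in seeds:
        if not (0 <= s < n):
            raise GraphInputError(
                f"seed {s} outside version {version_id}'s vertex range [0, {n})"
            )
    return _prune_to_seeds(net, list(seeds))


def _check_composable(g: VersionedCSR, version_ids: Sequence[int]) -> None:
    if not version_ids:
        raise GraphInputError("no versions to compose")
    depths = {d: g.depth(d) for d in version_ids}
    if len(set(depths.values())) > 1:
        detail = ", ".join(f"v{d} at depth {depths[d]}" for d in version_ids)
        raise GraphInputError(
            f"cannot compose versions at different tree depths ({detail}); "
            "their shared-prefix semantics differ"
        )


def partition_vertices(
    g: VersionedCSR, version_ids: Sequence[int]
) -> tuple[set[int], set[int]]:
    """Split vertices into ``S_p`` (identical row descriptors across all the
    given versions) and ``S_n`` (the rest).

    The test is bitwise equality of decompressed descriptors — conservative:
    a vertex whose adjacency happens to be equal through different storage
    lands in ``S_n``, which costs speed but never correctness.  Vertices not
    present in every version are always in ``S_n``.
    """
    _check_composable(g, version_ids)
    segs = [g.decompress_ia(d) for d in version_ids]
    n_min = min(g.n_vertices(d) for d in version_ids)
    n_max = max(g.n_vertices(d) for d in version_ids)
    first = segs[0]
    s_p = {
        v
        for v in range(n_min)
        if all(seg[v] == first[v] for seg in segs[1:])
    }
    s_n = set(range(n_max)) - s_p
    return s_p, s_n


def _default_reducer(mode: str) -> Callable[[Sequence[float]], float]:
    return max if mode == "union" else min


def compose_versions(
    g: VersionedCSR,
    version_ids: Sequence[int],
    mode: str = "union",
    weight_reducer: Callable[[Sequence[float]], float] | None = None,
) -> PlainCSR:
    """Horizontally integrate sibling versions into one CSR network.

    The result's edge set is the union or intersection of the versions' edge
    sets; shared ancestral edges are identical in every sibling and survive
    both modes.  Weights of an edge found in several versions are combined by
    ``weight_reducer`` (default: ``max`` for union, ``min`` for intersection;
    the reducer should be insensitive to argument order and to duplicated
    identical values so that results are version-order invariant).
    """
    if mode not in ("union", "intersection"):
        raise GraphInputError(f"unknown mode {mode!r}")
    version_ids = list(dict.fromkeys(version_ids))  # dedupe, keep order
    if len(version_ids) == 1:
        return extract_version(g, version_ids[0])
    reducer = weight_reducer or _default_reducer(mode)
    s_p, _s_n = partition_vertices(g, version_ids)
    b = len(version_ids)
    n = max(g.n_vertices(d) for d in version_ids)
    rows: list[list[tuple[int, float]]] = []
    for v in range(n):
        if v in s_p:
            # identical descriptors: a single pass over one version suffices
            rows.append(g.neighbors(version_ids[0], v))
            continue
        per_version = [
            g.neighbors(d, v) if v < g.n_vertices(d) else []
            for d in version_ids
        ]
        weights: dict[int, list[float]] = {}
        for row in per_version:
            for nbr, w in row:
                weights.setdefault(nbr, []).append(w)
        if mode == "union":
            merged = [(nbr, reducer(ws)) for nbr, ws in weights.items()]
        else:
            merged = [
                (nbr, reducer(ws)) for nbr, ws in weights.items() if len(ws) == b
            ]
        merged.sort(key=lambda p: p[0])
        rows.append(merged)
    return PlainCSR(matrix=_rows_to_csr(rows, n), vertex_ids=np.arange(n))


def resolve_query(
    g: VersionedCSR,
    meta: VersionMeta,
    registry: VertexRegistry,
    spec: QuerySpec,
) -> tuple[PlainCSR, np.ndarray]:
    """Turn a :class:`QuerySpec` into a composed network plus local seed rows.

    The deepest selected layer picks one stored version per tissue (vertical
    integration along the path is implicit in the cumulative versions);
    tissue versions are then horizontally integrated with ``spec.mode``.
    Generic-only selections bypass horizontal integration.  When seeds are
    given, the composed network is pruned to their reachable part.
    """
    deepest = spec.layers[-1]
    if deepest in ("GD", "GA"):
        layer = LAYER_ONTOLOGY if deepest == "GD" else LAYER_ASSOCIATION
        version_ids = [meta.version_for(layer)]
    else:
        layer = LAYER_TISSUE_PPI if deepest == "GP" else LAYER_TISSUE_EQTL
        known = set(meta.tissue_names)
        for t in spec.tissues:
            if t not in known:
                raise GraphInputError(f"unknown tissue {t!r}")
        version_ids = [meta.version_for(layer, t) for t in spec.tissues]
    net = compose_versions(g, version_ids, mode=spec.mode)

    seed_globals = []
    for label in spec.seeds:
        idx = registry.index(label)
        if registry.kind(idx) not in (KIND_DISEASE, KIND_PROTEIN, KIND_LOCUS):
            raise GraphInputError(f"seed {label!r} has unknown kind")
        if idx >= net.n_vertices:
            raise GraphInputError(
                f"seed {label!r} is not part of the selected layers/tissues"
            )
        seed_globals.append(idx)
    if seed_globals:
        net = _prune_to_seeds(net, seed_globals)
        seed_rows = np.array([net.local_index(s) for s in seed_globals], dtype=np.int64)
    else:
        seed_rows = np.empty(0, dtype=np.int64)
    return net, seed_rows
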