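"""Versioned compressed-sparse-row (CSR) storage for families of related networks.

A *version tree* stores many overlapping undirected networks in one structure.
Each tree node is a network version obtained from its parent by adding edges;
the network of a node is the cumulative edge set along the root-to-node path.
All versions share a single pair of weight/column arrays (``A``/``JA``): edges
present in an ancestor are never re-stored for a descendant.  Per-version row
descriptors live in an *augmented IA array* whose entries are 4-tuples
``(e0, e1, e2, e3)`` with a 2-bit row-type flag packed into the two least
significant bits of ``e3``:

``N`` (normal)
    One contiguous ``JA`` segment: offset ``e0``, length ``e1``.
``S`` (split)
    Two contiguous ``JA`` segments — ``(e0, e1)`` and ``(e2, e3 >> 2)`` —
    merged on read.  Splits let a child reuse its parent's adjacency data.
``C`` (compressed row set)
    A run of ``e1`` row descriptors copied verbatim from the version's
    key-frame segment, starting at absolute ``IA`` index ``e0``.  Key-frame
    segments themselves never contain ``C`` entries, so decompression never
    chases more than one hop.

The per-version descriptor segments are delimited by the offset array ``D``
(version ``d`` owns ``IA[D[d]:D[d+1]]``), key-frame assignments live in ``K``
and the tree shape in ``parent``.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "FLAG_NORMAL",
    "FLAG_SPLIT",
    "FLAG_COMPRESSED",
    "EdgeList",
    "GraphInputError",
    "IntegrityError",
    "VersionedCSR",
    "create_graph",
    "add_version",
    "neighbors",
    "decompress_ia",
    "compress_ia_segment",
    "storage_stats",
    "pack_e3",
    "unpack_e3",
]

FLAG_NORMAL = 0
FLAG_SPLIT = 1
FLAG_COMPRESSED = 2

_ROW_TYPE_NAMES = {FLAG_NORMAL: "N", FLAG_SPLIT: "S", FLAG_COMPRESSED: "C"}

#: bytes per stored element under the declared 64-bit field widths
_WORD = 8
_IA_ENTRY_BYTES = 4 * _WORD


class GraphInputError(ValueError):
    """Raised for malformed caller input (bad indices, duplicate edges, ...)."""


class IntegrityError(RuntimeError):
    """Raised when the stored structure violates its own invariants."""


def pack_e3(payload: int, flag: int) -> int:
    """Pack a length payload and a 2-bit row-type flag into one ``e3`` word."""
    return (payload << 2) | flag


def unpack_e3(e3: int) -> tuple[int, int]:
    """Split an ``e3`` word into ``(payload, flag)``."""
    return e3 >> 2, e3 & 0x3


@dataclass
class EdgeList:
    """A plain undirected edge list over a dense integer vertex space.

    ``edges`` holds ``(u, v, w)`` triples with ``0 <= u, v < n_vertices``;
    unordered pairs must be unique and weights finite.  Self-loops are
    permitted and are stored once in the incident row.
    """

    edges: list[tuple[int, int, float]]
    n_vertices: int

    def validate(self) -> None:
        if self.n_vertices < 0:
            raise GraphInputError(f"negative vertex count {self.n_vertices}")
        seen: set[tuple[int, int]] = set()
        for u, v, w in self.edges:
            if not (0 <= u < self.n_vertices and 0 <= v < self.n_vertices):
                raise GraphInputError(
                    f"edge ({u}, {v}) out of range for {self.n_vertices} vertices"
                )
            if not math.isfinite(w):
                raise GraphInputError(f"edge ({u}, {v}) has non-finite weight {w!r}")
            key = (u, v) if u <= v else (v, u)
            if key in seen:
                raise GraphInputError(f"duplicate edge ({u}, {v})")
            seen.add(key)

    def pair_set(self) -> set[tuple[int, int]]:
        return {(u, v) if u <= v else (v, u) for u, v, _ in self.edges}


@dataclass
class AccessCounter:
    """Instrumentation for ``JA``/``A`` traffic (used to check O(bE) passes)."""

    ja_ranges: int = 0
    ja_elements: int = 0

    def reset(self) -> None:
        self.ja_ranges = 0
        self.ja_elements = 0


def _merge_sorted(*runs: Sequence[tuple[int, float]]) -> list[tuple[int, float]]:
    """Merge sorted duplicate-free adjacency runs into one sorted list."""
    out: list[tuple[int, float]] = []
    for run in runs:
        out.extend(run)
    out.sort(key=lambda p: p[0])
    return out


class VersionedCSR:
    """The shared store for a tree of network versions.

    Instances are built with :meth:`from_edge_list` (the root version) and
    grown with :meth:`add_version`.  All mutation is append-only: data already
    readable for an existing version is never rewritten, so ancestor versions
    are bit-stable under later additions.
    """

    def __init__(self, h: float = 0.5) -> None:
        if not (0.0 < h <= 1.0):
            raise GraphInputError(f"key-frame threshold h must be in (0, 1], got {h}")
        self.h = float(h)
        self._A: list[float] = []
        self._JA: list[int] = []
        self._IA: list[tuple[int, int, int, int]] = []
        self._D: list[int] = [0]
        self._K: list[int] = []
        self._parent: list[int] = []
        self._n_vertices: list[int] = []
        # first vertex covered by each stored IA entry, one list per version
        self._seg_cover: list[list[int]] = []
        self.access = AccessCounter()

    # ------------------------------------------------------------------ build

    @classmethod
    def from_edge_list(cls, edges: EdgeList, h: float = 0.5) -> "VersionedCSR":
        """Create a store whose single root version holds ``edges``."""
        edges.validate()
        g = cls(h=h)
        adj: list[list[tuple[int, float]]] = [[] for _ in range(edges.n_vertices)]
        for u, v, w in edges.edges:
            adj[u].append((v, float(w)))
            if u != v:
                adj[v].append((u, float(w)))
        entries: list[tuple[int, int, int, int]] = []
        for row in adj:
            row.sort(key=lambda p: p[0])
            off = len(g._JA)
            g._JA.extend(n for n, _ in row)
            g._A.extend(w for _, w in row)
            entries.append((off, len(row), 0, pack_e3(0, FLAG_NORMAL)))
        g._IA.extend(entries)
        g._D.append(len(g._IA))
        g._K.append(0)
        g._parent.append(0)
        g._n_vertices.append(edges.n_vertices)
        g._seg_cover.append(list(range(edges.n_vertices)))
        return g

    def add_version(
        self,
        parent_id: int,
        new_edges: EdgeList,
        *,
        join_splits: bool = True,
    ) -> int:
        """Append a child of ``parent_id`` whose network adds ``new_edges``.

        Every updated row undergoes exactly one of: split of a normal row,
        split of a split row (the old second segment is merged with the new
        edges and re-appended) or a join back to a normal row.  The join fires
        when the prospective second segment would be at least as long as the
        first (``e3 + t >= e1``), which bounds duplication of adjacency data
        across a chain of versions.  ``join_splits=False`` disables the join
        (useful only to observe the unbounded-duplication behaviour).

        Returns the new version id.  The parent's (and every ancestor's)
        stored data is unchanged.
        """
        self._check_version(parent_id)
        new_edges.validate()
        nvp = self._n_vertices[parent_id]
        if new_edges.n_vertices < nvp:
            raise GraphInputError(
                f"child vertex count {new_edges.n_vertices} shrinks parent's {nvp}"
            )
        additions: dict[int, list[tuple[int, float]]] = {}
        for u, v, w in new_edges.edges:
            if u < nvp and v < nvp and self._has_edge(parent_id, u, v):
                raise GraphInputError(
                    f"edge ({u}, {v}) already exists in parent version {parent_id}; "
                    "re-adding or re-weighting stored edges is not supported"
                )
            additions.setdefault(u, []).append((v, float(w)))
            if u != v:
                additions.setdefault(v, []).append((u, float(w)))

        entries = list(self.decompress_ia(parent_id))
        for _ in range(nvp, new_edges.n_vertices):
            entries.append((len(self._JA), 0, 0, pack_e3(0, FLAG_NORMAL)))

        for v in sorted(additions):
            adds = sorted(additions[v], key=lambda p: p[0])
            t = len(adds)
            e0, e1, e2, e3 = entries[v]
            payload, flag = unpack_e3(e3)
            if flag == FLAG_NORMAL:
                off = len(self._JA)
                if e1 == 0:
                    # vertex had no edges yet: its row stays normal
                    self._append_run(adds)
                    entries[v] = (off, t, 0, pack_e3(0, FLAG_NORMAL))
                else:
                    # split the normal row: old data stays as segment 1
                    self._append_run(adds)
                    entries[v] = (e0, e1, off, pack_e3(t, FLAG_SPLIT))
            elif flag == FLAG_SPLIT:
                seg2 = list(
                    zip(self._JA[e2 : e2 + payload], self._A[e2 : e2 + payload])
                )
                if join_splits and payload + t >= e1:
                    # join back to a normal row holding the full adjacency
                    seg1 = list(
                        zip(self._JA[e0 : e0 + e1], self._A[e0 : e0 + e1])
                    )
                    merged = _merge_sorted(seg1, seg2, adds)
                    off = len(self._JA)
                    self._append_run(merged)
                    entries[v] = (off, len(merged), 0, pack_e3(0, FLAG_NORMAL))
                else:
                    # split the split row: re-append segment 2 merged with adds
                    merged2 = _merge_sorted(seg2, adds)
                    off = len(self._JA)
                    self._append_run(merged2)
                    entries[v] = (e0, e1, off, pack_e3(len(merged2), FLAG_SPLIT))
            else:  # pragma: no cover - decompress_ia never yields C entries
                raise IntegrityError("compressed entry leaked out of decompression")

        child = len(self._n_vertices)
        kf = self._K[parent_id]
        kf_seg = self._IA[self._D[kf] : self._D[kf + 1]]
        compressed, ratio = compress_ia_segment(
            entries, kf_seg, keyframe_offset=self._D[kf]
        )
        if ratio <= self.h:
            stored, child_kf = compressed, kf
        else:
            stored, child_kf = entries, child
        self._IA.extend(stored)
        self._D.append(len(self._IA))
        self._K.append(child_kf)
        self._parent.append(parent_id)
        self._n_vertices.append(new_edges.n_vertices)
        cover: list[int] = []
        pos = 0
        for e0, e1, _, e3 in stored:
            cover.append(pos)
            pos += e1 if (e3 & 0x3) == FLAG_COMPRESSED else 1
        self._seg_cover.append(cover)
        return child

    # ------------------------------------------------------------------ reads

    @property
    def n_versions(self) -> int:
        return len(self._n_vertices)

    def n_vertices(self, version_id: int) -> int:
        self._check_version(version_id)
        return self._n_vertices[version_id]

    def parent(self, version_id: int) -> int:
        self._check_version(version_id)
        return self._parent[version_id]

    def keyframe(self, version_id: int) -> int:
        self._check_version(version_id)
        return self._K[version_id]

    def depth(self, version_id: int) -> int:
        """Distance from the root along parent pointers."""
        self._check_version(version_id)
        d = 0
        v = version_id
        while self._parent[v] != v:
            v = self._parent[v]
            d += 1
        return d

    def neighbors(self, version_id: int, v: int) -> list[tuple[int, float]]:
        """Sorted ``(neighbor, weight)`` adjacency of ``v`` in one version.

        Access cost is independent of the version's depth in the tree: one
        row-descriptor fetch (two ``IA`` reads when the descriptor lives in a
        compressed row set) plus at most two contiguous ``JA`` range reads.
        """
        self._check_version(version_id)
        if not (0 <= v < self._n_vertices[version_id]):
            raise GraphInputError(
                f"vertex {v} out of range for version {version_id} "
                f"({self._n_vertices[version_id]} vertices)"
            )
        e0, e1, e2, e3 = self._entry_for(version_id, v)
        payload, flag = unpack_e3(e3)
        if flag == FLAG_NORMAL:
            return self._read_run(e0, e1)
        seg1 = self._read_run(e0, e1)
        seg2 = self._read_run(e2, payload)
        return _merge_sorted(seg1, seg2)

    def degree(self, version_id: int, v: int) -> int:
        e0, e1, e2, e3 = self._entry_for(version_id, v)
        payload, flag = unpack_e3(e3)
        return e1 + (payload if flag == FLAG_SPLIT else 0)

    def decompress_ia(self, version_id: int) -> list[tuple[int, int, int, int]]:
        """The version's row descriptors with all ``C`` entries expanded.

        Single pass over the stored segment; compressed row sets resolve in
        one hop into the version's key-frame segment.
        """
        self._check_version(version_id)
        kf = self._K[version_id]
        kf_lo, kf_hi = self._D[kf], self._D[kf + 1]
        out: list[tuple[int, int, int, int]] = []
        for entry in self._IA[self._D[version_id] : self._D[version_id + 1]]:
            e0, e1, _, e3 = entry
            if (e3 & 0x3) != FLAG_COMPRESSED:
                out.append(entry)
                continue
            if not (kf_lo <= e0 and e0 + e1 <= kf_hi):
                raise IntegrityError(
                    f"compressed row set [{e0}, {e0 + e1}) escapes key-frame "
                    f"segment [{kf_lo}, {kf_hi}) of version {version_id}"
                )
            for sub in self._IA[e0 : e0 + e1]:
                if (sub[3] & 0x3) == FLAG_COMPRESSED:
                    raise IntegrityError(
                        "compressed row set references another compressed entry"
                    )
                out.append(sub)
        if len(out) != self._n_vertices[version_id]:
            raise IntegrityError(
                f"version {version_id} decompressed to {len(out)} rows, "
                f"expected {self._n_vertices[version_id]}"
            )
        return out

    def row_type(self, version_id: int, v: int) -> str:
        """``'N'``/``'S'`` row type of vertex ``v`` (after ``C`` resolution)."""
        _, _, _, e3 = self._entry_for(version_id, v)
        return _ROW_TYPE_NAMES[e3 & 0x3]

    def stored_segment(self, version_id: int) -> list[tuple[int, int, int, int]]:
        """The raw (possibly compressed) ``IA`` segment of one version."""
        self._check_version(version_id)
        return self._IA[self._D[version_id] : self._D[version_id + 1]]

    # ------------------------------------------------------------- statistics

    def storage_stats(self) -> dict[str, int | float]:
        """Array lengths and byte sizes, versus per-version standalone CSRs.

        ``bytes_total`` uses the declared 64-bit field widths (8-byte weights
        and indices, 32-byte augmented ``IA`` entries).
        ``per_version_separate_bytes`` is what storing every version as its
        own standard CSR would cost.
        """
        len_a, len_ja, len_ia = len(self._A), len(self._JA), len(self._IA)
        bookkeeping = len(self._D) + len(self._K) + len(self._parent) + len(
            self._n_vertices
        )
        bytes_total = (
            _WORD * (len_a + len_ja + bookkeeping) + _IA_ENTRY_BYTES * len_ia
        )
        separate = 0
        for d in range(self.n_versions):
            nnz = 0
            for e0, e1, _, e3 in self.decompress_ia(d):
                payload, flag = unpack_e3(e3)
                nnz += e1 + (payload if flag == FLAG_SPLIT else 0)
            separate += 2 * _WORD * nnz + _WORD * (self._n_vertices[d] + 1)
        return {
            "len_a": len_a,
            "len_ja": len_ja,
            "len_ia": len_ia,
            "bytes_total": bytes_total,
            "per_version_separate_bytes": separate,
            "compression_ratio": separate / bytes_total if bytes_total else 1.0,
        }

    def row_ja_footprint(self, v: int) -> int:
        """Distinct ``JA`` slots used by vertex ``v``'s rows over all versions.

        Segments shared between versions are counted once; this is the storage
        actually attributable to the vertex across the whole tree.
        """
        intervals: set[tuple[int, int]] = set()
        for d in range(self.n_versions):
            if v >= self._n_vertices[d]:
                continue
            e0, e1, e2, e3 = self._entry_for(d, v)
            payload, flag = unpack_e3(e3)
            if e1:
                intervals.add((e0, e0 + e1))
            if flag == FLAG_SPLIT and payload:
                intervals.add((e2, e2 + payload))
        covered = 0
        last = -1
        for lo, hi in sorted(intervals):
            lo = max(lo, last)
            if hi > lo:
                covered += hi - lo
                last = hi
        return covered

    # ----------------------------------------------------------- unsupported

    def delete_edges(self, *_args, **_kwargs):
        raise NotImplementedError(
            "edge deletion is not supported: the version tree is additive "
            "(derive a new root from a filtered edge list instead)"
        )

    # -------------------------------------------------------------- internal

    def _check_version(self, version_id: int) -> None:
        if not (0 <= version_id < len(self._n_vertices)):
            raise GraphInputError(
                f"unknown version id {version_id} (have {len(self._n_vertices)})"
            )

    def _entry_for(self, version_id: int, v: int) -> tuple[int, int, int, int]:
        """Resolve the (decompressed) row descriptor of one vertex.

        At most two ``IA`` fetches: the stored entry and, when that entry is a
        compressed row set, the referenced key-frame entry.
        """
        cover = self._seg_cover[version_id]
        pos = bisect_right(cover, v) - 1
        entry = self._IA[self._D[version_id] + pos]
        if (entry[3] & 0x3) == FLAG_COMPRESSED:
            inner = self._IA[entry[0] + (v - cover[pos])]
            if (inner[3] & 0x3) == FLAG_COMPRESSED:
                raise IntegrityError(
                    "compressed row set references another compressed entry"
                )
            return inner
        return entry

    def _has_edge(self, version_id: int, u: int, v: int) -> bool:
        return any(n == v for n, _ in self.neighbors(version_id, u))

    def _read_run(self, off: int, length: int) -> list[tuple[int, float]]:
        self.access.ja_ranges += 1
        self.access.ja_elements += length
        return list(zip(self._JA[off : off + length], self._A[off : off + length]))

    def _append_run(self, run: Iterable[tuple[int, float]]) -> None:
        for n, w in run:
            self._JA.append(n)
            self._A.append(w)


# --------------------------------------------------------------------------
# module-level operation surface


def create_graph(edges: EdgeList, h: float = 0.5) -> VersionedCSR:
    """Create a versioned store whose root version is ``edges``."""
    return VersionedCSR.from_edge_list(edges, h=h)


def add_version(
    g: VersionedCSR, parent_id: int, new_edges: EdgeList, *, join_splits: bool = True
) -> int:
    """Add a child version of ``parent_id``; see :meth:`VersionedCSR.add_version`."""
    return g.add_version(parent_id, new_edges, join_splits=join_splits)


def neighbors(g: VersionedCSR, version_id: int, v: int) -> list[tuple[int, float]]:
    """Sorted adjacency of ``v`` in ``version_id``."""
    return g.neighbors(version_id, v)


def decompress_ia(g: VersionedCSR, version_id: int) -> list[tuple[int, int, int, int]]:
    """Fully expanded row-descriptor array of one version."""
    return g.decompress_ia(version_id)


def storage_stats(g: VersionedCSR) -> dict[str, int | float]:
    """Size accounting; see :meth:`VersionedCSR.storage_stats`."""
    return g.storage_stats()


def compress_ia_segment(
    new_segment: Sequence[tuple[int, int, int, int]],
    keyframe_segment: Sequence[tuple[int, int, int, int]],
    keyframe_offset: int = 0,
) -> tuple[list[tuple[int, int, int, int]], float]:
    """Run-compress a row-descriptor segment against a key-frame segment.

    Maximal runs (length >= 2) of entries identical to the entry at the same
    vertex position of the key-frame are replaced by a single ``C`` entry
    pointing at the key-frame's ``IA`` range (``keyframe_offset`` is the
    absolute ``IA`` index of the key-frame segment's first entry).  Returns
    the compressed segment and the length ratio compressed/new, in ``(0, 1]``.
    Decompression (:meth:`VersionedCSR.decompress_ia`) is exactly inverse.
    """
    for entry in keyframe_segment:
        if (entry[3] & 0x3) == FLAG_COMPRESSED:
            raise IntegrityError("key-frame segment contains a compressed entry")
    n = len(new_segment)
    out: list[tuple[int, int, int, int]] = []
    i = 0
    limit = min(n, len(keyframe_segment))
    while i < n:
        if i < limit and new_segment[i] == keyframe_segment[i]:
            j = i
            while j < limit and new_segment[j] == keyframe_segment[j]:
                j += 1
            if j - i >= 2:
                out.append(
                    (keyframe_offset + i, j - i, 0, pack_e3(0, FLAG_COMPRESSED))
                )
                i = j
                continue
        out.append(tuple(new_segment[i]))
        i += 1
    ratio = len(out) / n if n else 1.0
    return out, ratio
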