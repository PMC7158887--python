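"""Unit and property tests for the versioned CSR store."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from vcsrnet import (
    EdgeList,
    GraphInputError,
    VersionedCSR,
    compress_ia_segment,
    create_graph,
    random_version_tree,
    two_version_fixture,
)
from vcsrnet.core import FLAG_COMPRESSED, FLAG_NORMAL, FLAG_SPLIT, pack_e3, unpack_e3

from conftest import cumulative_adjacency, oracle_neighbors


class TestCreateGraph:
    def test_empty_graph_single_normal_row(self):
        g = create_graph(EdgeList([], 1))
        seg = g.decompress_ia(0)
        assert len(seg) == 1
        assert unpack_e3(seg[0][3])[1] == FLAG_NORMAL
        assert seg[0][1] == 0
        assert g.neighbors(0, 0) == []

    def test_undirected_symmetry_on_path(self):
        g = create_graph(EdgeList([(0, 1, 1.0), (1, 2, 1.0)], 3))
        assert g.neighbors(0, 1) == [(0, 1.0), (2, 1.0)]
        assert g.neighbors(0, 0) == [(1, 1.0)]
        assert g.neighbors(0, 2) == [(1, 1.0)]

    def test_array_lengths_are_twice_edge_count(self):
        g, plan = random_version_tree(seed=0, n_versions=1, n_vertices=30,
                                      root_edges=40)
        assert len(g._A) == len(g._JA) == 2 * len(plan[0][1].edges)

    def test_matches_adjacency_map_oracle(self):
        g, plan = random_version_tree(seed=5, n_versions=1, n_vertices=50,
                                      root_edges=120)
        (adj,) = cumulative_adjacency(plan)
        for v in range(50):
            assert g.neighbors(0, v) == oracle_neighbors(adj, v)

    def test_self_loop_stored_once(self):
        g = create_graph(EdgeList([(0, 0, 2.0), (0, 1, 1.0)], 2))
        assert g.neighbors(0, 0) == [(0, 2.0), (1, 1.0)]
        assert len(g._JA) == 3

    @pytest.mark.parametrize(
        "edges, n, message",
        [
            ([(0, 1, 1.0), (1, 0, 2.0)], 2, "duplicate"),
            ([(0, 5, 1.0)], 2, "out of range"),
            ([(0, 1, float("nan"))], 2, "non-finite"),
        ],
    )
    def test_invalid_input_rejected(self, edges, n, message):
        with pytest.raises(GraphInputError, match=message):
            create_graph(EdgeList(edges, n))


class TestAddVersion:
    def test_identity_child_shares_everything(self):
        g, _ = random_version_tree(seed=2, n_versions=1, n_vertices=40,
                                   root_edges=60)
        ja_before = len(g._JA)
        child = g.add_version(0, EdgeList([], 40))
        assert len(g._JA) == ja_before  # no edge data duplicated
        # IA grows by at most one compressed entry for the whole segment
        assert len(g.stored_segment(child)) == 1
        for v in range(40):
            assert g.neighbors(child, v) == g.neighbors(0, v)

    def test_split_normal_row_fields(self):
        g = create_graph(EdgeList([(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0)], 6))
        child = g.add_version(0, EdgeList([(0, 4, 1.0), (0, 5, 1.0)], 6))
        e0, e1, e2, e3 = g.decompress_ia(child)[0]
        payload, flag = unpack_e3(e3)
        assert flag == FLAG_SPLIT and e1 == 3 and payload == 2
        assert g.neighbors(0, 0) == [(1, 1.0), (2, 1.0), (3, 1.0)]

    def test_parent_reads_bit_identical_after_additions(self):
        g, plan = random_version_tree(seed=9, n_versions=4, n_vertices=50)
        snapshot = {
            (d, v): g.neighbors(d, v)
            for d in range(g.n_versions)
            for v in range(g.n_vertices(d))
        }
        segs = [g.decompress_ia(d) for d in range(g.n_versions)]
        g.add_version(g.n_versions - 1, EdgeList([], 50))
        g.add_version(0, EdgeList([(0, 49, 9.0)] if (0, 49) not in
                                  plan[0][1].pair_set() else [], 50))
        for (d, v), row in snapshot.items():
            assert g.neighbors(d, v) == row
        for d, seg in enumerate(segs):
            assert g.decompress_ia(d) == seg

    def test_chain_matches_cumulative_oracle_and_space_bound(self):
        ell = 8
        g = create_graph(EdgeList([], 1))
        plan = [(0, EdgeList([], 1))]
        parent = 0
        for d in range(1, ell + 1):
            adds = EdgeList([(0, d, 1.0)], d + 1)
            parent = g.add_version(parent, adds)
            plan.append((parent - 1, adds))
        maps = cumulative_adjacency(plan)
        for d in range(g.n_versions):
            assert g.neighbors(d, 0) == oracle_neighbors(maps[d], 0)
        r = ell
        assert g.row_ja_footprint(0) <= 4 * r * (1 + math.log2(ell))

    def test_duplicate_of_parent_edge_rejected(self):
        g = create_graph(EdgeList([(0, 1, 1.0)], 2))
        with pytest.raises(GraphInputError, match="already exists"):
            g.add_version(0, EdgeList([(1, 0, 2.0)], 2))

    def test_shrinking_vertex_count_rejected(self):
        g = create_graph(EdgeList([(0, 1, 1.0)], 5))
        with pytest.raises(GraphInputError, match="shrinks"):
            g.add_version(0, EdgeList([], 3))

    def test_unknown_parent_rejected(self):
        g = create_graph(EdgeList([], 1))
        with pytest.raises(GraphInputError, match="unknown version"):
            g.add_version(7, EdgeList([], 1))

    def test_new_vertices_start_isolated(self):
        g = create_graph(EdgeList([(0, 1, 1.0)], 2))
        child = g.add_version(0, EdgeList([], 5))
        for v in (2, 3, 4):
            assert g.neighbors(child, v) == []


class TestNeighbors:
    def test_isolated_vertex(self):
        g = create_graph(EdgeList([(0, 1, 1.0)], 3))
        assert g.neighbors(0, 2) == []

    def test_split_row_two_way_merge(self):
        g = create_graph(EdgeList([(0, 1, 1.0), (0, 5, 1.0)], 10))
        child = g.add_version(0, EdgeList([(0, 3, 2.0), (0, 9, 2.0)], 10))
        assert g.neighbors(child, 0) == [(1, 1.0), (3, 2.0), (5, 1.0), (9, 2.0)]

    def test_out_of_range_rejected(self):
        g = create_graph(EdgeList([], 2))
        with pytest.raises(GraphInputError):
            g.neighbors(0, 2)
        with pytest.raises(GraphInputError):
            g.neighbors(1, 0)

    def test_randomized_tree_against_oracle(self):
        g, plan = random_version_tree(seed=17, n_versions=5, n_vertices=40)
        maps = cumulative_adjacency(plan)
        for d in range(g.n_versions):
            for v in range(g.n_vertices(d)):
                assert g.neighbors(d, v) == oracle_neighbors(maps[d], v)

    def test_access_depth_independent(self):
        """Any row read costs at most two contiguous JA range reads."""
        g, _ = random_version_tree(seed=21, n_versions=10, n_vertices=30,
                                   root_edges=50, added_edges=8)
        deepest = max(range(g.n_versions), key=g.depth)
        for v in range(g.n_vertices(deepest)):
            g.access.reset()
            g.neighbors(deepest, v)
            assert g.access.ja_ranges <= 2


class TestIACompression:
    def test_keyframe_returns_own_segment(self):
        g = two_version_fixture()
        kf = g.keyframe(0)
        assert kf == 0
        assert g.decompress_ia(0) == g.stored_segment(0)

    def test_identical_child_decompresses_to_parent(self):
        g, _ = random_version_tree(seed=3, n_versions=1, n_vertices=30)
        child = g.add_version(0, EdgeList([], 30))
        assert g.decompress_ia(child) == g.decompress_ia(0)

    def test_neighbors_agree_through_both_paths(self):
        """Reading via the compressed segment equals reading via the
        decompressed entries."""
        g, _ = random_version_tree(seed=13, n_versions=6, n_vertices=60)
        for d in range(g.n_versions):
            entries = g.decompress_ia(d)
            for v in range(g.n_vertices(d)):
                assert g._entry_for(d, v) == entries[v]

    def test_full_match_compresses_to_single_entry(self):
        seg = [(0, 3, 0, pack_e3(0, FLAG_NORMAL)), (3, 2, 0, pack_e3(0, FLAG_NORMAL))]
        comp, ratio = compress_ia_segment(seg, seg, keyframe_offset=10)
        assert comp == [(10, 2, 0, pack_e3(0, FLAG_COMPRESSED))]
        assert ratio == 0.5

    def test_disjoint_segments_unchanged(self):
        a = [(0, 1, 0, pack_e3(0, FLAG_NORMAL))] * 3
        b = [(9, 1, 0, pack_e3(0, FLAG_NORMAL))] * 3
        comp, ratio = compress_ia_segment(a, b)
        assert comp == a and ratio == 1.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True,
              database=None)
    def test_round_trip_identity_property(self, seed):
        """decompress(compress(x)) == x on random segments with shared runs."""
        import numpy as np

        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 40))
        kf = [
            (int(rng.integers(0, 100)), int(rng.integers(0, 5)), 0,
             pack_e3(0, FLAG_NORMAL))
            for _ in range(n)
        ]
        new = [
            kf[i] if rng.random() < 0.6 else
            (int(rng.integers(100, 200)), int(rng.integers(0, 5)), 0,
             pack_e3(0, FLAG_NORMAL))
            for i in range(n)
        ]
        offset = 7
        comp, ratio = compress_ia_segment(new, kf, keyframe_offset=offset)
        assert 0 < ratio <= 1.0
        # inline decompression against the keyframe
        out = []
        for e0, e1, _, e3 in comp:
            if unpack_e3(e3)[1] == FLAG_COMPRESSED:
                out.extend(kf[e0 - offset : e0 - offset + e1])
            else:
                out.append((e0, e1, _, e3))
        assert out == new

    def test_keyframe_segments_have_no_compressed_entries(self):
        g, _ = random_version_tree(seed=29, n_versions=8, n_vertices=40)
        for d in range(g.n_versions):
            kf = g.keyframe(d)
            assert kf <= d and g.keyframe(kf) == kf
            for entry in g.stored_segment(kf):
                assert unpack_e3(entry[3])[1] != FLAG_COMPRESSED


class TestStorageStats:
    def test_single_version_close_to_standalone_csr(self):
        g, _ = random_version_tree(seed=1, n_versions=1, n_vertices=40,
                                   root_edges=100)
        st_ = g.storage_stats()
        # the augmented IA entry is 4x wider than a plain offset
        assert st_["bytes_total"] <= st_["per_version_separate_bytes"] + 32 * 41

    def test_identical_versions_reuse_all_edges(self):
        g, _ = random_version_tree(seed=4, n_versions=1, n_vertices=30,
                                   root_edges=60)
        base_ja = len(g._JA)
        parent = 0
        for _ in range(5):
            parent = g.add_version(parent, EdgeList([], 30))
        assert len(g._JA) == base_ja

    def test_high_overlap_family_beats_separate_storage(self, small_family):
        _, g, _, _ = small_family
        st_ = g.storage_stats()
        assert st_["bytes_total"] < st_["per_version_separate_bytes"]


def test_deletion_is_not_supported():
    g = two_version_fixture()
    with pytest.raises(NotImplementedError, match="not supported"):
        g.delete_edges(0, [(0, 1)])
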