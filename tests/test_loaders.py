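"""Collation, worker sharding, and the three loading backends."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from molgnn.chem import build_vocabulary
from molgnn.loaders import (collate, export_objects, make_loader,
                            shard_indices)
from molgnn.model import global_mean_pool
from tests.conftest import random_feature_graph


class TestCollate:
    def test_two_triangles_offsets(self):
        rng = np.random.default_rng(0)
        tri = [random_feature_graph(rng, 3) for _ in range(2)]
        batch = collate(tri)
        assert batch.num_nodes == 6
        second = batch.edge_index[:, tri[0].num_edges:]
        assert second.min() >= 3 and second.max() <= 5
        assert np.array_equal(batch.graph_id, [0, 0, 0, 1, 1, 1])

    def test_single_graph_identity(self):
        rng = np.random.default_rng(1)
        g = random_feature_graph(rng, 4)
        batch = collate([g])
        assert np.array_equal(batch.x, g.x)
        assert np.array_equal(batch.edge_index, g.edge_index)
        assert np.all(batch.graph_id == 0)

    def test_pooling_matches_independent_means(self):
        rng = np.random.default_rng(2)
        graphs = [random_feature_graph(rng, int(n)) for n in
                  rng.integers(2, 9, size=5)]
        batch = collate(graphs)
        pooled = global_mean_pool(batch.x.astype(np.float64), batch.graph_id,
                                  batch.num_graphs)
        for i, g in enumerate(graphs):
            np.testing.assert_allclose(pooled[i], g.x.mean(axis=0), rtol=1e-6)

    def test_merge_equals_concatenated_collate(self):
        """Collation is associative with concatenation after offsetting."""
        rng = np.random.default_rng(3)
        A = [random_feature_graph(rng, int(n)) for n in rng.integers(2, 7, 3)]
        B = [random_feature_graph(rng, int(n)) for n in rng.integers(2, 7, 4)]
        whole = collate(A + B)
        pa, pb = collate(A), collate(B)
        np.testing.assert_array_equal(
            whole.x, np.concatenate([pa.x, pb.x]))
        np.testing.assert_array_equal(
            whole.edge_index,
            np.concatenate([pa.edge_index, pb.edge_index + pa.num_nodes],
                           axis=1))
        np.testing.assert_array_equal(
            whole.graph_id,
            np.concatenate([pa.graph_id, pb.graph_id + pa.num_graphs]))

    def test_graph_id_nondecreasing_and_edges_within_graphs(self, small_graphs):
        batch = collate(small_graphs[:10])
        assert np.all(np.diff(batch.graph_id) >= 0)
        assert np.array_equal(batch.graph_id[batch.edge_index[0]],
                              batch.graph_id[batch.edge_index[1]])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            collate([])


class TestShardIndices:
    def test_floor_rule_with_drop_remainder(self):
        shards = [shard_indices(10, 3, w, seed=0) for w in range(3)]
        assert all(len(s) == 3 for s in shards)
        union = np.concatenate([s.indices for s in shards])
        assert len(set(union.tolist())) == 9

    def test_single_worker_full_permutation(self):
        s = shard_indices(8, 1, 0, seed=0)
        assert sorted(s.indices.tolist()) == list(range(8))

    def test_seed_determinism_and_sensitivity(self):
        a = shard_indices(1000, 4, 1, seed=7)
        b = shard_indices(1000, 4, 1, seed=7)
        c = shard_indices(1000, 4, 1, seed=8)
        assert np.array_equal(a.indices, b.indices)
        assert not np.array_equal(a.indices, c.indices)

    def test_epoch_reshuffles(self):
        a = shard_indices(100, 2, 0, seed=3, epoch=0)
        b = shard_indices(100, 2, 0, seed=3, epoch=1)
        assert not np.array_equal(a.indices, b.indices)

    def test_invalid_worker_id(self):
        with pytest.raises(ValueError):
            shard_indices(10, 3, 3, seed=0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(n=st.integers(4, 200), workers=st.integers(1, 4),
           seed=st.integers(0, 10), drop=st.booleans())
    def test_disjointness_and_coverage(self, n, workers, seed, drop):
        if workers > n:
            return
        shards = [shard_indices(n, workers, w, seed, drop_remainder=drop)
                  for w in range(workers)]
        union = np.concatenate([s.indices for s in shards])
        assert len(union) == len(set(union.tolist()))  # pairwise disjoint
        if drop:
            assert all(len(s) == n // workers for s in shards)
        else:
            assert sorted(union.tolist()) == list(range(n))


class TestBackends:
    def test_counts_and_object_export(self, small_graphs, tmp_path):
        n = export_objects(small_graphs, str(tmp_path / "obj"))
        assert n == len(small_graphs)
        n2 = export_objects(small_graphs, str(tmp_path / "obj"))  # idempotent
        assert n2 == n

    def test_object_round_trip(self, small_graphs, tmp_path):
        export_objects(small_graphs, str(tmp_path / "obj"))
        batches = list(make_loader("object", str(tmp_path / "obj"),
                                   batch_size=1))
        assert len(batches) == len(small_graphs)
        for b, g in zip(batches, small_graphs):
            assert np.array_equal(b.x, g.x)
            assert np.array_equal(b.y[0], g.y)

    def test_batch_count_ceil_rule(self, corpus_dir, aisd_vocab):
        shard = shard_indices(10, 1, 0, seed=0, drop_remainder=False)
        batches = list(make_loader("pack", corpus_dir.pack, batch_size=3,
                                   shard=shard))
        assert [b.num_graphs for b in batches] == [3, 3, 3, 1]
        batches = list(make_loader("pack", corpus_dir.pack, batch_size=3,
                                   shard=shard, drop_remainder=True))
        assert [b.num_graphs for b in batches] == [3, 3, 3]

    def test_exact_batch_size_single_batch(self, corpus_dir):
        shard = shard_indices(128, 1, 0, seed=1)
        batches = list(make_loader("pack", corpus_dir.pack, batch_size=128,
                                   shard=shard))
        assert len(batches) == 1 and batches[0].num_graphs == 128

    @pytest.mark.parametrize("seed", [0, 1])
    @pytest.mark.parametrize("batch_size", [16, 37])
    def test_backend_equivalence(self, corpus_dir, aisd_vocab, seed,
                                 batch_size):
        """inline, object, and pack backends yield element-wise identical
        batch sequences for the same shard."""
        shard = shard_indices(corpus_dir.n, 2, 1, seed=seed)
        sources = {"inline": corpus_dir.csv, "object": corpus_dir.objects,
                   "pack": corpus_dir.pack}
        sequences = {
            backend: list(make_loader(backend, src, batch_size, shard=shard,
                                      vocab=aisd_vocab))
            for backend, src in sources.items()
        }
        ref = sequences["inline"]
        for backend in ("object", "pack"):
            got = sequences[backend]
            assert len(got) == len(ref)
            for a, b in zip(ref, got):
                np.testing.assert_array_equal(a.x, b.x)
                np.testing.assert_array_equal(a.edge_index, b.edge_index)
                np.testing.assert_array_equal(a.edge_attr, b.edge_attr)
                np.testing.assert_array_equal(a.y, b.y)
                np.testing.assert_array_equal(a.graph_id, b.graph_id)

    def test_epoch_determinism(self, corpus_dir):
        shard = shard_indices(corpus_dir.n, 2, 0, seed=5, epoch=3)
        a = list(make_loader("pack", corpus_dir.pack, 32, shard=shard))
        b = list(make_loader("pack", corpus_dir.pack, 32, shard=shard))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.x, y.x)

    def test_inline_parse_error_names_line(self, tmp_path, aisd_vocab):
        csv = tmp_path / "bad.csv"
        csv.write_text("smiles,gap\nCC,1.0\nC(,2.0\n")
        loader = make_loader("inline", str(csv), 2, vocab=aisd_vocab)
        with pytest.raises(ValueError, match="line 2"):
            list(loader)

    def test_unknown_backend(self):
        with pytest.raises(ValueError):
            list(make_loader("bogus", "x", 1))
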