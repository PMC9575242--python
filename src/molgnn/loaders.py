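"""Batch iteration over graph datasets: collation, sharding, and the three
interchangeable loading backends.

* ``inline`` — reads a ``smiles,gap`` CSV and converts SMILES to graphs at
  every batch yield (deliberately uncached: this is the baseline whose
  repeated featurization cost the other two backends amortize away).
* ``object`` — one serialized graph object per file, deserialized per index.
* ``pack``  — random-access reads from a packed global-array dataset.

All three backends yield identical batch contents for identical index
shards and batch sizes. Worker shards are disjoint round-robin splits of a
seeded epoch permutation, the standard distributed-sampler contract.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .chem import ElementVocabulary, MolecularGraph, smiles_to_graph
from .pack import GraphPackStore

__all__ = ["BatchGraph", "WorkerShard", "collate", "shard_indices",
           "make_loader", "export_objects", "load_object_dir_meta",
           "BACKENDS"]

BACKENDS = ("inline", "object", "pack")
OBJECT_META_NAME = "objects_meta.json"


@dataclass
class BatchGraph:
    """Disjoint union of several molecular graphs.

    Node blocks are concatenated in list order; ``edge_index`` has each
    graph's node offset applied; ``graph_id`` maps every node to its
    position in the batch.
    """

    x: np.ndarray           # (total nodes, F)
    edge_index: np.ndarray  # (2, total edges), offsets applied
    edge_attr: np.ndarray   # (total edges, E)
    y: np.ndarray           # (batch size, T)
    graph_id: np.ndarray    # (total nodes,)
    num_graphs: int

    @property
    def num_nodes(self) -> int:
        return self.x.shape[0]

    @property
    def num_edges(self) -> int:
        return self.edge_index.shape[1]


@dataclass(frozen=True)
class WorkerShard:
    """One worker's ordered slice of an epoch permutation."""

    worker_id: int
    n_workers: int
    seed: int
    epoch: int
    indices: np.ndarray

    def __len__(self) -> int:
        return len(self.indices)


def collate(graphs) -> BatchGraph:
    """Batch graphs into one disjoint union with offset edge indices."""
    graphs = list(graphs)
    if not graphs:
        raise ValueError("cannot collate an empty graph list")
    node_dim = graphs[0].x.shape[1]
    edge_dim = graphs[0].edge_attr.shape[1]
    target_dim = graphs[0].y.shape[0]
    xs, eis, eas, ys, gids = [], [], [], [], []
    offset = 0
    for g, graph in enumerate(graphs):
        if (graph.x.shape[1] != node_dim
                or graph.edge_attr.shape[1] != edge_dim
                or graph.y.shape[0] != target_dim):
            raise ValueError(f"graph {g} has mismatched feature dims")
        xs.append(graph.x)
        eis.append(graph.edge_index + offset)
        eas.append(graph.edge_attr)
        ys.append(graph.y)
        gids.append(np.full(graph.num_nodes, g, dtype=np.int64))
        offset += graph.num_nodes
    return BatchGraph(
        x=np.concatenate(xs, axis=0),
        edge_index=np.concatenate(eis, axis=1),
        edge_attr=np.concatenate(eas, axis=0),
        y=np.stack(ys),
        graph_id=np.concatenate(gids),
        num_graphs=len(graphs),
    )


def epoch_seed(base_seed: int, epoch: int) -> int:
    """Deterministic per-epoch permutation seed derived from the base seed."""
    ss = np.random.SeedSequence([int(base_seed), int(epoch)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def shard_indices(n_items: int, n_workers: int, worker_id: int, seed: int,
                  drop_remainder: bool = True, epoch: int = 0) -> WorkerShard:
    """Disjoint per-worker index shard for one epoch.

    A permutation of ``[0, n_items)`` seeded by (seed, epoch) is dealt
    round-robin: index position ``j`` goes to worker ``j mod n_workers``.
    With ``drop_remainder`` every shard is truncated to
    ``floor(n_items / n_workers)`` so all workers see equally many items.
    """
    if not 0 <= worker_id < n_workers:
        raise ValueError(f"worker_id {worker_id} not in [0, {n_workers})")
    if n_workers > n_items:
        raise ValueError(f"n_workers {n_workers} exceeds n_items {n_items}")
    perm = np.random.default_rng(epoch_seed(seed, epoch)).permutation(n_items)
    mine = perm[worker_id::n_workers]
    if drop_remainder:
        mine = mine[: n_items // n_workers]
    return WorkerShard(worker_id=worker_id, n_workers=n_workers, seed=seed,
                       epoch=epoch, indices=mine)


# ---------------------------------------------------------------------------
# Object backend serialization
# ---------------------------------------------------------------------------

def export_objects(graphs, directory: str, vocabulary=()) -> int:
    """Serialize one graph object per file; returns the number written."""
    graphs = list(graphs)
    os.makedirs(directory, exist_ok=True)
    for i, g in enumerate(graphs):
        np.savez(os.path.join(directory, f"graph_{i:08d}.npz"),
                 x=g.x.astype(np.float32),
                 edge_index=g.edge_index.astype(np.int64),
                 edge_attr=g.edge_attr.astype(np.float32),
                 y=g.y.astype(np.float32))
    meta = {"num_graphs": len(graphs), "vocabulary": list(vocabulary)}
    with open(os.path.join(directory, OBJECT_META_NAME), "w") as f:
        json.dump(meta, f)
    return len(graphs)


def load_object_dir_meta(directory: str) -> dict:
    with open(os.path.join(directory, OBJECT_META_NAME)) as f:
        return json.load(f)


def _load_object(directory: str, i: int) -> MolecularGraph:
    path = os.path.join(directory, f"graph_{i:08d}.npz")
    with np.load(path) as npz:
        return MolecularGraph(x=npz["x"], edge_index=npz["edge_index"],
                              edge_attr=npz["edge_attr"], y=npz["y"])


# ---------------------------------------------------------------------------
# Unified loader
# ---------------------------------------------------------------------------

def _read_csv_rows(path: str) -> tuple[list[str], np.ndarray]:
    import pandas as pd

    frame = pd.read_csv(path)
    if list(frame.columns[:2]) != ["smiles", "gap"]:
        raise ValueError(
            f"{path}: expected header 'smiles,gap', got {list(frame.columns)}")
    return list(frame["smiles"]), frame["gap"].to_numpy(dtype=np.float64)


def _batched(indices: np.ndarray, batch_size: int, drop_remainder: bool):
    n_full = len(indices) // batch_size
    for b in range(n_full):
        yield indices[b * batch_size : (b + 1) * batch_size]
    if not drop_remainder and len(indices) % batch_size:
        yield indices[n_full * batch_size :]


def make_loader(backend: str, source, batch_size: int,
                shard: WorkerShard | None = None,
                vocab: ElementVocabulary | None = None,
                drop_remainder: bool = False):
    """Iterate ``BatchGraph`` objects over a data source.

    ``source`` is a CSV path (inline), an object directory (object), or a
    pack path / open :class:`GraphPackStore` (pack). Batches follow the
    shard's index order; when no shard is given the whole dataset is
    iterated in natural order.
    """
    if backend not in BACKENDS:
        raise ValueError(f"unknown backend {backend!r}; expected {BACKENDS}")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")

    if backend == "inline":
        if vocab is None:
            raise ValueError("inline backend requires an element vocabulary")
        smiles, gaps = _read_csv_rows(source)
        n = len(smiles)

        def fetch(idx_batch):
            graphs = []
            for i in idx_batch:
                try:
                    g = smiles_to_graph(smiles[i], vocab)
                except Exception as exc:
                    raise ValueError(
                        f"{source}: SMILES parse failure at data line "
                        f"{i + 1}: {exc}") from exc
                g.y = np.array([gaps[i]], dtype=np.float32)
                graphs.append(g)
            return graphs

    elif backend == "object":
        meta = load_object_dir_meta(source)
        n = meta["num_graphs"]

        def fetch(idx_batch):
            return [_load_object(source, int(i)) for i in idx_batch]

    else:  # pack
        store = source if isinstance(source, GraphPackStore) else GraphPackStore(source)
        n = store.num_graphs

        def fetch(idx_batch):
            return store.read_slice(idx_batch)

    indices = shard.indices if shard is not None else np.arange(n)
    if len(indices) and indices.max() >= n:
        raise IndexError(f"shard index {int(indices.max())} out of range for "
                         f"{n}-graph source")
    for idx_batch in _batched(np.asarray(indices), batch_size, drop_remainder):
        yield collate(fetch(idx_batch))
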