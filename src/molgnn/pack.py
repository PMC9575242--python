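"""Packed on-disk graph datasets: concatenated global arrays with per-graph counts.

An entire dataset is stored as six named arrays — ``x`` (all node features
concatenated), ``edge_index`` (2 x all directed edges), ``edge_attr``,
``y`` (one row per graph), ``num_nodes`` and ``num_edges`` — sharded over
``num_writers`` HDF5 subfiles plus a JSON manifest. Graph order is preserved
across shards; edge indices are stored local to each graph, so a single
graph can be reconstructed from one shard without touching any other.
Floats are stored as little-endian float32, integers as int64.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import h5py
import numpy as np

from .chem import MolecularGraph

__all__ = ["SCHEMA_VERSION", "PackFormatError", "PackManifest",
           "GraphPackStore", "write_pack", "read_header", "read_graph",
           "read_slice", "shard_ranges"]

SCHEMA_VERSION = 1
MANIFEST_NAME = "manifest.json"
ARRAY_NAMES = ("x", "edge_index", "edge_attr", "y", "num_nodes", "num_edges")

logger = logging.getLogger(__name__)


class PackFormatError(RuntimeError):
    """Raised when a pack's metadata or payload is missing or inconsistent."""


@dataclass
class ShardInfo:
    file: str
    start: int   # first graph index (inclusive)
    stop: int    # last graph index (exclusive)
    nodes: int
    edges: int


@dataclass
class PackManifest:
    schema_version: int
    num_graphs: int
    node_dim: int
    edge_dim: int
    target_dim: int
    vocabulary: list[str]
    shards: list[ShardInfo]
    extra: dict

    def to_json(self) -> str:
        doc = {
            "schema_version": self.schema_version,
            "num_graphs": self.num_graphs,
            "node_dim": self.node_dim,
            "edge_dim": self.edge_dim,
            "target_dim": self.target_dim,
            "vocabulary": self.vocabulary,
            "num_shards": len(self.shards),
            "shards": [vars(s) for s in self.shards],
            "extra": self.extra,
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PackManifest":
        try:
            doc = json.loads(text)
            manifest = cls(
                schema_version=doc["schema_version"],
                num_graphs=doc["num_graphs"],
                node_dim=doc["node_dim"],
                edge_dim=doc["edge_dim"],
                target_dim=doc["target_dim"],
                vocabulary=list(doc["vocabulary"]),
                shards=[ShardInfo(**s) for s in doc["shards"]],
                extra=doc.get("extra", {}),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise PackFormatError(
                f"corrupt or incompatible pack manifest "
                f"(expected schema version {SCHEMA_VERSION}): {exc}"
            ) from exc
        if manifest.schema_version != SCHEMA_VERSION:
            raise PackFormatError(
                f"pack schema version {manifest.schema_version} "
                f"not supported (expected {SCHEMA_VERSION})"
            )
        starts = [s.start for s in manifest.shards]
        stops = [s.stop for s in manifest.shards]
        if starts != sorted(starts) or (
            manifest.shards
            and (starts[0] != 0 or stops[-1] != manifest.num_graphs
                 or any(a.stop != b.start for a, b in
                        zip(manifest.shards[:-1], manifest.shards[1:])))
        ):
            raise PackFormatError("shard ranges are not contiguous and covering")
        return manifest


def shard_ranges(n_graphs: int, num_writers: int) -> list[tuple[int, int]]:
    """Contiguous shard ranges with sizes differing by at most one.

    The first ``n_graphs % num_writers`` shards receive the extra graph.
    ``num_writers`` greater than ``n_graphs`` is clamped.
    """
    if num_writers < 1:
        raise ValueError("num_writers must be >= 1")
    if num_writers > n_graphs:
        logger.warning("num_writers=%d exceeds %d graphs; clamping",
                       num_writers, n_graphs)
        num_writers = n_graphs
    base, extra = divmod(n_graphs, num_writers)
    ranges, start = [], 0
    for w in range(num_writers):
        size = base + (1 if w < extra else 0)
        ranges.append((start, start + size))
        start += size
    return ranges


def _check_dims(graphs) -> tuple[int, int, int]:
    node_dim = graphs[0].x.shape[1]
    edge_dim = graphs[0].edge_attr.shape[1]
    target_dim = graphs[0].y.shape[0]
    for i, g in enumerate(graphs):
        if (g.x.shape[1] != node_dim or g.edge_attr.shape[1] != edge_dim
                or g.y.shape[0] != target_dim):
            raise PackFormatError(
                f"graph {i} has inconsistent feature dims "
                f"({g.x.shape[1]}, {g.edge_attr.shape[1]}, {g.y.shape[0]}) "
                f"vs ({node_dim}, {edge_dim}, {target_dim})"
            )
    return node_dim, edge_dim, target_dim


def _write_shard(path: str, graphs) -> tuple[int, int]:
    x = np.concatenate([g.x for g in graphs], axis=0).astype("<f4")
    edge_index = np.concatenate([g.edge_index for g in graphs], axis=1).astype("<i8")
    edge_attr = np.concatenate([g.edge_attr for g in graphs], axis=0).astype("<f4")
    y = np.stack([g.y for g in graphs]).astype("<f4")
    num_nodes = np.array([g.num_nodes for g in graphs], dtype="<i8")
    num_edges = np.array([g.num_edges for g in graphs], dtype="<i8")
    with h5py.File(path, "w") as f:
        f.create_dataset("x", data=x)
        f.create_dataset("edge_index", data=edge_index)
        f.create_dataset("edge_attr", data=edge_attr)
        f.create_dataset("y", data=y)
        f.create_dataset("num_nodes", data=num_nodes)
        f.create_dataset("num_edges", data=num_edges)
    return int(num_nodes.sum()), int(num_edges.sum())


def write_pack(graphs, path: str, num_writers: int = 1,
               vocabulary=(), extra: dict | None = None) -> PackManifest:
    """Write a sequence of graphs as a sharded pack under directory ``path``.

    Graphs are partitioned into ``num_writers`` contiguous shards written
    independently; concatenation order preserves input order and each
    graph's edge indices remain local (un-offset).
    """
    graphs = list(graphs)
    if not graphs:
        raise ValueError("cannot write an empty pack")
    node_dim, edge_dim, target_dim = _check_dims(graphs)
    os.makedirs(path, exist_ok=True)
    shards = []
    for w, (start, stop) in enumerate(shard_ranges(len(graphs), num_writers)):
        fname = f"shard_{w:04d}.h5"
        nodes, edges = _write_shard(os.path.join(path, fname), graphs[start:stop])
        shards.append(ShardInfo(fname, start, stop, nodes, edges))
    manifest = PackManifest(
        schema_version=SCHEMA_VERSION,
        num_graphs=len(graphs),
        node_dim=node_dim,
        edge_dim=edge_dim,
        target_dim=target_dim,
        vocabulary=list(vocabulary),
        shards=shards,
        extra=extra or {},
    )
    with open(os.path.join(path, MANIFEST_NAME), "w") as f:
        f.write(manifest.to_json())
    return manifest


def read_header(path: str) -> PackManifest:
    """Read pack metadata and global counts without loading array payloads."""
    manifest_path = os.path.join(path, MANIFEST_NAME)
    if not os.path.exists(manifest_path):
        raise PackFormatError(
            f"no pack manifest at {manifest_path} "
            f"(expected schema version {SCHEMA_VERSION})"
        )
    with open(manifest_path) as f:
        return PackManifest.from_json(f.read())


class GraphPackStore:
    """Random-access reader over a sharded pack.

    Shard payloads are opened lazily; per-shard count arrays and their
    prefix sums are cached so that reading graph ``i`` touches only the
    shard containing it.
    """

    def __init__(self, path: str):
        self.path = path
        self.manifest = read_header(path)
        self._shard_cache: dict[int, dict] = {}

    @property
    def num_graphs(self) -> int:
        return self.manifest.num_graphs

    def _shard_of(self, i: int) -> int:
        for w, s in enumerate(self.manifest.shards):
            if s.start <= i < s.stop:
                return w
        raise IndexError(f"graph index {i} out of range [0, {self.num_graphs})")

    def _load_shard(self, w: int) -> dict:
        if w not in self._shard_cache:
            info = self.manifest.shards[w]
            fpath = os.path.join(self.path, info.file)
            try:
                with h5py.File(fpath, "r") as f:
                    data = {name: f[name][...] for name in ARRAY_NAMES}
            except (OSError, KeyError) as exc:
                raise PackFormatError(
                    f"shard {info.file} unreadable or missing datasets "
                    f"(schema version {SCHEMA_VERSION}): {exc}"
                ) from exc
            if (int(data["num_nodes"].sum()) != data["x"].shape[0]
                    or int(data["num_edges"].sum()) != data["edge_index"].shape[1]
                    or data["edge_attr"].shape[0] != data["edge_index"].shape[1]):
                raise PackFormatError(
                    f"shard {info.file}: counts inconsistent with array extents")
            data["node_offsets"] = np.concatenate(
                [[0], np.cumsum(data["num_nodes"])])
            data["edge_offsets"] = np.concatenate(
                [[0], np.cumsum(data["num_edges"])])
            self._shard_cache[w] = data
        return self._shard_cache[w]

    def read_graph(self, i: int) -> MolecularGraph:
        """Reconstruct graph ``i`` exactly from its shard's arrays."""
        if not 0 <= i < self.num_graphs:
            raise IndexError(
                f"graph index {i} out of range [0, {self.num_graphs})")
        w = self._shard_of(i)
        data = self._load_shard(w)
        k = i - self.manifest.shards[w].start
        n0, n1 = data["node_offsets"][k], data["node_offsets"][k + 1]
        e0, e1 = data["edge_offsets"][k], data["edge_offsets"][k + 1]
        return MolecularGraph(
            x=np.array(data["x"][n0:n1], dtype=np.float32),
            edge_index=np.array(data["edge_index"][:, e0:e1], dtype=np.int64),
            edge_attr=np.array(data["edge_attr"][e0:e1], dtype=np.float32),
            y=np.array(data["y"][k], dtype=np.float32),
        )

    def read_slice(self, indices) -> list[MolecularGraph]:
        """Read several graphs; output order matches ``indices``."""
        indices = [int(i) for i in indices]
        for i in indices:  # validate everything before any I/O
            if not 0 <= i < self.num_graphs:
                raise IndexError(
                    f"graph index {i} out of range [0, {self.num_graphs})")
        return [self.read_graph(i) for i in indices]


def read_graph(store: GraphPackStore, i: int) -> MolecularGraph:
    return store.read_graph(i)


def read_slice(store: GraphPackStore, indices) -> list[MolecularGraph]:
    return store.read_slice(indices)
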