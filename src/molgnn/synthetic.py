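"""Synthetic molecule corpora with a known HOMO-LUMO-gap surrogate.

Random valence-respecting molecules (a spanning tree over heavy atoms plus
an optional single ring closure) are emitted as SMILES strings, and a
graph-level target is computed from a fixed additive formula:

    y = 10.0 - sum_e w_e * count_e - 0.8 * rings - 0.3 * double_bonds + eps

with published per-element weights and Gaussian noise eps ~ N(0, sigma^2).
The formula gives a known ground truth for learnability and end-to-end
weight-recovery tests; it stands in for externally computed quantum-
chemistry labels, not for their physics.

Note: triple bonds are generated with small probability on purpose —
without them the hydrogen count is an exact linear function of the other
count features (valence bookkeeping), and the generator weights would not
be identifiable by a linear readout.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from .chem import (AISD_ELEMENTS, PCQM_ELEMENTS, VALENCES, Molecule,
                   add_hydrogens, build_vocabulary, parse_smiles,
                   smiles_to_graph)
from .loaders import BACKENDS, export_objects, make_loader
from .pack import write_pack

__all__ = ["GAP_WEIGHTS", "SyntheticSpec", "CorpusPaths", "generate_molecules",
           "base_gap", "synthetic_gap", "make_corpus", "bench_io",
           "linear_readout_features", "fit_linear_readout"]

#: Fixed per-element weights of the surrogate gap formula. Elements outside
#: the 6-element set contribute 0.1 each.
GAP_WEIGHTS = {**{e: 0.1 for e in PCQM_ELEMENTS},
               "H": 0.05, "C": 0.10, "N": 0.15, "O": 0.20, "S": 0.25,
               "F": 0.12}
RING_WEIGHT = 0.8
DOUBLE_BOND_WEIGHT = 0.3
GAP_OFFSET = 10.0

# heavy-atom sampling weights: roughly organic-like, carbon dominated
_AISD_HEAVY = {"C": 0.55, "N": 0.12, "O": 0.15, "S": 0.06, "F": 0.12}
_PCQM_HEAVY = {"C": 0.40, "N": 0.10, "O": 0.12, "S": 0.05, "F": 0.08,
               "B": 0.04, "P": 0.05, "Cl": 0.06, "Br": 0.05, "I": 0.05}
_BOND_ORDER_PROBS = {1: 0.80, 2: 0.15, 3: 0.05}
_ORDER_SYMBOL = {1: "", 2: "=", 3: "#"}


@dataclass
class SyntheticSpec:
    """Generation parameters for one synthetic corpus."""

    n: int = 1000
    elements: str = "aisd"            # "aisd" (6 elements) or "pcqm" (31)
    heavy_atoms: tuple[int, int] = (4, 40)
    ring_probability: float = 0.3
    sigma: float = 0.05               # label noise sd, in gap units (eV)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.heavy_atoms
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid heavy-atom range {self.heavy_atoms}")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.elements not in ("aisd", "pcqm"):
            raise ValueError("elements must be 'aisd' or 'pcqm'")

    @property
    def vocabulary_symbols(self) -> tuple[str, ...]:
        return AISD_ELEMENTS if self.elements == "aisd" else PCQM_ELEMENTS

    @property
    def heavy_weights(self) -> dict[str, float]:
        return _AISD_HEAVY if self.elements == "aisd" else _PCQM_HEAVY


def _substream(seed: int, name: str) -> np.random.Generator:
    tag = int.from_bytes(name.encode(), "little") % (2 ** 31)
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def _sample_order(rng: np.random.Generator, max_order: int) -> int:
    orders = [o for o in (1, 2, 3) if o <= max_order]
    probs = np.array([_BOND_ORDER_PROBS[o] for o in orders])
    return int(rng.choice(orders, p=probs / probs.sum()))


def _random_molecule(rng: np.random.Generator, n_heavy: int,
                     weights: dict[str, float], ring_p: float
                     ) -> tuple[list[str], list[tuple[int, int, int]]]:
    """Random tree over heavy atoms plus at most one ring-closing bond.

    Returns element symbols and bonds (a, b, order); bond orders respect the
    remaining valence on both endpoints at every step.
    """
    symbols = list(weights)
    probs = np.array([weights[s] for s in symbols], dtype=np.float64)
    probs /= probs.sum()

    elems = [str(rng.choice(symbols, p=probs))]
    remaining = [VALENCES[elems[0]]]
    bonds: list[tuple[int, int, int]] = []
    adjacent: set[tuple[int, int]] = set()
    for _ in range(1, n_heavy):
        open_atoms = [i for i, r in enumerate(remaining) if r >= 1]
        parent = int(rng.choice(open_atoms))
        child_sym = str(rng.choice(symbols, p=probs))
        atoms_left = n_heavy - len(elems) - 1
        total_rem = sum(remaining)
        if atoms_left > 0 and total_rem + VALENCES[child_sym] - 2 < 1:
            child_sym = "C"  # keep the tree extendable
        cap = min(remaining[parent], VALENCES[child_sym])
        if atoms_left > 0:
            # a bond of order o consumes 2o valence but adds val(child):
            # keep at least one open slot for the atoms still to come
            cap = min(cap, (total_rem + VALENCES[child_sym] - 1) // 2)
        order = _sample_order(rng, cap)
        child = len(elems)
        elems.append(child_sym)
        remaining.append(VALENCES[child_sym] - order)
        remaining[parent] -= order
        bonds.append((parent, child, order))
        adjacent.add((parent, child))
    if n_heavy >= 3 and rng.random() < ring_p:
        open_atoms = [i for i, r in enumerate(remaining) if r >= 1]
        pairs = [(a, b) for ai, a in enumerate(open_atoms)
                 for b in open_atoms[ai + 1:]
                 if (min(a, b), max(a, b)) not in adjacent]
        if pairs:
            a, b = pairs[int(rng.integers(len(pairs)))]
            bonds.append((a, b, 1))
    return elems, bonds


def _to_smiles(elems: list[str], bonds: list[tuple[int, int, int]]) -> str:
    """Serialize an atom/bond list as SMILES via DFS from atom 0."""
    adj: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(elems))}
    order_of = {}
    for a, b, o in bonds:
        adj[a].append((b, o))
        adj[b].append((a, o))
        order_of[(min(a, b), max(a, b))] = o

    visited = set()
    parent_of: dict[int, int | None] = {0: None}
    tree_children: dict[int, list[int]] = {i: [] for i in range(len(elems))}
    back_edges: list[tuple[int, int]] = []
    stack = [0]
    visited.add(0)
    while stack:
        u = stack.pop()
        for v, _ in adj[u]:
            if v not in visited:
                visited.add(v)
                parent_of[v] = u
                tree_children[u].append(v)
                stack.append(v)
            elif v != parent_of.get(u) and u < v:
                back_edges.append((u, v))

    ring_digit: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(elems))}
    for digit, (u, v) in enumerate(back_edges, start=1):
        if digit > 9:
            raise ValueError("more than 9 ring closures not supported")
        o = order_of[(min(u, v), max(u, v))]
        ring_digit[u].append((digit, o))
        ring_digit[v].append((digit, o))

    def emit(u: int, bond_sym: str) -> str:
        parts = [bond_sym, elems[u]]
        for digit, o in ring_digit[u]:
            parts.append(_ORDER_SYMBOL[o] + str(digit))
        children = tree_children[u]
        for child in children[:-1]:
            o = order_of[(min(u, child), max(u, child))]
            parts.append("(" + emit(child, _ORDER_SYMBOL[o]) + ")")
        if children:
            child = children[-1]
            o = order_of[(min(u, child), max(u, child))]
            parts.append(emit(child, _ORDER_SYMBOL[o]))
        return "".join(parts)

    return emit(0, "")


def generate_molecules(spec: SyntheticSpec) -> list[str]:
    """Generate ``spec.n`` parseable SMILES strings, deterministic in the seed."""
    if not spec.heavy_weights:
        raise ValueError("element set is empty")
    structure_rng = _substream(spec.seed, "structure")
    lo, hi = spec.heavy_atoms
    out = []
    for _ in range(spec.n):
        n_heavy = int(structure_rng.integers(lo, hi + 1))
        elems, bonds = _random_molecule(structure_rng, n_heavy,
                                        spec.heavy_weights,
                                        spec.ring_probability)
        out.append(_to_smiles(elems, bonds))
    return out


def base_gap(mol: Molecule) -> float:
    """Noise-free surrogate gap of a molecule with explicit hydrogens."""
    total = GAP_OFFSET
    for atom in mol.atoms:
        try:
            total -= GAP_WEIGHTS[atom.symbol]
        except KeyError:
            raise ValueError(
                f"no gap weight for element {atom.symbol!r}") from None
    n_rings = len(mol.bonds) - (len(mol.atoms) - 1)
    n_double = sum(1 for b in mol.bonds if b.order == "double")
    return total - RING_WEIGHT * n_rings - DOUBLE_BOND_WEIGHT * n_double


def synthetic_gap(mol: Molecule, sigma: float,
                  rng: np.random.Generator) -> float:
    """Surrogate gap with Gaussian label noise drawn from ``rng``."""
    eps = float(rng.normal(0.0, sigma)) if sigma > 0 else 0.0
    return base_gap(mol) + eps


@dataclass
class CorpusPaths:
    """Locations of one corpus materialized in all three backend formats."""

    csv: str
    pack: str
    objects: str
    manifest: str
    vocabulary: tuple[str, ...]
    n: int


def make_corpus(spec: SyntheticSpec, out_dir: str,
                num_writers: int = 1) -> CorpusPaths:
    """Materialize one synthetic corpus as CSV, pack, and object directory.

    Targets written to the CSV are rounded to 6 decimals, and the pack and
    object stores are built from the re-parsed CSV values, so all three
    backends carry bit-identical float32 targets.
    """
    os.makedirs(out_dir, exist_ok=True)
    smiles = generate_molecules(spec)
    noise_rng = _substream(spec.seed, "noise")
    vocab = build_vocabulary(spec.vocabulary_symbols)

    csv_path = os.path.join(out_dir, "corpus.csv")
    targets = []
    with open(csv_path, "w") as f:
        f.write("smiles,gap\n")
        for s in smiles:
            mol = add_hydrogens(parse_smiles(s))
            gap = synthetic_gap(mol, spec.sigma, noise_rng)
            text = f"{gap:.6f}"
            targets.append(float(text))
            f.write(f"{s},{text}\n")

    graphs = []
    for s, y in zip(smiles, targets):
        g = smiles_to_graph(s, vocab)
        g.y = np.array([y], dtype=np.float32)
        graphs.append(g)

    pack_path = os.path.join(out_dir, "corpus.pack")
    write_pack(graphs, pack_path, num_writers=num_writers,
               vocabulary=vocab.symbols, extra={"spec": asdict(spec)})
    obj_dir = os.path.join(out_dir, "objects")
    export_objects(graphs, obj_dir, vocabulary=vocab.symbols)

    manifest_path = os.path.join(out_dir, "corpus_manifest.json")
    with open(manifest_path, "w") as f:
        json.dump({"spec": asdict(spec), "n": spec.n,
                   "vocabulary": list(vocab.symbols),
                   "files": {"csv": "corpus.csv", "pack": "corpus.pack",
                             "objects": "objects"}}, f, indent=2)
    return CorpusPaths(csv=csv_path, pack=pack_path, objects=obj_dir,
                       manifest=manifest_path, vocabulary=vocab.symbols,
                       n=spec.n)


def _backend_source(paths: CorpusPaths, backend: str):
    return {"inline": paths.csv, "object": paths.objects,
            "pack": paths.pack}[backend]


def _batch_equal(a, b) -> bool:
    return (np.array_equal(a.x, b.x)
            and np.array_equal(a.edge_index, b.edge_index)
            and np.array_equal(a.edge_attr, b.edge_attr)
            and np.array_equal(a.y, b.y)
            and np.array_equal(a.graph_id, b.graph_id))


def bench_io(paths: CorpusPaths, backends=BACKENDS, batch_size: int = 128,
             epochs: int = 1) -> list[dict]:
    """Wall-clock data-loading times per backend per epoch.

    Batch-content equality across the requested backends is verified before
    any timing; the report is descriptive (no pass/fail on absolute times).
    """
    vocab = build_vocabulary(paths.vocabulary)
    for backend in backends:
        if backend not in BACKENDS:
            raise ValueError(f"unknown backend {backend!r}")
        src = _backend_source(paths, backend)
        if not os.path.exists(src):
            raise FileNotFoundError(f"{backend} source missing: {src}")

    reference = None
    for backend in backends:
        batches = list(make_loader(backend, _backend_source(paths, backend),
                                   batch_size, vocab=vocab))
        if reference is None:
            reference = batches
        else:
            if len(batches) != len(reference) or not all(
                    _batch_equal(a, b) for a, b in zip(reference, batches)):
                raise AssertionError(
                    f"backend {backend!r} produced different batches")

    report = []
    for backend in backends:
        for epoch in range(epochs):
            t0 = time.perf_counter()
            n_batches = 0
            for _ in make_loader(backend, _backend_source(paths, backend),
                                 batch_size, vocab=vocab):
                n_batches += 1
            report.append({"backend": backend, "epoch": epoch,
                           "seconds": time.perf_counter() - t0,
                           "batches": n_batches})
    return report


# ---------------------------------------------------------------------------
# Linear-readout debug mode: end-to-end weight recovery
# ---------------------------------------------------------------------------

def linear_readout_features(graphs, n_elements: int) -> np.ndarray:
    """Per-graph count features: element counts, ring count, double bonds.

    Derived from the numeric graphs (one-hot block sums, edge bookkeeping),
    exercising the same data path the model consumes.
    """
    rows = []
    for g in graphs:
        counts = g.x[:, :n_elements].sum(axis=0)
        n_bonds = g.num_edges / 2
        n_rings = n_bonds - (g.num_nodes - 1)
        n_double = g.edge_attr[:, 1].sum() / 2
        rows.append(np.concatenate([counts, [n_rings, n_double]]))
    return np.asarray(rows, dtype=np.float64)


def fit_linear_readout(graphs, targets, vocabulary_symbols) -> dict[str, float]:
    """Least-squares fit of the surrogate-gap formula from graph features.

    Returns the fitted per-element weights plus ring and double-bond
    coefficients and the intercept, keyed by symbol/name. With noise-free
    targets the fit is exact up to conditioning.
    """
    symbols = list(vocabulary_symbols)
    X = linear_readout_features(graphs, len(symbols))
    X = np.hstack([X, np.ones((X.shape[0], 1))])
    y = np.asarray(targets, dtype=np.float64)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    out = {s: -coef[i] for i, s in enumerate(symbols)}
    out["ring"] = -coef[len(symbols)]
    out["double_bond"] = -coef[len(symbols) + 1]
    out["intercept"] = coef[-1]
    return out
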