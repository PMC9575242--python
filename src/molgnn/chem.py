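"""SMILES parsing and molecular-graph featurization.

Molecules are read from a restricted but practical SMILES subset (organic
elements, branches, ring closures, explicit bond orders, aromatic lowercase
atoms, charge-free bracket atoms). Implicit hydrogens are materialized as
first-class graph nodes, and graphs are encoded numerically as a node-feature
matrix (element one-hot plus degree), a symmetric directed edge list, and a
bond-order one-hot edge-attribute matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "Bond",
    "Molecule",
    "ElementVocabulary",
    "MolecularGraph",
    "SmilesParseError",
    "FeaturizationError",
    "BOND_ORDERS",
    "AISD_ELEMENTS",
    "PCQM_ELEMENTS",
    "VALENCES",
    "parse_smiles",
    "add_hydrogens",
    "build_vocabulary",
    "featurize",
]

# Bond-order categories, in the fixed order used for edge one-hots.
BOND_ORDERS = ("single", "double", "triple", "aromatic")
_BOND_VALENCE = {"single": 1.0, "double": 2.0, "triple": 3.0, "aromatic": 1.5}

#: Element list of the PCQM4Mv2 corpus (31 symbols).
PCQM_ELEMENTS = (
    "H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Ca", "Ge", "As",
    "Se", "Br", "I", "Mg", "Ti", "Ga", "Zn", "Ar", "Be", "He", "Al", "Kr",
    "V", "Na", "Li", "Cu", "Ne", "Ni",
)

#: Element list of the AISD HOMO-LUMO corpus (6 symbols).
AISD_ELEMENTS = ("H", "C", "N", "O", "S", "F")

#: Standard organic valences used to infer implicit hydrogen counts.
VALENCES = {
    "H": 1, "B": 3, "C": 4, "N": 3, "O": 2, "F": 1,
    "P": 3, "S": 2, "Cl": 1, "Br": 1, "I": 1,
}

_AROMATIC_LOWER = {"b": "B", "c": "C", "n": "N", "o": "O", "s": "S", "p": "P"}
_REJECTED = set("/\\@+-") - {"-"}  # '-' is a valid bond symbol outside brackets


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed under the supported subset."""


class FeaturizationError(ValueError):
    """Raised when a molecule cannot be converted to numeric features."""


@dataclass(frozen=True)
class Atom:
    symbol: str
    aromatic: bool = False
    explicit_h: int | None = None  # H count from a bracket atom, e.g. [NH2]


@dataclass(frozen=True)
class Bond:
    a: int
    b: int
    order: str  # one of BOND_ORDERS


@dataclass
class Molecule:
    """Parsed chemical structure: ordered atoms plus an undirected bond list."""

    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)

    @property
    def num_atoms(self) -> int:
        return len(self.atoms)

    def validate(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for bond in self.bonds:
            if not (0 <= bond.a < n and 0 <= bond.b < n):
                raise ValueError(f"bond ({bond.a},{bond.b}) out of range for {n} atoms")
            if bond.a == bond.b:
                raise ValueError(f"self-bond on atom {bond.a}")
            key = (min(bond.a, bond.b), max(bond.a, bond.b))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
            if bond.order == "aromatic":
                if not (self.atoms[bond.a].aromatic and self.atoms[bond.b].aromatic):
                    raise ValueError(
                        f"aromatic bond {key} joins non-aromatic atom(s)"
                    )


@dataclass(frozen=True)
class ElementVocabulary:
    """Ordered, de-duplicated element list with O(1) symbol lookup."""

    symbols: tuple[str, ...]
    _index: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self):
        object.__setattr__(
            self, "_index", {s: i for i, s in enumerate(self.symbols)}
        )

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    def index(self, symbol: str) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise FeaturizationError(
                f"element {symbol!r} not in vocabulary {list(self.symbols)}"
            ) from None


@dataclass
class MolecularGraph:
    """Numeric molecular graph.

    x          : (num_nodes, F) float32 node features
    edge_index : (2, num_edges) int64 directed edges, symmetric
    edge_attr  : (num_edges, E) float32 edge features
    y          : (T,) float32 graph-level target (empty until attached)
    """

    x: np.ndarray
    edge_index: np.ndarray
    edge_attr: np.ndarray
    y: np.ndarray

    @property
    def num_nodes(self) -> int:
        return self.x.shape[0]

    @property
    def num_edges(self) -> int:
        return self.edge_index.shape[1]

    def validate(self) -> None:
        if self.edge_index.shape[0] != 2:
            raise ValueError("edge_index must have leading dimension 2")
        if self.edge_attr.shape[0] != self.num_edges:
            raise ValueError("edge_attr rows must equal number of directed edges")
        if self.num_edges and (
            self.edge_index.min() < 0 or self.edge_index.max() >= self.num_nodes
        ):
            raise ValueError("edge_index entries out of node range")

    def equals(self, other: "MolecularGraph") -> bool:
        return (
            np.array_equal(self.x, other.x)
            and np.array_equal(self.edge_index, other.edge_index)
            and np.array_equal(self.edge_attr, other.edge_attr)
            and np.array_equal(self.y, other.y)
        )


# ---------------------------------------------------------------------------
# SMILES parsing
# ---------------------------------------------------------------------------

def _err(text: str, pos: int, msg: str) -> SmilesParseError:
    return SmilesParseError(f"{msg} at position {pos} in {text!r}")


def _read_atom(text: str, i: int) -> tuple[Atom, int]:
    """Read one atom token starting at text[i]; returns (atom, next index)."""
    ch = text[i]
    if ch == "[":
        j = text.find("]", i)
        if j < 0:
            raise _err(text, i, "unclosed bracket atom")
        body = text[i + 1 : j]
        atom = _parse_bracket_body(text, i + 1, body)
        return atom, j + 1
    if ch.isupper():
        if i + 1 < len(text) and text[i : i + 2] in ("Cl", "Br"):
            return Atom(text[i : i + 2]), i + 2
        if ch in VALENCES or ch in PCQM_ELEMENTS:
            return Atom(ch), i + 1
        raise _err(text, i, f"unsupported element {ch!r}")
    if ch in _AROMATIC_LOWER:
        return Atom(_AROMATIC_LOWER[ch], aromatic=True), i + 1
    raise _err(text, i, f"unsupported token {ch!r}")


def _parse_bracket_body(text: str, pos: int, body: str) -> Atom:
    if not body:
        raise _err(text, pos, "empty bracket atom")
    for bad in "+-@/\\":
        if bad in body:
            kind = {"@": "stereo marker", "/": "stereo marker", "\\": "stereo marker"}.get(
                bad, "charge"
            )
            raise _err(text, pos + body.index(bad), f"unsupported {kind} {bad!r}")
    if body[0].isdigit():
        raise _err(text, pos, f"unsupported isotope specification {body!r}")
    k = 0
    if k + 1 < len(body) and body[k].isupper() and body[k + 1].islower() \
            and body[: k + 2] != "H" and (body[k : k + 2] in PCQM_ELEMENTS or body[k : k + 2] in VALENCES):
        symbol, aromatic, k = body[:2], False, 2
    elif body[k].isupper():
        symbol, aromatic, k = body[0], False, 1
    elif body[k] in _AROMATIC_LOWER:
        symbol, aromatic, k = _AROMATIC_LOWER[body[k]], True, 1
    else:
        raise _err(text, pos, f"unsupported token {body[k]!r}")
    explicit_h = 0
    if k < len(body):
        if body[k] != "H":
            raise _err(text, pos + k, f"unsupported token {body[k]!r}")
        k += 1
        digits = ""
        while k < len(body) and body[k].isdigit():
            digits += body[k]
            k += 1
        explicit_h = int(digits) if digits else 1
        if k < len(body):
            raise _err(text, pos + k, f"unsupported token {body[k]!r}")
    return Atom(symbol, aromatic=aromatic, explicit_h=explicit_h)


def parse_smiles(text: str) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    Atom order follows SMILES reading order; ring-closure digits (including
    the two-digit ``%nn`` form) produce the corresponding bond; branches
    restore the attachment point. Stereo markers, charges and isotopes are
    rejected with positional errors.
    """
    if not text:
        raise SmilesParseError("empty SMILES string")
    mol = Molecule()
    stack: list[int] = []
    prev: int | None = None
    pending_bond: str | None = None
    # ring closure number -> (atom index, bond symbol at open, position)
    open_rings: dict[int, tuple[int, str | None, int]] = {}

    def add_bond(a: int, b: int, symbol: str | None) -> None:
        if symbol is not None:
            order = symbol
        elif mol.atoms[a].aromatic and mol.atoms[b].aromatic:
            order = "aromatic"
        else:
            order = "single"
        mol.bonds.append(Bond(a, b, order))

    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "(":
            if prev is None:
                raise _err(text, i, "branch with no preceding atom")
            stack.append(prev)
            i += 1
        elif ch == ")":
            if not stack:
                raise _err(text, i, "unbalanced parenthesis")
            prev = stack.pop()
            i += 1
        elif ch in "-=#":
            if pending_bond is not None:
                raise _err(text, i, "two consecutive bond symbols")
            pending_bond = {"-": "single", "=": "double", "#": "triple"}[ch]
            i += 1
        elif ch.isdigit() or ch == "%":
            if prev is None:
                raise _err(text, i, "ring closure with no preceding atom")
            if ch == "%":
                if i + 2 >= n or not (text[i + 1].isdigit() and text[i + 2].isdigit()):
                    raise _err(text, i, "%% ring closure needs two digits")
                num = int(text[i + 1 : i + 3])
                step = 3
            else:
                num = int(ch)
                step = 1
            if num in open_rings:
                a, open_sym, _ = open_rings.pop(num)
                symbol = pending_bond if pending_bond is not None else open_sym
                if a == prev:
                    raise _err(text, i, f"ring closure {num} forms a self-bond")
                add_bond(a, prev, symbol)
            else:
                open_rings[num] = (prev, pending_bond, i)
            pending_bond = None
            i += step
        elif ch in _REJECTED or ch in "@/\\+":
            kind = "charge" if ch == "+" else "stereo marker"
            raise _err(text, i, f"unsupported {kind} {ch!r}")
        else:
            atom, j = _read_atom(text, i)
            mol.atoms.append(atom)
            idx = len(mol.atoms) - 1
            if prev is not None:
                add_bond(prev, idx, pending_bond)
            elif pending_bond is not None:
                raise _err(text, i, "bond symbol with no preceding atom")
            pending_bond = None
            prev = idx
            i = j
    if stack:
        raise SmilesParseError(f"unbalanced parenthesis in {text!r}")
    if open_rings:
        num, (_, _, pos) = next(iter(open_rings.items()))
        raise _err(text, pos, f"unclosed ring closure digit {num}")
    if pending_bond is not None:
        raise SmilesParseError(f"dangling bond symbol at end of {text!r}")
    if not mol.atoms:
        raise SmilesParseError(f"no atoms in {text!r}")
    mol.validate()
    return mol


# ---------------------------------------------------------------------------
# Hydrogen addition and featurization
# ---------------------------------------------------------------------------

def _implicit_h_count(mol: Molecule, idx: int) -> int:
    atom = mol.atoms[idx]
    if atom.explicit_h is not None:
        return atom.explicit_h
    bond_sum = sum(
        _BOND_VALENCE[b.order] for b in mol.bonds if idx in (b.a, b.b)
    )
    if atom.symbol in VALENCES:
        # aromatic bonds contribute 1.5; round the total to the nearest integer
        used = int(np.floor(bond_sum + 0.5))
        return max(0, VALENCES[atom.symbol] - used)
    if atom.symbol in PCQM_ELEMENTS:
        return 0
    raise FeaturizationError(
        f"no valence rule and no explicit H count for element {atom.symbol!r}"
    )


def add_hydrogens(mol: Molecule) -> Molecule:
    """Return a new molecule with implicit hydrogens appended as atoms.

    One H atom plus a single bond is added per implicit hydrogen, computed
    from the standard valence minus the sum of explicit bond orders. Original
    atom indices are preserved.
    """
    out = Molecule(atoms=list(mol.atoms), bonds=list(mol.bonds))
    n_heavy = len(mol.atoms)
    for idx in range(n_heavy):
        for _ in range(_implicit_h_count(mol, idx)):
            out.atoms.append(Atom("H"))
            out.bonds.append(Bond(idx, len(out.atoms) - 1, "single"))
    out.validate()
    return out


def build_vocabulary(symbols) -> ElementVocabulary:
    """De-duplicate element symbols preserving first-appearance order."""
    symbols = list(symbols)
    if not symbols:
        raise ValueError("element symbol list is empty")
    seen: dict[str, None] = {}
    for s in symbols:
        seen.setdefault(s)
    return ElementVocabulary(tuple(seen))


def featurize(mol: Molecule, vocab: ElementVocabulary) -> MolecularGraph:
    """Encode a molecule as a numeric graph.

    Node features are a one-hot element encoding (vocab size) concatenated
    with the raw node degree; edge features are a bond-order one-hot over
    (single, double, triple, aromatic). Every undirected bond is emitted as
    two directed edges with identical attributes. ``y`` is left empty.
    """
    n = mol.num_atoms
    V = len(vocab)
    x = np.zeros((n, V + 1), dtype=np.float32)
    degree = np.zeros(n, dtype=np.float32)
    for i, atom in enumerate(mol.atoms):
        x[i, vocab.index(atom.symbol)] = 1.0
    src, dst, attr_rows = [], [], []
    for bond in mol.bonds:
        onehot = np.zeros(len(BOND_ORDERS), dtype=np.float32)
        onehot[BOND_ORDERS.index(bond.order)] = 1.0
        src.extend((bond.a, bond.b))
        dst.extend((bond.b, bond.a))
        attr_rows.extend((onehot, onehot))
        degree[bond.a] += 1.0
        degree[bond.b] += 1.0
    x[:, V] = degree
    edge_index = np.array([src, dst], dtype=np.int64).reshape(2, -1)
    edge_attr = (
        np.stack(attr_rows).astype(np.float32)
        if attr_rows
        else np.zeros((0, len(BOND_ORDERS)), dtype=np.float32)
    )
    g = MolecularGraph(
        x=x,
        edge_index=edge_index,
        edge_attr=edge_attr,
        y=np.zeros((0,), dtype=np.float32),
    )
    g.validate()
    return g


def smiles_to_graph(text: str, vocab: ElementVocabulary) -> MolecularGraph:
    """Convenience pipeline: parse -> add hydrogens -> featurize."""
    return featurize(add_hydrogens(parse_smiles(text)), vocab)
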