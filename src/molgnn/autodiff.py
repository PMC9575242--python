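"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the graph network needs: affine maps, ReLU,
elementwise arithmetic with simple broadcasting, row gather, segment
reductions (sum / mean / min / max) over sorted or unsorted segment ids, and
scalar reductions. Computation runs in float64 or float32, following the dtype of the
operands; gradient correctness is established by finite-difference tests
in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "matmul", "relu", "concat", "gather_rows",
           "segment_sum", "segment_mean", "segment_min", "segment_max",
           "sqrt", "mean_all", "sum_all"]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # convenience operators -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._backward is not None for t in tensors)


def _wants(t: Tensor) -> bool:
    return t.requires_grad or t._backward is not None


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _needs(*parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce gradient g to the given (possibly broadcast) operand shape."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        if _wants(a):
            a._accumulate(_unbroadcast(g, a.data.shape))
        if _wants(b):
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        if _wants(a):
            a._accumulate(_unbroadcast(g, a.data.shape))
        if _wants(b):
            b._accumulate(-_unbroadcast(g, b.data.shape))

    return _make(a.data - b.data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        if _wants(a):
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if _wants(b):
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        if not g.flags.c_contiguous:
            g = np.ascontiguousarray(g)
        if _wants(a):
            a._accumulate(g @ b.data.T)
        if _wants(b):
            b._accumulate(a.data.T @ g)

    return _make(a.data @ b.data, (a, b), backward)


def relu(a) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return _make(a.data * mask, (a,), backward)


def sqrt(a) -> Tensor:
    a = _wrap(a)
    root = np.sqrt(a.data)

    def backward(g):
        a._accumulate(g * 0.5 / root)

    return _make(root, (a,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if not _wants(t):
                continue
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(np.ascontiguousarray(g[tuple(sl)]))

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tensors, backward)


class SegmentIndex:
    """Precomputed sort order for repeated segment reductions over one id set.

    Sorting the rows by segment id once lets every reduction use
    ``ufunc.reduceat`` over contiguous blocks instead of the much slower
    ``ufunc.at`` scatter path; the same object also accelerates the
    scatter-add in the gather gradient.
    """

    def __init__(self, seg, n_segments: int):
        self.seg = np.asarray(seg, dtype=np.int64)
        self.n_segments = int(n_segments)
        self.order = np.argsort(self.seg, kind="stable")
        self.presorted = bool(np.all(np.diff(self.seg) >= 0)) if len(self.seg) else True
        self.counts = np.bincount(self.seg, minlength=n_segments)
        self.nonempty = np.flatnonzero(self.counts)
        block_starts = np.concatenate([[0], np.cumsum(self.counts)])[:-1]
        self.starts = block_starts[self.nonempty]

    def _sorted(self, data: np.ndarray) -> np.ndarray:
        return data if self.presorted else data[self.order]

    def reduce(self, data: np.ndarray, ufunc) -> np.ndarray:
        out = np.zeros((self.n_segments,) + data.shape[1:], dtype=data.dtype)
        if len(self.order):
            out[self.nonempty] = ufunc.reduceat(self._sorted(data),
                                                self.starts, axis=0)
        return out

    def scatter_add(self, idx_rows: int, g: np.ndarray) -> np.ndarray:
        """Sum g rows sharing the same target id; ids are self.seg."""
        acc = np.zeros((self.n_segments,) + g.shape[1:], dtype=g.dtype)
        if len(self.order):
            acc[self.nonempty] = np.add.reduceat(self._sorted(g), self.starts,
                                                 axis=0)
        return acc


def _index_for(seg, n_segments: int, index: "SegmentIndex | None") -> "SegmentIndex":
    if index is not None:
        return index
    return SegmentIndex(seg, n_segments)


def gather_rows(a, idx, index: "SegmentIndex | None" = None) -> Tensor:
    """Select rows a[idx] (idx may repeat); gradient scatters with addition.

    Passing a :class:`SegmentIndex` built over ``idx`` (with
    ``n_segments == a.shape[0]``) accelerates the backward scatter.
    """
    a = _wrap(a)
    idx = np.asarray(idx, dtype=np.int64)

    def backward(g):
        si = _index_for(idx, a.data.shape[0], index)
        a._accumulate(si.scatter_add(a.data.shape[0], g))

    return _make(a.data[idx], (a,), backward)


def segment_sum(a, seg, n_segments: int,
                index: "SegmentIndex | None" = None) -> Tensor:
    """Sum rows of a into n_segments buckets given per-row segment ids."""
    a = _wrap(a)
    seg = np.asarray(seg, dtype=np.int64)
    si = _index_for(seg, n_segments, index)
    out = si.reduce(a.data, np.add)

    def backward(g):
        a._accumulate(g[seg])

    return _make(out, (a,), backward)


def segment_mean(a, seg, n_segments: int,
                 index: "SegmentIndex | None" = None) -> Tensor:
    """Mean of rows per segment; empty segments yield zeros."""
    a = _wrap(a)
    seg = np.asarray(seg, dtype=np.int64)
    si = _index_for(seg, n_segments, index)
    safe = np.maximum(si.counts.astype(np.float64), 1.0)
    total = segment_sum(a, seg, n_segments, index=si)
    inv = (1.0 / safe).reshape((n_segments,) + (1,) * (a.data.ndim - 1))
    return mul(total, Tensor(inv))


def _segment_extreme(a: Tensor, si: SegmentIndex, kind: str) -> Tensor:
    rows = a.data.shape[0]
    ufunc = np.minimum if kind == "min" else np.maximum
    out = si.reduce(a.data, ufunc)

    def backward(g):
        # route gradient to the first row attaining the extreme per
        # (segment, feature); ties broken by row order
        acc = np.zeros_like(a.data)
        if rows:
            sorted_data = si._sorted(a.data)
            hit = sorted_data == out[si._sorted(si.seg)]
            pos = np.where(
                hit, np.arange(rows)[:, None] if a.data.ndim > 1
                else np.arange(rows), rows)
            winner_sorted = np.minimum.reduceat(pos, si.starts, axis=0)
            winner = si.order[winner_sorted]  # rows-sentinel never selected:
            # every non-empty block has at least one hit
            gf = g[si.nonempty].reshape(len(si.nonempty), -1)
            wf = winner.reshape(len(si.nonempty), -1)
            accf = acc.reshape(rows, -1)
            np.add.at(accf, (wf, np.arange(wf.shape[1])), gf)
        a._accumulate(acc)

    return _make(out, (a,), backward)


def segment_min(a, seg, n_segments: int,
                index: "SegmentIndex | None" = None) -> Tensor:
    """Per-segment minimum; empty segments yield zeros. Gradient flows to the
    first row attaining the minimum (ties broken by row order)."""
    a = _wrap(a)
    return _segment_extreme(
        a, _index_for(np.asarray(seg, dtype=np.int64), n_segments, index), "min")


def segment_max(a, seg, n_segments: int,
                index: "SegmentIndex | None" = None) -> Tensor:
    """Per-segment maximum; see segment_min for tie handling."""
    a = _wrap(a)
    return _segment_extreme(
        a, _index_for(np.asarray(seg, dtype=np.int64), n_segments, index), "max")


def sum_all(a) -> Tensor:
    a = _wrap(a)

    def backward(g):
        a._accumulate(np.full_like(a.data, float(g)))

    return _make(np.array(a.data.sum()), (a,), backward)


def mean_all(a) -> Tensor:
    a = _wrap(a)
    n = a.data.size

    def backward(g):
        a._accumulate(np.full_like(a.data, float(g) / n))

    return _make(np.array(a.data.mean()), (a,), backward)
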