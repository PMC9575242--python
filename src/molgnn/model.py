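"""PNA-style graph convolutional regressor.

Architecture: a linear input embedding, ``num_conv_layers`` principal-
neighbourhood-aggregation (PNA) convolutions, global mean pooling, and a
two-layer fully connected head producing one scalar per graph. Each PNA
layer transforms every directed edge message ``[h_dst || h_src || e]``
through a one-layer MLP, reduces messages per destination node with four
aggregators (mean, min, max, std), rescales each aggregate with three
degree-dependent scalers (identity, amplification log(d+1)/delta,
attenuation delta/log(d+1)), concatenates the 12 blocks, and applies an
affine map plus ReLU. Isolated nodes receive zero aggregates.

Two routes compute the convolution: the vectorized autodiff route used for
training (:func:`pna_conv`, :func:`forward`) and a naive per-node double
loop (:func:`pna_conv_reference`) kept as a definitional oracle for tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .loaders import BatchGraph

__all__ = [
    "ModelConfig", "init_params", "pna_conv", "pna_conv_reference",
    "global_mean_pool", "forward", "forward_tensor", "mse_loss", "mae_metric",
    "compute_delta", "node_degrees",
]

AGGREGATORS = ("mean", "min", "max", "std")
SCALERS = ("identity", "amplification", "attenuation")

# regulariser inside the std aggregator's square root; part of the layer
# definition, shared with the reference implementation
VAR_EPS = 1e-9


@dataclass
class ModelConfig:
    """Hyperparameters of the regressor.

    ``hidden_dim`` defaults to 55 (the scaling configuration); 200 is the
    convergence configuration. ``delta`` is the PNA degree normalizer: the
    mean of log(degree+1) over all nodes of the training set.
    """

    node_dim: int
    edge_dim: int
    hidden_dim: int = 55
    num_conv_layers: int = 6
    num_fc_layers: int = 2
    fc_dim: int | None = None
    out_dim: int = 1
    aggregators: tuple[str, ...] = AGGREGATORS
    scalers: tuple[str, ...] = SCALERS
    delta: float = 1.0
    seed: int = 0
    standardize_targets: bool = False
    target_mean: float = 0.0
    target_std: float = 1.0

    def __post_init__(self):
        if self.fc_dim is None:
            self.fc_dim = self.hidden_dim
        if min(self.node_dim, self.edge_dim, self.hidden_dim, self.out_dim) <= 0:
            raise ValueError("all dimensions must be positive")
        if not set(self.aggregators) <= set(AGGREGATORS):
            raise ValueError(f"aggregators must be a subset of {AGGREGATORS}")
        if not set(self.scalers) <= set(SCALERS):
            raise ValueError(f"scalers must be a subset of {SCALERS}")
        if self.delta <= 0:
            raise ValueError("delta must be positive")


def node_degrees(edge_index: np.ndarray, num_nodes: int) -> np.ndarray:
    """In-degree of every node (equals out-degree for symmetric edge lists)."""
    return np.bincount(edge_index[1], minlength=num_nodes).astype(np.float64)


def compute_delta(graphs) -> float:
    """PNA degree normalizer: mean log(degree+1) over all training-set nodes."""
    logs = [
        np.log(node_degrees(g.edge_index, g.num_nodes) + 1.0) for g in graphs
    ]
    return float(np.mean(np.concatenate(logs)))


def _uniform_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


def init_params(config: ModelConfig) -> dict[str, Tensor]:
    """Seeded fan-in uniform initialization of all weights and biases."""
    rng = np.random.default_rng(config.seed)
    H, F, E = config.hidden_dim, config.node_dim, config.edge_dim
    n_blocks = len(config.aggregators) * len(config.scalers)
    params: dict[str, Tensor] = {}

    def lin(name: str, n_in: int, n_out: int) -> None:
        params[f"{name}.W"] = Tensor(_uniform_init(rng, n_in, (n_in, n_out)),
                                     requires_grad=True)
        params[f"{name}.b"] = Tensor(_uniform_init(rng, n_in, (n_out,)),
                                     requires_grad=True)

    lin("embed", F, H)
    for layer in range(config.num_conv_layers):
        lin(f"conv{layer}.msg", 2 * H + E, H)
        lin(f"conv{layer}.upd", n_blocks * H, H)
    dims = [H] + [config.fc_dim] * (config.num_fc_layers - 1) + [config.out_dim]
    for i, (n_in, n_out) in enumerate(zip(dims[:-1], dims[1:])):
        lin(f"fc{i}", n_in, n_out)
    return params


def _scaler_factors(degrees: np.ndarray, delta: float,
                    dtype=np.float64) -> dict[str, np.ndarray]:
    # clamp to degree 1 so attenuation stays finite; isolated nodes have zero
    # aggregates anyway, so the clamped factor multiplies zeros
    log_d = np.log(np.maximum(degrees, 1.0) + 1.0).astype(dtype)
    return {
        "identity": np.ones_like(log_d),
        "amplification": log_d / delta,
        "attenuation": delta / log_d,
    }


def _pna_layer(h: Tensor, edge_index: np.ndarray, edge_attr: Tensor,
               degrees: np.ndarray, w_msg: Tensor, b_msg: Tensor,
               w_upd: Tensor, b_upd: Tensor, config: ModelConfig,
               si_dst: ad.SegmentIndex | None = None,
               si_src: ad.SegmentIndex | None = None) -> Tensor:
    src, dst = edge_index[0], edge_index[1]
    n = h.data.shape[0]
    if si_dst is None:
        si_dst = ad.SegmentIndex(dst, n)
    if si_src is None:
        si_src = ad.SegmentIndex(src, n)
    msg_in = ad.concat([ad.gather_rows(h, dst, index=si_dst),
                        ad.gather_rows(h, src, index=si_src),
                        edge_attr], axis=1)
    m = ad.relu(ad.matmul(msg_in, w_msg) + b_msg)

    aggs: dict[str, Tensor] = {}
    if "mean" in config.aggregators or "std" in config.aggregators:
        mean = ad.segment_mean(m, dst, n, index=si_dst)
    for name in config.aggregators:
        if name == "mean":
            aggs[name] = mean
        elif name == "min":
            aggs[name] = ad.segment_min(m, dst, n, index=si_dst)
        elif name == "max":
            aggs[name] = ad.segment_max(m, dst, n, index=si_dst)
        elif name == "std":
            # sqrt(var + eps) - sqrt(eps): finite gradient at zero variance,
            # exactly zero for identical messages and for isolated nodes
            sq_mean = ad.segment_mean(ad.mul(m, m), dst, n, index=si_dst)
            var = ad.relu(sq_mean - ad.mul(mean, mean))
            dt = var.data.dtype
            root = ad.sqrt(var + Tensor(np.full(var.shape, VAR_EPS, dt)))
            aggs[name] = root - Tensor(np.full(var.shape, np.sqrt(VAR_EPS), dt))

    factors = _scaler_factors(degrees, config.delta, dtype=m.data.dtype)
    blocks = [
        ad.mul(aggs[agg], Tensor(factors[sc][:, None]))
        for agg in config.aggregators
        for sc in config.scalers
    ]
    return ad.relu(ad.matmul(ad.concat(blocks, axis=1), w_upd) + b_upd)


def pna_conv(h: np.ndarray, edge_index: np.ndarray, edge_attr: np.ndarray,
             degrees: np.ndarray, params: dict[str, Tensor],
             config: ModelConfig, layer: int = 0) -> np.ndarray:
    """Apply one PNA convolution (NumPy in / NumPy out)."""
    for arr in (h, edge_attr, degrees):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError("non-finite input to pna_conv")
    out = _pna_layer(Tensor(h), edge_index, Tensor(edge_attr), degrees,
                     params[f"conv{layer}.msg.W"], params[f"conv{layer}.msg.b"],
                     params[f"conv{layer}.upd.W"], params[f"conv{layer}.upd.b"],
                     config)
    return out.data


def pna_conv_reference(h: np.ndarray, edge_index: np.ndarray,
                       edge_attr: np.ndarray, degrees: np.ndarray,
                       params: dict[str, Tensor], config: ModelConfig,
                       layer: int = 0) -> np.ndarray:
    """Naive per-node, per-edge loop implementing the PNA formulas verbatim.

    Kept deliberately independent of the vectorized route: used as a
    definitional oracle in tests.
    """
    w_msg = params[f"conv{layer}.msg.W"].data
    b_msg = params[f"conv{layer}.msg.b"].data
    w_upd = params[f"conv{layer}.upd.W"].data
    b_upd = params[f"conv{layer}.upd.b"].data
    n = h.shape[0]
    H = w_msg.shape[1]
    out = np.zeros((n, w_upd.shape[1]))
    for v in range(n):
        messages = []
        for e in range(edge_index.shape[1]):
            u, w = edge_index[0, e], edge_index[1, e]
            if w != v:
                continue
            z = np.concatenate([h[v], h[u], edge_attr[e]])
            messages.append(np.maximum(z @ w_msg + b_msg, 0.0))
        if messages:
            M = np.stack(messages)
            agg_values = {
                "mean": M.mean(axis=0),
                "min": M.min(axis=0),
                "max": M.max(axis=0),
                "std": np.sqrt(np.maximum(
                    (M * M).mean(axis=0) - M.mean(axis=0) ** 2, 0.0) + VAR_EPS)
                - np.sqrt(VAR_EPS),
            }
        else:
            agg_values = {a: np.zeros(H) for a in AGGREGATORS}
        d = max(degrees[v], 1.0)
        scaler_values = {
            "identity": 1.0,
            "amplification": np.log(d + 1.0) / config.delta,
            "attenuation": config.delta / np.log(d + 1.0),
        }
        row = np.concatenate([
            agg_values[a] * scaler_values[s]
            for a in config.aggregators for s in config.scalers
        ])
        out[v] = np.maximum(row @ w_upd + b_upd, 0.0)
    return out


def global_mean_pool(h, graph_id: np.ndarray, num_graphs: int):
    """Average node states per graph. Accepts a Tensor or an ndarray."""
    graph_id = np.asarray(graph_id, dtype=np.int64)
    counts = np.bincount(graph_id, minlength=num_graphs)
    if np.any(counts == 0):
        raise ValueError("batch contains an empty graph")
    if isinstance(h, Tensor):
        return ad.segment_mean(h, graph_id, num_graphs)
    return ad.segment_mean(Tensor(h), graph_id, num_graphs).data


def forward_tensor(batch: BatchGraph, params: dict[str, Tensor],
                   config: ModelConfig) -> Tensor:
    """Differentiable forward pass; returns predictions (#graphs, out_dim)."""
    if batch.x.shape[1] != config.node_dim:
        raise ValueError(
            f"node feature dim {batch.x.shape[1]} != config {config.node_dim}")
    if batch.edge_attr.shape[1] != config.edge_dim:
        raise ValueError(
            f"edge feature dim {batch.edge_attr.shape[1]} != config {config.edge_dim}")
    degrees = node_degrees(batch.edge_index, batch.num_nodes)
    # iterate edges sorted by destination: aggregation blocks become
    # contiguous, and the edge order does not affect the layer semantics
    perm = np.argsort(batch.edge_index[1], kind="stable")
    edge_index = batch.edge_index[:, perm]
    si_dst = ad.SegmentIndex(edge_index[1], batch.num_nodes)
    si_src = ad.SegmentIndex(edge_index[0], batch.num_nodes)
    edge_attr = Tensor(batch.edge_attr[perm])
    h = ad.relu(ad.matmul(Tensor(batch.x), params["embed.W"]) + params["embed.b"])
    for layer in range(config.num_conv_layers):
        h = _pna_layer(h, edge_index, edge_attr, degrees,
                       params[f"conv{layer}.msg.W"], params[f"conv{layer}.msg.b"],
                       params[f"conv{layer}.upd.W"], params[f"conv{layer}.upd.b"],
                       config, si_dst=si_dst, si_src=si_src)
    pooled = global_mean_pool(h, batch.graph_id, batch.num_graphs)
    out = pooled
    for i in range(config.num_fc_layers):
        out = ad.matmul(out, params[f"fc{i}.W"]) + params[f"fc{i}.b"]
        if i < config.num_fc_layers - 1:
            out = ad.relu(out)
    return out


def forward(batch: BatchGraph, params: dict[str, Tensor],
            config: ModelConfig) -> np.ndarray:
    """Predictions on the original target scale (#graphs, out_dim)."""
    pred = forward_tensor(batch, params, config).data
    if config.standardize_targets:
        pred = pred * config.target_std + config.target_mean
    return pred


def mse_loss(pred: np.ndarray, y: np.ndarray) -> float:
    """Mean squared error over all elements."""
    pred, y = np.asarray(pred, dtype=np.float64), np.asarray(y, dtype=np.float64)
    if pred.shape != y.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {y.shape}")
    return float(np.mean((pred - y) ** 2))


def mae_metric(pred: np.ndarray, y: np.ndarray) -> float:
    """Mean absolute error over all elements."""
    pred, y = np.asarray(pred, dtype=np.float64), np.asarray(y, dtype=np.float64)
    if pred.shape != y.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {y.shape}")
    return float(np.mean(np.abs(pred - y)))
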