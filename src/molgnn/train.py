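"""Dataset splitting, AdamW optimization, and data-parallel training.

Data parallelism is simulated in-process: P worker replicas share one
parameter set, each computes the gradient of its local mean loss on a
disjoint equally-sized batch, gradients are combined by arithmetic
averaging, and a single optimizer step is applied. With equal local batch
sizes this is algebraically identical to one serial step on the union
batch, which the test suite verifies to near machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .loaders import BatchGraph, collate, shard_indices
from .model import (ModelConfig, compute_delta, forward, forward_tensor,
                    init_params, mae_metric, mse_loss)

__all__ = ["SplitSpec", "TrainState", "AdamW", "split_dataset",
           "aggregate_gradients", "ddp_train_step", "fit", "evaluate"]

TRAIN_FRACTION = 0.94  # remainder: 1/3 validation, 2/3 test


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint train/validation/test index sets covering [0, n)."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return len(self.train) + len(self.validation) + len(self.test)


def split_dataset(n: int, seed: int = 0) -> SplitSpec:
    """Random split: 94% train; of the remainder, 1/3 validation, 2/3 test.

    After a seeded permutation, train takes the first ``round(0.94 n)``
    indices, validation the next ``floor(r / 3)`` of the remainder ``r``,
    and test the rest.
    """
    if n < 3:
        raise ValueError(f"dataset of size {n} cannot be split three ways")
    n_train = round(TRAIN_FRACTION * n)
    r = n - n_train
    n_val = r // 3
    if n_train == 0 or n_val == 0 or r - n_val == 0:
        raise ValueError(f"dataset of size {n} yields an empty split")
    perm = np.random.default_rng(seed).permutation(n)
    return SplitSpec(
        train=perm[:n_train],
        validation=perm[n_train : n_train + n_val],
        test=perm[n_train + n_val :],
        seed=seed,
    )


class AdamW(object):
    """AdamW with decoupled weight decay (beta 0.9/0.999, eps 1e-8, wd 0.01)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1 ** self.t)
            v_hat = self.v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * (m_hat / (np.sqrt(v_hat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()


@dataclass
class TrainState:
    """Parameters, optimizer state, and per-epoch history of one run."""

    params: dict[str, Tensor]
    config: ModelConfig
    optimizer: AdamW
    epoch: int = 0
    train_loss_history: list[float] = field(default_factory=list)
    val_mae_history: list[float] = field(default_factory=list)
    seed: int = 0


def aggregate_gradients(per_worker_grads: list[dict[str, np.ndarray]]
                        ) -> dict[str, np.ndarray]:
    """Parameter-wise arithmetic mean of the workers' gradient sets."""
    if not per_worker_grads:
        raise ValueError("no worker gradients to aggregate")
    keys = set(per_worker_grads[0])
    for g in per_worker_grads[1:]:
        if set(g) != keys:
            raise ValueError("workers produced mismatched gradient sets")
        for k in keys:
            if g[k].shape != per_worker_grads[0][k].shape:
                raise ValueError(f"gradient shape mismatch for {k!r}")
    P = len(per_worker_grads)
    return {k: sum(g[k] for g in per_worker_grads) / P
            for k in per_worker_grads[0]}


def _standardized_targets(batch: BatchGraph, config: ModelConfig,
                          dtype=np.float64) -> np.ndarray:
    y = batch.y.astype(np.float64)
    if config.standardize_targets:
        y = (y - config.target_mean) / config.target_std
    return y.astype(dtype)


def local_loss_and_grads(batch: BatchGraph, params: dict[str, Tensor],
                         config: ModelConfig
                         ) -> tuple[float, dict[str, np.ndarray]]:
    """One worker's mean MSE loss and its parameter gradients."""
    for p in params.values():
        p.zero_grad()
    pred = forward_tensor(batch, params, config)
    diff = pred - Tensor(_standardized_targets(batch, config,
                                               pred.data.dtype))
    loss = ad.mean_all(diff * diff)
    loss.backward()
    grads = {k: p.grad.copy() for k, p in params.items()}
    if not np.isfinite(loss.data):
        raise FloatingPointError("non-finite training loss")
    return float(loss.data), grads


def ddp_train_step(local_batches: list[BatchGraph], state: TrainState
                   ) -> float:
    """One synchronized data-parallel step over P equal-size local batches.

    Every worker computes the gradient of its local mean loss; gradients
    are averaged and a single optimizer step updates the shared parameters.
    Returns the mean of the local losses (== the union-batch mean loss).
    """
    sizes = {b.num_graphs for b in local_batches}
    if len(sizes) != 1:
        raise ValueError(
            f"unequal local batch sizes {sorted(sizes)}: the averaged "
            "gradient would no longer equal the serial union-batch gradient")
    losses, grad_sets = [], []
    for batch in local_batches:
        loss, grads = local_loss_and_grads(batch, state.params, state.config)
        losses.append(loss)
        grad_sets.append(grads)
    avg = aggregate_gradients(grad_sets)
    for k, p in state.params.items():
        p.grad = avg[k]
    state.optimizer.step()
    return float(np.mean(losses))


def _fetch(dataset, indices) -> list:
    return [dataset[int(i)] for i in indices]


def fit(dataset, split: SplitSpec, config: ModelConfig | None = None,
        workers: int = 1, epochs: int = 3, batch_size: int = 128,
        lr: float = 1e-3, weight_decay: float = 0.01, seed: int = 0,
        standardize_targets: bool = False, hidden_dim: int = 55,
        num_conv_layers: int = 6, eval_batch_size: int = 256,
        dtype=np.float64) -> TrainState:
    """Train the regressor with P simulated data-parallel workers.

    ``dataset`` is a sequence of featurized graphs with targets attached.
    Each epoch reshuffles the training indices with a seed derived from
    (seed, epoch), deals them round-robin to the workers, and drops the
    remainder so every worker takes the same number of steps.
    """
    if len(split.train) == 0:
        raise ValueError("empty training split")
    if workers < 1:
        raise ValueError("workers must be >= 1")
    train_idx = np.asarray(split.train)
    train_graphs = _fetch(dataset, train_idx)
    if config is None:
        g0 = train_graphs[0]
        config = ModelConfig(
            node_dim=g0.x.shape[1], edge_dim=g0.edge_attr.shape[1],
            hidden_dim=hidden_dim, num_conv_layers=num_conv_layers,
            seed=seed, standardize_targets=standardize_targets,
        )
    if config.delta == 1.0:
        config.delta = compute_delta(train_graphs)
    if config.standardize_targets:
        targets = np.concatenate([g.y for g in train_graphs]).astype(np.float64)
        config.target_mean = float(targets.mean())
        config.target_std = float(max(targets.std(), 1e-12))
    params = init_params(config)
    for p in params.values():
        p.data = p.data.astype(dtype)
    optimizer = AdamW(params, lr=lr, weight_decay=weight_decay)
    state = TrainState(params=params, config=config, optimizer=optimizer,
                       seed=seed)

    local_batch = batch_size
    for epoch in range(epochs):
        shards = [shard_indices(len(train_idx), workers, w, seed,
                                drop_remainder=True, epoch=epoch)
                  for w in range(workers)]
        steps = len(shards[0]) // local_batch
        if steps == 0:
            raise ValueError(
                f"batch_size {local_batch} exceeds the {len(shards[0])}-item "
                "worker shard; no full batch available")
        epoch_losses = []
        for s in range(steps):
            local_batches = []
            for w in range(workers):
                pos = shards[w].indices[s * local_batch:(s + 1) * local_batch]
                local_batches.append(
                    collate(_fetch(dataset, train_idx[pos])))
            epoch_losses.append(ddp_train_step(local_batches, state))
        state.epoch = epoch + 1
        state.train_loss_history.append(float(np.mean(epoch_losses)))
        if len(split.validation):
            val_mae, _ = evaluate(dataset, split.validation, state,
                                  batch_size=eval_batch_size)
            state.val_mae_history.append(val_mae)
    return state


def evaluate(dataset, indices, state: TrainState,
             batch_size: int = 256) -> tuple[float, float]:
    """MAE and MSE over an index set, invariant to the internal batch size.

    Partial sums are weighted by batch size so the result does not depend
    on how the index set is chunked.
    """
    indices = np.asarray(indices)
    if len(indices) == 0:
        raise ValueError("empty evaluation index set")
    abs_sum = sq_sum = 0.0
    count = 0
    for b in range(0, len(indices), batch_size):
        graphs = _fetch(dataset, indices[b : b + batch_size])
        batch = collate(graphs)
        pred = forward(batch, state.params, state.config)
        y = batch.y.astype(np.float64)
        n = y.size
        abs_sum += mae_metric(pred, y) * n
        sq_sum += mse_loss(pred, y) * n
        count += n
    return abs_sum / count, sq_sum / count
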