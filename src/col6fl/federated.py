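"""Horizontal federated training with FedAvg, plus the single-node baseline.

Each node holds its own (frozen) feature matrix and labels; a round
broadcasts the global head parameters, lets every node run local gradient
descent, and aggregates the returned parameters by (sample-count-weighted)
element-wise averaging.  The aggregator surface accepts only
``(ModelParams, n_k)`` pairs — never raw images or features — which is the
module's structural privacy boundary.

With one local full-batch epoch per round and sample-count weighting, a
FedAvg round is algebraically identical to one full-batch gradient step on
the pooled objective, because the weighted mean of per-node gradients of
mean-cross-entropy (+ an identical L2 term) equals the pooled gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import HeadTrainConfig, ModelParams, head_loss, train_head

__all__ = [
    "Node",
    "FedAvgConfig",
    "TrainingHistory",
    "local_update",
    "fedavg_aggregate",
    "run_federated",
    "run_single_node",
]


@dataclass
class Node:
    """One institution's private training partition (features + labels)."""

    site_id: str
    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        if self.features.ndim != 2:
            raise ValueError("features must be an (n, d) matrix")
        if self.features.shape[0] != self.labels.size:
            raise ValueError("features/labels length mismatch")

    @property
    def n_k(self) -> int:
        return self.features.shape[0]


@dataclass(frozen=True)
class FedAvgConfig:
    """Federation schedule: R rounds of E local epochs per node."""

    rounds: int = 750
    local_epochs: int = 2
    batch_size: int | None = None  # None = full batch
    learning_rate: float = 0.03
    l2: float = 1e-3
    weighting: str = "sample_count"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 0:
            raise ValueError("rounds must be >= 0")
        if self.local_epochs < 1:
            raise ValueError("local_epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.weighting not in ("sample_count", "uniform"):
            raise ValueError("weighting must be 'sample_count' or 'uniform'")


@dataclass
class TrainingHistory:
    """Per-round diagnostics: losses at the broadcast parameters and the
    norm of the global parameter change produced by the round."""

    global_loss: list[float] = field(default_factory=list)
    local_losses: list[dict[str, float]] = field(default_factory=list)
    param_delta_norm: list[float] = field(default_factory=list)


def _round_seed(seed: int, round_idx: int, node_idx: int) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=(round_idx, node_idx))
    return int(ss.generate_state(1)[0] % (2**31))


def local_update(
    node: Node, global_params: ModelParams, cfg: FedAvgConfig, round_idx: int = 0
) -> tuple[ModelParams, int]:
    """One node's contribution to a round: E local epochs from the broadcast
    parameters; returns the updated parameters and the local sample count."""
    if node.n_k == 0:
        raise ValueError(f"node {node.site_id} has no training samples")
    hyper = HeadTrainConfig(
        learning_rate=cfg.learning_rate,
        epochs=cfg.local_epochs,
        l2=cfg.l2,
        batch_size=cfg.batch_size,
        seed=_round_seed(cfg.seed, round_idx, 0),
    )
    params = train_head(node.features, node.labels, global_params, hyper)
    return params, node.n_k


def fedavg_aggregate(
    updates: list[tuple[ModelParams, int]], weighting: str = "sample_count"
) -> ModelParams:
    """Element-wise weighted mean of parameter updates (FedAvg).

    Weights are n_k / sum(n_k) for ``sample_count`` or 1/M for ``uniform``.
    """
    if not updates:
        raise ValueError("no updates to aggregate")
    shapes = {(p.weights.shape, p.bias.shape) for p, _ in updates}
    if len(shapes) != 1:
        raise ValueError(f"parameter shape mismatch across updates: {shapes}")
    if weighting == "sample_count":
        total = sum(n for _, n in updates)
        if total <= 0:
            raise ValueError("total sample count is zero")
        w = np.array([n / total for _, n in updates])
    elif weighting == "uniform":
        w = np.full(len(updates), 1.0 / len(updates))
    else:
        raise ValueError("weighting must be 'sample_count' or 'uniform'")
    weights = sum(wi * p.weights for wi, (p, _) in zip(w, updates))
    bias = sum(wi * p.bias for wi, (p, _) in zip(w, updates))
    return ModelParams(weights, bias)


def run_federated(
    nodes: list[Node],
    cfg: FedAvgConfig,
    params0: ModelParams,
) -> tuple[ModelParams, TrainingHistory]:
    """R rounds of broadcast -> local update (all nodes) -> FedAvg."""
    if not nodes:
        raise ValueError("at least one node is required")
    params = params0.copy()
    history = TrainingHistory()
    total_n = sum(n.n_k for n in nodes)
    for r in range(cfg.rounds):
        updates = []
        local_losses = {}
        for k, node in enumerate(nodes):
            hyper = HeadTrainConfig(
                learning_rate=cfg.learning_rate,
                epochs=cfg.local_epochs,
                l2=cfg.l2,
                batch_size=cfg.batch_size,
                seed=_round_seed(cfg.seed, r, k),
            )
            local_losses[node.site_id] = head_loss(
                params, node.features, node.labels, cfg.l2
            )
            updates.append(
                (train_head(node.features, node.labels, params, hyper), node.n_k)
            )
        new_params = fedavg_aggregate(updates, cfg.weighting)
        history.local_losses.append(local_losses)
        history.global_loss.append(
            sum(node.n_k * local_losses[node.site_id] for node in nodes) / total_n
        )
        history.param_delta_norm.append(
            float(
                np.sqrt(
                    np.sum((new_params.weights - params.weights) ** 2)
                    + np.sum((new_params.bias - params.bias) ** 2)
                )
            )
        )
        params = new_params
    return params, history


def run_single_node(
    node: Node, cfg: FedAvgConfig, params0: ModelParams
) -> tuple[ModelParams, TrainingHistory]:
    """Baseline trained on one node only, with the same R x E epoch budget
    and per-round seed discipline as the federated run (so a singleton
    federation and this baseline coincide)."""
    return run_federated([node], cfg, params0)
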