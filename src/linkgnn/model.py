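"""Model configuration and the functional view of the network.

:class:`ModelConfig` fixes the architecture: which propagation operators the
graph convolution aggregates (ablation works by shrinking this subset), the
per-layer output widths, the sort-pooling size and the read-out head.  The
functions here expose each stage of the network on a single subgraph —
convenient for inspection and for the oracle tests — while training runs
through the batched engine in :mod:`linkgnn.nn`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import yaml

from . import nn
from .nn import (
    ALL_PROPAGATORS,
    A_SQUARED,
    RAW_A,
    RW_NORM,
    SYM_NORM,
    build_propagator_matrices,
)
from .subgraph import LabeledSubgraph

CHECKPOINT_FORMAT = "linkgnn-checkpoint-v1"

__all__ = [
    "ModelConfig",
    "PropagatorStack",
    "TrainedModel",
    "build_propagators",
    "graph_conv_layer",
    "stack_conv_layers",
    "sort_pooling",
    "conv1d_head",
    "forward",
    "nll_loss",
    "save_checkpoint",
    "load_checkpoint",
    "ABLATION_VARIANTS",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``propagators`` is an ordered subset of {A, A2, rw_norm, sym_norm};
    removing one reproduces the ablation variants, and ``("sym_norm",)``
    alone gives a plain single-propagator (DGCNN-style) baseline.
    ``pooling_k`` may be an integer or a fraction in (0, 1) resolved as that
    quantile of the training subgraph sizes.
    """

    propagators: tuple[str, ...] = ALL_PROPAGATORS
    conv_dims: tuple[int, ...] = (32, 32, 1)
    pooling_k: int | float | None = 0.6
    conv1_channels: int = 16
    pool_size: int = 2
    pool_stride: int = 2
    conv2_channels: int = 32
    conv2_kernel: int = 5
    dense_units: int = 128
    activation: str = "tanh"
    seed: int = 0

    def __post_init__(self) -> None:
        self.propagators = tuple(self.propagators)
        self.conv_dims = tuple(int(d) for d in self.conv_dims)
        if not self.propagators:
            raise ValueError("at least one propagator is required")
        unknown = set(self.propagators) - set(ALL_PROPAGATORS)
        if unknown:
            raise ValueError(f"unknown propagators: {sorted(unknown)}")
        if len(set(self.propagators)) != len(self.propagators):
            raise ValueError("duplicate propagators")
        if not self.conv_dims or self.conv_dims[-1] != 1:
            raise ValueError("last graph-conv dimension must be 1 (sort-pool key)")
        if self.activation not in nn._ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if isinstance(self.pooling_k, int) and self.pooling_k < 1:
            raise ValueError("pooling_k must be >= 1")

    @property
    def embed_dim(self) -> int:
        """Width of the concatenated per-node embedding, sum of layer dims."""
        return sum(self.conv_dims)

    def min_pooling_k(self) -> int:
        """Smallest k for which the read-out head has a valid receptive field."""
        return self.conv2_kernel * self.pool_stride

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["propagators"] = list(self.propagators)
        d["conv_dims"] = list(self.conv_dims)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)


#: propagator subsets of the published ablation study: variant x removes one
#: operator; the baseline keeps only the symmetric-normalized adjacency.
ABLATION_VARIANTS: dict[str, tuple[str, ...]] = {
    "full": ALL_PROPAGATORS,
    "a": (A_SQUARED, RW_NORM, SYM_NORM),
    "b": (RAW_A, RW_NORM, SYM_NORM),
    "c": (RAW_A, A_SQUARED, SYM_NORM),
    "d": (RAW_A, A_SQUARED, RW_NORM),
    "baseline": (SYM_NORM,),
}


@dataclass
class PropagatorStack:
    """Per-subgraph propagation operators, in config order."""

    names: tuple[str, ...]
    matrices: list[sp.csr_matrix]

    def __getitem__(self, name: str) -> sp.csr_matrix:
        return self.matrices[self.names.index(name)]


def build_propagators(
    adj: np.ndarray, which: Sequence[str] = ALL_PROPAGATORS
) -> PropagatorStack:
    mats = build_propagator_matrices(adj, which)
    return PropagatorStack(tuple(which), [mats[p] for p in which])


@dataclass
class TrainedModel:
    """Learned parameters plus everything needed to reproduce a forward pass."""

    config: ModelConfig
    parameters: dict
    resolved_k: int
    feature_width: int


def _single_batch(subgraph: LabeledSubgraph, prop_names) -> nn.SubgraphBatch:
    return nn.make_batches([subgraph], batch_size=1, prop_names=prop_names)


def graph_conv_layer(
    Z_in: np.ndarray,
    props: PropagatorStack,
    W_t: np.ndarray,
    activation: str = "tanh",
) -> np.ndarray:
    """One layer: splice the propagated node matrices, mix, activate."""
    H = np.concatenate([np.asarray(P @ Z_in) for P in props.matrices], axis=1)
    if H.shape[1] != W_t.shape[0]:
        raise ValueError(
            f"spliced width {H.shape[1]} does not match W ({W_t.shape[0]})"
        )
    act, _ = nn._ACTIVATIONS[activation]
    return act(H @ W_t)


def stack_conv_layers(
    X: np.ndarray,
    props: PropagatorStack,
    weights: Sequence[np.ndarray],
    activation: str = "tanh",
) -> np.ndarray:
    """Run every conv layer from Z0 = X and concatenate all layer outputs."""
    Z = np.asarray(X, dtype=np.float64)
    outs = []
    for W in weights:
        Z = graph_conv_layer(Z, props, W, activation)
        outs.append(Z)
    return np.concatenate(outs, axis=1)


def sort_pooling(Z_cat: np.ndarray, k: int) -> np.ndarray:
    """Fixed-size representation: descending lexicographic sort keyed on the
    last channel (ties resolved by the penultimate channel and so on), top-k
    rows kept, zero rows appended when the graph has fewer than k nodes."""
    if k < 1:
        raise ValueError("k must be >= 1")
    offsets = np.array([0, Z_cat.shape[0]])
    pooled, _ = nn._sort_pool(np.asarray(Z_cat, dtype=np.float64), offsets, k)
    return pooled[0]


def conv1d_head(pooled: np.ndarray, model: TrainedModel) -> np.ndarray:
    """Read-out on one pooled tensor; returns 2-class log-probabilities."""
    cfg = model.config
    k, D = pooled.shape
    if (k, D) != (model.resolved_k, cfg.embed_dim):
        raise ValueError("pooled tensor shape does not match the model")
    logp = _head_forward(model.parameters, cfg, pooled[None, :, :], k)
    return logp[0]


def _head_forward(params, cfg, pooled, k):
    # reuse the batched engine's head by faking the conv caches
    B = pooled.shape[0]
    c1 = pooled @ params["Wc1"] + params["bc1"]
    r1 = np.maximum(c1, 0.0)
    k2 = k // cfg.pool_stride
    win1 = r1[:, : k2 * cfg.pool_stride].reshape(B, k2, cfg.pool_stride, -1)
    mp = win1.max(axis=2)
    L2 = k2 - cfg.conv2_kernel + 1
    widx = np.arange(L2)[:, None] + np.arange(cfg.conv2_kernel)[None, :]
    win2 = mp[:, widx, :].reshape(B, L2, cfg.conv2_kernel * mp.shape[2])
    r2 = np.maximum(win2 @ params["Wc2"] + params["bc2"], 0.0)
    flat = r2.reshape(B, -1)
    rd1 = np.maximum(flat @ params["Wd1"] + params["bd1"], 0.0)
    logits = rd1 @ params["Wd2"] + params["bd2"]
    mx = logits.max(axis=1, keepdims=True)
    return logits - (mx + np.log(np.exp(logits - mx).sum(axis=1, keepdims=True)))


def forward(subgraph: LabeledSubgraph, model: TrainedModel) -> float:
    """Probability that the subgraph's center pair is associated."""
    if subgraph.features.shape[1] != model.feature_width:
        raise ValueError(
            f"feature width {subgraph.features.shape[1]} does not match the "
            f"model ({model.feature_width})"
        )
    batch = _single_batch(subgraph, model.config.propagators)[0]
    logp, _ = nn.net_forward(model.parameters, model.config, batch, model.resolved_k)
    return float(np.exp(logp[0, 1]))


def nll_loss(log_probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-probability of the true class."""
    labels = np.asarray(labels, dtype=np.int64)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    loss, _ = nn.nll_from_logp(np.asarray(log_probs, dtype=np.float64), labels)
    return float(loss)


# ---------------------------------------------------------------------------
# checkpoint: single .npz archive, config embedded as JSON


def save_checkpoint(model: TrainedModel, path: str | Path) -> None:
    meta = {
        "format": CHECKPOINT_FORMAT,
        "config": {
            **asdict(model.config),
            "propagators": list(model.config.propagators),
            "conv_dims": list(model.config.conv_dims),
        },
        "resolved_k": model.resolved_k,
        "feature_width": model.feature_width,
    }
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **model.parameters,
    )


def load_checkpoint(path: str | Path) -> TrainedModel:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        if meta.get("format") != CHECKPOINT_FORMAT:
            raise ValueError("unrecognized checkpoint format")
        params = {k: archive[k] for k in archive.files if k != "__meta__"}
    return TrainedModel(
        config=ModelConfig(**meta["config"]),
        parameters=params,
        resolved_k=int(meta["resolved_k"]),
        feature_width=int(meta["feature_width"]),
    )
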