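"""Numerical engine for the subgraph classifier.

Implements the forward and backward passes of the network in numpy/scipy:

* multi-propagator graph convolution layers
  ``Z_{t+1} = sigma([P_1 Z_t, ..., P_m Z_t] W_t)`` where each ``P`` is one of
  the propagation operators A, A^2, D^-1 A, D^-1/2 A D^-1/2,
* concatenation of all layer outputs per node,
* sort pooling to a fixed ``k x sum(d_t)`` tensor,
* a 1-D convolutional read-out (kernel = stride = sum(d_t), max pool 2/2,
  second conv, dense layer) ending in a 2-class log-softmax,
* negative log-likelihood loss and an Adam optimizer.

Subgraphs are trained in minibatches: the per-subgraph propagator matrices
are stacked block-diagonally so one sparse product propagates the whole
batch.  Gradients are exact (verified against finite differences in the test
suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp

RAW_A = "A"
A_SQUARED = "A2"
RW_NORM = "rw_norm"
SYM_NORM = "sym_norm"
ALL_PROPAGATORS = (RAW_A, A_SQUARED, RW_NORM, SYM_NORM)

_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    # name -> (f, f' expressed in terms of the output)
    "tanh": (np.tanh, lambda out: 1.0 - out ** 2),
    "relu": (lambda x: np.maximum(x, 0.0), lambda out: (out > 0).astype(np.float64)),
    "identity": (lambda x: x, lambda out: np.ones_like(out)),
}

__all__ = [
    "RAW_A",
    "A_SQUARED",
    "RW_NORM",
    "SYM_NORM",
    "ALL_PROPAGATORS",
    "build_propagator_matrices",
    "SubgraphBatch",
    "make_batches",
    "init_params",
    "net_forward",
    "net_backward",
    "nll_from_logp",
    "Adam",
    "train_network",
]


def build_propagator_matrices(
    adj: np.ndarray | sp.spmatrix, which: Sequence[str] = ALL_PROPAGATORS
) -> dict[str, sp.csr_matrix]:
    """Build the requested propagation operators for one subgraph adjacency.

    ``A`` and ``A^2`` use the adjacency as-is; the two normalized operators
    add self-loops (``A~ = A + I``) before normalizing, so an isolated node
    still propagates its own feature.  Rows of any inverse degree matrix are
    zero for zero-degree nodes rather than raising.
    """
    A = sp.csr_matrix(adj, dtype=np.float64)
    n = A.shape[0]
    out: dict[str, sp.csr_matrix] = {}
    need_norm = any(p in which for p in (RW_NORM, SYM_NORM))
    if need_norm:
        At = (A + sp.identity(n, format="csr")).tocsr()
        deg = np.asarray(At.sum(axis=1)).ravel()
        with np.errstate(divide="ignore"):
            dinv = np.where(deg > 0, 1.0 / deg, 0.0)
            dinv_sqrt = np.sqrt(dinv)
    for p in which:
        if p == RAW_A:
            out[p] = A
        elif p == A_SQUARED:
            out[p] = (A @ A).tocsr()
        elif p == RW_NORM:
            out[p] = sp.diags(dinv) @ At
        elif p == SYM_NORM:
            out[p] = sp.diags(dinv_sqrt) @ At @ sp.diags(dinv_sqrt)
        else:
            raise ValueError(f"unknown propagator {p!r}")
        out[p] = sp.csr_matrix(out[p])
    return out


@dataclass
class SubgraphBatch:
    """A minibatch of subgraphs with block-diagonal propagators precomputed."""

    X: sp.csr_matrix                       # (N, L) stacked one-hot features
    y: np.ndarray                          # (B,) 0/1 labels
    sizes: np.ndarray                      # (B,) node counts
    offsets: np.ndarray                    # (B+1,) node offsets into the stack
    props: dict[str, sp.csr_matrix]        # block-diagonal operators
    props_T: dict[str, sp.csr_matrix]      # their transposes (CSR)
    _stack_cache: dict = field(default_factory=dict, repr=False)

    def stacked(self, which: tuple[str, ...]):
        """Vertically stacked operators [P_1; ...; P_m] and the transposed
        stack [P_1^T, ..., P_m^T]; one sparse product then propagates all m
        operators at once.  Cached per propagator subset."""
        key = tuple(which)
        if key not in self._stack_cache:
            S = sp.vstack([self.props[p] for p in which], format="csr")
            ST = sp.hstack([self.props_T[p] for p in which], format="csr")
            self._stack_cache[key] = (S, ST)
        return self._stack_cache[key]


def make_batches(
    subgraphs: Sequence,
    batch_size: int,
    prop_names: Sequence[str] = ALL_PROPAGATORS,
    rng: np.random.Generator | None = None,
    dtype=np.float64,
) -> list[SubgraphBatch]:
    """Group subgraphs into fixed minibatches with stacked operators.

    Membership is fixed once (after an optional seeded shuffle); training
    epochs then shuffle only the batch order.  Precomputing all four
    operators lets ablation configs reuse the same batches.
    """
    order = np.arange(len(subgraphs))
    if rng is not None:
        order = rng.permutation(order)
    batches = []
    for start in range(0, len(order), batch_size):
        members = [subgraphs[i] for i in order[start : start + batch_size]]
        per_graph = [build_propagator_matrices(g.adj, prop_names) for g in members]
        props = {
            p: sp.block_diag([pg[p] for pg in per_graph], format="csr").astype(dtype)
            for p in prop_names
        }
        props_T = {p: sp.csr_matrix(m.T) for p, m in props.items()}
        sizes = np.array([g.n_nodes for g in members], dtype=np.int64)
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        X = sp.vstack(
            [sp.csr_matrix(g.features) for g in members], format="csr"
        ).astype(dtype)
        y = np.array([g.true_label for g in members], dtype=np.int64)
        batches.append(SubgraphBatch(X, y, sizes, offsets, props, props_T))
    return batches


# ---------------------------------------------------------------------------
# parameters


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out))


def init_params(
    config, feature_width: int, k: int, rng: np.random.Generator, dtype=np.float64
) -> dict:
    """Glorot-uniform initial weights for every layer, shapes fixed by config."""
    m = len(config.propagators)
    dims = list(config.conv_dims)
    params: dict[str, np.ndarray] = {}
    d_in = feature_width
    for t, d_out in enumerate(dims):
        params[f"W{t}"] = glorot(rng, m * d_in, d_out)
        d_in = d_out
    D = sum(dims)
    c1, c2 = config.conv1_channels, config.conv2_channels
    params["Wc1"] = glorot(rng, D, c1)
    params["bc1"] = np.zeros(c1)
    params["Wc2"] = glorot(rng, config.conv2_kernel * c1, c2)
    params["bc2"] = np.zeros(c2)
    k2 = k // config.pool_stride
    flat = (k2 - config.conv2_kernel + 1) * c2
    if flat < 1:
        raise ValueError(
            f"pooling size k={k} too small for the read-out head "
            f"(needs k >= {config.min_pooling_k()})"
        )
    params["Wd1"] = glorot(rng, flat, config.dense_units)
    params["bd1"] = np.zeros(config.dense_units)
    params["Wd2"] = glorot(rng, config.dense_units, 2)
    params["bd2"] = np.zeros(2)
    return {key: v.astype(dtype) for key, v in params.items()}


# ---------------------------------------------------------------------------
# forward / backward


def _sort_pool(Zcat: np.ndarray, offsets: np.ndarray, k: int):
    """Per-graph sort pooling: descending lexicographic order keyed on the
    last channel, ties broken by earlier channels; top-k rows kept, zero rows
    appended when a graph has fewer than k nodes."""
    B = len(offsets) - 1
    D = Zcat.shape[1]
    pooled = np.zeros((B, k, D))
    take = np.full((B, k), -1, dtype=np.int64)
    N = Zcat.shape[0]
    gid = np.repeat(np.arange(B), np.diff(offsets))
    # group by graph, descending on the last channel within each group
    order = np.lexsort((-Zcat[:, -1], gid))
    key_sorted = Zcat[order, -1]
    same_graph = gid[order][1:] == gid[order][:-1]
    if np.any(same_graph & (key_sorted[1:] == key_sorted[:-1])):
        # ties on the sort key: full lexicographic comparison, last
        # channel primary, earlier channels breaking ties
        order = np.lexsort(tuple(-Zcat[:, c] for c in range(D)) + (gid,))
    pos_in_graph = np.arange(N) - offsets[gid[order]]
    keep = pos_in_graph < k
    rows = order[keep]
    pooled[gid[rows], pos_in_graph[keep]] = Zcat[rows]
    take[gid[rows], pos_in_graph[keep]] = rows
    return pooled, take


def net_forward(params: dict, config, batch: SubgraphBatch, k: int):
    """Forward pass over a batch; returns (log-probs (B,2), cache)."""
    act, _ = _ACTIVATIONS[config.activation]
    S, _ = batch.stacked(tuple(config.propagators))
    m = len(config.propagators)
    N = batch.X.shape[0]
    Z = batch.X
    Zs, SZs = [], []
    for t in range(len(config.conv_dims)):
        SZ = S @ Z
        if sp.issparse(SZ):
            SZ = SZ.toarray()
        SZ_r = SZ.reshape(m, N, -1)
        # [P_1 Z, ..., P_m Z] W  ==  sum_i (P_i Z) W_i with W in m blocks
        W_r = params[f"W{t}"].reshape(m, SZ_r.shape[2], -1)
        Z = act(np.matmul(SZ_r, W_r).sum(axis=0))
        SZs.append(SZ_r)
        Zs.append(Z)
    Zcat = np.concatenate(Zs, axis=1)

    pooled, take = _sort_pool(Zcat, batch.offsets, k)
    B, _, D = pooled.shape

    c1 = pooled @ params["Wc1"] + params["bc1"]          # (B, k, C1)
    r1 = np.maximum(c1, 0.0)
    stride = config.pool_stride
    k2 = k // stride
    win1 = r1[:, : k2 * stride].reshape(B, k2, stride, -1)
    arg = win1.argmax(axis=2)
    mp = np.take_along_axis(win1, arg[:, :, None, :], axis=2)[:, :, 0, :]  # (B,k2,C1)

    kern = config.conv2_kernel
    L2 = k2 - kern + 1
    widx = np.arange(L2)[:, None] + np.arange(kern)[None, :]
    win2 = mp[:, widx, :].reshape(B, L2, kern * mp.shape[2])
    c2 = win2 @ params["Wc2"] + params["bc2"]            # (B, L2, C2)
    r2 = np.maximum(c2, 0.0)

    flat = r2.reshape(B, -1)
    d1 = flat @ params["Wd1"] + params["bd1"]
    rd1 = np.maximum(d1, 0.0)
    logits = rd1 @ params["Wd2"] + params["bd2"]
    mx = logits.max(axis=1, keepdims=True)
    logp = logits - (mx + np.log(np.exp(logits - mx).sum(axis=1, keepdims=True)))

    cache = dict(
        SZs=SZs, Zs=Zs, Zcat=Zcat, take=take, pooled=pooled, r1=r1, arg=arg,
        mp=mp, win2=win2, r2=r2, flat=flat, rd1=rd1, logp=logp, k2=k2, L2=L2,
        widx=widx, stride=stride,
    )
    return logp, cache


def net_backward(params: dict, config, batch: SubgraphBatch, cache: dict,
                 dlogp: np.ndarray) -> dict:
    """Exact gradients of the scalar loss w.r.t. every parameter."""
    _, dact = _ACTIVATIONS[config.activation]
    grads: dict[str, np.ndarray] = {}
    B = dlogp.shape[0]

    # log-softmax
    p = np.exp(cache["logp"])
    dlogits = dlogp - p * dlogp.sum(axis=1, keepdims=True)

    grads["Wd2"] = cache["rd1"].T @ dlogits
    grads["bd2"] = dlogits.sum(axis=0)
    drd1 = dlogits @ params["Wd2"].T
    dd1 = drd1 * (cache["rd1"] > 0)
    grads["Wd1"] = cache["flat"].T @ dd1
    grads["bd1"] = dd1.sum(axis=0)
    dflat = dd1 @ params["Wd1"].T

    dr2 = dflat.reshape(cache["r2"].shape)
    dc2 = dr2 * (cache["r2"] > 0)
    grads["Wc2"] = (
        cache["win2"].reshape(-1, cache["win2"].shape[2]).T
        @ dc2.reshape(-1, dc2.shape[2])
    )
    grads["bc2"] = dc2.sum(axis=(0, 1))
    dwin2 = dc2 @ params["Wc2"].T                         # (B, L2, kern*C1)
    kern = config.conv2_kernel
    C1 = cache["mp"].shape[2]
    dmp = np.zeros_like(cache["mp"])
    dwin2 = dwin2.reshape(B, cache["L2"], kern, C1)
    np.add.at(dmp, (slice(None), cache["widx"], slice(None)), dwin2)

    # max-pool backward: route to argmax positions
    stride = cache["stride"]
    k2 = cache["k2"]
    dwin1 = np.zeros((B, k2, stride, C1))
    np.put_along_axis(dwin1, cache["arg"][:, :, None, :], dmp[:, :, None, :], axis=2)
    dr1 = np.zeros_like(cache["r1"])
    dr1[:, : k2 * stride] = dwin1.reshape(B, k2 * stride, C1)

    dc1 = dr1 * (cache["r1"] > 0)
    D = cache["pooled"].shape[2]
    grads["Wc1"] = cache["pooled"].reshape(-1, D).T @ dc1.reshape(-1, C1)
    grads["bc1"] = dc1.sum(axis=(0, 1))
    dpooled = dc1 @ params["Wc1"].T                       # (B, k, D)

    # sort-pool backward: scatter rows back to their source nodes
    dZcat = np.zeros_like(cache["Zcat"])
    take = cache["take"]
    valid = take >= 0
    dZcat[take[valid]] += dpooled[valid]

    # graph conv layers, from the top down; each Z_t receives gradient both
    # from the concatenated embedding and from layer t+1
    T = len(config.conv_dims)
    dims = list(config.conv_dims)
    splits = np.cumsum(dims)[:-1]
    dZ_parts = np.split(dZcat, splits, axis=1)
    m = len(config.propagators)
    _, ST = batch.stacked(tuple(config.propagators))
    N = dZcat.shape[0]
    dZ_above: np.ndarray | None = None
    for t in reversed(range(T)):
        dZ = dZ_parts[t].copy()
        if dZ_above is not None:
            dZ += dZ_above
        dZpre = dZ * dact(cache["Zs"][t])
        SZ_r = cache["SZs"][t]
        d_in = SZ_r.shape[2]
        # per-propagator weight blocks: dW_i = (P_i Z)^T dZpre
        gW = np.matmul(SZ_r.transpose(0, 2, 1), dZpre[None])
        grads[f"W{t}"] = gW.reshape(m * d_in, -1)
        if t > 0:
            W_r = params[f"W{t}"].reshape(m, d_in, -1)
            dH_r = np.matmul(dZpre[None], W_r.transpose(0, 2, 1))  # (m, N, d)
            dZ_above = ST @ dH_r.reshape(m * N, d_in)
    return grads


def nll_from_logp(logp: np.ndarray, y: np.ndarray):
    """Mean negative log-likelihood and its gradient w.r.t. the log-probs."""
    B = len(y)
    loss = -logp[np.arange(B), y].mean()
    dlogp = np.zeros_like(logp)
    dlogp[np.arange(B), y] = -1.0 / B
    return loss, dlogp


class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(self, params: dict, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for key, g in grads.items():
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / b1t
            vhat = self.v[key] / b2t
            params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def resolve_pooling_k(config, train_sizes: Sequence[int]) -> int:
    """Resolve the sort-pooling size against the training-size distribution.

    A fractional ``pooling_k`` q is read as the q-th quantile of subgraph
    node counts (DGCNN convention); the result is clamped so the 1-D
    convolutional head keeps a valid receptive field.
    """
    kmin = config.min_pooling_k()
    pk = config.pooling_k
    if pk is None:
        pk = 0.6
    if isinstance(pk, float) and 0 < pk < 1:
        k = int(np.ceil(np.quantile(np.asarray(train_sizes, dtype=float), pk)))
        return max(k, kmin)
    k = int(pk)
    if k < kmin:
        raise ValueError(f"pooling_k={k} below the head's minimum {kmin}")
    return k


def train_network(
    batches: list[SubgraphBatch],
    config,
    k: int,
    feature_width: int,
    epochs: int,
    learning_rate: float,
    seed: int,
    dtype=np.float32,
) -> tuple[dict, list[float]]:
    """Train on fixed minibatches; returns (parameters, per-epoch mean loss).

    Single precision is the default training dtype (sufficient for the
    optimization and about 1.4x faster on one core); the backward pass is
    exact in whatever precision is used.
    """
    rng = np.random.default_rng(seed)
    params = init_params(config, feature_width, k, rng, dtype=dtype)
    opt = Adam(params, lr=learning_rate)
    history: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(len(batches))
        total, count = 0.0, 0
        for bi in order:
            batch = batches[bi]
            logp, cache = net_forward(params, config, batch, k)
            loss, dlogp = nll_from_logp(logp, batch.y)
            grads = net_backward(params, config, batch, cache, dlogp)
            opt.step(params, grads)
            total += loss * len(batch.y)
            count += len(batch.y)
        history.append(total / count)
        if not np.isfinite(history[-1]):
            raise FloatingPointError("training loss diverged")
    return params, history
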