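"""Enclosing-subgraph extraction and double-radius node labeling (DRNL).

For a candidate pair (one side-A node, one side-B node) the *h-hop enclosing
subgraph* is the subgraph induced on every node within graph distance ``h``
of either center, with the pair's own edge removed.  Each node is then given
an integer structural label from its distances ``(dx, dy)`` to the two
centers via the double-radius hash

    fl(i) = 1 + min(dx, dy) + (d // 2) * ((d // 2) + (d % 2) - 1),  d = dx + dy

with both centers labeled 1 and nodes disconnected from either center
labeled 0.  Labels are one-hot encoded into the node feature matrix that the
graph classifier consumes.

Global node indexing convention: side-A node ``i`` is global node ``i``;
side-B node ``j`` is global node ``nm + j``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path

from .data import AssociationMatrix, PairSample

__all__ = [
    "LabelEncoding",
    "LabeledSubgraph",
    "bipartite_adjacency",
    "khop_node_set",
    "drnl_label",
    "build_features",
    "extract_enclosing_subgraph",
    "batch_extract",
    "save_subgraphs",
    "load_subgraphs",
]


@dataclass(frozen=True)
class LabelEncoding:
    """One-hot layout for DRNL labels.

    Labels ``1..cap`` get their own slot, label 0 (disconnected) gets slot 0,
    and anything above ``cap`` shares a single overflow slot, so the feature
    width ``L = cap + 2`` is fixed across subgraphs.
    """

    cap: int = 50

    def __post_init__(self) -> None:
        if self.cap < 1:
            raise ValueError("label cap must be >= 1")

    @property
    def L(self) -> int:
        return self.cap + 2

    def slot(self, label: int) -> int:
        if label < 0:
            raise ValueError("labels must be non-negative")
        return label if label <= self.cap else self.cap + 1


@dataclass
class LabeledSubgraph:
    """One labeled enclosing subgraph, the unit of classification.

    Local node order is ``[center_x, center_y, others]`` with the remaining
    nodes sorted by (label, side, global index) for determinism.
    """

    adj: np.ndarray              # symmetric 0/1, zero diagonal, n x n
    sides: np.ndarray            # 0 = side A, 1 = side B, per local node
    global_indices: np.ndarray   # within-side index of each local node
    labels: np.ndarray           # DRNL integer labels, fl >= 0
    features: np.ndarray         # one-hot n x L
    h: int
    true_label: int
    center_positions: tuple[int, int] = (0, 1)

    @property
    def n_nodes(self) -> int:
        return self.adj.shape[0]


def bipartite_adjacency(Y: np.ndarray) -> sp.csr_matrix:
    """Symmetric (nm+nd) x (nm+nd) adjacency of the bipartite graph of Y."""
    B = sp.csr_matrix(Y.astype(np.float64))
    nm, nd = Y.shape
    return sp.bmat(
        [[None, B], [B.T, None]], format="csr", dtype=np.float64
    ) if nm and nd else sp.csr_matrix((nm + nd, nm + nd))


def khop_node_set(
    mat: AssociationMatrix, center_row: int, center_col: int, h: int
) -> set[int]:
    """Global nodes within distance ``h`` of either center (centers included)."""
    if h < 1:
        raise ValueError("h must be >= 1")
    nm, nd = mat.nm, mat.nd
    if not (0 <= center_row < nm) or not (0 <= center_col < nd):
        raise IndexError("center indices out of range")
    adj = bipartite_adjacency(mat.Y)
    return _khop(adj, center_row, nm + center_col, h)


def _khop(adj: sp.csr_matrix, gx: int, gy: int, h: int) -> set[int]:
    n = adj.shape[0]
    visited = np.zeros(n, dtype=bool)
    frontier = np.zeros(n, dtype=bool)
    frontier[[gx, gy]] = True
    visited |= frontier
    for _ in range(h):
        reach = adj @ frontier.astype(np.float64) > 0
        frontier = reach & ~visited
        if not frontier.any():
            break
        visited |= frontier
    return set(np.flatnonzero(visited).tolist())


def _masked_distances(adj: np.ndarray, source: int, removed: int) -> np.ndarray:
    """BFS distances from ``source`` with node ``removed`` cut out of the graph."""
    a = adj.astype(np.float64, copy=True)
    a[removed, :] = 0
    a[:, removed] = 0
    d = shortest_path(sp.csr_matrix(a), method="D", unweighted=True, indices=source)
    return d


def drnl_label(
    subgraph_adj: np.ndarray, center_positions: tuple[int, int] = (0, 1)
) -> np.ndarray:
    """Double-radius node labels for one enclosing subgraph.

    ``dx`` is computed with center ``y`` removed from the graph and ``dy``
    with center ``x`` removed, so the label reflects paths that do not run
    through the opposite center.  Disconnected nodes get label 0; the two
    centers get label 1.
    """
    x, y = center_positions
    dx = _masked_distances(subgraph_adj, x, y)
    dy = _masked_distances(subgraph_adj, y, x)
    return drnl_from_distances(dx, dy, center_positions)


def drnl_from_distances(
    dx: np.ndarray, dy: np.ndarray, center_positions: tuple[int, int] = (0, 1)
) -> np.ndarray:
    n = len(dx)
    labels = np.zeros(n, dtype=np.int64)
    for i in range(n):
        if i in center_positions:
            labels[i] = 1
            continue
        a, b = dx[i], dy[i]
        if not np.isfinite(a) or not np.isfinite(b):
            labels[i] = 0
            continue
        d = int(a) + int(b)
        labels[i] = 1 + min(int(a), int(b)) + (d // 2) * ((d // 2) + (d % 2) - 1)
    return labels


def build_features(labels: np.ndarray, encoding: LabelEncoding) -> np.ndarray:
    """Expand integer labels into the one-hot feature matrix X (n x L)."""
    X = np.zeros((len(labels), encoding.L), dtype=np.float64)
    for i, lab in enumerate(labels):
        X[i, encoding.slot(int(lab))] = 1.0
    return X


def extract_enclosing_subgraph(
    mat: AssociationMatrix,
    sample: PairSample,
    h: int,
    encoding: LabelEncoding | None = None,
    distance_scope: str = "subgraph",
    _adj_cache: sp.csr_matrix | None = None,
) -> LabeledSubgraph:
    """Extract, label and featurize the h-hop enclosing subgraph of a pair.

    The center-center edge is always removed from the extracted adjacency
    (label-leakage prevention for positive samples; a no-op for negatives).
    ``distance_scope`` chooses whether DRNL distances are measured on the
    extracted subgraph (default) or on the full graph.
    """
    if encoding is None:
        encoding = LabelEncoding()
    if distance_scope not in ("subgraph", "full"):
        raise ValueError("distance_scope must be 'subgraph' or 'full'")
    nm = mat.nm
    full_adj = _adj_cache if _adj_cache is not None else bipartite_adjacency(mat.Y)
    gx, gy = sample.row_index, nm + sample.col_index
    if not (0 <= sample.row_index < nm) or not (0 <= sample.col_index < mat.nd):
        raise IndexError("sample indices out of range")
    nodes = _khop(full_adj, gx, gy, h)

    # provisional local order: centers first, the rest by (side, global index)
    others = sorted(g for g in nodes if g not in (gx, gy))
    order = [gx, gy] + others
    idx = np.array(order)
    sub = full_adj[np.ix_(idx, idx)].toarray()
    sub[0, 1] = sub[1, 0] = 0.0  # mask the target link

    if distance_scope == "subgraph":
        labels = drnl_label(sub, (0, 1))
    else:
        masked = full_adj.tolil(copy=True)
        masked[gx, gy] = masked[gy, gx] = 0
        masked = masked.tocsr()
        dxf = _masked_distances_sparse(masked, gx, gy)
        dyf = _masked_distances_sparse(masked, gy, gx)
        labels = drnl_from_distances(dxf[idx], dyf[idx], ())
        labels[0] = labels[1] = 1

    sides = (idx >= nm).astype(np.int8)
    gidx = np.where(sides == 0, idx, idx - nm)

    # final deterministic order: centers, then (label, side, global index)
    rest = np.arange(2, len(idx))
    key = sorted(rest, key=lambda i: (labels[i], sides[i], gidx[i]))
    perm = np.array([0, 1] + key, dtype=np.int64)
    sub = sub[np.ix_(perm, perm)]
    labels = labels[perm]
    sides = sides[perm]
    gidx = gidx[perm]

    return LabeledSubgraph(
        adj=sub.astype(np.uint8),
        sides=sides,
        global_indices=gidx.astype(np.int64),
        labels=labels,
        features=build_features(labels, encoding),
        h=h,
        true_label=int(sample.label),
    )


def _masked_distances_sparse(adj: sp.csr_matrix, source: int, removed: int) -> np.ndarray:
    a = adj.tolil(copy=True)
    a[removed, :] = 0
    a[:, removed] = 0
    return shortest_path(a.tocsr(), method="D", unweighted=True, indices=source)


def batch_extract(
    mat: AssociationMatrix,
    samples: Sequence[PairSample],
    h: int,
    encoding: LabelEncoding | None = None,
    distance_scope: str = "subgraph",
) -> list[LabeledSubgraph]:
    """Extract labeled subgraphs for a list of samples (deterministic order)."""
    if encoding is None:
        encoding = LabelEncoding()
    adj = bipartite_adjacency(mat.Y)
    return [
        extract_enclosing_subgraph(
            mat, s, h, encoding, distance_scope=distance_scope, _adj_cache=adj
        )
        for s in samples
    ]


# ---------------------------------------------------------------------------
# serialization: JSON manifest + one JSON-lines record per subgraph


def save_subgraphs(
    subgraphs: Sequence[LabeledSubgraph],
    directory: str | Path,
    encoding: LabelEncoding,
    seed: int | None = None,
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    hs = {g.h for g in subgraphs}
    manifest = {
        "format": "linkgnn-subgraphs-v1",
        "h": sorted(hs)[0] if len(hs) == 1 else sorted(hs),
        "label_cap": encoding.cap,
        "count": len(subgraphs),
        "seed": seed,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    with open(directory / "records.jsonl", "w") as fh:
        for g in subgraphs:
            r, c = np.nonzero(np.triu(g.adj))
            rec = {
                "n": int(g.n_nodes),
                "edges": [[int(a), int(b)] for a, b in zip(r, c)],
                "sides": g.sides.tolist(),
                "global_indices": g.global_indices.tolist(),
                "labels": g.labels.tolist(),
                "h": int(g.h),
                "true_label": int(g.true_label),
            }
            fh.write(json.dumps(rec) + "\n")


def load_subgraphs(directory: str | Path) -> tuple[list[LabeledSubgraph], LabelEncoding]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    if manifest.get("format") != "linkgnn-subgraphs-v1":
        raise ValueError("unrecognized subgraph dataset format")
    encoding = LabelEncoding(cap=manifest["label_cap"])
    out: list[LabeledSubgraph] = []
    with open(directory / "records.jsonl") as fh:
        for line in fh:
            rec = json.loads(line)
            n = rec["n"]
            adj = np.zeros((n, n), dtype=np.uint8)
            for a, b in rec["edges"]:
                adj[a, b] = adj[b, a] = 1
            labels = np.array(rec["labels"], dtype=np.int64)
            out.append(
                LabeledSubgraph(
                    adj=adj,
                    sides=np.array(rec["sides"], dtype=np.int8),
                    global_indices=np.array(rec["global_indices"], dtype=np.int64),
                    labels=labels,
                    features=build_features(labels, encoding),
                    h=int(rec["h"]),
                    true_label=int(rec["true_label"]),
                )
            )
    return out, encoding
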