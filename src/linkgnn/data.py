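"""Bipartite association data: loading, indexing, splitting.

The central object is :class:`AssociationMatrix`, a dense 0/1 matrix ``Y`` of
shape ``nm x nd`` whose rows are side-A entities (e.g. miRNAs) and whose
columns are side-B entities (e.g. diseases), together with ordered identifier
registries for both sides.  Ones are recorded associations; zeros are
*potential* associations from which negative training pairs are sampled.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

__all__ = [
    "AssociationMatrix",
    "PairSample",
    "CVFoldPlan",
    "load_edge_list",
    "save_edge_list",
    "load_matrix_market",
    "save_matrix_market",
    "sample_negative_pairs",
    "make_cv_folds",
    "mask_test_positives",
]


class PairSample(NamedTuple):
    """One (row, column) candidate pair with its supervision label.

    ``label`` is 1 for a recorded association and 0 for a sampled potential
    association.
    """

    row_index: int
    col_index: int
    label: int


@dataclass
class AssociationMatrix:
    """0/1 bipartite association matrix with identifier registries."""

    Y: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y)
        if self.Y.ndim != 2:
            raise ValueError("Y must be a 2-D matrix")
        vals = np.unique(self.Y)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("Y must contain only 0/1 entries")
        self.Y = self.Y.astype(np.uint8)
        if len(self.row_ids) != self.Y.shape[0]:
            raise ValueError("row_ids length does not match Y")
        if len(self.col_ids) != self.Y.shape[1]:
            raise ValueError("col_ids length does not match Y")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("duplicate row identifiers")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise ValueError("duplicate column identifiers")

    @property
    def nm(self) -> int:
        return self.Y.shape[0]

    @property
    def nd(self) -> int:
        return self.Y.shape[1]

    @property
    def n_associations(self) -> int:
        return int(self.Y.sum())

    def positive_pairs(self) -> list[PairSample]:
        """All recorded associations as labeled pairs (label 1)."""
        rows, cols = np.nonzero(self.Y)
        return [PairSample(int(r), int(c), 1) for r, c in zip(rows, cols)]

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(self.Y.copy(), list(self.row_ids), list(self.col_ids))


@dataclass
class CVFoldPlan:
    """Balanced random partition of samples into folds.

    ``assignments[i]`` is the fold index of sample ``i``; fold sizes differ
    by at most one.
    """

    n_folds: int
    assignments: np.ndarray
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def load_edge_list(
    path: str | Path,
    delimiter: str = "\t",
    header: bool = False,
) -> AssociationMatrix:
    """Read a two-column edge list into an association matrix.

    Each line names one association ``side-A id <delimiter> side-B id``.
    Duplicate lines are idempotent (the matrix is 0/1).  Row and column
    identifiers are ordered by first appearance.
    """
    path = Path(path)
    row_index: dict[str, int] = {}
    col_index: dict[str, int] = {}
    edges: list[tuple[int, int]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for lineno, parts in enumerate(reader, start=1):
            if header and lineno == 1:
                continue
            if not parts or (len(parts) == 1 and not parts[0].strip()):
                continue  # blank line
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(f"{path}: malformed line {lineno}: {parts!r}")
            a, b = parts[0].strip(), parts[1].strip()
            i = row_index.setdefault(a, len(row_index))
            j = col_index.setdefault(b, len(col_index))
            edges.append((i, j))
    if not edges:
        raise ValueError(f"{path}: no associations found")
    Y = np.zeros((len(row_index), len(col_index)), dtype=np.uint8)
    for i, j in edges:
        Y[i, j] = 1
    return AssociationMatrix(Y, list(row_index), list(col_index))


def save_edge_list(mat: AssociationMatrix, path: str | Path, delimiter: str = "\t") -> None:
    """Write one line per association, in row-major order."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        for i, j in zip(*np.nonzero(mat.Y)):
            writer.writerow([mat.row_ids[i], mat.col_ids[j]])


def save_matrix_market(mat: AssociationMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.mtx`` plus ``<prefix>.rows.txt`` / ``<prefix>.cols.txt`` sidecars."""
    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), sp.coo_matrix(mat.Y))
    prefix.with_suffix(".rows.txt").write_text("\n".join(mat.row_ids) + "\n")
    prefix.with_suffix(".cols.txt").write_text("\n".join(mat.col_ids) + "\n")


def load_matrix_market(prefix: str | Path) -> AssociationMatrix:
    prefix = Path(prefix)
    Y = np.asarray(scipy.io.mmread(str(prefix.with_suffix(".mtx"))).todense())
    row_ids = prefix.with_suffix(".rows.txt").read_text().splitlines()
    col_ids = prefix.with_suffix(".cols.txt").read_text().splitlines()
    return AssociationMatrix((Y != 0).astype(np.uint8), row_ids, col_ids)


def sample_negative_pairs(mat: AssociationMatrix, n: int, seed: int) -> list[PairSample]:
    """Sample ``n`` distinct zero entries of Y uniformly without replacement.

    Zeros are *potential* associations; nothing beyond known positives is
    excluded from the candidate pool.
    """
    zeros = np.argwhere(mat.Y == 0)
    if n > len(zeros):
        raise ValueError(f"requested {n} negatives but only {len(zeros)} zero entries exist")
    rng = np.random.default_rng(seed)
    chosen = zeros[rng.choice(len(zeros), size=n, replace=False)]
    return [PairSample(int(r), int(c), 0) for r, c in chosen]


def make_cv_folds(samples: Sequence[PairSample], n_folds: int, seed: int) -> CVFoldPlan:
    """Randomly partition samples into ``n_folds`` folds of near-equal size."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > len(samples):
        raise ValueError("more folds than samples")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    assignments = np.empty(len(samples), dtype=np.int64)
    assignments[order] = np.arange(len(samples)) % n_folds
    return CVFoldPlan(n_folds=n_folds, assignments=assignments, seed=seed)


def mask_test_positives(
    mat: AssociationMatrix, test_samples: Iterable[PairSample]
) -> AssociationMatrix:
    """Return a copy of ``mat`` with every test-positive cell set to zero.

    Held-out positives must be removed from the observed adjacency before
    subgraph extraction so the supervised label cannot leak into training
    inputs.  Raises if a test positive is not actually a 1 in Y (a split
    bookkeeping bug).
    """
    out = mat.copy()
    for s in test_samples:
        if s.label != 1:
            continue
        if out.Y[s.row_index, s.col_index] != 1:
            raise ValueError(
                f"test positive ({s.row_index},{s.col_index}) is not a 1 in Y"
            )
        out.Y[s.row_index, s.col_index] = 0
    return out
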