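"""Balanced cell-wise hold-out patterns for cross-validation.

Rank selection by cross-validation removes individual cells of the count
matrix, not whole samples: in fold k, every tumor has an equal share of its
mutation types held out, cycling deterministically across types and tumors
("balanced separation").  Because the pattern depends only on the indices
(P, N, K, k) and never on the observed counts, the held-out cells are
missing completely at random (MCAR) and the training-cell estimates are
unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FoldMask", "balanced_folds", "three_way_split", "masks_to_frame"]


@dataclass(frozen=True)
class FoldMask:
    """Hold-out pattern of one cross-validation fold.

    ``held_out[p, n]`` is True when cell (p, n) belongs to this fold's
    validation set; the complement is the fold's training set.
    """

    held_out: np.ndarray  # bool, P x N
    fold_index: int  # 1-based
    n_folds: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.held_out.shape

    @property
    def n_held_out(self) -> int:
        return int(self.held_out.sum())


def balanced_folds(P: int, N: int, K: int) -> list[FoldMask]:
    """Deterministic balanced K-fold hold-out masks for a P×N matrix.

    For tumor n (1-based) in fold k (1-based), the held-out mutation-type
    indices are ``p = base + a*K`` for a = 0, 1, 2, ... restricted to
    ``1 <= p <= P``, with ``base = ((n + k - 2) mod K) + 1``.  Every tumor
    therefore loses ⌊P/K⌋ or ⌈P/K⌉ types per fold, and across the K folds
    the masks partition all P×N cells.  With P=96, K=10 the first tumor's
    fold-1 hold-out is types (1, 11, ..., 91) and fold-2 is (2, 12, ..., 92).
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    if K > P:
        raise ValueError(f"K={K} exceeds the number of mutation types P={P}")
    masks = []
    cols = np.arange(1, N + 1)
    for k in range(1, K + 1):
        held = np.zeros((P, N), dtype=bool)
        base = (cols + k - 2) % K  # 0-based starting type per tumor
        for n in range(N):
            held[base[n] :: K, n] = True
        masks.append(FoldMask(held, k, K))
    return masks


def three_way_split(
    P: int, N: int, fractions: tuple[float, float, float] = (0.9, 0.05, 0.05)
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split all P×N cells into train/validation/test sets by whole folds.

    The fractions must each be a whole multiple of the smallest one, which
    defines K = 1/min(fractions) balanced folds; the last folds are assigned
    to test, the ones before to validation, the rest form the training set.
    The default 0.9/0.05/0.05 split uses K=20 with fold 19 as validation and
    fold 20 as test.

    Returns boolean (train, validation, test) cell masks — pairwise disjoint
    and jointly covering the matrix.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.size != 3 or np.any(fr <= 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be three positive numbers summing to 1")
    K = round(1.0 / fr.min())
    counts = fr * K
    if K > P or not np.allclose(counts, np.round(counts), atol=1e-9):
        near = np.round(counts) / K
        raise ValueError(
            f"fractions {tuple(fr)} not representable by whole folds of 1/{K}; "
            f"nearest representable split is {tuple(near)}"
        )
    n_train, n_val, n_test = np.round(counts).astype(int)
    masks = balanced_folds(P, N, K)
    val = np.zeros((P, N), dtype=bool)
    test = np.zeros((P, N), dtype=bool)
    for m in masks[K - n_test :]:
        test |= m.held_out
    for m in masks[K - n_test - n_val : K - n_test]:
        val |= m.held_out
    train = ~(val | test)
    return train, val, test


def masks_to_frame(
    masks: list[FoldMask],
    row_labels: list[str] | None = None,
    col_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Export a fold scheme as a (sample, mutation_type, fold) audit table."""
    P, N = masks[0].shape
    rows = row_labels or [f"type{i + 1}" for i in range(P)]
    cols = col_labels or [f"sample{j + 1}" for j in range(N)]
    records = []
    for m in masks:
        pp, nn = np.nonzero(m.held_out)
        for p, n in zip(pp, nn):
            records.append((cols[n], rows[p], m.fold_index))
    df = pd.DataFrame(records, columns=["sample", "mutation_type", "fold"])
    return df.sort_values(["sample", "mutation_type"], kind="stable").reset_index(drop=True)
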