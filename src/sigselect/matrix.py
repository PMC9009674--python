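"""Core domain containers and divergence kernels.

A mutational-signature analysis starts from a mutation-type count matrix
``V`` of shape P×N: P mutation types (canonically the 96 pyrimidine-centred
single-base-substitution trinucleotide classes) by N tumors.  Non-negative
matrix factorization approximates ``V ≈ W·H`` where each column of ``W`` is a
unit-sum signature profile over the P types and each column of ``H`` holds
the signature activities (expected mutation counts contributed) of one
tumor.  The factorization objective used throughout this package is the
generalized Kullback-Leibler divergence, whose minimization is equivalent to
maximum likelihood under independent Poisson counts with mean ``W·H``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MutationTypeMatrix",
    "sbs96_labels",
    "kl_divergence",
    "normalize_factorization",
    "filter_hypermutators",
    "FilterResult",
    "EPS",
]

#: Numerical floor applied to model means inside logarithms and denominators.
EPS = 1e-12

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")


def sbs96_labels() -> list[str]:
    """Canonical SBS96 mutation-type labels.

    Substitution-major order (C>A, C>G, C>T, T>A, T>C, T>G); within each
    substitution the 16 flanking contexts in alphabetical order
    (A[C>A]A, A[C>A]C, ..., T[C>A]T).
    """
    return [
        f"{five}[{sub}]{three}"
        for sub in SUBSTITUTION_CLASSES
        for five in _BASES
        for three in _BASES
    ]


@dataclass
class MutationTypeMatrix:
    """A labelled P×N matrix of non-negative integer mutation counts.

    Parameters
    ----------
    counts : ndarray of shape (P, N)
        Non-negative integer counts, mutation types in rows, tumors in
        columns.
    row_labels : sequence of str
        Mutation-type identifiers (e.g. ``"A[C>G]G"``); unique.
    col_labels : sequence of str
        Sample identifiers; unique.
    """

    counts: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        P, N = self.counts.shape
        if P < 2 or N < 2:
            raise ValueError(f"need at least 2 mutation types and 2 samples, got {P}x{N}")
        if not self.row_labels:
            self.row_labels = [f"type{i + 1}" for i in range(P)]
        if not self.col_labels:
            self.col_labels = [f"sample{j + 1}" for j in range(N)]
        self.row_labels = list(map(str, self.row_labels))
        self.col_labels = list(map(str, self.col_labels))
        if len(self.row_labels) != P:
            raise ValueError("row_labels length does not match counts")
        if len(self.col_labels) != N:
            raise ValueError("col_labels length does not match counts")
        if len(set(self.row_labels)) != P:
            raise ValueError("duplicate mutation-type labels")
        if len(set(self.col_labels)) != N:
            raise ValueError("duplicate sample labels")
        if np.any(self.counts < 0):
            p, n = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at ({self.row_labels[p]}, {self.col_labels[n]})"
            )
        if not np.allclose(self.counts, np.round(self.counts)):
            p, n = np.argwhere(~np.isclose(self.counts, np.round(self.counts)))[0]
            raise ValueError(
                f"non-integer count at ({self.row_labels[p]}, {self.col_labels[n]})"
            )
        self.counts = np.round(self.counts).astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_types(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MutationTypeMatrix":
        """Build from a DataFrame with mutation-type index and sample columns."""
        return cls(df.to_numpy(), list(df.index.astype(str)), list(df.columns.astype(str)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.row_labels, name="mutation_type"),
            columns=self.col_labels,
        )

    def burdens(self, genome_size_mb: float = 3000.0) -> pd.Series:
        """Per-sample mutation burden in mutations/Mb."""
        return pd.Series(
            self.counts.sum(axis=0) / genome_size_mb, index=self.col_labels, name="burden"
        )


def _as_array(V) -> np.ndarray:
    if isinstance(V, MutationTypeMatrix):
        return V.counts
    if isinstance(V, pd.DataFrame):
        return V.to_numpy()
    return np.asarray(V)


def kl_divergence(V, M, cells: np.ndarray | None = None) -> float:
    """Generalized Kullback-Leibler divergence ``D_KL(V | M)``.

    Computes ``sum over cells of v*log(v/m) + m - v`` with the convention
    ``0*log 0 = 0``; ``m`` is floored at :data:`EPS` inside the logarithm.
    Non-negative, and zero iff ``v == m`` on every evaluated cell.

    Parameters
    ----------
    V : array-like or MutationTypeMatrix
        Observed counts (non-negative).
    M : array-like
        Model means, same shape as ``V``.
    cells : boolean ndarray, optional
        Restrict the sum to cells where True.  Defaults to all cells.
    """
    v = _as_array(V).astype(np.float64)
    m = _as_array(M).astype(np.float64)
    if v.shape != m.shape:
        raise ValueError(f"shape mismatch: V {v.shape} vs M {m.shape}")
    if np.any(v < 0):
        raise ValueError("V contains negative entries")
    if cells is not None:
        cells = np.asarray(cells, dtype=bool)
        if cells.shape != v.shape:
            raise ValueError("cells mask shape does not match V")
        v = v[cells]
        m = m[cells]
    m = np.maximum(m, EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        logterm = np.where(v > 0, v * np.log(np.maximum(v, EPS) / m), 0.0)
    return float(np.sum(logterm + m - v))


def observed_loglik(V, W, H, observed_cells: np.ndarray | None = None) -> float:
    """Poisson NMF log-likelihood up to an additive constant.

    Returns ``-D_KL(V | W·H)`` over the observed cells; the data-dependent
    constant (log-factorial terms) is dropped, so only differences and
    orderings of this value are meaningful.
    """
    W = np.asarray(W, dtype=np.float64)
    H = np.asarray(H, dtype=np.float64)
    return -kl_divergence(V, W @ H, observed_cells)


def normalize_factorization(
    W: np.ndarray, H: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale so each signature column of W sums to 1, preserving ``W·H``.

    The activity rows of H absorb the column sums of W, so activities are on
    the mutation-count scale.
    """
    W = np.asarray(W, dtype=np.float64)
    H = np.asarray(H, dtype=np.float64)
    colsum = W.sum(axis=0)
    bad = np.where(colsum <= EPS)[0]
    if bad.size:
        raise ValueError(f"all-zero signature column(s): {bad.tolist()}")
    return W / colsum, H * colsum[:, None]


class FilterResult(NamedTuple):
    matrix: "MutationTypeMatrix"
    dropped: list[str]


def filter_hypermutators(
    V: MutationTypeMatrix,
    genome_size_mb: float = 3000.0,
    threshold_per_mb: float = 10.0,
) -> FilterResult:
    """Drop hypermutator samples before signature analysis.

    A sample whose total mutation count divided by ``genome_size_mb``
    strictly exceeds ``threshold_per_mb`` (default 10 mutations/Mb, with the
    ~3,000 Mb human genome) is excluded; the dropped sample IDs are returned
    alongside the filtered matrix.
    """
    if genome_size_mb <= 0:
        raise ValueError("genome_size_mb must be positive")
    burden = V.counts.sum(axis=0) / genome_size_mb
    keep = burden <= threshold_per_mb
    if not keep.any():
        raise ValueError("all samples exceed the hypermutator threshold")
    dropped = [lab for lab, k in zip(V.col_labels, keep) if not k]
    if not dropped:
        return FilterResult(V, [])
    out = MutationTypeMatrix(
        V.counts[:, keep],
        V.row_labels,
        [lab for lab, k in zip(V.col_labels, keep) if k],
    )
    return FilterResult(out, dropped)
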