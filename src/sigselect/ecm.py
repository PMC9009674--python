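"""Poisson NMF with held-out cells, fitted by expectation/conditional
maximization (ECM).

The model: counts ``v_pn`` are independent Poisson with mean
``sum_j w_pj h_jn``.  Cells marked held-out by a fold mask are treated as
missing data; each iteration imputes them with the current model mean
(E-step) and applies the generalized-KL multiplicative updates to the
completed matrix — W first, then H against the updated W (the two
conditional-maximization steps).  With no held-out cells the algorithm
reduces exactly to the standard Lee–Seung multiplicative-update algorithm
for KL-NMF.

The observed-data log-likelihood ``-D_KL(V|W·H)`` over non-held-out cells
is evaluated at every iterate; EM theory guarantees the sequence is
non-decreasing, and the loop stops when its relative change
``|l_t - l_{t-1}| / (|l_{t-1}| + 1)`` drops below ``tol``.

Because multiplicative updates can stall in local optima or saddle points,
fits are repeated from many random initializations and the one with the
largest observed log-likelihood is kept (``fit_multistart``).

Implementation note: the inner loop works on flat index arrays of the two
cell classes that carry information — observed cells with positive counts
(which need the ``v log(v/m)`` term and drive the updates) and held-out
cells (which need imputation) — while model means come from dense BLAS
products; observed zero-count cells enter only through factor-sum
identities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .folds import FoldMask
from .matrix import EPS, MutationTypeMatrix, kl_divergence, normalize_factorization

__all__ = [
    "PoissonNMF",
    "PoissonNMFResults",
    "init_impute",
    "random_init",
    "e_step",
    "cm_update",
    "fit_ecm",
    "fit_multistart",
]

DEFAULT_TOL = 1e-5
DEFAULT_MAX_ITERATIONS = 2000
DEFAULT_N_STARTS = 300


def _counts(V) -> np.ndarray:
    if isinstance(V, MutationTypeMatrix):
        return V.counts.astype(np.float64)
    V = np.asarray(V, dtype=np.float64)
    if V.ndim != 2:
        raise ValueError("count matrix must be 2-D")
    if np.any(V < 0):
        raise ValueError("count matrix has negative entries")
    return V


def _held(mask, shape) -> np.ndarray:
    if mask is None:
        return np.zeros(shape, dtype=bool)
    if isinstance(mask, FoldMask):
        held = mask.held_out
    else:
        held = np.asarray(mask, dtype=bool)
    if held.shape != shape:
        raise ValueError(f"mask shape {held.shape} does not match matrix {shape}")
    return held


def init_impute(V, mask=None) -> np.ndarray:
    """Complete the matrix by per-type medians of the training cells.

    Observed cells are copied; each held-out cell is replaced by the median
    of the observed cells in its row.  The held-out values of ``V`` are
    never read.
    """
    v = _counts(V)
    held = _held(mask, v.shape)
    if not held.any():
        return v.copy()
    out = v.copy()
    for p in range(v.shape[0]):
        row_held = held[p]
        if row_held.all():
            raise ValueError(f"row {p} has no observed cells to impute from")
        if row_held.any():
            out[p, row_held] = np.median(v[p, ~row_held])
    return out


def random_init(
    P: int, N: int, r: int, seed: int, V0: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Random starting factors for one ECM run.

    W0 entries are i.i.d. uniform(0,1) with columns normalized to sum 1;
    H0 entries are i.i.d. uniform(0,1) with each column rescaled so its sum
    matches the corresponding column total of the completed matrix ``V0``
    (so the initial model is on the right overall count scale).  Strictly
    positive and bit-reproducible per seed.
    """
    rng = np.random.default_rng(seed)
    W0 = rng.uniform(size=(P, r))
    W0 /= W0.sum(axis=0)
    H0 = rng.uniform(size=(r, N))
    totals = np.maximum(np.asarray(V0).sum(axis=0), EPS)
    H0 *= totals / H0.sum(axis=0)
    return np.maximum(W0, EPS), np.maximum(H0, EPS)


def e_step(V, mask, W, H) -> np.ndarray:
    """Impute held-out cells with the current model means.

    Returns the completed matrix V*: observed cells copied from ``V``,
    held-out cells set to ``(W·H)_pn``.
    """
    v = _counts(V)
    held = _held(mask, v.shape)
    out = v.copy()
    if held.any():
        out[held] = (np.asarray(W) @ np.asarray(H))[held]
    return out


def cm_update(Vstar, W, H) -> tuple[np.ndarray, np.ndarray]:
    """One pass of the generalized-KL multiplicative updates on a completed
    matrix: W is updated first, then H using the updated W.

    Guaranteed not to increase ``D_KL(V* | W·H)``.
    """
    Vstar = np.asarray(Vstar, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    H = np.asarray(H, dtype=np.float64)
    WH = np.maximum(W @ H, EPS)
    W1 = W * ((Vstar / WH) @ H.T) / np.maximum(H.sum(axis=1), EPS)
    W1 = np.maximum(W1, EPS)
    WH2 = np.maximum(W1 @ H, EPS)
    H1 = H * (W1.T @ (Vstar / WH2)) / np.maximum(W1.sum(axis=0), EPS)[:, None]
    return W1, np.maximum(H1, EPS)


@dataclass
class PoissonNMFResults:
    """Converged (or iteration-capped) fit of a Poisson NMF.

    Attributes
    ----------
    W, H : ndarray
        Raw factors as returned by the ECM loop (W columns not normalized).
    observed_loglik : float
        ``-D_KL(V | W·H)`` over observed (non-held-out) cells; additive
        constants are dropped so only comparisons are meaningful.
    loglik_path : ndarray or None
        Observed log-likelihood at each iterate (kept on request);
        non-decreasing.
    """

    W: np.ndarray
    H: np.ndarray
    observed_loglik: float
    n_iterations: int
    converged: bool
    seed: int
    rank: int
    loglik_path: np.ndarray | None = None
    model: "PoissonNMF | None" = None

    def predicted(self) -> np.ndarray:
        """Model mean matrix W·H (the imputation for held-out cells)."""
        return self.W @ self.H

    def normalized(self) -> tuple[np.ndarray, np.ndarray]:
        """(W, H) rescaled so W columns sum to 1, product preserved."""
        return normalize_factorization(self.W, self.H)

    def summary(self) -> str:
        lines = [
            "Poisson NMF (ECM) fit",
            f"  rank:            {self.rank}",
            f"  observed loglik: {self.observed_loglik:.4f}",
            f"  iterations:      {self.n_iterations}",
            f"  converged:       {self.converged}",
            f"  seed:            {self.seed}",
        ]
        return "\n".join(lines)


class PoissonNMF:
    """Poisson non-negative matrix factorization with optional held-out cells.

    Parameters
    ----------
    V : MutationTypeMatrix, DataFrame or ndarray
        P×N non-negative count matrix.
    rank : int
        Number of signatures r.
    mask : FoldMask or boolean ndarray, optional
        Cells to treat as missing (a cross-validation hold-out pattern).
        ``None`` fits the plain KL-NMF on all cells.

    Examples
    --------
    >>> model = PoissonNMF(V, rank=3, mask=folds[0])
    >>> res = model.fit_multistart(n_starts=20, master_seed=1)
    >>> res.observed_loglik
    """

    def __init__(self, V, rank: int, mask=None):
        if hasattr(V, "to_numpy") and not isinstance(V, MutationTypeMatrix):
            V = MutationTypeMatrix.from_dataframe(V)
        self.V = _counts(V)
        if rank < 1:
            raise ValueError("rank must be >= 1")
        if rank > min(self.V.shape):
            raise ValueError(f"rank {rank} exceeds matrix dimensions {self.V.shape}")
        self.rank = rank
        self.held = _held(mask, self.V.shape)
        self.mask = mask
        # flat indices of the informative cell classes
        obs = ~self.held
        flatV = self.V.ravel()
        self._nzf = np.flatnonzero(((self.V > 0) & obs).ravel())
        self._hf = np.flatnonzero(self.held.ravel())
        self._vnz = flatV[self._nzf].copy()
        self._vlogv = float(self._vnz @ np.log(self._vnz)) if self._vnz.size else 0.0
        self._vsum = float(flatV[obs.ravel()].sum())
        self._V0 = None  # median-completed matrix, computed lazily

    @classmethod
    def from_dataframe(cls, df, rank: int, mask=None) -> "PoissonNMF":
        return cls(MutationTypeMatrix.from_dataframe(df), rank, mask)

    def _completed(self) -> np.ndarray:
        if self._V0 is None:
            self._V0 = init_impute(self.V, self.held)
        return self._V0

    def _loop(
        self, W: np.ndarray, H: np.ndarray, tol: float, max_iterations: int
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
        """Iterate E-step + CM updates in place; returns (W, H, path, flag).

        ``path[t]`` is the observed log-likelihood of the t-th iterate;
        the returned factors correspond to the last entry.
        """
        P, N = self.V.shape
        nzf, hf, vnz = self._nzf, self._hf, self._vnz
        Ht = np.ascontiguousarray(H.T)  # (N, r); BLAS-friendly both ways
        WH = np.empty((P, N))
        WHf = WH.ravel()
        R = np.zeros(P * N)
        Rm = R.reshape(P, N)
        path = np.empty(max_iterations + 1)
        prev = 0.0
        converged = False
        t = 0
        for t in range(max_iterations + 1):
            np.matmul(W, Ht.T, out=WH)
            mnz = np.maximum(WHf[nzf], EPS)
            mh = np.maximum(WHf[hf], EPS)
            # sum of means over observed cells, via factor sums minus held
            tot = float(W.sum(axis=0) @ Ht.sum(axis=0))
            ll = float(np.log(mnz) @ vnz) - self._vlogv - (tot - mh.sum()) + self._vsum
            path[t] = ll
            if t > 0 and abs(ll - prev) / (abs(prev) + 1.0) < tol:
                converged = True
                break
            prev = ll
            if t == max_iterations:
                break
            # CM1: W *= (V*/WH) @ H^T / rowsum(H); V*/WH is vnz/m at observed
            # nonzero cells, 1 at held-out cells, 0 elsewhere
            R[nzf] = vnz / mnz
            R[hf] = 1.0
            np.multiply(W, Rm @ Ht, out=W)
            W /= np.maximum(Ht.sum(axis=0), EPS)
            np.maximum(W, EPS, out=W)
            # CM2 against updated W; held-out V* values are the E-step means
            np.matmul(W, Ht.T, out=WH)
            R[nzf] = vnz / np.maximum(WHf[nzf], EPS)
            R[hf] = mh / np.maximum(WHf[hf], EPS)
            np.multiply(Ht, Rm.T @ W, out=Ht)
            Ht /= np.maximum(W.sum(axis=0), EPS)
            np.maximum(Ht, EPS, out=Ht)
        return W, np.ascontiguousarray(Ht.T), path[: t + 1], converged

    def fit(
        self,
        seed: int = 0,
        tol: float = DEFAULT_TOL,
        max_iterations: int = DEFAULT_MAX_ITERATIONS,
        keep_path: bool = False,
    ) -> PoissonNMFResults:
        """Run the ECM algorithm from one random initialization."""
        if tol <= 0:
            raise ValueError("tol must be positive")
        P, N = self.V.shape
        W0, H0 = random_init(P, N, self.rank, seed, self._completed())
        W, H, path, converged = self._loop(W0, H0, tol, max_iterations)
        ll = float(path[-1])
        if not np.isfinite(ll):
            raise FloatingPointError(
                f"non-finite observed log-likelihood at iteration {len(path) - 1}"
            )
        return PoissonNMFResults(
            W=W,
            H=H,
            observed_loglik=ll,
            n_iterations=len(path) - 1,
            converged=converged,
            seed=seed,
            rank=self.rank,
            loglik_path=path if keep_path else None,
            model=self,
        )

    def fit_multistart(
        self,
        n_starts: int = DEFAULT_N_STARTS,
        master_seed: int = 0,
        tol: float = DEFAULT_TOL,
        max_iterations: int = DEFAULT_MAX_ITERATIONS,
        fold_index: int = 0,
        n_jobs: int = 1,
    ) -> PoissonNMFResults:
        """Fit from ``n_starts`` seeds and keep the best observed loglik.

        Per-start seeds derive deterministically from
        (master_seed, fold_index, rank, start_index) via NumPy SeedSequence
        spawning, so the selected fit does not depend on execution order or
        worker count.  Ties go to the lowest start index.
        """
        if n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        seeds = derive_seeds(master_seed, fold_index, self.rank, n_starts)
        self._completed()  # share the median completion across starts

        def one(seed):
            try:
                return self.fit(seed=seed, tol=tol, max_iterations=max_iterations)
            except FloatingPointError:
                return None

        if n_jobs == 1 or n_starts == 1:
            fits = [one(s) for s in seeds]
        else:
            from joblib import Parallel, delayed

            fits = Parallel(n_jobs=n_jobs, backend="threading")(
                delayed(one)(s) for s in seeds
            )
        fits = [f for f in fits if f is not None]
        if not fits:
            raise FloatingPointError("all multistart fits failed numerically")
        best = fits[0]
        for f in fits[1:]:
            if f.observed_loglik > best.observed_loglik:
                best = f
        return best

    def fold_error(self, results: PoissonNMFResults) -> float:
        """KL prediction error on this model's held-out cells."""
        if not self.held.any():
            raise ValueError("model has no held-out cells")
        return kl_divergence(self.V, results.predicted(), self.held)


def derive_seeds(
    master_seed: int, fold_index: int, rank: int, n_starts: int
) -> list[int]:
    """Deterministic per-start seeds, independent of execution order.

    Each seed is a pure function of (master_seed, fold_index, rank,
    start_index); values are kept below 2**31.
    """
    return [
        int(
            np.random.SeedSequence(
                entropy=master_seed, spawn_key=(fold_index, rank, i)
            ).generate_state(1)[0]
            & 0x7FFFFFFF
        )
        for i in range(n_starts)
    ]


def fit_ecm(
    V,
    mask,
    r: int,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    keep_path: bool = False,
) -> PoissonNMFResults:
    """Functional form of :meth:`PoissonNMF.fit`."""
    return PoissonNMF(V, r, mask).fit(
        seed=seed, tol=tol, max_iterations=max_iterations, keep_path=keep_path
    )


def fit_multistart(
    V,
    mask,
    r: int,
    n_starts: int = DEFAULT_N_STARTS,
    master_seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    fold_index: int | None = None,
    n_jobs: int = 1,
) -> PoissonNMFResults:
    """Functional form of :meth:`PoissonNMF.fit_multistart`."""
    if fold_index is None:
        fold_index = mask.fold_index if isinstance(mask, FoldMask) else 0
    return PoissonNMF(V, r, mask).fit_multistart(
        n_starts=n_starts,
        master_seed=master_seed,
        tol=tol,
        max_iterations=max_iterations,
        fold_index=fold_index,
        n_jobs=n_jobs,
    )
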