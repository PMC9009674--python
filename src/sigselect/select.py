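"""Cross-validated selection of the number of mutational signatures.

For each candidate rank r and each balanced fold k, the Poisson NMF is
fitted on the training cells with the fold's cells held out; the fold's
prediction error is the generalized KL divergence between the held-out
counts and the fitted model means on those cells,

    ERR_{r,k} = D_KL(V_heldout | (W·H)_heldout),

and the per-rank curve is ERR_r = sum_k ERR_{r,k}.  Underfitted models
(too few signatures) and overfitted ones (too many) both predict held-out
counts poorly, so the curve is typically U-shaped; the selected rank r* is
its argmin, with ties broken toward the smaller (more parsimonious) rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecm import (
    DEFAULT_MAX_ITERATIONS,
    DEFAULT_N_STARTS,
    DEFAULT_TOL,
    PoissonNMF,
    PoissonNMFResults,
)
from .folds import FoldMask, balanced_folds
from .matrix import MutationTypeMatrix, kl_divergence

__all__ = ["RankSelectionResults", "select_rank", "fold_error", "test_error"]


def fold_error(V, mask: FoldMask, fit: PoissonNMFResults) -> float:
    """KL prediction error of a fitted fold on its held-out cells."""
    if isinstance(V, MutationTypeMatrix):
        V = V.counts
    held = mask.held_out if isinstance(mask, FoldMask) else np.asarray(mask, dtype=bool)
    if held.shape != np.asarray(V).shape:
        raise ValueError("mask does not match the matrix the fit was trained on")
    return kl_divergence(V, fit.predicted(), held)


@dataclass
class RankSelectionResults:
    """Outcome of cross-validated rank selection.

    Attributes
    ----------
    fold_errors : DataFrame
        One row per (rank, fold): prediction error, training error,
        observed loglik, iteration count, convergence flag and seed.
    curve : Series
        ERR_r indexed by rank (sum of per-fold errors).
    selected_rank : int
        Argmin of the curve; ties broken to the smallest rank.
    """

    rank_grid: list[int]
    fold_errors: pd.DataFrame
    curve: pd.Series
    selected_rank: int
    n_folds: int
    messages: list[str] = field(default_factory=list)

    @property
    def training_curve(self) -> pd.Series:
        return self.fold_errors.groupby("rank")["train_error"].sum()

    def summary(self) -> str:
        lines = [
            "Cross-validated signature-number selection",
            f"  ranks evaluated: {self.rank_grid[0]}..{self.rank_grid[-1]}"
            f"  ({self.n_folds}-fold balanced hold-out)",
            f"  selected rank:   {self.selected_rank}",
            "",
            "  rank  validation ERR_r   training error",
        ]
        train = self.training_curve
        for r in self.rank_grid:
            mark = " *" if r == self.selected_rank else ""
            lines.append(f"  {r:4d}  {self.curve[r]:16.2f}  {train[r]:15.2f}{mark}")
        for msg in self.messages:
            lines.append(f"  note: {msg}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Training and validation prediction-error curves vs rank."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ranks = list(self.rank_grid)
        ax.plot(ranks, self.curve.loc[ranks], "o-", color="tab:red", label="validation")
        tw = ax.twinx()
        tw.plot(
            ranks,
            self.training_curve.loc[ranks],
            "s--",
            color="tab:blue",
            label="training",
        )
        ax.axvline(self.selected_rank, color="grey", lw=0.8, ls=":")
        ax.set_xlabel("number of signatures r")
        ax.set_ylabel("validation prediction error ERR_r")
        tw.set_ylabel("training error")
        ax.figure.legend(loc="upper center", ncol=2)
        return ax

    def to_frame(self) -> pd.DataFrame:
        return self.fold_errors.copy()


def argmin_rank(curve: pd.Series) -> int:
    """Rank minimizing the error curve; ties broken to the smallest rank."""
    return int(curve.index[np.argmin(curve.to_numpy())])


def select_rank(
    V,
    r_min: int = 1,
    r_max: int = 10,
    n_folds: int = 10,
    n_starts: int = DEFAULT_N_STARTS,
    master_seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    n_jobs: int = 1,
) -> RankSelectionResults:
    """Select the number of signatures minimizing cross-validated error.

    Runs ``fit_multistart`` for every (rank, fold) pair on the balanced
    hold-out pattern and aggregates held-out KL prediction errors.  Results
    are a deterministic function of the inputs and ``master_seed``,
    independent of execution order.

    Parameters follow the method's defaults: rank grid 1..10, 10 folds,
    300 random starts per fit, tolerance 1e-5, at most 2000 ECM iterations.
    """
    Vmat = V if isinstance(V, MutationTypeMatrix) else MutationTypeMatrix(np.asarray(V))
    P, N = Vmat.shape
    if not (1 <= r_min <= r_max <= min(P, N)):
        raise ValueError(f"rank grid {r_min}..{r_max} invalid for a {P}x{N} matrix")
    masks = balanced_folds(P, N, n_folds)
    grid = list(range(r_min, r_max + 1))
    rows = []
    for r in grid:
        for mask in masks:
            model = PoissonNMF(Vmat, r, mask)
            try:
                fit = model.fit_multistart(
                    n_starts=n_starts,
                    master_seed=master_seed,
                    tol=tol,
                    max_iterations=max_iterations,
                    fold_index=mask.fold_index,
                    n_jobs=n_jobs,
                )
            except FloatingPointError as err:
                raise FloatingPointError(
                    f"fit failed at rank {r}, fold {mask.fold_index}: {err}"
                ) from err
            pred = fit.predicted()
            rows.append(
                {
                    "rank": r,
                    "fold": mask.fold_index,
                    "error": kl_divergence(Vmat.counts, pred, mask.held_out),
                    "train_error": kl_divergence(Vmat.counts, pred, ~mask.held_out),
                    "loglik": fit.observed_loglik,
                    "n_iterations": fit.n_iterations,
                    "converged": fit.converged,
                    "seed": fit.seed,
                }
            )
    fold_df = pd.DataFrame(rows)
    curve = fold_df.groupby("rank")["error"].sum()
    curve = curve.loc[grid]
    selected = argmin_rank(curve)
    messages = []
    if selected == r_max:
        msg = (
            f"selected rank {selected} sits at the top of the grid; "
            "consider increasing r_max"
        )
        messages.append(msg)
        warnings.warn(msg, stacklevel=2)
    return RankSelectionResults(
        rank_grid=grid,
        fold_errors=fold_df,
        curve=curve,
        selected_rank=selected,
        n_folds=n_folds,
        messages=messages,
    )


def test_error(
    V,
    split: tuple[np.ndarray, np.ndarray, np.ndarray],
    r: int,
    n_starts: int = DEFAULT_N_STARTS,
    master_seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    include_validation: bool = True,
    n_jobs: int = 1,
) -> float:
    """KL prediction error on the test cells of a train/validation/test split.

    By default the final model is fitted with training and validation cells
    observed and test cells missing; ``include_validation=False`` holds out
    validation cells as well (the configuration used while choosing r).
    """
    train, val, test = (np.asarray(m, dtype=bool) for m in split)
    if (train & val).any() or (train & test).any() or (val & test).any():
        raise ValueError("split subsets must be pairwise disjoint")
    if not (train | val | test).all():
        raise ValueError("split subsets must cover every cell")
    missing = test if include_validation else (test | val)
    Vmat = V if isinstance(V, MutationTypeMatrix) else MutationTypeMatrix(np.asarray(V))
    fit = PoissonNMF(Vmat, r, missing).fit_multistart(
        n_starts=n_starts,
        master_seed=master_seed,
        tol=tol,
        max_iterations=max_iterations,
        fold_index=0,
        n_jobs=n_jobs,
    )
    return kl_divergence(Vmat.counts, fit.predicted(), test)
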