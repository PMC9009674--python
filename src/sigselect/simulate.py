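"""Synthetic mutation-count generators for benchmarking rank selection.

All generators share the Poisson NMF sampling model: given true profiles W
(unit-sum columns) and activities H, each count is an independent Poisson
draw with mean (W·H)_pn.  Three study designs are built in:

``single``
    One signature, 500 tumors, per-tumor activities uniform on
    [20000, 40000] — a high-burden setting where any second signature found
    is a false positive.
``bootstrap``
    Nine (or any) reference signatures with activity columns resampled by a
    tumor-level bootstrap from a reference activity matrix, 200 tumors;
    correlated signature pairs can be resampled jointly.
``errors``
    Eight signatures covering the six substitution classes, 300 tumors,
    activities uniform on [0, 100] with a fraction zeroed, plus uniform
    "mutation calling error" counts on [0, a·b_n] per cell (b_n the tumor's
    mean per-type true count), at error level a in {0, 0.4, 0.8, 1.2}.

Reference profiles (e.g. COSMIC columns) can be supplied; otherwise seeded
stand-in profiles with the same qualitative structure (spiky vs flat,
distinct dominant substitution classes) are generated, since the selection
mechanism under test does not depend on the specific catalog shapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MutationTypeMatrix, sbs96_labels

__all__ = [
    "SimulationResult",
    "simulate_poisson_nmf",
    "sim_single_signature",
    "sim_bootstrap_activities",
    "sim_with_errors",
    "random_profile",
    "standin_profiles",
]


@dataclass
class SimulationResult:
    """A simulated count matrix together with its generating truth."""

    matrix: MutationTypeMatrix
    profiles: np.ndarray  # P x r, unit columns
    activities: np.ndarray  # r x N
    seed: int
    error_counts: np.ndarray | None = None  # P x N calling-error counts, if any

    @property
    def rank(self) -> int:
        return self.profiles.shape[1]


def _labels(P: int) -> list[str]:
    return sbs96_labels() if P == 96 else [f"type{i + 1}" for i in range(P)]


def simulate_poisson_nmf(
    W, H, seed: int, row_labels=None, col_labels=None
) -> MutationTypeMatrix:
    """Draw a count matrix with independent Poisson cells of mean W·H."""
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(W @ H)
    P, N = counts.shape
    return MutationTypeMatrix(
        counts,
        row_labels if row_labels is not None else _labels(P),
        col_labels if col_labels is not None else [f"tumor{j + 1}" for j in range(N)],
    )


def random_profile(seed: int, concentration: float = 0.1, n_types: int = 96) -> np.ndarray:
    """A seeded stand-in signature profile from a symmetric Dirichlet.

    Small ``concentration`` gives a spiky profile (mass on few mutation
    types), large gives a flat one; the vector is non-negative and sums
    to 1.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.full(n_types, concentration))


def standin_profiles(
    n_signatures: int = 8,
    seed: int = 0,
    n_types: int = 96,
    dominant_weight: float = 0.85,
) -> np.ndarray:
    """Well-separated stand-in profiles with distinct dominant classes.

    Signature j concentrates ``dominant_weight`` of its mass inside one of
    the six 16-type substitution blocks (cycling so that all classes are
    covered, as in a design spanning C>A .. T>G), drawn from a spiky
    Dirichlet; the remainder is a flat-ish Dirichlet over all types.  For
    non-96-type matrices the block structure is adapted to P/6 blocks.
    """
    rng = np.random.default_rng(seed)
    n_blocks = 6 if n_types % 6 == 0 else 1
    block = n_types // n_blocks
    W = np.zeros((n_types, n_signatures))
    for j in range(n_signatures):
        b = j % n_blocks
        spike = rng.dirichlet(np.full(block, 0.3))
        back = rng.dirichlet(np.full(n_types, 2.0))
        W[b * block : (b + 1) * block, j] = dominant_weight * spike
        W[:, j] += (1 - dominant_weight) * back
    return W / W.sum(axis=0)


def sim_single_signature(
    profile: np.ndarray | None = None,
    n_tumors: int = 500,
    activity_range: tuple[float, float] = (20000.0, 40000.0),
    seed: int = 0,
) -> SimulationResult:
    """One-signature design: rank-1 mean structure, high activities.

    Activities are i.i.d. uniform on [20000, 40000] for 500 tumors by
    default.  When no profile is given, a seeded spiky stand-in is used
    (mass dominated by a couple of substitution classes).
    """
    rng = np.random.default_rng(seed)
    if profile is None:
        profile = random_profile(seed=seed + 1, concentration=0.05)
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1:
        raise ValueError("profile must be a vector")
    if not np.isclose(profile.sum(), 1.0, atol=1e-6):
        raise ValueError("profile must sum to 1")
    lo, hi = activity_range
    H = rng.uniform(lo, hi, size=(1, n_tumors))
    W = profile[:, None]
    V = simulate_poisson_nmf(W, H, seed=int(rng.integers(2**31)), row_labels=_labels(len(profile)))
    return SimulationResult(V, W, H, seed)


def sim_bootstrap_activities(
    W_ref,
    H_ref,
    n_tumors: int = 200,
    joint_groups: list[list[int]] | None = None,
    seed: int = 0,
) -> SimulationResult:
    """Bootstrap-activity design: resample tumor activities from a reference.

    Each simulated tumor's activity column is assembled by drawing reference
    tumors uniformly with replacement: signatures listed together in a
    ``joint_groups`` entry copy their activities jointly from one drawn
    tumor (preserving their dependence, e.g. SBS1 with SBS5, SBS2 with
    SBS13), while every remaining signature is resampled independently.
    Counts are then Poisson with mean W_ref · H_boot.
    """
    W_ref = np.asarray(W_ref, dtype=float)
    H_ref = np.asarray(H_ref, dtype=float)
    r, n_ref = H_ref.shape
    if n_ref < 1:
        raise ValueError("reference activity matrix has no tumors")
    if W_ref.shape[1] != r:
        raise ValueError("W_ref and H_ref disagree on the number of signatures")
    joint_groups = joint_groups or []
    grouped = [i for g in joint_groups for i in g]
    if len(grouped) != len(set(grouped)):
        raise ValueError("joint_groups must not overlap")
    singles = [j for j in range(r) if j not in grouped]
    rng = np.random.default_rng(seed)
    H_boot = np.empty((r, n_tumors))
    for t in range(n_tumors):
        for g in joint_groups:
            idx = rng.integers(n_ref)
            H_boot[g, t] = H_ref[g, idx]
        for j in singles:
            H_boot[j, t] = H_ref[j, rng.integers(n_ref)]
    V = simulate_poisson_nmf(
        W_ref, H_boot, seed=int(rng.integers(2**31)), row_labels=_labels(W_ref.shape[0])
    )
    return SimulationResult(V, W_ref, H_boot, seed)


def sim_with_errors(
    profiles: np.ndarray | None = None,
    n_tumors: int = 300,
    error_level: float = 0.0,
    zero_fraction: float = 0.3,
    activity_range: tuple[float, float] = (0.0, 100.0),
    seed: int = 0,
) -> SimulationResult:
    """Calling-error design: low activities, sparsified, plus uniform noise.

    Activities are uniform on [0, 100] with ``zero_fraction`` of entries set
    to zero; error-free counts V0 are Poisson with mean W·H.  For tumor n
    with per-type average true count b_n (the column mean of V0), each cell
    receives an additional error count drawn uniformly on [0, a·b_n] and
    rounded to the nearest integer, where a = ``error_level`` (0 means no
    errors; the study grid is {0, 0.4, 0.8, 1.2}).
    """
    if error_level < 0:
        raise ValueError("error_level must be non-negative")
    rng = np.random.default_rng(seed)
    if profiles is None:
        profiles = standin_profiles(8, seed=seed + 1)
    W = np.asarray(profiles, dtype=float)
    P, r = W.shape
    lo, hi = activity_range
    H = rng.uniform(lo, hi, size=(r, n_tumors))
    H[rng.uniform(size=H.shape) < zero_fraction] = 0.0
    V0 = rng.poisson(W @ H)
    b = V0.mean(axis=0)
    if error_level > 0:
        errors = np.rint(rng.uniform(0.0, error_level * b, size=(P, n_tumors))).astype(
            np.int64
        )
    else:
        errors = np.zeros((P, n_tumors), dtype=np.int64)
    V = MutationTypeMatrix(
        V0 + errors, _labels(P), [f"tumor{j + 1}" for j in range(n_tumors)]
    )
    return SimulationResult(V, W, H, seed, error_counts=errors)
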