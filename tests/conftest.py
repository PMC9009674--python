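import numpy as np
import pytest

from sigselect import MutationTypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_counts(rng):
    """A modest 12x10 random count matrix."""
    return MutationTypeMatrix(rng.poisson(5.0, size=(12, 10)))


def separable_low_rank_matrix(P, N, r, seed, scale=60):
    """A noiseless count matrix whose rank-r factorization is identifiable.

    Each signature dominates its own block of mutation types (separable
    NMF), with integer outer-product components so the matrix is exactly
    rank r.  Suitable for parameter-recovery oracles where the factors,
    not just the fit, must be unique.
    """
    g = np.random.default_rng(seed)
    block = P // r
    col_block = N // (r + 1)
    V = np.zeros((P, N))
    W = np.zeros((P, r))
    H = np.zeros((r, N))
    for j in range(r):
        w = np.zeros(P)
        w[j * block : (j + 1) * block] = np.rint(
            g.dirichlet(np.full(block, 0.5)) * scale
        )
        if w.sum() == 0:
            w[j * block] = 1.0
        h = g.integers(20, 60, size=N).astype(float)
        # tumors where only signature j is active pin down its profile
        for i in range(r):
            if i != j:
                h[i * col_block : (i + 1) * col_block] = 0.0
        V += np.outer(w, h)
        W[:, j] = w / w.sum()
        H[j] = h * w.sum()
    return MutationTypeMatrix(V), W, H


def exact_low_rank_matrix(P, N, r, seed, scale=40):
    """A noiseless count matrix with exact rank-r structure.

    Each component is an outer product of integer vectors, so the sum is an
    integer matrix of rank at most r with no sampling noise.  Returns the
    matrix together with the true (normalized) profiles and activities.
    """
    g = np.random.default_rng(seed)
    V = np.zeros((P, N))
    W = np.zeros((P, r))
    H = np.zeros((r, N))
    for j in range(r):
        w = np.rint(g.dirichlet(np.full(P, 0.3)) * scale)
        if w.sum() == 0:
            w[g.integers(P)] = 1.0
        h = g.integers(20, 60, size=N).astype(float)
        V += np.outer(w, h)
        W[:, j] = w / w.sum()
        H[j] = h * w.sum()
    return MutationTypeMatrix(V), W, H
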