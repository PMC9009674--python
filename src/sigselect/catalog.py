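"""Signature extraction at a fixed rank and reference-catalog annotation.

After the number of signatures r* has been chosen, profiles and activities
are extracted by maximizing the Poisson NMF likelihood on the *full* count
matrix (no held-out cells) with multistart ECM.  De novo profiles are then
annotated against a reference catalog (e.g. COSMIC SBS profiles) by cosine
similarity; a de novo signature is considered matched when its best cosine
similarity exceeds a threshold (0.8 by default, 0.9 as a stringent
alternative).  Matching is a per-signature argmax — several de novo
signatures may legitimately map to the same catalog entry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ecm import DEFAULT_MAX_ITERATIONS, DEFAULT_N_STARTS, DEFAULT_TOL, PoissonNMF
from .matrix import MutationTypeMatrix

__all__ = [
    "SignatureCatalog",
    "cosine_similarity",
    "match_to_catalog",
    "extract_signatures",
]

DEFAULT_COSINE_THRESHOLD = 0.8
STRINGENT_COSINE_THRESHOLD = 0.9


def cosine_similarity(u, v) -> float:
    """Cosine similarity of two non-negative profiles; 1 is a perfect match.

    Invariant to positive rescaling of either argument, hence insensitive to
    whether profiles are normalized.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(u @ v / (nu * nv))


@dataclass
class SignatureCatalog:
    """Reference signature profiles (P types × S signatures, unit columns)."""

    profiles: pd.DataFrame  # index: mutation-type labels, columns: signature ids

    def __post_init__(self) -> None:
        if (self.profiles.to_numpy() < 0).any():
            raise ValueError("catalog profiles must be non-negative")
        sums = self.profiles.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            self.profiles = self.profiles / sums

    @property
    def signature_ids(self) -> list[str]:
        return list(self.profiles.columns)

    @classmethod
    def from_tsv(cls, path) -> "SignatureCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def aligned_to(self, row_labels) -> pd.DataFrame:
        """Profiles reordered to match the analyzed matrix's row labels."""
        missing = set(row_labels) - set(self.profiles.index)
        extra = set(self.profiles.index) - set(row_labels)
        if missing or extra:
            raise ValueError(
                "catalog mutation types do not match the matrix: "
                f"missing {sorted(missing)[:5]}, unexpected {sorted(extra)[:5]}"
            )
        return self.profiles.loc[list(row_labels)]


def match_to_catalog(
    W,
    catalog: SignatureCatalog,
    threshold: float = DEFAULT_COSINE_THRESHOLD,
    row_labels=None,
) -> pd.DataFrame:
    """Annotate de novo signatures with their closest catalog entries.

    Parameters
    ----------
    W : DataFrame or ndarray
        De novo profiles, P×r.  If a DataFrame, its index must carry the
        mutation-type labels used to align the catalog.
    threshold : float
        A signature is flagged matched when best cosine > threshold;
        unmatched signatures are candidate novel signatures.

    Returns
    -------
    DataFrame with columns (de_novo, best_match, cosine, matched), one row
    per de novo signature.
    """
    if isinstance(W, pd.DataFrame):
        labels = list(W.index)
        names = list(W.columns)
        Wv = W.to_numpy(dtype=float)
    else:
        Wv = np.asarray(W, dtype=float)
        labels = row_labels
        names = [f"denovo{j + 1}" for j in range(Wv.shape[1])]
    ref = (
        catalog.aligned_to(labels).to_numpy(dtype=float)
        if labels is not None
        else catalog.profiles.to_numpy(dtype=float)
    )
    if ref.shape[0] != Wv.shape[0]:
        raise ValueError("catalog and profiles have different numbers of types")
    ids = catalog.signature_ids
    rows = []
    for j, name in enumerate(names):
        sims = np.array([cosine_similarity(Wv[:, j], ref[:, s]) for s in range(len(ids))])
        best = int(np.argmax(sims))
        rows.append(
            {
                "de_novo": name,
                "best_match": ids[best],
                "cosine": float(sims[best]),
                "matched": bool(sims[best] > threshold),
            }
        )
    return pd.DataFrame(rows)


def extract_signatures(
    V,
    r_star: int,
    n_starts: int = DEFAULT_N_STARTS,
    master_seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    n_jobs: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract profiles and activities at the selected rank.

    Multistart ECM on the full matrix (no missing cells), keeping the
    best-likelihood fit; output is normalized (profile columns sum to 1,
    activities on the count scale) and ordered by descending total activity.

    Returns
    -------
    (W, H) : DataFrames of shape (P, r*) and (r*, N), with signatures named
    S1..S{r*} in activity order.
    """
    Vmat = V if isinstance(V, MutationTypeMatrix) else MutationTypeMatrix(np.asarray(V))
    fit = PoissonNMF(Vmat, r_star, mask=None).fit_multistart(
        n_starts=n_starts,
        master_seed=master_seed,
        tol=tol,
        max_iterations=max_iterations,
        fold_index=0,
        n_jobs=n_jobs,
    )
    W, H = fit.normalized()
    order = np.argsort(-H.sum(axis=1), kind="stable")
    W = W[:, order]
    H = H[order]
    names = [f"S{j + 1}" for j in range(r_star)]
    Wdf = pd.DataFrame(W, index=pd.Index(Vmat.row_labels, name="mutation_type"), columns=names)
    Hdf = pd.DataFrame(H, index=pd.Index(names, name="signature"), columns=Vmat.col_labels)
    return Wdf, Hdf
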