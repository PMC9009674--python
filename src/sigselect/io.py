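"""Readers and writers for the on-disk tab-delimited formats.

Count matrix format: first column holds the mutation-type label, the header
row holds sample IDs, remaining cells are integer counts.  SBS96 labels in
either the bracket dialect ``A[C>A]A`` or the triplet dialect ``ACA>AAA``
are accepted; the latter is normalized to the bracket form on load.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .catalog import SignatureCatalog
from .matrix import MutationTypeMatrix

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_catalog",
    "normalize_sbs_label",
    "write_rank_report",
]

_BRACKET = re.compile(r"^[ACGT]\[[ACGT]>[ACGT]\][ACGT]$")
_TRIPLET = re.compile(r"^([ACGT])([ACGT])([ACGT])>([ACGT])([ACGT])([ACGT])$")


def normalize_sbs_label(label: str) -> str:
    """Normalize an SBS96 label to the bracket dialect ``A[C>A]A``.

    Accepts the bracket dialect unchanged and converts the triplet dialect
    ``ACA>AAA`` (matching flanks, substituted middle base).  Any other label
    is returned as-is — arbitrary mutation-type alphabets (e.g. 83 INDEL
    classes) are allowed.
    """
    label = label.strip()
    if _BRACKET.match(label):
        return label
    m = _TRIPLET.match(label)
    if m:
        f5, ref, f3, a5, alt, a3 = m.groups()
        if f5 != a5 or f3 != a3:
            raise ValueError(f"inconsistent flanking bases in SBS label {label!r}")
        if ref == alt:
            raise ValueError(f"reference and alternate base identical in {label!r}")
        return f"{f5}[{ref}>{alt}]{f3}"
    return label


def read_matrix(path) -> MutationTypeMatrix:
    """Read a tab-delimited mutation-type count matrix.

    Raises ValueError naming the offending cell or line for negative or
    non-integer counts, duplicate labels, or ragged rows.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as err:
        raise ValueError(f"{path}: malformed table: {err}") from err
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if not all(df.dtypes.apply(pd.api.types.is_numeric_dtype)):
        bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
        raise ValueError(f"{path}: non-numeric counts in column(s) {bad}")
    df.index = [normalize_sbs_label(str(x)) for x in df.index]
    return MutationTypeMatrix.from_dataframe(df)


def write_matrix(V: MutationTypeMatrix, path) -> None:
    V.to_dataframe().to_csv(path, sep="\t")


def read_catalog(path) -> SignatureCatalog:
    """Read a COSMIC-style reference catalog (type label + one column per
    signature), normalizing SBS label dialects."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = [normalize_sbs_label(str(x)) for x in df.index]
    return SignatureCatalog(df)


def write_rank_report(results, prefix) -> None:
    """Write per-fold errors and the summary curve for a rank selection."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    results.fold_errors.to_csv(f"{prefix}_folds.tsv", sep="\t", index=False)
    curve = results.curve.rename("err").to_frame()
    curve["train_error"] = results.training_curve
    curve["selected"] = curve.index == results.selected_rank
    curve.to_csv(f"{prefix}_curve.tsv", sep="\t")
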