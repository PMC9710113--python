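"""Delimited-text input/output for expression matrices, score matrices,
edge lists and TF lists.

All artifacts are plain TSV/CSV (delimiter autodetected from the file
extension: .csv comma, everything else tab) with identifier headers.
Reads are strict: ragged rows, non-numeric cells and duplicate gene
identifiers are rejected with the offending location named.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "read_expression", "write_expression",
    "read_score_matrix", "write_score_matrix",
    "read_edge_list", "write_edge_list", "read_tf_list",
]


@dataclass
class ExpressionMatrix:
    """Observations x genes real matrix with sample and gene identifiers."""

    values: np.ndarray
    sample_ids: list
    gene_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        M, G = self.values.shape
        if len(self.sample_ids) != M or len(self.gene_ids) != G:
            raise ValueError("identifier lengths do not match matrix shape")
        if len(set(self.gene_ids)) != G:
            dupes = {g for g in self.gene_ids if self.gene_ids.count(g) > 1}
            raise ValueError(f"duplicate gene identifiers: {sorted(dupes)[:5]}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at sample {self.sample_ids[bad[0]]!r}, "
                f"gene {self.gene_ids[bad[1]]!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       orientation: str = "samples_by_genes") -> "ExpressionMatrix":
        if orientation == "genes_by_samples":
            df = df.T
        elif orientation != "samples_by_genes":
            raise ValueError(f"unknown orientation {orientation!r}")
        return cls(values=df.to_numpy(dtype=float),
                   sample_ids=list(df.index.astype(str)),
                   gene_ids=list(df.columns.astype(str)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.gene_ids)


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        dupes = sorted({g for g in header if header.count(g) > 1})
        raise ValueError(f"{path}: duplicate column identifiers: {dupes[:5]}")
    # round_trip parser: the default fast parser can be off by one ulp,
    # which would break bitwise write-read round trips
    df = pd.read_csv(path, sep=sep, index_col=0,
                     float_precision="round_trip")
    # strict numeric conversion with the offending cell named
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = df.index[(bad | df[col].isna()).to_numpy().argmax()]
            raise ValueError(
                f"{path}: non-numeric or missing cell at row {row!r}, "
                f"column {col!r}")
        df[col] = converted
    return df


def read_expression(path, orientation: str = "samples_by_genes") -> ExpressionMatrix:
    """Read a delimited expression table, normalizing to samples x genes."""
    df = _read_table(path)
    return ExpressionMatrix.from_dataframe(df, orientation=orientation)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.to_dataframe().to_csv(path, sep=_sep_for(path), float_format="%.17g")


def write_score_matrix(S, path) -> None:
    """Write a square score matrix with gene identifiers on both axes.

    Full printed precision (17 significant digits) so write-read
    round-trips are exact.
    """
    S.to_dataframe().to_csv(path, sep=_sep_for(path), float_format="%.17g")


def read_score_matrix(path):
    """Read a square score matrix; warn (not fail) on out-of-range values."""
    from .engine import ScoreMatrix

    df = _read_table(path)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: score matrix must be square, got {df.shape}")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"{path}: row labels do not match column headers")
    vals = df.to_numpy(dtype=float)
    if vals.min() < 0 or vals.max() > 1:
        warnings.warn(f"{path}: score values outside [0, 1] "
                      "(foreign score matrix accepted)")
    return ScoreMatrix(S=vals, gene_ids=list(df.index.astype(str)))


def read_edge_list(path):
    """Read a 2- or 3-column (regulator, target[, weight]) edge list.

    Returns a GRNetwork over the genes appearing in the list.  A missing
    third column defaults every weight to +1.
    """
    from .simulate import GRNetwork

    df = pd.read_csv(path, sep=_sep_for(path), header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: edge list needs at least 2 columns")
    regs = df.iloc[:, 0].astype(str)
    tgts = df.iloc[:, 1].astype(str)
    if df.shape[1] >= 3:
        w = pd.to_numeric(df.iloc[:, 2], errors="coerce").fillna(1.0)
    else:
        w = pd.Series(1.0, index=df.index)
    genes = sorted(set(regs) | set(tgts))
    edges = [(r, t, float(wi)) for r, t, wi in zip(regs, tgts, w) if r != t]
    return GRNetwork(gene_ids=genes, edges=edges)


def write_edge_list(net, path, signed: bool = True) -> None:
    net.to_edge_frame(signed=signed).to_csv(path, sep=_sep_for(path),
                                            header=False, index=False)


def read_tf_list(path) -> list:
    """One transcription-factor identifier per line."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
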