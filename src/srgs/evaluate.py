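"""Network evaluation: ranked edge lists and cutoff-sweep AUROC/AUPR.

The inferred score matrix is converted to a ranked list of all ordered
gene pairs (self-loops excluded).  Positives are the ground-truth
edges inside the evaluated universe; every other ordered pair is a
negative.  AUROC uses trapezoidal credit (ties counted half); AUPR uses
the step-wise interpolation in which precision is held between recall
points.  Optionally only edges outgoing from known transcription
factors are evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "RankedEdgeList", "EvalResult",
    "scores_to_edges", "restrict_to_tf_outgoing", "auroc_aupr",
    "bonferroni_top_genes",
]


@dataclass
class RankedEdgeList:
    """Scored directed edges (regulator, target, score); no self-loops."""

    entries: list

    def __post_init__(self):
        seen = set()
        for reg, tgt, s in self.entries:
            if reg == tgt:
                raise ValueError(f"self-loop edge {reg}->{tgt}")
            if (reg, tgt) in seen:
                raise ValueError(f"duplicate edge {reg}->{tgt}")
            if not np.isfinite(s):
                raise ValueError(f"non-finite score on {reg}->{tgt}")
            seen.add((reg, tgt))

    def __len__(self):
        return len(self.entries)

    def genes(self) -> set:
        out = set()
        for reg, tgt, _ in self.entries:
            out.add(reg)
            out.add(tgt)
        return out

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.entries,
                            columns=["regulator", "target", "score"])


@dataclass
class EvalResult:
    auroc: float
    aupr: float
    n_pos: int
    n_neg: int


def scores_to_edges(S) -> RankedEdgeList:
    """All G*(G-1) ordered pairs of a score matrix as scored edges.

    Row = target convention: the score of gene_j -> gene_i is S[i, j].
    Diagonal (self-loop) entries never appear.
    """
    genes = list(S.gene_ids)
    G = len(genes)
    entries = []
    for i in range(G):
        for j in range(G):
            if i == j:
                continue
            entries.append((genes[j], genes[i], float(S.S[i, j])))
    return RankedEdgeList(entries=entries)


def restrict_to_tf_outgoing(edges: RankedEdgeList, tf_ids) -> RankedEdgeList:
    """Keep only edges whose regulator is a known transcription factor."""
    tf_ids = set(tf_ids)
    if not tf_ids:
        raise ValueError("tf_ids must be non-empty")
    return RankedEdgeList(
        entries=[e for e in edges.entries if e[0] in tf_ids])


def auroc_aupr(edges: RankedEdgeList, truth) -> EvalResult:
    """Cutoff-sweep AUROC and AUPR of a ranked edge list against truth.

    The evaluated universe is exactly the ordered pairs present in
    ``edges``; ground-truth edges outside it (e.g. endpoints absent from
    the expression matrix, or regulators dropped by a TF restriction)
    are unreachable and therefore ignored.
    """
    if len(edges) == 0:
        raise ValueError("empty edge list")
    true_edges = truth.edge_set() if hasattr(truth, "edge_set") else set(truth)
    scores = np.array([s for _, _, s in edges.entries], dtype=float)
    labels = np.array([(r, t) in true_edges for r, t, _ in edges.entries],
                      dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"undefined metric: {n_pos} positives and {n_neg} negatives "
            "in the evaluated universe")
    auroc = float(roc_auc_score(labels, scores))
    aupr = float(average_precision_score(labels, scores))
    return EvalResult(auroc=auroc, aupr=aupr, n_pos=n_pos, n_neg=n_neg)


def bonferroni_top_genes(variances, pvalues, top_n: int = 500,
                         alpha: float = 0.01) -> list:
    """Top-variable-gene preselection with Bonferroni-corrected P-values.

    ``variances`` and ``pvalues`` are mappings or Series aligned on gene
    identifiers.  Corrected P = min(1, p * n_genes); genes passing
    corrected P < alpha are ranked by variance (descending) and the top
    ``top_n`` returned (fewer if not enough pass).
    """
    import pandas as pd

    if top_n <= 0:
        raise ValueError("top_n must be positive")
    var = pd.Series(variances, dtype=float)
    pv = pd.Series(pvalues, dtype=float)
    if set(var.index) != set(pv.index):
        raise ValueError("variances and pvalues must cover the same genes")
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("P-values must lie in [0, 1]")
    n = len(pv)
    corrected = (pv * n).clip(upper=1.0)
    passed = var[corrected.reindex(var.index) < alpha]
    return list(passed.sort_values(ascending=False).index[:top_n])
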