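"""Model/Results interface over the SRGS engine.

Follows the familiar fit-object idiom: build an :class:`SRGS` model
from an expression matrix (or DataFrame), call :meth:`SRGS.fit`, and
work with the returned :class:`SRGSResults` — the directed score
matrix, the ranked edge list, evaluation against a ground-truth
network, and a text summary.
"""

from __future__ import annotations

from dataclasses import asdict, replace

import numpy as np
import pandas as pd

from .engine import ScoreMatrix, SRGSConfig, srgs_infer, tune_p
from .evaluate import auroc_aupr, restrict_to_tf_outgoing, scores_to_edges
from .io import ExpressionMatrix

__all__ = ["SRGS", "SRGSResults"]


class SRGS:
    """SPLS-based recursive gene selection over an expression matrix.

    Parameters
    ----------
    expr : ExpressionMatrix
        Observations (samples/cells) x genes.
    config : SRGSConfig, optional
        Hyperparameters; keyword overrides may be passed directly
        (e.g. ``SRGS(expr, dropout=True, p=0.6, seed=1)``).

    Examples
    --------
    >>> model = SRGS.from_dataframe(df, seed=0)
    >>> res = model.fit()
    >>> res.evaluate(truth).auroc
    """

    def __init__(self, expr: ExpressionMatrix, config: SRGSConfig | None = None,
                 **overrides):
        if config is None:
            config = SRGSConfig()
        if overrides:
            config = replace(config, **overrides)
        self.expr = expr
        self.config = config

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       orientation: str = "samples_by_genes",
                       config: SRGSConfig | None = None, **overrides) -> "SRGS":
        expr = ExpressionMatrix.from_dataframe(df, orientation=orientation)
        return cls(expr, config=config, **overrides)

    def fit(self, n_workers: int | None = None) -> "SRGSResults":
        """Run the per-target lambda-sweep and return the fitted results."""
        cfg = self.config
        if n_workers is not None:
            cfg = replace(cfg, n_workers=n_workers)
        scores = srgs_infer(self.expr, cfg)
        return SRGSResults(model=self, config=cfg, scores=scores)

    def tune_p(self, truth, p_grid=None, repeats: int = 10):
        """Mean-AUROC selection of the Bernoulli keep-probability p."""
        return tune_p(self.expr, truth, self.config, p_grid=p_grid,
                      repeats=repeats)


class SRGSResults:
    """Fitted SRGS run: score matrix plus evaluation and export helpers."""

    def __init__(self, model: SRGS, config: SRGSConfig, scores: ScoreMatrix):
        self.model = model
        self.config = config
        self.scores = scores

    @property
    def score_frame(self) -> pd.DataFrame:
        """Score matrix as a DataFrame (rows = targets, columns = regulators)."""
        return self.scores.to_dataframe()

    def to_edges(self, tf_ids=None):
        """Ranked directed edge list; optionally TF-outgoing only."""
        edges = scores_to_edges(self.scores)
        if tf_ids is not None:
            edges = restrict_to_tf_outgoing(edges, tf_ids)
        return edges

    def top_edges(self, n: int = 10, tf_ids=None) -> pd.DataFrame:
        df = self.to_edges(tf_ids=tf_ids).to_frame()
        return df.sort_values("score", ascending=False,
                              kind="stable").head(n).reset_index(drop=True)

    def evaluate(self, truth, tf_ids=None):
        """AUROC/AUPR of the ranked edges against a ground-truth network."""
        return auroc_aupr(self.to_edges(tf_ids=tf_ids), truth)

    def summary(self, truth=None, top: int = 10) -> str:
        cfg = self.config
        G = len(self.scores.gene_ids)
        M = self.model.expr.n_samples
        lines = [
            "SRGS network inference results",
            "=" * 46,
            f"genes: {G}    observations: {M}",
            f"K={cfg.K}  lambda grid=[{cfg.lam_min:g}, {cfg.lam_max:g}] "
            f"step {cfg.lam_step:g}",
            f"dropout mode: {'on (p=%g, iter=%d)' % (cfg.p, cfg.iter) if cfg.dropout else 'off'}",
            f"seed: {cfg.seed}",
        ]
        if truth is not None:
            res = self.evaluate(truth)
            lines.append(f"AUROC: {res.auroc:.4f}    AUPR: {res.aupr:.4f} "
                         f"({res.n_pos} positives / {res.n_neg} negatives)")
        lines.append("-" * 46)
        lines.append(f"top {top} edges (regulator -> target, score):")
        for _, row in self.top_edges(top).iterrows():
            lines.append(f"  {row.regulator:>8s} -> {row.target:<8s} "
                         f"{row.score:.4f}")
        return "\n".join(lines)

    def manifest(self) -> dict:
        """Config record sufficient to reproduce this score matrix bitwise."""
        return dict(asdict(self.config))

    def plot_scores(self, ax=None):
        """Heatmap of the directed score matrix (rows = targets)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(self.scores.S, cmap="viridis", vmin=0, vmax=1)
        ax.set_xlabel("regulator")
        ax.set_ylabel("target")
        ticks = np.arange(len(self.scores.gene_ids))
        if len(ticks) <= 30:
            ax.set_xticks(ticks, self.scores.gene_ids, rotation=90, fontsize=6)
            ax.set_yticks(ticks, self.scores.gene_ids, fontsize=6)
        ax.figure.colorbar(im, ax=ax, label="score")
        return ax
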