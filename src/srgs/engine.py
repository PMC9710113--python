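"""The SRGS procedure: per-target recursive lambda-sweep scoring.

For each target gene i the expression of every other gene forms the
predictor matrix X and the target's expression the response y.  The
SPLS sparsity parameter lambda is swept over a grid (default 0.01 to
0.99 in steps of 0.01); at each lambda the genes selected by SPLS get
their score incremented by one, provided the selection is informative
(more than zero but fewer than all d candidates).  Cumulative scores
are min-max normalized into row i of a directed G x G score matrix:
entry S[i, j] scores the edge gene_j -> gene_i.

Dropout-robust mode builds ``iter`` masked copies of the data per
target: samples are jointly permuted, each X entry is kept with
Bernoulli probability p (zeroed otherwise; y is never masked), and the
selection counts accumulate across all copies before the single
normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from joblib import Parallel, delayed

from .spls import standardize, spls_fit

logger = logging.getLogger(__name__)

__all__ = [
    "SRGSConfig", "ScoreMatrix", "RawScoreVector",
    "lambda_grid", "minmax_normalize", "score_target",
    "dropout_iteration", "srgs_infer", "tune_p",
]


@dataclass(frozen=True)
class SRGSConfig:
    """Full hyperparameter record for one SRGS run.

    Attributes
    ----------
    K : int
        Number of SPLS latent components (default 1, the tuned optimum).
    lam_min, lam_max, lam_step : float
        Sparsity-parameter grid, default 0.01..0.99 step 0.01 (99 values).
    dropout : bool
        Enable the multi-copy masked/permuted robustness mode.
    p : float
        Bernoulli keep-probability for X entries in dropout mode; p = 1
        keeps everything (no multiple datasets in effect).
    iter : int
        Number of masked copies accumulated per target in dropout mode.
    seed : int
        Base seed; per-(target, iteration) streams are derived from it.
    scale : bool
        Unit-scale predictor columns before SPLS (default on).
    n_workers : int
        Parallel workers over target genes; results are worker-invariant.
    """

    K: int = 1
    lam_min: float = 0.01
    lam_max: float = 0.99
    lam_step: float = 0.01
    dropout: bool = False
    p: float = 1.0
    iter: int = 10
    seed: int = 0
    scale: bool = True
    n_workers: int = 1

    def __post_init__(self):
        if not (0 < self.lam_min <= self.lam_max < 1):
            raise ValueError("require 0 < lam_min <= lam_max < 1")
        if self.lam_step <= 0:
            raise ValueError("lam_step must be positive")
        if self.K < 1 or self.iter < 1 or self.n_workers < 1:
            raise ValueError("K, iter and n_workers must be positive")
        if self.dropout and not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


@dataclass
class ScoreMatrix:
    """Directed score matrix: S[i, j] in [0, 1] scores gene_j -> gene_i."""

    S: np.ndarray
    gene_ids: list

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        G = len(self.gene_ids)
        if self.S.shape != (G, G):
            raise ValueError("score matrix must be square over gene_ids")

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.S, index=self.gene_ids, columns=self.gene_ids)


@dataclass
class RawScoreVector:
    """Un-normalized cumulative selection counts for one target gene."""

    counts: np.ndarray
    target_id: object = None


def lambda_grid(cfg: SRGSConfig) -> np.ndarray:
    """Arithmetic lambda sequence lam_min, lam_min+step, ... <= lam_max.

    The upper endpoint is included when the step divides the range
    (within 1e-9 to absorb floating drift).
    """
    n = int(np.floor((cfg.lam_max - cfg.lam_min) / cfg.lam_step + 1e-9)) + 1
    grid = cfg.lam_min + cfg.lam_step * np.arange(n)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    return grid


def minmax_normalize(v) -> np.ndarray:
    """Rescale to [0, 1] via (v - min) / (max - min).

    A constant vector carries no ranking information and maps to all
    zeros rather than dividing by zero.
    """
    counts = np.asarray(v.counts if isinstance(v, RawScoreVector) else v, dtype=float)
    lo, hi = counts.min(), counts.max()
    if hi == lo:
        return np.zeros_like(counts)
    return (counts - lo) / (hi - lo)


def score_target(X_cand: np.ndarray, y_target: np.ndarray,
                 cfg: SRGSConfig, target_id=None) -> RawScoreVector:
    """Sweep the lambda grid once over (X_cand, y_target).

    For each lambda, fit SPLS and — when 0 < |active| < d — add one to
    the count of each selected candidate.  A constant response yields
    all-zero counts with a logged warning and no fit attempt.
    """
    X_cand = np.asarray(X_cand, dtype=float)
    y_target = np.asarray(y_target, dtype=float).ravel()
    d = X_cand.shape[1]
    counts = np.zeros(d)
    if np.all(y_target == y_target[0]):
        logger.warning("target %s has constant expression; scores left at zero",
                       target_id)
        return RawScoreVector(counts=counts, target_id=target_id)

    data = standardize(X_cand, y_target, scale=cfg.scale)
    grid = lambda_grid(cfg)
    if cfg.K == 1:
        # K=1 active set is the support of the thresholded covariance
        # vector, so one matvec serves the whole grid.
        Z = data.X.T @ data.y
        Z[data.degenerate] = 0.0
        absZ = np.abs(Z)
        zmax = absZ.max()
        if zmax > 0.0:
            for lam in grid:
                sel = absZ >= lam * zmax
                nsel = int(sel.sum())
                if 0 < nsel < d:
                    counts[sel] += 1.0
    else:
        for lam in grid:
            fit = spls_fit(data, K=cfg.K, lam=lam)
            nsel = len(fit.active)
            if 0 < nsel < d:
                counts[sorted(fit.active)] += 1.0
    return RawScoreVector(counts=counts, target_id=target_id)


def dropout_iteration(X_cand: np.ndarray, y_target: np.ndarray,
                      cfg: SRGSConfig, iteration_seed,
                      target_id=None) -> RawScoreVector:
    """One masked/permuted copy of the data, scored with score_target.

    Rows of X_cand and y_target are permuted jointly (sample pairing is
    preserved); an independent Bernoulli(p) keep-mask zeroes X entries
    (never y).  Deterministic given iteration_seed.
    """
    rng = np.random.default_rng(iteration_seed)
    X_cand = np.asarray(X_cand, dtype=float)
    y_target = np.asarray(y_target, dtype=float).ravel()
    M, d = X_cand.shape
    perm = rng.permutation(M)
    Xp = X_cand[perm]
    yp = y_target[perm]
    if cfg.p < 1.0:
        keep = rng.random((M, d)) < cfg.p
        Xp = np.where(keep, Xp, 0.0)
        if cfg.p == 0.0:
            logger.warning("p=0 zeroes the whole predictor matrix")
    return score_target(Xp, yp, cfg, target_id=target_id)


def _seed_for(base_seed: int, target_idx: int, iteration: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=base_seed,
                                  spawn_key=(target_idx, iteration))


def _score_one_target(values: np.ndarray, i: int, cfg: SRGSConfig,
                      gene_ids) -> np.ndarray:
    mask = np.arange(values.shape[1]) != i
    X_cand = values[:, mask]
    y = values[:, i]
    if cfg.dropout:
        counts = np.zeros(X_cand.shape[1])
        for it in range(cfg.iter):
            rv = dropout_iteration(X_cand, y, cfg, _seed_for(cfg.seed, i, it),
                                   target_id=gene_ids[i])
            counts += rv.counts
    else:
        counts = score_target(X_cand, y, cfg, target_id=gene_ids[i]).counts
    row = np.zeros(values.shape[1])
    row[mask] = minmax_normalize(RawScoreVector(counts))
    return row


def srgs_infer(expr, cfg: SRGSConfig = SRGSConfig()) -> ScoreMatrix:
    """Run SRGS over every target gene and assemble the score matrix.

    ``expr`` is an :class:`srgs.io.ExpressionMatrix` (or anything with
    ``values`` (M x G) and ``gene_ids``).  Row i of the result holds the
    min-max normalized cumulative scores of all candidate regulators of
    gene i; the diagonal is zero.  Output is invariant to ``n_workers``.
    """
    values = np.asarray(expr.values, dtype=float)
    gene_ids = list(expr.gene_ids)
    G = len(gene_ids)
    if len(set(gene_ids)) != G:
        raise ValueError("duplicated gene identifiers")
    if G < 3:
        raise ValueError(f"need at least 3 genes, got {G}")
    if values.shape[0] < 2:
        raise ValueError("need at least 2 observations")

    if cfg.n_workers > 1:
        rows = Parallel(n_jobs=cfg.n_workers)(
            delayed(_score_one_target)(values, i, cfg, gene_ids) for i in range(G)
        )
    else:
        rows = [_score_one_target(values, i, cfg, gene_ids) for i in range(G)]
    return ScoreMatrix(S=np.vstack(rows), gene_ids=gene_ids)


def tune_p(expr, truth, cfg: SRGSConfig, p_grid=None, repeats: int = 10):
    """Select the Bernoulli keep-probability p by mean AUROC against truth.

    Each p in the grid (default 0.1..1.0 step 0.1) is run ``repeats``
    times with distinct derived seeds; the mean AUROC profile and the
    argmax p (ties broken toward smaller p) are returned.
    """
    from .evaluate import auroc_aupr, scores_to_edges

    if p_grid is None:
        p_grid = np.round(np.arange(0.1, 1.01, 0.1), 10)
    p_grid = list(p_grid)
    profile = {}
    for pi, p in enumerate(p_grid):
        aurocs = []
        for r in range(repeats):
            seed = int(np.random.SeedSequence(
                entropy=cfg.seed, spawn_key=(10_000 + pi, r)
            ).generate_state(1)[0] % (2**31))
            cfg_r = replace(cfg, dropout=True, p=float(p), seed=seed)
            S = srgs_infer(expr, cfg_r)
            res = auroc_aupr(scores_to_edges(S), truth)
            aurocs.append(res.auroc)
        profile[float(p)] = float(np.mean(aurocs))
    best_p = min(profile, key=lambda p: (-profile[p], p))
    return best_p, profile
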