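"""Sparse partial least squares (SPLS) regression with a single response.

PLS decomposes a predictor matrix X (M observations x D genes) and a
response y into latent components chosen to maximise the covariance
between predictor and response scores.  The sparse variant thresholds
each direction vector against a fraction ``lam`` of its largest absolute
entry, so only the strongest predictors enter the model; ``lam`` close
to 1 keeps almost nothing, ``lam`` close to 0 keeps almost everything.

For K = 1 (the default used throughout the network-inference engine)
the selected set has a closed form: the support of the soft-thresholded
covariance vector Z = X'y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StandardizedData",
    "SPLSFit",
    "standardize",
    "sparse_direction",
    "spls_fit",
    "DegenerateDirectionError",
]


class DegenerateDirectionError(ValueError):
    """Raised when the covariance direction Z = X'y is identically zero."""


@dataclass
class StandardizedData:
    """Centered (optionally unit-scaled) predictors and centered response.

    Zero-variance predictor columns are mapped to all-zero columns and
    recorded in ``degenerate``; they can never be selected downstream.
    """

    X: np.ndarray
    y: np.ndarray
    col_means: np.ndarray
    col_scales: np.ndarray
    y_mean: float
    degenerate: np.ndarray = field(default=None)  # boolean mask, True = zero variance

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_pred(self) -> int:
        return self.X.shape[1]


@dataclass
class SPLSFit:
    """Result of one SPLS regression.

    ``active`` is the set of selected predictor indices; ``beta`` is the
    coefficient vector on the standardized scale with zeros off-support.
    """

    active: frozenset
    W: np.ndarray         # D x K sparse direction matrix
    T_scores: np.ndarray  # M x K latent scores
    P_load: np.ndarray    # D x K predictor loadings
    q_load: np.ndarray    # length-K response loadings
    beta: np.ndarray      # length-D coefficients (standardized scale)
    lam: float
    K: int

    @property
    def is_empty(self) -> bool:
        return len(self.active) == 0


def standardize(X, y, scale: bool = True) -> StandardizedData:
    """Center predictor columns and the response; optionally unit-scale X.

    Parameters
    ----------
    X : (M, D) array_like
        Raw predictor matrix, M >= 2 observations.
    y : (M,) array_like
        Raw response vector.
    scale : bool
        If True, divide each predictor column by its sample standard
        deviation (ddof=1).  Zero-variance columns become all-zero and
        are flagged degenerate either way.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    M, D = X.shape
    if M < 2:
        raise ValueError(f"need at least 2 observations, got {M}")
    if y.shape[0] != M:
        raise ValueError("X and y have incompatible numbers of observations")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("X and y must be finite")

    col_means = X.mean(axis=0)
    Xc = X - col_means
    sd = X.std(axis=0, ddof=1)
    degenerate = sd == 0.0
    if scale:
        col_scales = np.where(degenerate, 1.0, sd)
        Xc = Xc / col_scales
    else:
        col_scales = np.ones(D)
    # zero-variance columns are exactly zero after centering already;
    # enforce it to kill rounding residue
    Xc[:, degenerate] = 0.0

    y_mean = float(y.mean())
    return StandardizedData(
        X=Xc, y=y - y_mean, col_means=col_means,
        col_scales=col_scales, y_mean=y_mean, degenerate=degenerate,
    )


def sparse_direction(Z, lam: float) -> np.ndarray:
    """Soft-threshold Z against the fraction ``lam`` of max|Z|.

    Returns w with w[j] = sign(Z[j]) * (|Z[j]| - lam*max|Z|) where
    |Z[j]| >= lam*max|Z|, else 0.  The comparison is inclusive, so the
    argmax always survives and the support is non-empty for nonzero Z.
    """
    Z = np.asarray(Z, dtype=float)
    if not 0.0 < lam < 1.0:
        raise ValueError(f"lam must lie in (0, 1), got {lam}")
    zmax = np.max(np.abs(Z)) if Z.size else 0.0
    if zmax == 0.0:
        raise DegenerateDirectionError("direction vector X'y is identically zero")
    thresh = lam * zmax
    absZ = np.abs(Z)
    w = np.where(absZ >= thresh, np.sign(Z) * (absZ - thresh), 0.0)
    return w


def _pls1_refit(X_active: np.ndarray, y: np.ndarray, K: int):
    """Ordinary PLS1 (NIPALS) on the active columns only.

    Returns per-component direction, score, loading and response-loading
    arrays.  y is not deflated; X is deflated by its fitted component.
    """
    M, a = X_active.shape
    Xd = X_active.copy()
    Ws, Ts, Ps, qs = [], [], [], []
    for _ in range(K):
        z = Xd.T @ y
        nz = np.linalg.norm(z)
        if nz == 0.0:
            break
        w = z / nz
        t = Xd @ w
        tt = float(t @ t)
        if tt == 0.0:
            break
        p = Xd.T @ t / tt
        q = float(y @ t) / tt
        Xd = Xd - np.outer(t, p)
        Ws.append(w); Ts.append(t); Ps.append(p); qs.append(q)
    if not Ws:
        return (np.zeros((a, 0)), np.zeros((M, 0)), np.zeros((a, 0)), np.zeros(0))
    return (np.column_stack(Ws), np.column_stack(Ts),
            np.column_stack(Ps), np.array(qs))


def spls_fit(data: StandardizedData, K: int = 1, lam: float = 0.5) -> SPLSFit:
    """Fit SPLS with K components and sparsity parameter lam.

    At each component the covariance direction Z = X'y is computed on
    the current X residual and soft-thresholded via
    :func:`sparse_direction`; surviving indices join the active set, an
    ordinary PLS1 model is refit on the active columns, and X is
    deflated.  For K = 1 the active set equals exactly the support of
    ``sparse_direction(X'y, lam)``.

    A zero covariance direction at the first component yields an empty
    fit (``active`` empty, ``beta`` all zero) rather than an error.
    """
    M, D = data.X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > min(M - 1, D):
        raise ValueError(f"K={K} exceeds min(M-1, D)={min(M - 1, D)}")

    y = data.y
    Xd = data.X.copy()
    active: set[int] = set()
    for k in range(K):
        Z = Xd.T @ y
        Z[data.degenerate] = 0.0
        try:
            w = sparse_direction(Z, lam)
        except DegenerateDirectionError:
            break
        active |= set(np.flatnonzero(w).tolist())
        idx = np.array(sorted(active))
        W_a, T, P_a, q = _pls1_refit(data.X[:, idx], y, k + 1)
        # deflate the full X by the refit components for the next Z
        P_full = np.zeros((D, P_a.shape[1]))
        P_full[idx, :] = P_a
        Xd = data.X - T @ P_full.T

    if not active:
        k0 = 0
        return SPLSFit(
            active=frozenset(), W=np.zeros((D, k0)), T_scores=np.zeros((M, k0)),
            P_load=np.zeros((D, k0)), q_load=np.zeros(k0),
            beta=np.zeros(D), lam=lam, K=K,
        )

    idx = np.array(sorted(active))
    W_a, T, P_a, q = _pls1_refit(data.X[:, idx], y, K)
    kk = W_a.shape[1]
    W = np.zeros((D, kk)); W[idx, :] = W_a
    P = np.zeros((D, kk)); P[idx, :] = P_a
    # beta on active columns: W (P'W)^-1 q  (standard PLS coefficient form)
    beta = np.zeros(D)
    if kk:
        PW = P_a.T @ W_a
        beta_a = W_a @ np.linalg.solve(PW, q)
        beta[idx] = beta_a
    return SPLSFit(
        active=frozenset(int(j) for j in idx), W=W, T_scores=T,
        P_load=P, q_load=q, beta=beta, lam=lam, K=K,
    )
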