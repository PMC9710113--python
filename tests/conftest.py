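import numpy as np
import pytest

import srgs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_active(X, y, lam, scale=True):
    """Independent K=1 selection oracle: threshold |X'y| at lam * max."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xc = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if scale:
        Xc[:, keep] = Xc[:, keep] / sd[keep]
    Xc[:, ~keep] = 0.0
    Z = Xc.T @ (y - y.mean())
    zmax = np.max(np.abs(Z))
    if zmax == 0:
        return frozenset()
    return frozenset(np.flatnonzero(np.abs(Z) >= lam * zmax).tolist())


def brute_force_auroc_aupr(scores, labels):
    """Cutoff-enumeration oracle for ROC/PR areas.

    Every distinct score is one cutoff; predictions at or above the
    cutoff are called positive.  AUROC by trapezoid over (FPR, TPR),
    AUPR by the step rule sum (R_k - R_{k-1}) * P_k.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    P = labels.sum()
    N = (~labels).sum()
    cutoffs = np.unique(scores)[::-1]
    fpr = [0.0]
    tpr = [0.0]
    prec_pts = []
    for c in cutoffs:
        called = scores >= c
        tp = np.sum(called & labels)
        fp = np.sum(called & ~labels)
        fpr.append(fp / N)
        tpr.append(tp / P)
        prec_pts.append((tp / P, tp / (tp + fp)))
    auroc = np.trapezoid(tpr, fpr)
    aupr = 0.0
    prev_r = 0.0
    for r, p in prec_pts:
        aupr += (r - prev_r) * p
        prev_r = r
    return float(auroc), float(aupr)


@pytest.fixture(scope="session")
def planted_pipeline():
    """Seeded 20-gene planted-network pipeline shared by recovery tests."""
    net = srgs.random_network(20, 0.15, seed=0)
    ts = srgs.simulate_timeseries(net, n_series=300, seed=1)
    expr = srgs.sample_cells(ts, 100, seed=2)
    return net, expr
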