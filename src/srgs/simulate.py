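"""Synthetic gene-regulatory-network data generation.

A lightweight in-silico benchmark generator in the GeneNetWeaver
tradition: a random signed directed network drives stochastic
expression time-series; single cells are sampled one time point per
series following fixed schemes; knockout steady states and
quantile-targeted Bernoulli dropout complete the benchmark inputs.

The dynamical model is an explicit stand-in, not a reimplementation of
any particular simulator: each gene g follows

    dx_g = (alpha * sigma(s * (sum_j w_jg u_j + b_g)) - gamma * x_g) dt
           + noise_sd dW,        u_j = 2 * x_j * gamma / alpha - 1

with sigma the logistic function, integrated by Euler-Maruyama and
clipped at zero.  Regulator levels enter through u_j, i.e. rescaled to
roughly [-1, 1] around the natural expression scale alpha/gamma, so the
sigmoid stays in its responsive range and regulatory influences
propagate along network edges instead of saturating.

Each time-series experiment follows the multifactorial-perturbation
protocol of in-silico benchmark generators: the system is first relaxed
to its unperturbed steady state, then at t = 0 a random subset of genes
receives a persistent bias perturbation which is removed again at
``pert_until``, so the recorded window covers a response transient and
a recovery transient, both shaped by the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix

__all__ = [
    "GRNetwork", "TimeSeriesSet",
    "random_network", "simulate_timeseries", "sample_cells",
    "induce_dropout", "simulate_knockouts", "SAMPLING_SCHEMES",
]


@dataclass
class GRNetwork:
    """Directed signed network: edges are (regulator, target, weight)."""

    gene_ids: list
    edges: list  # (regulator_id, target_id, weight)
    tf_ids: list | None = None

    def __post_init__(self):
        genes = set(self.gene_ids)
        for reg, tgt, w in self.edges:
            if reg == tgt:
                raise ValueError(f"self-loop edge on {reg}")
            if reg not in genes or tgt not in genes:
                raise ValueError(f"edge endpoint not in gene_ids: {reg}->{tgt}")
            if not np.isfinite(w) or w == 0:
                raise ValueError(f"edge weight must be finite and nonzero: {reg}->{tgt}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def edge_set(self) -> set:
        """Unsigned directed edge set {(regulator, target)}."""
        return {(r, t) for r, t, _ in self.edges}

    def weight_matrix(self) -> np.ndarray:
        """W[j, g] = weight of edge gene_j -> gene_g (zero if absent)."""
        idx = {g: k for k, g in enumerate(self.gene_ids)}
        W = np.zeros((self.n_genes, self.n_genes))
        for r, t, w in self.edges:
            W[idx[r], idx[t]] = w
        return W

    def to_edge_frame(self, signed: bool = True):
        import pandas as pd
        cols = {"regulator": [e[0] for e in self.edges],
                "target": [e[1] for e in self.edges]}
        if signed:
            cols["weight"] = [e[2] for e in self.edges]
        return pd.DataFrame(cols)


@dataclass
class TimeSeriesSet:
    """n_series x T x G expression tensor on a shared time grid."""

    values: np.ndarray
    times: np.ndarray
    gene_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def random_network(G: int, density: float, seed: int,
                   tf_fraction: float | None = None) -> GRNetwork:
    """Erdos-Renyi-style directed network with random signed weights.

    Each ordered non-self pair is an edge independently with probability
    ``density``; weights are uniform on [-1, -0.25] u [0.25, 1].
    """
    if G < 2:
        raise ValueError("need at least 2 genes")
    if not 0.0 < density < 1.0:
        raise ValueError(f"density must lie in (0, 1), got {density}")
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{k + 1}" for k in range(G)]
    edges = []
    for i in range(G):
        for j in range(G):
            if i == j:
                continue
            if rng.random() < density:
                mag = rng.uniform(0.25, 1.0)
                sign = 1.0 if rng.random() < 0.5 else -1.0
                edges.append((gene_ids[i], gene_ids[j], sign * mag))
    tf_ids = None
    if tf_fraction is not None:
        n_tf = max(1, int(round(tf_fraction * G)))
        tf_ids = list(rng.choice(gene_ids, size=n_tf, replace=False))
    return GRNetwork(gene_ids=gene_ids, edges=edges, tf_ids=tf_ids)


def _drift(x: np.ndarray, W: np.ndarray, b: np.ndarray,
           alpha: float, gamma: float, steepness: float) -> np.ndarray:
    u = 2.0 * x * gamma / alpha - 1.0  # regulator level on ~[-1, 1]
    act = 1.0 / (1.0 + np.exp(-steepness * (u @ W + b)))
    return alpha * act - gamma * x


def simulate_timeseries(net: GRNetwork, n_series: int = 1000,
                        times=None, noise_sd: float = 0.01, seed: int = 0,
                        alpha: float = 0.03, gamma: float = 0.003,
                        steepness: float = 3.0, bias: float = 0.0,
                        dt: float = 1.0, pert_frac: float = 0.3,
                        pert_mag: float = 3.0, pert_until: float = 500.0,
                        burn_in: float = 800.0) -> TimeSeriesSet:
    """Euler-Maruyama integration of the sigmoid-activation model.

    ``times`` (default 0..1000 in steps of 50) are the recorded time
    points; integration proceeds on the internal step ``dt``.  Each
    series is first relaxed for ``burn_in`` time units toward the
    unperturbed steady state; at t = 0 each gene independently receives
    (with probability ``pert_frac``) a persistent bias perturbation of
    magnitude ``pert_mag`` and random sign, removed again at
    ``pert_until``.  Values are clipped at zero.  Deterministic per
    seed.  Set ``pert_frac=0`` (or ``pert_mag=0``) for unperturbed
    dynamics started from random states.
    """
    if times is None:
        times = np.arange(0.0, 1000.0 + 1e-9, 50.0)
    times = np.asarray(times, dtype=float)
    if times[0] != 0.0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must start at 0 and be strictly increasing")
    rng = np.random.default_rng(seed)
    G = net.n_genes
    W = net.weight_matrix()
    b = np.broadcast_to(np.asarray(bias, dtype=float), (G,)).copy()
    hit = rng.random((n_series, G)) < pert_frac
    pert = hit * rng.choice([-pert_mag, pert_mag], size=(n_series, G))
    if pert_frac > 0 and pert_mag != 0:
        # perturbation protocol: relax from the mid state to the common
        # unperturbed steady state during burn-in
        x = np.full((n_series, G), 0.5 * alpha / gamma)
    else:
        x = rng.uniform(0.0, alpha / gamma, size=(n_series, G))
    sqdt = np.sqrt(dt)

    def advance(x, bias_term, step):
        x = x + step * _drift(x, W, bias_term, alpha, gamma, steepness)
        if noise_sd > 0:
            x = x + noise_sd * (np.sqrt(step) if step != dt else sqdt) \
                * rng.standard_normal(x.shape)
        np.clip(x, 0.0, None, out=x)
        return x

    for _ in range(int(np.ceil(burn_in / dt))):
        x = advance(x, b, dt)

    out = np.empty((n_series, len(times), G))
    t = 0.0
    ti = 0
    if times[0] == 0.0:
        out[:, 0, :] = x
        ti = 1
    while ti < len(times):
        step = min(dt, times[ti] - t)
        bias_term = b + pert if t < pert_until else b
        x = advance(x, bias_term, step)
        t += step
        if t >= times[ti] - 1e-9:
            out[:, ti, :] = x
            ti += 1
    return TimeSeriesSet(values=out, times=times, gene_ids=list(net.gene_ids))


# cells-per-time-point and time step for the six standard sample sizes
SAMPLING_SCHEMES = {
    5000: (250, 50.0),
    1000: (50, 50.0),
    500: (50, 100.0),
    100: (10, 100.0),
    50: (25, 500.0),
    10: (5, 500.0),
}


def sample_cells(ts: TimeSeriesSet, n_cells: int, seed: int = 0) -> ExpressionMatrix:
    """Sample one time point per series to represent single cells.

    The six standard sizes use fixed schemes (e.g. 100 cells = 10 cells
    at each of times 0, 100, ..., 900); time points start at 0 and
    number exactly n_cells / cells_per_point.  Cells at a time point are
    drawn without replacement from distinct series.  Other sizes spread
    cells as evenly as possible over all available time points.
    """
    rng = np.random.default_rng(seed)
    n_series, T, G = ts.values.shape
    if n_cells in SAMPLING_SCHEMES:
        per_point, step = SAMPLING_SCHEMES[n_cells]
        n_points = n_cells // per_point
        wanted = [i * step for i in range(n_points)]
        t_idx = []
        for w in wanted:
            hits = np.flatnonzero(np.isclose(ts.times, w))
            if hits.size == 0:
                raise ValueError(f"time point {w} not present in the series")
            t_idx.append(int(hits[0]))
        counts = [per_point] * n_points
    else:
        t_idx = list(range(T))
        base, extra = divmod(n_cells, T)
        counts = [base + (1 if k < extra else 0) for k in range(T)]
    rows, ids = [], []
    for k, (tix, c) in enumerate(zip(t_idx, counts)):
        if c == 0:
            continue
        if c > n_series:
            raise ValueError(
                f"requested {c} cells at time {ts.times[tix]:g} "
                f"but only {n_series} series are available")
        series = rng.choice(n_series, size=c, replace=False)
        rows.append(ts.values[series, tix, :])
        ids.extend(f"cell_t{ts.times[tix]:g}_{s}" for s in series)
    values = np.vstack(rows)
    return ExpressionMatrix(values=values, sample_ids=ids,
                            gene_ids=list(ts.gene_ids))


def induce_dropout(expr: ExpressionMatrix, rate: float, bern_prob: float = 0.5,
                   seed: int = 0) -> ExpressionMatrix:
    """Zero out low-expression entries per gene to mimic dropout.

    For each gene, the lowest ceil(rate * M) entries (ties broken by
    rank order) are eligible; each eligible entry is independently
    zeroed with probability ``bern_prob``.  Entries above the quantile
    are never touched.
    """
    if not 0.0 <= rate <= 1.0 or not 0.0 <= bern_prob <= 1.0:
        raise ValueError("rate and bern_prob must lie in [0, 1]")
    values = np.array(expr.values, dtype=float, copy=True)
    if rate == 0.0 or bern_prob == 0.0:
        return ExpressionMatrix(values=values, sample_ids=list(expr.sample_ids),
                                gene_ids=list(expr.gene_ids))
    rng = np.random.default_rng(seed)
    M, G = values.shape
    n_low = int(np.ceil(rate * M))
    for g in range(G):
        order = np.argsort(values[:, g], kind="stable")
        eligible = order[:n_low]
        hit = eligible[rng.random(n_low) < bern_prob]
        values[hit, g] = 0.0
    return ExpressionMatrix(values=values, sample_ids=list(expr.sample_ids),
                            gene_ids=list(expr.gene_ids))


def simulate_knockouts(net: GRNetwork, seed: int = 0, alpha: float = 0.03,
                       gamma: float = 0.003, steepness: float = 3.0,
                       bias: float = 0.0, dt: float = 1.0,
                       horizon: float = 6000.0,
                       tol: float = 1e-8) -> ExpressionMatrix:
    """Noise-free steady states: wild type plus one row per knockout.

    Row 0 is the wild-type steady state; row g clamps gene g to zero
    throughout the integration.  Divergent or non-convergent dynamics
    raise a simulation error with diagnostics.
    """
    G = net.n_genes
    if G < 2:
        raise ValueError("need at least 2 genes")
    rng = np.random.default_rng(seed)
    W = net.weight_matrix()
    b = np.broadcast_to(np.asarray(bias, dtype=float), (G,)).copy()
    # one state per condition: row 0 wild type, row g+... clamps gene g
    x = rng.uniform(0.0, alpha / gamma, size=(G + 1, G))
    clamp = np.zeros((G + 1, G), dtype=bool)
    clamp[np.arange(1, G + 1), np.arange(G)] = True
    x[clamp] = 0.0
    n_steps = int(np.ceil(horizon / dt))
    for _ in range(n_steps):
        dx = _drift(x, W, b, alpha, gamma, steepness)
        dx[clamp] = 0.0
        x = x + dt * dx
        np.clip(x, 0.0, None, out=x)
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > 1e6:
            raise RuntimeError(
                "knockout integration diverged: "
                f"max |x| = {np.max(np.abs(x)):g}")
    resid = _drift(x, W, b, alpha, gamma, steepness)
    resid[clamp] = 0.0
    # decaying states pinned at the zero clip are stationary too
    resid[(x == 0.0) & (resid < 0)] = 0.0
    if np.max(np.abs(resid)) > max(tol, 1e-6 * alpha / gamma):
        raise RuntimeError(
            "knockout integration did not converge: "
            f"max |dx/dt| = {np.max(np.abs(resid)):g} after t={horizon:g}")
    sample_ids = ["WT"] + [f"KO_{g}" for g in net.gene_ids]
    return ExpressionMatrix(values=x, sample_ids=sample_ids,
                            gene_ids=list(net.gene_ids))
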