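"""Independent oracles used by the tests.

Everything here is deliberately naive (pure-Python loops, generic optimisers)
and shares no code with the package's implementation paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, optimize


def naive_breslow_loglik(beta, records, covariates):
    """Brute-force stratified Breslow partial log-likelihood.

    ``records`` is a DataFrame with stratum/t_start/t_stop/event columns; risk
    sets are rebuilt from scratch for every event by explicit comparison.
    """
    beta = np.asarray(beta, dtype=float)
    ll = 0.0
    for _, g in records.groupby("stratum"):
        ts = g["t_start"].to_numpy(dtype=float)
        tp = g["t_stop"].to_numpy(dtype=float)
        ev = g["event"].to_numpy(dtype=bool)
        X = g[list(covariates)].to_numpy(dtype=float)
        eta = X @ beta
        for i in np.flatnonzero(ev):
            t = tp[i]
            at_risk = (ts < t) & (t <= tp)
            ll += eta[i] - np.log(np.exp(eta[at_risk]).sum())
    return ll


def maximise_naive_breslow(records, covariates, x0=None):
    """Maximise the naive partial likelihood with a generic optimiser."""
    p = len(covariates)
    x0 = np.zeros(p) if x0 is None else np.asarray(x0, dtype=float)
    res = optimize.minimize(
        lambda b: -naive_breslow_loglik(b, records, covariates), x0,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20_000, "maxfev": 20_000})
    # Polish with a second start to guard against simplex stalls.
    res2 = optimize.minimize(
        lambda b: -naive_breslow_loglik(b, records, covariates), res.x,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20_000, "maxfev": 20_000})
    return res2.x


def grid_search_floated(cov, span=8.0, rounds=10, width_factor=0.35, n_grid=21):
    """Dense iterative grid search for the floated-variance least squares.

    Minimises sum over pairs (f_i + f_j - C_ij)^2 subject to f >= 0 by
    coordinate-free shrinking grids; independent of the NNLS solver.
    """
    V = np.asarray(cov, dtype=float)
    K = V.shape[0] + 1
    pairs = [(i, j) for i in range(K) for j in range(i + 1, K)]
    C = {}
    for i, j in pairs:
        if i == 0:
            C[(i, j)] = V[j - 1, j - 1]
        else:
            C[(i, j)] = V[i - 1, i - 1] + V[j - 1, j - 1] - 2 * V[i - 1, j - 1]

    def objective(f):
        return sum((f[i] + f[j] - C[(i, j)]) ** 2 for i, j in pairs)

    centre = np.full(K, span / 4.0)
    width = span / 2.0
    best = centre.copy()
    for _ in range(rounds):
        axes = [np.clip(np.linspace(c - width, c + width, n_grid), 0.0, None)
                for c in best]
        grids = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([g.ravel() for g in grids], axis=1)
        vals = np.zeros(len(pts))
        for i, j in pairs:
            vals += (pts[:, i] + pts[:, j] - C[(i, j)]) ** 2
        best = pts[np.argmin(vals)]
        width *= width_factor
    return best, objective(best)


def quadrature_life_expectancy(rates, edges, step=0.001):
    """Partial life expectancy by fine-grained numerical integration of S."""
    rates = np.asarray(rates, dtype=float)
    edges = np.asarray(edges, dtype=float)
    t = np.arange(edges[0], edges[-1] + step / 2, step)
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(rates) - 1)
    # Cumulative hazard at each grid point, band by band.
    cumhaz = np.zeros_like(t)
    for k, (lo, rate) in enumerate(zip(edges[:-1], rates)):
        below = np.minimum(np.maximum(t - lo, 0.0), edges[k + 1] - lo)
        cumhaz += rate * below
    S = np.exp(-cumhaz)
    return float(integrate.simpson(S, x=t))
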