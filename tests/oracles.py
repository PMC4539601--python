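"""Independent reference computations for the test suite.

These are deliberately naive: exhaustive enumeration of the Boltzmann
distribution over all grid configurations of a row's in-edges, and direct
fixed-point evaluation of steady states. They share no code with the
package's BP engine.
"""

import itertools

import numpy as np

GRID = np.round(np.linspace(-1.0, 1.0, 11), 10)


def boltzmann_row_marginals(X, U, target_idx, parent_idx, beta, lam,
                            eta_vectors=None):
    """Exact per-edge marginals of one target row by full enumeration.

    Weight of a configuration {w_j}: exp(-beta * SSE - lam * #nonzero -
    sum_j eta_j(w_j)) with SSE = sum_mu (x_t - tanh(sum_j w_j x_j + u_t))^2.

    Returns a list of (11,) probability vectors, one per parent in order.
    """
    K = len(parent_idx)
    if eta_vectors is None:
        eta_vectors = [np.zeros(11)] * K
    acc = [np.full(11, -np.inf) for _ in range(K)]
    xt = X[:, target_idx]
    Xp = X[:, parent_idx]
    ut = U[:, target_idx]
    for cfg in itertools.product(range(11), repeat=K):
        w = GRID[list(cfg)]
        sse = float(((xt - np.tanh(Xp @ w + ut)) ** 2).sum())
        logw = -beta * sse - lam * np.count_nonzero(w)
        logw -= sum(eta_vectors[k][c] for k, c in enumerate(cfg))
        for k, c in enumerate(cfg):
            acc[k][c] = np.logaddexp(acc[k][c], logw)
    out = []
    for a in acc:
        v = np.exp(a - a.max())
        out.append(v / v.sum())
    return out


def boltzmann_min_cost(X, U, target_idx, parent_idx, beta, lam):
    """Minimum row cost over all grid configurations (exact)."""
    best = np.inf
    xt = X[:, target_idx]
    Xp = X[:, parent_idx]
    ut = U[:, target_idx]
    for cfg in itertools.product(range(11), repeat=len(parent_idx)):
        w = GRID[list(cfg)]
        sse = float(((xt - np.tanh(Xp @ w + ut)) ** 2).sum())
        best = min(best, beta * sse + lam * np.count_nonzero(w))
    return best


def fixed_point(W, u, eps=None, alpha=None, n_iter=20000, damping=0.5):
    """Damped fixed-point iteration for x = (eps/alpha) tanh(Wx + u)."""
    n = len(u)
    eps = np.ones(n) if eps is None else np.asarray(eps, float)
    alpha = np.ones(n) if alpha is None else np.asarray(alpha, float)
    x = np.zeros(n)
    for _ in range(n_iter):
        x_new = (1 - damping) * (eps / alpha) * np.tanh(W @ x + u) + damping * x
        if np.max(np.abs(x_new - x)) < 1e-14:
            return x_new
        x = x_new
    return x
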