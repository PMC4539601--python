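"""Belief-propagation inference of edge-strength distributions.

The inference problem: find sparse edge matrices W (on the discrete grid)
whose steady states reproduce the measured response map. The Boltzmann
weight of a configuration is exp(-C(W)) with the cost

    C(W) = beta * SSE + lambda * ||W||_0 + sum_ij eta(w_ij)

where the steady-state closure evaluates x_i* = tanh(sum_j w_ij x_j* + u_i)
per condition, and eta is the prior prize. Because each row of W couples
only to its own target's data, the distribution factorizes over target
nodes and BP runs independently per row.

Messages: for every condition mu and candidate edge (i, k) a cavity bias
rho^mu(w_ik) over the grid; the cavity marginal excluding condition mu is

    P^mu(w_ij) ∝ exp(-lambda*delta(w)) * exp(-eta(w)) * prod_{nu != mu} rho^nu(w)

and rho^mu is refreshed from the data constraint by summing the non-cavity
parents out — exactly when they are few, otherwise through a Gaussian
mean-field integral (Gauss–Hermite quadrature) whose mean and variance come
from the cavity marginals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import logsumexp

from .grid import EDGE_GRID, GRID_SIZE, NONZERO_MASK
from .model import NetworkModel
from .prior import PriorEdge, PriorNetwork, prior_prize_gaussian, prior_prize_simplified
from .registry import NodeRegistry
from .response import ResponseMap

logger = logging.getLogger(__name__)

_LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class BPSettings:
    """Tunable knobs of the inference.

    beta is the inverse-temperature on the data misfit, lambda_ the
    complexity penalty per nonzero edge (lambda_phenotype replaces it on
    edges into phenotypic nodes when prior information is in use), kappa
    the prize weight of simplified (database) priors. Defaults follow the
    published parameter choice beta=2, lambda=5, kappa=5.
    """

    beta: float = 2.0
    lambda_: float = 5.0
    lambda_phenotype: float = 2.5
    kappa: float = 5.0
    convergence_tol: float = 1e-3
    max_sweeps: int = 500
    damping: float = 0.5
    seed: int = 0
    quad_order: int = 20
    exact_cutoff: int = 3
    allow_phenotype_sources: bool = False

    def __post_init__(self) -> None:
        if min(self.beta, self.lambda_, self.lambda_phenotype, self.kappa) < 0:
            raise ValueError("beta, lambda_, lambda_phenotype, kappa must be >= 0")
        if not 0 <= self.damping < 1:
            raise ValueError("damping must be in [0, 1)")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")


@dataclass
class EdgeMarginals:
    """Converged per-pair probability vectors over the edge grid."""

    registry: NodeRegistry
    P: dict[tuple[str, str], np.ndarray]   # (target, source) -> (G,) probs
    converged: bool = True
    n_sweeps: int = 0

    def __getitem__(self, pair: tuple[str, str]) -> np.ndarray:
        return self.P[pair]

    def pairs(self):
        return self.P.keys()


# ---------------------------------------------------------------------------
# message-update primitives
# ---------------------------------------------------------------------------

def _penalty_log_factor(lambda_eff: float, prior_edge: PriorEdge | None,
                        settings: BPSettings) -> np.ndarray:
    """log of the single-edge factor exp(-lambda*delta(w)) * exp(-eta(w)).

    Simplified (database) priors take the global settings.kappa so that
    kappa = 0 switches the inference to de novo mode; Gaussian priors carry
    their own (E, sigma, kappa) triple.
    """
    pen = -lambda_eff * NONZERO_MASK.astype(float)
    if prior_edge is not None:
        if prior_edge.expected_w is not None and prior_edge.sigma is not None:
            eta = np.array([prior_prize_gaussian(w, prior_edge.expected_w,
                                                 prior_edge.sigma, prior_edge.kappa)
                            for w in EDGE_GRID])
        else:
            eta = np.array([prior_prize_simplified(w, prior_edge.relation,
                                                   settings.kappa)
                            for w in EDGE_GRID])
        pen = pen - eta
    return pen


def update_edge_marginal(incoming, prior_edge: PriorEdge | None = None,
                         settings: BPSettings | None = None,
                         lambda_eff: float | None = None) -> np.ndarray:
    """Cavity marginal of one edge from its incoming condition messages.

    ``incoming`` are the normalized messages rho^nu(w) from every condition
    nu except the one being updated. The product with the sparsity and
    prior factors is renormalized in log space.
    """
    settings = settings or BPSettings()
    lam = settings.lambda_ if lambda_eff is None else lambda_eff
    logp = _penalty_log_factor(lam, prior_edge, settings).copy()
    for msg in incoming:
        v = np.asarray(msg, dtype=float)
        if v.shape != (GRID_SIZE,):
            raise ValueError("messages must live on the edge grid")
        logp += np.log(np.clip(v, _LOG_FLOOR, None))
    logp -= logsumexp(logp)
    out = np.exp(logp)
    return out / out.sum()


def _exact_cavity_lognew(P_others: np.ndarray, x_others: np.ndarray,
                         x_k: float, x_target: float, u_eff: float,
                         beta: float) -> np.ndarray:
    """Exact Eq.-8b summation over all grid configurations of the
    non-cavity parents. Cost 11^n_others; used for small parent sets."""
    sums = np.zeros(1)
    logw = np.zeros(1)
    for P_j, x_j in zip(P_others, x_others):
        sums = (sums[:, None] + EDGE_GRID[None, :] * x_j).ravel()
        logw = (logw[:, None]
                + np.log(np.clip(P_j, _LOG_FLOOR, None))[None, :]).ravel()
    arg = x_target - np.tanh(u_eff + sums[None, :] + EDGE_GRID[:, None] * x_k)
    return logsumexp(logw[None, :] - beta * arg ** 2, axis=1)


def _gaussian_cavity_lognew(s_bar: np.ndarray, delta: np.ndarray,
                            x_k: np.ndarray, x_target: float, beta: float,
                            quad_t: np.ndarray, quad_logh: np.ndarray,
                            ) -> np.ndarray:
    """Gaussian mean-field cavity update via Gauss–Hermite quadrature.

    Vectorized over cavity edges: s_bar, delta, x_k have shape (K,);
    returns (K, G) unnormalized log messages.
    """
    s = s_bar[:, None] + np.sqrt(2.0 * np.clip(delta, 0.0, None))[:, None] * quad_t
    arg = x_target - np.tanh(s[:, None, :]
                             + (EDGE_GRID[None, :, None] * x_k[:, None, None]))
    return logsumexp(quad_logh[None, None, :] - beta * arg ** 2, axis=2)


def update_cavity_bias(cavity_marginals, x_noncavity, x_k: float,
                       x_target: float, u: float = 0.0,
                       settings: BPSettings | None = None,
                       exact: bool | None = None) -> np.ndarray:
    """One cavity-bias message rho^mu(w_ik) from the condition constraint.

    ``cavity_marginals`` are the cavity marginals P^mu(w_ij) of the
    non-cavity parents j != k with data values ``x_noncavity``; ``x_k`` is
    the cavity parent's value and ``x_target`` the target node's measured
    response in condition mu.

    ``exact=None`` picks the route automatically: exhaustive summation when
    there are at most ``settings.exact_cutoff`` non-cavity parents, the
    Gaussian approximation otherwise.
    """
    settings = settings or BPSettings()
    P = [np.asarray(p, dtype=float) for p in cavity_marginals]
    x_nc = np.asarray(x_noncavity, dtype=float)
    if len(P) != x_nc.size:
        raise ValueError("one marginal per non-cavity parent required")
    if exact is None:
        exact = len(P) <= settings.exact_cutoff
    if exact:
        lognew = _exact_cavity_lognew(P, x_nc, x_k, x_target, u, settings.beta)
    else:
        means = np.array([p @ EDGE_GRID for p in P])
        second = np.array([p @ EDGE_GRID ** 2 for p in P])
        var = np.clip(second - means ** 2, 0.0, None)
        s_bar = np.array([means @ x_nc + u])
        delta = np.array([var @ x_nc ** 2])
        t, h = hermgauss(settings.quad_order)
        lognew = _gaussian_cavity_lognew(
            s_bar, delta, np.array([x_k]), x_target, settings.beta,
            t, np.log(h) - 0.5 * np.log(np.pi))[0]
    lognew -= logsumexp(lognew)
    out = np.exp(lognew)
    return out / out.sum()


# ---------------------------------------------------------------------------
# the per-target-row engine
# ---------------------------------------------------------------------------

def candidate_parents(registry: NodeRegistry, target: str,
                      allow_phenotype_sources: bool = False) -> list[str]:
    """Candidate upstream nodes of ``target``: every other node, minus
    phenotype sources unless explicitly allowed. (Edges into activity
    nodes never exist: activity targets have no rows at all.)"""
    out = []
    for n in registry.node_ids:
        if n == target:
            continue
        if not allow_phenotype_sources and registry.node_class[n] == "phenotypic":
            continue
        out.append(n)
    return out


class _Row:
    """BP state for the in-edges of one target node."""

    def __init__(self, target: str, data: ResponseMap, prior: PriorNetwork,
                 settings: BPSettings, prior_active: bool):
        reg = data.registry
        self.target = target
        self.settings = settings
        self.parents = candidate_parents(reg, target,
                                         settings.allow_phenotype_sources)
        pidx = [reg.index(p) for p in self.parents]
        X = data.matrix()
        U = data.u_matrix()
        self.x = X[:, pidx]                      # (M, K) parent responses
        self.xt = X[:, reg.index(target)]        # (M,) target responses
        self.u = U[:, reg.index(target)]         # (M,) direct input (0 if measured)
        self.M, self.K = self.x.shape
        lam = settings.lambda_
        if prior_active and reg.node_class[target] == "phenotypic":
            lam = settings.lambda_phenotype
        self.logpen = np.stack([
            _penalty_log_factor(lam, prior.get(target, p), settings)
            for p in self.parents]) if self.K else np.zeros((0, GRID_SIZE))
        self.rho = np.full((self.M, self.K, GRID_SIZE), 1.0 / GRID_SIZE)
        self.fixed = np.zeros(self.K, dtype=bool)
        self.wfix = np.zeros(self.K)
        self.converged = True
        self.n_sweeps = 0
        t, h = hermgauss(settings.quad_order)
        self._quad_t = t
        self._quad_logh = np.log(h) - 0.5 * np.log(np.pi)

    # -- state ------------------------------------------------------------
    def randomize_messages(self, rng: np.random.Generator) -> None:
        raw = rng.uniform(0.5, 1.5, size=(self.M, self.K, GRID_SIZE))
        self.rho = raw / raw.sum(axis=2, keepdims=True)

    def fixed_offset(self) -> np.ndarray:
        """(M,) contribution of clamped parents to each condition's input."""
        if not self.fixed.any():
            return np.zeros(self.M)
        return self.x[:, self.fixed] @ self.wfix[self.fixed]

    def clamp(self, parent: str, w: float) -> None:
        k = self.parents.index(parent)
        self.fixed[k] = True
        self.wfix[k] = w

    # -- one full (parallel) sweep over all conditions --------------------
    def sweep(self, rng: np.random.Generator) -> float:
        """Flooding update: every cavity message of every condition is
        refreshed simultaneously from the current state, then damped.
        Returns the largest absolute message change."""
        act = np.flatnonzero(~self.fixed)
        if act.size == 0 or self.M == 0:
            return 0.0
        s = self.settings
        beta = s.beta
        u_eff = self.u + self.fixed_offset()               # (M,)
        logrho = np.log(np.clip(self.rho[:, act], _LOG_FLOOR, None))
        # cavity marginals P^mu(w_ij) for every condition at once
        logP = self.logpen[None, act] + logrho.sum(axis=0, keepdims=True) - logrho
        logP -= logsumexp(logP, axis=2, keepdims=True)
        P = np.exp(logP)
        P /= P.sum(axis=2, keepdims=True)                  # (M, A, G)
        X = self.x[:, act]                                 # (M, A)
        xt = self.xt
        n_nc = act.size - 1
        if n_nc <= s.exact_cutoff:
            lognew = np.empty((self.M, act.size, GRID_SIZE))
            for a in range(act.size):
                others = [b for b in range(act.size) if b != a]
                sums = np.zeros((self.M, 1))
                logw = np.zeros((self.M, 1))
                for b in others:
                    sums = (sums[:, :, None]
                            + EDGE_GRID[None, None, :] * X[:, b, None, None]
                            ).reshape(self.M, -1)
                    logw = (logw[:, :, None]
                            + np.log(np.clip(P[:, b], _LOG_FLOOR, None)
                                     )[:, None, :]).reshape(self.M, -1)
                arg = xt[:, None, None] - np.tanh(
                    u_eff[:, None, None] + sums[:, None, :]
                    + EDGE_GRID[None, :, None] * X[:, a, None, None])
                lognew[:, a] = logsumexp(logw[:, None, :] - beta * arg ** 2,
                                         axis=2)
        else:
            m = P @ EDGE_GRID                              # (M, A)
            v = np.clip(P @ EDGE_GRID ** 2 - m ** 2, 0.0, None)
            cm = m * X
            cv = v * X ** 2
            s_bar = (cm.sum(axis=1, keepdims=True) + u_eff[:, None]) - cm
            delta = np.clip(cv.sum(axis=1, keepdims=True) - cv, 0.0, None)
            sq = s_bar[:, :, None] + np.sqrt(2.0 * delta)[:, :, None] * self._quad_t
            arg = xt[:, None, None, None] - np.tanh(
                sq[:, :, None, :] + (EDGE_GRID[None, None, :, None]
                                     * X[:, :, None, None]))
            lognew = logsumexp(self._quad_logh[None, None, None, :]
                               - beta * arg ** 2, axis=3)
        lognew -= logsumexp(lognew, axis=2, keepdims=True)
        new = np.exp(lognew)
        new /= new.sum(axis=2, keepdims=True)
        old = self.rho[:, act]
        damped = s.damping * old + (1.0 - s.damping) * new
        damped /= damped.sum(axis=2, keepdims=True)
        max_delta = float(np.max(np.abs(damped - old)))
        self.rho[:, act] = damped
        return max_delta

    def run(self, rng: np.random.Generator) -> None:
        s = self.settings
        delta = np.inf
        self.n_sweeps = 0
        while self.n_sweeps < s.max_sweeps:
            delta = self.sweep(rng)
            self.n_sweeps += 1
            if delta < s.convergence_tol:
                break
        self.converged = delta < s.convergence_tol

    # -- results ----------------------------------------------------------
    def marginals(self) -> dict[str, np.ndarray]:
        logrho = np.log(np.clip(self.rho, _LOG_FLOOR, None))
        logM = self.logpen + logrho.sum(axis=0)
        logM -= logsumexp(logM, axis=1, keepdims=True)
        P = np.exp(logM)
        P /= P.sum(axis=1, keepdims=True)
        out = {}
        for k, p in enumerate(self.parents):
            if self.fixed[k]:
                vec = np.zeros(GRID_SIZE)
                vec[int(np.argmin(np.abs(EDGE_GRID - self.wfix[k])))] = 1.0
                out[p] = vec
            else:
                out[p] = P[k]
        return out


class BPEngine:
    """Row-independent BP over all candidate edges of a response map."""

    def __init__(self, data: ResponseMap, prior: PriorNetwork | None,
                 settings: BPSettings):
        self.data = data
        self.registry = data.registry
        self.settings = settings
        self.prior = prior if prior is not None else PriorNetwork()
        has_gaussian = any(e.expected_w is not None and e.sigma is not None
                           for e in self.prior.edges.values())
        self.prior_active = (not self.prior.is_empty
                             and (settings.kappa > 0 or has_gaussian))
        self.rows = {t: _Row(t, data, self.prior, settings, self.prior_active)
                     for t in self.registry.measured}

    def run(self, rng: np.random.Generator, warm: bool = False,
            rows: list[str] | None = None) -> None:
        targets = rows if rows is not None else list(self.rows)
        for t in targets:
            row = self.rows[t]
            if not warm:
                row.randomize_messages(rng)
            row.run(rng)

    @property
    def converged(self) -> bool:
        return all(r.converged for r in self.rows.values())

    @property
    def n_sweeps(self) -> int:
        return max((r.n_sweeps for r in self.rows.values()), default=0)

    def marginals(self) -> EdgeMarginals:
        P = {}
        for t, row in self.rows.items():
            for src, vec in row.marginals().items():
                P[(t, src)] = vec
        return EdgeMarginals(registry=self.registry, P=P,
                             converged=self.converged, n_sweeps=self.n_sweeps)


def run_bp(data: ResponseMap, prior: PriorNetwork | None = None,
           settings: BPSettings | None = None) -> EdgeMarginals:
    """Run belief propagation to convergence and return edge marginals.

    Non-convergence within ``max_sweeps`` is reported on the result (and
    logged), not raised: the best marginals found are still returned.
    """
    settings = settings or BPSettings()
    rng = np.random.default_rng(settings.seed)
    engine = BPEngine(data, prior, settings)
    engine.run(rng)
    if not engine.converged:
        logger.warning("BP did not converge within %d sweeps", settings.max_sweeps)
    return engine.marginals()


# ---------------------------------------------------------------------------
# map-estimate network and the full model cost
# ---------------------------------------------------------------------------

def map_network(marginals: EdgeMarginals) -> NetworkModel:
    """Maximum-probability network: per-pair argmax of P(w_ij).

    Ties (exact equal probability) prefer the value closer to 0, then the
    lower grid index.
    """
    reg = marginals.registry
    n = len(reg)
    W = np.zeros((n, n))
    order = np.lexsort((np.arange(GRID_SIZE), np.abs(EDGE_GRID)))
    for (t, s), P in marginals.P.items():
        best = max(P)
        for idx in order:
            if P[idx] >= best - 1e-12:
                W[reg.index(t), reg.index(s)] = EDGE_GRID[idx]
                break
    return NetworkModel(W=W, registry=reg)


def model_cost(model: NetworkModel, data: ResponseMap,
               prior: PriorNetwork | None = None,
               settings: BPSettings | None = None,
               ss_tol: float = 1e-6, breakdown: bool = False):
    """Full cost C(W) = beta*SSE + complexity + prior prize of one model.

    SSE compares simulated steady states against the response map on every
    column; edges into phenotypic nodes cost lambda_phenotype when prior
    information is active. Simulation divergence yields +inf.
    """
    from .simulate import steady_state_response

    settings = settings or BPSettings()
    prior = prior if prior is not None else PriorNetwork()
    reg = data.registry
    X = data.matrix()
    U = data.u_matrix()
    sse = 0.0
    diverged = []
    for idx, cid in enumerate(data.condition_ids):
        ss = steady_state_response(model, U[idx], ss_tol=ss_tol)
        if not ss.converged:
            diverged.append(cid)
            continue
        sse += float(((X[idx] - ss.x) ** 2).sum())
    if diverged:
        logger.warning("model_cost: simulation did not converge in %d "
                       "condition(s): %s", len(diverged), diverged[:5])
        result = {"total": float("inf"), "sse": float("inf"),
                  "complexity": np.nan, "prior": np.nan,
                  "diverged": diverged}
        return result if breakdown else float("inf")

    has_gaussian = any(e.expected_w is not None and e.sigma is not None
                       for e in prior.edges.values())
    prior_active = not prior.is_empty and (settings.kappa > 0 or has_gaussian)
    complexity = 0.0
    for t in reg.measured:
        lam = settings.lambda_
        if prior_active and reg.node_class[t] == "phenotypic":
            lam = settings.lambda_phenotype
        complexity += lam * np.count_nonzero(model.W[reg.index(t), :])

    prize = 0.0
    for (t, s), edge in prior.edges.items():
        if t not in reg or s not in reg:
            continue
        w = model.W[reg.index(t), reg.index(s)]
        if edge.expected_w is not None and edge.sigma is not None:
            prize += prior_prize_gaussian(w, edge.expected_w, edge.sigma,
                                          edge.kappa)
        else:
            prize += prior_prize_simplified(w, edge.relation, settings.kappa)

    total = settings.beta * sse + complexity + prize
    if breakdown:
        return {"total": total, "sse": sse, "complexity": complexity,
                "prior": prize, "diverged": []}
    return float(total)
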