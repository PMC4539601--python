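"""Model execution: integrate the network ODEs to steady state.

dx_i/dt = ε_i tanh(Σ_j w_ij x_j + u_i) − α_i x_i

Perturbations enter as a real-valued input vector u. Every trajectory is
bounded: |x_i| ≤ ε_i/α_i. Simulations start from the basal state x = 0 and
run until the largest time derivative falls below a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .model import ModelEnsemble, NetworkModel


@dataclass(frozen=True)
class SteadyState:
    x: np.ndarray
    converged: bool
    residual: float     # max_i |dx_i/dt| at the returned state
    t_final: float


def _rhs(model: NetworkModel, u: np.ndarray):
    W, eps, alpha = model.W, model.epsilon, model.alpha

    def rhs(_t, x):
        return eps * np.tanh(W @ x + u) - alpha * x

    return rhs


def integrate_odes(model: NetworkModel, u: np.ndarray,
                   x0: np.ndarray | None = None, t_max: float = 1000.0,
                   n_points: int = 200, rtol: float = 1e-10,
                   atol: float = 1e-10, strict: bool = False):
    """Numerically integrate the model ODEs with LSODA.

    ``strict=True`` passes the legacy literal tolerance rtol=1e-20 to the
    solver (below double precision; kept for record compatibility), the
    default uses rtol=1e-10.

    Returns (t, X) with X of shape (n_points, n_nodes).
    """
    n = model.n_nodes
    u = np.asarray(u, dtype=float)
    if u.shape != (n,):
        raise ValueError(f"u must have shape ({n},)")
    x0 = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float)
    if strict:
        rtol = 1e-20
    t_eval = np.linspace(0.0, t_max, n_points)
    sol = solve_ivp(_rhs(model, u), (0.0, t_max), x0, method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.t, sol.y.T


def steady_state_response(model: NetworkModel, u: np.ndarray,
                          ss_tol: float = 1e-6, t_max: float = 1000.0,
                          chunk: float = 50.0, rtol: float = 1e-10,
                          atol: float = 1e-10) -> SteadyState:
    """Integrate from the basal state until steady state.

    Integration proceeds in time chunks; after each chunk the residual
    max_i |dx_i/dt| is checked against ``ss_tol``. Non-convergent dynamics
    (e.g. sustained oscillations) are returned with ``converged=False``
    rather than raised.
    """
    n = model.n_nodes
    u = np.asarray(u, dtype=float)
    rhs = _rhs(model, u)
    x = np.zeros(n)
    t = 0.0
    while t < t_max:
        t_next = min(t + chunk, t_max)
        sol = solve_ivp(rhs, (t, t_next), x, method="LSODA",
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        x = sol.y[:, -1]
        t = t_next
        residual = float(np.max(np.abs(rhs(t, x))))
        if residual < ss_tol:
            return SteadyState(x=x, converged=True, residual=residual, t_final=t)
    return SteadyState(x=x, converged=False,
                       residual=float(np.max(np.abs(rhs(t, x)))), t_final=t)


def fixed_point_response(model: NetworkModel, u: np.ndarray,
                         tol: float = 1e-12, max_iter: int = 10000,
                         damping: float = 0.5) -> SteadyState:
    """Damped fixed-point iteration x ← (1−d)·(ε/α)·tanh(Wx + u) + d·x.

    An independent route to the same steady state on contractive models;
    used for cross-checks against the ODE integrator.
    """
    n = model.n_nodes
    u = np.asarray(u, dtype=float)
    gain = model.epsilon / model.alpha
    x = np.zeros(n)
    for _ in range(max_iter):
        x_new = (1 - damping) * gain * np.tanh(model.W @ x + u) + damping * x
        if np.max(np.abs(x_new - x)) < tol:
            x = x_new
            break
    else:
        resid = float(np.max(np.abs(
            model.epsilon * np.tanh(model.W @ x + u) - model.alpha * x)))
        return SteadyState(x=x, converged=False, residual=resid, t_final=np.inf)
    resid = float(np.max(np.abs(
        model.epsilon * np.tanh(model.W @ x + u) - model.alpha * x)))
    return SteadyState(x=x, converged=True, residual=resid, t_final=np.inf)


def predict_ensemble_response(ensemble: ModelEnsemble, u: np.ndarray,
                              ss_tol: float = 1e-6, t_max: float = 1000.0,
                              ) -> dict:
    """Mean and SEM of per-node steady states over the converged models.

    Non-converged models are excluded and counted. Raises if no model
    converges.
    """
    states = []
    n_failed = 0
    for m in ensemble:
        ss = steady_state_response(m, u, ss_tol=ss_tol, t_max=t_max)
        if ss.converged:
            states.append(ss.x)
        else:
            n_failed += 1
    if not states:
        raise RuntimeError("no model converged to steady state")
    X = np.stack(states)
    sem = (X.std(axis=0, ddof=1) / np.sqrt(len(X))) if len(X) > 1 \
        else np.zeros(X.shape[1])
    return {"mean": X.mean(axis=0), "sem": sem,
            "n_converged": len(X), "n_failed": n_failed}
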