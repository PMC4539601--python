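"""BP-guided decimation: instantiate executable models from BP marginals.

One decimation round turns the converged probability distributions into a
single fully specified network: repeatedly pick a random unfixed edge,
draw its value from its current marginal, clamp it (posterior becomes 1),
and refresh the interaction landscape by re-running BP.

Refreshing after every clamp is the bottleneck, so a conditional-update
heuristic is used: BP is only re-run when the clamped value's pre-fix
probability was below 0.95 — fixing a near-certain edge barely shifts the
global landscape — but is always forced after five consecutive skipped
updates to stop residual shifts from accumulating. Clamps at probability
exactly 1 change nothing at all and do not count as skips.

Each of the n_models rounds restarts from freshly randomized messages, so
the solution degeneracy of the cost landscape is sampled.
"""

from __future__ import annotations

import logging

import numpy as np

from .bp import BPEngine, BPSettings
from .grid import EDGE_GRID, GRID_SIZE
from .model import ModelEnsemble, NetworkModel
from .prior import PriorNetwork
from .response import ResponseMap

logger = logging.getLogger(__name__)

#: Clamps at or above this pre-fix probability skip the BP refresh.
SKIP_UPDATE_PROB = 0.95
#: Forced refresh after this many consecutive skipped updates.
MAX_SKIPPED_UPDATES = 5


def _decimate_one(engine: BPEngine, rng: np.random.Generator) -> NetworkModel:
    """One decimation round on a freshly converged engine."""
    reg = engine.registry
    unfixed = [(t, src) for t, row in engine.rows.items() for src in row.parents]
    skip_count = 0
    dirty: set[str] = set()
    while unfixed:
        t, src = unfixed.pop(int(rng.integers(len(unfixed))))
        row = engine.rows[t]
        P = row.marginals()[src]
        idx = int(rng.choice(GRID_SIZE, p=P))
        p_unfixed = float(P[idx])
        row.clamp(src, float(EDGE_GRID[idx]))
        dirty.add(t)
        if not unfixed:
            break
        if p_unfixed < SKIP_UPDATE_PROB:
            engine.run(rng, warm=True, rows=sorted(dirty))
            dirty.clear()
            skip_count = 0
        elif p_unfixed < 1.0 - 1e-12:
            skip_count += 1
            if skip_count >= MAX_SKIPPED_UPDATES:
                engine.run(rng, warm=True, rows=sorted(dirty))
                dirty.clear()
                skip_count = 0
    n = len(reg)
    W = np.zeros((n, n))
    for t, row in engine.rows.items():
        i = reg.index(t)
        for k, src in enumerate(row.parents):
            W[i, reg.index(src)] = row.wfix[k]
    return NetworkModel(W=W, registry=reg)


def decimate(data: ResponseMap, prior: PriorNetwork | None = None,
             settings: BPSettings | None = None,
             n_models: int = 1) -> ModelEnsemble:
    """Generate an ensemble of ``n_models`` decimated model solutions.

    Every round re-computes the BP marginals from scratch (randomized
    initial messages seeded per model), then runs the clamp/refresh loop.
    A BP failure mid-round aborts that model and continues the ensemble.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    settings = settings or BPSettings()
    models = []
    for m in range(n_models):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=settings.seed, spawn_key=(m,)))
        try:
            engine = BPEngine(data, prior, settings)
            engine.run(rng)
            models.append(_decimate_one(engine, rng))
        except Exception:
            logger.exception("decimation round %d failed; continuing", m)
    if not models:
        raise RuntimeError("all decimation rounds failed")
    return ModelEnsemble(models=models, registry=data.registry,
                         settings={"n_models": n_models,
                                   "seed": settings.seed,
                                   "beta": settings.beta,
                                   "lambda": settings.lambda_,
                                   "kappa": settings.kappa})
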