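"""Scikit-learn-style front end to the inference pipeline.

``BeliefPropagationInference`` wraps BP + BP-guided decimation as an
estimator: ``fit`` consumes a ResponseMap (optionally with a prior
network) and exposes the converged marginals, the decimated model
ensemble, and the average model as fitted attributes; ``predict`` runs the
ensemble under new in silico perturbations.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .analysis import AverageModel, average_model
from .bp import BPSettings, EdgeMarginals, run_bp
from .decimation import decimate
from .model import ModelEnsemble
from .prior import PriorNetwork
from .response import ResponseMap
from .simulate import predict_ensemble_response


class BeliefPropagationInference(BaseEstimator):
    """Infer an ensemble of executable signaling-network models.

    Parameters mirror the BP settings: ``beta`` (inverse temperature on
    the data misfit), ``lambda_`` / ``lambda_phenotype`` (edge-complexity
    penalties), ``kappa`` (prior prize weight; 0 = de novo), plus the
    decimation ensemble size ``n_models``.

    Attributes (after ``fit``)
    --------------------------
    marginals_ : EdgeMarginals
        Converged BP edge-value distributions.
    ensemble_ : ModelEnsemble
        ``n_models`` decimated executable model solutions.
    average_model_ : AverageModel
        Element-wise mean <W_ij> over the ensemble.
    """

    def __init__(self, beta: float = 2.0, lambda_: float = 5.0,
                 lambda_phenotype: float = 2.5, kappa: float = 5.0,
                 n_models: int = 100, convergence_tol: float = 1e-3,
                 max_sweeps: int = 500, damping: float = 0.5,
                 quad_order: int = 20, exact_cutoff: int = 3,
                 allow_phenotype_sources: bool = False,
                 random_state: int = 0):
        self.beta = beta
        self.lambda_ = lambda_
        self.lambda_phenotype = lambda_phenotype
        self.kappa = kappa
        self.n_models = n_models
        self.convergence_tol = convergence_tol
        self.max_sweeps = max_sweeps
        self.damping = damping
        self.quad_order = quad_order
        self.exact_cutoff = exact_cutoff
        self.allow_phenotype_sources = allow_phenotype_sources
        self.random_state = random_state

    def _settings(self) -> BPSettings:
        return BPSettings(
            beta=self.beta, lambda_=self.lambda_,
            lambda_phenotype=self.lambda_phenotype, kappa=self.kappa,
            convergence_tol=self.convergence_tol, max_sweeps=self.max_sweeps,
            damping=self.damping, quad_order=self.quad_order,
            exact_cutoff=self.exact_cutoff,
            allow_phenotype_sources=self.allow_phenotype_sources,
            seed=self.random_state)

    def fit(self, X: ResponseMap, y=None, prior: PriorNetwork | None = None):
        """Run BP to convergence on ``X`` and decimate an ensemble."""
        if not isinstance(X, ResponseMap):
            raise TypeError("X must be a ResponseMap")
        settings = self._settings()
        self.marginals_: EdgeMarginals = run_bp(X, prior, settings)
        self.ensemble_: ModelEnsemble = decimate(X, prior, settings,
                                                 n_models=self.n_models)
        self.average_model_: AverageModel = average_model(self.ensemble_)
        self.registry_ = X.registry
        self.n_features_in_ = len(X.registry)
        return self

    def predict(self, U) -> np.ndarray:
        """Ensemble-mean steady states for each perturbation vector in U.

        U has shape (n_conditions, n_nodes) in registry order; returns the
        matching matrix of predicted responses.
        """
        if not hasattr(self, "ensemble_"):
            raise RuntimeError("estimator is not fitted")
        U = np.atleast_2d(np.asarray(U, dtype=float))
        if U.shape[1] != len(self.registry_):
            raise ValueError(f"U must have {len(self.registry_)} columns")
        return np.stack([predict_ensemble_response(self.ensemble_, u)["mean"]
                         for u in U])
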