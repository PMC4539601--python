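"""Executable network models and model ensembles.

A NetworkModel is one fully specified parameterization: the edge-strength
matrix W on the discrete grid plus per-node dynamic-range (ε) and
relaxation (α) constants. Ensembles of models — the output of BP-guided
decimation — support averaging, edge frequencies, and ensemble prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import EDGE_GRID
from .registry import NodeRegistry


@dataclass
class NetworkModel:
    """One executable model: x'_i = ε_i tanh(Σ_j w_ij x_j + u_i) − α_i x_i.

    ``W[i, j]`` is the influence of upstream node j on the time derivative
    of node i; rows/columns follow registry order. Activity nodes receive
    no in-edges (their rows are zero): they are pure inputs.
    """

    W: np.ndarray
    registry: NodeRegistry
    epsilon: np.ndarray | None = None
    alpha: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.registry)
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (n, n):
            raise ValueError(f"W must be {n}x{n}")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("self-interactions (diagonal of W) must be 0")
        act_rows = [self.registry.index(a) for a in self.registry.activity]
        if act_rows and np.any(self.W[act_rows, :] != 0):
            raise ValueError("activity nodes must receive no in-edges")
        self.epsilon = (np.ones(n) if self.epsilon is None
                        else np.asarray(self.epsilon, dtype=float))
        self.alpha = (np.ones(n) if self.alpha is None
                      else np.asarray(self.alpha, dtype=float))
        if np.any(self.epsilon <= 0) or np.any(self.alpha <= 0):
            raise ValueError("epsilon and alpha must be positive")

    @property
    def n_nodes(self) -> int:
        return len(self.registry)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.W))

    def edge_list(self) -> list[tuple[str, str, float]]:
        """(source, target, w) triples for the nonzero edges."""
        out = []
        nodes = self.registry.node_ids
        for i, j in zip(*np.nonzero(self.W)):
            out.append((nodes[j], nodes[i], float(self.W[i, j])))
        return out

    def to_networkx(self):
        import networkx as nx
        g = nx.DiGraph()
        g.add_nodes_from(self.registry.node_ids)
        for s, t, w in self.edge_list():
            g.add_edge(s, t, weight=w)
        return g


@dataclass
class ModelEnsemble:
    """A collection of decimated model solutions sharing one registry."""

    models: list[NetworkModel]
    registry: NodeRegistry
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in self.models:
            if m.registry.node_ids != self.registry.node_ids:
                raise ValueError("all models must share the ensemble registry")

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def stacked_W(self) -> np.ndarray:
        """(n_models × n × n) array of all edge matrices."""
        return np.stack([m.W for m in self.models])

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "settings": self.settings,
            "registry": self.registry.to_frame().to_dict(orient="records"),
            "models": [
                {"edges": [[s, t, w] for s, t, w in m.edge_list()]}
                for m in self.models
            ],
        }
        return json.dumps(doc, indent=1)

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def read_json(cls, path) -> "ModelEnsemble":
        with open(path) as fh:
            doc = json.load(fh)
        registry = NodeRegistry.from_frame(pd.DataFrame(doc["registry"]))
        n = len(registry)
        models = []
        for m in doc["models"]:
            W = np.zeros((n, n))
            for s, t, w in m["edges"]:
                W[registry.index(t), registry.index(s)] = w
            models.append(NetworkModel(W=W, registry=registry))
        return cls(models=models, registry=registry,
                   settings=doc.get("settings", {}))

    def edges_frame(self) -> pd.DataFrame:
        """Flat table: model_index, source, target, w."""
        rows = [(k, s, t, w)
                for k, m in enumerate(self.models)
                for s, t, w in m.edge_list()]
        return pd.DataFrame(rows, columns=["model_index", "source", "target", "w"])

    def write_tsv(self, path) -> None:
        self.edges_frame().to_csv(path, sep="\t", index=False)


def snap_matrix_to_grid(W: np.ndarray) -> np.ndarray:
    """Round every entry of W to the nearest grid value."""
    idx = np.argmin(np.abs(np.asarray(W, float)[..., None] - EDGE_GRID), axis=-1)
    return EDGE_GRID[idx]
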