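"""Perturbation design: which drugs hit which activity nodes, and how hard.

Each experimental condition applies one or two targeted drugs. A drug acts
on its activity node with a nonnegative strength (a dose-derived number);
in simulations the perturbation input is ``u = -strength`` (inhibitory).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import NodeRegistry


@dataclass(frozen=True)
class Perturbation:
    """A single targeted intervention within a condition."""
    node: str              # activity node id
    strength: float        # u magnitude, >= 0
    dose_label: str = ""   # free-text dose tag (e.g. IC40, 2xIC40)

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ValueError("perturbation strength must be >= 0")


@dataclass(frozen=True)
class PerturbationDesign:
    """Map from condition id to its set of perturbations.

    Invariant: each condition perturbs one or two activity nodes
    (single agents and paired combinations).
    """

    conditions: dict[str, tuple[Perturbation, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, perts in self.conditions.items():
            if not 1 <= len(perts) <= 2:
                raise ValueError(
                    f"condition {cid!r} perturbs {len(perts)} nodes; expected 1 or 2")
            if len({p.node for p in perts}) != len(perts):
                raise ValueError(f"condition {cid!r} targets a node twice")

    def __len__(self) -> int:
        return len(self.conditions)

    def __contains__(self, cid: str) -> bool:
        return cid in self.conditions

    @property
    def condition_ids(self) -> tuple[str, ...]:
        return tuple(self.conditions)

    def targeted_nodes(self, cid: str) -> tuple[str, ...]:
        return tuple(p.node for p in self.conditions[cid])

    def conditions_with_node(self, node: str) -> tuple[str, ...]:
        return tuple(cid for cid, perts in self.conditions.items()
                     if any(p.node == node for p in perts))

    def is_pair(self, cid: str) -> bool:
        return len(self.conditions[cid]) == 2

    # -- numeric views ----------------------------------------------------
    def u_vector(self, cid: str, registry: NodeRegistry) -> np.ndarray:
        """Perturbation input vector u for one condition.

        Drug perturbations are inhibitory: u = -strength on each targeted
        activity node, 0 elsewhere.
        """
        u = np.zeros(len(registry))
        for p in self.conditions[cid]:
            u[registry.index(p.node)] = -p.strength
        return u

    def u_matrix(self, registry: NodeRegistry) -> np.ndarray:
        """Stacked u vectors, one row per condition (design order)."""
        return np.array([self.u_vector(c, registry) for c in self.conditions]) \
            if self.conditions else np.zeros((0, len(registry)))

    def activity_scores(self, cid: str, registry: NodeRegistry) -> dict[str, float]:
        """Design-derived inhibition score in [-1, 0] per activity node.

        Activity nodes are not measured; their response-map column is the
        steady state an isolated activity node reaches under its input,
        tanh(-strength) in [-1, 0] (0 = untargeted).
        """
        scores = {a: 0.0 for a in registry.activity}
        for p in self.conditions[cid]:
            scores[p.node] = float(np.tanh(-p.strength))
        return scores

    def subset(self, condition_ids) -> "PerturbationDesign":
        missing = [c for c in condition_ids if c not in self.conditions]
        if missing:
            raise KeyError(f"conditions not in design: {missing}")
        return PerturbationDesign({c: self.conditions[c] for c in condition_ids})

    # -- IO ----------------------------------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame, registry: NodeRegistry | None = None,
                   ) -> "PerturbationDesign":
        """Build from a long table with columns condition_id, drug,
        dose_label, strength. ``drug`` may also be an activity node id."""
        required = {"condition_id", "drug", "strength"}
        if not required.issubset(frame.columns):
            raise ValueError(f"design table needs columns {sorted(required)}")
        conditions: dict[str, list[Perturbation]] = {}
        for _, row in frame.iterrows():
            drug = str(row["drug"])
            node = drug
            if registry is not None:
                if drug in registry and registry.node_class[drug] == "activity":
                    node = drug
                else:
                    node = registry.activity_node_for_drug(drug)
            label = str(row.get("dose_label", "") or "")
            conditions.setdefault(str(row["condition_id"]), []).append(
                Perturbation(node=node, strength=float(row["strength"]),
                             dose_label=label))
        return cls({c: tuple(p) for c, p in conditions.items()})

    @classmethod
    def read_tsv(cls, path, registry: NodeRegistry | None = None) -> "PerturbationDesign":
        return cls.from_frame(pd.read_csv(path, sep="\t"), registry=registry)

    def to_frame(self) -> pd.DataFrame:
        rows = [(cid, p.node, p.dose_label, p.strength)
                for cid, perts in self.conditions.items() for p in perts]
        return pd.DataFrame(rows, columns=["condition_id", "drug",
                                           "dose_label", "strength"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
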