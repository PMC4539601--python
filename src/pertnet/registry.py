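"""Node registry: the typed index of network nodes.

Nodes come in three classes:

* ``proteomic`` — measured (phospho)protein levels;
* ``phenotypic`` — measured cellular phenotypes (cell cycle, viability);
* ``activity`` — unmeasured nodes that couple a drug's activity into the
  network; every activity node is the target of exactly one drug and
  receives no incoming edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

NODE_CLASSES = ("proteomic", "phenotypic", "activity")


@dataclass(frozen=True)
class NodeRegistry:
    """Ordered registry of node ids with their class and (for activity
    nodes) the drug that targets them."""

    node_ids: tuple[str, ...]
    node_class: dict[str, str] = field(repr=False)
    target_of: dict[str, str] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("duplicate node ids in registry")
        for n in self.node_ids:
            cls = self.node_class.get(n)
            if cls not in NODE_CLASSES:
                raise ValueError(f"node {n!r} has invalid class {cls!r}")
            if cls == "activity" and n not in self.target_of:
                raise ValueError(f"activity node {n!r} names no drug")
            if cls != "activity" and n in self.target_of:
                raise ValueError(f"non-activity node {n!r} must not name a drug")
        drugs = list(self.target_of.values())
        if len(set(drugs)) != len(drugs):
            raise ValueError("two activity nodes name the same drug")

    # -- views ------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.node_ids)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.node_class

    def index(self, node_id: str) -> int:
        return self.node_ids.index(node_id)

    def nodes_of_class(self, cls: str) -> tuple[str, ...]:
        if cls not in NODE_CLASSES:
            raise ValueError(f"unknown node class {cls!r}")
        return tuple(n for n in self.node_ids if self.node_class[n] == cls)

    @property
    def proteomic(self) -> tuple[str, ...]:
        return self.nodes_of_class("proteomic")

    @property
    def phenotypic(self) -> tuple[str, ...]:
        return self.nodes_of_class("phenotypic")

    @property
    def activity(self) -> tuple[str, ...]:
        return self.nodes_of_class("activity")

    @property
    def measured(self) -> tuple[str, ...]:
        """Proteomic + phenotypic nodes (the experimentally observed ones)."""
        return tuple(n for n in self.node_ids
                     if self.node_class[n] != "activity")

    def activity_node_for_drug(self, drug: str) -> str:
        for node, d in self.target_of.items():
            if d == drug:
                return node
        raise KeyError(f"no activity node targets drug {drug!r}")

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(self.target_of[n] for n in self.activity)

    # -- construction / IO -------------------------------------------------
    @classmethod
    def from_lists(cls, proteomic=(), phenotypic=(), activity=()) -> "NodeRegistry":
        """Build a registry from per-class id lists.

        ``activity`` may be node ids (drug name defaults to the node id)
        or (node_id, drug) pairs.
        """
        act_pairs = [(a, a) if isinstance(a, str) else tuple(a) for a in activity]
        node_ids = tuple(proteomic) + tuple(phenotypic) + tuple(a for a, _ in act_pairs)
        node_class = {n: "proteomic" for n in proteomic}
        node_class.update({n: "phenotypic" for n in phenotypic})
        node_class.update({a: "activity" for a, _ in act_pairs})
        return cls(node_ids=node_ids, node_class=node_class,
                   target_of={a: d for a, d in act_pairs})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "NodeRegistry":
        required = {"node_id", "node_class"}
        if not required.issubset(frame.columns):
            raise ValueError(f"registry table needs columns {sorted(required)}")
        target_of = {}
        if "drug" in frame.columns:
            for _, row in frame.iterrows():
                if row["node_class"] == "activity" and pd.notna(row["drug"]) and row["drug"] != "":
                    target_of[row["node_id"]] = str(row["drug"])
        return cls(node_ids=tuple(frame["node_id"].astype(str)),
                   node_class=dict(zip(frame["node_id"].astype(str),
                                       frame["node_class"].astype(str))),
                   target_of=target_of)

    @classmethod
    def read_tsv(cls, path) -> "NodeRegistry":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "node_id": self.node_ids,
            "node_class": [self.node_class[n] for n in self.node_ids],
            "drug": [self.target_of.get(n, "") for n in self.node_ids],
        })

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
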