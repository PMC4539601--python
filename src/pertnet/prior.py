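"""Prior-knowledge interactions and the prior-prize term of the cost function.

Pathway databases supply qualitative directed interactions (activating,
inhibitory, or generic). Each prior edge contributes a *prize* — a negative
cost term η(w_ij) — when the inferred edge value conforms to it, acting as a
soft restraint the inference is free to override.

Two forms of η are exposed:

* the simplified step function used with binary database priors
  (η = -κ on the conforming half of the grid, 0 otherwise), and
* the generalized Gaussian form for quantitative priors with an expected
  value E[w^prior] and spread σ^prior,
  η(w) = -κ ln(1/(σ√(2π))) + κ (w - E)² / (2σ²).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grid import EDGE_GRID
from .registry import NodeRegistry

logger = logging.getLogger(__name__)

RELATIONS = ("activating", "inhibitory", "generic")

#: Case-insensitive SIF relation synonyms (colors follow the usual
#: green/red/black edge rendering of prior networks).
DEFAULT_RELATION_MAP = {
    "activates": "activating", "activating": "activating", "green": "activating",
    "inhibits": "inhibitory", "inhibitory": "inhibitory", "red": "inhibitory",
    "generic": "generic", "black": "generic", "interacts": "generic",
}


@dataclass(frozen=True)
class PriorEdge:
    source: str
    target: str
    relation: str                 # activating | inhibitory | generic
    kappa: float = 5.0
    expected_w: float | None = None   # Gaussian form only
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("prior self-edges are not allowed")
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma_prior must be > 0")


@dataclass
class PriorNetwork:
    """Set of directed prior edges keyed by ordered (target, source) pair."""

    edges: dict[tuple[str, str], PriorEdge] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.edges

    def add(self, edge: PriorEdge) -> None:
        self.edges[(edge.target, edge.source)] = edge

    def get(self, target: str, source: str) -> PriorEdge | None:
        return self.edges.get((target, source))

    def kappa_of(self, target: str, source: str) -> float:
        e = self.get(target, source)
        return e.kappa if e is not None else 0.0

    @property
    def is_empty(self) -> bool:
        return not self.edges

    def to_networkx(self):
        import networkx as nx
        g = nx.DiGraph()
        for (t, s), e in self.edges.items():
            g.add_edge(s, t, relation=e.relation, kappa=e.kappa)
        return g

    def write_sif(self, path) -> None:
        inverse = {"activating": "activates", "inhibitory": "inhibits",
                   "generic": "generic"}
        with open(path, "w") as fh:
            for (t, s), e in self.edges.items():
                fh.write(f"{s}\t{inverse[e.relation]}\t{t}\n")


def read_sif_prior(path, registry: NodeRegistry, kappa: float = 5.0,
                   relation_map: dict[str, str] | None = None) -> PriorNetwork:
    """Read a three-column SIF file (source TAB relation TAB target).

    Edges with endpoints outside the registry, and self-edges, are skipped
    with a logged count; a uniform prize weight κ is assigned to every
    retained edge.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    rmap = {k.lower(): v for k, v in (relation_map or DEFAULT_RELATION_MAP).items()}
    prior = PriorNetwork()
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: malformed SIF line: {line!r}")
            src, rel, tgt = parts
            relation = rmap.get(rel.lower())
            if relation is None:
                raise ValueError(f"{path}:{lineno}: unknown relation {rel!r}")
            if src not in registry or tgt not in registry or src == tgt:
                skipped += 1
                continue
            prior.add(PriorEdge(source=src, target=tgt, relation=relation,
                                kappa=kappa))
    if skipped:
        logger.info("read_sif_prior: skipped %d edge(s) with unregistered or "
                    "identical endpoints", skipped)
    return prior


def prior_prize_simplified(w: float, relation: str | None, kappa: float) -> float:
    """Step-function prize η(w) for a binary database prior.

    generic: -κ if w ≠ 0; activating: -κ if w > 0; inhibitory: -κ if w < 0;
    no prior (relation None): 0. Nonconforming values earn no prize.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if relation is None:
        return 0.0
    if relation not in RELATIONS:
        raise ValueError(f"unknown relation {relation!r}")
    conforms = {"generic": w != 0, "activating": w > 0,
                "inhibitory": w < 0}[relation]
    return -kappa if conforms else 0.0


def prior_prize_gaussian(w: float, expected_w: float, sigma: float,
                         kappa: float) -> float:
    """Gaussian-form prize: inverse-Boltzmann of a normal prior density.

    η(w) = -κ ln(1/(σ√(2π))) + κ (w - E)²/(2σ²). The first term is the
    maximum prize, attained at w = E; the second penalizes discrepancy.
    """
    if sigma <= 0:
        raise ValueError("sigma_prior must be > 0")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    return (-kappa * np.log(1.0 / (sigma * np.sqrt(2.0 * np.pi)))
            + kappa * (w - expected_w) ** 2 / (2.0 * sigma ** 2))


def prize_vector(edge: PriorEdge | None) -> np.ndarray:
    """η evaluated on the whole edge grid for one ordered pair (0 if no prior)."""
    if edge is None:
        return np.zeros_like(EDGE_GRID)
    if edge.expected_w is not None and edge.sigma is not None:
        return np.array([prior_prize_gaussian(w, edge.expected_w, edge.sigma,
                                              edge.kappa) for w in EDGE_GRID])
    return np.array([prior_prize_simplified(w, edge.relation, edge.kappa)
                     for w in EDGE_GRID])


def total_prior_prize(W: np.ndarray, prior: PriorNetwork,
                      registry: NodeRegistry) -> float:
    """Cumulative prize Σ_ij η(w_ij) of a full edge-strength matrix."""
    total = 0.0
    for (t, s), edge in prior.edges.items():
        w = W[registry.index(t), registry.index(s)]
        total += prize_vector(edge)[int(np.argmin(np.abs(EDGE_GRID - w)))]
    return float(total)


def generate_random_prior(registry: NodeRegistry, n_edges: int, seed: int,
                          kappa: float = 5.0) -> PriorNetwork:
    """Sample a pseudoprior: ``n_edges`` distinct ordered non-self pairs,
    uniformly without replacement, all with generic relation.

    Used for the rejection test that compares the number of accepted prior
    interactions under database-driven vs random restraints.
    """
    nodes = list(registry.node_ids)
    n = len(nodes)
    n_pairs = n * (n - 1)
    if n_edges > n_pairs:
        raise ValueError(f"n_edges={n_edges} exceeds {n_pairs} ordered pairs")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_pairs, size=n_edges, replace=False)
    prior = PriorNetwork()
    for flat in chosen:
        i, j = divmod(int(flat), n - 1)
        j = j if j < i else j + 1      # skip the diagonal
        prior.add(PriorEdge(source=nodes[j], target=nodes[i],
                            relation="generic", kappa=kappa))
    return prior
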