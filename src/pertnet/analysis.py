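"""Ensemble summaries, cross-validation, and the in silico screen.

Everything downstream of inference lives here: the average model and edge
frequencies over an ensemble, the accepted-prior count used in the
random-pseudoprior rejection test, leave-k-out cross-validation of
predictive power, the combinatorial single/pair perturbation screen,
phenotype-response ranking, and two-drug response surfaces (isobologram
inputs).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bp import BPSettings
from .decimation import decimate
from .model import ModelEnsemble
from .prior import PriorNetwork
from .registry import NodeRegistry
from .response import ResponseMap
from .simulate import predict_ensemble_response

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ensemble summaries
# ---------------------------------------------------------------------------

@dataclass
class AverageModel:
    """Element-wise mean <W_ij> over an ensemble, with a display threshold."""

    mean_w: np.ndarray
    registry: NodeRegistry
    display_threshold: float = 0.2

    def edge_list(self, threshold: float | None = None
                  ) -> list[tuple[str, str, float]]:
        """(source, target, <w>) triples with |<w>| > threshold."""
        thr = self.display_threshold if threshold is None else threshold
        nodes = self.registry.node_ids
        out = []
        for i, j in zip(*np.nonzero(np.abs(self.mean_w) > thr)):
            out.append((nodes[j], nodes[i], float(self.mean_w[i, j])))
        return out

    def to_networkx(self, threshold: float | None = None):
        import networkx as nx
        g = nx.DiGraph()
        g.add_nodes_from(self.registry.node_ids)
        for s, t, w in self.edge_list(threshold):
            g.add_edge(s, t, weight=w)
        return g


def average_model(ensemble: ModelEnsemble,
                  display_threshold: float = 0.2) -> AverageModel:
    """Average signaling interactions <W_ij> over all model solutions."""
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    return AverageModel(mean_w=ensemble.stacked_W().mean(axis=0),
                        registry=ensemble.registry,
                        display_threshold=display_threshold)


def edge_frequency(ensemble: ModelEnsemble,
                   magnitude_min: float = 0.2) -> pd.DataFrame:
    """Fraction of models with |w_ij| strictly above ``magnitude_min``.

    Returns a long table (source, target, frequency) for pairs with
    nonzero frequency.
    """
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    freq = (np.abs(ensemble.stacked_W()) > magnitude_min).mean(axis=0)
    nodes = ensemble.registry.node_ids
    rows = [(nodes[j], nodes[i], float(freq[i, j]))
            for i, j in zip(*np.nonzero(freq))]
    out = pd.DataFrame(rows, columns=["source", "target", "frequency"])
    return out.astype({"frequency": float})


def accepted_prior_count(model_or_ensemble, prior: PriorNetwork):
    """Number of prior edges realized with the prior-consistent sign.

    A generic prior is accepted if w != 0, activating if w > 0, inhibitory
    if w < 0. For an ensemble the per-model counts are returned as an
    array.
    """
    def count_one(W: np.ndarray, registry: NodeRegistry) -> int:
        c = 0
        for (t, s), edge in prior.edges.items():
            if t not in registry or s not in registry:
                continue
            w = W[registry.index(t), registry.index(s)]
            ok = {"generic": w != 0, "activating": w > 0,
                  "inhibitory": w < 0}[edge.relation]
            c += bool(ok)
        return c

    if isinstance(model_or_ensemble, ModelEnsemble):
        ens = model_or_ensemble
        return np.array([count_one(m.W, ens.registry) for m in ens])
    model = model_or_ensemble
    return count_one(model.W, model.registry)


# ---------------------------------------------------------------------------
# leave-k-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CrossValReport:
    drug: str
    withheld_conditions: tuple[str, ...]
    training_conditions: tuple[str, ...]
    predictions: pd.DataFrame           # condition_id, node_id, predicted, observed
    r_all: float
    r_phenotype: float
    ensemble: ModelEnsemble = field(repr=False, default=None)


def crossval_partition(data: ResponseMap, drug: str
                       ) -> tuple[list[str], list[str]]:
    """Split conditions for one drug's leave-k-out round.

    Every *paired* condition containing the drug's activity node is
    withheld; the drug's single-agent doses stay in training along with
    everything else.
    """
    node = data.registry.activity_node_for_drug(drug)
    withheld = [c for c in data.condition_ids
                if data.design.is_pair(c)
                and node in data.design.targeted_nodes(c)]
    if not withheld:
        raise ValueError(f"drug {drug!r} has no paired conditions to withhold")
    training = [c for c in data.condition_ids if c not in set(withheld)]
    return training, withheld


def leave_k_out_cv(data: ResponseMap, drug: str,
                   prior: PriorNetwork | None = None,
                   settings: BPSettings | None = None,
                   n_models: int = 100) -> CrossValReport:
    """Leave-k-out cross-validation for one drug.

    Trains a fresh ensemble on the partial data, simulates the withheld in
    silico conditions, and reports the cumulative Pearson correlation R
    between predicted and withheld responses — pooled over all measured
    (condition, node) pairs, and separately for phenotype nodes only.
    """
    settings = settings or BPSettings()
    training, withheld = crossval_partition(data, drug)
    train_map = data.subset_conditions(training)
    ensemble = decimate(train_map, prior, settings, n_models=n_models)

    reg = data.registry
    measured = list(reg.measured)
    rows = []
    for cid in withheld:
        u = data.design.u_vector(cid, reg)
        pred = predict_ensemble_response(ensemble, u)
        for node in measured:
            i = reg.index(node)
            rows.append((cid, node, float(pred["mean"][i]),
                         float(data.values.loc[cid, node])))
    frame = pd.DataFrame(rows, columns=["condition_id", "node_id",
                                        "predicted", "observed"])

    def pooled_r(sub: pd.DataFrame) -> float:
        if len(sub) < 2 or sub["observed"].std() == 0 or sub["predicted"].std() == 0:
            return float("nan")
        return float(stats.pearsonr(sub["predicted"], sub["observed"])[0])

    pheno = frame[frame["node_id"].isin(reg.phenotypic)]
    return CrossValReport(drug=drug, withheld_conditions=tuple(withheld),
                          training_conditions=tuple(training),
                          predictions=frame, r_all=pooled_r(frame),
                          r_phenotype=pooled_r(pheno), ensemble=ensemble)


# ---------------------------------------------------------------------------
# in silico combinatorial screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """Predicted phenotype responses of every enumerated condition.

    ``conditions`` is a table with columns node_a, node_b (empty for
    singles), strength_a, strength_b, plus one column per phenotype when
    predictions were simulated.
    """

    conditions: pd.DataFrame
    phenotypes: tuple[str, ...] = ()
    simulated: bool = False

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)


def enumerate_screen_conditions(targets, strengths) -> pd.DataFrame:
    """All single and unordered-pair perturbation conditions.

    n targets at s strengths give n*s singles plus C(n,2)*s^2 pairs.
    """
    targets = list(targets)
    strengths = list(strengths)
    if not strengths:
        raise ValueError("strengths must be nonempty")
    if len(set(targets)) != len(targets):
        raise ValueError("duplicate screen targets")
    rows = [(a, "", s, 0.0) for a in targets for s in strengths]
    for a, b in itertools.combinations(targets, 2):
        for sa in strengths:
            for sb in strengths:
                rows.append((a, b, sa, sb))
    return pd.DataFrame(rows, columns=["node_a", "node_b",
                                       "strength_a", "strength_b"])


def in_silico_screen(ensemble: ModelEnsemble, targets, strengths,
                     simulate: bool = True, ss_tol: float = 1e-6,
                     ) -> ScreenResult:
    """Combinatorial screen: predict phenotype response to every single and
    paired perturbation of ``targets`` over ``strengths``.

    Perturbation inputs are inhibitory: u = -strength on each targeted
    node. With ``simulate=False`` only the condition table is enumerated
    (useful for design counting).
    """
    reg = ensemble.registry
    for t in targets:
        if t not in reg:
            raise ValueError(f"screen target {t!r} not in registry")
    table = enumerate_screen_conditions(targets, strengths)
    phenotypes = reg.phenotypic
    if not simulate:
        return ScreenResult(conditions=table, phenotypes=phenotypes,
                            simulated=False)
    preds = {p: [] for p in phenotypes}
    n = len(reg)
    for _, row in table.iterrows():
        u = np.zeros(n)
        u[reg.index(row["node_a"])] = -row["strength_a"]
        if row["node_b"]:
            u[reg.index(row["node_b"])] = -row["strength_b"]
        out = predict_ensemble_response(ensemble, u, ss_tol=ss_tol)
        for p in phenotypes:
            preds[p].append(float(out["mean"][reg.index(p)]))
    table = table.assign(**preds)
    return ScreenResult(conditions=table, phenotypes=phenotypes, simulated=True)


#: Desired response direction per phenotype kind: "min" ranks the most
#: negative responses first (e.g. viability loss), "max" the most positive
#: (e.g. arrest phenotypes).
DEFAULT_DIRECTIONS = {"min": ("viability", "cellviability", "g2m"),
                      "max": ("g1arrest", "g2arrest", "sarrest", "apoptosis")}


def rank_phenotypic_responses(screen: ScreenResult, phenotype: str,
                              top_n: int = 100,
                              direction: str | None = None) -> pd.DataFrame:
    """Top-ranked conditions for one phenotype.

    ``direction``: "max" ranks the largest responses first, "min" the most
    negative (viability-like phenotypes). If not given it is looked up by
    phenotype name, defaulting to "max".
    """
    if phenotype not in screen.phenotypes:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    if not screen.simulated:
        raise ValueError("screen was enumerated without simulation")
    if direction is None:
        key = phenotype.replace("_", "").replace("-", "").lower()
        direction = "min" if key in DEFAULT_DIRECTIONS["min"] else "max"
    if direction not in ("min", "max"):
        raise ValueError("direction must be 'min' or 'max'")
    tbl = screen.conditions.copy()
    tbl["_cid"] = (tbl["node_a"] + "+" + tbl["node_b"] + "@"
                   + tbl["strength_a"].astype(str) + ","
                   + tbl["strength_b"].astype(str))
    tbl = tbl.sort_values(
        [phenotype, "_cid"], ascending=[direction == "min", True],
        kind="mergesort").head(top_n)
    tbl = tbl.reset_index(drop=True)
    tbl.insert(0, "rank", np.arange(1, len(tbl) + 1))
    return tbl.drop(columns="_cid")


def response_surface(ensemble: ModelEnsemble, node_a: str, node_b: str,
                     phenotype: str, grid) -> np.ndarray:
    """Predicted phenotype response over a two-drug strength grid.

    Entry [i, j] is the ensemble-mean phenotype response with u_a =
    -grid[i] and u_b = -grid[j]; row and column 0 of a grid starting at 0
    reproduce the single-agent sweeps. Isocontours of the returned matrix
    are the model's isobologram.
    """
    reg = ensemble.registry
    grid = np.asarray(list(grid), dtype=float)
    if not np.all(np.isfinite(grid)):
        raise ValueError("grid values must be finite")
    ia, ib, ip = reg.index(node_a), reg.index(node_b), reg.index(phenotype)
    out = np.zeros((grid.size, grid.size))
    n = len(reg)
    for i, sa in enumerate(grid):
        for j, sb in enumerate(grid):
            u = np.zeros(n)
            u[ia] = -sa
            u[ib] = -sb
            out[i, j] = float(predict_ensemble_response(ensemble, u)["mean"][ip])
    return out
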