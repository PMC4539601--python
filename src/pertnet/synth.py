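"""Synthetic ground truths and simulated response maps.

Everything needed to exercise inference end-to-end without any download: a
sparse ground-truth network with the full study-scale node composition
(proteomic / phenotypic / activity), a perturbation design mirroring the
experimental scheme (paired combinations of all drugs plus two doses of
single agents), response maps generated by executing the true model to
steady state (plus additive Gaussian noise on the log2 scale), and a
parameter-recovery report comparing an inferred ensemble to the truth.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import Perturbation, PerturbationDesign
from .grid import EDGE_GRID
from .model import ModelEnsemble, NetworkModel
from .registry import NodeRegistry
from .response import ResponseMap
from .simulate import steady_state_response

logger = logging.getLogger(__name__)


@dataclass
class GroundTruth:
    model: NetworkModel
    design: PerturbationDesign
    noise_sd: float = 0.05
    seed: int = 0

    @property
    def registry(self) -> NodeRegistry:
        return self.model.registry


def synthetic_registry(n_proteomic: int, n_phenotypic: int,
                       n_activity: int) -> NodeRegistry:
    """Registry with generated ids PROT*, PHEN*, ACT* (drug DRUG*)."""
    return NodeRegistry.from_lists(
        proteomic=[f"PROT{i + 1}" for i in range(n_proteomic)],
        phenotypic=[f"PHEN{i + 1}" for i in range(n_phenotypic)],
        activity=[(f"ACT{i + 1}", f"DRUG{i + 1}") for i in range(n_activity)])


def generate_design(registry: NodeRegistry,
                    single_doses=(1.0, 2.0),
                    pair_dose_combos=((1.0, 1.0),),
                    drop_last_single: bool = False) -> PerturbationDesign:
    """Design mirroring the experimental scheme: every unordered drug pair
    plus single agents at multiple doses.

    ``pair_dose_combos`` lists (dose_a, dose_b) applied to each pair;
    ``drop_last_single`` omits the final single-agent condition (used to
    mirror the published 89-condition map, one short of 12 drugs x 2
    doses + 66 pairs).
    """
    acts = registry.activity
    conditions: dict[str, tuple[Perturbation, ...]] = {}
    for (a, b) in itertools.combinations(acts, 2):
        for da, db in pair_dose_combos:
            cid = f"{a}+{b}@{da:g},{db:g}"
            conditions[cid] = (Perturbation(a, da), Perturbation(b, db))
    singles = [(a, d) for a in acts for d in single_doses]
    if drop_last_single and singles:
        singles = singles[:-1]
    for a, d in singles:
        conditions[f"{a}@{d:g}"] = (Perturbation(a, d),)
    return PerturbationDesign(conditions)


def full_scale_design(registry: NodeRegistry) -> PerturbationDesign:
    """The published experimental layout at full scale: 12 drugs give 66
    pairwise combinations plus 23 single-agent doses, 89 conditions."""
    if len(registry.activity) != 12:
        raise ValueError("full-scale design needs 12 activity nodes")
    return generate_design(registry, single_doses=(1.0, 2.0),
                           pair_dose_combos=((1.0, 1.0),),
                           drop_last_single=True)


def sample_ground_truth_network(n_proteomic: int, n_phenotypic: int,
                                n_activity: int, n_edges: int, seed: int,
                                design: PerturbationDesign | None = None,
                                noise_sd: float = 0.05,
                                min_abs_w: float = 0.2) -> GroundTruth:
    """Sample a sparse ground-truth model.

    Edge slots respect the structural constraints of inference: targets
    are measured nodes, sources are non-phenotype nodes, no self-edges.
    Each activity node is wired to at least one proteomic target; edge
    values are drawn uniformly from the nonzero grid values with
    |w| >= min_abs_w.
    """
    registry = synthetic_registry(n_proteomic, n_phenotypic, n_activity)
    rng = np.random.default_rng(seed)
    n = len(registry)
    W = np.zeros((n, n))

    slots = [(t, s) for t in registry.measured for s in registry.node_ids
             if s != t and registry.node_class[s] != "phenotypic"]
    if n_edges > len(slots):
        raise ValueError(f"n_edges={n_edges} exceeds {len(slots)} feasible slots")
    values = EDGE_GRID[np.abs(EDGE_GRID) >= max(min_abs_w, 0.2) - 1e-12]
    values = values[values != 0]

    chosen: list[tuple[str, str]] = []
    if n_edges > 0:
        if n_edges < n_activity:
            raise ValueError("n_edges must cover one edge per activity node "
                             "(or be 0 for an empty network)")
        if n_proteomic == 0:
            raise ValueError("activity nodes need proteomic targets")
        for a in registry.activity:
            t = registry.proteomic[rng.integers(n_proteomic)]
            chosen.append((t, a))
        rest = [sl for sl in slots if sl not in set(chosen)]
        extra = rng.choice(len(rest), size=n_edges - len(chosen), replace=False)
        chosen += [rest[i] for i in sorted(extra)]
    for t, s in chosen:
        W[registry.index(t), registry.index(s)] = values[rng.integers(values.size)]

    model = NetworkModel(W=W, registry=registry)
    if design is None:
        design = generate_design(registry)
    return GroundTruth(model=model, design=design, noise_sd=noise_sd, seed=seed)


def simulate_response_map(truth: GroundTruth,
                          design: PerturbationDesign | None = None,
                          noise_sd: float | None = None,
                          seed: int | None = None) -> ResponseMap:
    """Execute the true model on every design condition to steady state.

    The response value of every node (including activity nodes, which
    settle at tanh(u)) is its steady state; additive Gaussian noise of sd
    ``noise_sd`` is applied to the measured (proteomic/phenotypic) columns
    only. Non-convergent conditions are excluded with a logged warning.
    """
    design = design if design is not None else truth.design
    noise_sd = truth.noise_sd if noise_sd is None else noise_sd
    seed = truth.seed if seed is None else seed
    reg = truth.registry
    rng = np.random.default_rng(seed)

    rows, kept = [], []
    n_dropped = 0
    for cid in design.condition_ids:
        u = design.u_vector(cid, reg)
        ss = steady_state_response(truth.model, u)
        if not ss.converged:
            n_dropped += 1
            continue
        rows.append(ss.x)
        kept.append(cid)
    if n_dropped:
        logger.warning("simulate_response_map: %d non-convergent condition(s) "
                       "excluded", n_dropped)
    values = pd.DataFrame(np.array(rows).reshape(len(kept), len(reg)),
                          index=pd.Index(kept, name="condition_id"),
                          columns=list(reg.node_ids))
    if noise_sd > 0 and kept:
        meas = list(reg.measured)
        values[meas] = values[meas] + rng.normal(
            0.0, noise_sd, size=(len(kept), len(meas)))
    return ResponseMap(values=values, design=design.subset(kept), registry=reg)


def parameter_recovery_eval(truth: GroundTruth, inferred: ModelEnsemble,
                            strong_min: float = 0.6,
                            false_edge_threshold: float = 0.2) -> dict:
    """Compare an inferred ensemble's average model against the truth.

    Reports sign accuracy on the true nonzero edges (overall and on strong
    edges with |w| >= strong_min), the Pearson correlation between the
    true W and <W> over all candidate edge slots, and the false-edge rate
    (fraction of truly absent slots with |<W>| > false_edge_threshold).
    """
    reg = truth.registry
    if inferred.registry.node_ids != reg.node_ids:
        raise ValueError("truth and ensemble must share a registry")
    mean_w = inferred.stacked_W().mean(axis=0)
    Wt = truth.model.W

    slots = [(reg.index(t), reg.index(s))
             for t in reg.measured for s in reg.node_ids
             if s != t and reg.node_class[s] != "phenotypic"]
    ti, si = zip(*slots)
    true_vals = Wt[ti, si]
    est_vals = mean_w[ti, si]

    nonzero = true_vals != 0
    strong = np.abs(true_vals) >= strong_min
    sign_ok = np.sign(est_vals) == np.sign(true_vals)

    def frac(mask):
        return float(sign_ok[mask].mean()) if mask.any() else float("nan")

    if np.std(true_vals) > 0 and np.std(est_vals) > 0:
        r = float(np.corrcoef(true_vals, est_vals)[0, 1])
    else:
        r = float("nan")
    absent = ~nonzero
    fer = float((np.abs(est_vals[absent]) > false_edge_threshold).mean()) \
        if absent.any() else 0.0
    return {"sign_accuracy": frac(nonzero),
            "sign_accuracy_strong": frac(nonzero & strong),
            "pearson_r": r,
            "false_edge_rate": fer,
            "n_true_edges": int(nonzero.sum()),
            "n_strong_edges": int((nonzero & strong).sum())}
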