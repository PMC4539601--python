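"""Perturbation-response map: loading, normalization, and quality filters.

The response map is a condition × node matrix of log2(perturbed/unperturbed)
changes. Proteomic and phenotypic columns are measured; activity-node
columns are synthesized from the perturbation design (activity nodes are
unmeasured model inputs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import PerturbationDesign
from .registry import NodeRegistry

logger = logging.getLogger(__name__)


@dataclass
class ResponseMap:
    """Condition × node matrix of log2 relative responses.

    ``values`` rows are conditions (index = condition ids), columns are the
    registry's nodes in registry order. ``replicates`` optionally keeps the
    per-condition replicate values that were averaged into each entry.
    """

    values: pd.DataFrame
    design: PerturbationDesign
    registry: NodeRegistry
    replicates: dict[str, pd.DataFrame] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.registry.node_ids):
            raise ValueError("response columns must match registry node order")
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("response map contains non-finite values")
        missing = [c for c in self.values.index if c not in self.design]
        if missing:
            raise ValueError(f"conditions missing from design: {missing}")

    @property
    def condition_ids(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def n_conditions(self) -> int:
        return len(self.values)

    def matrix(self) -> np.ndarray:
        """Values as a (conditions × nodes) float array in registry order."""
        return self.values.to_numpy(dtype=float)

    def u_matrix(self) -> np.ndarray:
        return np.array([self.design.u_vector(c, self.registry)
                         for c in self.condition_ids])

    def subset_conditions(self, condition_ids) -> "ResponseMap":
        ids = list(condition_ids)
        return ResponseMap(values=self.values.loc[ids],
                           design=self.design.subset(ids),
                           registry=self.registry,
                           replicates=self.replicates)

    def restrict_nodes(self, keep_measured) -> tuple["ResponseMap", NodeRegistry]:
        """Drop measured nodes not in ``keep_measured`` (activity nodes are
        always kept). Returns the reduced map and its reduced registry."""
        keep = set(keep_measured)
        reg = self.registry
        new_reg = NodeRegistry.from_lists(
            proteomic=[n for n in reg.proteomic if n in keep],
            phenotypic=[n for n in reg.phenotypic if n in keep],
            activity=[(a, reg.target_of[a]) for a in reg.activity])
        sub = ResponseMap(values=self.values[list(new_reg.node_ids)],
                          design=self.design, registry=new_reg,
                          replicates=self.replicates)
        return sub, new_reg

    def write_tsv(self, path) -> None:
        out = self.values[list(self.registry.measured)].copy()
        out.index.name = "condition_id"
        out.to_csv(path, sep="\t")


def normalize_log2(perturbed: np.ndarray, unperturbed: np.ndarray) -> np.ndarray:
    """log2 ratio of perturbed intensities to the unperturbed baseline.

    Parameters
    ----------
    perturbed : (conditions × nodes) strictly positive intensities.
    unperturbed : (nodes,) strictly positive baseline intensities.
    """
    perturbed = np.asarray(perturbed, dtype=float)
    unperturbed = np.asarray(unperturbed, dtype=float)
    if np.any(perturbed <= 0) or np.any(unperturbed <= 0):
        raise ValueError("intensities must be strictly positive for log2 ratios")
    return np.log2(perturbed / unperturbed)


def load_response_map(matrix_file, design_file, registry: NodeRegistry,
                      sep: str = "\t") -> ResponseMap:
    """Load a measured response matrix and its design into a ResponseMap.

    The matrix file has a header of node ids and a first column of condition
    ids; it covers measured (proteomic/phenotypic) nodes. Activity-node
    columns are synthesized from the design as inhibition scores in [-1, 0].
    """
    frame = pd.read_csv(matrix_file, sep=sep, index_col=0)
    frame.index = frame.index.astype(str)
    if frame.empty:
        raise ValueError(f"{matrix_file}: no conditions in response matrix")
    unknown = [c for c in frame.columns if c not in registry]
    if unknown:
        raise ValueError(f"{matrix_file}: columns not in registry: {unknown}")
    bad_class = [c for c in frame.columns
                 if registry.node_class[c] == "activity"]
    if bad_class:
        raise ValueError(
            f"{matrix_file}: activity nodes must not appear as measured "
            f"columns: {bad_class}")
    missing_meas = [n for n in registry.measured if n not in frame.columns]
    if missing_meas:
        raise ValueError(f"{matrix_file}: measured nodes absent: {missing_meas}")
    for col in frame.columns:
        bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(
                f"{matrix_file}: non-numeric cell at row {bad[0]!r}, column {col!r}")
    if frame.isna().any().any():
        raise ValueError(f"{matrix_file}: missing cells are not allowed")

    design = PerturbationDesign.read_tsv(design_file, registry=registry)
    missing_design = [c for c in frame.index if c not in design]
    if missing_design:
        raise ValueError(f"conditions without design rows: {missing_design}")

    values = pd.DataFrame(index=frame.index, columns=list(registry.node_ids),
                          dtype=float)
    for n in registry.measured:
        values[n] = frame[n].astype(float)
    for cid in frame.index:
        for a, s in design.activity_scores(cid, registry).items():
            values.loc[cid, a] = s
    return ResponseMap(values=values, design=design.subset(list(frame.index)),
                       registry=registry)


def iterative_signal_filter(values: pd.DataFrame | dict,
                            threshold_sd: float = 2.5,
                            max_iter: int = 100) -> set[str]:
    """Iterative signal-to-noise detection of responding nodes.

    Pools every data point of every node, then iterates: compute the mean
    and standard deviation over the not-yet-flagged points, flag points
    deviating more than ``threshold_sd`` standard deviations from that
    mean, and repeat until no new point is flagged. A node "responds" if it
    owns at least one flagged point.

    Parameters
    ----------
    values : DataFrame (conditions × nodes) or mapping node -> 1d values.
    threshold_sd : flagging threshold in running-σ units (default 2.5).

    Returns
    -------
    set of node ids owning at least one signal point.
    """
    if isinstance(values, pd.DataFrame):
        per_node = {str(c): values[c].to_numpy(dtype=float) for c in values.columns}
    else:
        per_node = {str(k): np.asarray(v, dtype=float) for k, v in values.items()}
    owners = np.concatenate([np.full(len(v), i)
                             for i, v in enumerate(per_node.values())]) \
        if per_node else np.array([], dtype=int)
    data = np.concatenate(list(per_node.values())) if per_node else np.array([])
    if data.size < 2:
        raise ValueError("signal filter needs at least 2 data points")

    flagged = np.zeros(data.size, dtype=bool)
    for _ in range(max_iter):
        rest = data[~flagged]
        if rest.size < 2:
            break
        mu, sigma = rest.mean(), rest.std()
        if sigma == 0:
            break
        new = (~flagged) & (np.abs(data - mu) > threshold_sd * sigma)
        if not new.any():
            break
        flagged |= new

    names = list(per_node)
    return {names[i] for i in np.unique(owners[flagged])}


def coefficient_of_variation(replicates) -> float:
    """Sample CV (sd/mean, ddof=1) of a replicate group on the linear scale."""
    r = np.asarray(replicates, dtype=float)
    if r.size < 2:
        raise ValueError("CV needs at least 2 replicates")
    mean = r.mean()
    if mean == 0:
        return float("nan")
    return float(r.std(ddof=1) / mean)


def reproducibility_filter(replicate_sets: dict, cv_max: float = 0.15) -> set[str]:
    """Retain nodes whose replicate coefficient of variation is acceptable.

    ``replicate_sets`` maps node id to one replicate group or a list of
    groups (e.g. intra- and inter-slide); a node is dropped if any group's
    CV exceeds ``cv_max``. Zero-mean groups have undefined CV and the node
    is dropped with a warning.
    """
    retained: set[str] = set()
    for node, groups in replicate_sets.items():
        first = np.asarray(groups, dtype=object)
        if first.ndim == 1 and np.isscalar(first[0]):
            groups = [groups]
        keep = True
        for g in groups:
            cv = coefficient_of_variation(g)
            if np.isnan(cv):
                logger.warning("node %s: zero-mean replicate group, CV undefined; "
                               "dropping", node)
                keep = False
                break
            if cv > cv_max:
                keep = False
                break
        if keep:
            retained.add(str(node))
    return retained
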