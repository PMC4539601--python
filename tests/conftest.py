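import numpy as np
import pytest

import pertnet as pn


@pytest.fixture
def tiny_registry():
    """1 proteomic + 1 activity node."""
    return pn.NodeRegistry.from_lists(proteomic=["PROT1"],
                                      activity=[("ACT1", "D1")])


@pytest.fixture
def three_node_registry():
    """1 proteomic + 2 activity nodes (two candidate parents)."""
    return pn.NodeRegistry.from_lists(
        proteomic=["PROT1"], activity=[("ACT1", "D1"), ("ACT2", "D2")])


@pytest.fixture
def small_registry():
    """3 proteomic + 1 phenotypic + 2 activity nodes."""
    return pn.NodeRegistry.from_lists(
        proteomic=["PROT1", "PROT2", "PROT3"], phenotypic=["PHEN1"],
        activity=[("ACT1", "D1"), ("ACT2", "D2")])


def planted_truth(registry, edges, design=None, **design_kw):
    """GroundTruth with explicitly planted edges (source, target, w)."""
    n = len(registry)
    W = np.zeros((n, n))
    for s, t, w in edges:
        W[registry.index(t), registry.index(s)] = w
    model = pn.NetworkModel(W=W, registry=registry)
    if design is None:
        design = pn.generate_design(registry, **design_kw)
    return pn.GroundTruth(model=model, design=design, noise_sd=0.0)


@pytest.fixture
def planted_two_node(tiny_registry):
    """ACT1 -> PROT1 with w = +0.8, noiseless responses at 4 doses."""
    truth = planted_truth(
        tiny_registry, [("ACT1", "PROT1", 0.8)],
        design=pn.PerturbationDesign({
            f"c{k}": (pn.Perturbation("ACT1", s),)
            for k, s in enumerate((0.5, 1.0, 1.5, 2.0))}))
    data = pn.simulate_response_map(truth, noise_sd=0.0)
    return truth, data
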