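"""Response-map loading, normalization, and quality filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st

import pertnet as pn


def write_inputs(tmp_path, registry, values, design_rows):
    matrix = tmp_path / "response.tsv"
    frame = pd.DataFrame(values, columns=list(registry.measured))
    frame.insert(0, "condition_id", [f"c{i}" for i in range(len(frame))])
    frame.to_csv(matrix, sep="\t", index=False)
    design = tmp_path / "design.tsv"
    pd.DataFrame(design_rows, columns=["condition_id", "drug", "dose_label",
                                       "strength"]).to_csv(design, sep="\t",
                                                           index=False)
    return matrix, design


class TestLoadResponseMap:
    def test_loads_conditions_and_synthesizes_activity_columns(
            self, small_registry, tmp_path):
        values = np.arange(8.0).reshape(2, 4) / 10
        rows = [("c0", "D1", "IC40", 1.0), ("c1", "D1", "IC40", 1.0),
                ("c1", "D2", "IC40", 2.0)]
        matrix, design = write_inputs(tmp_path, small_registry, values, rows)
        rmap = pn.load_response_map(matrix, design, small_registry)
        assert rmap.condition_ids == ("c0", "c1")
        # activity columns come from the design: tanh(-strength), 0 untargeted
        assert rmap.values.loc["c0", "ACT1"] == pytest.approx(np.tanh(-1.0))
        assert rmap.values.loc["c0", "ACT2"] == 0.0
        assert rmap.values.loc["c1", "ACT2"] == pytest.approx(np.tanh(-2.0))
        assert np.allclose(rmap.values.loc["c0", list(small_registry.measured)],
                           values[0])

    def test_empty_condition_list_is_an_error(self, small_registry, tmp_path):
        matrix, design = write_inputs(tmp_path, small_registry,
                                      np.zeros((0, 4)), [])
        with pytest.raises(ValueError, match="no conditions"):
            pn.load_response_map(matrix, design, small_registry)

    def test_all_zero_single_condition(self, small_registry, tmp_path):
        matrix, design = write_inputs(tmp_path, small_registry,
                                      np.zeros((1, 4)),
                                      [("c0", "D1", "", 0.0)])
        rmap = pn.load_response_map(matrix, design, small_registry)
        assert np.all(rmap.matrix() == 0.0)

    def test_unknown_node_id_is_schema_error(self, small_registry, tmp_path):
        matrix, design = write_inputs(tmp_path, small_registry,
                                      np.zeros((1, 4)),
                                      [("c0", "D1", "", 1.0)])
        frame = pd.read_csv(matrix, sep="\t")
        frame["MYSTERY"] = 0.0
        frame.to_csv(matrix, sep="\t", index=False)
        with pytest.raises(ValueError, match="MYSTERY"):
            pn.load_response_map(matrix, design, small_registry)

    def test_non_numeric_cell_reports_location(self, small_registry, tmp_path):
        matrix, design = write_inputs(tmp_path, small_registry,
                                      np.zeros((1, 4)),
                                      [("c0", "D1", "", 1.0)])
        frame = pd.read_csv(matrix, sep="\t", dtype=str)
        frame.loc[0, "PROT2"] = "oops"
        frame.to_csv(matrix, sep="\t", index=False)
        with pytest.raises(ValueError, match="PROT2"):
            pn.load_response_map(matrix, design, small_registry)


class TestNormalizeLog2:
    @pytest.mark.parametrize("perturbed, unperturbed, expected", [
        ([[3.0, 7.0]], [3.0, 7.0], [[0.0, 0.0]]),        # identity
        ([[6.0, 14.0]], [3.0, 7.0], [[1.0, 1.0]]),       # doubling
        ([[1.5]], [3.0], [[-1.0]]),                      # halving
    ])
    def test_reference_values(self, perturbed, unperturbed, expected):
        assert np.allclose(pn.normalize_log2(perturbed, unperturbed), expected)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            pn.normalize_log2([[0.0]], [1.0])
        with pytest.raises(ValueError):
            pn.normalize_log2([[1.0]], [-2.0])

    @given(st.lists(st.floats(0.01, 1e4), min_size=1, max_size=8))
    @hyp_settings(max_examples=50, deadline=None)
    def test_round_trip(self, baseline):
        baseline = np.array(baseline)
        rng = np.random.default_rng(0)
        perturbed = baseline * rng.uniform(0.1, 10, size=baseline.size)
        x = pn.normalize_log2(perturbed[None, :], baseline)
        assert np.allclose(2.0 ** x * baseline, perturbed, rtol=1e-12)


class TestIterativeSignalFilter:
    def test_constant_data_selects_nothing(self):
        values = pd.DataFrame({"a": [1.0] * 10, "b": [1.0] * 10})
        assert pn.iterative_signal_filter(values) == set()

    def test_isolated_outlier_is_signal(self):
        # bounded noise: |x| <= 1 < 2.5 sigma, so the cluster never flags
        rng = np.random.default_rng(42)
        cluster = rng.uniform(-1.0, 1.0, size=100)
        values = {"quiet": cluster, "loud": np.array([50.0 * cluster.std()])}
        assert pn.iterative_signal_filter(values) == {"loud"}

    def test_iteration_tightens_sigma(self):
        # one huge outlier inflates sigma enough to hide a medium one at
        # first; removing it on iteration 1 exposes the medium outlier
        base = np.zeros(200)
        values = {"quiet": base, "medium": np.array([6.0]),
                  "huge": np.array([1000.0])}
        flagged = pn.iterative_signal_filter(values, threshold_sd=2.5)
        assert flagged == {"medium", "huge"}

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(-1, 1, 50)
        b = np.array([30.0, -30.0])
        direct = pn.iterative_signal_filter({"a": a, "b": b})
        shuffled = pn.iterative_signal_filter(
            {"a": a[rng.permutation(50)], "b": b[::-1]})
        assert direct == shuffled == {"b"}

    def test_requires_two_points(self):
        with pytest.raises(ValueError):
            pn.iterative_signal_filter({"a": np.array([1.0])})


class TestReproducibilityFilter:
    def test_perfect_replicates_retained(self):
        assert pn.reproducibility_filter({"n": [100.0, 100.0, 100.0]}) == {"n"}

    def test_noisy_pair_dropped(self):
        # CV of (100, 140) = sd/mean = 28.28/120 ~ 0.2357 > 0.15
        assert pn.coefficient_of_variation([100.0, 140.0]) == pytest.approx(
            0.23570, abs=1e-4)
        assert pn.reproducibility_filter({"n": [100.0, 140.0]}) == set()

    def test_zero_mean_group_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            kept = pn.reproducibility_filter({"n": [-1.0, 1.0]})
        assert kept == set()
        assert "CV undefined" in caplog.text

    def test_multiple_groups_any_failure_drops(self):
        groups = {"n": [[10.0, 10.1, 9.9], [10.0, 15.0]]}
        assert pn.reproducibility_filter(groups) == set()

    def test_filters_shrink_and_preserve_classes(self, small_registry):
        truth = pn.sample_ground_truth_network(3, 1, 2, 4, seed=1)
        data = pn.simulate_response_map(truth, noise_sd=0.0)
        keep = set(truth.registry.measured) - {"PROT2"}
        sub, reg = data.restrict_nodes(keep)
        assert set(reg.measured) < set(truth.registry.measured)
        for n in reg.node_ids:
            assert reg.node_class[n] == truth.registry.node_class[n]
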