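"""BP update equations, marginals, cost function, and map networks."""

import numpy as np
import pytest

import pertnet as pn
from pertnet.bp import candidate_parents
from pertnet.grid import EDGE_GRID, GRID_SIZE
from .conftest import planted_truth
from .oracles import boltzmann_row_marginals


UNIFORM = np.full(GRID_SIZE, 1.0 / GRID_SIZE)


class TestUpdateEdgeMarginal:
    def test_sparsity_factor_closed_form(self):
        # uniform incoming, no prior, lambda=5:
        # P(0) = 1 / (1 + 10 e^-5) ~ 0.9369, rest uniform
        out = pn.update_edge_marginal([UNIFORM, UNIFORM],
                                      settings=pn.BPSettings(lambda_=5.0))
        p0 = 1.0 / (1.0 + 10.0 * np.exp(-5.0))
        assert out[EDGE_GRID == 0.0][0] == pytest.approx(p0, abs=1e-12)
        assert out[EDGE_GRID == 0.0][0] == pytest.approx(0.9369, abs=1e-4)
        nonzero = out[EDGE_GRID != 0.0]
        assert np.allclose(nonzero, nonzero[0])

    def test_no_penalty_no_prior_gives_uniform(self):
        out = pn.update_edge_marginal([UNIFORM] * 3,
                                      settings=pn.BPSettings(lambda_=0.0,
                                                             kappa=0.0))
        assert np.allclose(out, UNIFORM)

    def test_huge_kappa_forces_prior_sign(self):
        edge = pn.PriorEdge("ACT1", "PROT1", "activating", kappa=1.0)
        out = pn.update_edge_marginal(
            [UNIFORM], prior_edge=edge,
            settings=pn.BPSettings(lambda_=5.0, kappa=500.0))
        assert out[EDGE_GRID > 0].sum() == pytest.approx(1.0, abs=1e-12)

    def test_messages_renormalized(self):
        rng = np.random.default_rng(0)
        msgs = [rng.dirichlet(np.ones(GRID_SIZE)) for _ in range(5)]
        out = pn.update_edge_marginal(msgs)
        assert out.sum() == pytest.approx(1.0)
        assert np.all(out >= 0)


class TestUpdateCavityBias:
    def test_beta_zero_gives_uniform(self):
        out = pn.update_cavity_bias([UNIFORM], [0.5], x_k=0.7, x_target=0.3,
                                    settings=pn.BPSettings(beta=0.0))
        assert np.allclose(out, UNIFORM)

    def test_delta_marginals_collapse_to_point_evaluation(self):
        # all non-cavity marginals are delta functions -> the integral
        # collapses to a point evaluation at s_bar
        delta = np.zeros(GRID_SIZE)
        delta[EDGE_GRID == 0.6] = 1.0
        s = pn.BPSettings(beta=2.0)
        xs, xk, xt = 0.5, 0.8, 0.4
        out = pn.update_cavity_bias([delta], [xs], x_k=xk, x_target=xt,
                                    settings=s)
        expect = np.exp(-s.beta * (xt - np.tanh(0.6 * xs
                                                + EDGE_GRID * xk)) ** 2)
        expect /= expect.sum()
        assert np.allclose(out, expect, atol=1e-12)

    def test_gaussian_route_matches_exact_when_variance_small(self):
        # nearly deterministic non-cavity marginal: the Gaussian
        # approximation converges to the exhaustive summation
        sharp = np.full(GRID_SIZE, 1e-9)
        sharp[EDGE_GRID == 0.4] = 1.0
        sharp /= sharp.sum()
        kw = dict(x_noncavity=[0.6], x_k=0.9, x_target=0.5,
                  settings=pn.BPSettings(beta=2.0, quad_order=40))
        exact = pn.update_cavity_bias([sharp], exact=True, **kw)
        gauss = pn.update_cavity_bias([sharp], exact=False, **kw)
        assert np.max(np.abs(exact - gauss)) < 1e-4

    def test_two_node_single_condition_matches_enumeration(self, tiny_registry,
                                                           planted_two_node):
        # exhaustive Boltzmann summation over every configuration of a
        # 2-node system reproduces the converged BP marginal exactly
        truth, data = planted_two_node
        s = pn.BPSettings(seed=1, convergence_tol=1e-9, max_sweeps=2000)
        marg = pn.run_bp(data, settings=s)
        ref = boltzmann_row_marginals(
            data.matrix(), data.u_matrix(),
            tiny_registry.index("PROT1"), [tiny_registry.index("ACT1")],
            beta=s.beta, lam=s.lambda_)[0]
        assert np.max(np.abs(marg[("PROT1", "ACT1")] - ref)) < 1e-6


class TestRunBp:
    def test_zero_data_peaks_at_zero(self, three_node_registry):
        truth = planted_truth(three_node_registry, [],
                              single_doses=(0.0,), pair_dose_combos=())
        data = pn.simulate_response_map(truth, noise_sd=0.0)
        marg = pn.run_bp(data, settings=pn.BPSettings(seed=2))
        for pair in marg.pairs():
            assert EDGE_GRID[np.argmax(marg[pair])] == 0.0

    def test_planted_activation_recovers_positive_mass(self, planted_two_node):
        # four conditions carry beta*dSSE ~ 2.5 of evidence, below the
        # default sparsity penalty of 5; at lambda = 2 the planted
        # activation dominates the marginal
        truth, data = planted_two_node
        marg = pn.run_bp(data, settings=pn.BPSettings(seed=3, lambda_=1.0))
        P = marg[("PROT1", "ACT1")]
        assert P[EDGE_GRID > 0].sum() > 0.9
        assert EDGE_GRID[np.argmax(P)] == 0.8      # the planted strength

    def test_marginals_normalized(self, planted_two_node):
        _, data = planted_two_node
        marg = pn.run_bp(data, settings=pn.BPSettings(seed=4))
        for pair in marg.pairs():
            assert marg[pair].sum() == pytest.approx(1.0)
            assert np.all(marg[pair] >= 0)

    def test_structural_exclusions(self, small_registry):
        truth = pn.sample_ground_truth_network(3, 1, 2, 5, seed=6)
        data = pn.simulate_response_map(truth, noise_sd=0.0)
        marg = pn.run_bp(data, settings=pn.BPSettings(seed=6))
        targets = {t for (t, _s) in marg.pairs()}
        sources = {s for (_t, s) in marg.pairs()}
        assert not targets & set(small_registry.activity)      # inputs only
        assert not sources & set(small_registry.phenotypic)    # sinks
        assert all(t != s for t, s in marg.pairs())

    def test_phenotype_sources_configurable(self, small_registry):
        assert "PHEN1" not in candidate_parents(small_registry, "PROT1")
        assert "PHEN1" in candidate_parents(small_registry, "PROT1",
                                            allow_phenotype_sources=True)


class TestMapNetwork:
    def _marginals(self, registry, vectors):
        return pn.EdgeMarginals(registry=registry, P=vectors)

    def test_peaked_at_zero_gives_no_edge(self, tiny_registry):
        P = np.full(GRID_SIZE, 0.01)
        P[EDGE_GRID == 0.0] = 0.9
        P /= P.sum()
        net = pn.map_network(self._marginals(tiny_registry,
                                             {("PROT1", "ACT1"): P}))
        assert net.n_edges == 0

    def test_tie_prefers_smaller_magnitude_then_lower_index(self, tiny_registry):
        P = np.zeros(GRID_SIZE)
        P[EDGE_GRID == 0.2] = 0.5
        P[EDGE_GRID == -0.2] = 0.5
        net = pn.map_network(self._marginals(tiny_registry,
                                             {("PROT1", "ACT1"): P}))
        # equal |w|: the lower grid index (-0.2) wins
        assert net.W[tiny_registry.index("PROT1"),
                     tiny_registry.index("ACT1")] == -0.2

        P2 = np.zeros(GRID_SIZE)
        P2[EDGE_GRID == 0.4] = 0.5
        P2[EDGE_GRID == -0.8] = 0.5
        net2 = pn.map_network(self._marginals(tiny_registry,
                                              {("PROT1", "ACT1"): P2}))
        assert net2.W[tiny_registry.index("PROT1"),
                      tiny_registry.index("ACT1")] == 0.4


class TestModelCost:
    def test_empty_network_zero_data_costs_nothing(self, three_node_registry):
        truth = planted_truth(three_node_registry, [],
                              single_doses=(0.0,), pair_dose_combos=())
        data = pn.simulate_response_map(truth, noise_sd=0.0)
        cost = pn.model_cost(truth.model, data, settings=pn.BPSettings())
        assert cost == pytest.approx(0.0, abs=1e-12)

    def test_perfect_fit_costs_complexity_only(self, planted_two_node):
        truth, data = planted_two_node
        cost = pn.model_cost(truth.model, data,
                             settings=pn.BPSettings(lambda_=5.0))
        assert cost == pytest.approx(5.0, abs=1e-8)

    def test_matching_prior_cancels_complexity(self, planted_two_node):
        truth, data = planted_two_node
        prior = pn.PriorNetwork()
        prior.add(pn.PriorEdge("ACT1", "PROT1", "activating", kappa=5.0))
        cost = pn.model_cost(truth.model, data, prior=prior,
                             settings=pn.BPSettings(lambda_=5.0, kappa=5.0))
        assert cost == pytest.approx(0.0, abs=1e-8)

    def test_breakdown_components(self, planted_two_node):
        truth, data = planted_two_node
        out = pn.model_cost(truth.model, data, settings=pn.BPSettings(),
                            breakdown=True)
        assert out["sse"] == pytest.approx(0.0, abs=1e-10)
        assert out["complexity"] == 5.0
        assert out["prior"] == 0.0
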