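"""Causal effects, mediation, aggregates, mediation graphs, DTE."""

import numpy as np
import pytest

import lagcausal as lc
from helpers import enumerate_paths_psi, random_sparse_stable_model


def _graph_from_phi(phi, labels=None):
    """A TimeSeriesGraph whose links are exactly the nonzero phi entries."""
    n, _, lp1 = phi.shape
    val = np.abs(np.sign(phi)).astype(float)
    p = np.where(phi != 0, 0.0, 1.0)
    return lc.TimeSeriesGraph(
        val_matrix=val, p_matrix=p, tau_max=lp1 - 1, alpha=0.01,
        labels=labels or [f"X{i + 1}" for i in range(n)],
    )


class TestPathCoefficients:
    def test_single_link_recovered(self):
        m = lc.make_var_model(2, [(0, 1, 1, 0.5)], unit_variance=True)
        s = lc.preprocess(lc.simulate(m, 2000, seed=0))
        phi = lc.fit_path_coefficients(s, _graph_from_phi(m.phi))
        assert phi.phi[1, 0, 1] == pytest.approx(0.5, abs=0.05)
        assert phi.phi[0, 1, 1] == 0.0

    def test_empty_graph_gives_zero_phi(self):
        m = lc.make_var_model(3)
        s = lc.preprocess(lc.simulate(m, 500, seed=1))
        phi = lc.fit_path_coefficients(s, _graph_from_phi(np.zeros((3, 3, 3))))
        assert np.all(phi.phi == 0)

    def test_ar1_autolink_coefficient(self):
        m = lc.make_var_model(1, [(0, 0, 1, 0.6)])
        s = lc.preprocess(lc.simulate(m, 2000, seed=2))
        phi = lc.fit_path_coefficients(s, _graph_from_phi(m.phi))
        assert phi.phi[0, 0, 1] == pytest.approx(0.6, abs=0.05)

    def test_collinear_parents_rejected_with_names(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=300)
        s = lc.ROITimeSeries(np.column_stack([x, x, rng.normal(size=300)]),
                             ["a", "b", "c"])
        phi_struct = np.zeros((3, 3, 2))
        phi_struct[2, 0, 1] = 1  # both identical columns are parents of c
        phi_struct[2, 1, 1] = 1
        with pytest.raises(ValueError, match="collinear.*a.*b"):
            lc.fit_path_coefficients(s, _graph_from_phi(phi_struct, ["a", "b", "c"]))

    def test_recovery_bias_small_over_replicates(self):
        m = lc.make_var_model(
            2, [(0, 0, 1, 0.5), (1, 1, 1, 0.5), (0, 1, 1, 0.4)],
            unit_variance=True,
        )
        g = _graph_from_phi(m.phi)
        est = []
        for rep in range(20):
            s = lc.preprocess(lc.simulate(m, 1000, seed=300 + rep))
            est.append(lc.fit_path_coefficients(s, g).phi[1, 0, 1])
        assert abs(np.mean(est) - 0.4) <= 0.05


class TestCausalEffectMatrices:
    def test_single_link(self):
        phi = np.zeros((2, 2, 2))
        phi[1, 0, 1] = 0.5
        psi = lc.causal_effect_matrices(phi, tau_max=4).psi
        assert psi[1, 0, 1] == 0.5
        assert np.all(psi[1, 0, 2:] == 0)
        np.testing.assert_array_equal(psi[:, :, 0], np.eye(2))

    def test_chain_composition(self, chain_phi):
        psi = lc.causal_effect_matrices(chain_phi, tau_max=3).psi
        assert psi[2, 0, 2] == pytest.approx(0.5 * 0.4)

    def test_autolink_plus_cross_link_path(self):
        phi = np.zeros((2, 2, 2))
        phi[0, 0, 1] = 0.7
        phi[1, 0, 1] = 0.5
        psi = lc.causal_effect_matrices(phi, tau_max=3).psi
        # path 0 ->(auto) 0 -> 1 of total lag 2: 0.7 * 0.5
        assert psi[1, 0, 2] == pytest.approx(0.35)

    def test_recursion_matches_path_enumeration_on_random_models(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            m = random_sparse_stable_model(rng)
            psi = lc.causal_effect_matrices(m.phi, tau_max=5).psi
            oracle = enumerate_paths_psi(
                np.concatenate(
                    [m.phi, np.zeros((m.n_vars, m.n_vars, 6 - m.phi.shape[2]))],
                    axis=2,
                ) if m.phi.shape[2] < 6 else m.phi,
                5,
            )
            np.testing.assert_allclose(psi, oracle, atol=1e-10)

    def test_negative_effect_sign_preserved_end_to_end(self):
        m = lc.make_var_model(
            2, [(0, 1, 1, -0.4), (0, 0, 1, 0.4)], unit_variance=True
        )
        s = lc.simulate(m, 2000, seed=5)
        est = lc.PCMCI(tau_max=3).fit(s)
        eff = lc.CausalEffectAnalysis().fit(lc.preprocess(s), est.graph_)
        assert eff.phi_.phi[1, 0, 1] < -0.3
        assert eff.psi_.psi[1, 0, 1] < -0.3


class TestMediation:
    def test_chain_unique_mediator_carries_whole_effect(self, chain_phi):
        _, mce = lc.mediated_causal_effect(chain_phi, k=1, tau_max=3)
        psi = lc.causal_effect_matrices(chain_phi, tau_max=3).psi
        assert mce[2, 0, 2] == pytest.approx(psi[2, 0, 2])

    def test_off_path_node_mediates_nothing(self, chain_phi):
        phi = np.zeros((4, 4, 2))
        phi[:3, :3, :] = chain_phi
        _, mce = lc.mediated_causal_effect(phi, k=3, tau_max=3)
        assert np.all(mce == 0)

    def test_diamond_branch_products(self, diamond_phi):
        psi = lc.causal_effect_matrices(diamond_phi, tau_max=2).psi
        _, mce1 = lc.mediated_causal_effect(diamond_phi, k=1, tau_max=2)
        _, mce2 = lc.mediated_causal_effect(diamond_phi, k=2, tau_max=2)
        assert psi[3, 0, 2] == pytest.approx(0.20 + 0.12)
        assert mce1[3, 0, 2] == pytest.approx(0.20)
        assert mce2[3, 0, 2] == pytest.approx(0.12)

    def test_blocking_soundness_on_random_models(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            m = random_sparse_stable_model(rng)
            n = m.n_vars
            for k in range(n):
                blocked, _ = lc.mediated_causal_effect(m.phi, k, tau_max=5)
                # no effect may reach k once all links into k are removed
                off = [i for i in range(n) if i != k]
                assert np.all(blocked.psi[k, off, 1:] == 0)

    def test_single_membership_paths_mce_sums_to_ce(self, diamond_phi):
        # mediators 1 and 2 partition all 0 -> 3 paths
        psi = lc.causal_effect_matrices(diamond_phi, tau_max=2).psi
        total = sum(
            lc.mediated_causal_effect(diamond_phi, k, tau_max=2)[1][3, 0, 2]
            for k in (1, 2)
        )
        assert total == pytest.approx(psi[3, 0, 2])


class TestAggregates:
    def test_hand_enumerated_three_node_example(self):
        phi = np.zeros((3, 3, 2))
        phi[1, 0, 1] = 0.5
        agg = lc.aggregate_measures(phi, tau_max=2)
        np.testing.assert_allclose(agg.ace, [0.25, 0.0, 0.0])
        np.testing.assert_allclose(agg.acs, [0.0, 0.25, 0.0])

    def test_random_phi_matches_direct_enumeration(self):
        rng = np.random.default_rng(7)
        phi = np.zeros((4, 4, 3))
        phi[:, :, 1:] = rng.uniform(-0.3, 0.3, size=(4, 4, 2))
        phi[:, :, 1:] *= rng.random(size=(4, 4, 2)) < 0.5
        agg = lc.aggregate_measures(phi, tau_max=4)
        psi = lc.causal_effect_matrices(phi, tau_max=4).psi
        ce_max = np.abs(psi[:, :, 1:]).max(axis=2)
        for i in range(4):
            expected_ace = np.mean([ce_max[j, i] for j in range(4) if j != i])
            expected_acs = np.mean([ce_max[i, j] for j in range(4) if j != i])
            assert agg.ace[i] == pytest.approx(expected_ace)
            assert agg.acs[i] == pytest.approx(expected_acs)

    def test_chain_amce_only_for_true_mediator(self, chain_phi):
        agg = lc.aggregate_measures(chain_phi, tau_max=3)
        assert agg.amce[1] > 0
        assert agg.amce[0] == 0
        assert agg.amce[2] == 0
        assert agg.c_k_cardinality[1] == 1

    def test_single_component_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            lc.aggregate_measures(np.zeros((1, 1, 2)))


class TestMediationGraph:
    def test_chain_query_yields_unique_path(self, chain_phi):
        g = _graph_from_phi(chain_phi)
        phi = lc.PathCoefficients(chain_phi, g.labels)
        res = lc.mediation_graph(g, phi, 0, 2, 2)
        assert set(res.ts_graph.nodes) == {"X1@t-2", "X2@t-1", "X3@t"}
        assert res.ts_graph.number_of_edges() == 2
        assert res.total_ce == pytest.approx(0.2)
        assert res.mce["X2"] == pytest.approx(0.2)

    def test_unconnected_query_is_empty_not_error(self, chain_phi):
        g = _graph_from_phi(chain_phi)
        phi = lc.PathCoefficients(chain_phi, g.labels)
        res = lc.mediation_graph(g, phi, 2, 0, 2)  # against the arrows
        assert res.is_empty
        assert res.total_ce == 0.0

    def test_diamond_query_contains_both_branches(self, diamond_phi):
        g = _graph_from_phi(diamond_phi)
        phi = lc.PathCoefficients(diamond_phi, g.labels)
        res = lc.mediation_graph(g, phi, 0, 3, 2)
        assert "X2@t-1" in res.ts_graph and "X3@t-1" in res.ts_graph
        assert res.mce["X2"] == pytest.approx(0.20)
        assert res.mce["X3"] == pytest.approx(0.12)
        assert set(res.summary_graph.nodes) == {"X1", "X2", "X3", "X4"}

    def test_export_round_trip(self, tmp_path, diamond_phi):
        import networkx as nx

        g = _graph_from_phi(diamond_phi)
        phi = lc.PathCoefficients(diamond_phi, g.labels)
        res = lc.mediation_graph(g, phi, 0, 3, 2)
        p = tmp_path / "med.graphml"
        res.write_graphml(p)
        back = nx.read_graphml(p)
        assert back.number_of_nodes() == res.ts_graph.number_of_nodes()
        res.write_dot(tmp_path / "med.dot")
        assert "->" in (tmp_path / "med.dot").read_text()


class TestDecomposedTransferEntropy:
    def test_absent_coupling_gives_near_zero_dte(self):
        m = lc.make_var_model(
            2, [(0, 0, 1, 0.5), (1, 1, 1, 0.5)], unit_variance=True
        )
        s = lc.preprocess(lc.simulate(m, 800, seed=8))
        g = _graph_from_phi(m.phi)
        total, terms = lc.decomposed_transfer_entropy(s, g, 0, 1, tau_star=1)
        assert abs(total) < 0.05

    def test_single_gaussian_link_matches_closed_form(self):
        m = lc.make_var_model(
            2, [(0, 0, 1, 0.5), (1, 1, 1, 0.5), (0, 1, 1, 0.5)],
            unit_variance=True,
        )
        s = lc.preprocess(lc.simulate(m, 1500, seed=9))
        g = _graph_from_phi(m.phi)
        # oracle: Gaussian CMI = -0.5 ln(1 - rho_partial^2) with rho_partial
        # the sample partial correlation of the same lagged triple
        rho_p = lc.parcorr_test(
            s.values[1:-1, 0], s.values[2:, 1],
            np.column_stack([s.values[:-2, 0], s.values[1:-1, 1]]),
        ).statistic
        truth = -0.5 * np.log(1 - rho_p**2)
        total, terms = lc.decomposed_transfer_entropy(s, g, 0, 1, tau_star=1)
        assert terms[0] == pytest.approx(truth, abs=0.07)

    def test_irrelevant_third_variable_leaves_dte_unchanged(self):
        links = [(0, 0, 1, 0.5), (1, 1, 1, 0.5), (0, 1, 1, 0.5)]
        m2 = lc.make_var_model(2, links, unit_variance=True)
        m3 = lc.make_var_model(3, links + [(2, 2, 1, 0.5)], unit_variance=True)
        s2 = lc.preprocess(lc.simulate(m2, 1000, seed=10))
        s3 = lc.preprocess(lc.simulate(m3, 1000, seed=10))
        pad2 = np.pad(m2.phi, ((0, 0), (0, 0), (0, 1)))
        pad3 = np.pad(m3.phi, ((0, 0), (0, 0), (0, 1)))
        t2, _ = lc.decomposed_transfer_entropy(s2, _graph_from_phi(pad2), 0, 1, 2)
        t3, _ = lc.decomposed_transfer_entropy(s3, _graph_from_phi(pad3), 0, 1, 2)
        # graph-derived conditions exclude the extra variable entirely
        assert t2 == pytest.approx(t3, abs=0.08)

    def test_infeasible_condition_dimension_advises_max_conds(self):
        m = lc.make_var_model(
            2, [(0, 0, 1, 0.5), (1, 1, 1, 0.5), (0, 1, 1, 0.5)],
            unit_variance=True,
        )
        s = lc.preprocess(lc.simulate(m, 40, seed=11))
        g = _graph_from_phi(np.pad(m.phi, ((0, 0), (0, 0), (0, 14))))
        with pytest.raises(ValueError, match="max_conds"):
            lc.decomposed_transfer_entropy(s, g, 0, 1, tau_star=15)
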