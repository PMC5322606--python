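"""Analytic per-branch expectations: integral factors, endpoint conditioning,
branch posteriors, whole-tree mapping."""

import numpy as np
import pytest

import statemap as sm
from statemap.expectations import (
    _branch_expectations_quadrature,
    integral_factor_matrix,
)
from .conftest import (
    enumeration_node_marginals,
    quadrature_dwell,
    quadrature_transitions,
    random_ard_model,
    random_reversible_model,
)


class TestIntegralFactors:
    def test_single_zero_eigenvalue(self):
        J = integral_factor_matrix(np.array([0.0]), 3.0).J
        np.testing.assert_allclose(J, [[3.0]])

    def test_zero_branch_returns_zero_matrix(self):
        J = integral_factor_matrix(np.array([0.0, -2.0, -5.0]), 0.0).J
        np.testing.assert_allclose(J, 0.0)

    def test_matches_quadrature(self):
        from scipy.integrate import quad
        lam = np.array([0.0, -2.0])
        J = integral_factor_matrix(lam, 1.0).J
        expected, _ = quad(lambda tau: np.exp(-2.0 * (1 - tau)), 0, 1, epsabs=1e-13)
        assert J[0, 1] == pytest.approx(expected, abs=1e-10)
        assert J[0, 1] == pytest.approx((1 - np.exp(-2)) / 2, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        lam = -rng.uniform(0, 4, size=5)
        lam[0] = 0.0
        T = rng.uniform(0.1, 3.0)
        J = integral_factor_matrix(lam, T).J
        np.testing.assert_allclose(J, J.T, atol=1e-10)
        assert np.all(J >= 0)
        bound = T * np.exp(T * np.maximum(lam[:, None], lam[None, :]))
        assert np.all(J <= bound + 1e-10)

    def test_equal_eigenvalue_limit(self):
        lam = np.array([-1.0, -1.0 + 1e-12])
        J = integral_factor_matrix(lam, 2.0).J
        np.testing.assert_allclose(J, 2.0 * np.exp(-2.0), atol=1e-9)


class TestEndpointConditioned:
    def test_dwell_conservation_over_states(self):
        rng = np.random.default_rng(3)
        model = random_reversible_model(3, rng)
        d = sm.spectral_decompose(model)
        T = 1.3
        total = sum(sm.endpoint_conditioned_dwell(d, T, i) for i in range(3))
        np.testing.assert_allclose(total, T, atol=1e-8)

    def test_short_branch_limit(self, er2_model):
        d = sm.spectral_decompose(er2_model)
        T = 1e-8
        D0 = sm.endpoint_conditioned_dwell(d, T, 0)
        D1 = sm.endpoint_conditioned_dwell(d, T, 1)
        assert D0[0, 0] == pytest.approx(T, rel=1e-4)
        assert D1[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_dwell_matches_closed_form_quadrature(self, er2_model):
        d = sm.spectral_decompose(er2_model)
        D0 = sm.endpoint_conditioned_dwell(d, 1.0, 0)
        from scipy.integrate import quad
        p00 = lambda t: (1 + np.exp(-2 * t)) / 2
        expected = quad(lambda tau: p00(tau) * p00(1 - tau), 0, 1)[0] / p00(1)
        assert D0[0, 0] == pytest.approx(expected, abs=1e-8)

    def test_diagonal_count_requested_is_error(self, er2_model):
        d = sm.spectral_decompose(er2_model)
        with pytest.raises(ValueError):
            sm.endpoint_conditioned_transitions(d, er2_model.Q, 1.0, 1, 1)

    def test_transitions_short_branch_and_parity(self, er2_model):
        d = sm.spectral_decompose(er2_model)
        Q = er2_model.Q
        N = sm.endpoint_conditioned_transitions(d, Q, 1e-9, 0, 1)
        assert N[0, 0] == pytest.approx(0.0, abs=1e-6)
        # different endpoints force at least one change in total
        T = 0.8
        total = (
            sm.endpoint_conditioned_transitions(d, Q, T, 0, 1)
            + sm.endpoint_conditioned_transitions(d, Q, T, 1, 0)
        )
        assert total[0, 1] >= 1.0 - 1e-10
        assert total[1, 0] >= 1.0 - 1e-10

    @pytest.mark.parametrize("s,seed", [(2, 0), (2, 1), (3, 2), (3, 3), (3, 4)])
    def test_matches_general_quadrature(self, s, seed):
        rng = np.random.default_rng(seed)
        model = random_ard_model(s, rng) if seed % 2 else random_reversible_model(s, rng)
        d = sm.spectral_decompose(model)
        T = float(rng.uniform(0.2, 2.0))
        a, b = rng.integers(s), rng.integers(s)
        i = int(rng.integers(s))
        j = (i + 1) % s
        D = sm.endpoint_conditioned_dwell(d, T, i)
        assert D[a, b] == pytest.approx(
            quadrature_dwell(model.Q, T, i, a, b), rel=1e-8, abs=1e-10
        )
        N = sm.endpoint_conditioned_transitions(d, model.Q, T, i, j)
        assert N[a, b] == pytest.approx(
            quadrature_transitions(model.Q, T, i, j, a, b), rel=1e-8, abs=1e-10
        )

    def test_sampler_triangle_closes(self, er2_model):
        """Endpoint-conditioned path sampler agrees with the analytic
        conditional dwell (the analytic <-> simulation leg)."""
        Q = er2_model.Q
        d = sm.spectral_decompose(er2_model)
        D0 = sm.endpoint_conditioned_dwell(d, 1.0, 0)[0, 0]
        rng = np.random.default_rng(123)
        draws = np.empty(30_000)
        for k in range(len(draws)):
            segs = sm.sample_endpoint_conditioned_path(Q, 1.0, 0, 0, rng=rng)
            draws[k] = sum(dur for st, dur in segs if st == 0)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - D0) < 3 * se


class TestBranchPosteriors:
    def test_no_data_identity(self, er2_model):
        tree = sm.simulate_pure_birth_tree(8, 1.0, seed=5)
        data = sm.CharacterData.from_dict(
            {t: "?" for t in tree.taxon_namespace}, alphabet=["0", "1"]
        )
        d = sm.spectral_decompose(er2_model)
        bp = sm.branch_posteriors(tree, data, er2_model)
        for v, b in bp.items():
            P = sm.transition_probabilities(d, float(tree.edge_length[v]))
            np.testing.assert_allclose(b.W, 0.5 * P, atol=1e-10)
            np.testing.assert_allclose(b.parent_marginal, 0.5, atol=1e-10)

    def test_observed_tips_are_point_masses(self, cherry, er2_model):
        data = sm.CharacterData.from_dict({"A": "0", "B": "1"}, alphabet=["0", "1"])
        bp = sm.branch_posteriors(cherry, data, er2_model)
        for v, b in bp.items():
            lab = cherry.labels[v]
            want = 0 if lab == "A" else 1
            np.testing.assert_allclose(b.child_marginal[want], 1.0, atol=1e-12)

    def test_sums_and_adjacent_consistency(self, yule16, er2_model):
        tree, data, _ = yule16
        bp = sm.branch_posteriors(tree, data, er2_model)
        for v, b in bp.items():
            assert b.W.sum() == pytest.approx(1.0, abs=1e-10)
            p = tree.parent[v]
            if p != tree.root and p >= 0:
                np.testing.assert_allclose(
                    b.parent_marginal, bp[p].child_marginal, atol=1e-10
                )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_marginals_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        tree = sm.simulate_pure_birth_tree(6, 1.0, seed=400 + seed)
        model = random_reversible_model(3, rng)
        data = sm.simulate_history(tree, model, seed=seed).tip_states()
        marg = enumeration_node_marginals(tree, data, model)
        bp = sm.branch_posteriors(tree, data, model)
        for v, b in bp.items():
            np.testing.assert_allclose(b.child_marginal, marg[v], atol=1e-10)


class TestMapTree:
    def test_conservation_every_branch(self, yule16, er2_model):
        tree, data, _ = yule16
        res = sm.map_tree(tree, data, er2_model)
        np.testing.assert_allclose(
            res.dwell.sum(axis=1), res.branch_lengths, atol=1e-8
        )

    @pytest.mark.parametrize("s,constraint", [(2, "ER"), (3, "SYM"), (3, "ARD")])
    def test_no_data_unconditional_identity(self, s, constraint):
        """Fully ambiguous tips + stationary prior reproduce the closed-form
        unconditional CTMC expectations pi_i*T and pi_i*(-q_ii)*T."""
        rng = np.random.default_rng(s + len(constraint))
        k = {"ER": 1, "SYM": s * (s - 1) // 2, "ARD": s * (s - 1)}[constraint]
        model = sm.build_rate_matrix(rng.uniform(0.4, 1.8, size=k), constraint, s,
                                     pi="stationary")
        tree = sm.simulate_pure_birth_tree(10, 1.0, seed=s)
        data = sm.CharacterData.from_dict(
            {t: "?" for t in tree.taxon_namespace},
            alphabet=[str(i) for i in range(s)],
        )
        res = sm.map_tree(tree, data, model)
        T = res.branch_lengths[:, None]
        np.testing.assert_allclose(res.dwell, model.pi[None, :] * T, atol=1e-8)
        expected_away = model.pi[None, :] * (-np.diag(model.Q))[None, :] * T
        np.testing.assert_allclose(res.away, expected_away, atol=1e-8)

    def test_away_is_row_sum_of_pairwise(self, yule16, er2_model):
        tree, data, _ = yule16
        res = sm.map_tree(tree, data, er2_model)
        np.testing.assert_allclose(res.away, res.pairwise.sum(axis=2), atol=1e-12)
        assert np.all(res.pairwise >= 0)
        np.testing.assert_allclose(np.diagonal(res.pairwise, axis1=1, axis2=2), 0.0)

    def test_zero_length_branch_has_zero_expectations(self, er2_model):
        tree = sm.Tree([-1, 0, 0, 1, 1], [0.0, 0.5, 1.0, 0.0, 0.7],
                       [None, None, "C", "A", "B"])
        data = sm.CharacterData.from_dict({"A": "0", "B": "1", "C": "0"},
                                          alphabet=["0", "1"])
        res = sm.map_tree(tree, data, er2_model)
        i = res.branch_index()[3]  # the zero-length tip branch
        np.testing.assert_allclose(res.dwell[i], 0.0)
        np.testing.assert_allclose(res.away[i], 0.0)

    def test_quadrature_method_agrees_with_spectral(self, er2_model):
        tree = sm.simulate_pure_birth_tree(6, 1.0, seed=9)
        data = sm.simulate_history(tree, er2_model, seed=2).tip_states()
        a = sm.map_tree(tree, data, er2_model, method="spectral")
        b = sm.map_tree(tree, data, er2_model, method="quadrature")
        np.testing.assert_allclose(a.dwell, b.dwell, atol=1e-7)
        np.testing.assert_allclose(a.pairwise, b.pairwise, atol=1e-7)

    def test_tsv_roundtrip_columns(self, yule16, er2_model, tmp_path):
        tree, data, _ = yule16
        res = sm.map_tree(tree, data, er2_model)
        p = tmp_path / "m.tsv"
        res.to_tsv(p)
        import pandas as pd
        df = pd.read_csv(p, sep="\t")
        assert {"branch_clade", "branch_length", "dwell_0", "dwell_frac_0",
                "away_0"} <= set(df.columns)
        np.testing.assert_allclose(
            df[["dwell_0", "dwell_1"]].sum(axis=1), df["branch_length"], atol=1e-6
        )


class TestMapTreeSet:
    def test_identical_trees_identical_results(self, yule16, er2_model):
        tree, data, _ = yule16
        ts = sm.TreeSet([tree, tree, tree])
        out = sm.map_treeset(ts, data, q_mode="per-tree", constraint="ER", seed=0)
        assert len(out) == 3
        for r in out[1:]:
            np.testing.assert_allclose(r.dwell, out[0].dwell, atol=1e-12)
            np.testing.assert_allclose(r.pairwise, out[0].pairwise, atol=1e-12)

    def test_user_q_skips_optimization(self, yule16, er2_model):
        tree, data, _ = yule16
        ts = sm.TreeSet([tree])
        a = sm.map_treeset(ts, data, q_mode="user", rate_matrix=er2_model,
                           constraint="ER")
        b = sm.map_treeset(ts, data, q_mode="user", rate_matrix=er2_model,
                           constraint="ARD")  # constraint ignored in user mode
        np.testing.assert_allclose(a[0].dwell, b[0].dwell, atol=1e-12)

    def test_failure_reports_tree_index(self, er2_model):
        t1 = sm.simulate_pure_birth_tree(4, 1.0, seed=0)
        ts = sm.TreeSet([t1])
        data = sm.CharacterData.from_dict(
            {t: "0" for t in t1.taxon_namespace}, alphabet=["0", "1"]
        )
        data2 = sm.CharacterData.from_dict(
            {t: "0" for t in list(t1.taxon_namespace)[:-1]} | {"zzz": "1"},
            alphabet=["0", "1"],
        )
        with pytest.raises(Exception):
            sm.map_treeset(ts, data2, q_mode="user", rate_matrix=er2_model)
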