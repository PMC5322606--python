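"""Rate matrices, transition probabilities, pruning likelihood, MLE."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import statemap as sm
from statemap.trees import ValidationError
from .conftest import (
    enumeration_log_likelihood,
    random_ard_model,
    random_reversible_model,
    series_expm,
)


class TestBuildRateMatrix:
    def test_er_two_states(self):
        m = sm.build_rate_matrix([1.0], "ER", 2)
        np.testing.assert_allclose(m.Q, [[-1, 1], [1, -1]])
        assert len(m.free_params) == 1

    def test_sym_three_states(self):
        m = sm.build_rate_matrix([0.5, 1.5, 2.5], "SYM", 3)
        assert m.Q[0, 1] == m.Q[1, 0] == 0.5
        assert m.Q[0, 2] == m.Q[2, 0] == 1.5
        assert m.Q[1, 2] == m.Q[2, 1] == 2.5
        np.testing.assert_allclose(m.Q.sum(axis=1), 0, atol=1e-12)

    def test_ard_six_distinct_rates(self):
        rates = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        m = sm.build_rate_matrix(rates, "ARD", 3)
        off = m.Q[~np.eye(3, dtype=bool)]
        assert len(set(np.round(off, 12))) == 6
        np.testing.assert_allclose(m.Q.sum(axis=1), 0, atol=1e-12)

    @pytest.mark.parametrize("constraint,s,k", [("ER", 2, 1), ("SYM", 4, 6), ("ARD", 4, 12)])
    def test_free_param_counts(self, constraint, s, k):
        rates = np.linspace(0.5, 1.5, k)
        m = sm.build_rate_matrix(rates, constraint, s)
        assert len(m.free_params) == k

    def test_wrong_count_and_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            sm.build_rate_matrix([1.0, 2.0], "ER", 2)
        with pytest.raises(ValidationError):
            sm.build_rate_matrix([0.0], "ER", 2)

    def test_stationary_prior_of_ard(self):
        rng = np.random.default_rng(4)
        m = random_ard_model(3, rng).with_pi("stationary")
        np.testing.assert_allclose(m.pi @ m.Q, 0, atol=1e-12)
        assert m.pi.sum() == pytest.approx(1.0)


class TestSpectralDecomposition:
    def test_known_spectrum_er2(self):
        d = sm.spectral_decompose(sm.build_rate_matrix([1.0], "ER", 2))
        np.testing.assert_allclose(sorted(d.lam), [-2.0, 0.0], atol=1e-12)

    @pytest.mark.parametrize("s", [2, 3, 5])
    def test_reconstruction(self, s):
        rng = np.random.default_rng(s)
        for maker in (random_reversible_model, random_ard_model):
            m = maker(s, rng)
            d = sm.spectral_decompose(m)
            rec = (d.U * d.lam) @ d.U_inv
            assert np.abs(np.real_if_close(rec) - m.Q).max() < 1e-9
            assert np.min(np.abs(d.lam)) < 1e-9  # a zero eigenvalue exists

    def test_matches_series_expm_oracle(self):
        rng = np.random.default_rng(99)
        m = random_reversible_model(5, rng)
        d = sm.spectral_decompose(m)
        for t in (0.1, 0.7, 2.3):
            P = sm.transition_probabilities(d, t)
            np.testing.assert_allclose(P, series_expm(m.Q, t), atol=1e-9)


class TestTransitionProbabilities:
    def test_identity_at_zero(self, er2_model):
        d = sm.spectral_decompose(er2_model)
        np.testing.assert_allclose(sm.transition_probabilities(d, 0.0), np.eye(2), atol=1e-12)

    def test_stationary_limit(self, er2_model):
        d = sm.spectral_decompose(er2_model)
        P = sm.transition_probabilities(d, 50.0)
        np.testing.assert_allclose(P, 0.5, atol=1e-10)

    def test_closed_form_2state(self, er2_model):
        d = sm.spectral_decompose(er2_model)
        P = sm.transition_probabilities(d, 1.0)
        assert P[0, 0] == pytest.approx((1 + np.exp(-2)) / 2, abs=1e-12)

    def test_negative_time_rejected(self, er2_model):
        d = sm.spectral_decompose(er2_model)
        with pytest.raises(ValueError):
            sm.transition_probabilities(d, -0.1)

    @given(
        t1=st.floats(0.0, 3.0), t2=st.floats(0.0, 3.0),
        seed=st.integers(0, 50), s=st.sampled_from([2, 3, 4]),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_chapman_kolmogorov(self, t1, t2, seed, s):
        rng = np.random.default_rng(seed)
        m = random_ard_model(s, rng) if seed % 2 else random_reversible_model(s, rng)
        d = sm.spectral_decompose(m)
        P1 = sm.transition_probabilities(d, t1)
        P2 = sm.transition_probabilities(d, t2)
        P12 = sm.transition_probabilities(d, t1 + t2)
        np.testing.assert_allclose(P1 @ P2, P12, atol=1e-9)
        np.testing.assert_allclose(P12.sum(axis=1), 1.0, atol=1e-10)


class TestLikelihood:
    def test_all_ambiguous_gives_zero_loglik(self, yule16, er2_model):
        tree, _, _ = yule16
        data = sm.CharacterData.from_dict(
            {t: "?" for t in tree.taxon_namespace}, alphabet=["0", "1"]
        )
        assert sm.tree_log_likelihood(tree, data, er2_model) == pytest.approx(0.0, abs=1e-12)

    def test_two_tip_zero_branches_forced(self, er2_model):
        tree = sm.Tree([-1, 0, 0], [0.0, 0.0, 0.0], [None, "A", "B"])
        data = sm.CharacterData.from_dict({"A": "0", "B": "0"}, alphabet=["0", "1"])
        ll = sm.tree_log_likelihood(tree, data, er2_model)
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        tree = sm.simulate_pure_birth_tree(5, 1.0, seed=200 + seed)
        s = 3
        model = random_reversible_model(s, rng)
        hist = sm.simulate_history(tree, model, seed=seed)
        data = hist.tip_states()
        ll = sm.tree_log_likelihood(tree, data, model)
        assert ll == pytest.approx(enumeration_log_likelihood(tree, data, model), abs=1e-10)

    def test_alphabet_permutation_invariance(self):
        tree = sm.simulate_pure_birth_tree(6, 1.0, seed=1)
        rng = np.random.default_rng(10)
        model = random_ard_model(3, rng)
        hist = sm.simulate_history(tree, model, seed=0)
        data = hist.tip_states()
        ll = sm.tree_log_likelihood(tree, data, model)
        perm = [2, 0, 1]
        Qp = model.Q[np.ix_(perm, perm)]
        pip = model.pi[perm]
        modp = sm.RateModel(Qp, "ARD", pip, model.free_params)
        alpha = tuple(data.state_alphabet[p] for p in perm)
        datap = sm.CharacterData(alpha, data.assignments)
        llp = sm.tree_log_likelihood(tree, datap, modp)
        assert llp == pytest.approx(ll, abs=1e-10)


class TestEstimateMLE:
    def test_invariant_character_hits_lower_bound(self):
        tree = sm.simulate_pure_birth_tree(8, 1.0, seed=0)
        data = sm.CharacterData.from_dict(
            {t: "0" for t in tree.taxon_namespace}, alphabet=["0", "1"]
        )
        lo, _ = sm.model.default_rate_bounds(tree)
        fit = sm.estimate_mle(tree, data, "ER", starts=2, seed=0)
        assert fit.free_params[0] == pytest.approx(lo, rel=1e-3)

    def test_beats_grid_search(self, yule16):
        tree, data, _ = yule16
        fit = sm.estimate_mle(tree, data, "ER", starts=3, seed=0)
        assert fit.log_likelihood is not None
        lo, hi = sm.model.default_rate_bounds(tree)
        grid = np.geomspace(lo, hi, 50)
        for r in grid:
            m = sm.build_rate_matrix([r], "ER", 2)
            assert fit.log_likelihood >= sm.tree_log_likelihood(tree, data, m) - 1e-8

    def test_pooled_rate_recovery(self):
        """Joint fit of many independent characters recovers the true rate."""
        tree = sm.simulate_pure_birth_tree(128, 1.0, seed=21)
        truth = sm.build_rate_matrix([1.0], "ER", 2)
        datasets = [
            sm.simulate_history(tree, truth, seed=3000 + c).tip_states()
            for c in range(100)
        ]
        fit = sm.estimate_mle(tree, datasets, "ER", starts=1, seed=0)
        assert abs(fit.free_params[0] - 1.0) < 0.2
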