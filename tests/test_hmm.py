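"""Hidden-rates model: generator structure, likelihood, root prior, fitting."""

import numpy as np
import pytest

from conftest import make_tree, random_binary_tree
from oracles import enumerate_likelihood, expm_taylor, two_state_loglik
from phylostab import hmm
from phylostab._treeindex import as_indexed
from phylostab.hmm import RateMatrix


def rand_rates(rng):
    return RateMatrix.from_vector(np.exp(rng.uniform(np.log(0.05), np.log(5.0), 8)))


class TestRateMatrix:
    def test_generator_structure(self):
        Q = RateMatrix(0.5, 1.0, 2.0, 3.0, 0.1, 0.2, 0.3, 0.4).generator()
        assert np.allclose(Q.sum(axis=1), 0.0)
        # dual transitions (value and class change at once) are exactly zero
        assert Q[0, 3] == 0.0 and Q[3, 0] == 0.0
        assert Q[1, 2] == 0.0 and Q[2, 1] == 0.0
        assert Q[0, 2] == 0.5  # gain_S: 0S -> 1S
        assert Q[3, 1] == 3.0  # loss_F: 1F -> 0F

    def test_bounds_enforced(self):
        with pytest.raises(ValueError, match="outside bounds"):
            RateMatrix(0.5, 1.0, 2.0, 300.0, 0.1, 0.2, 0.3, 0.4)


class TestTransitionMatrix:
    def test_zero_time_identity(self):
        Q = RateMatrix(0.5, 1.0, 2.0, 3.0, 0.1, 0.2, 0.3, 0.4)
        assert np.allclose(hmm.transition_matrix(Q, 0.0), np.eye(4))

    def test_negative_time_rejected(self):
        Q = RateMatrix(0.5, 1.0, 2.0, 3.0, 0.1, 0.2, 0.3, 0.4)
        with pytest.raises(ValueError, match="nonnegative"):
            hmm.transition_matrix(Q, -1.0)

    def test_long_time_reaches_stationary(self):
        Q = RateMatrix(0.5, 1.0, 2.0, 3.0, 0.3, 0.2, 0.4, 0.1)
        G = Q.generator()
        # stationary vector: left null space of the generator
        w, V = np.linalg.eig(G.T)
        pi = np.real(V[:, np.argmin(np.abs(w))])
        pi = np.abs(pi) / np.abs(pi).sum()
        P = hmm.transition_matrix(Q, 1e4)
        for row in P:
            assert np.allclose(row, pi, atol=1e-8)

    def test_matches_taylor_series(self):
        rng = np.random.default_rng(13)
        Q = rand_rates(rng)
        P = hmm.transition_matrix(Q, 0.37)
        assert np.allclose(P, expm_taylor(Q.generator(), 0.37), atol=1e-9)

    def test_rows_stochastic(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            Q = rand_rates(rng)
            t = float(rng.uniform(0, 3))
            P = hmm.transition_matrix(Q, t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert P.min() >= 0.0 and P.max() <= 1.0


class TestRootWeighting:
    @pytest.mark.parametrize(
        "partials,prior,combined",
        [
            ((1, 1, 1, 1), (0.25, 0.25, 0.25, 0.25), 1.0),
            ((2, 0, 0, 0), (1, 0, 0, 0), 2.0),
            ((3, 1, 0, 0), (0.75, 0.25, 0, 0), 2.5),
        ],
    )
    def test_conditional_weighting(self, partials, prior, combined):
        p, c = hmm.root_weighting(np.array(partials, dtype=float))
        assert np.allclose(p, prior)
        assert c == pytest.approx(combined)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            hmm.root_weighting(np.zeros(4))


class TestPruningLoglik:
    def test_two_tip_cherry_hand_computation(self):
        """Closed-form sum over root states for a two-tip tree."""
        tree = make_tree("(A:0.4,B:0.9);")
        Q = RateMatrix(0.5, 1.0, 2.0, 3.0, 0.1, 0.2, 0.3, 0.4)
        G = Q.generator()
        from scipy.linalg import expm

        PA, PB = expm(G * 0.4), expm(G * 0.9)
        # A present, B absent
        LA = PA[:, 2] + PA[:, 3]
        LB = PB[:, 0] + PB[:, 1]
        L = LA * LB
        prior = L / L.sum()
        expected = np.log(prior @ L)
        got = hmm.pruning_loglik(tree, {"A": "present", "B": "absent"}, Q)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_all_missing_likelihood_one(self, balanced4):
        Q = RateMatrix(0.5, 1.0, 2.0, 3.0, 0.1, 0.2, 0.3, 0.4)
        ll = hmm.pruning_loglik(balanced4, {t: "missing" for t in "ABCD"}, Q)
        assert ll == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_enumeration_small_trees(self, seed):
        """Pruning equals exhaustive enumeration over all ancestral and
        ambiguous-tip assignments on 4-6 tip trees."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        idx = as_indexed(random_binary_tree(rng, n))
        Q = rand_rates(rng)
        states = ["present", "absent", "missing"]
        trait = {l: states[rng.integers(0, 3)] for l in idx.tip_labels}
        if all(v == "missing" for v in trait.values()):
            trait[idx.tip_labels[0]] = "present"
        ll_enum, _ = enumerate_likelihood(idx, trait, Q.generator())
        ll = hmm.pruning_loglik(idx, trait, Q)
        assert ll == pytest.approx(ll_enum, abs=1e-10)

    def test_loglik_nonpositive(self):
        rng = np.random.default_rng(17)
        idx = as_indexed(random_binary_tree(rng, 8))
        Q = rand_rates(rng)
        trait = {l: ("present" if rng.uniform() < 0.5 else "absent") for l in idx.tip_labels}
        assert hmm.pruning_loglik(idx, trait, Q) <= 0.0

    def test_class_collapse_equals_two_state(self):
        """With class-tied rates the hidden class marginalizes out: the
        4-state likelihood equals the 2-state likelihood for any switch
        rates."""
        rng = np.random.default_rng(23)
        idx = as_indexed(random_binary_tree(rng, 10))
        trait = {l: ("present" if rng.uniform() < 0.5 else "absent") for l in idx.tip_labels}
        trait[idx.tip_labels[0]] = "missing"
        gain, loss = 0.7, 1.3
        ll2 = two_state_loglik(idx, trait, gain, loss)
        for switch in (0.01, 0.5, 7.0):
            Q = RateMatrix(gain, loss, gain, loss, switch, switch, switch, switch)
            ll4 = hmm.pruning_loglik(idx, trait, Q)
            assert ll4 == pytest.approx(ll2, abs=1e-6)


class TestSummarizeRates:
    @pytest.mark.parametrize(
        "occ,expected_gain",
        [(0.0, 0.1), (1.0, 10.0), (0.5, 5.05)],
    )
    def test_occupancy_weighting(self, occ, expected_gain):
        rates = RateMatrix(0.1, 1.0, 10.0, 2.0, 0.1, 0.1, 0.1, 0.1)
        gain, loss = hmm.summarize_rates(rates, occ)
        assert gain == pytest.approx(expected_gain)

    def test_occupancy_bounds(self):
        rates = RateMatrix(0.1, 1.0, 10.0, 2.0, 0.1, 0.1, 0.1, 0.1)
        with pytest.raises(ValueError):
            hmm.summarize_rates(rates, 1.5)


class TestLog10Rate:
    @pytest.mark.parametrize(
        "rate,expected",
        [(0.0, -10.0), (100.0, 2.0), (0.33, np.log10(0.33)), (1e-10, -10.0)],
    )
    def test_floor_and_values(self, rate, expected):
        assert hmm.log10_rate(rate) == pytest.approx(expected, abs=1e-9)

    def test_loss_rate_log_consistency(self):
        # a raw rate of 0.33 transforms to about -0.48 on the log10 scale
        assert hmm.log10_rate(0.33) == pytest.approx(-0.48, abs=0.005)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            hmm.log10_rate(-0.1)


class TestFit:
    def test_all_present_loss_at_floor(self):
        rng = np.random.default_rng(31)
        tree = random_binary_tree(rng, 12)
        trait = {f"t{i+1}": "present" for i in range(12)}
        f = hmm.fit(tree, trait, seed=0, n_starts=2)
        assert f.summary_loss <= 1e-8
        assert hmm.log10_rate(f.summary_loss) == -10.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(37)
        tree = random_binary_tree(rng, 10)
        trait = {f"t{i+1}": ("present" if i < 4 else "absent") for i in range(10)}
        a = hmm.fit(tree, trait, seed=5, n_starts=2)
        b = hmm.fit(tree, trait, seed=5, n_starts=2)
        assert a == b

    def test_no_informative_tip_rejected(self, balanced4):
        with pytest.raises(ValueError, match="non-missing"):
            hmm.fit(balanced4, {t: "missing" for t in "ABCD"}, seed=0)

    def test_monotone_data_support(self):
        """Turning an ambiguous tip into a certain one cannot raise the
        maximized log-likelihood (pure ML selection)."""
        rng = np.random.default_rng(41)
        tree = random_binary_tree(rng, 8)
        base = {f"t{i+1}": ("present" if i % 2 else "absent") for i in range(8)}
        ambiguous = dict(base)
        ambiguous["t1"] = "missing"
        ll_ambiguous = hmm.fit(tree, ambiguous, seed=3, n_starts=3, select="ml").log_likelihood
        ll_certain = hmm.fit(tree, base, seed=3, n_starts=3, select="ml").log_likelihood
        assert ll_certain <= ll_ambiguous + 1e-9

    def test_fit_log_likelihood_nonpositive(self):
        rng = np.random.default_rng(43)
        tree = random_binary_tree(rng, 8)
        trait = {f"t{i+1}": ("present" if i < 3 else "absent") for i in range(8)}
        f = hmm.fit(tree, trait, seed=1, n_starts=2)
        assert f.log_likelihood <= 0.0
        assert 0.0 <= f.class_occupancy <= 1.0
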