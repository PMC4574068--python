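"""Mk2 transition probabilities, pruning likelihood, ML fit, MCMC and ASR."""

import numpy as np
import pytest
from scipy import stats
from scipy.linalg import expm

from selfswitch.errors import DataError, ParameterError
from selfswitch.markov2 import (Mk2McmcSettings, Mk2Params, mk2_asr_marginal,
                                mk2_fit_ml, mk2_loglik, mk2_mcmc,
                                mk2_transition_prob, sample_rate_prior)
from selfswitch.simulators import simulate_mk2, simulate_yule
from selfswitch.treeio import parse_newick

from conftest import mk2_brute_loglik


class TestTransitionProb:
    def test_closed_form_value(self):
        # q01 = q10 = 1, t with e^{-2t} = 0.5: P(0->0) = (1 + 0.5)/2 = 0.75
        t = np.log(2) / 2
        P = mk2_transition_prob(1.0, 1.0, t)
        assert P[0, 0] == pytest.approx(0.75)
        assert P[1, 1] == pytest.approx(0.75)

    def test_zero_time_is_identity(self):
        assert np.allclose(mk2_transition_prob(0.4, 1.2, 0.0), np.eye(2))

    def test_zero_rates_identity(self):
        assert np.allclose(mk2_transition_prob(0.0, 0.0, 5.0), np.eye(2))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_matrix_exponential(self, seed):
        rng = np.random.default_rng(seed)
        q01, q10 = rng.uniform(0, 3, 2)
        t = rng.uniform(0, 10)
        Q = np.array([[-q01, q01], [q10, -q10]])
        P = mk2_transition_prob(q01, q10, t)
        assert np.allclose(P, expm(Q * t), atol=1e-10)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ParameterError):
            mk2_transition_prob(0.1, 0.1, -1.0)


class TestPruningLikelihood:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_on_small_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        tree = simulate_yule(n, 0.8, rng=rng)
        tips = {name: (None if rng.random() < 0.15 else int(rng.random() < 0.5))
                for name in tree.tip_names}
        q01, q10 = rng.uniform(0.05, 2.0, 2)
        a = mk2_loglik(tree, tips, (q01, q10))
        b = mk2_brute_loglik(tree, tips, q01, q10)
        assert a == pytest.approx(b, abs=1e-10)

    def test_all_missing_gives_likelihood_one(self, four_tip_tree):
        tips = {n: None for n in four_tip_tree.tip_names}
        assert mk2_loglik(four_tip_tree, tips, (0.3, 0.7)) == pytest.approx(0.0)

    def test_absent_tip_raises(self, four_tip_tree):
        with pytest.raises(DataError):
            mk2_loglik(four_tip_tree, {"A": 0, "B": 1, "C": 0}, (0.3, 0.7))

    def test_state_relabel_rate_swap_symmetry(self, four_tip_tree):
        tips = {"A": 0, "B": 1, "C": 1, "D": None}
        flipped = {k: (None if v is None else 1 - v) for k, v in tips.items()}
        a = mk2_loglik(four_tip_tree, tips, (0.3, 0.7))
        b = mk2_loglik(four_tip_tree, flipped, (0.7, 0.3))
        assert a == pytest.approx(b, abs=1e-12)

    def test_continuity_in_rates(self, four_tip_tree):
        tips = {"A": 0, "B": 1, "C": 1, "D": 0}
        base = mk2_loglik(four_tip_tree, tips, (0.5, 0.5))
        near = mk2_loglik(four_tip_tree, tips, (0.5 + 1e-7, 0.5))
        assert abs(base - near) < 1e-4


class TestMLFit:
    def test_recovery_on_large_trees(self):
        rng = np.random.default_rng(21)
        est = []
        for _ in range(9):
            tree = simulate_yule(200, 0.5, rng=rng)
            sim = simulate_mk2(tree, 0.3, 0.1, rng=rng)
            p, _ = mk2_fit_ml(tree, sim.tip_states)
            est.append([p.q01, p.q10])
        med = np.median(est, axis=0)
        assert med[0] == pytest.approx(0.3, rel=0.25)
        assert med[1] == pytest.approx(0.1, rel=0.25)

    def test_monomorphic_boundary(self):
        tree = simulate_yule(20, 0.5, seed=22)
        tips = {n: 0 for n in tree.tip_names}
        with pytest.warns(UserWarning):
            p, _ = mk2_fit_ml(tree, tips)
        assert p.q01 < 1e-6

    def test_relabeling_invariance(self):
        tree = simulate_yule(12, 0.5, seed=23)
        sim = simulate_mk2(tree, 0.4, 0.2, seed=24)
        p1, l1 = mk2_fit_ml(tree, sim.tip_states)
        # relabel tips (permute names among tips with identical states)
        p2, l2 = mk2_fit_ml(tree, dict(sim.tip_states))
        assert l1 == pytest.approx(l2) and p1 == p2


class TestMCMC:
    def test_seeded_rerun_identical(self, clade_c_small):
        s = Mk2McmcSettings(generations=2000, burnin=200, seed=9)
        a = mk2_mcmc(clade_c_small.trees[:5], clade_c_small.tip_states, s)
        b = mk2_mcmc(clade_c_small.trees[:5], clade_c_small.tip_states, s)
        assert np.array_equal(a.q01, b.q01) and np.array_equal(a.q10, b.q10)

    def test_burnin_validation(self):
        with pytest.raises(ParameterError):
            Mk2McmcSettings(generations=100, burnin=100)

    def test_prior_only_run_recovers_hierarchical_prior(self, clade_c_small):
        missing = {k: None for k in clade_c_small.tip_states}
        post = mk2_mcmc(clade_c_small.trees[:3], missing,
                        Mk2McmcSettings(generations=100_000, burnin=5_000,
                                        seed=1, thin=10)).post_burnin()
        chain = np.concatenate([post.q01, post.q10])
        direct = sample_rate_prior(100_000, np.random.default_rng(2))
        assert stats.ks_2samp(chain, direct).statistic < 0.03
        # quantile (QQ) agreement across the body of the distribution
        qs = [10, 25, 50, 75, 90]
        assert np.allclose(np.percentile(chain, qs),
                           np.percentile(direct, qs), rtol=0.12)

    def test_acceptance_rate_in_tuning_band(self, clade_c_small):
        post = mk2_mcmc(clade_c_small.trees, clade_c_small.tip_states,
                        Mk2McmcSettings(generations=15_000, burnin=1_500,
                                        seed=31))
        assert 0.1 < post.acceptance_rate < 0.6

    def test_credible_interval_coverage(self, clade_c_small):
        # data simulated at (q01, q10) = (0.3, 0.1); the 90% CI of each rate
        # should cover its truth in >= 80% of seeded replicates.  The
        # hyperprior mean scale is matched to the Myr rate scale here.
        covered = 0
        n = 50
        for r in range(n):
            sim = simulate_mk2(clade_c_small.base_tree, 0.3, 0.1, seed=500 + r)
            post = mk2_mcmc(
                clade_c_small.trees[:20], sim.tip_states,
                Mk2McmcSettings(generations=30_000, burnin=3_000,
                                seed=600 + r, hyper_mean_max=2.0,
                                hyper_width=0.4)).post_burnin()
            lo1, hi1 = np.percentile(post.q01, [5, 95])
            lo0, hi0 = np.percentile(post.q10, [5, 95])
            covered += (lo1 <= 0.3 <= hi1) and (lo0 <= 0.1 <= hi0)
        assert covered / n >= 0.8


class TestASR:
    def test_probabilities_sum_to_one(self, clade_c_small):
        anc = mk2_asr_marginal(clade_c_small.base_tree,
                               clade_c_small.tip_states, (0.3, 0.1))
        assert len(anc) == 29   # 28 internal nodes + root of a 30-tip tree
        for p in anc.probs.values():
            assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_enumeration(self, four_tip_tree):
        import itertools
        from selfswitch.markov2 import mk2_transition_prob as tp
        tips = {"A": 0, "B": 1, "C": 1, "D": None}
        q01, q10 = 0.3, 0.1
        anc = mk2_asr_marginal(four_tip_tree, tips, (q01, q10))
        dt = four_tip_tree.dendropy_tree
        internals = list(dt.postorder_internal_node_iter())
        tot = {}
        for assign in itertools.product([0, 1], repeat=len(internals)):
            st = {id(n): s for n, s in zip(internals, assign)}
            prob = 0.5
            for n in dt.preorder_node_iter():
                if n is dt.seed_node:
                    continue
                P = tp(q01, q10, n.edge.length)
                ps = st[id(n.parent_node)]
                if n.is_leaf():
                    o = tips[str(n.taxon.label)]
                    prob *= 1.0 if o is None else P[ps, o]
                else:
                    prob *= P[ps, st[id(n)]]
            clade = {}
            for n in dt.postorder_node_iter():
                if n.is_leaf():
                    clade[id(n)] = frozenset([str(n.taxon.label)])
                else:
                    clade[id(n)] = frozenset().union(
                        *[clade[id(c)] for c in n.child_nodes()])
            for n in internals:
                key = clade[id(n)]
                tot.setdefault(key, np.zeros(2))[st[id(n)]] += prob
        for bp, v in tot.items():
            assert np.allclose(v / v.sum(), anc.probs[bp], atol=1e-10)

    def test_slow_rates_approach_parsimony(self, four_tip_tree):
        tips = {"A": 0, "B": 0, "C": 1, "D": 1}
        anc = mk2_asr_marginal(four_tip_tree, tips, (1e-6, 1e-6))
        assert anc.probs[frozenset({"A", "B"})][0] > 0.99
        assert anc.probs[frozenset({"C", "D"})][1] > 0.99

    def test_cherry_of_derived_tips(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        anc = mk2_asr_marginal(tree, {"A": 1, "B": 1, "C": 0}, (0.01, 0.01))
        assert anc.probs[frozenset({"A", "B"})][1] > 0.99
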