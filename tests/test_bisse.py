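"""BiSSE likelihood, constraints, model suite, LRT and ancestral states."""

import numpy as np
import pandas as pd
import pytest

from selfswitch.bisse import (MODEL_SUITE, SUITE_BY_NAME, BisseConstraint,
                              BisseOptions, bisse_asr_marginal, bisse_fit,
                              bisse_fit_one, bisse_loglik, bisse_model_suite,
                              bisse_param_distributions, lrt)
from selfswitch.diversification import pb_loglik
from selfswitch.errors import ConvergenceError, ParameterError
from selfswitch.markov2 import mk2_asr_marginal
from selfswitch.params import BisseParams
from selfswitch.simulators import simulate_bd, simulate_bisse, simulate_mk2, simulate_yule
from selfswitch.treeio import branching_times, parse_newick

from conftest import bisse_fixed_step_loglik

TWO_TIP = "(A:1,B:1);"


class TestLikelihood:
    def test_two_tip_closed_form_unconditioned(self):
        tree = parse_newick(TWO_TIP)
        p = BisseParams(0.5, 0.5, 0, 0, 0, 0)
        lnl = bisse_loglik(tree, {"A": 0, "B": 0}, p,
                           BisseOptions(condition_on_survival=False))
        assert lnl == pytest.approx(np.log(0.5) - 1.0, abs=1e-6)   # -1.6931

    def test_two_tip_closed_form_conditioned(self):
        tree = parse_newick(TWO_TIP)
        p = BisseParams(0.5, 0.5, 0, 0, 0, 0)
        lnl = bisse_loglik(tree, {"A": 0, "B": 0}, p, BisseOptions())
        assert lnl == pytest.approx(-1.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_fixed_step_integrator(self, seed):
        rng = np.random.default_rng(seed)
        tree = simulate_yule(6, 0.8, rng=rng)
        tips = {n: int(rng.random() < 0.5) for n in tree.tip_names}
        p = BisseParams(*rng.uniform(0.05, 0.8, 6))
        for cond in (True, False):
            a = bisse_loglik(tree, tips, p,
                             BisseOptions(condition_on_survival=cond))
            b = bisse_fixed_step_loglik(tree, tips, p, condition=cond)
            assert a == pytest.approx(b, abs=1e-6)

    def test_reduces_to_pure_birth_on_monomorphic_tips(self):
        # mu = q = 0, flat root weighting + survival conditioning:
        # lnL_bisse(lambda) = ln(1/2) + PB branching-time lnL(lambda)
        tree = simulate_yule(12, 0.6, seed=33)
        tips = {n: 0 for n in tree.tip_names}
        bt = branching_times(tree)
        for lam in (0.2, 0.6, 1.1):
            p = BisseParams(lam, lam, 0, 0, 0, 0)
            lnl = bisse_loglik(tree, tips, p, BisseOptions(root="flat"))
            assert lnl - np.log(0.5) == pytest.approx(
                pb_loglik(bt, lam), abs=1e-5)

    def test_state_relabel_parameter_swap_symmetry(self):
        tree = simulate_yule(8, 0.6, seed=34)
        rng = np.random.default_rng(35)
        tips = {n: int(rng.random() < 0.4) for n in tree.tip_names}
        p = BisseParams(0.6, 0.2, 0.1, 0.05, 0.3, 0.07)
        swapped = BisseParams(0.2, 0.6, 0.05, 0.1, 0.07, 0.3)
        flipped = {k: 1 - v for k, v in tips.items()}
        a = bisse_loglik(tree, tips, p)
        b = bisse_loglik(tree, flipped, swapped)
        assert a == pytest.approx(b, abs=1e-7)

    def test_missing_tips_and_sampling_fraction(self):
        tree = parse_newick(TWO_TIP)
        p = BisseParams(0.5, 0.5, 0, 0, 0, 0)
        full = bisse_loglik(tree, {"A": 0, "B": None}, p,
                            BisseOptions(condition_on_survival=False))
        # missing tip sums over both states; with q = 0 only state O persists
        assert full == pytest.approx(np.log(0.5) - 1.0, abs=1e-6)


class TestConstraints:
    def test_suite_has_thirteen_models_with_expected_df(self):
        assert len(MODEL_SUITE) == 13
        df = {c.name: c.n_free for c in MODEL_SUITE}
        assert df["full"] == 6
        assert df["lamO=lamS"] == 5
        assert df["lamS=0,muO=0"] == 4
        assert df["lamS=0,muO=0,qSO=0"] == 3
        assert df["lamS=0,muO=0,muS=0,qSO=0"] == 2

    def test_expand_reduce_roundtrip(self):
        c = SUITE_BY_NAME["lamS=0,muO=0,qSO=0"]
        free = np.array([0.7, 0.25, 0.28])
        full = c.expand(free)
        assert full[1] == 0 and full[2] == 0 and full[5] == 0
        assert np.allclose(c.reduce(full), free)

    def test_tie_shares_value(self):
        c = SUITE_BY_NAME["lamO=lamS"]
        full = c.expand(np.array([0.5, 0.1, 0.2, 0.3, 0.4]))
        assert full[0] == full[1] == 0.5

    def test_invalid_constraints_rejected(self):
        with pytest.raises(ParameterError):
            BisseConstraint("bad", ties=(("lam_o", "nope"),))
        with pytest.raises(ParameterError):
            BisseConstraint("bad", ties=(("lam_o", "lam_s"),), zeros=("lam_s",))


class TestLRT:
    def test_study_table_arithmetic_equal_speciation(self):
        stat, p = lrt(-58.68, -61.89, 1)
        assert stat == pytest.approx(6.42, abs=1e-9)
        assert p == pytest.approx(0.0113, abs=5e-4)
        assert p < 0.05

    def test_study_table_arithmetic_no_forward_transition(self):
        stat, p = lrt(-58.68, -66.97, 1)
        assert stat == pytest.approx(16.58, abs=1e-9)
        assert p < 1e-4

    def test_equal_likelihoods(self):
        stat, p = lrt(-10.0, -10.0, 2)
        assert stat == 0.0 and p == 1.0

    def test_negative_statistic_raises(self):
        with pytest.raises(ConvergenceError):
            lrt(-12.0, -10.0, 1)


@pytest.fixture(scope="module")
def bisse_fixture_sim():
    return simulate_bisse(BisseParams(0.7, 0.0, 0.0, 0.0, 0.2, 0.0),
                          n=30, seed=11)


class TestFitting:
    def test_zero_fixed_parameters_stay_zero(self, bisse_fixture_sim):
        sim = bisse_fixture_sim
        fit = bisse_fit_one(sim.tree, sim.tip_states,
                            SUITE_BY_NAME["lamS=0,muO=0,muS=0,qSO=0"])
        a = fit.params.as_array()
        assert a[1] == 0 and a[2] == 0 and a[3] == 0 and a[5] == 0
        assert fit.n_free == 2

    def test_constrained_never_beats_full(self, bisse_fixture_sim):
        sim = bisse_fixture_sim
        full = bisse_fit_one(sim.tree, sim.tip_states, SUITE_BY_NAME["full"])
        for name in ("lamO=lamS", "qOS=0", "lamS=0,muO=0"):
            c = bisse_fit_one(sim.tree, sim.tip_states, SUITE_BY_NAME[name])
            assert c.lnl <= full.lnl + 1e-4

    def test_state_symmetric_constraint_recovers_bd_rates(self):
        # tie all O/S pairs and fit trees simulated under plain birth-death
        tie_all = BisseConstraint("bd-like",
                                  ties=(("lam_o", "lam_s"), ("mu_o", "mu_s"),
                                        ("q_os", "q_so")))
        # 100-tip trees: extinction-rate estimates from reconstructed trees
        # carry a strong upward small-sample bias, so recovery within 25% is
        # only a fair ask at this size
        rng = np.random.default_rng(36)
        lam_hat, mu_hat = [], []
        for _ in range(30):
            tree = simulate_bd(100, 0.6, 0.3, rng=rng)
            tips = {n: int(rng.random() < 0.5) for n in tree.tip_names}
            fit = bisse_fit_one(tree, tips, tie_all, n_restarts=1)
            lam_hat.append(fit.params.lam_o)
            mu_hat.append(fit.params.mu_o)
        assert np.median(lam_hat) == pytest.approx(0.6, rel=0.25)
        assert np.median(mu_hat) == pytest.approx(0.3, rel=0.25)

    def test_suite_ranking_on_generating_regime(self, bisse_fixture_sim):
        sim = bisse_fixture_sim
        suite = bisse_model_suite(sim.tree, sim.tip_states)
        assert len(suite.table) == 13
        best = suite.table.iloc[0]
        truth = suite.table[suite.table.model == "lamS=0,muO=0,muS=0,qSO=0"]
        assert float(truth.delta_aic.iloc[0]) >= -2.0
        assert suite.table.delta_aic.max() == pytest.approx(0.0)

    def test_median_summaries_across_trees(self, clade_c_small):
        ds = clade_c_small
        summ = bisse_fit(ds.trees[:5], ds.tip_states,
                         SUITE_BY_NAME["lamS=0,muO=0,muS=0,qSO=0"],
                         n_restarts=1)
        assert len(summ.per_tree) == 5
        med = summ.medians
        assert med["lam_o"] > 0 and med["q_os"] > 0
        for _, row in summ.per_tree.iterrows():
            assert row.aic == pytest.approx(2 * 2 - 2 * row.lnl, abs=1e-9)


class TestASR:
    def test_probabilities_sum_to_one(self, bisse_fixture_sim):
        sim = bisse_fixture_sim
        anc = bisse_asr_marginal(sim.tree, sim.tip_states,
                                 BisseParams(0.7, 0, 0, 0, 0.2, 0))
        assert len(anc) == 29
        for p in anc.probs.values():
            assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_mk2_when_diversification_state_independent(self):
        rng = np.random.default_rng(37)
        for _ in range(3):
            tree = simulate_yule(6, 0.8, rng=rng)
            sim = simulate_mk2(tree, 0.4, 0.2, rng=rng)
            p = BisseParams(0.6, 0.6, 0.1, 0.1, 0.4, 0.2)
            a = bisse_asr_marginal(tree, sim.tip_states, p,
                                   BisseOptions(root="flat"))
            b = mk2_asr_marginal(tree, sim.tip_states, (0.4, 0.2))
            for bp in b.probs:
                assert abs(a.probs[bp][1] - b.probs[bp][1]) <= 0.05

    def test_all_internal_nodes_outcrossing_on_fixture(self, clade_c_small):
        ds = clade_c_small
        anc = bisse_asr_marginal(ds.base_tree, ds.tip_states, ds.params)
        assert all(p[0] >= 0.5 for p in anc.probs.values())


class TestParamDistributions:
    def test_summary_contract(self):
        rng = np.random.default_rng(38)
        df = pd.DataFrame({k: rng.uniform(0, 1, 40)
                           for k in ("lam_o", "lam_s", "mu_o", "mu_s",
                                     "q_os", "q_so")})
        df["converged"] = True
        out = bisse_param_distributions(df)
        assert (out["lower"] <= out["median"]).all()
        assert (out["median"] <= out["upper"]).all()
        # identical distributions must overlap
        df2 = df.copy()
        df2["lam_s"] = df2["lam_o"]
        assert bisse_param_distributions(df2).attrs["overlap"]["lam_o|lam_s"]

    def test_separated_rates_do_not_overlap(self):
        rng = np.random.default_rng(39)
        df = pd.DataFrame({
            "lam_o": rng.normal(0.7, 0.02, 50), "lam_s": rng.normal(0.0, 0.001, 50) + 1e-6,
            "mu_o": rng.uniform(0, 0.1, 50), "mu_s": rng.uniform(0, 0.1, 50),
            "q_os": rng.uniform(0.1, 0.3, 50), "q_so": rng.uniform(0.1, 0.3, 50)})
        df["converged"] = True
        out = bisse_param_distributions(df)
        assert not out.attrs["overlap"]["lam_o|lam_s"]
        assert out.attrs["overlap"]["mu_o|mu_s"]

    def test_too_few_fits_rejected(self):
        with pytest.raises(ParameterError):
            bisse_param_distributions(pd.DataFrame({"lam_o": [0.1]}))
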