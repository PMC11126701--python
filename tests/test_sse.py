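import numpy as np
import pytest

from nectarevo import mk, synth, treeio
from nectarevo.sse import (
    BisseParams,
    _integrate_branch,
    aicc_table,
    bisse_loglik,
    bisse_mcmc,
    bisse_mle,
    fit_sse_model,
    hisse_fit_set,
    sse_loglik,
    turnover_eps_to_rates,
    _model_spec,
)
from nectarevo.treeio import node_ages


class TestOdeIntegration:
    def test_extinction_probability_closed_form(self):
        """lam = 0: E(t) = 1 - e^(-mu t); mu=0.1, t=10 -> 0.63212."""
        lam = np.zeros(2)
        mu = np.array([0.1, 0.1])
        Q = np.zeros((2, 2))
        E, D = _integrate_branch(np.zeros(2), np.ones(2), lam, mu, Q, 10.0, 400)
        assert E[0] == pytest.approx(0.63212, abs=1e-5)

    def test_density_decay_closed_form(self):
        """mu = q = 0: D(t) = D(0) e^(-lam t); lam=0.2, t=5 -> 0.36788."""
        lam = np.array([0.2, 0.2])
        mu = np.zeros(2)
        Q = np.zeros((2, 2))
        E, D = _integrate_branch(np.zeros(2), np.array([1.0, 0.0]), lam, mu, Q, 5.0, 400)
        assert D[0] == pytest.approx(0.36788, abs=1e-5)

    def test_half_step_consistency_random_branches(self):
        """Integration is stable against halving the step size."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            k = 2
            lam = rng.uniform(0.01, 0.3, k)
            mu = rng.uniform(0.0, 0.2, k)
            q = rng.uniform(0.0, 0.1)
            Q = np.array([[-q, q], [q, -q]])
            t = rng.uniform(0.5, 30.0)
            E0 = rng.uniform(0, 0.5, k)
            D0 = rng.uniform(0.1, 1.0, k)
            n = 80
            E1, D1 = _integrate_branch(E0, D0, lam, mu, Q, t, n)
            E2, D2 = _integrate_branch(E0, D0, lam, mu, Q, t, 2 * n)
            assert np.allclose(E1, E2, rtol=1e-5, atol=1e-9)
            assert np.allclose(D1, D2, rtol=1e-5, atol=1e-12)
            assert np.all((E2 >= 0) & (E2 <= 1)) and np.all(D2 >= 0)

    def test_equal_rates_factorize_into_bd_times_mk(self):
        """With state-blind lam/mu the likelihood splits into a constant-rate
        birth-death tree density times the Mk tip-state probability."""
        lam_, mu_ = 0.1, 0.03
        p = BisseParams(lam_, lam_, mu_, mu_, 0.01, 0.01)
        tree = synth.sim_bd_tree(0.1, 0.03, stop_n=60, seed=5)
        Qs = mk.build_q([0.01], 2, "ER")
        tips, _ = synth.sim_mk_traits(tree, Qs, 0, seed=6)
        ll = bisse_loglik(tree, tips, p, root_mode="flat", condition_surv=False)
        ages = node_ages(tree)
        r, eps = lam_ - mu_, mu_ / lam_

        def lnpsi(t):
            return -r * t + 2 * np.log1p(-eps) - 2 * np.log1p(-eps * np.exp(-r * t))

        lnbd = 0.0
        for v in range(tree.n_nodes):
            if not tree.is_tip(v):
                lnbd += np.log(lam_)
            pnt = tree.parent[v]
            if pnt >= 0:
                lnbd += lnpsi(ages[pnt]) - lnpsi(ages[v])
        lnmk = mk.mk_loglik(tree, tips, Qs, np.array([0.5, 0.5]))
        assert ll == pytest.approx(lnbd + lnmk, abs=1e-5)


class TestBisseFit:
    def test_full_nests_null(self):
        p = BisseParams(0.12, 0.24, 0.03, 0.03, 0.01, 0.01)
        tree, tips = synth.sim_bisse(p, stop_n=100, seed=21)
        fits = hisse_fit_set(tree, tips, models=("BiSSE-null", "BiSSE-full"),
                             n_starts=1, seed=0)
        null, full = fits
        assert full.lnL >= null.lnL - 1e-6

    def test_rate_ratio_recovery(self):
        """lam1 = 2*lam0 simulations: the fitted speciation ratio should
        be materially above 1 (median across replicate trees in [1.3, 3.0])."""
        ratios = []
        for rep in range(10):
            p = BisseParams(0.10, 0.20, 0.03, 0.03, 0.02, 0.02)
            tree, tips = synth.sim_bisse(p, stop_n=150, seed=600 + rep)
            if not 0.15 <= np.mean(list(tips.values())) <= 0.9:
                continue
            fit = bisse_mle(tree, tips, n_starts=1, seed=rep)
            ratios.append(fit.params["lambda1"] / fit.params["lambda0"])
        assert 1.3 <= np.median(ratios) <= 3.0

    def test_null_data_constrained_fit_close_to_full(self):
        close = 0
        reps = 8
        for rep in range(reps):
            p = BisseParams(0.12, 0.12, 0.03, 0.03, 0.02, 0.02)
            tree, tips = synth.sim_bisse(p, stop_n=100, seed=800 + rep)
            if len(set(tips.values())) < 2:
                continue
            null, full = hisse_fit_set(tree, tips,
                                       models=("BiSSE-null", "BiSSE-full"),
                                       n_starts=1, seed=rep)
            if full.lnL - null.lnL < 2.0:
                close += 1
        assert close / reps >= 0.8


class TestMcmc:
    @pytest.fixture(scope="module")
    def chain_setup(self):
        p = BisseParams(0.12, 0.24, 0.03, 0.03, 0.02, 0.02)
        tree, tips = synth.sim_bisse(p, stop_n=100, seed=31)
        mle = bisse_mle(tree, tips, n_starts=1, seed=0)
        return tree, tips, mle

    def test_same_seed_identical_chain(self, chain_setup):
        tree, tips, mle = chain_setup
        start = BisseParams(**mle.params)
        c1 = bisse_mcmc(tree, tips, n_gen=120, seed=9, start=start)
        c2 = bisse_mcmc(tree, tips, n_gen=120, seed=9, start=start)
        assert np.array_equal(c1.samples, c2.samples)

    def test_chain_length_and_posterior_near_mle(self, chain_setup):
        tree, tips, mle = chain_setup
        start = BisseParams(**mle.params)
        chain = bisse_mcmc(tree, tips, n_gen=200, seed=10, start=start)
        assert len(chain) == 200
        med = np.median(chain.samples[50:], axis=0)
        for i, name in enumerate(["lambda0", "lambda1"]):
            assert abs(med[i] - mle.params[name]) / mle.params[name] < 0.5

    def test_too_few_generations_rejected(self, chain_setup):
        tree, tips, mle = chain_setup
        with pytest.raises(ValueError):
            bisse_mcmc(tree, tips, n_gen=10, seed=1, start=BisseParams(**mle.params))


class TestHisseModelSet:
    def test_turnover_eps_roundtrip(self):
        lam, mu = turnover_eps_to_rates(0.3, 0.5)
        assert lam + mu == pytest.approx(0.3)
        assert mu / lam == pytest.approx(0.5)

    def test_parameter_counts(self):
        ks = {m: len(_model_spec(m)[1]) for m in
              ("BiSSE-full", "BiSSE-null", "CID-2", "CID-4", "HiSSE-2")}
        assert ks["BiSSE-full"] == 6 and ks["BiSSE-null"] == 4
        assert ks["CID-2"] < ks["HiSSE-2"]

    def test_hisse_collapse_to_bisse(self):
        """HiSSE-2 with tied hidden classes equals BiSSE-full likelihood."""
        p = BisseParams(0.1, 0.2, 0.03, 0.05, 0.02, 0.01)
        tree, tips = synth.sim_bisse(p, stop_n=80, seed=41)
        tau = np.array([0.13, 0.25])
        eps = np.array([0.3, 0.25])
        q01, q10, alpha = 0.02, 0.01, 0.3
        _, _, expand2 = _model_spec("BiSSE-full")
        lam2, mu2, Q2, obs2 = expand2(np.array([tau[0], tau[1], eps[0], eps[1], q01, q10]))
        _, _, expand4 = _model_spec("HiSSE-2")
        lam4, mu4, Q4, obs4 = expand4(np.array(
            [tau[0], tau[1], tau[0], tau[1], eps[0], eps[1], eps[0], eps[1], q01, q10, alpha]))
        ll2 = sse_loglik(tree, tips, lam2, mu2, Q2, obs_of_state=obs2, root_mode="obs0")
        ll4 = sse_loglik(tree, tips, lam4, mu4, Q4, obs_of_state=obs4, root_mode="obs0")
        assert ll4 == pytest.approx(ll2, abs=1e-5)

    def test_cid_specificity(self):
        """Trait-independent (CID-2-style) data should rarely prefer
        HiSSE-2 over CID-2 by more than 2 AICc units."""
        from nectarevo.synth import MultiStateParams

        prefer = 0
        reps = 6
        for rep in range(reps):
            # hidden class B doubles turnover; observed trait neutral
            lam = np.array([0.08, 0.08, 0.16, 0.16])
            mu = np.array([0.02, 0.02, 0.04, 0.04])
            from nectarevo.sse import _hidden_q

            Q = _hidden_q(0.03, 0.03, 0.02, 2)
            par = MultiStateParams(lam, mu, Q, obs_of_state=np.array([0, 1, 0, 1]))
            tree, tips = synth.sim_bisse(par, stop_n=90, seed=900 + rep)
            if len(set(tips.values())) < 2:
                continue
            cid, hisse = hisse_fit_set(tree, tips, models=("CID-2", "HiSSE-2"),
                                       n_starts=1, seed=rep)
            if cid.AICc - hisse.AICc > 2.0:
                prefer += 1
        assert prefer / reps <= 0.34

    def test_five_model_table_shape(self):
        p = BisseParams(0.1, 0.1, 0.03, 0.03, 0.02, 0.02)
        tree, tips = synth.sim_bisse(p, stop_n=60, seed=51)
        fits = hisse_fit_set(tree, tips, n_starts=1, seed=0)
        tab = aicc_table(fits)
        assert set(tab["model"]) == {"BiSSE-full", "BiSSE-null", "CID-2", "CID-4", "HiSSE-2"}
        assert tab["dAICc"].iloc[0] == 0.0
        assert tab["weight"].sum() == pytest.approx(1.0)

    def test_akaike_weight_formula(self):
        from nectarevo.sse import SseFit

        a = SseFit("A", {}, lnL=-10.0, k_params=2, n_tips=1000)
        b = SseFit("B", {}, lnL=-12.0, k_params=2, n_tips=1000)
        tab = aicc_table([a, b])
        assert tab["weight"].iloc[0] == pytest.approx(0.8808, abs=1e-4)
        assert tab["weight"].iloc[1] == pytest.approx(0.1192, abs=1e-4)

    def test_turnover_increase_recovered_qualitatively(self):
        """Faster turnover in the trait-positive state yields a best-model
        turnover ratio above 1 in most replicates."""
        above = 0
        reps = 6
        for rep in range(reps):
            p = BisseParams(0.08, 0.24, 0.02, 0.06, 0.02, 0.02)
            tree, tips = synth.sim_bisse(p, stop_n=120, seed=1000 + rep)
            if not 0.1 <= np.mean(list(tips.values())) <= 0.95:
                continue
            null, full = hisse_fit_set(tree, tips,
                                       models=("BiSSE-null", "BiSSE-full"),
                                       n_starts=1, seed=rep)
            best = full if full.AICc <= null.AICc else null
            if best.model == "BiSSE-full" and best.params["tau1"] > best.params["tau0"]:
                above += 1
        assert above / reps >= 0.7
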