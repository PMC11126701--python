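import numpy as np
import pytest

from nectarevo import corrhmm, mk, synth
from nectarevo.corrhmm import (
    aicc,
    build_model,
    correlation_test,
    count_dual_transitions,
    dual_states,
    fit_hidden_model,
    simmap_hidden,
)
from nectarevo.mk import mk_loglik, stationary_distribution

from .conftest import random_small_tree
from .oracles import enum_loglik


def _dep_q(rng=None, canopy_boost=1.0):
    """Dependent R=1 generator; trait1 gains boosted when trait2 = 1."""
    base = 0.02
    params = np.array([base, base * canopy_boost, 0.05, 0.05,
                       0.02, 0.02, 0.01, 0.01])
    return build_model("dependent", 1).build_q(params)


class TestModelConstruction:
    @pytest.mark.parametrize("structure,R,expected", [
        ("dependent", 1, 8), ("independent", 1, 4),
        ("independent", 2, 9), ("dependent", 2, 17),
    ])
    def test_free_parameter_counts(self, structure, R, expected):
        assert build_model(structure, R).n_params == expected

    def test_rows_sum_to_zero_and_no_dual_changes(self):
        rng = np.random.default_rng(1)
        for structure in ("independent", "dependent"):
            for R in (1, 2):
                m = build_model(structure, R)
                Q = m.build_q(rng.uniform(0.01, 0.5, m.n_params))
                assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
                for i in range(m.n_states):
                    for j in range(m.n_states):
                        di, dj = i % 4, j % 4
                        ci, cj = i // 4, j // 4
                        both_traits = (di // 2 != dj // 2) and (di % 2 != dj % 2)
                        if i != j and (both_traits or (di != dj and ci != cj)):
                            assert Q[i, j] == 0.0

    def test_independent_ties_rates_across_background(self):
        m = build_model("independent", 1)
        Q = m.build_q(np.array([0.1, 0.2, 0.3, 0.4]))
        # trait1 gain rate identical whatever trait2 is
        assert Q[0, 2] == Q[1, 3]
        assert Q[2, 0] == Q[3, 1]

    def test_aicc_formula(self):
        assert aicc(-10.0, 4, 20) == pytest.approx(30.666667, abs=1e-5)


class TestFitHiddenModel:
    def test_matches_enumeration_oracle_small_trees(self):
        """Likelihood with marginalized hidden classes equals enumeration."""
        rng = np.random.default_rng(5)
        for rep in range(6):
            tree = random_small_tree(rng, int(rng.integers(3, 5)))
            m = build_model("dependent", 2)
            Q = m.build_q(rng.uniform(0.02, 0.4, m.n_params))
            dual = {l: int(rng.integers(4)) for l in tree.tip_labels}
            partials = m.tip_partials(tree, dual)
            pi = stationary_distribution(Q)
            ours = mk_loglik(tree, partials, Q, pi)
            oracle = enum_loglik(tree, partials, Q, pi)
            assert ours == pytest.approx(oracle, abs=1e-8)

    def test_hidden_collapse_identity(self, bd_tree_60):
        """R=2 with zero class switching and tied class rates gives the
        same likelihood as the R=1 model."""
        rng = np.random.default_rng(6)
        Q1 = _dep_q()
        dual, _, _ = synth.sim_hidden_dual(bd_tree_60, Q1, seed=7)
        m1 = build_model("dependent", 1)
        m2 = build_model("dependent", 2)
        p1 = np.array([0.02, 0.06, 0.05, 0.05, 0.02, 0.02, 0.01, 0.01])
        p2 = np.concatenate([p1, p1, [1e-12]])
        ll1 = mk_loglik(bd_tree_60, m1.tip_partials(bd_tree_60, dual), m1.build_q(p1))
        ll2 = mk_loglik(bd_tree_60, m2.tip_partials(bd_tree_60, dual), m2.build_q(p2))
        assert ll2 == pytest.approx(ll1, abs=1e-6)

    def test_nesting_chain_of_fitted_lnl(self, bd_tree_60):
        Q = _dep_q(canopy_boost=5.0)
        dual, _, _ = synth.sim_hidden_dual(bd_tree_60, Q, seed=8)
        t1 = {s: d // 2 for s, d in dual.items()}
        t2 = {s: d % 2 for s, d in dual.items()}
        res = correlation_test(bd_tree_60, t1, t2, n_starts=1, seed=0)
        f = res.fits
        assert f["dependent_R1"].lnL >= f["independent_R1"].lnL - 1e-6
        assert f["independent_R2"].lnL >= f["independent_R1"].lnL - 1e-6
        assert f["dependent_R2"].lnL >= f["dependent_R1"].lnL - 1e-6


class TestCorrelationTest:
    def test_constant_trait_raises(self, bd_tree_60):
        t1 = {l: 0 for l in bd_tree_60.tip_labels}
        t2 = {l: i % 2 for i, l in enumerate(bd_tree_60.tip_labels)}
        with pytest.raises(ValueError):
            correlation_test(bd_tree_60, t1, t2)

    def test_aicc_ranking_prefers_true_structure(self, bd_tree_60):
        """One strongly dependent dataset should rank a dependent model
        first (the replicated specificity/sensitivity rates live in the
        acceptance suite)."""
        p = np.array([0.01, 0.10, 0.15, 0.015, 0.02, 0.02, 0.01, 0.01])
        Q = build_model("dependent", 1).build_q(p)
        tree = synth.scale_tree_height(bd_tree_60, 120.0)
        dual, _, _ = synth.sim_hidden_dual(tree, Q, seed=777)
        t1 = {s: d // 2 for s, d in dual.items()}
        t2 = {s: d % 2 for s, d in dual.items()}
        res = correlation_test(tree, t1, t2, n_starts=1, seed=0)
        assert res.best_name.startswith("dependent")

    def test_gain_rate_ratio_recovered(self, bd_tree_60):
        """With canopy gains 3x understory gains, the fitted dependent
        model's gain-rate ratio should exceed 1 in most replicates."""
        Q = _dep_q(canopy_boost=3.0)
        above = 0
        reps = 15
        done = 0
        for rep in range(reps):
            tree = synth.sim_bd_tree(0.1, 0.02, stop_n=80, seed=500 + rep)
            tree = synth.scale_tree_height(tree, 150.0)
            dual, _, _ = synth.sim_hidden_dual(tree, Q, seed=550 + rep)
            t1 = {s: d // 2 for s, d in dual.items()}
            t2 = {s: d % 2 for s, d in dual.items()}
            if len(set(t1.values())) < 2 or len(set(t2.values())) < 2:
                continue
            done += 1
            fit = fit_hidden_model(tree, dual_states(t1, t2),
                                   build_model("dependent", 1), n_starts=2, seed=rep)
            g_under, g_canopy = fit.rates[0], fit.rates[1]
            if g_canopy > g_under:
                above += 1
        assert done >= 5
        assert above / done >= 0.80


class TestHiddenSimmaps:
    @pytest.fixture(scope="module")
    def fitted(self, bd_tree_60):
        Q = _dep_q(canopy_boost=4.0)
        dual, _, _ = synth.sim_hidden_dual(bd_tree_60, Q, seed=20)
        fit = fit_hidden_model(bd_tree_60, dual, build_model("dependent", 1),
                               n_starts=1, seed=1)
        return bd_tree_60, dual, fit

    def test_root_state_frequencies_match_marginals(self, fitted):
        tree, dual, fit = fitted
        n = 2000
        ens = simmap_hidden(tree, fit, n=n, seed=2, dual=dual)
        m = mk.marginal_states(tree, fit.model.tip_partials(tree, dual), fit.Q)
        freqs = np.bincount([r.node_states[tree.root] for r in ens.realizations],
                            minlength=4) / n
        for s in range(4):
            se = np.sqrt(max(m[tree.root, s] * (1 - m[tree.root, s]), 1e-9) / n)
            assert abs(freqs[s] - m[tree.root, s]) <= 3 * se + 1e-12

    def test_no_dual_simultaneous_transitions(self, fitted):
        tree, dual, fit = fitted
        ens = simmap_hidden(tree, fit, n=50, seed=3, dual=dual)
        mat = count_dual_transitions(ens)
        for i in range(4):
            for j in range(4):
                if (i // 2 != j // 2) and (i % 2 != j % 2):
                    assert mat[i, j] == 0.0
        assert np.all(np.diag(mat) == 0.0)

    def test_zero_rate_means_zero_simmap_transitions(self, fitted):
        """A fitted rate of zero for canopy+nectary -> understory+nectary
        yields no such transitions in the sampled histories."""
        tree, dual, fit = fitted
        rates = fit.rates.copy()
        rates[7] = 1e-12  # t2 loss when t1 = 1 (nectary-bearing leaves canopy)
        refit_q = fit.model.build_q(rates)
        ens = mk.sample_simmaps(tree, fit.model.tip_partials(tree, dual),
                                refit_q, n=30, seed=4)
        mat = count_dual_transitions(ens)
        assert mat[3, 2] == 0.0  # state 11 -> 10

    def test_hand_painted_single_change(self, cherry):
        real = mk.SimmapRealization(
            np.array([0, 2, 0]),
            [[(0, 1.0)], [(0, 0.4), (2, 0.6)], []],
        )
        ens = mk.SimmapEnsemble(tree=cherry, realizations=[real], states=4)
        mat = count_dual_transitions(ens)
        expected = np.zeros((4, 4))
        expected[0, 2] = 1.0
        assert np.array_equal(mat, expected)

    def test_marginalizing_r1_hidden_class_is_identity(self, fitted):
        tree, dual, fit = fitted
        ens = simmap_hidden(tree, fit, n=5, seed=5, dual=dual)
        proj = corrhmm.dual_view(ens)
        for a, b in zip(ens.realizations, proj.realizations):
            assert np.array_equal(a.node_states % 4, b.node_states)


class TestFourStateScheme:
    def test_parameter_counts_and_structure(self):
        from nectarevo.corrhmm import FourStateModel

        ind = FourStateModel("independent")
        dep = FourStateModel("dependent")
        assert ind.n_params == 3 and dep.n_params == 9
        Q = dep.build_q(np.arange(1, 10) / 10)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        # no dual simultaneous changes: trait flip keeps habit
        for i in range(8):
            for j in range(8):
                if i != j and (i // 4 != j // 4) and (i % 4 != j % 4):
                    assert Q[i, j] == 0.0

    def test_habit_specific_gains_detected(self, bd_tree_60):
        from nectarevo.corrhmm import correlation_test_four_state

        tree = synth.scale_tree_height(bd_tree_60, 120.0)
        from nectarevo.corrhmm import FourStateModel

        gen = FourStateModel("dependent")
        # gains concentrated in tree-fern habit (h=3)
        p = np.array([0.001, 0.001, 0.001, 0.12, 0.05, 0.05, 0.05, 0.005, 0.01])
        Q = gen.build_q(p)
        tips, _ = synth.sim_mk_traits(tree, Q, root_state=0, seed=42)
        trait1 = {sp: s // 4 for sp, s in tips.items()}
        habit4 = {sp: s % 4 for sp, s in tips.items()}
        if len(set(trait1.values())) < 2:
            pytest.skip("degenerate simulation")
        res = correlation_test_four_state(tree, trait1, habit4, seed=1)
        f = res.fits
        assert f["dependent"].lnL >= f["independent"].lnL - 1e-6
        rates = dict(zip(f["dependent"].model.param_names(), f["dependent"].rates))
        # the generating process gains almost only in tree-fern lineages
        assert rates["q_t1gain_tree"] > rates["q_t1gain_terr"]
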