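import math
import warnings

import numpy as np
import pytest

from burrowstats import mk_simmap as mk
from burrowstats import treeio
from burrowstats.fixtures import SUPERSTRUCTURE_STATES, synthetic_tree_sample
from burrowstats.synthetic_data import simulate_mk_character, simulate_yule_tree
from conftest import enumerate_loglik, enumerate_marginal


class TestRateMatrix:
    def test_er_rows_sum_to_zero(self):
        rm = mk.er_matrix(0.7, k=3)
        assert np.allclose(rm.Q.sum(axis=1), 0.0, atol=1e-12)

    def test_transition_rows_are_distributions(self):
        rm = mk.er_matrix(1.3)
        for t in (0.0, 0.01, 0.5, 3.0, 50.0):
            P = rm.transition(t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert (P >= -1e-12).all()

    def test_invalid_generator_rejected(self):
        with pytest.raises(ValueError):
            mk.RateMatrix(np.array([[-1.0, 0.5], [1.0, -1.0]]))


class TestMkLoglik:
    def test_zero_rate_concordant(self, two_tip_tree):
        ll = mk.mk_loglik(two_tip_tree, {"A": 0, "B": 0}, mk.er_matrix(0.0))
        assert ll == pytest.approx(math.log(0.5))

    def test_zero_rate_discordant_impossible(self, two_tip_tree):
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            ll = mk.mk_loglik(two_tip_tree, {"A": 0, "B": 1}, mk.er_matrix(0.0))
        assert ll == float("-inf")
        assert len(w) == 1

    def test_two_tip_closed_form(self, two_tip_tree):
        # log[0.5 (p00^2 + p10^2)] with p00 = (1+e^-2qt)/2, q = 0.5, t = 1
        p00 = 0.5 * (1 + math.exp(-1.0))
        p10 = 1 - p00
        expect = math.log(0.5 * (p00**2 + p10**2))
        ll = mk.mk_loglik(two_tip_tree, {"A": 0, "B": 0}, mk.er_matrix(0.5))
        assert ll == pytest.approx(expect, rel=1e-12)

    def test_matches_enumeration_on_small_trees(self):
        """Pruning equals the exhaustive sum over internal-node assignments."""
        rng = np.random.default_rng(42)
        for rep in range(25):
            t = simulate_yule_tree(int(rng.integers(3, 6)), 300 + rep)
            q = float(rng.uniform(0.05, 3.0))
            rm = mk.er_matrix(q)
            tips = {lb: int(rng.integers(2)) for lb in t.tip_labels}
            prior = np.array([0.5, 0.5])
            a = mk.mk_loglik(t, tips, rm, prior)
            b = enumerate_loglik(t, tips, rm, prior)
            assert a == pytest.approx(b, rel=1e-9)

    def test_state_relabeling_invariance(self):
        t = simulate_yule_tree(5, 77)
        tips = {lb: i % 2 for i, lb in enumerate(t.tip_labels)}
        rm01 = mk.er_matrix(0.9, states=(0, 1))
        rmAB = mk.er_matrix(0.9, states=("absent", "present"))
        relabeled = {k: ("absent", "present")[v] for k, v in tips.items()}
        assert mk.mk_loglik(t, tips, rm01) == pytest.approx(
            mk.mk_loglik(t, relabeled, rmAB), rel=1e-12)

    def test_unknown_tip_marginalized(self, three_taxon_tree):
        """An 'unknown' tip contributes a flat partial likelihood: the result
        must equal the probability-weighted sum over its possible states."""
        rm = mk.er_matrix(0.6)
        ll_unknown = mk.mk_loglik(three_taxon_tree, {"A": 0, "B": 1, "C": "unknown"}, rm)
        l0 = math.exp(mk.mk_loglik(three_taxon_tree, {"A": 0, "B": 1, "C": 0}, rm))
        l1 = math.exp(mk.mk_loglik(three_taxon_tree, {"A": 0, "B": 1, "C": 1}, rm))
        assert ll_unknown == pytest.approx(math.log(l0 + l1), rel=1e-10)


class TestFitMk:
    def test_constant_character_boundary_warning(self):
        t = simulate_yule_tree(6, 8)
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            rm, ll = mk.fit_mk(t, {lb: 1 for lb in t.tip_labels}, "ER")
        assert any("constant" in str(x.message) for x in w)
        assert rm.Q[0, 1] == pytest.approx(mk.RATE_LOWER)

    def test_ml_estimate_consistency(self):
        """Median ML rate over replicates on 200-tip trees generated with
        q = 1 must land in [0.7, 1.4]."""
        ests = []
        for rep in range(50):
            t = simulate_yule_tree(200, 1000 + rep)
            tips, _ = simulate_mk_character(t, np.array([[-1.0, 1.0], [1.0, -1.0]]), seed=rep)
            if len(set(tips.values())) < 2:
                continue
            rm, _ = mk.fit_mk(t, tips, "ER")
            ests.append(rm.Q[0, 1])
        assert 0.7 <= float(np.median(ests)) <= 1.4

    def test_ml_at_least_truth_likelihood(self):
        for rep in range(5):
            t = simulate_yule_tree(30, 60 + rep)
            tips, _ = simulate_mk_character(t, np.array([[-1.0, 1.0], [1.0, -1.0]]), seed=rep)
            if len(set(tips.values())) < 2:
                continue
            rm, ll = mk.fit_mk(t, tips, "ER")
            ll_truth = mk.mk_loglik(t, tips, mk.er_matrix(1.0))
            assert ll >= ll_truth - 1e-9

    def test_ard_beats_or_matches_er(self):
        t = simulate_yule_tree(30, 91)
        tips, _ = simulate_mk_character(t, np.array([[-2.0, 2.0], [0.5, -0.5]]), seed=4)
        if len(set(tips.values())) < 2:
            pytest.skip("degenerate draw")
        _, ll_er = mk.fit_mk(t, tips, "ER")
        _, ll_ard = mk.fit_mk(t, tips, "ARD")
        assert ll_ard >= ll_er - 1e-6


class TestMarginalPosteriors:
    def test_low_rate_uniform_character(self):
        t = simulate_yule_tree(6, 21)
        tips = {lb: 1 for lb in t.tip_labels}
        post = mk.marginal_node_posteriors(t, tips, mk.er_matrix(1e-8))
        for v in t.internal_ids:
            assert post[v][1] > 0.999

    def test_two_tip_symmetry(self, two_tip_tree):
        post = mk.marginal_node_posteriors(two_tip_tree, {"A": 0, "B": 1}, mk.er_matrix(0.8))
        assert post[two_tip_tree.root] == pytest.approx([0.5, 0.5])

    def test_matches_enumeration(self):
        """Exact marginals equal the brute-force sum at every internal node."""
        rng = np.random.default_rng(7)
        for rep in range(10):
            t = simulate_yule_tree(4, 400 + rep)
            rm = mk.er_matrix(float(rng.uniform(0.2, 2.0)))
            tips = {lb: int(rng.integers(2)) for lb in t.tip_labels}
            if len(set(tips.values())) < 2:
                continue
            post = mk.marginal_node_posteriors(t, tips, rm)
            for v in t.internal_ids:
                oracle = enumerate_marginal(t, tips, rm, np.array([0.5, 0.5]), v)
                assert np.abs(post[v] - oracle).max() < 1e-10


class TestCharacterHistories:
    def test_zero_rate_no_events(self):
        t = simulate_yule_tree(5, 31)
        tips = {lb: 0 for lb in t.tip_labels}
        maps = mk.sample_character_histories(t, tips, mk.er_matrix(0.0), n_maps=20, seed=3)
        assert all(m.n_events() == 0 for m in maps)

    def test_discordant_tips_force_events(self, two_tip_tree):
        maps = mk.sample_character_histories(
            two_tip_tree, {"A": 0, "B": 1}, mk.er_matrix(0.3), n_maps=50, seed=4)
        assert all(m.n_events() >= 1 for m in maps)

    def test_endpoint_consistency(self):
        t = simulate_yule_tree(7, 55)
        tips = {lb: i % 2 for i, lb in enumerate(t.tip_labels)}
        maps = mk.sample_character_histories(t, tips, mk.er_matrix(1.5), n_maps=50, seed=6)
        for m in maps:
            for v in range(t.n_nodes):
                if t.parent[v] < 0:
                    continue
                s = m.node_state[t.parent[v]]
                for tau, ns in m.events[v]:
                    assert 0.0 < tau <= float(t.length[v]) + 1e-12
                    s = ns
                assert s == m.node_state[v]

    def test_uniformization_path_matches_rejection_frequencies(self):
        """The uniformization fallback must sample the same endpoint-
        conditioned event-count distribution as rejection sampling."""
        rng = np.random.default_rng(0)
        Q = np.array([[-1.2, 1.2], [0.8, -0.8]])
        t_len, a, b = 0.9, 0, 1
        p_ab = mk.RateMatrix(Q, (0, 1)).transition(t_len)[a, b]
        n = 4000
        rej = [len(mk._path_rejection(rng, Q, a, b, t_len)) for _ in range(n)]
        uni = [len(mk._path_uniformization(rng, Q, a, b, t_len, p_ab)) for _ in range(n)]
        fr = np.bincount(rej, minlength=6)[:6] / n
        fu = np.bincount(uni, minlength=6)[:6] / n
        assert np.abs(fr - fu).max() < 4 * math.sqrt(0.25 / n) + 0.01


class TestNodePPAggregation:
    def test_repeated_tree_equals_single_tree(self):
        """A sample made of one tree repeated gives the same PPs as more maps
        on that single tree, within Monte-Carlo error."""
        t = treeio.to_unit_height(simulate_yule_tree(6, 70))
        tips = {lb: i % 2 for i, lb in enumerate(t.tip_labels)}
        rep = treeio.TreeSample([t] * 10, frozenset(t.tip_labels))
        one = treeio.TreeSample([t], frozenset(t.tip_labels))
        tab_rep = mk.summarize_node_pp(rep, tips, n_maps_per_tree=200, seed=1)
        tab_one = mk.summarize_node_pp(one, tips, n_maps_per_tree=2000, seed=2)
        for clade, pp in tab_rep.pp.items():
            for s, p in pp.items():
                assert abs(p - tab_one.pp[clade].get(s, 0.0)) < 0.06

    def test_draw_counts_and_row_sums(self):
        sample = synthetic_tree_sample(20, seed=3)
        tab = mk.summarize_node_pp(sample, SUPERSTRUCTURE_STATES["TT"],
                                   n_maps_per_tree=5, seed=8)
        full = frozenset(sample.taxa)
        assert tab.draws[full] == 20 * 5
        assert tab.coverage[full] == 1.0
        for clade, pp in tab.pp.items():
            assert sum(pp.values()) == pytest.approx(1.0, abs=1e-9)
            assert tab.draws[clade] <= 20 * 5

    def test_partial_clade_coverage(self):
        """A clade present in only part of the sample is averaged over those
        trees only, with the coverage fraction reported."""
        a = treeio.parse_newick("(((A:1,B:1):1,C:2):1,D:3);")
        b = treeio.parse_newick("(((A:1,C:1):1,B:2):1,D:3);")
        sample = treeio.TreeSample([treeio.to_unit_height(x) for x in (a, b)],
                                   frozenset("ABCD"))
        tips = {"A": 0, "B": 0, "C": 1, "D": 1}
        tab = mk.summarize_node_pp(sample, tips, n_maps_per_tree=10, seed=5)
        ab = frozenset("AB")
        assert tab.coverage[ab] == 0.5
        assert tab.draws[ab] == 10

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mk.summarize_node_pp(treeio.TreeSample([], frozenset()), {}, seed=0)
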