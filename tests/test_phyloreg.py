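import math

import numpy as np
import pytest

from burrowstats import morphodata as md
from burrowstats import phyloreg as pr
from burrowstats.synthetic_data import (
    simulate_measurements,
    simulate_varying_effects,
    simulate_yule_tree,
)
from burrowstats.treeio import phylo_correlation


def _dataset(n_species=8, n_per=30, bbar=0.3, sigma=0.05, sds=(0.1, 0.1, 0.1, 0.1),
             seed=0):
    ss = np.random.SeedSequence(seed).spawn(3)
    s = [int(x.generate_state(1)[0] % 2**31) for x in ss]
    tree = simulate_yule_tree(n_species, s[0])
    truth = simulate_varying_effects(tree, 3.4, bbar, *sds, seed=s[1])
    rec = simulate_measurements(truth, n_per_species=n_per, sigma=sigma, seed=s[2])
    ds = md.build_dataset(rec, "IFA", tree)
    R = phylo_correlation(tree, ds.species)
    return ds, R, truth


def _fake_posterior(loglik, include_bm=True, extra=None):
    params = {"abar": np.zeros((2, max(2, loglik.shape[0] // 2)))}
    post = pr.PosteriorSample(params=params, species=["s1"], include_bm=include_bm,
                              seed=0, loglik=loglik)
    if extra:
        post.params.update(extra)
    return post


class TestWAIC:
    def test_degenerate_standard_normal(self):
        """One observation y=0 under a posterior fixed at N(0,1):
        lppd = log N(0|0,1), pWAIC = 0, WAIC = -2 lppd = 1.8378771."""
        ll = np.full((10, 1), -0.5 * math.log(2 * math.pi))
        w = pr.compute_waic(_fake_posterior(ll))
        assert w.lppd == pytest.approx(-0.9189385, abs=1e-7)
        assert w.p_waic == pytest.approx(0.0, abs=1e-12)
        assert w.waic == pytest.approx(1.8378771, abs=1e-6)

    def test_matches_direct_formula_on_toy_draws(self):
        """Hand-written 3-draw, 5-observation table vs the formulas computed
        independently below."""
        rng = np.random.default_rng(3)
        ll = rng.normal(-1.0, 0.4, size=(3, 5))
        w = pr.compute_waic(_fake_posterior(ll))
        lppd = sum(math.log(np.mean(np.exp(ll[:, i]))) for i in range(5))
        p = sum(np.var(ll[:, i], ddof=1) for i in range(5))
        assert w.lppd == pytest.approx(lppd, rel=1e-12)
        assert w.p_waic == pytest.approx(p, rel=1e-12)
        assert w.waic == pytest.approx(-2 * (lppd - p), rel=1e-12)

    def test_p_waic_nonnegative(self):
        rng = np.random.default_rng(8)
        w = pr.compute_waic(_fake_posterior(rng.normal(-1, 1, size=(50, 20))))
        assert w.p_waic >= 0

    def test_needs_two_draws(self):
        with pytest.raises(ValueError):
            pr.compute_waic(_fake_posterior(np.zeros((1, 3))))


class TestCompareModels:
    def test_identical_models(self):
        ll = np.random.default_rng(0).normal(-1, 0.3, size=(20, 6))
        a = pr.compute_waic(_fake_posterior(ll))
        b = pr.compute_waic(_fake_posterior(ll.copy()))
        c = pr.compare_models(a, b)
        assert c.delta_waic == pytest.approx(0.0, abs=1e-12)
        assert c.delta_se == pytest.approx(0.0, abs=1e-12)

    def test_constant_pointwise_difference(self):
        """Pointwise differences all equal to c give dWAIC = n|c|, dSE = 0."""
        rng = np.random.default_rng(1)
        ll = rng.normal(-1, 0.3, size=(30, 8))
        a = pr.compute_waic(_fake_posterior(ll))
        b = pr.compute_waic(_fake_posterior(ll))
        c = 0.37
        b.pointwise = a.pointwise + c
        b.waic = float(b.pointwise.sum())
        comp = pr.compare_models(a, b)
        assert comp.delta_waic == pytest.approx(8 * c, rel=1e-9)
        assert comp.delta_se == pytest.approx(0.0, abs=1e-9)
        assert comp.preferred == "full"

    def test_mismatched_n_rejected(self):
        a = pr.compute_waic(_fake_posterior(np.zeros((3, 4)) - 1.0))
        b = pr.compute_waic(_fake_posterior(np.zeros((3, 5)) - 1.0))
        with pytest.raises(ValueError):
            pr.compare_models(a, b)


class TestPosteriorSummary:
    def test_constant_draws(self):
        post = _fake_posterior(np.zeros((4, 2)) - 1.0)
        post.params = {"abar": np.full((2, 50), 3.0)}
        s = pr.posterior_summary(post)
        row = s.iloc[0]
        assert row["mean"] == pytest.approx(3.0)
        assert row["q5.5"] == pytest.approx(3.0)
        assert row["q94.5"] == pytest.approx(3.0)

    def test_interval_matches_normal_quantiles(self):
        rng = np.random.default_rng(5)
        draws = rng.standard_normal((2, 50_000))
        post = _fake_posterior(np.zeros((4, 2)) - 1.0)
        post.params = {"abar": draws}
        s = pr.posterior_summary(post, interval=0.89)
        row = s.iloc[0]
        assert row["q5.5"] == pytest.approx(-1.598, abs=0.02)
        assert row["q94.5"] == pytest.approx(1.598, abs=0.02)

    def test_rhat_flags_disjoint_chains(self):
        rng = np.random.default_rng(6)
        draws = np.stack([rng.normal(0, 1, 400), rng.normal(5, 1, 400)])
        post = _fake_posterior(np.zeros((4, 2)) - 1.0)
        post.params = {"abar": draws}
        s = pr.posterior_summary(post)
        assert s.iloc[0]["rhat"] > 1.05
        assert not s.iloc[0]["converged"]


class TestVarianceShares:
    def _post_with_scales(self, aphy, asp):
        post = _fake_posterior(np.zeros((4, 2)) - 1.0, include_bm=False)
        post.params = {
            "sigma_a_phy": np.asarray(aphy, float).reshape(2, -1),
            "sigma_a_sp": np.asarray(asp, float).reshape(2, -1),
        }
        return post

    def test_pure_phylogenetic(self):
        post = self._post_with_scales(np.full(10, 0.4), np.zeros(10))
        s = pr.variance_shares(post)
        assert s.iloc[0]["phylo_share_mean"] == pytest.approx(1.0)

    def test_equal_components(self):
        post = self._post_with_scales(np.full(10, 0.3), np.full(10, 0.3))
        s = pr.variance_shares(post)
        assert s.iloc[0]["phylo_share_mean"] == pytest.approx(0.5)

    def test_zero_draws_skipped(self):
        aphy = np.array([0.4] * 8 + [0.0] * 2)
        asp = np.array([0.0] * 10)
        s = pr.variance_shares(self._post_with_scales(aphy, asp))
        assert s.iloc[0]["n_skipped"] == 2
        assert s.iloc[0]["n_draws"] == 8


class TestFitVaryingEffects:
    def test_recovers_slope_and_covers_truth(self):
        ds, R, truth = _dataset(seed=12)
        spec = pr.ModelSpec(R=R, chains=4, iterations=1000, warmup_frac=0.5, seed=1)
        post = pr.fit_varying_effects(ds, spec)
        b = post.flat("bbar")
        lo, hi = np.quantile(b, [0.055, 0.945])
        assert abs(b.mean() - 0.3) < 0.25
        assert lo < 0.3 < hi or abs(b.mean() - 0.3) < 0.1

    def test_tight_concentration_without_heterogeneity(self):
        """With zero between-species sds and low noise the grand parameters
        concentrate at truth and chains agree (R-hat < 1.01)."""
        ds, R, truth = _dataset(n_per=100, sds=(0, 0, 0, 0), sigma=0.02, seed=5)
        spec = pr.ModelSpec(R=R, chains=4, iterations=3000, warmup_frac=0.5, seed=2)
        post = pr.fit_varying_effects(ds, spec)
        assert abs(post.flat("bbar").mean() - 0.3) < 0.05
        assert abs(post.flat("abar").mean() - 3.4) < 0.1
        summ = pr.posterior_summary(post)
        grand = summ[summ["parameter"].isin(["abar", "bbar", "sigma"])]
        assert (grand["rhat"] < 1.01).all()

    def test_wrong_R_shape_rejected(self):
        ds, R, _ = _dataset(seed=3)
        with pytest.raises(ValueError):
            pr.fit_varying_effects(ds, pr.ModelSpec(R=R[:5, :5], seed=0))

    def test_requires_two_chains(self):
        ds, R, _ = _dataset(seed=3)
        with pytest.raises(ValueError):
            pr.ModelSpec(R=R, chains=1)

    def test_identity_R_matches_emcee_reference(self):
        """Dual-route check of the full joint posterior: the blocked Gibbs
        sampler must agree with an independent affine-invariant ensemble
        sampler (emcee) run on the identical log-posterior density."""
        emcee = pytest.importorskip("emcee")
        ds, R, _ = _dataset(n_species=4, n_per=12, bbar=0.0, sigma=0.1,
                            sds=(0.15, 0.15, 0, 0), seed=21)
        # no-BM model keeps the dimension small for the reference sampler
        S, n = ds.n_species, ds.n
        y, sidx = ds.y, ds.species_idx
        ybar = y.mean()
        Rc = np.linalg.cholesky(R + 1e-10 * np.eye(S))

        def logpost(th):
            abar, aphy, asp = th[0], th[1:1 + S], th[1 + S:1 + 2 * S]
            ls, lap, lasp = th[1 + 2 * S:]
            sg, sap, sasp = np.exp([ls, lap, lasp])
            mu = abar + aphy[sidx] + asp[sidx]
            u = np.linalg.solve(Rc, aphy)
            return (
                -n * ls - 0.5 * np.sum((y - mu) ** 2) / sg**2
                - 0.5 * (abar - ybar) ** 2
                - S * lap - 0.5 * (u @ u) / sap**2
                - S * lasp - 0.5 * (asp @ asp) / sasp**2
                - sg + ls - sap + lap - sasp + lasp
            )

        ndim = 1 + 2 * S + 3
        rng = np.random.default_rng(0)
        p0 = rng.normal(0, 0.1, size=(48, ndim))
        p0[:, 0] += ybar
        p0[:, -3:] = np.log(0.2) + 0.2 * rng.normal(size=(48, 3))
        sampler = emcee.EnsembleSampler(48, ndim, logpost)
        sampler.run_mcmc(p0, 4000, progress=False)
        chain = sampler.get_chain(discard=1500, thin=8, flat=True)

        post = pr.fit_varying_effects(
            ds, pr.ModelSpec(R=R, include_bm=False, chains=4, iterations=3000,
                             warmup_frac=0.5, seed=9))
        assert abs(post.flat("abar").mean() - chain[:, 0].mean()) < 0.05
        assert abs(post.flat("sigma").mean() - np.exp(chain[:, -3]).mean()) < 0.01
        assert abs(post.flat("sigma_a_phy").mean() - np.exp(chain[:, -2]).mean()) < 0.08
        assert abs(post.flat("sigma_a_sp").mean() - np.exp(chain[:, -1]).mean()) < 0.08
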