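"""Bayesian varying-intercept / varying-slope regression with a phylogenetic
and an independent species component, plus WAIC model comparison.

Model, for individual *i* of species *s(i)*:

    y_i ~ Normal(mu_i, sigma)
    mu_i = (abar + a_phy[s(i)] + a_sp[s(i)])
         + (bbar + b_phy[s(i)] + b_sp[s(i)]) * x_i

with a_phy ~ MVN(0, sigma_a_phy^2 R) on the Brownian correlation matrix R of
the tree, a_sp ~ Normal(0, sigma_a_sp) i.i.d., and the same split for slopes.
Priors: abar ~ Normal(mean(y), 1), bbar ~ Normal(0, 1), all five scale
parameters ~ Exponential(1).  Setting ``include_bm=False`` drops the slope
terms entirely (the "no body mass" model).

Sampling is a blocked Gibbs scheme that is exact for this conditionally
Gaussian model: the full coefficient vector (grand terms plus all varying
effects) is drawn jointly from its multivariate-normal conditional; the
residual sd by slice sampling; each variance-component sd by a slice update
in the centered parameterization followed by an interweaved truncated-normal
update in the non-centered parameterization (ASIS), which keeps mixing fast
when a component is near zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import log_ndtr, ndtri
import pandas as pd

from .morphodata import RegressionDataset

__all__ = [
    "ModelSpec",
    "PosteriorSample",
    "WAICResult",
    "ComparisonResult",
    "fit_varying_effects",
    "compute_waic",
    "compare_models",
    "posterior_summary",
    "variance_shares",
]

_SCALE_NAMES = ("sigma", "sigma_a_phy", "sigma_a_sp", "sigma_b_phy", "sigma_b_sp")


@dataclass
class ModelSpec:
    """Model and MCMC configuration.

    ``R`` is the phylogenetic correlation matrix over the dataset's species
    (tip order must match ``RegressionDataset.species``).
    """

    R: np.ndarray
    include_bm: bool = True
    chains: int = 4
    iterations: int = 5000
    warmup_frac: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.warmup_frac < 1.0):
            raise ValueError("warmup fraction must be in (0, 1)")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for split-chain diagnostics")
        self.R = np.asarray(self.R, dtype=float)


@dataclass
class PosteriorSample:
    """Post-warmup MCMC draws, kept per chain.

    ``params[name]`` has shape (chains, draws) for scalars and
    (chains, draws, S) for per-species vectors.  The pointwise log-likelihood
    matrix has shape (chains*draws, n).
    """

    params: dict
    species: list
    include_bm: bool
    seed: int
    loglik: Optional[np.ndarray] = None

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def flat(self, name: str) -> np.ndarray:
        a = self.params[name]
        return a.reshape(-1, *a.shape[2:])


# ---------------------------------------------------------------- sampler
def _slice_sample(logp, x0, rng, width=1.0, max_steps=50):
    """Univariate stepping-out slice sampler (Neal 2003)."""
    y = logp(x0) - rng.exponential(1.0)
    lo = x0 - width * rng.random()
    hi = lo + width
    for _ in range(max_steps):
        if logp(lo) <= y:
            break
        lo -= width
    for _ in range(max_steps):
        if logp(hi) <= y:
            break
        hi += width
    while True:
        x1 = lo + (hi - lo) * rng.random()
        if logp(x1) > y:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1


def _trunc_normal_pos(rng, mean, sd):
    """One draw from Normal(mean, sd) truncated to [0, inf).

    Inverse-CDF through the upper tail: with a = -mean/sd the standardized
    bound, P(Z > z) = (1-u) * Phi(-a), so z = -ndtri((1-u) * Phi(-a)).  Far in
    the tail (a >> 0) the draw collapses to the exponential boundary layer.
    """
    a = -mean / sd
    u = rng.random()
    tail = math.exp(log_ndtr(-a))  # Phi(-a) = P(Z > a)
    q = (1.0 - u) * tail
    if q > 1e-300:
        z = -ndtri(q)
        return float(mean + sd * z)
    # boundary layer: (z - a) is approximately Exp(a)
    return float(sd * rng.exponential(1.0 / max(a, 1.0)))


def fit_varying_effects(data: RegressionDataset, spec: ModelSpec) -> PosteriorSample:
    """Posterior sampling of the varying-effects model by blocked Gibbs."""
    y = data.y
    x = data.x
    s_idx = data.species_idx
    n = data.n
    S = data.n_species
    if S < 2:
        raise ValueError("need at least 2 species")
    if spec.R.shape != (S, S):
        raise ValueError(
            f"R has shape {spec.R.shape}, expected ({S}, {S}) for species {data.species}"
        )
    if n < S:
        raise ValueError("need at least as many observations as species")
    # R must be positive (semi-)definite; factor with a tiny ridge
    try:
        R_chol = np.linalg.cholesky(spec.R + 1e-10 * np.eye(S))
    except np.linalg.LinAlgError as exc:
        raise ValueError("phylogenetic correlation matrix is not PSD") from exc
    Rinv = cho_solve((R_chol, True), np.eye(S))

    include_bm = spec.include_bm
    # coefficient layout: [abar, (bbar), a_phy(S), a_sp(S), (b_phy(S), b_sp(S))]
    n_grand = 2 if include_bm else 1
    p = n_grand + (4 * S if include_bm else 2 * S)

    X = np.zeros((n, p))
    X[:, 0] = 1.0
    if include_bm:
        X[:, 1] = x
    off_aphy = n_grand
    off_asp = n_grand + S
    X[np.arange(n), off_aphy + s_idx] = 1.0
    X[np.arange(n), off_asp + s_idx] = 1.0
    if include_bm:
        off_bphy = n_grand + 2 * S
        off_bsp = n_grand + 3 * S
        X[np.arange(n), off_bphy + s_idx] = x
        X[np.arange(n), off_bsp + s_idx] = x

    XtX = X.T @ X
    Xty = X.T @ y
    ybar = float(y.mean())

    # prior mean vector (only abar has a nonzero prior mean)
    mu0 = np.zeros(p)
    mu0[0] = ybar

    kept = spec.iterations - int(round(spec.iterations * spec.warmup_frac))
    warm = spec.iterations - kept

    scale_names = _SCALE_NAMES if include_bm else ("sigma", "sigma_a_phy", "sigma_a_sp")
    comps = [("a", off_aphy, off_asp)] + ([("b", off_bphy, off_bsp)] if include_bm else [])

    store = {
        "abar": np.zeros((spec.chains, kept)),
        "a_phy": np.zeros((spec.chains, kept, S)),
        "a_sp": np.zeros((spec.chains, kept, S)),
    }
    for nm in scale_names:
        store[nm] = np.zeros((spec.chains, kept))
    if include_bm:
        store["bbar"] = np.zeros((spec.chains, kept))
        store["b_phy"] = np.zeros((spec.chains, kept, S))
        store["b_sp"] = np.zeros((spec.chains, kept, S))

    theta_store = np.zeros((spec.chains, kept, p))

    ss = np.random.SeedSequence(spec.seed)
    chain_seeds = ss.spawn(spec.chains)

    for ch in range(spec.chains):
        rng = np.random.default_rng(chain_seeds[ch])
        # dispersed but modest initial values
        sigma = float(np.std(y)) * (0.5 + rng.random())
        scales = {nm: 0.2 + 0.3 * rng.random() for nm in scale_names if nm != "sigma"}
        theta = np.zeros(p)
        theta[0] = ybar + 0.1 * rng.standard_normal()
        if include_bm:
            theta[1] = 0.1 * rng.standard_normal()

        for it in range(spec.iterations):
            # ---- joint Gaussian draw of all coefficients -------------------
            Lam = np.zeros((p, p))
            Lam[0, 0] = 1.0  # abar prior sd 1
            if include_bm:
                Lam[1, 1] = 1.0  # bbar prior sd 1
            Lam[off_aphy:off_aphy + S, off_aphy:off_aphy + S] = Rinv / scales["sigma_a_phy"] ** 2
            Lam[off_asp:off_asp + S, off_asp:off_asp + S] = np.eye(S) / scales["sigma_a_sp"] ** 2
            if include_bm:
                Lam[off_bphy:off_bphy + S, off_bphy:off_bphy + S] = Rinv / scales["sigma_b_phy"] ** 2
                Lam[off_bsp:off_bsp + S, off_bsp:off_bsp + S] = np.eye(S) / scales["sigma_b_sp"] ** 2
            P = XtX / sigma**2 + Lam
            b = Xty / sigma**2 + Lam @ mu0
            cf = cho_factor(P, lower=True)
            mean = cho_solve(cf, b)
            z = rng.standard_normal(p)
            theta = mean + solve_triangular(cf[0], z, lower=True, trans="T")

            resid = y - X @ theta

            # ---- residual sd (slice on log sigma) --------------------------
            ssr = float(resid @ resid)

            def logp_sigma(ls):
                sg = math.exp(ls)
                return -n * ls - 0.5 * ssr / sg**2 - sg + ls  # + Jacobian

            sigma = math.exp(_slice_sample(logp_sigma, math.log(sigma), rng))

            # ---- variance-component sds ------------------------------------
            for tag, off_phy, off_sp in comps:
                for kind, off in (("phy", off_phy), ("sp", off_sp)):
                    nm = f"sigma_{tag}_{kind}"
                    a_vec = theta[off:off + S]
                    if kind == "phy":
                        u = solve_triangular(R_chol, a_vec, lower=True)
                        qform = float(u @ u)
                    else:
                        qform = float(a_vec @ a_vec)

                    def logp_sc(ls, qform=qform):
                        sc = math.exp(ls)
                        return -S * ls - 0.5 * qform / sc**2 - sc + ls

                    sc = math.exp(_slice_sample(logp_sc, math.log(scales[nm]), rng))

                    # interweaved (non-centered) update: with the standardized
                    # effects fixed, the scale enters the likelihood linearly
                    tilde = a_vec / sc
                    w = tilde[s_idx] * (x if tag == "b" else 1.0)
                    r_ex = resid + a_vec[s_idx] * (x if tag == "b" else 1.0)
                    ww = float(w @ w)
                    if ww > 0:
                        v = sigma**2 / ww
                        m_hat = float(w @ r_ex) / ww
                        sc_new = _trunc_normal_pos(rng, m_hat - v, math.sqrt(v))
                        sc_new = max(sc_new, 1e-12)
                    else:
                        sc_new = sc
                    theta[off:off + S] = sc_new * tilde
                    resid = r_ex - theta[off:off + S][s_idx] * (x if tag == "b" else 1.0)
                    scales[nm] = sc_new

            if it >= warm:
                j = it - warm
                theta_store[ch, j] = theta
                store["abar"][ch, j] = theta[0]
                store["a_phy"][ch, j] = theta[off_aphy:off_aphy + S]
                store["a_sp"][ch, j] = theta[off_asp:off_asp + S]
                store["sigma"][ch, j] = sigma
                for nm in scale_names[1:]:
                    store[nm][ch, j] = scales[nm]
                if include_bm:
                    store["bbar"][ch, j] = theta[1]
                    store["b_phy"][ch, j] = theta[off_bphy:off_bphy + S]
                    store["b_sp"][ch, j] = theta[off_bsp:off_bsp + S]

    # pointwise log-likelihood matrix (all kept draws, flattened)
    Theta = theta_store.reshape(-1, p)
    Sig = store["sigma"].reshape(-1)
    Mu = Theta @ X.T
    loglik = (
        -0.5 * np.log(2.0 * np.pi)
        - np.log(Sig)[:, None]
        - 0.5 * ((y[None, :] - Mu) / Sig[:, None]) ** 2
    )
    return PosteriorSample(
        params=store, species=list(data.species), include_bm=include_bm,
        seed=spec.seed, loglik=loglik,
    )


# -------------------------------------------------------------------- WAIC
@dataclass
class WAICResult:
    lppd: float
    p_waic: float
    waic: float
    pointwise: np.ndarray  # per-observation WAIC contributions (deviance scale)
    n: int


def compute_waic(post: PosteriorSample, data: Optional[RegressionDataset] = None) -> WAICResult:
    """WAIC on the deviance scale from the stored pointwise log-likelihoods.

    lppd_i = log mean_d p(y_i|d);  p_i = var_d log p(y_i|d);
    WAIC = -2 * sum_i (lppd_i - p_i).
    """
    ll = post.loglik
    if ll is None or ll.shape[0] < 2:
        raise ValueError("need a pointwise log-likelihood matrix with >= 2 draws")
    d = ll.shape[0]
    lppd_i = np.logaddexp.reduce(ll, axis=0) - math.log(d)
    p_i = ll.var(axis=0, ddof=1)
    pointwise = -2.0 * (lppd_i - p_i)
    return WAICResult(
        lppd=float(lppd_i.sum()),
        p_waic=float(p_i.sum()),
        waic=float(pointwise.sum()),
        pointwise=pointwise,
        n=ll.shape[1],
    )


@dataclass
class ComparisonResult:
    delta_waic: float
    delta_se: float
    preferred: str  # "full" or "reduced"
    waic_full: float
    waic_reduced: float


def compare_models(full: WAICResult, reduced: WAICResult) -> ComparisonResult:
    """ΔWAIC (worse minus better, >= 0) and its pointwise standard error."""
    if full.n != reduced.n:
        raise ValueError(f"mismatched observation counts: {full.n} vs {reduced.n}")
    d_i = full.pointwise - reduced.pointwise
    if full.waic <= reduced.waic:
        preferred, delta = "full", reduced.waic - full.waic
    else:
        preferred, delta = "reduced", full.waic - reduced.waic
    delta_se = float(np.sqrt(full.n * d_i.var(ddof=0))) if full.n > 1 else 0.0
    return ComparisonResult(
        delta_waic=float(delta),
        delta_se=delta_se,
        preferred=preferred,
        waic_full=full.waic,
        waic_reduced=reduced.waic,
    )


# ----------------------------------------------------------------- summary
def posterior_summary(post: PosteriorSample, interval: float = 0.89) -> pd.DataFrame:
    """Per-parameter mean, sd, central interval, split-chain R-hat and ESS.

    Vector parameters are expanded one row per species.  A ``converged``
    column flags R-hat <= 1.05.
    """
    import arviz as az

    lo_q = (1.0 - interval) / 2.0
    hi_q = 1.0 - lo_q
    rows = []
    for name, a in post.params.items():
        if a.ndim == 2:
            entries = [(name, a)]
        else:
            entries = [(f"{name}[{post.species[s]}]", a[:, :, s]) for s in range(a.shape[2])]
        for label, arr in entries:
            flat = arr.reshape(-1)
            if np.allclose(arr, arr.reshape(-1)[0]):
                rhat, ess = 1.0, float(flat.size)
            else:
                da = az.convert_to_dataset({"v": arr})
                rhat = float(np.asarray(az.rhat(da)["v"]))
                ess = float(np.asarray(az.ess(da)["v"]))
            rows.append(
                {
                    "parameter": label,
                    "mean": float(flat.mean()),
                    "sd": float(flat.std(ddof=1)) if flat.size > 1 else 0.0,
                    f"q{100 * lo_q:g}": float(np.quantile(flat, lo_q)),
                    f"q{100 * hi_q:g}": float(np.quantile(flat, hi_q)),
                    "rhat": rhat,
                    "ess": ess,
                    "converged": bool(rhat <= 1.05),
                }
            )
    return pd.DataFrame(rows)


def variance_shares(post: PosteriorSample, interval: float = 0.89) -> pd.DataFrame:
    """Posterior share of between-species variance attributed to phylogeny.

    Per draw: share = sigma_phy^2 / (sigma_phy^2 + sigma_sp^2), separately for
    intercepts and (when present) slopes.  Draws with both components zero are
    skipped and counted.
    """
    lo_q = (1.0 - interval) / 2.0
    hi_q = 1.0 - lo_q
    rows = []
    pairs = [("intercept", "sigma_a_phy", "sigma_a_sp")]
    if post.include_bm:
        pairs.append(("slope", "sigma_b_phy", "sigma_b_sp"))
    for label, phy, sp in pairs:
        vp = post.flat(phy) ** 2
        vs = post.flat(sp) ** 2
        tot = vp + vs
        ok = tot > 0
        share = vp[ok] / tot[ok]
        rows.append(
            {
                "component": label,
                "phylo_share_mean": float(share.mean()),
                f"q{100 * lo_q:g}": float(np.quantile(share, lo_q)),
                f"q{100 * hi_q:g}": float(np.quantile(share, hi_q)),
                "n_draws": int(ok.sum()),
                "n_skipped": int((~ok).sum()),
            }
        )
    return pd.DataFrame(rows)
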