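"""Mk-model likelihood, maximum-likelihood rate estimation, exact marginal
ancestral-state posteriors, stochastic character mapping, and aggregation of
node posterior probabilities over a sample of trees.

The likelihood is the classic pruning (post-order dynamic programming)
computation with per-branch transition matrices ``expm(Q·t)``.  Marginal node
posteriors come from the standard two-pass (post-order + pre-order) message
passing and serve as the exact oracle for the sampled maps.  Character
histories are drawn by sampling node states from the joint posterior
(root marginal, then child given parent) and filling each branch with an
endpoint-conditioned CTMC path — rejection sampling with the forced-first-
event variant when the endpoints differ, falling back to uniformization when
rejection stalls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize, minimize_scalar

from .treeio import PhyloTree, TreeSample, clade_keys

__all__ = [
    "RateMatrix",
    "CharacterHistory",
    "NodePosteriorTable",
    "mk_loglik",
    "fit_mk",
    "marginal_node_posteriors",
    "sample_character_histories",
    "summarize_node_pp",
    "er_matrix",
]

RATE_LOWER = 1e-8
RATE_UPPER = 100.0


@dataclass
class RateMatrix:
    """CTMC generator with state labels; rates are per unit branch length."""

    Q: np.ndarray
    states: tuple = (0, 1)

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        k = self.Q.shape[0]
        if self.Q.shape != (k, k) or len(self.states) != k:
            raise ValueError("Q shape and state labels disagree")
        off = self.Q - np.diag(np.diag(self.Q))
        if (off < 0).any():
            raise ValueError("off-diagonal rates must be >= 0")
        if np.abs(self.Q.sum(axis=1)).max() > 1e-10:
            raise ValueError("rows of Q must sum to 0 (within 1e-10)")

    @property
    def k(self) -> int:
        return self.Q.shape[0]

    def transition(self, t: float) -> np.ndarray:
        """``expm(Q t)``; closed form for symmetric binary generators."""
        if self.k == 2 and abs(self.Q[0, 1] - self.Q[1, 0]) < 1e-300:
            q = self.Q[0, 1]
            e = math.exp(-2.0 * q * t)
            p_stay, p_move = 0.5 * (1 + e), 0.5 * (1 - e)
            return np.array([[p_stay, p_move], [p_move, p_stay]])
        return expm(self.Q * t)


def er_matrix(rate: float, k: int = 2, states: Optional[tuple] = None) -> RateMatrix:
    """Equal-rates generator: every off-diagonal rate equals ``rate``."""
    Q = np.full((k, k), rate, dtype=float)
    np.fill_diagonal(Q, -rate * (k - 1))
    return RateMatrix(Q, states=states if states is not None else tuple(range(k)))


@dataclass
class CharacterHistory:
    """One sampled realization of a character's evolution over a tree.

    ``node_state`` maps node id → state index; ``events[v]`` is the ordered
    list of ``(time_from_branch_start, new_state)`` on the branch above v.
    """

    node_state: dict
    events: dict = field(default_factory=dict)

    def n_events(self) -> int:
        return sum(len(e) for e in self.events.values())


# ------------------------------------------------------------------ pruning
def _state_indices(rm: RateMatrix) -> dict:
    return {s: i for i, s in enumerate(rm.states)}


def _tip_likelihoods(tree: PhyloTree, tips: dict, rm: RateMatrix) -> dict:
    """Per-tip partial-likelihood rows; 'unknown'/None = all-ones."""
    idx = _state_indices(rm)
    out = {}
    for i in tree.tip_ids:
        name = tree.label[i]
        if name not in tips:
            raise ValueError(f"tip {name!r} has no state entry")
        s = tips[name]
        row = np.ones(rm.k)
        if s is not None and s != "unknown":
            if s not in idx:
                raise ValueError(f"state {s!r} of tip {name!r} not in {rm.states}")
            row = np.zeros(rm.k)
            row[idx[s]] = 1.0
        out[i] = row
    return out


def _branch_matrices(tree: PhyloTree, rm: RateMatrix) -> dict:
    return {v: rm.transition(float(tree.length[v])) for v in range(tree.n_nodes) if tree.parent[v] >= 0}


def _pruning(tree: PhyloTree, tips: dict, rm: RateMatrix):
    """Scaled post-order partial likelihoods.

    Returns (L, log_scale, P) where L[v] are conditional likelihoods of data
    below v given the state at v (rescaled), log_scale the summed log scaling
    factors, and P the per-branch transition matrices.
    """
    P = _branch_matrices(tree, rm)
    tipL = _tip_likelihoods(tree, tips, rm)
    L = np.zeros((tree.n_nodes, rm.k))
    log_scale = 0.0
    for v in tree.postorder():
        if not tree.children[v]:
            L[v] = tipL[v]
            continue
        row = np.ones(rm.k)
        for c in tree.children[v]:
            row = row * (P[c] @ L[c])
        m = row.max()
        if m > 0:
            row = row / m
            log_scale += math.log(m)
        L[v] = row
    return L, log_scale, P


def mk_loglik(
    tree: PhyloTree,
    tips: dict,
    rm: RateMatrix,
    root_prior: Optional[np.ndarray] = None,
) -> float:
    """Log-likelihood of tip states under the Mk model (pruning algorithm).

    Returns ``-inf`` (with a warning) when the data have zero probability,
    e.g. a zero-rate generator with discordant tips.
    """
    prior = _root_prior(rm, root_prior)
    L, log_scale, _ = _pruning(tree, tips, rm)
    lik = float(prior @ L[tree.root])
    if lik <= 0.0:
        warnings.warn("tip data impossible under this rate matrix (likelihood 0)")
        return float("-inf")
    return math.log(lik) + log_scale


def _root_prior(rm: RateMatrix, root_prior) -> np.ndarray:
    if root_prior is None:
        return np.full(rm.k, 1.0 / rm.k)
    p = np.asarray(root_prior, dtype=float)
    if p.shape != (rm.k,) or abs(p.sum() - 1.0) > 1e-8 or (p < 0).any():
        raise ValueError("root prior must be a probability vector over the states")
    return p


# ---------------------------------------------------------------------- fit
def fit_mk(
    tree: PhyloTree,
    tips: dict,
    model: str = "ER",
    root_prior: Optional[np.ndarray] = None,
    states: Optional[tuple] = None,
) -> tuple[RateMatrix, float]:
    """Maximum-likelihood rate matrix under the ER or (binary) ARD model.

    ER uses a bounded 1-D search on [1e-8, 100] (tree assumed near unit
    height); binary ARD a 2-D quasi-Newton search on log rates.  A constant
    character has its optimum at the zero-rate boundary; the boundary estimate
    is returned with a warning.
    """
    if states is None:
        observed = sorted({v for v in tips.values() if v not in (None, "unknown")})
        states = tuple(observed) if len(observed) >= 2 else (0, 1)
    k = len(states)

    observed_states = {v for v in tips.values() if v not in (None, "unknown")}
    if len(observed_states) < 2:
        warnings.warn("constant character: ML rate estimate is at the lower boundary")
        rm = er_matrix(RATE_LOWER, k, states)
        return rm, mk_loglik(tree, tips, rm, root_prior)

    if model.upper() == "ER":
        def nll(q):
            return -mk_loglik(tree, tips, er_matrix(float(q), k, states), root_prior)

        res = minimize_scalar(
            nll, bounds=(RATE_LOWER, RATE_UPPER), method="bounded",
            options={"xatol": 1e-8},
        )
        rm = er_matrix(float(res.x), k, states)
        return rm, float(-res.fun)

    if model.upper() == "ARD":
        if k != 2:
            raise NotImplementedError("ARD is implemented for binary characters")

        def nll(logq):
            q01, q10 = np.exp(logq)
            Q = np.array([[-q01, q01], [q10, -q10]])
            return -mk_loglik(tree, tips, RateMatrix(Q, states), root_prior)

        best = None
        for start in ([0.0, 0.0], [-2.0, -2.0], [1.0, -1.0]):
            res = minimize(nll, np.array(start), method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
            if best is None or res.fun < best.fun:
                best = res
        q01, q10 = np.exp(best.x)
        rm = RateMatrix(np.array([[-q01, q01], [q10, -q10]]), states)
        return rm, float(-best.fun)

    raise ValueError(f"unknown model {model!r}; expected 'ER' or 'ARD'")


# ----------------------------------------------------------------- marginals
def marginal_node_posteriors(
    tree: PhyloTree,
    tips: dict,
    rm: RateMatrix,
    root_prior: Optional[np.ndarray] = None,
) -> dict:
    """Exact marginal posterior of the state at every node.

    Two-pass algorithm: post-order partials, then a pre-order "outside"
    message G[v] (likelihood of all data outside v's subtree as a function of
    v's state); the marginal at v is ∝ G[v] * L[v].
    """
    prior = _root_prior(rm, root_prior)
    L, _, P = _pruning(tree, tips, rm)
    G = np.zeros_like(L)
    G[tree.root] = prior
    post = {}
    for v in tree.preorder():
        if tree.children[v]:
            # message from v into each child: combine G[v] with the other
            # children's upward messages, then push through the transition
            up = {c: P[c] @ L[c] for c in tree.children[v]}
            for c in tree.children[v]:
                others = G[v].copy()
                for c2 in tree.children[v]:
                    if c2 != c:
                        others = others * up[c2]
                G[c] = others @ P[c]
                m = G[c].max()
                if m > 0:
                    G[c] = G[c] / m
        w = G[v] * L[v]
        tot = w.sum()
        if tot <= 0:
            raise ValueError("zero posterior mass; data impossible under Q")
        post[v] = w / tot
    return post


# ------------------------------------------------------- history simulation
def _path_rejection(rng, Q, a, b, t, max_tries=10_000):
    """Endpoint-conditioned CTMC path by rejection; None when the cap is hit.

    When a != b the first event is forced (Nielsen's modification) by drawing
    its time from the exponential truncated to [0, t).
    """
    k = Q.shape[0]
    for _ in range(max_tries):
        events = []
        s, tau = a, 0.0
        if a != b:
            rate = -Q[a, a]
            if rate <= 0:
                return None
            u = rng.random()
            tau = -math.log(1.0 - u * (1.0 - math.exp(-rate * t))) / rate
            probs = Q[a].clip(min=0.0)
            probs[a] = 0.0
            s = int(rng.choice(k, p=probs / probs.sum()))
            events.append((tau, s))
        while True:
            rate = -Q[s, s]
            if rate <= 0:
                break
            tau += float(rng.exponential(1.0 / rate))
            if tau >= t:
                break
            probs = Q[s].clip(min=0.0)
            probs[s] = 0.0
            s = int(rng.choice(k, p=probs / probs.sum()))
            events.append((tau, s))
        if s == b:
            return events
    return None


def _path_uniformization(rng, Q, a, b, t, p_ab, max_jumps=10_000):
    """Endpoint-conditioned path via uniformization (always succeeds for
    valid Q with p_ab > 0)."""
    mu = float(np.max(-np.diag(Q)))
    if mu <= 0:
        return []
    k = Q.shape[0]
    R = np.eye(k) + Q / mu
    # sample the number of uniformized jumps n | endpoints
    Rpow = [np.eye(k)]
    log_poisson = -mu * t
    weights = []
    total = 0.0
    target = p_ab
    n = 0
    while True:
        w = math.exp(log_poisson) * Rpow[n][a, b]
        weights.append(w)
        total += w
        if total >= target * (1.0 - 1e-12) or n >= max_jumps:
            break
        n += 1
        Rpow.append(Rpow[-1] @ R)
        log_poisson += math.log(mu * t) - math.log(n)
    weights = np.array(weights)
    wsum = weights.sum()
    if wsum <= 0:
        raise RuntimeError("uniformization failed: zero endpoint probability")
    n_jumps = int(rng.choice(len(weights), p=weights / wsum))
    while len(Rpow) <= n_jumps:
        Rpow.append(Rpow[-1] @ R)
    times = np.sort(rng.random(n_jumps)) * t
    states = []
    s = a
    for j in range(n_jumps):
        m = n_jumps - j - 1
        probs = R[s] * Rpow[m][:, b]
        tot = probs.sum()
        if tot <= 0:
            raise RuntimeError("uniformization bridge has zero mass")
        s = int(rng.choice(k, p=probs / tot))
        states.append(s)
    events = []
    prev = a
    for tau, s in zip(times, states):
        if s != prev:  # drop virtual (self) jumps
            events.append((float(tau), int(s)))
            prev = s
    return events


def sample_character_histories(
    tree: PhyloTree,
    tips: dict,
    rm: RateMatrix,
    root_prior: Optional[np.ndarray] = None,
    n_maps: int = 1,
    seed: int = 0,
) -> list:
    """Draw stochastic character maps from the posterior of histories.

    Node states are sampled jointly (root from its marginal, each child from
    transition × child partial likelihood); each branch is then filled with an
    endpoint-conditioned CTMC path.
    """
    prior = _root_prior(rm, root_prior)
    L, _, P = _pruning(tree, tips, rm)
    root_w = prior * L[tree.root]
    if root_w.sum() <= 0:
        raise ValueError("tip data impossible under this rate matrix")
    root_p = root_w / root_w.sum()
    rng = np.random.default_rng(seed)
    idx_to_state = dict(enumerate(rm.states))
    Q = rm.Q
    maps = []
    pre = tree.preorder()
    for _ in range(n_maps):
        node_state = {tree.root: int(rng.choice(rm.k, p=root_p))}
        events: dict[int, list] = {}
        for v in pre:
            if v == tree.root:
                continue
            j = node_state[tree.parent[v]]
            w = P[v][j] * L[v]
            node_state[v] = i = int(rng.choice(rm.k, p=w / w.sum()))
            t = float(tree.length[v])
            path = _path_rejection(rng, Q, j, i, t)
            if path is None:
                path = _path_uniformization(rng, Q, j, i, t, float(P[v][j, i]))
            events[v] = path
        maps.append(
            CharacterHistory(
                node_state={v: idx_to_state[s] for v, s in node_state.items()},
                events={v: [(tau, idx_to_state[s]) for tau, s in ev] for v, ev in events.items()},
            )
        )
    return maps


# -------------------------------------------------------------- aggregation
@dataclass
class NodePosteriorTable:
    """Clade-keyed posterior state probabilities pooled over (tree, map) draws.

    ``pp[clade][state]`` is the pooled frequency; ``draws[clade]`` the number
    of contributing (tree, map) draws; ``coverage[clade]`` the fraction of
    trees containing the clade.
    """

    pp: dict
    draws: dict
    coverage: dict
    n_trees: int
    n_maps_per_tree: int
    states: tuple

    def to_frame(self):
        import pandas as pd

        rows = []
        for clade in sorted(self.pp, key=lambda c: (len(c), sorted(c))):
            row = {"clade": "|".join(sorted(clade)),
                   "n_draws": self.draws[clade],
                   "tree_coverage": self.coverage[clade]}
            for s in self.states:
                row[f"pp_{s}"] = self.pp[clade].get(s, 0.0)
            rows.append(row)
        return pd.DataFrame(rows)


def summarize_node_pp(
    trees: TreeSample,
    tips: dict,
    model: str = "ER",
    root_prior: Optional[np.ndarray] = None,
    n_maps_per_tree: int = 1,
    seed: int = 0,
    states: Optional[tuple] = None,
) -> NodePosteriorTable:
    """Empirical stochastic mapping over a tree sample.

    Per tree: the rate matrix is re-estimated by maximum likelihood, then
    ``n_maps_per_tree`` histories are sampled; internal-node states are pooled
    by clade key (descendant tip set) across all (tree, map) draws.
    """
    if len(trees) == 0:
        raise ValueError("empty tree sample")
    counts: dict = {}
    clade_trees: dict = {}
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(trees))
    rm0 = None
    for tree, cs in zip(trees, child_seeds):
        rm, _ = fit_mk(tree, tips, model=model, root_prior=root_prior, states=states)
        rm0 = rm
        keys = clade_keys(tree)
        for clade in keys.values():
            clade_trees[clade] = clade_trees.get(clade, 0) + 1
        maps = sample_character_histories(
            tree, tips, rm, root_prior=root_prior, n_maps=n_maps_per_tree,
            seed=int(cs.generate_state(1)[0] % (2**31)),
        )
        for m in maps:
            for v, clade in keys.items():
                d = counts.setdefault(clade, {})
                s = m.node_state[v]
                d[s] = d.get(s, 0) + 1
    pp = {c: {s: n / sum(d.values()) for s, n in d.items()} for c, d in counts.items()}
    draws = {c: sum(d.values()) for c, d in counts.items()}
    coverage = {c: clade_trees[c] / len(trees) for c in counts}
    return NodePosteriorTable(
        pp=pp, draws=draws, coverage=coverage,
        n_trees=len(trees), n_maps_per_tree=n_maps_per_tree,
        states=rm0.states,
    )
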