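"""Seeded generators with exactly the statistical structure the two inference
stages assume.

* ``simulate_yule_tree`` — pure-birth tree, rescaled to unit height; a
  stand-in for a dated posterior tree whose only job is to supply a Brownian
  correlation structure.
* ``simulate_varying_effects`` — species intercepts/slopes as the sum of a
  grand mean, a phylogenetically correlated deviation (zero-mean MVN with
  covariance sd² × Brownian correlation), and an independent species
  deviation.
* ``simulate_measurements`` — per-individual log body mass and log index
  values normally scattered around the species line.
* ``simulate_mk_character`` — a binary (or k-state) character evolved along
  the tree under a continuous-time Markov process with generator Q, keeping
  the full event history as ground truth.

Every generator is a pure function of (parameters, seed); the seed is stored
in the returned :class:`SyntheticTruth` so a dataset can be regenerated
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fixtures import BODY_MASS_G
from .treeio import PhyloTree, phylo_correlation, to_unit_height

__all__ = [
    "SyntheticTruth",
    "simulate_yule_tree",
    "simulate_varying_effects",
    "simulate_measurements",
    "simulate_mk_character",
    "default_species_log_bm",
]


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic dataset (generating-side parameters)."""

    seed: int
    grand_intercept: float = 0.0
    grand_slope: float = 0.0
    sigma: float = 0.0
    sigma_a_phy: float = 0.0
    sigma_a_sp: float = 0.0
    sigma_b_phy: float = 0.0
    sigma_b_sp: float = 0.0
    a_phy: Optional[np.ndarray] = None
    a_sp: Optional[np.ndarray] = None
    b_phy: Optional[np.ndarray] = None
    b_sp: Optional[np.ndarray] = None
    species: Optional[list] = None
    Q: Optional[np.ndarray] = None
    node_states: Optional[dict] = None
    history: Optional[dict] = None

    @property
    def intercepts(self) -> np.ndarray:
        return self.grand_intercept + self.a_phy + self.a_sp

    @property
    def slopes(self) -> np.ndarray:
        return self.grand_slope + self.b_phy + self.b_sp

    def to_dict(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, np.ndarray):
                out[k] = v.tolist()
            elif isinstance(v, dict):
                out[k] = {str(kk): vv for kk, vv in v.items()}
            else:
                out[k] = v
        return out


# ----------------------------------------------------------------- yule tree
def simulate_yule_tree(n_taxa: int, seed: int) -> PhyloTree:
    """Pure-birth (Yule) tree on ``n_taxa`` tips, scaled to unit height.

    Speciation events happen at exponential waiting times (rate = number of
    extant lineages); each event splits a uniformly chosen extant lineage.
    Tips are labelled ``t1..tn`` in creation order.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)

    parent = [-1, 0, 0]
    start = [0.0, 0.0, 0.0]  # birth time of each node's branch
    active = [1, 2]  # currently extant lineages
    t = 0.0
    end = {}
    while len(active) < n_taxa:
        k = len(active)
        t += float(rng.exponential(1.0 / k))
        i = active[int(rng.integers(k))]
        end[i] = t
        c1, c2 = len(parent), len(parent) + 1
        parent.extend([i, i])
        start.extend([t, t])
        active.remove(i)
        active.extend([c1, c2])
    # final epoch: extend all extant lineages to a common present
    t += float(rng.exponential(1.0 / len(active)))
    for i in active:
        end[i] = t

    n = len(parent)
    length = np.zeros(n)
    children: list = [[] for _ in range(n)]
    for i in range(1, n):
        length[i] = end[i] - start[i]
        children[parent[i]].append(i)
    label: list = [None] * n
    for k, i in enumerate(sorted(active)):
        label[i] = f"t{k + 1}"
    tree = PhyloTree(
        parent=np.array(parent, dtype=int),
        length=length,
        label=label,
        children=children,
        root=0,
    )
    tree.validate()
    return to_unit_height(tree)


# ------------------------------------------------------------ varying effects
def simulate_varying_effects(
    tree: PhyloTree,
    grand_intercept: float,
    grand_slope: float,
    sigma_a_phy: float,
    sigma_a_sp: float,
    sigma_b_phy: float,
    sigma_b_sp: float,
    seed: int,
) -> SyntheticTruth:
    """Draw per-species intercepts and slopes with a Brownian phylogenetic
    component plus an independent species component."""
    for name, s in (
        ("sigma_a_phy", sigma_a_phy), ("sigma_a_sp", sigma_a_sp),
        ("sigma_b_phy", sigma_b_phy), ("sigma_b_sp", sigma_b_sp),
    ):
        if s < 0:
            raise ValueError(f"{name} must be >= 0")
    species = tree.tip_labels
    R = phylo_correlation(tree, species)
    S = len(species)
    rng = np.random.default_rng(seed)
    # Cholesky with a tiny ridge so star trees / duplicated tips stay valid
    L = np.linalg.cholesky(R + 1e-12 * np.eye(S))
    truth = SyntheticTruth(
        seed=seed,
        grand_intercept=grand_intercept,
        grand_slope=grand_slope,
        sigma_a_phy=sigma_a_phy,
        sigma_a_sp=sigma_a_sp,
        sigma_b_phy=sigma_b_phy,
        sigma_b_sp=sigma_b_sp,
        a_phy=sigma_a_phy * (L @ rng.standard_normal(S)),
        a_sp=sigma_a_sp * rng.standard_normal(S),
        b_phy=sigma_b_phy * (L @ rng.standard_normal(S)),
        b_sp=sigma_b_sp * rng.standard_normal(S),
        species=species,
    )
    return truth


def default_species_log_bm(species: Sequence[str]) -> np.ndarray:
    """Centered log body masses for the generator's species.

    Species named like the built-in mole-rat taxa use their recorded mean
    masses; other species are spread evenly over the same log-mass range
    (34–867 g), emulating the family's size span.
    """
    known = [s for s in species if s in BODY_MASS_G]
    if len(known) == len(species):
        logs = np.log([BODY_MASS_G[s] for s in species])
    else:
        lo, hi = np.log(min(BODY_MASS_G.values())), np.log(max(BODY_MASS_G.values()))
        logs = np.linspace(lo, hi, len(species))
    return logs - logs.mean()


def simulate_measurements(
    truth: SyntheticTruth,
    n_per_species=30,
    bm_log_mean: Optional[np.ndarray] = None,
    bm_log_sd: float = 0.15,
    sigma: float = 0.1,
    seed: int = 0,
    index: str = "IFA",
    bm_offset: Optional[float] = None,
    absent_species: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-individual index records around the species lines.

    For individual *j* of species *s*: x ~ Normal(bm_log_mean[s], bm_log_sd),
    y = intercept_s + slope_s·x + Normal(0, sigma).  Records carry
    index = exp(y) and body mass = exp(x + bm_offset) grams; ``bm_offset``
    defaults to the mean log of the built-in species masses.  Species listed
    in ``absent_species`` get NaN index values (structure absent), emulating
    a taxon that lacks the superstructure.  ``n_per_species`` may be a single
    count or a mapping species → count.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    species = truth.species
    S = len(species)
    if isinstance(n_per_species, dict):
        counts = [int(n_per_species[sp]) for sp in species]
    else:
        counts = [int(n_per_species)] * S
    if min(counts) < 1:
        raise ValueError("n_per_species must be >= 1")
    if bm_log_mean is None:
        bm_log_mean = default_species_log_bm(species)
    if bm_offset is None:
        bm_offset = float(np.mean(np.log(list(BODY_MASS_G.values()))))
    rng = np.random.default_rng(seed)
    truth.sigma = sigma
    alphas, betas = truth.intercepts, truth.slopes
    rows = []
    for s in range(S):
        for j in range(counts[s]):
            x = float(rng.normal(bm_log_mean[s], bm_log_sd))
            y = float(alphas[s] + betas[s] * x + rng.normal(0.0, sigma))
            absent = species[s] in absent_species
            rows.append(
                {
                    "specimen_id": f"{species[s]}_{j + 1}",
                    "species": species[s],
                    "index": index,
                    "value": np.nan if absent else float(np.exp(y)),
                    "body_mass_g": float(np.exp(x + bm_offset)),
                }
            )
    return pd.DataFrame(rows)


# -------------------------------------------------------------- Mk character
def _check_generator(Q: np.ndarray) -> np.ndarray:
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("Q must be square")
    off = Q - np.diag(np.diag(Q))
    if (off < 0).any():
        raise ValueError("off-diagonal rates must be >= 0")
    if np.abs(Q.sum(axis=1)).max() > 1e-10:
        raise ValueError("rows of Q must sum to 0")
    return Q


def simulate_mk_character(
    tree: PhyloTree,
    Q: np.ndarray,
    seed: int,
    root_state: Optional[int] = None,
    root_prior: Optional[np.ndarray] = None,
) -> tuple[dict, SyntheticTruth]:
    """Evolve a discrete character root→tips under the Mk process.

    Returns ``(tip_states, truth)`` where ``tip_states`` maps taxon → state
    and ``truth`` records the root/internal node states and the full per-branch
    event history (list of ``(time_from_branch_start, new_state)``).
    """
    Q = _check_generator(Q)
    k = Q.shape[0]
    rng = np.random.default_rng(seed)
    if root_state is None:
        p = np.full(k, 1.0 / k) if root_prior is None else np.asarray(root_prior, float)
        root_state = int(rng.choice(k, p=p / p.sum()))
    node_state = {tree.root: int(root_state)}
    history: dict[int, list] = {}
    for v in tree.preorder():
        if v == tree.root:
            continue
        s = node_state[tree.parent[v]]
        t, tmax = 0.0, float(tree.length[v])
        events = []
        while True:
            rate = -Q[s, s]
            if rate <= 0:
                break
            t += float(rng.exponential(1.0 / rate))
            if t >= tmax:
                break
            probs = Q[s].clip(min=0.0)
            probs[s] = 0.0
            s = int(rng.choice(k, p=probs / probs.sum()))
            events.append((t, s))
        node_state[v] = s
        history[v] = events
    tips = {tree.label[i]: node_state[i] for i in tree.tip_ids}
    truth = SyntheticTruth(seed=seed, Q=Q, node_states=dict(node_state), history=history)
    return tips, truth
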