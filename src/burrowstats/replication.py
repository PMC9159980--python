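"""Stand-in replication runs of the study's two headline analyses.

The original inputs — the downloaded posterior tree sample and the
per-specimen measurement table — are not redistributable, so these helpers
run the full pipelines on the package's synthetic stand-ins: the calibrated
chronogram sample (:func:`burrowstats.fixtures.synthetic_tree_sample`) with
the real tip-state codings, and a synthetic olecranon-index (IFA) cohort of
247 individuals at the published per-species sample sizes generated under the
weak-allometry study conditions (:data:`burrowstats.fixtures.IFA_GENERATOR`).
"""

from __future__ import annotations

import numpy as np

from . import mk_simmap as mk
from . import morphodata as md
from . import phyloreg as pr
from . import treeio
from .fixtures import (
    IFA_GENERATOR,
    SAMPLE_SIZES,
    SUPERSTRUCTURE_STATES,
    ifa_sample_sizes,
    synthetic_consensus_tree,
    synthetic_tree_sample,
)
from .synthetic_data import simulate_measurements, simulate_varying_effects

__all__ = ["map_superstructures", "ifa_waic_comparison", "FOCAL_CLADES"]

#: named internal nodes whose posterior state probabilities the study reports
FOCAL_CLADES = {
    "root": frozenset(["Hg", "Ha", "Bs", "Bj", "Gc", "Ch", "Fm", "Fd", "Hya", "Pt", "Ts"]),
    "bathyergid_crown": frozenset(["Hg", "Ha", "Bs", "Bj", "Gc", "Ch", "Fm", "Fd"]),
    "petromuridae_thryonomyidae": frozenset(["Pt", "Ts"]),
    "heliophobius_plus_derived": frozenset(["Ha", "Bs", "Bj", "Gc", "Ch", "Fm", "Fd"]),
}


def map_superstructures(n_trees: int = 1000, n_maps_per_tree: int = 1,
                        seed: int = 0, characters=("DT", "TT", "DFTFi")) -> dict:
    """Stochastic mapping of the bone superstructures over the stand-in
    chronogram sample; returns character → NodePosteriorTable."""
    ss = np.random.SeedSequence(seed).spawn(2)
    sample = synthetic_tree_sample(
        n_trees, seed=int(ss[0].generate_state(1)[0] % 2**31))
    unit = treeio.TreeSample(
        [treeio.to_unit_height(t) for t in sample.trees], sample.taxa)
    char_seeds = ss[1].spawn(len(characters))
    return {
        char: mk.summarize_node_pp(
            unit, SUPERSTRUCTURE_STATES[char],
            n_maps_per_tree=n_maps_per_tree,
            seed=int(cs.generate_state(1)[0] % 2**31))
        for char, cs in zip(characters, char_seeds)
    }


def ifa_waic_comparison(seed: int = 0, chains: int = 4, iterations: int = 1500):
    """Fit the with/without body-mass models to a synthetic IFA cohort at the
    published sample sizes (247 individuals, 8 species) and compare by WAIC.

    Returns the :class:`burrowstats.phyloreg.ComparisonResult`.
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    s = [int(x.generate_state(1)[0] % 2**31) for x in ss]
    tree = synthetic_consensus_tree()
    sub = treeio.extract_subtree(tree, sorted(SAMPLE_SIZES))
    g = IFA_GENERATOR
    truth = simulate_varying_effects(
        sub, g["grand_intercept"], g["grand_slope"],
        g["sigma_a_phy"], g["sigma_a_sp"], g["sigma_b_phy"], g["sigma_b_sp"],
        seed=s[0])
    rec = simulate_measurements(
        truth, n_per_species=ifa_sample_sizes(247), sigma=g["sigma"], seed=s[1])
    ds = md.build_dataset(rec, "IFA", sub)
    R = treeio.phylo_correlation(treeio.to_unit_height(sub), ds.species)
    full = pr.fit_varying_effects(
        ds, pr.ModelSpec(R=R, include_bm=True, chains=chains,
                         iterations=iterations, warmup_frac=0.5, seed=s[2]))
    red = pr.fit_varying_effects(
        ds, pr.ModelSpec(R=R, include_bm=False, chains=chains,
                         iterations=iterations, warmup_frac=0.5, seed=s[3]))
    return pr.compare_models(pr.compute_waic(full), pr.compute_waic(red))
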