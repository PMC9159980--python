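"""Built-in study data: taxon set, tip-state codings, body masses, and a
synthetic calibrated chronogram.

The eleven taxa are the eight African mole-rat species (Bathyergidae) plus
three phiomorph outgroups (Hystricidae, Petromuridae, Thryonomyidae), coded by
the usual two/three-letter abbreviations.

``synthetic_consensus_tree`` is a *synthetic* stand-in for a time-calibrated
consensus phylogeny of these taxa: the topology follows the well-established
generic relationships of Bathyergidae and its outgroups, two node ages are the
published molecular dates (Heterocephalus split 29.02 Ma, Heliophobius split
13.37 Ma), and the remaining ages are round literature-scale values.  It is
not a downloaded posterior sample; ``synthetic_tree_sample`` adds seeded
lognormal jitter to the node ages to emulate dating uncertainty across a
posterior sample of trees.
"""

from __future__ import annotations

import numpy as np

from .treeio import PhyloTree, TreeSample, parse_newick, to_unit_height

__all__ = [
    "TAXA",
    "FULL_NAMES",
    "BODY_MASS_G",
    "SAMPLE_SIZES",
    "SUPERSTRUCTURE_STATES",
    "IFA_GENERATOR",
    "ifa_sample_sizes",
    "synthetic_consensus_tree",
    "synthetic_tree_sample",
]

TAXA = ("Bs", "Bj", "Ch", "Fd", "Fm", "Gc", "Ha", "Hg", "Hya", "Pt", "Ts")

FULL_NAMES = {
    "Bs": "Bathyergus suillus",
    "Bj": "Bathyergus janetta",
    "Ch": "Cryptomys hottentotus",
    "Fd": "Fukomys damarensis",
    "Fm": "Fukomys mechowii",
    "Gc": "Georychus capensis",
    "Ha": "Heliophobius argenteocinereus",
    "Hg": "Heterocephalus glaber",
    "Hya": "Hystrix africaeaustralis",
    "Pt": "Petromus typicus",
    "Ts": "Thryonomys swinderianus",
}

#: mean adult body mass in grams (sexes pooled) for the eight mole-rat species
BODY_MASS_G = {
    "Bs": 866.85,
    "Bj": 384.5,
    "Ha": 176.0,
    "Gc": 180.5,
    "Ch": 56.3,
    "Fm": 480.8,
    "Fd": 140.0,
    "Hg": 33.9,
}

#: specimens per species in the morphometric sample
SAMPLE_SIZES = {
    "Bs": 78,
    "Bj": 6,
    "Ha": 38,
    "Gc": 51,
    "Ch": 53,
    "Fm": 32,
    "Fd": 48,
    "Hg": 76,
}

#: binary codings (1 = present, 0 = absent) of the three variable bone
#: superstructures across the eleven taxa.  The olecranon process is present
#: in every taxon and therefore carries no phylogenetic signal to map.
SUPERSTRUCTURE_STATES = {
    # projected deltoid tuberosity: absent only in the naked mole-rat
    "DT": {t: (0 if t == "Hg" else 1) for t in TAXA},
    # third trochanter: present in the eight bathyergids, absent in outgroups
    "TT": {t: (0 if t in ("Hya", "Pt", "Ts") else 1) for t in TAXA},
    # distal tibio-fibular fusion: present in seven bathyergids, absent in
    # the naked mole-rat and all three outgroups
    "DFTFi": {t: (0 if t in ("Hg", "Hya", "Pt", "Ts") else 1) for t in TAXA},
}

#: A-priori generating parameters for synthetic olecranon-index (IFA) data in
#: the weak-allometry regime the family exhibits: grand intercept log 30
#: (IFA around 30%), a weak grand slope of 0.1 on log body mass, 10%
#: within-species scatter, between-species variability dominated by
#: species-specific rather than phylogenetic effects.  Chosen once as the
#: package's study conditions; see docs/methods.md.
IFA_GENERATOR = {
    "grand_intercept": float(np.log(30.0)),
    "grand_slope": 0.1,
    "sigma": 0.1,
    "sigma_a_phy": 0.05,
    "sigma_a_sp": 0.15,
    "sigma_b_phy": 0.02,
    "sigma_b_sp": 0.05,
}


def ifa_sample_sizes(total: int = 247) -> dict:
    """Per-species counts for a synthetic IFA cohort of ``total`` individuals,
    allocated proportionally to the published per-species sample sizes
    (largest-remainder rounding)."""
    species = sorted(SAMPLE_SIZES)
    weights = np.array([SAMPLE_SIZES[s] for s in species], dtype=float)
    raw = weights / weights.sum() * total
    base = np.floor(raw).astype(int)
    rem = total - int(base.sum())
    order = np.argsort(-(raw - base))
    for i in order[:rem]:
        base[i] += 1
    return dict(zip(species, (int(b) for b in base)))


# Node ages in Ma for the synthetic chronogram.  29.02 and 13.37 are published
# molecular dates; the rest are round values on the literature scale.
_AGES = {
    "root": 45.0,        # Hystricidae vs (Petromuridae+Thryonomyidae, Bathyergidae)
    "phiomorph": 39.0,   # (Pt,Ts) vs Bathyergidae
    "pt_ts": 32.0,       # Petromus vs Thryonomys
    "bathyergidae": 29.02,  # Heterocephalus vs remaining bathyergids
    "heliophobius": 13.37,  # Heliophobius vs derived bathyergids
    "derived": 12.0,     # (Georychus, Bathyergus) vs (Cryptomys, Fukomys)
    "gc_bath": 10.0,     # Georychus vs Bathyergus
    "bs_bj": 5.0,
    "cf": 11.0,          # Cryptomys vs Fukomys
    "fm_fd": 6.0,
}


def _newick_from_ages(ages: dict) -> str:
    a = ages
    return (
        "((((((Gc:{gc_bath},(Bs:{bs_bj},Bj:{bs_bj}):{bsbj_up}):{gc_up},"
        "(Ch:{cf},(Fm:{fm_fd},Fd:{fm_fd}):{fmfd_up}):{cf_up}):{der_up},"
        "Ha:{heliophobius}):{hel_up},Hg:{bathyergidae}):{bath_up},"
        "(Pt:{pt_ts},Ts:{pt_ts}):{ptts_up}):{phio_up},Hya:{root});"
    ).format(
        gc_bath=a["gc_bath"],
        bs_bj=a["bs_bj"],
        bsbj_up=a["gc_bath"] - a["bs_bj"],
        gc_up=a["derived"] - a["gc_bath"],
        cf=a["cf"],
        fm_fd=a["fm_fd"],
        fmfd_up=a["cf"] - a["fm_fd"],
        cf_up=a["derived"] - a["cf"],
        der_up=a["heliophobius"] - a["derived"],
        heliophobius=a["heliophobius"],
        hel_up=a["bathyergidae"] - a["heliophobius"],
        bathyergidae=a["bathyergidae"],
        bath_up=a["phiomorph"] - a["bathyergidae"],
        pt_ts=a["pt_ts"],
        ptts_up=a["phiomorph"] - a["pt_ts"],
        phio_up=a["root"] - a["phiomorph"],
        root=a["root"],
    )


def synthetic_consensus_tree(unit_height: bool = False) -> PhyloTree:
    """The synthetic calibrated 11-taxon chronogram (branch lengths in Ma)."""
    tree = parse_newick(_newick_from_ages(_AGES))
    return to_unit_height(tree) if unit_height else tree


def synthetic_tree_sample(n_trees: int = 1000, seed: int = 0, jitter_sd: float = 0.08) -> TreeSample:
    """Seeded synthetic stand-in for a posterior sample of dated trees.

    Each tree keeps the consensus topology; every node age is multiplied by an
    independent lognormal factor with log-sd ``jitter_sd``, then ages are
    nudged to respect parent-older-than-child ordering.
    """
    rng = np.random.default_rng(seed)
    order = [
        "root", "phiomorph", "pt_ts", "bathyergidae", "heliophobius",
        "derived", "gc_bath", "bs_bj", "cf", "fm_fd",
    ]
    parents = {
        "phiomorph": "root", "pt_ts": "phiomorph", "bathyergidae": "phiomorph",
        "heliophobius": "bathyergidae", "derived": "heliophobius",
        "gc_bath": "derived", "bs_bj": "gc_bath", "cf": "derived", "fm_fd": "cf",
    }
    trees = []
    for _ in range(n_trees):
        ages = {k: v * float(np.exp(rng.normal(0.0, jitter_sd))) for k, v in _AGES.items()}
        for name in order[1:]:  # enforce ultrametric-consistent nesting
            pa = ages[parents[name]]
            if ages[name] >= pa:
                ages[name] = 0.99 * pa
        trees.append(parse_newick(_newick_from_ages(ages)))
    return TreeSample(trees=trees, taxa=frozenset(TAXA))
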