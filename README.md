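# burrowstats

Phylogenetic comparative analysis of limb-bone fossorial adaptations in
African mole-rats (Bathyergidae) and their phiomorph outgroups.

Subterranean rodents dig with claws or incisors, and their limb bones carry
superstructures — the deltoid tuberosity (DT) on the humerus, the olecranon
process on the ulna, the third trochanter on the femur, and the distal
tibio-fibular fusion (DFTFi) — whose development reflects that behaviour.
`burrowstats` is for comparative morphologists who want to ask two questions
about such data:

1. **Do morpho-functional indices scale with body mass once species and
   phylogeny are accounted for?** Per-individual percent indices (RDT, IFA,
   TJI) are log-transformed and modelled with a Bayesian varying-intercept /
   varying-slope regression in which each species effect splits into a
   phylogenetically correlated part (multivariate normal with the Brownian
   correlation matrix of the tree) and an independent species part:

   ```
   y_i  ~ Normal(mu_i, sigma)
   mu_i = (ᾱ + a_phy[s(i)] + a_sp[s(i)]) + (β̄ + b_phy[s(i)] + b_sp[s(i)]) x_i
   ```

   Models with and without body mass are compared by WAIC
   (ΔWAIC with its pointwise standard error), and between-species
   variability is attributed to phylogeny vs species-specific effects.

2. **When did the discrete superstructures appear?** Binary presence/absence
   codings evolve under a continuous-time Markov (Mk) model; stochastic
   character maps are sampled over a posterior sample of trees (rate matrix
   re-estimated by maximum likelihood per tree), and node posterior
   probabilities are pooled across trees by clade.

The package includes seeded synthetic-data generators with exactly the
statistical structure both stages assume, the published tip-state codings
and body masses for the eleven-taxon mole-rat study system, and a synthetic
calibrated chronogram stand-in for the non-redistributable posterior tree
sample. See `docs/methods.md` for the full model description.

## Worked example

Simulate a dataset, then run the regression pipeline from the CLI:

```sh
cat > sim.yaml <<EOF
out_dir: sim
seed: 3
n_taxa: 6
n_per_species: 25
grand_slope: 0.3
index: IFA
EOF
burrowstats simulate --config sim.yaml

cat > run.yaml <<EOF
measurements: sim/index_records.csv
consensus_tree: sim/tree.nwk
index: IFA
out_dir: out
seed: 4
chains: 4
iterations: 2000
EOF
burrowstats regression --config run.yaml
```

which prints

```
IFA: dWAIC=30.662 dSE=11.604 preferred=with_bm
tables written to out
```

A ΔWAIC of ~31 (SE ~12) says the generating slope of 0.3 makes body mass
clearly useful for out-of-sample prediction of the olecranon index — the
with-body-mass model is preferred by far more than the comparison's standard
error. `out/` then contains the posterior summary for each model (means,
89% compatibility intervals, split-chain R-hat and effective sample sizes),
the WAIC comparison table, and the phylogenetic-vs-species variance shares.

The mapping stage runs the same way from tip states and a multi-tree file:

```sh
burrowstats asr --config asr.yaml   # tip_states + tree_sample + seed
```

writing one clade-keyed node-posterior-probability table per variable
character and skipping constant characters (like the olecranon process,
present in every taxon) with a notice.

In Python the same objects are a few calls:

```python
from burrowstats import fixtures, mk_simmap, treeio

sample = fixtures.synthetic_tree_sample(1000, seed=0)
unit = treeio.TreeSample([treeio.to_unit_height(t) for t in sample], sample.taxa)
table = mk_simmap.summarize_node_pp(
    unit, fixtures.SUPERSTRUCTURE_STATES["DFTFi"], n_maps_per_tree=1, seed=1)
clade = frozenset(["Ha", "Bs", "Bj", "Gc", "Ch", "Fm", "Fd"])
print(round(100 * table.pp[clade][1], 1))   # -> 99.5
```

— the tibio-fibular fusion is present with ~99% posterior probability in the
ancestor of *Heliophobius* plus the derived mole-rat genera, the clade where
the fusion is universal today.

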