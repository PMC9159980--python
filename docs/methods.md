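# Methods

`burrowstats` implements a phylogenetic comparative analysis of limb-bone
fossorial adaptations in African mole-rats (Bathyergidae) and their phiomorph
outgroups. It has two inference stages — a Bayesian varying-effects
regression of morpho-functional indices on body mass, and stochastic
character mapping of discrete bone superstructures — plus the index
construction and synthetic-data machinery needed to test both stages end to
end without external downloads.

## Morpho-functional indices

Three percent indices quantify how developed three digging-related
superstructures are. With lengths in mm:

* RDT (relative deltoid-tuberosity position) = `landmark / humerus length × 100`
* IFA (index of fossorial ability) = `olecranon / (ulna − olecranon) × 100`
* TJI (tibio-fibular junction index) = `junction / tibia length × 100`

All three are scale-invariant (unchanged when both measurements are
multiplied by a constant), which the suite verifies by property test. A
structure that is genuinely absent — the naked mole-rat *Heterocephalus
glaber* lacks a projected deltoid tuberosity and a distal tibio-fibular
fusion — is a distinct missing state, never a zero; rows with missing values
are dropped when the regression dataset is built, which removes such species
from the RDT and TJI models while keeping them for IFA. The IFA denominator
is the functional ulna length (total minus olecranon), the standard
construction for fossorial-ability comparisons; RDT and TJI are
proximal-end-referenced proportions of total bone length. These landmark
conventions are package decisions: they are the field-standard readings of
the three indices, and any monotone variant would change coefficients but
not the model-comparison logic.

## Regression model

For individual *i* of species *s(i)*, with `y = log index` and `x = log body
mass (g)` centered at the retained-rows mean:

```
y_i  ~ Normal(mu_i, sigma)
mu_i = (abar + a_phy[s(i)] + a_sp[s(i)]) + (bbar + b_phy[s(i)] + b_sp[s(i)]) x_i

a_phy ~ MVN(0, sigma_a_phy² R)     a_sp ~ Normal(0, sigma_a_sp)
b_phy ~ MVN(0, sigma_b_phy² R)     b_sp ~ Normal(0, sigma_b_sp)
```

`R` is the Brownian-motion correlation matrix of the unit-height consensus
tree (entry = shared root-to-MRCA path length / tree height). Splitting each
varying effect into a phylogenetically correlated and an independent species
part is what lets the model attribute between-species variability to
phylogeny versus species-specific effects. Natural logs are used throughout;
body mass is centered so the intercept is the expected log index at the
sample's geometric-mean mass.

Priors: `abar ~ Normal(mean(y), 1)`, `bbar ~ Normal(0, 1)`, and
`Exponential(1)` on all five scale parameters. These are weakly informative
on the scale of log-percent indices (sd 1 on the grand intercept spans a
factor of e either way) and keep all variances proper when a component is
unsupported by the data.

The "without body mass" model drops `bbar`, `b_phy` and `b_sp`; everything
else is identical, and the two models are compared by WAIC on the deviance
scale, `WAIC = −2(lppd − pWAIC)`, with the difference's standard error
computed from the pointwise contributions (`ΔSE = sqrt(n · var(Δ_i))`).

### Sampling

The model is conditionally Gaussian, so the sampler is a blocked Gibbs
scheme rather than HMC:

1. the full coefficient vector (grand terms plus all varying effects) is
   drawn exactly from its multivariate-normal full conditional (Cholesky of
   the posterior precision);
2. the residual sd is updated by stepping-out slice sampling on `log sigma`;
3. each variance-component sd gets a slice update in the centered
   parameterization followed by an interweaved update in the non-centered
   parameterization (with the standardized effects held fixed the scale
   enters the likelihood linearly, giving a truncated-normal draw). The
   interweaving (ASIS) step is the Gibbs analogue of a non-centered
   parameterization and keeps mixing fast when a component sits near zero.

Defaults mirror the study configuration: 4 chains × 5000 iterations with 50%
warm-up and a recorded seed; the test suite and acceptance script use
4 × 1000–3000 to keep runs short, a problem-size choice recorded here.
Convergence is monitored with rank-normalized split-chain R-hat and ESS
(arviz); parameters with R-hat > 1.05 are flagged in the run summary. The
sampler was validated end to end against an independent affine-invariant
ensemble sampler (emcee) running on the identical log-posterior density: all
posterior means and quantiles agree within Monte-Carlo error (see
`tests/test_phyloreg.py`).

Variance attribution is reported per draw as
`share = sigma_phy² / (sigma_phy² + sigma_sp²)` for intercepts and slopes.
With eight species this ratio is weakly identified: the posterior leans on
the prior, and in simulation even an exact posterior attributes more than
half the variance to phylogeny in a nontrivial fraction of replicates when
the generating process is purely species-specific. The package reports the
share with its 89% interval rather than a point claim.

## Discrete-character stage (Mk model and stochastic mapping)

Binary superstructure states evolve by a continuous-time Markov process with
generator `Q`. The likelihood is computed by the pruning algorithm
(post-order dynamic programming with per-branch `expm(Q t)`, closed form for
the symmetric binary case, with per-node rescaling against underflow). Exact
marginal node posteriors come from the standard two-pass (post-order +
pre-order) message passing and serve as the in-suite oracle for the sampler.

Stochastic maps are drawn by sampling node states from the joint posterior
(root from its marginal; each child proportional to transition probability ×
child partial likelihood) and filling every branch with an
endpoint-conditioned CTMC path: rejection sampling with the forced-first-
event modification when the endpoints differ, capped at 10,000 attempts,
with a uniformization bridge as fallback. The two path samplers are verified
against each other distributionally in the suite.

Per sampled tree, `Q` is re-estimated by maximum likelihood (the "empirical"
variant of the mapping method): a bounded 1-D search on [1e-8, 100] for the
equal-rates model on unit-height trees, a 2-D Nelder-Mead search on log
rates for binary all-rates-different. Constant characters sit at the
zero-rate boundary and are skipped by the pipeline with a notice (the
olecranon process, present in every taxon, is the motivating case). Defaults:
equal-rates model, uniform root prior, one map per tree so that a
1000-tree sample yields 1000 maps. Node posterior probabilities are pooled
across (tree, map) draws by clade key — the set of descendant tip labels —
so nodes are matched across topologically differing trees; the fraction of
trees containing each clade is reported alongside.

## Trees

Branch lengths are treated as time. Trees used for the regression covariance
and for rate estimation are normalized to unit height, so variance
parameters are in trait units and ML rates are per tree depth, portable
across chronograms; non-ultrametric trees (beyond 1e-6 relative tolerance)
are rejected rather than silently repaired. Newick/Nexus parsing and
serialization are delegated to dendropy; validation, unit-height scaling,
the Brownian correlation matrix, clade keys, and induced-subtree extraction
are package code on a light array-based structure.

## Synthetic data and built-in fixtures

The generators produce data with exactly the structure the two stages
assume: pure-birth (Yule) trees rescaled to unit height; species intercepts
and slopes as grand mean + Brownian MVN deviation + independent deviation;
individual log measurements normal around the species line; characters
evolved by exponential waiting times with the full event history kept as
ground truth. Every generator is a pure function of (parameters, seed).

Built-in study data: the eleven-taxon set (eight bathyergid species, three
outgroups), the published mean body masses and per-species sample sizes, and
the binary codings of the three variable superstructures (DT absent only in
*H. glaber*; TT absent in the three outgroups; DFTFi absent in the outgroups
and *H. glaber*).

Because the original downloaded tree sample is not redistributable, the
package ships a *synthetic* calibrated chronogram: literature topology, two
published node ages (Heterocephalus split 29.02 Ma, Heliophobius split 13.37
Ma), round literature-scale ages elsewhere, and seeded lognormal age jitter
(log-sd 0.08) to emulate dating uncertainty across a posterior sample. The
synthetic IFA cohort used by the replication runs fixes its generating
parameters a priori at the weak-allometry regime the study describes: grand
intercept log 30, grand slope 0.1, residual sd 0.1, species-specific sds
0.15/0.05 (intercept/slope) dominating phylogenetic sds 0.05/0.02, with 247
individuals allocated to species proportionally to the published sample
sizes.

What passing tests on these stand-ins do and do not show: they verify the
estimators (likelihoods against exhaustive enumeration, maps against exact
marginals, the Gibbs sampler against an independent sampler, parameter and
preference recovery against generator truth), and they reproduce the
branch-length-robust published quantities (the ~98% posterior probability of
the tibio-fibular fusion at the Heliophobius-plus-derived ancestor; a WAIC
difference of the published order for IFA). They do not certify the
deep-node posterior probabilities for DT and TT, which depend on the actual
posterior tree sample's branch lengths and are reported as computed on the
stand-in.

## Numerical choices and limitations

* Ultrametricity tolerance 1e-6 relative; correlation-matrix Cholesky uses a
  1e-10 ridge so polytomies and near-duplicate tips stay factorable.
* ER rate search bracket [1e-8, 100] with 1e-8 tolerance assumes unit-height
  trees; rates on unnormalized chronograms should be fitted after scaling.
* Inverse-CDF categorical sampling on a fixed state order makes all
  stochastic-map draws reproducible from the supplied seed; seeds are
  spawned per stage from one global seed in the pipelines.
* The regression assumes individual-level observations with a common
  residual sd across species, no measurement-error model on body mass, and
  one index per fit (no multivariate response).
* ARD fitting is implemented for binary characters only; correlated
  characters and continuous traits are out of scope.
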