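# Methods

## The model

`mkasr` reconstructs ancestral states of discrete morphological characters
(two or three states) on a rooted phylogeny whose topology and branch
lengths are themselves uncertain, represented by a posterior sample of
trees. A character evolves along each branch as a continuous-time Markov
chain (an Mk-type model) with instantaneous rates q_ij ≥ 0 between states;
for a binary character these are the forward rate q01 (state 0 → 1) and the
backward rate q10. Branch lengths b (expected substitutions per site from
the molecular analysis that produced the trees) are first transformed as
b → b^κ. κ = 1 leaves change proportional to molecular branch lengths,
κ = 0 makes every branch equally long so that change depends on topology
only (a punctuational reading), and intermediate values interpolate.

The likelihood of a character on a given tree is computed by the pruning
algorithm: per-state conditional likelihoods are propagated from the tips
to the root in post-order, with per-node rescaling accumulated in log space
so that 60-tip trees with short branches cannot underflow. Missing
observations ("?") enter as all-ones tip vectors (compatible with every
state). For binary characters the branch transition probabilities use the
closed form P00(t) = (q10 + q01 e^{−(q01+q10)t})/(q01+q10); for three
states the matrix exponential is used (an eigendecomposition fast path
validated against `scipy.linalg.expm`, with the exact scaled-and-squared
exponential as fallback).

## Priors and the sampler

For one binary character the rate-model space contains exactly four
models: both rates free; rates constrained equal; and the two one-way
models with q10 = 0 or q01 = 0. The sampler is a reversible-jump
Metropolis–Hastings chain over (model, rates, κ, m, tree index) with:

* rates ~ Exponential(mean m), hierarchically with m ~ Uniform(0, 10) —
  moderate rates are a priori more likely than high ones, and the
  hyperprior lets the data set the scale;
* κ ~ Uniform(0, 5);
* a uniform prior over the four models;
* a uniform prior over the trees in the posterior sample, so inference
  integrates over topological and branch-length uncertainty.

Moves: (i) within-model rate perturbation by a Normal kernel reflected at
zero; (ii) κ perturbation reflected into (0, 5); (iii) m perturbation
reflected into (0, 10), accepted on the rate-prior ratio; (iv) a model jump
that picks one of the other models uniformly and redraws its full free-rate
vector from the current Exponential(m) prior — with prior-draw proposals
the prior and proposal densities cancel and the acceptance ratio is the
likelihood ratio alone (this independence scheme is validated against a
Gauss–Legendre quadrature oracle for the model posterior on small
instances); (v) a uniform redraw of the tree index accepted on the
likelihood ratio. Three-state characters use a single all-rates-free
six-parameter model with no trans-model jumps; rate-class partitioning of
multistate generators is out of scope.

During burn-in the rate-proposal deviation is multiplicatively tuned
(×0.8 below 20% acceptance, ×1.25 above 40%, clamped to [1e-6, 1e3]) every
`tuning_interval` generations toward the 20–40% acceptance band, and
frozen after burn-in so the post-burn-in kernel satisfies detailed
balance. κ and m proposal deviations default to 1.0 and 2.0, chosen as a
fifth of their support widths so a handful of steps crosses the prior
range. Initial states are drawn from the prior, redrawing (bounded) if the
likelihood underflows to zero.

Chains are initialized from the prior, run for a configured number of
generations (desk-scale default 2×10⁶; the full-scale protocol of 220×10⁶
generations with 20×10⁶ burn-in ships as the `FULL_SCALE_PROFILE` constant),
thinned every 1000 generations by default, and repeated three times with
seeds spawned deterministically from the run seed; replicate agreement is
checked by requiring each run's posterior mean (κ by default) to lie
within two Monte-Carlo standard errors (from the effective sample size) of
the grand mean.

## Reported quantities

* **q01/q10** — the ratio of the posterior-average forward rate to the
  posterior-average backward rate, averaging over the full model-averaged
  posterior (samples from models that fix a rate at zero contribute zeros:
  they are legitimate posterior mass). A ratio of averages, not an average
  of ratios.
* **κ mean and 95% HPD** — the HPD is the shortest order-statistic window
  containing 95% of the pooled post-burn-in samples. Replicate chains are
  pooled after the per-run agreement check.
* **Node state probabilities** — nodes are addressed as MRCAs of named
  taxon sets so "the same node" exists in every sampled topology. For each
  saved sample the MRCA is resolved on that sample's tree and the marginal
  reconstruction (below-node conditional likelihoods combined with an
  outside pass over the rest of the tree) is computed under that sample's
  model, rates and κ; vectors are averaged with equal weight. For binary
  characters the probability of state 0 is reported (state 1 is its
  complement); three-state runs report the full simplex.
* **Model posterior** — the four models' sample frequencies.
* **ESS** — n/(1 + 2Στ) with Geyer initial-positive-sequence truncation.

The root state prior defaults to uniform over the state space; the
stationary distribution of the current rate matrix is available as an
alternative (`root_prior="stationary"`). The choice is recorded in every
summary and trace header. The with-outgroup and without-outgroup analysis
modes differ only in whether the outgroup taxa are pruned (degree-2 nodes
collapsed with branch lengths summed) before inference; κ applies to
whatever tree the engine receives, pruning being a data-preparation step.

## Character coding

State codes follow the field conventions for the system that motivated the
package: growth form lianescent 0 / arborescent 1 (herbaceous 2 only
relevant when the outgroup is retained, making the character three-state
in with-outgroup runs and binary otherwise — the state space is per-run
configuration, not auto-detected); inflorescence headed 0 / non-headed 1;
flower size large 0 / small 1 via the corolla ratio rule (tube/lobe > 1 →
large, < 1 → small; exactly 1 is undefined by the rule and coded missing
with a warning); fruit simple 0 / fused 1.

## The synthetic-data generator

Real inputs to this kind of analysis are a Bayesian posterior tree sample
and a morphological matrix; neither is bundled, so the generator emulates
their statistical structure:

* **Trees**: one focal Yule (pure-birth, rate 1.0) topology of ~60 tips;
  each sample member multiplies every branch by independent lognormal
  jitter (sd 0.1, mild posterior branch-length uncertainty), optionally
  with random NNI rearrangements for topological variation. This mimics
  what integration-over-trees machinery must handle; it does not reproduce
  the correlated branch-length and clade-support structure of a real
  MCMC sample, so passing tests demonstrate correct integration mechanics,
  not calibration against any real posterior.
* **Characters**: simulated forward along the κ-transformed focal tree
  from a root state drawn from a configurable distribution — the exact
  generative twin of the inference model. Real morphological characters
  can violate the model (rate heterogeneity across lineages, correlated
  characters); recovery results say nothing about such violations.
* **Rate magnitudes**: recovery fixtures use q01 = 1.0, q10 = 0.2
  (ratio 5). On Yule trees of height ≈ 4.6 this puts tips near the
  asymmetric stationary distribution (≈ 5/6 in state 1), matching the
  strongly skewed state frequencies and high lability of the characters
  this method is applied to; a design analysis showed the likelihood
  information about rate asymmetry increases with lability in this regime,
  whereas weakly labile characters leave the ratio dominated by the
  equal-rates model's point mass at 1.
* **Named fixtures**: `symmetric` (truth ratio 1), `asymmetric-ratio5`
  (truth ratio 5), `morindeae-like` (61 ingroup tips in four clades of
  6/12/8/35 on an (A,(B,(C,D))) backbone plus two outgroup taxa, four
  clade-biased characters, seven MRCA queries A–G), and `prior-only`
  (all observations missing, so the posterior must reproduce the prior).

## Numerical choices and degenerate inputs

* 0^0 = 1 in the κ transform, so κ = 0 maps zero-length branches to unit
  length like every other branch; the transition matrix at t = 0 is the
  identity, making zero-length branches legal.
* An all-zero generator yields the identity transition matrix with a
  warning (the character cannot change).
* Corolla ratio exactly 1 codes as missing rather than guessing a side of
  an undefined boundary.
* HPD requires ≥ 20 samples, ESS ≥ 50; a constant series reports ESS 1.
* A character with fewer than two observed states runs with a warning and
  returns prior-shaped posteriors instead of failing, since the
  prior-recovery mode is itself useful.
* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; identical seeds give byte-identical traces.

## Problem sizes

Test and example runs use chains of 10⁴–10⁶ generations with thinning
10–50 on trees of 12–63 tips and samples of 5–50 trees — sizes chosen so
the full statistical battery (exact oracles, prior recovery, quadrature
equivalence, 20-replicate recovery) completes in minutes while keeping
Monte-Carlo error well inside the asserted tolerances. The full-scale
protocol constants are preserved in `FULL_SCALE_PROFILE` for production use.

## Known limitations

* No correlated-character (dependent) models, covarion/hidden-rate
  models, ordered multistate constraints, or stochastic character mapping.
* Tree inference, consensus computation and marginal-likelihood estimation
  are out of scope: the engine consumes a tree sample, it does not produce
  one.
* The three-state model space is the single all-rates-free model;
  reversible-jump partitioning of multistate rate classes is not
  implemented.
* Polymorphic tips (a set of states at one tip) are not supported beyond
  fully missing.
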