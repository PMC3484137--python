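# Methods

`traitcorr` implements Bayesian comparative tests of correlated
evolution between a binary habitat character (0 = soil/unexposed,
1 = epiphytic/exposed) and binary morphological characters on a rooted
phylogeny, together with fossil-constrained ancestral-state
reconstruction and a "which changed first" rate-ordering test.  This
note records the models, the numerical choices, and the limits of what
the synthetic data can show.

## Models

**Single character.**  A two-state continuous-time Markov chain with
gain rate α (0→1) and loss rate β (1→0) per unit branch length.
Transition probabilities are `expm(Q t)`; for two states the closed
form `P01 = α/(α+β) (1 − e^{−(α+β)t})` holds and is used as a test
oracle.

**Joint (habitat, morphology).**  A four-state chain over combined
states 1 = (h0,m0), 2 = (h1,m0), 3 = (h0,m1), 4 = (h1,m1) with eight
single-change rates q12, q13, q21, q24, q31, q34, q42, q43;
simultaneous dual transitions (1↔4, 2↔3) have rate 0.  Under this
indexing **q12 is a habitat gain with ancestral morphology and q13 a
morphology gain with ancestral habitat** — the ordering test compares
exactly these two.  (Published descriptions of this model family are
not always consistent about which index is which; we follow the
convention in which the "habitat shifts first" hypothesis corresponds
to q12 > q13, and say so explicitly wherever the rates are reported.)

The *independent* model is the special case q12 = q34, q21 = q43,
q13 = q24, q31 = q42 (each trait's rates do not depend on the other's
state; four free parameters).  The *restricted* model shares one value
for q12 and q13 (seven parameters) and is the null of the ordering
test.

**Likelihood.**  Felsenstein pruning with per-node rescaling.  Missing
tip values ("−") contribute a partial likelihood of 1 in every
compatible state — total ambiguity, never a third state; a tip missing
one trait of the pair is ambiguous over exactly the combined states
consistent with the observed trait.  Node constraints ("fossilising")
zero the partial likelihoods outside the allowed state set at that
node, so a constrained likelihood is the joint probability
P(data, node ∈ allowed); constraining each state in turn and
normalising therefore yields exact marginal ancestral probabilities.
The root state distribution is uniform by default (1/2 or 1/4), with a
stationary-distribution option.

**Matrix exponential.**  Eigendecomposition, vectorised over all
branches of a tree at once; when the generator is defective or the
eigenvector matrix ill-conditioned (symmetric equal-rate settings) the
code falls back to scaling-and-squaring per branch.  Rows are clipped
to [0, 1] and renormalised; agreement with a 60-term series expansion
is better than 1e-10 in the tests.

## MCMC

Rates carry independent uniform priors on [0, 100].  The
Metropolis-Hastings proposal updates one randomly chosen rate per
iteration by a symmetric sliding window with reflection at the prior
bounds.  **Each parameter keeps its own window half-width**, tuned
toward the target acceptance (default 0.20) during burn-in only and
frozen afterwards, preserving detailed balance for the retained
samples.  Per-parameter widths matter: rates the data cannot identify
accept any proposal, and a single shared width tuned on aggregate
acceptance is dragged to the prior width, starving the identified
rates of accepted moves — which biases the sampled likelihoods of the
eight-parameter model downward relative to the four-parameter model
and corrupts harmonic-mean comparisons.

Burn-in defaults to 10% of the chain and is excluded from all
summaries.  Thinning retains every k-th iteration; the retained count
is `floor((iterations − burn_in)/thinning)`.  With a tree sample
instead of a single tree, iterations propose swapping to a uniformly
drawn tree, accepted by likelihood ratio.  Every run is bit-reproducible
from its seed.

**Reversible jump.**  The RJ sampler walks over assignments of a
model family's rates to rate classes: the eight dependent rates
(uniform prior over the 4140 set partitions; an optional zero class,
off by default, pins members to rate 0 and enlarges the space to
21147) or, for the independent family, its four rates (15 partitions).  The partition kernel
reassigns one randomly chosen rate to another existing class, a fresh
singleton class, or the zero class.  New class values are drawn from
the prior, which cancels against the prior ratio, leaving acceptance =
likelihood ratio x (forward target count / reverse target count).
This single-element kernel is irreducible over the partition space and
its Hastings ratio is exact; with all-missing data the sampled
partition distribution matches the uniform prior (chi-square on the
class-count statistic against Stirling-number expectations) and
sampled rates pass a Kolmogorov–Smirnov test against U(0, 100).
A retained sample counts as a visit to the *independent* model iff its
partition places q12 with q34, q21 with q43, q13 with q24 and q31 with
q42 — model identity is structural, not numerical coincidence.

## Model comparison

The correlation test samples *both* model families with
reversible-jump chains over their rate-class partitions — replicate D
chains (8 rates, unrestricted) and replicate I chains (4 rates) — and
reports two routes side by side:

1. **Harmonic-mean Bayes factors.**  The log marginal likelihood of a
   run is `ln N − logsumexp(−lnL_i)` over retained samples; BF = 2 ×
   (lnL_D − lnL_I), with >2 "positive" and >5 "strong".  Replicate
   runs are summarised by their mean, SD, and maximum; BFs use the
   best (maximum harmonic mean) run of each family, ties broken by
   lowest seed.  Sampling both families with rate-class averaging is
   essential here: fixed-rate chains give the eight-parameter model a
   ~10-nat harmonic-mean deficit from its extra prior volume alone,
   swamping the signal, whereas RJ chains keep both families'
   effective dimension comparable (on uninformative data both collapse
   toward few classes).  The harmonic-mean estimator is known to be
   unstable (its variance is infinite for diffuse priors); it is
   retained because the reported quantities are defined on it, and its
   noise is visible in the replicate SDs.
2. **Visit odds.**  From the best unrestricted (D) run, posterior
   odds = (visits_total − visits_independent)/visits_independent,
   divided by the *exactly enumerated* prior odds of dependent vs
   independent partitions (4125/15 = 275 without the zero class,
   405.67 with it), and BF = 2 ln(odds ratio).  Zero independent
   visits — the strongest possible dependent signal — propagate as NA.

The ordering test takes posterior samples of q12 and q13 from the best
dependent-model chain and applies a two-sided Mann-Whitney test (exact
enumeration for ≤20 samples without ties, tie-corrected normal
approximation otherwise), plus a BF comparing the restricted
(q12 = q13) model against the full dependent model.  The rank test is
applied to autocorrelated MCMC samples, as is conventional for this
pipeline; `AnalysisConfig.ess_thinning` optionally thins further
before the test, and without it the p-values overstate significance
and should be read as descriptive.

## Synthetic data

The generator replaces the study's tree and character matrix, which
exist only as supplementary documents.  `moss_epiphyte` (44 taxa) draws a
pure-birth tree rescaled to total branch length 2, simulates one
habitat character (gain 4, loss 1.5 per unit length, giving a handful
of clade-level shift lineages and roughly balanced tip frequencies),
four habitat-linked morphological characters and four
independent ones (gain = loss = 1), then blanks 5% of morphology cells
(habitat is fully scored, as in the emulated study design).  Linked
characters follow the *habitat-first* regime: morphology gain 0.5 in
the unexposed state vs 10 in the exposed state, losses 1.  They are
simulated jointly with the habitat by conditioning each character's
event-driven simulation on the single shared habitat path — exact
joint simulation under a dependent generator whose habitat rates do
not depend on morphology, which is what "habitat shifts first" means.
All trait histories use exact event-driven CTMC simulation
(exponential waiting times, jumps proportional to off-diagonal rates),
so dual transitions are impossible by construction and full event logs
exist.

The 64-taxon power scenarios (`habitat_first`: q12 = 5, q13 = 0.5,
q24 = 10, q34 = 5, all losses 1) use trees rescaled to total length 4.
At total length 2 each morphology character realises only ~3 changes
and the dependent-vs-independent likelihood ratio is ~1 nat —
uninformative; at length 4 each character sees roughly ten changes and
the likelihood ratio reaches 4–10 nats.  This is more change than the
44-taxon fixture's 2–6 per character; the scenarios deliberately trade
realism for identifiability.

What passing tests on these data do **not** show: performance under
real-data features the generator omits — non-ultrametric branch-length
error, phylogenetic uncertainty correlated with the traits,
non-binary or miscoded characters, and habitat codings that are
themselves inferences.  Tree-sample support exists (uniform sampling
over a posterior tree set) but the bundled fixtures are single trees.

## Desk-scale settings

Published analyses of this kind run 10⁸–10⁹ generations; the package
default is 10⁶ iterations thinned to 20,000 retained samples, and the
bundled analyses and acceptance script use 30,000–50,000 iterations
with 20% burn-in, 2,000–2,500 retained samples and 2–3 replicates,
which keeps a full analysis of the 44-taxon fixture within minutes on
one core.  Harmonic means at this scale carry replicate noise of
roughly 0.5–2 log units (visible in the reported SDs), and they drift
downward as chains lengthen (the estimator keeps encountering rarer
low-likelihood excursions), so Bayes factors are comparable only
between runs with the same chain settings, and values within a few
units of zero should not be over-read.  All bundled drivers and the
acceptance script therefore share one setting.

## Known limitations

- **Harmonic-mean noise near zero.**  On 64-taxon habitat-first
  simulations the maximised D-vs-I log-likelihood ratio varies between
  ~1 and ~10 nats across datasets (few realised transitions).  At desk
  scale the harmonic-mean BF carries replicate noise of roughly ±2, so
  datasets whose true signal sits within a couple of nats of zero get
  BFs of either sign, and the two BF routes can disagree in sign
  there.  Published analyses suppress this noise with chains four
  orders of magnitude longer.  The acceptance suite runs at the
  nominal power targets and reports what the method actually delivers
  at desk scale.
- The enumerated prior odds (275, or 405.67 with the zero class) are
  what the uniform-partition prior implies for *this* sampler's model
  space; published analyses using other RJ priors report different
  values, so visit-odds BFs are comparable only within a prior.
- Ancestral-state probabilities are posterior means over sampled
  rates; with uniform [0, 100] rate priors and few taxa the rate
  posterior can remain prior-dominated, pulling marginals toward 1/2.
  This mirrors the behaviour of the emulated pipeline.
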