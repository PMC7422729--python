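# Methods

## Model

The package models the probability that examinee *i* answers item *j*
correctly as

    p_ij = c_j + (1 - c_j) / (1 + exp(-D a_j (θ_i - b_j)) + exp(-t*_ij))

a three-parameter logistic response function whose denominator carries an
extra `exp(-t*)` term for the transformed response time.  The two
exponential terms act independently: the first is the usual
ability–difficulty trade-off, the second a pure time effect.  Two limits
anchor the interpretation: `t* → +∞` recovers the plain 3PL (unlimited
time does not guarantee success beyond the ability-determined ceiling),
and `t* → -∞` drives `p → c_j` — under this functional form the
probability floors at the guessing parameter, not at zero, because the
`(1 - c_j)` rescaling never touches the floor.  Setting `c_j = 0` gives
the two-parameter variant; additionally sharing one discrimination
across items gives the one-parameter variant.

Inverting the two limiting curves at a target probability `p` gives the
thresholds

    θ  = b - log((1-p)/(p-c)) / (D a)      (ability needed with unlimited time)
    t* = -log((1-p)/(p-c))                 (time needed with unlimited ability)

both implemented with natural logarithms and defined for `c < p < 1`.

**Time transformation.** `t* = (log t - μ_t)/σ_t + W`, where μ_t and σ_t
are the mean and SD of the pooled log-times of the whole matrix (so the
standardized part is mean-0, SD-1) and the weight W ∈ [0, 8] encodes how
much the test's stakes let time pressure bite; W ≈ 8 makes `exp(-t*)`
negligible for typical `t*`.  The "standardize the pooled log-times"
reading is used because it makes the standardized times unit-normal,
which is the scale every other quantity in the package assumes.

**Conventions.** Responses are coded 1 = correct.  Normal distributions
are parameterized as N(mean, variance) everywhere.  D defaults to 1.7;
the worked-example reproduction (`run_table2`) uses D = 1 because the
published estimates for that three-item bank are only consistent with
the unscaled logistic (verified numerically: with D = 1 all 27 estimates
agree with the printed table to ~1e-4; with D = 1.7 none do).

## Maximum-likelihood scoring

Ability for a single examinee maximizes the Bernoulli log-likelihood
over θ ∈ [−6, 6].  With a guessing floor the log-likelihood need not be
concave, so the optimizer scans a 0.01-step grid and refines the winner
with a bounded scalar search (tolerance 1e-10); estimates within 1e-6 of
a bound are flagged as boundary solutions (e.g. all-correct patterns).
For a fixed response pattern the estimate is non-increasing in a scalar
t* applied to all items: the faster the same answers were produced, the
higher the inferred ability.

## Synthetic data

`g3plt.simulate` emulates a timed power test:

- discriminations: N(1, 0.2) truncated to a > 0 (rejection sampling);
- difficulties and abilities: N(0, 1) — the latter is also the model's
  identification constraint (latent mean 0, variance 1);
- guessing: Beta(2, 10) (mean 1/6);
- item time locations: log-average times N(0.5, 0.25) standardized to
  t*_j ~ N(0, 1), then **rank-paired with difficulty** (harder items get
  larger time locations);
- person-by-item times: N(t*_j, 0.5) within each item, the draws sorted
  and **rank-paired with ability** (per item, Spearman(θ, t*) is exactly
  −1: the ablest examinee is always the fastest);
- responses: Bernoulli at the model probability evaluated at `t* + W`,
  so a fit supplying the same weight uses the exact generating model.

What this emulates — and does not.  The generator captures the two
dependences a timed power test is believed to show (harder items take
longer; abler examinees answer faster) in their most extreme, exactly
rank-deterministic form.  Real response times are far noisier, times are
missing or censored at section ends, and speed–accuracy trade-offs vary
across persons.  Passing tests on this generator therefore demonstrate
correctness of the machinery, not validity of the model for any given
real data set.

A calibration caveat follows from the exact pairing and is documented
here deliberately: because the observed times are deterministic in the
ranks of θ (and the item time locations in the ranks of b), the times
are strongly informative about the latent parameters, while the
estimation priors treat them as independent.  A correct Bayesian fit of
the matched model on this generator is therefore *not* frequency-
calibrated over replications: difficulty estimates carry a persistent
positive bias and HPD coverage for difficulty/guessing falls well below
the nominal 0.95 (and degrades as N grows).  The package's sampler has
been validated against independent oracles (grid quadrature; an
ability-marginalized ensemble sampler), so this is a property of the
generating design, not of the sampler.  With the person-level pairing
removed, coverage returns to ≈0.9, and under a plain-3PL
generate-and-fit it is nominal.

## Bayesian estimation

`run_mcmc` cycles four Metropolis–Hastings blocks per iteration:

1. θᵢ: normal random walk, prior N(0, 1);
2. bⱼ: normal random walk, prior N(0, 1);
3. aⱼ: lognormal random walk (`log a* ~ N(log a, v²)`), prior
   logN(0, 1); the proposal's asymmetry contributes the factor a*/a to
   the acceptance ratio — omitting it visibly shifts the posterior (a
   regression test checks this against quadrature);
4. cⱼ: uniform ±0.01 proposal, prior Beta(2, 10); proposals outside
   (0, 1) are auto-rejected.

All ratios are computed in log space on clipped probabilities
(ε = 1e-12), making them invariant to likelihood rescaling.  Proposal
SDs default to 1.0 / 0.5 / 0.3 (θ / b / a) and are adapted
per-parameter during burn-in toward a 20–50% acceptance window
(multiplicative 0.7/1.4 updates every 50 iterations), frozen at the end
of burn-in so retained draws target the exact posterior.  The guessing
half-width stays fixed at 0.01; it is the slowest-mixing block.

Initialization is moment-based (standardized person/item logits, a = 1,
c at prior mean); extra chains jitter this start (θ, b + N(0, 1),
a × exp(N(0, 0.5²)), c resampled from its prior) to give overdispersed
starting points for the Gelman–Rubin diagnostic.  `psrf` implements the
classic between/within variance ratio; with four chains of 10,000
iterations (5,000 burn-in) all parameters fall below the conventional
1.2 cut on moderate problems.  HPD intervals are the shortest
order-statistic interval containing the target mass.  Identification
relies on the N(0, 1) prior for θ only; draws are never rescaled.

## Model assessment

DIC uses the plug-in deviance at the element-wise posterior mean of all
blocks on their natural scales, plus twice the effective parameter count
p_D = (mean deviance − plug-in deviance).  LPML sums per-cell log CPO
values estimated by the harmonic mean of per-draw likelihoods with a
per-cell max shift for numerical stability; the estimator is invariant
to draw order and bounded above by the best per-draw log-likelihood.
For large fits the draws may be thinned before assessment
(`assess_fit(..., thin=5)` is used in the scripted studies); the
harmonic-mean estimator is noisy in its extreme cells, which is the
known cost of CPO without case-specific reweighting.

## Scripted studies and problem sizes

`run_sim1` (recovery) draws item truths once per condition and redraws
abilities/times/responses each replication, so bias/MSE/simulation-SE
are averages over data sets at fixed truth; the simulation SE uses the
1/M-normalized sample variance.  `run_sim2` (model comparison) fits the
plain 3PL and the matched time-aware model to the same data and
tabulates DIC/LPML quartiles and selection frequencies.

The full designs (200 replications, chains of 10,000/5,000, N up to
2,000, J up to 60) are configurable via `ExperimentSpec`.  The package's
own test suite runs scaled versions chosen as a sensible desk protocol:
single chains of 6,000 iterations (3,000 burn-in); recovery at N = 500
(10 replications) and N = 2,000 (4 replications) with J = 20, W = 1;
model comparison at N = 1,000, J = 20 with 5 replications per case for
true weights 0 and 8, assessing every 5th draw.  At these sizes the
directional model-comparison findings reproduce (the matched model wins
DIC/LPML when the time effect is strong; the criteria tie when W = 8),
while the recovery study exhibits the calibration caveat described
above.

## Numerical choices and limitations

- Exponentials are guarded (arguments effectively capped near ±700);
  probabilities are clipped to [1e-12, 1−1e-12] inside logarithms.
- Tie-breaks in the rank pairing use stable sorts, so generation is
  bit-reproducible for a given seed.
- Degenerate inputs: constant raw times (σ_t = 0) are rejected;
  non-binary responses and non-positive times are rejected with the
  offending cell named; J = 0 is allowed in the sampler (the θ chain
  then samples its prior, which the tests exploit).
- No polytomous items, no missing-response handling (rows with missing
  cells should be removed upstream), no EAP/MAP scoring in the ML
  module, and no WAIC/Bayes factors.
- The discrimination parameters of items answered almost uniformly
  correctly or incorrectly (|b| ≳ 2 relative to the ability spread) are
  weakly identified; under the heavy-tailed logN(0, 1) prior their
  posterior means can sit far from truth, which dominates
  discrimination-class MSE at realistic sizes.
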