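# Methods

`autrel` models how people revise judgments of an automated decision aid's
reliability from trial-by-trial experience. The observable data are, per
participant, a sequence of automation-correctness bits `AC_t` (1 when the
aid's classification of contact *t* was correct) and a 0-100 slider judgment
elicited after each contact ("what is the probability that the automation's
next classification will be correct?"). The package fits eight candidate
learning processes to each participant's series by maximum likelihood and
compares them with BIC.

## Observation model

Judgments are divided by 100 and modelled as draws from a normal distribution
truncated to [0, 1]:

    y_t / 100 ~ TruncNormal(r_t, sigma; 0, 1)

where `r_t` is the latent reliability estimate produced by the learning
process after contact *t*, and `sigma` (one free parameter per model fit)
captures response noise independent of learning. Judgments of exactly 0 or
100 are ordinary observations at the bounds: the truncated density is
continuous and there is no censoring mass, so no special handling is needed.
For memory-sampling models the latent estimate is a finite mixture (one
sampled memory drives each judgment), and the likelihood of a judgment is the
weight-averaged truncated-normal density over components. Because outcomes
are binary, those mixtures collapse exactly to a handful of distinct
components (e.g. {0, 1, r0} for recency sampling), which keeps likelihood
evaluation cheap without approximation.

An optional linear-in-log-odds (LLO) distortion can be interposed between the
latent estimate and the response: `logit(pi') = gamma_llo * logit(pi) +
(1 - gamma_llo) * logit(p0_llo)`. `gamma_llo` is the log-odds slope (1 =
identity) and `p0_llo` the crossover probability that the distortion leaves
fixed. The distortion is applied to **each mixture component mean** rather
than to the mixture mean; this choice (the parameterization is genuinely open)
keeps the single-sample semantics of the sampling models intact and is
isolated in `observation.llo_transform` plus one call site in the likelihood.
Component means are clamped to [1e-6, 1 - 1e-6] before the logit because
sampling components are exactly 0 or 1. Two models are never LLO-augmented:
recency sampling (its components are raw 0/1 outcomes, which the logit
saturates) and the no-updating baseline (the distortion is absorbed by the
intercept) - both are flagged `supports_llo=False` in the registry.

## Learning processes

* **Static Bayesian** - beta-binomial updating with prior pseudo-counts
  (p, q); the latent estimate is the posterior mean `(p + N_AC)/(p + q + t)`.
  Exchangeable in the outcomes, hence no recency effect. k = 3 with sigma.
* **Delta rule** - `r_t = r_{t-1} + alpha (AC_t - r_{t-1})` from start point
  r0; equivalently a geometric recency-weighted average (the closed form is
  implemented separately and used as a test oracle). k = 3.
* **Two-kernel delta rule** - slow and fast delta learners share r0 and
  update on every contact; the fast kernel's estimate is reported when
  `|fast - slow| > T` (strict, absolute difference), otherwise the slow
  kernel's. Kernels never reset after a switch. k = 5.
* **Recency sampling** - a single memory is sampled from
  {AC_t, ..., AC_1, r0} with the delta-rule weights
  {a, a(1-a), ..., (1-a)^t}; the sampled value is the estimate. Its mixture
  mean equals the delta-rule prediction, but single-sample judgments make the
  likelihood very different. k = 3.
* **Last-or-average sampling** - with probability prob_last the most recent
  outcome is sampled; otherwise the average of all outcomes so far, with the
  initial belief r0 contributing weight_r0 pseudo-observations. k = 4.
* **Contingent sampling** - the estimate is the mean outcome over earlier
  occasions whose preceding *m* outcomes match the current m-history; for
  t <= m the estimate is r0. The original model resamples a random observed
  history when no match exists; here that fallback is **marginalized** into a
  uniform mixture over the observed histories' following-outcome means, which
  makes the likelihood deterministic without changing its expectation. *m* is
  a discrete parameter, fitted by exhaustive grid over 1..5 - histories
  longer than 5 essentially never recur within 160 contacts. k = 3 (m counts
  as a parameter).
* **IIAB change-point model** - the estimate is the mean of a beta belief
  (prior p, q) over outcomes since the last perceived change point. Each
  contact runs a two-stage test. Stage 1 asks whether the current estimate is
  "broken": the evidence statistic is `n * KL(p_hat || anchor)`, the segment
  length times the Bernoulli Kullback-Leibler divergence between the observed
  proportion since the last change point and the estimate adopted when that
  segment began. Comparing against the anchor rather than the continuously
  updated posterior mean is deliberate: against the latter the statistic is
  degenerate (the posterior tracks the data, KL -> 0) and no change point
  could ever fire. If the statistic exceeds T1, stage 2 performs Bayesian
  model comparison with beta-binomial marginal likelihoods: the best
  within-segment split is compared against no split, the log Bayes factor is
  added to the log prior odds of a change point under a
  Beta(p_changepoint + #changepoints, q_changepoint + #non-changepoint
  contacts) belief, and a change point is added when the posterior odds
  exceed T2. When the addition fails and a change point exists, a "second
  thought" test symmetrically evaluates dropping the most recent change
  point. With T1 = +inf the model reduces exactly to the static Bayesian
  learner, which is tested. Both statistics are isolated in
  `models._iiab_forward` (pure-Python reference) and a numba-jitted twin that
  is verified against it in the test suite, so alternative constructions can
  be substituted in one place. k = 7.
* **No updating** - a constant intercept r0; the baseline any learning model
  should beat. k = 2.

Prediction convention: the judgment elicited after feedback on contact *t* is
paired with the latent prediction that incorporates contacts 1..t (the slider
asks about the *next* classification, after feedback on the current one).

## Experimental designs

Eight between-subjects conditions across three experiments are built in.
Experiment 1: 15 trials x 8 contacts; the high condition starts at 90%
reliability (one 8/8 trial, four 7/8 trials in the first five trials), the
low condition at 60% (one 4/8, four 5/8); both continue at 75% (6/8).
Experiment 2: 16 trials x 10 contacts; constant 75% (7/10 for half the
trials, 8/10 for the other half), and start-high/start-low conditions
alternating 95% (two 10/10 + two 9/10 per 4-trial phase) and 55% (two 5/10 +
two 6/10) phases in opposite orders. Experiment 3: 90% (9/10) in trials 1-4
and 9-16 with a drop to 30/50/70% (3, 5, or 7 of 10) in trials 5-8.

The designs pin down only per-trial correct counts. Two aspects are therefore
seeded-random choices of this implementation: which trial within a phase
carries an off count (e.g. the single 8/8 trial), and the order of outcomes
within a trial, both uniform permutations. Whether the original experiments
randomized within-trial order per participant is not documented; the
synthetic cohorts here give each participant an independent realization,
which is the assumption under which position effects average out across a
cohort. Per-trial counts - hence every phase reliability - are exact and
seed-invariant.

## Fitting

Per participant and model, parameters are estimated by maximum likelihood
with multi-start bounded local optimization: 20 uniform seeded draws within
the bounds (default; recorded in the fit result), each polished by L-BFGS-B,
or by Nelder-Mead for the two-kernel and IIAB models whose regime switches
make the surface only piecewise smooth (Nelder-Mead evaluations are capped at
400 per restart). Bounds: rates, probabilities and thresholds in [0, 1];
sigma in [0.01, 1]; weight_r0 in [0, 20]; IIAB T1 in [0.1, 20], T2 in
[0.5, 50]; beta pseudo-counts in [0.1, 50]; LLO gamma in [0.1, 10], p0 in
[0.01, 0.99]. The bounds are chosen to cover the scale of estimates reported
for this paradigm with generous headroom.

Two identifiability/robustness devices: the two-kernel learner is fitted in
the reparameterization `alpha_fast = alpha_slow + d (1 - alpha_slow)`,
d in [0, 1], which enforces `alpha_fast >= alpha_slow` smoothly (the labels
are otherwise exchangeable); and one extra two-kernel restart starts from the
fitted single delta rule mapped into two-kernel space (threshold 1, equal
rates - an exact special case), which guarantees the nested dominance
`loglik(two_kernel) >= loglik(delta)` on every series. If every restart
diverges the fit is flagged `converged=False` and the best raw start is
reported rather than raising.

Model comparison uses BIC = k ln(n) - 2 loglik with n the number of
judgments. Group tables sum BIC across participants per condition and
subtract the condition minimum (the winning model reads 0). Individual
classification converts the best-vs-runner-up BIC difference to an
approximate Bayes factor exp(dBIC/2); participants with BF < 3.2 (Jeffreys'
scale), including exact ties, are labelled inconclusive. Stratified fit
curves are reported only for models supported by at least 20% of a
condition's conclusive participants (configurable); single-participant strata
omit the standard error.

## Synthetic cohorts and exclusion rules

`simulate_participant` draws each judgment from the truncated normal around
the model's latent estimate (one mixture component sampled per contact for
sampling models). Disengaged responders come in two styles: constant-default
(the 50 default on more than half of contacts) and run-heavy (runs of >= 10
identical 0/50/100 judgments). The exclusion screen mirrors the engagement
rules applied to the real cohorts: exclude when more than half of judgments
are exactly 50, or when any run of >= 10 consecutive identical judgments of
0, 50, or 100 occurs. The original screening used visual inspection; the
run-length threshold of 10 is this package's operationalization and is a
keyword argument, so results quoting it should state the threshold.
Model-generated responders are essentially never excluded (continuous noise
never produces exact repeats), which the acceptance suite verifies across 100
seeds.

What the generator does *not* emulate: participants' own classification
decisions and confidence, advice acceptance, anchoring to the 50 default,
drifting strategies, or any dependence of automation accuracy on task
features. Passing recovery tests therefore show that the estimation machinery
is sound under the stated generative assumptions - not that real participants
satisfy them.

## Recovery studies and problem sizes

`recovery.parameter_recovery` refits the generating model to its own cohort;
`recovery.model_recovery` fits all eight models and classifies. Generating
parameters (module constants, chosen once at the scale typical for this
paradigm): delta (r0 = 0.5, alpha = 0.3), two-kernel (r0 = 0.7, alpha_slow =
0.03, alpha_fast = 0.35, T = 0.30), Bayesian (p = 3, q = 1), no-updating
(r0 = 0.7), all with sigma = 0.10 on the 160-contact start-high design.

Problem sizes are the package's own defaults, chosen to keep a full run on a
single CPU in the tens of minutes: parameter recovery uses 100 participants
per generator with 20 restarts in the test suite (50 in the acceptance
script); model recovery fits all eight models to 24 participants per
generator with 10 restarts in the test suite (16 in the acceptance script).
Under these conditions median absolute errors are approximately 0.01-0.015
for the delta learning rate, 0.05-0.06 for the delta start point, and
~0.005 for sigma, and the generating model is the modal classification for
the delta, Bayesian, and no-updating generators.

## Numerical choices

* Truncated-normal log-density computed in closed form from
  `scipy.special.ndtr` (vectorized); verified against
  `scipy.stats.truncnorm.logpdf` in the tests. The interval mass is never
  small because latent means live in [0, 1].
* Delta recursions (including the recency-sampling weight on "correct"
  memories, which satisfies the same recursion) via `scipy.signal.lfilter`.
* Mixture log-likelihoods via `logaddexp.reduceat` over flat component
  arrays; zero-weight components contribute -inf and drop out exactly.
* Contingent-sampling prediction structure (match means and fallback
  mixtures) depends only on (bits, m), not on r0, and is LRU-cached so the
  per-m continuous refits are cheap.
* The IIAB stage-1 reference probability is clamped to [1e-9, 1 - 1e-9]
  before the KL; `0 log 0 = 0` by convention.
* Ties in BIC classification are inconclusive by construction (BF = 1).

## Known limitations

* The IIAB stage-1 statistic and stage-2 Bayes-factor construction follow the
  published verbal description; the original source leaves details to its own
  supplement, so other faithful constructions exist. Both are isolated behind
  single functions for substitution.
* The two-kernel switch compares absolute kernel differences; a signed
  variant is not implemented (the published description does not say which
  was used).
* The LLO-augmented likelihood can be weakly identified when learning
  parameters and distortion trade off; fits with `use_llo=True` should be
  read with that caveat.
* No hierarchical pooling across participants: every fit is per-individual
  maximum likelihood, as in the source analysis.
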