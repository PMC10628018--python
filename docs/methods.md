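# Methods

## The screening model

Each diagnostic group has its own additive scorecard: a list of binary
features with non-negative weights and a decision threshold θ.  A feature
is either an exact categorical-variable value or a literal substring of
the triage note after normalization (lowercase, whitespace collapsed).
The record's score is the sum of weights over fired features, and the
record is positive iff score ≥ θ.  Ties at θ classify positive; the
convention is arbitrary but must be fixed, and the positive choice
maximises sensitivity at any given threshold.  Evaluation (ROC, Youden)
uses the same tie rule so reported operating points are the deployed ones.

Text matching is deliberately literal — no stemming, no negation
handling, no regular expressions.  This keeps the clinician-chosen
feature list auditable, at the cost that superficially different variants
of the same phrase are distinct features and negated mentions ("denies
suicidal ideation") still fire.  Those error modes are exactly why the
prevalence series must be corrected for misclassification, and the
synthetic generator reproduces both of them.

## Genetic-algorithm training

Weights are searched by a generational GA: uniform initialisation in
[0, w_max]; per generation, elitism (2), tournament selection (size 3),
per-gene uniform crossover (rate 0.5), per-gene Gaussian mutation (rate
0.05, scale 0.5, clipped to bounds).  Defaults: population 100, 200
generations, bounds [0, 10].  Elitism makes best-so-far fitness monotone
non-increasing; a single named RNG seeded from the config makes runs
bit-reproducible.

The threshold is *calibrated*, not evolved.  Candidates are the distinct
training scores plus max+1; among candidates with training specificity
≥ 95% (the screening requirement), the one maximising sensitivity is
chosen, ties breaking toward the larger θ.  Because max+1 always has
specificity 1, a feasible candidate always exists; the degenerate case —
the best feasible candidate has sensitivity 0, i.e. the scorecard cannot
separate at all — is flagged infeasible.  Fitness is
`1 − Se(θ) + 1{infeasible}`, which folds the specificity constraint and
the sensitivity objective into one number without double-counting.  The
threshold is calibrated on the training split and frozen before any
validation, so held-out Se/Sp are leakage-free.

## Diagnostic evaluation

Se and Sp carry Clopper–Pearson exact binomial 95% CIs (beta-quantile
form; lower bound 0 at x = 0, upper bound 1 at x = n).  AUC is the
trapezoidal area over the ROC built at all distinct score thresholds,
which equals the Mann–Whitney statistic with ties counted ½.  Youden's
cut-point maximises J = Se + Sp − 1 over distinct scores, ties toward the
larger cut-point (higher specificity, consistent with the screening
stance).  Monthly crude prevalence uses a logit-scale 95% CI
(z = 1.959964); at x = 0 or x = n the logit interval is undefined and the
exact interval is used instead.

## Bayesian adjustment

Model: T_P ~ Binomial(n, P_C), P_C = P_T·Se + (1 − P_T)(1 − Sp),
independent beta priors on P_T, Se, Sp.  One Gibbs sweep draws

* Y1 ~ Binomial(T_P, P_T·Se / (P_T·Se + (1−P_T)(1−Sp))) — diseased among
  test-positives,
* Y2 ~ Binomial(n−T_P, P_T·(1−Se) / (P_T·(1−Se) + (1−P_T)·Sp)) — diseased
  among test-negatives,
* P_T ~ Beta(a_PT + Y1 + Y2, b_PT + n − Y1 − Y2),
* Se ~ Beta(a_Se + Y1, b_Se + Y2),
* Sp ~ Beta(a_Sp + n − T_P − Y2, b_Sp + T_P − Y1).

Defaults: 50,000 sweeps, the first 5,000 discarded (a conventional 10%
burn-in), no thinning (quantiles use all retained draws; thinning only
discards information).  Chains initialise at the prior means; all draws
are clamped to [1e−12, 1 − 1e−12] to guard the mixture denominators.  The
posterior for P_T is summarised by its median and the 2.5/97.5
percentiles.  Independent month-group cells share one prior set per group
and are advanced as vectorised lockstep chains, which is statistically
identical to separate runs and fast on one CPU.  With Se and Sp pinned at
1 the sampler collapses to the conjugate Beta(a + T_P, b + n − T_P)
closed form — the main correctness oracle — and for large n with tight
accuracy priors the posterior median approaches the Rogan–Gladen point
estimate (P̂_C + Sp − 1)/(Se + Sp − 1).

### Prior elicitation

`elicit_beta` solves the two-equation system exactly: a central-tendency
constraint (mean a/(a+b), or mode (a−1)/(a+b−2) with a, b > 1) plus the
regularised-incomplete-beta CDF at one percentile, by bracketed
root-finding on log a (plug-back residual ≤ 1e−6 enforced).  Both
conventions are supported; the package default is **mode**, the
convention of the standard epidemiological elicitation utilities.  Under
the mean convention the CDF profile can cross the target level twice; the
most informative (largest-a) root is returned.

A caution that matters in practice: the solved hyperparameters scale
roughly like (percentile − central)⁻², so elicitation from *rounded*
summary inputs is ill-conditioned.  For example, the pair
(a, b) = (828.7, 27485.7) has mean 0.029268 and 95th percentile 0.030934;
re-eliciting from those values reproduces it exactly, but eliciting from
the two-decimal summaries 0.029 and 0.031 lands ~30% away under either
convention while describing a nearly identical distribution.  Downstream
posteriors are essentially unaffected; the hyperparameters themselves are
not reproducible from rounded inputs.

`priors_from_validation` builds the three priors from a validation
confusion matrix: Se and Sp centred (mode) on their point estimates with
the one-sided exact 95% lower bound as the 5th percentile; the P_T prior
centred on the Rogan–Gladen-corrected validation prevalence with its 95th
percentile at `pt_spread` × the centre (default 1.25; the trajectory-
recovery experiment uses 1.5 so anticipated ±20–30% seasonal swings are
not over-shrunk).  Degenerate cases fall back to pseudo-count priors
Beta(x+1, n−x+1).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes —
it is the test bed, not a simulator of any real service.  Monthly volumes
are Poisson around a mean (first/last months scaled by a partial-month
fraction, mirroring incomplete extract ends).  True prevalence per group
follows baseline × (1 + trend·t) × seasonal × trough, clamped to
(1e−6, 0.5); seasonal peaks default to Nov–Jan (configurable), troughs
are explicit month multipliers.  Labels are drawn through a
latent-threshold Gaussian copula so groups co-occur non-exclusively with
controllable pairwise correlation (default: suicidality–substance-use
0.3); infeasible correlation matrices are eigenvalue-clipped.  Positives
embed ≥ 1 signal phrase from their group lexicon and bias their linked
categorical values; negatives embed a decoy phrase with probability 0.01,
wrapped in a negation template 30% of the time; each embedded phrase is
misspelled (one adjacent-character transposition) with probability 0.05.
Notes are 2–6 background phrases plus signals, shuffled and joined with
". ", so substring matching cannot rely on position.  The variable
vocabulary and lexicons are invented (the originating services' value
lists are not public) and fully overridable.

What the generator does *not* reproduce: realistic clinical language and
its long-tail variability, drifting documentation habits, repeat
presentations by the same patient, and correlation between text noise and
case severity.  Passing tests therefore demonstrate correctness of the
machinery and recoverability under the stated noise model, not expected
performance on real triage notes.

## Validation experiments (problem sizes)

* **Threshold rule across cohorts**: 20 cohorts of 3 months × ~700
  presentations, one GA run each (population 24, 12 generations);
  training specificity ≥ 95% on every feasible run.
* **Interval coverage**: 100 replicates of T_P ~ Binomial(20,000, P_C)
  at P_T = 0.03, Se = Sp = 0.95 with correctly centred priors; the 95%
  probability interval covers the truth ≥ 90 times.
* **Trajectory recovery**: 24 months × 5,000/month, suicidality baseline
  0.03 with December ×1.2 and one ×0.7 trough; train on months 1–5
  (~25,000 presentations), elicit priors from months 6–10, run the
  pipeline (50,000 sweeps).  The adjusted trough median falls below, and
  the December medians above, the mean of baseline-month medians, and
  MAE against the generating trajectory is < 0.005 (the uncorrected
  crude series is ~20× worse).  The group-mean ranking comparison is
  used because at n = 5,000 the month-level binomial noise (σ ≈ 0.0024)
  makes all-pairs orderings a test of noise rather than recovery.

GA budgets in these experiments are desk-scale; the calibration rule and
all invariants they check are budget-independent.

## Known limitations

Scorecards have no feature interactions and no probabilistic output; the
literal matcher inherits every superficial-variant and negation error of
keyword screening.  The Bayesian model assumes Se/Sp are exchangeable
between the validation split and deployment months — drift in
documentation style violates this silently.  One prior set per group is
shared across months; months are treated independently (no smoothing
across the series).  No MCMC convergence diagnostics beyond seed
stability are computed; the conjugate-limit and recovery oracles are the
correctness evidence.
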