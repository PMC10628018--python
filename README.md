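# edscreen

Scorecard-based screening of emergency-department (ED) triage records for
mental-health presentations, with Bayesian correction of the resulting
monthly prevalence series for classifier misclassification.

ED surveillance of mental-health crises (suicidality, eating disorder,
mania, psychosis, substance use) typically starts from triage extracts: a
few categorical intake variables plus the free-text note written by the
triage nurse.  Manually coding hundreds of thousands of presentations is
infeasible, so screening is automated with simple additive scorecards —
per-feature risk weights summed and compared to a threshold.  Scorecards
are auditable and fast, but imperfect, and at prevalences of 0.1–3% even a
95%-specific classifier reports a *crude* monthly prevalence that can be
more than double the truth.  This package implements the full workflow:

1. **Scorecard classifiers** over exact categorical matches and literal,
   case-insensitive substrings of the normalized triage note, trained by a
   **genetic algorithm** (tournament selection, uniform crossover, Gaussian
   mutation, elitism) whose objective maximises sensitivity subject to a
   **specificity-constrained decision threshold**: θ is the largest score
   achieving Sp ≥ 95% on training data while maximising Se.
2. **Diagnostic evaluation**: Se/Sp with Clopper–Pearson exact binomial
   CIs, ROC/AUC under the deployment tie rule (score ≥ t positive),
   Youden's optimal cut-point, and monthly proportions with logit 95% CIs.
3. **Bayesian prevalence adjustment**.  The observed monthly positive
   count is T_P ~ Binomial(n, P_C) with

       P_C = P_T·Se + (1 − P_T)·(1 − Sp),

   and independent beta priors on P_T, Se and Sp (elicited from a central
   value and one percentile).  A data-augmentation Gibbs sampler draws the
   latent true-positive/false-negative counts and the conjugate beta
   updates, yielding a posterior median and 95% probability interval for
   the true prevalence P_T each month.
4. **A synthetic cohort generator** with known ground truth — monthly
   Poisson volumes, low-prevalence non-exclusive labels with copula
   co-occurrence, trend/seasonal/trough trajectories, label-linked
   variables and signal phrases in noisy text (false signals, negations,
   misspellings) — so the whole pipeline is testable end to end.

## Worked example

Suppose a month of 20,000 presentations yields 1,550 scorecard positives,
and a validation split put the classifier's Se and Sp near 0.95 (5th
percentile 0.93):

```python
import edscreen as es

prior_se = es.elicit_beta(central=0.95, percentile_value=0.93, percentile_level=0.05)
prior_sp = es.elicit_beta(central=0.95, percentile_value=0.93, percentile_level=0.05)
est = es.gibbs_true_prevalence(
    es.PrevalenceModelInput(
        t_p=1550, n=20_000,
        prior_pt=es.BetaPrior(1, 1), prior_se=prior_se, prior_sp=prior_sp,
    ),
    es.GibbsConfig(iterations=50_000, burn_in=5_000, seed=7),
)
print(f"crude prevalence      {1550/20000:.4f}")
print(f"adjusted (posterior)  {est.median:.4f}  (95% PI {est.lo:.4f}-{est.hi:.4f})")
```

prints

```
crude prevalence      0.0775
adjusted (posterior)  0.0294  (95% PI 0.0057-0.0475)
```

The crude 7.75% is mostly false positives; the posterior places the true
prevalence near 2.9%, with an interval honestly widened by the remaining
uncertainty in Se and Sp.

Training and the full monthly pipeline are available both as a library
(`ScorecardClassifier`, a scikit-learn estimator; `run_pipeline`) and as a
CLI:

```sh
edscreen simulate --config cohort.yaml --out cohort.csv
edscreen train    --cohort cohort.csv --group suicidality --out model.json
edscreen evaluate --cohort holdout.csv --model model.json --out metrics.json
edscreen pipeline --cohort cohort.csv --models models/ --priors priors.yaml --out-dir out/
```

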