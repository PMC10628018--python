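"""Simulation studies exercising the full method on synthetic cohorts.

These runners define the package's standard validation experiments:

* :func:`multi_cohort_specificity` — does the specificity-constrained
  threshold rule hold on freshly generated labelled cohorts, across
  diagnostic groups?
* :func:`coverage_study` — does the Gibbs posterior's 95% probability
  interval cover the true prevalence at its nominal rate when priors are
  correctly centred?
* :func:`recovery_experiment` — end to end: generate a cohort with a
  known trajectory (seasonal peak + lockdown-style trough), train a
  scorecard, elicit priors from a validation split, run the pipeline, and
  compare adjusted monthly medians to the generating trajectory.

Problem sizes default to desk-scale runs (a few minutes on one CPU);
every source of randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import cohort as cohort_mod
from .bayes import GibbsConfig, crude_from_true, elicit_beta, gibbs_chains, priors_from_validation
from .cohort import CohortConfig, TrajectoryParams, prevalence_at
from .features import classify_many, default_patterns
from .metrics import confusion_from_predictions
from .pipeline import run_pipeline
from .records import DIAGNOSTIC_GROUPS, month_range
from .scorecard import ScorecardClassifier


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))


# ---------------------------------------------------------------------------
# Specificity of GA-calibrated scorecards across cohorts
# ---------------------------------------------------------------------------

_T5_BASELINES = {
    "suicidality": 0.03,
    "eating_disorder": 0.01,
    "mania": 0.01,
    "psychosis": 0.015,
    "substance_use": 0.027,
}


def multi_cohort_specificity(
    seed: int,
    n_cohorts: int = 20,
    monthly_volume: float = 700.0,
    population_size: int = 24,
    generations: int = 12,
    sp_target: float = 0.95,
) -> list[dict]:
    """Train one scorecard per fresh cohort; report training Se/Sp.

    Cohorts are three months at ``monthly_volume`` mean presentations,
    rotating through the five diagnostic groups (group baselines raised
    to >= 1% so every cohort contains positives to train on).
    """
    ss = np.random.SeedSequence(seed).spawn(n_cohorts)
    rows = []
    for i in range(n_cohorts):
        group = DIAGNOSTIC_GROUPS[i % len(DIAGNOSTIC_GROUPS)]
        cohort_seed = _child_seed(ss[i])
        config = CohortConfig(
            months=((2021, 1), (2021, 2), (2021, 3)),
            monthly_volume=monthly_volume,
            trajectories={
                g: TrajectoryParams(baseline=b, seasonal_peak=1.0)
                for g, b in _T5_BASELINES.items()
            },
            seed=cohort_seed,
        )
        records = cohort_mod.generate_cohort(config)
        labels = np.array([r.labels[group] for r in records])
        clf = ScorecardClassifier(
            patterns=default_patterns(group),
            population_size=population_size,
            generations=generations,
            sp_target=sp_target,
            random_state=cohort_seed + 1,
        ).fit(records, labels)
        rows.append(
            {
                "cohort": i,
                "group": group,
                "n": len(records),
                "se": clf.se_,
                "sp": clf.sp_,
                "feasible": clf.feasible_,
            }
        )
    return rows


# ---------------------------------------------------------------------------
# Interval coverage under correctly-centred priors
# ---------------------------------------------------------------------------


def coverage_study(
    seed: int,
    reps: int = 100,
    p_t_true: float = 0.03,
    se: float = 0.95,
    sp: float = 0.95,
    n: int = 20_000,
    gibbs: GibbsConfig | None = None,
) -> dict:
    """Replicate T_P ~ Binomial(n, P_C(p_t_true, se, sp)); count how often
    the 95% posterior probability interval covers the true prevalence.

    Se/Sp priors are tight and centred on the truth (5th percentile 0.005
    below the mode); the P_T prior is centred on the truth but loose
    (95th percentile at 1.5x).  All replicate chains advance in lockstep.
    """
    ss = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(_child_seed(ss[0]))
    p_c = crude_from_true(p_t_true, se, sp)
    t_p = rng.binomial(n, p_c, size=reps)

    prior_se = elicit_beta(central=se, percentile_value=se - 0.005, percentile_level=0.05)
    prior_sp = elicit_beta(central=sp, percentile_value=sp - 0.005, percentile_level=0.05)
    prior_pt = elicit_beta(central=p_t_true, percentile_value=1.5 * p_t_true,
                           percentile_level=0.95)
    gibbs = gibbs or GibbsConfig(seed=_child_seed(ss[1]))
    draws = gibbs_chains(
        t_p, np.full(reps, n), prior_pt, prior_se, prior_sp, gibbs
    )["p_t"]
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    covered = int(((lo <= p_t_true) & (p_t_true <= hi)).sum())
    return {"covered": covered, "reps": reps, "lo": lo, "hi": hi, "t_p": t_p}


# ---------------------------------------------------------------------------
# End-to-end trajectory recovery
# ---------------------------------------------------------------------------


@dataclass
class RecoveryResult:
    true_prevalence: np.ndarray
    adjusted_median: np.ndarray
    crude: np.ndarray
    mae: float
    trough_median: float
    baseline_mean: float
    peak_medians: np.ndarray
    validation_counts: dict
    model_se: float
    model_sp: float


def recovery_experiment(
    seed: int,
    n_months: int = 24,
    monthly_volume: float = 5000.0,
    baseline: float = 0.03,
    peak_mult: float = 1.2,
    trough_mult: float = 0.7,
    ga_population: int = 40,
    ga_generations: int = 30,
    gibbs: GibbsConfig | None = None,
) -> RecoveryResult:
    """Known-trajectory recovery for the suicidality group.

    The cohort spans ``n_months`` full months with a December-only
    seasonal peak and a single mid-2020 trough.  The scorecard is trained
    on the first five months (about 25,000 presentations), priors are
    elicited from the next five, and the pipeline is run over the whole
    span; the result compares adjusted monthly medians to the generating
    trajectory.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    months = tuple(month_range((2020, 1), (2020, 12)))
    while len(months) < n_months:
        y, m = months[-1]
        months = months + ((y + (m == 12), m % 12 + 1),)
    troughs = {(2020, 6): trough_mult}
    target = TrajectoryParams(
        baseline=baseline,
        seasonal_peak=peak_mult,
        peak_months=frozenset({12}),
        troughs=troughs,
    )
    trajectories = {"suicidality": target}
    for g in DIAGNOSTIC_GROUPS:
        trajectories.setdefault(g, TrajectoryParams(baseline=0.002, seasonal_peak=1.0))
    config = CohortConfig(
        months=months,
        monthly_volume=monthly_volume,
        trajectories=trajectories,
        seed=_child_seed(ss[0]),
    )
    records = cohort_mod.generate_cohort(config)

    train = [r for r in records if r.month in months[:5]]
    valid = [r for r in records if r.month in months[5:10]]
    y_train = np.array([r.labels["suicidality"] for r in train])
    clf = ScorecardClassifier(
        patterns=default_patterns("suicidality"),
        population_size=ga_population,
        generations=ga_generations,
        random_state=_child_seed(ss[1]),
    ).fit(train, y_train)
    model = clf.to_scoring_model("suicidality")

    y_valid = np.array([r.labels["suicidality"] for r in valid])
    counts = confusion_from_predictions(y_valid, classify_many(valid, model))
    # 95th prior percentile at 1.5x the centre: loose enough for seasonal swings
    priors = priors_from_validation(
        counts.tp, counts.fp, counts.tn, counts.fn, pt_spread=1.5
    )

    gibbs = gibbs or GibbsConfig(seed=_child_seed(ss[2]))
    series = run_pipeline(
        records, {"suicidality": model}, {"suicidality": priors}, gibbs
    )
    table = series.table.sort_values(["year", "month"], kind="stable")
    med = table["post_median"].to_numpy()
    crude = table["crude_p"].to_numpy()
    true = np.array([prevalence_at(target, i, m) for i, m in enumerate(months)])

    is_peak = np.array([m[1] == 12 for m in months])
    is_trough = np.array([m in troughs for m in months])
    base = med[~is_peak & ~is_trough]
    return RecoveryResult(
        true_prevalence=true,
        adjusted_median=med,
        crude=crude,
        mae=float(np.abs(med - true).mean()),
        trough_median=float(med[is_trough][0]),
        baseline_mean=float(base.mean()),
        peak_medians=med[is_peak],
        validation_counts={
            "tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn
        },
        model_se=clf.se_,
        model_sp=clf.sp_,
    )
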