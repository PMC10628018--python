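"""Genetic-algorithm training of scorecard classifiers.

The classifier is an additive scorecard: non-negative per-feature weights
summed and compared to a threshold θ.  Training searches weight space with
a standard generational genetic algorithm (tournament selection, uniform
crossover, Gaussian mutation, elitism); for every candidate weight vector
the threshold is *calibrated*, not evolved — it is set to the largest
candidate value that achieves the target specificity (default 95%) on the
training data while maximising sensitivity.  Fitness is ``1 − sensitivity``
at that threshold, plus a unit penalty when calibration is degenerate
(the threshold had to be pushed past every score, i.e. sensitivity 0).

The threshold is calibrated on the training split and frozen before any
validation, so held-out performance estimates are leakage-free.

:class:`ScorecardClassifier` wraps the GA as a scikit-learn estimator and
composes with sklearn model selection; :func:`evolve` is the functional
core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .features import FeaturePattern, ScoringModel, design_matrix
from .records import PresentationRecord


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm hyperparameters.

    Defaults are desk-scale conventions (population 100 for 200
    generations, tournament size 3, per-gene crossover 0.5, per-gene
    Gaussian mutation at rate 0.05 with scale 0.5, weights in [0, 10],
    2 elites); all are overridable.
    """

    population_size: int = 100
    generations: int = 200
    tournament_size: int = 3
    crossover_rate: float = 0.5
    mutation_rate: float = 0.05
    mutation_scale: float = 0.5
    weight_max: float = 10.0
    elitism_count: int = 2
    sp_target: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.tournament_size < 2:
            raise ValueError("tournament_size must be >= 2")
        for rate, name in (
            (self.crossover_rate, "crossover_rate"),
            (self.mutation_rate, "mutation_rate"),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mutation_scale <= 0:
            raise ValueError("mutation_scale must be positive")
        if self.weight_max <= 0:
            raise ValueError("weight_max must be positive")
        if not 0 <= self.elitism_count < self.population_size:
            raise ValueError("elitism_count must be in [0, population_size)")
        if not 0.0 < self.sp_target < 1.0:
            raise ValueError("sp_target must be in (0, 1)")


def calibrate_threshold(
    scores, labels, sp_target: float = 0.95
) -> tuple[float, bool]:
    """Specificity-constrained threshold selection.

    Candidates are the distinct observed scores plus ``max(score) + 1``.
    Among candidates whose training specificity (fraction of negatives
    scoring strictly below the threshold) reaches ``sp_target``, the one
    maximising sensitivity is returned; sensitivity ties break toward the
    larger threshold.  Returns ``(threshold, feasible)`` where ``feasible``
    is False only in the degenerate case where the best Sp-respecting
    candidate classifies every record negative (sensitivity 0).

    Raises :class:`ValueError` if only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present to calibrate a threshold")

    candidates = np.unique(scores)
    candidates = np.append(candidates, candidates[-1] + 1.0)
    # decision rule is score >= t: sensitivity = P(pos >= t), specificity = P(neg < t)
    se = 1.0 - np.searchsorted(pos, candidates, side="left") / pos.size
    sp = np.searchsorted(neg, candidates, side="left") / neg.size

    ok = sp >= sp_target - 1e-12
    se_ok = se[ok]
    cand_ok = candidates[ok]
    best_se = se_ok.max()
    theta = cand_ok[se_ok >= best_se - 1e-12].max()
    return float(theta), bool(best_se > 0.0)


def _se_sp_at(scores: np.ndarray, labels: np.ndarray, theta: float) -> tuple[float, float]:
    pred = scores >= theta
    pos = labels == 1
    return float(pred[pos].mean()), float((~pred[~pos]).mean())


def fitness(
    weights, X, y, sp_target: float = 0.95
) -> float:
    """GA objective (lower is better): 1 − Se at the calibrated threshold,
    plus 1 if calibration is degenerate."""
    scores = np.asarray(X, dtype=float) @ np.asarray(weights, dtype=float)
    theta, feasible = calibrate_threshold(scores, y, sp_target)
    se, _ = _se_sp_at(scores, np.asarray(y), theta)
    return (1.0 - se) + (0.0 if feasible else 1.0)


@dataclass
class EvolutionResult:
    weights: np.ndarray
    threshold: float
    feasible: bool
    fitness: float
    se: float
    sp: float
    history: pd.DataFrame = field(repr=False)


def evolve(X, y, config: GAConfig) -> EvolutionResult:
    """Run the genetic algorithm on a binary design matrix.

    Returns the best individual with its calibrated threshold and a
    per-generation history (best/mean fitness, best Se/Sp, threshold).
    Best-so-far fitness is non-increasing across generations (elitism),
    and the run is bit-reproducible given ``config.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, p) with one label per row")
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    n, p = X.shape
    rng = np.random.default_rng(config.seed)

    pop = rng.uniform(0.0, config.weight_max, size=(config.population_size, p))

    def eval_all(population: np.ndarray) -> np.ndarray:
        scores = X @ population.T  # (n, P)
        fits = np.empty(population.shape[0])
        for k in range(population.shape[0]):
            theta, feasible = calibrate_threshold(scores[:, k], y, config.sp_target)
            se, _ = _se_sp_at(scores[:, k], y, theta)
            fits[k] = (1.0 - se) + (0.0 if feasible else 1.0)
        return fits

    fits = eval_all(pop)
    rows = []
    for gen in range(config.generations):
        order = np.argsort(fits, kind="stable")
        pop, fits = pop[order], fits[order]

        # log the incumbent
        best_scores = X @ pop[0]
        theta, feasible = calibrate_threshold(best_scores, y, config.sp_target)
        se, sp = _se_sp_at(best_scores, y, theta)
        rows.append(
            {
                "generation": gen,
                "best_fitness": fits[0],
                "mean_fitness": fits.mean(),
                "best_se": se,
                "best_sp": sp,
                "best_threshold": theta,
            }
        )

        elites = pop[: config.elitism_count].copy()
        n_children = config.population_size - config.elitism_count
        children = np.empty((n_children, p))
        for c in range(n_children):
            # tournament selection for two parents
            idx1 = rng.integers(0, config.population_size, size=config.tournament_size)
            idx2 = rng.integers(0, config.population_size, size=config.tournament_size)
            p1 = pop[idx1[np.argmin(fits[idx1])]]
            p2 = pop[idx2[np.argmin(fits[idx2])]]
            # uniform crossover: start from parent 1, swap genes in at crossover_rate
            child = p1.copy()
            swap = rng.random(p) < config.crossover_rate
            child[swap] = p2[swap]
            # Gaussian mutation, clipped to bounds
            mutate = rng.random(p) < config.mutation_rate
            child[mutate] += rng.normal(0.0, config.mutation_scale, size=mutate.sum())
            children[c] = np.clip(child, 0.0, config.weight_max)

        pop = np.vstack([elites, children]) if config.elitism_count else children
        child_fits = eval_all(pop[config.elitism_count :])
        fits = np.concatenate([fits[: config.elitism_count], child_fits])

    order = np.argsort(fits, kind="stable")
    best = pop[order[0]]
    best_scores = X @ best
    theta, feasible = calibrate_threshold(best_scores, y, config.sp_target)
    se, sp = _se_sp_at(best_scores, y, theta)
    rows.append(
        {
            "generation": config.generations,
            "best_fitness": fits[order[0]],
            "mean_fitness": fits.mean(),
            "best_se": se,
            "best_sp": sp,
            "best_threshold": theta,
        }
    )
    return EvolutionResult(
        weights=best,
        threshold=theta,
        feasible=feasible,
        fitness=float(fits[order[0]]),
        se=se,
        sp=sp,
        history=pd.DataFrame(rows),
    )


class ScorecardClassifier(ClassifierMixin, BaseEstimator):
    """GA-trained additive scorecard with a specificity-constrained threshold.

    Parameters mirror :class:`GAConfig`.  ``X`` may be a binary design
    matrix, or a sequence of :class:`PresentationRecord` /
    records-DataFrame when ``patterns`` is given (features are then
    extracted internally).

    Attributes (after :meth:`fit`)
    ------------------------------
    weights_ : ndarray of shape (n_features,)
        Evolved non-negative feature weights.
    threshold_ : float
        Calibrated decision threshold θ (ties classify positive).
    feasible_ : bool
        False only if calibration was degenerate (sensitivity 0).
    se_, sp_ : float
        Training sensitivity and specificity at ``threshold_``.
    history_ : DataFrame
        Per-generation best/mean fitness trajectory.
    """

    def __init__(
        self,
        patterns: Sequence[FeaturePattern] | None = None,
        population_size: int = 100,
        generations: int = 200,
        tournament_size: int = 3,
        crossover_rate: float = 0.5,
        mutation_rate: float = 0.05,
        mutation_scale: float = 0.5,
        weight_max: float = 10.0,
        elitism_count: int = 2,
        sp_target: float = 0.95,
        random_state: int = 0,
    ):
        self.patterns = patterns
        self.population_size = population_size
        self.generations = generations
        self.tournament_size = tournament_size
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate
        self.mutation_scale = mutation_scale
        self.weight_max = weight_max
        self.elitism_count = elitism_count
        self.sp_target = sp_target
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------

    def _ga_config(self) -> GAConfig:
        return GAConfig(
            population_size=self.population_size,
            generations=self.generations,
            tournament_size=self.tournament_size,
            crossover_rate=self.crossover_rate,
            mutation_rate=self.mutation_rate,
            mutation_scale=self.mutation_scale,
            weight_max=self.weight_max,
            elitism_count=self.elitism_count,
            sp_target=self.sp_target,
            seed=self.random_state,
        )

    def _to_matrix(self, X) -> np.ndarray:
        if isinstance(X, np.ndarray):
            return X.astype(float)
        if len(X) > 0 and isinstance(X[0], PresentationRecord):
            if self.patterns is None:
                raise ValueError("patterns required to featurize records")
            return design_matrix(X, self.patterns).astype(float)
        return np.asarray(X, dtype=float)

    # -- sklearn API -----------------------------------------------------

    def fit(self, X, y):
        y = np.asarray(y).astype(int)
        M = self._to_matrix(X)
        if M.ndim != 2:
            raise ValueError("X must be 2-D after featurization")
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        result = evolve(M, y, self._ga_config())
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = M.shape[1]
        self.weights_ = result.weights
        self.threshold_ = result.threshold
        self.feasible_ = result.feasible
        self.fitness_ = result.fitness
        self.se_ = result.se
        self.sp_ = result.sp
        self.history_ = result.history
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        return self._to_matrix(X) @ self.weights_

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= self.threshold_).astype(int)

    def to_scoring_model(self, group: str) -> ScoringModel:
        """Export as a serializable ScoringModel (requires patterns)."""
        check_is_fitted(self, "weights_")
        if self.patterns is None:
            raise ValueError("patterns are required to export a ScoringModel")
        entries = tuple(
            (pat, float(w)) for pat, w in zip(self.patterns, self.weights_)
        )
        return ScoringModel(group=group, entries=entries, threshold=self.threshold_)


def train_scoring_model(
    records: Sequence[PresentationRecord],
    group: str,
    patterns: Sequence[FeaturePattern],
    config: GAConfig | None = None,
) -> tuple[ScoringModel, pd.DataFrame]:
    """Train one group's scorecard from labelled records (thin wrapper)."""
    config = config or GAConfig()
    labels = np.array([r.labels[group] for r in records], dtype=int)
    clf = ScorecardClassifier(
        patterns=list(patterns),
        population_size=config.population_size,
        generations=config.generations,
        tournament_size=config.tournament_size,
        crossover_rate=config.crossover_rate,
        mutation_rate=config.mutation_rate,
        mutation_scale=config.mutation_scale,
        weight_max=config.weight_max,
        elitism_count=config.elitism_count,
        sp_target=config.sp_target,
        random_state=config.seed,
    ).fit(list(records), labels)
    return clf.to_scoring_model(group), clf.history_
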