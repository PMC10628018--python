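"""Bayesian true-prevalence estimation under an imperfect classifier.

The observed monthly positive count is modelled as
``T_P ~ Binomial(n, P_C)`` with crude prevalence tied to true prevalence
through the misclassification identity

    P_C = P_T * Se + (1 - P_T) * (1 - Sp).

With independent beta priors on P_T, Se and Sp, the posterior is sampled
by data augmentation: latent Y1 (true positives among test-positives) and
Y2 (false negatives among test-negatives) have binomial full
conditionals, after which P_T, Se and Sp are conjugate beta updates.  The
posterior of P_T is summarised by its median and central 95% probability
interval.

Beta priors are elicited from a central value (mean or mode) and one
percentile by solving the two defining equations numerically.  Note that
this elicitation is ill-conditioned: the solved hyperparameters scale
roughly like ``(percentile − central)**-2``, so rounded inputs can move
(a, b) by large factors while barely moving the distribution itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import optimize, stats

_EPS = 1e-12


def crude_from_true(p_t: float, se: float, sp: float) -> float:
    """Crude (apparent) prevalence implied by true prevalence and test accuracy.

    Affine and increasing in ``p_t`` whenever ``se + sp > 1``; equals
    ``p_t`` for a perfect test.
    """
    for name, v in (("p_t", p_t), ("se", se), ("sp", sp)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]: {v}")
    return p_t * se + (1.0 - p_t) * (1.0 - sp)


def rogan_gladen(p_c: float, se: float, sp: float) -> float:
    """Misclassification-corrected point estimate (P_C + Sp − 1)/(Se + Sp − 1).

    Clipped to [0, 1]; requires an informative test (Se + Sp > 1).
    """
    if se + sp <= 1.0:
        raise ValueError("requires Se + Sp > 1")
    return float(np.clip((p_c + sp - 1.0) / (se + sp - 1.0), 0.0, 1.0))


@dataclass(frozen=True)
class BetaPrior:
    """Beta(a, b) prior for a probability."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("hyperparameters must be positive")

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def mode(self) -> float:
        if self.a <= 1 or self.b <= 1:
            raise ValueError("mode requires a > 1 and b > 1")
        return (self.a - 1) / (self.a + self.b - 2)

    def quantile(self, q: float) -> float:
        return float(stats.beta.ppf(q, self.a, self.b))


#: A flat prior, the default when nothing is known.
UNIFORM_PRIOR = BetaPrior(1.0, 1.0)


@dataclass(frozen=True)
class ElicitationSpec:
    """A central value plus one percentile pinning down a beta prior.

    ``central_kind`` is ``"mean"`` or ``"mode"``; the percentile must lie
    on the same side of the central value as its level is of 0.5 (e.g. a
    95th percentile must exceed the central value).
    """

    central: float
    percentile_value: float
    percentile_level: float = 0.95
    central_kind: str = "mode"

    def __post_init__(self) -> None:
        if not 0.0 < self.central < 1.0:
            raise ValueError("central must be in (0, 1)")
        if not 0.0 < self.percentile_value < 1.0:
            raise ValueError("percentile_value must be in (0, 1)")
        if not 0.0 < self.percentile_level < 1.0:
            raise ValueError("percentile_level must be in (0, 1)")
        if self.central_kind not in ("mean", "mode"):
            raise ValueError("central_kind must be 'mean' or 'mode'")
        if (self.percentile_value - self.central) * (self.percentile_level - 0.5) <= 0:
            raise ValueError(
                "percentile must lie on the same side of the central value "
                "as its level is of 0.5"
            )


def elicit_beta(
    spec: ElicitationSpec | None = None,
    *,
    central: float | None = None,
    percentile_value: float | None = None,
    percentile_level: float = 0.95,
    central_kind: str = "mode",
) -> BetaPrior:
    """Solve for Beta(a, b) matching a central value and one percentile.

    The central-tendency equation (``a/(a+b) = central`` for the mean, or
    ``(a−1)/(a+b−2) = central`` with a, b > 1 for the mode) pins b to a;
    the remaining one-dimensional root-find makes the beta CDF at
    ``percentile_value`` equal ``percentile_level``.  When the CDF profile
    crosses the level more than once (possible under the mean convention),
    the most informative (largest-a) root is returned.  Raises
    :class:`ValueError` with a diagnostic when no solution exists.
    """
    if spec is None:
        spec = ElicitationSpec(
            central=central,
            percentile_value=percentile_value,
            percentile_level=percentile_level,
            central_kind=central_kind,
        )
    c = spec.central

    if spec.central_kind == "mean":
        def b_of(a: float) -> float:
            return a * (1.0 - c) / c
        a_min = 1e-6
    else:
        def b_of(a: float) -> float:
            return 1.0 + (a - 1.0) * (1.0 - c) / c
        a_min = 1.0 + 1e-9

    def f(log_a: float) -> float:
        a = np.exp(log_a)
        return stats.beta.cdf(spec.percentile_value, a, b_of(a)) - spec.percentile_level

    grid = np.linspace(np.log(a_min), np.log(1e12), 600)
    vals = np.array([f(g) for g in grid])
    crossings = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
    if crossings.size == 0:
        exact = np.nonzero(vals == 0.0)[0]
        if exact.size:
            a = float(np.exp(grid[exact[-1]]))
            return BetaPrior(a, b_of(a))
        raise ValueError(
            f"no beta prior matches {spec}: the CDF constraint is never met "
            f"(range of residuals [{vals.min():.3g}, {vals.max():.3g}])"
        )
    k = crossings[-1]  # most informative root
    log_a = optimize.brentq(f, grid[k], grid[k + 1], xtol=1e-13, rtol=1e-15)
    a = float(np.exp(log_a))
    prior = BetaPrior(a, b_of(a))
    # plug-back guard: both defining equations must hold
    resid = abs(stats.beta.cdf(spec.percentile_value, prior.a, prior.b) - spec.percentile_level)
    if resid > 1e-6:
        raise ValueError(f"elicitation did not converge (residual {resid:.2e})")
    return prior


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GibbsConfig:
    iterations: int = 50_000
    burn_in: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("need 0 <= burn_in < iterations")


@dataclass(frozen=True)
class PrevalenceModelInput:
    """Observed month: positive count, total, and the three beta priors."""

    t_p: int
    n: int
    prior_pt: BetaPrior = UNIFORM_PRIOR
    prior_se: BetaPrior = UNIFORM_PRIOR
    prior_sp: BetaPrior = UNIFORM_PRIOR

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0 <= self.t_p <= self.n:
            raise ValueError("need 0 <= t_p <= n")


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Posterior summary for one month's true prevalence."""

    median: float
    lo: float
    hi: float
    draws: Mapping[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not self.lo <= self.median <= self.hi:
            raise ValueError("interval must bracket the median")


def gibbs_chains(
    t_p,
    n,
    prior_pt: BetaPrior,
    prior_se: BetaPrior,
    prior_sp: BetaPrior,
    config: GibbsConfig,
    keep: tuple[str, ...] = ("p_t",),
) -> dict[str, np.ndarray]:
    """Advance independent chains in lockstep; one chain per (t_p, n) pair.

    Returns retained draws as ``{name: array of shape (kept, n_chains)}``.
    This is the computational core shared by single-month estimation and
    replicate simulation studies.
    """
    t_p = np.atleast_1d(np.asarray(t_p, dtype=np.int64))
    n = np.atleast_1d(np.asarray(n, dtype=np.int64))
    if t_p.shape != n.shape:
        raise ValueError("t_p and n must have the same shape")
    if (n <= 0).any() or (t_p < 0).any() or (t_p > n).any():
        raise ValueError("need 0 <= t_p <= n with n > 0 for every chain")
    k = t_p.size
    rng = np.random.default_rng(config.seed)

    def clamp(x: np.ndarray) -> np.ndarray:
        return np.clip(x, _EPS, 1.0 - _EPS)

    p_t = np.full(k, clamp(np.array([prior_pt.mean]))[0])
    se = np.full(k, clamp(np.array([prior_se.mean]))[0])
    sp = np.full(k, clamp(np.array([prior_sp.mean]))[0])

    kept = config.iterations - config.burn_in
    out = {name: np.empty((kept, k)) for name in keep}
    store = {"p_t": None, "se": None, "sp": None}

    neg = n - t_p
    for it in range(config.iterations):
        # P(diseased | test positive) and P(diseased | test negative)
        num1 = p_t * se
        p1 = num1 / (num1 + (1.0 - p_t) * (1.0 - sp))
        num2 = p_t * (1.0 - se)
        p2 = num2 / (num2 + (1.0 - p_t) * sp)
        y1 = rng.binomial(t_p, clamp(p1))
        y2 = rng.binomial(neg, clamp(p2))
        p_t = clamp(rng.beta(prior_pt.a + y1 + y2, prior_pt.b + n - y1 - y2))
        se = clamp(rng.beta(prior_se.a + y1, prior_se.b + y2))
        sp = clamp(rng.beta(prior_sp.a + neg - y2, prior_sp.b + t_p - y1))
        if it >= config.burn_in:
            j = it - config.burn_in
            store["p_t"], store["se"], store["sp"] = p_t, se, sp
            for name in keep:
                out[name][j] = store[name]
    return out


def gibbs_true_prevalence(
    model_input: PrevalenceModelInput,
    config: GibbsConfig | None = None,
    keep_draws: bool = True,
) -> PrevalenceEstimate:
    """Posterior median and 95% probability interval for true prevalence."""
    config = config or GibbsConfig()
    draws = gibbs_chains(
        model_input.t_p,
        model_input.n,
        model_input.prior_pt,
        model_input.prior_se,
        model_input.prior_sp,
        config,
        keep=("p_t", "se", "sp"),
    )
    p_t = draws["p_t"][:, 0]
    lo, med, hi = np.percentile(p_t, [2.5, 50.0, 97.5])
    return PrevalenceEstimate(
        median=float(med),
        lo=float(lo),
        hi=float(hi),
        draws={name: arr[:, 0] for name, arr in draws.items()} if keep_draws else None,
    )


# ---------------------------------------------------------------------------
# Prior construction from a validation split
# ---------------------------------------------------------------------------


def priors_from_validation(
    tp: int,
    fp: int,
    tn: int,
    fn: int,
    pt_spread: float = 1.25,
    central_kind: str = "mode",
) -> dict[str, BetaPrior]:
    """Elicit P_T, Se and Sp priors from validation confusion counts.

    Se and Sp priors use the point estimate as the central value and the
    one-sided exact 95% lower confidence bound as the 5th percentile; the
    P_T prior is centred on the misclassification-corrected
    (Rogan–Gladen) prevalence with its 95th percentile at
    ``pt_spread``\\ × the centre, deliberately loose so month-to-month
    variation is not over-shrunk.  Degenerate counts (e.g. a perfect
    split, where no percentile below the central value exists) fall back
    to pseudo-count priors ``Beta(x + 1, n − x + 1)``.
    """
    n_pos, n_neg = tp + fn, tn + fp
    if n_pos == 0 or n_neg == 0:
        raise ValueError("validation data must contain both classes")
    n = n_pos + n_neg

    def accuracy_prior(x: int, m: int) -> BetaPrior:
        point = x / m
        lower = float(stats.beta.ppf(0.05, x, m - x + 1)) if x > 0 else 0.0
        central = min(point, 1.0 - 1e-4)
        if not 0.0 < lower < central:
            return BetaPrior(x + 1.0, m - x + 1.0)
        try:
            return elicit_beta(
                central=central,
                percentile_value=lower,
                percentile_level=0.05,
                central_kind=central_kind,
            )
        except ValueError:
            return BetaPrior(x + 1.0, m - x + 1.0)

    prior_se = accuracy_prior(tp, n_pos)
    prior_sp = accuracy_prior(tn, n_neg)

    se_hat, sp_hat = tp / n_pos, tn / n_neg
    p_c = (tp + fp) / n
    if se_hat + sp_hat > 1.0:
        center = rogan_gladen(p_c, se_hat, sp_hat)
    else:
        center = p_c
    center = float(np.clip(center, 1e-4, 1.0 - 1e-4))
    upper = min(center * pt_spread, center + 0.5 * (1.0 - center))
    try:
        prior_pt = elicit_beta(
            central=center,
            percentile_value=upper,
            percentile_level=0.95,
            central_kind=central_kind,
        )
    except ValueError:
        x = center * n
        prior_pt = BetaPrior(x + 1.0, n - x + 1.0)
    return {"p_t": prior_pt, "se": prior_se, "sp": prior_sp}
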