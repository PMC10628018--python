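"""Synthetic emergency-department cohort generator.

Produces labelled presentation records whose statistical structure mirrors
what the downstream analysis assumes about real triage extracts:

* monthly batches of presentations, Poisson-sized around a mean volume,
  with optionally incomplete first and last months;
* five non-mutually-exclusive diagnostic-group labels drawn at low,
  month-varying prevalences (trend, end-of-year seasonal peaks,
  lockdown-style troughs);
* pairwise label co-occurrence (e.g. suicidality with substance use) via a
  latent-threshold Gaussian copula;
* label-linked categorical triage variables and signal phrases embedded in
  noisy free text — with false signals in negatives, negation wrappers
  ("denies ..."), and superficial misspellings (adjacent-character
  transpositions) so that literal substring matching is imperfect in both
  directions.

Everything is driven by one :class:`numpy.random.Generator`; identical seed
and config give a byte-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

from .records import DIAGNOSTIC_GROUPS, Month, PresentationRecord

_PREV_FLOOR = 1e-6
_PREV_CEIL = 0.5

# ---------------------------------------------------------------------------
# Default feature schema.  The study's variable/value lists are not public,
# so this vocabulary is invented; it is documented as such in docs/methods.md
# and is fully overridable through CohortConfig.
# ---------------------------------------------------------------------------

DEFAULT_VARIABLES: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = {
    "presenting_complaint": (
        ("injury", "medical", "mental_health", "intoxication", "pain", "other"),
        (0.25, 0.30, 0.04, 0.05, 0.26, 0.10),
    ),
    "arrival_mode": (
        ("walk_in", "ambulance", "police", "referral"),
        (0.55, 0.30, 0.05, 0.10),
    ),
    "triage_category": (
        ("1", "2", "3", "4", "5"),
        (0.02, 0.10, 0.35, 0.40, 0.13),
    ),
}

#: For each group: (variable, value, probability the value is forced when
#: the label is positive).
DEFAULT_VARIABLE_BIASES: dict[str, tuple[tuple[str, str, float], ...]] = {
    "suicidality": (
        ("presenting_complaint", "mental_health", 0.70),
        ("triage_category", "2", 0.40),
    ),
    "eating_disorder": (("presenting_complaint", "mental_health", 0.50),),
    "mania": (("presenting_complaint", "mental_health", 0.60),),
    "psychosis": (
        ("presenting_complaint", "mental_health", 0.60),
        ("arrival_mode", "police", 0.30),
    ),
    "substance_use": (
        ("presenting_complaint", "intoxication", 0.60),
        ("arrival_mode", "ambulance", 0.50),
    ),
}

DEFAULT_LEXICONS: dict[str, tuple[str, ...]] = {
    "suicidality": (
        "suicidal ideation",
        "attempted to end her life",
        "self harm by cutting",
        "took tablets with intent",
        "wants to die",
    ),
    "eating_disorder": (
        "restrictive eating",
        "diagnosed anorexia nervosa",
        "binge purge cycle",
        "severe food restriction",
    ),
    "mania": (
        "manic episode",
        "elevated and grandiose mood",
        "not slept for four days",
        "pressured speech",
    ),
    "psychosis": (
        "hearing voices",
        "paranoid delusions",
        "responding to unseen stimuli",
        "acute psychotic symptoms",
    ),
    "substance_use": (
        "acute alcohol intoxication",
        "methamphetamine use today",
        "heroin overdose accidental",
        "intoxicated on arrival",
    ),
}

DEFAULT_BACKGROUND_PHRASES: tuple[str, ...] = (
    "bib qps after disturbance in public",
    "chest pain on exertion",
    "laceration to left hand",
    "abdominal pain since this morning",
    "fall from ladder at home",
    "fever and productive cough",
    "ankle injury playing football",
    "headache and nausea",
    "shortness of breath overnight",
    "back pain after lifting",
    "allergic reaction to unknown agent",
    "mhx asthma on regular inhaler",
)


@dataclass(frozen=True)
class TrajectoryParams:
    """Monthly true-prevalence trajectory for one diagnostic group.

    ``prevalence(month) = baseline * (1 + trend * month_index)
    * seasonal_peak  (if the calendar month is in peak_months)
    * troughs[(y, m)]  (if that month is a trough)``,
    clamped to ``(1e-6, 0.5)``.

    ``baseline = 0`` is allowed as a degenerate override (the trajectory is
    identically zero, no clamping); generating a cohort in which *every*
    group is degenerate requires an explicit opt-in.
    """

    baseline: float
    trend: float = 0.0
    seasonal_peak: float = 1.0
    peak_months: frozenset[int] = frozenset({11, 12, 1})
    troughs: Mapping[Month, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline < 1.0:
            raise ValueError(f"baseline must be in [0, 1): {self.baseline}")
        if self.seasonal_peak < 1.0:
            raise ValueError("seasonal_peak must be >= 1")
        for m, mult in self.troughs.items():
            if not 0.0 < mult <= 1.0:
                raise ValueError(f"trough multiplier out of (0, 1]: {m} -> {mult}")
        object.__setattr__(self, "peak_months", frozenset(self.peak_months))
        object.__setattr__(self, "troughs", dict(self.troughs))


def prevalence_at(params: TrajectoryParams, month_index: int, month_tag: Month) -> float:
    """True prevalence for one month of a trajectory (deterministic)."""
    if month_index < 0:
        raise ValueError("month_index must be >= 0")
    if params.baseline == 0.0:
        return 0.0
    p = params.baseline * (1.0 + params.trend * month_index)
    if month_tag[1] in params.peak_months:
        p *= params.seasonal_peak
    mult = params.troughs.get(tuple(month_tag))
    if mult is not None:
        p *= mult
    return float(min(max(p, _PREV_FLOOR), _PREV_CEIL))


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort.

    Noise rates: ``false_signal_rate`` is the probability a *negative*
    record still contains a randomly chosen group phrase;
    ``negation_rate`` is the probability such a false signal is wrapped in
    a negation template ("denies ..."); ``misspelling_rate`` is the
    per-embedded-phrase probability of one adjacent-character
    transposition.  ``label_correlations`` maps group pairs to
    latent-normal (Gaussian copula) correlations.
    """

    months: tuple[Month, ...]
    monthly_volume: float = 5000.0
    trajectories: Mapping[str, TrajectoryParams] = field(default_factory=dict)
    lexicons: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_LEXICONS)
    )
    background_phrases: Sequence[str] = DEFAULT_BACKGROUND_PHRASES
    variables: Mapping[str, tuple[tuple[str, ...], tuple[float, ...]]] = field(
        default_factory=lambda: dict(DEFAULT_VARIABLES)
    )
    variable_biases: Mapping[str, Sequence[tuple[str, str, float]]] = field(
        default_factory=lambda: dict(DEFAULT_VARIABLE_BIASES)
    )
    false_signal_rate: float = 0.01
    negation_rate: float = 0.30
    misspelling_rate: float = 0.05
    label_correlations: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {("suicidality", "substance_use"): 0.3}
    )
    partial_month_fraction: tuple[float, float] = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.months:
            raise ValueError("months must be non-empty")
        object.__setattr__(self, "months", tuple((int(y), int(m)) for y, m in self.months))
        if self.monthly_volume <= 0:
            raise ValueError("monthly_volume must be positive")
        missing = set(DIAGNOSTIC_GROUPS) - set(self.trajectories)
        if missing:
            raise ValueError(f"trajectories missing groups: {sorted(missing)}")
        for rate, name in (
            (self.false_signal_rate, "false_signal_rate"),
            (self.negation_rate, "negation_rate"),
            (self.misspelling_rate, "misspelling_rate"),
        ):
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must be in [0, 1): {rate}")
        for frac in self.partial_month_fraction:
            if not 0.0 < frac <= 1.0:
                raise ValueError("partial_month_fraction entries must be in (0, 1]")
        for g in DIAGNOSTIC_GROUPS:
            if not self.lexicons.get(g):
                raise ValueError(f"lexicon for {g!r} must be non-empty")
        for (g1, g2), rho in self.label_correlations.items():
            if g1 not in DIAGNOSTIC_GROUPS or g2 not in DIAGNOSTIC_GROUPS or g1 == g2:
                raise ValueError(f"bad correlation pair {(g1, g2)!r}")
            if not -0.99 <= rho <= 0.99:
                raise ValueError(f"correlation out of range: {rho}")


def study_shaped_config(seed: int = 0, monthly_volume: float = 5000.0) -> CohortConfig:
    """A cohort config shaped like the motivating surveillance setting.

    Thirty-five months (April 2019 – February 2022) with incomplete first
    and last months, per-group baselines at the low prevalences typical of
    mental-health ED surveillance, a gentle upward trend, end-of-year
    seasonal peaks, and lockdown-style troughs in April 2020, April 2021
    and August 2021.
    """
    from .records import month_range

    troughs = {(2020, 4): 0.7, (2021, 4): 0.75, (2021, 8): 0.8}
    baselines = {
        "suicidality": 0.029,
        "eating_disorder": 0.0011,
        "mania": 0.0009,
        "psychosis": 0.014,
        "substance_use": 0.027,
    }
    trajectories = {
        g: TrajectoryParams(
            baseline=b, trend=0.002, seasonal_peak=1.15, troughs=troughs
        )
        for g, b in baselines.items()
    }
    return CohortConfig(
        months=tuple(month_range((2019, 4), (2022, 2))),
        monthly_volume=monthly_volume,
        trajectories=trajectories,
        partial_month_fraction=(0.5, 0.5),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _correlation_matrix(config: CohortConfig) -> np.ndarray:
    k = len(DIAGNOSTIC_GROUPS)
    idx = {g: i for i, g in enumerate(DIAGNOSTIC_GROUPS)}
    corr = np.eye(k)
    for (g1, g2), rho in config.label_correlations.items():
        corr[idx[g1], idx[g2]] = corr[idx[g2], idx[g1]] = rho
    # Clip eigenvalues if the user-specified pairwise entries are jointly
    # infeasible, then restore unit diagonal.
    w, v = np.linalg.eigh(corr)
    if w.min() < 1e-10:
        w = np.clip(w, 1e-10, None)
        corr = (v * w) @ v.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
    return corr


def _transpose_chars(phrase: str, u: float) -> str:
    """One adjacent-character transposition at a u-selected position."""
    if len(phrase) < 2:
        return phrase
    i = min(int(u * (len(phrase) - 1)), len(phrase) - 2)
    return phrase[:i] + phrase[i + 1] + phrase[i] + phrase[i + 2 :]


def generate_cohort(
    config: CohortConfig, allow_degenerate: bool = False
) -> list[PresentationRecord]:
    """Generate a labelled synthetic cohort.

    Raises :class:`ValueError` if every group's trajectory is identically
    zero (useless training data), unless ``allow_degenerate`` is set.
    """
    groups = DIAGNOSTIC_GROUPS
    n_groups = len(groups)
    prev = np.array(
        [
            [prevalence_at(config.trajectories[g], i, m) for g in groups]
            for i, m in enumerate(config.months)
        ]
    )
    if prev.max() <= 0.0 and not allow_degenerate:
        raise ValueError(
            "all trajectories are identically zero; pass allow_degenerate=True "
            "if this is intentional"
        )

    rng = np.random.default_rng(config.seed)
    chol = np.linalg.cholesky(_correlation_matrix(config))
    # threshold on the latent normal scale; prevalence 0 -> -inf, never fires
    with np.errstate(divide="ignore"):
        z_thresh = stats.norm.ppf(prev)

    lexicons = [list(config.lexicons[g]) for g in groups]
    background = list(config.background_phrases)
    n_bg_pool = len(background)
    # sorted so generation is invariant to mapping insertion order
    var_names = sorted(config.variables)
    biases = {
        g: list(config.variable_biases.get(g, ())) for g in groups
    }

    records: list[PresentationRecord] = []
    counter = 0
    last = len(config.months) - 1
    for mi, month in enumerate(config.months):
        vol = config.monthly_volume
        if mi == 0:
            vol *= config.partial_month_fraction[0]
        if mi == last:
            vol *= config.partial_month_fraction[1]
        n = int(rng.poisson(vol))
        if n == 0:
            continue

        z = rng.standard_normal((n, n_groups)) @ chol.T
        labels = z < z_thresh[mi]  # (n, 5) bool

        # categorical variables: base draw, then label-linked biasing
        var_values: dict[str, np.ndarray] = {}
        for name in var_names:
            values, probs = config.variables[name]
            idx = rng.choice(len(values), size=n, p=np.asarray(probs) / np.sum(probs))
            var_values[name] = idx
        for gi, g in enumerate(groups):
            pos = labels[:, gi]
            for var, value, bias in biases[g]:
                values, _ = config.variables[var]
                vi = values.index(value)
                hit = pos & (rng.random(n) < bias)
                var_values[var][hit] = vi

        # pre-drawn randomness for text assembly
        n_bg = rng.integers(2, 7, size=n)
        bg_idx = rng.integers(0, n_bg_pool, size=(n, 6))
        sig_idx = rng.integers(0, 2**31 - 1, size=(n, n_groups))
        fs_coin = rng.random(n)
        fs_group = rng.integers(0, n_groups, size=n)
        fs_phrase = rng.integers(0, 2**31 - 1, size=n)
        neg_coin = rng.random(n)
        miss_coin = rng.random((n, n_groups + 1))
        miss_pos = rng.random((n, n_groups + 1))
        order_keys = rng.random((n, 6 + n_groups + 1))

        for i in range(n):
            phrases: list[tuple[float, str]] = []
            for j in range(n_bg[i]):
                phrases.append((order_keys[i, j], background[bg_idx[i, j]]))
            slot = 6
            for gi in range(n_groups):
                if labels[i, gi]:
                    lex = lexicons[gi]
                    phrase = lex[sig_idx[i, gi] % len(lex)]
                    if miss_coin[i, gi] < config.misspelling_rate:
                        phrase = _transpose_chars(phrase, miss_pos[i, gi])
                    phrases.append((order_keys[i, slot], phrase))
                slot += 1
            if not labels[i].any() and fs_coin[i] < config.false_signal_rate:
                lex = lexicons[fs_group[i]]
                phrase = lex[fs_phrase[i] % len(lex)]
                if miss_coin[i, n_groups] < config.misspelling_rate:
                    phrase = _transpose_chars(phrase, miss_pos[i, n_groups])
                if neg_coin[i] < config.negation_rate:
                    phrase = f"denies {phrase}"
                phrases.append((order_keys[i, 6 + n_groups], phrase))

            phrases.sort(key=lambda t: t[0])
            text = ". ".join(p.capitalize() for _, p in phrases)

            records.append(
                PresentationRecord(
                    record_id=f"r{counter:07d}",
                    month=month,
                    variables={
                        name: config.variables[name][0][var_values[name][i]]
                        for name in var_names
                    },
                    triage_text=text,
                    labels={g: int(labels[i, gi]) for gi, g in enumerate(groups)},
                )
            )
            counter += 1
    return records


# ---------------------------------------------------------------------------
# Config (de)serialization
# ---------------------------------------------------------------------------


def config_to_dict(config: CohortConfig) -> dict:
    return {
        "months": [list(m) for m in config.months],
        "monthly_volume": config.monthly_volume,
        "trajectories": {
            g: {
                "baseline": t.baseline,
                "trend": t.trend,
                "seasonal_peak": t.seasonal_peak,
                "peak_months": sorted(t.peak_months),
                "troughs": {f"{y}-{m:02d}": v for (y, m), v in t.troughs.items()},
            }
            for g, t in config.trajectories.items()
        },
        "lexicons": {g: list(v) for g, v in config.lexicons.items()},
        "background_phrases": list(config.background_phrases),
        "variables": {
            name: {"values": list(vals), "probs": list(probs)}
            for name, (vals, probs) in config.variables.items()
        },
        "variable_biases": {
            g: [list(b) for b in bs] for g, bs in config.variable_biases.items()
        },
        "false_signal_rate": config.false_signal_rate,
        "negation_rate": config.negation_rate,
        "misspelling_rate": config.misspelling_rate,
        "label_correlations": {
            f"{g1}|{g2}": rho for (g1, g2), rho in config.label_correlations.items()
        },
        "partial_month_fraction": list(config.partial_month_fraction),
        "seed": config.seed,
    }


def config_from_dict(d: dict) -> CohortConfig:
    def parse_month_key(key: str) -> Month:
        y, m = key.split("-")
        return (int(y), int(m))

    trajectories = {
        g: TrajectoryParams(
            baseline=t["baseline"],
            trend=t.get("trend", 0.0),
            seasonal_peak=t.get("seasonal_peak", 1.0),
            peak_months=frozenset(t.get("peak_months", (11, 12, 1))),
            troughs={parse_month_key(k): v for k, v in t.get("troughs", {}).items()},
        )
        for g, t in d["trajectories"].items()
    }
    kwargs: dict = {
        "months": tuple(tuple(m) for m in d["months"]),
        "trajectories": trajectories,
        "seed": d.get("seed", 0),
    }
    if "variables" in d:
        kwargs["variables"] = {
            name: (tuple(v["values"]), tuple(v["probs"]))
            for name, v in d["variables"].items()
        }
    if "variable_biases" in d:
        kwargs["variable_biases"] = {
            g: tuple(tuple(b) for b in bs) for g, bs in d["variable_biases"].items()
        }
    if "label_correlations" in d:
        kwargs["label_correlations"] = {
            tuple(k.split("|")): v for k, v in d["label_correlations"].items()
        }
    for key in (
        "monthly_volume",
        "lexicons",
        "background_phrases",
        "false_signal_rate",
        "negation_rate",
        "misspelling_rate",
    ):
        if key in d:
            kwargs[key] = d[key]
    if "partial_month_fraction" in d:
        kwargs["partial_month_fraction"] = tuple(d["partial_month_fraction"])
    return CohortConfig(**kwargs)


def save_config(config: CohortConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def load_config(path) -> CohortConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def with_seed(config: CohortConfig, seed: int) -> CohortConfig:
    """Copy of the config with a different seed."""
    return replace(config, seed=seed)
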