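"""Binary feature extraction and additive scorecard scoring.

A scorecard classifier for one diagnostic group is a list of
``(FeaturePattern, weight)`` entries plus a decision threshold θ.  A
pattern is either an exact categorical-variable value or a literal,
case-insensitive substring of the (whitespace-normalized) triage note —
no regular-expression syntax is exposed, so the clinician-chosen feature
list stays auditable.  The record's score is the sum of the weights of
the patterns that fire, and the record is classified positive iff
``score >= θ`` (ties at the threshold are positive; the convention is
fixed so that evaluation and deployment agree).

Text matching is deliberately literal: no stemming and no negation
handling, so superficially different but semantically equivalent strings
are distinct patterns.  This mirrors how keyword scorecards behave on
real triage notes and is the reason downstream prevalence estimates must
be corrected for misclassification.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .records import PresentationRecord

_WS = re.compile(r"\s+")


class PatternConfigError(KeyError):
    """A pattern references a variable absent from the record schema."""


def normalize_text(text: str) -> str:
    """Lowercase and collapse runs of whitespace to single spaces."""
    return _WS.sub(" ", text.lower()).strip()


@dataclass(frozen=True)
class FeaturePattern:
    """One binary feature.

    ``kind`` is ``"categorical"`` (exact match of ``variable`` against
    ``match_value``) or ``"text"`` (case-insensitive literal substring of
    the normalized triage note).  ``pattern_id`` must be unique within a
    model.
    """

    kind: str
    match_value: str
    variable: str | None = None
    pattern_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "text"):
            raise ValueError(f"unknown pattern kind: {self.kind!r}")
        if not self.match_value:
            raise ValueError("match_value must be non-empty")
        if self.kind == "categorical" and not self.variable:
            raise ValueError("categorical pattern requires a variable name")
        if self.pattern_id is None:
            pid = (
                f"text:{normalize_text(self.match_value)}"
                if self.kind == "text"
                else f"cat:{self.variable}={self.match_value}"
            )
            object.__setattr__(self, "pattern_id", pid)

    def fires(self, record: PresentationRecord) -> bool:
        if self.kind == "categorical":
            if self.variable not in record.variables:
                raise PatternConfigError(
                    f"pattern {self.pattern_id!r} references unknown variable "
                    f"{self.variable!r}"
                )
            return record.variables[self.variable] == self.match_value
        return normalize_text(self.match_value) in normalize_text(record.triage_text)


def _check_unique_ids(patterns: Sequence[FeaturePattern]) -> None:
    ids = [p.pattern_id for p in patterns]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate pattern ids: {dupes}")


def extract_features(
    record: PresentationRecord, patterns: Sequence[FeaturePattern]
) -> np.ndarray:
    """Binary vector (len(patterns),) — 1 where the pattern fires."""
    _check_unique_ids(patterns)
    return np.array([p.fires(record) for p in patterns], dtype=np.uint8)


def design_matrix(
    records: Sequence[PresentationRecord], patterns: Sequence[FeaturePattern]
) -> np.ndarray:
    """Stack feature vectors for many records into an (n, p) uint8 matrix."""
    _check_unique_ids(patterns)
    out = np.zeros((len(records), len(patterns)), dtype=np.uint8)
    # text patterns dominate the cost; normalize each note once
    norm_texts = [normalize_text(r.triage_text) for r in records]
    for j, p in enumerate(patterns):
        if p.kind == "categorical":
            out[:, j] = [
                p.fires(r) for r in records
            ]
        else:
            needle = normalize_text(p.match_value)
            out[:, j] = [needle in t for t in norm_texts]
    return out


@dataclass(frozen=True)
class ScoringModel:
    """Additive scorecard for one diagnostic group."""

    group: str
    entries: tuple[tuple[FeaturePattern, float], ...]
    threshold: float

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("entries must be non-empty")
        object.__setattr__(self, "entries", tuple(self.entries))
        for pat, w in self.entries:
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"weight must be finite and >= 0: {pat.pattern_id}={w}")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        _check_unique_ids([p for p, _ in self.entries])

    @property
    def patterns(self) -> tuple[FeaturePattern, ...]:
        return tuple(p for p, _ in self.entries)

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.entries], dtype=float)


def score(record: PresentationRecord, model: ScoringModel) -> float:
    """Sum of weights over fired patterns (order-independent)."""
    fired = extract_features(record, model.patterns)
    return float(fired @ model.weights)


def classify(record: PresentationRecord, model: ScoringModel) -> int:
    """1 iff score(record) >= threshold."""
    return int(score(record, model) >= model.threshold)


def score_many(
    records: Sequence[PresentationRecord], model: ScoringModel
) -> np.ndarray:
    return design_matrix(records, model.patterns) @ model.weights


def classify_many(
    records: Sequence[PresentationRecord], model: ScoringModel
) -> np.ndarray:
    return (score_many(records, model) >= model.threshold).astype(np.uint8)


# ---------------------------------------------------------------------------
# JSON round trip
# ---------------------------------------------------------------------------


def model_to_dict(model: ScoringModel) -> dict:
    return {
        "group": model.group,
        "entries": [
            {
                "kind": p.kind,
                "variable": p.variable,
                "match_value": p.match_value,
                "pattern_id": p.pattern_id,
                "weight": w,
            }
            for p, w in model.entries
        ],
        "threshold": model.threshold,
    }


def model_from_dict(d: dict) -> ScoringModel:
    entries = tuple(
        (
            FeaturePattern(
                kind=e["kind"],
                variable=e.get("variable"),
                match_value=e["match_value"],
                pattern_id=e.get("pattern_id"),
            ),
            float(e["weight"]),
        )
        for e in d["entries"]
    )
    return ScoringModel(group=d["group"], entries=entries, threshold=float(d["threshold"]))


def save_model(model: ScoringModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=2, sort_keys=True)


def load_model(path) -> ScoringModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))


def default_patterns(
    group: str,
    lexicons=None,
    variable_biases=None,
) -> list[FeaturePattern]:
    """Candidate feature list for one group from a cohort's schema.

    Text patterns from the group's signal lexicon plus categorical patterns
    for its label-linked variable values — the feature pool the genetic
    algorithm weights.
    """
    from .cohort import DEFAULT_LEXICONS, DEFAULT_VARIABLE_BIASES

    lexicons = lexicons or DEFAULT_LEXICONS
    variable_biases = variable_biases or DEFAULT_VARIABLE_BIASES
    patterns = [FeaturePattern(kind="text", match_value=s) for s in lexicons[group]]
    for var, value, _bias in variable_biases.get(group, ()):
        patterns.append(
            FeaturePattern(kind="categorical", variable=var, match_value=value)
        )
    return patterns
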