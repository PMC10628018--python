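"""Presentation records and tabular serialization.

A *presentation* is a single patient encounter with an emergency department
(ED).  Each record carries a calendar month, a small set of categorical
triage variables, the free-text triage note written by the intake nurse,
and — for labelled (training/synthetic) data — one 0/1 ground-truth label
per diagnostic group.  The five diagnostic groups are not mutually
exclusive: a presentation may be positive for any subset of them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: The five mental-health diagnostic groups, in canonical order.
DIAGNOSTIC_GROUPS: tuple[str, ...] = (
    "suicidality",
    "eating_disorder",
    "mania",
    "psychosis",
    "substance_use",
)

Month = tuple[int, int]  # (year, month)


def _check_month(month: Month) -> Month:
    year, m = int(month[0]), int(month[1])
    if not 1 <= m <= 12:
        raise ValueError(f"month out of range: {month!r}")
    return (year, m)


@dataclass(frozen=True)
class PresentationRecord:
    """One ED presentation.

    Parameters
    ----------
    record_id:
        Unique identifier within a cohort.
    month:
        Calendar month as ``(year, month)``.
    variables:
        Mapping of categorical variable name to its value.
    triage_text:
        Unstructured triage note.
    labels:
        Optional ground-truth 0/1 labels, one per diagnostic group.  When
        present they must cover all groups in :data:`DIAGNOSTIC_GROUPS`.
    """

    record_id: str
    month: Month
    variables: Mapping[str, str]
    triage_text: str
    labels: Mapping[str, int] | None = field(default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "month", _check_month(self.month))
        if self.labels is not None:
            missing = set(DIAGNOSTIC_GROUPS) - set(self.labels)
            if missing:
                raise ValueError(f"labels missing groups: {sorted(missing)}")
            bad = {g: v for g, v in self.labels.items() if v not in (0, 1)}
            if bad:
                raise ValueError(f"labels must be 0/1, got {bad}")


def records_to_frame(records: Sequence[PresentationRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame (one row per presentation).

    Columns: ``record_id``, ``year``, ``month``, one column per categorical
    variable, ``triage_text``, and — if labels are present — one
    ``label_<group>`` column per diagnostic group.
    """
    if not records:
        raise ValueError("no records to serialize")
    rows = []
    for r in records:
        row: dict[str, object] = {
            "record_id": r.record_id,
            "year": r.month[0],
            "month": r.month[1],
        }
        row.update(r.variables)
        row["triage_text"] = r.triage_text
        if r.labels is not None:
            for g in DIAGNOSTIC_GROUPS:
                row[f"label_{g}"] = int(r.labels[g])
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[PresentationRecord]:
    """Inverse of :func:`records_to_frame`."""
    label_cols = [c for c in frame.columns if c.startswith("label_")]
    reserved = {"record_id", "year", "month", "triage_text", *label_cols}
    var_cols = [c for c in frame.columns if c not in reserved]
    out = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        labels = (
            {c[len("label_"):]: int(d[c]) for c in label_cols} if label_cols else None
        )
        out.append(
            PresentationRecord(
                record_id=str(d["record_id"]),
                month=(int(d["year"]), int(d["month"])),
                variables={c: str(d[c]) for c in var_cols},
                triage_text=str(d["triage_text"]),
                labels=labels,
            )
        )
    return out


def write_cohort_csv(records: Sequence[PresentationRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_cohort_csv(path) -> list[PresentationRecord]:
    return frame_to_records(pd.read_csv(path, dtype={"record_id": str}))


def write_cohort_jsonl(records: Sequence[PresentationRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                json.dumps(
                    {
                        "record_id": r.record_id,
                        "year": r.month[0],
                        "month": r.month[1],
                        "variables": dict(r.variables),
                        "triage_text": r.triage_text,
                        "labels": dict(r.labels) if r.labels is not None else None,
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def read_cohort_jsonl(path) -> list[PresentationRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            out.append(
                PresentationRecord(
                    record_id=d["record_id"],
                    month=(d["year"], d["month"]),
                    variables=d["variables"],
                    triage_text=d["triage_text"],
                    labels=d["labels"],
                )
            )
    return out


def month_range(start: Month, end: Month) -> list[Month]:
    """Inclusive list of consecutive calendar months from start to end."""
    start = _check_month(start)
    end = _check_month(end)
    months = []
    y, m = start
    while (y, m) <= end:
        months.append((y, m))
        m += 1
        if m == 13:
            y, m = y + 1, 1
    if not months:
        raise ValueError(f"empty month range {start}..{end}")
    return months
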