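"""Synthetic cohort generator: trajectories, labels, text and serialization."""

import io

import numpy as np
import pytest
from scipy import stats

import edscreen as es
from edscreen.cohort import DEFAULT_LEXICONS
from edscreen.features import normalize_text

from conftest import flat_trajectories


def test_prevalence_at_products():
    flat = es.TrajectoryParams(baseline=0.03, seasonal_peak=1.0)
    assert es.prevalence_at(flat, 5, (2021, 6)) == pytest.approx(0.03)

    trough = es.TrajectoryParams(
        baseline=0.03, seasonal_peak=1.0, troughs={(2021, 6): 0.5}
    )
    assert es.prevalence_at(trough, 5, (2021, 6)) == pytest.approx(0.015)
    assert es.prevalence_at(trough, 5, (2021, 7)) == pytest.approx(0.03)

    # trend + seasonal peak: recompute the product by hand
    params = es.TrajectoryParams(
        baseline=0.001, trend=0.01, seasonal_peak=1.3, peak_months=frozenset({12})
    )
    expect = 0.001 * (1 + 0.01 * 24) * 1.3
    assert es.prevalence_at(params, 24, (2021, 12)) == pytest.approx(expect)
    assert es.prevalence_at(params, 24, (2021, 11)) == pytest.approx(expect / 1.3)


def test_prevalence_clamped_to_valid_range():
    params = es.TrajectoryParams(baseline=0.4, seasonal_peak=2.0)
    assert es.prevalence_at(params, 0, (2021, 12)) == 0.5
    shrinking = es.TrajectoryParams(baseline=0.01, trend=-0.2)
    assert es.prevalence_at(shrinking, 100, (2021, 3)) == pytest.approx(1e-6)


def _config(**kwargs):
    base = dict(
        months=tuple(es.month_range((2021, 1), (2021, 4))),
        monthly_volume=500,
        trajectories=flat_trajectories(),
        seed=1,
    )
    base.update(kwargs)
    return es.CohortConfig(**base)


def test_zero_prevalence_cohort_has_no_labels_or_signals():
    config = _config(
        trajectories={
            g: es.TrajectoryParams(baseline=0.0) for g in es.DIAGNOSTIC_GROUPS
        },
        false_signal_rate=0.0,  # decoy phrases off: negatives must stay clean
    )
    with pytest.raises(ValueError):
        es.generate_cohort(config)
    records = es.generate_cohort(config, allow_degenerate=True)
    assert records
    phrases = [p for lex in DEFAULT_LEXICONS.values() for p in lex]
    for r in records:
        assert all(v == 0 for v in r.labels.values())
        text = normalize_text(r.triage_text)
        assert not any(p in text for p in phrases)


def test_same_seed_gives_byte_identical_cohort():
    config = _config()
    r1 = es.generate_cohort(config)
    r2 = es.generate_cohort(config)
    buf1, buf2 = io.StringIO(), io.StringIO()
    es.records_to_frame(r1).to_csv(buf1)
    es.records_to_frame(r2).to_csv(buf2)
    assert buf1.getvalue() == buf2.getvalue()
    r3 = es.generate_cohort(es.cohort.with_seed(config, 2))
    assert es.records_to_frame(r3).to_csv() != buf1.getvalue()


def test_monthly_label_frequency_matches_trajectory():
    """Empirical per-month prevalence sits in the exact binomial 99% band
    of the configured trajectory in >= 95% of months across seeds."""
    months = tuple(es.month_range((2021, 1), (2021, 12)))
    inside = total = 0
    for seed in (0, 1, 2):
        config = es.CohortConfig(
            months=months,
            monthly_volume=5000,
            trajectories=flat_trajectories(),
            label_correlations={},
            seed=seed,
        )
        records = es.generate_cohort(config)
        month_of = np.array([months.index(r.month) for r in records])
        for g in ("suicidality", "psychosis", "substance_use"):
            p = config.trajectories[g].baseline
            lab = np.array([r.labels[g] for r in records])
            for mi in range(len(months)):
                sel = month_of == mi
                n, x = int(sel.sum()), int(lab[sel].sum())
                lo = stats.binom.ppf(0.005, n, p)
                hi = stats.binom.ppf(0.995, n, p)
                inside += lo <= x <= hi
                total += 1
    assert inside / total >= 0.95


def test_noise_free_signals_imply_labels():
    """With all noise rates zero, a group's lexicon phrase appears in the
    note iff that record is labelled positive for the group."""
    config = _config(
        false_signal_rate=0.0, negation_rate=0.0, misspelling_rate=0.0,
        monthly_volume=2000,
    )
    records = es.generate_cohort(config)
    any_pos = 0
    for r in records:
        text = normalize_text(r.triage_text)
        for g in es.DIAGNOSTIC_GROUPS:
            hit = any(p in text for p in DEFAULT_LEXICONS[g])
            if hit:
                assert r.labels[g] == 1
            if r.labels[g] == 1:
                assert hit  # every positive embeds >= 1 phrase
                any_pos += 1
    assert any_pos > 0


def test_trough_lowers_positive_count():
    """Coupled comparison: same seed with and without a trough multiplier."""
    months = tuple(es.month_range((2021, 1), (2021, 3)))
    troughs = {(2021, 2): 0.5}
    kwargs = dict(months=months, monthly_volume=8000, seed=9)
    cfg_plain = es.CohortConfig(trajectories=flat_trajectories(), **kwargs)
    cfg_trough = es.CohortConfig(
        trajectories=flat_trajectories(troughs=troughs), **kwargs
    )

    def count(config):
        return sum(
            r.labels["suicidality"]
            for r in es.generate_cohort(config)
            if r.month == (2021, 2)
        )

    assert count(cfg_trough) < count(cfg_plain)


def test_label_correlation_raises_cooccurrence():
    kwargs = dict(
        months=((2021, 1),), monthly_volume=60000,
        trajectories=flat_trajectories(), seed=5,
    )
    rho0 = es.CohortConfig(label_correlations={}, **kwargs)
    rho7 = es.CohortConfig(
        label_correlations={("suicidality", "substance_use"): 0.7}, **kwargs
    )

    def joint(config):
        recs = es.generate_cohort(config)
        both = sum(
            r.labels["suicidality"] and r.labels["substance_use"] for r in recs
        )
        return both / len(recs)

    assert joint(rho7) > 2 * joint(rho0)


def test_config_yaml_roundtrip(tmp_path):
    config = _config(
        trajectories=flat_trajectories(troughs={(2021, 2): 0.7}),
        partial_month_fraction=(0.5, 1.0),
    )
    path = tmp_path / "cohort.yaml"
    es.save_config(config, path)
    loaded = es.load_config(path)
    assert es.generate_cohort(loaded) == es.generate_cohort(config)


def test_cohort_csv_and_jsonl_roundtrip(tmp_path, small_cohort):
    _, records = small_cohort
    sample = records[:200]
    es.write_cohort_csv(sample, tmp_path / "c.csv")
    assert es.read_cohort_csv(tmp_path / "c.csv") == sample
    es.write_cohort_jsonl(sample, tmp_path / "c.jsonl")
    assert es.read_cohort_jsonl(tmp_path / "c.jsonl") == sample


@pytest.mark.parametrize(
    "kwargs",
    [
        {"monthly_volume": 0},
        {"false_signal_rate": 1.0},
        {"negation_rate": -0.1},
        {"partial_month_fraction": (0.0, 1.0)},
        {"lexicons": {g: [] for g in es.DIAGNOSTIC_GROUPS}},
        {"label_correlations": {("suicidality", "suicidality"): 0.2}},
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ValueError):
        _config(**kwargs)


def test_partial_month_fractions_scale_first_and_last_months():
    config = _config(monthly_volume=4000, partial_month_fraction=(0.25, 0.5))
    records = es.generate_cohort(config)
    counts = {}
    for r in records:
        counts[r.month] = counts.get(r.month, 0) + 1
    months = config.months
    assert counts[months[0]] < 0.5 * counts[months[1]]
    assert counts[months[-1]] < 0.75 * counts[months[1]]
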