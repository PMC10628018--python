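import numpy as np
import pytest

import edscreen as es


def flat_trajectories(baselines=None, **kwargs):
    """Trajectories with no seasonality/trend unless overridden."""
    defaults = {
        "suicidality": 0.03,
        "eating_disorder": 0.004,
        "mania": 0.004,
        "psychosis": 0.015,
        "substance_use": 0.027,
    }
    baselines = baselines or defaults
    return {
        g: es.TrajectoryParams(baseline=b, seasonal_peak=1.0, **kwargs)
        for g, b in baselines.items()
    }


@pytest.fixture(scope="session")
def small_cohort():
    """Six months x ~800 presentations with default noise, fixed seed."""
    config = es.CohortConfig(
        months=tuple(es.month_range((2021, 1), (2021, 6))),
        monthly_volume=800,
        trajectories=flat_trajectories(),
        seed=42,
    )
    return config, es.generate_cohort(config)


@pytest.fixture(scope="session")
def suicidality_model(small_cohort):
    """A quickly trained suicidality scorecard reused across tests."""
    _, records = small_cohort
    patterns = es.default_patterns("suicidality")
    labels = np.array([r.labels["suicidality"] for r in records])
    clf = es.ScorecardClassifier(
        patterns=patterns, population_size=30, generations=20, random_state=11
    ).fit(records, labels)
    return clf.to_scoring_model("suicidality"), clf
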