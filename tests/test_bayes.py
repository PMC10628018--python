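"""Misclassification identity, beta elicitation, Gibbs posterior."""

import numpy as np
import pytest
from scipy import stats

import edscreen as es


# ---------------------------------------------------------------------------
# Crude/true identity
# ---------------------------------------------------------------------------


def test_perfect_test_reports_true_prevalence():
    assert es.crude_from_true(0.04, 1.0, 1.0) == pytest.approx(0.04)
    assert es.crude_from_true(0.0, 0.7, 1.0) == 0.0


def test_good_but_imperfect_test_inflates_rare_prevalence():
    crude = es.crude_from_true(0.04, 0.95, 0.95)
    assert crude == pytest.approx(0.086)
    assert round(crude, 2) == 0.09  # more than double the true 4%


def test_identity_is_affine_increasing_when_test_informative():
    grid = np.linspace(0, 1, 21)
    vals = [es.crude_from_true(p, 0.9, 0.85) for p in grid]
    diffs = np.diff(vals)
    assert (diffs > 0).all()
    assert np.allclose(diffs, diffs[0])  # affine
    assert es.crude_from_true(0.3, 1.0, 1.0) == pytest.approx(0.3)


def test_rogan_gladen_inverts_the_identity():
    p_c = es.crude_from_true(0.07, 0.9, 0.93)
    assert es.rogan_gladen(p_c, 0.9, 0.93) == pytest.approx(0.07)
    with pytest.raises(ValueError):
        es.rogan_gladen(0.1, 0.5, 0.5)


# ---------------------------------------------------------------------------
# Beta elicitation
# ---------------------------------------------------------------------------


def test_uniform_distribution_identity():
    prior = es.elicit_beta(
        central=0.5, percentile_value=0.95, percentile_level=0.95,
        central_kind="mean",
    )
    assert prior.a == pytest.approx(1.0, abs=1e-6)
    assert prior.b == pytest.approx(1.0, abs=1e-6)


@pytest.mark.parametrize("central_kind", ["mean", "mode"])
@pytest.mark.parametrize(
    "central,pv,pl",
    [
        (0.029, 0.031, 0.95),
        (0.1, 0.2, 0.9),
        (0.95, 0.9, 0.05),
        (0.5, 0.8, 0.99),
    ],
)
def test_elicitation_plugs_back_into_both_equations(central, pv, pl, central_kind):
    prior = es.elicit_beta(
        central=central, percentile_value=pv, percentile_level=pl,
        central_kind=central_kind,
    )
    assert stats.beta.cdf(pv, prior.a, prior.b) == pytest.approx(pl, abs=1e-6)
    if central_kind == "mean":
        assert prior.mean == pytest.approx(central, abs=1e-8)
    else:
        assert prior.mode == pytest.approx(central, abs=1e-8)


def test_elicitation_recovers_prior_from_its_own_moments():
    """Ill-conditioning check: a worked pair (a=828.7, b=27485.7) is
    recovered exactly when the inputs are its own (unrounded) mean and
    95th percentile — input rounding, not the solver, is what moves
    hyperparameters by large factors."""
    a, b = 828.7, 27485.7
    mean = a / (a + b)
    q95 = float(stats.beta.ppf(0.95, a, b))
    prior = es.elicit_beta(
        central=mean, percentile_value=q95, percentile_level=0.95,
        central_kind="mean",
    )
    assert prior.a == pytest.approx(a, rel=1e-3)
    assert prior.b == pytest.approx(b, rel=1e-3)


def test_inconsistent_percentile_raises():
    with pytest.raises(ValueError):
        es.elicit_beta(central=0.5, percentile_value=0.4, percentile_level=0.95)
    with pytest.raises(ValueError):
        es.ElicitationSpec(central=0.0, percentile_value=0.1)


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

POINT_MASS_ONE = es.BetaPrior(1e8, 1e-2)  # Se/Sp effectively pinned at 1


def tight_prior(center, rel=0.02, level=0.05):
    return es.elicit_beta(
        central=center, percentile_value=center * (1 - rel),
        percentile_level=level, central_kind="mode",
    )


def test_perfect_test_posterior_matches_conjugate_closed_form():
    t_p, n = 50, 1000
    est = es.gibbs_true_prevalence(
        es.PrevalenceModelInput(
            t_p=t_p, n=n,
            prior_pt=es.BetaPrior(1, 1),
            prior_se=POINT_MASS_ONE, prior_sp=POINT_MASS_ONE,
        ),
        es.GibbsConfig(iterations=15_000, burn_in=2_500, seed=21),
    )
    post = stats.beta(1 + t_p, 1 + n - t_p)
    assert est.median == pytest.approx(post.ppf(0.5), abs=0.002)
    assert est.lo == pytest.approx(post.ppf(0.025), abs=0.002)
    assert est.hi == pytest.approx(post.ppf(0.975), abs=0.002)


def test_chain_is_deterministic_and_seed_stable():
    inp = es.PrevalenceModelInput(
        t_p=95, n=2000,
        prior_pt=es.BetaPrior(1, 1),
        prior_se=tight_prior(0.95), prior_sp=tight_prior(0.95),
    )
    cfg = es.GibbsConfig(iterations=8_000, burn_in=1_000, seed=5)
    e1 = es.gibbs_true_prevalence(inp, cfg)
    e2 = es.gibbs_true_prevalence(inp, cfg)
    assert e1.median == e2.median and e1.lo == e2.lo and e1.hi == e2.hi
    e3 = es.gibbs_true_prevalence(
        inp, es.GibbsConfig(iterations=8_000, burn_in=1_000, seed=6)
    )
    assert e3.median == pytest.approx(e1.median, abs=0.004)


def test_posterior_median_monotone_in_observed_positives():
    prior_se, prior_sp = tight_prior(0.95), tight_prior(0.95)
    medians = []
    for t_p in (60, 120, 240, 480):
        est = es.gibbs_true_prevalence(
            es.PrevalenceModelInput(
                t_p=t_p, n=5000,
                prior_pt=es.BetaPrior(1, 1),
                prior_se=prior_se, prior_sp=prior_sp,
            ),
            es.GibbsConfig(iterations=6_000, burn_in=1_000, seed=9),
            keep_draws=False,
        )
        medians.append(est.median)
    assert (np.diff(medians) > -1e-3).all()
    assert medians[-1] > medians[0]


def test_draws_stay_in_unit_interval_and_interval_ordered():
    est = es.gibbs_true_prevalence(
        es.PrevalenceModelInput(
            t_p=0, n=500,
            prior_pt=es.BetaPrior(2, 50),
            prior_se=tight_prior(0.9), prior_sp=tight_prior(0.9),
        ),
        es.GibbsConfig(iterations=4_000, burn_in=500, seed=13),
    )
    p_t = est.draws["p_t"]
    assert ((p_t > 0) & (p_t < 1)).all()
    assert est.lo <= est.median <= est.hi
    # with zero observed positives the posterior sits below the prior centre
    assert est.median < es.BetaPrior(2, 50).mean


def test_posterior_tracks_rogan_gladen_for_large_samples():
    p_t_true, se, sp = 0.03, 0.95, 0.95
    p_c = es.crude_from_true(p_t_true, se, sp)
    n = 50_000
    t_p = int(round(p_c * n))
    est = es.gibbs_true_prevalence(
        es.PrevalenceModelInput(
            t_p=t_p, n=n,
            prior_pt=es.BetaPrior(1, 1),
            prior_se=tight_prior(se, rel=0.01),
            prior_sp=tight_prior(sp, rel=0.01),
        ),
        es.GibbsConfig(iterations=10_000, burn_in=2_000, seed=17),
        keep_draws=False,
    )
    rg = es.rogan_gladen(p_c, se, sp)
    assert est.median == pytest.approx(rg, rel=0.10)


def test_vectorized_chains_match_single_runs_distributionally():
    prior_pt = es.BetaPrior(1, 1)
    prior_se, prior_sp = tight_prior(0.92), tight_prior(0.97)
    cfg = es.GibbsConfig(iterations=8_000, burn_in=1_000, seed=31)
    multi = es.gibbs_chains(
        [100, 300], [4000, 4000], prior_pt, prior_se, prior_sp, cfg
    )["p_t"]
    for k, t_p in enumerate((100, 300)):
        single = es.gibbs_true_prevalence(
            es.PrevalenceModelInput(
                t_p=t_p, n=4000,
                prior_pt=prior_pt, prior_se=prior_se, prior_sp=prior_sp,
            ),
            es.GibbsConfig(iterations=8_000, burn_in=1_000, seed=77),
            keep_draws=False,
        )
        assert np.median(multi[:, k]) == pytest.approx(single.median, abs=0.005)


def test_priors_from_validation_center_on_observed_accuracy():
    priors = es.priors_from_validation(tp=190, fp=60, tn=2940, fn=10)
    assert priors["se"].mode == pytest.approx(0.95, abs=0.01)
    assert priors["sp"].mode == pytest.approx(0.98, abs=0.01)
    # P_T prior centres on the corrected, not crude, prevalence
    se_hat, sp_hat = 0.95, 0.98
    p_c = 250 / 3200
    rg = es.rogan_gladen(p_c, se_hat, sp_hat)
    assert priors["p_t"].mode == pytest.approx(rg, rel=0.05)
    # a perfect split still yields a proper prior concentrated near 1,
    # with its 5th percentile at the one-sided exact lower bound
    perfect = es.priors_from_validation(tp=50, fp=0, tn=500, fn=0)
    assert perfect["se"].mean > 0.95
    assert perfect["se"].quantile(0.05) == pytest.approx(0.05 ** (1 / 50), abs=1e-4)


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        es.PrevalenceModelInput(t_p=5, n=0)
    with pytest.raises(ValueError):
        es.PrevalenceModelInput(t_p=10, n=5)
    with pytest.raises(ValueError):
        es.GibbsConfig(iterations=100, burn_in=100)
    with pytest.raises(ValueError):
        es.BetaPrior(0.0, 1.0)
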