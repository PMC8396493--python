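"""Generator behaviour: validation, determinism, and convergence of realized
moments to the analytic expectations of the grid-rounded laws."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import binom, gamma

from cohortlife import (
    ConfigurationError,
    default_configs,
    demographic_params,
    expected_life_table,
    generate_cohort,
)


@pytest.mark.parametrize(
    "field, value",
    [
        ("n_eggs", 0),
        ("n_eggs", -3),
        ("n_trays", 0),
        ("stage_mean_durations", (1.0, 0.5, -1.0, 1.6)),
        ("stage_survival", (0.9, 1.2, 0.9, 0.9)),
        ("preoviposition_mean", 0.0),
        ("oviposition_mean", -1.0),
        ("proportion_female", 0.0),
        ("progeny_female_fraction", 1.5),
        ("stage_duration_cv", -0.1),
        ("daily_egg_mean", -2.0),
        ("egg_count_law", "binomial"),
        ("diet_label", ""),
    ],
)
def test_invalid_config_names_offending_field(small_config, field, value):
    bad = replace(small_config, **{field: value})
    with pytest.raises(ConfigurationError, match=field):
        bad.validate()


def test_deterministic_egg_law_requires_whole_mean(small_config):
    bad = replace(small_config, egg_count_law="deterministic", daily_egg_mean=1.4)
    with pytest.raises(ConfigurationError, match="daily_egg_mean"):
        bad.validate()


def test_zero_variance_cohort_is_degenerate(small_config):
    """With cv = 0 everywhere, full survival and all-female sexing, every
    individual carries the same transition ages and egg schedule."""
    cfg = replace(
        small_config,
        stage_duration_cv=0.0, adult_period_cv=0.0,
        stage_survival=(1.0, 1.0, 1.0, 1.0),
        proportion_female=1.0,
        daily_egg_mean=2.0, egg_count_law="deterministic",
    ).validate()
    recs = generate_cohort(cfg)
    assert len(recs) == cfg.n_eggs
    first = recs[0]
    for r in recs[1:]:
        assert r.transition_ages == first.transition_ages
        assert r.daily_eggs == first.daily_eggs
        assert r.adult_death_age == first.adult_death_age
        assert r.sex == "female"


def test_same_seed_reproduces_different_seed_varies(small_config):
    a = generate_cohort(small_config)
    b = generate_cohort(small_config)
    assert a == b
    c = generate_cohort(small_config.with_seed(small_config.seed + 1))
    assert c != a


def _expected_rounded_mean(mean, cv, step):
    """E[ceil-to-grid(Gamma(mean, cv))], by direct summation of the CDF."""
    if cv == 0:
        return step * max(1, math.ceil(mean / step - 1e-9))
    d = gamma(1 / cv**2, scale=mean * cv**2)
    kmax = int(math.ceil(d.ppf(1 - 1e-14) / step)) + 1
    # E[X] = sum_{k>=1} k*step * P(rounded = k*step) = step * sum_{k>=0} P(X > k*step)
    return step * sum(d.sf(k * step) for k in range(kmax))


def test_marginal_means_match_rounded_law(small_config):
    """At n = 2000, realized stage-duration means sit within 3 SE of the
    analytic mean of the rounded gamma law (rounding up to the half-day grid
    shifts the mean above the configured continuous mean)."""
    cfg = replace(small_config, n_eggs=2000, stage_survival=(1.0,) * 4)
    recs = generate_cohort(cfg)
    durs = np.array([
        [r.transition_ages[0],
         r.transition_ages[1] - r.transition_ages[0],
         r.transition_ages[2] - r.transition_ages[1],
         r.transition_ages[3] - r.transition_ages[2]]
        for r in recs
    ])
    for s in range(4):
        expect = _expected_rounded_mean(
            cfg.stage_mean_durations[s], cfg.stage_duration_cv, 0.5)
        se = durs[:, s].std(ddof=1) / math.sqrt(len(recs))
        assert abs(durs[:, s].mean() - expect) < 3 * se


def test_realized_stage_survival_within_binomial_ci(small_config):
    cfg = replace(small_config, n_eggs=2000)
    recs = generate_cohort(cfg)
    entered = [len(recs)] + [
        sum(len(r.transition_ages) >= s for r in recs) for s in range(1, 5)
    ]
    for s in range(4):
        lo, hi = binom(entered[s], cfg.stage_survival[s]).ppf([0.0025, 0.9975])
        assert lo <= entered[s + 1] <= hi


def test_poisson_egg_totals_match_mean(small_config):
    """Realized daily egg mean over oviposition days ≈ daily_egg_mean."""
    cfg = replace(small_config, n_eggs=2000, proportion_female=0.99)
    recs = generate_cohort(cfg)
    eggs, days = 0, 0
    for r in recs:
        if r.sex != "female":
            continue
        # oviposition window days are those between first and last possible
        # laying day; count every day with the window's Poisson draws
        eggs += r.total_eggs
    # expected eggs/female = mu * E[rounded oviposition period]
    n_f = sum(r.sex == "female" for r in recs)
    expect = cfg.daily_egg_mean * _expected_rounded_mean(
        cfg.oviposition_mean, cfg.adult_period_cv, 1.0)
    per_f = eggs / n_f
    assert abs(per_f - expect) / expect < 0.05


def test_expected_life_table_is_valid_and_consistent(small_config):
    lt = expected_life_table(small_config)
    assert lt.lx[0] == 1.0
    assert np.all(np.diff(lt.lx) <= 1e-12)
    assert np.all(lt.mx >= 0)
    p = demographic_params(lt)
    assert p.r0 > 1 and p.rm > 0


def test_large_cohort_recovers_expected_parameters(small_config):
    """The simulated cohort's R0 and rm converge to those of the analytic
    expected schedule."""
    from cohortlife import build_life_table

    cfg = replace(small_config, n_eggs=8000)
    lt = build_life_table(generate_cohort(cfg), cfg.progeny_female_fraction)
    p = demographic_params(lt)
    pe = demographic_params(expected_life_table(cfg))
    assert p.rm == pytest.approx(pe.rm, abs=0.003)
    assert p.r0 == pytest.approx(pe.r0, rel=0.05)


def test_default_experiment_shape():
    cfgs = default_configs(5)
    assert len(cfgs) == 3
    assert len({c.diet_label for c in cfgs}) == 3
    assert len({c.seed for c in cfgs}) == 3
    for c in cfgs:
        recs = generate_cohort(c)
        assert len(recs) == c.n_eggs
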