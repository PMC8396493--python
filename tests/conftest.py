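import pytest

from cohortlife import CohortConfig, IndividualRecord


def female(i, transitions, death_age, eggs, diet="test", tray="T01"):
    return IndividualRecord(
        individual_id=f"{diet}-{i}", diet_label=diet, tray_id=tray,
        transition_ages=tuple(transitions), died_in_stage="none", sex="female",
        adult_death_age=float(death_age), daily_eggs=tuple(eggs),
    ).validate()


def male(i, transitions, diet="test", tray="T01"):
    return IndividualRecord(
        individual_id=f"{diet}-{i}", diet_label=diet, tray_id=tray,
        transition_ages=tuple(transitions), died_in_stage="none", sex="male",
    ).validate()


def immature_death(i, transitions, stage, diet="test", tray="T01"):
    return IndividualRecord(
        individual_id=f"{diet}-{i}", diet_label=diet, tray_id=tray,
        transition_ages=tuple(transitions), died_in_stage=stage,
    ).validate()


@pytest.fixture
def two_female_cohort():
    """Two identical females: adult day 5, 4 eggs each on day 7, dead day 8."""
    eggs = (0, 0, 4)
    return [
        female(1, (1.0, 2.0, 3.0, 5.0), 8, eggs),
        female(2, (1.0, 2.0, 3.0, 5.0), 8, eggs),
    ]


@pytest.fixture
def mixed_cohort10():
    """10 records: 3 immature deaths, 2 males, 5 females (one never lays)."""
    return [
        immature_death(1, (), "egg"),
        immature_death(2, (1.5,), "larva"),
        immature_death(3, (1.5, 2.5, 4.0), "deutonymph"),
        male(4, (1.5, 2.0, 3.5, 5.0)),
        male(5, (2.0, 3.0, 4.5, 6.5)),
        female(6, (1.5, 2.5, 4.0, 5.5), 16, (0, 0, 2, 2, 2, 2, 2, 2, 0, 0)),
        female(7, (2.0, 2.5, 4.5, 6.0), 14, (0, 1, 1, 2, 0, 2, 1, 0)),
        female(8, (1.0, 2.0, 3.0, 4.0), 18, (0, 0, 0, 3, 3, 3, 3, 3, 0, 0, 0, 0, 0, 0)),
        female(9, (1.5, 3.0, 4.0, 6.5), 12, (2, 2, 1, 0, 0)),
        female(10, (1.5, 2.0, 3.0, 4.5), 9, (0, 0, 0, 0)),
    ]


@pytest.fixture
def small_config():
    """A valid small configuration for generator tests."""
    return CohortConfig(
        diet_label="test", n_eggs=30, n_trays=5,
        stage_mean_durations=(1.5, 0.7, 1.6, 1.6),
        stage_survival=(0.95, 0.95, 0.95, 0.98),
        preoviposition_mean=3.0, oviposition_mean=20.0, postoviposition_mean=2.0,
        daily_egg_mean=1.4, seed=42,
    ).validate()
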