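"""Age-specific survival and fecundity schedules.

A cohort life table pairs, on a whole-day age grid starting at egg
deposition, the age-specific survival rate ``lx`` (proportion of the initial
egg cohort alive at age x, with only females tracked after the final molt
under the assumption that immature survival is sex-independent) and the
age-specific fecundity rate ``mx`` (female eggs per living female per day).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError, InputError
from .records import IndividualRecord


@dataclass(frozen=True)
class LifeTable:
    """Paired lx/mx schedules for one diet cohort.

    ``ages`` is the whole-day grid x = 0, 1, 2, ... days since egg
    deposition; ``lx[0] == 1`` and ``lx`` is non-increasing; ``mx`` is zero
    before the earliest adult female age.
    """

    diet_label: str
    ages: np.ndarray
    lx: np.ndarray
    mx: np.ndarray
    n_initial: int
    n_females: int

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        lx = np.asarray(self.lx, dtype=float)
        mx = np.asarray(self.mx, dtype=float)
        if not (len(ages) == len(lx) == len(mx)):
            raise InputError("ages, lx and mx must have equal length")
        if len(lx) == 0 or lx[0] != 1.0:
            raise InputError("lx must start at l0 = 1")
        if np.any(np.diff(lx) > 1e-12):
            raise InputError("lx must be non-increasing")
        if np.any(mx < 0) or np.any(lx < -1e-12) or np.any(lx > 1 + 1e-12):
            raise InputError("lx must lie in [0, 1] and mx must be nonnegative")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "lx", lx)
        object.__setattr__(self, "mx", mx)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "lx": self.lx, "mx": self.mx})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, diet_label="", n_initial=0, n_females=0) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(
            diet_label=diet_label,
            ages=df["age"].to_numpy(float),
            lx=df["lx"].to_numpy(float),
            mx=df["mx"].to_numpy(float),
            n_initial=n_initial,
            n_females=n_females,
        )


def build_life_table(
    records: list[IndividualRecord],
    progeny_female_fraction: float,
) -> LifeTable:
    """Construct the lx/mx schedule of a single-diet cohort.

    For each whole-day age x::

        lx(x) = (fraction surviving the immature stages up to x)
              × (fraction of adult females still alive at x, among females
                 reaching adulthood)
        mx(x) = progeny_female_fraction × mean daily eggs at age x
                over adult females alive at x

    Males are removed from the denominator from adulthood onward; females
    that die without ovipositing stay in lx and contribute zero mx.
    Individuals dying immature, whose death age is not observed, drop out of
    the survivorship at the age they entered their fatal stage.

    Raises
    ------
    InputError
        If the records span more than one diet.
    AnalysisError
        If the cohort is empty or contains no adult female.
    """
    records = list(records)
    if not records:
        raise AnalysisError("cannot build a life table from an empty cohort")
    diets = {r.diet_label for r in records}
    if len(diets) > 1:
        raise InputError(f"records mix several diets: {sorted(diets)}")
    if not 0.0 <= progeny_female_fraction <= 1.0:
        raise InputError("progeny_female_fraction must lie in [0, 1]")

    females = [
        r for r in records
        if r.sex == "female" and r.adult_death_age is not None
    ]
    if not females:
        raise AnalysisError("no adult female with a recorded death age in cohort")

    n_initial = len(records)
    dropouts = np.array(
        [r.immature_dropout_age for r in records if not r.reached_adulthood],
        dtype=float,
    )
    death_ages = np.array([r.adult_death_age for r in females], dtype=float)
    max_age = int(math.ceil(death_ages.max()))
    ages = np.arange(max_age + 1, dtype=float)

    # survivorship through the immature phase (all individuals, both sexes)
    if dropouts.size:
        f_imm = 1.0 - (dropouts[None, :] < ages[:, None]).sum(axis=1) / n_initial
    else:
        f_imm = np.ones_like(ages)
    # adult-female survivorship: alive at x iff x < death age
    alive = ages[:, None] < death_ages[None, :]
    f_adf = alive.sum(axis=1) / len(females)
    lx = f_imm * f_adf

    # eggs laid per absolute age, per female
    eggs = np.zeros((len(ages), len(females)))
    for j, r in enumerate(females):
        a0 = r.adult_day
        for d, e in enumerate(r.daily_eggs):
            if e:
                eggs[a0 + d, j] = e
    n_alive = alive.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = np.where(n_alive > 0, eggs.sum(axis=1) / np.maximum(n_alive, 1), 0.0)
    mx = progeny_female_fraction * mx

    return LifeTable(
        diet_label=records[0].diet_label,
        ages=ages,
        lx=lx,
        mx=mx,
        n_initial=n_initial,
        n_females=len(females),
    )
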