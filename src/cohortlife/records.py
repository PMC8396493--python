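"""Individual-level rearing records.

One :class:`IndividualRecord` describes a single individual followed from egg
deposition to death in a cohort rearing experiment: its stage-transition ages
(observed on a half-day grid, immatures being checked twice a day), the stage
in which it died (if it died immature), its sex (known only once adulthood is
reached), and — for adult females — the death age and the daily egg counts
from the 24-hour adult checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InputError

#: Immature stages in developmental order.
STAGES = ("egg", "larva", "protonymph", "deutonymph")

#: Accepted values for ``died_in_stage``; ``"none"`` means adulthood was reached.
FATES = STAGES + ("none",)

SEXES = ("female", "male", "unknown")


@dataclass(frozen=True)
class IndividualRecord:
    """A single reared individual.

    Parameters
    ----------
    individual_id
        Unique identifier within the experiment.
    diet_label
        Diet (food item) the individual was reared on.
    tray_id
        Rearing tray / replicate unit.
    transition_ages
        Ages in days since egg deposition at which the individual was observed
        to have hatched, molted larva→protonymph, protonymph→deutonymph and
        deutonymph→adult, at 0.5-day resolution.  Truncated at the first
        failed transition: an individual that died as a larva has only its
        hatch age.
    died_in_stage
        Stage of immature death, or ``"none"`` if adulthood was reached.
    sex
        ``"female"`` or ``"male"`` for adults, ``"unknown"`` for individuals
        that died immature (immatures cannot be sexed).
    adult_death_age
        Age in whole days since egg deposition at which the female was found
        dead at a daily check.  ``None`` for males and immature deaths.
    daily_eggs
        Egg counts indexed by whole days of adult life (day 0 is the first
        daily check on or after the final molt).  Empty for males and
        immature deaths.
    """

    individual_id: str
    diet_label: str
    tray_id: str
    transition_ages: tuple[float, ...] = ()
    died_in_stage: str = "none"
    sex: str = "unknown"
    adult_death_age: float | None = None
    daily_eggs: tuple[int, ...] = field(default_factory=tuple)

    # -- derived views -----------------------------------------------------

    @property
    def reached_adulthood(self) -> bool:
        return self.died_in_stage == "none"

    @property
    def adult_emergence_age(self) -> float | None:
        """Age of the final molt (days since egg deposition), half-day grid."""
        return self.transition_ages[3] if len(self.transition_ages) == 4 else None

    @property
    def adult_day(self) -> int | None:
        """First whole-day age at which the individual was observed as an adult."""
        a = self.adult_emergence_age
        return None if a is None else math.ceil(a - 1e-9)

    @property
    def total_eggs(self) -> int:
        return int(sum(self.daily_eggs))

    @property
    def first_egg_day(self) -> int | None:
        """Absolute age (whole days) of the first oviposition day, or None."""
        for d, e in enumerate(self.daily_eggs):
            if e > 0:
                return self.adult_day + d
        return None

    @property
    def last_egg_day(self) -> int | None:
        for d in range(len(self.daily_eggs) - 1, -1, -1):
            if self.daily_eggs[d] > 0:
                return self.adult_day + d
        return None

    @property
    def immature_dropout_age(self) -> float | None:
        """Age at which an immature death leaves the cohort bookkeeping.

        Immature deaths carry no observed death age, so the individual is
        counted as alive through the age at which it entered the stage it died
        in (0 for egg deaths) and dead thereafter.  ``None`` for adults.
        """
        if self.reached_adulthood:
            return None
        k = STAGES.index(self.died_in_stage)
        return 0.0 if k == 0 else self.transition_ages[k - 1]

    # -- validation --------------------------------------------------------

    def violations(self) -> list[str]:
        """Return invariant violations as human-readable strings."""
        out: list[str] = []
        if self.died_in_stage not in FATES:
            out.append(f"died_in_stage {self.died_in_stage!r} not in {FATES}")
            return out
        if self.sex not in SEXES:
            out.append(f"sex {self.sex!r} not in {SEXES}")

        ages = self.transition_ages
        if any(b <= a for a, b in zip(ages, ages[1:])):
            out.append(f"transition ages not strictly increasing: {ages}")
        if any(a <= 0 for a in ages):
            out.append("transition ages must be positive")

        n_expected = (
            4 if self.reached_adulthood else STAGES.index(self.died_in_stage)
        )
        if len(ages) != n_expected:
            out.append(
                f"{len(ages)} transition ages recorded but "
                f"died_in_stage={self.died_in_stage!r} implies {n_expected}"
            )
        if self.reached_adulthood != (self.sex != "unknown"):
            out.append("sex must be known exactly for individuals reaching adulthood")

        if self.sex == "female" and self.reached_adulthood:
            if self.adult_death_age is not None:
                if not ages or self.adult_death_age <= ages[-1]:
                    out.append("adult_death_age must exceed the final molt age")
                if self.adult_death_age != int(self.adult_death_age):
                    out.append("adult_death_age must be a whole day")
                if self.adult_day is not None and self.daily_eggs:
                    span = self.adult_death_age - self.adult_day
                    if len(self.daily_eggs) > span:
                        out.append(
                            "daily_eggs longer than the adult lifespan "
                            f"({len(self.daily_eggs)} > {span:g})"
                        )
        else:
            if self.adult_death_age is not None:
                out.append("adult_death_age is recorded for adult females only")
            if self.daily_eggs:
                out.append("daily_eggs are recorded for adult females only")
        if any(e < 0 or e != int(e) for e in self.daily_eggs):
            out.append("daily egg counts must be nonnegative integers")
        return out

    def validate(self) -> "IndividualRecord":
        bad = self.violations()
        if bad:
            raise InputError(
                f"invalid record {self.individual_id!r}: " + "; ".join(bad)
            )
        return self


def split_by_diet(records) -> dict[str, list[IndividualRecord]]:
    """Group records by diet label, preserving order of first appearance."""
    out: dict[str, list[IndividualRecord]] = {}
    for r in records:
        out.setdefault(r.diet_label, []).append(r)
    return out
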