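"""Descriptive summaries of development, survival, reproduction and longevity.

Reproduces the classic two descriptive tables of a cohort rearing study:
stage-by-stage development times and survival (including the percentage of
eggs reaching adulthood), and the female reproductive parameters
(pre-oviposition / oviposition / post-oviposition periods, total fecundity,
oviposition rate and adult longevity), all as mean ± SE over individuals.

Conventions: longevity is the adult lifespan (first adult day to death);
the oviposition rate is total fecundity divided by longevity, per female;
females that die without ovipositing are counted in longevity but excluded
from the period and fecundity means, which are otherwise undefined for them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .records import STAGES, IndividualRecord


class MeanSE(NamedTuple):
    """Sample mean, classical standard error (sd/√n) and n."""

    mean: float
    se: float
    n: int

    @classmethod
    def of(cls, values) -> "MeanSE | None":
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            return None
        se = float(values.std(ddof=1) / math.sqrt(values.size)) if values.size > 1 else float("nan")
        return cls(float(values.mean()), se, int(values.size))


@dataclass(frozen=True)
class StageSummary:
    """Development times and survival of the immature stages of one cohort."""

    diet_label: str
    n_initial: int
    stage_durations: dict[str, MeanSE | None]
    egg_to_female: MeanSE | None
    egg_to_male: MeanSE | None
    egg_to_adult: MeanSE | None
    stage_survival_pct: dict[str, float | None]
    maturity_pct: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in STAGES:
            d = self.stage_durations[s]
            rows.append({
                "quantity": f"{s} duration (d)",
                "mean": None if d is None else d.mean,
                "se": None if d is None else d.se,
                "n": None if d is None else d.n,
            })
        for label, d in (("egg to female (d)", self.egg_to_female),
                         ("egg to male (d)", self.egg_to_male),
                         ("egg to adult (d)", self.egg_to_adult)):
            rows.append({"quantity": label,
                         "mean": None if d is None else d.mean,
                         "se": None if d is None else d.se,
                         "n": None if d is None else d.n})
        for s in STAGES:
            rows.append({"quantity": f"{s} survival (%)",
                         "mean": self.stage_survival_pct[s], "se": None, "n": None})
        rows.append({"quantity": "reaching maturity (%)",
                     "mean": self.maturity_pct, "se": None, "n": self.n_initial})
        df = pd.DataFrame(rows)
        df.insert(0, "diet", self.diet_label)
        return df


@dataclass(frozen=True)
class ReproductiveSummary:
    """Female reproductive parameters and adult longevity of one cohort."""

    diet_label: str
    n_females: int
    n_ovipositing: int
    total_fecundity: MeanSE
    oviposition_rate: MeanSE
    longevity: MeanSE
    preoviposition: MeanSE
    oviposition: MeanSE
    postoviposition: MeanSE

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("total fecundity (eggs/female)", self.total_fecundity),
            ("oviposition rate (eggs/female/day)", self.oviposition_rate),
            ("longevity (d)", self.longevity),
            ("preoviposition (d)", self.preoviposition),
            ("oviposition (d)", self.oviposition),
            ("postoviposition (d)", self.postoviposition),
        ]
        df = pd.DataFrame(
            [{"quantity": q, "mean": v.mean, "se": v.se, "n": v.n} for q, v in rows]
        )
        df.insert(0, "diet", self.diet_label)
        return df


def summarize_stages(records: list[IndividualRecord]) -> StageSummary:
    """Stage durations (mean ± SE over completers) and stage-entry survival.

    A stage's survival is 100 × (individuals entering the next stage) /
    (individuals entering this stage); the percentage reaching maturity is
    100 × adults / initial eggs.
    """
    records = list(records)
    if not records:
        raise AnalysisError("empty cohort")
    n0 = len(records)

    # entered[s]: individuals alive at the start of stage s; entered[0] = all
    entered = [n0] + [
        sum(len(r.transition_ages) >= s for r in records) for s in range(1, 5)
    ]
    survival: dict[str, float | None] = {}
    for s, name in enumerate(STAGES):
        survival[name] = (100.0 * entered[s + 1] / entered[s]) if entered[s] else None

    durations: dict[str, MeanSE | None] = {}
    for s, name in enumerate(STAGES):
        vals = [
            r.transition_ages[s] - (r.transition_ages[s - 1] if s else 0.0)
            for r in records
            if len(r.transition_ages) > s
        ]
        durations[name] = MeanSE.of(vals)

    dev = {
        sex: MeanSE.of([
            r.transition_ages[3] for r in records
            if r.reached_adulthood and (sex is None or r.sex == sex)
        ])
        for sex in ("female", "male", None)
    }
    return StageSummary(
        diet_label=records[0].diet_label,
        n_initial=n0,
        stage_durations=durations,
        egg_to_female=dev["female"],
        egg_to_male=dev["male"],
        egg_to_adult=dev[None],
        stage_survival_pct=survival,
        maturity_pct=100.0 * entered[4] / n0,
    )


def percent_reaching_maturity(stage_survival_pct) -> float:
    """Percentage reaching maturity implied by per-stage survival percentages.

    With no censoring the fraction of eggs reaching adulthood is exactly the
    product of the stage survival proportions.
    """
    out = 100.0
    for p in stage_survival_pct:
        out *= p / 100.0
    return out


def oviposition_rate(total_fecundity: float, longevity: float) -> float:
    """Eggs per female per day of adult life: total fecundity / longevity."""
    if longevity <= 0:
        raise AnalysisError("longevity must be positive")
    return total_fecundity / longevity


def summarize_reproduction(records: list[IndividualRecord]) -> ReproductiveSummary:
    """Per-female reproductive periods, fecundity, rate and adult longevity.

    With the first adult day A (first daily check at or after the final
    molt), first and last oviposition days F and L, and death day D:
    preoviposition = F − A, oviposition = L − F + 1, postoviposition = D − L,
    longevity = D − A, oviposition rate = total eggs / longevity.
    """
    females = [
        r for r in records
        if r.sex == "female" and r.adult_death_age is not None
    ]
    if not females:
        raise AnalysisError("no adult female with a recorded death age in cohort")

    longevity = [r.adult_death_age - r.adult_day for r in females]
    laying = [r for r in females if r.total_eggs > 0]
    pre, ovi, post, fec, rate = [], [], [], [], []
    for r in laying:
        f, l = r.first_egg_day, r.last_egg_day
        pre.append(f - r.adult_day)
        ovi.append(l - f + 1)
        post.append(r.adult_death_age - l)
        fec.append(r.total_eggs)
        rate.append(r.total_eggs / (r.adult_death_age - r.adult_day))

    empty = MeanSE(float("nan"), float("nan"), 0)
    return ReproductiveSummary(
        diet_label=records[0].diet_label if records else "",
        n_females=len(females),
        n_ovipositing=len(laying),
        total_fecundity=MeanSE.of(fec) or empty,
        oviposition_rate=MeanSE.of(rate) or empty,
        longevity=MeanSE.of(longevity) or empty,
        preoviposition=MeanSE.of(pre) or empty,
        oviposition=MeanSE.of(ovi) or empty,
        postoviposition=MeanSE.of(post) or empty,
    )
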