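"""Individual-based simulation of a cohort rearing experiment.

Emulates the standard phytoseiid rearing protocol: single eggs isolated in
rearing arenas, immatures checked twice a day (0.5-day observation grid) for
molts and deaths through four immature stages (egg, larva, protonymph,
deutonymph), sexing at the final molt, and adult females followed at daily
checks through pre-oviposition, oviposition and post-oviposition periods with
daily egg counts.

Stage durations and adult periods are gamma-distributed with configurable
mean and coefficient of variation and are rounded *up* to the observation
grid — an event is detected at the first check after it occurs.  Stage
survival is Bernoulli per stage; daily egg counts are Poisson during the
oviposition window.

:func:`expected_life_table` computes the exact population lx/mx schedule
implied by a configuration (the "noiseless" schedule), using the discrete
distributions of the grid-rounded gamma laws; it is the estimand that
cohort-level estimates converge to as the cohort grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy.stats import gamma as _gamma

from .errors import ConfigurationError
from .life_table import LifeTable
from .records import STAGES, IndividualRecord

__all__ = ["CohortConfig", "generate_cohort", "expected_life_table", "default_configs"]

#: Half-day observation grid for immatures; whole days for adults.
IMMATURE_STEP = 0.5
ADULT_STEP = 1.0


def _ceil_to(x: float, step: float) -> float:
    """Round up to the observation grid (events are seen at the next check)."""
    return step * max(1, math.ceil(x / step - 1e-9))


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters for one diet cohort.

    Durations are in days.  ``stage_mean_durations`` and ``stage_survival``
    are ordered (egg, larva, protonymph, deutonymph).  ``daily_egg_mean`` is
    eggs per female per day *during the oviposition window*;
    ``progeny_female_fraction`` converts eggs to female eggs downstream.
    ``egg_count_law`` is ``"poisson"`` (default) or ``"deterministic"``
    (each oviposition day yields exactly ``daily_egg_mean`` eggs, which must
    then be a whole number).  ``tray_fecundity_sd`` adds an optional
    tray-level normal offset to ``daily_egg_mean`` (default off).
    """

    diet_label: str
    n_eggs: int
    stage_mean_durations: tuple[float, float, float, float]
    stage_survival: tuple[float, float, float, float]
    preoviposition_mean: float
    oviposition_mean: float
    postoviposition_mean: float
    daily_egg_mean: float
    seed: int
    n_trays: int = 8
    stage_duration_cv: float = 0.25
    adult_period_cv: float = 0.25
    proportion_female: float = 0.67
    progeny_female_fraction: float = 0.67
    egg_count_law: str = "poisson"
    tray_fecundity_sd: float = 0.0

    def validate(self) -> "CohortConfig":
        def bad(name, why):
            raise ConfigurationError(f"{name}: {why}")

        if not self.diet_label:
            bad("diet_label", "must be a nonempty string")
        if not isinstance(self.n_eggs, (int, np.integer)) or self.n_eggs < 1:
            bad("n_eggs", f"must be a positive integer, got {self.n_eggs!r}")
        if not isinstance(self.n_trays, (int, np.integer)) or self.n_trays < 1:
            bad("n_trays", f"must be a positive integer, got {self.n_trays!r}")
        if len(self.stage_mean_durations) != 4 or any(
            d <= 0 for d in self.stage_mean_durations
        ):
            bad("stage_mean_durations", "needs four positive durations (days)")
        if len(self.stage_survival) != 4 or any(
            not 0.0 <= p <= 1.0 for p in self.stage_survival
        ):
            bad("stage_survival", "needs four probabilities in [0, 1]")
        for name in ("preoviposition_mean", "oviposition_mean", "postoviposition_mean"):
            if getattr(self, name) <= 0:
                bad(name, "must be positive (days)")
        for name in ("stage_duration_cv", "adult_period_cv", "tray_fecundity_sd"):
            if getattr(self, name) < 0:
                bad(name, "must be nonnegative")
        for name in ("proportion_female", "progeny_female_fraction"):
            # 1.0 is allowed: an all-female (or female-only bookkeeping) cohort
            if not 0.0 < getattr(self, name) <= 1.0:
                bad(name, "must lie in (0, 1]")
        if self.daily_egg_mean < 0:
            bad("daily_egg_mean", "must be nonnegative")
        if self.egg_count_law not in ("poisson", "deterministic"):
            bad("egg_count_law", "must be 'poisson' or 'deterministic'")
        if self.egg_count_law == "deterministic" and (
            self.daily_egg_mean != int(self.daily_egg_mean)
        ):
            bad("daily_egg_mean", "must be a whole number under the deterministic law")
        return self

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=int(seed))

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in ("stage_mean_durations", "stage_survival"):
            if key in d:
                d[key] = tuple(float(v) for v in d[key])
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"{sorted(unknown)[0]}: unknown configuration field")
        return cls(**d).validate()


def _draw_duration(rng, mean: float, cv: float, step: float) -> float:
    if cv == 0.0:
        return _ceil_to(mean, step)
    shape = 1.0 / cv**2
    return _ceil_to(rng.gamma(shape, mean * cv**2), step)


def generate_cohort(config: CohortConfig) -> list[IndividualRecord]:
    """Simulate one diet cohort of ``config.n_eggs`` individuals.

    Two calls with an identical configuration (including ``seed``) return
    identical records.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    if config.tray_fecundity_sd > 0:
        tray_offsets = rng.normal(0.0, config.tray_fecundity_sd, config.n_trays)
    else:
        tray_offsets = np.zeros(config.n_trays)

    out: list[IndividualRecord] = []
    for i in range(config.n_eggs):
        tray = i % config.n_trays
        ages: list[float] = []
        age = 0.0
        died: str | None = None
        for s, (mean, p_surv) in enumerate(
            zip(config.stage_mean_durations, config.stage_survival)
        ):
            dur = _draw_duration(rng, mean, config.stage_duration_cv, IMMATURE_STEP)
            if rng.random() >= p_surv:
                died = STAGES[s]
                break
            age += dur
            ages.append(age)

        base = dict(
            individual_id=f"{config.diet_label}-{i + 1:04d}",
            diet_label=config.diet_label,
            tray_id=f"T{tray + 1:02d}",
            transition_ages=tuple(ages),
        )
        if died is not None:
            out.append(IndividualRecord(**base, died_in_stage=died))
            continue

        if rng.random() < config.proportion_female:
            pre = int(_draw_duration(rng, config.preoviposition_mean,
                                     config.adult_period_cv, ADULT_STEP))
            ovi = int(_draw_duration(rng, config.oviposition_mean,
                                     config.adult_period_cv, ADULT_STEP))
            post = int(_draw_duration(rng, config.postoviposition_mean,
                                      config.adult_period_cv, ADULT_STEP))
            mu = max(0.0, config.daily_egg_mean + tray_offsets[tray])
            daily = [0] * (pre + ovi + post)
            for d in range(pre, pre + ovi):
                if config.egg_count_law == "poisson":
                    daily[d] = int(rng.poisson(mu))
                else:
                    daily[d] = int(round(mu))
            adult_day = math.ceil(age - 1e-9)
            out.append(IndividualRecord(
                **base,
                sex="female",
                adult_death_age=float(adult_day + pre + ovi + post),
                daily_eggs=tuple(daily),
            ))
        else:
            out.append(IndividualRecord(**base, sex="male"))
    return out


# ---------------------------------------------------------------------------
# Exact population schedule implied by a configuration


def _rounded_gamma_pmf(mean: float, cv: float, step: float) -> np.ndarray:
    """PMF of a gamma duration rounded up to the grid, in units of ``step``.

    Index i of the returned array carries P(rounded value = i*step); index 0
    is always zero (rounding up never yields less than one grid step).
    """
    if cv == 0.0:
        k = max(1, math.ceil(mean / step - 1e-9))
        p = np.zeros(k + 1)
        p[k] = 1.0
        return p
    dist = _gamma(1.0 / cv**2, scale=mean * cv**2)
    kmax = max(1, math.ceil(dist.ppf(1.0 - 1e-12) / step))
    cdf = dist.cdf(np.arange(kmax + 1) * step)
    p = np.concatenate([[0.0], np.diff(cdf)])
    p[-1] += 1.0 - p.sum()  # fold the remote tail into the last atom
    return p


def _conv(*pmfs: np.ndarray) -> np.ndarray:
    out = np.array([1.0])
    for p in pmfs:
        out = np.convolve(out, p)
    return out


def expected_life_table(config: CohortConfig) -> LifeTable:
    """Exact lx/mx schedule of the population a configuration describes.

    All sources of individual variation — grid-rounded gamma durations and
    periods, Bernoulli stage survival — are integrated out analytically
    (Poisson egg noise has no effect on expectations).  The result is the
    schedule whose demographic parameters cohort estimates recover as
    ``n_eggs`` grows.
    """
    config.validate()
    cv, step = config.stage_duration_cv, IMMATURE_STEP
    stage_pmfs = [
        _rounded_gamma_pmf(m, cv, step) for m in config.stage_mean_durations
    ]
    p_surv = np.asarray(config.stage_survival, float)

    # immature drop-out: die in stage s => leave the bookkeeping at the entry
    # age into s (distribution = convolution of the first s durations)
    entry_pmfs = [_conv(*stage_pmfs[:s]) for s in range(4)]
    q = [float(np.prod(p_surv[:s]) * (1.0 - p_surv[s])) for s in range(4)]

    # adult emergence age (half-day units) and its whole-day first check
    emergence = _conv(*stage_pmfs)
    c_day = np.zeros(len(emergence) // 2 + 1)
    for i, pr in enumerate(emergence):
        c_day[(i + 1) // 2] += pr

    acv = config.adult_period_cv
    pre = _rounded_gamma_pmf(config.preoviposition_mean, acv, ADULT_STEP)
    ovi = _rounded_gamma_pmf(config.oviposition_mean, acv, ADULT_STEP)
    post = _rounded_gamma_pmf(config.postoviposition_mean, acv, ADULT_STEP)

    start = _conv(c_day, pre)          # age of the first oviposition-window day
    death = _conv(start, ovi, post)    # adult death age (found dead at this check)
    ovi_sf = 1.0 - np.cumsum(ovi)      # ovi_sf[k] = P(V > k) = P(V >= k+1)

    ages = np.arange(len(death), dtype=float)
    xmax = len(death) - 1

    # lx = P(no immature death before x) * P(adult female alive at x | adult)
    f_imm = np.ones(xmax + 1)
    for s in range(4):
        cum = np.cumsum(entry_pmfs[s])
        for x in range(xmax + 1):
            # entry age i*0.5 < x  <=>  i < 2x  <=>  i <= 2x-1
            p_lt = cum[min(2 * x - 1, len(cum) - 1)] if x >= 1 else 0.0
            f_imm[x] -= q[s] * p_lt
    alive = 1.0 - np.cumsum(death)     # P(death age > x)
    alive = np.clip(alive, 0.0, 1.0)
    lx = f_imm * alive

    # P(x inside the oviposition window) = sum_s P(start=s) P(V >= x-s+1), s <= x
    win = np.zeros(xmax + 1)
    for s, pr in enumerate(start):
        if pr == 0.0:
            continue
        for x in range(s, xmax + 1):
            k = x - s
            if k < len(ovi_sf):
                win[x] += pr * ovi_sf[k]
    mu = (round(config.daily_egg_mean) if config.egg_count_law == "deterministic"
          else config.daily_egg_mean)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = np.where(alive > 1e-15,
                      config.progeny_female_fraction * mu * win / np.maximum(alive, 1e-300),
                      0.0)

    p_adult = float(np.prod(p_surv))
    return LifeTable(
        diet_label=config.diet_label,
        ages=ages,
        lx=lx,
        mx=mx,
        n_initial=config.n_eggs,
        n_females=round(config.n_eggs * p_adult * config.proportion_female),
    )


# ---------------------------------------------------------------------------
# Default experiment: three diet cohorts of a predatory mite

_DIET_DEFAULTS = {
    # diet: (n_eggs, n_trays, stage means, stage survival,
    #        preovi, ovi, postovi, total fecundity)
    "Oligonychus ununguis": (
        47, 8, (1.53, 0.76, 1.70, 1.61), (0.9574, 0.9556, 0.9535, 1.0),
        3.28, 20.4, 2.70, 29.2,
    ),
    "Pentamerismus taxi": (
        55, 10, (1.48, 0.62, 1.40, 1.66), (0.9636, 0.9767, 0.9762, 0.9756),
        2.02, 24.4, 1.83, 33.3,
    ),
    "pine pollen": (
        53, 9, (1.79, 0.84, 2.09, 1.79), (0.9811, 0.9615, 0.9200, 0.9130),
        3.50, 19.1, 1.47, 24.2,
    ),
}


def default_configs(seed: int = 0, n_eggs: int | None = None) -> list[CohortConfig]:
    """The three-diet rearing experiment the simulator emulates by default.

    Cohorts of a predatory mite (*Amblyseius andersoni*) reared on spruce
    spider mite, a false spider mite, or pine pollen, with stage durations,
    stage survival, adult periods and fecundity set to the measured cohort
    means of that experiment.  ``daily_egg_mean`` is total fecundity divided
    by the oviposition period.  ``n_eggs`` overrides the per-diet historical
    cohort sizes (e.g. for parameter-recovery studies at larger n).  Each
    diet gets a distinct stream seed derived from ``seed``.
    """
    out = []
    for k, (diet, row) in enumerate(_DIET_DEFAULTS.items()):
        n, trays, means, surv, pre, ovi, post, fec = row
        out.append(CohortConfig(
            diet_label=diet,
            n_eggs=int(n_eggs if n_eggs is not None else n),
            n_trays=trays,
            stage_mean_durations=means,
            stage_survival=surv,
            preoviposition_mean=pre,
            oviposition_mean=ovi,
            postoviposition_mean=post,
            daily_egg_mean=fec / ovi,
            seed=int(seed) + k,
        ).validate())
    return out
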