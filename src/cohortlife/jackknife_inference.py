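"""Jackknife pseudovalue inference for demographic parameters.

Cohort parameters such as rm are nonlinear functionals of the whole cohort,
so no per-individual replicate variance exists directly.  The leave-one-out
jackknife supplies one: with θ the full-cohort estimate and θ(−i) the
estimate with individual i removed (the life table rebuilt from scratch),
the pseudovalues

    φ_i = n·θ − (n−1)·θ(−i)

behave approximately like i.i.d. replicates; their mean is the
bias-corrected point estimate and sd(φ)/√n its standard error.  Pairwise
diet comparisons are two-sample t tests on the pseudovalue sets, reported
without multiplicity adjustment; a compact letter display summarizes all
pairs of an experiment.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .demography import DEFAULT_TOL, PARAMETERS, demographic_params
from .errors import AnalysisError, CohortLifeError, InputError
from .life_table import build_life_table
from .records import IndividualRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class JackknifeEstimate:
    """Leave-one-out pseudovalue summary of one parameter for one cohort.

    ``n`` is the cohort size used in the pseudovalue formula; ``n_effective``
    (= ``len(pseudovalues)``) may be smaller when some leave-one-out cohorts
    were degenerate (no reproducing female) and were excluded with a warning.
    """

    parameter_name: str
    diet_label: str
    theta_all: float
    pseudovalues: tuple[float, ...]
    n: int

    @property
    def n_effective(self) -> int:
        return len(self.pseudovalues)

    @property
    def estimate(self) -> float:
        """Jackknife (bias-corrected) point estimate: mean of the pseudovalues."""
        return float(np.mean(self.pseudovalues))

    @property
    def se(self) -> float:
        """Standard error: sd(pseudovalues)/sqrt(n_effective)."""
        pv = np.asarray(self.pseudovalues)
        if len(pv) < 2:
            return float("nan")
        return float(pv.std(ddof=1) / math.sqrt(len(pv)))


@dataclass(frozen=True)
class PairwiseComparison:
    """Unadjusted two-sample t comparison of one parameter between two diets."""

    parameter_name: str
    diet_a: str
    diet_b: str
    difference: float
    t_statistic: float
    df: int
    p_value: float


def jackknife_statistic(values, statfunc, parameter_name="statistic",
                        diet_label="") -> JackknifeEstimate:
    """Jackknife an arbitrary per-individual statistic.

    For a linear statistic such as the arithmetic mean the pseudovalues equal
    the observations themselves, so the jackknife SE reduces exactly to the
    classical sd/√n.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        raise InputError("jackknife needs at least 3 observations")
    theta = float(statfunc(values))
    mask = ~np.eye(n, dtype=bool)
    pv = [n * theta - (n - 1) * float(statfunc(values[mask[i]])) for i in range(n)]
    return JackknifeEstimate(parameter_name, diet_label, theta, tuple(pv), n)


def _loo_params(records, progeny_female_fraction, tol, pivotal_age):
    """Full-cohort and leave-one-out DemographicParams; degenerate LOO -> None."""
    records = list(records)
    theta_all = demographic_params(
        build_life_table(records, progeny_female_fraction),
        tol, pivotal_age=pivotal_age,
    )
    loo = []
    for i, r in enumerate(records):
        rest = records[:i] + records[i + 1:]
        try:
            loo.append(demographic_params(
                build_life_table(rest, progeny_female_fraction),
                tol, pivotal_age=pivotal_age,
            ))
        except CohortLifeError as exc:
            logger.info(
                "degenerate leave-one-out cohort without %s (%s); "
                "pseudovalue excluded", r.individual_id, exc,
            )
            loo.append(None)
    n_bad = sum(p is None for p in loo)
    if n_bad:
        warnings.warn(
            f"{n_bad} degenerate leave-one-out cohort(s); "
            f"effective n reduced to {len(records) - n_bad}",
            stacklevel=3,
        )
    return theta_all, loo


def jackknife_parameter(
    records: list[IndividualRecord],
    parameter: str,
    progeny_female_fraction: float,
    tol: float = DEFAULT_TOL,
    *,
    pivotal_age: bool = False,
) -> JackknifeEstimate:
    """Jackknife one demographic parameter ("R0", "T", "rm" or "lambda").

    The leave-one-out unit is the individual entering the cohort as an egg;
    every replicate rebuilds the life table and re-solves Euler-Lotka.
    """
    if parameter not in PARAMETERS:
        raise InputError(f"unknown parameter {parameter!r}; expected one of {PARAMETERS}")
    records = list(records)
    if len(records) < 3:
        raise InputError("jackknife needs at least 3 records")
    theta_all, loo = _loo_params(records, progeny_female_fraction, tol, pivotal_age)
    n = len(records)
    pv = tuple(
        n * theta_all[parameter] - (n - 1) * p[parameter]
        for p in loo if p is not None
    )
    return JackknifeEstimate(
        parameter_name=parameter,
        diet_label=records[0].diet_label,
        theta_all=theta_all[parameter],
        pseudovalues=pv,
        n=n,
    )


def jackknife_all(
    records: list[IndividualRecord],
    progeny_female_fraction: float,
    tol: float = DEFAULT_TOL,
    *,
    pivotal_age: bool = False,
) -> dict[str, JackknifeEstimate]:
    """All four parameters from a single sweep of leave-one-out replicates."""
    records = list(records)
    if len(records) < 3:
        raise InputError("jackknife needs at least 3 records")
    theta_all, loo = _loo_params(records, progeny_female_fraction, tol, pivotal_age)
    n = len(records)
    out = {}
    for name in PARAMETERS:
        pv = tuple(
            n * theta_all[name] - (n - 1) * p[name] for p in loo if p is not None
        )
        out[name] = JackknifeEstimate(name, records[0].diet_label,
                                      theta_all[name], pv, n)
    return out


def compare_diets(
    a: JackknifeEstimate,
    b: JackknifeEstimate,
    *,
    welch: bool = False,
) -> PairwiseComparison:
    """Two-sample t test between the pseudovalue sets of two diets.

    Pooled-variance by default with df = n_a + n_b − 2 (the form used with
    jackknife pseudovalues); Welch's unequal-variance test is available as an
    option.  The p-value is two-sided and unadjusted.
    """
    if a.parameter_name != b.parameter_name:
        raise InputError(
            f"cannot compare {a.parameter_name!r} with {b.parameter_name!r}"
        )
    pa, pb = np.asarray(a.pseudovalues), np.asarray(b.pseudovalues)
    if len(pa) < 2 or len(pb) < 2:
        raise InputError("each pseudovalue set needs at least 2 values")
    res = stats.ttest_ind(pa, pb, equal_var=not welch)
    df = res.df if welch else len(pa) + len(pb) - 2
    return PairwiseComparison(
        parameter_name=a.parameter_name,
        diet_a=a.diet_label,
        diet_b=b.diet_label,
        difference=float(pa.mean() - pb.mean()),
        t_statistic=float(res.statistic),
        df=int(df) if not welch else float(df),
        p_value=float(res.pvalue),
    )


def letter_groups(
    comparisons: list[PairwiseComparison],
    estimates: dict[str, float],
    alpha: float = 0.05,
) -> dict[str, str]:
    """Compact letter display over all pairwise comparisons of one parameter.

    Two diets share a letter iff their comparison is non-significant at
    ``alpha``.  Letters are the maximal cliques of the non-significance
    graph (so intransitive patterns yield multi-letter labels), ordered by
    ascending parameter estimate.
    """
    diets = sorted(estimates, key=lambda d: estimates[d])
    names = {c.parameter_name for c in comparisons}
    if len(names) > 1:
        raise InputError(f"comparisons mix parameters: {sorted(names)}")
    seen = set()
    g = nx.Graph()
    g.add_nodes_from(diets)
    for c in comparisons:
        if c.diet_a not in estimates or c.diet_b not in estimates:
            raise InputError(f"no estimate for pair ({c.diet_a!r}, {c.diet_b!r})")
        seen.add(frozenset((c.diet_a, c.diet_b)))
        if c.p_value > alpha:
            g.add_edge(c.diet_a, c.diet_b)
    expected = {frozenset(p) for p in _all_pairs(diets)}
    if seen != expected:
        raise InputError("comparisons must cover every diet pair exactly")

    cliques = sorted(
        (sorted(cl, key=lambda d: estimates[d]) for cl in nx.find_cliques(g)),
        key=lambda cl: (min(estimates[d] for d in cl),
                        sorted(diets.index(d) for d in cl)),
    )
    letters = {d: "" for d in diets}
    for k, cl in enumerate(cliques):
        ch = chr(ord("a") + k)
        for d in cl:
            letters[d] += ch
    return letters


def _all_pairs(items):
    return [(a, b) for i, a in enumerate(items) for b in items[i + 1:]]
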