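"""Jackknife pseudovalues, pairwise t comparisons and compact letter display."""

import itertools
import math
from dataclasses import replace

import numpy as np
import pytest

from cohortlife import (
    InputError,
    JackknifeEstimate,
    PairwiseComparison,
    build_life_table,
    compare_diets,
    demographic_params,
    generate_cohort,
    jackknife_all,
    jackknife_parameter,
    jackknife_statistic,
    letter_groups,
)


class TestPseudovalues:
    def test_mean_reproduces_classical_se(self):
        est = jackknife_statistic([2, 4, 6], np.mean)
        assert sorted(est.pseudovalues) == [2, 4, 6]
        assert est.estimate == 4.0
        assert est.se == pytest.approx(2 / math.sqrt(3), rel=1e-14)

    def test_identical_individuals_give_zero_se(self, two_female_cohort):
        cohort = two_female_cohort + [
            replace(two_female_cohort[0], individual_id="test-3")
        ]
        est = jackknife_parameter(cohort, "rm", 0.5)
        assert len(set(est.pseudovalues)) == 1
        assert est.se == 0.0

    def test_matches_independent_leave_one_out_loop(self, small_config):
        """Pseudovalues for rm agree to 10 digits with a separately coded
        leave-one-out loop on a 6-record cohort."""
        cfg = replace(small_config, n_eggs=6, stage_survival=(1.0,) * 4,
                      proportion_female=1.0)
        recs = generate_cohort(cfg)
        assert all(r.sex == "female" for r in recs)
        est = jackknife_parameter(recs, "rm", 0.67)

        n = len(recs)
        theta = demographic_params(build_life_table(recs, 0.67)).rm
        oracle = []
        for i in range(n):
            rest = [r for j, r in enumerate(recs) if j != i]
            loo = demographic_params(build_life_table(rest, 0.67)).rm
            oracle.append(n * theta - (n - 1) * loo)
        np.testing.assert_allclose(est.pseudovalues, oracle, rtol=1e-10)

    def test_pseudovalue_mean_near_theta_for_large_cohort(self, small_config):
        cfg = replace(small_config, n_eggs=500)
        recs = generate_cohort(cfg)
        est = jackknife_parameter(recs, "rm", cfg.progeny_female_fraction)
        assert abs(est.estimate - est.theta_all) < 2 * est.se

    def test_degenerate_replicates_reduce_effective_n(self):
        """Removing the only reproducing female yields a flagged replicate."""
        from conftest import female, male

        cohort = [
            female(1, (1.0, 2.0, 3.0, 5.0), 9, (0, 2, 2, 0)),
            male(2, (1.0, 2.0, 3.0, 5.0)),
            male(3, (1.0, 2.0, 3.5, 5.5)),
        ]
        with pytest.warns(UserWarning, match="degenerate"):
            est = jackknife_parameter(cohort, "R0", 0.5)
        assert est.n == 3
        assert est.n_effective == 2

    def test_jackknife_all_consistent_with_per_parameter(self, small_config):
        recs = generate_cohort(replace(small_config, n_eggs=20))
        all_est = jackknife_all(recs, 0.67)
        rm_est = jackknife_parameter(recs, "rm", 0.67)
        assert all_est["rm"].pseudovalues == rm_est.pseudovalues

    def test_unknown_parameter_rejected(self, two_female_cohort):
        with pytest.raises(InputError, match="parameter"):
            jackknife_parameter(two_female_cohort * 2, "r0max", 0.5)


def _estimate(pseudovalues, name="rm", diet="d"):
    pv = tuple(float(v) for v in pseudovalues)
    return JackknifeEstimate(name, diet, float(np.mean(pv)), pv, len(pv))


class TestCompareDiets:
    def test_textbook_example(self):
        c = compare_diets(_estimate([1, 2, 3], diet="a"),
                          _estimate([4, 5, 6], diet="b"))
        assert c.difference == -3.0
        assert c.t_statistic == pytest.approx(-3.674, abs=5e-4)
        assert c.df == 4
        assert c.p_value == pytest.approx(0.0213, abs=5e-4)

    def test_identical_sets(self):
        c = compare_diets(_estimate([1, 2, 3], diet="a"),
                          _estimate([1, 2, 3], diet="b"))
        assert c.t_statistic == 0.0
        assert c.p_value == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        a = _estimate(rng.normal(0.16, 0.01, 12), diet="a")
        b = _estimate(rng.normal(0.15, 0.01, 9), diet="b")
        ab, ba = compare_diets(a, b), compare_diets(b, a)
        assert ab.difference == -ba.difference
        assert ab.t_statistic == pytest.approx(-ba.t_statistic, rel=1e-12)
        assert ab.p_value == pytest.approx(ba.p_value, rel=1e-12)
        assert ab.df == ba.df

    def test_mismatched_parameters_rejected(self):
        with pytest.raises(InputError):
            compare_diets(_estimate([1, 2, 3], name="rm"),
                          _estimate([1, 2, 3], name="R0"))


def _comparison(a, b, p, name="rm"):
    return PairwiseComparison(name, a, b, 0.0, 0.0, 4, p)


def _cld_oracle(diets, estimates, nonsig_pairs):
    """Brute-force compact letter display for 3 groups: smallest set of
    letters (subsets) whose shared-membership pattern equals nonsignificance."""
    best = None
    nodes = list(diets)
    subsets = [
        frozenset(c) for r in range(1, len(nodes) + 1)
        for c in itertools.combinations(nodes, r)
    ]
    for k in range(1, len(subsets) + 1):
        for cover in itertools.combinations(subsets, k):
            ok = all(any(d in s for s in cover) for d in nodes)
            for a, b in itertools.combinations(nodes, 2):
                share = any(a in s and b in s for s in cover)
                if share != (frozenset((a, b)) in nonsig_pairs):
                    ok = False
                    break
            if ok:
                best = cover
                break
        if best:
            return len(best)
    return None


class TestLetterGroups:
    def test_full_separation(self):
        comps = [_comparison("A", "B", 0.01), _comparison("A", "C", 0.001),
                 _comparison("B", "C", 0.02)]
        est = {"A": 18.7, "B": 23.3, "C": 15.4}
        assert letter_groups(comps, est) == {"C": "a", "A": "b", "B": "c"}

    def test_one_nonsignificant_pair(self):
        comps = [_comparison("A", "B", 0.2), _comparison("A", "C", 0.01),
                 _comparison("B", "C", 0.02)]
        est = {"A": 0.160, "B": 0.166, "C": 0.139}
        labels = letter_groups(comps, est)
        assert labels["A"] == labels["B"]
        assert labels["C"] != labels["A"]
        assert labels == {"C": "a", "A": "b", "B": "b"}

    def test_random_p_matrices_match_set_cover_oracle(self):
        rng = np.random.default_rng(11)
        diets = ["A", "B", "C"]
        for _ in range(50):
            ps = {}
            comps = []
            for a, b in itertools.combinations(diets, 2):
                p = float(rng.choice([0.001, 0.2], p=[0.5, 0.5]))
                ps[frozenset((a, b))] = p
                comps.append(_comparison(a, b, p))
            est = {d: float(rng.uniform(0, 1)) for d in diets}
            labels = letter_groups(comps, est, alpha=0.05)
            nonsig = {k for k, p in ps.items() if p > 0.05}
            # sharing pattern must equal nonsignificance exactly
            for a, b in itertools.combinations(diets, 2):
                share = bool(set(labels[a]) & set(labels[b]))
                assert share == (frozenset((a, b)) in nonsig)
            n_letters = len(set("".join(labels.values())))
            assert n_letters == _cld_oracle(diets, est, nonsig)

    def test_incomplete_pair_coverage_rejected(self):
        comps = [_comparison("A", "B", 0.2)]
        with pytest.raises(InputError, match="pair"):
            letter_groups(comps, {"A": 1.0, "B": 2.0, "C": 3.0})
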