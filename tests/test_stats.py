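"""Exact tests, ΔΔCT quantification and the reduction arithmetic,
checked against brute-force enumeration oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st_
from scipy import stats as sps

from ictal import (ContingencyTable2x2, GroupOutcome, QPCRPlate,
                   ddct_fold_change, fisher_exact_two_sided,
                   fjb_protection_class, frequency_reduction,
                   incidence_reduction, mann_whitney, percent_of_day0)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def pmf(k):
        return math.comb(r1, k) * math.comb(r2, c1 - k) / denom

    p_obs = pmf(a)
    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    return sum(pmf(k) for k in range(kmin, kmax + 1)
               if pmf(k) <= p_obs * (1 + 1e-12))


class TestFisher:
    def test_balanced_table_is_one(self):
        assert fisher_exact_two_sided(ContingencyTable2x2(1, 1, 1, 1)) == 1.0

    def test_tiny_table_enumeration(self):
        # margins (2,2)/(2,2): three admissible tables, p = 1/3
        assert fisher_exact_two_sided(ContingencyTable2x2(2, 0, 0, 2)) \
            == pytest.approx(1.0 / 3.0)

    def test_srs_incidence_table(self):
        # 10/10 vs 3/11 rats with at least one spontaneous seizure
        p = fisher_exact_two_sided(ContingencyTable2x2(10, 0, 3, 8))
        assert p == pytest.approx(0.001, abs=5e-4)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 1, 1, 1)

    @given(st_.integers(0, 12), st_.integers(0, 12),
           st_.integers(0, 12), st_.integers(0, 12))
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
        assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9)

    @given(st_.integers(0, 12), st_.integers(0, 12),
           st_.integers(0, 12), st_.integers(0, 12))
    def test_invariant_under_double_swap(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p1 = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
        p2 = fisher_exact_two_sided(ContingencyTable2x2(d, c, b, a))
        assert p1 == pytest.approx(p2, rel=1e-9)


def mw_oracle(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration of group
    assignments (midranks)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    mean_u = n1 * (len(y)) / 2.0
    obs_u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    obs_dev = abs(obs_u1 - mean_u)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u1 = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u1 - mean_u) >= obs_dev - 1e-9:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_identical_samples(self):
        u, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert u == 4.5  # n1 n2 / 2
        assert p == 1.0

    def test_fully_separated_samples(self):
        u, p = mann_whitney([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_scale_shift_invariance(self):
        x, y = [1.0, 5.0, 2.0, 8.0], [3.0, 9.0, 4.0]
        u1, p1 = mann_whitney(x, y)
        u2, p2 = mann_whitney([3 * v + 7 for v in x], [3 * v + 7 for v in y])
        assert (u1, p1) == (u2, p2)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @given(st_.lists(st_.integers(0, 6), min_size=4, max_size=4),
           st_.lists(st_.integers(0, 6), min_size=4, max_size=4))
    def test_exact_path_matches_permutation_oracle(self, x, y):
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(mw_oracle(x, y), rel=1e-9)

    def test_exact_path_matches_scipy_without_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            x = rng.normal(size=6)
            y = rng.normal(size=7)
            _, p = mann_whitney(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="exact").pvalue
            assert p == pytest.approx(float(ref), rel=1e-9)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        y = rng.normal(1.0, size=20)
        _, p = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic").pvalue
        assert p == pytest.approx(float(ref), rel=1e-9)


def make_plate(delta_shift=0.0):
    """Two control and two treated samples with known CT structure."""
    hk = {"ACTB": 18.2, "GAPDH": 17.3, "HPRT1": 21.3}
    samples, groups = {}, {}
    for i, (group, shift) in enumerate([("control", 0.0), ("control", 0.0),
                                        ("dfp_se", delta_shift),
                                        ("dfp_se", delta_shift)]):
        sid = f"s{i}"
        samples[sid] = dict(hk, CCL2=25.0 + shift)
        groups[sid] = group
    return QPCRPlate(samples=samples, groups=groups)


class TestDdct:
    def test_housekeeping_geomean_matches_published_value(self):
        plate = make_plate()
        assert round(plate.housekeeping_geomean("s0"), 1) == 18.9

    def test_sample_at_control_mean_has_unit_fold(self):
        result = ddct_fold_change(make_plate(0.0), "CCL2")
        assert result["group_mean"]["control"] == pytest.approx(1.0)
        assert result["group_mean"]["dfp_se"] == pytest.approx(1.0)

    def test_two_cycles_earlier_is_fourfold(self):
        # ΔCT two cycles below control -> 2^2 = 4-fold induction
        result = ddct_fold_change(make_plate(-2.0), "CCL2")
        assert result["group_mean"]["dfp_se"] == pytest.approx(4.0)

    def test_missing_housekeeping_rejected(self):
        with pytest.raises(ValueError, match="housekeeping"):
            QPCRPlate(samples={"s0": {"ACTB": 18.0, "GAPDH": 17.0}},
                      groups={"s0": "control"})

    def test_missing_target_rejected(self):
        plate = make_plate()
        with pytest.raises(ValueError, match="target"):
            ddct_fold_change(plate, "IL6")


class TestClassificationAndReductions:
    @pytest.mark.parametrize("count,expected", [
        (0, "protected"), (10, "protected"),
        (11, "degenerating"), (254, "degenerating"),
    ])
    def test_fjb_rule(self, count, expected):
        assert fjb_protection_class(count) == expected

    def test_fjb_negative_rejected(self):
        with pytest.raises(ValueError):
            fjb_protection_class(-1)

    def test_incidence_reduction_from_study_counts(self):
        urethane = GroupOutcome("urethane", 11, n_positive=3)
        diazepam = GroupOutcome("diazepam", 10, n_positive=10)
        assert incidence_reduction(urethane, diazepam) == 73

    def test_incidence_reduction_edges(self):
        g = GroupOutcome("a", 10, n_positive=5)
        assert incidence_reduction(g, g) == 0
        assert incidence_reduction(GroupOutcome("z", 8, n_positive=0), g) \
            == 100
        with pytest.raises(ValueError):
            incidence_reduction(g, GroupOutcome("r", 10, n_positive=0))

    def test_frequency_reduction_from_study_counts(self):
        urethane = GroupOutcome("urethane", 11, events_total=7)
        diazepam = GroupOutcome("diazepam", 10, events_total=76)
        assert frequency_reduction(urethane, diazepam) \
            == pytest.approx(91.6, abs=0.05)

    def test_frequency_reduction_edges(self):
        g = GroupOutcome("a", 10, events_total=30)
        assert frequency_reduction(g, g) == 0.0
        assert frequency_reduction(GroupOutcome("z", 5, events_total=0), g) \
            == 100.0
        with pytest.raises(ValueError):
            frequency_reduction(g, GroupOutcome("r", 10, events_total=0))

    def test_percent_of_day0(self):
        weights = {0: 250.0, 1: 227.5, 4: 240.0}
        out = percent_of_day0(weights)
        assert out[0] == 100.0
        assert out[1] == pytest.approx(91.0)
        assert out[4] == pytest.approx(96.0)
        with pytest.raises(ValueError):
            percent_of_day0({0: 0.0, 1: 10.0})

    def test_group_outcome_validation(self):
        with pytest.raises(ValueError):
            GroupOutcome("x", 5, n_positive=6)
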