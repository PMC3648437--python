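import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import stdtr

from seroarray import (
    DifferentialReactivityAnalysis,
    Thresholds,
    anova_pvalue,
    cantelli_pvalue,
    fold_change,
    gen_array_dataset,
    m_pvalue,
    m_statistic,
    prepost_compare,
    rlm_normalize,
    select_significant,
    ttest_from_summary,
    ttest_unpaired,
)
from seroarray.errors import ValidationError


def enumerated_m_tail(m, n_case, n_control):
    """Exhaustive oracle: fraction of label assignments of distinct ranks
    with at least m of the top ranks in the case group."""
    n = n_case + n_control
    hits = total = 0
    for case_ranks in itertools.combinations(range(n), n_case):
        case = set(case_ranks)
        ctrl_max = max(r for r in range(n) if r not in case)
        hits += sum(r > ctrl_max for r in case) >= m
        total += 1
    return Fraction(hits, total)


class TestMStatistic:
    def test_counts_cases_above_control_max(self):
        assert m_statistic([9, 8, 2], [7, 1, 0]) == 2

    def test_zero_when_cases_below_control_max(self):
        assert m_statistic([1, 2, 3], [5, 6]) == 0

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            m_statistic([], [1.0])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_count(self, seed):
        rng = np.random.default_rng(seed)
        case = rng.normal(size=10)
        ctrl = rng.normal(size=10)
        oracle = sum(1 for c in case if all(c > x for x in ctrl))
        assert m_statistic(case, ctrl) == oracle

    def test_ties_with_control_max_never_count(self):
        ctrl = [1.0, 5.0]
        assert m_statistic([5.0, 6.0], ctrl) == 1
        # adding a value epsilon below the control max cannot increase m
        assert m_statistic([5.0, 6.0, 5.0 - 1e-12], ctrl) == 1


class TestMPValue:
    def test_ten_vs_ten_full_sweep_equals_closed_form(self):
        assert m_pvalue(10, 10, 10) == pytest.approx(1 / 184756)

    def test_m_zero_is_one(self):
        assert m_pvalue(0, 7, 3) == 1.0

    def test_enumeration_example_small_groups(self):
        # all 20 assignments of 6 ranks; top 2 in group 1 in 3 of 15... = 0.2
        assert m_pvalue(2, 3, 3) == pytest.approx(0.2)
        assert enumerated_m_tail(2, 3, 3) == Fraction(3, 15)

    def test_m_exceeding_group_size_rejected(self):
        with pytest.raises(ValidationError):
            m_pvalue(4, 3, 3)

    @given(st.integers(1, 6), st.integers(1, 6))
    @settings(max_examples=36, deadline=None)
    def test_strictly_decreasing_in_m(self, n_case, n_control):
        values = [m_pvalue(m, n_case, n_control) for m in range(n_case + 1)]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestCantelli:
    @pytest.mark.parametrize(
        "z,two_sided,expected",
        [
            (3.0, False, 0.1),
            (3.0, True, 1 / 9),
            (0.0, False, 1.0),
            (0.0, True, 1.0),
            (-2.0, False, 1.0),
            (0.5, True, 1.0),
        ],
    )
    def test_known_values(self, z, two_sided, expected):
        assert cantelli_pvalue(z, two_sided=two_sided) == pytest.approx(expected)

    def test_upper_bounds_gaussian_tail(self):
        rng = np.random.default_rng(42)
        draws = rng.standard_normal(10_000)
        for z in (1.0, 2.0, 3.0):
            assert (draws >= z).mean() <= cantelli_pvalue(z)


class TestFoldChange:
    def test_ratio_of_means(self):
        assert fold_change([150, 250], [50, 150]) == pytest.approx(2.0)

    def test_identical_groups_give_one(self):
        assert fold_change([3, 4], [3, 4]) == pytest.approx(1.0)

    def test_zero_control_mean_rejected(self):
        with pytest.raises(ValidationError):
            fold_change([1.0], [0.0])

    def test_injected_eighteen_fold_recovered(self):
        exp, truth = gen_array_dataset(
            n_features=300,
            n_elevated=5,
            n_control_spots=50,
            fold_range=(18.0, 18.0),
            cv=0.2,
            seed=13,
        )
        norm = rlm_normalize(exp)
        lin = 2.0**norm.normalized_log2
        for fid in truth.elevated_ids:
            fc = fold_change(lin.loc[fid, exp.case_ids], lin.loc[fid, exp.control_ids])
            assert 18.0 * 0.75 <= fc <= 18.0 * 1.25


class TestTTests:
    def test_identical_groups_give_one(self):
        assert ttest_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_pooled_p_against_t_distribution(self):
        # groups with exact moments mean 1 vs 0, sd 1, n=10 each
        e = np.arange(10, dtype=float)
        e = (e - e.mean()) / e.std(ddof=1)
        p = ttest_unpaired(1.0 + e, e, welch=False)
        t = 1.0 / np.sqrt(2.0 / 10.0)
        assert p == pytest.approx(2 * stdtr(18, -t), abs=1e-12)
        assert p == pytest.approx(0.038, abs=1e-3)

    def test_summary_form_matches_moment_matched_samples(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m1, m2 = rng.normal(size=2)
            s1, s2 = rng.uniform(0.5, 2.0, size=2)
            n1, n2 = rng.integers(3, 12, size=2)
            a = rng.normal(size=n1)
            a = m1 + s1 * (a - a.mean()) / a.std(ddof=1)
            b = rng.normal(size=n2)
            b = m2 + s2 * (b - b.mean()) / b.std(ddof=1)
            for welch in (False, True):
                assert ttest_from_summary(
                    m1, s1, n1, m2, s2, n2, welch=welch
                ) == pytest.approx(ttest_unpaired(a, b, welch=welch), abs=1e-10)

    def test_discovery_cohort_ages_not_different(self):
        p = ttest_from_summary(29.6, 12.2, 10, 27.8, 10.7, 10, welch=False)
        assert round(p, 2) == 0.73

    def test_equal_means_from_summary(self):
        assert ttest_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10) == pytest.approx(1.0)


class TestAnova:
    def test_identical_groups_give_one(self):
        assert anova_pvalue([1.0, 2.0], [1.0, 2.0]) == pytest.approx(1.0)

    def test_equals_pooled_t_squared(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            a = rng.normal(size=rng.integers(2, 9))
            b = rng.normal(1.0, 2.0, size=rng.integers(2, 9))
            assert anova_pvalue(a, b) == pytest.approx(
                ttest_unpaired(a, b, welch=False), abs=1e-12
            )

    def test_hand_computed_sums_of_squares(self):
        case, ctrl = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
        # between SS = 6, within SS = 10, F = 6 / (10/4) = 2.4 on (1, 4) df
        expected = stats.f.sf(2.4, 1, 4)
        assert anova_pvalue(case, ctrl) == pytest.approx(expected, abs=1e-12)


class TestSelection:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["feature_id", "gene_symbol", "m", "p_m", "fold_change"]
        )

    def test_fold_boundary_is_strict_and_p_boundary_inclusive(self):
        table = self._table(
            [
                ("f1", "A", 5, 0.01, 2.0),  # fold exactly at cut: excluded
                ("f2", "B", 5, 0.05, 2.5),  # p exactly at cut: included
                ("f3", "C", 5, 0.051, 9.0),  # p above cut: excluded
            ]
        )
        kept = select_significant(table, Thresholds())
        assert kept["feature_id"].tolist() == ["f2"]

    def test_ordering_p_then_fold_then_id(self):
        table = self._table(
            [
                ("fb", "B", 5, 0.01, 3.0),
                ("fa", "A", 5, 0.01, 3.0),
                ("fc", "C", 5, 0.001, 2.5),
                ("fd", "D", 5, 0.01, 8.0),
            ]
        )
        kept = select_significant(table, Thresholds())
        assert kept["feature_id"].tolist() == ["fc", "fd", "fa", "fb"]

    def test_recovers_injected_features_end_to_end(self, small_dataset):
        experiment, truth = small_dataset
        norm = rlm_normalize(experiment)
        results = DifferentialReactivityAnalysis(norm).fit()
        selected = set(results.select_significant()["feature_id"])
        elevated = truth.elevated_ids
        assert len(selected & elevated) / len(elevated) >= 0.9
        assert len(selected - elevated) <= 10

    def test_cantelli_column_bounds_the_t_pvalue_scale(self, small_dataset):
        # the Cantelli bound is distribution-free, hence conservative:
        # never smaller than 1/(1+z^2) evaluated at the pooled z
        experiment, _ = small_dataset
        results = DifferentialReactivityAnalysis(rlm_normalize(experiment)).fit()
        table = results.table
        assert ((table["p_cheb"] > 0) & (table["p_cheb"] <= 1)).all()
        assert (table.loc[table["m"] == 0, "p_m"] == 1.0).all()


class TestPrePost:
    @pytest.mark.parametrize(
        "m,expected",
        [(4, 5 / 210), (3, 10 / 120), (5, 1 / 252)],
    )
    def test_five_vs_five_tail_levels(self, m, expected):
        assert m_pvalue(m, 5, 5) == pytest.approx(expected)
        assert m_pvalue(m, 5, 5) == pytest.approx(float(enumerated_m_tail(m, 5, 5)))

    def test_prepost_uses_five_vs_five_levels(self, small_dataset):
        experiment, _ = small_dataset
        norm = rlm_normalize(experiment)
        table = prepost_compare(norm)
        attainable = {m_pvalue(m, 5, 5) for m in range(6)}
        assert set(np.round(table["p_active"], 12)) <= set(np.round(sorted(attainable), 12))

    def test_unmatched_subjects_warn(self, small_dataset):
        experiment, _ = small_dataset
        norm = rlm_normalize(experiment)
        pre = [s for s in experiment.samples.index[experiment.samples.timepoint == "pre"]]
        post = [s for s in experiment.samples.index[experiment.samples.timepoint == "post"]]
        with pytest.warns(UserWarning, match="not matched"):
            prepost_compare(norm, pre_ids=pre[:3], post_ids=post)
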