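"""Tests for the nonparametric cohort-comparison layer."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from melcurve import (
    b_max,
    boxplot_summary,
    cohort_medians,
    compare_cohorts,
    dlmo,
    kruskal_wallis,
    mann_whitney,
    truncate_2dp,
    wilcoxon_signed_rank,
)
from melcurve.datasets import angelman_reference_cohort
from melcurve.simulate import draw_params, group_default_spec
from melcurve.stats import PARAMETER_COLUMNS


def exact_mw_p(a, b):
    """Independent oracle: two-sided exact Mann-Whitney p by enumerating
    every assignment of pooled ranks to the first sample."""
    pooled = np.concatenate([a, b])
    n = len(a)
    order = np.argsort(pooled)
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2.0
    mn = len(a) * len(b)
    stat_obs = min(u_obs, mn - u_obs)
    count = total = 0
    all_ranks = np.arange(1, len(pooled) + 1)
    for idx in combinations(range(len(pooled)), n):
        u = all_ranks[list(idx)].sum() - n * (n + 1) / 2.0
        if min(u, mn - u) <= stat_obs + 1e-9:
            count += 1
        total += 1
    return count / total


class TestMedians:
    def test_reference_phase_median(self):
        ref = angelman_reference_cohort()
        med = cohort_medians(ref["b3"])
        assert med == pytest.approx(3.5904)
        assert truncate_2dp(med) == 3.59

    def test_reference_max_gamma_median_truncates_not_rounds(self):
        med = cohort_medians(angelman_reference_cohort()["max_gamma"])
        assert med == pytest.approx(2.657)
        assert truncate_2dp(med) == 2.65  # rounding would give 2.66

    def test_single_value_and_empty(self):
        assert cohort_medians([4.2]) == 4.2
        with pytest.raises(ValueError):
            cohort_medians([])

    def test_median_invariances(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=11)
        assert cohort_medians(rng.permutation(x)) == cohort_medians(x)
        assert cohort_medians(x + 3.0) == pytest.approx(cohort_medians(x) + 3.0)

    @pytest.mark.parametrize(
        "value, expected", [(10.4783, 10.47), (2.657, 2.65), (8.720665, 8.72), (7.0, 7.0)]
    )
    def test_truncation_rule(self, value, expected):
        assert truncate_2dp(value) == expected


class TestMannWhitney:
    def test_identical_multisets_give_central_u(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney(a, a)
        assert res.u_statistic == len(a) ** 2 / 2
        assert res.p_value > 0.9

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for n_a, n_b in [(3, 3), (4, 4), (3, 5), (5, 4), (2, 6)]:
            vals = rng.choice(np.arange(100), size=n_a + n_b, replace=False).astype(float)
            a, b = vals[:n_a], vals[n_a:]
            res = mann_whitney(a, b, mode="exact")
            assert res.p_value == pytest.approx(exact_mw_p(a, b), abs=1e-12)

    def test_complete_separation_minimal_p(self):
        from math import comb

        a = [1.0, 2.0, 3.0, 4.0]
        b = [10.0, 11.0, 12.0, 13.0]
        res = mann_whitney(a, b, mode="exact")
        assert res.u_statistic in (0.0, 16.0)
        assert res.p_value == pytest.approx(2 / comb(8, 4))

    def test_u_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.normal(size=rng.integers(2, 12))
            b = rng.normal(size=rng.integers(2, 12))
            assert (
                mann_whitney(a, b).u_statistic + mann_whitney(b, a).u_statistic
                == len(a) * len(b)
            )

    def test_auto_mode_switches_on_ties_and_size(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 5.0]
        assert mann_whitney(a, b).method == "normal-approx"  # tie present
        assert mann_whitney([1.0, 2.0], [3.0, 4.0]).method == "exact"
        big = list(np.arange(30.0))
        assert mann_whitney(big, [x + 0.5 for x in big]).method == "normal-approx"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestKruskalWallis:
    def test_hand_computed_instance(self):
        # three tie-free groups; H computed by hand from pooled ranks:
        # ranks a={1,2,4}, b={3,5,7}, c={6,8,9}; rank sums 7, 15, 23;
        # H = 12/(9*10) * (49/3 + 225/3 + 529/3) - 3*10 = 5.6889
        a, b, c = [1.0, 2.0, 4.5], [3.0, 5.5, 8.0], [7.0, 9.0, 10.0]
        h, p = kruskal_wallis([a, b, c])
        assert h == pytest.approx(12 / 90 * (49 + 225 + 529) / 3 - 30, abs=1e-9)
        assert 0 < p < 1

    def test_all_tied_convention(self):
        h, p = kruskal_wallis([[5.0, 5.0], [5.0, 5.0, 5.0]])
        assert (h, p) == (0.0, 1.0)

    def test_two_groups_agree_with_mann_whitney(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
        _, p_kw = kruskal_wallis([a, b])
        p_mw = mann_whitney(a, b, mode="normal-approx").p_value
        assert p_kw == pytest.approx(p_mw, abs=0.02)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])


def test_wilcoxon_signed_rank_detects_paired_shift():
    rng = np.random.default_rng(5)
    a = rng.normal(0, 1, 20)
    _, p = wilcoxon_signed_rank(a, a + 1.5)
    assert p < 0.01


def _marker_table(group: str, n: int, seed: int) -> pd.DataFrame:
    spec = group_default_spec(group, n, seed=seed)
    params = draw_params(spec, np.random.default_rng(seed))
    rows = []
    for p in params:
        d = dlmo(p)
        rows.append(
            {"b1": p.b1, "b2": p.b2, "b3": p.b3, "b4": p.b4, "b_max": b_max(p),
             "dlmo_on50": d.on50, "dlmo_off50": d.off50,
             "dlmo_on25": d.on25, "dlmo_off25": d.off25, "max_gamma": 1.0}
        )
    return pd.DataFrame(rows)


class TestCompareCohorts:
    def test_self_comparison_is_null(self):
        tab = _marker_table("AG", 9, seed=60)
        for comp in compare_cohorts(tab, tab):
            assert comp.p_value >= 0.95
            assert not comp.significant
            assert comp.u_statistic == comp.n_a * comp.n_b / 2

    def test_missing_column_rejected(self):
        tab = _marker_table("AG", 9, seed=61)
        with pytest.raises(ValueError, match="missing columns"):
            compare_cohorts(tab.drop(columns=["b4"]), tab)
        with pytest.raises(ValueError, match="empty"):
            compare_cohorts(tab.iloc[:0], tab)

    def test_synthetic_cohorts_mirror_group_significance_pattern(self):
        """Angelman-like vs control cohorts (9 vs 40 subjects, default
        priors): phase, sleep duration and the DLMO offsets separate the
        groups; the onsets and the baseline do not.  Judged on median
        p-values across 15 seeded replicate cohort draws."""
        pvals = {c: [] for c in PARAMETER_COLUMNS if c not in ("b2", "b_max", "max_gamma")}
        for rep in range(15):
            ta = _marker_table("AG", 9, seed=1000 + rep)
            tc = _marker_table("CG", 40, seed=5000 + rep)
            for comp in compare_cohorts(ta, tc, parameters=list(pvals)):
                pvals[comp.parameter_name].append(comp.p_value)
        med = {k: float(np.median(v)) for k, v in pvals.items()}
        for name in ("b3", "b4", "dlmo_off50", "dlmo_off25"):
            assert med[name] < 0.05, (name, med[name])
        for name in ("b1", "dlmo_on50", "dlmo_on25"):
            assert med[name] >= 0.05, (name, med[name])


def test_boxplot_summary_tukey_fences():
    vals = [1.0, 2.0, 3.0, 4.0, 5.0, 100.0]
    s = boxplot_summary(vals)
    assert s["min"] == 1.0 and s["max"] == 100.0
    assert 100.0 in s["outliers"]
    assert s["whisker_high"] == 5.0
    assert s["q1"] <= s["median"] <= s["q3"]
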