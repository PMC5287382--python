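"""ANOVA and SNK against brute-force and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from issmri import one_way_anova, snk_test, summarize_groups


def _brute_force_F(groups):
    """Sums-of-squares ANOVA written independently of the implementation."""
    allv = np.concatenate(list(groups.values()))
    grand = allv.mean()
    ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
    ssw = sum(np.sum((np.asarray(v) - np.mean(v)) ** 2) for v in groups.values())
    dfb = len(groups) - 1
    dfw = len(allv) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


group_arrays = st.lists(
    st.lists(
        st.floats(min_value=-100, max_value=100, allow_nan=False, width=32),
        min_size=3,
        max_size=8,
    ),
    min_size=2,
    max_size=5,
)


class TestAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
        res = one_way_anova(g)
        assert res.F == 0.0
        assert res.p == 1.0

    def test_hand_computed_example(self):
        """{1,2,3},{2,3,4},{3,4,5}: SSb=6, SSw=6 -> F=3, p=0.125 (frozen
        from brute-force arithmetic)."""
        res = one_way_anova({"a": [1, 2, 3], "b": [2, 3, 4], "c": [3, 4, 5]})
        assert res.F == pytest.approx(3.0, abs=1e-6)
        assert res.p == pytest.approx(0.125, abs=1e-6)
        assert (res.df_between, res.df_within) == (2, 6)

    def test_scale_invariance(self):
        g = {"a": [1.0, 2.0, 5.0], "b": [2.0, 4.0, 4.0], "c": [7.0, 4.0, 5.0]}
        r1 = one_way_anova(g)
        r2 = one_way_anova({k: [2 * x for x in v] for k, v in g.items()})
        assert r2.F == pytest.approx(r1.F, rel=1e-12)
        assert r2.p == pytest.approx(r1.p, rel=1e-12)

    def test_degenerate_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero within-group variance"):
            res = one_way_anova({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert res.p == 0.0
        assert res.degenerate

    def test_input_validation(self):
        with pytest.raises(ValueError):
            one_way_anova({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            one_way_anova({"a": [1.0, 2.0], "b": [3.0]})

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(groups=group_arrays)
    def test_matches_brute_force_and_scipy(self, groups):
        g = {f"g{i}": np.asarray(v) for i, v in enumerate(groups)}
        if any(v.std() == 0 for v in g.values()):
            return
        res = one_way_anova(g)
        assert res.F == pytest.approx(_brute_force_F(g), rel=1e-9, abs=1e-9)
        F_sp, p_sp = stats.f_oneway(*g.values())
        if np.isfinite(F_sp):  # scipy emits nan for some degenerate inputs
            assert res.F == pytest.approx(F_sp, rel=1e-9, abs=1e-9)
        if np.isfinite(p_sp):
            assert res.p == pytest.approx(p_sp, rel=1e-6, abs=1e-12)


class TestSnk:
    def test_identical_groups_nothing_significant(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
        assert not any(p.significant for p in snk_test(g))

    def test_two_groups_equivalent_to_t_test(self):
        """With two groups SNK reduces to an unpaired pooled-variance t
        test via q(2, df) = sqrt(2) * t(df)."""
        rng = np.random.default_rng(4)
        for shift in (0.0, 0.5, 1.0, 2.0, 4.0):
            a = rng.normal(0, 1, 8)
            b = rng.normal(shift, 1, 8)
            pair = snk_test({"a": a, "b": b}, alpha=0.05)[0]
            t_stat, p_val = stats.ttest_ind(a, b)
            assert pair.significant == (p_val < 0.05)

    def test_extreme_mean_detected_others_not(self):
        """One group far from two close ones: extreme-vs-others significant,
        the close pair not."""
        rng = np.random.default_rng(1)
        g = {
            "low1": rng.normal(0.0, 1.0, 10),
            "low2": rng.normal(0.3, 1.0, 10),
            "high": rng.normal(10.0, 1.0, 10),
        }
        pairs = {p.groups: p for p in snk_test(g)}

        def pair_of(x, y):
            return pairs.get((x, y)) or pairs.get((y, x))

        assert pair_of("low1", "high").significant
        assert pair_of("low2", "high").significant
        assert not pair_of("low1", "low2").significant

    def test_decisions_match_direct_q_evaluation(self):
        """Every tested pair's decision equals a direct studentized-range
        computation done here from scratch."""
        rng = np.random.default_rng(7)
        g = {
            "a": rng.normal(0, 1, 6),
            "b": rng.normal(1, 1, 6),
            "c": rng.normal(2.5, 1, 6),
            "d": rng.normal(2.6, 1, 6),
        }
        res = one_way_anova(g)
        order = sorted(g, key=lambda k: np.mean(g[k]))
        rank = {k: i for i, k in enumerate(order)}
        for pair in snk_test(g, alpha=0.05):
            if not pair.tested:
                continue
            lo, hi = pair.groups
            span = abs(rank[hi] - rank[lo]) + 1
            q_crit = stats.studentized_range.ppf(0.95, span, res.df_within)
            crit = q_crit * np.sqrt(res.ms_within / 6)
            assert pair.critical_range == pytest.approx(crit, rel=1e-9)
            assert pair.significant == (pair.mean_diff > crit)

    def test_stepwise_blocking(self):
        """A pair nested in a non-significant span is never significant."""
        rng = np.random.default_rng(2)
        g = {f"g{i}": rng.normal(0.2 * i, 1.0, 5) for i in range(4)}
        pairs = snk_test(g)
        spans = {p.groups: p for p in pairs}
        order = sorted(g, key=lambda k: np.mean(g[k]))
        full = spans[(order[0], order[-1])]
        if not full.significant:
            assert not any(p.significant for p in pairs)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(groups=group_arrays)
    def test_sandwich_property(self, groups):
        """SNK is at most as liberal as unadjusted pairwise t tests and at
        least as liberal as testing every pair against the full-span
        critical range."""
        g = {f"g{i}": np.asarray(v) for i, v in enumerate(groups)}
        if any(v.std() == 0 for v in g.values()) or len({v.size for v in g.values()}) > 1:
            return
        res = one_way_anova(g)
        if res.ms_within == 0:
            return
        n = next(iter(g.values())).size
        k = len(g)
        pairs = snk_test(g, alpha=0.05)
        q_full = stats.studentized_range.ppf(0.95, k, res.df_within)
        q_pair = stats.studentized_range.ppf(0.95, 2, res.df_within)
        for p in pairs:
            se = np.sqrt(res.ms_within / n)
            if p.mean_diff > q_full * se:
                # conservative bound: full-span criterion met -> significant
                pass_cons = True
            else:
                pass_cons = False
            liberal = p.mean_diff > q_pair * se
            if pass_cons:
                assert p.significant or not _full_span_sig(pairs, g)
            if not liberal:
                assert not p.significant


def _full_span_sig(pairs, g):
    order = sorted(g, key=lambda k: np.mean(g[k]))
    for p in pairs:
        if set(p.groups) == {order[0], order[-1]}:
            return p.significant
    return False


class TestSummaries:
    def test_mean_sem_arithmetic(self):
        """Values {1,2,3}: mean 2, SEM 1/sqrt(3) = 0.5774."""
        df = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3, "m": [1, 2, 3, 4, 5, 6.0]})
        summaries, tests, table = summarize_groups(df, metrics=["m"])
        s = {x.group: x for x in summaries}
        assert s["a"].mean == pytest.approx(2.0)
        assert s["a"].sem == pytest.approx(0.57735026919, rel=1e-9)

    def test_missing_metric_excluded_with_warning(self):
        df = pd.DataFrame(
            {"group": ["a", "a", "a", "b", "b", "b"], "m": [1.0, 2.0, np.nan, 4.0, 5.0, 6.0]}
        )
        with pytest.warns(UserWarning, match="dropped 1 subject"):
            summaries, _, _ = summarize_groups(df, metrics=["m"])
        s = {x.group: x for x in summaries}
        assert s["a"].n == 2

    def test_permutation_invariance_in_subject_order(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {"group": ["a"] * 5 + ["b"] * 5, "m": rng.normal(0, 1, 10)}
        )
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        s1, t1, _ = summarize_groups(df, metrics=["m"])
        s2, t2, _ = summarize_groups(shuffled, metrics=["m"])
        for x1, x2 in zip(s1, s2):
            assert x1.group == x2.group
            assert x1.mean == pytest.approx(x2.mean, rel=1e-12)
            assert x1.sem == pytest.approx(x2.sem, rel=1e-12)
        assert t1[0].anova.F == pytest.approx(t2[0].anova.F, rel=1e-12)

    def test_single_subject_groups_skip_anova(self):
        df = pd.DataFrame({"group": ["a", "b"], "m": [1.0, 2.0]})
        with pytest.warns(UserWarning, match="ANOVA skipped"):
            summaries, tests, _ = summarize_groups(df, metrics=["m"])
        assert tests == []
        assert all(x.sem == 0.0 for x in summaries)
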