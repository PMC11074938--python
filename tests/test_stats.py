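"""Statistical procedures against hand computations and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from splxann import (
    AblationCondition,
    dunnett,
    kruskal_wallis,
    one_way_anova,
    rm_anova,
    shapiro_wilk,
    summarize_grid_significance,
    t_test,
)
from splxann.ablation import ConditionResult, GridResult, enumerate_conditions
from splxann.ensemble import AccuracyResult
from splxann.errors import (
    ConfigError,
    IncompleteGridError,
    UndefinedStatisticError,
)

# ---------------------------------------------------------------------------
# oracles


def anova_ss_oracle(groups):
    """One-way ANOVA F from explicit sums of squares."""
    all_x = np.concatenate(groups)
    grand = all_x.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_x) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


def mixed_anova_ss_oracle(table, response="y"):
    """Balanced two-group x within-day mixed ANOVA from cell means and SS."""
    wide = table.pivot(index="animal_id", columns="day", values=response)
    groups = table.groupby("animal_id")["group"].first()
    k = wide.shape[1]
    n_total = wide.shape[0]
    g_labels = sorted(groups.unique())
    grand = wide.to_numpy().mean()
    subj_means = wide.mean(axis=1)
    day_means = wide.mean(axis=0)
    group_means = {g: wide[groups == g].to_numpy().mean() for g in g_labels}
    n_per_group = {g: (groups == g).sum() for g in g_labels}

    ss_group = k * sum(n_per_group[g] * (group_means[g] - grand) ** 2 for g in g_labels)
    ss_between_subj = k * ((subj_means - grand) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_group
    ss_day = n_total * ((day_means - grand) ** 2).sum()
    ss_inter = 0.0
    for g in g_labels:
        cell = wide[groups == g].mean(axis=0)
        ss_inter += n_per_group[g] * (
            (cell - group_means[g] - day_means + grand) ** 2
        ).sum()
    ss_ws_total = ((wide.sub(subj_means, axis=0)) ** 2).to_numpy().sum()
    ss_err = ss_ws_total - ss_day - ss_inter

    n_groups = len(g_labels)
    df_err_b = n_total - n_groups
    df_err_w = df_err_b * (k - 1)
    f_group = (ss_group / (n_groups - 1)) / (ss_subj_within / df_err_b)
    f_day = (ss_day / (k - 1)) / (ss_err / df_err_w)
    f_inter = (ss_inter / ((n_groups - 1) * (k - 1))) / (ss_err / df_err_w)
    return f_group, f_day, f_inter


def dunnett_critical_mc_oracle(k, n, alpha=0.05, draws=1_000_000, seed=0):
    """Monte-Carlo 1-alpha quantile of max |T_i| for balanced Dunnett.

    T_i = (xbar_i - xbar_0) / (s * sqrt(2/n)) with the pooled s on N - k df.
    Returns (critical value, Monte-Carlo standard error estimate).
    """
    rng = np.random.default_rng(seed)
    df = k * n - k
    means = rng.normal(0.0, 1.0 / np.sqrt(n), size=(draws, k))
    s = np.sqrt(rng.chisquare(df, size=draws) / df)
    t_stats = (means[:, 1:] - means[:, [0]]) / (s[:, None] * np.sqrt(2.0 / n))
    max_abs = np.abs(t_stats).max(axis=1)
    crit = np.quantile(max_abs, 1 - alpha)
    # SE of the quantile via the asymptotic density estimate
    band = np.mean((max_abs > crit - 0.01) & (max_abs < crit + 0.01)) / 0.02
    se = np.sqrt(alpha * (1 - alpha) / draws) / max(band, 1e-9)
    return crit, se


def make_grid(accs_by_condition, day_filter="all-days"):
    """Fabricate a GridResult from {condition_id_suffix: (splx, sham)} lists."""
    variables = ("day", "mr_il")
    conditions = enumerate_conditions(variables, day_filter)
    results = []
    for cond in conditions:
        key = "baseline" if cond.is_baseline else "+".join(sorted(cond.excluded))
        splx_acc, sham_acc = accs_by_condition[key]
        results.append(
            ConditionResult(
                cond,
                AccuracyResult(cond.condition_id, "SPLX", list(splx_acc)),
                AccuracyResult(cond.condition_id, "SPL-sham", list(sham_acc)),
                seed=0,
            )
        )
    return GridResult(results)


# ---------------------------------------------------------------------------
# tests


class TestShapiroWilk:
    def test_too_small_sample_rejected(self):
        with pytest.raises(ConfigError):
            shapiro_wilk([1.0, 2.0])

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=25)
        w1 = shapiro_wilk(x).statistic
        w2 = shapiro_wilk(3.5 * x + 11.0).statistic
        assert w1 == pytest.approx(w2, abs=1e-10)

    def test_reference_sample_against_oracle(self):
        # frozen from R's shapiro.test (Royston's algorithm) on this sample:
        # W = 0.7888146948, p = 0.0067038141
        x = np.array([148, 154, 158, 160, 161, 162, 166, 170, 182, 195, 236.0])
        res = shapiro_wilk(x)
        assert res.statistic == pytest.approx(0.7888146948, abs=1e-6)
        assert res.p == pytest.approx(0.0067038141, abs=1e-4)


class TestTTest:
    def test_identical_samples(self):
        res = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "student")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-12)

    def test_welch_df_closed_form(self):
        """Samples with exact variances 1 (n=5) and 4 (n=10) give df = 12.96."""
        x = np.array([-1.0, -1.0, 0.0, 1.0, 1.0])          # var exactly 1
        y = np.array([-3.0, -3.0, 0, 0, 0, 0, 0, 0, 3.0, 3.0]) + 1.0  # var 4
        res = t_test(x, y, "welch")
        closed = (1 / 5 + 4 / 10) ** 2 / ((1 / 5) ** 2 / 4 + (4 / 10) ** 2 / 9)
        assert closed == pytest.approx(12.96, abs=1e-12)
        assert res.df == pytest.approx(closed, abs=1e-10)

    def test_student_hand_example(self):
        res = t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0], "student")
        assert res.statistic == pytest.approx(-np.sqrt(1.5), abs=1e-10)  # -1.2247
        assert res.df == 4

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            t_test([2.0, 2.0], [2.0, 2.0])

    def test_paired_variant(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = t_test(x, x + [0.5, 1.5, 0.5, 1.5], "paired")
        assert res.df == 3


class TestOneWayAnova:
    def test_two_groups_equals_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=10), rng.normal(0.5, 1, size=12)
        f = one_way_anova(a, b)
        t = t_test(a, b, "student")
        assert f.statistic == pytest.approx(t.statistic**2, abs=1e-10)
        assert f.p == pytest.approx(t.p, abs=1e-10)

    def test_equal_means_zero_f(self):
        res = one_way_anova([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [2.0, 1.0, 3.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_ss_oracle(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(m, 1, size=6) for m in (0.0, 0.4, 1.1)]
        res = one_way_anova(*groups)
        assert res.statistic == pytest.approx(anova_ss_oracle(groups), abs=1e-10)
        assert res.df == (2.0, 15.0)


class TestKruskalWallis:
    def test_all_identical_h_zero(self):
        res = kruskal_wallis([2.0, 2.0], [2.0, 2.0])
        assert (res.statistic, res.p) == (0.0, 1.0)

    def test_hand_rank_example(self):
        res = kruskal_wallis([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == pytest.approx(2.4, abs=1e-10)

    def test_tie_correction_increases_h(self):
        # tie-corrected H divides by a factor <= 1
        tied = kruskal_wallis([1.0, 1.0, 2.0], [2.0, 3.0, 3.0])
        h_uncorrected = 12 / (6 * 7) * (
            3 * (np.mean([1.5, 1.5, 3.5]) - 3.5) ** 2
            + 3 * (np.mean([3.5, 5.5, 5.5]) - 3.5) ** 2
        )
        assert tied.statistic >= h_uncorrected - 1e-12


class TestDunnett:
    def test_k2_reduces_to_unadjusted_t(self):
        rng = np.random.default_rng(3)
        control, treat = rng.normal(size=8), rng.normal(0.8, 1, size=8)
        comp = dunnett([control, treat], control_index=0)[0]
        t = t_test(treat, control, "student")
        assert comp.statistic == pytest.approx(t.statistic, abs=1e-10)
        assert comp.p_adjusted == pytest.approx(t.p, abs=5e-4)  # MVT quadrature

    @pytest.mark.filterwarnings("ignore:Precision loss")
    def test_identical_groups_not_significant(self):
        g = [1.0, 2.0, 3.0, 4.0]
        comps = dunnett([g, list(g), list(g)], control_index=0)
        assert not any(c.significant for c in comps)

    def test_critical_value_matches_mc_oracle(self):
        """Balanced k=3, n=10: scipy's allowance vs a multivariate-t MC draw."""
        rng = np.random.default_rng(4)
        groups = [rng.normal(size=10) for _ in range(3)]
        res = sps.dunnett(*groups[1:], control=groups[0])
        ci = res.confidence_interval(0.95)
        diff = np.array([np.mean(g) - np.mean(groups[0]) for g in groups[1:]])
        pooled = np.sqrt(
            sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups) / (30 - 3)
        )
        crit_scipy = float(np.mean((ci.high - diff) / (pooled * np.sqrt(2 / 10))))
        crit_mc, se = dunnett_critical_mc_oracle(k=3, n=10, draws=1_000_000, seed=0)
        assert se < 0.01
        assert crit_scipy == pytest.approx(crit_mc, abs=0.01 + 3 * se)

    def test_control_index_validated(self):
        with pytest.raises(ConfigError):
            dunnett([[1.0, 2.0], [2.0, 3.0]], control_index=5)


class TestRMAnova:
    @staticmethod
    def _balanced_table(k_days=3, n_per_group=4, seed=0, group_shift=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for g_idx, group in enumerate(("SPLX", "SPL-sham")):
            for i in range(n_per_group):
                base = rng.normal(0, 1)
                for d in range(k_days):
                    rows.append(
                        {
                            "animal_id": f"{group}-{i}",
                            "group": group,
                            "day": d,
                            "y": base
                            + 0.5 * d
                            + group_shift * g_idx
                            + rng.normal(0, 0.7),
                        }
                    )
        return pd.DataFrame(rows)

    def test_matches_ss_oracle(self):
        table = self._balanced_table(k_days=3, n_per_group=4, seed=5, group_shift=0.6)
        res = rm_anova(table, "y")
        f_group, f_day, f_inter = mixed_anova_ss_oracle(table)
        assert res.between.statistic == pytest.approx(f_group, abs=1e-10)
        assert res.within.statistic == pytest.approx(f_day, abs=1e-10)
        assert res.interaction.statistic == pytest.approx(f_inter, abs=1e-10)

    def test_epsilon_bounds(self):
        for seed in range(3):
            table = self._balanced_table(k_days=4, n_per_group=5, seed=seed)
            res = rm_anova(table, "y")
            assert 1 / 3 - 1e-12 <= res.epsilon <= 1 + 1e-12
            df1, df2 = res.within.df
            cdf1, cdf2 = res.within_corrected.df
            assert cdf1 == pytest.approx(res.epsilon * df1)
            assert cdf2 == pytest.approx(res.epsilon * df2)

    def test_two_within_levels_epsilon_one(self):
        table = self._balanced_table(k_days=2, n_per_group=5, seed=1)
        res = rm_anova(table, "y")
        assert res.epsilon == 1.0
        assert res.within_corrected.p == pytest.approx(res.within.p, abs=1e-12)

    def test_incomplete_data_rejected(self):
        table = self._balanced_table().iloc[1:]
        with pytest.raises(Exception, match="listwise"):
            rm_anova(table, "y")

    def test_huynh_feldt_flag(self):
        table = self._balanced_table(k_days=4, n_per_group=6, seed=2)
        gg = rm_anova(table, "y", correction="gg")
        hf = rm_anova(table, "y", correction="hf")
        assert hf.epsilon >= gg.epsilon - 1e-12  # HF is the less severe correction


class TestGridSummary:
    def test_identical_replicates_nothing_significant(self):
        grid = make_grid(
            {
                "baseline": ([0.7, 0.7, 0.7], [0.7, 0.7, 0.7]),
                "day": ([0.7, 0.7, 0.7], [0.7, 0.7, 0.7]),
                "mr_il": ([0.7, 0.7, 0.7], [0.7, 0.7, 0.7]),
            }
        )
        report = summarize_grid_significance(grid)
        assert report.splx_vs_baseline_significant == 0
        assert report.sham_vs_baseline_significant == 0
        assert report.class_vs_class_significant == 0

    def test_hand_tallied_counts(self):
        # mr_il exclusion collapses SPLX accuracy far below baseline and far
        # below its own sham accuracy; the day exclusion changes nothing
        base = [0.80, 0.81, 0.79, 0.80, 0.80]
        low = [0.40, 0.41, 0.39, 0.40, 0.40]
        grid = make_grid(
            {
                "baseline": (base, base),
                "day": (base, base),
                "mr_il": (low, base),
            }
        )
        report = summarize_grid_significance(grid)
        assert report.splx_vs_baseline_significant == 1
        assert report.sham_vs_baseline_significant == 0
        assert report.class_vs_class_significant == 1
        assert report.sham_higher == 1 and report.splx_higher == 0
        assert report.largest_sham_minus_splx[1] == pytest.approx(0.40, abs=1e-9)

    def test_denominators(self):
        grid = make_grid(
            {
                "baseline": ([0.7, 0.71], [0.7, 0.72]),
                "day": ([0.68, 0.70], [0.71, 0.69]),
                "mr_il": ([0.66, 0.72], [0.70, 0.68]),
            }
        )
        report = summarize_grid_significance(grid)
        assert report.n_conditions == 3
        assert report.n_exclusions == 2  # #conditions - 1 baseline comparisons

    def test_incomplete_grid_lists_missing(self):
        grid = make_grid(
            {
                "baseline": ([0.7, 0.71], [0.7, 0.72]),
                "day": ([0.68, 0.70], [0.71, 0.69]),
                "mr_il": ([0.66, 0.72], [0.70, 0.68]),
            }
        )
        grid.results = grid.results[:-1]
        with pytest.raises(IncompleteGridError, match="mr_il"):
            summarize_grid_significance(grid, variables=("day", "mr_il"))
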