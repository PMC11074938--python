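"""Frequentist test battery and grid significance summaries.

Wraps the procedures the analysis relies on behind one uniform surface:
Shapiro-Wilk normality gate, Student/Welch/paired t tests, one-way ANOVA,
Kruskal-Wallis H, Dunnett many-to-one comparisons against a control, and
mixed between x within repeated-measures ANOVA with Greenhouse-Geisser
sphericity correction (Huynh-Feldt available behind a flag).  Each result
carries the statistic, degrees of freedom (fractional where the method
produces them), the p-value and the alpha used.

The grid summary compares every exclusion condition's per-class accuracy
against the complete-variable baseline with Dunnett's test and each
condition's two class accuracies against each other with a t test, and
reports significance counts, fractions, and the largest signed
class-accuracy differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .errors import (
    ConfigError,
    IncompleteGridError,
    SplxannError,
    UndefinedStatisticError,
)

__all__ = [
    "TestResult",
    "DunnettComparison",
    "RMAnovaResult",
    "ComparisonReport",
    "shapiro_wilk",
    "t_test",
    "one_way_anova",
    "kruskal_wallis",
    "dunnett",
    "rm_anova",
    "summarize_grid_significance",
]


@dataclass
class TestResult:
    """One hypothesis-test outcome."""

    name: str
    statistic: float
    df: float | tuple[float, float]
    p: float
    alpha: float = 0.05
    adjusted_p: float | None = None
    note: str = ""

    @property
    def significant(self) -> bool:
        p = self.adjusted_p if self.adjusted_p is not None else self.p
        return bool(p < self.alpha)


def shapiro_wilk(sample, alpha: float = 0.05) -> TestResult:
    """Shapiro-Wilk normality test (requires 3 <= n <= 5000)."""
    x = np.asarray(sample, dtype=float)
    if len(x) < 3 or len(x) > 5000:
        raise ConfigError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={len(x)}")
    res = sps.shapiro(x)
    return TestResult("W", float(res.statistic), float(len(x)), float(res.pvalue), alpha)


def t_test(x, y, variant: str = "welch", alpha: float = 0.05) -> TestResult:
    """Two-sided t test: ``student``, ``welch`` or ``paired``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ConfigError("t test needs n >= 2 per sample")
    if variant == "paired":
        if len(x) != len(y):
            raise ConfigError("paired t test needs equal-length samples")
        if np.ptp(x - y) == 0.0:
            raise UndefinedStatisticError("paired differences have zero variance")
        res = sps.ttest_rel(x, y)
        df = float(len(x) - 1)
    elif variant in ("student", "welch"):
        if np.ptp(x) == 0.0 and np.ptp(y) == 0.0 and x[0] == y[0]:
            raise UndefinedStatisticError(
                "both samples have zero variance with equal means"
            )
        res = sps.ttest_ind(x, y, equal_var=(variant == "student"))
        df = float(res.df)
    else:
        raise ConfigError(f"unknown t-test variant {variant!r}")
    return TestResult(
        "t", float(res.statistic), df, float(res.pvalue), alpha, note=variant
    )


def one_way_anova(*groups, alpha: float = 0.05) -> TestResult:
    """One-way fixed-effects ANOVA, F with (k-1, N-k) df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ConfigError("one-way ANOVA needs >= 2 groups with n >= 2 each")
    if all(np.ptp(g) == 0.0 for g in groups) and len({float(g[0]) for g in groups}) == 1:
        raise UndefinedStatisticError("zero within-group variance with equal means")
    res = sps.f_oneway(*groups)
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    return TestResult(
        "F", float(res.statistic), (float(k - 1), float(n_total - k)), float(res.pvalue), alpha
    )


def kruskal_wallis(*groups, alpha: float = 0.05) -> TestResult:
    """Kruskal-Wallis H with tie correction; all-identical data give H=0, p=1."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or sum(len(g) for g in groups) < 3:
        raise ConfigError("Kruskal-Wallis needs >= 2 groups and total N >= 3")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult("H", 0.0, float(len(groups) - 1), 1.0, alpha)
    res = sps.kruskal(*groups)
    return TestResult(
        "H", float(res.statistic), float(len(groups) - 1), float(res.pvalue), alpha
    )


@dataclass
class DunnettComparison:
    """One treatment-vs-control comparison from Dunnett's procedure."""

    index: int
    statistic: float
    p_adjusted: float
    alpha: float
    significant: bool


def dunnett(
    groups, control_index: int = 0, alpha: float = 0.05
) -> list[DunnettComparison]:
    """Dunnett many-to-one comparisons against a designated control.

    Familywise error is controlled through the multivariate-t distribution
    of the comparison statistics (scipy's implementation).  Degenerate
    all-constant inputs yield no significant comparison.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ConfigError("Dunnett needs >= 2 groups")
    if not (0 <= control_index < len(groups)):
        raise ConfigError(f"control index {control_index} out of range")
    control = groups[control_index]
    treatments = [g for i, g in enumerate(groups) if i != control_index]
    res = sps.dunnett(*treatments, control=control)
    out = []
    treat_positions = [i for i in range(len(groups)) if i != control_index]
    for pos, stat, p in zip(treat_positions, res.statistic, res.pvalue):
        p = float(p)
        significant = bool(p < alpha) if np.isfinite(p) else False
        out.append(DunnettComparison(pos, float(stat), p, alpha, significant))
    return out


@dataclass
class RMAnovaResult:
    """Mixed between x within ANOVA with sphericity-corrected variants."""

    between: TestResult
    within: TestResult
    within_corrected: TestResult
    interaction: TestResult
    interaction_corrected: TestResult
    epsilon: float
    correction: str


def _epsilon_corrected(tr: TestResult, eps: float, label: str) -> TestResult:
    df1, df2 = tr.df
    cdf1, cdf2 = eps * df1, eps * df2
    p = float(sps.f.sf(tr.statistic, cdf1, cdf2))
    return TestResult("F", tr.statistic, (cdf1, cdf2), p, tr.alpha, note=label)


def rm_anova(
    table: pd.DataFrame,
    response: str,
    subject: str = "animal_id",
    within: str = "day",
    between: str = "group",
    correction: str = "gg",
    alpha: float = 0.05,
) -> RMAnovaResult:
    """Mixed repeated-measures ANOVA (between groups x within days).

    Requires complete balanced within-subject data: every subject observed
    at every within level.  Sphericity is handled by epsilon-scaling both
    dfs of the within and interaction F tests — Greenhouse-Geisser by
    default, Huynh-Feldt with ``correction="hf"``.  With two within
    levels, epsilon is exactly 1 and the corrected tests equal the
    uncorrected ones.
    """
    if correction not in ("gg", "hf"):
        raise ConfigError(f"correction must be 'gg' or 'hf', got {correction!r}")
    data = table[[subject, within, between, response]].copy()
    wide = data.pivot_table(index=subject, columns=within, values=response, aggfunc="size")
    if wide.isna().any().any() or (wide != 1).any().any():
        missing = wide.stack(future_stack=True)
        bad = missing[(missing != 1) | missing.isna()].index.tolist()[:5]
        raise SplxannError(
            "incomplete within-subject data (each subject must be observed once "
            f"at every {within} level); apply listwise deletion or imputation "
            f"upstream. First offending (subject, {within}) cells: {bad}"
        )
    k = data[within].nunique()
    aov = pg.mixed_anova(
        data=data,
        dv=response,
        within=within,
        subject=subject,
        between=between,
        correction=True,
        effsize="np2",
    )
    aov = aov.set_index("Source")
    between_row = aov.loc[between]
    within_row = aov.loc[within]
    inter_row = aov.loc["Interaction"]
    if k == 2:
        eps = 1.0
    elif correction == "gg":
        eps = float(within_row["eps"])
    else:
        pivot = data.pivot_table(index=subject, columns=within, values=response)
        eps = float(pg.epsilon(pivot, correction="hf"))

    def _tr(row) -> TestResult:
        return TestResult(
            "F",
            float(row["F"]),
            (float(row["DF1"]), float(row["DF2"])),
            float(row["p_unc"]),
            alpha,
        )

    between_tr = TestResult(
        "F",
        float(between_row["F"]),
        (float(between_row["DF1"]), float(between_row["DF2"])),
        float(between_row["p_unc"]),
        alpha,
        note="between",
    )
    within_tr = _tr(within_row)
    inter_tr = _tr(inter_row)
    label = "greenhouse-geisser" if correction == "gg" else "huynh-feldt"
    return RMAnovaResult(
        between=between_tr,
        within=within_tr,
        within_corrected=_epsilon_corrected(within_tr, eps, label),
        interaction=inter_tr,
        interaction_corrected=_epsilon_corrected(inter_tr, eps, label),
        epsilon=eps,
        correction=correction,
    )


# ---------------------------------------------------------------------------
# grid significance summary


@dataclass
class ComparisonReport:
    """Significance tally of an ablation grid for one day filter."""

    day_filter: str
    alpha: float
    n_conditions: int
    n_exclusions: int
    splx_vs_baseline_significant: int
    sham_vs_baseline_significant: int
    class_vs_class_significant: int
    splx_higher: int
    sham_higher: int
    largest_splx_minus_sham: tuple[str, float]
    largest_sham_minus_splx: tuple[str, float]
    per_condition: pd.DataFrame = field(repr=False, default=None)

    @property
    def splx_vs_baseline_fraction(self) -> float:
        return self.splx_vs_baseline_significant / self.n_exclusions

    @property
    def sham_vs_baseline_fraction(self) -> float:
        return self.sham_vs_baseline_significant / self.n_exclusions

    @property
    def class_vs_class_fraction(self) -> float:
        return self.class_vs_class_significant / self.n_conditions

    def summary_lines(self) -> list[str]:
        return [
            f"day filter: {self.day_filter} (alpha={self.alpha})",
            (
                f"SPLX vs baseline significant: {self.splx_vs_baseline_significant}/"
                f"{self.n_exclusions} ({100 * self.splx_vs_baseline_fraction:.0f}%)"
            ),
            (
                f"SPL-sham vs baseline significant: {self.sham_vs_baseline_significant}/"
                f"{self.n_exclusions} ({100 * self.sham_vs_baseline_fraction:.0f}%)"
            ),
            (
                f"SPLX vs SPL-sham significant: {self.class_vs_class_significant}/"
                f"{self.n_conditions} ({100 * self.class_vs_class_fraction:.0f}%); "
                f"SPLX higher in {self.splx_higher}, SPL-sham higher in {self.sham_higher}"
            ),
            (
                f"largest SPLX - SPL-sham: {self.largest_splx_minus_sham[1]:+.4f} "
                f"at {self.largest_splx_minus_sham[0]}"
            ),
            (
                f"largest SPL-sham - SPLX: {self.largest_sham_minus_splx[1]:+.4f} "
                f"at {self.largest_sham_minus_splx[0]}"
            ),
        ]


def _expected_conditions(grid, variables=None) -> list:
    """Conditions a complete grid must contain.

    The variable universe is taken from ``variables`` when given; otherwise
    it is inferred as the union of all excluded sets (in a complete grid
    over k >= 2 variables every single variable occurs as an exclusion).
    A baseline-only grid (k = 1) is complete as is.
    """
    from .ablation import enumerate_conditions

    day_filter = grid.results[0].condition.day_filter
    universe = (
        set(variables)
        if variables is not None
        else set().union(*(r.condition.excluded for r in grid.results))
    )
    if not universe:
        return [r.condition for r in grid.results]
    return enumerate_conditions(universe, day_filter)


def summarize_grid_significance(
    grid, alpha: float = 0.05, variables=None
) -> ComparisonReport:
    """Tally Dunnett-vs-baseline and class-vs-class significance for a grid.

    ``grid`` must contain every enumerated condition of one day filter
    (checked against the subset lattice implied by its exclusions).
    Comparisons use the stored per-replicate accuracies: Dunnett on each
    class's accuracies with the baseline condition as control, and a Welch
    t test between the two classes within each condition.  Degenerate
    zero-variance comparisons count as non-significant.
    """
    if len(grid) == 0:
        raise IncompleteGridError("empty grid")
    day_filters = {r.condition.day_filter for r in grid}
    if len(day_filters) != 1:
        raise IncompleteGridError(
            f"grid mixes day filters {sorted(day_filters)}; summarize one at a time"
        )
    day_filter = day_filters.pop()
    baseline = grid.baseline(day_filter)
    exclusions = [r for r in grid if not r.condition.is_baseline]
    expected = _expected_conditions(grid, variables)
    have = {r.condition for r in grid}
    missing = [c.condition_id for c in expected if c not in have]
    if missing:
        raise IncompleteGridError(
            f"grid incomplete for {day_filter!r}; missing conditions: {missing}"
        )

    sig_splx = np.zeros(len(exclusions), dtype=bool)
    sig_sham = np.zeros(len(exclusions), dtype=bool)
    if exclusions:
        for which, flags in (("splx", sig_splx), ("sham", sig_sham)):
            control = getattr(baseline, which).accuracies
            samples = [getattr(r, which).accuracies for r in exclusions]
            if all(np.ptp(s) == 0 for s in samples) and np.ptp(control) == 0:
                continue  # every sample constant: nothing can be significant
            comparisons = dunnett([control] + samples, control_index=0, alpha=alpha)
            for comp in comparisons:
                flags[comp.index - 1] = comp.significant

    class_sig = []
    diffs = []
    for r in grid:
        d = r.splx.mean_acc - r.sham.mean_acc
        diffs.append((r.condition.condition_id, d))
        try:
            tr = t_test(r.splx.accuracies, r.sham.accuracies, variant="welch", alpha=alpha)
            class_sig.append((tr.significant, d))
        except UndefinedStatisticError:
            class_sig.append((False, d))
    n_sig = sum(1 for s, _ in class_sig if s)
    splx_higher = sum(1 for s, d in class_sig if s and d > 0)
    sham_higher = sum(1 for s, d in class_sig if s and d < 0)
    largest_pos = max(diffs, key=lambda t: t[1])
    largest_neg = min(diffs, key=lambda t: t[1])

    per_condition = pd.DataFrame(
        {
            "condition_id": [r.condition.condition_id for r in grid],
            "splx_mean": [r.splx.mean_acc for r in grid],
            "splx_sd": [r.splx.sd_acc for r in grid],
            "sham_mean": [r.sham.mean_acc for r in grid],
            "sham_sd": [r.sham.sd_acc for r in grid],
            "splx_minus_sham": [d for _, d in diffs],
            "class_vs_class_significant": [s for s, _ in class_sig],
        }
    )
    excl_ids = [r.condition.condition_id for r in exclusions]
    per_condition["splx_vs_baseline_significant"] = per_condition["condition_id"].map(
        dict(zip(excl_ids, sig_splx))
    )
    per_condition["sham_vs_baseline_significant"] = per_condition["condition_id"].map(
        dict(zip(excl_ids, sig_sham))
    )

    return ComparisonReport(
        day_filter=day_filter,
        alpha=alpha,
        n_conditions=len(grid),
        n_exclusions=len(exclusions),
        splx_vs_baseline_significant=int(sig_splx.sum()),
        sham_vs_baseline_significant=int(sig_sham.sum()),
        class_vs_class_significant=n_sig,
        splx_higher=splx_higher,
        sham_higher=sham_higher,
        largest_splx_minus_sham=(largest_pos[0], float(largest_pos[1])),
        largest_sham_minus_splx=(largest_neg[0], float(-largest_neg[1] + 0.0)),
        per_condition=per_condition,
    )
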