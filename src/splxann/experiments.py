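"""Canned study-condition experiments: calibration, power, error rates.

These functions run the full chain — generate a cohort at the study's
design (13 SPLX / 14 sham, days 2/4/7/28), fit per-cell estimators,
simulate an artificial population (ci-perturbed, 500 per group), and
evaluate the consensus ensemble at the desk-scale setting (5 members,
epochs 50) — under controlled generator effects.  They are the package's
own measurement of how the procedure behaves under a true null, under a
single localized effect, and across a ramp of effect sizes, plus type-I
error checks of the frequentist battery.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import stats as sps

from .ablation import AblationCondition, apply_condition
from .cohort import CohortConfig, generate_cohort
from .ensemble import EnsembleConfig, evaluate_condition
from .estimators import SimulationConfig, fit_estimators, simulate_population
from .mlp import NetworkSpec
from .seeds import derive_rng, derive_seed
from .stats import dunnett

__all__ = [
    "SCALED_DOWN_SPEC",
    "scaled_down_ensemble",
    "evaluate_cohort_effect",
    "null_calibration",
    "single_variable_power",
    "effect_size_sweep",
    "type_i_error_rates",
    "dunnett_familywise_error",
]

#: Desk-scale network: the default architecture trained for 50 epochs.
SCALED_DOWN_SPEC = NetworkSpec(epochs=50)


def scaled_down_ensemble(seed: int, replicates: int = 5) -> EnsembleConfig:
    """Desk-scale ensemble: 5 members, configurable replicates."""
    return EnsembleConfig(n_members=5, replicates=replicates, seed=seed)


def evaluate_cohort_effect(
    master_seed: int,
    cohort_config: CohortConfig,
    replicates: int = 5,
    excluded: frozenset | None = None,
    population_size: int = 500,
    condition_id: str = "all-variables",
):
    """Cohort -> estimators -> ci-perturbed population -> ensemble evaluation.

    All stage seeds derive from ``master_seed`` only, so two calls with
    different cohort effects but one master seed are paired (same noise
    realisations everywhere except the injected effect).
    """
    cohort = generate_cohort(replace(cohort_config, seed=derive_seed(master_seed, "cohort")))
    est = fit_estimators(cohort)
    population = simulate_population(
        est,
        SimulationConfig(
            population_size=population_size,
            mode="ci-perturbed",
            seed=derive_seed(master_seed, "population"),
        ),
    )
    dataset = population.table
    if excluded:
        dataset = apply_condition(dataset, AblationCondition("all-days", frozenset(excluded)))
    return evaluate_condition(
        dataset,
        SCALED_DOWN_SPEC,
        scaled_down_ensemble(derive_seed(master_seed, "evaluate"), replicates),
        condition_id=condition_id,
    )


def null_calibration(master_seed: int, replicates: int = 20) -> dict:
    """Zero-effect cohort evaluated on all variables.

    Returns both classes' mean +/- SD consensus accuracy.  A calibrated
    procedure would sit near 0.5; the measured elevation quantifies how
    much small-sample estimator noise the simulated populations convert
    into learnable class separation.
    """
    splx, sham = evaluate_cohort_effect(
        master_seed, CohortConfig().null(), replicates=replicates, condition_id="null"
    )
    return {
        "splx_mean": splx.mean_acc,
        "splx_sd": splx.sd_acc,
        "sham_mean": sham.mean_acc,
        "sham_sd": sham.sd_acc,
    }


def single_variable_power(
    master_seed: int, effect_sd: float = 2.0, replicates: int = 5
) -> dict:
    """A lone ``effect_sd``-SD group effect on mr_il, with and without mr_il.

    Measures the SPLX consensus accuracy when the carrying variable is
    retained versus excluded from the feature set.
    """
    config = CohortConfig().effect_on("mr_il", effect_sd)
    with_var, _ = evaluate_cohort_effect(
        master_seed, config, replicates=replicates, condition_id="mr_il-effect"
    )
    without_var, _ = evaluate_cohort_effect(
        master_seed,
        config,
        replicates=replicates,
        excluded=frozenset({"mr_il"}),
        condition_id="mr_il-effect-excluded",
    )
    return {
        "retained_splx_mean": with_var.mean_acc,
        "retained_splx_sd": with_var.sd_acc,
        "excluded_splx_mean": without_var.mean_acc,
        "excluded_splx_sd": without_var.sd_acc,
    }


def effect_size_sweep(
    master_seed: int,
    sizes: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0),
    replicates: int = 5,
) -> dict[float, float]:
    """Mean SPLX accuracy across group-effect sizes with paired seeds."""
    out = {}
    for size in sizes:
        splx, _ = evaluate_cohort_effect(
            master_seed,
            CohortConfig().effect_on("mr_il", size),
            replicates=replicates,
            condition_id=f"effect-{size}",
        )
        out[float(size)] = splx.mean_acc
    return out


def type_i_error_rates(
    master_seed: int, n_sim: int = 10_000, alpha: float = 0.05
) -> dict[str, float]:
    """Rejection rates of t / one-way ANOVA / Kruskal-Wallis under the null.

    Gaussian nulls at the study's sample sizes (13 vs 14 for the two-sample
    tests; three groups of 10 for the k-sample tests).
    """
    rng = derive_rng(master_seed, "type-i")
    x = rng.standard_normal((n_sim, 13))
    y = rng.standard_normal((n_sim, 14))
    t_rate = float(np.mean(sps.ttest_ind(x, y, axis=1).pvalue < alpha))

    g = [rng.standard_normal((n_sim, 10)) for _ in range(3)]
    f_rate = float(np.mean(sps.f_oneway(*g, axis=1).pvalue < alpha))

    kw_hits = 0
    for i in range(n_sim):
        kw_hits += sps.kruskal(g[0][i], g[1][i], g[2][i]).pvalue < alpha
    kw_rate = kw_hits / n_sim
    return {"t": t_rate, "anova": f_rate, "kruskal": float(kw_rate)}


def dunnett_familywise_error(
    master_seed: int, n_sim: int = 2000, k: int = 6, n: int = 10, alpha: float = 0.05
) -> float:
    """Fraction of global-null datasets with any Dunnett comparison significant."""
    rng = derive_rng(master_seed, "dunnett-fwer")
    hits = 0
    for _ in range(n_sim):
        groups = [rng.standard_normal(n) for _ in range(k)]
        comps = dunnett(groups, control_index=0, alpha=alpha)
        hits += any(c.significant for c in comps)
    return hits / n_sim
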