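"""End-to-end pipeline: generate -> fit -> simulate -> ablate -> summarize.

A run is a pure function of its :class:`RunConfig` and master seed: every
stage draws its randomness from a named derivation of the master seed, the
fully-resolved configuration is persisted next to the results, and
re-running the same configuration reproduces every result file.

The pipeline also produces the frequentist baseline report (repeated-
measures ANOVA per variable, per-day two-sample t tests, normality gates
and CI-overlap summaries) that the ensemble analysis is contrasted with.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import stats
from .ablation import CANONICAL_FEATURES, DAY_FILTERS, enumerate_conditions, run_grid
from .cohort import (
    GROUPS,
    MEASUREMENT_VARIABLES,
    CohortConfig,
    generate_cohort,
    write_table,
)
from .ensemble import EnsembleConfig
from .errors import ConfigError, SplxannError
from .estimators import SimulationConfig, fit_estimators, simulate_population
from .mlp import NetworkSpec
from .seeds import derive_seed

__all__ = [
    "PROFILES",
    "RunConfig",
    "BaselineReport",
    "run_pipeline",
    "baseline_report",
    "make_report",
]

logger = logging.getLogger("splxann")

#: Scale profiles cap the expensive knobs; ``full`` keeps the defaults.
PROFILES = {
    "full": {},
    "scaled-down": {
        "n_members": 5,
        "replicates": 5,
        "epochs": 50,
        "day_filters": ("all-days",),
    },
    "smoke": {
        "n_members": 3,
        "replicates": 3,
        "epochs": 20,
        "day_filters": ("all-days",),
        "variables": ("day", "mr_il"),
        "population_size": 60,
    },
}


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    day_filters: Sequence[str] = ("all-days", "no-day2", "no-day2-day4")
    variables: Sequence[str] = CANONICAL_FEATURES
    alpha: float = 0.05
    sphericity_correction: str = "gg"
    master_seed: int = 0
    profile: str = "full"

    def validate(self) -> None:
        self.cohort.validate()
        self.simulation.validate()
        self.network.validate()
        self.ensemble.validate()
        for df in self.day_filters:
            if df not in DAY_FILTERS:
                raise ConfigError(f"unknown day filter {df!r}")
        unknown = set(self.variables) - set(CANONICAL_FEATURES)
        if unknown:
            raise ConfigError(f"unknown variables {sorted(unknown)}")
        if self.profile not in PROFILES:
            raise ConfigError(f"profile must be one of {tuple(PROFILES)}")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must be in (0, 1)")

    def resolved(self) -> "RunConfig":
        """Apply the scale profile caps and propagate the master seed."""
        caps = PROFILES[self.profile]
        ensemble = replace(
            self.ensemble,
            n_members=caps.get("n_members", self.ensemble.n_members),
            replicates=caps.get("replicates", self.ensemble.replicates),
        )
        network = replace(self.network, epochs=caps.get("epochs", self.network.epochs))
        simulation = replace(
            self.simulation,
            population_size=caps.get("population_size", self.simulation.population_size),
            seed=derive_seed(self.master_seed, "simulate"),
        )
        cohort = replace(self.cohort, seed=derive_seed(self.master_seed, "cohort"))
        return replace(
            self,
            cohort=cohort,
            simulation=simulation,
            network=network,
            ensemble=replace(ensemble, seed=derive_seed(self.master_seed, "ensemble")),
            day_filters=tuple(caps.get("day_filters", self.day_filters)),
            variables=tuple(caps.get("variables", self.variables)),
        )

    def to_dict(self) -> dict:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [encode(v) for v in obj]
            if isinstance(obj, dict):
                return {str(k): encode(v) for k, v in obj.items()}
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return encode(self)


@dataclass
class BaselineReport:
    """Frequentist baseline analyses of one observation table."""

    rm_anova: pd.DataFrame
    per_day_t: pd.DataFrame
    normality: pd.DataFrame
    ci_overlap: pd.DataFrame
    notes: list[str] = field(default_factory=list)


def baseline_report(
    table: pd.DataFrame, alpha: float = 0.05, correction: str = "gg"
) -> BaselineReport:
    """Run the frequentist suite per variable.

    Per variable: mixed repeated-measures ANOVA (group x day) when at
    least two days are present and the data are balanced, per-day Welch t
    tests between the groups, Shapiro-Wilk per (group, day), and per-day
    95% CI overlap between groups.
    """
    notes: list[str] = []
    days = sorted(int(d) for d in table["day"].unique())
    rm_rows, t_rows, norm_rows, ci_rows = [], [], [], []
    for var in MEASUREMENT_VARIABLES:
        if len(days) >= 2:
            try:
                res = stats.rm_anova(table, var, correction=correction, alpha=alpha)
                for effect, tr in (
                    ("group", res.between),
                    ("day", res.within),
                    ("day (corrected)", res.within_corrected),
                    ("group x day", res.interaction),
                    ("group x day (corrected)", res.interaction_corrected),
                ):
                    df1, df2 = tr.df
                    rm_rows.append(
                        {
                            "variable": var,
                            "effect": effect,
                            "F": tr.statistic,
                            "df1": df1,
                            "df2": df2,
                            "p": tr.p,
                            "epsilon": res.epsilon,
                            "significant": tr.significant,
                        }
                    )
            except SplxannError as exc:
                notes.append(f"rm_anova skipped for {var}: {exc}")
        else:
            notes.append(
                f"rm_anova skipped for {var}: single observation day ({days}); "
                "within-subject analysis needs >= 2 days"
            )
        for day in days:
            sub = table[table["day"] == day]
            samples = {g: sub.loc[sub["group"] == g, var].to_numpy(float) for g in GROUPS}
            try:
                tr = stats.t_test(samples[GROUPS[0]], samples[GROUPS[1]], "welch", alpha)
                t_rows.append(
                    {
                        "variable": var,
                        "day": day,
                        "t": tr.statistic,
                        "df": tr.df,
                        "p": tr.p,
                        "significant": tr.significant,
                    }
                )
            except SplxannError as exc:
                notes.append(f"t test skipped for {var} day {day}: {exc}")
            cis = {}
            for g, x in samples.items():
                n = len(x)
                if n >= 3:
                    w = stats.shapiro_wilk(x, alpha)
                    norm_rows.append(
                        {
                            "variable": var,
                            "group": g,
                            "day": day,
                            "W": w.statistic,
                            "p": w.p,
                            "normal": not w.significant,
                        }
                    )
                sem = np.std(x, ddof=1) / np.sqrt(n)
                half = sps.t.ppf(0.975, n - 1) * sem
                cis[g] = (np.mean(x) - half, np.mean(x) + half)
            lo = max(ci[0] for ci in cis.values())
            hi = min(ci[1] for ci in cis.values())
            ci_rows.append(
                {
                    "variable": var,
                    "day": day,
                    **{
                        f"{g}_ci": f"[{cis[g][0]:.4g}, {cis[g][1]:.4g}]" for g in GROUPS
                    },
                    "overlap": bool(lo <= hi),
                }
            )
    return BaselineReport(
        rm_anova=pd.DataFrame(rm_rows),
        per_day_t=pd.DataFrame(t_rows),
        normality=pd.DataFrame(norm_rows),
        ci_overlap=pd.DataFrame(ci_rows),
        notes=notes,
    )


def _write_frame(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig, out_dir: str | Path, resume: bool = False) -> Path:
    """Execute all stages, writing inputs, intermediates, results and logs.

    Stage order: cohort generation, frequentist baseline, estimator fit,
    per-day-filter population simulation, ablation grid, significance
    summaries, consolidated report.  Any stage failure aborts with the
    stage name; completed artifacts persist.
    """
    config.validate()
    resolved = config.resolved()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="a" if resume else "w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "configure"
    try:
        with open(out / "config.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(resolved.to_dict(), fh, sort_keys=True)

        stage = "generate-cohort"
        t0 = time.perf_counter()
        cohort = generate_cohort(resolved.cohort)
        write_table(cohort, out / "cohort.csv")
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "baseline-report"
        t0 = time.perf_counter()
        base = baseline_report(cohort, resolved.alpha, resolved.sphericity_correction)
        base_dir = out / "baseline"
        base_dir.mkdir(exist_ok=True)
        _write_frame(base.rm_anova, base_dir / "rm_anova.csv")
        _write_frame(base.per_day_t, base_dir / "per_day_t.csv")
        _write_frame(base.normality, base_dir / "normality.csv")
        _write_frame(base.ci_overlap, base_dir / "ci_overlap.csv")
        (base_dir / "notes.txt").write_text("\n".join(base.notes), encoding="utf-8")
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "fit-estimators"
        t0 = time.perf_counter()
        est = fit_estimators(cohort, correlation=True)
        est.to_json(out / "estimators.json")
        _write_frame(est.to_frame(), out / "estimators.csv")
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        summaries = {}
        for day_filter in resolved.day_filters:
            stage = f"simulate[{day_filter}]"
            t0 = time.perf_counter()
            removed = set(DAY_FILTERS[day_filter])
            kept = [d for d in est.days if d not in removed]
            sim_config = replace(
                resolved.simulation,
                seed=derive_seed(resolved.master_seed, "simulate", day_filter),
            )
            population = simulate_population(est.restrict_days(kept), sim_config)
            write_table(population.table, out / f"population_{day_filter}.csv")
            (out / f"population_{day_filter}.provenance.json").write_text(
                json.dumps(population.provenance, sort_keys=True, default=str),
                encoding="utf-8",
            )
            logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

            stage = f"ablate[{day_filter}]"
            t0 = time.perf_counter()
            # days already removed from the population; apply_condition's
            # filter is then a no-op row-wise but still drops features
            conditions = enumerate_conditions(resolved.variables, day_filter)
            grid_input = population.table[
                ["animal_id", "group"]
                + [v for v in CANONICAL_FEATURES if v in resolved.variables]
            ]
            grid = run_grid(
                grid_input,
                conditions,
                resolved.network,
                replace(
                    resolved.ensemble,
                    seed=derive_seed(resolved.master_seed, "grid", day_filter),
                ),
                checkpoint_dir=out / "checkpoints" / day_filter,
            )
            _write_frame(grid.to_frame(), out / f"grid_{day_filter}.csv")
            logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

            stage = f"summarize[{day_filter}]"
            report = stats.summarize_grid_significance(
                grid, resolved.alpha, variables=resolved.variables
            )
            summaries[day_filter] = report
            _write_frame(report.per_condition, out / f"summary_{day_filter}.csv")
            (out / f"summary_{day_filter}.txt").write_text(
                "\n".join(report.summary_lines()) + "\n", encoding="utf-8"
            )

        stage = "report"
        make_report(out)
        return out
    except Exception as exc:
        raise SplxannError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()


def make_report(run_dir: str | Path) -> Path:
    """Consolidate a run directory into a human-readable markdown report.

    Regenerating the report from the same directory is byte-identical; a
    run missing grid results yields a report flagged as partial.
    """
    run_dir = Path(run_dir)
    lines = ["# splxann run report", ""]
    config_path = run_dir / "config.yaml"
    if config_path.exists():
        lines += ["## Configuration", "", "```yaml", config_path.read_text().rstrip(), "```", ""]
    grids = sorted(run_dir.glob("grid_*.csv"))
    partial = not grids
    for grid_path in grids:
        day_filter = grid_path.stem.replace("grid_", "")
        frame = pd.read_csv(grid_path)
        lines += [f"## Ablation grid — {day_filter}", ""]
        lines += [f"conditions: {frame['condition_id'].nunique()}", ""]
        summary_txt = run_dir / f"summary_{day_filter}.txt"
        if summary_txt.exists():
            lines += ["```", summary_txt.read_text().rstrip(), "```", ""]
        show = frame[
            ["condition_id", "class", "mean_acc", "sd_acc", "n_replicates"]
        ].copy()
        lines += ["| condition | class | mean ± SD | replicates |", "|---|---|---|---|"]
        for _, row in show.iterrows():
            lines.append(
                f"| {row['condition_id']} | {row['class']} | "
                f"{row['mean_acc']:.4f} ± {row['sd_acc']:.4f} | {row['n_replicates']} |"
            )
        lines.append("")
    base_dir = run_dir / "baseline"
    if base_dir.exists():
        rm = pd.read_csv(base_dir / "rm_anova.csv") if (base_dir / "rm_anova.csv").exists() else None
        if rm is not None and len(rm):
            lines += ["## Frequentist baseline (repeated-measures ANOVA)", ""]
            lines += ["| variable | effect | F | df | p |", "|---|---|---|---|---|"]
            for _, row in rm.iterrows():
                lines.append(
                    f"| {row['variable']} | {row['effect']} | {row['F']:.3f} | "
                    f"({row['df1']:.3f}, {row['df2']:.3f}) | {row['p']:.4f} |"
                )
            lines.append("")
    else:
        partial = True
    if partial:
        lines.insert(1, "")
        lines.insert(2, "**PARTIAL RUN** — some stages have no persisted results.")
    report_path = run_dir / "report.md"
    report_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return report_path
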