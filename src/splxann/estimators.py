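"""Parameter estimators and simulation of artificial populations.

A small observed cohort is reduced to per-cell estimators — for every
(group x day x variable) cell the sample size, mean, SD, SEM and a t-based
95% confidence interval, optionally with a per-(group x day) correlation
matrix across the measured variables — and large "artificial populations"
are then simulated from those estimators for classifier training.

Two simulation modes are exposed:

``plugin``
    each cell's values are drawn from a distribution with exactly the
    estimated mean and SD (the parametric plug-in bootstrap);
``ci-perturbed``
    each cell's population mean is first drawn uniformly from the cell's
    95% CI, then values are drawn around it with the estimated SD.  This
    propagates small-sample parameter uncertainty into the simulated
    population and is the pipeline default.

Marginals match the cohort generator: Gaussian for mass, NS (rounded and
clamped after the draw) and the MRI volumes, moment-matched log-normal for
the BLI variables.  With ``correlation="mv-normal"`` the per-cell variable
vector is drawn jointly through a Gaussian copula using the estimated
(shrunken) correlation matrix.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    GROUPS,
    LOGNORMAL_VARIABLES,
    MEASUREMENT_VARIABLES,
    NS_MAX,
    NS_MIN,
    TABLE_COLUMNS,
    round_half_away,
    validate_table,
)
from .errors import ConfigError, EstimationError
from .seeds import derive_rng

__all__ = [
    "CellEstimate",
    "EstimatorSet",
    "SimulationConfig",
    "SimulatedPopulation",
    "fit_estimators",
    "simulate_population",
]


@dataclass(frozen=True)
class CellEstimate:
    """Sample statistics for one (group, day, variable) cell."""

    group: str
    day: int
    variable: str
    n: int
    mean: float
    sd: float
    sem: float
    ci_low: float
    ci_high: float


@dataclass
class EstimatorSet:
    """All cell estimators of a cohort, plus optional per-cell correlations.

    ``correlations`` maps (group, day) to a correlation matrix across the
    measured variables (on the modelling scale: log for the BLI variables),
    used by the mv-normal simulation mode.
    """

    cells: dict[tuple[str, int, str], CellEstimate]
    groups: tuple[str, ...]
    days: tuple[int, ...]
    variables: tuple[str, ...] = MEASUREMENT_VARIABLES
    correlations: dict[tuple[str, int], np.ndarray] | None = None

    def cell(self, group: str, day: int, variable: str) -> CellEstimate:
        try:
            return self.cells[(group, int(day), variable)]
        except KeyError:
            raise EstimationError(
                f"no estimator for cell (group={group!r}, day={day}, variable={variable!r})"
            ) from None

    def restrict_days(self, keep_days: Sequence[int]) -> "EstimatorSet":
        keep = tuple(int(d) for d in self.days if int(d) in set(int(k) for k in keep_days))
        cells = {k: v for k, v in self.cells.items() if k[1] in keep}
        corrs = None
        if self.correlations is not None:
            corrs = {k: v for k, v in self.correlations.items() if k[1] in keep}
        return EstimatorSet(cells, self.groups, keep, self.variables, corrs)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        payload = {
            "groups": list(self.groups),
            "days": [int(d) for d in self.days],
            "variables": list(self.variables),
            "cells": [vars(c) for c in sorted(self.cells.values(), key=_cell_key)],
        }
        if self.correlations is not None:
            payload["correlations"] = {
                f"{g}|{d}": m.tolist() for (g, d), m in sorted(self.correlations.items())
            }
        return payload

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    def to_frame(self) -> pd.DataFrame:
        """One record per cell, the canonical delimited-text export."""
        return pd.DataFrame([vars(c) for c in sorted(self.cells.values(), key=_cell_key)])

    @classmethod
    def from_dict(cls, payload: Mapping) -> "EstimatorSet":
        cells = {}
        for rec in payload["cells"]:
            est = CellEstimate(**{**rec, "day": int(rec["day"]), "n": int(rec["n"])})
            cells[(est.group, est.day, est.variable)] = est
        corrs = None
        if "correlations" in payload:
            corrs = {}
            for key, m in payload["correlations"].items():
                g, d = key.rsplit("|", 1)
                corrs[(g, int(d))] = np.asarray(m, dtype=float)
        return cls(
            cells,
            tuple(payload["groups"]),
            tuple(int(d) for d in payload["days"]),
            tuple(payload["variables"]),
            corrs,
        )

    @classmethod
    def from_json(cls, path) -> "EstimatorSet":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def fingerprint(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode("utf-8")
        return hashlib.sha256(blob).hexdigest()[:16]


def _cell_key(c: CellEstimate) -> tuple:
    return (c.group, c.day, MEASUREMENT_VARIABLES.index(c.variable))


@dataclass(frozen=True)
class SimulationConfig:
    """How to expand estimators into an artificial population."""

    population_size: int = 500
    mode: str = "ci-perturbed"
    correlation: str = "independent"
    positive_floor_frac: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.population_size < 2:
            raise ConfigError(f"population_size must be >= 2, got {self.population_size}")
        if self.mode not in ("plugin", "ci-perturbed"):
            raise ConfigError(f"mode must be 'plugin' or 'ci-perturbed', got {self.mode!r}")
        if self.correlation not in ("independent", "mv-normal"):
            raise ConfigError(
                f"correlation must be 'independent' or 'mv-normal', got {self.correlation!r}"
            )


@dataclass
class SimulatedPopulation:
    """An artificial population plus full provenance of how it was drawn."""

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def fit_estimators(table: pd.DataFrame, correlation: bool = False) -> EstimatorSet:
    """Fit per-cell sample statistics from an observation table.

    Mean and SD are the sample mean and (n-1)-denominator SD; the CI is the
    central-t two-sided 95% interval.  With ``correlation=True`` a
    per-(group, day) correlation matrix across the measured variables is
    estimated on the modelling scale (log for BLI variables) and shrunk
    toward the identity until positive definite.
    """
    validate_table(table)
    groups = tuple(g for g in GROUPS if g in set(table["group"]))
    days = tuple(sorted(int(d) for d in table["day"].unique()))
    cells: dict[tuple[str, int, str], CellEstimate] = {}
    corrs: dict[tuple[str, int], np.ndarray] = {}
    for group in groups:
        for day in days:
            sub = table[(table["group"] == group) & (table["day"] == day)]
            n = len(sub)
            if n < 2:
                raise EstimationError(
                    f"cell (group={group!r}, day={day}) has n={n} < 2 animals"
                )
            for var in MEASUREMENT_VARIABLES:
                x = sub[var].to_numpy(dtype=float)
                mean = float(np.mean(x))
                sd = float(np.std(x, ddof=1))
                sem = sd / math.sqrt(n)
                half = float(stats.t.ppf(0.975, n - 1)) * sem
                cells[(group, day, var)] = CellEstimate(
                    group, day, var, n, mean, sd, sem, mean - half, mean + half
                )
            if correlation:
                mat = np.column_stack(
                    [
                        np.log(sub[v].to_numpy(dtype=float))
                        if v in LOGNORMAL_VARIABLES
                        else sub[v].to_numpy(dtype=float)
                        for v in MEASUREMENT_VARIABLES
                    ]
                )
                corrs[(group, day)] = _shrunk_correlation(mat)
    return EstimatorSet(
        cells, groups, days, MEASUREMENT_VARIABLES, corrs if correlation else None
    )


def _shrunk_correlation(mat: np.ndarray, base_weight: float = 0.1) -> np.ndarray:
    """Sample correlation shrunk toward identity until positive definite.

    Constant columns (zero variance) get unit self-correlation and zero
    cross-correlation.  Shrinkage starts at ``base_weight`` on the identity
    and doubles the remaining gap until the smallest eigenvalue clears 1e-8.
    """
    p = mat.shape[1]
    sds = np.std(mat, axis=0, ddof=1)
    safe = sds > 0
    corr = np.eye(p)
    if safe.sum() >= 2:
        sub = np.corrcoef(mat[:, safe], rowvar=False)
        corr[np.ix_(safe, safe)] = sub
    lam = base_weight
    shrunk = (1 - lam) * corr + lam * np.eye(p)
    while np.linalg.eigvalsh(shrunk).min() < 1e-8 and lam < 1.0:
        lam = min(1.0, lam * 2.0)
        shrunk = (1 - lam) * corr + lam * np.eye(p)
    return shrunk


def _marginal_draw(
    variable: str, mean: float, sd: float, z: np.ndarray
) -> np.ndarray:
    """Transform standard-normal draws into the cell's marginal."""
    if variable in LOGNORMAL_VARIABLES:
        if sd == 0.0:
            return np.full_like(z, mean)
        sigma2 = math.log1p((sd / mean) ** 2)
        mu = math.log(mean) - sigma2 / 2.0
        return np.exp(mu + math.sqrt(sigma2) * z)
    return mean + sd * z


def simulate_population(est: EstimatorSet, config: SimulationConfig) -> SimulatedPopulation:
    """Simulate an artificial population from an estimator set.

    ``population_size`` animals per group each receive one row per day in
    the estimator set; rows of one animal across days share the animal id
    but are drawn independently per cell.  Deterministic under the seed.
    """
    config.validate()
    if config.correlation == "mv-normal" and est.correlations is None:
        raise ConfigError(
            "mv-normal correlation requested but the estimator set carries no "
            "correlation matrices (fit with correlation=True)"
        )
    rng = derive_rng(config.seed, "simulate")
    n = config.population_size
    n_vars = len(est.variables)
    frames = []
    for group in est.groups:
        ids = [f"SIM-{group}-{i + 1:05d}" for i in range(n)]
        for day in est.days:
            if config.correlation == "mv-normal":
                corr = est.correlations[(group, day)]
                chol = np.linalg.cholesky(corr)
                z = rng.standard_normal((n, n_vars)) @ chol.T
            else:
                z = rng.standard_normal((n, n_vars))
            data = {"animal_id": ids, "group": group, "day": int(day)}
            for j, var in enumerate(est.variables):
                cell = est.cell(group, day, var)
                if config.mode == "ci-perturbed":
                    mean = float(rng.uniform(cell.ci_low, cell.ci_high))
                else:
                    mean = cell.mean
                values = _marginal_draw(var, mean, cell.sd, z[:, j])
                if var == "ns":
                    values = np.clip(round_half_away(values), NS_MIN, NS_MAX)
                else:
                    floor = config.positive_floor_frac * max(cell.mean, 1e-12)
                    values = np.maximum(values, floor)
                data[var] = values
            frames.append(pd.DataFrame(data))
    table = pd.concat(frames, ignore_index=True)[list(TABLE_COLUMNS)]
    # sort rows animal-major so the table reads like the cohort table
    table = table.sort_values(["group", "animal_id", "day"], kind="stable").reset_index(
        drop=True
    )
    validate_table(table)
    provenance = {
        "estimator_fingerprint": est.fingerprint(),
        "config": vars(config).copy(),
        "seed": config.seed,
    }
    return SimulatedPopulation(table=table, provenance=provenance)
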