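"""Synthetic splenectomy-MCAO cohort generation.

The study design this module emulates: two groups of mice — splenectomized
(SPLX) and sham-operated (SPL-sham) — undergo middle cerebral artery
occlusion (MCAO) and are observed on post-stroke days 2, 4, 7 and 28 for
seven variables: body mass (g), Garcia neurological score (NS, integer
3-18), MRI ipsilateral / contralateral hemisphere volume (mm^3), and peak
bioluminescence flux (photons/s) and radiance (photons/s/cm^2/sr) from a
Tlr2 luciferase reporter.

The generator produces a long-format table with

* large *time* effects (post-stroke mass loss, neurological deficit,
  ipsilateral edema, inflammatory BLI surge) shared by both groups,
* small-to-zero *group* effects, expressed per variable in units of the
  variable's baseline SD, and
* within-animal correlation across days via a shared per-animal random
  intercept.

Mass, NS and the MRI volumes are Gaussian on the raw scale (NS is rounded
and clamped to the Garcia range afterwards); the two BLI variables are
log-normal because photon counts span orders of magnitude and are strictly
positive.  All default magnitudes are stand-ins chosen to be realistic for
a C57BL/6 MCAO cohort — no raw data from a real study backs them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ParseError, TableValidationError
from .seeds import derive_rng

__all__ = [
    "GROUP_SPLX",
    "GROUP_SHAM",
    "MEASUREMENT_VARIABLES",
    "LOGNORMAL_VARIABLES",
    "TABLE_COLUMNS",
    "NS_MIN",
    "NS_MAX",
    "CohortConfig",
    "generate_cohort",
    "validate_table",
    "write_table",
    "read_table",
    "round_half_away",
]

GROUP_SPLX = "SPLX"
GROUP_SHAM = "SPL-sham"
GROUPS = (GROUP_SPLX, GROUP_SHAM)

#: The six measured variables (the seventh model input, ``day``, is the
#: observation day itself).
MEASUREMENT_VARIABLES = ("mass", "ns", "mr_il", "mr_cl", "bli_flux", "bli_radiance")

#: Variables modelled as log-normal (positive, heavy right skew).
LOGNORMAL_VARIABLES = frozenset({"bli_flux", "bli_radiance"})

TABLE_COLUMNS = (
    "animal_id",
    "group",
    "day",
    "mass",
    "ns",
    "mr_il",
    "mr_cl",
    "bli_flux",
    "bli_radiance",
)

NS_MIN, NS_MAX = 3, 18

_DEFAULT_DAYS = (2, 4, 7, 28)

_DEFAULT_BASELINE_MEAN = {
    "mass": 24.0,          # g
    "ns": 18.0,            # healthy Garcia score
    "mr_il": 228.0,        # mm^3
    "mr_cl": 225.0,        # mm^3
    "bli_flux": 1.2e7,     # photons/s
    "bli_radiance": 2.4e5, # photons/s/cm^2/sr
}

_DEFAULT_BASELINE_SD = {
    "mass": 1.6,
    "ns": 1.2,
    "mr_il": 11.0,
    "mr_cl": 9.0,
    # for log-normal variables the SD is on the raw scale too; the
    # generator moment-matches a log-normal to (mean, sd)
    "bli_flux": 6.0e6,
    "bli_radiance": 1.2e5,
}

# Additive day offsets for Gaussian variables, multiplicative factors for
# log-normal ones: mass dips at days 2-7 and mostly recovers by day 28; NS
# is depressed early and recovers; the ipsilateral hemisphere swells early
# (edema) then declines; BLI surges in the acute phase.
_DEFAULT_TIME_PROFILE = {
    "mass": {2: -3.0, 4: -3.5, 7: -2.5, 28: -0.5},
    "ns": {2: -8.0, 4: -7.0, 7: -5.5, 28: -3.0},
    "mr_il": {2: 30.0, 4: 24.0, 7: 14.0, 28: -6.0},
    "mr_cl": {2: 0.0, 4: 0.0, 7: 0.0, 28: -2.0},
    "bli_flux": {2: 6.0, 4: 9.0, 7: 5.0, 28: 1.5},
    "bli_radiance": {2: 6.0, 4: 9.0, 7: 5.0, 28: 1.5},
}

# Default standardized SPLX - sham differences (units of baseline SD):
# neuroprotection shows as slightly better NS, less ipsilateral swelling
# and less inflammatory BLI signal.  All magnitudes <= 0.3 SD so that
# per-timepoint t tests at n = 13/14 are typically non-significant.
_DEFAULT_GROUP_EFFECT = {
    "mass": 0.0,
    "ns": 0.25,
    "mr_il": -0.3,
    "mr_cl": 0.0,
    "bli_flux": -0.3,
    "bli_radiance": -0.3,
}


def round_half_away(x: np.ndarray | float) -> np.ndarray:
    """Round to nearest integer, halves away from zero (platform-stable)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    ``group_effect`` entries may be scalars (constant over days) or
    sequences aligned with ``days``; values are standardized SPLX-minus-sham
    differences in units of the variable's ``baseline_sd``.  For log-normal
    variables the shift is applied on the log scale in units of the
    log-scale SD.  ``within_animal_rho`` is the correlation between the
    same animal's standardized deviations on any two days (exchangeable
    random-intercept structure).
    """

    n_splx: int = 13
    n_sham: int = 14
    days: Sequence[int] = _DEFAULT_DAYS
    baseline_mean: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BASELINE_MEAN)
    )
    baseline_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BASELINE_SD)
    )
    time_profile: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {v: dict(p) for v, p in _DEFAULT_TIME_PROFILE.items()}
    )
    group_effect: Mapping[str, float | Sequence[float]] = field(
        default_factory=lambda: dict(_DEFAULT_GROUP_EFFECT)
    )
    within_animal_rho: float = 0.5
    positive_floor_frac: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_splx < 2:
            raise ConfigError(f"n_splx must be >= 2, got {self.n_splx}")
        if self.n_sham < 2:
            raise ConfigError(f"n_sham must be >= 2, got {self.n_sham}")
        days = list(self.days)
        if not days or any(d <= 0 for d in days):
            raise ConfigError(f"days must be positive and non-empty, got {days}")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ConfigError(f"days must be strictly increasing, got {days}")
        for var in MEASUREMENT_VARIABLES:
            if var not in self.baseline_mean:
                raise ConfigError(f"baseline_mean missing variable {var!r}")
            if var not in self.baseline_sd:
                raise ConfigError(f"baseline_sd missing variable {var!r}")
            if self.baseline_sd[var] < 0:
                raise ConfigError(f"baseline_sd[{var!r}] must be >= 0")
            profile = self.time_profile.get(var)
            if profile is None:
                raise ConfigError(f"time_profile missing variable {var!r}")
            for d in days:
                if d not in profile:
                    raise ConfigError(f"time_profile[{var!r}] missing day {d}")
            eff = self.group_effect.get(var, 0.0)
            if not np.isscalar(eff) and len(list(eff)) != len(days):
                raise ConfigError(
                    f"group_effect[{var!r}] must be scalar or length {len(days)}"
                )
        if not (0.0 <= self.within_animal_rho < 1.0):
            raise ConfigError(
                f"within_animal_rho must be in [0, 1), got {self.within_animal_rho}"
            )
        if not (0.0 <= self.positive_floor_frac < 1.0):
            raise ConfigError("positive_floor_frac must be in [0, 1)")

    def null(self) -> "CohortConfig":
        """Copy of this config with all group effects set to zero."""
        return replace(self, group_effect={v: 0.0 for v in MEASUREMENT_VARIABLES})

    def effect_on(self, variable: str, size_sd: float) -> "CohortConfig":
        """Copy with a ``size_sd``-SD group effect on one variable, zero elsewhere."""
        effects = {v: 0.0 for v in MEASUREMENT_VARIABLES}
        effects[variable] = size_sd
        return replace(self, group_effect=effects)


def _effect_by_day(config: CohortConfig, var: str) -> np.ndarray:
    eff = config.group_effect.get(var, 0.0)
    n_days = len(list(config.days))
    if np.isscalar(eff):
        return np.full(n_days, float(eff))
    return np.asarray(list(eff), dtype=float)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a log-normal to a raw-scale (mean, sd)."""
    if mean <= 0:
        raise ConfigError(f"log-normal mean must be positive, got {mean}")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a synthetic cohort table, one row per (animal, day).

    Per variable and animal the deviation splits into a shared intercept
    (variance ``rho``) and independent per-day noise (variance ``1 - rho``),
    both in standardized units, so that the marginal SD at any day equals
    ``baseline_sd`` while adjacent-day deviations correlate at ``rho``.
    """
    config.validate()
    rng = derive_rng(config.seed, "cohort")
    days = np.asarray(list(config.days), dtype=int)
    n_days = len(days)
    groups = [GROUP_SPLX] * config.n_splx + [GROUP_SHAM] * config.n_sham
    animal_ids = [f"SPLX-{i + 1:02d}" for i in range(config.n_splx)] + [
        f"SHAM-{i + 1:02d}" for i in range(config.n_sham)
    ]
    n_animals = len(animal_ids)
    is_splx = np.array([g == GROUP_SPLX for g in groups])
    rho = config.within_animal_rho

    columns: dict[str, np.ndarray] = {}
    for var in MEASUREMENT_VARIABLES:
        intercept = rng.standard_normal(n_animals)
        noise = rng.standard_normal((n_animals, n_days))
        z = math.sqrt(rho) * intercept[:, None] + math.sqrt(1.0 - rho) * noise
        eff = _effect_by_day(config, var)  # standardized, per day
        shift = np.where(is_splx[:, None], eff[None, :], 0.0)
        mean0 = config.baseline_mean[var]
        sd0 = config.baseline_sd[var]
        profile = np.array([config.time_profile[var][int(d)] for d in days])
        if var in LOGNORMAL_VARIABLES:
            mu0, sigma0 = _lognormal_params(mean0, sd0)
            log_values = mu0 + np.log(profile)[None, :] + sigma0 * (z + shift)
            values = np.exp(log_values)
        else:
            values = mean0 + profile[None, :] + sd0 * (z + shift)
        if var == "ns":
            values = np.clip(round_half_away(values), NS_MIN, NS_MAX)
        else:
            floor = config.positive_floor_frac * mean0
            values = np.maximum(values, floor)
        columns[var] = values.reshape(-1)

    table = pd.DataFrame(
        {
            "animal_id": np.repeat(animal_ids, n_days),
            "group": np.repeat(groups, n_days),
            "day": np.tile(days, n_animals),
            **{var: columns[var] for var in MEASUREMENT_VARIABLES},
        }
    )[list(TABLE_COLUMNS)]
    validate_table(table)
    return table


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the observation-table contract; return the table on success."""
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"table is missing required columns: {missing}")
    dup = table.duplicated(subset=["animal_id", "day"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        key = table.iloc[row][["animal_id", "day"]].tolist()
        raise TableValidationError(
            f"duplicate (animal_id, day) pair {tuple(key)} at row {row}"
        )
    bad_group = ~table["group"].isin(GROUPS)
    if bad_group.any():
        row = int(np.flatnonzero(bad_group.to_numpy())[0])
        raise TableValidationError(
            f"unknown group label {table['group'].iloc[row]!r} at row {row}; "
            f"expected one of {GROUPS}"
        )
    n_labels = table.groupby("animal_id")["group"].nunique()
    inconsistent = n_labels[n_labels > 1]
    if len(inconsistent):
        raise TableValidationError(
            f"animal {inconsistent.index[0]!r} carries more than one group label"
        )
    ns = table["ns"].to_numpy(dtype=float)
    out_of_range = (ns < NS_MIN) | (ns > NS_MAX)
    if out_of_range.any():
        row = int(np.flatnonzero(out_of_range)[0])
        raise TableValidationError(
            f"ns = {ns[row]} at row {row} outside the Garcia scale bounds "
            f"[{NS_MIN}, {NS_MAX}]"
        )
    for var in ("mass", "mr_il", "mr_cl", "bli_flux", "bli_radiance"):
        vals = table[var].to_numpy(dtype=float)
        nonpos = ~(vals > 0)
        if nonpos.any():
            row = int(np.flatnonzero(nonpos)[0])
            raise TableValidationError(
                f"{var} = {vals[row]} at row {row} must be strictly positive"
            )
    return table


def write_table(table: pd.DataFrame, destination) -> None:
    """Write a validated observation table as UTF-8 CSV with dot decimals."""
    validate_table(table)
    table.to_csv(destination, index=False, columns=list(TABLE_COLUMNS))


def read_table(source) -> pd.DataFrame:
    """Read and validate an observation table from CSV."""
    try:
        table = pd.read_csv(source)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise ParseError(f"could not parse observation table: {exc}") from exc
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"table is missing required columns: {missing}")
    table = table[list(TABLE_COLUMNS)]
    table["day"] = table["day"].astype(int)
    return validate_table(table)
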