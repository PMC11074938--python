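"""Exhaustive variable-exclusion x day-exclusion experiment grid.

The seven canonical model inputs are day, MR IL, MR CL, animal mass, NS,
BLI peak flux and BLI peak radiance.  An ablation condition pairs a
post-stroke day filter (all days / without day 2 / without days 2 and 4)
with a set of excluded input variables; the grid enumerates the baseline
(nothing excluded) plus every non-empty proper subset of the variables as
an exclusion — 2^7 - 1 = 127 conditions for the full variable set.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .cohort import GROUP_SHAM, GROUP_SPLX
from .ensemble import AccuracyResult, EnsembleConfig, evaluate_condition
from .errors import ConfigError, ResumeError
from .mlp import NetworkSpec
from .seeds import derive_seed

__all__ = [
    "CANONICAL_FEATURES",
    "DAY_FILTERS",
    "AblationCondition",
    "ConditionResult",
    "GridResult",
    "enumerate_conditions",
    "apply_condition",
    "run_grid",
]

#: Canonical input variables in the field's reporting order.
CANONICAL_FEATURES = ("day", "mr_il", "mr_cl", "mass", "ns", "bli_flux", "bli_radiance")

#: Day filter name -> post-stroke days removed from the dataset.
DAY_FILTERS = {"all-days": (), "no-day2": (2,), "no-day2-day4": (2, 4)}


@dataclass(frozen=True)
class AblationCondition:
    """A day filter plus a set of excluded input variables."""

    day_filter: str = "all-days"
    excluded: frozenset = frozenset()

    def __post_init__(self):
        if self.day_filter not in DAY_FILTERS:
            raise ConfigError(
                f"day_filter must be one of {tuple(DAY_FILTERS)}, got {self.day_filter!r}"
            )
        unknown = set(self.excluded) - set(CANONICAL_FEATURES)
        if unknown:
            raise ConfigError(f"unknown excluded variables: {sorted(unknown)}")
        if set(self.excluded) >= set(CANONICAL_FEATURES):
            raise ConfigError("excluded set must leave at least one input variable")

    @property
    def is_baseline(self) -> bool:
        return not self.excluded

    @property
    def condition_id(self) -> str:
        if self.is_baseline:
            return f"{self.day_filter}/baseline"
        ordered = [f for f in CANONICAL_FEATURES if f in self.excluded]
        return f"{self.day_filter}/excl={'+'.join(ordered)}"


@dataclass
class ConditionResult:
    condition: AblationCondition
    splx: AccuracyResult
    sham: AccuracyResult
    seed: int


@dataclass
class GridResult:
    """Per-condition accuracy results for one or more day filters."""

    results: list[ConditionResult] = field(default_factory=list)

    def __iter__(self):
        return iter(self.results)

    def __len__(self):
        return len(self.results)

    def for_day_filter(self, day_filter: str) -> "GridResult":
        return GridResult([r for r in self.results if r.condition.day_filter == day_filter])

    def baseline(self, day_filter: str) -> ConditionResult:
        base = [
            r
            for r in self.results
            if r.condition.day_filter == day_filter and r.condition.is_baseline
        ]
        if len(base) != 1:
            raise ConfigError(
                f"expected exactly one baseline condition for {day_filter!r}, "
                f"found {len(base)}"
            )
        return base[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            for res in (r.splx, r.sham):
                rows.append(
                    {
                        "condition_id": r.condition.condition_id,
                        "day_filter": r.condition.day_filter,
                        "excluded": "+".join(
                            f for f in CANONICAL_FEATURES if f in r.condition.excluded
                        ),
                        "class": res.class_label,
                        "mean_acc": res.mean_acc,
                        "sd_acc": res.sd_acc,
                        "n_replicates": len(res.accuracies),
                        "accuracies": ";".join(f"{a:.6f}" for a in res.accuracies),
                        "seed": r.seed,
                    }
                )
        return pd.DataFrame(rows)


def _subset_sort_key(subset: frozenset) -> tuple:
    idx = tuple(i for i, f in enumerate(CANONICAL_FEATURES) if f in subset)
    return (len(idx), idx)


def enumerate_conditions(
    variables: Iterable[str] = CANONICAL_FEATURES, day_filter: str = "all-days"
) -> list[AblationCondition]:
    """Baseline plus every non-empty proper exclusion subset.

    For k variables this yields 2^k - 1 conditions (127 for the canonical
    seven), ordered by subset size then canonical variable order.
    """
    variables = [f for f in CANONICAL_FEATURES if f in set(variables)]
    if not variables:
        raise ConfigError("variable set must be non-empty")
    subsets: list[frozenset] = [frozenset()]
    n = len(variables)
    for mask in range(1, 2**n - 1):  # non-empty proper subsets
        subsets.append(frozenset(v for i, v in enumerate(variables) if mask >> i & 1))
    subsets.sort(key=_subset_sort_key)
    return [AblationCondition(day_filter, s) for s in subsets]


def apply_condition(table: pd.DataFrame, condition: AblationCondition) -> pd.DataFrame:
    """Model-ready dataset: day-filtered rows, excluded features dropped.

    The class label and animal id are always retained.  When ``day`` is
    excluded the rows of the filtered days remain but the column is
    dropped from the feature set.
    """
    removed_days = DAY_FILTERS[condition.day_filter]
    if removed_days and "day" in table.columns:
        out = table[~table["day"].isin(removed_days)].reset_index(drop=True)
    else:
        out = table.reset_index(drop=True)
    keep = ["animal_id", "group"] + [
        f for f in table.columns if f in CANONICAL_FEATURES and f not in condition.excluded
    ]
    return out[keep]


def _condition_seed(master_seed: int, condition: AblationCondition) -> int:
    # keyed on the condition id: independent of grid composition and order
    return derive_seed(master_seed, "condition", condition.condition_id)


def _checkpoint_path(checkpoint_dir: Path, condition: AblationCondition) -> Path:
    safe = re.sub(r"[^A-Za-z0-9._+-]", "_", condition.condition_id)
    return checkpoint_dir / f"{safe}.json"


def _result_to_payload(result: ConditionResult) -> dict:
    return {
        "condition_id": result.condition.condition_id,
        "day_filter": result.condition.day_filter,
        "excluded": sorted(result.condition.excluded),
        "seed": result.seed,
        "splx_accuracies": result.splx.accuracies,
        "sham_accuracies": result.sham.accuracies,
    }


def _payload_to_result(payload: dict, condition: AblationCondition) -> ConditionResult:
    if payload.get("condition_id") != condition.condition_id:
        raise ResumeError(
            f"checkpoint holds {payload.get('condition_id')!r}, "
            f"expected {condition.condition_id!r}"
        )
    cid = condition.condition_id
    return ConditionResult(
        condition,
        AccuracyResult(cid, GROUP_SPLX, list(payload["splx_accuracies"])),
        AccuracyResult(cid, GROUP_SHAM, list(payload["sham_accuracies"])),
        int(payload["seed"]),
    )


def run_grid(
    table: pd.DataFrame,
    conditions: Sequence[AblationCondition],
    spec: NetworkSpec,
    config: EnsembleConfig,
    checkpoint_dir: str | Path | None = None,
    progress: bool = False,
) -> GridResult:
    """Evaluate every condition with per-condition derived seeds.

    Seeds are keyed on the condition id, so results are independent of
    execution order.  With a checkpoint directory, finished conditions are
    persisted as JSON and reloaded on resume; a corrupt checkpoint raises
    :class:`ResumeError` rather than being silently recomputed.
    """
    if checkpoint_dir is not None:
        checkpoint_dir = Path(checkpoint_dir)
        checkpoint_dir.mkdir(parents=True, exist_ok=True)
    results = []
    for condition in conditions:
        ckpt = (
            _checkpoint_path(checkpoint_dir, condition) if checkpoint_dir is not None else None
        )
        if ckpt is not None and ckpt.exists():
            try:
                payload = json.loads(ckpt.read_text(encoding="utf-8"))
            except (json.JSONDecodeError, OSError) as exc:
                raise ResumeError(f"corrupt checkpoint {ckpt}: {exc}") from exc
            results.append(_payload_to_result(payload, condition))
            continue
        seed = _condition_seed(config.seed, condition)
        dataset = apply_condition(table, condition)
        splx, sham = evaluate_condition(
            dataset,
            spec,
            replace(config, seed=seed),
            condition_id=condition.condition_id,
        )
        result = ConditionResult(condition, splx, sham, seed)
        if ckpt is not None:
            ckpt.write_text(
                json.dumps(_result_to_payload(result), sort_keys=True), encoding="utf-8"
            )
        if progress:
            print(
                f"[grid] {condition.condition_id}: "
                f"SPLX {splx.mean_acc:.4f}+/-{splx.sd_acc:.4f} "
                f"SPL-sham {sham.mean_acc:.4f}+/-{sham.sd_acc:.4f}"
            )
        results.append(result)
    return GridResult(results)
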