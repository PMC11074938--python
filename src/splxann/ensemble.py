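"""Bootstrap consensus ensembles of MLPs and per-class accuracy.

The evaluation unit is: split the animals 70/30 (stratified by class, all
rows of an animal staying together), train ``n_members`` networks on
animal-level bootstrap resamples of the training partition, classify every
validation record by majority vote of the members' thresholded P(SPLX),
and score each class by its class-conditional accuracy (recall).  The
whole unit is repeated over independent replicates and each class's
accuracy is reported as mean +/- SD over replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import GROUP_SHAM, GROUP_SPLX, GROUPS
from .errors import (
    ConfigError,
    PredictionError,
    SplitError,
    TrainingError,
    UndefinedAccuracyError,
)
from .mlp import MLPNetwork, NetworkSpec, fit_members
from .seeds import derive_rng, derive_seed

__all__ = [
    "EnsembleConfig",
    "AccuracyResult",
    "FittedMember",
    "TrainedEnsemble",
    "feature_columns",
    "split_data",
    "train_member",
    "train_ensemble",
    "consensus_predict",
    "class_accuracy",
    "evaluate_condition",
]

_NON_FEATURE_COLUMNS = ("animal_id", "group")


@dataclass(frozen=True)
class EnsembleConfig:
    """Ensemble and replication settings."""

    n_members: int = 15
    train_fraction: float = 0.70
    bootstrap: bool = True
    tie_break: str = GROUP_SHAM
    replicates: int = 20
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ConfigError(f"train_fraction must be in (0, 1), got {self.train_fraction}")
        if self.n_members < 1:
            raise ConfigError(f"n_members must be >= 1, got {self.n_members}")
        if self.replicates < 2:
            raise ConfigError(
                f"replicates must be >= 2 so an SD is computable, got {self.replicates}"
            )
        if self.tie_break not in GROUPS:
            raise ConfigError(f"tie_break must be one of {GROUPS}, got {self.tie_break!r}")


@dataclass
class AccuracyResult:
    """Per-class consensus accuracy over training replicates."""

    condition_id: str
    class_label: str
    accuracies: list[float]
    mean_acc: float = field(init=False)
    sd_acc: float = field(init=False)

    def __post_init__(self) -> None:
        acc = np.asarray(self.accuracies, dtype=float)
        if np.any((acc < 0) | (acc > 1)):
            raise ConfigError("accuracies must lie in [0, 1]")
        self.mean_acc = float(np.mean(acc))
        self.sd_acc = float(np.std(acc, ddof=1)) if len(acc) > 1 else 0.0


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Model input columns: everything except animal id and class label."""
    return [c for c in table.columns if c not in _NON_FEATURE_COLUMNS]


def split_data(
    table: pd.DataFrame, train_fraction: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Animal-level stratified split.

    Per class, ``floor(train_fraction * n_class)`` animals (at least 1) go
    to training and the rest to validation; all rows of an animal stay in
    one partition.  Deterministic under the seed.
    """
    rng = derive_rng(seed, "split")
    train_animals: list = []
    val_animals: list = []
    for group in GROUPS:
        animals = np.sort(table.loc[table["group"] == group, "animal_id"].unique())
        if len(animals) < 2:
            raise SplitError(
                f"class {group!r} has {len(animals)} animal(s); need at least 2 to split"
            )
        n_train = max(1, int(math.floor(train_fraction * len(animals))))
        if n_train >= len(animals):
            n_train = len(animals) - 1
        perm = rng.permutation(len(animals))
        train_animals.extend(animals[perm[:n_train]])
        val_animals.extend(animals[perm[n_train:]])
    train = table[table["animal_id"].isin(train_animals)].reset_index(drop=True)
    val = table[table["animal_id"].isin(val_animals)].reset_index(drop=True)
    return train, val


@dataclass
class FittedMember:
    """A trained network plus the frozen standardisation of its inputs."""

    network: MLPNetwork
    features: list[str]
    center: np.ndarray
    scale: np.ndarray
    history: dict = field(default_factory=dict)

    def _design(self, table: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in table.columns]
        if missing:
            raise PredictionError(f"records are missing trained features: {missing}")
        X = table[self.features].to_numpy(dtype=float)
        return (X - self.center) / self.scale

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        """P(SPLX) per record."""
        return self.network.predict_proba(self._design(table))


def _labels(table: pd.DataFrame) -> np.ndarray:
    return (table["group"] == GROUP_SPLX).to_numpy(dtype=float)


def train_member(
    train_table: pd.DataFrame,
    spec: NetworkSpec,
    seed: int,
    monitor_table: pd.DataFrame | None = None,
) -> FittedMember:
    """Train one network on a training table.

    Features are z-scored with training-set statistics that are frozen
    into the member.  ``monitor_table`` (typically the 30% validation
    partition) drives early stopping when given.
    """
    if len(train_table) == 0:
        raise TrainingError("empty training table")
    if train_table["group"].nunique() < 2:
        raise TrainingError("training table contains a single class")
    features = feature_columns(train_table)
    X = train_table[features].to_numpy(dtype=float)
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0.0] = 1.0
    spec = replace(spec, input_dim=len(features))
    rng = derive_rng(seed, "member-init")
    network = MLPNetwork(spec, len(features), rng)
    member = FittedMember(network, features, center, scale)
    X_mon = y_mon = None
    if monitor_table is not None and len(monitor_table) > 0:
        X_mon = member._design(monitor_table)
        y_mon = _labels(monitor_table)
    member.history = network.fit((X - center) / scale, _labels(train_table), X_mon, y_mon)
    return member


@dataclass
class TrainedEnsemble:
    """A consensus ensemble with its split frozen in."""

    members: list[FittedMember]
    features: list[str]
    train_table: pd.DataFrame
    validation_table: pd.DataFrame
    tie_break: str = GROUP_SHAM


def _bootstrap_animals(
    train_table: pd.DataFrame, rng: np.random.Generator, max_tries: int = 100
) -> pd.DataFrame:
    """Animal-level bootstrap resample; redrawn if a single class results."""
    animals = np.sort(train_table["animal_id"].unique())
    row_index = train_table.groupby("animal_id", sort=False).indices
    for _ in range(max_tries):
        chosen = rng.choice(animals, size=len(animals), replace=True)
        blocks = [row_index[a] for a in chosen]
        rows = np.concatenate(blocks)
        sample = train_table.iloc[rows].reset_index(drop=True)
        # keep (animal, day) pairs unique across bootstrap copies
        sample["animal_id"] = np.repeat(
            [f"{a}#bs{i}" for i, a in enumerate(chosen)],
            [len(b) for b in blocks],
        )
        if sample["group"].nunique() == 2:
            return sample
    raise TrainingError("bootstrap resampling produced a single class repeatedly")


def train_ensemble(
    table: pd.DataFrame, spec: NetworkSpec, config: EnsembleConfig
) -> TrainedEnsemble:
    """One 70/30 split, then ``n_members`` bootstrap-trained networks.

    Members are trained through the stacked joint trainer, which performs
    the same arithmetic as training each member alone (so ``n_members=1``
    with bootstrap off reduces exactly to :func:`train_member`).
    """
    config.validate()
    train, val = split_data(table, config.train_fraction, config.seed)
    if val["group"].nunique() < 2 or train["group"].nunique() < 2:
        raise SplitError("split left a partition without both classes")
    features = feature_columns(table)
    spec = replace(spec, input_dim=len(features))
    members: list[FittedMember] = []
    networks, Xs, ys, X_mons = [], [], [], []
    for m in range(config.n_members):
        if config.bootstrap:
            member_train = _bootstrap_animals(train, derive_rng(config.seed, "bootstrap", m))
        else:
            member_train = train
        if member_train["group"].nunique() < 2:
            raise TrainingError("training table contains a single class")
        X = member_train[features].to_numpy(dtype=float)
        center = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0.0] = 1.0
        rng = derive_rng(derive_seed(config.seed, "member", m), "member-init")
        network = MLPNetwork(spec, len(features), rng)
        member = FittedMember(network, features, center, scale)
        members.append(member)
        networks.append(network)
        Xs.append((X - center) / scale)
        ys.append(_labels(member_train))
        X_mons.append(member._design(val))
    histories = fit_members(networks, Xs, ys, X_mons, _labels(val))
    for member, history in zip(members, histories):
        member.history = history
    return TrainedEnsemble(members, features, train, val, tie_break=config.tie_break)


def consensus_predict(ensemble: TrainedEnsemble, records: pd.DataFrame) -> np.ndarray:
    """Majority vote of member-thresholded predictions.

    Each member votes SPLX when its P(SPLX) >= 0.5; exact vote ties go to
    the configured tie-break class.
    """
    votes = np.zeros(len(records), dtype=int)
    for member in ensemble.members:
        votes += (member.predict_proba(records) >= 0.5).astype(int)
    n = len(ensemble.members)
    labels = np.where(votes * 2 > n, GROUP_SPLX, GROUP_SHAM)
    tie = votes * 2 == n
    labels[tie] = ensemble.tie_break
    return labels


def class_accuracy(
    true_labels: np.ndarray, predicted_labels: np.ndarray, target_class: str
) -> float:
    """Class-conditional accuracy (recall) of ``target_class``."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    of_class = true_labels == target_class
    if not of_class.any():
        raise UndefinedAccuracyError(
            f"no records of class {target_class!r}; accuracy undefined"
        )
    return float(np.mean(predicted_labels[of_class] == target_class))


def evaluate_condition(
    dataset: pd.DataFrame,
    spec: NetworkSpec,
    config: EnsembleConfig,
    condition_id: str = "all-variables",
) -> tuple[AccuracyResult, AccuracyResult]:
    """Replicated split/train/vote evaluation of one dataset.

    Returns (SPLX result, SPL-sham result), each mean +/- SD over
    ``config.replicates`` independent replicates with derived seeds.
    """
    config.validate()
    acc: dict[str, list[float]] = {GROUP_SPLX: [], GROUP_SHAM: []}
    for r in range(config.replicates):
        rep_config = replace(config, seed=derive_seed(config.seed, "replicate", r))
        ensemble = train_ensemble(dataset, spec, rep_config)
        predicted = consensus_predict(ensemble, ensemble.validation_table)
        truth = ensemble.validation_table["group"].to_numpy()
        for group in (GROUP_SPLX, GROUP_SHAM):
            acc[group].append(class_accuracy(truth, predicted, group))
    return (
        AccuracyResult(condition_id, GROUP_SPLX, acc[GROUP_SPLX]),
        AccuracyResult(condition_id, GROUP_SHAM, acc[GROUP_SHAM]),
    )
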