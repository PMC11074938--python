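"""Splitting, consensus voting, per-class accuracy and replication."""

import numpy as np
import pandas as pd
import pytest

from splxann import (
    AccuracyResult,
    EnsembleConfig,
    class_accuracy,
    consensus_predict,
    evaluate_condition,
    split_data,
    train_ensemble,
    train_member,
)
from splxann.ensemble import TrainedEnsemble, feature_columns
from splxann.errors import (
    ConfigError,
    PredictionError,
    SplitError,
    UndefinedAccuracyError,
)


class TestSplit:
    def test_floor_rule_and_stratification(self, separable_table):
        train, val = split_data(separable_table, 0.7, seed=0)
        for group in ("SPLX", "SPL-sham"):
            n_train = train.loc[train["group"] == group, "animal_id"].nunique()
            n_val = val.loc[val["group"] == group, "animal_id"].nunique()
            assert (n_train, n_val) == (14, 6)  # floor(0.7 * 20) = 14

    def test_no_animal_straddles_partitions(self, default_cohort):
        train, val = split_data(default_cohort, 0.7, seed=1)
        assert set(train["animal_id"]).isdisjoint(set(val["animal_id"]))
        # every row of each animal landed in exactly one partition
        assert len(train) + len(val) == len(default_cohort)

    def test_deterministic(self, default_cohort):
        a = split_data(default_cohort, 0.7, seed=2)
        b = split_data(default_cohort, 0.7, seed=2)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_small_class_rejected(self, default_cohort):
        one_splx = default_cohort[
            (default_cohort["group"] == "SPL-sham")
            | (default_cohort["animal_id"] == "SPLX-01")
        ]
        with pytest.raises(SplitError, match="SPLX"):
            split_data(one_splx, 0.7, seed=0)


class TestConsensus:
    @staticmethod
    def _fake_ensemble(probabilities, tie_break="SPL-sham"):
        """Members that output fixed probabilities regardless of input."""

        class Fixed:
            def __init__(self, p):
                self.p = p

            def predict_proba(self, records):
                return np.full(len(records), self.p)

        members = [Fixed(p) for p in probabilities]
        return TrainedEnsemble(members, ["mr_il"], None, None, tie_break=tie_break)

    def test_unanimous(self):
        records = pd.DataFrame({"mr_il": [1.0, 2.0]})
        ens = self._fake_ensemble([0.9, 0.8, 0.7])
        assert list(consensus_predict(ens, records)) == ["SPLX", "SPLX"]

    def test_majority(self):
        records = pd.DataFrame({"mr_il": [1.0]})
        ens = self._fake_ensemble([0.9, 0.8, 0.2])
        assert list(consensus_predict(ens, records)) == ["SPLX"]

    def test_tie_goes_to_tie_break_class(self):
        records = pd.DataFrame({"mr_il": [1.0]})
        ens = self._fake_ensemble([0.9, 0.9, 0.1, 0.1], tie_break="SPL-sham")
        assert list(consensus_predict(ens, records)) == ["SPL-sham"]
        ens2 = self._fake_ensemble([0.9, 0.9, 0.1, 0.1], tie_break="SPLX")
        assert list(consensus_predict(ens2, records)) == ["SPLX"]

    def test_feature_mismatch_rejected(self, separable_table, tiny_spec):
        member = train_member(separable_table, tiny_spec, seed=0)
        with pytest.raises(PredictionError, match="missing"):
            member.predict_proba(separable_table.drop(columns=["mr_il"]))


class TestClassAccuracy:
    def test_perfect(self):
        y = np.array(["SPLX", "SPL-sham", "SPLX"])
        assert class_accuracy(y, y, "SPLX") == 1.0

    def test_direct_count(self):
        truth = np.array(["SPLX"] * 4 + ["SPL-sham"])
        pred = np.array(["SPLX", "SPLX", "SPLX", "SPL-sham", "SPL-sham"])
        assert class_accuracy(truth, pred, "SPLX") == 0.75

    def test_absent_class_rejected(self):
        truth = np.array(["SPL-sham", "SPL-sham"])
        with pytest.raises(UndefinedAccuracyError):
            class_accuracy(truth, truth, "SPLX")


class TestEnsemble:
    def test_member_learns_separable_data(self, separable_table, tiny_spec):
        member = train_member(separable_table, tiny_spec, seed=3)
        p = member.predict_proba(separable_table)
        truth = (separable_table["group"] == "SPLX").to_numpy()
        assert (((p >= 0.5) == truth)).mean() >= 0.95
        assert member.history["train_loss"][-1] < member.history["train_loss"][0]

    def test_single_member_no_bootstrap_reduces_to_train_member(
        self, separable_table, tiny_spec
    ):
        config = EnsembleConfig(n_members=1, bootstrap=False, replicates=2, seed=4)
        ens = train_ensemble(separable_table, tiny_spec, config)
        train, val = split_data(separable_table, 0.7, seed=config.seed)
        from splxann.seeds import derive_seed

        solo = train_member(
            train, tiny_spec, derive_seed(config.seed, "member", 0), monitor_table=val
        )
        np.testing.assert_allclose(
            ens.members[0].predict_proba(val), solo.predict_proba(val), atol=1e-6
        )

    def test_bootstrap_members_differ(self, separable_table, tiny_spec):
        noisy = separable_table.copy()
        rng = np.random.default_rng(0)
        noisy["mr_il"] = 228 + rng.normal(0, 1, len(noisy))  # remove the signal
        config = EnsembleConfig(n_members=5, replicates=2, seed=5)
        ens = train_ensemble(noisy, tiny_spec, config)
        probs = np.stack([m.predict_proba(ens.validation_table) for m in ens.members])
        votes = probs >= 0.5
        assert (votes.any(axis=0) & ~votes.all(axis=0)).any()  # some disagreement

    def test_deterministic_under_seed(self, separable_table, tiny_spec):
        config = EnsembleConfig(n_members=2, replicates=2, seed=6)
        a = train_ensemble(separable_table, tiny_spec, config)
        b = train_ensemble(separable_table, tiny_spec, config)
        np.testing.assert_array_equal(
            consensus_predict(a, a.validation_table),
            consensus_predict(b, b.validation_table),
        )


class TestEvaluateCondition:
    def test_results_consistent_with_replicates(self, separable_table, tiny_spec):
        config = EnsembleConfig(n_members=3, replicates=3, seed=7)
        splx, sham = evaluate_condition(separable_table, tiny_spec, config, "toy")
        for res in (splx, sham):
            assert len(res.accuracies) == 3
            assert res.mean_acc == pytest.approx(np.mean(res.accuracies))
            assert res.sd_acc == pytest.approx(np.std(res.accuracies, ddof=1))
            assert all(0 <= a <= 1 for a in res.accuracies)
        # 10-SD separation: high accuracy even from a 3-member consensus
        # voting on only 12 validation records per class
        assert splx.mean_acc >= 0.8
        assert sham.mean_acc >= 0.8

    def test_equal_accuracies_zero_sd(self):
        res = AccuracyResult("c", "SPLX", [0.8, 0.8])
        assert res.sd_acc == 0.0

    def test_accuracy_result_rejects_out_of_range(self):
        with pytest.raises(ConfigError):
            AccuracyResult("c", "SPLX", [1.2])

    def test_determinism_full_evaluation(self, separable_table, tiny_spec):
        config = EnsembleConfig(n_members=2, replicates=2, seed=8)
        a = evaluate_condition(separable_table, tiny_spec, config)
        b = evaluate_condition(separable_table, tiny_spec, config)
        assert a[0].accuracies == b[0].accuracies
        assert a[1].accuracies == b[1].accuracies


def test_feature_columns_excludes_identity():
    frame = pd.DataFrame(
        {"animal_id": ["a"], "group": ["SPLX"], "day": [2], "mass": [24.0]}
    )
    assert feature_columns(frame) == ["day", "mass"]
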