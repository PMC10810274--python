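"""Validation designs: fold structure, determinism, ground-truth recovery."""

import numpy as np
import pytest

import odorid.validate as ov
from odorid import (
    DriftCorrectionSpec,
    EndpointTable,
    KNNConfig,
    drift_correct,
    feature_columns,
    run_accumulated_days,
    run_across_day_holdout,
    run_loo,
    run_repeated_one_out_per_participant,
    subset,
)
from odorid.datamodel import ValidationError
from odorid.validate import AccuracyDistribution, FoldScheme


def _body_table(n_participants=4, n_days=1, reps=3, d=3, noise=0.05, seed=0,
                identical_for=None):
    """Separable body-only table; participant `identical_for` gets exact
    duplicate replicates."""
    rng = np.random.default_rng(seed)
    feats = feature_columns(1, d)
    centers = rng.uniform(1.0, 4.0, size=(n_participants, d))
    rows = []
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        for day in range(1, n_days + 1):
            base = centers[p] * rng.uniform(0.9, 1.1, d)
            for rep in range(1, reps + 1):
                vec = base if (identical_for == pid) else base * np.exp(
                    rng.normal(0, noise, d))
                rows.append({"participant": pid, "day": day, "kind": "body",
                             "region": "ear", "replicate": rep,
                             **dict(zip(feats, vec))})
    return EndpointTable.from_rows(rows, feats)


class TestLOO:
    def test_duplicate_replicates_always_correct_with_k1(self):
        table = _body_table(identical_for="P02", noise=0.5)
        # P02's replicates are exact copies: each held-out copy has an exact
        # twin in training, so k=1 classifies all of them correctly
        x, y = table.matrix(), table.labels()
        from odorid import fit, predict

        mask = y == "P02"
        n = len(y)
        sel = np.ones(n, bool)
        for i in np.flatnonzero(mask):
            sel[i] = False
            model = fit(x[sel], y[sel], KNNConfig(k=1))
            assert predict(model, x[i:i + 1])[0] == "P02"
            sel[i] = True

    def test_row_order_invariance(self):
        table = _body_table(noise=0.3, seed=3)
        acc1 = run_loo(table, KNNConfig(k=2)).accuracies[0]
        perm = np.random.default_rng(1).permutation(len(table))
        shuffled = EndpointTable(frame=table.frame.iloc[perm].reset_index(drop=True),
                                 features=table.features)
        acc2 = run_loo(shuffled, KNNConfig(k=2)).accuracies[0]
        assert acc1 == acc2

    def test_perfect_recovery_on_strong_cohort(self, strong_ear_day1):
        assert run_loo(strong_ear_day1, KNNConfig(k=2)).accuracies[0] >= 0.95

    def test_needs_two_samples(self):
        table = _body_table(n_participants=2, reps=1)
        one = EndpointTable(frame=table.frame.iloc[:1].copy(), features=table.features)
        with pytest.raises(ValidationError):
            run_loo(one, KNNConfig(k=1))

    def test_rejects_tables_with_control_rows(self, default_cohort):
        table, _ = default_cohort
        with pytest.raises(ValidationError, match="body-only"):
            run_loo(table, KNNConfig(k=2))


class TestRepeatedOneOutPerParticipant:
    def test_fold_structure_one_day(self, monkeypatch):
        """One day, 3 replicates -> 3 folds, each training on 2 and testing
        on 1 sample per participant."""
        table = _body_table(n_participants=4, reps=3)
        calls = []
        real_fit = ov.fit

        def spy(x, y, cfg):
            calls.append((len(y), x.shape))
            return real_fit(x, y, cfg)

        monkeypatch.setattr(ov, "fit", spy)
        run_repeated_one_out_per_participant(table, KNNConfig(k=2), n_iterations=1)
        assert len(calls) == 3  # folds
        assert all(n == 4 * 2 for n, _ in calls)  # train 2 per participant

    def test_deterministic_given_seed(self):
        table = _body_table(noise=0.3)
        a = run_repeated_one_out_per_participant(table, KNNConfig(k=2), 10, seed=5)
        b = run_repeated_one_out_per_participant(table, KNNConfig(k=2), 10, seed=5)
        assert np.array_equal(a.accuracies, b.accuracies)
        c = run_repeated_one_out_per_participant(table, KNNConfig(k=2), 10, seed=6)
        assert not np.array_equal(a.accuracies, c.accuracies)

    def test_perfectly_separable_data_gives_sd_zero(self, strong_ear_day1):
        dist = run_repeated_one_out_per_participant(
            strong_ear_day1, KNNConfig(k=2), n_iterations=25, seed=1)
        assert dist.mean == 1.0 and dist.sd == 0.0

    def test_unequal_replicate_counts_rejected(self):
        table = _body_table(n_participants=3, reps=2)
        frame = table.frame.iloc[:-1].reset_index(drop=True)
        broken = EndpointTable(frame=frame, features=table.features)
        with pytest.raises(ValidationError, match="unequal"):
            run_repeated_one_out_per_participant(broken, KNNConfig(k=2), 1)


class TestAccumulatedDays:
    def test_fold_arithmetic_matches_design(self, monkeypatch):
        """2 days -> 6 folds training 5/person; 4 days -> 12 folds training
        11/person (3 replicates/day)."""
        table = _body_table(n_participants=3, n_days=4, reps=3)
        sizes = {}
        real_fit = ov.fit

        def spy(x, y, cfg):
            key = len(y) // 3  # train samples per participant
            sizes.setdefault(key, 0)
            sizes[key] += 1
            return real_fit(x, y, cfg)

        monkeypatch.setattr(ov, "fit", spy)
        run_accumulated_days(table, KNNConfig(k=2), n_iterations=1, seed=0)
        # windows 1-2, 1-3, 1-4 -> train per person 5, 8, 11
        assert sizes == {5: 6, 8: 9, 11: 12}

    def test_single_day_window_matches_one_out_scheme(self):
        table = _body_table(n_participants=4, n_days=2, reps=3, noise=0.4)
        result = run_accumulated_days(table, KNNConfig(k=2), day_sets=[[1]],
                                      n_iterations=8, seed=9)
        window = result[(1,)]
        direct = run_repeated_one_out_per_participant(
            subset(table, days=[1]), KNNConfig(k=2), n_iterations=8,
            seed=window.scheme.seed)
        assert np.array_equal(window.accuracies, direct.accuracies)


class TestAcrossDayHoldout:
    def test_perfect_on_noiseless_coupled_cohort(self, strong_cohort):
        table, _ = strong_cohort
        body = drift_correct(table, DriftCorrectionSpec())
        ear = subset(body, regions=["ear"])
        assert run_across_day_holdout(ear, KNNConfig(k=2), [1, 2, 3, 4], 5) >= 0.9

    def test_train_test_overlap_rejected(self):
        table = _body_table(n_days=3)
        with pytest.raises(ValidationError, match="must not appear"):
            run_across_day_holdout(table, KNNConfig(k=2), [1, 2], 2)

    def test_missing_test_day_rejected(self):
        table = _body_table(n_days=2)
        with pytest.raises(ValidationError, match="test day"):
            run_across_day_holdout(table, KNNConfig(k=2), [1, 2], 9)


class TestAccuracyDistribution:
    def test_summaries_recomputed_from_list(self):
        dist = AccuracyDistribution(np.array([0.2, 0.4, 0.9]), FoldScheme())
        assert np.isclose(dist.mean, 0.5)
        assert np.isclose(dist.median, 0.4)
        assert dist.sd > 0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            AccuracyDistribution(np.array([0.5, 1.2]), FoldScheme())

    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            FoldScheme(kind="bootstrap")
        with pytest.raises(ValueError):
            FoldScheme(n_iterations=0)
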