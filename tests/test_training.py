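import collections

import numpy as np
import pytest

from slidemil import mil_core as mc
from slidemil import synthetic_data as sd
from slidemil import training as tr


class TestSplits:
    def test_152_patients_largest_remainder(self):
        ids = [f"p{i}" for i in range(152)]
        split = tr.split_patients(ids, seed=0)
        sizes = collections.Counter(split.values())
        assert sizes["train"] + sizes["val"] + sizes["test"] == 152
        assert abs(sizes["train"] - 121.6) <= 1
        assert abs(sizes["val"] - 15.2) <= 1
        assert abs(sizes["test"] - 15.2) <= 1

    def test_ten_patients_8_1_1(self):
        split = tr.split_patients([f"p{i}" for i in range(10)], seed=3)
        sizes = collections.Counter(split.values())
        assert (sizes["train"], sizes["val"], sizes["test"]) == (8, 1, 1)

    def test_seeded_reproducibility(self):
        ids = [f"p{i}" for i in range(37)]
        assert tr.split_patients(ids, seed=5) == tr.split_patients(ids, seed=5)
        assert tr.split_patients(ids, seed=5) != tr.split_patients(ids, seed=6)

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            tr.split_patients(["a", "b"], ratios=(0.5, 0.2, 0.2), seed=0)


class TestFolds:
    def test_ten_patients_five_folds_of_two(self):
        labels = {f"p{i}": 0 for i in range(10)}
        folds = tr.make_cv_folds(labels, k=5, seed=0)
        assert sorted(collections.Counter(folds.values()).values()) == [2] * 5

    def test_fold_sizes_differ_by_at_most_one(self):
        labels = {f"p{i}": i % 3 for i in range(23)}
        folds = tr.make_cv_folds(labels, k=5, seed=1)
        sizes = collections.Counter(folds.values()).values()
        assert max(sizes) - min(sizes) <= 1

    def test_stratification_where_counts_permit(self):
        labels = {f"p{i}": i % 2 for i in range(20)}
        folds = tr.make_cv_folds(labels, k=5, seed=2)
        per_fold = collections.defaultdict(collections.Counter)
        for pid, f in folds.items():
            per_fold[f][labels[pid]] += 1
        for f, counter in per_fold.items():
            assert counter[0] == 2 and counter[1] == 2

    def test_small_class_warns_and_still_assigns(self):
        labels = {f"p{i}": (0 if i < 8 else 1) for i in range(10)}
        with pytest.warns(UserWarning, match="stratification"):
            folds = tr.make_cv_folds(labels, k=5, seed=0)
        assert set(folds) == set(labels)

    def test_seeded_rerun_identical(self):
        labels = {f"p{i}": i % 4 for i in range(40)}
        assert tr.make_cv_folds(labels, 5, seed=9) == \
               tr.make_cv_folds(labels, 5, seed=9)


class TestSchedule:
    @pytest.fixture()
    def cfg(self):
        return tr.TrainConfig.for_level("patient")

    @pytest.mark.parametrize("epoch,expected", [
        (0, 1e-4),          # initial rate
        (10, 5e-5),         # cos(pi/2) = 0 midway through the first cycle
        (20, 1e-4),         # first warm restart
        (60, 1e-4),         # second restart after a 40-epoch cycle
        (40, 5e-5),         # midway through the second cycle
        (100, 5e-5),        # midway through the 80-epoch third cycle
    ])
    def test_cosine_warm_restarts_closed_form(self, cfg, epoch, expected):
        assert tr.cosine_lr(epoch, cfg) == pytest.approx(expected, rel=1e-12)

    def test_slide_level_schedule_is_constant(self):
        cfg = tr.TrainConfig.for_level("slide")
        assert {tr.cosine_lr(e, cfg) for e in range(0, 200, 7)} == {1e-5}


class TestEarlyStopping:
    @pytest.fixture()
    def cfg(self):
        return tr.TrainConfig.for_level("patient")

    def test_stops_exactly_after_patience_without_improvement(self, cfg):
        aucs = [0.80] + [0.8009] * 15   # never beats best by > 0.001
        assert tr.early_stopping_step(aucs[:15], cfg) == "continue"
        assert tr.early_stopping_step(aucs, cfg) == "stop"

    def test_steady_improvement_never_stops(self, cfg):
        aucs = [0.5 + 0.002 * i for i in range(300)]
        assert tr.early_stopping_step(aucs, cfg) == "continue"

    def test_max_epochs_cap(self):
        cfg = tr.TrainConfig.for_level("patient", max_epochs=30)
        aucs = [0.5 + 0.002 * i for i in range(30)]
        assert tr.early_stopping_step(aucs, cfg) == "stop"

    def test_improvement_below_delta_does_not_reset_patience(self, cfg):
        # a +0.0005 bump at epoch 10 must not count as improvement
        aucs = [0.9] + [0.9] * 8 + [0.9005] + [0.9] * 6
        assert tr.early_stopping_step(aucs, cfg) == "stop"


class TestHooks:
    def test_identity_hook_is_default_and_bitwise(self, rng):
        patch = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        hook = tr.get_hook(None)
        assert np.array_equal(hook(patch), patch)

    def test_registered_hook_preserves_shape_and_dtype(self, rng):
        tr.register_hook("flip", lambda p: p[::-1].copy())
        patch = rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)
        out = tr.get_hook("flip")(patch)
        assert out.shape == patch.shape and out.dtype == patch.dtype

    def test_unknown_hook_rejected(self):
        with pytest.raises(ValueError, match="unknown augmentation hook"):
            tr.get_hook("no-such-hook")

    def test_evaluation_encodings_unaffected_by_training_hook(self):
        # encoding without a hook is identical whether or not one exists
        from slidemil import encoders as en
        from slidemil import tiling_qc as tq
        img = np.full((512, 512, 3), 140, dtype=np.uint8)
        img[::7] = 60
        rec = tq.PatchRecord("s", 0, 0, 512, "40x", qc_pass=True)
        enc = en.StubEncoder(embedding_dim=8, seed=0)
        tr.register_hook("darken", lambda p: (p // 2).astype(p.dtype))
        plain = en.encode_slide([rec], img, enc).embeddings
        again = en.encode_slide([rec], img, enc).embeddings
        augmented = en.encode_slide([rec], img, enc,
                                    augmentation=tr.get_hook("darken")).embeddings
        assert np.array_equal(plain, again)
        assert not np.array_equal(plain, augmented)


@pytest.fixture(scope="module")
def split_cohort(small_cohort):
    small_cohort.split = tr.split_patients(small_cohort.patient_ids, seed=11)
    return small_cohort


class TestTrainModel:
    def test_leakage_assertion_runs_on_every_cohort(self, split_cohort):
        split_cohort.assert_no_leakage()
        broken = dict(split_cohort.split)
        pid = split_cohort.patient_ids[0]
        # simulate a duplicated-assignment bug via an unknown split name
        broken[pid] = "trainval"
        split_cohort_copy = split_cohort
        old = split_cohort_copy.split
        split_cohort_copy.split = broken
        try:
            with pytest.raises(AssertionError):
                split_cohort_copy.assert_no_leakage()
        finally:
            split_cohort_copy.split = old

    def test_same_seed_identical_history(self, split_cohort):
        cfg = tr.TrainConfig.for_level("slide", seed=4, hidden_dim=8,
                                       max_epochs=4, patience=10)
        _, h1 = tr.train_model(split_cohort, "slide", cfg)
        _, h2 = tr.train_model(split_cohort, "slide", cfg)
        assert h1.to_dataframe()["val_auc"].tolist() == \
               h2.to_dataframe()["val_auc"].tolist()
        assert h1.to_dataframe()["train_loss"].tolist() == \
               h2.to_dataframe()["train_loss"].tolist()

    def test_loss_halves_within_fifty_epochs_when_optimizer_moves(
            self, split_cohort):
        cfg = tr.TrainConfig.for_level("slide", seed=4, hidden_dim=16,
                                       max_epochs=50, patience=10**6)
        cfg.lr0 = 1e-3
        _, hist = tr.train_model(split_cohort, "slide", cfg)
        losses = hist.to_dataframe()["train_loss"]
        assert losses.iloc[-1] <= 0.5 * losses.iloc[0]

    def test_lr_trace_matches_closed_form(self, split_cohort):
        cfg = tr.TrainConfig.for_level("patient", seed=1, hidden_dim=8,
                                       max_epochs=25, patience=10**6)
        patient_cohort = sd.make_patient_cohort(
            sd.BagCohortSpec(n_patients=24, seed=13))
        patient_cohort.split = tr.split_patients(patient_cohort.patient_ids,
                                                 seed=13)
        _, hist = tr.train_model(patient_cohort, "patient", cfg)
        for row in hist.epochs:
            assert row["lr"] == pytest.approx(
                tr.cosine_lr(row["epoch"] - 1, cfg), rel=1e-12)

    def test_returns_best_validation_checkpoint(self, split_cohort):
        cfg = tr.TrainConfig.for_level("slide", seed=4, hidden_dim=8,
                                       max_epochs=6, patience=10**6)
        cfg.lr0 = 1e-3
        model, hist = tr.train_model(split_cohort, "slide", cfg)
        # recompute validation AUC of the returned parameters
        val = split_cohort.slide_items("val")
        probs = np.vstack([mc.slide_forward(b, model).probabilities
                           for _, b, _ in val])
        truth = np.array([y for _, _, y in val])
        got = tr._macro_ovr_auc(probs, truth, split_cohort.n_classes)
        assert got == pytest.approx(hist.best_val_auc, abs=1e-9)

    def test_encoder_untouched_by_training(self, split_cohort):
        from slidemil import encoders as en
        enc = en.StubEncoder(embedding_dim=16, seed=2)
        before = enc.parameter_hash()
        cfg = tr.TrainConfig.for_level("slide", seed=0, hidden_dim=8,
                                       max_epochs=2, patience=10)
        tr.train_model(split_cohort, "slide", cfg)
        assert enc.parameter_hash() == before
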