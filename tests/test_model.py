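"""Model building, training mechanics, patient-level CV, learning curves.

Training checks run at reduced scale (64-px phantoms, few epochs); the
full end-to-end accuracy property lives in the acceptance suite.
"""

import numpy as np
import pytest

from cervalign._nn import rmse_loss
from cervalign.model import (
    HeatmapLandmarkRegressor,
    ModelConfig,
    TrainConfig,
    build_model,
    learning_curve,
    load_training_arrays,
    patient_kfold,
    run_cross_validation,
    train_model,
)
from cervalign.phantom import PhantomSpec, generate_arrays


def _small_reg(**kw):
    defaults = dict(input_size=64, max_epochs=3, patience=2, random_state=0)
    defaults.update(kw)
    return HeatmapLandmarkRegressor(**defaults)


@pytest.fixture(scope="module")
def small_arrays():
    X, y, pids, postures, targets = generate_arrays(
        8, PhantomSpec(image_size=64, seed=77)
    )
    return X, y, pids


class TestPatientKFold:
    def test_balanced_folds_of_two(self):
        split = patient_kfold([f"p{i}" for i in range(10)], k=5, seed=0)
        sizes = sorted(len(f) for f in split.folds())
        assert sizes == [2, 2, 2, 2, 2]

    def test_deterministic_given_seed(self):
        ids = [f"p{i}" for i in range(23)]
        a = patient_kfold(ids, 5, seed=3)
        b = patient_kfold(ids, 5, seed=3)
        c = patient_kfold(ids, 5, seed=4)
        assert a.assignments == b.assignments
        assert a.assignments != c.assignments

    def test_partition_properties_over_many_seeds(self):
        ids = [f"p{i}" for i in range(17)]
        for seed in range(200):
            split = patient_kfold(ids, 5, seed)
            folds = split.folds()
            all_ids = [p for f in folds for p in f]
            assert sorted(all_ids) == sorted(ids)  # each patient exactly once
            sizes = [len(f) for f in folds]
            assert max(sizes) - min(sizes) <= 1

    def test_input_order_irrelevant(self):
        ids = [f"p{i}" for i in range(12)]
        a = patient_kfold(ids, 4, seed=1)
        b = patient_kfold(ids[::-1] * 3, 4, seed=1)  # duplicates + reorder
        assert a.assignments == b.assignments

    def test_images_of_one_patient_stay_together(self):
        # three images per patient in a toy manifest all land in one fold
        ids = [f"p{i}" for i in range(6) for _ in range(3)]
        split = patient_kfold(ids, 3, seed=0)
        for i in range(6):
            folds = {split.fold_of(f"p{i}") for _ in range(3)}
            assert len(folds) == 1

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            patient_kfold(["a", "b"], 3, seed=0)


class TestBuildModel:
    def test_desk_scale_forward_is_fast_finite_and_bounded(self):
        import time

        model = build_model(ModelConfig(variant="desk_scale"))
        zero = np.zeros((1, 128, 128), dtype=np.uint8)
        t0 = time.time()
        stacks = model.predict_heatmaps(zero)
        assert time.time() - t0 < 1.0
        values = stacks[0].values
        assert values.shape == (4, 64, 64)
        assert np.all(np.isfinite(values))
        assert values.min() >= 0.0 and values.max() <= 1.0  # sigmoid head

    def test_paper_scale_snapshot_echoes_backbone(self):
        model = build_model(ModelConfig(variant="paper_scale"))
        assert model.config_snapshot_["model"]["backbone"] == "efficientnet-b4"

    def test_unknown_variant_lists_valid_options(self):
        with pytest.raises(ValueError, match="desk_scale"):
            ModelConfig(variant="resnet")

    def test_out_channels_fixed_at_four(self):
        with pytest.raises(ValueError):
            ModelConfig(out_channels=5)

    def test_input_size_must_match_stride(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(input_size=130)


class TestTraining:
    def test_loss_decreases_on_small_phantom_set(self, small_arrays):
        X, y, pids = small_arrays
        reg = _small_reg(max_epochs=4).fit(X, y, groups=pids)
        hist = reg.history_["train_loss"]
        assert len(hist) >= 3
        assert hist[reg.history_["best_epoch"] - 1] < hist[0]

    def test_scripted_early_stopping_restores_best_epoch(self, small_arrays):
        X, y, pids = small_arrays
        losses = {1: 1.0, 2: 0.5, 3: 0.7, 4: 0.9, 5: 0.95}
        snapshots = {}

        def hook(model, epoch):
            snapshots[epoch] = model.net_.get_state()
            return losses[epoch]

        reg = _small_reg(max_epochs=5, patience=1)
        reg.fit(X, y, groups=pids, validation_hook=hook)
        assert len(reg.history_["val_loss"]) == 3  # stopped after epoch 3
        assert reg.history_["best_epoch"] == 2
        for got, want in zip(reg.net_.get_state(), snapshots[2]):
            assert np.array_equal(got, want)
        assert min(reg.history_["val_loss"]) == 0.5

    def test_fixed_seed_reproduces_epoch_one_loss(self, small_arrays):
        X, y, pids = small_arrays
        a = _small_reg(max_epochs=1).fit(X, y, groups=pids)
        b = _small_reg(max_epochs=1).fit(X, y, groups=pids)
        assert a.history_["train_loss"][0] == b.history_["train_loss"][0]

    def test_zero_variance_targets_warn_but_train(self, small_arrays):
        X, _, pids = small_arrays
        y_const = np.tile(
            np.array([[10, 10], [40, 12], [12, 50], [44, 52]], dtype=float),
            (len(X), 1, 1),
        )
        with pytest.warns(RuntimeWarning, match="identical"):
            reg = _small_reg(max_epochs=1).fit(X, y_const, groups=pids)
        assert len(reg.history_["train_loss"]) == 1

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            _small_reg().fit(np.zeros((0, 64, 64)), np.zeros((0, 4, 2)))

    def test_validation_loss_never_below_recorded_minimum(self, small_arrays):
        X, y, pids = small_arrays
        reg = _small_reg(max_epochs=4).fit(X, y, groups=pids)
        best = reg.history_["val_loss"][reg.history_["best_epoch"] - 1]
        assert best == min(reg.history_["val_loss"])

    def test_save_load_round_trip(self, small_arrays, tmp_path):
        X, y, pids = small_arrays
        reg = _small_reg(max_epochs=1).fit(X, y, groups=pids)
        path = tmp_path / "model.npz"
        reg.save(path)
        loaded = HeatmapLandmarkRegressor.load(path)
        assert np.array_equal(loaded.predict(X[:2]), reg.predict(X[:2]))
        assert loaded.history_ == reg.history_

    def test_rmse_loss_matches_definition(self, rng):
        pred = rng.uniform(size=(2, 4, 8, 8)).astype(np.float32)
        target = rng.uniform(size=(2, 4, 8, 8)).astype(np.float32)
        loss, _ = rmse_loss(pred, target)
        assert loss == pytest.approx(
            float(np.sqrt(np.mean((pred - target) ** 2))), rel=1e-6
        )


class TestManifestPlumbing:
    def test_train_model_on_manifest(self, tiny_dataset):
        reg = _small_reg(max_epochs=1)
        train_model(reg, tiny_dataset["manifest"],
                    tiny_dataset["manifest_path"])
        assert len(reg.history_["train_loss"]) == 1

    def test_cross_validation_partitions_exactly(self, tiny_dataset):
        result = run_cross_validation(
            tiny_dataset["manifest"], tiny_dataset["manifest_path"], k=5,
            model_config=ModelConfig(input_size=64),
            train_config=TrainConfig(max_epochs=1, seed=0),
        )
        tested = [r.image_id for r in result.records]
        assert sorted(tested) == sorted(tiny_dataset["manifest"]["image"])
        assert result.pooled_summary.n == 30
        assert len(result.fold_summaries) == 5
        # fold test sets are patient-disjoint by construction of the split
        for rec in result.records:
            fold = result.split.fold_of(rec.patient_id)
            assert fold in range(5)

    def test_learning_curve_plumbing_and_errors(self, tiny_dataset):
        manifest = tiny_dataset["manifest"]
        train_df = manifest[manifest["patient_id"] < "P0007"]
        test_df = manifest[manifest["patient_id"] >= "P0007"]
        results = learning_curve(
            train_df, test_df, tiny_dataset["manifest_path"], sizes=[3, 6],
            model_config=ModelConfig(input_size=64),
            train_config=TrainConfig(max_epochs=1, seed=0),
        )
        assert [size for size, _ in results] == [3, 6]
        with pytest.raises(ValueError):
            learning_curve(
                train_df, test_df, tiny_dataset["manifest_path"], sizes=[0],
                model_config=ModelConfig(input_size=64),
            )
        with pytest.raises(ValueError):
            learning_curve(
                train_df, test_df, tiny_dataset["manifest_path"], sizes=[999],
                model_config=ModelConfig(input_size=64),
            )

    def test_resize_maps_landmarks_consistently(self):
        from cervalign.model import _resize_with_landmarks

        img = np.zeros((100, 50), dtype=np.uint8)
        img[80, 30] = 255
        pts = np.array([[30.0, 80.0]])
        resized, mapped, scale = _resize_with_landmarks(img, pts, 64)
        assert resized.shape == (64, 64)
        assert scale == pytest.approx(0.64)
        assert mapped[0] == pytest.approx([19.2, 51.2])
        # brightest pixel of the resized image sits near the mapped point
        r, c = np.unravel_index(np.argmax(resized), resized.shape)
        assert abs(c - 19.2) <= 1.5 and abs(r - 51.2) <= 1.5
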