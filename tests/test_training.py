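import numpy as np
import pytest

from sfnet.image_io import LabeledDataset, ValidationError
from sfnet.model import SFNetConfig, build_sfnet
from sfnet.synthetic import PhantomSpec, generate_dataset
from sfnet.training import (
    TrainConfig,
    augment,
    augment_dataset,
    fit_arrays,
    split_dataset,
    train,
)


def tiny_config():
    return SFNetConfig(input_side=32, input_channels=1, conv_widths=(4, 8), dense_units=16)


def tiny_data(n_per_class=20, noise=0.05, seed=0):
    spec = PhantomSpec(side=32, shaft_width=8, noise_sigma=noise)
    return generate_dataset(n_per_class, template=spec, seed=seed)


class TestAugment:
    @pytest.fixture
    def img(self):
        return np.clip(np.random.default_rng(0).random((24, 24)), 0, 1)

    def test_one_output_per_op_plus_original(self, img):
        out = augment(img, seed=1)
        assert len(out) == 5
        assert np.array_equal(out[0], img)
        assert all(o.shape == img.shape for o in out)

    def test_hflip_involution(self, img):
        flipped = augment(img, ops=("hflip",), seed=0)[1]
        assert np.array_equal(flipped[:, ::-1], img)

    def test_vflip_of_hflip_is_rotation_180(self, img):
        h = augment(img, ops=("hflip",), seed=0)[1]
        vh = augment(h, ops=("vflip",), seed=0)[1]
        assert np.array_equal(vh, img[::-1, ::-1])

    def test_deterministic_given_seed(self, img):
        a = augment(img, seed=42)
        b = augment(img, seed=42)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_unknown_op_rejected(self, img):
        with pytest.raises(ValidationError, match="sharpen"):
            augment(img, ops=("sharpen",))

    def test_dataset_augmentation_grows_fivefold(self):
        ds = tiny_data(3)
        out = augment_dataset(ds, seed=0)
        assert len(out) == 5 * len(ds)
        assert out.class_counts["fracture"] == 5 * ds.class_counts["fracture"]


class TestSplitDataset:
    def _dummy(self, n_per_class):
        items = [(f"f_{i}.png", "fracture") for i in range(n_per_class)]
        items += [(f"h_{i}.png", "healthy") for i in range(n_per_class)]
        return LabeledDataset(items)

    def test_published_split_arithmetic(self):
        """A balanced 34,000-item dataset at ratio 0.8 gives 13,600 train and
        3,400 test items per class."""
        split = split_dataset(self._dummy(17_000), ratio=0.8, seed=0)
        assert split.train.class_counts == {"fracture": 13_600, "healthy": 13_600}
        assert split.test.class_counts == {"fracture": 3_400, "healthy": 3_400}

    def test_small_split(self):
        split = split_dataset(self._dummy(10), ratio=0.8, seed=0)
        assert split.train.class_counts == {"fracture": 8, "healthy": 8}
        assert split.test.class_counts == {"fracture": 2, "healthy": 2}

    def test_disjoint_and_complete(self):
        ds = self._dummy(25)
        split = split_dataset(ds, ratio=0.8, seed=3)
        train_paths = {p for p, _ in split.train.items}
        test_paths = {p for p, _ in split.test.items}
        assert not train_paths & test_paths
        assert train_paths | test_paths == {p for p, _ in ds.items}

    def test_deterministic_membership(self):
        ds = self._dummy(30)
        s1 = split_dataset(ds, ratio=0.7, seed=5)
        s2 = split_dataset(ds, ratio=0.7, seed=5)
        assert [p for p, _ in s1.test.items] == [p for p, _ in s2.test.items]

    @pytest.mark.parametrize("n,ratio", [(10, 0.8), (17, 0.6), (51, 0.75)])
    def test_stratification_within_one_item(self, n, ratio):
        split = split_dataset(self._dummy(n), ratio=ratio, seed=1)
        for cls in ("fracture", "healthy"):
            got = split.train.class_counts[cls]
            assert abs(got - ratio * n) < 1

    def test_tiny_class_rejected(self):
        ds = LabeledDataset([("a.png", "fracture"), ("b.png", "healthy"), ("c.png", "healthy")])
        with pytest.raises(ValidationError, match="fracture"):
            split_dataset(ds, ratio=0.5, seed=0)


@pytest.fixture(scope="module")
def short_run():
    """One small seeded run shared by the contract tests."""
    ds = tiny_data(16)
    split = split_dataset(ds, ratio=0.75, seed=0)
    model = build_sfnet(tiny_config(), seed=0)
    cfg = TrainConfig(epochs=3, batch_size=8, seed=0)
    history = train(model, split, cfg)
    return model, history, split


class TestTrainingLoop:
    def test_history_has_epochs_entries(self, short_run):
        _, history, _ = short_run
        assert all(len(v) == 3 for v in history.values())
        assert set(history) == {"train_loss", "train_acc", "val_loss", "val_acc"}

    def test_same_seed_identical_curves(self, short_run):
        _, history, split = short_run
        model2 = build_sfnet(tiny_config(), seed=0)
        history2 = train(model2, split, TrainConfig(epochs=3, batch_size=8, seed=0))
        assert history == history2

    def test_rmsprop_optimizer_runs(self):
        ds = tiny_data(8)
        split = split_dataset(ds, ratio=0.75, seed=0)
        model = build_sfnet(tiny_config(), seed=0)
        cfg = TrainConfig(epochs=1, batch_size=8, optimizer="rmsprop", learning_rate=1e-4, seed=0)
        history = train(model, split, cfg)
        assert len(history["train_loss"]) == 1

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            TrainConfig(split_ratio=1.2)
        with pytest.raises(ValidationError):
            TrainConfig(optimizer="sgd")


class TestLearnability:
    def test_overfits_small_phantom_set(self):
        """The model has the capacity to memorize 200 phantom image pairs:
        train accuracy reaches 0.99 within 20 epochs."""
        ds = tiny_data(100, noise=0.05, seed=7)
        split = split_dataset(ds, ratio=0.9, seed=0)
        cfg = SFNetConfig(input_side=32, input_channels=1,
                          conv_widths=(8, 16, 32), dense_units=32)
        model = build_sfnet(cfg, seed=0)
        history = train(model, split, TrainConfig(epochs=20, batch_size=32, seed=0))
        assert history["train_acc"][-1] >= 0.99
        # loss decreases on average between the first and last three epochs
        assert np.mean(history["train_loss"][:3]) > np.mean(history["train_loss"][-3:])
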