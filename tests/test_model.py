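import numpy as np
import pytest

from eegaffect.model import (NetworkConfig, ResidualBlockConfig, TrainingConfig,
                             binary_form_crossentropy, build_network,
                             categorical_crossentropy, relu, select_best_epoch,
                             softmax, split_dataset, train)
from eegaffect.model.network import Bottleneck
from eegaffect.model.training import EpochRecord, one_hot


class TestActivations:
    @pytest.mark.parametrize("x,expected", [(5, 5), (-3, 0), (0, 0)])
    def test_relu(self, x, expected):
        assert relu(x) == expected

    def test_softmax_symmetry(self):
        np.testing.assert_allclose(softmax([0.0, 0.0, 0.0]), [1 / 3] * 3)

    @pytest.mark.parametrize("c", [-100.0, 0.0, 42.0])
    def test_softmax_shift_invariance_closed_form(self, c):
        out = softmax([c, c + np.log(2), c])
        np.testing.assert_allclose(out, [0.25, 0.5, 0.25], atol=1e-12)

    def test_softmax_large_magnitudes_stable(self):
        out = softmax([1000.0, 0.0, 0.0])
        assert np.all(np.isfinite(out))
        np.testing.assert_allclose(out, [1.0, 0.0, 0.0], atol=1e-200)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)

    def test_softmax_rejects_empty(self):
        with pytest.raises(ValueError):
            softmax(np.array([]))


class TestLoss:
    def test_perfect_prediction_zero(self):
        assert categorical_crossentropy([1, 0, 0], [1, 0, 0]) == pytest.approx(0, abs=1e-6)

    def test_uniform_prediction(self):
        assert categorical_crossentropy([1, 0, 0], [1 / 3] * 3) == pytest.approx(
            np.log(3), abs=1e-9)

    def test_binary_sum_form_worked_example(self):
        # -[ln(1/3) + 2 ln(2/3)] for a one-hot target vs the uniform output
        expected = -(np.log(1 / 3) + 2 * np.log(2 / 3))
        assert expected == pytest.approx(1.9095, abs=5e-4)
        assert binary_form_crossentropy([1, 0, 0], [1 / 3] * 3) == pytest.approx(
            expected, abs=1e-6)

    def test_batch_mean_equals_single_item(self):
        y = np.array([[1, 0, 0], [1, 0, 0]], dtype=float)
        a = np.array([[0.7, 0.2, 0.1], [0.7, 0.2, 0.1]])
        assert categorical_crossentropy(y, a) == pytest.approx(
            categorical_crossentropy(y[0], a[0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            categorical_crossentropy([1, 0], [0.5, 0.3, 0.2])


class TestSplitDataset:
    def test_paper_corpus_split(self):
        train_idx, test_idx = split_dataset(675, (9, 1), seed=0)
        assert len(train_idx) == 607
        assert len(test_idx) == 68

    def test_exact_division(self):
        train_idx, test_idx = split_dataset(10, (9, 1), seed=0)
        assert len(train_idx) == 9 and len(test_idx) == 1

    def test_disjoint_exhaustive(self):
        train_idx, test_idx = split_dataset(101, (9, 1), seed=3)
        merged = np.sort(np.concatenate([train_idx, test_idx]))
        np.testing.assert_array_equal(merged, np.arange(101))

    def test_seed_determinism(self):
        a = split_dataset(100, (9, 1), seed=7)
        b = split_dataset(100, (9, 1), seed=7)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])
        c = split_dataset(100, (9, 1), seed=8)
        assert not np.array_equal(a[1], c[1])

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            split_dataset(3, (9, 1), seed=0)


class TestNetworkStructure:
    def test_small_preset_forward_is_probability(self):
        net = build_network(NetworkConfig.small(), seed=0)
        x = np.random.default_rng(0).random((2, 224, 224), dtype=np.float32)
        probs = net.predict_proba(x)
        assert probs.shape == (2, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs > 0)

    def test_seeded_init_reproducible(self):
        a = build_network(NetworkConfig.small(), seed=5)
        b = build_network(NetworkConfig.small(), seed=5)
        for (na, pa, _), (nb, pb, _) in zip(a.parameters(), b.parameters()):
            assert na == nb
            np.testing.assert_array_equal(pa, pb)

    def test_input_shape_rejected(self):
        net = build_network(NetworkConfig.small(), seed=0)
        with pytest.raises(ValueError, match="224"):
            net.forward_logits(np.zeros((1, 112, 112)))

    def test_resnet50_preset_requires_canonical_counts(self):
        with pytest.raises(ValueError, match="3, 4, 6, 3"):
            NetworkConfig(depth_preset="resnet50", stage_block_counts=(1, 1, 1, 1),
                          stage_widths=((4, 16),) * 4)

    def test_projection_required_on_shape_change(self):
        with pytest.raises(ValueError, match="projection"):
            ResidualBlockConfig(kind="bottleneck", channels_in=16, channels_out=32,
                                stride=1, projection=False)

    def test_zeroed_branch_is_identity(self):
        rng = np.random.default_rng(0)
        block = Bottleneck(16, 4, 16, stride=1, rng=rng)
        block.zero_branch()
        x = np.abs(rng.normal(size=(2, 16, 8, 8))).astype(np.float32)
        np.testing.assert_array_equal(block.forward(x, train=False), x)

    def test_projected_shortcut_with_zero_branch(self):
        rng = np.random.default_rng(0)
        block = Bottleneck(8, 4, 16, stride=2, rng=rng)
        block.zero_branch()
        x = rng.normal(size=(1, 8, 8, 8)).astype(np.float32)
        out = block.forward(x, train=False)
        sc = block.shortcut.forward(x, train=False)
        np.testing.assert_array_equal(out, np.maximum(sc, 0))


class TestSelectBestEpoch:
    def test_argmax(self):
        records = [EpochRecord(1, 0.5), EpochRecord(2, 0.7), EpochRecord(3, 0.6)]
        assert select_best_epoch(records) == 2

    def test_earliest_wins_on_tie(self):
        records = [EpochRecord(1, 0.7), EpochRecord(2, 0.7)]
        assert select_best_epoch(records) == 1

    def test_single_record(self):
        assert select_best_epoch([EpochRecord(1, 0.3)]) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best_epoch([])


def synthetic_images(n_per_class, seed, noise=0.05):
    """Linearly separable 224x224 images: one bright band strip per class."""
    rng = np.random.default_rng(seed)
    images, labels = [], []
    strips = {-1: slice(0, 74), 0: slice(74, 148), 1: slice(148, 224)}
    for label, strip in strips.items():
        for _ in range(n_per_class):
            img = rng.random((224, 224), dtype=np.float32) * noise
            img[strip] += 0.5
            images.append(img)
            labels.append(label)
    return np.stack(images), np.array(labels)


class TestTraining:
    def test_record_count_matches_epochs(self):
        images, labels = synthetic_images(4, seed=0)
        net = build_network(NetworkConfig.small(), seed=0)
        config = TrainingConfig(epochs=3, seed=0, keep_checkpoints=True)
        records, checkpoints = train(net, images[:9], labels[:9], images[9:], labels[9:],
                                     config)
        assert len(records) == 3
        assert len(checkpoints) == 3
        assert [r.epoch for r in records] == [1, 2, 3]

    def test_separable_images_reach_high_accuracy(self):
        images, labels = synthetic_images(10, seed=1)
        train_idx, test_idx = split_dataset(len(images), (9, 1), seed=1)
        net = build_network(NetworkConfig.small(), seed=1)
        config = TrainingConfig(epochs=8, seed=1, keep_checkpoints=False)
        records, _ = train(net, images[train_idx], labels[train_idx],
                           images[test_idx], labels[test_idx], config)
        assert max(r.test_accuracy for r in records) >= 0.9

    def test_bit_reproducible_from_seed(self):
        images, labels = synthetic_images(2, seed=2)
        config = TrainingConfig(epochs=2, seed=9, keep_checkpoints=False)
        runs = []
        for _ in range(2):
            net = build_network(NetworkConfig.small(), seed=9)
            records, _ = train(net, images[:5], labels[:5], images[5:], labels[5:],
                               config)
            runs.append([(r.train_loss, r.test_accuracy) for r in records])
        assert runs[0] == runs[1]

    def test_empty_sets_rejected(self):
        net = build_network(NetworkConfig.small(), seed=0)
        with pytest.raises(ValueError, match="non-empty"):
            train(net, np.zeros((0, 224, 224)), [], np.zeros((1, 224, 224)), [0],
                  TrainingConfig(epochs=1))


def test_one_hot_label_mapping():
    out = one_hot([-1, 0, 1])
    np.testing.assert_array_equal(out, np.eye(3))
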