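import numpy as np
import pytest

from sacseg.confident_learning import (PixelDataset, class_thresholds,
                                       correct_labels, counting_matrix,
                                       joint_distribution, refine_dataset,
                                       refine_pixels)


def worked_example():
    """Five pixels, two mislabeled; the binary example every step of the
    procedure can be traced through by hand."""
    p1 = np.array([0.9, 0.2, 0.1, 0.8, 0.3])
    probs = np.stack([1 - p1, p1], axis=1)
    labels = np.array([1, 1, 0, 0, 0])
    return PixelDataset(probs=probs, labels=labels)


def naive_counting_matrix(data, t):
    """Literal per-pixel loop over the counting rule."""
    m = data.probs.shape[1]
    C = np.zeros((m, m), dtype=np.int64)
    for z in range(len(data)):
        j = int(np.argmax(data.probs[z]))
        p = data.probs[z, j]
        ok = p >= t[j] if t[j] >= 1.0 else p > t[j]
        if ok:
            C[data.labels[z], j] += 1
    return C


class TestThresholds:
    def test_one_hot_correct_predictions_give_unit_thresholds(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        labels = np.array([0, 1, 0])
        t = class_thresholds(PixelDataset(probs=probs, labels=labels))
        assert np.allclose(t, [1.0, 1.0])

    def test_hand_example(self):
        t = class_thresholds(worked_example())
        assert t[1] == pytest.approx(0.55)
        assert t[0] == pytest.approx(0.6)

    def test_invariant_to_pixel_order(self):
        d = worked_example()
        perm = np.array([4, 2, 0, 3, 1])
        d2 = PixelDataset(probs=d.probs[perm], labels=d.labels[perm])
        assert np.allclose(class_thresholds(d), class_thresholds(d2))

    def test_missing_class_is_an_error(self):
        d = PixelDataset(probs=np.array([[0.4, 0.6]]), labels=np.array([1]))
        with pytest.raises(ValueError):
            class_thresholds(d)


class TestCountingMatrix:
    def test_hand_example(self):
        d = worked_example()
        C = counting_matrix(d, class_thresholds(d))
        assert C.tolist() == [[2, 1], [1, 1]]

    def test_one_hot_diagonal(self):
        probs = np.eye(2)[[0, 1, 0, 1]]
        labels = np.array([0, 1, 0, 1])
        d = PixelDataset(probs=probs, labels=labels)
        C = counting_matrix(d, class_thresholds(d))
        assert C.tolist() == [[2, 0], [0, 2]]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(100, 10_001))
        p1 = rng.random(n)
        probs = np.stack([1 - p1, p1], axis=1)
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        d = PixelDataset(probs=probs, labels=labels)
        t = class_thresholds(d)
        assert np.array_equal(counting_matrix(d, t),
                              naive_counting_matrix(d, t))

    def test_total_count_bounded_by_n(self):
        d = worked_example()
        assert counting_matrix(d, class_thresholds(d)).sum() <= len(d)


class TestJointDistribution:
    def test_hand_example(self):
        d = worked_example()
        Q = joint_distribution(np.array([[2, 1], [1, 1]]), d)
        assert np.allclose(Q, [[0.4, 0.2], [0.2, 0.2]])

    def test_sums_to_one_with_label_frequency_rows(self):
        rng = np.random.default_rng(0)
        n = 5000
        p1 = rng.random(n)
        probs = np.stack([1 - p1, p1], axis=1)
        labels = (rng.random(n) < 0.3).astype(int)
        d = PixelDataset(probs=probs, labels=labels)
        t = class_thresholds(d)
        Q = joint_distribution(counting_matrix(d, t), d)
        assert Q.min() >= 0
        assert Q.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(Q.sum(axis=1),
                           [np.mean(labels == 0), np.mean(labels == 1)])

    def test_empty_row_is_an_error(self):
        d = worked_example()
        with pytest.raises(ValueError, match="train longer|thresholds"):
            joint_distribution(np.array([[0, 0], [1, 1]]), d)


class TestCorrectLabels:
    def test_diagonal_q_flips_nothing(self):
        d = worked_example()
        labels, flip = correct_labels(d, np.diag([0.6, 0.4]))
        assert np.array_equal(labels, d.labels)
        assert not flip.any()

    def test_hand_example_flips_the_two_mislabeled_pixels(self):
        d = worked_example()
        labels, flip, nm = refine_pixels(d)
        assert np.array_equal(labels, [1, 0, 0, 1, 0])
        assert set(np.nonzero(flip)[0].tolist()) == {1, 3}

    @pytest.mark.parametrize("seed,k", [(0, 5), (1, 17), (2, 40)])
    def test_one_hot_probabilities_recover_all_injected_flips(self, seed, k):
        """With probabilities equal to the one-hot true labels, the counting
        matrix counts exactly the mislabeled pixels and the margins separate
        them perfectly, so recovery is total."""
        rng = np.random.default_rng(seed)
        n = 600
        true = rng.integers(0, 2, n)
        probs = np.eye(2)[true]
        noisy = true.copy()
        zeros = np.nonzero(true == 0)[0]
        ones = np.nonzero(true == 1)[0]
        noisy[rng.choice(zeros, k, replace=False)] = 1
        noisy[rng.choice(ones, k, replace=False)] = 0
        d = PixelDataset(probs=probs, labels=noisy)
        labels, flip, _ = refine_pixels(d)
        assert np.array_equal(labels, true)
        assert flip.sum() == 2 * k


class TestNoiseRecoveryProperty:
    @pytest.mark.parametrize("seed", range(20))
    def test_true_flip_recovery_beats_false_flip_rate(self, seed):
        """Beta(8,2)-calibrated probabilities, 10% injected label noise:
        the fraction of injected flips recovered must strictly exceed the
        fraction of clean labels falsely flipped."""
        rng = np.random.default_rng(1000 + seed)
        n = 4000
        true = rng.integers(0, 2, n)
        p_true = rng.beta(8, 2, n)
        probs = np.empty((n, 2))
        probs[np.arange(n), true] = p_true
        probs[np.arange(n), 1 - true] = 1 - p_true
        noisy = true.copy()
        flip_idx = rng.choice(n, int(0.1 * n), replace=False)
        noisy[flip_idx] = 1 - noisy[flip_idx]
        d = PixelDataset(probs=probs, labels=noisy)
        labels, flip, _ = refine_pixels(d)
        injected = np.zeros(n, bool)
        injected[flip_idx] = True
        recovered = flip[injected].mean()
        false_rate = flip[~injected].mean()
        assert recovered > false_rate


class TestRefineDataset:
    def _maps(self, seed=0):
        rng = np.random.default_rng(seed)
        prob = rng.random((12, 12))
        label = (rng.random((12, 12)) > 0.5).astype(np.uint8)
        return {"img": prob}, {"img": label}

    def test_per_image_composition_matches_single_pipeline(self):
        probs, labels = self._maps()
        refined, summary = refine_dataset(probs, labels, scope="per_image")
        d = PixelDataset.from_probability_map(probs["img"], labels["img"])
        flat, flip, _ = refine_pixels(d)
        assert np.array_equal(refined["img"].label.values.ravel(), flat)
        assert np.array_equal(refined["img"].flip_mask.ravel(), flip)

    def test_flip_fraction_equals_mask_mean(self):
        probs, labels = self._maps(3)
        refined, summary = refine_dataset(probs, labels)
        assert summary["flip_fraction"] == \
            pytest.approx(refined["img"].flip_mask.mean())

    def test_refined_label_differs_exactly_on_flip_mask(self):
        probs, labels = self._maps(4)
        refined, _ = refine_dataset(probs, labels)
        diff = refined["img"].label.values != labels["img"]
        assert np.array_equal(diff, refined["img"].flip_mask)

    def test_pooled_scope_runs_on_multiple_images(self):
        rng = np.random.default_rng(5)
        probs = {f"i{k}": rng.random((8, 8)) for k in range(3)}
        labels = {f"i{k}": (rng.random((8, 8)) > 0.5).astype(np.uint8)
                  for k in range(3)}
        refined, summary = refine_dataset(probs, labels, scope="pooled")
        assert set(refined) == set(probs)
        assert "pooled" in summary

    def test_mismatched_ids_rejected(self):
        probs, labels = self._maps()
        with pytest.raises(ValueError):
            refine_dataset(probs, {"other": list(labels.values())[0]})
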