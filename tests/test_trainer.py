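"""Split logic, early stopping, toy training runs and pipeline composition."""

import numpy as np
import pytest

from rectseg.imgio import SubjectRecord
from rectseg.nets import NetConfig, bce_with_logits, build_segmenter
from rectseg.trainer import (
    EarlyStopping,
    SliceDataset,
    TrainConfig,
    crossvalidate,
    predict_pipeline,
    stratified_split,
    train_classifier,
    train_segmenter,
)


def make_records(n_male, n_female):
    records = []
    for i in range(n_male):
        records.append(SubjectRecord(f"m{i}", "male", "prostate", "i", "l", 98.0))
    for i in range(n_female):
        records.append(SubjectRecord(f"f{i}", "female", "cervical", "i", "l", 86.0))
    return records


SMALL_NET = NetConfig(n_levels=2, base_channels=4, dims=2)


def toy_dataset(n, rng, size=16, sex_rule="half"):
    """Images whose left half is bright for males, dark for females; the
    mask is a centred square shifted by sex."""
    images = np.zeros((n, size, size), dtype=np.float32)
    masks = np.zeros((n, size, size), dtype=np.float32)
    sexes = []
    for i in range(n):
        sex = "male" if i % 2 == 0 else "female"
        sexes.append(sex)
        images[i] = rng.normal(0, 0.1, (size, size))
        if sex == "male":
            images[i, : size // 2] += 1.0
        off = 2 if sex == "male" else -2
        c = size // 2 + off
        masks[i, c - 3:c + 3, c - 3:c + 3] = 1.0
        images[i, c - 3:c + 3, c - 3:c + 3] += 2.0
    ids = [f"s{i}" for i in range(n)]
    return SliceDataset(ids, images, masks, sexes)


class TestStratifiedSplit:
    def test_exact_stratum_arithmetic(self):
        plan = stratified_split(make_records(10, 10), TrainConfig(seed=0))
        test_sexes = [sid[0] for sid in plan.test_ids]
        assert len(plan.test_ids) == 4
        assert test_sexes.count("m") == 2 and test_sexes.count("f") == 2

    def test_deterministic_for_seed(self):
        records = make_records(12, 12)
        p1 = stratified_split(records, TrainConfig(seed=3))
        p2 = stratified_split(records, TrainConfig(seed=3))
        assert p1.test_ids == p2.test_ids and p1.fold_of == p2.fold_of

    def test_fold_partition_of_training_pool(self):
        plan = stratified_split(make_records(15, 15), TrainConfig(seed=1))
        fold_sets = [
            {s for s, f in plan.fold_of.items() if f == k} for k in range(5)
        ]
        union = set().union(*fold_sets)
        assert union == set(plan.train_ids)
        for i in range(5):
            for j in range(i + 1, 5):
                assert not fold_sets[i] & fold_sets[j]

    def test_no_test_train_overlap(self):
        plan = stratified_split(make_records(10, 10), TrainConfig(seed=2))
        assert not set(plan.test_ids) & set(plan.train_ids)
        plan.assert_no_leakage()

    def test_small_stratum_rejected(self):
        with pytest.raises(ValueError, match="stratum"):
            stratified_split(make_records(3, 10), TrainConfig())


class TestEarlyStopping:
    def test_patience_arithmetic(self):
        """Losses [1.0, 0.9, then 7 non-improving] stop at epoch 9, best 2."""
        stopper = EarlyStopping(patience=7)
        losses = [1.0, 0.9] + [0.95] * 7
        stopped_at = None
        for epoch, loss in enumerate(losses):
            if stopper.update(epoch, loss):
                stopped_at = epoch
                break
        assert stopped_at == 8  # 0-based epoch 8 == 9th epoch
        assert stopper.best_epoch == 1  # 0-based epoch 1 == 2nd epoch

    def test_no_stop_while_improving(self):
        stopper = EarlyStopping(patience=3)
        assert not any(stopper.update(e, 1.0 - 0.1 * e) for e in range(8))


class TestTrainClassifier:
    def test_separable_toy_perfect_accuracy(self, rng):
        """Bright-vs-dark-half images are learnable within 20 epochs."""
        train = toy_dataset(16, rng)
        val = toy_dataset(8, np.random.default_rng(1))
        config = TrainConfig(lr=3e-3, max_epochs=20, patience=10, seed=0,
                             net=SMALL_NET)
        clf, hist = train_classifier(train, val, config)
        held_out = toy_dataset(10, np.random.default_rng(2))
        p = clf.forward(held_out.images[:, None])
        acc = np.mean((p >= 0.5) == np.array([s == "male" for s in held_out.sexes]))
        assert acc == 1.0

    def test_single_sex_rejected(self, rng):
        ds = toy_dataset(8, rng)
        ds.sexes = ["male"] * 8
        with pytest.raises(ValueError, match="single-sex"):
            train_classifier(ds, ds, TrainConfig(net=SMALL_NET))

    def test_training_deterministic(self, rng):
        train = toy_dataset(8, rng)
        val = toy_dataset(4, np.random.default_rng(5))
        config = TrainConfig(lr=1e-3, max_epochs=3, patience=2, seed=9, net=SMALL_NET)
        c1, _ = train_classifier(train, val, config)
        c2, _ = train_classifier(train, val, config)
        for w1, w2 in zip(c1.get_weights(), c2.get_weights()):
            np.testing.assert_array_equal(w1, w2)


class TestTrainSegmenter:
    def test_bce_ordering_perfect_vs_inverted(self, rng):
        mask = (rng.random((1, 1, 8, 8)) > 0.5).astype(np.float32)
        good = 10.0 * (2 * mask - 1)  # logits agreeing with the mask
        loss_good, _ = bce_with_logits(good, mask)
        loss_bad, _ = bce_with_logits(-good, mask)
        assert loss_good < loss_bad

    def test_mostly_empty_masks_rejected(self, rng):
        ds = toy_dataset(8, rng)
        ds.masks[:5] = 0.0
        with pytest.raises(ValueError, match="empty"):
            train_segmenter(ds, ds, TrainConfig(net=SMALL_NET))

    def test_learns_toy_masks_and_logs_dsc(self, rng):
        train = toy_dataset(16, rng)
        val = toy_dataset(8, np.random.default_rng(3))
        config = TrainConfig(lr=3e-3, max_epochs=60, patience=40, seed=1,
                             net=SMALL_NET)
        seg, hist = train_segmenter(train, val, config)
        assert len(hist["val_dsc"]) == len(hist["val_loss"])
        assert hist["val_dsc"][-1] > 0.8


class TestPredictPipeline:
    def _trained_pair(self, rng):
        train = toy_dataset(16, rng)
        val = toy_dataset(8, np.random.default_rng(7))
        config = TrainConfig(lr=3e-3, max_epochs=15, patience=10, seed=2,
                             net=SMALL_NET)
        clf, _ = train_classifier(train, val, config)
        seg, _ = train_segmenter(train, val, config)
        return clf, seg, config

    def test_composition_identity(self, rng):
        from rectseg.nets import condition_input

        clf, seg, config = self._trained_pair(rng)
        img = toy_dataset(2, np.random.default_rng(8)).images[0]
        p_male, mask, prob = predict_pipeline(clf, seg, img, config)
        sex = "male" if p_male >= 0.5 else "female"
        manual = seg.forward(condition_input(img, sex)[None])[0, 0]
        np.testing.assert_array_equal(mask, manual >= config.threshold)

    def test_threshold_semantics(self, rng):
        clf, seg, config = self._trained_pair(rng)
        img = toy_dataset(2, np.random.default_rng(9)).images[1]
        _, mask, prob = predict_pipeline(clf, seg, img, config)
        np.testing.assert_array_equal(mask, prob >= 0.5)

    def test_predicted_sex_channels_change_output(self, rng):
        """A trained sex-conditioned segmenter is not sex-invariant."""
        from rectseg.nets import condition_input

        _, seg, _ = self._trained_pair(rng)
        img = toy_dataset(2, np.random.default_rng(10)).images[0]
        out_m = seg.forward(condition_input(img, "male")[None])
        out_f = seg.forward(condition_input(img, "female")[None])
        assert not np.array_equal(out_m, out_f)


class TestCrossValidate:
    def test_fold_count_and_leakage(self, rng):
        ds = toy_dataset(25, rng)
        records = [
            SubjectRecord(sid, sex, "prostate" if sex == "male" else "cervical",
                          "i", "l", 90.0)
            for sid, sex in zip(ds.subject_ids, ds.sexes)
        ]
        config = TrainConfig(lr=3e-3, max_epochs=2, patience=1, seed=4,
                             net=SMALL_NET)
        plan = stratified_split(records, config)
        metrics, reports = crossvalidate(ds, plan, config)
        assert len(reports) == 5
        assert set(metrics["fold"].unique()) == set(range(5))
        assert metrics.groupby("fold").size().sum() == len(plan.train_ids)
        fold_means = metrics.groupby("fold")["dsc"].mean()
        assert len(fold_means) == 5
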