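"""LSDM model surface: shapes, prediction contracts, guards, maps, nulls.

Small-scale training tests use a 7x7x7 grid with a planted one-hot class
signal so they run in seconds; the full simulation benchmark lives in the
acceptance suite.
"""

import numpy as np
import pytest

from lsdm.core_data import GroupScheme, ROIMask, TrialDataset, VolumeGrid, assign_folds
from lsdm.model import (
    LSDMConfig,
    accuracy_map,
    build_model,
    evaluate_on_subset,
    extract_latent,
    load_model,
    patch_accuracy,
    permutation_threshold,
    predict,
    receptive_field_size,
    save_model,
    train,
)


class TestReceptiveField:
    @pytest.mark.parametrize("k,L,expected", [(2, 4, 5), (5, 1, 5), (1, 7, 1), (3, 3, 7)])
    def test_layered_growth(self, k, L, expected):
        assert receptive_field_size(k, L) == expected

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            receptive_field_size(0, 4)
        with pytest.raises(ValueError):
            receptive_field_size(2, 0)


class TestBuildModel:
    def test_output_grid_is_valid_convolution(self):
        m = build_model(LSDMConfig(), VolumeGrid(shape=(16, 16, 16)))
        assert m.out_shape == (12, 12, 12)
        centers = m.patch_centers()
        assert centers.min() == 2 and centers.max() == 13

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            build_model(LSDMConfig(), VolumeGrid(shape=(4, 4, 4)))

    def test_penultimate_latent_has_ch_channels(self, planted_dataset, scheme):
        m = build_model(_fast_config(), planted_dataset.grid)
        lat = extract_latent(m, planted_dataset, np.arange(4))
        assert lat.shape[1] == 3


def _fast_config(**kw):
    base = dict(
        k=2, L=4, ch=3, c_in=1, n_classes=12,
        lr=5e-3, epochs=30, batch_size=96, patience=6, min_epochs=6, seed=0,
    )
    base.update(kw)
    return LSDMConfig(**base)


@pytest.fixture(scope="module")
def planted_dataset():
    """7^3 volume; a 3x3x3 block carries a strong per-class pattern."""
    rng = np.random.default_rng(7)
    n_per = 24
    labels = np.repeat(np.arange(1, 13), n_per)
    n = labels.size
    data = rng.normal(0, 1.0, size=(n, 1, 7, 7, 7)).astype(np.float32)
    patterns = rng.normal(0, 1.5, size=(12, 3, 3, 3)).astype(np.float32)
    data[:, 0, 2:5, 2:5, 2:5] += patterns[labels - 1]
    from lsdm.core_data import default_class_table

    table = default_class_table(12).set_index("label")
    ds = TrialDataset(
        grid=VolumeGrid(shape=(7, 7, 7)),
        data=data,
        labels=labels,
        modality=np.full(n, "C", dtype=object),
        group=table.loc[labels, "group"].to_numpy(),
        luminance=table.loc[labels, "luminance"].to_numpy(),
        correct=rng.random(n) > 0.2,
        choice_label=rng.integers(1, 13, n),
        fold=np.full(n, -1),
    )
    return assign_folds(ds, 4, seed=0)


@pytest.fixture(scope="module")
def trained(planted_dataset, scheme):
    model = build_model(_fast_config(), planted_dataset.grid)
    return train(model, planted_dataset, 0, scheme)


class TestTraining:
    def test_recovers_planted_signal(self, trained, planted_dataset, scheme):
        test = np.where(planted_dataset.fold == 0)[0]
        preds = predict(trained, planted_dataset, test)
        acc = patch_accuracy(preds, planted_dataset.labels[test])
        assert acc.max() > 1 / 3 + 0.15

    def test_training_never_reads_test_fold(self, trained, planted_dataset):
        test_ids = set(planted_dataset.trial_id[planted_dataset.fold == 0].tolist())
        assert not (trained.train_trial_ids & test_ids)

    def test_determinism_same_seed_same_weights(self, planted_dataset, scheme):
        cfg = _fast_config(epochs=6, min_epochs=2)
        runs = []
        for _ in range(2):
            m = build_model(cfg, planted_dataset.grid)
            train(m, planted_dataset, 1, scheme)
            runs.append(m.net.state_arrays())
        for key in runs[0]:
            np.testing.assert_array_equal(runs[0][key], runs[1][key])

    def test_pure_noise_stays_at_chance(self, scheme):
        rng = np.random.default_rng(3)
        n = 12 * 16
        labels = np.tile(np.arange(1, 13), 16)
        from lsdm.core_data import default_class_table

        table = default_class_table(12).set_index("label")
        ds = TrialDataset(
            grid=VolumeGrid(shape=(6, 6, 6)),
            data=rng.normal(0, 1, (n, 1, 6, 6, 6)),
            labels=labels,
            modality=np.full(n, "C", dtype=object),
            group=table.loc[labels, "group"].to_numpy(),
            luminance=table.loc[labels, "luminance"].to_numpy(),
            correct=np.ones(n, bool),
            choice_label=np.zeros(n, np.int64),
            fold=np.full(n, -1),
        )
        ds = assign_folds(ds, 4, seed=1)
        m = build_model(_fast_config(epochs=10, min_epochs=4), ds.grid)
        train(m, ds, 0, scheme)
        test = np.where(ds.fold == 0)[0]
        acc = patch_accuracy(predict(m, ds, test), ds.labels[test])
        # mean over patches within a few MC standard errors of chance
        se = np.sqrt((1 / 3) * (2 / 3) / test.size)
        assert abs(acc.mean() - 1 / 3) < 4 * se


class TestPredict:
    def test_group_blocks_sum_to_one(self, trained, planted_dataset, scheme):
        preds = predict(trained, planted_dataset, np.arange(8))
        for members in scheme.group_members():
            s = preds.probs[..., members - 1].sum(-1)
            np.testing.assert_allclose(s, 1.0, atol=1e-5)

    def test_grid_mismatch_rejected(self, trained):
        rng = np.random.default_rng(0)
        other = TrialDataset(
            grid=VolumeGrid(shape=(8, 8, 8)),
            data=rng.normal(size=(2, 1, 8, 8, 8)),
            labels=[1, 2],
            modality=["C", "C"],
            group=["A", "B"],
            luminance=["light", "light"],
            correct=[True, True],
            choice_label=[0, 0],
            fold=[0, 1],
        )
        with pytest.raises(ValueError, match="grid"):
            predict(trained, other)

    def test_linear_probe_matches_full_model(self, trained, planted_dataset, scheme):
        """Classes are linearly separable in the latent space: a fresh linear
        readout fit on train-fold latents performs within a small margin of the
        full model at the best patch."""
        from sklearn.linear_model import LogisticRegression

        tr = np.where(planted_dataset.fold != 0)[0]
        te = np.where(planted_dataset.fold == 0)[0]
        preds = predict(trained, planted_dataset, te)
        acc = patch_accuracy(preds, planted_dataset.labels[te])
        best = int(np.argmax(acc))
        # latents of the k^3 locations feeding the best patch
        lat_tr = extract_latent(trained, planted_dataset, tr)
        lat_te = extract_latent(trained, planted_dataset, te)
        ax = np.unravel_index(best, trained.out_shape)
        k = trained.config.k

        def stack(lat):
            block = lat[:, :, ax[0] : ax[0] + k, ax[1] : ax[1] + k, ax[2] : ax[2] + k]
            return block.reshape(lat.shape[0], -1)

        probe = LogisticRegression(max_iter=2000, C=10.0)
        probe.fit(stack(lat_tr), planted_dataset.labels[tr])
        scores = probe.decision_function(stack(lat_te))
        # compare like for like: argmax restricted to the true label's group
        labels_te = planted_dataset.labels[te]
        l2g = scheme.label_to_group()
        correct = []
        for row, lab in zip(scores, labels_te):
            members = np.array(scheme.groups[l2g[lab]])
            cols = [list(probe.classes_).index(m) for m in members]
            correct.append(members[int(np.argmax(row[cols]))] == lab)
        probe_acc = np.mean(correct)
        # granularity is 1/len(te) per trial, so allow a few-trial margin
        assert probe_acc > acc[best] - 0.06


class TestAccuracyMap:
    def test_perfect_predictions_map_of_ones(self, scheme):
        from lsdm.model import PatchPredictions

        labels = np.tile(np.arange(1, 13), 4)
        probs = np.zeros((48, 2, 12), np.float32)
        probs[np.arange(48), :, labels - 1] = 1.0
        preds = PatchPredictions(
            probs=probs,
            centers=np.array([[1, 1, 1], [2, 2, 2]]),
            out_shape=(2, 1, 1),
            trial_ids=np.arange(48),
            scheme=scheme,
        )
        vol = accuracy_map(preds, labels, (4, 4, 4))
        assert vol[1, 1, 1] == 1.0 and vol[2, 2, 2] == 1.0
        assert np.isnan(vol[0, 0, 0])

    def test_chance_subtract_centers_map_at_zero(self, trained, planted_dataset):
        test = np.where(planted_dataset.fold == 0)[0]
        preds = predict(trained, planted_dataset, test)
        rng = np.random.default_rng(0)
        perm = rng.permutation(planted_dataset.labels[test])
        vol = accuracy_map(preds, perm, planted_dataset.grid.shape, chance_subtract=True)
        assert abs(np.nanmean(vol)) < 0.05


class TestPermutationThreshold:
    def test_quantiles_bracket_chance(self, trained, planted_dataset):
        test = np.where(planted_dataset.fold == 0)[0]
        preds = predict(trained, planted_dataset, test)
        pairs = [(preds, planted_dataset.labels[test])]
        thr95, dist = permutation_threshold(
            pairs, n_perm=300, quantile=0.95, seed=0, return_distribution=True
        )
        thr50 = permutation_threshold(pairs, n_perm=300, quantile=0.5, seed=0)
        se = np.sqrt((1 / 3) * (2 / 3) / test.size)
        assert 1 / 3 < thr95 < 1 / 3 + 3 * se
        assert abs(thr50 - 1 / 3) < se
        assert abs(dist.mean() - 1 / 3) < se

    def test_seed_stability(self, trained, planted_dataset):
        test = np.where(planted_dataset.fold == 0)[0]
        preds = predict(trained, planted_dataset, test)
        pairs = [(preds, planted_dataset.labels[test])]
        a = permutation_threshold(pairs, n_perm=400, seed=1)
        b = permutation_threshold(pairs, n_perm=400, seed=2)
        assert abs(a - b) < 0.02


class TestEvaluateOnSubset:
    def test_leakage_guard(self, trained, planted_dataset):
        train_fold_idx = np.where(planted_dataset.fold == 1)[0]  # in training set of fold-0 model
        with pytest.raises(ValueError, match="overlap"):
            evaluate_on_subset([trained], planted_dataset, train_fold_idx)

    def test_stimulus_above_chance_choice_at_chance(self, trained, planted_dataset):
        """Planted labels decode; random 'choice' labels do not."""
        test = np.where(planted_dataset.fold == 0)[0]
        acc_stim = evaluate_on_subset([trained], planted_dataset, test, "label")
        acc_choice = evaluate_on_subset([trained], planted_dataset, test, "choice")
        assert acc_stim.max() > 1 / 3 + 0.15
        se = np.sqrt((1 / 3) * (2 / 3) / test.size)
        assert abs(acc_choice.mean() - 1 / 3) < 4 * se

    def test_null_choices_rejected(self, trained, planted_dataset):
        test = np.where(planted_dataset.fold == 0)[0]
        ds = planted_dataset.subset(test)
        ds.choice_label[:] = 0
        with pytest.raises(ValueError, match="choice"):
            evaluate_on_subset([trained], ds, np.arange(ds.n_trials), "choice")

    def test_empty_subset_rejected(self, trained, planted_dataset):
        with pytest.raises(ValueError, match="empty"):
            evaluate_on_subset([trained], planted_dataset, np.array([], dtype=int))


class TestSerialization:
    def test_save_load_round_trip(self, trained, planted_dataset, tmp_path):
        save_model(trained, tmp_path / "m")
        back = load_model(tmp_path / "m")
        x = planted_dataset.data[:3]
        ref, _ = trained.net.forward(x)
        out, _ = back.net.forward(x)
        np.testing.assert_array_equal(ref, out)
        assert back.fold_id == trained.fold_id
        assert back.train_trial_ids == trained.train_trial_ids
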