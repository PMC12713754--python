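"""Planted-signal generator and the de Bruijn counterbalancing utility."""

import numpy as np
import pytest

from lsdm.simulation import (
    SimConfig,
    crop_to_roi,
    debruijn_runs,
    debruijn_sequence,
    generate_dataset,
    make_circular_signal,
    make_highdim_signal,
)


class TestCircularSignal:
    def test_within_luminance_hexagon_distances(self):
        """Six evenly spaced points on the unit circle: distance multiset {1, sqrt3, 2}."""
        vecs, _ = make_circular_signal(0)
        light = vecs[:6]
        d = np.linalg.norm(light[:, None] - light[None, :], axis=-1)
        expected = {1: 6, np.sqrt(3): 6, 2: 3}
        off = d[np.triu_indices(6, 1)]
        for val, count in expected.items():
            assert np.sum(np.abs(off - val) < 1e-8) == count

    def test_light_dark_offset_norm_is_one(self):
        vecs, _ = make_circular_signal(1)
        offsets = vecs[6:] - vecs[:6]
        np.testing.assert_allclose(np.linalg.norm(offsets, axis=1), 1.0, atol=1e-8)
        # single common offset direction orthogonal to the circle plane
        np.testing.assert_allclose(offsets - offsets[0], 0.0, atol=1e-8)

    def test_projection_orthonormal(self):
        _, basis = make_circular_signal(2)
        np.testing.assert_allclose(basis.T @ basis, np.eye(3), atol=1e-8)


class TestHighdimSignal:
    def test_orthogonal_with_norm_1_5(self):
        v = make_highdim_signal(0)
        gram = v @ v.T
        np.testing.assert_allclose(gram, np.eye(12) * 1.5**2, atol=1e-8)

    def test_independent_draws_uncorrelated(self):
        a = make_highdim_signal(1)
        b = make_highdim_signal(2)
        # expected cross inner product 0, sd ~ scale^2/sqrt(dim)
        cross = (a * b).sum(axis=1)
        assert np.abs(cross).max() < 1.5**2 * 5 / np.sqrt(125)
        assert not np.allclose(a, b)


class TestGenerateDataset:
    def test_no_noise_limit_zero_outside_regions(self):
        cfg = SimConfig(n_per_class=1, noise_sd=0.0, seed=4)
        ds_s, ds_c, gt = generate_dataset(cfg)
        outside = ~(gt.roi1.mask | gt.roi2.mask)
        assert np.abs(ds_s.data[:, 0, outside]).max() == 0.0
        assert np.abs(ds_c.data[:, 0, outside]).max() == 0.0
        # C carries signal only in the LR region
        ul = np.zeros(cfg.shape, bool)
        ul[cfg.region_slices(cfg.ul_corner)] = True
        assert np.abs(ds_c.data[:, 0, ul]).max() == 0.0
        assert np.abs(ds_s.data[:, 0, ul]).max() > 0.0

    def test_noise_spread_matches_config(self):
        cfg = SimConfig(n_per_class=30, seed=5)
        ds_s, _, gt = generate_dataset(cfg)
        outside = ~(gt.roi1.mask | gt.roi2.mask)
        sd = ds_s.data[:, 0, outside].std()
        assert sd == pytest.approx(1.5, rel=0.02)

    def test_deterministic_given_seed(self):
        cfg = SimConfig(n_per_class=2, seed=9)
        a_s, a_c, _ = generate_dataset(cfg)
        b_s, b_c, _ = generate_dataset(cfg)
        np.testing.assert_array_equal(a_s.data, b_s.data)
        np.testing.assert_array_equal(a_c.data, b_c.data)
        np.testing.assert_array_equal(a_s.fold, b_s.fold)

    def test_rois_disjoint_and_contain_regions(self):
        cfg = SimConfig(n_per_class=1, seed=0)
        _, _, gt = generate_dataset(cfg)
        assert not (gt.roi1.mask & gt.roi2.mask).any()
        region2 = np.zeros(cfg.shape, bool)
        region2[cfg.region_slices(cfg.lr_corner)] = True
        assert (gt.roi2.mask & region2).sum() == region2.sum()

    def test_structured_noise_adds_group_offset(self):
        cfg = SimConfig(n_per_class=8, seed=6)
        base_s, _, _ = generate_dataset(cfg, structured_noise=False)
        noisy_s, _, _ = generate_dataset(cfg, structured_noise=True)
        delta = noisy_s.data - base_s.data
        for g in ("A", "B"):
            sel = noisy_s.group == g
            group_delta = delta[sel, 0]
            # identical offset within group, sd ~0.3 across voxels
            assert np.abs(group_delta - group_delta[0]).max() < 1e-6
            assert group_delta[0].std() == pytest.approx(0.3, rel=0.1)
        assert np.abs(delta[noisy_s.group == "A"][0] - delta[noisy_s.group == "B"][0]).max() > 0

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SimConfig(ul_corner=(1, 1, 6), lr_corner=(3, 3, 6))


class TestCropToRoi:
    def test_crop_preserves_roi_and_data(self):
        cfg = SimConfig(n_per_class=1, seed=1)
        ds_s, _, gt = generate_dataset(cfg)
        crop, roi = crop_to_roi(ds_s, gt.roi2, receptive_field=5)
        assert roi.n_voxels == gt.roi2.n_voxels
        assert crop.grid.shape <= ds_s.grid.shape
        lo, hi = gt.roi2.bounding_box()
        lo = np.maximum(lo - 2, 0)
        np.testing.assert_array_equal(
            crop.data[0, 0],
            ds_s.data[0, 0, lo[0] : lo[0] + crop.grid.shape[0],
                      lo[1] : lo[1] + crop.grid.shape[1],
                      lo[2] : lo[2] + crop.grid.shape[2]],
        )


class TestEvalDataset:
    def test_same_signals_fresh_noise_disjoint_ids(self):
        from lsdm.simulation import generate_eval_dataset

        cfg = SimConfig(n_per_class=4, seed=2)
        ds_s, ds_c, gt = generate_dataset(cfg)
        ev = generate_eval_dataset(cfg, gt, "C", n_per_class=3, seed=9)
        assert ev.n_trials == 36
        assert not (set(ev.trial_id.tolist()) & set(ds_c.trial_id.tolist()))
        # same planted class signal: difference of class means shrinks noise only
        sig = gt.signals["class_volumes"]["C"]
        lr = cfg.region_slices(cfg.lr_corner)
        noisefree = sig[ev.labels - 1][:, lr[0], lr[1], lr[2]]
        observed = ev.data[:, 0, lr[0], lr[1], lr[2]]
        resid = observed - noisefree
        assert resid.std() == pytest.approx(cfg.noise_sd, rel=0.05)

    def test_structured_eval_requires_offsets(self):
        from lsdm.simulation import generate_eval_dataset

        cfg = SimConfig(n_per_class=4, seed=2)
        _, _, gt = generate_dataset(cfg, structured_noise=False)
        with pytest.raises(ValueError, match="structured"):
            generate_eval_dataset(cfg, gt, "C", 2, seed=1, structured_noise=True)


class TestRunBenchmark:
    def test_small_benchmark_table_structure(self):
        from lsdm.baseline import StandardConfig
        from lsdm.model import LSDMConfig
        from lsdm.simulation import run_benchmark

        fast = dict(lr=5e-3, epochs=8, batch_size=96, patience=4, min_epochs=4)
        df = run_benchmark(
            sizes=(16,),
            methods=("lsdm", "standard"),
            seed=5,
            n_folds=4,
            lsdm_config=LSDMConfig(seed=5, **fast),
            standard_config=StandardConfig(seed=5, **fast),
            n_boot=100,
        )
        assert set(df.method) == {"lsdm", "standard"}
        assert set(df.metric) == {"identity", "cross"}
        assert len(df) == 16 * 1  # 2 methods x 2 metrics x 4 folds
        summary = df.attrs["summary"]
        assert {"mean", "ci_low", "ci_high"} <= set(summary.columns)
        assert (summary["ci_low"] <= summary["mean"] + 1e-12).all()


class TestDeBruijn:
    def test_four_trial_pairs_give_four_runs_of_17(self):
        runs = debruijn_runs(4)
        assert len(runs) == 4
        assert all(len(r) == 17 for r in runs)

    def test_every_ordered_pair_exactly_once(self):
        """Brute-force pair enumeration over the cyclic sequence of 8 cues."""
        seq = debruijn_sequence(8)
        assert len(seq) == 64
        pairs = {(seq[i], seq[(i + 1) % len(seq)]) for i in range(len(seq))}
        assert len(pairs) == 64  # all 8*8 ordered pairs, each exactly once

    def test_run_boundaries_repeat_previous_last(self):
        runs = debruijn_runs(4)
        for r in range(4):
            assert runs[r][0] == runs[(r - 1) % 4][-1]

    def test_two_cue_alphabet_cycle_length_four(self):
        seq = debruijn_sequence(2)
        assert len(seq) == 4
        pairs = {(seq[i], seq[(i + 1) % 4]) for i in range(4)}
        assert len(pairs) == 4

    def test_seed_permutes_but_preserves_property(self):
        seq = debruijn_sequence(4, seed=7)
        pairs = {(seq[i], seq[(i + 1) % len(seq)]) for i in range(len(seq))}
        assert len(pairs) == 16
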