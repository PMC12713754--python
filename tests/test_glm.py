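"""HRF kernel, drift basis, design construction, GLM fitting, beta extraction."""

import numpy as np
import pandas as pd
import pytest

from lsdm.glm import (
    HRFParams,
    build_active_design,
    cosine_drift_basis,
    extract_trial_betas,
    fit_glm,
    hrf_kernel,
)


def _events(n_trials=4, start=3, spacing=7):
    return pd.DataFrame(
        {"trial_id": np.arange(n_trials), "onset_tr": start + spacing * np.arange(n_trials)}
    )


class TestHrfKernel:
    def test_peak_between_2_5_and_3_seconds(self):
        k = hrf_kernel(0.1)
        t_peak = 0.1 * np.argmax(k)
        assert 2.5 <= t_peak <= 3.0

    def test_unit_area(self):
        for tr in (0.1, 1.0, 3.0):
            k = hrf_kernel(tr)
            assert k.sum() * tr == pytest.approx(1.0, abs=1e-6)

    def test_delta_kernel_identity_convolution(self):
        k = hrf_kernel(3.0, HRFParams(kind="delta"))
        x = np.random.default_rng(0).random(20)
        np.testing.assert_allclose(np.convolve(x, k * 3.0)[:20], x, atol=1e-12)

    def test_nonpositive_tr_rejected(self):
        with pytest.raises(ValueError):
            hrf_kernel(0.0)


class TestDriftBasis:
    def test_highest_frequency_below_cutoff(self):
        cols = cosine_drift_basis(200, tr=3.0, cutoff_hz=0.03)
        n_basis = cols.shape[1] - 1  # minus constant
        f_max = n_basis / (2 * 200 * 3.0)
        assert f_max < 0.03
        assert (n_basis + 1) / (2 * 200 * 3.0) >= 0.03

    def test_cutoff_below_fundamental_gives_constant_only(self):
        cols = cosine_drift_basis(50, tr=3.0, cutoff_hz=1e-5)
        assert cols.shape[1] == 1
        np.testing.assert_allclose(cols[:, 0], 1.0)

    def test_columns_mutually_orthogonal(self):
        cols = cosine_drift_basis(120, tr=3.0, cutoff_hz=0.05)
        gram = cols.T @ cols
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8


class TestBuildActiveDesign:
    def test_impulse_columns_single_nonzero(self):
        design = build_active_design(_events(), n_trs=40)
        for name in design.columns:
            if "_cue_tr" in name:
                col = design[name].to_numpy()
                assert (col != 0).sum() == 1 and col.max() == 1.0

    def test_cue_hrf_zeroed_on_cue_trs_nonzero_after(self):
        events = _events(2)
        design = build_active_design(events, n_trs=40)
        for tid, onset in zip(events.trial_id, events.onset_tr):
            col = design[f"trial{tid}_cue_hrf"].to_numpy()
            assert np.all(col[onset : onset + 3] == 0.0)
            assert np.all(col[: onset + 1] == 0.0)  # causal
            assert col[onset + 3 : onset + 6].max() > 0  # tail survives

    def test_column_count_by_construction(self):
        n_trials, n_trs = 5, 60
        confounds = np.random.default_rng(0).random((n_trs, 2))
        design = build_active_design(_events(n_trials), n_trs, confounds=confounds)
        drift_cols = cosine_drift_basis(n_trs, 3.0, 0.03).shape[1]
        assert design.shape[1] == 3 * n_trials + n_trials + n_trials + drift_cols + 2

    def test_no_trials_gives_drift_and_confounds_only(self):
        design = build_active_design(_events(0), n_trs=30)
        assert all(c.startswith("drift_") for c in design.columns)

    def test_delta_hrf_reduces_to_indicator_design(self):
        events = _events(1)
        design = build_active_design(
            events, n_trs=30, hrf=HRFParams(kind="delta"), drift_cutoff_hz=1e-9
        )
        choice = design["trial0_choice_hrf"].to_numpy()
        onset = int(events.onset_tr[0])
        assert choice[onset + 3] == pytest.approx(1.0)
        assert (choice != 0).sum() == 1
        # cue HRF becomes a boxcar fully zeroed by the impulse rule
        np.testing.assert_allclose(design["trial0_cue_hrf"], 0.0, atol=1e-12)

    def test_overlapping_trials_rejected(self):
        events = pd.DataFrame({"trial_id": [0, 1], "onset_tr": [3, 5]})
        with pytest.raises(ValueError, match="verlap"):
            build_active_design(events, n_trs=30)


class TestFitGlm:
    def test_noiseless_exact_recovery(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((60, 5))
        beta = rng.standard_normal((5, 3))
        fit = fit_glm(x @ beta, x)
        np.testing.assert_allclose(fit.betas, beta, atol=1e-8)

    def test_white_noise_recovery_within_2_se(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((200, 6))
        beta = rng.standard_normal(6)
        y = x @ beta + rng.normal(0, 0.5, 200)
        fit = fit_glm(y, x)
        err = np.abs(fit.betas[:, 0] - beta)
        assert (err < 2.5 * fit.se[:, 0]).all()

    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        x = rng.standard_normal((80, 4))
        y = x @ np.array([1.0, -2.0, 0.5, 0.0]) + rng.normal(0, 1, 80)
        ours = fit_glm(y, x)
        ref = sm.OLS(y, x).fit()
        np.testing.assert_allclose(ours.betas[:, 0], ref.params, atol=1e-10)
        np.testing.assert_allclose(ours.se[:, 0], ref.bse, atol=1e-10)

    def test_rank_deficient_rejected(self):
        x = np.ones((20, 2))
        with pytest.raises(np.linalg.LinAlgError):
            fit_glm(np.zeros(20), x)

    def test_ar1_ses_better_calibrated_than_ols(self):
        """On AR1 noise, mean AR1 SE should approximate the empirical SD of the
        estimates better than the (too small) OLS SE."""
        rng = np.random.default_rng(4)
        n, rho_true = 150, 0.6
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        beta = np.array([0.0, 1.0])
        b_ols, b_ar1, se_ols, se_ar1 = [], [], [], []
        for _ in range(150):
            e = np.zeros(n)
            innov = rng.normal(0, 1.0, n)
            e[0] = innov[0] / np.sqrt(1 - rho_true**2)
            for t in range(1, n):
                e[t] = rho_true * e[t - 1] + innov[t]
            y = x @ beta + e
            f0 = fit_glm(y, x, ar1=False)
            f1 = fit_glm(y, x, ar1=True)
            b_ols.append(f0.betas[1, 0])
            b_ar1.append(f1.betas[1, 0])
            se_ols.append(f0.se[1, 0])
            se_ar1.append(f1.se[1, 0])
        emp_sd = np.std(b_ols)
        gap_ols = abs(np.mean(se_ols) - emp_sd)
        gap_ar1 = abs(np.mean(se_ar1) - np.std(b_ar1))
        assert gap_ar1 < gap_ols

    def test_ar1_estimates_rho(self):
        rng = np.random.default_rng(5)
        n = 400
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        e = np.zeros(n)
        for t in range(1, n):
            e[t] = 0.5 * e[t - 1] + rng.normal()
        fit = fit_glm(x @ [1.0, 2.0] + e, x, ar1=True)
        assert fit.rho[0] == pytest.approx(0.5, abs=0.12)


class TestExtractTrialBetas:
    def _fitted(self, n_trials=5):
        events = _events(n_trials)
        n_trs = int(events.onset_tr.max()) + 10
        design = build_active_design(events, n_trs)
        rng = np.random.default_rng(6)
        beta = rng.standard_normal((design.shape[1], 4))
        y = design.to_numpy() @ beta + rng.normal(0, 0.01, (n_trs, 4))
        return fit_glm(y, design), events, beta, design

    def test_shape_and_channels(self):
        fit, events, _, _ = self._fitted()
        out = extract_trial_betas(fit, events)
        assert out.shape == (5, 2, 4)

    def test_values_match_named_regressors(self):
        fit, events, beta, design = self._fitted()
        out = extract_trial_betas(fit, events)
        cols = list(design.columns)
        i2 = cols.index("trial0_cue_tr2")
        np.testing.assert_allclose(out[0, 0], beta[i2], atol=0.05)

    def test_tr1_requires_opt_in(self):
        fit, events, _, _ = self._fitted()
        with pytest.raises(ValueError, match="include_tr1"):
            extract_trial_betas(fit, events, cue_channels=(1, 2))
        ok = extract_trial_betas(fit, events, cue_channels=(1, 2), include_tr1=True)
        assert ok.shape[1] == 2


class TestEndToEndDecoding:
    def test_planted_cue_patterns_survive_extraction_and_decode(self, scheme):
        """Simulate a run time series with per-class patterns injected at cue
        TRs 2-3; extracted betas must support above-chance decoding."""
        from lsdm.core_data import TrialDataset, VolumeGrid, assign_folds, default_class_table
        from lsdm.model import LSDMConfig, build_model, patch_accuracy, predict, train

        rng = np.random.default_rng(8)
        shape = (6, 6, 6)
        n_vox = int(np.prod(shape))
        n_trials_per_run, n_runs = 24, 4
        patterns = rng.normal(0, 1.0, size=(12, n_vox))
        all_betas, all_labels = [], []
        for run in range(n_runs):
            labels = rng.permutation(np.repeat(np.arange(1, 13), 2))
            events = pd.DataFrame(
                {"trial_id": np.arange(n_trials_per_run), "onset_tr": 3 + 7 * np.arange(n_trials_per_run)}
            )
            n_trs = int(events.onset_tr.max()) + 10
            design = build_active_design(events, n_trs)
            x = design.to_numpy()
            beta = rng.normal(0, 0.2, (x.shape[1], n_vox))
            cols = list(design.columns)
            for t, lab in enumerate(labels):
                for c in (2, 3):
                    beta[cols.index(f"trial{t}_cue_tr{c}")] = patterns[lab - 1]
            y = x @ beta + rng.normal(0, 1.0, (n_trs, n_vox))
            fit = fit_glm(y, design)
            all_betas.append(extract_trial_betas(fit, events))
            all_labels.append(labels)
        data = np.concatenate(all_betas).reshape(-1, 2, *shape)
        labels = np.concatenate(all_labels)
        table = default_class_table(12).set_index("label")
        ds = TrialDataset(
            grid=VolumeGrid(shape=shape),
            data=data,
            labels=labels,
            modality=np.full(labels.size, "C", dtype=object),
            group=table.loc[labels, "group"].to_numpy(),
            luminance=table.loc[labels, "luminance"].to_numpy(),
            correct=np.ones(labels.size, bool),
            choice_label=np.zeros(labels.size, np.int64),
            fold=np.full(labels.size, -1),
        )
        ds = assign_folds(ds, 4, seed=0)
        cfg = LSDMConfig(c_in=2, lr=5e-3, epochs=25, batch_size=96, patience=6, min_epochs=6, seed=0)
        model = build_model(cfg, ds.grid)
        train(model, ds, 0, scheme)
        te = np.where(ds.fold == 0)[0]
        acc = patch_accuracy(predict(model, ds, te), ds.labels[te])
        assert acc.max() > 1 / 3 + 0.15
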