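"""Shared fixtures.

The heavyweight ``sim_study`` session fixture runs the scaled-down validation
benchmark once (sizes 60 and 120 examples per class, 8-fold CV) and is shared
by the acceptance tests and several property tests; everything else is small
and cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pytest

from lsdm.baseline import StandardConfig, train_standard
from lsdm.core_data import GroupScheme
from lsdm.geometry import circular_rank_correlation, lsdm_roi_rdm, raw_rsa
from lsdm.model import LSDMConfig, build_model, patch_accuracy, predict, train
from lsdm.simulation import (
    BENCHMARK_TRAIN,
    SimConfig,
    crop_to_roi,
    generate_dataset,
    generate_eval_dataset,
)
from lsdm.stacking import (
    fit_stacking,
    naive_roi_accuracy,
    roi_accuracy_from_predictions,
)

SIM_SEED = 20240
SIM_SIZES = (60, 120)
N_FOLDS = 8

LSDM_TRAIN = dict(BENCHMARK_TRAIN)
STD_TRAIN = dict(BENCHMARK_TRAIN)


@pytest.fixture(scope="session")
def scheme() -> GroupScheme:
    return GroupScheme.default(12)


@dataclass
class FoldResult:
    identity: float
    cross: float
    identity_naive: float
    rho_latent: float | None = None
    rho_raw: float | None = None


@dataclass
class SimStudy:
    """Everything the scaled-down validation study produces."""

    # accuracies[(size, method)] -> list of FoldResult (ROI 2)
    accuracies: dict = field(default_factory=dict)
    # per-fold (weights, predictions, labels) triples for permutation nulls,
    # LSDM at the smaller study size
    identity_triples: list = field(default_factory=list)
    cross_triples: list = field(default_factory=list)
    roi2_cropped: object = None
    roi1_cross: list = field(default_factory=list)  # LSDM cross accuracy, ROI 1
    roi1_n_test: int = 0
    rho_structured_latent: list = field(default_factory=list)
    rho_structured_raw: list = field(default_factory=list)
    params_per_patch: dict = field(default_factory=dict)

    def folds(self, size, method, metric):
        return np.array([getattr(f, metric) for f in self.accuracies[(size, method)]])


def _lsdm_factory(crop, fold, scheme):
    cfg = LSDMConfig(seed=0, **LSDM_TRAIN)
    model = build_model(cfg, crop.grid)
    return train(model, crop, fold, scheme)


def _std_factory(crop, fold, scheme):
    cfg = StandardConfig(seed=0, **STD_TRAIN)
    return train_standard(crop, fold, scheme, config=cfg).model


@pytest.fixture(scope="session")
def sim_study(scheme) -> SimStudy:
    study = SimStudy()
    factories = {"lsdm": _lsdm_factory, "standard": _std_factory}

    for size in SIM_SIZES:
        cfg = SimConfig(n_per_class=size, seed=SIM_SEED + size, n_folds=N_FOLDS)
        ds_s, ds_c, gt = generate_dataset(cfg)
        crop_c, roi2 = crop_to_roi(ds_c, gt.roi2, 5)
        crop_s, _ = crop_to_roi(ds_s, gt.roi2, 5)
        if size == SIM_SIZES[0]:
            # independent evaluation set from the same planted signals, large
            # enough for stable class-mean embeddings in the geometry analysis
            eval_c = generate_eval_dataset(cfg, gt, "C", n_per_class=60, seed=SIM_SEED + 991)
            eval_crop, _ = crop_to_roi(eval_c, gt.roi2, 5)
            study.roi2_cropped = roi2
        for method, factory in factories.items():
            results = []
            for f in range(N_FOLDS):
                model = factory(crop_c, f, scheme)
                tr = np.where(crop_c.fold != f)[0]
                te_c = np.where(crop_c.fold == f)[0]
                te_s = np.where(crop_s.fold == f)[0]
                w = fit_stacking(predict(model, crop_c, tr), crop_c.labels[tr])
                preds_c = predict(model, crop_c, te_c)
                preds_s = predict(model, crop_s, te_s)
                res = FoldResult(
                    identity=roi_accuracy_from_predictions(w, preds_c, crop_c.labels[te_c], roi2),
                    cross=roi_accuracy_from_predictions(w, preds_s, crop_s.labels[te_s], roi2),
                    identity_naive=naive_roi_accuracy(preds_c, crop_c.labels[te_c], roi2),
                )
                if method == "lsdm" and size == SIM_SIZES[0]:
                    study.identity_triples.append((w, preds_c, crop_c.labels[te_c]))
                    study.cross_triples.append((w, preds_s, crop_s.labels[te_s]))
                    rdm = lsdm_roi_rdm(model, eval_crop, np.arange(eval_crop.n_trials), w, roi2)
                    res.rho_latent = circular_rank_correlation(rdm).rho
                    raw = raw_rsa(eval_crop, model.config.k, w, roi2)
                    res.rho_raw = circular_rank_correlation(raw).rho
                results.append(res)
                if size == SIM_SIZES[0] and f == 0:
                    study.params_per_patch[method] = model.n_params / model.n_patches
            study.accuracies[(size, method)] = results

    # ROI 1 (S-only region): cross-decoding of a C-trained model must be at chance
    cfg = SimConfig(n_per_class=SIM_SIZES[0], seed=SIM_SEED + SIM_SIZES[0], n_folds=N_FOLDS)
    ds_s, ds_c, gt = generate_dataset(cfg)
    crop_c1, roi1 = crop_to_roi(ds_c, gt.roi1, 5)
    crop_s1, _ = crop_to_roi(ds_s, gt.roi1, 5)
    for f in range(N_FOLDS):
        model = _lsdm_factory(crop_c1, f, scheme)
        tr = np.where(crop_c1.fold != f)[0]
        te_s = np.where(crop_s1.fold == f)[0]
        w = fit_stacking(predict(model, crop_c1, tr), crop_c1.labels[tr])
        preds_s = predict(model, crop_s1, te_s)
        study.roi1_cross.append(
            roi_accuracy_from_predictions(w, preds_s, crop_s1.labels[te_s], roi1)
        )
        study.roi1_n_test += te_s.size

    # structured-noise geometry: latent-space RSA must beat raw RSA
    cfg = SimConfig(n_per_class=SIM_SIZES[0], seed=SIM_SEED + 7, n_folds=N_FOLDS)
    _, ds_c, gt = generate_dataset(cfg, structured_noise=True)
    crop_c, roi2 = crop_to_roi(ds_c, gt.roi2, 5)
    eval_c = generate_eval_dataset(
        cfg, gt, "C", n_per_class=60, seed=SIM_SEED + 992, structured_noise=True
    )
    eval_crop, _ = crop_to_roi(eval_c, gt.roi2, 5)
    for f in range(N_FOLDS):
        model = _lsdm_factory(crop_c, f, scheme)
        tr = np.where(crop_c.fold != f)[0]
        w = fit_stacking(predict(model, crop_c, tr), crop_c.labels[tr])
        rdm = lsdm_roi_rdm(model, eval_crop, np.arange(eval_crop.n_trials), w, roi2)
        study.rho_structured_latent.append(circular_rank_correlation(rdm).rho)
        raw = raw_rsa(eval_crop, model.config.k, w, roi2)
        study.rho_structured_raw.append(circular_rank_correlation(raw).rho)

    return study
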