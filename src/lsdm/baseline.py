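"""Standard multinomial logistic searchlight baseline.

One independent multinomial logistic classifier per overlapping 5x5x5 patch,
sharing the within-group objective, oversampling, dynamic class weighting,
cross-validation and evaluation machinery of the layered model.  It is fit by
the same gradient procedure (it is exactly the single-layer, kernel-5 case of
the layered architecture), so head-to-head comparisons isolate the
architecture rather than the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core_data import GroupScheme, ROIMask, TrialDataset, VolumeGrid
from .model import LSDMConfig, LSDMModel, build_model, train

__all__ = ["StandardConfig", "LogisticSearchlight", "train_standard", "compare", "params_per_patch"]


@dataclass
class StandardConfig:
    """Hyperparameters of the standard searchlight (defaults match the LSDM's)."""

    patch_size: int = 5
    c_in: int = 1
    n_classes: int = 12
    lr: float = 1e-3
    epochs: int = 120
    batch_size: int = 64
    seed: int = 0
    weight_floor: float = 0.05
    weight_ema: float = 0.5
    patience: int = 10
    min_epochs: int = 20
    min_delta: float = 1e-4
    val_fraction: float = 0.125

    def to_lsdm_config(self) -> LSDMConfig:
        return LSDMConfig(
            k=self.patch_size,
            L=1,
            ch=1,  # unused: a single layer has no hidden channels
            c_in=self.c_in,
            n_classes=self.n_classes,
            lr=self.lr,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=self.seed,
            weight_floor=self.weight_floor,
            weight_ema=self.weight_ema,
            patience=self.patience,
            min_epochs=self.min_epochs,
            min_delta=self.min_delta,
            val_fraction=self.val_fraction,
        )


def params_per_patch(patch_size: int, c_in: int, n_classes: int) -> int:
    """Closed-form per-patch parameter count: ``(p^3 * c_in + 1) * n_classes``."""
    return (patch_size**3 * c_in + 1) * n_classes


class LogisticSearchlight:
    """A bank of per-patch multinomial logistic models over cubes of side ``patch_size``.

    Internally realized as a single locally connected layer (the ``k=patch_size,
    L=1`` case of the layered architecture), which is architecturally identical
    to fitting one flattened-patch logistic regression per location.
    """

    def __init__(self, config: StandardConfig, grid: VolumeGrid, mask: ROIMask | None = None):
        self.config = config
        self.model: LSDMModel = build_model(config.to_lsdm_config(), grid, mask)
        layer = self.model.net.layers[0]
        expected = params_per_patch(config.patch_size, config.c_in, config.n_classes)
        actual = (layer.W.shape[1] + 1) * config.n_classes
        assert actual == expected, "per-patch parameter count must match the closed form"

    @property
    def patch_weights(self) -> np.ndarray:
        """(n_patches, patch_voxels * c_in, n_classes) weight blocks."""
        return self.model.net.layers[0].W

    @property
    def patch_bias(self) -> np.ndarray:
        return self.model.net.layers[0].b

    def params_per_patch(self) -> int:
        return params_per_patch(self.config.patch_size, self.config.c_in, self.config.n_classes)


def train_standard(
    dataset: TrialDataset,
    fold_id: int | None,
    scheme: GroupScheme,
    patch_size: int = 5,
    config: StandardConfig | None = None,
    mask: ROIMask | None = None,
) -> LogisticSearchlight:
    """Train the standard searchlight on all folds except ``fold_id``.

    Uses the same oversampling, within-group weighted cross-entropy, dynamic
    class weights and early stopping as the layered model.
    """
    cfg = config or StandardConfig(patch_size=patch_size, c_in=dataset.c_in, n_classes=dataset.n_classes)
    if config is not None and config.c_in != dataset.c_in:
        cfg = replace(config, c_in=dataset.c_in)
    sl = LogisticSearchlight(cfg, dataset.grid, mask)
    train(sl.model, dataset, fold_id, scheme)
    return sl


def compare(
    lsdm_results: dict[int, float],
    standard_results: dict[int, float],
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Paired per-fold accuracy difference (LSDM - standard) with bootstrap CI.

    Both inputs map fold id -> accuracy on that fold's held-out trials; the
    fold sets must match.  The CI is a percentile bootstrap (``n_boot``
    resamples) over the paired per-fold differences.
    """
    folds = sorted(lsdm_results)
    if folds != sorted(standard_results):
        raise ValueError("fold sets of the two results do not match")
    diffs = np.array([lsdm_results[f] - standard_results[f] for f in folds])
    rng = np.random.default_rng(seed)
    boots = rng.choice(diffs, size=(n_boot, diffs.size), replace=True).mean(axis=1)
    return {
        "folds": folds,
        "per_fold_difference": diffs,
        "mean_difference": float(diffs.mean()),
        "ci_low": float(np.percentile(boots, 2.5)),
        "ci_high": float(np.percentile(boots, 97.5)),
    }
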