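"""The layered searchlight decoding model (LSDM).

A stack of ``L`` locally connected linear layers of kernel size ``k`` (stride
1, valid padding) assigns an independent filter to every spatial location, so
each output location is a small classifier whose receptive field is a cube of
side ``L*k - L + 1`` voxels (5 at the defaults k=2, L=4).  Per-location batch
normalization is applied between layers; no nonlinear activation is used by
default, and the intermediate channel width ``ch`` (default 3) forms a
low-dimensional latent space per patch in which the classes are linearly
separable.

Setting ``k=5, L=1`` recovers a bank of standard multinomial searchlight
classifiers over 5x5x5 cubes; the layered parameterization shares weights
between overlapping patches and is therefore much smaller.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .core_data import GroupScheme, ROIMask, TrialDataset, VolumeGrid, oversample_balance
from .nn import Adam, LocallyConnectedNet, to_batch_major, to_location_major
from .objective import (
    group_softmax,
    update_class_weights,
    within_group_accuracy,
    within_group_loss,
)

__all__ = [
    "LSDMConfig",
    "LSDMModel",
    "PatchPredictions",
    "receptive_field_size",
    "build_model",
    "train",
    "train_all_folds",
    "predict",
    "extract_latent",
    "accuracy_map",
    "patch_accuracy",
    "permutation_threshold",
    "evaluate_on_subset",
    "save_model",
    "load_model",
]


def receptive_field_size(k: int, L: int) -> int:
    """Side length of the input cube seen by one output unit of an L-layer stack.

    Each valid convolution with kernel ``k`` grows the receptive field by
    ``k - 1``, so the stack sees ``L*k - L + 1`` voxels per axis.
    """
    if k < 1 or L < 1:
        raise ValueError("k and L must be positive integers")
    return L * k - L + 1


@dataclass
class LSDMConfig:
    """Architecture and training hyperparameters.

    ``k``/``L``/``ch`` control the layered architecture; ``c_in`` is the number
    of input channels per trial (e.g. 2 cue-TR coefficient maps) and
    ``n_classes`` the readout width.  Training uses Adam with oversampled
    classes, dynamic difficulty-based class weights, and early stopping on a
    training-loss plateau.
    """

    k: int = 2
    L: int = 4
    ch: int = 3
    c_in: int = 1
    n_classes: int = 12
    lr: float = 1e-3
    epochs: int = 120
    batch_size: int = 64
    bn_momentum: float = 0.1
    bn_eps: float = 1e-5
    seed: int = 0
    weight_floor: float = 0.05
    weight_ema: float = 0.5
    patience: int = 10
    min_epochs: int = 20
    min_delta: float = 1e-4
    val_fraction: float = 0.125
    dropout: float = 0.0
    activation: str | None = None

    @property
    def receptive_field(self) -> int:
        return receptive_field_size(self.k, self.L)


@dataclass
class PatchPredictions:
    """Per-trial, per-patch class distributions from a searchlight model.

    ``probs[b, i]`` is the group-blockwise distribution over the 12 classes for
    trial ``b`` at patch ``i`` (each comparison group's 3 entries sum to 1).
    ``centers[i]`` is the center voxel of patch ``i`` on the model's grid.
    """

    probs: np.ndarray
    centers: np.ndarray
    out_shape: tuple[int, int, int]
    trial_ids: np.ndarray
    scheme: GroupScheme

    @property
    def n_patches(self) -> int:
        return self.probs.shape[1]

    def subset_patches(self, patch_index: np.ndarray) -> "PatchPredictions":
        patch_index = np.asarray(patch_index)
        return PatchPredictions(
            probs=self.probs[:, patch_index],
            centers=self.centers[patch_index],
            out_shape=self.out_shape,
            trial_ids=self.trial_ids,
            scheme=self.scheme,
        )


class LSDMModel:
    """A (possibly trained) layered searchlight over a fixed grid."""

    def __init__(self, config: LSDMConfig, grid: VolumeGrid, mask: ROIMask | None = None):
        if mask is not None and mask.grid.shape != grid.shape:
            raise ValueError("mask grid does not match data grid")
        self.config = config
        self.grid = grid
        self.mask = mask
        self.net = LocallyConnectedNet(
            grid.shape,
            c_in=config.c_in,
            k=config.k,
            n_layers=config.L,
            ch=config.ch,
            n_classes=config.n_classes,
            seed=config.seed,
            bn_momentum=config.bn_momentum,
            bn_eps=config.bn_eps,
            activation=config.activation,
            dropout=config.dropout,
        )
        self.fold_id: int | None = None
        self.train_trial_ids: set[int] = set()
        self.loss_history: list[float] = []

    @property
    def out_shape(self) -> tuple[int, int, int]:
        return self.net.out_shape

    @property
    def n_patches(self) -> int:
        return int(np.prod(self.out_shape))

    @property
    def center_offset(self) -> int:
        # valid convolution anchors a patch at its corner; the patch is
        # assigned to the geometric center of its (odd-sided) receptive field
        return (self.config.receptive_field - 1) // 2

    def patch_centers(self) -> np.ndarray:
        grids = np.meshgrid(*[np.arange(s) for s in self.out_shape], indexing="ij")
        anchors = np.stack([g.ravel() for g in grids], axis=1)
        return anchors + self.center_offset

    def patch_in_mask(self) -> np.ndarray:
        """Boolean (n_patches,): patch retained iff its center voxel is in the mask."""
        if self.mask is None:
            return np.ones(self.n_patches, dtype=bool)
        c = self.patch_centers()
        return self.mask.mask[c[:, 0], c[:, 1], c[:, 2]]

    def masked_input(self, data: np.ndarray) -> np.ndarray:
        """Zero-fill voxels outside the brain mask."""
        if self.mask is None:
            return data
        return data * self.mask.mask[None, None].astype(data.dtype)

    @property
    def n_params(self) -> int:
        return self.net.n_params

    def params_per_patch(self) -> float:
        """Total parameter count divided by the number of output patches."""
        return self.net.n_params / self.n_patches


def build_model(
    config: LSDMConfig, grid: VolumeGrid, mask: ROIMask | None = None
) -> LSDMModel:
    """Construct an untrained LSDM; errors if the grid is smaller than the RF."""
    return LSDMModel(config, grid, mask)


# ---------------------------------------------------------------------------
# Training


def _check_labels_valid(dataset: TrialDataset, scheme: GroupScheme):
    if dataset.n_classes != scheme.n_classes:
        raise ValueError("dataset and scheme disagree on n_classes")


def train(
    model: LSDMModel,
    dataset: TrialDataset,
    fold_id: int | None,
    scheme: GroupScheme,
    verbose: bool = False,
) -> LSDMModel:
    """Train the model on all folds except ``fold_id`` (or all data if None).

    The training split is oversampled to balance classes; the within-group
    cross-entropy is weighted by dynamic difficulty-based class weights
    (updated each epoch from an EMA of per-class training accuracy).  A
    fraction of the training split (``val_fraction``, never test data) is held
    out for epoch selection: training stops when its mean within-group patch
    accuracy has not improved for ``patience`` epochs, and the best-epoch
    weights are restored.  With ``val_fraction=0`` a training-loss plateau is
    used instead.  Deterministic given the config seed.  Raises if the loss
    diverges.
    """
    cfg = model.config
    _check_labels_valid(dataset, scheme)
    if dataset.c_in != cfg.c_in:
        raise ValueError(f"dataset has {dataset.c_in} channels, config expects {cfg.c_in}")
    if fold_id is None:
        train_idx = np.arange(dataset.n_trials)
    else:
        if np.all(dataset.fold < 0):
            raise ValueError("dataset has no fold assignment; call assign_folds first")
        train_idx = np.where(dataset.fold != fold_id)[0]
        if train_idx.size == 0:
            raise ValueError(f"no training trials outside fold {fold_id}")

    rng = np.random.default_rng(cfg.seed + 1009 * (0 if fold_id is None else fold_id + 1))
    if cfg.val_fraction > 0:
        perm = rng.permutation(train_idx)
        n_val = max(scheme.n_classes, int(round(cfg.val_fraction * perm.size)))
        val_idx, fit_idx = perm[:n_val], perm[n_val:]
    else:
        val_idx, fit_idx = None, train_idx
    resampled = oversample_balance(
        fit_idx,
        dataset.labels[fit_idx],
        seed=int(rng.integers(2**31 - 1)),
        required_classes=range(1, scheme.n_classes + 1),
    )
    X = to_location_major(model.masked_input(dataset.data[resampled]))
    y = dataset.labels[resampled]
    if val_idx is not None:
        X_val = to_location_major(model.masked_input(dataset.data[val_idx]))
        y_val = dataset.labels[val_idx]

    params = model.net.params()
    opt = Adam(params, lr=cfg.lr)
    n = X.shape[3]
    n_out = model.n_patches
    class_weights = np.ones(cfg.n_classes)
    running_acc = np.full(cfg.n_classes, 1.0 / 3.0)
    best_metric = -np.inf  # val accuracy (or -train loss) to maximize
    best_state = None
    stall = 0
    mask_patches = model.patch_in_mask().reshape(model.out_shape)

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_acc = np.zeros(cfg.n_classes)
        epoch_cnt = np.zeros(cfg.n_classes)
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            scores, _ = model.net.forward_loc(X[:, :, :, batch], train=True, keep_cache=True)
            b = len(batch)
            loss, per_class_acc, grad = within_group_loss(
                scores.reshape(n_out, b, cfg.n_classes).swapaxes(0, 1),
                y[batch],
                scheme,
                class_weights,
                return_grad=True,
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training loss diverged (epoch {epoch}, loss {loss}); "
                    "lower the learning rate or check the inputs"
                )
            if model.mask is not None:
                grad *= mask_patches.reshape(1, n_out, 1)
            grad_loc = np.ascontiguousarray(
                grad.swapaxes(0, 1).astype(np.float32)
            ).reshape(*model.out_shape, b, cfg.n_classes)
            opt.step(model.net.backward_loc(grad_loc))
            epoch_loss += loss * b
            seen = np.isfinite(per_class_acc)
            epoch_acc[seen] += per_class_acc[seen]
            epoch_cnt[seen] += 1
        epoch_loss /= n
        model.loss_history.append(epoch_loss)
        with np.errstate(invalid="ignore"):
            mean_acc = np.where(epoch_cnt > 0, epoch_acc / np.maximum(epoch_cnt, 1), np.nan)
        running_acc = np.where(
            np.isnan(mean_acc), running_acc, cfg.weight_ema * running_acc + (1 - cfg.weight_ema) * mean_acc
        )
        class_weights = update_class_weights(running_acc, floor=cfg.weight_floor)

        if val_idx is not None:
            scores, _ = model.net.forward_loc(X_val, train=False)
            probs = group_softmax(
                scores.reshape(n_out, y_val.size, cfg.n_classes).swapaxes(0, 1), scheme
            )
            if model.mask is not None:
                probs = probs[:, mask_patches.ravel(), :]
            metric = float(np.mean(within_group_accuracy(probs, y_val, scheme)))
        else:
            metric = -epoch_loss
        if verbose:
            print(f"epoch {epoch:3d}  loss {epoch_loss:.4f}  metric {metric:.4f}")
        if metric > best_metric + cfg.min_delta:
            best_metric = metric
            best_state = {k: v.copy() for k, v in model.net.state_arrays().items()}
            stall = 0
        else:
            stall += 1
            if epoch + 1 >= cfg.min_epochs and stall >= cfg.patience:
                break

    if best_state is not None:
        model.net.load_state_arrays(best_state)
    model.net.clear_caches()
    model.fold_id = fold_id
    model.train_trial_ids = set(int(t) for t in dataset.trial_id[train_idx])
    return model


def train_all_folds(
    dataset: TrialDataset,
    config: LSDMConfig,
    scheme: GroupScheme,
    mask: ROIMask | None = None,
    n_folds: int | None = None,
) -> list[LSDMModel]:
    """One trained model per held-out fold (the standard 8-fold CV protocol)."""
    folds = sorted(set(int(f) for f in dataset.fold if f >= 0)) if n_folds is None else list(range(n_folds))
    models = []
    for f in folds:
        model = build_model(config, dataset.grid, mask)
        models.append(train(model, dataset, f, scheme))
    return models


# ---------------------------------------------------------------------------
# Evaluation


def predict(
    model: LSDMModel,
    dataset: TrialDataset,
    indices: np.ndarray | None = None,
    batch_size: int = 256,
) -> PatchPredictions:
    """Group-masked class distributions for each trial at each patch (eval mode)."""
    if tuple(dataset.grid.shape) != tuple(model.grid.shape):
        raise ValueError(
            f"dataset grid {dataset.grid.shape} does not match model grid {model.grid.shape}"
        )
    idx = np.arange(dataset.n_trials) if indices is None else np.asarray(indices)
    scheme = GroupScheme.default(model.config.n_classes)
    n_out = model.n_patches
    probs = []
    for start in range(0, idx.size, batch_size):
        chunk = idx[start : start + batch_size]
        x_loc = to_location_major(model.masked_input(dataset.data[chunk]))
        scores, _ = model.net.forward_loc(x_loc, train=False)
        s = scores.reshape(n_out, chunk.size, model.config.n_classes).swapaxes(0, 1)
        probs.append(group_softmax(s, scheme).astype(np.float32))
    return PatchPredictions(
        probs=np.concatenate(probs, axis=0),
        centers=model.patch_centers(),
        out_shape=model.out_shape,
        trial_ids=dataset.trial_id[idx],
        scheme=scheme,
    )


def extract_latent(
    model: LSDMModel,
    dataset: TrialDataset,
    indices: np.ndarray | None = None,
    batch_size: int = 256,
) -> np.ndarray:
    """Latent states: the input to the final layer, shape (B, ch, *penultimate grid).

    Uses evaluation-mode (running-statistics) normalization.
    """
    if tuple(dataset.grid.shape) != tuple(model.grid.shape):
        raise ValueError("dataset grid does not match model grid")
    idx = np.arange(dataset.n_trials) if indices is None else np.asarray(indices)
    out = []
    for start in range(0, idx.size, batch_size):
        chunk = idx[start : start + batch_size]
        x_loc = to_location_major(model.masked_input(dataset.data[chunk]))
        _, latent = model.net.forward_loc(x_loc, train=False)
        out.append(to_batch_major(latent))
    return np.concatenate(out, axis=0)


def patch_accuracy(
    predictions: PatchPredictions, labels: np.ndarray, scheme: GroupScheme | None = None
) -> np.ndarray:
    """Within-group accuracy per patch, shape (n_patches,)."""
    scheme = scheme or predictions.scheme
    return within_group_accuracy(predictions.probs, labels, scheme)


def accuracy_map(
    predictions: PatchPredictions,
    labels: np.ndarray,
    grid_shape: tuple[int, int, int],
    scheme: GroupScheme | None = None,
    chance_subtract: bool = False,
) -> np.ndarray:
    """Per-patch accuracy placed at each patch's center voxel; NaN elsewhere."""
    acc = patch_accuracy(predictions, labels, scheme)
    if chance_subtract:
        scheme = scheme or predictions.scheme
        acc = acc - 1.0 / len(scheme.groups[0])
    vol = np.full(grid_shape, np.nan)
    c = predictions.centers
    vol[c[:, 0], c[:, 1], c[:, 2]] = acc
    return vol


def _group_argmax_labels(probs: np.ndarray, scheme: GroupScheme) -> np.ndarray:
    """(B, N, n_groups) array of the argmax label within each group."""
    b, n, _ = probs.shape
    out = np.empty((b, n, scheme.n_groups), dtype=np.int64)
    for gi, members in enumerate(scheme.group_members()):
        out[:, :, gi] = members[probs[:, :, members - 1].argmax(axis=-1)]
    return out


def permutation_threshold(
    fold_predictions: list[tuple[PatchPredictions, np.ndarray]],
    n_perm: int = 1000,
    quantile: float = 0.95,
    seed: int = 0,
    return_distribution: bool = False,
):
    """Chance threshold for per-patch accuracy maps via label permutation.

    For each held-out fold's predictions, the class labels of the test set are
    randomly permuted ``n_perm`` times and per-patch within-group accuracies
    recomputed; all (fold, permutation, patch) accuracies are pooled and the
    requested quantile of the pooled null distribution is returned.
    """
    rng = np.random.default_rng(seed)
    pooled = []
    for preds, labels in fold_predictions:
        labels = np.asarray(labels)
        scheme = preds.scheme
        am = _group_argmax_labels(preds.probs, scheme)  # (B, N, G)
        l2g = scheme.label_to_group()
        b = labels.shape[0]
        rows = np.arange(b)
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            pred = am[rows, :, l2g[perm]]  # (B, N)
            pooled.append((pred == perm[:, None]).mean(axis=0))
    dist = np.concatenate(pooled)
    thr = float(np.quantile(dist, quantile))
    return (thr, dist) if return_distribution else thr


def evaluate_on_subset(
    models: list[LSDMModel],
    dataset: TrialDataset,
    subset_indices: np.ndarray,
    label_column: str = "label",
) -> np.ndarray:
    """Accuracy per patch on a designated trial subset, averaged over models.

    The subset must be disjoint from every model's training trials (leakage
    guard).  ``label_column`` selects stimulus labels (``"label"``) or the
    subject's choices (``"choice"``); trials with no recorded choice are an
    error in the latter case.
    """
    subset_indices = np.asarray(subset_indices)
    if subset_indices.size == 0:
        raise ValueError("empty evaluation subset")
    ids = set(int(t) for t in dataset.trial_id[subset_indices])
    for m in models:
        overlap = ids & m.train_trial_ids
        if overlap:
            raise ValueError(
                f"evaluation subset overlaps training data of fold {m.fold_id} "
                f"({len(overlap)} trials)"
            )
    if label_column == "label":
        labels = dataset.labels[subset_indices]
    elif label_column == "choice":
        labels = dataset.choice_label[subset_indices]
        if np.any(labels < 1):
            raise ValueError("subset contains trials with no recorded choice")
    else:
        raise ValueError(f"unknown label column {label_column!r}")
    accs = []
    for m in models:
        preds = predict(m, dataset, subset_indices)
        accs.append(patch_accuracy(preds, labels))
    return np.mean(accs, axis=0)


# ---------------------------------------------------------------------------
# Serialization (npz weights + JSON manifest)


def save_model(model: LSDMModel, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arrays = model.net.state_arrays()
    if model.mask is not None:
        arrays["mask"] = model.mask.mask
    np.savez_compressed(out_dir / "weights.npz", **arrays)
    manifest = {
        "format": "lsdm-model-v1",
        "config": asdict(model.config),
        "grid_shape": list(model.grid.shape),
        "voxel_size": list(model.grid.voxel_size),
        "affine": np.asarray(model.grid.affine).tolist(),
        "fold_id": model.fold_id,
        "train_trial_ids": sorted(model.train_trial_ids),
        "loss_history": model.loss_history,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir


def load_model(model_dir: str | Path) -> LSDMModel:
    model_dir = Path(model_dir)
    manifest = json.loads((model_dir / "manifest.json").read_text())
    cfg = LSDMConfig(**manifest["config"])
    grid = VolumeGrid(
        shape=tuple(manifest["grid_shape"]),
        voxel_size=tuple(manifest["voxel_size"]),
        affine=np.asarray(manifest["affine"]),
    )
    arrays = dict(np.load(model_dir / "weights.npz"))
    mask = None
    if "mask" in arrays:
        mask = ROIMask(grid=grid, mask=arrays.pop("mask"))
    model = LSDMModel(cfg, grid, mask)
    model.net.load_state_arrays(arrays)
    model.fold_id = manifest["fold_id"]
    model.train_trial_ids = set(manifest["train_trial_ids"])
    model.loss_history = list(manifest["loss_history"])
    return model
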