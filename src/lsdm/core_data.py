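"""Data model and I/O for volumetric trial datasets.

A trial dataset holds one small multi-channel 3-D volume per trial (for example
the GLM coefficient maps of the second and third cue TRs of an active-task
trial), together with per-trial metadata: class label, modality (shape ``S`` or
color ``C``), counterbalancing group (``A``/``B``), luminance level, behavioral
correctness, the subject's choice, and a cross-validation fold.

Volumes and masks are exchanged as NIfTI-1 files; trial metadata as a
tab-separated events table with a header row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGrid",
    "GroupScheme",
    "TrialDataset",
    "ROIMask",
    "default_class_table",
    "load_dataset",
    "save_dataset",
    "load_mask",
    "assign_folds",
    "oversample_balance",
]

EVENT_COLUMNS = [
    "trial_id",
    "label",
    "modality",
    "group",
    "luminance",
    "correct",
    "choice_label",
    "fold",
]
_REQUIRED_EVENT_COLUMNS = ["trial_id", "label", "modality"]


@dataclass(frozen=True)
class VolumeGrid:
    """Geometry of the functional voxel grid.

    All computation is done in 0-based voxel coordinates in NIfTI array order;
    the affine (voxel -> world, mm) is carried along for I/O only.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be three positive integers, got {self.shape}")
        vs = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        affine = self.affine
        if affine is None:
            affine = np.diag([*vs, 1.0])
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (4, 4) or abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vs)
        object.__setattr__(self, "affine", affine)

    def __eq__(self, other):
        return (
            isinstance(other, VolumeGrid)
            and self.shape == other.shape
            and np.allclose(self.affine, other.affine)
        )


def default_class_table(n_classes: int = 12) -> pd.DataFrame:
    """Canonical class layout: ``n_classes/2`` hues at two luminance levels.

    Label ``b`` (1-based) has hue index ``(b-1) % (n_classes/2)``; labels in the
    first half are "light", the rest "dark".  Counterbalancing groups alternate
    around the hue circle (even hues -> group A, odd hues -> group B), so each
    (group, luminance) cell holds ``n_classes/4`` classes.
    """
    if n_classes % 4:
        raise ValueError("default scheme needs n_classes divisible by 4")
    n_hues = n_classes // 2
    labels = np.arange(1, n_classes + 1)
    hue = (labels - 1) % n_hues
    lum = np.where(labels <= n_hues, "light", "dark")
    group = np.where(hue % 2 == 0, "A", "B")
    return pd.DataFrame({"label": labels, "hue": hue, "luminance": lum, "group": group})


@dataclass(frozen=True)
class GroupScheme:
    """Partition of the class labels into valid comparison groups.

    Decoding objectives (softmax, cross-entropy, accuracy) are evaluated only
    among labels of the same group, so chance level is ``1/len(group)``.
    The default crosses counterbalancing set (A/B) with luminance level,
    yielding four groups of three classes and a chance level of 1/3.
    """

    groups: tuple[tuple[int, ...], ...]
    n_classes: int

    def __post_init__(self):
        seen: set[int] = set()
        for g in self.groups:
            if not g:
                raise ValueError("empty comparison group")
            if seen & set(g):
                raise ValueError("comparison groups must be disjoint")
            seen |= set(g)
        if seen != set(range(1, self.n_classes + 1)):
            raise ValueError("groups must cover labels 1..n_classes exactly")

    @classmethod
    def default(cls, n_classes: int = 12) -> "GroupScheme":
        table = default_class_table(n_classes)
        groups = []
        for (_, _), sub in table.groupby(["group", "luminance"], sort=True):
            groups.append(tuple(int(v) for v in sorted(sub["label"])))
        return cls(groups=tuple(sorted(groups)), n_classes=n_classes)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def label_to_group(self) -> np.ndarray:
        """Array mapping label (1-based; index 0 unused) -> group index."""
        out = np.full(self.n_classes + 1, -1, dtype=np.int64)
        for gi, g in enumerate(self.groups):
            for lab in g:
                out[lab] = gi
        return out

    def group_members(self) -> list[np.ndarray]:
        return [np.asarray(g, dtype=np.int64) for g in self.groups]

    def group_of(self, label: int) -> int:
        gi = self.label_to_group()[label]
        if gi < 0:
            raise ValueError(f"label {label} not in any comparison group")
        return int(gi)


@dataclass
class TrialDataset:
    """Per-trial multi-channel volumes plus trial metadata.

    ``data`` has shape ``(n_trials, c_in, x, y, z)``.  Labels are 1-based class
    indices.  ``choice_label`` uses 0 for "no recorded choice".  ``fold`` uses
    -1 for "not yet assigned".
    """

    grid: VolumeGrid
    data: np.ndarray
    labels: np.ndarray
    modality: np.ndarray
    group: np.ndarray
    luminance: np.ndarray
    correct: np.ndarray
    choice_label: np.ndarray
    fold: np.ndarray
    n_classes: int = 12
    trial_id: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        n = self.data.shape[0]
        if self.data.ndim != 5:
            raise ValueError("data must be (n_trials, channels, x, y, z)")
        if tuple(self.data.shape[2:]) != self.grid.shape:
            raise ValueError(
                f"data volume shape {self.data.shape[2:]} does not match grid {self.grid.shape}"
            )
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (n,):
            raise ValueError("labels must be one per trial")
        if self.labels.min(initial=1) < 1 or self.labels.max(initial=1) > self.n_classes:
            raise ValueError(f"labels must lie in 1..{self.n_classes}")
        for name in ("modality", "group", "luminance"):
            arr = np.asarray(getattr(self, name), dtype=object)
            if arr.shape != (n,):
                raise ValueError(f"{name} must be one per trial")
            setattr(self, name, arr)
        self.correct = np.asarray(self.correct, dtype=bool)
        self.choice_label = np.asarray(self.choice_label, dtype=np.int64)
        self.fold = np.asarray(self.fold, dtype=np.int64)
        if self.trial_id is None:
            self.trial_id = np.arange(n, dtype=np.int64)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def c_in(self) -> int:
        return self.data.shape[1]

    def events(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_id": self.trial_id,
                "label": self.labels,
                "modality": self.modality,
                "group": self.group,
                "luminance": self.luminance,
                "correct": self.correct.astype(int),
                "choice_label": self.choice_label,
                "fold": self.fold,
            }
        )

    def subset(self, index: np.ndarray) -> "TrialDataset":
        index = np.asarray(index)
        return TrialDataset(
            grid=self.grid,
            data=self.data[index],
            labels=self.labels[index],
            modality=self.modality[index],
            group=self.group[index],
            luminance=self.luminance[index],
            correct=self.correct[index],
            choice_label=self.choice_label[index],
            fold=self.fold[index],
            n_classes=self.n_classes,
            trial_id=self.trial_id[index],
        )

    def crop(self, lo: Sequence[int], hi: Sequence[int]) -> "TrialDataset":
        """Restrict volumes to the voxel box ``[lo, hi)`` (new origin at ``lo``)."""
        lo = tuple(int(v) for v in lo)
        hi = tuple(int(v) for v in hi)
        if any(a < 0 or b > s or b <= a for a, b, s in zip(lo, hi, self.grid.shape)):
            raise ValueError(f"crop box {lo}..{hi} outside grid {self.grid.shape}")
        sub = self.data[:, :, lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        new_grid = VolumeGrid(
            shape=sub.shape[2:], voxel_size=self.grid.voxel_size, affine=self.grid.affine
        )
        out = replace(self)
        out.data = np.ascontiguousarray(sub)
        out.grid = new_grid
        return out


@dataclass(frozen=True)
class ROIMask:
    """Set of member voxels of a region of interest on a grid."""

    grid: VolumeGrid
    mask: np.ndarray = field(repr=False)

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != self.grid.shape:
            raise ValueError(f"mask shape {mask.shape} does not match grid {self.grid.shape}")
        object.__setattr__(self, "mask", mask)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def member_voxels(self) -> np.ndarray:
        return np.argwhere(self.mask)

    def crop(self, lo: Sequence[int], hi: Sequence[int]) -> "ROIMask":
        sub = self.mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        return ROIMask(grid=VolumeGrid(shape=sub.shape, voxel_size=self.grid.voxel_size), mask=sub)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        idx = self.member_voxels()
        if idx.size == 0:
            raise ValueError("empty ROI mask")
        return idx.min(axis=0), idx.max(axis=0) + 1


# ---------------------------------------------------------------------------
# I/O


def _grid_from_img(img) -> VolumeGrid:
    zooms = img.header.get_zooms()[:3]
    return VolumeGrid(shape=img.shape[:3], voxel_size=zooms, affine=img.affine)


def load_mask(path: str | Path, grid: VolumeGrid | None = None) -> ROIMask:
    img = nib.load(str(path))
    mgrid = _grid_from_img(img)
    if grid is not None and mgrid.shape != grid.shape:
        raise ValueError(f"mask grid {mgrid.shape} does not match data grid {grid.shape}")
    return ROIMask(grid=grid or mgrid, mask=np.asanyarray(img.dataobj) > 0)


def load_dataset(
    volume_files: Sequence[str | Path],
    events: str | Path,
    n_classes: int = 12,
) -> TrialDataset:
    """Load one 4-D NIfTI per trial (x, y, z, channels) plus an events TSV.

    The events table must carry at least ``trial_id``, ``label`` and
    ``modality``; ``group`` and ``luminance`` default to the canonical class
    layout, ``correct`` to true, ``choice_label`` to 0 and ``fold`` to -1.
    Rows align with ``volume_files`` in order.
    """
    table = pd.read_csv(events, sep="\t")
    missing = [c for c in _REQUIRED_EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"events table missing required columns: {missing}")
    if len(table) != len(volume_files):
        raise ValueError(
            f"{len(volume_files)} volumes but {len(table)} event rows; they must align"
        )

    vols = []
    grid = None
    for path in volume_files:
        img = nib.load(str(path))
        g = _grid_from_img(img)
        if grid is None:
            grid = g
        elif g.shape != grid.shape:
            raise ValueError(f"volume {path} grid {g.shape} does not match {grid.shape}")
        arr = np.asanyarray(img.dataobj, dtype=np.float32)
        if arr.ndim == 3:
            arr = arr[..., None]
        vols.append(np.moveaxis(arr, -1, 0))  # (channels, x, y, z)
    data = np.stack(vols, axis=0)

    labels = table["label"].to_numpy()
    if labels.min() < 1 or labels.max() > n_classes:
        raise ValueError(f"labels outside 1..{n_classes}")

    defaults = default_class_table(n_classes).set_index("label")
    group = (
        table["group"].to_numpy()
        if "group" in table
        else defaults.loc[labels, "group"].to_numpy()
    )
    lum = (
        table["luminance"].to_numpy()
        if "luminance" in table
        else defaults.loc[labels, "luminance"].to_numpy()
    )
    correct = table["correct"].to_numpy(dtype=bool) if "correct" in table else np.ones(len(table), bool)
    choice = table["choice_label"].fillna(0).to_numpy(dtype=np.int64) if "choice_label" in table else np.zeros(len(table), np.int64)
    fold = table["fold"].to_numpy(dtype=np.int64) if "fold" in table else np.full(len(table), -1)

    return TrialDataset(
        grid=grid,
        data=data,
        labels=labels,
        modality=table["modality"].to_numpy(),
        group=group,
        luminance=lum,
        correct=correct,
        choice_label=choice,
        fold=fold,
        n_classes=n_classes,
        trial_id=table["trial_id"].to_numpy(),
    )


def save_dataset(dataset: TrialDataset, out_dir: str | Path) -> tuple[list[Path], Path]:
    """Write one 4-D NIfTI per trial plus ``events.tsv``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(dataset.n_trials):
        vol = np.moveaxis(dataset.data[i], 0, -1)
        img = nib.Nifti1Image(vol, affine=dataset.grid.affine)
        p = out_dir / f"trial_{i:05d}.nii.gz"
        nib.save(img, str(p))
        paths.append(p)
    events_path = out_dir / "events.tsv"
    dataset.events().to_csv(events_path, sep="\t", index=False)
    return paths, events_path


# ---------------------------------------------------------------------------
# Cross-validation bookkeeping


def assign_folds(dataset: TrialDataset, n_folds: int = 8, seed: int = 0) -> TrialDataset:
    """Assign a stratified fold partition, balanced within each (label, modality) cell.

    Every trial lands in exactly one fold; each cell's trials are dealt to the
    folds as evenly as possible (shuffled, then round-robin from a random
    starting fold).  Deterministic given ``seed``.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    rng = np.random.default_rng(seed)
    fold = np.full(dataset.n_trials, -1, dtype=np.int64)
    keys = pd.Series(
        [f"{l}|{m}" for l, m in zip(dataset.labels, dataset.modality)], dtype=object
    )
    for _, idx in keys.groupby(keys).groups.items():
        idx = np.asarray(idx)
        if len(idx) < n_folds:
            raise ValueError(
                f"cell with {len(idx)} trials cannot be split into {n_folds} folds"
            )
        perm = rng.permutation(idx)
        start = rng.integers(n_folds)
        fold[perm] = (start + np.arange(len(perm))) % n_folds
    out = replace(dataset)
    out.fold = fold
    return out


def oversample_balance(
    train_indices: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    required_classes: Sequence[int] | None = None,
) -> np.ndarray:
    """Oversample a training split so every class reaches the max class count.

    ``labels`` are the labels of ``train_indices`` (same length).  Duplicates
    are drawn uniformly with replacement from the class's own indices; the
    returned index list contains only members of ``train_indices``.  Applied to
    training splits only, never to test data.  If ``required_classes`` is
    given, a class with zero examples in the split is an error.
    """
    train_indices = np.asarray(train_indices)
    labels = np.asarray(labels)
    if train_indices.shape != labels.shape:
        raise ValueError("train_indices and labels must align")
    classes, counts = np.unique(labels, return_counts=True)
    if train_indices.size == 0:
        raise ValueError("empty training split")
    if required_classes is not None:
        absent = sorted(set(required_classes) - set(classes.tolist()))
        if absent:
            raise ValueError(f"classes {absent} have no examples in the training split")
    target = counts.max()
    rng = np.random.default_rng(seed)
    out = [train_indices]
    for cls, cnt in zip(classes, counts):
        deficit = target - cnt
        if deficit > 0:
            pool = train_indices[labels == cls]
            out.append(rng.choice(pool, size=deficit, replace=True))
    return np.concatenate(out)
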