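"""Synthetic volumetric datasets with planted, known class structure.

The generator emulates the two-modality active-task design: two features
("shape" S and "color" C), 12 classes arranged as 6 hues at two luminance
levels, split into counterbalancing groups A and B.  Each example is a 16^3
volume containing two 5^3 signal regions:

* the upper-left (UL) region carries information about S only;
* the lower-right (LR) region carries a *shared* circular signal for associated
  S and C classes plus a modality-private high-dimensional signal.

The circular signal places the 6 same-luminance classes evenly on the unit
circle and embeds the circle in the 125-dimensional region via a random
orthonormal transform; dark classes are offset by 1 along a random axis
orthogonal to the circle plane.  The high-dimensional signal orthogonalizes
the 12 classes (orthonormal one-hot embedding scaled by 1.5).  Isotropic
Gaussian noise of spread 1.5 is added over the whole volume per example; in
the structured-noise variant an additional Gaussian vector of spread 0.3 is
drawn per counterbalancing group and added to that group's examples, making
the noise depend on class identity through group membership.

Also provided: the second-order de Bruijn trial-sequence utility used for run
counterbalancing, and a benchmark driver comparing the layered and standard
searchlights across dataset sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core_data import (
    GroupScheme,
    ROIMask,
    TrialDataset,
    VolumeGrid,
    assign_folds,
    default_class_table,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "make_circular_signal",
    "make_highdim_signal",
    "generate_dataset",
    "debruijn_sequence",
    "debruijn_runs",
    "crop_to_roi",
    "run_benchmark",
]


# Training protocol of the scaled benchmark: identical for the layered and
# standard searchlights (same optimizer, oversampling, dynamic class weights
# and validation-based epoch selection), so comparisons isolate architecture.
BENCHMARK_TRAIN = dict(lr=2e-3, epochs=120, batch_size=120, patience=10, min_epochs=20)


@dataclass
class SimConfig:
    """Full parameterization of the validation simulation (defaults as studied)."""

    shape: tuple[int, int, int] = (16, 16, 16)
    region_size: int = 5
    ul_corner: tuple[int, int, int] = (1, 1, 6)
    lr_corner: tuple[int, int, int] = (10, 10, 6)
    n_classes: int = 12
    lum_offset: float = 1.0
    highdim_scale: float = 1.5
    noise_sd: float = 1.5
    structured_sd: float = 0.3
    n_per_class: int = 180
    n_folds: int = 8
    seed: int = 0
    structured_mode: str = "per_group"  # or "per_example"

    def __post_init__(self):
        r = self.region_size
        for name, corner in (("UL", self.ul_corner), ("LR", self.lr_corner)):
            if any(c < 0 or c + r > s for c, s in zip(corner, self.shape)):
                raise ValueError(f"{name} region leaves the volume")
        ul = set(self._region_indices(self.ul_corner))
        lr = set(self._region_indices(self.lr_corner))
        if ul & lr:
            raise ValueError("signal regions overlap")

    @property
    def region_dim(self) -> int:
        return self.region_size**3

    def _region_indices(self, corner) -> list[tuple[int, int, int]]:
        r = self.region_size
        return [
            (corner[0] + i, corner[1] + j, corner[2] + l)
            for i in range(r)
            for j in range(r)
            for l in range(r)
        ]

    def region_slices(self, corner) -> tuple[slice, slice, slice]:
        r = self.region_size
        return tuple(slice(c, c + r) for c in corner)


@dataclass
class GroundTruth:
    """Planted structure of a generated dataset."""

    roi1: ROIMask  # contains the UL (S-only) region
    roi2: ROIMask  # contains the LR (shared S & C) region
    circle_coords: np.ndarray  # (n_classes, 3): cos, sin, luminance offset
    signals: dict = field(repr=False, default_factory=dict)
    hue: np.ndarray | None = None


def _random_orthonormal(rng: np.random.Generator, dim: int, n_cols: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((dim, n_cols)))
    return q * np.sign(np.diag(r))


def make_circular_signal(
    seed_or_rng,
    n_classes: int = 12,
    dim: int = 125,
    lum_offset: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class circular signal vectors, shape (n_classes, dim).

    The 6 hues of each luminance level sit evenly on the unit circle; the
    circle plane is a random 2-D plane of the ``dim``-dimensional region (via a
    random orthonormal transform) and the dark classes are offset by
    ``lum_offset`` along a random axis orthogonal to that plane.  Returns
    ``(vectors, basis)`` where ``basis`` is the (dim, 3) orthonormal frame.
    """
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) else np.random.default_rng(seed_or_rng)
    table = default_class_table(n_classes)
    n_hues = n_classes // 2
    basis = _random_orthonormal(rng, dim, 3)
    theta = 2 * np.pi * table["hue"].to_numpy() / n_hues
    plane = np.stack([np.cos(theta), np.sin(theta)], axis=1)  # (n_classes, 2)
    lum = (table["luminance"].to_numpy() == "dark").astype(float) * lum_offset
    coords = np.column_stack([plane, lum])
    return coords @ basis.T, basis


def make_highdim_signal(
    seed_or_rng, n_classes: int = 12, dim: int = 125, scale: float = 1.5
) -> np.ndarray:
    """Mutually orthogonal per-class vectors of norm ``scale`` (one-hot embedding).

    An orthonormal transform maps the one-hot class codes into a random
    ``n_classes``-dimensional subspace of the region, scaled by ``scale``.
    """
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) else np.random.default_rng(seed_or_rng)
    return scale * _random_orthonormal(rng, dim, n_classes).T  # (n_classes, dim)


def _dilate(mask: np.ndarray) -> np.ndarray:
    out = mask.copy()
    for axis in range(3):
        for shift in (-1, 1):
            out |= np.roll(mask, shift, axis=axis) & ~_edge_wrap(mask, shift, axis)
    return out


def _edge_wrap(mask: np.ndarray, shift: int, axis: int) -> np.ndarray:
    # voxels that wrapped around the volume edge under np.roll
    wrap = np.zeros_like(mask)
    sl = [slice(None)] * 3
    sl[axis] = slice(0, 1) if shift == 1 else slice(-1, None)
    wrap[tuple(sl)] = True
    return wrap


def generate_dataset(
    config: SimConfig, structured_noise: bool = False
) -> tuple[TrialDataset, TrialDataset, GroundTruth]:
    """Generate the paired S and C trial datasets plus ground truth.

    Deterministic given ``config.seed``.  Fold assignments (``config.n_folds``)
    are included.
    """
    rng = np.random.default_rng(config.seed)
    n_classes = config.n_classes
    dim = config.region_dim
    r = config.region_size

    circ_ul_s, _ = make_circular_signal(rng, n_classes, dim, config.lum_offset)
    circ_lr, basis_lr = make_circular_signal(rng, n_classes, dim, config.lum_offset)
    hd_ul_s = make_highdim_signal(rng, n_classes, dim, config.highdim_scale)
    hd_lr_s = make_highdim_signal(rng, n_classes, dim, config.highdim_scale)
    hd_lr_c = make_highdim_signal(rng, n_classes, dim, config.highdim_scale)

    table = default_class_table(n_classes)
    labels = np.repeat(np.arange(1, n_classes + 1), config.n_per_class)
    n = labels.size
    ul = config.region_slices(config.ul_corner)
    lr = config.region_slices(config.lr_corner)

    group_of_label = table.set_index("label")["group"]

    structured_offsets: dict = {}
    class_volumes: dict = {}

    def build(modality: str) -> TrialDataset:
        data = rng.normal(0.0, config.noise_sd, size=(n, 1, *config.shape)).astype(np.float32)
        sig = np.zeros((n_classes, *config.shape), dtype=np.float32)
        if modality == "S":
            sig[:, ul[0], ul[1], ul[2]] += (circ_ul_s + hd_ul_s).reshape(n_classes, r, r, r)
            sig[:, lr[0], lr[1], lr[2]] += (circ_lr + hd_lr_s).reshape(n_classes, r, r, r)
        else:
            sig[:, lr[0], lr[1], lr[2]] += (circ_lr + hd_lr_c).reshape(n_classes, r, r, r)
        class_volumes[modality] = sig
        data[:, 0] += sig[labels - 1]
        if structured_noise:
            groups = group_of_label.loc[labels].to_numpy()
            if config.structured_mode == "per_group":
                offsets = {
                    g: rng.normal(0.0, config.structured_sd, size=config.shape).astype(np.float32)
                    for g in ("A", "B")
                }
                for g, off in offsets.items():
                    data[groups == g, 0] += off
                    structured_offsets[(modality, g)] = off
            elif config.structured_mode == "per_example":
                for g in ("A", "B"):
                    sel = np.where(groups == g)[0]
                    data[sel, 0] += rng.normal(
                        0.0, config.structured_sd, size=(sel.size, *config.shape)
                    ).astype(np.float32)
            else:
                raise ValueError(f"unknown structured_mode {config.structured_mode!r}")
        ds = TrialDataset(
            grid=VolumeGrid(shape=config.shape),
            data=data,
            labels=labels,
            modality=np.full(n, modality, dtype=object),
            group=group_of_label.loc[labels].to_numpy(),
            luminance=table.set_index("label").loc[labels, "luminance"].to_numpy(),
            correct=np.ones(n, dtype=bool),
            choice_label=np.zeros(n, dtype=np.int64),
            fold=np.full(n, -1, dtype=np.int64),
            n_classes=n_classes,
        )
        fold_seed = int(rng.integers(2**31 - 1))
        if config.n_per_class < config.n_folds:
            return ds  # too few examples per class to stratify; folds unassigned
        return assign_folds(ds, config.n_folds, seed=fold_seed)

    ds_s = build("S")
    ds_c = build("C")

    grid = VolumeGrid(shape=config.shape)
    region1 = np.zeros(config.shape, dtype=bool)
    region1[ul] = True
    region2 = np.zeros(config.shape, dtype=bool)
    region2[lr] = True
    roi1 = ROIMask(grid=grid, mask=_dilate(region1))
    roi2 = ROIMask(grid=grid, mask=_dilate(region2))
    if np.any(roi1.mask & roi2.mask):
        raise ValueError("ROIs overlap after dilation")

    theta = 2 * np.pi * table["hue"].to_numpy() / (n_classes // 2)
    lumc = (table["luminance"].to_numpy() == "dark").astype(float) * config.lum_offset
    gt = GroundTruth(
        roi1=roi1,
        roi2=roi2,
        circle_coords=np.column_stack([np.cos(theta), np.sin(theta), lumc]),
        signals={
            "circ_ul_s": circ_ul_s,
            "circ_lr": circ_lr,
            "hd_ul_s": hd_ul_s,
            "hd_lr_s": hd_lr_s,
            "hd_lr_c": hd_lr_c,
            "basis_lr": basis_lr,
            "class_volumes": class_volumes,
            "structured_offsets": structured_offsets,
        },
        hue=table["hue"].to_numpy(),
    )
    return ds_s, ds_c, gt


def generate_eval_dataset(
    config: SimConfig,
    ground_truth: GroundTruth,
    modality: str = "C",
    n_per_class: int = 60,
    seed: int = 1,
    structured_noise: bool = False,
    trial_id_offset: int = 1_000_000,
) -> TrialDataset:
    """Fresh evaluation trials drawn from an existing dataset's planted signals.

    Uses the stored per-class signal volumes (and, for the structured case, the
    same per-group noise offsets) of ``ground_truth`` with independent noise,
    so the result is an independent sample from the same generative process —
    useful for representational-geometry analyses that need more trials per
    class than a single held-out fold contains.  Trial ids are offset so the
    evaluation set can never be mistaken for training trials.
    """
    rng = np.random.default_rng(seed)
    sig = ground_truth.signals["class_volumes"][modality]
    n_classes = config.n_classes
    labels = np.repeat(np.arange(1, n_classes + 1), n_per_class)
    n = labels.size
    data = rng.normal(0.0, config.noise_sd, size=(n, 1, *config.shape)).astype(np.float32)
    data[:, 0] += sig[labels - 1]
    table = default_class_table(n_classes).set_index("label")
    groups = table.loc[labels, "group"].to_numpy()
    if structured_noise:
        offsets = ground_truth.signals["structured_offsets"]
        if not offsets:
            raise ValueError("ground truth has no structured-noise offsets stored")
        for g in ("A", "B"):
            data[groups == g, 0] += offsets[(modality, g)]
    return TrialDataset(
        grid=VolumeGrid(shape=config.shape),
        data=data,
        labels=labels,
        modality=np.full(n, modality, dtype=object),
        group=groups,
        luminance=table.loc[labels, "luminance"].to_numpy(),
        correct=np.ones(n, dtype=bool),
        choice_label=np.zeros(n, dtype=np.int64),
        fold=np.full(n, -1, dtype=np.int64),
        n_classes=n_classes,
        trial_id=trial_id_offset + np.arange(n, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# de Bruijn trial counterbalancing


def debruijn_sequence(n_symbols: int, seed: int | None = None) -> list[int]:
    """Cyclic second-order de Bruijn sequence over ``n_symbols`` cue symbols.

    Every ordered pair of symbols (including repeats) occurs exactly once when
    the sequence is read cyclically, so the length is ``n_symbols**2``.  Built
    as an Eulerian circuit of the complete directed graph with self-loops.
    """
    g = nx.MultiDiGraph()
    symbols = list(range(n_symbols))
    if seed is not None:
        rng = np.random.default_rng(seed)
        symbols = [int(s) for s in rng.permutation(n_symbols)]
    for u in symbols:
        for v in symbols:
            g.add_edge(u, v)
    circuit = list(nx.eulerian_circuit(g, source=symbols[0]))
    seq = [u for u, _ in circuit]
    assert len(seq) == n_symbols**2
    return seq


def debruijn_runs(
    n_trial_pairs: int, order: int = 2, n_runs: int = 4, seed: int | None = None
) -> list[list[int]]:
    """Counterbalanced trial sequences split into runs with first-trial repeats.

    ``n_trial_pairs`` trial pairs give ``2 * n_trial_pairs`` cue symbols.  The
    cyclic order-2 de Bruijn sequence over the cues is split into ``n_runs``
    equal blocks, and each run starts with a repeat of the last trial of the
    previous run (cyclically), preserving the pair counterbalancing across run
    boundaries.  For 4 trial pairs this yields 4 runs of 17 trials.
    """
    if order != 2:
        raise NotImplementedError("only second-order counterbalancing is implemented")
    if n_trial_pairs < 1:
        raise ValueError("need at least one trial pair")
    n_cues = 2 * n_trial_pairs
    seq = debruijn_sequence(n_cues, seed=seed)
    total = len(seq)
    if total % n_runs:
        raise ValueError(f"cyclic length {total} not divisible into {n_runs} runs")
    block = total // n_runs
    runs = []
    for r in range(n_runs):
        chunk = seq[r * block : (r + 1) * block]
        prev_last = seq[(r * block - 1) % total]
        runs.append([prev_last] + chunk)
    return runs


# ---------------------------------------------------------------------------
# ROI-local training support and the benchmark driver


def crop_to_roi(
    dataset: TrialDataset, roi: ROIMask, receptive_field: int
) -> tuple[TrialDataset, ROIMask]:
    """Crop a dataset to the ROI bounding box padded by the patch half-width.

    Because the searchlight assigns an independent model to every location, the
    patches whose centers lie in the ROI depend only on voxels within half a
    receptive field of the ROI; training on this crop is equivalent to training
    the corresponding locations of the whole-volume model, at a fraction of the
    cost.  Returns the cropped dataset and the ROI mask on the cropped grid.
    """
    margin = (receptive_field - 1) // 2
    lo, hi = roi.bounding_box()
    lo = np.maximum(lo - margin, 0)
    hi = np.minimum(hi + margin, dataset.grid.shape)
    return dataset.crop(lo, hi), roi.crop(lo, hi)


def run_benchmark(
    sizes: Sequence[int] = (60, 120, 180, 300, 420, 660),
    methods: Sequence[str] = ("lsdm", "standard"),
    seed: int = 0,
    structured_noise: bool = False,
    n_folds: int = 8,
    sim_config: SimConfig | None = None,
    lsdm_config=None,
    standard_config=None,
    n_boot: int = 1000,
) -> pd.DataFrame:
    """Identity and cross-decoding accuracy in ROI 2 across dataset sizes.

    For each size and method, models are trained per held-out fold on the color
    (C) dataset restricted to the ROI-2 neighborhood, and evaluated on the
    held-out C fold (identity) and the matching S fold (cross-decoding), with
    ROI accuracy computed through the stacking weights.  Returns a long-format
    table with per-fold accuracies and bootstrap 95% CIs of the mean.
    """
    from .baseline import StandardConfig, train_standard
    from .model import LSDMConfig, predict, train_all_folds
    from .stacking import fit_stacking, roi_accuracy_from_predictions

    rows = []
    for size in sizes:
        cfg = sim_config or SimConfig()
        cfg = SimConfig(**{**cfg.__dict__, "n_per_class": size, "seed": seed + size, "n_folds": n_folds})
        ds_s, ds_c, gt = generate_dataset(cfg, structured_noise=structured_noise)
        for method in methods:
            if method == "lsdm":
                mcfg = lsdm_config or LSDMConfig(seed=seed, **BENCHMARK_TRAIN)
                rf = mcfg.receptive_field
            elif method == "standard":
                mcfg = standard_config or StandardConfig(seed=seed, **BENCHMARK_TRAIN)
                rf = mcfg.patch_size
            else:
                raise ValueError(f"unknown method {method!r}")
            crop_c, roi2_c = crop_to_roi(ds_c, gt.roi2, rf)
            crop_s, _ = crop_to_roi(ds_s, gt.roi2, rf)
            if method == "lsdm":
                models = train_all_folds(crop_c, mcfg, GroupScheme.default(cfg.n_classes))
            else:
                models = [
                    train_standard(crop_c, f, GroupScheme.default(cfg.n_classes), config=mcfg).model
                    for f in range(n_folds)
                ]
            for f, m in enumerate(models):
                test_c = np.where(crop_c.fold == f)[0]
                test_s = np.where(crop_s.fold == f)[0]
                train_idx = np.where(crop_c.fold != f)[0]
                w = fit_stacking(predict(m, crop_c, train_idx), crop_c.labels[train_idx])
                for metric, ds_eval, idx in (
                    ("identity", crop_c, test_c),
                    ("cross", crop_s, test_s),
                ):
                    preds = predict(m, ds_eval, idx)
                    acc = roi_accuracy_from_predictions(
                        w, preds, ds_eval.labels[idx], roi2_c
                    )
                    rows.append(
                        dict(size=size, method=method, metric=metric, fold=f, accuracy=acc)
                    )
    df = pd.DataFrame(rows)
    rng = np.random.default_rng(seed + 17)
    summaries = []
    for (size, method, metric), sub in df.groupby(["size", "method", "metric"]):
        acc = sub["accuracy"].to_numpy()
        boots = rng.choice(acc, size=(n_boot, acc.size), replace=True).mean(axis=1)
        summaries.append(
            dict(
                size=size,
                method=method,
                metric=metric,
                mean=acc.mean(),
                ci_low=float(np.percentile(boots, 2.5)),
                ci_high=float(np.percentile(boots, 97.5)),
            )
        )
    df.attrs["summary"] = pd.DataFrame(summaries)
    return df
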