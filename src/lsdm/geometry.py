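"""Representational geometry in decoder latent space and in voxel space.

Per-location class embeddings (mean latent vectors per class) give a 12x12
Pearson-distance matrix ``D_j`` at every location; averaging over the k^3
locations feeding each final-layer filter (a uniform filter) gives the matrix
of the representation each searchlight patch reads out, and a stacking-weight
normalized average over an ROI gives a single ROI matrix ``D_R``.

The circular-rank correlation ``rho`` compares the ranked pairwise distances
of the six same-luminance classes with the canonical ranking of six evenly
spaced items on a circle (the hue circle of a perceptually uniform color
space), averaged over the light and dark sub-matrices.  Significance comes
from a permutation null over random orderings of six items (exhaustive over
all 720 orderings, or Monte Carlo), or optionally by permuting the observed
rank vector while preserving its tie structure.

A classic RSA variant computes the same quantities from raw voxel-space
condition means instead of the decoder's latent states, and a classical MDS
embedding is provided for visualization.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .core_data import ROIMask, TrialDataset
from .model import LSDMModel, extract_latent
from .stacking import StackingWeights

__all__ = [
    "class_embeddings",
    "patch_rdm",
    "uniform_filter_rdm",
    "roi_rdm",
    "lsdm_roi_rdm",
    "raw_rsa",
    "canonical_circular_matrix",
    "canonical_circular_ranks",
    "CircularRho",
    "circular_rank_correlation",
    "permutation_null",
    "mds_embed",
]


# ---------------------------------------------------------------------------
# Dissimilarity matrices


def class_embeddings(latents: np.ndarray, labels: np.ndarray, n_classes: int = 12) -> np.ndarray:
    """Mean latent vector per class at every location.

    ``latents``: (B, ch, *grid); returns (n_classes, ch, *grid).  The latents
    must come from a model fit on data disjoint from these trials.
    """
    latents = np.asarray(latents)
    labels = np.asarray(labels)
    out = np.empty((n_classes, *latents.shape[1:]), dtype=np.float64)
    for b in range(1, n_classes + 1):
        sel = labels == b
        if not sel.any():
            raise ValueError(f"class {b} has no trials to average")
        out[b - 1] = latents[sel].mean(axis=0)
    return out


def _pearson_distance_matrix(vectors: np.ndarray) -> np.ndarray:
    """(n, d) -> (n, n) matrix of 1 - Pearson r; zero diagonal, entries in [0, 2]."""
    v = np.asarray(vectors, dtype=np.float64)
    v = v - v.mean(axis=-1, keepdims=True)
    norm = np.sqrt((v**2).sum(axis=-1, keepdims=True))
    v = v / np.maximum(norm, 1e-30)
    d = 1.0 - v @ v.T
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def patch_rdm(embeddings: np.ndarray) -> np.ndarray:
    """Per-location Pearson-distance matrices.

    ``embeddings``: (n_classes, ch, *grid) -> (*grid, n_classes, n_classes).
    """
    emb = np.asarray(embeddings, dtype=np.float64)
    n_classes, ch = emb.shape[:2]
    grid = emb.shape[2:]
    e = emb.reshape(n_classes, ch, -1)
    e = e - e.mean(axis=1, keepdims=True)
    norm = np.sqrt((e**2).sum(axis=1, keepdims=True))
    e = e / np.maximum(norm, 1e-30)
    corr = np.einsum("bcn,dcn->nbd", e, e)
    d = 1.0 - corr
    idx = np.arange(n_classes)
    d[:, idx, idx] = 0.0
    return np.clip(d, 0.0, 2.0).reshape(*grid, n_classes, n_classes)


def uniform_filter_rdm(rdm_field: np.ndarray, k: int) -> np.ndarray:
    """Element-wise mean of the k^3 matrices feeding each downstream location.

    ``rdm_field``: (*grid, n, n) -> (*(grid - k + 1), n, n); equivalent to a
    valid-mode (k, k, k) uniform filter over the matrix field.  Symmetry and
    the zero diagonal are preserved (means of symmetric zero-diagonal inputs).
    """
    field = np.asarray(rdm_field, dtype=np.float64)
    gx, gy, gz = field.shape[:3]
    if min(gx, gy, gz) < k:
        raise ValueError(f"grid {field.shape[:3]} smaller than filter size {k}")
    out = np.zeros((gx - k + 1, gy - k + 1, gz - k + 1, *field.shape[3:]))
    for i in range(k):
        for j in range(k):
            for l in range(k):
                out += field[i : i + gx - k + 1, j : j + gy - k + 1, l : l + gz - k + 1]
    return out / k**3


def roi_rdm(
    rdm_field: np.ndarray,
    weights: StackingWeights,
    roi: ROIMask,
) -> np.ndarray:
    """Stacking-weight-normalized average RDM over an ROI.

    ``rdm_field`` holds one matrix per searchlight patch, flattened in the
    patch order of ``weights.centers`` or shaped (*patch_grid, n, n).
    ``D_R = sum_{j in R} w_j D_j / sum_{j in R} w_j`` — a convex combination.
    """
    field = np.asarray(rdm_field, dtype=np.float64)
    if field.ndim == 5:
        field = field.reshape(-1, *field.shape[3:])
    if field.shape[0] != weights.w.size:
        raise ValueError("rdm field and stacking weights disagree on patch count")
    idx, w = weights.roi_subset(roi)
    return np.einsum("j,jbc->bc", w, field[idx])


def lsdm_roi_rdm(
    model: LSDMModel,
    dataset: TrialDataset,
    indices: np.ndarray,
    weights: StackingWeights,
    roi: ROIMask,
) -> np.ndarray:
    """ROI dissimilarity matrix from a trained model's latent states.

    Extracts eval-mode latents of the designated trials (which must be disjoint
    from the model's training data), averages them per class at each
    penultimate-layer location, computes per-location Pearson-distance
    matrices, uniform-filters them over each final-layer filter's k^3 inputs,
    and stacking-weight averages over the ROI.
    """
    indices = np.asarray(indices)
    ids = set(int(t) for t in dataset.trial_id[indices])
    if ids & model.train_trial_ids:
        raise ValueError("RDM trials overlap the model's training data")
    latents = extract_latent(model, dataset, indices)
    emb = class_embeddings(latents, dataset.labels[indices], model.config.n_classes)
    field = patch_rdm(emb)
    field = uniform_filter_rdm(field, model.config.k)
    return roi_rdm(field, weights, roi)


def raw_rsa(
    dataset: TrialDataset,
    k: int,
    weights: StackingWeights,
    roi: ROIMask,
    indices: np.ndarray | None = None,
    receptive_field: int = 5,
) -> np.ndarray:
    """Classic-RSA ROI matrix: condition vectors in voxel space.

    For every searchlight patch, the per-class mean volumes are concatenated
    over a (k, k, k) cube of voxels within the patch's receptive field (the
    cube sits at offset ``(receptive_field - k) // 2`` from the patch anchor;
    ``k=1`` degenerates to single-voxel condition vectors), Pearson-distance
    matrices are computed from these condition vectors, and the matrices are
    stacking-weight averaged over the ROI exactly as in :func:`roi_rdm`.
    """
    idx = np.arange(dataset.n_trials) if indices is None else np.asarray(indices)
    data = dataset.data[idx]
    labels = dataset.labels[idx]
    n_classes = dataset.n_classes
    means = class_embeddings(data, labels, n_classes)  # (n_classes, c_in, x, y, z)
    off = (receptive_field - k) // 2
    centers = weights.centers
    anchors = centers - (receptive_field - 1) // 2
    n_cl, c_in = means.shape[:2]
    vecs = np.empty((len(anchors), n_cl, c_in * k**3))
    for p, a in enumerate(anchors):
        cube = means[
            :, :, a[0] + off : a[0] + off + k, a[1] + off : a[1] + off + k, a[2] + off : a[2] + off + k
        ]
        vecs[p] = cube.reshape(n_cl, -1)
    field = np.stack([_pearson_distance_matrix(v) for v in vecs])
    return roi_rdm(field, weights, roi)


# ---------------------------------------------------------------------------
# Circular-rank correlation against color-space geometry


def canonical_circular_matrix(n_items: int = 6) -> np.ndarray:
    """Circulant matrix of circular distances among ``n_items`` evenly spaced items."""
    i = np.arange(n_items)
    d = np.abs(i[:, None] - i[None, :])
    return np.minimum(d, n_items - d)


def canonical_circular_ranks(n_items: int = 6) -> np.ndarray:
    """Tie-averaged ranks of the canonical matrix's upper triangle (row-major)."""
    m = canonical_circular_matrix(n_items)
    return rankdata(m[np.triu_indices(n_items, k=1)])


def _upper(mat: np.ndarray) -> np.ndarray:
    n = mat.shape[0]
    return mat[np.triu_indices(n, k=1)]


@dataclass
class CircularRho:
    """Circular-rank correlation with its light/dark components.

    ``degenerate`` flags a constant distance vector (undefined correlation); in
    that case the affected component (and rho) is NaN rather than 0.
    """

    rho: float
    rho_light: float
    rho_dark: float
    degenerate: bool = False


def _rank_corr(dist_vec: np.ndarray, ref_ranks: np.ndarray) -> float:
    # round before ranking so distances equal up to float error share a tie
    ranks = rankdata(np.round(dist_vec, 10))  # fractional (average) ranks for ties
    if np.ptp(ranks) == 0 or np.ptp(ref_ranks) == 0:
        return np.nan
    return float(np.corrcoef(ranks, ref_ranks)[0, 1])


def circular_rank_correlation(
    roi_matrix: np.ndarray,
    light_labels: np.ndarray | None = None,
    dark_labels: np.ndarray | None = None,
) -> CircularRho:
    """Mean of the light and dark sub-matrix rank correlations with the circle.

    ``light_labels``/``dark_labels`` list the six 1-based classes of each
    luminance level *in canonical hue order* (defaults: 1..6 and 7..12).  The
    15 upper-triangle distances of each 6x6 sub-matrix are ranked with average
    ranks for ties and Pearson-correlated with the canonical circular ranks.
    """
    n = roi_matrix.shape[0]
    light = np.arange(1, n // 2 + 1) if light_labels is None else np.asarray(light_labels)
    dark = np.arange(n // 2 + 1, n + 1) if dark_labels is None else np.asarray(dark_labels)
    ref = canonical_circular_ranks(light.size)
    rhos = []
    for labs in (light, dark):
        sub = roi_matrix[np.ix_(labs - 1, labs - 1)]
        rhos.append(_rank_corr(_upper(sub), ref))
    rho_light, rho_dark = rhos
    degenerate = bool(np.isnan(rho_light) or np.isnan(rho_dark))
    rho = np.nan if degenerate else (rho_light + rho_dark) / 2.0
    return CircularRho(rho=rho, rho_light=rho_light, rho_dark=rho_dark, degenerate=degenerate)


@dataclass
class PermutationNull:
    threshold: float  # the requested upper quantile (default 95th percentile)
    band: tuple[float, float]  # central 95% band (2.5-97.5 percentiles)
    distribution: np.ndarray


def permutation_null(
    n_orderings: int = 10000,
    n_measures_averaged: int = 1,
    seed: int = 0,
    n_items: int = 6,
    quantile: float = 0.95,
    exhaustive: bool = False,
    method: str = "orderings",
    observed_ranks: np.ndarray | None = None,
) -> PermutationNull:
    """Null distribution of rho under random orderings of the items.

    ``method="orderings"`` (default, matching the thresholding procedure):
    each draw places the six items in a random order around the circle and
    correlates the induced distance ranks with the canonical ranks.
    ``method="rank_permute"`` instead permutes the entries of a supplied
    observed rank vector (preserving its tie structure).  When several
    independent measures of rho are averaged before thresholding, pass
    ``n_measures_averaged``; the threshold shrinks as more measures are
    averaged.  ``exhaustive=True`` enumerates all orderings exactly (single
    measure only).
    """
    ref = canonical_circular_ranks(n_items)
    base = canonical_circular_matrix(n_items)

    def rho_of_order(order) -> float:
        d = base[np.ix_(order, order)]
        return _rank_corr(_upper(d), ref)

    if exhaustive:
        vals = np.array([rho_of_order(p) for p in itertools.permutations(range(n_items))])
        dist = vals
    else:
        rng = np.random.default_rng(seed)
        if method == "orderings":
            draws = np.array(
                [
                    rho_of_order(rng.permutation(n_items))
                    for _ in range(n_orderings * n_measures_averaged)
                ]
            )
        elif method == "rank_permute":
            if observed_ranks is None:
                raise ValueError("rank_permute needs the observed rank vector")
            obs = np.asarray(observed_ranks, dtype=float)
            draws = np.array(
                [
                    _rank_corr(rng.permutation(obs), ref)
                    for _ in range(n_orderings * n_measures_averaged)
                ]
            )
        else:
            raise ValueError(f"unknown null method {method!r}")
        dist = draws.reshape(n_orderings, n_measures_averaged).mean(axis=1)
    return PermutationNull(
        threshold=float(np.quantile(dist, quantile)),
        band=(float(np.quantile(dist, 0.025)), float(np.quantile(dist, 0.975))),
        distribution=dist,
    )


# ---------------------------------------------------------------------------
# Visualization


def mds_embed(roi_matrix: np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS coordinates of an RDM.

    Deterministic; the embedding is identified only up to rotation/reflection.
    Negative eigenvalues (non-Euclidean inputs) are truncated at zero.
    """
    d = np.asarray(roi_matrix, dtype=np.float64)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dims]
    vals = np.maximum(vals[order], 0.0)
    return vecs[:, order] * np.sqrt(vals)
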