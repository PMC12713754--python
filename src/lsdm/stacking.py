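"""Stacking weights over searchlight patches and ROI-level accuracy.

The naive ROI accuracy (mean over member patches) is diluted by uninformative
patches.  Instead, a single probability distribution ``w`` over all patches is
learned by maximizing the within-group log-likelihood of the stacked
distribution ``c* = sum_i w_i c_i``, where ``c_i`` is patch ``i``'s predicted
class distribution.  Restricting to an ROI renormalizes ``w`` over the member
patches (the maximum-likelihood solution for that subset), and ``c*`` over the
ROI yields one prediction — and one accuracy — per ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import GroupScheme, ROIMask
from .model import LSDMModel, PatchPredictions, predict

__all__ = [
    "StackingWeights",
    "fit_stacking",
    "roi_distribution",
    "roi_accuracy",
    "roi_accuracy_from_predictions",
    "naive_roi_accuracy",
]


@dataclass
class StackingWeights:
    """A probability distribution over searchlight patches."""

    w: np.ndarray
    centers: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("stacking weights must be a probability distribution")
        self.w = w

    def roi_subset(self, roi: ROIMask) -> tuple[np.ndarray, np.ndarray]:
        """(patch indices in ROI, renormalized weights); errors on zero mass."""
        c = self.centers
        inside = roi.mask[c[:, 0], c[:, 1], c[:, 2]]
        idx = np.where(inside)[0]
        if idx.size == 0:
            raise ValueError("no patch centers inside the ROI")
        mass = self.w[idx].sum()
        if mass <= 0:
            raise ValueError("ROI has zero total stacking weight")
        return idx, self.w[idx] / mass


def fit_stacking(
    predictions: PatchPredictions,
    labels: np.ndarray,
    n_iter: int = 400,
    lr: float = 0.1,
    tol: float = 1e-8,
    seed: int = 0,
) -> StackingWeights:
    """Maximum-likelihood stacking weights on the probability simplex.

    Maximizes ``sum_b log(sum_i w_i c_i[y_b])`` with ``w = softmax(theta)``
    (simplex parameterization) by deterministic full-batch gradient ascent with
    adaptive moments.  ``predictions`` must come from training folds only.
    """
    labels = np.asarray(labels)
    if predictions.n_patches == 0:
        raise ValueError("no patches to stack")
    # m[b, i] = patch i's probability for trial b's true class
    m = predictions.probs[np.arange(labels.size), :, labels - 1].astype(np.float64)
    n_patches = m.shape[1]
    theta = np.zeros(n_patches)
    mom = np.zeros(n_patches)
    vel = np.zeros(n_patches)
    prev = -np.inf
    for t in range(1, n_iter + 1):
        w = np.exp(theta - theta.max())
        w /= w.sum()
        p = m @ w  # (B,)
        ll = np.log(np.maximum(p, 1e-300)).sum()
        g_w = (m / np.maximum(p[:, None], 1e-300)).sum(axis=0)  # dll/dw
        # softmax Jacobian: dll/dtheta = w * (g_w - g_w . w)
        g = w * (g_w - g_w @ w)
        mom = 0.9 * mom + 0.1 * g
        vel = 0.999 * vel + 0.001 * g * g
        theta += lr * mom / (np.sqrt(vel / (1 - 0.999**t)) + 1e-8) / (1 - 0.9**t)
        if abs(ll - prev) < tol * max(1.0, abs(ll)):
            break
        prev = ll
    w = np.exp(theta - theta.max())
    w /= w.sum()
    return StackingWeights(w=w, centers=predictions.centers)


def roi_distribution(
    weights: StackingWeights, predictions: PatchPredictions, roi: ROIMask
) -> np.ndarray:
    """Stacked class distribution ``c*`` per trial over the ROI's patches.

    ``c* = sum_{i in ROI} (w_i / sum w_i) c_i``; each comparison group's block
    remains a valid distribution (convexity).
    """
    idx, w = weights.roi_subset(roi)
    return np.einsum("bic,i->bc", predictions.probs[:, idx].astype(np.float64), w)


def _stacked_accuracy(cstar: np.ndarray, labels: np.ndarray, scheme: GroupScheme) -> float:
    labels = np.asarray(labels)
    l2g = scheme.label_to_group()
    correct = np.zeros(labels.size, dtype=bool)
    for gi, members in enumerate(scheme.group_members()):
        sel = np.where(l2g[labels] == gi)[0]
        if sel.size:
            pred = members[cstar[sel][:, members - 1].argmax(axis=1)]
            correct[sel] = pred == labels[sel]
    return float(correct.mean())


def roi_accuracy_from_predictions(
    weights: StackingWeights,
    predictions: PatchPredictions,
    labels: np.ndarray,
    roi: ROIMask,
) -> float:
    """Within-group accuracy of argmax(c*) over an ROI."""
    cstar = roi_distribution(weights, predictions, roi)
    return _stacked_accuracy(cstar, labels, predictions.scheme)


def roi_accuracy(
    weights: StackingWeights,
    model: LSDMModel,
    dataset,
    roi: ROIMask,
    fold_id: int,
) -> float:
    """Combined (searchlight + stacking) accuracy on the held-out fold in an ROI.

    Guards against leakage: the evaluated trials must be outside the model's
    training set.
    """
    test_idx = np.where(dataset.fold == fold_id)[0]
    if test_idx.size == 0:
        raise ValueError(f"fold {fold_id} has no trials")
    ids = set(int(t) for t in dataset.trial_id[test_idx])
    if ids & model.train_trial_ids:
        raise ValueError("held-out fold overlaps the model's training trials")
    preds = predict(model, dataset, test_idx)
    return roi_accuracy_from_predictions(weights, preds, dataset.labels[test_idx], roi)


def roi_accuracy_null(
    fold_data: list[tuple["StackingWeights", PatchPredictions, np.ndarray]],
    roi: ROIMask,
    n_perm: int = 1000,
    quantile: float = 0.95,
    seed: int = 0,
    return_distribution: bool = False,
):
    """Permutation chance threshold for the fold-mean stacked ROI accuracy.

    ``fold_data`` holds (stacking weights, held-out predictions, held-out
    labels) per fold.  For each permutation the labels of every fold's test
    set are shuffled, the stacked ROI accuracy recomputed, and the per-fold
    accuracies averaged; the requested quantile of the ``n_perm`` fold-mean
    values is the chance threshold for the cross-validated ROI accuracy.
    """
    rng = np.random.default_rng(seed)
    prepared = []
    for w, preds, labels in fold_data:
        scheme = preds.scheme
        cstar = roi_distribution(w, preds, roi)  # (B, n_classes)
        am = np.empty((cstar.shape[0], scheme.n_groups), dtype=np.int64)
        for gi, members in enumerate(scheme.group_members()):
            am[:, gi] = members[cstar[:, members - 1].argmax(axis=1)]
        prepared.append((am, np.asarray(labels), scheme.label_to_group()))
    vals = np.empty(n_perm)
    for p in range(n_perm):
        accs = [
            float((am[np.arange(labels.size), l2g[perm]] == perm).mean())
            for am, labels, l2g in prepared
            for perm in [rng.permutation(labels)]
        ]
        vals[p] = np.mean(accs)
    thr = float(np.quantile(vals, quantile))
    return (thr, vals) if return_distribution else thr


def naive_roi_accuracy(
    predictions: PatchPredictions, labels: np.ndarray, roi: ROIMask
) -> float:
    """Mean per-patch accuracy over ROI member patches (the naive aggregate)."""
    from .model import patch_accuracy

    c = predictions.centers
    inside = roi.mask[c[:, 0], c[:, 1], c[:, 2]]
    if not inside.any():
        raise ValueError("no patch centers inside the ROI")
    return float(patch_accuracy(predictions, labels)[inside].mean())
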