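"""Within-group decoding objective.

Not all class comparisons are meaningful in the counterbalanced design: stimuli
are split into two sets (A/B) and two luminance levels, and only classes in the
same (set, luminance) cell are ever compared.  The softmax, cross-entropy and
accuracy are therefore computed only over the 3 classes of the true label's
comparison group, giving a chance level of 1/3 while the network still embeds
all 12 classes in one latent space.
"""

from __future__ import annotations

import numpy as np

from .core_data import GroupScheme

__all__ = ["group_softmax", "within_group_loss", "within_group_accuracy", "update_class_weights"]


def _as_bnc(scores: np.ndarray) -> tuple[np.ndarray, tuple]:
    """Normalize scores to (B, N, C): accepts (B, C), (B, N, C) or (B, C, *spatial)."""
    scores = np.asarray(scores)
    if scores.ndim == 2:
        return scores[:, None, :], scores.shape
    if scores.ndim == 3:
        return scores, scores.shape
    b, c = scores.shape[:2]
    return scores.reshape(b, c, -1).transpose(0, 2, 1), scores.shape


def group_softmax(scores: np.ndarray, scheme: GroupScheme) -> np.ndarray:
    """Blockwise softmax: within each comparison group probabilities sum to 1.

    Returns an array shaped (B, N, n_classes) whose entries for each group's
    classes form a probability distribution over that group.
    """
    s, _ = _as_bnc(scores)
    out = np.empty_like(s, dtype=np.float64)
    for members in scheme.group_members():
        idx = members - 1
        sub = s[..., idx].astype(np.float64)
        sub -= sub.max(axis=-1, keepdims=True)
        np.exp(sub, out=sub)
        sub /= sub.sum(axis=-1, keepdims=True)
        out[..., idx] = sub
    return out


def within_group_loss(
    scores: np.ndarray,
    labels: np.ndarray,
    scheme: GroupScheme,
    class_weights: np.ndarray | None = None,
    return_grad: bool = False,
):
    """Weighted within-group cross-entropy plus per-class accuracy.

    ``scores`` may be (B, C), (B, N, C), or (B, C, *spatial); ``labels`` are
    1-based.  The loss is the mean over trials and locations of
    ``w_y * (-log p_y)`` where the softmax runs only over the true label's
    comparison group.  Accuracy is argmax-within-group (ties broken toward the
    lowest class index).  If ``return_grad`` is set, also returns d(loss)/d(scores)
    in the original score layout.
    """
    s, orig_shape = _as_bnc(scores)
    labels = np.asarray(labels)
    n_classes = scheme.n_classes
    if s.shape[-1] != n_classes:
        raise ValueError(f"scores last axis {s.shape[-1]} != n_classes {n_classes}")
    if labels.min() < 1 or labels.max() > n_classes:
        raise ValueError("labels outside 1..n_classes")
    w = np.ones(n_classes) if class_weights is None else np.asarray(class_weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("class weights must be non-negative")

    b, n, _ = s.shape
    label_group = scheme.label_to_group()[labels]
    if np.any(label_group < 0):
        raise ValueError("some labels belong to no comparison group")

    loss = 0.0
    grad = np.zeros_like(s, dtype=np.float64) if return_grad else None
    class_correct = np.zeros(n_classes)
    class_count = np.zeros(n_classes)
    denom = b * n
    for gi, members in enumerate(scheme.group_members()):
        sel = np.where(label_group == gi)[0]
        if sel.size == 0:
            continue
        idx = members - 1
        sub = s[sel][:, :, idx].astype(np.float64)  # (Bg, N, 3)
        sub -= sub.max(axis=-1, keepdims=True)
        np.exp(sub, out=sub)
        sub /= sub.sum(axis=-1, keepdims=True)
        pos = np.searchsorted(members, labels[sel])  # position of label within group
        p_true = sub[np.arange(sel.size)[:, None], np.arange(n)[None, :], pos[:, None]]
        wt = w[labels[sel] - 1]
        loss += float((wt[:, None] * -np.log(np.maximum(p_true, 1e-12))).sum()) / denom
        correct = (sub.argmax(axis=-1) == pos[:, None]).mean(axis=1)  # per trial
        np.add.at(class_correct, labels[sel] - 1, correct)
        np.add.at(class_count, labels[sel] - 1, 1.0)
        if return_grad:
            g = sub
            g[np.arange(sel.size)[:, None], np.arange(n)[None, :], pos[:, None]] -= 1.0
            g *= wt[:, None, None] / denom
            tmp = np.zeros((sel.size, n, n_classes))
            tmp[:, :, idx] = g
            grad[sel] += tmp

    with np.errstate(invalid="ignore"):
        per_class_acc = np.where(class_count > 0, class_correct / np.maximum(class_count, 1), np.nan)
    if return_grad:
        if len(orig_shape) == 2:
            grad = grad[:, 0, :]
        elif len(orig_shape) > 3 or orig_shape != s.shape:
            grad = grad.transpose(0, 2, 1).reshape(orig_shape)
        return loss, per_class_acc, grad
    return loss, per_class_acc


def within_group_accuracy(
    probs: np.ndarray, labels: np.ndarray, scheme: GroupScheme
) -> np.ndarray:
    """Per-location accuracy (N,) of argmax-within-group predictions.

    ``probs``: (B, N, n_classes) group-blockwise distributions.
    """
    probs = np.asarray(probs)
    labels = np.asarray(labels)
    label_group = scheme.label_to_group()[labels]
    correct = np.zeros(probs.shape[:2], dtype=bool)
    for gi, members in enumerate(scheme.group_members()):
        sel = np.where(label_group == gi)[0]
        if sel.size == 0:
            continue
        idx = members - 1
        pred = members[probs[sel][:, :, idx].argmax(axis=-1)]
        correct[sel] = pred == labels[sel][:, None]
    return correct.mean(axis=0)


def update_class_weights(
    running_accuracy: np.ndarray, floor: float = 0.05
) -> np.ndarray:
    """Difficulty-based class weights: ``w_b ∝ (1 - acc_b) + floor``, mean 1.

    Classes the model currently finds hard (low running accuracy) get more
    weight; the floor keeps perfectly decoded classes in the objective.
    Deterministic; accuracies must lie in [0, 1] (NaN treated as chance-free 1).
    """
    acc = np.asarray(running_accuracy, dtype=float)
    if np.nanmin(acc) < 0 or np.nanmax(acc) > 1:
        raise ValueError("accuracies must lie in [0, 1]")
    acc = np.where(np.isnan(acc), 1.0, acc)
    raw = (1.0 - acc) + floor
    return raw / raw.mean()
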