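"""Passive-task contrast statistics and the multi-subject bootstrap.

Selectivity index, z-score contrast maps and percent signal change operate on
GLM beta coefficients per run and voxel; confidence intervals use an
equal-subject-probability bootstrap in which each example from subject ``i``
(of ``m`` subjects with ``|D_i|`` examples) is drawn with probability
``1 / (m |D_i|)``, so every subject contributes equally in expectation
regardless of how much data it has.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "selectivity_index",
    "z_contrast",
    "percent_signal_change",
    "multi_subject_bootstrap",
    "responsive_voxels",
    "BootstrapResult",
]


def selectivity_index(b1, b2, tol: float = 1e-12) -> np.ndarray:
    """Normalized contrast ``(b1 - b2) / (b1 + b2)`` per voxel per run.

    Antisymmetric in its arguments.  Voxels with an additive response within
    ``tol`` of zero are flagged missing (NaN) rather than divided.
    """
    b1 = np.asarray(b1, dtype=float)
    b2 = np.asarray(b2, dtype=float)
    denom = b1 + b2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.abs(denom) < tol, np.nan, (b1 - b2) / denom)
    return out


def z_contrast(diffs, variances) -> np.ndarray:
    """Mean contrast difference divided by the contrast standard error.

    ``diffs`` and ``variances`` hold per-run contrast differences and their GLM
    variances along the first axis; ``z = mean(d) / sqrt(sum(var) / n^2)``.
    A zero standard error is flagged (NaN).
    """
    d = np.atleast_1d(np.asarray(diffs, dtype=float))
    v = np.atleast_1d(np.asarray(variances, dtype=float))
    if np.any(v < 0):
        raise ValueError("variances must be non-negative")
    n = d.shape[0]
    se = np.sqrt(v.sum(axis=0) / n**2)
    mean = d.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, mean / np.where(se > 0, se, 1.0), np.where(mean == 0, 0.0, np.nan))
    return z


def percent_signal_change(beta, baseline_mean: float) -> np.ndarray:
    """``100 * beta / baseline_mean`` (baseline: mean whole-brain response)."""
    if baseline_mean <= 0:
        raise ValueError("baseline mean must be positive")
    return 100.0 * np.asarray(beta, dtype=float) / baseline_mean


@dataclass
class BootstrapResult:
    mean: float
    ci_low: float
    ci_high: float
    distribution: np.ndarray


def multi_subject_bootstrap(
    subject_samples: list[np.ndarray],
    statistic=None,
    n_iter: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Equal-subject-probability bootstrap of a statistic (default: the mean).

    All subjects' examples are concatenated and resampled with replacement with
    per-example probability ``1 / (m |D_i|)``; the statistic of each resample
    forms the bootstrap distribution and the 2.5/97.5 percentiles give the 95%
    CI.  With one subject this reduces to the ordinary bootstrap.
    """
    samples = [np.asarray(s, dtype=float) for s in subject_samples]
    m = len(samples)
    if m < 1 or any(s.size == 0 for s in samples):
        raise ValueError("each subject must contribute at least one example")
    data = np.concatenate(samples)
    probs = np.concatenate([np.full(s.size, 1.0 / (m * s.size)) for s in samples])
    probs = probs / probs.sum()  # exact normalization against rounding
    stat = statistic or (lambda x: x.mean())
    rng = np.random.default_rng(seed)
    n = data.size
    draws = rng.choice(n, size=(n_iter, n), replace=True, p=probs)
    dist = np.array([stat(data[row]) for row in draws])
    return BootstrapResult(
        mean=float(stat(data)),
        ci_low=float(np.percentile(dist, 2.5)),
        ci_high=float(np.percentile(dist, 97.5)),
        distribution=dist,
    )


def responsive_voxels(
    betas: np.ndarray,
    ses: np.ndarray,
    alpha: float = 0.01,
    n_conditions: int | None = None,
) -> np.ndarray:
    """Visually responsive voxels: any condition above baseline.

    One-sided z-test of each condition's beta against zero, Bonferroni
    corrected over the number of conditions; a voxel is retained if any
    condition is significant.  ``betas``/``ses``: (n_conditions, n_voxels).
    """
    betas = np.atleast_2d(np.asarray(betas, dtype=float))
    ses = np.atleast_2d(np.asarray(ses, dtype=float))
    k = n_conditions or betas.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(ses > 0, betas / np.where(ses > 0, ses, 1.0), np.inf * np.sign(betas))
    p = norm.sf(z)
    return (p < alpha / k).any(axis=0)
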