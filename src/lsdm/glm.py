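"""Trial-wise GLM design matrices for the active task, and GLM fitting.

The active-task design deliberately avoids attributing any hemodynamically
delayed signal to the cue period: each cue TR gets its own *impulse* regressor
(active for that single TR only), while a per-trial cue HRF regressor —
convolved with the intravascular-contrast (MION) response, which peaks 2.5-3 s
after onset — is *zeroed at every TR where one of that trial's cue impulses is
active*, so it absorbs only the residual cue signal after the cue period.  A
separate per-trial HRF regressor models the choice TR, and discrete-cosine
drift plus user-supplied confound columns (all HRF-convolved) complete the
design.  After fitting, the coefficient maps of the second and third cue TRs
of each trial become the decoder's input channels (the first cue TR carries
little hemodynamic signal and is excluded by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

__all__ = [
    "HRFParams",
    "hrf_kernel",
    "cosine_drift_basis",
    "build_active_design",
    "fit_glm",
    "GLMFit",
    "extract_trial_betas",
    "TRIAL_N_CUE_TRS",
    "TRIAL_LENGTH_TRS",
]

TRIAL_N_CUE_TRS = 3  # cue shown for 3 TRs (9 s at TR = 3 s)
TRIAL_LENGTH_TRS = 7  # 3 cue + 1 choice + 3 inter-trial TRs


@dataclass(frozen=True)
class HRFParams:
    """Gamma-variate hemodynamic kernel.

    Defaults place the peak at ~2.76 s with FWHM ~3.8 s, matching the
    intravascular-contrast (MION) response peaking between 2.5 and 3 s after
    stimulus onset.  Polarity handling (the MION signal decreases with
    activation) is left to the caller.  ``kind="delta"`` gives an identity
    kernel (convolution is a no-op), useful for limit checks.
    """

    kind: str = "gamma"
    shape: float = 4.7
    scale: float = 0.745
    duration: float = 24.0


def hrf_kernel(tr: float, params: HRFParams | None = None) -> np.ndarray:
    """Sampled unimodal HRF kernel at resolution ``tr`` seconds, unit area.

    The kernel is sampled at ``t = 0, tr, 2*tr, ...`` up to ``params.duration``
    and normalized so that ``kernel.sum() * tr == 1``.  Pass a small ``tr``
    (e.g. 0.1) to inspect the continuous shape; the default gamma-variate peaks
    between 2.5 and 3 s.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    params = params or HRFParams()
    if params.kind == "delta":
        return np.array([1.0 / tr])
    if params.kind != "gamma":
        raise ValueError(f"unknown HRF kind {params.kind!r}")
    t = np.arange(0.0, params.duration + tr / 2, tr)
    k = gamma_dist.pdf(t, a=params.shape, scale=params.scale)
    area = k.sum() * tr
    if area <= 0:
        raise ValueError("degenerate HRF sampling; decrease TR or increase duration")
    return k / area


def cosine_drift_basis(n_trs: int, tr: float, cutoff_hz: float = 0.03) -> np.ndarray:
    """Discrete-cosine drift regressors with all frequencies below ``cutoff_hz``.

    Returns (n_trs, n_basis) columns: a constant column plus DCT-II cosines
    ``cos(pi * m * (n + 1/2) / N)`` of frequency ``m / (2 N tr) < cutoff_hz``.
    Columns are mutually orthogonal.
    """
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    n = np.arange(n_trs)
    cols = [np.ones(n_trs)]
    m = 1
    while m / (2.0 * n_trs * tr) < cutoff_hz and m < n_trs:
        cols.append(np.cos(np.pi * m * (n + 0.5) / n_trs))
        m += 1
    return np.column_stack(cols)


def _convolve_tr(x: np.ndarray, kernel: np.ndarray, tr: float) -> np.ndarray:
    return np.convolve(x, kernel * tr)[: len(x)]


def build_active_design(
    events: pd.DataFrame,
    n_trs: int,
    tr: float = 3.0,
    confounds: np.ndarray | pd.DataFrame | None = None,
    hrf: HRFParams | None = None,
    drift_cutoff_hz: float = 0.03,
    n_cue_trs: int = TRIAL_N_CUE_TRS,
) -> pd.DataFrame:
    """Build the active-task design matrix (rows: TRs; named columns).

    ``events`` needs columns ``trial_id`` and ``onset_tr`` (0-based TR index of
    the first cue TR); the choice TR is ``onset_tr + n_cue_trs``.  Per trial the
    design gets: one impulse column per cue TR, one cue HRF column (boxcar over
    the cue TRs convolved with the HRF, then zeroed wherever that trial has an
    active cue impulse), and one choice HRF column.  Drift columns and
    HRF-convolved confound columns are appended.  Trials must not overlap.
    """
    for col in ("trial_id", "onset_tr"):
        if col not in events.columns:
            raise ValueError(f"events table missing column {col!r}")
    onsets = events["onset_tr"].to_numpy(dtype=int)
    order = np.argsort(onsets)
    if np.any(np.diff(onsets[order]) < TRIAL_LENGTH_TRS - 3):
        # the next trial may begin during the ITI tail, but never before the
        # choice TR has passed
        raise ValueError("overlapping trials in events table")
    if np.any(onsets < 0) or np.any(onsets + n_cue_trs >= n_trs):
        raise ValueError("trial epochs leave the run")

    kernel = hrf_kernel(tr, hrf)
    cols: dict[str, np.ndarray] = {}
    for tid, onset in zip(events["trial_id"], onsets):
        cue_trs = np.arange(onset, onset + n_cue_trs)
        for c, t_idx in enumerate(cue_trs, start=1):
            imp = np.zeros(n_trs)
            imp[t_idx] = 1.0
            cols[f"trial{tid}_cue_tr{c}"] = imp
        boxcar = np.zeros(n_trs)
        boxcar[cue_trs] = 1.0
        cue_hrf = _convolve_tr(boxcar, kernel, tr)
        cue_hrf[cue_trs] = 0.0  # zero wherever a cue impulse of this trial is active
        cols[f"trial{tid}_cue_hrf"] = cue_hrf
        choice_tr = onset + n_cue_trs
        choice = np.zeros(n_trs)
        choice[choice_tr] = 1.0
        cols[f"trial{tid}_choice_hrf"] = _convolve_tr(choice, kernel, tr)

    drift = cosine_drift_basis(n_trs, tr, drift_cutoff_hz)
    for m in range(drift.shape[1]):
        cols[f"drift_{m}"] = drift[:, m]

    if confounds is not None:
        conf = pd.DataFrame(confounds)
        for name in conf.columns:
            cols[f"confound_{name}"] = _convolve_tr(conf[name].to_numpy(dtype=float), kernel, tr)

    return pd.DataFrame(cols)


@dataclass
class GLMFit:
    """Coefficients and per-coefficient variances of a (possibly AR1) GLM."""

    betas: np.ndarray  # (n_regressors, n_targets)
    var: np.ndarray  # (n_regressors, n_targets)
    columns: list[str]
    sigma2: np.ndarray  # (n_targets,)
    rho: np.ndarray | None = None  # per-target AR1 coefficient, if used
    ridged: bool = False  # set when a ridge fallback rescued a deficient design

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(self.var)


def _ar1_transform(x: np.ndarray, rho: float) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    out[0] = np.sqrt(1.0 - rho**2) * x[0]
    out[1:] = x[1:] - rho * x[:-1]
    return out


def fit_glm(
    y: np.ndarray,
    design: pd.DataFrame | np.ndarray,
    ar1: bool = False,
    ridge: float = 0.0,
) -> GLMFit:
    """Fit ``y = X b + e`` by OLS, or by exact AR1-prewhitened GLS.

    ``y`` may be (n_trs,) or (n_trs, n_targets) (e.g. voxels).  With
    ``ar1=True`` the lag-1 autocorrelation is estimated per target from OLS
    residuals and both sides are prewhitened with the exact AR1 square-root
    transform before refitting.  A rank-deficient design raises unless a
    positive ``ridge`` penalty is supplied, in which case the penalized
    solution is returned with ``fit.ridged`` set.
    """
    x = design.to_numpy(dtype=float) if isinstance(design, pd.DataFrame) else np.asarray(design, float)
    columns = (
        list(design.columns)
        if isinstance(design, pd.DataFrame)
        else [f"x{i}" for i in range(x.shape[1])]
    )
    y = np.asarray(y, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    n, p = x.shape
    ridged = False
    if np.linalg.matrix_rank(x) < p:
        if ridge > 0:
            ridged = True
        else:
            raise np.linalg.LinAlgError(
                "design matrix is rank deficient (pass ridge > 0 for a penalized fit)"
            )

    def ols(xm, ym):
        xtx_inv = np.linalg.inv(xm.T @ xm + ridge * np.eye(p))
        b = xtx_inv @ (xm.T @ ym)
        resid = ym - xm @ b
        dof = max(n - p, 1)
        s2 = (resid**2).sum(axis=0) / dof
        v = np.diag(xtx_inv)[:, None] * s2[None, :]
        return b, v, s2, resid

    betas, var, s2, resid = ols(x, y)
    rho = None
    if ar1:
        num = (resid[1:] * resid[:-1]).sum(axis=0)
        den = (resid[:-1] ** 2).sum(axis=0)
        rho = np.clip(np.where(den > 0, num / np.maximum(den, 1e-30), 0.0), -0.99, 0.99)
        betas = np.empty_like(betas)
        var = np.empty_like(var)
        s2 = np.empty(y.shape[1])
        for v_i in range(y.shape[1]):
            xw = _ar1_transform(x, rho[v_i])
            yw = _ar1_transform(y[:, v_i], rho[v_i])
            b, vv, ss, _ = ols(xw, yw[:, None])
            betas[:, v_i] = b[:, 0]
            var[:, v_i] = vv[:, 0]
            s2[v_i] = ss[0]
    if squeeze:
        betas, var = betas[:, 0:1], var[:, 0:1]
    return GLMFit(betas=betas, var=var, columns=columns, sigma2=s2, rho=rho, ridged=ridged)


def extract_trial_betas(
    fit: GLMFit,
    events: pd.DataFrame,
    cue_channels: tuple[int, ...] = (2, 3),
    include_tr1: bool = False,
) -> np.ndarray:
    """Per-trial decoder inputs from the cue-TR impulse coefficients.

    Returns (n_trials, n_channels, n_targets): by default the coefficients of
    the second and third cue TRs (channels 2 and 3).  The first cue TR carries
    little hemodynamically delayed signal; requesting it requires the explicit
    ``include_tr1`` opt-in.
    """
    if 1 in cue_channels and not include_tr1:
        raise ValueError(
            "cue TR 1 is excluded from decoding by default; pass include_tr1=True to override"
        )
    col_index = {name: i for i, name in enumerate(fit.columns)}
    out = []
    for tid in events["trial_id"]:
        chans = []
        for c in cue_channels:
            name = f"trial{tid}_cue_tr{c}"
            if name not in col_index:
                raise KeyError(f"design has no regressor {name!r}")
            chans.append(fit.betas[col_index[name]])
        out.append(np.stack(chans))
    return np.stack(out)
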