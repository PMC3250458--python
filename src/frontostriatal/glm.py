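"""First- and second-level GLM machinery for the saccade tasks.

Design matrices convolve event delta trains or block box-cars with the
canonical double-gamma hemodynamic response function.  Fitting adds a
discrete-cosine high-pass basis (cutoff 128 s), estimates a per-voxel AR(1)
residual autocorrelation in a first OLS pass, pre-whitens data and design,
and refits.  Contrast t-maps and a random-effects one-sample group t-test
complete the inference chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, special, stats

from .designs import AMPLITUDES, BlockSchedule, EventSchedule, SIDES, TASKS

__all__ = [
    "DesignMatrix", "GLMFit", "ContrastMap", "double_gamma_hrf", "hrf_regressor",
    "build_task1_design", "build_block_design", "dct_highpass_basis",
    "fit_prewhitened", "contrast_t", "group_ttest", "smooth_fwhm",
]

TASK1_TARGET_LABELS = [f"target_{s}_{a}_{t}" for t in TASKS for s in SIDES for a in AMPLITUDES]
TASK1_RETURN_LABELS = [f"return_{s}_{a}" for s in SIDES for a in AMPLITUDES]
TASK1_CUE_LABELS = ["cue_anti", "cue_pro"]


@dataclass
class DesignMatrix:
    """Time x regressor matrix with labels and per-column provenance."""

    matrix: np.ndarray
    labels: list[str]
    kinds: list[str]  # event | block | nuisance_physio | baseline | highpass
    tr: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.labels) or len(self.labels) != len(self.kinds):
            raise ValueError("labels/kinds must match the number of columns")
        if "baseline" not in self.kinds:
            raise ValueError("design must contain a baseline column")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def columns_of_kind(self, kind: str) -> list[int]:
        return [i for i, k in enumerate(self.kinds) if k == kind]

    def contrast_vector(self, plus, minus=()) -> np.ndarray:
        """Unit-weighted contrast from label sets (averaged within each set)."""
        if isinstance(plus, str):
            plus = [plus]
        if isinstance(minus, str):
            minus = [minus]
        c = np.zeros(len(self.labels))
        for lab in plus:
            c[self.labels.index(lab)] += 1.0 / len(plus)
        for lab in minus:
            c[self.labels.index(lab)] -= 1.0 / len(minus)
        return c

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class GLMFit:
    """Per-voxel pre-whitened GLM estimates."""

    betas: np.ndarray              # (n_regressors, n_voxels)
    residual_variance: np.ndarray  # (n_voxels,)
    ar1_rho: np.ndarray            # (n_voxels,) quantized AR(1) coefficients
    df_effective: float
    design: DesignMatrix           # includes appended high-pass columns

    def __post_init__(self) -> None:
        if np.any(self.residual_variance < -1e-12):
            raise ValueError("negative residual variance")
        if np.any(np.abs(self.ar1_rho) >= 1):
            raise ValueError("|AR(1) rho| must be < 1")


@dataclass
class ContrastMap:
    """A contrast with its voxel-wise t statistic."""

    contrast_vector: np.ndarray
    t: np.ndarray
    effect: np.ndarray
    df: float


def double_gamma_hrf(
    t: np.ndarray,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma HRF, normalized to unit peak amplitude.

    Response gamma with shape *peak_s* (mode at peak_s - 1 s), undershoot
    gamma with shape *undershoot_s*, mixed at *ratio*; unit dispersion
    (scale 1 s) for both.  Normalization uses the function's true peak (on
    a dense internal grid), so samples on any grid are consistent.
    """
    t = np.asarray(t, dtype=float)

    def raw(u):
        return stats.gamma.pdf(u, a=peak_s) - ratio * stats.gamma.pdf(u, a=undershoot_s)

    h = raw(t)
    h[t < 0] = 0.0
    peak = raw(np.arange(0.0, peak_s + undershoot_s, 1e-3)).max()
    return h / peak


def hrf_regressor(
    onsets: np.ndarray,
    n_volumes: int,
    tr: float,
    durations: np.ndarray | float = 0.0,
    oversample: int = 16,
    hrf_length_s: float = 32.0,
) -> np.ndarray:
    """HRF-convolved regressor sampled at volume onsets.

    A delta train (or box-car, for positive *durations*) is built on a fine
    grid of tr/oversample, convolved with the canonical HRF, and sampled at
    volume times i*tr.  An empty onset list yields an all-zero column with
    a warning.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    run_length = n_volumes * tr
    if onsets.size == 0:
        warnings.warn("no events for regressor: returning an all-zero column")
        return np.zeros(n_volumes)
    if np.any(onsets < 0) or np.any(onsets >= run_length):
        raise ValueError("event onsets must lie within the run")
    durations = np.broadcast_to(np.atleast_1d(np.asarray(durations, dtype=float)), onsets.shape)
    dt = tr / oversample
    n_fine = int(np.ceil(run_length / dt)) + 1
    train = np.zeros(n_fine)
    for o, d in zip(onsets, durations):
        i0 = int(round(o / dt))
        if d <= 0:
            train[i0] += 1.0
        else:
            i1 = min(n_fine, int(round((o + d) / dt)))
            train[i0:max(i1, i0 + 1)] += 1.0
    kernel = double_gamma_hrf(np.arange(0, hrf_length_s, dt))
    conv = np.convolve(train, kernel)[:n_fine]
    vol_idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)
    return conv[vol_idx]


def _append_physio(cols, labels, kinds, physio_matrix, n_volumes):
    if physio_matrix is None:
        return
    pm = physio_matrix.to_numpy() if hasattr(physio_matrix, "to_numpy") else np.asarray(physio_matrix)
    if pm.shape[0] != n_volumes:
        raise ValueError("physio matrix rows must equal the number of volumes")
    names = list(physio_matrix.columns) if hasattr(physio_matrix, "columns") else [
        f"physio_{i}" for i in range(pm.shape[1])
    ]
    for j, name in enumerate(names):
        cols.append(pm[:, j])
        labels.append(name)
        kinds.append("nuisance_physio")


def build_task1_design(
    schedule: EventSchedule,
    n_volumes: int,
    tr: float,
    model: int = 1,
    physio_matrix=None,
) -> DesignMatrix:
    """Event-related design for task 1.

    Model 1: 8 peripheral-target regressors (pro/anti x left/right x
    small/large) plus 4 return regressors (side x amplitude).  Model 2 adds
    2 cue regressors (anti, pro) for the preparatory-set analysis.  Physio
    nuisance columns and a baseline complete the matrix.
    """
    if model not in (1, 2):
        raise ValueError("model must be 1 or 2")
    event_labels = TASK1_TARGET_LABELS + TASK1_RETURN_LABELS
    if model == 2:
        event_labels = event_labels + TASK1_CUE_LABELS
    cols, labels, kinds = [], [], []
    for lab in event_labels:
        onsets = schedule.onsets(lab)
        onsets = onsets[(onsets >= 0) & (onsets < n_volumes * tr)]
        if onsets.size == 0:
            warnings.warn(f"condition {lab} absent from schedule: zero column")
            col = np.zeros(n_volumes)
        else:
            col = hrf_regressor(onsets, n_volumes, tr)
        cols.append(col)
        labels.append(lab)
        kinds.append("event")
    _append_physio(cols, labels, kinds, physio_matrix, n_volumes)
    cols.append(np.ones(n_volumes))
    labels.append("baseline")
    kinds.append("baseline")
    return DesignMatrix(np.column_stack(cols), labels, kinds, tr)


def build_block_design(
    schedule: BlockSchedule,
    active_labels,
    n_volumes: int,
    tr: float,
    physio_matrix=None,
) -> DesignMatrix:
    """Blocked design: one HRF-convolved box-car per active block label."""
    if isinstance(active_labels, str):
        active_labels = [active_labels]
    known = set(schedule.blocks["trial_type"])
    unknown = [lab for lab in active_labels if lab not in known]
    if unknown:
        raise ValueError(f"labels not in schedule: {unknown}")
    cols, labels, kinds = [], [], []
    for lab in active_labels:
        sel = schedule.blocks[schedule.blocks["trial_type"] == lab]
        col = hrf_regressor(
            sel["onset"].to_numpy(), n_volumes, tr, durations=sel["duration"].to_numpy()
        )
        cols.append(col)
        labels.append(lab)
        kinds.append("block")
    if not cols:
        warnings.warn("no task columns in block design")
    _append_physio(cols, labels, kinds, physio_matrix, n_volumes)
    cols.append(np.ones(n_volumes))
    labels.append("baseline")
    kinds.append("baseline")
    return DesignMatrix(np.column_stack(cols), labels, kinds, tr)


def dct_highpass_basis(n_volumes: int, tr: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine regressors spanning drifts with period > cutoff_s."""
    if cutoff_s <= 0:  # filtering disabled
        return np.zeros((n_volumes, 0))
    n_basis = int(np.floor(2.0 * n_volumes * tr / cutoff_s))
    i = np.arange(n_volumes)
    basis = [
        np.sqrt(2.0 / n_volumes) * np.cos(np.pi * (2 * i + 1) * k / (2 * n_volumes))
        for k in range(1, n_basis + 1)
    ]
    return np.column_stack(basis) if basis else np.zeros((n_volumes, 0))


def _check_rank(X: np.ndarray, labels: list[str]) -> None:
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = X.shape[0] * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = [labels[i] for i in np.where(diag <= tol)[0]]
        raise ValueError(f"rank-deficient design; dependent columns include: {bad or labels}")


def _projection_lag1_bias(X: np.ndarray) -> float:
    """E[lag-1 autocorrelation] of OLS residuals of white noise.

    For residuals r = M eps with M the residual-forming matrix,
    E[r'Ar] / E[r'r] = tr(MAM) / tr(M) with A the symmetrized lag-1
    operator; subtracting this removes the projection-induced downward
    bias of the AR(1) estimate.
    """
    n = X.shape[0]
    Q, _ = np.linalg.qr(X)
    # tr(M) = n - p; tr(MAM) = tr(A) - 2 tr(Q'AQ) + tr(Q'AQQ'Q) via M = I - QQ'
    AQ = np.empty_like(Q)
    AQ[0] = 0.5 * Q[1]
    AQ[-1] = 0.5 * Q[-2]
    AQ[1:-1] = 0.5 * (Q[:-2] + Q[2:])
    # tr(MAM) = tr(A) - 2 tr(Q'AQ) + tr(Q'AQ) = -tr(Q'AQ), since tr(A) = 0
    tr_MAM = -np.trace(Q.T @ AQ)
    return float(tr_MAM / (n - Q.shape[1]))


def _whitening_groups(rho: np.ndarray, step: float = 0.01) -> np.ndarray:
    """Quantize per-voxel rho so voxels sharing a value whiten together."""
    return np.round(np.clip(rho, -0.99, 0.99) / step) * step


def fit_prewhitened(
    Y: np.ndarray,
    X: DesignMatrix,
    hp_cutoff_s: float = 128.0,
    rho_step: float = 0.01,
) -> GLMFit:
    """Two-pass AR(1) pre-whitened GLM fit.

    *Y* is (n_volumes, n_voxels).  Discrete-cosine high-pass columns for
    periods above *hp_cutoff_s* are appended to the design.  A first OLS
    pass estimates each voxel's lag-1 residual autocorrelation; data and
    design are then whitened per voxel (rho quantized to *rho_step* so
    voxels with equal rho share one solve) and refit.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != X.n_volumes:
        raise ValueError("Y rows must equal design rows")
    hp = dct_highpass_basis(X.n_volumes, X.tr, hp_cutoff_s)
    Xfull = DesignMatrix(
        np.column_stack([X.matrix, hp]) if hp.size else X.matrix,
        X.labels + [f"highpass_{k+1}" for k in range(hp.shape[1])],
        X.kinds + ["highpass"] * hp.shape[1],
        X.tr,
    )
    M = Xfull.matrix
    _check_rank(M, Xfull.labels)
    n, p = M.shape
    # first pass: OLS residual lag-1 autocorrelation, corrected for the
    # spurious autocorrelation the residual-forming projection induces
    # (expected lag-1 autocorrelation of projected white noise)
    beta0, *_ = np.linalg.lstsq(M, Y, rcond=None)
    resid = Y - M @ beta0
    denom = np.sum(resid**2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, np.sum(resid[1:] * resid[:-1], axis=0) / denom, 0.0)
    rho = rho - _projection_lag1_bias(M)
    rho_q = _whitening_groups(rho, rho_step)

    betas = np.empty((p, Y.shape[1]))
    rss = np.empty(Y.shape[1])
    for r in np.unique(rho_q):
        idx = np.where(rho_q == r)[0]
        Wx = _whiten(M, r)
        Wy = _whiten(Y[:, idx], r)
        b, *_ = np.linalg.lstsq(Wx, Wy, rcond=None)
        betas[:, idx] = b
        rss[idx] = np.sum((Wy - Wx @ b) ** 2, axis=0)
    df = float(n - p)
    return GLMFit(
        betas=betas,
        residual_variance=rss / df,
        ar1_rho=rho_q,
        df_effective=df,
        design=Xfull,
    )


def _whiten(A: np.ndarray, rho: float) -> np.ndarray:
    """AR(1) whitening: first row scaled, then first differences with rho."""
    W = np.empty_like(A, dtype=float)
    W[0] = np.sqrt(max(1.0 - rho**2, 1e-12)) * A[0]
    W[1:] = A[1:] - rho * A[:-1]
    return W


def contrast_t(fit: GLMFit, c: np.ndarray) -> ContrastMap:
    """Voxel-wise t statistic for contrast *c* on the whitened design.

    *c* may cover only the pre-high-pass regressors; it is zero-padded over
    the appended high-pass columns.
    """
    c = np.asarray(c, dtype=float)
    p = fit.design.matrix.shape[1]
    if c.size < p:
        c = np.concatenate([c, np.zeros(p - c.size)])
    if c.size != p:
        raise ValueError("contrast length does not match the design")
    if not np.any(c):
        raise ValueError("all-zero contrast vector")
    effect = c @ fit.betas
    varfac = np.empty_like(fit.residual_variance)
    for r in np.unique(fit.ar1_rho):
        idx = fit.ar1_rho == r
        Wx = _whiten(fit.design.matrix, r)
        xtx_inv = np.linalg.pinv(Wx.T @ Wx)
        varfac[idx] = c @ xtx_inv @ c
    with np.errstate(invalid="ignore", divide="ignore"):
        t = effect / np.sqrt(fit.residual_variance * varfac)
    t[~np.isfinite(t)] = np.nan
    return ContrastMap(contrast_vector=c, t=t, effect=effect, df=fit.df_effective)


def group_ttest(contrast_images: np.ndarray) -> ContrastMap:
    """Random-effects one-sample t-test across participants.

    *contrast_images* is (n_participants, ...); zero-variance voxels are
    masked to NaN.  df = n - 1.
    """
    imgs = np.asarray(contrast_images, dtype=float)
    if imgs.shape[0] < 2:
        raise ValueError("need >= 2 participants for a group test")
    n = imgs.shape[0]
    mean = imgs.mean(axis=0)
    sd = imgs.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[sd == 0] = np.nan
    return ContrastMap(contrast_vector=np.ones(n) / n, t=t, effect=mean, df=float(n - 1))


def smooth_fwhm(data: np.ndarray, voxel_size_mm, fwhm_mm: float) -> np.ndarray:
    """Separable Gaussian smoothing at the given FWHM (mm).

    Periodic boundary handling keeps the normalized kernel mass inside the
    grid, so the image mean is preserved exactly.  4-D inputs are smoothed
    volume by volume (no temporal smoothing).
    """
    voxel_size_mm = np.broadcast_to(np.atleast_1d(voxel_size_mm).astype(float), (3,))
    sigma_vox = (fwhm_mm / np.sqrt(8 * np.log(2))) / voxel_size_mm
    data = np.asarray(data, dtype=float)
    if data.ndim == 3:
        return ndimage.gaussian_filter(data, sigma=sigma_vox, mode="wrap")
    if data.ndim == 4:
        sigma4 = tuple(sigma_vox) + (0.0,)
        return ndimage.gaussian_filter(data, sigma=sigma4, mode="wrap")
    raise ValueError("expected a 3-D or 4-D array")
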