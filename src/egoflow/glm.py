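"""First-level GLM: design matrix with canonical HRF regressors and a
DCT high-pass set, AR(1) prewhitening, F contrasts, FDR plus
cluster-extent thresholding, and percent signal change.

Estimation is the standard two-pass scheme: ordinary least squares,
pooled lag-1 autocorrelation of the residuals (one rho per run, shared
by all voxels), AR(1) whitening of data and design, refit.  This is a
documented approximation to full ReML with an AR(1) covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import f as f_dist
from statsmodels.stats.multitest import multipletests

from .design import TrialSequence, BlockDesign
from .synth_bold import HRFModel, condition_regressors, unit_trial_regressor_peak

__all__ = [
    "DesignMatrix",
    "GLMFit",
    "StatMap",
    "dct_highpass_basis",
    "build_design_matrix",
    "fit_glm",
    "f_contrast",
    "motion_vs_static_contrast",
    "fdr_cluster_threshold",
    "percent_signal_change",
    "CONNECTIVITY_STRUCTS",
]


@dataclass
class DesignMatrix:
    values: np.ndarray  # (n_volumes, n_regressors)
    labels: list[str]
    TR: float
    highpass_cutoff: float = 128.0
    task_labels: list[str] = field(default_factory=list)

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    def column(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class GLMFit:
    betas: np.ndarray  # (n_regressors,) or (n_voxels, n_regressors)
    residual_variance: np.ndarray | float
    dof: float
    rho_hat: float
    whitened: bool
    labels: list[str]
    # whitened design pieces needed for contrasts
    xtx_inv: np.ndarray = None

    def beta(self, label: str) -> np.ndarray | float:
        idx = self.labels.index(label)
        b = np.atleast_2d(self.betas)[:, idx]
        return float(b[0]) if np.ndim(self.betas) == 1 else b


@dataclass
class StatMap:
    statistic: np.ndarray  # F per voxel (any shape)
    p: np.ndarray
    dof: tuple[float, float]
    threshold_meta: dict = field(default_factory=dict)


def dct_highpass_basis(n: int, TR: float, cutoff: float = 128.0) -> np.ndarray:
    """Orthonormal DCT-II drift regressors with periods above ``cutoff``
    seconds: k = 1 .. floor(2*n*TR/cutoff) (constant term excluded)."""
    order = int(np.floor(2.0 * n * TR / cutoff))
    t = np.arange(n)
    cols = [
        np.sqrt(2.0 / n) * np.cos(np.pi * k * (2 * t + 1) / (2.0 * n))
        for k in range(1, order + 1)
    ]
    return np.stack(cols, axis=1) if cols else np.empty((n, 0))


def build_design_matrix(
    design: TrialSequence | BlockDesign,
    hrf: HRFModel,
    n_volumes: int | None = None,
    highpass: float = 128.0,
) -> DesignMatrix:
    """Design matrix: one HRF-convolved regressor per modeled condition
    (null/fixation is the implicit baseline), DCT high-pass set, and a
    constant column."""
    n_volumes = n_volumes or design.n_volumes
    regs = condition_regressors(design, hrf, n_volumes)
    task_labels = sorted(regs)
    dct = dct_highpass_basis(n_volumes, design.TR, highpass)
    cols = [regs[c] for c in task_labels]
    cols += [dct[:, i] for i in range(dct.shape[1])]
    cols.append(np.ones(n_volumes))
    labels = (
        task_labels
        + [f"dct_{i + 1}" for i in range(dct.shape[1])]
        + ["constant"]
    )
    X = np.stack(cols, axis=1)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return DesignMatrix(X, labels, design.TR, highpass, task_labels)


def _ols(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pinv = np.linalg.pinv(X)
    betas = Y @ pinv.T
    resid = Y - betas @ X.T
    return betas, resid, pinv


def _pooled_rho(resid: np.ndarray) -> float:
    num = float(np.sum(resid[:, 1:] * resid[:, :-1]))
    den = float(np.sum(resid**2))
    return 0.0 if den == 0 else num / den


def _bias_corrected_rho(r_obs: float, X: np.ndarray) -> float:
    """Solve for the AR(1) rho whose expected OLS-residual lag-1
    autocorrelation equals the observed one.

    Projection onto the residual space of X biases the raw estimate
    (toward negative values for designs with many regressors); under an
    AR(1) process with parameter rho,
    E[sum e_t e_{t-1}] / E[sum e_t^2] = tr(M S M V(rho)) / tr(M V(rho))
    with M the residual maker and S the symmetrized lag operator.
    """
    from scipy.optimize import brentq

    n = X.shape[0]
    if n > 2000:
        # projection bias ~ p/n is negligible and the trace correction
        # would need O(n^2) memory
        return float(np.clip(r_obs, -0.98, 0.98))
    M = np.eye(n) - X @ np.linalg.pinv(X)
    S = np.zeros((n, n))
    idx = np.arange(n - 1)
    S[idx, idx + 1] = 0.5
    S[idx + 1, idx] = 0.5
    MSM = M @ S @ M
    lags = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))

    def expected_r(rho: float) -> float:
        V = rho**lags if rho != 0 else np.eye(n)
        return float(np.trace(MSM @ V) / np.trace(M @ V))

    def objective(rho: float) -> float:
        return expected_r(rho) - r_obs

    lo, hi = -0.98, 0.98
    if objective(lo) * objective(hi) > 0:  # observed r outside the model range
        return float(np.clip(r_obs, lo, hi))
    return float(brentq(objective, lo, hi, xtol=1e-6))


def _whiten(A: np.ndarray, rho: float) -> np.ndarray:
    """Apply the AR(1) whitening transform along the time axis (rows of
    a design, last axis of data)."""
    W = np.empty_like(np.asarray(A, dtype=float))
    W[0] = np.sqrt(1 - rho**2) * A[0]
    W[1:] = A[1:] - rho * A[:-1]
    return W


def fit_glm(Y: np.ndarray, X: DesignMatrix, rho: float | None = None) -> GLMFit:
    """Fit the GLM voxel-by-voxel with AR(1) prewhitening.

    ``Y`` may be a single series (n_volumes,), a matrix
    (n_voxels, n_volumes), or a 4-D volume (..., n_volumes); the fit is
    idempotent and keeps no hidden state.  ``rho`` fixes the whitening
    autocorrelation instead of estimating it from the pooled residuals.
    """
    Xv = X.values
    orig_shape = Y.shape
    Y2 = np.atleast_2d(Y.reshape(-1, orig_shape[-1]) if Y.ndim > 2 else Y)
    if Y2.shape[1] != Xv.shape[0]:
        raise ValueError("time dimension of Y does not match the design")

    if rho is None:
        _, resid, _ = _ols(Y2, Xv)
        # machine-precision residuals (perfect noiseless fit) carry no
        # autocorrelation information
        if float((resid**2).sum()) < 1e-16 * float((Y2**2).sum()):
            rho = 0.0
        else:
            rho = _bias_corrected_rho(_pooled_rho(resid), Xv)

    Xw = _whiten(Xv, rho)
    Yw = _whiten(Y2.T, rho).T
    betas, resid_w, _ = _ols(Yw, Xw)
    dof = Xw.shape[0] - np.linalg.matrix_rank(Xw)
    sigma2 = (resid_w**2).sum(axis=1) / dof
    # zero out per-voxel variances at rounding-error level so that
    # noiseless fits report exact zeros instead of ~1e-22 garbage
    floor = 1e-16 * (Yw**2).mean(axis=1)
    sigma2 = np.where(sigma2 <= floor, 0.0, sigma2)
    xtx_inv = np.linalg.inv(Xw.T @ Xw)

    single = Y.ndim == 1
    return GLMFit(
        betas=betas[0] if single else betas.reshape(orig_shape[:-1] + (Xv.shape[1],)),
        residual_variance=float(sigma2[0]) if single else sigma2.reshape(orig_shape[:-1]),
        dof=float(dof),
        rho_hat=rho,
        whitened=True,
        labels=list(X.labels),
        xtx_inv=xtx_inv,
    )


def motion_vs_static_contrast(X: DesignMatrix) -> np.ndarray:
    """The five motion-minus-static rows of the joint F contrast."""
    motion = [c for c in X.task_labels if c != "static"]
    rows = np.zeros((len(motion), len(X.labels)))
    j_static = X.column("static")
    for i, cond in enumerate(motion):
        rows[i, X.column(cond)] = 1.0
        rows[i, j_static] = -1.0
    return rows


def f_contrast(fit: GLMFit, X: DesignMatrix, contrast: np.ndarray) -> StatMap:
    """Joint F test that all contrast rows of effects are zero."""
    C = np.atleast_2d(np.asarray(contrast, dtype=float))
    if C.shape[1] != len(fit.labels):
        raise ValueError("contrast width does not match the design")
    q = np.linalg.matrix_rank(C)
    betas = np.atleast_2d(fit.betas.reshape(-1, len(fit.labels)))
    sigma2 = np.atleast_1d(np.asarray(fit.residual_variance, dtype=float)).ravel()
    cb = betas @ C.T  # (n_voxels, q)
    middle = np.linalg.inv(C @ fit.xtx_inv @ C.T)
    quad = np.einsum("vi,ij,vj->v", cb, middle, cb)
    with np.errstate(divide="ignore", invalid="ignore"):
        # zero residual variance: infinite F for a real effect, but a
        # numerically null effect (e.g. a constant voxel) is no effect
        F = np.where(
            sigma2 > 0, quad / (q * sigma2), np.where(quad > 1e-8, np.inf, 0.0)
        )
    p = f_dist.sf(F, q, fit.dof)
    shape = np.shape(fit.residual_variance) or ()
    return StatMap(
        statistic=F.reshape(shape) if shape else float(F[0]),
        p=p.reshape(shape) if shape else float(p[0]),
        dof=(float(q), fit.dof),
    )


CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def fdr_cluster_threshold(
    stat_map: StatMap,
    q: float = 0.05,
    extent: int = 10,
    connectivity: int = 6,
) -> np.ndarray:
    """Benjamini-Hochberg FDR at level ``q`` on the voxelwise p-values,
    then removal of connected components smaller than ``extent`` voxels
    (face connectivity by default).  Returns a boolean mask; an empty
    result is a legitimate outcome."""
    p = np.asarray(stat_map.p, dtype=float)
    reject, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    mask = reject.reshape(p.shape)
    stat_map.threshold_meta = {"q": q, "extent": extent, "connectivity": connectivity}
    if mask.ndim != 3:
        return mask
    labeled, n = ndimage.label(mask, structure=CONNECTIVITY_STRUCTS[connectivity])
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= extent) + 1
    return np.isin(labeled, keep)


def percent_signal_change(
    fit: GLMFit,
    condition: str,
    run_mean: float,
    hrf: HRFModel | None = None,
    trial_duration: float = 3.0,
) -> float | np.ndarray:
    """Condition amplitude as percent of the run-mean signal, scaled by
    the peak of a unit-amplitude single-trial regressor."""
    if run_mean <= 0:
        raise ValueError("run_mean must be positive")
    peak = unit_trial_regressor_peak(hrf or HRFModel(), trial_duration)
    return 100.0 * fit.beta(condition) * peak / run_mean
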