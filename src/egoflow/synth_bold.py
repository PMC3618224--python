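"""Synthetic BOLD generator with known ground truth.

Produces ROI-level time series and 4-D volumes in which each condition's
response amplitude is planted, so that the downstream GLM / ROI /
coherence chain can be validated by parameter recovery.  The noise model
is AR(1) serial correlation plus a slow cosine drift; per-voxel noise is
independent (the synthetic layouts are spheres, and spatial smoothing of
real data is out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.signal import lfilter
from scipy.stats import gamma as gamma_dist

from .design import BlockDesign, TrialSequence

__all__ = [
    "HRFModel",
    "NoiseModel",
    "ROISpec",
    "SyntheticVolume",
    "canonical_hrf",
    "condition_regressors",
    "unit_trial_regressor_peak",
    "ar1_noise",
    "simulate_roi_timeseries",
    "simulate_volume",
    "save_volume",
    "load_volume",
]


@dataclass(frozen=True)
class HRFModel:
    """Canonical double-gamma hemodynamic response.

    h(t) = pdf_gamma(t; peak_delay/peak_disp, peak_disp)
         - pdf_gamma(t; under_delay/under_disp, under_disp) / ratio

    peak-normalized to 1.  Defaults (delays 6/16 s, dispersions 1/1,
    ratio 6, 32-s support) are the de-facto canonical parameters.
    """

    TR: float = 2.0
    peak_delay: float = 6.0
    under_delay: float = 16.0
    peak_disp: float = 1.0
    under_disp: float = 1.0
    ratio: float = 6.0
    length: float = 32.0


@dataclass(frozen=True)
class NoiseModel:
    """AR(1) noise + slow cosine drift around a constant baseline.

    ``sigma`` is the marginal (stationary) standard deviation of the
    AR(1) process; ``rho`` its lag-1 autocorrelation.  The drift is a
    single cosine with period ``drift_period`` (> 128 s, so that the
    high-pass filter in the GLM should remove it).
    """

    sigma: float = 1.0
    rho: float = 0.3
    drift_amplitude: float = 0.0
    drift_period: float = 256.0
    #: None -> drawn uniformly per simulated run (scanner drift is not
    #: phase-locked to the paradigm); set a float for deterministic tests
    drift_phase: float | None = None
    baseline: float = 100.0

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class ROISpec:
    """Ground-truth spherical ROI: center/radius in world mm, and the
    planted response amplitude per condition (baseline 0)."""

    name: str
    hemisphere: str  # "left" | "right"
    amplitudes: dict[str, float]
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius_mm: float = 6.0
    ipsilateral_responsive: bool = True

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")


@dataclass
class SyntheticVolume:
    """4-D synthetic scan with its affine and ground-truth layout."""

    data: np.ndarray  # (x, y, z, t)
    affine: np.ndarray  # 4x4, mm
    ground_truth: list[ROISpec] = field(default_factory=list)
    seed: int | None = None

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return tuple(np.abs(np.diag(self.affine)[:3]))

    def roi_mask(self, spec: ROISpec) -> np.ndarray:
        return sphere_mask(self.data.shape[:3], self.affine, spec.center_mm, spec.radius_mm)


def _hrf_fine(model: HRFModel, dt: float) -> tuple[np.ndarray, np.ndarray]:
    t = np.arange(0.0, model.length + dt / 2, dt)
    peak = gamma_dist.pdf(t, model.peak_delay / model.peak_disp, scale=model.peak_disp)
    under = gamma_dist.pdf(t, model.under_delay / model.under_disp, scale=model.under_disp)
    h = peak - under / model.ratio
    return t, h / h.max()


def canonical_hrf(model: HRFModel | None = None, dt: float | None = None) -> np.ndarray:
    """Sample the canonical HRF kernel at ``dt`` (default: the model's
    TR), peak-normalized to 1 on a fine grid."""
    model = model or HRFModel()
    if model.TR <= 0:
        raise ValueError("TR must be positive")
    dt = dt or model.TR
    _, h_fine = _hrf_fine(model, 0.01)
    t = np.arange(0.0, model.length + dt / 2, dt)
    idx = np.round(t / 0.01).astype(int)
    return h_fine[idx]


def _event_list(design: TrialSequence | BlockDesign) -> list[tuple[float, float, str]]:
    """(onset, duration, condition) of modeled (non-null) events."""
    if isinstance(design, TrialSequence):
        return [
            (t.onset, t.duration, t.condition)
            for t in design.trials
            if t.condition != "null"
        ]
    return [(o, d, design.on_condition) for o, d in design.on_blocks()]


def condition_regressors(
    design: TrialSequence | BlockDesign,
    hrf: HRFModel,
    n_volumes: int,
    dt: float = 0.01,
) -> dict[str, np.ndarray]:
    """One regressor per modeled condition: the boxcar event train
    convolved with the canonical HRF on a fine grid, sampled at volume
    acquisition times (null/fixation stays unmodeled)."""
    TR = design.TR if hasattr(design, "TR") else hrf.TR
    t_end = n_volumes * TR
    n_fine = int(round(t_end / dt)) + 1
    _, kernel = _hrf_fine(hrf, dt)
    conditions: dict[str, np.ndarray] = {}
    for onset, duration, cond in _event_list(design):
        box = conditions.setdefault(cond, np.zeros(n_fine))
        i0 = int(round(onset / dt))
        i1 = min(int(round((onset + duration) / dt)), n_fine)
        box[i0:i1] = 1.0
    vol_idx = np.round(np.arange(n_volumes) * TR / dt).astype(int)
    out = {}
    for cond, box in conditions.items():
        conv = np.convolve(box, kernel)[:n_fine] * dt
        out[cond] = conv[vol_idx]
    return out


def unit_trial_regressor_peak(
    hrf: HRFModel, duration: float = 3.0, dt: float = 0.01
) -> float:
    """Peak of the regressor of a single unit-amplitude trial of the
    given duration — the scaling used for percent signal change."""
    n_fine = int(round((duration + hrf.length) / dt)) + 1
    box = np.zeros(n_fine)
    box[: int(round(duration / dt))] = 1.0
    _, kernel = _hrf_fine(hrf, dt)
    return float((np.convolve(box, kernel)[:n_fine] * dt).max())


def ar1_noise(
    n: int, sigma: float, rho: float, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Stationary AR(1) noise with marginal s.d. ``sigma`` and lag-1
    autocorrelation ``rho``; shape (n,) or (size, n)."""
    shape = (n,) if size is None else (size, n)
    if sigma == 0:
        return np.zeros(shape)
    innov = rng.standard_normal(shape) * sigma * np.sqrt(1.0 - rho**2)
    # seed the recursion from the stationary distribution
    x_prev = rng.standard_normal(shape[:-1] + (1,)) * sigma
    out, _ = lfilter([1.0], [1.0, -rho], innov, axis=-1, zi=rho * x_prev)
    return out


def _drift(
    noise: NoiseModel, n_volumes: int, TR: float, phase: float = 0.0
) -> np.ndarray:
    t = np.arange(n_volumes) * TR
    return noise.drift_amplitude * np.cos(2 * np.pi * t / noise.drift_period + phase)


def _draw_drift_phase(noise: NoiseModel, rng: np.random.Generator) -> float:
    if noise.drift_phase is not None:
        return noise.drift_phase
    return float(rng.uniform(0.0, 2 * np.pi))


def simulate_roi_timeseries(
    design: TrialSequence | BlockDesign,
    spec: ROISpec,
    noise: NoiseModel,
    hrf: HRFModel,
    seed: int,
    n_volumes: int | None = None,
) -> np.ndarray:
    """One ROI-level time series: baseline + drift + sum of planted
    condition responses + AR(1) noise."""
    if hasattr(design, "TR") and design.TR != hrf.TR:
        raise ValueError("design and HRF must share the same TR")
    n_volumes = n_volumes or design.n_volumes
    regs = condition_regressors(design, hrf, n_volumes)
    rng = np.random.default_rng(seed)
    y = np.full(n_volumes, noise.baseline, dtype=float)
    y += _drift(noise, n_volumes, hrf.TR, _draw_drift_phase(noise, rng))
    for cond, reg in regs.items():
        y += spec.amplitudes.get(cond, 0.0) * reg
    y += ar1_noise(n_volumes, noise.sigma, noise.rho, rng)
    return y


def sphere_mask(
    shape: tuple[int, int, int],
    affine: np.ndarray,
    center_mm: tuple[float, float, float],
    radius_mm: float,
) -> np.ndarray:
    """Boolean mask of voxels whose world coordinates lie within
    ``radius_mm`` of ``center_mm``."""
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
    world = vox @ affine.T
    d2 = ((world[..., :3] - np.asarray(center_mm)) ** 2).sum(axis=-1)
    return d2 <= radius_mm**2


def default_affine(shape: tuple[int, int, int], voxel_mm: float = 3.0) -> np.ndarray:
    """RAS affine with isotropic voxels, world origin at grid center."""
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    aff[:3, 3] = -voxel_mm * (np.asarray(shape) - 1) / 2.0
    return aff


def _roi_is_driven(spec: ROISpec, design: TrialSequence | BlockDesign) -> bool:
    """Hemifield gating: under a lateralised-aperture localizer, a
    contralateral-only ROI is driven only when the stimulated hemifield
    is opposite the ROI's hemisphere."""
    aperture = getattr(design, "aperture", None)
    if aperture is None or spec.ipsilateral_responsive:
        return True
    return aperture["hemifield"] != spec.hemisphere


def simulate_volume(
    design: TrialSequence | BlockDesign,
    layout: list[ROISpec],
    noise: NoiseModel,
    hrf: HRFModel,
    shape: tuple[int, int, int] = (24, 24, 18),
    voxel_mm: float = 3.0,
    seed: int = 0,
    affine: np.ndarray | None = None,
) -> SyntheticVolume:
    """4-D synthetic volume: every voxel inside a ground-truth sphere
    carries that ROI's signal (with independent noise per voxel);
    background voxels carry baseline + noise only."""
    affine = default_affine(shape, voxel_mm) if affine is None else affine
    n_volumes = design.n_volumes
    regs = condition_regressors(design, hrf, n_volumes)
    rng = np.random.default_rng(seed)
    phase = _draw_drift_phase(noise, rng)

    task = {}  # roi name -> planted task signal
    masks = {}
    for spec in layout:
        m = sphere_mask(shape, affine, spec.center_mm, spec.radius_mm)
        if not m.any():
            raise ValueError(f"ROI {spec.name!r} lies outside the grid")
        masks[spec.name] = m
        s = np.zeros(n_volumes)
        if _roi_is_driven(spec, design):
            for cond, reg in regs.items():
                s += spec.amplitudes.get(cond, 0.0) * reg
        task[spec.name] = s

    data = np.full(shape + (n_volumes,), noise.baseline, dtype=np.float64)
    data += _drift(noise, n_volumes, hrf.TR, phase)
    if noise.sigma > 0:
        data += ar1_noise(
            n_volumes, noise.sigma, noise.rho, rng, size=int(np.prod(shape))
        ).reshape(shape + (n_volumes,))
    for spec in layout:
        data[masks[spec.name]] += task[spec.name]
    return SyntheticVolume(data=data, affine=affine, ground_truth=list(layout), seed=seed)


def save_volume(vol: SyntheticVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), vol.affine), str(path))


def load_volume(path: str | Path) -> SyntheticVolume:
    img = nib.load(str(path))
    return SyntheticVolume(
        data=np.asarray(img.dataobj, dtype=np.float64), affine=img.affine
    )
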