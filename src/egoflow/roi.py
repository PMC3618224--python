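"""ROI definition and regional profiling.

Regions are defined from thresholded statistical maps as the voxels
within 8 mm of each strict local maximum.  The MT / MST+ distinction
follows the ipsilateral-stimulation rule: MST+ is the contiguous set of
voxels driven by ipsilateral motion; MT is the contralateral-only set,
trimmed of voxels anterior to the MST+ median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .design import TrialSequence, BlockDesign
from .glm import (
    CONNECTIVITY_STRUCTS,
    StatMap,
    build_design_matrix,
    fit_glm,
    percent_signal_change,
)
from .synth_bold import HRFModel, SyntheticVolume

__all__ = [
    "ROI",
    "RegionalProfile",
    "MSTUndefinedError",
    "define_rois_from_peaks",
    "split_mt_mst",
    "regional_profile",
]


class MSTUndefinedError(ValueError):
    """No ipsilaterally driven voxels: MST+ cannot be defined in this
    hemisphere (a legitimate empirical outcome, not a bug)."""


@dataclass
class ROI:
    name: str
    voxels: np.ndarray  # (n, 3) integer indices
    peak_mm: np.ndarray | None = None
    hemisphere: str | None = None

    @property
    def n_voxels(self) -> int:
        return self.voxels.shape[0]

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[tuple(self.voxels.T)] = True
        return m

    def centroid_mm(self, affine: np.ndarray) -> np.ndarray:
        world = _voxels_to_world(self.voxels, affine)
        return world.mean(axis=0)


@dataclass
class RegionalProfile:
    roi_name: str
    amplitudes: dict[str, float]  # condition -> beta (signal units)
    psc: dict[str, float]  # condition -> percent signal change
    hemisphere: str | None = None


def _voxels_to_world(voxels: np.ndarray, affine: np.ndarray) -> np.ndarray:
    hom = np.column_stack([voxels, np.ones(len(voxels))])
    return (hom @ affine.T)[:, :3]


def define_rois_from_peaks(
    stat_map: StatMap,
    mask: np.ndarray,
    affine: np.ndarray,
    radius_mm: float = 8.0,
    connectivity: int = 26,
) -> list[ROI]:
    """Partition a thresholded map into peak-centered regions.

    Local maxima are masked voxels strictly greater than all their
    neighbors (26-neighborhood by default; flat plateaus therefore yield
    none).  Each region collects the masked voxels within ``radius_mm``
    (world-coordinate Euclidean distance) of its maximum; voxels in
    reach of several maxima go to the nearest one, ties to the maximum
    with the larger statistic.
    """
    F = np.asarray(stat_map.statistic, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    struct = CONNECTIVITY_STRUCTS[connectivity]
    # strict local maxima within the mask: strictly greater than the max
    # over the neighborhood with the center voxel excluded
    fp = struct.copy()
    fp[1, 1, 1] = False
    neighbor_max = ndimage.maximum_filter(
        np.where(mask, F, -np.inf), footprint=fp, mode="constant", cval=-np.inf
    )
    peaks = np.argwhere(mask & (np.where(mask, F, -np.inf) > neighbor_max))
    if len(peaks) == 0:
        return []

    peak_world = _voxels_to_world(peaks, affine)
    peak_stat = F[tuple(peaks.T)]
    vox = np.argwhere(mask)
    world = _voxels_to_world(vox, affine)
    d = np.linalg.norm(world[:, None, :] - peak_world[None, :, :], axis=2)
    within = d <= radius_mm + 1e-9
    # nearest peak among those in range; ties -> larger statistic
    d_masked = np.where(within, d, np.inf)
    order = np.lexsort((-peak_stat[None, :] * np.ones_like(d_masked), d_masked), axis=1)
    nearest = order[:, 0]
    assigned = within[np.arange(len(vox)), nearest]

    rois = []
    for i in range(len(peaks)):
        members = vox[assigned & (nearest == i)]
        if len(members) == 0:
            continue
        rois.append(ROI(name=f"roi_{i:02d}", voxels=members, peak_mm=peak_world[i]))
    return rois


def _largest_component(mask: np.ndarray, connectivity: int) -> np.ndarray:
    labeled, n = ndimage.label(mask, structure=CONNECTIVITY_STRUCTS[connectivity])
    if n == 0:
        return np.zeros_like(mask)
    sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
    return labeled == (int(np.argmax(sizes)) + 1)


def split_mt_mst(
    contra_mask: np.ndarray,
    ipsi_mask: np.ndarray,
    affine: np.ndarray,
    anterior_axis: int = 1,
    connectivity: int = 6,
) -> tuple[ROI, ROI]:
    """Split the MT+ complex into MT and MST+ from the two localizer
    masks.

    MST+ = largest connected component of the ipsilaterally driven
    voxels.  MT = contralateral-only voxels (largest component of
    contra minus ipsi), with every voxel lying anterior to the median
    MST+ coordinate on the anterior axis (world mm, posterior->anterior)
    removed.  Returns ``(MT, MST+)``.
    """
    contra_mask = np.asarray(contra_mask, dtype=bool)
    ipsi_mask = np.asarray(ipsi_mask, dtype=bool)
    if contra_mask.shape != ipsi_mask.shape:
        raise ValueError("masks must share a grid")
    if not ipsi_mask.any():
        raise MSTUndefinedError("no ipsilaterally driven voxels")

    mst = _largest_component(ipsi_mask, connectivity)
    mst_vox = np.argwhere(mst)
    mst_world = _voxels_to_world(mst_vox, affine)
    median_anterior = float(np.median(mst_world[:, anterior_axis]))

    mt_only = _largest_component(contra_mask & ~ipsi_mask, connectivity)
    mt_vox = np.argwhere(mt_only)
    if len(mt_vox):
        mt_world = _voxels_to_world(mt_vox, affine)
        mt_vox = mt_vox[mt_world[:, anterior_axis] <= median_anterior]
    return (
        ROI(name="MT", voxels=mt_vox),
        ROI(name="MST+", voxels=mst_vox),
    )


def regional_profile(
    volume: SyntheticVolume,
    roi: ROI,
    design: TrialSequence | BlockDesign,
    hrf: HRFModel | None = None,
    highpass: float = 128.0,
) -> RegionalProfile:
    """Spatially average the ROI time series, then fit the GLM to the
    averaged series; returns per-condition betas and percent signal
    change relative to the ROI run mean."""
    if roi.n_voxels == 0:
        raise ValueError("empty ROI")
    hrf = hrf or HRFModel(TR=design.TR)
    series = volume.data[tuple(roi.voxels.T)].mean(axis=0)
    X = build_design_matrix(design, hrf, n_volumes=len(series), highpass=highpass)
    fit = fit_glm(series, X)
    run_mean = float(series.mean())
    amplitudes = {c: float(fit.beta(c)) for c in X.task_labels}
    trial_dur = (
        design.trials[0].duration
        if isinstance(design, TrialSequence)
        else design.cycle_length / 2.0
    )
    psc = {
        c: float(percent_signal_change(fit, c, run_mean, hrf, trial_dur))
        for c in X.task_labels
    }
    return RegionalProfile(roi.name, amplitudes, psc, roi.hemisphere)
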