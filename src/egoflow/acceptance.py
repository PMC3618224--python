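"""Recompute the package's headline quantities from scratch.

Each function simulates its inputs with the bundled study conditions,
runs the analysis chain, and measures the result; nothing is looked up.
Used by both ``scripts/acceptance.py`` and the validation test suite.
"""

from __future__ import annotations

import numpy as np

from . import flowfield as ff
from .design import build_ff3d_design
from .pipeline import ACCEPTANCE_NOISE, recover_region_coefficient
from .synth_bold import NoiseModel

__all__ = [
    "max_dot_age_ms",
    "reversal_interval_ms",
    "mean_low_tier_speed",
    "unit_coefficient_noiseless",
    "recovered_coefficient",
]


def max_dot_age_ms(seed: int, duration_s: float = 3.0) -> float:
    """Maximum dot age (ms) across 3-s clips of all five motion
    conditions (the lifetime rule caps it at 350 ms)."""
    worst = 0.0
    for i, cond in enumerate(ff.MOTION_CONDITIONS):
        frames = ff.simulate_clip(cond, duration_s, seed=seed + i)
        worst = max(worst, max(float(f.ages.max()) for f in frames))
    return worst * 1000.0


def reversal_interval_ms(seed: int, duration_s: float = 3.0) -> float:
    """Spacing (ms) between successive sign flips of the mean radial
    velocity component in a radial clip."""
    frames = ff.simulate_clip("radial", duration_s, seed=seed)
    radial_mean = []
    for f in frames:
        r = np.hypot(f.positions[:, 0], f.positions[:, 1])
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(r[:, None] > 0, f.positions / r[:, None], 0.0)
        radial_mean.append(float((f.velocities * unit).sum(axis=1).mean()))
    radial_mean = np.asarray(radial_mean)
    flips = np.flatnonzero(np.sign(radial_mean[1:]) != np.sign(radial_mean[:-1]))
    times = np.array([frames[i + 1].sim_time for i in flips])
    intervals = np.diff(times)
    return float(np.mean(intervals) * 1000.0)


def mean_low_tier_speed(seed: int, duration_s: float = 3.0) -> float:
    """Number-weighted mean dot speed (deg/s) over all dots and frames
    of a radial clip with the low (1-20 deg/s) profile."""
    frames = ff.simulate_clip(
        "radial", duration_s, seed=seed, profile=ff.SPEED_PROFILES["low"]
    )
    return ff.summarize_stimulus(frames)["mean_speed"]


def unit_coefficient_noiseless(seed: int) -> float:
    """MC/MI for a noiseless ROI with identical amplitudes in all five
    motion conditions, recovered through the full GLM chain."""
    design = build_ff3d_design(seed)
    silent = NoiseModel(sigma=0.0, drift_amplitude=0.0)
    prof = recover_region_coefficient(
        "equal", 1.0, n_hemispheres=1, design=design, noise=silent, seed=seed
    )
    return prof.mean_ratio


def recovered_coefficient(
    region: str, planted: float, n_hemispheres: int, seed: int
) -> float:
    """Hemisphere-averaged MC/MI recovered from simulated hemisphere
    ROIs with the given coefficient planted, under the bundled AR(1)
    noise model."""
    design = build_ff3d_design(seed)
    prof = recover_region_coefficient(
        region, planted, n_hemispheres, design, noise=ACCEPTANCE_NOISE, seed=seed
    )
    return prof.mean_ratio
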