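"""Phase-encoded retinotopy analysis on gridded data.

A periodic stimulus (rotating wedge or expanding ring, 8 cycles per
scan) evokes a traveling wave; the response is characterised per voxel
by an F ratio between the spectral power at the stimulus frequency and
the mean power in the noise band, and by the response phase, which maps
to a retinotopic coordinate after correcting for the hemodynamic delay.
The visual field sign — mirror vs. non-mirror local mapping — is the
sign of the Jacobian of the (polar angle, eccentricity) map, computed
from the gradients of the two phase maps on a flat grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist

__all__ = [
    "PeriodicResponse",
    "FieldSignMap",
    "periodic_f_ratio",
    "response_phase",
    "field_sign",
]

DEFAULT_STIMULUS_BIN = 8
DEFAULT_HEMODYNAMIC_DELAY_S = 5.0


@dataclass
class PeriodicResponse:
    amplitude: np.ndarray  # per rfft bin
    phase: np.ndarray  # raw spectral phase per bin (rad)
    n_timepoints: int
    stimulus_bin: int
    noise_bins: np.ndarray  # bins contributing to the noise estimate

    @property
    def excluded_bins(self) -> np.ndarray:
        all_bins = np.arange(len(self.amplitude))
        return np.setdiff1d(all_bins, self.noise_bins)


@dataclass
class FieldSignMap:
    polar: np.ndarray
    eccentricity: np.ndarray
    sign: np.ndarray  # +1 non-mirror, -1 mirror, 0 undefined


def _noise_bins(n: int, stimulus_bin: int) -> np.ndarray:
    """Noise band: all rfft bins except DC, the stimulus bin and its two
    neighbors, and the 2nd/3rd harmonics."""
    n_bins = n // 2 + 1
    excluded = {0, stimulus_bin - 1, stimulus_bin, stimulus_bin + 1,
                2 * stimulus_bin, 3 * stimulus_bin}
    return np.array([b for b in range(n_bins) if b not in excluded])


def periodic_f_ratio(
    series: np.ndarray, stimulus_bin: int = DEFAULT_STIMULUS_BIN
) -> tuple[float, tuple[int, int], PeriodicResponse]:
    """F ratio of stimulus-frequency power to mean noise-band power.

    dof = (2, 2 * n_noise_bins): each spectral bin of real data carries
    two degrees of freedom (sine and cosine).
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if n < 4 * stimulus_bin:
        raise ValueError("series too short for the requested stimulus frequency")
    spec = np.fft.rfft(series)
    power = np.abs(spec) ** 2
    noise = _noise_bins(n, stimulus_bin)
    resp = PeriodicResponse(
        amplitude=np.abs(spec),
        phase=np.angle(spec),
        n_timepoints=n,
        stimulus_bin=stimulus_bin,
        noise_bins=noise,
    )
    noise_power = power[noise].mean()
    F = float(power[stimulus_bin] / noise_power) if noise_power > 0 else np.inf
    return F, (2, 2 * len(noise)), resp


def response_phase(
    resp: PeriodicResponse,
    hemodynamic_delay: float = DEFAULT_HEMODYNAMIC_DELAY_S,
    TR: float = 2.0,
) -> float:
    """Stimulus-locked response phase in [0, 2*pi).

    The raw spectral phase is negated so that a signal
    cos(2*pi*f*(t - t0)) maps to phase 2*pi*f*t0 (the fraction of the
    cycle traversed before the response), then the fixed hemodynamic
    delay is subtracted.
    """
    if resp.amplitude[resp.stimulus_bin] <= 0:
        raise ValueError("zero power at the stimulus frequency: phase undefined")
    period = resp.n_timepoints * TR / resp.stimulus_bin
    phase = -resp.phase[resp.stimulus_bin] - 2 * np.pi * hemodynamic_delay / period
    return float(np.mod(phase, 2 * np.pi))


def field_sign(polar: np.ndarray, ecc: np.ndarray) -> FieldSignMap:
    """Visual field sign from polar-angle and eccentricity maps.

    Computed per grid node as the sign of the Jacobian determinant of
    the (polar, ecc) mapping (central differences inside, one-sided at
    the borders), oriented so that the identity visual-field map
    (polar = atan2(y, x), ecc = hypot(x, y) with axis 0 as x) gives +1.
    Nodes where either gradient vanishes are undefined (0).
    """
    polar = np.asarray(polar, dtype=float)
    ecc = np.asarray(ecc, dtype=float)
    if polar.shape != ecc.shape:
        raise ValueError("polar and eccentricity grids must share a shape")
    if polar.ndim != 2 or min(polar.shape) < 3:
        raise ValueError("need a 2-D grid of at least 3 x 3 nodes")
    dp0, dp1 = np.gradient(polar)
    de0, de1 = np.gradient(ecc)
    jac = de0 * dp1 - de1 * dp0
    sign = np.sign(jac)
    degenerate = ((dp0 == 0) & (dp1 == 0)) | ((de0 == 0) & (de1 == 0))
    sign[degenerate] = 0
    return FieldSignMap(polar=polar, eccentricity=ecc, sign=sign.astype(int))
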