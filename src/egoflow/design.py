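"""Timed condition sequences: the event-related 3D flow-field run, the
block localizers (V6 and MT/MST+), and phase-encoded retinotopy runs.

All timing is expressed in seconds from the start of image acquisition.
The first 8 s (four volumes at TR = 2 s) are a discarded lead-in; the
task starts at the beginning of the fifth volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Trial",
    "TrialSequence",
    "BlockDesign",
    "build_ff3d_design",
    "build_localizer_design",
    "build_retinotopy_design",
    "events_to_csv",
    "events_from_csv",
]

TR_S = 2.0
LEAD_IN_S = 8.0
TRIAL_DURATION_S = 3.0
SPEED_TIERS = ("low", "mid", "high")
FF3D_CONDITIONS = ("translational", "circular", "radial", "spiral", "random", "static")
N_TRIALS_PER_CONDITION = 15
NULL_EVERY = 18  # one null triplet after every 18 non-null trials
LOCALIZER_KINDS = ("v6", "mtmst_left", "mtmst_right")


@dataclass(frozen=True)
class Trial:
    onset: float  # s from acquisition start
    duration: float
    condition: str
    speed_tier: str | None = None


@dataclass
class TrialSequence:
    """Event-related run: ordered, contiguous trials (ITI = 0)."""

    trials: list[Trial]
    TR: float = TR_S
    discarded_lead_in: float = LEAD_IN_S

    @property
    def total_stimulus_time(self) -> float:
        return sum(t.duration for t in self.trials)

    @property
    def n_volumes(self) -> int:
        return math.ceil((self.discarded_lead_in + self.total_stimulus_time) / self.TR)

    @property
    def scan_duration(self) -> float:
        return self.n_volumes * self.TR

    def condition_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.trials:
            counts[t.condition] = counts.get(t.condition, 0) + 1
        return counts


@dataclass
class BlockDesign:
    """Periodic block run: n_cycles of (ON, OFF) alternation, or a
    continuously traveling periodic stimulus for retinotopy."""

    cycle_length: float
    n_cycles: int
    on_condition: str
    off_condition: str
    TR: float = TR_S
    # block runs are timed so that cycles fill the whole acquisition
    discarded_lead_in: float = 0.0
    # (center_x_deg, center_y_deg), diameter_deg, hemifield for MT/MST+
    aperture: dict | None = None
    # within-ON radial in/out alternation period (s), MT/MST+ localizer
    inout_period: float | None = None

    @property
    def total_stimulus_time(self) -> float:
        return self.cycle_length * self.n_cycles

    @property
    def n_volumes(self) -> int:
        return math.ceil(
            (self.discarded_lead_in + self.total_stimulus_time) / self.TR
        )

    @property
    def stimulus_frequency_per_volume(self) -> float:
        """Cycles per volume of the periodic stimulus."""
        return self.n_cycles / (self.total_stimulus_time / self.TR)

    def on_blocks(self) -> list[tuple[float, float]]:
        """(onset, duration) of each ON half-cycle, relative to task
        start (after the lead-in)."""
        half = self.cycle_length / 2.0
        return [
            (self.discarded_lead_in + i * self.cycle_length, half)
            for i in range(self.n_cycles)
        ]


def _null_free_order(rng: np.random.Generator) -> list[tuple[str, str]]:
    """Pseudo-random order of the 90 non-null trials: 6 conditions x 3
    tiers x 5 repeats, with no two consecutive trials sharing both
    condition and speed tier (rejection sampling)."""
    cells = [
        (cond, tier) for cond in FF3D_CONDITIONS for tier in SPEED_TIERS for _ in range(5)
    ]
    cells = np.array(cells, dtype=object)
    for _ in range(100_000):
        perm = rng.permutation(len(cells))
        order = [tuple(cells[i]) for i in perm]
        if all(order[i] != order[i + 1] for i in range(len(order) - 1)):
            return order
    raise RuntimeError("pseudo-randomization failed to converge")


def build_ff3d_design(seed: int) -> TrialSequence:
    """Event-related 3D flow-field run.

    105 contiguous 3-s trials: 15 per condition (5 per speed tier) for
    the five motion conditions and static, plus 15 null trials inserted
    as consecutive triplets after every 18 non-null trials.  Total
    stimulus time 315 s; with the 8-s lead-in the run needs 162 volumes
    at TR = 2 s (324 s).
    """
    rng = np.random.default_rng(seed)
    order = _null_free_order(rng)
    trials: list[Trial] = []
    t = LEAD_IN_S
    n_since_null = 0
    for cond, tier in order:
        trials.append(Trial(t, TRIAL_DURATION_S, cond, tier))
        t += TRIAL_DURATION_S
        n_since_null += 1
        if n_since_null == NULL_EVERY:
            for _ in range(3):
                trials.append(Trial(t, TRIAL_DURATION_S, "null", None))
                t += TRIAL_DURATION_S
            n_since_null = 0
    return TrialSequence(trials)


def build_localizer_design(kind: str) -> BlockDesign:
    """Block localizer: 8 cycles of 32 s (16 s ON / 16 s OFF), 256 s of
    stimulation, 128 volumes at TR = 2 s.

    ``v6``: coherent flow ON vs. scrambled motion OFF.  ``mtmst_left`` /
    ``mtmst_right``: radial dots (alternating inward/outward every 2 s)
    in a 15-deg aperture centered 10 deg left or right of fixation,
    ON vs. static dots OFF.
    """
    if kind not in LOCALIZER_KINDS:
        raise ValueError(f"unknown localizer kind {kind!r}")
    if kind == "v6":
        return BlockDesign(32.0, 8, on_condition="coherent", off_condition="scrambled")
    side = -1.0 if kind == "mtmst_left" else 1.0
    return BlockDesign(
        32.0,
        8,
        on_condition="radial_inout",
        off_condition="static",
        aperture={
            "center_deg": (10.0 * side, 0.0),
            "diameter_deg": 15.0,
            "hemifield": "left" if side < 0 else "right",
        },
        inout_period=2.0,
    )


def build_retinotopy_design() -> BlockDesign:
    """Phase-encoded retinotopy run: 64-s cycles, 8 cycles per scan,
    512 s of stimulation, 256 volumes at TR = 2 s.  The stimulus
    frequency is 8 cycles per 256 volumes (1/32 volumes^-1)."""
    return BlockDesign(64.0, 8, on_condition="traveling_wave", off_condition="")


def events_table(design: TrialSequence | BlockDesign) -> pd.DataFrame:
    """Event table (onset, duration, condition, speed_tier) for either
    design kind; block designs yield one row per ON block."""
    if isinstance(design, TrialSequence):
        return pd.DataFrame(
            {
                "onset": [t.onset for t in design.trials],
                "duration": [t.duration for t in design.trials],
                "condition": [t.condition for t in design.trials],
                "speed_tier": [t.speed_tier for t in design.trials],
            }
        )
    rows = design.on_blocks()
    return pd.DataFrame(
        {
            "onset": [o for o, _ in rows],
            "duration": [d for _, d in rows],
            "condition": design.on_condition,
            "speed_tier": None,
        }
    )


def events_to_csv(design: TrialSequence | BlockDesign, path: str | Path | StringIO) -> None:
    events_table(design).to_csv(path, index=False)


def events_from_csv(path: str | Path | StringIO) -> TrialSequence:
    """Read an event CSV back into a TrialSequence."""
    # keep_default_na: "null" is a condition label, not a missing value
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    trials = [
        Trial(
            float(r.onset),
            float(r.duration),
            str(r.condition),
            None if pd.isna(r.speed_tier) else str(r.speed_tier),
        )
        for r in df.itertuples()
    ]
    return TrialSequence(trials)
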