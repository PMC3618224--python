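"""Motion-coherence coefficient and repeated-measures ANOVAs.

The MC/MI coefficient of an ROI is the ratio of MC — the mean response
amplitude across the four coherent flow conditions (translational,
circular, radial, spiral) — to MI, the response to incoherent (random)
motion.  The ratio is formed per hemisphere and then averaged across
hemispheres (ratio of means first, mean of ratios second), reported as
mean +/- SEM.  A coefficient of 1 means coherent and incoherent motion
drive the region equally; values above 1 mean a coherence preference;
negative values arise when random motion suppresses the region below
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "COHERENT_SET",
    "CoherenceProfile",
    "AnovaResult",
    "mc_mi_coefficient",
    "rm_anova_oneway",
    "rm_anova_region_by_condition",
    "pairwise_posthoc",
]

COHERENT_SET = ("translational", "circular", "radial", "spiral")
MOTION_SET = COHERENT_SET + ("random",)

#: |MI| below this fraction of |MC| flags the per-hemisphere ratio as
#: numerically unstable (the ratio is still reported, never clamped)
MI_STABILITY_FRACTION = 0.05


@dataclass
class CoherenceProfile:
    mc: np.ndarray  # per-hemisphere mean coherent amplitude
    mi: np.ndarray  # per-hemisphere random amplitude
    ratio: np.ndarray  # per-hemisphere MC/MI
    mean_ratio: float
    sem_ratio: float
    unstable: bool  # any hemisphere with |MI| < 5% of |MC|

    @property
    def n_hemispheres(self) -> int:
        return len(self.ratio)


@dataclass
class AnovaResult:
    effect: str
    F: float
    df: tuple[int, int]
    p: float
    cell_means: dict = field(default_factory=dict)


def mc_mi_coefficient(profiles: list[dict[str, float]]) -> CoherenceProfile:
    """Coherence coefficient from per-hemisphere condition amplitudes.

    ``profiles``: one mapping condition -> amplitude per hemisphere,
    which must include all five motion conditions.
    """
    mc, mi = [], []
    for amp in profiles:
        missing = [c for c in MOTION_SET if c not in amp]
        if missing:
            raise ValueError(f"profile missing conditions: {missing}")
        mc.append(np.mean([amp[c] for c in COHERENT_SET]))
        mi.append(amp["random"])
    mc = np.asarray(mc, dtype=float)
    mi = np.asarray(mi, dtype=float)
    ratio = mc / mi
    n = len(ratio)
    sem = float(np.std(ratio, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    unstable = bool(np.any(np.abs(mi) < MI_STABILITY_FRACTION * np.abs(mc)))
    return CoherenceProfile(
        mc=mc,
        mi=mi,
        ratio=ratio,
        mean_ratio=float(ratio.mean()),
        sem_ratio=sem,
        unstable=unstable,
    )


def _check_matrix(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need a complete subjects x conditions matrix (>= 2 each)")
    if np.isnan(data).any():
        raise ValueError("unbalanced design: missing cells are not supported")
    return data


def rm_anova_oneway(data: np.ndarray, effect: str = "condition") -> AnovaResult:
    """One-way repeated-measures ANOVA (subjects x conditions).

    Classical within-subject decomposition:
    F = MS_condition / MS_(condition x subject),
    df = (k - 1, (k - 1)(n - 1)).
    """
    data = _check_matrix(data)
    n, k = data.shape
    grand = data.mean()
    subj_means = data.mean(axis=1, keepdims=True)
    cond_means = data.mean(axis=0, keepdims=True)
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    resid = data - subj_means - cond_means + grand
    ss_err = (resid**2).sum()
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond, ms_err = ss_cond / df1, ss_err / df2
    F = 0.0 if ms_err == 0 and ms_cond == 0 else ms_cond / ms_err
    p = float(stats.f.sf(F, df1, df2))
    return AnovaResult(
        effect=effect,
        F=float(F),
        df=(df1, df2),
        p=p,
        cell_means={"condition": cond_means.ravel().tolist()},
    )


def rm_anova_region_by_condition(data: np.ndarray) -> AnovaResult:
    """Region-by-condition interaction for a 2 x k within-subject
    design (data: subjects x 2 regions x k conditions).

    With two regions the interaction reduces to a one-way RM ANOVA on
    the per-subject region-difference scores, giving
    df = (k - 1, (k - 1)(n - 1)).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3 or data.shape[1] != 2:
        raise ValueError("expected subjects x 2 regions x conditions data")
    diff = data[:, 0, :] - data[:, 1, :]
    res = rm_anova_oneway(diff, effect="region x condition")
    # the difference-score SS double-counts the two regions; halving both
    # numerator and denominator SS leaves F unchanged
    res.cell_means = {
        "region_by_condition": data.mean(axis=0).tolist(),
    }
    return res


def pairwise_posthoc(data: np.ndarray, labels: list[str] | None = None) -> list[dict]:
    """Pairwise paired t-tests across conditions with Holm correction
    (post-hoc follow-up to the one-way RM ANOVA)."""
    data = _check_matrix(data)
    k = data.shape[1]
    labels = labels or [f"c{i}" for i in range(k)]
    pairs = list(combinations(range(k), 2))
    raw = [stats.ttest_rel(data[:, i], data[:, j]) for i, j in pairs]
    adj = multipletests([r.pvalue for r in raw], method="holm")[1]
    return [
        {
            "pair": (labels[i], labels[j]),
            "t": float(r.statistic),
            "p_raw": float(r.pvalue),
            "p_holm": float(p),
        }
        for (i, j), r, p in zip(pairs, raw, adj)
    ]
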