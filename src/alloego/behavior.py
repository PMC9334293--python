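"""Behavioral statistics: gaze errors and the allocentric weight (AW).

The allocentric weight of a trial projects the gaze-endpoint displacement
onto the axis from the target T to the virtually shifted target T':

    AW = ((G - T) . (T' - T)) / ||T' - T||^2

so AW = 0 when gaze lands on the target (purely egocentric) and AW = 1
when it lands on the shifted target (purely allocentric).  AW is defined
only for trials with a nonzero landmark shift.

Gaze endpoints can first be normalized by subtracting, separately for each
target location, the mean gaze error measured on the no-shift trials —
removing target-specific systematic biases before the shift influence is
quantified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "normalize_gaze",
    "allocentric_weight",
    "AWResult",
    "error_distribution",
    "compare_aw_distributions",
]


def _target_bins(targets: np.ndarray, bin_size: float) -> np.ndarray:
    """Integer bin id per trial (nearest-grid-cell grouping)."""
    cells = np.rint(np.asarray(targets, dtype=float) / bin_size).astype(int)
    return cells[:, 0] * 1_000_003 + cells[:, 1]


def normalize_gaze(gaze: np.ndarray, targets: np.ndarray,
                   shifts: np.ndarray, bin_size: float = 1.0) -> np.ndarray:
    """Subtract the per-target mean no-shift gaze error from every trial.

    Targets are grouped to the nearest ``bin_size``-degree cell (exact
    identity for grid datasets with unit bins).  Targets without any
    no-shift reference trial are left unchanged.
    """
    gaze = np.asarray(gaze, dtype=float)
    targets = np.asarray(targets, dtype=float)
    shifts = np.asarray(shifts, dtype=float)
    err = gaze - targets
    zero = np.linalg.norm(shifts, axis=1) == 0.0
    if not np.any(zero):
        raise ValueError("dataset has no zero-shift trials to normalize by")
    bins = _target_bins(targets, bin_size)
    out = gaze.copy()
    for b in np.unique(bins):
        ref = zero & (bins == b)
        if np.any(ref):
            out[bins == b] -= err[ref].mean(axis=0)
    return out


@dataclass
class AWResult:
    """Per-trial allocentric weights with summary statistics."""

    values: np.ndarray
    mean: float = field(init=False)
    median: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mean = float(np.mean(self.values))
        self.median = float(np.median(self.values))


def allocentric_weight(gaze: np.ndarray, targets: np.ndarray,
                       shifts: np.ndarray) -> AWResult:
    """Project gaze displacement onto the T -> T' axis, per shifted trial."""
    gaze = np.asarray(gaze, dtype=float)
    targets = np.asarray(targets, dtype=float)
    shifts = np.asarray(shifts, dtype=float)
    norm2 = np.sum(shifts ** 2, axis=1)
    mask = norm2 > 0.0
    if not np.any(mask):
        raise ValueError("allocentric weight requires shifted trials")
    d = gaze[mask] - targets[mask]
    aw = np.sum(d * shifts[mask], axis=1) / norm2[mask]
    return AWResult(values=aw)


def error_distribution(gaze: np.ndarray, targets: np.ndarray,
                       bin_width: float = 2.0,
                       reward_band: tuple[float, float] = (8.0, 12.0)
                       ) -> dict:
    """Histogram of angular gaze errors ||G - T|| with reward-band summary."""
    err = np.linalg.norm(np.asarray(gaze, dtype=float)
                         - np.asarray(targets, dtype=float), axis=1)
    edges = np.arange(0.0, err.max() + 2 * bin_width, bin_width)
    counts, edges = np.histogram(err, bins=edges)
    lo, hi = reward_band
    return {
        "errors": err,
        "counts": counts,
        "edges": edges,
        "frac_within_lower": float(np.mean(err <= lo)),
        "frac_within_upper": float(np.mean(err <= hi)),
        "median_error": float(np.median(err)),
    }


def compare_aw_distributions(a: np.ndarray | AWResult,
                             b: np.ndarray | AWResult) -> dict:
    """Wilcoxon signed-rank comparison of two (paired) AW distributions."""
    av = a.values if isinstance(a, AWResult) else np.asarray(a, dtype=float)
    bv = b.values if isinstance(b, AWResult) else np.asarray(b, dtype=float)
    if len(av) != len(bv):
        raise ValueError("paired comparison requires equal-length samples")
    diff = av - bv
    if np.allclose(diff, 0.0):
        statistic, pvalue = 0.0, 1.0  # no signed ranks to compare
    else:
        res = stats.wilcoxon(av, bv)
        statistic, pvalue = float(res.statistic), float(res.pvalue)
    return {
        "statistic": statistic,
        "pvalue": pvalue,
        "mean_a": float(np.mean(av)), "mean_b": float(np.mean(bv)),
        "median_a": float(np.median(av)), "median_b": float(np.median(bv)),
    }
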