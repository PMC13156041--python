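"""Spatial-map correlations across contexts/days and run-to-run reliability.

Remapping between two contexts (or two days) is quantified as the Pearson
correlation of the 80-bin activity maps and categorized as low (r <= 0.1),
medium (0.1 < r < 0.6) or high (r >= 0.6).  Trial-to-trial reliability is
the mean pairwise correlation of per-run maps; pairs involving a
zero-variance (silent) run map are dropped rather than zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .environments import EnvironmentSpec
from .metrics import SPEED_MIN_CM_S, activity_map, smooth_map
from .synthetic import SessionTrack

HIGH_R = 0.6
LOW_R = 0.1


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r; NaN when either input has zero variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("inputs must have equal length")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def map_correlation(map_a: np.ndarray, map_b: np.ndarray) -> float:
    return pearson(map_a, map_b)


def remapping_category(r: float) -> str:
    if np.isnan(r):
        raise ValueError("undefined correlation has no category")
    if r <= LOW_R:
        return "low"
    if r >= HIGH_R:
        return "high"
    return "medium"


def per_run_maps(
    masked_dff: np.ndarray,
    track: SessionTrack,
    env: EnvironmentSpec,
    context: str,
    speed_min_cm_s: float = SPEED_MIN_CM_S,
    smoothed: bool = True,
) -> np.ndarray:
    """(n_runs, n_bins) activity maps, one per completed run."""
    runs = track.runs_of(context)
    maps = []
    for r in runs:
        amap = activity_map(masked_dff, track, env, context=context,
                            runs=[r], speed_min_cm_s=speed_min_cm_s)
        maps.append(smooth_map(amap.lambda_) if smoothed else amap.lambda_)
    return np.asarray(maps)


def trial_reliability(run_maps: np.ndarray) -> float:
    """Mean pairwise Pearson r over run pairs with defined variance."""
    run_maps = np.asarray(run_maps, dtype=float)
    if run_maps.shape[0] < 2:
        return float("nan")
    rs = [pearson(run_maps[i], run_maps[j])
          for i, j in combinations(range(run_maps.shape[0]), 2)]
    rs = [r for r in rs if not np.isnan(r)]
    return float(np.mean(rs)) if rs else float("nan")


@dataclass
class RemappingResult:
    comparison: str  # e.g. "familiar|novel" or "day1|day2"
    r: float
    category: str | None
    reliability: float | None = None

    @classmethod
    def from_maps(cls, comparison: str, map_a, map_b,
                  reliability: float | None = None) -> "RemappingResult":
        r = map_correlation(map_a, map_b)
        cat = None if np.isnan(r) else remapping_category(r)
        return cls(comparison=comparison, r=r, category=cat,
                   reliability=reliability)
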