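"""Spatial binning, activity maps, spatial/speed information and licking.

All positional analyses use running, non-blank frames only (speed >= 5
cm/s).  The activity map divides the 4-m track into 80 5-cm bins; lambda_i
is the mean transient-masked dF/F in bin i, p_i the fraction of running
time spent there.  Spatial information follows the occupancy-weighted
information rate SI = sum_i p_i * lambda_i * log2(lambda_i / lambda_bar)
(bits * s^-1 by convention; the log base is switchable).  Significance is
assessed by circularly shifting activity against position (minimum 30-s
offset) 1,000 times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .environments import EnvironmentSpec
from .synthetic import SessionTrack

SPEED_MIN_CM_S = 5.0
ACTIVE_RATE_PER_S = 1.0 / 60.0  # "> 1 transient per minute"


def bin_track(track_length_m: float, bin_size_m: float = 0.05) -> np.ndarray:
    """Half-open bin edges; the track length must divide evenly."""
    ratio = track_length_m / bin_size_m
    n = round(ratio)
    if abs(ratio - n) > 1e-9:
        raise ValueError(
            f"track length {track_length_m} not a multiple of {bin_size_m}")
    return np.arange(n + 1) * bin_size_m


def position_bins(position_m: np.ndarray, bin_size_m: float,
                  n_bins: int) -> np.ndarray:
    b = np.floor(np.asarray(position_m) / bin_size_m).astype(int)
    return np.clip(b, 0, n_bins - 1)


def binning_matrix(bin_idx: np.ndarray, n_bins: int) -> sparse.csr_matrix:
    """Sparse one-hot frames x bins matrix (for batched binned sums)."""
    m = bin_idx.size
    return sparse.csr_matrix(
        (np.ones(m), (np.arange(m), bin_idx)), shape=(m, n_bins))


def smooth_map(lam: np.ndarray) -> np.ndarray:
    """Average each bin with its neighbors (window shrinks to 2 at edges)."""
    lam = np.atleast_2d(np.asarray(lam, dtype=float))
    out = np.empty_like(lam)
    out[:, 1:-1] = (lam[:, :-2] + lam[:, 1:-1] + lam[:, 2:]) / 3.0
    out[:, 0] = (lam[:, 0] + lam[:, 1]) / 2.0
    out[:, -1] = (lam[:, -2] + lam[:, -1]) / 2.0
    return out[0] if out.shape[0] == 1 else out


@dataclass
class ActivityMap:
    """Binned spatial activity of one unit in one context."""

    lambda_: np.ndarray        # per-bin mean masked dF/F (0 where unvisited)
    p: np.ndarray              # per-bin occupancy fraction of running time
    occupancy_s: np.ndarray
    visited: np.ndarray
    bin_size_m: float
    empty: bool = False

    def __post_init__(self) -> None:
        if not self.empty and self.visited.any():
            assert abs(self.p[self.visited].sum() - 1.0) < 1e-9

    @property
    def n_bins(self) -> int:
        return self.lambda_.size

    @property
    def lambda_bar(self) -> float:
        return float((self.p * self.lambda_).sum())

    @property
    def smoothed(self) -> np.ndarray:
        return smooth_map(self.lambda_)


def activity_map(
    masked_dff: np.ndarray,
    track: SessionTrack,
    env: EnvironmentSpec,
    context: str | None = None,
    runs=None,
    speed_min_cm_s: float = SPEED_MIN_CM_S,
) -> ActivityMap:
    """Per-bin mean masked dF/F and occupancy over running frames."""
    sel = track.running_mask(speed_min_cm_s) & track.select(context, runs)
    n_bins = env.n_bins
    if not np.any(sel):
        z = np.zeros(n_bins)
        return ActivityMap(z, z.copy(), z.copy(),
                           np.zeros(n_bins, dtype=bool), env.bin_size_m,
                           empty=True)
    bins = position_bins(track.position_m[sel], env.bin_size_m, n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    sums = np.bincount(bins, weights=np.asarray(masked_dff)[sel],
                       minlength=n_bins)
    visited = counts > 0
    lam = np.zeros(n_bins)
    lam[visited] = sums[visited] / counts[visited]
    p = counts / counts.sum()
    occ = counts / track.frame_rate_hz
    return ActivityMap(lam, p, occ, visited, env.bin_size_m)


def spatial_information(amap: ActivityMap, log_base: float = 2.0) -> float:
    """Occupancy-weighted information rate of the (unsmoothed) map.

    Returns NaN when the overall mean activity is zero.
    """
    lam, p = amap.lambda_, amap.p
    lbar = amap.lambda_bar
    if lbar <= 0:
        return float("nan")
    pos = lam > 0
    si = np.sum(p[pos] * lam[pos] * np.log(lam[pos] / lbar))
    return float(si / np.log(log_base))


def _si_rows(lam_rows: np.ndarray, p: np.ndarray,
             log_base: float) -> np.ndarray:
    """Vectorized SI over rows of per-bin activity (shared occupancy)."""
    lam_rows = np.atleast_2d(lam_rows)
    lbar = lam_rows @ p
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lam_rows > 0, lam_rows / lbar[:, None], 1.0)
        terms = p[None, :] * lam_rows * np.log(ratio)
    si = terms.sum(axis=1) / np.log(log_base)
    si[lbar <= 0] = np.nan
    return si


def si_shuffle_test(
    masked_dff: np.ndarray,
    track: SessionTrack,
    env: EnvironmentSpec,
    context: str | None = None,
    n_shuffles: int = 1000,
    min_shift_s: float = 30.0,
    log_base: float = 2.0,
    seed=None,
    speed_min_cm_s: float = SPEED_MIN_CM_S,
) -> tuple[float, float]:
    """(observed SI, p) with a circular-shift null.

    Each shuffle circularly shifts the masked activity relative to the
    position trace (over the selected running frames) by a random offset of
    at least ``min_shift_s``; p is the fraction of shuffles whose SI meets
    or exceeds the observed value.
    """
    if n_shuffles <= 0:
        raise ValueError("n_shuffles must be positive")
    rng = np.random.default_rng(seed)
    sel = track.running_mask(speed_min_cm_s) & track.select(context)
    v = np.asarray(masked_dff, dtype=float)[sel]
    m = v.size
    min_shift = int(round(min_shift_s * track.frame_rate_hz))
    if m < 2 * min_shift:
        raise ValueError("trace shorter than twice the minimum shift")
    bins = position_bins(track.position_m[sel], env.bin_size_m, env.n_bins)
    counts = np.bincount(bins, minlength=env.n_bins)
    p = counts / counts.sum()
    B = binning_matrix(bins, env.n_bins)
    inv_counts = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)

    obs = _si_rows((v @ B) * inv_counts, p, log_base)[0]
    shifts = rng.integers(min_shift, m - min_shift + 1, size=n_shuffles)
    hits = 0
    idx = np.arange(m)
    for chunk in np.array_split(shifts, max(1, n_shuffles // 250)):
        rows = v[(idx[None, :] + chunk[:, None]) % m]
        si = _si_rows((rows @ B) * inv_counts, p, log_base)
        hits += int(np.sum(si >= obs))
    return float(obs), hits / n_shuffles


def transient_rate_and_active(
    transients: np.ndarray,
    track: SessionTrack,
    context: str | None = None,
    speed_min_cm_s: float = SPEED_MIN_CM_S,
) -> tuple[float, bool]:
    """Transient onsets per running second and the >1/min active flag."""
    sel = track.running_mask(speed_min_cm_s) & track.select(context)
    seconds = sel.sum() / track.frame_rate_hz
    if seconds == 0:
        return float("nan"), False
    onsets = np.asarray(transients, dtype=int).reshape(-1, 2)[:, 0]
    count = int(sel[onsets].sum()) if onsets.size else 0
    rate = count / seconds
    return rate, bool(rate > ACTIVE_RATE_PER_S)


def speed_metrics(
    masked_dff: np.ndarray,
    track: SessionTrack,
    context: str | None = None,
    n_shuffles: int = 1000,
    speed_bin_cm_s: float = 2.0,
    min_shift_s: float = 30.0,
    log_base: float = 2.0,
    seed=None,
    speed_min_cm_s: float = SPEED_MIN_CM_S,
) -> tuple[float, float, str]:
    """(speed information, speed score, speed class).

    The speed score is the Pearson correlation between masked dF/F and
    running speed; class '+' requires shuffle p < 0.05 and a score at or
    above the 99th shuffle percentile, class '-' a score at or below the
    1st percentile, otherwise 'NS'.
    """
    rng = np.random.default_rng(seed)
    sel = track.running_mask(speed_min_cm_s) & track.select(context)
    v = np.asarray(masked_dff, dtype=float)[sel]
    s = track.speed_cm_s[sel]
    if v.size < 2 or s.std() == 0 or v.std() == 0:
        return float("nan"), float("nan"), "NS"
    # speed information over 2-cm/s bins up to the 99th speed percentile
    hi = np.percentile(s, 99)
    edges = np.arange(speed_min_cm_s, max(hi, speed_min_cm_s + speed_bin_cm_s),
                      speed_bin_cm_s)
    sbin = np.clip(np.digitize(s, edges) - 1, 0, edges.size - 1)
    counts = np.bincount(sbin, minlength=edges.size)
    p = counts / counts.sum()
    lam = np.zeros(edges.size)
    np.add.at(lam, sbin, v)
    lam[counts > 0] /= counts[counts > 0]
    lbar = float((p * lam).sum())
    if lbar > 0:
        pos = lam > 0
        speed_info = float(np.sum(p[pos] * lam[pos] * np.log(lam[pos] / lbar))
                           / np.log(log_base))
    else:
        speed_info = float("nan")

    score = float(np.corrcoef(v, s)[0, 1])
    m = v.size
    min_shift = min(int(round(min_shift_s * track.frame_rate_hz)), m // 3)
    shifts = rng.integers(max(min_shift, 1), m - max(min_shift, 1) + 1,
                          size=n_shuffles)
    sc = (s - s.mean()) / s.std()
    vc = (v - v.mean()) / v.std()
    idx = np.arange(m)
    shuf = np.empty(n_shuffles)
    for k0 in range(0, n_shuffles, 250):
        chunk = shifts[k0:k0 + 250]
        rows = vc[(idx[None, :] + chunk[:, None]) % m]
        shuf[k0:k0 + chunk.size] = rows @ sc / m
    p_val = float(np.mean(shuf >= score))
    if p_val < 0.05 and score >= np.percentile(shuf, 99):
        cls = "+"
    elif score <= np.percentile(shuf, 1):
        cls = "-"
    else:
        cls = "NS"
    return speed_info, score, cls


def activity_difference_score(rate_a: float, rate_b: float) -> float:
    """|A - B| / (A + B); NaN when both rates are zero."""
    if rate_a < 0 or rate_b < 0:
        raise ValueError("rates must be non-negative")
    total = rate_a + rate_b
    if total == 0:
        return float("nan")
    return abs(rate_a - rate_b) / total


def reward_zone_bins(env: EnvironmentSpec) -> np.ndarray:
    """Bins of the 30-cm (6-bin) zones centered on each reward site."""
    centers = (np.arange(env.n_bins) + 0.5) * env.bin_size_m
    zone = np.zeros(env.n_bins, dtype=bool)
    for pos in env.positions("reward"):
        zone |= np.abs(centers - pos) <= 0.15 + 1e-9
    return np.flatnonzero(zone)


def lick_ratio(track: SessionTrack, env: EnvironmentSpec,
               context: str | None = None) -> float:
    """Mean in-reward-zone lick rate over the out-of-zone rate.

    Returns +inf when licking occurs only inside the zones, NaN when no
    lick data (or no frames) are available.
    """
    sel = track.select(context)
    if not np.any(sel):
        return float("nan")
    bins = position_bins(track.position_m[sel], env.bin_size_m, env.n_bins)
    env_ctx = env
    zone_bins = set(reward_zone_bins(env_ctx).tolist())
    in_zone = np.isin(bins, list(zone_bins))
    licks = track.lick_flag[sel]
    fs = track.frame_rate_hz
    t_in, t_out = in_zone.sum() / fs, (~in_zone).sum() / fs
    if t_in == 0 or t_out == 0:
        return float("nan")
    rate_in = licks[in_zone].sum() / t_in
    rate_out = licks[~in_zone].sum() / t_out
    if rate_out == 0:
        return float("inf") if rate_in > 0 else float("nan")
    return float(rate_in / rate_out)
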