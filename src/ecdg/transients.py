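"""DeltaF/F conversion and FPR-calibrated significant-transient detection.

Raw fluorescence is corrected for slow drift by subtracting a rolling 8th
percentile (20-s centered window, truncated at the trace edges).  Baseline
mean and s.d. are estimated from samples within 1.9 s.d. of the whole-trace
mean, giving dF/F in units of the baseline standard deviation.  Transient
detection scans a grid of (onset threshold, minimum duration) pairs and
keeps the least stringent pair whose false-positive rate — the ratio of
negative- to positive-oriented detected events — stays below 5%.  Detected
events are extended until the trace falls back below 0.5 sigma, the
baseline statistics are recomputed from transient-free samples, and all
samples outside significant transients are zeroed ("masked" trace).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

DEFAULT_THRESHOLDS_SIGMA = (2.0, 2.5, 3.0, 3.5, 4.0)
OFFSET_SIGMA = 0.5


@dataclass
class TransientParams:
    threshold_sigma: float
    min_duration_frames: int
    measured_fpr: float
    compliant: bool = True

    def __post_init__(self) -> None:
        if self.threshold_sigma <= 0 or self.min_duration_frames < 1:
            raise ValueError("invalid transient parameters")


@dataclass
class DffTrace:
    """Per-unit dF/F in baseline-sigma units with detected transients."""

    dff: np.ndarray
    f0: float
    sigma: float
    transients: np.ndarray  # (k, 2) onset/offset frames, offset inclusive
    masked_dff: np.ndarray
    flags: dict = field(default_factory=dict)

    @property
    def transient_flag(self) -> np.ndarray:
        """Boolean per-frame flag: inside a significant transient."""
        out = np.zeros(self.dff.size, dtype=bool)
        for on, off in self.transients:
            out[on:off + 1] = True
        return out


def baseline_correct(
    raw: np.ndarray, frame_rate: float,
    window_s: float = 20.0, percentile: float = 8.0,
) -> np.ndarray:
    """Subtract a centered rolling percentile; edge windows are truncated."""
    raw = np.asarray(raw, dtype=float)
    n = raw.size
    if n < 2:
        raise ValueError("trace must have at least 2 frames")
    w = int(round(window_s * frame_rate))
    if w >= n:  # degenerate: single global percentile
        return raw - np.percentile(raw, percentile)
    half = w // 2
    out = np.empty(n)
    windows = np.lib.stride_tricks.sliding_window_view(raw, w)
    full = np.percentile(windows, percentile, axis=1)
    # frame t uses window [t - half, t - half + w); full windows cover
    # t = half .. half + (n - w)
    out[half:half + n - w + 1] = raw[half:half + n - w + 1] - full
    for t in range(half):
        out[t] = raw[t] - np.percentile(raw[: t - half + w], percentile)
    for t in range(half + n - w + 1, n):
        out[t] = raw[t] - np.percentile(raw[t - half:], percentile)
    return out


def estimate_baseline_stats(corrected: np.ndarray,
                            clip_sd: float = 1.9) -> tuple[float, float, dict]:
    """Mean/s.d. over samples within ``clip_sd`` total-s.d. of the mean."""
    x = np.asarray(corrected, dtype=float)
    if x.size == 0:
        raise ValueError("empty trace")
    mu, sd = x.mean(), x.std()
    sel = np.abs(x - mu) <= clip_sd * sd
    flags: dict = {}
    if not np.any(sel):
        flags["baseline_fallback"] = True
        sel = np.ones(x.size, dtype=bool)
    f0 = float(x[sel].mean())
    sigma = float(x[sel].std())
    if sigma == 0.0:
        flags["degenerate_sigma"] = True
    return f0, sigma, flags


def _run_lengths(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start indices and lengths of True runs."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    d = np.diff(m.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.r_[0, starts]
    if m[-1]:
        ends = np.r_[ends, m.size]
    return starts, ends - starts


def _count_events(dff: np.ndarray, threshold: float,
                  durations: np.ndarray) -> np.ndarray:
    """Counts of supra-threshold runs lasting >= d, for each duration d."""
    _, lengths = _run_lengths(dff >= threshold)
    if lengths.size == 0:
        return np.zeros(durations.size, dtype=int)
    return np.array([(lengths >= d).sum() for d in durations])


def _extract_intervals(dff: np.ndarray, threshold: float,
                       min_duration: int,
                       offset_sigma: float = OFFSET_SIGMA) -> np.ndarray:
    """Supra-threshold events, extended until dff falls below offset_sigma.

    Returns (k, 2) onset/offset frames (offset inclusive), merged if the
    extensions overlap.
    """
    starts, lengths = _run_lengths(dff >= threshold)
    keep = lengths >= min_duration
    starts, lengths = starts[keep], lengths[keep]
    if starts.size == 0:
        return np.empty((0, 2), dtype=int)
    below = dff < offset_sigma
    n = dff.size
    intervals = []
    for s, ln in zip(starts, lengths):
        e = s + ln - 1
        nxt = np.flatnonzero(below[e + 1:])
        e = n - 1 if nxt.size == 0 else e + nxt[0]
        intervals.append((int(s), int(e)))
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return np.asarray(merged, dtype=int)


def detect_transients(
    dff: np.ndarray,
    frame_rate: float,
    fpr_target: float = 0.05,
    thresholds_sigma=DEFAULT_THRESHOLDS_SIGMA,
    durations_frames=None,
) -> tuple[TransientParams, list[np.ndarray]]:
    """Grid-search detection parameters at a target false-positive rate.

    ``dff`` is (units, frames) in sigma units (a 1-D trace is treated as a
    single unit).  Events are pooled across units for the parameter search;
    the least stringent compliant pair (smallest threshold, then shortest
    duration) is selected, and per-unit transient intervals are returned
    for it.  If no pair is compliant the most stringent pair is returned
    with ``compliant=False``.
    """
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    if durations_frames is None:
        durations_frames = np.arange(int(round(0.2 * frame_rate)),
                                     int(round(1.0 * frame_rate)) + 1)
    durations = np.asarray(durations_frames, dtype=int)
    thresholds = tuple(thresholds_sigma)

    pos = np.zeros((len(thresholds), durations.size), dtype=int)
    neg = np.zeros_like(pos)
    for u in range(dff.shape[0]):
        for i, thr in enumerate(thresholds):
            pos[i] += _count_events(dff[u], thr, durations)
            neg[i] += _count_events(-dff[u], thr, durations)

    chosen = None
    for i, j in product(range(len(thresholds)), range(durations.size)):
        p, q = pos[i, j], neg[i, j]
        fpr = 0.0 if q == 0 else (np.inf if p == 0 else q / p)
        if fpr < fpr_target:
            chosen = (i, j, fpr, True)
            break
    if chosen is None:
        i, j = len(thresholds) - 1, durations.size - 1
        p, q = pos[i, j], neg[i, j]
        fpr = 0.0 if q == 0 else (np.inf if p == 0 else q / p)
        chosen = (i, j, fpr, False)
    i, j, fpr, ok = chosen
    params = TransientParams(
        threshold_sigma=float(thresholds[i]),
        min_duration_frames=int(durations[j]),
        measured_fpr=float(fpr), compliant=ok,
    )
    intervals = [
        _extract_intervals(dff[u], params.threshold_sigma,
                           params.min_duration_frames)
        for u in range(dff.shape[0])
    ]
    return params, intervals


def mask_trace(dff: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    """Zero every sample outside the transient intervals."""
    dff = np.asarray(dff, dtype=float)
    intervals = np.asarray(intervals, dtype=int).reshape(-1, 2)
    if intervals.size:
        order = np.argsort(intervals[:, 0])
        intervals = intervals[order]
        if np.any(intervals[1:, 0] <= intervals[:-1, 1]):
            raise ValueError("overlapping transient intervals")
    out = np.zeros_like(dff)
    for on, off in intervals:
        out[on:off + 1] = dff[on:off + 1]
    return out


def process_traces(
    raw: np.ndarray,
    frame_rate: float,
    fpr_target: float = 0.05,
    window_s: float = 20.0,
    percentile: float = 8.0,
) -> tuple[list[DffTrace], TransientParams]:
    """Full per-session trace processing.

    Baseline-correct each unit, estimate initial baseline statistics,
    convert to sigma units, run the pooled parameter search, recompute
    definitive baseline statistics from transient-free samples, and return
    the final dF/F with intervals re-extracted on the definitive trace.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    n_units = raw.shape[0]
    corrected = np.stack([
        baseline_correct(raw[u], frame_rate, window_s, percentile)
        for u in range(n_units)
    ])
    init = [estimate_baseline_stats(corrected[u]) for u in range(n_units)]
    dff0 = np.stack([
        (corrected[u] - f0) / (sigma if sigma > 0 else 1.0)
        for u, (f0, sigma, _) in enumerate(init)
    ])
    params, intervals0 = detect_transients(dff0, frame_rate, fpr_target)

    traces: list[DffTrace] = []
    for u in range(n_units):
        outside = np.ones(raw.shape[1], dtype=bool)
        for on, off in intervals0[u]:
            outside[on:off + 1] = False
        flags = dict(init[u][2])
        if outside.sum() >= 2:
            f0 = float(corrected[u][outside].mean())
            sigma = float(corrected[u][outside].std())
        else:
            f0, sigma = init[u][0], init[u][1]
            flags["definitive_fallback"] = True
        if sigma <= 0:
            sigma = init[u][1] if init[u][1] > 0 else 1.0
            flags["degenerate_sigma"] = True
        dff = (corrected[u] - f0) / sigma
        iv = _extract_intervals(dff, params.threshold_sigma,
                                params.min_duration_frames)
        traces.append(DffTrace(
            dff=dff, f0=f0, sigma=sigma, transients=iv,
            masked_dff=mask_trace(dff, iv), flags=flags,
        ))
    return traces, params
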