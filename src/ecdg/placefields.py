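"""Place-field detection on 1-D activity maps.

Candidate fields are contiguous bins of the smoothed map lying strictly
above baseline + 25% of the peak-to-baseline range, where the baseline is
the mean of the 20 lowest bins.  Accepted fields must span at least three
bins (15 cm), show an in-field mean at least seven times the out-of-field
mean, and contain significant transients on at least 20% of the running
time spent inside the field.  A per-unit bootstrap permutes 50-frame
segments of the masked trace against the unshuffled behavior; the field
p-value is the fraction of shuffles in which any accepted candidate
appears anywhere on the track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environments import EnvironmentSpec
from .metrics import (
    SPEED_MIN_CM_S, binning_matrix, position_bins, smooth_map,
)
from .synthetic import SessionTrack

CANDIDATE_FRACTION = 0.25
MIN_WIDTH_BINS = 3
MIN_IN_OUT_RATIO = 7.0
MIN_TRANSIENT_OCCUPANCY = 0.2
N_BASELINE_BINS = 20
BOOTSTRAP_SEGMENT_FRAMES = 50


@dataclass
class PlaceField:
    """One accepted place field (bins inclusive, 0-based)."""

    start_bin: int
    end_bin: int
    peak_bin: int
    width_bins: int
    in_out_ratio: float
    transient_occupancy_fraction: float
    bootstrap_p: float

    def peak_m(self, bin_size_m: float) -> float:
        return (self.peak_bin + 0.5) * bin_size_m


def detect_candidate_fields(smoothed_map: np.ndarray) -> list[tuple[int, int]]:
    """Maximal contiguous runs of bins strictly above the 25% threshold."""
    lam = np.asarray(smoothed_map, dtype=float)
    if lam.size < N_BASELINE_BINS:
        raise ValueError("map needs at least 20 bins")
    baseline = float(np.sort(lam)[:N_BASELINE_BINS].mean())
    peak = float(lam.max())
    if peak <= baseline:
        return []
    thr = baseline + CANDIDATE_FRACTION * (peak - baseline)
    above = lam > thr
    out: list[tuple[int, int]] = []
    start = None
    for i, a in enumerate(above):
        if a and start is None:
            start = i
        elif not a and start is not None:
            out.append((start, i - 1))
            start = None
    if start is not None:
        out.append((start, above.size - 1))
    return out


def field_metrics(
    candidate: tuple[int, int],
    smoothed_map: np.ndarray,
    transient_bin_sums: np.ndarray,
    frame_bin_counts: np.ndarray,
    all_candidates: list[tuple[int, int]] | None = None,
) -> tuple[int, float, float]:
    """(width, in/out ratio, transient-occupancy fraction) of a candidate.

    ``transient_bin_sums`` counts running frames inside significant
    transients per bin; ``frame_bin_counts`` counts all running frames per
    bin.  The out-of-field region excludes every candidate field (a
    multi-field unit's other fields are not "outside"); the ratio is +inf
    when the out-of-field mean is zero or the out region is empty.
    """
    s, e = candidate
    lam = np.asarray(smoothed_map, dtype=float)
    inside = np.zeros(lam.size, dtype=bool)
    inside[s:e + 1] = True
    outside = ~inside
    for cs, ce in all_candidates or []:
        outside[cs:ce + 1] = False
    width = e - s + 1
    in_mean = float(lam[inside].mean())
    out_mean = float(lam[outside].mean()) if outside.any() else 0.0
    ratio = np.inf if out_mean <= 0 else in_mean / out_mean
    frames_in = frame_bin_counts[inside].sum()
    occ = (transient_bin_sums[inside].sum() / frames_in
           if frames_in > 0 else 0.0)
    return width, float(ratio), float(occ)


def _passes(width: int, ratio: float, occ: float) -> bool:
    return (width >= MIN_WIDTH_BINS and ratio >= MIN_IN_OUT_RATIO
            and occ >= MIN_TRANSIENT_OCCUPANCY)


def _accepted_candidates(
    smoothed_map: np.ndarray,
    transient_bin_sums: np.ndarray,
    frame_bin_counts: np.ndarray,
) -> list[tuple[tuple[int, int], tuple[int, float, float]]]:
    cands = detect_candidate_fields(smoothed_map)
    # two passes: the out-of-field region excludes other *field-like*
    # candidates (width and occupancy passers), not every noise clump —
    # a multi-field unit's other fields are not "outside", but weak bumps
    # under a shuffled trace are.
    fieldlike = []
    for cand in cands:
        w, _, occ = field_metrics(cand, smoothed_map, transient_bin_sums,
                                  frame_bin_counts, all_candidates=[cand])
        if w >= MIN_WIDTH_BINS and occ >= MIN_TRANSIENT_OCCUPANCY:
            fieldlike.append(cand)
    out = []
    for cand in cands:
        m = field_metrics(cand, smoothed_map, transient_bin_sums,
                          frame_bin_counts,
                          all_candidates=list({*fieldlike, cand}))
        if _passes(*m):
            out.append((cand, m))
    return out


def bootstrap_field_p(
    masked_sel: np.ndarray,
    flag_sel: np.ndarray,
    bin_idx: np.ndarray,
    n_bins: int,
    n_shuffles: int = 1000,
    segment_frames: int = BOOTSTRAP_SEGMENT_FRAMES,
    seed=None,
) -> float:
    """Fraction of segment-shuffled traces yielding any accepted field.

    ``masked_sel``/``flag_sel`` are the masked trace and transient flags at
    the analyzed context's running frames (the frames that enter the map)
    and ``bin_idx`` their spatial bins.  Whole 50-frame segments of that
    sequence are permuted jointly for trace and flags; a trailing partial
    segment stays in place.  Behavior is never shuffled, so the null
    preserves the unit's activity content while destroying its alignment
    to position.
    """
    if n_shuffles <= 0:
        raise ValueError("n_shuffles must be positive")
    rng = np.random.default_rng(seed)
    v = np.asarray(masked_sel, dtype=float)
    flag = np.asarray(flag_sel, dtype=float)
    n = v.size
    n_seg = n // segment_frames
    if n_seg < 2:
        raise ValueError("trace shorter than two bootstrap segments")
    seg_idx = np.arange(n_seg * segment_frames).reshape(n_seg, segment_frames)
    tail = np.arange(n_seg * segment_frames, n)
    counts = np.bincount(bin_idx, minlength=n_bins).astype(float)
    B = binning_matrix(bin_idx, n_bins)
    inv = np.where(counts > 0, 1.0 / np.maximum(counts, 1.0), 0.0)

    positives = 0
    for chunk in np.array_split(np.arange(n_shuffles),
                                max(1, n_shuffles // 200)):
        k = chunk.size
        perm = np.argsort(rng.random((k, n_seg)), axis=1)
        idx = np.concatenate(
            [seg_idx[perm].reshape(k, -1),
             np.broadcast_to(tail, (k, tail.size))], axis=1)
        vsel = v[idx]
        fsel = flag[idx]
        lam = (vsel @ B) * inv
        tsums = fsel @ B
        sm = np.atleast_2d(smooth_map(lam))
        for r in range(k):
            if _accepted_candidates(sm[r], tsums[r], counts):
                positives += 1
    return positives / n_shuffles


def find_place_fields(
    masked_dff: np.ndarray,
    transient_flag: np.ndarray,
    track: SessionTrack,
    env: EnvironmentSpec,
    context: str,
    n_shuffles: int = 1000,
    seed=None,
    speed_min_cm_s: float = SPEED_MIN_CM_S,
    accept_p: float = 0.05,
    bootstrap_accept_high: bool = False,
) -> list[PlaceField]:
    """All fields passing the candidate, criteria and bootstrap steps.

    ``bootstrap_accept_high`` flips the acceptance sense to the literal
    "p exceeds 0.05" reading.
    """
    sel = track.running_mask(speed_min_cm_s) & track.select(context)
    if not np.any(sel):
        return []
    bin_idx = position_bins(track.position_m[sel], env.bin_size_m, env.n_bins)
    counts = np.bincount(bin_idx, minlength=env.n_bins).astype(float)
    v = np.asarray(masked_dff, dtype=float)
    lam = np.bincount(bin_idx, weights=v[sel], minlength=env.n_bins)
    lam = np.where(counts > 0, lam / np.maximum(counts, 1.0), 0.0)
    tsums = np.bincount(bin_idx,
                        weights=np.asarray(transient_flag, dtype=float)[sel],
                        minlength=env.n_bins)
    sm = smooth_map(lam)
    accepted = _accepted_candidates(sm, tsums, counts)
    if not accepted:
        return []
    p = bootstrap_field_p(v[sel], np.asarray(transient_flag)[sel], bin_idx,
                          env.n_bins, n_shuffles=n_shuffles, seed=seed)
    ok = (p > accept_p) if bootstrap_accept_high else (p < accept_p)
    if not ok:
        return []
    fields = []
    for (s, e), (width, ratio, occ) in accepted:
        peak = int(s + np.argmax(sm[s:e + 1]))
        fields.append(PlaceField(
            start_bin=s, end_bin=e, peak_bin=peak, width_bins=width,
            in_out_ratio=ratio, transient_occupancy_fraction=occ,
            bootstrap_p=p,
        ))
    return fields
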