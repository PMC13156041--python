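"""Ordered rule-based classification of units into cue/spatial classes.

Each active unit is tested, in fixed order, for: generalization (place
fields in both contexts, map correlation >= 0.6), odor / reward / sound
association (fields within 40 cm after the stimulus in both contexts, and
a lagged map cross-correlation peaking inside the stimulus's displacement
window with r >= 0.6), single-object association (60-cm windows around
each object), multi-object association (per-run identification frequency
>= 0.7 for the same >= 2 objects in both contexts), grid-like periodicity
(field-count, transition, width, bin-assignment and in/out-ratio
criteria), then place, else nonspatial.  The first matching label wins, so
every unit receives exactly one label.

Window geometry is bin-resolved exactly as printed: "40 cm after onset" =
8 bins starting at the stimulus bin; "60 cm around the object" = 12 bins
starting three bins before the object bin.  Displacement windows are
+0.7..+1.3 m for odor and reward, 1.6..2.4 m (opposite sign) for the
sound, and 0.8-1.2 / 1.7-2.3 / 2.6-3.4 m for objects moved by 1, 2 or 3 m;
window signs follow the actual cue displacement in the environment pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .environments import (
    CONTEXTS, FAMILIAR, NOVEL, OBJECT_KINDS, STIMULUS_KINDS,
    EnvironmentSpec, circular_lag, cue_displacement,
)
from .placefields import PlaceField, detect_candidate_fields
from .remapping import pearson

XCORR_MIN_R = 0.6
MULTI_OBJECT_MIN_FREQ = 0.7
STIMULUS_WINDOW_BINS = 8     # 40 cm after onset
OBJECT_WINDOW_BINS = 12      # 60 cm around the object
OBJECT_WINDOW_LEAD_BINS = 3  # starting three bins before the object bin

#: displacement windows in meters, unsigned (sign taken from the layout)
STIMULUS_OFFSET_WINDOWS = {"odor": (0.7, 1.3), "reward": (0.7, 1.3),
                           "sound": (1.6, 2.4)}
OBJECT_OFFSET_WINDOWS = {1: (0.8, 1.2), 2: (1.7, 2.3), 3: (2.6, 3.4)}

CLASS_ORDER = ("generalizing", "odor", "reward", "sound", "object",
               "multi_object", "grid_like", "place", "nonspatial")


# ---------------------------------------------------------------------------
# window geometry


def stimulus_window_bins(env: EnvironmentSpec, kind: str) -> np.ndarray:
    """8 bins starting at the stimulus bin (clipped at the track end)."""
    s = env.position_to_bin(env.positions(kind)[0])
    return np.arange(s, min(s + STIMULUS_WINDOW_BINS, env.n_bins))

def object_window_bins(env: EnvironmentSpec, kind: str) -> np.ndarray:
    """12 bins starting three bins before the object bin (clipped)."""
    k = env.position_to_bin(env.positions(kind)[0])
    lo = max(k - OBJECT_WINDOW_LEAD_BINS, 0)
    return np.arange(lo, min(k - OBJECT_WINDOW_LEAD_BINS
                             + OBJECT_WINDOW_BINS, env.n_bins))


def offset_window(kind: str, displacement_m: float) -> tuple[float, float]:
    """Signed displacement window for a cue moved by ``displacement_m``."""
    if kind in STIMULUS_OFFSET_WINDOWS:
        lo, hi = STIMULUS_OFFSET_WINDOWS[kind]
    elif kind in OBJECT_KINDS:
        mag = int(np.clip(round(abs(displacement_m)), 1, 3))
        lo, hi = OBJECT_OFFSET_WINDOWS[mag]
    else:
        raise KeyError(f"no offset window for cue kind {kind!r}")
    if displacement_m < 0:
        return -hi, -lo
    return lo, hi


def lag_in_window(lag_m: float, window: tuple[float, float],
                  track_length_m: float) -> bool:
    """Circular membership of a lag in a signed window."""
    lo, hi = window
    return ((lag_m - lo) % track_length_m) <= (hi - lo) + 1e-9


# ---------------------------------------------------------------------------
# lagged cross-correlation


def lagged_map_xcorr(
    map_fam: np.ndarray, map_nov: np.ndarray,
    bin_size_m: float, max_lag_m: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r between the maps at every circular 1-bin shift.

    A positive lag means the novel map is displaced toward increasing
    positions relative to the familiar map (peak lag estimates the
    novel-minus-familiar cue displacement).
    """
    fam = np.asarray(map_fam, dtype=float)
    nov = np.asarray(map_nov, dtype=float)
    if fam.size != nov.size:
        raise ValueError("maps must have equal bin counts")
    n = fam.size
    lags_bins = np.arange(-(n // 2), n // 2)
    if max_lag_m is not None:
        max_bins = int(round(max_lag_m / bin_size_m))
        lags_bins = lags_bins[np.abs(lags_bins) <= max_bins]
    rs = np.array([pearson(fam, np.roll(nov, -l)) for l in lags_bins])
    return lags_bins * bin_size_m, rs


def peak_lag(map_fam, map_nov, bin_size_m) -> tuple[float, float]:
    """(lag_m, r) at the cross-correlation peak; (nan, nan) if undefined."""
    lags, rs = lagged_map_xcorr(map_fam, map_nov, bin_size_m)
    if np.all(np.isnan(rs)):
        return float("nan"), float("nan")
    k = int(np.nanargmax(rs))
    return float(lags[k]), float(rs[k])


# ---------------------------------------------------------------------------
# per-unit inputs


@dataclass
class UnitProfile:
    """Everything the classifier needs about one unit on one day."""

    unit_id: int
    active: bool
    fields: dict[str, list[PlaceField]]          # context -> accepted PFs
    maps: dict[str, np.ndarray]                  # context -> smoothed map
    run_maps: dict[str, np.ndarray]              # context -> (runs, bins)

    def has_fields(self, ctx: str) -> bool:
        return bool(self.fields.get(ctx))

    def peaks(self, ctx: str) -> list[int]:
        return [f.peak_bin for f in self.fields.get(ctx, [])]


@dataclass
class UnitClassification:
    unit_id: int
    label: str
    object_ids: tuple[str, ...] = ()
    peak_lag_m: float = float("nan")
    peak_lag_r: float = float("nan")
    grid_metrics: dict = dc_field(default_factory=dict)
    conjunctive: tuple[str, ...] | None = None
    n_fields: dict[str, int] = dc_field(default_factory=dict)


# ---------------------------------------------------------------------------
# checks


def check_generalizing(profile: UnitProfile) -> bool:
    if not (profile.has_fields(FAMILIAR) and profile.has_fields(NOVEL)):
        return False
    r = pearson(profile.maps[FAMILIAR], profile.maps[NOVEL])
    return bool(r >= XCORR_MIN_R)


def _cue_check(
    profile: UnitProfile,
    env_pair: tuple[EnvironmentSpec, EnvironmentSpec],
    kind: str,
    window_fn,
) -> tuple[bool, float, float]:
    """Shared machinery of the stimulus and single-object checks."""
    fam, nov = env_pair
    if not (fam.has(kind) and nov.has(kind)):
        return False, float("nan"), float("nan")
    for ctx in CONTEXTS:
        pfs = profile.fields.get(ctx, [])
        if not (1 <= len(pfs) <= 2):
            return False, float("nan"), float("nan")
    for ctx, env in zip(CONTEXTS, env_pair):
        window = set(window_fn(env, kind).tolist())
        if not any(p in window for p in profile.peaks(ctx)):
            return False, float("nan"), float("nan")
    lag, r = peak_lag(profile.maps[FAMILIAR], profile.maps[NOVEL],
                      fam.bin_size_m)
    if np.isnan(r) or r < XCORR_MIN_R:
        return False, lag, r
    d = cue_displacement(fam, nov, kind)
    win = offset_window(kind, d)
    ok = lag_in_window(lag, win, fam.track_length_m)
    return bool(ok), lag, r


def check_stimulus(
    profile: UnitProfile,
    env_pair: tuple[EnvironmentSpec, EnvironmentSpec],
    kind: str,
) -> tuple[bool, float, float]:
    if kind not in STIMULUS_KINDS:
        raise ValueError(f"not a stimulus kind: {kind!r}")
    return _cue_check(profile, env_pair, kind, stimulus_window_bins)


def check_single_object(
    profile: UnitProfile,
    env_pair: tuple[EnvironmentSpec, EnvironmentSpec],
) -> tuple[bool, str | None, float, float]:
    for kind in OBJECT_KINDS:
        if env_pair[0].has(kind) and env_pair[1].has(kind):
            ok, lag, r = _cue_check(profile, env_pair, kind,
                                    object_window_bins)
            if ok:
                return True, kind, lag, r
    return False, None, float("nan"), float("nan")


def object_vote_frequencies(
    run_maps: np.ndarray, env: EnvironmentSpec,
) -> dict[str, float]:
    """Per-object fraction of runs with a supra-threshold peak in window."""
    kinds = [k for k in OBJECT_KINDS if env.has(k)]
    votes = {k: 0 for k in kinds}
    n_runs = run_maps.shape[0]
    windows = {k: set(object_window_bins(env, k).tolist()) for k in kinds}
    for r in range(n_runs):
        cands = detect_candidate_fields(run_maps[r])
        peaks = [int(s + np.argmax(run_maps[r][s:e + 1])) for s, e in cands]
        for k in kinds:
            if any(p in windows[k] for p in peaks):
                votes[k] += 1
    return {k: votes[k] / n_runs for k in kinds} if n_runs else {}


def check_multi_object(
    profile: UnitProfile,
    env_pair: tuple[EnvironmentSpec, EnvironmentSpec],
) -> tuple[bool, tuple[str, ...]]:
    if not (profile.has_fields(FAMILIAR) and profile.has_fields(NOVEL)):
        return False, ()
    rep: dict[str, set[str]] = {}
    for ctx, env in zip(CONTEXTS, env_pair):
        freq = object_vote_frequencies(profile.run_maps[ctx], env)
        rep[ctx] = {k for k, f in freq.items()
                    if f >= MULTI_OBJECT_MIN_FREQ}
    same = rep[FAMILIAR] == rep[NOVEL]
    if same and len(rep[FAMILIAR]) >= 2:
        return True, tuple(sorted(rep[FAMILIAR]))
    return False, ()


def grid_metrics(
    smoothed_map: np.ndarray,
    fields: list[PlaceField],
    track_length_m: float,
    bin_size_m: float,
) -> dict:
    """Raw quantities entering the grid-like criteria for one context."""
    lam = np.asarray(smoothed_map, dtype=float)
    widths = np.array([f.width_bins for f in fields]) * bin_size_m
    W = float(widths.mean()) if widths.size else 0.0
    baseline = float(np.sort(lam)[:20].mean())
    rng_ = float(lam.max()) - baseline
    thr_in = baseline + 0.25 * rng_
    thr_out = baseline + 0.10 * rng_
    in_bins = lam > thr_in
    out_bins = lam < thr_out
    assigned = in_bins | out_bins
    labels = in_bins[assigned].astype(int)
    transitions = int(np.sum(np.abs(np.diff(labels)))) if labels.size else 0
    in_mean = float(lam[in_bins].mean()) if in_bins.any() else 0.0
    out_mean = float(lam[out_bins].mean()) if out_bins.any() else 0.0
    ratio = np.inf if out_mean <= 0 else in_mean / max(out_mean, 1e-12)
    return {
        "n_fields": len(fields),
        "mean_width_m": W,
        "largest_width_m": float(widths.max()) if widths.size else 0.0,
        "transitions": transitions,
        "assigned_fraction": float(assigned.mean()),
        "in_out_activity_ratio": float(ratio),
    }


def check_grid_like(
    smoothed_map: np.ndarray,
    fields: list[PlaceField],
    track_length_m: float,
    bin_size_m: float,
    alt_transition_parse: bool = False,
) -> tuple[bool, dict]:
    """Grid criteria for one context's map and accepted fields.

    Transition criterion parsed as transitions > L / (5 * W); the literal
    alternative (L / 5) * W is available via ``alt_transition_parse``.
    """
    m = grid_metrics(smoothed_map, fields, track_length_m, bin_size_m)
    W = m["mean_width_m"]
    if m["n_fields"] < 2 or W <= 0:
        return False, m
    need = (track_length_m / 5.0) * W if alt_transition_parse \
        else track_length_m / (5.0 * W)
    ok = (
        m["transitions"] > need
        and m["largest_width_m"] < 5.0 * W
        and m["assigned_fraction"] >= 0.3
        and m["in_out_activity_ratio"] > 2.0
    )
    return bool(ok), m


def check_conjunctive(
    profile: UnitProfile,
    env_pair: tuple[EnvironmentSpec, EnvironmentSpec],
    label: str,
) -> tuple[str, ...] | None:
    """Cue set if the unit reliably encodes >= 2 modalities in both contexts.

    Multi-object units are excluded from this assay.
    """
    if label == "multi_object":
        return None
    for ctx in CONTEXTS:
        if len(profile.fields.get(ctx, [])) < 2:
            return None
    rep: dict[str, set[str]] = {}
    for ctx, env in zip(CONTEXTS, env_pair):
        windows: dict[str, set[int]] = {}
        for kind in STIMULUS_KINDS:
            if env.has(kind):
                windows[kind] = set(stimulus_window_bins(env, kind).tolist())
        for kind in OBJECT_KINDS:
            if env.has(kind):
                windows[kind] = set(object_window_bins(env, kind).tolist())
        cues = set()
        for p in profile.peaks(ctx):
            hit = [k for k, w in windows.items() if p in w]
            if not hit:
                return None  # every PF peak must sit in a cue window
            cues.update(hit)
        rep[ctx] = cues
    if len(rep[FAMILIAR]) >= 2 and rep[FAMILIAR] == rep[NOVEL]:
        return tuple(sorted(rep[FAMILIAR]))
    return None


def classify_unit(
    profile: UnitProfile,
    env_pair: tuple[EnvironmentSpec, EnvironmentSpec],
    alt_transition_parse: bool = False,
) -> UnitClassification:
    """First matching label in the fixed order wins."""
    fam, nov = env_pair
    n_fields = {ctx: len(profile.fields.get(ctx, [])) for ctx in CONTEXTS}
    out = UnitClassification(unit_id=profile.unit_id, label="nonspatial",
                             n_fields=n_fields)
    if check_generalizing(profile):
        out.label = "generalizing"
        out.peak_lag_r = pearson(profile.maps[FAMILIAR], profile.maps[NOVEL])
        out.peak_lag_m = 0.0
    else:
        for kind in STIMULUS_KINDS:
            if fam.has(kind) and nov.has(kind):
                ok, lag, r = check_stimulus(profile, env_pair, kind)
                if ok:
                    out.label = kind
                    out.peak_lag_m, out.peak_lag_r = lag, r
                    break
        if out.label == "nonspatial":
            ok, kind, lag, r = check_single_object(profile, env_pair)
            if ok:
                out.label = "object"
                out.object_ids = (kind,)
                out.peak_lag_m, out.peak_lag_r = lag, r
        if out.label == "nonspatial":
            ok, objs = check_multi_object(profile, env_pair)
            if ok:
                out.label = "multi_object"
                out.object_ids = objs
        if out.label == "nonspatial":
            for ctx in CONTEXTS:
                ok, gm = check_grid_like(
                    profile.maps[ctx], profile.fields.get(ctx, []),
                    fam.track_length_m, fam.bin_size_m,
                    alt_transition_parse=alt_transition_parse)
                if ctx == FAMILIAR or ok:
                    out.grid_metrics = gm
                if ok:
                    out.label = "grid_like"
                    break
        if out.label == "nonspatial" and any(n_fields.values()):
            out.label = "place"
    out.conjunctive = check_conjunctive(profile, env_pair, out.label)
    return out
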