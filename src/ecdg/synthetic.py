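"""Synthetic virtual-navigation sessions with ground-truth tuned units.

Emulates the study conditions of a head-fixed two-photon experiment on a
4-m virtual linear track: 30 runs per day in alternating familiar/novel
blocks of five, a single imaging plane at 15.5 Hz, and ~90-145 recorded
units whose classes span place, generalizing, odor-, reward-, sound-,
object-, multi-object-anchored, grid-like and untuned activity.  Raw
fluorescence is rendered with a GCaMP6s-like forward model: Poisson-like
event trains following each unit's positional tuning, convolved with a
mono-exponential decay kernel, on a noisy baseline.

Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .environments import (
    CONTEXTS, FAMILIAR, NOVEL, OBJECT_KINDS, EnvironmentSpec,
    cue_displacement,
)

FRAME_RATE_HZ = 15.5

UNIT_CLASSES = (
    "place", "generalizing", "odor", "reward", "sound",
    "object", "multi_object", "grid_like", "nonspatial",
)

#: default class mixture of one simulated session (fractions sum to 1)
DEFAULT_CLASS_MIX = {
    "place": 0.35, "generalizing": 0.06, "odor": 0.05, "reward": 0.03,
    "sound": 0.03, "object": 0.06, "multi_object": 0.04,
    "grid_like": 0.08, "nonspatial": 0.30,
}

#: GCaMP6s-like decay constant for small axonal/somatic structures
DEFAULT_KERNEL_TAU_S = 0.8
DEFAULT_AMPLITUDE_SIGMA = 6.0
DEFAULT_NOISE_SIGMA = 1.0
DEFAULT_BASELINE_F0 = 50.0


@dataclass
class SessionTrack:
    """Per-frame behavior of one recording day."""

    frame_time_s: np.ndarray
    position_m: np.ndarray
    speed_cm_s: np.ndarray
    context_id: np.ndarray  # unicode array, "familiar" | "novel"
    run_index: np.ndarray
    block_index: np.ndarray
    lick_flag: np.ndarray
    blank_flag: np.ndarray
    frame_rate_hz: float = FRAME_RATE_HZ

    @property
    def n_frames(self) -> int:
        return self.frame_time_s.size

    def running_mask(self, speed_min_cm_s: float = 5.0) -> np.ndarray:
        return (self.speed_cm_s >= speed_min_cm_s) & ~self.blank_flag

    def select(self, context: str | None = None, runs=None) -> np.ndarray:
        """Boolean mask of non-blank frames in a context and/or run set."""
        m = ~self.blank_flag
        if context is not None:
            m &= self.context_id == context
        if runs is not None:
            m &= np.isin(self.run_index, np.asarray(list(runs)))
        return m

    def runs_of(self, context: str) -> np.ndarray:
        sel = (self.context_id == context) & ~self.blank_flag
        return np.unique(self.run_index[sel])


@dataclass
class GroundTruthUnit:
    """Latent tuning of one simulated unit.

    ``tuning`` maps context -> list of (center_m, width_m, peak_rate_hz)
    Gaussian fields; ``anchors`` records which cue(s) a cue class is locked
    to (object kinds for object/multi-object units).
    """

    unit_id: int
    source: str  # "LEC" | "MEC" | "GC"
    true_class: str
    tuning: dict[str, list[tuple[float, float, float]]]
    anchors: tuple[str, ...] = ()
    baseline_rate_hz: float = 0.0
    amplitude_sigma: float = DEFAULT_AMPLITUDE_SIGMA
    baseline_noise_sigma: float = DEFAULT_NOISE_SIGMA
    kernel_tau_s: float = DEFAULT_KERNEL_TAU_S


@dataclass
class RawTraceSet:
    """Raw fluorescence (units x frames, arbitrary units)."""

    fluorescence: np.ndarray
    frame_rate_hz: float = FRAME_RATE_HZ
    event_frames: list[np.ndarray] | None = None  # ground-truth bookkeeping

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError("fluorescence contains non-finite values")

    @property
    def n_units(self) -> int:
        return self.fluorescence.shape[0]

    @property
    def n_frames(self) -> int:
        return self.fluorescence.shape[1]


@dataclass
class DaySession:
    track: SessionTrack
    raw: RawTraceSet


@dataclass
class SessionDataset:
    """One multi-day experiment: environment pair, units, per-day data."""

    env_familiar: EnvironmentSpec
    env_novel: EnvironmentSpec
    units: list[GroundTruthUnit]
    days: list[DaySession]
    provenance: dict = field(default_factory=dict)

    @property
    def env_pair(self) -> tuple[EnvironmentSpec, EnvironmentSpec]:
        return self.env_familiar, self.env_novel

    def env_of(self, context: str) -> EnvironmentSpec:
        return self.env_familiar if context == FAMILIAR else self.env_novel


# ---------------------------------------------------------------------------
# behavior


def simulate_behavior(
    env_pair: tuple[EnvironmentSpec, EnvironmentSpec],
    n_runs_per_context: int = 15,
    block_size: int = 5,
    frame_rate: float = FRAME_RATE_HZ,
    speed_mean_cm_s: float = 20.0,
    speed_sd_cm_s: float = 8.0,
    speed_max_cm_s: float = 70.0,
    blank_range_s: tuple[float, float] = (4.0, 10.0),
    seed=None,
) -> SessionTrack:
    """Simulate one day of alternating familiar/novel runs.

    Speed follows an Ornstein-Uhlenbeck process around ``speed_mean_cm_s``
    clipped to [0, ``speed_max_cm_s``]; position increases monotonically
    from 0 to L within each run; runs are separated by 4-10-s blank
    (teleport) gaps.  ``speed_max_cm_s`` is kept below bin_size*frame_rate
    so every 5-cm bin collects at least one frame on every run.
    """
    if frame_rate <= 0 or block_size <= 0:
        raise ValueError("frame rate and block size must be positive")
    if n_runs_per_context % block_size:
        raise ValueError("n_runs_per_context must be divisible by block_size")
    rng = np.random.default_rng(seed)
    fam, nov = env_pair
    L = fam.track_length_m
    dt = 1.0 / frame_rate
    theta = 0.5  # OU mean-reversion rate, 1/s
    sig = speed_sd_cm_s * math.sqrt(2.0 * theta)

    n_blocks = 2 * n_runs_per_context // block_size
    cols: dict[str, list] = {k: [] for k in (
        "t", "x", "v", "ctx", "run", "block", "lick", "blank")}
    t = 0.0
    run = 0
    for block in range(n_blocks):
        ctx = FAMILIAR if block % 2 == 0 else NOVEL
        env = fam if ctx == FAMILIAR else nov
        reward_pos = np.asarray(env.positions("reward"))
        for _ in range(block_size):
            v = float(np.clip(rng.normal(speed_mean_cm_s, speed_sd_cm_s),
                              0.0, speed_max_cm_s))
            x = 0.0
            while x < L:
                cols["t"].append(t)
                cols["x"].append(x)
                cols["v"].append(v)
                cols["ctx"].append(ctx)
                cols["run"].append(run)
                cols["block"].append(block)
                in_zone = np.any(np.abs(x - reward_pos) <= 0.15)
                lick_rate = 6.0 if in_zone else 0.3
                cols["lick"].append(rng.random() < lick_rate * dt)
                cols["blank"].append(False)
                x = min(x + (v / 100.0) * dt, L)
                if x >= L:  # final frame at the track end
                    cols["t"].append(t + dt)
                    cols["x"].append(L)
                    cols["v"].append(v)
                    cols["ctx"].append(ctx)
                    cols["run"].append(run)
                    cols["block"].append(block)
                    cols["lick"].append(False)
                    cols["blank"].append(False)
                    t += dt
                t += dt
                v = v + theta * (speed_mean_cm_s - v) * dt \
                    + sig * math.sqrt(dt) * rng.standard_normal()
                v = float(np.clip(v, 0.0, speed_max_cm_s))
            # teleport gap
            gap = rng.uniform(*blank_range_s)
            n_gap = int(round(gap * frame_rate))
            next_ctx = ctx if (run + 1) % block_size else (
                NOVEL if ctx == FAMILIAR else FAMILIAR)
            if run + 1 == 2 * n_runs_per_context:
                next_ctx = ctx
            for _ in range(n_gap):
                cols["t"].append(t)
                cols["x"].append(0.0)
                cols["v"].append(0.0)
                cols["ctx"].append(next_ctx)
                cols["run"].append(run)  # gap attributed to finished run
                cols["block"].append(block)
                cols["lick"].append(False)
                cols["blank"].append(True)
                t += dt
            run += 1
    return SessionTrack(
        frame_time_s=np.asarray(cols["t"], dtype=float),
        position_m=np.asarray(cols["x"], dtype=float),
        speed_cm_s=np.asarray(cols["v"], dtype=float),
        context_id=np.asarray(cols["ctx"]),
        run_index=np.asarray(cols["run"], dtype=np.int32),
        block_index=np.asarray(cols["block"], dtype=np.int32),
        lick_flag=np.asarray(cols["lick"], dtype=bool),
        blank_flag=np.asarray(cols["blank"], dtype=bool),
        frame_rate_hz=frame_rate,
    )


# ---------------------------------------------------------------------------
# units


def _stimulus_window(env: EnvironmentSpec, kind: str) -> tuple[float, float]:
    # 8 bins starting at the stimulus bin = [cue_bin*b, cue_bin*b + 0.40) m
    b = env.bin_size_m
    lo = env.position_to_bin(env.positions(kind)[0]) * b
    return lo, lo + 8 * b


def _object_window(env: EnvironmentSpec, kind: str) -> tuple[float, float]:
    # 12 bins starting three bins before the object bin
    b = env.bin_size_m
    k = env.position_to_bin(env.positions(kind)[0])
    return (k - 3) * b, (k + 9) * b


def _matches_same_cue(pos_fam: float, pos_nov: float,
                      fam: EnvironmentSpec, nov: EnvironmentSpec,
                      margin_m: float = 0.0) -> bool:
    """True if one cue's windows contain both positions (fam and nov)."""
    for kind, window_fn in (
            [(k, _stimulus_window) for k in ("odor", "sound", "reward")]
            + [(k, _object_window) for k in OBJECT_KINDS]):
        if not (fam.has(kind) and nov.has(kind)):
            continue
        lo_f, hi_f = window_fn(fam, kind)
        lo_n, hi_n = window_fn(nov, kind)
        if (lo_f - margin_m <= pos_fam < hi_f + margin_m
                and lo_n - margin_m <= pos_nov < hi_n + margin_m):
            return True
    return False


def _apportion(class_mix: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of a mixture into exact counts."""
    raw = {k: v * n for k, v in class_mix.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def simulate_units(
    class_mix: dict[str, float],
    n_units: int,
    env_pair: tuple[EnvironmentSpec, EnvironmentSpec],
    seed=None,
    exact_counts: bool = False,
    source: str = "MEC",
    amplitude_sigma: float = DEFAULT_AMPLITUDE_SIGMA,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    kernel_tau_s: float = DEFAULT_KERNEL_TAU_S,
    peak_rate_hz: float = 2.2,
) -> list[GroundTruthUnit]:
    """Draw ground-truth units whose tuning satisfies their class geometry."""
    unknown = set(class_mix) - set(UNIT_CLASSES)
    if unknown:
        raise ValueError(f"unknown unit classes {sorted(unknown)}")
    if n_units and abs(sum(class_mix.values()) - 1.0) > 1e-6:
        raise ValueError("class mix proportions must sum to 1")
    rng = np.random.default_rng(seed)
    fam, nov = env_pair
    L = fam.track_length_m

    if exact_counts:
        counts = _apportion(class_mix, n_units)
        labels = [k for k, c in counts.items() for _ in range(c)]
    else:
        keys = list(class_mix)
        labels = list(rng.choice(keys, size=n_units,
                                 p=[class_mix[k] for k in keys]))

    units: list[GroundTruthUnit] = []
    for i, label in enumerate(labels):
        tuning: dict[str, list[tuple[float, float, float]]] = {
            FAMILIAR: [], NOVEL: []}
        anchors: tuple[str, ...] = ()
        baseline_rate = 0.0
        if label == "place":
            for _ in range(100):
                cf = rng.uniform(0.3, L - 0.3)
                cn = rng.uniform(0.3, L - 0.3)
                if abs(cn - cf) < 0.8:
                    continue  # smoothed/smeared maps would still correlate
                # margin covers indicator smearing of the detected peak
                if _matches_same_cue(cf, cn, fam, nov, margin_m=0.25):
                    continue  # would satisfy a cue class's geometry
                break
            w = rng.uniform(0.2, 0.3)
            tuning[FAMILIAR] = [(cf, w, peak_rate_hz)]
            tuning[NOVEL] = [(cn, w, peak_rate_hz)]
        elif label == "generalizing":
            c = rng.uniform(0.3, L - 0.3)
            w = rng.uniform(0.2, 0.3)
            for ctx in CONTEXTS:
                tuning[ctx] = [(c + rng.normal(0, 0.02), w, peak_rate_hz)]
        elif label in ("odor", "reward", "sound"):
            # the expressed calcium peak trails the center by the kernel
            # smear (~0.15 m at 20 cm/s); the class demands it stay within
            # the 40-cm post-stimulus window
            off = rng.uniform(0.05, 0.15)
            w = 0.2
            for ctx, env in zip(CONTEXTS, env_pair):
                if not env.has(label):
                    raise ValueError(
                        f"cannot place a {label} unit: cue missing from env")
                tuning[ctx] = [(env.positions(label)[0] + off, w, peak_rate_hz)]
            anchors = (label,)
        elif label == "object":
            kinds = [k for k in OBJECT_KINDS if fam.has(k) and nov.has(k)]
            if not kinds:
                raise ValueError("cannot place an object unit: no objects")
            kind = str(rng.choice(kinds))
            off = rng.uniform(-0.1, 0.25)
            w = 0.2
            for ctx, env in zip(CONTEXTS, env_pair):
                c = float(np.clip(env.positions(kind)[0] + off, 0.05, L - 0.05))
                tuning[ctx] = [(c, w, peak_rate_hz)]
            anchors = (kind,)
        elif label == "multi_object":
            # two objects whose displacements differ (no circular aliasing)
            pairs = []
            for a in OBJECT_KINDS:
                for b_ in OBJECT_KINDS:
                    if a < b_ and fam.has(a) and fam.has(b_):
                        da = cue_displacement(fam, nov, a)
                        db = cue_displacement(fam, nov, b_)
                        # the two fields must not alias under circular
                        # shifting and must stay separable given the
                        # indicator's forward smear
                        sep = min(
                            abs(fam.positions(a)[0] - fam.positions(b_)[0]),
                            abs(nov.positions(a)[0] - nov.positions(b_)[0]))
                        if (abs((da - db) % L) > 0.5
                                and abs((db - da) % L) > 0.5
                                and sep >= 1.1):
                            pairs.append((a, b_))
            if not pairs:
                raise ValueError("no usable object pair for multi_object unit")
            a, b_ = pairs[rng.integers(len(pairs))]
            w = 0.2
            for ctx, env in zip(CONTEXTS, env_pair):
                fields = []
                for kind in (a, b_):
                    off = rng.uniform(-0.1, 0.15)
                    c = float(np.clip(env.positions(kind)[0] + off,
                                      0.05, L - 0.05))
                    # multi-object identification votes run-by-run, so the
                    # class demands near-every-run reliability at each object
                    fields.append((c, w, peak_rate_hz * 1.7))
                tuning[ctx] = fields
            anchors = (a, b_)
        elif label == "grid_like":
            spacing = rng.uniform(1.15, 1.35)
            w = 0.12
            phase_f = rng.uniform(0.2, spacing)
            phase_n = 0.2 + (phase_f - 0.2 + spacing / 2
                             + rng.uniform(-0.08, 0.08)) % spacing
            for ctx, phase in ((FAMILIAR, phase_f), (NOVEL, phase_n)):
                centers = np.arange(phase, L - 0.1, spacing)
                tuning[ctx] = [(float(c), w, peak_rate_hz * 1.3)
                               for c in centers]
        elif label == "nonspatial":
            baseline_rate = 0.15
        else:  # pragma: no cover
            raise AssertionError(label)
        units.append(GroundTruthUnit(
            unit_id=i, source=source, true_class=label, tuning=tuning,
            anchors=anchors, baseline_rate_hz=baseline_rate,
            amplitude_sigma=amplitude_sigma,
            baseline_noise_sigma=noise_sigma, kernel_tau_s=kernel_tau_s,
        ))
    return units


# ---------------------------------------------------------------------------
# fluorescence forward model


def _event_rate(unit: GroundTruthUnit, track: SessionTrack) -> np.ndarray:
    """Per-frame event rate (Hz) from the unit's tuning along the track."""
    rate = np.full(track.n_frames, unit.baseline_rate_hz, dtype=float)
    for ctx in CONTEXTS:
        sel = track.context_id == ctx
        if not np.any(sel) or not unit.tuning.get(ctx):
            continue
        x = track.position_m[sel]
        r = np.zeros(x.size)
        for center, width, peak in unit.tuning[ctx]:
            r += peak * np.exp(-0.5 * ((x - center) / width) ** 2)
        rate[sel] = np.maximum(rate[sel], r + unit.baseline_rate_hz)
    rate[track.blank_flag] = 0.0
    return rate


def tuning_curve_activity(units: list[GroundTruthUnit],
                          track: SessionTrack) -> np.ndarray:
    """Deterministic rate-proxy activity (units x frames).

    Each unit's trace is its positional event rate evaluated along the
    track — the noiseless limit of the forward model with the event
    sampling, indicator kernel and measurement noise all removed.  Useful
    as an exactly-tuned population for decoder limit checks.
    """
    return np.stack([_event_rate(u, track) for u in units])


def expressed_field_peak_bin(
    unit: GroundTruthUnit,
    event_frames: np.ndarray,
    track: SessionTrack,
    env: EnvironmentSpec,
    context: str,
    speed_min_cm_s: float = 5.0,
) -> int:
    """Peak bin of the field the unit actually expressed in one session.

    Builds the noise-free signal (the recorded ground-truth event train
    convolved with the unit's decay kernel), bins it like the analysis
    does, and returns the smoothed-map argmax.  Detected field peaks are
    judged against this expressed field: the event realization, not the
    detector, owns the sampling scatter around the latent tuning center.
    """
    from scipy.signal import lfilter

    dt = 1.0 / track.frame_rate_hz
    imp = np.zeros(track.n_frames)
    imp[np.asarray(event_frames, dtype=int)] = 1.0
    decay = math.exp(-dt / unit.kernel_tau_s)
    clean = lfilter([1.0], [1.0, -decay], imp)
    sel = track.running_mask(speed_min_cm_s) & track.select(context)
    bins = np.clip(np.floor(track.position_m[sel] / env.bin_size_m)
                   .astype(int), 0, env.n_bins - 1)
    counts = np.bincount(bins, minlength=env.n_bins).astype(float)
    lam = np.bincount(bins, weights=clean[sel], minlength=env.n_bins)
    lam = np.where(counts > 0, lam / np.maximum(counts, 1.0), 0.0)
    from .metrics import smooth_map  # deferred: metrics imports this module

    return int(np.argmax(smooth_map(lam)))


def expected_peak_bin(
    unit: GroundTruthUnit,
    context: str,
    env: EnvironmentSpec,
    mean_speed_cm_s: float = 20.0,
) -> int:
    """Bin of the unit's expected fluorescence peak in one context.

    The calcium peak sits downstream of the event-rate peak because the
    indicator decays while the animal keeps running: the expected masked
    activity profile is the positional event rate convolved with a
    forward exponential of space constant tau * mean speed.  This, not
    the tuning center, is the ground truth for detected field peaks.
    """
    dx = 0.005
    L = env.track_length_m
    x = np.arange(0.0, L, dx)
    rate = np.zeros(x.size)
    for center, width, peak in unit.tuning[context]:
        rate += peak * np.exp(-0.5 * ((x - center) / width) ** 2)
    space_const = unit.kernel_tau_s * mean_speed_cm_s / 100.0
    kernel = np.exp(-np.arange(0, 5 * space_const, dx) / space_const)
    prof = np.convolve(rate, kernel)[: x.size]
    return env.position_to_bin(float(x[np.argmax(prof)]))


def render_fluorescence(
    units: list[GroundTruthUnit],
    track: SessionTrack,
    seed=None,
    baseline_f0: float = DEFAULT_BASELINE_F0,
) -> RawTraceSet:
    """Render raw traces: baseline + kernel-convolved events + noise.

    Each unit's trace is ``f0 + sum(events) * exp-decay kernel + N(0, sigma)``
    with event probability per frame following the unit's positional tuning
    (zero during blanks) and event amplitude expressed in units of the
    baseline noise sigma (amplitude is taken in arbitrary units when the
    unit is noiseless).
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / track.frame_rate_hz
    n = track.n_frames
    traces = np.empty((len(units), n), dtype=float)
    event_frames: list[np.ndarray] = []
    for i, unit in enumerate(units):
        rate = _event_rate(unit, track)
        events = rng.random(n) < rate * dt
        idx = np.flatnonzero(events)
        event_frames.append(idx)
        scale = unit.baseline_noise_sigma if unit.baseline_noise_sigma > 0 else 1.0
        amps = np.zeros(n)
        amps[idx] = unit.amplitude_sigma * scale * rng.uniform(0.8, 1.2, idx.size)
        decay = math.exp(-dt / unit.kernel_tau_s)
        signal = lfilter([1.0], [1.0, -decay], amps)
        noise = (unit.baseline_noise_sigma * rng.standard_normal(n)
                 if unit.baseline_noise_sigma > 0 else 0.0)
        traces[i] = baseline_f0 + signal + noise
    return RawTraceSet(traces, frame_rate_hz=track.frame_rate_hz,
                       event_frames=event_frames)


def simulate_session(
    kind: str = "openfield",
    n_units: int = 100,
    days: int = 1,
    class_mix: dict[str, float] | None = None,
    n_runs_per_context: int = 15,
    seed: int = 0,
    exact_counts: bool = False,
    source: str = "MEC",
    **unit_kwargs,
) -> SessionDataset:
    """Convenience wrapper: environments + units + per-day behavior/traces."""
    from .environments import default_environment_pair

    ss = np.random.SeedSequence(seed)
    s_units, *s_days = ss.spawn(1 + 2 * days)
    env_pair = default_environment_pair(kind)
    units = simulate_units(
        class_mix or DEFAULT_CLASS_MIX, n_units, env_pair,
        seed=s_units, exact_counts=exact_counts, source=source, **unit_kwargs)
    day_sessions = []
    for d in range(days):
        track = simulate_behavior(
            env_pair, n_runs_per_context=n_runs_per_context,
            seed=s_days[2 * d])
        raw = render_fluorescence(units, track, seed=s_days[2 * d + 1])
        day_sessions.append(DaySession(track=track, raw=raw))
    return SessionDataset(
        env_familiar=env_pair[0], env_novel=env_pair[1], units=units,
        days=day_sessions,
        provenance={"seed": seed, "kind": kind, "n_units": n_units,
                    "days": days, "n_runs_per_context": n_runs_per_context},
    )
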