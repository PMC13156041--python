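"""Population-vector decoding of context and position.

Runs are split into interleaved template and test halves per context.
Templates hold each unit's mean masked dF/F per 5-cm bin and context
(spatial mode, 2 x 80 rows) or per context only (mean-rate mode, 2 rows).
Test activity is resampled into 100-ms population vectors; each vector is
assigned to the template row with the highest Pearson correlation
(argmax over rows; ties -> lowest row index; zero-variance vectors are
excluded).  Context error is the 0/1 mis-context rate; spatial error is
the mean absolute decoded-vs-true distance in cm irrespective of context.
Chance levels come from permuting the true labels across time bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .environments import CONTEXTS, FAMILIAR, NOVEL, EnvironmentSpec
from .metrics import SPEED_MIN_CM_S, position_bins
from .synthetic import SessionTrack

DECODE_BIN_S = 0.1
N_SHUFFLES_CHANCE = 15
N_DRAWS = 15
FIXED_ENSEMBLE = 75


def split_runs(runs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interleaved halves: 1st, 3rd, ... -> template; 2nd, 4th, ... -> test."""
    runs = np.sort(np.asarray(runs))
    if runs.size < 2:
        raise ValueError("need at least 2 runs per context to split")
    return runs[::2], runs[1::2]


@dataclass
class TemplateSet:
    """Mean-activity templates: rows are (context, bin) or context only."""

    matrix: np.ndarray          # (rows, units)
    mode: str                   # "spatial" | "mean_rate"
    n_bins: int
    row_context: np.ndarray     # per-row context index (0 fam, 1 nov)
    row_bin: np.ndarray         # per-row spatial bin (-1 in mean_rate mode)
    template_runs: dict[str, np.ndarray] = dc_field(default_factory=dict)
    flagged_units: np.ndarray | None = None


def build_templates(
    masked_dff: np.ndarray,
    track: SessionTrack,
    env: EnvironmentSpec,
    template_runs: dict[str, np.ndarray],
    mode: str = "spatial",
    speed_min_cm_s: float = SPEED_MIN_CM_S,
) -> TemplateSet:
    """Per-(context, bin) or per-context mean activity of every unit."""
    if mode not in ("spatial", "mean_rate"):
        raise ValueError(f"unknown template mode {mode!r}")
    X = np.atleast_2d(np.asarray(masked_dff, dtype=float))
    n_units = X.shape[0]
    n_bins = env.n_bins
    rows, row_ctx, row_bin = [], [], []
    flagged = np.zeros(n_units, dtype=bool)
    for ci, ctx in enumerate(CONTEXTS):
        sel = (track.running_mask(speed_min_cm_s)
               & track.select(ctx, template_runs[ctx]))
        if not np.any(sel):
            raise ValueError(f"no template frames in context {ctx}")
        xs = X[:, sel]
        if mode == "spatial":
            bins = position_bins(track.position_m[sel], env.bin_size_m,
                                 n_bins)
            counts = np.bincount(bins, minlength=n_bins).astype(float)
            sums = np.stack([
                np.bincount(bins, weights=xs[u], minlength=n_bins)
                for u in range(n_units)])
            lam = np.where(counts > 0, sums / np.maximum(counts, 1.0), 0.0)
            rows.append(lam.T)          # (bins, units)
            row_ctx.extend([ci] * n_bins)
            row_bin.extend(range(n_bins))
        else:
            rows.append(xs.mean(axis=1)[None, :])
            row_ctx.append(ci)
            row_bin.append(-1)
        flagged |= ~np.any(xs != 0, axis=1)
    return TemplateSet(
        matrix=np.concatenate(rows, axis=0), mode=mode, n_bins=n_bins,
        row_context=np.asarray(row_ctx), row_bin=np.asarray(row_bin),
        template_runs={k: np.asarray(v) for k, v in template_runs.items()},
        flagged_units=flagged,
    )


@dataclass
class DecodedSeries:
    """Per-100-ms-bin decoding outcome on the test runs."""

    time_s: np.ndarray
    run_index: np.ndarray
    true_context: np.ndarray     # 0 familiar, 1 novel
    true_bin: np.ndarray
    decoded_context: np.ndarray
    decoded_bin: np.ndarray
    peak_r: np.ndarray
    excluded: np.ndarray         # zero-variance vectors, no error weight

    @property
    def included(self) -> np.ndarray:
        return ~self.excluded


def _population_vectors(
    masked_dff: np.ndarray,
    track: SessionTrack,
    env: EnvironmentSpec,
    test_runs: dict[str, np.ndarray],
    dt_s: float,
    speed_min_cm_s: float,
):
    X = np.atleast_2d(np.asarray(masked_dff, dtype=float))
    sel = np.zeros(track.n_frames, dtype=bool)
    for ctx in CONTEXTS:
        sel |= (track.running_mask(speed_min_cm_s)
                & track.select(ctx, test_runs[ctx]))
    idx = np.flatnonzero(sel)
    tbin = np.floor(track.frame_time_s[idx] / dt_s).astype(np.int64)
    # group frames sharing a 100-ms bin; frames are time-ordered
    uniq, start = np.unique(tbin, return_index=True)
    groups = np.split(idx, start[1:])
    n = len(groups)
    V = np.empty((n, X.shape[0]))
    time_s = np.empty(n)
    run_index = np.empty(n, dtype=int)
    true_ctx = np.empty(n, dtype=int)
    true_bin = np.empty(n, dtype=int)
    for g, frames in enumerate(groups):
        V[g] = X[:, frames].mean(axis=1)
        time_s[g] = track.frame_time_s[frames[0]]
        run_index[g] = track.run_index[frames[0]]
        true_ctx[g] = int(track.context_id[frames[0]] == NOVEL)
        pos = track.position_m[frames].mean()
        true_bin[g] = position_bins(np.array([pos]), env.bin_size_m,
                                    env.n_bins)[0]
    return V, time_s, run_index, true_ctx, true_bin


def decode_timebins(
    masked_dff: np.ndarray,
    track: SessionTrack,
    env: EnvironmentSpec,
    templates: TemplateSet,
    test_runs: dict[str, np.ndarray],
    dt_s: float = DECODE_BIN_S,
    speed_min_cm_s: float = SPEED_MIN_CM_S,
) -> DecodedSeries:
    """Correlate every 100-ms population vector with every template row."""
    X = np.atleast_2d(np.asarray(masked_dff, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("decoding needs at least 2 units")
    V, time_s, run_index, true_ctx, true_bin = _population_vectors(
        masked_dff, track, env, test_runs, dt_s, speed_min_cm_s)
    T = templates.matrix
    t_sd = T.std(axis=1)
    valid_rows = t_sd > 0
    if not np.any(valid_rows):
        raise ValueError("all template rows have zero variance")
    Tc = np.zeros_like(T)
    Tc[valid_rows] = ((T[valid_rows] - T[valid_rows].mean(axis=1, keepdims=True))
                      / t_sd[valid_rows, None])
    v_sd = V.std(axis=1)
    excluded = v_sd == 0
    Vc = np.zeros_like(V)
    ok = ~excluded
    Vc[ok] = (V[ok] - V[ok].mean(axis=1, keepdims=True)) / v_sd[ok, None]
    R = (Vc @ Tc.T) / V.shape[1]
    R[:, ~valid_rows] = -np.inf
    best = np.argmax(R, axis=1)         # ties -> lowest row index
    peak_r = R[np.arange(R.shape[0]), best]
    return DecodedSeries(
        time_s=time_s, run_index=run_index,
        true_context=true_ctx, true_bin=true_bin,
        decoded_context=templates.row_context[best],
        decoded_bin=templates.row_bin[best],
        peak_r=peak_r, excluded=excluded,
    )


@dataclass
class DecodingErrors:
    context_error: float
    spatial_error_cm: float
    per_context: dict = dc_field(default_factory=dict)
    chance_context_error: float = float("nan")
    chance_spatial_error_cm: float = float("nan")
    n_bins_used: int = 0


def decoding_errors(series: DecodedSeries,
                    bin_size_m: float = 0.05) -> DecodingErrors:
    """Mean 0/1 context error and mean |distance| in cm (included bins)."""
    inc = series.included
    if not np.any(inc):
        raise ValueError("all time bins excluded")
    ctx_err = float(np.mean(series.decoded_context[inc]
                            != series.true_context[inc]))
    cm = bin_size_m * 100.0
    has_bin = series.decoded_bin[inc] >= 0
    if np.any(has_bin):
        sp_err = float(np.mean(
            np.abs(series.decoded_bin[inc][has_bin]
                   - series.true_bin[inc][has_bin])) * cm)
    else:
        sp_err = float("nan")  # mean-rate templates carry no position
    per_ctx = {}
    for ci, ctx in enumerate(CONTEXTS):
        m = inc & (series.true_context == ci)
        if np.any(m):
            per_ctx[ctx] = {
                "context_error": float(np.mean(
                    series.decoded_context[m] != series.true_context[m])),
                "spatial_error_cm": float(np.mean(np.abs(
                    series.decoded_bin[m] - series.true_bin[m])) * cm)
                if np.all(series.decoded_bin[m] >= 0) else float("nan"),
            }
    return DecodingErrors(context_error=ctx_err, spatial_error_cm=sp_err,
                          per_context=per_ctx, n_bins_used=int(inc.sum()))


def chance_errors(
    series: DecodedSeries,
    bin_size_m: float = 0.05,
    n_shuffles: int = N_SHUFFLES_CHANCE,
    seed=None,
) -> tuple[float, float]:
    """Errors after permuting the true (context, bin) labels across bins."""
    rng = np.random.default_rng(seed)
    inc = series.included
    tc, tb = series.true_context[inc], series.true_bin[inc]
    dc, db = series.decoded_context[inc], series.decoded_bin[inc]
    cm = bin_size_m * 100.0
    ce, se = [], []
    for _ in range(n_shuffles):
        perm = rng.permutation(tc.size)
        ce.append(np.mean(dc != tc[perm]))
        if np.all(db >= 0):
            se.append(np.mean(np.abs(db - tb[perm])) * cm)
    return float(np.mean(ce)), float(np.mean(se)) if se else float("nan")


def uniform_chance_spatial_error_cm(n_bins: int = 80,
                                    bin_size_m: float = 0.05) -> float:
    """Closed form E|i - j| * bin over independent uniform bins."""
    i, j = np.meshgrid(np.arange(n_bins), np.arange(n_bins))
    return float(np.abs(i - j).mean() * bin_size_m * 100.0)


# ---------------------------------------------------------------------------
# ensemble protocols


def _decode_subset(X, subset, track, env, template_runs, test_runs,
                   mode="spatial"):
    t = build_templates(X[subset], track, env, template_runs, mode=mode)
    return decode_timebins(X[subset], track, env, t, test_runs)


def default_split(track: SessionTrack) -> tuple[dict, dict]:
    template_runs, test_runs = {}, {}
    for ctx in CONTEXTS:
        tpl, tst = split_runs(track.runs_of(ctx))
        template_runs[ctx], test_runs[ctx] = tpl, tst
    return template_runs, test_runs


def ensemble_sweep(
    masked_dff: np.ndarray,
    track: SessionTrack,
    env: EnvironmentSpec,
    sizes,
    n_draws: int = N_DRAWS,
    seed=None,
    bin_size_m: float | None = None,
) -> dict[int, DecodingErrors]:
    """Mean errors over random same-size ensembles, per ensemble size."""
    rng = np.random.default_rng(seed)
    X = np.atleast_2d(np.asarray(masked_dff, dtype=float))
    pool = X.shape[0]
    bin_size = bin_size_m or env.bin_size_m
    template_runs, test_runs = default_split(track)
    out: dict[int, DecodingErrors] = {}
    for size in sizes:
        if size > pool:
            continue  # flagged by omission
        draws = 1 if size == pool else n_draws
        ce, se = [], []
        for _ in range(draws):
            subset = (np.arange(pool) if size == pool
                      else rng.choice(pool, size=size, replace=False))
            series = _decode_subset(X, subset, track, env, template_runs,
                                    test_runs)
            err = decoding_errors(series, bin_size)
            ce.append(err.context_error)
            se.append(err.spatial_error_cm)
        out[size] = DecodingErrors(context_error=float(np.mean(ce)),
                                   spatial_error_cm=float(np.mean(se)))
    return out


def removal_analysis(
    masked_dff: np.ndarray,
    track: SessionTrack,
    env: EnvironmentSpec,
    order: np.ndarray,
    fractions,
    fixed_size: int,
    n_draws: int = N_DRAWS,
    seed=None,
) -> dict[float, DecodingErrors]:
    """Decode matched-size ensembles after removing leading units of ``order``.

    ``order`` ranks units by removal priority (e.g. ascending transient
    rate for "least active first", or the indices of one class).  Fractions
    where the remainder is smaller than ``fixed_size`` are omitted.
    """
    rng = np.random.default_rng(seed)
    X = np.atleast_2d(np.asarray(masked_dff, dtype=float))
    pool = X.shape[0]
    order = np.asarray(order)
    template_runs, test_runs = default_split(track)
    out: dict[float, DecodingErrors] = {}
    for frac in fractions:
        n_remove = int(round(frac * order.size))
        keep = np.setdiff1d(np.arange(pool), order[:n_remove])
        if keep.size < fixed_size:
            continue
        ce, se = [], []
        for _ in range(n_draws):
            subset = rng.choice(keep, size=fixed_size, replace=False)
            series = _decode_subset(X, subset, track, env, template_runs,
                                    test_runs)
            err = decoding_errors(series, env.bin_size_m)
            ce.append(err.context_error)
            se.append(err.spatial_error_cm)
        out[float(frac)] = DecodingErrors(
            context_error=float(np.mean(ce)),
            spatial_error_cm=float(np.mean(se)))
    return out


def cumulative_context_accuracy(
    series: DecodedSeries, dt_grid_s: np.ndarray, dt_bin_s: float = DECODE_BIN_S,
) -> np.ndarray:
    """Context accuracy after averaging decisions over Delta-t segments.

    Segments are non-overlapping chunks of consecutive included time bins
    within one run (the true context is constant inside a segment).  A
    segment is correct when the mean context decision falls closer to the
    true context; an exact tie counts as incorrect.
    """
    inc = series.included
    acc = np.empty(dt_grid_s.size)
    runs = series.run_index[inc]
    dec = series.decoded_context[inc].astype(float)
    true = series.true_context[inc]
    for k, dt in enumerate(dt_grid_s):
        m = max(1, int(round(dt / dt_bin_s)))
        correct, total = 0, 0
        for r in np.unique(runs):
            rm = runs == r
            d, t = dec[rm], true[rm]
            for s0 in range(0, d.size, m):
                mean_dec = d[s0:s0 + m].mean()
                dist_true = abs(mean_dec - t[s0])
                dist_other = abs(mean_dec - (1 - t[s0]))
                correct += int(dist_true < dist_other)
                total += 1
        acc[k] = correct / total if total else np.nan
    return acc


def time_to_accuracy(
    masked_dff: np.ndarray,
    track: SessionTrack,
    env: EnvironmentSpec,
    n_units: int = FIXED_ENSEMBLE,
    target: float = 0.9,
    n_draws: int = N_DRAWS,
    max_dt_s: float = 30.0,
    seed=None,
) -> float:
    """First Delta-t whose mean context accuracy exceeds ``target``.

    Returns +inf when the target is never reached within ``max_dt_s``.
    """
    rng = np.random.default_rng(seed)
    X = np.atleast_2d(np.asarray(masked_dff, dtype=float))
    pool = X.shape[0]
    if pool < n_units:
        raise ValueError("unit pool smaller than the requested ensemble")
    template_runs, test_runs = default_split(track)
    dt_grid = np.round(np.arange(DECODE_BIN_S, max_dt_s + 1e-9,
                                 DECODE_BIN_S), 10)
    accs = []
    for _ in range(n_draws):
        subset = rng.choice(pool, size=n_units, replace=False)
        series = _decode_subset(X, subset, track, env, template_runs,
                                test_runs)
        accs.append(cumulative_context_accuracy(series, dt_grid))
    mean_acc = np.nanmean(np.asarray(accs), axis=0)
    above = np.flatnonzero(mean_acc > target)
    return float(dt_grid[above[0]]) if above.size else float("inf")


def efficiency_indices(
    errors: DecodingErrors,
    chance_context_error: float,
    chance_spatial_error_cm: float,
    mean_transient_rate: float,
) -> tuple[float, float]:
    """(CDE, SDE) = ln(decoding gain over chance / mean transient rate).

    The context gain is the accuracy improvement over chance; the spatial
    gain is the error reduction over chance in cm.  Non-positive gains map
    to -inf.
    """
    if mean_transient_rate <= 0:
        raise ValueError("transient rate must be positive")
    ctx_gain = chance_context_error - errors.context_error
    sp_gain = chance_spatial_error_cm - errors.spatial_error_cm
    cde = float(np.log(ctx_gain / mean_transient_rate)) if ctx_gain > 0 \
        else float("-inf")
    sde = float(np.log(sp_gain / mean_transient_rate)) if sp_gain > 0 \
        else float("-inf")
    return cde, sde


def template_ratio(spatial_template_error: float,
                   mean_rate_template_error: float) -> float:
    """Spatial-template error over mean-rate-template error (<1 means the
    context-specific spatial maps add information beyond rate changes)."""
    if mean_rate_template_error <= 0:
        return float("inf")
    return spatial_template_error / mean_rate_template_error
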