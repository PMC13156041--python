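"""End-to-end pipeline: simulate -> detect -> metrics -> fields -> remap ->
classify -> decode -> report.

``run_pipeline`` drives every stage from a single config mapping (YAML/TOML
-friendly), writes tidy per-stage CSVs plus a JSON summary into an output
directory, and is deterministic under a fixed seed: all stage seeds derive
from ``config["seed"]`` and all floating-point output is formatted with a
fixed precision, so re-running an identical config produces byte-identical
files.
"""

from __future__ import annotations

import copy
import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier as cls
from .decoder import (
    chance_errors, decoding_errors, default_split, _decode_subset,
    efficiency_indices, ensemble_sweep, template_ratio,
)
from .environments import CONTEXTS, FAMILIAR, NOVEL
from .metrics import (
    activity_map, activity_difference_score, lick_ratio, si_shuffle_test,
    spatial_information, speed_metrics, transient_rate_and_active,
)
from .placefields import find_place_fields
from .remapping import RemappingResult, per_run_maps, trial_reliability
from .synthetic import DEFAULT_CLASS_MIX, SessionDataset, simulate_session
from .transients import process_traces

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "experiment": "openfield",
    "days": 1,
    "n_units": 40,
    "n_runs_per_context": 15,
    "class_mix": None,          # None -> generator default mixture
    "exact_counts": False,
    "detect": {"fpr_target": 0.05},
    "metrics": {"n_shuffles": 200, "log_base": 2.0},
    "fields": {"n_bootstrap": 200, "accept_p": 0.05,
               "bootstrap_accept_high": False},
    "classify": {"alt_transition_parse": False},
    "decode": {"sizes": None, "n_draws": 5, "n_chance_shuffles": 15},
}

_FLOAT_FMT = "%.10g"


def merge_config(config: dict | None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def validate_config(cfg: dict) -> None:
    if cfg["fields"]["n_bootstrap"] <= 0:
        raise ValueError("fields.n_bootstrap must be positive")
    if cfg["metrics"]["n_shuffles"] <= 0:
        raise ValueError("metrics.n_shuffles must be positive")
    if cfg["days"] <= 0 or cfg["n_units"] <= 0:
        raise ValueError("days and n_units must be positive")


def _seed_for(base_seed: int, *tags) -> np.random.SeedSequence:
    """Stable per-(stage, day, unit, context) seed derivation."""
    digest = [zlib.crc32(t.encode()) if isinstance(t, str) else int(t)
              for t in tags]
    return np.random.SeedSequence([int(base_seed)] + digest)


def run_pipeline(config: dict | None, out_dir) -> dict:
    """Run every stage; returns the per-stage tables and summary."""
    cfg = merge_config(config)
    validate_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    ds = simulate_session(
        kind=cfg["experiment"], n_units=cfg["n_units"], days=cfg["days"],
        class_mix=cfg["class_mix"] or DEFAULT_CLASS_MIX,
        n_runs_per_context=cfg["n_runs_per_context"], seed=seed,
        exact_counts=cfg["exact_counts"],
    )
    result = analyze_dataset(ds, cfg)
    write_outputs(result, cfg, out)
    return result


def analyze_dataset(ds: SessionDataset, config: dict | None = None) -> dict:
    """All analysis stages on an in-memory dataset."""
    cfg = merge_config(config)
    validate_config(cfg)
    seed = int(cfg["seed"])
    env_pair = ds.env_pair
    fam = ds.env_familiar

    transient_rows, metric_rows, field_rows = [], [], []
    remap_rows, class_rows = [], []
    decode_summary: dict = {}
    day_maps: dict[tuple[int, str, int], np.ndarray] = {}

    for d, day in enumerate(ds.days):
        track, raw = day.track, day.raw
        fs = track.frame_rate_hz
        traces, params = process_traces(
            raw.fluorescence, fs, fpr_target=cfg["detect"]["fpr_target"])
        masked = np.stack([t.masked_dff for t in traces])

        for u, t in enumerate(traces):
            for on, off in t.transients:
                transient_rows.append({
                    "unit_id": u, "day": d,
                    "onset_s": on / fs, "offset_s": off / fs,
                    "peak_sigma": float(t.dff[on:off + 1].max()),
                })

        profiles = []
        for u, t in enumerate(traces):
            fields_by_ctx, maps_by_ctx, runmaps_by_ctx = {}, {}, {}
            rates = {}
            for ctx in CONTEXTS:
                env = ds.env_of(ctx)
                amap = activity_map(t.masked_dff, track, env, context=ctx)
                day_maps[(d, ctx, u)] = amap.lambda_
                maps_by_ctx[ctx] = amap.smoothed
                rate, active = transient_rate_and_active(
                    t.transients, track, context=ctx)
                rates[ctx] = rate
                si = spatial_information(
                    amap, log_base=cfg["metrics"]["log_base"])
                if not np.isnan(si):
                    _, si_p = si_shuffle_test(
                        t.masked_dff, track, env, context=ctx,
                        n_shuffles=cfg["metrics"]["n_shuffles"],
                        log_base=cfg["metrics"]["log_base"],
                        seed=_seed_for(seed, "si", d, u, ctx))
                else:
                    si_p = float("nan")
                sp_info, sp_score, sp_class = speed_metrics(
                    t.masked_dff, track, context=ctx,
                    n_shuffles=cfg["metrics"]["n_shuffles"],
                    seed=_seed_for(seed, "speed", d, u, ctx))
                metric_rows.append({
                    "unit_id": u, "day": d, "context": ctx,
                    "transient_rate_per_s": rate, "active": active,
                    "si_bits_per_s": si, "si_p": si_p,
                    "speed_info_bits_per_s": sp_info,
                    "speed_score": sp_score, "speed_class": sp_class,
                })
                pfs = find_place_fields(
                    t.masked_dff, t.transient_flag, track, env, ctx,
                    n_shuffles=cfg["fields"]["n_bootstrap"],
                    seed=_seed_for(seed, "boot", d, u, ctx),
                    accept_p=cfg["fields"]["accept_p"],
                    bootstrap_accept_high=cfg["fields"][
                        "bootstrap_accept_high"])
                fields_by_ctx[ctx] = pfs
                for fi, f in enumerate(pfs):
                    field_rows.append({
                        "unit_id": u, "day": d, "context": ctx,
                        "field_index": fi,
                        "start_cm": f.start_bin * env.bin_size_m * 100,
                        "end_cm": (f.end_bin + 1) * env.bin_size_m * 100,
                        "peak_cm": f.peak_m(env.bin_size_m) * 100,
                        "in_out_ratio": f.in_out_ratio,
                        "occupancy": f.transient_occupancy_fraction,
                        "p": f.bootstrap_p,
                    })
                runmaps_by_ctx[ctx] = per_run_maps(
                    t.masked_dff, track, env, ctx)
            ads = activity_difference_score(
                float(np.nan_to_num(rates[FAMILIAR])),
                float(np.nan_to_num(rates[NOVEL])))
            for row in metric_rows[-2:]:
                row["ads"] = ads
            rel = {ctx: trial_reliability(runmaps_by_ctx[ctx])
                   for ctx in CONTEXTS}
            rr = RemappingResult.from_maps(
                f"{FAMILIAR}|{NOVEL}",
                day_maps[(d, FAMILIAR, u)], day_maps[(d, NOVEL, u)])
            remap_rows.append({
                "unit_id": u, "day": d, "comparison": rr.comparison,
                "r": rr.r, "category": rr.category,
                "reliability_familiar": rel[FAMILIAR],
                "reliability_novel": rel[NOVEL],
            })
            active_any = any(
                row["active"] for row in metric_rows[-2:])
            profiles.append(cls.UnitProfile(
                unit_id=u, active=active_any, fields=fields_by_ctx,
                maps=maps_by_ctx, run_maps=runmaps_by_ctx))

        for profile in profiles:
            if not profile.active:
                class_rows.append({
                    "unit_id": profile.unit_id, "day": d,
                    "label": "inactive", "object_ids": "",
                    "peak_lag_m": float("nan"),
                    "peak_lag_r": float("nan"), "conjunctive": "",
                })
                continue
            c = cls.classify_unit(
                profile, env_pair,
                alt_transition_parse=cfg["classify"][
                    "alt_transition_parse"])
            class_rows.append({
                "unit_id": c.unit_id, "day": d, "label": c.label,
                "object_ids": "+".join(c.object_ids),
                "peak_lag_m": c.peak_lag_m, "peak_lag_r": c.peak_lag_r,
                "conjunctive": "+".join(c.conjunctive or ()),
            })

        sizes = cfg["decode"]["sizes"] or [min(10, len(traces)),
                                           len(traces)]
        sizes = sorted({s for s in sizes if s <= len(traces)})
        sweep = ensemble_sweep(
            masked, track, fam, sizes,
            n_draws=cfg["decode"]["n_draws"],
            seed=_seed_for(seed, "sweep", d))
        template_runs, test_runs = default_split(track)
        series = _decode_subset(masked, np.arange(masked.shape[0]), track,
                                fam, template_runs, test_runs)
        err = decoding_errors(series, fam.bin_size_m)
        cce, cse = chance_errors(
            series, fam.bin_size_m,
            n_shuffles=cfg["decode"]["n_chance_shuffles"],
            seed=_seed_for(seed, "chance", d))
        rate_all = float(np.mean([
            row["transient_rate_per_s"] for row in metric_rows
            if row["day"] == d and np.isfinite(row["transient_rate_per_s"])
        ]))
        cde, sde = (efficiency_indices(err, cce, cse, rate_all)
                    if rate_all > 0 else (float("nan"), float("nan")))
        series_rate = _decode_subset(masked, np.arange(masked.shape[0]),
                                     track, fam, template_runs, test_runs,
                                     mode="mean_rate")
        err_rate = decoding_errors(series_rate, fam.bin_size_m)
        decode_summary[f"day{d}"] = {
            "context_error": err.context_error,
            "spatial_error_cm": err.spatial_error_cm,
            "chance_context_error": cce,
            "chance_spatial_error_cm": cse,
            "cde": cde, "sde": sde,
            "template_ratio_context": template_ratio(
                err.context_error, err_rate.context_error),
            "sweep": {str(s): {"context_error": e.context_error,
                               "spatial_error_cm": e.spatial_error_cm}
                      for s, e in sweep.items()},
            "lick_ratio_familiar": lick_ratio(track, ds.env_familiar,
                                              FAMILIAR),
            "lick_ratio_novel": lick_ratio(track, ds.env_novel, NOVEL),
        }

    tables = {
        "transients": pd.DataFrame(transient_rows),
        "metrics": pd.DataFrame(metric_rows),
        "fields": pd.DataFrame(field_rows),
        "remapping": pd.DataFrame(remap_rows),
        "classes": pd.DataFrame(class_rows),
    }
    if ds.units:
        truth = pd.DataFrame({
            "unit_id": [u.unit_id for u in ds.units],
            "true_class": [u.true_class for u in ds.units],
            "true_anchors": ["+".join(u.anchors) for u in ds.units],
        })
        tables["classes"] = tables["classes"].merge(truth, on="unit_id",
                                                    how="left")
    labels = tables["classes"]
    frac = (labels[labels["label"] != "inactive"]["label"]
            .value_counts(normalize=True).sort_index())
    summary = {
        "class_fractions": {k: float(v) for k, v in frac.items()},
        "decoding": decode_summary,
        "n_units": len(ds.units),
        "n_days": len(ds.days),
        "provenance": {**ds.provenance, "config": cfg},
    }
    return {"tables": tables, "summary": summary, "dataset": ds}


def write_outputs(result: dict, cfg: dict, out: Path) -> None:
    for name, df in result["tables"].items():
        df.to_csv(out / f"{name}.csv", index=False, float_format=_FLOAT_FMT)
    (out / "summary.json").write_text(
        json.dumps(result["summary"], indent=1, sort_keys=True,
                   default=_json_default))
    (out / "config.json").write_text(
        json.dumps(cfg, indent=1, sort_keys=True, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
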