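"""Session container: NPZ arrays plus a JSON sidecar.

A dataset directory holds ``arrays.npz`` (per-day behavior tracks, raw
fluorescence and ground-truth event frames) and ``meta.json`` (schema
version, environment pair, unit truth, provenance).  Round-trips are
bit-exact for all arrays.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .environments import Cue, EnvironmentSpec
from .synthetic import (
    DaySession, GroundTruthUnit, RawTraceSet, SessionDataset, SessionTrack,
)

SCHEMA_VERSION = "1"

_TRACK_FIELDS = ("frame_time_s", "position_m", "speed_cm_s", "context_id",
                 "run_index", "block_index", "lick_flag", "blank_flag")


class DatasetError(ValueError):
    """Raised for unreadable or inconsistent dataset containers."""


def _env_to_dict(env: EnvironmentSpec) -> dict:
    return {
        "context_id": env.context_id,
        "experiment_kind": env.experiment_kind,
        "texture_id": env.texture_id,
        "track_length_m": env.track_length_m,
        "bin_size_m": env.bin_size_m,
        "cues": [[c.kind, c.position_m] for c in env.cues],
    }


def _env_from_dict(d: dict) -> EnvironmentSpec:
    return EnvironmentSpec(
        context_id=d["context_id"], experiment_kind=d["experiment_kind"],
        texture_id=d["texture_id"], track_length_m=d["track_length_m"],
        bin_size_m=d["bin_size_m"],
        cues=tuple(Cue(k, p) for k, p in d["cues"]),
    )


def _unit_to_dict(u: GroundTruthUnit) -> dict:
    return {
        "unit_id": u.unit_id, "source": u.source,
        "true_class": u.true_class,
        "tuning": {ctx: [list(f) for f in fields]
                   for ctx, fields in u.tuning.items()},
        "anchors": list(u.anchors),
        "baseline_rate_hz": u.baseline_rate_hz,
        "amplitude_sigma": u.amplitude_sigma,
        "baseline_noise_sigma": u.baseline_noise_sigma,
        "kernel_tau_s": u.kernel_tau_s,
    }


def _unit_from_dict(d: dict) -> GroundTruthUnit:
    return GroundTruthUnit(
        unit_id=d["unit_id"], source=d["source"],
        true_class=d["true_class"],
        tuning={ctx: [tuple(f) for f in fields]
                for ctx, fields in d["tuning"].items()},
        anchors=tuple(d["anchors"]),
        baseline_rate_hz=d["baseline_rate_hz"],
        amplitude_sigma=d["amplitude_sigma"],
        baseline_noise_sigma=d["baseline_noise_sigma"],
        kernel_tau_s=d["kernel_tau_s"],
    )


def write_dataset(ds: SessionDataset, path) -> Path:
    """Write a dataset directory; returns its path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    for d, day in enumerate(ds.days):
        for f in _TRACK_FIELDS:
            arrays[f"day{d}/track/{f}"] = getattr(day.track, f)
        arrays[f"day{d}/fluorescence"] = day.raw.fluorescence
        if day.raw.event_frames is not None:
            for u, ev in enumerate(day.raw.event_frames):
                arrays[f"day{d}/truth/events/u{u}"] = ev
    np.savez(path / "arrays.npz", **arrays)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "n_days": len(ds.days),
        "frame_rate_hz": ds.days[0].track.frame_rate_hz if ds.days else None,
        "env_familiar": _env_to_dict(ds.env_familiar),
        "env_novel": _env_to_dict(ds.env_novel),
        "units": [_unit_to_dict(u) for u in ds.units],
        "provenance": ds.provenance,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_dataset(path) -> SessionDataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    path = Path(path)
    meta_path = path / "meta.json"
    npz_path = path / "arrays.npz"
    if not meta_path.exists() or not npz_path.exists():
        raise DatasetError(f"{path} is not a dataset directory")
    meta = json.loads(meta_path.read_text())
    version = meta.get("schema_version")
    if version != SCHEMA_VERSION:
        raise DatasetError(f"unsupported dataset schema version {version!r}")
    with np.load(npz_path, allow_pickle=False) as z:
        days = []
        n_units = len(meta["units"])
        for d in range(meta["n_days"]):
            try:
                track_arrays = {f: z[f"day{d}/track/{f}"]
                                for f in _TRACK_FIELDS}
                fluor = z[f"day{d}/fluorescence"]
            except KeyError as exc:
                raise DatasetError(f"missing member for day {d}: {exc}")
            track = SessionTrack(frame_rate_hz=meta["frame_rate_hz"],
                                 **track_arrays)
            if fluor.shape[1] != track.n_frames:
                raise DatasetError(
                    f"day {d}: fluorescence frames ({fluor.shape[1]}) do "
                    f"not match track frames ({track.n_frames})")
            if fluor.shape[0] != n_units:
                raise DatasetError(
                    f"day {d}: {fluor.shape[0]} traces for "
                    f"{n_units} units")
            key0 = f"day{d}/truth/events/u0"
            events = ([z[f"day{d}/truth/events/u{u}"]
                       for u in range(n_units)] if key0 in z else None)
            days.append(DaySession(
                track=track,
                raw=RawTraceSet(fluor, frame_rate_hz=meta["frame_rate_hz"],
                                event_frames=events)))
    return SessionDataset(
        env_familiar=_env_from_dict(meta["env_familiar"]),
        env_novel=_env_from_dict(meta["env_novel"]),
        units=[_unit_from_dict(u) for u in meta["units"]],
        days=days,
        provenance=meta.get("provenance", {}),
    )


def export_track_csv(track: SessionTrack, path) -> Path:
    import pandas as pd

    path = Path(path)
    pd.DataFrame({f: getattr(track, f) for f in _TRACK_FIELDS}).to_csv(
        path, index=False)
    return path
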