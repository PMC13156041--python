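"""Virtual-track environment geometry and cue layouts.

A session pairs two contexts ("familiar" and "novel") on a 4-m virtual
linear track discretized into 5-cm bins.  In the corridor paradigm the two
contexts differ in wall/floor texture and reward positions; in the
open-field-like paradigm they share the texture but the odor, sound, reward
and four objects are redistributed along the track.  The classifier's
offset windows constrain how far each cue may move between contexts
(roughly 1 m for odor/reward, 2 m for the sound, and 1, 2 or 3 m for
objects), and objects may not be placed closer than 0.6 m apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FAMILIAR = "familiar"
NOVEL = "novel"
CONTEXTS = (FAMILIAR, NOVEL)

STIMULUS_KINDS = ("odor", "sound", "reward")
OBJECT_KINDS = ("object1", "object2", "object3", "object4")
CUE_KINDS = STIMULUS_KINDS + OBJECT_KINDS

#: minimal center-to-center distance between two objects in one context
MIN_OBJECT_SEPARATION_M = 0.6


class LayoutError(ValueError):
    """Raised for physically invalid cue layouts."""


@dataclass(frozen=True)
class Cue:
    kind: str
    position_m: float


@dataclass(frozen=True)
class EnvironmentSpec:
    """Geometry and cue layout of one virtual context."""

    context_id: str
    experiment_kind: str  # "corridor" | "openfield"
    cues: tuple[Cue, ...]
    texture_id: str
    track_length_m: float = 4.0
    bin_size_m: float = 0.05

    def __post_init__(self) -> None:
        if self.context_id not in CONTEXTS:
            raise ValueError(f"unknown context {self.context_id!r}")
        if self.experiment_kind not in ("corridor", "openfield"):
            raise ValueError(f"unknown experiment kind {self.experiment_kind!r}")
        ratio = self.track_length_m / self.bin_size_m
        if abs(ratio - round(ratio)) > 1e-9:
            raise LayoutError(
                f"track length {self.track_length_m} m is not a multiple of "
                f"bin size {self.bin_size_m} m"
            )
        for cue in self.cues:
            if cue.kind not in CUE_KINDS:
                raise LayoutError(f"unknown cue kind {cue.kind!r}")
            if not (0.0 <= cue.position_m < self.track_length_m):
                raise LayoutError(
                    f"cue {cue.kind} at {cue.position_m} m lies outside "
                    f"[0, {self.track_length_m}) m"
                )
        obj = [c for c in self.cues if c.kind in OBJECT_KINDS]
        kinds = [c.kind for c in obj]
        if len(set(kinds)) != len(kinds):
            raise LayoutError("duplicate object kinds in one context")
        pos = sorted(c.position_m for c in obj)
        for a, b in zip(pos, pos[1:]):
            if b - a < MIN_OBJECT_SEPARATION_M - 1e-9:
                raise LayoutError(
                    f"objects {a} m and {b} m closer than "
                    f"{MIN_OBJECT_SEPARATION_M} m"
                )
        if not self.positions("reward"):
            raise LayoutError("every context needs at least one reward cue")

    @property
    def n_bins(self) -> int:
        return int(round(self.track_length_m / self.bin_size_m))

    def positions(self, kind: str) -> tuple[float, ...]:
        return tuple(c.position_m for c in self.cues if c.kind == kind)

    def has(self, kind: str) -> bool:
        return any(c.kind == kind for c in self.cues)

    def position_to_bin(self, position_m: float) -> int:
        """Half-open bins; the track end L falls into the last bin."""
        b = int(np.floor(position_m / self.bin_size_m))
        return min(max(b, 0), self.n_bins - 1)


def make_environment(
    kind: str,
    context: str,
    cue_layout: dict[str, float | tuple[float, ...]],
    texture_id: str | None = None,
) -> EnvironmentSpec:
    """Build and validate an :class:`EnvironmentSpec`.

    ``cue_layout`` maps cue kind to one position (or a tuple of positions,
    e.g. for two rewards).  Open-field contexts must define all seven cue
    slots (odor, sound, reward, object1-4).
    """
    cues: list[Cue] = []
    for cue_kind, value in cue_layout.items():
        values = value if isinstance(value, (tuple, list)) else (value,)
        for v in values:
            cues.append(Cue(cue_kind, float(v)))
    if kind == "openfield":
        missing = [k for k in CUE_KINDS if k not in cue_layout]
        if missing:
            raise LayoutError(f"openfield layout missing cue kinds {missing}")
    if texture_id is None:
        texture_id = f"{kind}-{context}"
    return EnvironmentSpec(
        context_id=context, experiment_kind=kind, cues=tuple(cues),
        texture_id=texture_id,
    )


# Default layouts.  Corridor contexts share no local cues beyond the two
# rewards and differ in texture; open-field contexts share the texture but
# redistribute every cue.  Open-field displacements (novel - familiar):
# odor +1.0, reward +1.0, sound -2.0, object1 +1.0, object2 +2.0,
# object3 -2.0, object4 -1.0 m, each consistent with one of the
# classifier's offset windows.
DEFAULT_CORRIDOR_LAYOUTS = {
    FAMILIAR: {"reward": (1.2, 3.0)},
    NOVEL: {"reward": (0.8, 2.4)},
}
DEFAULT_OPENFIELD_LAYOUTS = {
    FAMILIAR: {
        "odor": 0.5, "object1": 1.0, "object2": 1.7, "reward": 2.2,
        "object3": 2.7, "sound": 3.2, "object4": 3.6,
    },
    NOVEL: {
        "odor": 1.5, "object1": 2.0, "object2": 3.7, "reward": 3.2,
        "object3": 0.7, "sound": 1.2, "object4": 2.6,
    },
}


def default_environment_pair(kind: str = "openfield") -> tuple[EnvironmentSpec, EnvironmentSpec]:
    """Default familiar/novel pair for either paradigm."""
    if kind == "corridor":
        layouts = DEFAULT_CORRIDOR_LAYOUTS
        textures = {FAMILIAR: "corridor-A", NOVEL: "corridor-B"}
    elif kind == "openfield":
        layouts = DEFAULT_OPENFIELD_LAYOUTS
        textures = {FAMILIAR: "openfield-box", NOVEL: "openfield-box"}
    else:
        raise ValueError(f"unknown experiment kind {kind!r}")
    return tuple(
        make_environment(kind, ctx, layouts[ctx], texture_id=textures[ctx])
        for ctx in CONTEXTS
    )


def cue_displacement(
    fam: EnvironmentSpec, nov: EnvironmentSpec, kind: str
) -> float:
    """Signed displacement (novel minus familiar) of a cue, in meters."""
    pf, pn = fam.positions(kind), nov.positions(kind)
    if not pf or not pn:
        raise KeyError(f"cue {kind!r} missing from one context")
    return pn[0] - pf[0]


def circular_lag(lag_m: float, track_length_m: float) -> float:
    """Map a lag onto (-L/2, L/2]."""
    L = track_length_m
    x = (lag_m + L / 2) % L - L / 2
    return L / 2 if np.isclose(x, -L / 2) else x
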