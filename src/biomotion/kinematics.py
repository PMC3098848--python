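"""Parametric point-light action sequences.

A point-light (PL) figure is a human body reduced to 12 dots (head, torso and
the major joints).  Because the motion-capture recordings used in classical PL
studies are not available as data, this module synthesizes articulated figures
from closed-form joint kinematics: limbs swing as two-segment pendulums about
torso-anchored pivots, with per-joint sinusoidal angle profiles; the torso,
head and girdle dots bob and sway.  Generated sequences follow the standard
stimulus geometry of PL psychophysics: the figure fits a 7 deg x 7 deg window
centred on fixation and its mean per-dot speed is normalized to 4 deg/s.

Coordinates are degrees of visual angle; x rightward, y upward, origin at the
fixation mark.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DOT_LABELS",
    "PointLightSequence",
    "LimbParams",
    "ActionParams",
    "FormatError",
    "generate_action",
    "action_preset",
    "list_presets",
    "read_sequence",
    "write_sequence",
    "read_sequence_csv",
    "write_sequence_csv",
]

# Canonical dot order: head, torso, 2 shoulders, 2 elbows, 2 wrists, 2 hips,
# 2 ankles.  Knees are omitted so the joint set fits in 12 dots while keeping
# full arm articulation; the ankle still follows a two-segment leg pendulum.
DOT_LABELS = (
    "head",
    "torso",
    "l_shoulder",
    "r_shoulder",
    "l_elbow",
    "r_elbow",
    "l_wrist",
    "r_wrist",
    "l_hip",
    "r_hip",
    "l_ankle",
    "r_ankle",
)

FIGURE_WINDOW_DEG = 7.0
TARGET_MEAN_SPEED = 4.0  # deg/s

# Skeleton geometry in model units (scaled later to degrees).
_SKEL = {
    "head": (0.0, 0.80),
    "torso": (0.0, 0.30),
    "l_shoulder": (-0.22, 0.55),
    "r_shoulder": (0.22, 0.55),
    "l_hip": (-0.13, 0.0),
    "r_hip": (0.13, 0.0),
}
_UPPER_ARM = 0.30
_FOREARM = 0.30
_THIGH = 0.45
_SHANK = 0.45


class FormatError(ValueError):
    """Raised when a serialized sequence violates the file contract."""


@dataclass(frozen=True)
class PointLightSequence:
    """A T x D x 2 dot-position sequence in degrees of visual angle."""

    positions: np.ndarray
    frame_duration_s: float
    dot_labels: tuple[str, ...]
    action_name: str = ""
    is_cyclic: bool = False

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 3 or pos.shape[2] != 2:
            raise ValueError("positions must have shape (T, D, 2)")
        if pos.shape[0] < 2:
            raise ValueError("a sequence needs at least 2 frames")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        if self.frame_duration_s <= 0:
            raise ValueError("frame_duration_s must be > 0")
        if len(self.dot_labels) != pos.shape[1]:
            raise ValueError("dot_labels length must match dot count")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "dot_labels", tuple(self.dot_labels))

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_dots(self) -> int:
        return self.positions.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_duration_s

    def displacements(self) -> np.ndarray:
        """Per-dot frame-to-frame displacement vectors, shape (T-1, D, 2)."""
        return np.diff(self.positions, axis=0)

    def mean_dot_speed(self) -> float:
        """Mean per-dot speed in deg/s over all frame transitions."""
        d = np.linalg.norm(self.displacements(), axis=2)
        return float(d.mean() / self.frame_duration_s)

    def bounding_box(self) -> tuple[float, float]:
        """(width, height) of the box spanned by all dots over all frames."""
        lo = self.positions.reshape(-1, 2).min(axis=0)
        hi = self.positions.reshape(-1, 2).max(axis=0)
        return float(hi[0] - lo[0]), float(hi[1] - lo[1])

    def with_positions(self, positions: np.ndarray, **kw) -> "PointLightSequence":
        return replace(self, positions=positions, **kw)


@dataclass(frozen=True)
class LimbParams:
    """Sinusoidal swing of one two-segment limb about its girdle pivot.

    Angles are radians measured from straight down; ``frequency`` is in cycles
    per ``cycle_period_s`` and should be an integer for cyclic actions.
    """

    swing_amp: float = 0.0
    swing_phase: float = 0.0
    swing_mean: float = 0.0
    flex_amp: float = 0.0
    flex_phase: float = 0.0
    flex_mean: float = 0.0
    frequency: float = 1.0


@dataclass(frozen=True)
class ActionParams:
    action_name: str = "custom"
    cycle_period_s: float = 1.0
    translation: tuple[float, float] = (0.0, 0.0)  # model units / s
    l_arm: LimbParams = field(default_factory=LimbParams)
    r_arm: LimbParams = field(default_factory=LimbParams)
    l_leg: LimbParams = field(default_factory=LimbParams)
    r_leg: LimbParams = field(default_factory=LimbParams)
    bob_amp: float = 0.0  # vertical oscillation of trunk dots
    bob_freq: float = 2.0
    bob_phase: float = 0.0
    sway_amp: float = 0.0  # lateral oscillation of trunk dots
    sway_freq: float = 1.0
    sway_phase: float = 0.0
    random_start_phase: bool = True

    def validate(self) -> None:
        if self.cycle_period_s <= 0:
            raise ValueError("cycle_period_s must be > 0")
        for limb in (self.l_arm, self.r_arm, self.l_leg, self.r_leg):
            if limb.swing_amp < 0 or limb.flex_amp < 0:
                raise ValueError("limb amplitudes must be >= 0")
        if self.bob_amp < 0 or self.sway_amp < 0:
            raise ValueError("bob/sway amplitudes must be >= 0")

    def is_static(self) -> bool:
        amps = [
            self.l_arm.swing_amp, self.l_arm.flex_amp,
            self.r_arm.swing_amp, self.r_arm.flex_amp,
            self.l_leg.swing_amp, self.l_leg.flex_amp,
            self.r_leg.swing_amp, self.r_leg.flex_amp,
            self.bob_amp, self.sway_amp,
            abs(self.translation[0]), abs(self.translation[1]),
        ]
        return all(a == 0 for a in amps)


def _limb_points(pivot_x, pivot_y, limb: LimbParams, t, period, l_prox, l_dist):
    """Positions of the distal-segment joint and endpoint of one limb."""
    w = 2.0 * math.pi * limb.frequency / period
    theta = limb.swing_mean + limb.swing_amp * np.sin(w * t + limb.swing_phase)
    flex = limb.flex_mean + limb.flex_amp * np.sin(w * t + limb.flex_phase)
    jx = pivot_x + l_prox * np.sin(theta)
    jy = pivot_y - l_prox * np.cos(theta)
    ex = jx + l_dist * np.sin(theta + flex)
    ey = jy - l_dist * np.cos(theta + flex)
    return jx, jy, ex, ey


def _raw_positions(params: ActionParams, times: np.ndarray) -> np.ndarray:
    """Closed-form model-unit dot positions at the given times."""
    P = params.cycle_period_s
    t = times
    n = t.shape[0]
    pos = np.zeros((n, 12, 2))

    bob = params.bob_amp * np.sin(
        2 * math.pi * params.bob_freq * t / P + params.bob_phase
    )
    sway = params.sway_amp * np.sin(
        2 * math.pi * params.sway_freq * t / P + params.sway_phase
    )

    idx = {label: i for i, label in enumerate(DOT_LABELS)}
    for label in ("head", "torso", "l_shoulder", "r_shoulder", "l_hip", "r_hip"):
        x0, y0 = _SKEL[label]
        pos[:, idx[label], 0] = x0 + sway
        pos[:, idx[label], 1] = y0 + bob

    for side, arm in (("l", params.l_arm), ("r", params.r_arm)):
        sx = pos[:, idx[f"{side}_shoulder"], 0]
        sy = pos[:, idx[f"{side}_shoulder"], 1]
        jx, jy, ex, ey = _limb_points(sx, sy, arm, t, P, _UPPER_ARM, _FOREARM)
        pos[:, idx[f"{side}_elbow"], 0] = jx
        pos[:, idx[f"{side}_elbow"], 1] = jy
        pos[:, idx[f"{side}_wrist"], 0] = ex
        pos[:, idx[f"{side}_wrist"], 1] = ey

    for side, leg in (("l", params.l_leg), ("r", params.r_leg)):
        hx = pos[:, idx[f"{side}_hip"], 0]
        hy = pos[:, idx[f"{side}_hip"], 1]
        _, _, ax, ay = _limb_points(hx, hy, leg, t, P, _THIGH, _SHANK)
        pos[:, idx[f"{side}_ankle"], 0] = ax
        pos[:, idx[f"{side}_ankle"], 1] = ay

    pos[:, :, 0] += params.translation[0] * t[:, None]
    pos[:, :, 1] += params.translation[1] * t[:, None]
    return pos


def generate_action(
    params: ActionParams,
    n_frames: int = 20,
    frame_duration_s: float = 0.05,
    seed: int = 0,
) -> PointLightSequence:
    """Generate a 12-dot point-light sequence from articulated-figure params.

    The raw figure is rescaled so its mean per-dot speed is exactly 4 deg/s
    and recentred so the whole trajectory is centred on fixation; the result
    must fit within the 7 deg figure window, otherwise the params are
    rejected.  ``seed`` selects a random starting phase within the action
    cycle (disable via ``params.random_start_phase``), so different seeds give
    different exemplars of the same action.  Deterministic given
    ``(params, n_frames, frame_duration_s, seed)``.
    """
    params.validate()
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if frame_duration_s <= 0:
        raise ValueError("frame_duration_s must be > 0")

    t0 = 0.0
    if params.random_start_phase and not params.is_static():
        rng = np.random.default_rng([int(seed), 0x6B696E])
        t0 = float(rng.uniform(0.0, params.cycle_period_s))
    times = t0 + frame_duration_s * np.arange(n_frames)
    pos = _raw_positions(params, times)

    # Speed normalization on the sampled frames: mean per-dot speed -> 4 deg/s.
    disp = np.linalg.norm(np.diff(pos, axis=0), axis=2)
    mean_speed = disp.mean() / frame_duration_s
    if mean_speed > 1e-12:
        pos = pos * (TARGET_MEAN_SPEED / mean_speed)

    # Centre the full space-time bounding box on fixation.
    flat = pos.reshape(-1, 2)
    center = (flat.min(axis=0) + flat.max(axis=0)) / 2.0
    pos = pos - center

    if mean_speed > 1e-12:
        w, h = (pos.reshape(-1, 2).max(axis=0) - pos.reshape(-1, 2).min(axis=0))
        if max(w, h) > FIGURE_WINDOW_DEG + 1e-9:
            raise ValueError(
                f"action {params.action_name!r}: figure spans "
                f"{max(w, h):.2f} deg (> {FIGURE_WINDOW_DEG} deg) once mean dot "
                f"speed is normalized to {TARGET_MEAN_SPEED} deg/s; increase "
                "joint amplitudes/frequencies or reduce translation"
            )

    is_cyclic = (
        params.translation == (0.0, 0.0)
        and not params.is_static()
        and all(
            float(limb.frequency).is_integer()
            for limb in (params.l_arm, params.r_arm, params.l_leg, params.r_leg)
        )
        and float(params.bob_freq).is_integer()
        and float(params.sway_freq).is_integer()
    )
    return PointLightSequence(
        positions=pos,
        frame_duration_s=frame_duration_s,
        dot_labels=DOT_LABELS,
        action_name=params.action_name,
        is_cyclic=is_cyclic,
    )


# ---------------------------------------------------------------------------
# Action presets
# ---------------------------------------------------------------------------

def _walk_like(name, direction=1.0, speed=0.9, swing=0.55, arm=0.45):
    legs = dict(swing_amp=swing, flex_amp=0.5, flex_phase=-1.2, frequency=1.0)
    arms = dict(swing_amp=arm, flex_amp=0.35, flex_phase=0.6, frequency=1.0)
    return ActionParams(
        action_name=name,
        translation=(direction * speed, 0.0),
        l_leg=LimbParams(**legs, swing_phase=0.0),
        r_leg=LimbParams(**legs, swing_phase=math.pi),
        l_arm=LimbParams(**arms, swing_phase=math.pi),
        r_arm=LimbParams(**arms, swing_phase=0.0),
        bob_amp=0.05,
        bob_freq=2.0,
    )


def _presets() -> dict[str, ActionParams]:
    p: dict[str, ActionParams] = {}
    p["walk"] = _walk_like("walk")
    p["backward_walk"] = _walk_like("backward_walk", direction=-1.0, speed=0.8)
    p["run"] = _walk_like("run", speed=1.4, swing=0.8, arm=0.7)
    p["stair_climb"] = ActionParams(
        action_name="stair_climb",
        translation=(0.55, 0.45),
        l_leg=LimbParams(swing_amp=0.7, flex_amp=0.8, flex_phase=-1.0),
        r_leg=LimbParams(swing_amp=0.7, swing_phase=math.pi, flex_amp=0.8,
                         flex_phase=math.pi - 1.0),
        l_arm=LimbParams(swing_amp=0.35, swing_phase=math.pi),
        r_arm=LimbParams(swing_amp=0.35),
        bob_amp=0.08,
    )
    p["jump"] = ActionParams(
        action_name="jump",
        l_leg=LimbParams(swing_amp=0.35, flex_amp=0.9, flex_phase=-0.5),
        r_leg=LimbParams(swing_amp=0.35, flex_amp=0.9, flex_phase=-0.5),
        l_arm=LimbParams(swing_amp=1.1, swing_phase=0.4, flex_amp=0.4),
        r_arm=LimbParams(swing_amp=1.1, swing_phase=0.4, flex_amp=0.4),
        bob_amp=0.22,
        bob_freq=1.0,
        bob_phase=0.9,
    )
    p["rope_jump"] = ActionParams(
        action_name="rope_jump",
        l_leg=LimbParams(swing_amp=0.2, flex_amp=0.6, flex_phase=-0.4,
                         frequency=2.0),
        r_leg=LimbParams(swing_amp=0.2, flex_amp=0.6, flex_phase=-0.4,
                         frequency=2.0),
        l_arm=LimbParams(swing_amp=0.5, flex_amp=0.9, frequency=2.0),
        r_arm=LimbParams(swing_amp=0.5, flex_amp=0.9, frequency=2.0),
        bob_amp=0.16,
        bob_freq=2.0,
    )
    p["high_jump"] = ActionParams(
        action_name="high_jump",
        l_leg=LimbParams(swing_amp=0.8, flex_amp=0.7, flex_phase=-0.8),
        r_leg=LimbParams(swing_amp=0.8, swing_phase=2.2, flex_amp=0.7),
        l_arm=LimbParams(swing_amp=1.0, swing_phase=1.2),
        r_arm=LimbParams(swing_amp=1.0, swing_phase=1.2),
        bob_amp=0.20,
        bob_freq=1.0,
    )
    p["kick_front"] = ActionParams(
        action_name="kick_front",
        r_leg=LimbParams(swing_amp=1.0, flex_amp=0.9, flex_phase=-1.1),
        l_leg=LimbParams(swing_amp=0.25, swing_phase=math.pi),
        l_arm=LimbParams(swing_amp=0.7, swing_phase=math.pi),
        r_arm=LimbParams(swing_amp=0.7),
        bob_amp=0.08,
        sway_amp=0.06,
    )
    p["kick_side"] = ActionParams(
        action_name="kick_side",
        r_leg=LimbParams(swing_amp=1.1, swing_mean=0.3, flex_amp=0.6),
        l_leg=LimbParams(swing_amp=0.12),
        l_arm=LimbParams(swing_amp=0.6, swing_phase=math.pi / 2),
        r_arm=LimbParams(swing_amp=0.6, swing_phase=-math.pi / 2),
        sway_amp=0.12,
    )
    p["soccer_kick"] = ActionParams(
        action_name="soccer_kick",
        r_leg=LimbParams(swing_amp=1.2, flex_amp=1.0, flex_phase=-0.9),
        l_leg=LimbParams(swing_amp=0.2, swing_phase=math.pi),
        l_arm=LimbParams(swing_amp=0.7, swing_phase=math.pi),
        r_arm=LimbParams(swing_amp=0.7),
        bob_amp=0.07,
    )
    p["throw_overhead"] = ActionParams(
        action_name="throw_overhead",
        r_arm=LimbParams(swing_amp=1.4, swing_mean=1.2, flex_amp=1.0,
                         flex_phase=-1.0),
        l_arm=LimbParams(swing_amp=0.7),
        l_leg=LimbParams(swing_amp=0.45),
        r_leg=LimbParams(swing_amp=0.45, swing_phase=math.pi),
        bob_amp=0.1,
        sway_amp=0.08,
    )
    p["toss"] = ActionParams(
        action_name="toss",
        r_arm=LimbParams(swing_amp=1.0, swing_mean=0.4, flex_amp=0.6,
                         flex_phase=0.8),
        l_arm=LimbParams(swing_amp=0.6, swing_phase=math.pi),
        l_leg=LimbParams(swing_amp=0.35),
        r_leg=LimbParams(swing_amp=0.35, swing_phase=math.pi),
        bob_amp=0.1,
    )
    p["bowl"] = ActionParams(
        action_name="bowl",
        r_arm=LimbParams(swing_amp=1.3, swing_mean=-0.3, flex_amp=0.3),
        l_arm=LimbParams(swing_amp=0.55, swing_phase=math.pi),
        l_leg=LimbParams(swing_amp=0.6),
        r_leg=LimbParams(swing_amp=0.6, swing_phase=math.pi),
        bob_amp=0.12,
        bob_freq=1.0,
    )
    p["crouch"] = ActionParams(
        action_name="crouch",
        l_leg=LimbParams(swing_amp=0.5, flex_amp=1.1, flex_phase=-0.6),
        r_leg=LimbParams(swing_amp=0.5, flex_amp=1.1, flex_phase=-0.6),
        l_arm=LimbParams(swing_amp=0.7, swing_phase=0.5),
        r_arm=LimbParams(swing_amp=0.7, swing_phase=0.5),
        bob_amp=0.3,
        bob_freq=1.0,
        bob_phase=-0.6,
    )
    return p


_PRESETS = _presets()


def list_presets() -> list[str]:
    """Names of the shipped action presets."""
    return sorted(_PRESETS)


def action_preset(name: str) -> ActionParams:
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown action preset {name!r}; available: {', '.join(list_presets())}"
        ) from None


#: Activity set used by the paired-perturbation discrimination experiment.
EXP2_ACTIVITIES = (
    "jump", "rope_jump", "kick_front", "kick_side", "soccer_kick",
    "toss", "bowl", "throw_overhead", "crouch", "backward_walk",
)


# ---------------------------------------------------------------------------
# Serialization (JSON; CSV long format)
# ---------------------------------------------------------------------------

def write_sequence(seq: PointLightSequence, path) -> None:
    """Write a sequence to JSON.

    Layout: ``{action_name, frame_duration_s, is_cyclic, dot_labels,
    frames: [[[x, y] * D] * T]}``.
    """
    obj = {
        "action_name": seq.action_name,
        "frame_duration_s": seq.frame_duration_s,
        "is_cyclic": seq.is_cyclic,
        "dot_labels": list(seq.dot_labels),
        "frames": seq.positions.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(obj, fh)


def read_sequence(path) -> PointLightSequence:
    """Read a JSON sequence file, validating the format contract."""
    with open(path) as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"not valid JSON: {exc}") from exc
    for key in ("action_name", "frame_duration_s", "dot_labels", "frames"):
        if key not in obj:
            raise FormatError(f"missing required field {key!r}")
    frames = obj["frames"]
    if not isinstance(frames, list) or len(frames) < 2:
        raise FormatError("field 'frames' must list at least 2 frames")
    labels = obj["dot_labels"]
    n_dots = len(labels)
    arr = np.empty((len(frames), n_dots, 2))
    for t, frame in enumerate(frames):
        if len(frame) != n_dots:
            raise FormatError(
                f"field 'frames': frame {t} has {len(frame)} dots, "
                f"expected {n_dots}"
            )
        for d, xy in enumerate(frame):
            if (
                not isinstance(xy, (list, tuple))
                or len(xy) != 2
                or not all(isinstance(v, (int, float)) for v in xy)
            ):
                raise FormatError(
                    f"field 'frames': frame {t} dot {d} is not a numeric [x, y]"
                )
            arr[t, d] = xy
    if not np.all(np.isfinite(arr)):
        raise FormatError("field 'frames': non-finite coordinate")
    try:
        return PointLightSequence(
            positions=arr,
            frame_duration_s=float(obj["frame_duration_s"]),
            dot_labels=tuple(labels),
            action_name=str(obj["action_name"]),
            is_cyclic=bool(obj.get("is_cyclic", False)),
        )
    except (TypeError, ValueError) as exc:
        raise FormatError(str(exc)) from exc


def write_sequence_csv(seq: PointLightSequence, path) -> None:
    """Long-format CSV: one row per (frame, dot) with columns
    frame, dot, label, x, y."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "dot", "label", "x", "y"])
        for t in range(seq.n_frames):
            for d in range(seq.n_dots):
                x, y = seq.positions[t, d]
                w.writerow([t, d, seq.dot_labels[d], repr(float(x)), repr(float(y))])


def read_sequence_csv(
    path, frame_duration_s: float = 0.05, action_name: str = ""
) -> PointLightSequence:
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            try:
                rows.append(
                    (int(row["frame"]), int(row["dot"]), row["label"],
                     float(row["x"]), float(row["y"]))
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise FormatError(f"bad CSV row {row!r}: {exc}") from exc
    if not rows:
        raise FormatError("empty CSV sequence file")
    n_frames = max(r[0] for r in rows) + 1
    n_dots = max(r[1] for r in rows) + 1
    if len(rows) != n_frames * n_dots:
        raise FormatError(
            f"expected {n_frames * n_dots} rows for {n_frames} frames x "
            f"{n_dots} dots, got {len(rows)}"
        )
    arr = np.full((n_frames, n_dots, 2), np.nan)
    labels = [""] * n_dots
    for t, d, label, x, y in rows:
        arr[t, d] = (x, y)
        labels[d] = label
    if not np.all(np.isfinite(arr)):
        raise FormatError("missing (frame, dot) rows")
    return PointLightSequence(
        positions=arr,
        frame_duration_s=frame_duration_s,
        dot_labels=tuple(labels),
        action_name=action_name,
    )
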