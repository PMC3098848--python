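"""Stimulus manipulations for point-light sequences.

Four manipulations shared by the three experiment designs:

* **spatial scrambling** — dot positions are randomized in the first frame
  while every dot keeps its own frame-to-frame displacement trajectory, which
  destroys the global body configuration but preserves all local motion;
* **graded perturbation** — a per-dot linear morph between a sequence and its
  scrambled counterpart (``lam=0`` biological, ``lam=1`` fully scrambled);
  because the scramble preserves velocities, every morph level of one action
  has identical local motion and hence identical motion energy;
* **trajectory-matched noise masking** — noise dots that replay the
  displacement trajectory of a randomly chosen figure dot from a random start
  position, making the figure impossible to segment by local motion alone;
* **motion energy** — summed direction change (angular) or summed path length
  (excursion) of all dots, the index used to ask whether discrimination
  difficulty tracks the sheer amount of motion in an action.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kinematics import PointLightSequence

__all__ = [
    "ScrambleResult",
    "NoiseMaskSpec",
    "NoiseMaskResult",
    "MotionEnergyIndex",
    "scramble_spatial",
    "perturb",
    "add_noise_mask",
    "motion_energy",
]


@dataclass(frozen=True)
class ScrambleResult:
    """A spatially scrambled sequence plus the per-dot first-frame offsets."""

    scrambled: PointLightSequence
    offsets: np.ndarray  # (D, 2), scrambled_frame1 - original_frame1
    seed: int


@dataclass(frozen=True)
class NoiseMaskSpec:
    """Geometry of the noise-masked detection display.

    The figure (7 deg box) sits inside an 11 deg noise field; its location is
    jittered from trial to trial by up to 1.4 deg so no fixed subset of dot
    positions identifies the figure; dots are 5 arcmin.
    """

    n_noise: int = 0
    window_deg: float = 11.0
    figure_window_deg: float = 7.0
    jitter_deg: float = 1.4
    dot_size_arcmin: float = 5.0
    phase_offset: bool = False  # offset each noise trajectory's start frame
    seed: int = 0

    def __post_init__(self):
        if self.n_noise < 0:
            raise ValueError("n_noise must be >= 0")
        if self.window_deg < self.figure_window_deg:
            raise ValueError("noise window must contain the figure window")
        if self.jitter_deg < 0:
            raise ValueError("jitter_deg must be >= 0")


@dataclass(frozen=True)
class NoiseMaskResult:
    sequence: PointLightSequence
    figure_indices: np.ndarray  # positions of the 12 figure dots after shuffle
    trajectory_sources: np.ndarray  # figure-dot index copied by each noise dot
    jitter: tuple[float, float]
    seed: int


@dataclass(frozen=True)
class MotionEnergyIndex:
    angular_deviation_total: float  # deg of direction change, dots x frames
    path_excursion_total: float  # deg of path length, dots x frames
    method: str = "angular"

    @property
    def value(self) -> float:
        return (
            self.angular_deviation_total
            if self.method == "angular"
            else self.path_excursion_total
        )


def scramble_spatial(
    seq: PointLightSequence, window_deg: float = 7.0, seed: int = 0
) -> ScrambleResult:
    """Randomize first-frame dot locations, preserving each dot's trajectory.

    Scrambled positions satisfy ``S_i(t) = S_i(1) + (B_i(t) - B_i(1))`` with
    ``S_i(1)`` uniform in the ``window_deg`` square centred on fixation, so
    per-dot frame-to-frame displacements are exactly those of the source.
    """
    if window_deg < 0:
        raise ValueError("window_deg must be >= 0")
    rng = np.random.default_rng([int(seed), 0x5C6A])
    first = rng.uniform(
        -window_deg / 2.0, window_deg / 2.0, size=(seq.n_dots, 2)
    )
    rel = seq.positions - seq.positions[0]  # B_i(t) - B_i(1)
    scrambled = seq.with_positions(
        first[None, :, :] + rel,
        action_name=f"{seq.action_name}:scrambled",
        is_cyclic=False,
    )
    offsets = first - seq.positions[0]
    return ScrambleResult(scrambled=scrambled, offsets=offsets, seed=int(seed))


def perturb(
    seq: PointLightSequence, scr: ScrambleResult, lam: float
) -> PointLightSequence:
    """Morph ``seq`` toward its scrambled counterpart.

    ``P_i(t) = (1 - lam) * B_i(t) + lam * S_i(t)``, i.e. each dot is displaced
    by the constant vector ``lam * offsets_i``; velocities are untouched.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    if scr.scrambled.positions.shape != seq.positions.shape:
        raise ValueError("scramble result does not match the sequence shape")
    expected = seq.positions + scr.offsets[None, :, :]
    if not np.allclose(scr.scrambled.positions, expected, atol=1e-6):
        raise ValueError(
            "scramble result was not derived from this sequence "
            "(trajectories disagree)"
        )
    pos = seq.positions + lam * scr.offsets[None, :, :]
    return seq.with_positions(
        pos,
        action_name=f"{seq.action_name}:perturbed{lam:g}",
        is_cyclic=seq.is_cyclic and lam == 0.0,
    )


def _wrap(x: np.ndarray, half: float) -> np.ndarray:
    """Wrap coordinates torus-style into [-half, half)."""
    return (x + half) % (2.0 * half) - half


def add_noise_mask(
    figure: PointLightSequence, spec: NoiseMaskSpec
) -> NoiseMaskResult:
    """Embed the figure in trajectory-matched noise dots.

    The figure is translated by a uniform random jitter within a disc of
    radius ``jitter_deg``; each noise dot starts at a uniform position in the
    noise window and replays the displacement trajectory of a uniformly chosen
    figure dot (with replacement), wrapping at the window edge; the output dot
    order is shuffled so the figure cannot be identified by index.
    """
    rng = np.random.default_rng([int(spec.seed), 0x6D61])
    half = spec.window_deg / 2.0

    # Jitter: uniform draw in a disc of radius jitter_deg about window centre.
    r = spec.jitter_deg * math.sqrt(rng.uniform())
    phi = rng.uniform(0.0, 2.0 * math.pi)
    jitter = (r * math.cos(phi), r * math.sin(phi))
    fig_pos = figure.positions + np.asarray(jitter)[None, None, :]

    n_noise = spec.n_noise
    if n_noise > 0:
        sources = rng.integers(0, figure.n_dots, size=n_noise)
        starts = rng.uniform(-half, half, size=(n_noise, 2))
        rel = figure.positions[:, sources, :] - figure.positions[0, sources, :]
        if spec.phase_offset:
            shifts = rng.integers(0, figure.n_frames, size=n_noise)
            rel = np.stack(
                [np.roll(rel[:, j, :], -int(shifts[j]), axis=0)
                 for j in range(n_noise)],
                axis=1,
            )
            rel = rel - rel[0]
        noise_pos = _wrap(starts[None, :, :] + rel, half)
    else:
        sources = np.empty(0, dtype=int)
        noise_pos = np.empty((figure.n_frames, 0, 2))

    all_pos = np.concatenate([fig_pos, noise_pos], axis=1)
    labels = list(figure.dot_labels) + ["noise"] * n_noise
    order = rng.permutation(figure.n_dots + n_noise)
    inv = np.argsort(order)
    seq = PointLightSequence(
        positions=all_pos[:, order, :],
        frame_duration_s=figure.frame_duration_s,
        dot_labels=tuple(labels[i] for i in order),
        action_name=f"{figure.action_name}:masked{n_noise}",
        is_cyclic=False,
    )
    return NoiseMaskResult(
        sequence=seq,
        figure_indices=inv[: figure.n_dots],
        trajectory_sources=sources,
        jitter=jitter,
        seed=int(spec.seed),
    )


def motion_energy(
    seq: PointLightSequence, method: str = "angular"
) -> MotionEnergyIndex:
    """Summed motion of all dots over the sequence.

    ``excursion``: total path length (deg) summed over dots and frames.
    ``angular``: total absolute direction change (deg) of each dot's
    displacement vector, with zero-displacement steps contributing nothing.
    """
    if method not in ("angular", "excursion"):
        raise ValueError("method must be 'angular' or 'excursion'")
    disp = seq.displacements()  # (T-1, D, 2)
    norms = np.linalg.norm(disp, axis=2)
    excursion = float(norms.sum())

    if seq.n_frames < 3:
        if method == "angular":
            raise ValueError(
                "angular motion energy needs >= 3 frames "
                "(two consecutive displacement vectors)"
            )
        angular = 0.0
    else:
        ang = np.degrees(np.arctan2(disp[:, :, 1], disp[:, :, 0]))
        moving = norms > 1e-12
        delta = ang[1:] - ang[:-1]
        delta = (delta + 180.0) % 360.0 - 180.0
        # wrap to (-180, 180]; map the -180 edge to +180
        delta[delta == -180.0] = 180.0
        # a step contributes only when both adjacent displacements are nonzero
        valid = moving[1:] & moving[:-1]
        angular = float(np.abs(delta[valid]).sum())

    return MotionEnergyIndex(
        angular_deviation_total=angular,
        path_excursion_total=excursion,
        method=method,
    )
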