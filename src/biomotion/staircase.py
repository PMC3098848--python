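"""Transformed two-up/one-down adaptive staircase.

The staircase controls the number of noise dots in the masked detection task.
After two consecutive correct responses the noise level is *raised* (the task
gets harder); after any error it is lowered.  With this rule the level random-
walks around the point where the probability of two consecutive correct
responses is 1/2, i.e. where P(correct) = sqrt(1/2) ~ 70.7% — the classic
convergence point of the transformed up-down method.

A *reversal* is a trial at which the direction of level movement changes;
its value is the level of that trial (the local extremum of the track).  The
run starts at 20 noise dots, moves in steps of 6 until 12 reversals have been
recorded and in steps of 3 thereafter, stops at 16 reversals, and the
threshold is the mean level over the last six reversals.  The step size is
chosen *after* reversal bookkeeping, so the movement that records the 12th
reversal is already a small step; this ordering is what makes a scripted
correct-correct-error cycle produce the reversal tail ...26, 20, 23, 20, 23,
20 (threshold 22.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["StaircaseConfig", "StaircaseState", "update", "threshold"]


@dataclass(frozen=True)
class StaircaseConfig:
    start_level: int = 20
    big_step: int = 6
    small_step: int = 3
    step_change_after_reversals: int = 12
    stop_after_reversals: int = 16
    threshold_last_k: int = 6
    min_level: int = 0
    max_trials: int = 400

    def __post_init__(self):
        if min(self.big_step, self.small_step, self.step_change_after_reversals,
               self.stop_after_reversals, self.threshold_last_k,
               self.max_trials) <= 0:
            raise ValueError("staircase step/stop parameters must be positive")
        if self.min_level < 0:
            raise ValueError("min_level must be >= 0")
        if self.threshold_last_k > self.stop_after_reversals:
            raise ValueError("threshold_last_k cannot exceed stop_after_reversals")

    def step(self, n_reversals: int) -> int:
        return (
            self.small_step
            if n_reversals >= self.step_change_after_reversals
            else self.big_step
        )


@dataclass(frozen=True)
class StaircaseState:
    level: int
    consecutive_correct: int = 0
    last_direction: str = "none"  # "up" | "down" | "none"
    reversal_levels: tuple[int, ...] = ()
    trial_index: int = 0
    finished: bool = False

    @classmethod
    def initial(cls, cfg: StaircaseConfig) -> "StaircaseState":
        return cls(level=cfg.start_level)


def update(
    state: StaircaseState, correct: bool, cfg: StaircaseConfig
) -> StaircaseState:
    """Advance the staircase by one trial outcome.

    Returns a new state; raises if the staircase has already finished.
    """
    if state.finished:
        raise RuntimeError("staircase already finished; cannot update")

    trial_index = state.trial_index + 1
    level = state.level
    consec = state.consecutive_correct
    last_dir = state.last_direction
    reversals = state.reversal_levels

    direction = None
    if correct:
        consec += 1
        if consec >= 2:
            direction = "up"
            consec = 0
    else:
        direction = "down"
        consec = 0

    finished = False
    if direction is not None:
        if last_dir != "none" and direction != last_dir:
            reversals = reversals + (level,)
            if len(reversals) >= cfg.stop_after_reversals:
                finished = True
        last_dir = direction
        if not finished:
            step = cfg.step(len(reversals))
            level = level + step if direction == "up" else level - step
            level = max(level, cfg.min_level)

    if trial_index >= cfg.max_trials:
        finished = True

    return replace(
        state,
        level=level,
        consecutive_correct=consec,
        last_direction=last_dir,
        reversal_levels=reversals,
        trial_index=trial_index,
        finished=finished,
    )


def threshold(state: StaircaseState, cfg: StaircaseConfig) -> float:
    """Mean noise level over the last ``threshold_last_k`` reversals."""
    if len(state.reversal_levels) < cfg.threshold_last_k:
        raise ValueError(
            f"need >= {cfg.threshold_last_k} reversals to estimate a "
            f"threshold, have {len(state.reversal_levels)}"
        )
    tail = state.reversal_levels[-cfg.threshold_last_k:]
    return float(sum(tail)) / cfg.threshold_last_k
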