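"""End-to-end experiment runners on simulated observers.

Three designs, mirroring the behavioural arms of the study:

* **Detection in noise** (:func:`run_exp1`) — 2IFC trials (two successive 1 s
  sequences, one biological + noise, one scrambled + noise); the noise level
  follows the two-up/one-down staircase and the threshold is the mean of the
  last six reversal levels.
* **Paired perturbation discrimination** (:func:`run_exp2`) — constant
  stimuli; on each trial two morphs of the same activity differing by 15
  percentage points of perturbation appear side by side and the observer
  picks the more normal-looking one.  Four pairings (0/15, 15/30, 30/45,
  45/60 %), 40 trials each, activities cycled evenly, sides randomized.
* **Categorization** (:func:`run_exp3_behavioral`) — 216 yes/no trials in 9
  runs of 24 (8 biological, 8 fully scrambled, 8 intermediate 37%-scrambled
  per run, shuffled per run).  d' is computed from biological vs fully
  scrambled trials only; the proportion of "biological" responses to the
  intermediate class is reported separately because those responses have no
  objectively correct answer.

Trial logs carry full stimulus provenance (action, perturbation, noise level,
seeds) so any trial can be re-rendered; stimuli themselves are rendered on
demand rather than generated inline, which keeps large simulated cohorts
cheap.  Every runner is deterministic given (observer seed, design seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import staircase as sc
from . import sdt
from .kinematics import EXP2_ACTIVITIES, action_preset, generate_action
from .observers import (
    CategorizationObserver,
    DetectionObserver,
    DiscriminationObserver,
    sample_categorization_cohort,
    sample_detection_cohort,
    sample_discrimination_cohort,
)
from .transforms import NoiseMaskSpec, add_noise_mask, perturb, scramble_spatial

__all__ = [
    "EXP2_CONDITIONS",
    "EXP3_CLASSES",
    "Exp1Result",
    "Exp2Result",
    "Exp3Result",
    "GroupSummary",
    "run_exp1",
    "run_exp2",
    "run_exp3_behavioral",
    "run_group_exp1",
    "run_group_exp2",
    "run_group_exp3",
    "render_exp1_trial",
    "render_exp2_trial",
]

#: Perturbation pairings (lam_low, lam_high); labels use the percent notation.
EXP2_CONDITIONS = (
    (0.00, 0.15),
    (0.15, 0.30),
    (0.30, 0.45),
    (0.45, 0.60),
)

#: Stimulus classes of the categorization design.  The intermediate level is
#: stored as 0.375 (midway between the 30% and 45% perturbations) but labelled
#: "37%" for display.
EXP3_CLASSES = ("biological", "scrambled", "intermediate")
INTERMEDIATE_LAM = 0.375

_EXP1_ACTIONS = (
    "walk", "backward_walk", "run", "stair_climb", "jump", "rope_jump",
    "high_jump", "kick_front", "kick_side", "soccer_kick", "throw_overhead",
    "toss", "bowl", "crouch",
)


@dataclass(frozen=True)
class Exp1Result:
    trial_log: pd.DataFrame
    threshold: float
    reversal_levels: tuple[int, ...]
    n_trials: int
    observer_seed: int
    seed: int


@dataclass(frozen=True)
class Exp2Result:
    trial_log: pd.DataFrame
    accuracy: dict
    observer_seed: int
    seed: int


@dataclass(frozen=True)
class Exp3Result:
    sdt: sdt.SDTResult
    intermediate_biological_rate: float
    counts: dict
    trial_log: pd.DataFrame | None
    observer_seed: int
    seed: int


@dataclass(frozen=True)
class GroupSummary:
    group: str
    endpoints: np.ndarray
    mean: float
    se: float
    n: int

    @classmethod
    def from_endpoints(cls, group, values) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        se = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")
        return cls(group=group, endpoints=v, mean=float(v.mean()), se=se, n=len(v))


def run_exp1(
    observer: DetectionObserver,
    cfg: sc.StaircaseConfig | None = None,
    seed: int = 0,
    actions: tuple[str, ...] = _EXP1_ACTIONS,
) -> Exp1Result:
    """One staircase session of the 2IFC detection-in-noise task."""
    cfg = cfg or sc.StaircaseConfig()
    design_rng = np.random.default_rng([int(seed), 0xE1])
    state = sc.StaircaseState.initial(cfg)
    rows = []
    while not state.finished:
        trial = state.trial_index
        action = actions[trial % len(actions)]
        signal_interval = int(design_rng.integers(1, 3))
        level = state.level
        correct = observer.respond_detection(level, trial_index=trial)
        response = signal_interval if correct else 3 - signal_interval
        new_state = sc.update(state, correct, cfg)
        n_rev = len(new_state.reversal_levels)
        rows.append(
            {
                "trial": trial,
                "action": action,
                "stimulus_seed": int(seed) * 100_000 + trial,
                "level": level,
                "interval_of_signal": signal_interval,
                "response": response,
                "correct": correct,
                "reversal_flag": n_rev > len(state.reversal_levels),
                "step": cfg.step(len(state.reversal_levels)),
            }
        )
        state = new_state
    log = pd.DataFrame(rows)
    if len(state.reversal_levels) >= cfg.threshold_last_k:
        thr = sc.threshold(state, cfg)
    else:
        thr = float("nan")
    return Exp1Result(
        trial_log=log,
        threshold=thr,
        reversal_levels=state.reversal_levels,
        n_trials=state.trial_index,
        observer_seed=observer.seed,
        seed=int(seed),
    )


def render_exp1_trial(row, mask_spec: NoiseMaskSpec | None = None):
    """Re-render the two intervals of a logged detection trial.

    Returns ``(signal_interval_masked, noise_interval_masked)`` as
    :class:`~biomotion.transforms.NoiseMaskResult`.
    """
    params = action_preset(row["action"])
    stim_seed = int(row["stimulus_seed"])
    fig = generate_action(params, seed=stim_seed)
    scr = scramble_spatial(fig, window_deg=11.0, seed=stim_seed)
    spec = mask_spec or NoiseMaskSpec(n_noise=int(row["level"]), seed=stim_seed)
    return add_noise_mask(fig, spec), add_noise_mask(scr.scrambled, spec)


def run_exp2(
    observer: DiscriminationObserver,
    activities: tuple[str, ...] = EXP2_ACTIVITIES,
    n_trials_per_condition: int = 40,
    seed: int = 0,
) -> Exp2Result:
    """One session of the paired perturbation discrimination task."""
    if not activities:
        raise ValueError("need at least one activity")
    design_rng = np.random.default_rng([int(seed), 0xE2])
    trials = []
    for ci, (lam_lo, lam_hi) in enumerate(EXP2_CONDITIONS):
        label = f"{lam_lo * 100:.0f}% vs {lam_hi * 100:.0f}%"
        for k in range(n_trials_per_condition):
            activity = activities[k % len(activities)]
            trials.append((label, lam_lo, lam_hi, activity))
    order = design_rng.permutation(len(trials))

    rows = []
    for trial, idx in enumerate(order):
        label, lam_lo, lam_hi, activity = trials[idx]
        lower_side = "left" if design_rng.uniform() < 0.5 else "right"
        lam_left = lam_lo if lower_side == "left" else lam_hi
        lam_right = lam_hi if lower_side == "left" else lam_lo
        choice = observer.respond_discrimination(
            lam_left, lam_right, trial_index=trial
        )
        rows.append(
            {
                "trial": trial,
                "condition": label,
                "activity": activity,
                "lam_low": lam_lo,
                "lam_high": lam_hi,
                "side_of_lower": lower_side,
                "stimulus_seed": int(seed) * 100_000 + trial,
                "choice": choice,
                "correct": choice == lower_side,
            }
        )
    log = pd.DataFrame(rows)
    table = sdt.accuracy_table(log)
    return Exp2Result(
        trial_log=log, accuracy=table, observer_seed=observer.seed, seed=int(seed)
    )


def render_exp2_trial(row):
    """Re-render the two morphs of a logged discrimination trial."""
    params = action_preset(row["activity"])
    stim_seed = int(row["stimulus_seed"])
    fig = generate_action(params, seed=stim_seed)
    scr = scramble_spatial(fig, window_deg=7.0, seed=stim_seed)
    low = perturb(fig, scr, row["lam_low"])
    high = perturb(fig, scr, row["lam_high"])
    if row["side_of_lower"] == "left":
        return low, high
    return high, low


def run_exp3_behavioral(
    observer: CategorizationObserver,
    n_runs: int = 9,
    trials_per_class_per_run: int = 8,
    seed: int = 0,
    return_log: bool = True,
) -> Exp3Result:
    """One session of the yes/no categorization task (default 216 trials)."""
    rows = [] if return_log else None
    counts = {
        c: {"biological": 0, "scrambled": 0} for c in EXP3_CLASSES
    }
    trial = 0
    for run in range(n_runs):
        run_rng = np.random.default_rng([int(seed), 0xE3, run])
        classes = np.repeat(np.arange(3), trials_per_class_per_run)
        run_rng.shuffle(classes)
        for ci in classes:
            stim_class = EXP3_CLASSES[int(ci)]
            response = observer.respond_categorization(
                stim_class, trial_index=trial
            )
            counts[stim_class][response] += 1
            if return_log:
                rows.append(
                    {
                        "trial": trial,
                        "run": run,
                        "stimulus_class": stim_class,
                        "lam": {
                            "biological": 0.0,
                            "scrambled": 1.0,
                            "intermediate": INTERMEDIATE_LAM,
                        }[stim_class],
                        "stimulus_seed": int(seed) * 100_000 + trial,
                        "response": response,
                        "correct": (
                            None
                            if stim_class == "intermediate"
                            else (response == "biological")
                            == (stim_class == "biological")
                        ),
                    }
                )
            trial += 1

    hits = counts["biological"]["biological"]
    misses = counts["biological"]["scrambled"]
    fas = counts["scrambled"]["biological"]
    crs = counts["scrambled"]["scrambled"]
    res = sdt.dprime(hits, misses, fas, crs, correction="loglinear")
    n_int = sum(counts["intermediate"].values())
    int_rate = counts["intermediate"]["biological"] / n_int if n_int else float("nan")
    return Exp3Result(
        sdt=res,
        intermediate_biological_rate=int_rate,
        counts=counts,
        trial_log=pd.DataFrame(rows) if return_log else None,
        observer_seed=observer.seed,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Group-level simulation
# ---------------------------------------------------------------------------

def run_group_exp1(
    group: str,
    n: int = 15,
    seed: int = 0,
    cfg: sc.StaircaseConfig | None = None,
) -> tuple[GroupSummary, list[Exp1Result]]:
    """Simulate a cohort of detection staircases; endpoint = threshold."""
    cohort = sample_detection_cohort(group, n, seed=seed)
    results = [
        run_exp1(obs, cfg=cfg, seed=int(seed) * 1000 + i)
        for i, obs in enumerate(cohort)
    ]
    summary = GroupSummary.from_endpoints(group, [r.threshold for r in results])
    return summary, results


def run_group_exp2(
    group: str, n: int = 16, seed: int = 0
) -> tuple[dict, list[Exp2Result]]:
    """Simulate a discrimination cohort; endpoints = per-condition accuracy.

    Returns a dict mapping condition label to a :class:`GroupSummary` of
    percent-correct values, plus per-observer results.
    """
    cohort = sample_discrimination_cohort(group, n, seed=seed)
    results = [
        run_exp2(obs, seed=int(seed) * 1000 + i) for i, obs in enumerate(cohort)
    ]
    labels = results[0].accuracy["condition_labels"]
    summaries = {
        label: GroupSummary.from_endpoints(
            group, [r.accuracy["percent_correct"][label] for r in results]
        )
        for label in labels
    }
    return summaries, results


def run_group_exp3(
    group: str, n: int = 10, seed: int = 0, return_logs: bool = False
) -> tuple[dict, list[Exp3Result]]:
    """Simulate a categorization cohort; endpoints = d', rates."""
    cohort = sample_categorization_cohort(group, n, seed=seed)
    results = [
        run_exp3_behavioral(
            obs, seed=int(seed) * 1000 + i, return_log=return_logs
        )
        for i, obs in enumerate(cohort)
    ]
    summaries = {
        "dprime": GroupSummary.from_endpoints(group, [r.sdt.dprime for r in results]),
        "hit_rate": GroupSummary.from_endpoints(
            group, [r.sdt.hit_rate for r in results]
        ),
        "fa_rate": GroupSummary.from_endpoints(
            group, [r.sdt.fa_rate for r in results]
        ),
        "intermediate_biological_rate": GroupSummary.from_endpoints(
            group, [r.intermediate_biological_rate for r in results]
        ),
    }
    return summaries, results
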