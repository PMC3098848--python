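"""Signal-detection and behavioural statistics.

Sensitivity is the equal-variance d' = z(H) - z(F) with response bias
c = -(z(H) + z(F)) / 2.  Extreme rates (0 or 1) make z undefined, so the
log-linear correction (add 0.5 to each count, 1 to each trial total) is the
default; a near-ceiling hit rate makes some such convention mandatory.

Also here: the exact-binomial above-chance criterion used to classify
individual forced-choice accuracies (26/40 at one-sided alpha=.05), accuracy
tables for the paired-perturbation design, and thin wrappers over the
standard two-sample statistics (pooled t, Pearson r, Pearson chi-square
without continuity correction, summary-based Cohen's d).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SDTResult",
    "dprime",
    "binomial_above_chance_k",
    "cohens_d_from_summary",
    "pearson_r",
    "contingency_chi2",
    "two_sample_t",
    "accuracy_table",
]


@dataclass(frozen=True)
class SDTResult:
    n_signal: int
    n_noise_trials: int
    hits: int
    false_alarms: int
    hit_rate: float
    fa_rate: float
    dprime: float
    criterion_c: float
    correction: str = "loglinear"


def dprime(
    hits: int,
    misses: int,
    false_alarms: int,
    correct_rejections: int,
    correction: str = "loglinear",
) -> SDTResult:
    """Equal-variance d' from yes/no response counts.

    With ``correction="loglinear"`` the rates are (x + 0.5) / (n + 1); with
    ``"none"`` raw rates are used and an extreme rate raises an error that
    points at the correction.
    """
    for name, v in (("hits", hits), ("misses", misses),
                    ("false_alarms", false_alarms),
                    ("correct_rejections", correct_rejections)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    n_signal = hits + misses
    n_noise = false_alarms + correct_rejections
    if n_signal == 0 or n_noise == 0:
        raise ValueError("need at least one signal and one noise trial")

    if correction == "loglinear":
        h = (hits + 0.5) / (n_signal + 1.0)
        f = (false_alarms + 0.5) / (n_noise + 1.0)
    elif correction == "none":
        h = hits / n_signal
        f = false_alarms / n_noise
        if h in (0.0, 1.0) or f in (0.0, 1.0):
            raise ValueError(
                "hit or false-alarm rate is 0 or 1; use "
                "correction='loglinear' to compute a finite d'"
            )
    else:
        raise ValueError("correction must be 'loglinear' or 'none'")

    zh = float(stats.norm.ppf(h))
    zf = float(stats.norm.ppf(f))
    return SDTResult(
        n_signal=n_signal,
        n_noise_trials=n_noise,
        hits=hits,
        false_alarms=false_alarms,
        hit_rate=h,
        fa_rate=f,
        dprime=zh - zf,
        criterion_c=-(zh + zf) / 2.0,
        correction=correction,
    )


def binomial_above_chance_k(n_trials: int, p0: float = 0.5,
                            alpha: float = 0.05) -> int:
    """Smallest k with exact one-sided tail P(X >= k | n, p0) < alpha.

    The above-chance criterion for an individual accuracy count; for 40
    trials at p0=.5 and alpha=.05 this is 26 correct.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    for k in range(n_trials + 1):
        # P(X >= k) = sf(k - 1)
        if stats.binom.sf(k - 1, n_trials, p0) < alpha:
            return k
    return n_trials + 1  # unreachable for sensible alpha: even n/n not significant


def cohens_d_from_summary(
    mean1: float, se1: float, n1: int, mean2: float, se2: float, n2: int
) -> float:
    """Pooled-SD Cohen's d from group means and standard errors.

    SD_i is recovered as se_i * sqrt(n_i).  An approximation to the
    individual-data effect size when only summary statistics are available.
    """
    if n1 <= 1 or n2 <= 1:
        raise ValueError("each group needs n > 1")
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be > 0")
    sd1 = se1 * math.sqrt(n1)
    sd2 = se2 * math.sqrt(n2)
    sp = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    return abs(mean1 - mean2) / sp


def pearson_r(xs, ys) -> tuple[float, float]:
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.std() == 0 or ys.std() == 0:
        raise ValueError("degenerate (constant) variable in correlation")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p)


def contingency_chi2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def two_sample_t(
    a=None, b=None, *, summary: tuple | None = None
) -> tuple[float, float, float]:
    """Pooled-variance two-sample t-test.

    Either two sample arrays, or ``summary=(mean1, sd1, n1, mean2, sd2, n2)``.
    Returns (t, df, p).
    """
    if summary is not None:
        m1, s1, n1, m2, s2, n2 = summary
        if s1 <= 0 or s2 <= 0:
            raise ValueError("degenerate variance in t-test")
        res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
        df = n1 + n2 - 2
    else:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            raise ValueError("degenerate variance in t-test")
        res = stats.ttest_ind(a, b, equal_var=True)
        df = len(a) + len(b) - 2
    return float(res.statistic), float(df), float(res.pvalue)


def accuracy_table(
    trials: pd.DataFrame,
    most_extreme_condition: str | None = None,
) -> dict:
    """Per-condition and per-activity percent correct from an Exp-2 trial log.

    ``trials`` needs columns ``condition``, ``activity`` and ``correct``.
    Per-activity accuracy pools every perturbation pairing except the most
    extreme one (where performance is at chance for everyone); by default the
    lexicographically last condition label is taken as most extreme, which
    matches the "45% vs 60%" labelling.
    """
    required = {"condition", "activity", "correct"}
    if not required.issubset(trials.columns):
        raise ValueError(f"trial log must have columns {sorted(required)}")
    by_cond = trials.groupby("condition", sort=True)["correct"].agg(
        ["mean", "count"]
    )
    conditions = list(by_cond.index)
    if most_extreme_condition is None:
        most_extreme_condition = conditions[-1]
    pooled = trials[trials["condition"] != most_extreme_condition]
    by_act = pooled.groupby("activity", sort=True)["correct"].agg(
        ["mean", "count"]
    )
    return {
        "condition_labels": conditions,
        "n_trials_per_condition": by_cond["count"].to_dict(),
        "percent_correct": {c: 100.0 * m for c, m in by_cond["mean"].items()},
        "per_activity_percent_correct": {
            a: 100.0 * m for a, m in by_act["mean"].items()
        },
        "excluded_condition": most_extreme_condition,
    }
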