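"""Synthetic event-related / block fMRI on a voxel lattice, and ROI analysis.

The imaging arm of the pipeline replaces a scanned brain volume with a small
voxel lattice containing one embedded ellipsoidal "responsive region" (the
synthetic stand-in for STSp or MT).  Each voxel carries a baseline time
series plus AR(1)+white noise in percent-signal units; voxels inside the
region additionally respond to events with a double-gamma hemodynamic
response, scaled by a per-condition amplitude map.  Ground-truth region
labels are retained so recovery can be checked against an oracle.

The analysis chain mirrors standard response-contingent ROI practice:

1. a block-design localizer (alternating biological/scrambled blocks) is fit
   voxelwise with an OLS GLM of HRF-convolved boxcar regressors;
2. the ROI is the largest 6-connected component of voxels surviving
   Benjamini-Hochberg FDR at q < 0.05 on the contrast p-values, falling back
   to uncorrected p < 0.003 when nothing survives;
3. event-related runs are reduced to the ROI-mean time series, event-locked
   epochs are averaged per response category (hit / correct rejection /
   false alarm / intermediate) in percent-of-run-mean units, and the peak
   percent signal change is the post-onset maximum of the *measured* average
   minus its value at the onset sample — no curve fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EventDesign",
    "BlockDesign",
    "LatticeSpec",
    "VoxelLattice",
    "GlmResult",
    "RoiResult",
    "BoldExperimentResult",
    "double_gamma_hrf",
    "simulate_bold",
    "glm_contrast",
    "define_roi",
    "roi_mean_series",
    "event_related_average",
    "peak_percent_change",
    "run_bold_experiment",
    "classify_response_pattern",
    "save_lattice",
    "load_lattice",
    "LOCALIZER_AMPLITUDES",
    "EVENT_AMPLITUDES",
]

_FINE_DT = 0.1  # s, grid for HRF convolution

#: Peak percent-signal amplitudes of the synthetic responsive region.
LOCALIZER_AMPLITUDES = {"biological": 0.8, "scrambled": 0.3}
EVENT_AMPLITUDES = {
    # Controls: strong response whenever the percept is "biological"
    # (hits and false alarms), weaker on correct rejections.
    "control": {
        "hit": 0.55,
        "false_alarm": 0.50,
        "correct_rejection": 0.25,
        "intermediate": 0.35,
    },
    # Patients: undifferentiated response across categories.
    "patient": {
        "hit": 0.40,
        "false_alarm": 0.40,
        "correct_rejection": 0.40,
        "intermediate": 0.40,
    },
}


def double_gamma_hrf(t, peak_delay: float = 6.0, undershoot_delay: float = 16.0,
                     ratio: float = 1.0 / 6.0, dispersion: float = 1.0) -> np.ndarray:
    """Canonical double-gamma HRF, normalized to unit peak on a fine grid."""
    t = np.asarray(t, dtype=float)
    d1, d2 = peak_delay / dispersion, undershoot_delay / dispersion
    h = stats.gamma.pdf(t, d1, scale=dispersion) - ratio * stats.gamma.pdf(
        t, d2, scale=dispersion
    )
    grid = np.arange(0.0, 32.0, 0.01)
    hg = stats.gamma.pdf(grid, d1, scale=dispersion) - ratio * stats.gamma.pdf(
        grid, d2, scale=dispersion
    )
    return h / hg.max()


@dataclass(frozen=True)
class EventDesign:
    """Timing + response-category labels of one event-related run."""

    onsets_s: tuple[float, ...]
    conditions: tuple[str, ...]
    TR_s: float = 2.0
    stimulus_duration_s: float = 1.0
    isi_s: float = 11.0
    run_length_s: float | None = None

    def __post_init__(self):
        if len(self.onsets_s) != len(self.conditions):
            raise ValueError("onsets and conditions must have equal length")
        if list(self.onsets_s) != sorted(self.onsets_s):
            raise ValueError("onsets must be sorted")
        if self.run_length_s is None:
            tail = self.stimulus_duration_s + self.isi_s + 2.0
            object.__setattr__(
                self, "run_length_s",
                (self.onsets_s[-1] if self.onsets_s else 0.0) + tail,
            )
        object.__setattr__(self, "onsets_s", tuple(float(o) for o in self.onsets_s))
        object.__setattr__(self, "conditions", tuple(self.conditions))

    @property
    def n_volumes(self) -> int:
        return int(round(self.run_length_s / self.TR_s))

    @property
    def condition_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.conditions:
            seen.setdefault(c)
        return tuple(seen)

    @classmethod
    def balanced(
        cls,
        counts: dict[str, int] | None = None,
        TR_s: float = 2.0,
        stimulus_duration_s: float = 1.0,
        isi_s: float = 11.0,
        lead_in_s: float = 10.0,
        seed: int = 0,
    ) -> "EventDesign":
        """A run with fixed per-category event counts in shuffled order.

        Default counts follow a 24-trial run (8 biological, 8 scrambled split
        evenly into correct rejections and false alarms, 8 intermediate).
        """
        counts = counts or {
            "hit": 8, "correct_rejection": 4, "false_alarm": 4, "intermediate": 8,
        }
        conds = [c for c, n in counts.items() for _ in range(n)]
        rng = np.random.default_rng([int(seed), 0xB0]) if seed is not None else None
        if rng is not None:
            conds = [conds[i] for i in rng.permutation(len(conds))]
        spacing = stimulus_duration_s + isi_s
        onsets = [lead_in_s + i * spacing for i in range(len(conds))]
        return cls(
            onsets_s=tuple(onsets),
            conditions=tuple(conds),
            TR_s=TR_s,
            stimulus_duration_s=stimulus_duration_s,
            isi_s=isi_s,
        )

    @classmethod
    def from_trial_log(
        cls,
        trial_log,
        run: int,
        TR_s: float = 2.0,
        stimulus_duration_s: float = 1.0,
        isi_s: float = 11.0,
        lead_in_s: float = 10.0,
    ) -> "EventDesign":
        """Response-contingent design from one run of a categorization log.

        Categories: hit (biological judged biological), miss, correct
        rejection, false alarm, intermediate (all 37%-scrambled trials
        regardless of response, since those have no correct answer).
        """
        sub = trial_log[trial_log["run"] == run].sort_values("trial")
        if sub.empty:
            raise ValueError(f"trial log has no rows for run {run}")
        conds = []
        for _, row in sub.iterrows():
            cls_, resp = row["stimulus_class"], row["response"]
            if cls_ == "intermediate":
                conds.append("intermediate")
            elif cls_ == "biological":
                conds.append("hit" if resp == "biological" else "miss")
            else:
                conds.append("false_alarm" if resp == "biological"
                             else "correct_rejection")
        spacing = stimulus_duration_s + isi_s
        onsets = [lead_in_s + i * spacing for i in range(len(conds))]
        return cls(
            onsets_s=tuple(onsets),
            conditions=tuple(conds),
            TR_s=TR_s,
            stimulus_duration_s=stimulus_duration_s,
            isi_s=isi_s,
        )


@dataclass(frozen=True)
class BlockDesign:
    """Alternating two-condition block design (localizer runs).

    Each cycle presents one block per condition followed by a fixation rest
    block; with 7 cycles of 14 s blocks and an 8 s lead-in the scan lasts
    316 s.  Rest blocks provide the baseline against which both conditions
    are estimated (``rest_length_s=0`` gives a contiguous alternation).
    """

    conditions: tuple[str, str] = ("biological", "scrambled")
    block_length_s: float = 14.0
    n_blocks_per_condition: int = 7
    rest_length_s: float = 14.0
    TR_s: float = 2.0
    lead_in_s: float = 8.0

    def __post_init__(self):
        if self.n_blocks_per_condition < 1:
            raise ValueError("need at least one block per condition")

    @property
    def cycle_length_s(self) -> float:
        return 2 * self.block_length_s + self.rest_length_s

    @property
    def run_length_s(self) -> float:
        return (
            self.lead_in_s
            + self.n_blocks_per_condition * self.cycle_length_s
            + max(self.rest_length_s, 2 * self.TR_s)
        )

    @property
    def n_volumes(self) -> int:
        return int(round(self.run_length_s / self.TR_s))

    @property
    def condition_names(self) -> tuple[str, ...]:
        return self.conditions

    def block_onsets(self, condition: str) -> tuple[float, ...]:
        try:
            which = self.conditions.index(condition)
        except ValueError:
            raise ValueError(f"unknown condition {condition!r}") from None
        return tuple(
            self.lead_in_s + i * self.cycle_length_s + which * self.block_length_s
            for i in range(self.n_blocks_per_condition)
        )


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry and noise of the synthetic voxel lattice."""

    shape: tuple[int, int, int] = (20, 20, 10)
    region_center: tuple[float, float, float] | None = None
    region_radii: tuple[float, float, float] = (3.5, 2.5, 2.0)
    # Voxel noise after the preprocessing a scanned series would have seen
    # (smoothing, detrending): 0.5% white SD with mild AR(1) autocorrelation.
    noise_sd: float = 0.5
    ar1: float = 0.3
    baseline: float = 100.0

    def center(self) -> tuple[float, float, float]:
        if self.region_center is not None:
            return self.region_center
        return tuple((s - 1) / 2.0 for s in self.shape)

    def region_mask(self) -> np.ndarray:
        cx, cy, cz = self.center()
        rx, ry, rz = self.region_radii
        x, y, z = np.indices(self.shape)
        return (
            ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2
        ) <= 1.0


@dataclass(frozen=True)
class VoxelLattice:
    """4D simulated volume (x, y, z, t) plus ground-truth region labels."""

    data: np.ndarray
    TR_s: float
    region_mask: np.ndarray
    spec: LatticeSpec | None = None

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


def _sampled_regressor(design, condition: str) -> np.ndarray:
    """HRF-convolved boxcar for one condition, sampled at the TR grid.

    Normalized so an isolated stimulus event (or block, for block designs)
    peaks at 1.0 on the TR grid; amplitudes are then peak percent changes.
    """
    n_vol = design.n_volumes
    n_fine = int(round(design.run_length_s / _FINE_DT)) + 1
    box = np.zeros(n_fine)
    if isinstance(design, BlockDesign):
        dur = design.block_length_s
        events = [(o, dur) for c in [condition]
                  for o in design.block_onsets(condition)]
    else:
        dur = design.stimulus_duration_s
        events = [
            (o, dur)
            for o, c in zip(design.onsets_s, design.conditions)
            if c == condition
        ]
    if not events:
        return np.zeros(n_vol)
    for onset, d in events:
        i0 = int(round(onset / _FINE_DT))
        i1 = int(round((onset + d) / _FINE_DT))
        box[i0:i1] = 1.0
    hrf = double_gamma_hrf(np.arange(0.0, 32.0, _FINE_DT))
    conv = np.convolve(box, hrf)[:n_fine]

    # Unit-peak reference: one isolated event of the same duration.
    ref_len = int(round((dur + 34.0) / _FINE_DT))
    ref_box = np.zeros(ref_len)
    ref_box[: int(round(dur / _FINE_DT))] = 1.0
    ref = np.convolve(ref_box, hrf)[:ref_len]
    tr_stride = int(round(design.TR_s / _FINE_DT))
    ref_peak = ref[::tr_stride].max()
    conv = conv / ref_peak

    idx = (np.arange(n_vol) * tr_stride).clip(max=n_fine - 1)
    return conv[idx]


def simulate_bold(
    design,
    spec: LatticeSpec | None = None,
    amplitudes: dict[str, float] | None = None,
    seed: int = 0,
) -> VoxelLattice:
    """Simulate one run on the voxel lattice.

    Region voxels respond to each condition with ``amplitudes[condition]``
    percent peak signal change; all voxels carry AR(1)+white noise around the
    baseline.  Deterministic given ``seed``.
    """
    spec = spec or LatticeSpec()
    amplitudes = amplitudes or {}
    for c, a in amplitudes.items():
        if not np.isfinite(a):
            raise ValueError(f"amplitude for {c!r} must be finite")
    if isinstance(design, EventDesign) and len(design.onsets_s) > 1:
        gaps = np.diff(design.onsets_s)
        if np.any(gaps < design.TR_s):
            warnings.warn(
                "events closer than one TR; responses superpose", stacklevel=2
            )

    n_vol = design.n_volumes
    sig = np.zeros(n_vol)
    for cond in design.condition_names:
        a = amplitudes.get(cond, 0.0)
        if a != 0.0:
            sig += a * _sampled_regressor(design, cond)

    mask = spec.region_mask()
    n_vox = int(np.prod(spec.shape))
    rng = np.random.default_rng([int(seed), 0xB01D])
    white = rng.standard_normal((n_vox, n_vol))
    if spec.ar1 != 0.0:
        # AR(1) with unit marginal variance, then scaled to noise_sd
        innov_sd = np.sqrt(1.0 - spec.ar1**2)
        noise = signal.lfilter([innov_sd], [1.0, -spec.ar1], white, axis=1)
    else:
        noise = white
    data = spec.baseline + spec.noise_sd * noise
    data = data.reshape(*spec.shape, n_vol)
    data[mask] += sig[None, :]
    return VoxelLattice(
        data=data.astype(np.float32), TR_s=design.TR_s, region_mask=mask, spec=spec
    )


@dataclass(frozen=True)
class GlmResult:
    beta: np.ndarray  # contrast effect per voxel
    t: np.ndarray
    p: np.ndarray
    conditions: tuple[str, ...]
    dof: int


def glm_contrast(lattice, design, contrast: dict[str, float]) -> GlmResult:
    """Voxelwise OLS GLM with HRF-convolved regressors + intercept(s).

    ``lattice``/``design`` may be single objects or matched lists of runs
    (runs are concatenated with one intercept per run).  ``contrast`` maps
    condition names to weights; p-values are two-sided from the t
    distribution with residual degrees of freedom.
    """
    lattices = lattice if isinstance(lattice, (list, tuple)) else [lattice]
    designs = design if isinstance(design, (list, tuple)) else [design]
    if len(lattices) != len(designs):
        raise ValueError("need one design per run")

    conditions = tuple(
        dict.fromkeys(c for d in designs for c in d.condition_names)
    )
    for c in contrast:
        if c not in conditions:
            raise ValueError(f"contrast names unknown condition {c!r}")

    X_blocks, Y_blocks = [], []
    for li, (lat, des) in enumerate(zip(lattices, designs)):
        n_vol = lat.n_volumes
        cols = [
            _sampled_regressor(des, c) if c in des.condition_names
            else np.zeros(n_vol)
            for c in conditions
        ]
        icpts = np.zeros((n_vol, len(designs)))
        icpts[:, li] = 1.0
        X_blocks.append(np.column_stack(cols + [icpts]))
        Y_blocks.append(lat.data.reshape(-1, n_vol).T)
    X = np.vstack(X_blocks)
    Y = np.vstack(Y_blocks)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify (nearly) collinear columns for the error message
        names = list(conditions) + [f"intercept_run{j}" for j in range(len(designs))]
        bad = []
        keep = []
        for j in range(X.shape[1]):
            trial = keep + [j]
            if np.linalg.matrix_rank(X[:, trial]) < len(trial):
                bad.append(names[j])
            else:
                keep.append(j)
        raise ValueError(f"design matrix is rank deficient; collinear: {bad}")

    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    cvec = np.array([contrast.get(c, 0.0) for c in conditions] +
                    [0.0] * len(designs))
    xtx_inv = np.linalg.inv(X.T @ X)
    c_var = float(cvec @ xtx_inv @ cvec)
    eff = cvec @ beta
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = eff / np.sqrt(sigma2 * c_var)
    tvals = np.nan_to_num(tvals, nan=0.0, posinf=np.inf, neginf=-np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    pvals = np.maximum(pvals, np.finfo(float).tiny)

    shape = lattices[0].data.shape[:3]
    return GlmResult(
        beta=eff.reshape(shape),
        t=tvals.reshape(shape),
        p=pvals.reshape(shape),
        conditions=conditions,
        dof=dof,
    )


@dataclass(frozen=True)
class RoiResult:
    mask: np.ndarray
    threshold_used: str  # "fdr_q05" | "p003_uncorrected" | "none"
    localized: bool
    n_voxels: int
    timecourses: dict = field(default_factory=dict)
    peak_percent_change: dict = field(default_factory=dict)


def define_roi(
    p: np.ndarray,
    q: float = 0.05,
    fallback_p: float = 0.003,
    t: np.ndarray | None = None,
) -> RoiResult:
    """Threshold a p-value map and keep the largest 6-connected component.

    Benjamini-Hochberg step-up at ``q`` over all voxels; when nothing
    survives, re-threshold at uncorrected ``fallback_p``; an empty fallback
    yields an unlocalized (empty) ROI.  Component size ties break toward the
    higher mean |t| when a t-map is supplied.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject = multipletests(p.ravel(), alpha=q, method="fdr_bh")[0].reshape(p.shape)
    threshold_used = "fdr_q05"
    if not reject.any():
        reject = p < fallback_p
        threshold_used = "p003_uncorrected"
    if not reject.any():
        return RoiResult(
            mask=np.zeros(p.shape, dtype=bool),
            threshold_used="none",
            localized=False,
            n_voxels=0,
        )
    structure = ndimage.generate_binary_structure(p.ndim, 1)  # 6-connectivity
    labels, n_comp = ndimage.label(reject, structure=structure)
    sizes = np.bincount(labels.ravel())[1:]
    best_size = sizes.max()
    candidates = np.flatnonzero(sizes == best_size) + 1
    if len(candidates) > 1 and t is not None:
        t = np.asarray(t, dtype=float)
        means = [np.abs(t[labels == c]).mean() for c in candidates]
        chosen = candidates[int(np.argmax(means))]
    else:
        chosen = candidates[0]
    mask = labels == chosen
    return RoiResult(
        mask=mask,
        threshold_used=threshold_used,
        localized=True,
        n_voxels=int(best_size),
    )


def roi_mean_series(lattice: VoxelLattice, mask: np.ndarray) -> np.ndarray:
    """Mean time series over the ROI voxels (raw units)."""
    if not mask.any():
        raise ValueError("empty ROI mask")
    return lattice.data[mask].mean(axis=0)


def to_percent_signal(series: np.ndarray) -> np.ndarray:
    """Percent signal change relative to the series (run) mean."""
    m = float(np.mean(series))
    if m == 0:
        raise ValueError("zero-mean series cannot be expressed in percent units")
    return 100.0 * (series - m) / m


def event_related_average(
    series,
    design,
    condition: str,
    window_s: float = 10.0,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Event-locked average time course for one response category.

    ``series``/``design`` may be single run or matched lists.  Each run's
    series is converted to percent-of-run-mean units; epochs from stimulus
    onset to ``onset + window_s`` are averaged across all events of the
    category, pooling runs.  Returns ``(times_s, average, n_events)`` with
    ``times_s[0] = 0`` at the onset sample.
    """
    series_list = series if isinstance(series, (list, tuple)) else [series]
    design_list = design if isinstance(design, (list, tuple)) else [design]
    if len(series_list) != len(design_list):
        raise ValueError("need one design per run series")
    epochs = []
    n_samp = None
    for ser, des in zip(series_list, design_list):
        ser = np.asarray(ser, dtype=float)
        pct = to_percent_signal(ser)
        tr = des.TR_s
        n_post = int(round(window_s / tr))
        if n_samp is None:
            n_samp = n_post + 1
        for onset, cond in zip(des.onsets_s, des.conditions):
            if cond != condition:
                continue
            i0 = int(round(onset / tr))
            if i0 + n_post >= len(pct):
                continue
            epochs.append(pct[i0 : i0 + n_samp])
    if not epochs:
        raise ValueError(
            f"no usable events of condition {condition!r} "
            "(category too sparse to average)"
        )
    avg = np.mean(epochs, axis=0)
    times = np.arange(n_samp) * design_list[0].TR_s
    return times, avg, len(epochs)


def peak_percent_change(timecourse: np.ndarray) -> float:
    """Post-onset maximum minus the onset-sample value; no curve fitting."""
    tc = np.asarray(timecourse, dtype=float)
    if tc.size < 4:
        raise ValueError(
            "timecourse must include the onset sample and >= 3 post-onset samples"
        )
    return float(tc[1:].max() - tc[0])


@dataclass(frozen=True)
class BoldExperimentResult:
    roi: RoiResult
    peaks: dict[str, float]
    timecourses: dict[str, tuple[np.ndarray, np.ndarray]]
    n_events: dict[str, int]
    group: str
    seed: int


def run_bold_experiment(
    group: str = "control",
    seed: int = 0,
    spec: LatticeSpec | None = None,
    n_event_runs: int = 9,
    event_amplitudes: dict[str, float] | None = None,
    localizer_amplitudes: dict[str, float] | None = None,
    window_s: float = 10.0,
) -> BoldExperimentResult:
    """Localize the region, then measure per-category peak percent change.

    Simulates a block localizer, defines the ROI from its biological-vs-
    scrambled contrast (FDR q<.05, fallback p<.003), simulates balanced
    event-related runs with the group's amplitude map, and reduces them to
    per-category event-related averages and peaks.
    """
    spec = spec or LatticeSpec()
    if event_amplitudes is None:
        try:
            event_amplitudes = EVENT_AMPLITUDES[group]
        except KeyError:
            raise KeyError(
                f"unknown group {group!r}; available: "
                f"{', '.join(sorted(EVENT_AMPLITUDES))}"
            ) from None
    localizer_amplitudes = localizer_amplitudes or LOCALIZER_AMPLITUDES

    loc_design = BlockDesign()
    loc = simulate_bold(loc_design, spec, localizer_amplitudes,
                        seed=int(seed) * 7919 + 1)
    glm = glm_contrast(loc, loc_design, {"biological": 1.0, "scrambled": -1.0})
    roi = define_roi(glm.p, t=glm.t)
    if not roi.localized:
        return BoldExperimentResult(
            roi=roi, peaks={}, timecourses={}, n_events={},
            group=group, seed=int(seed),
        )

    runs, designs = [], []
    for r in range(n_event_runs):
        des = EventDesign.balanced(seed=int(seed) * 1009 + r)
        lat = simulate_bold(des, spec, event_amplitudes,
                            seed=int(seed) * 7919 + 100 + r)
        runs.append(roi_mean_series(lat, roi.mask))
        designs.append(des)

    peaks, tcs, n_events = {}, {}, {}
    for cond in ("hit", "correct_rejection", "false_alarm", "intermediate"):
        times, avg, n = event_related_average(runs, designs, cond, window_s)
        tcs[cond] = (times, avg)
        peaks[cond] = peak_percent_change(avg)
        n_events[cond] = n
    roi = RoiResult(
        mask=roi.mask,
        threshold_used=roi.threshold_used,
        localized=True,
        n_voxels=roi.n_voxels,
        timecourses=tcs,
        peak_percent_change=peaks,
    )
    return BoldExperimentResult(
        roi=roi, peaks=peaks, timecourses=tcs, n_events=n_events,
        group=group, seed=int(seed),
    )


def classify_response_pattern(peaks: dict[str, float], margin: float = 0.1) -> str:
    """Qualitative pattern of per-category peaks.

    ``"selective"``: hit and false-alarm peaks both exceed the correct-
    rejection peak by more than ``margin`` (the percept-contingent control
    pattern); ``"undifferentiated"``: all pairwise differences among hit,
    correct rejection and false alarm are within ``margin``; otherwise
    ``"other"``.
    """
    h, cr, fa = (peaks[k] for k in ("hit", "correct_rejection", "false_alarm"))
    if h - cr > margin and fa - cr > margin:
        return "selective"
    if max(abs(h - cr), abs(h - fa), abs(cr - fa)) <= margin:
        return "undifferentiated"
    return "other"


def save_lattice(lattice: VoxelLattice, path) -> None:
    """Write the 4D volume as NIfTI (TR in the time zoom)."""
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(lattice.data, dtype=np.float32), np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, lattice.TR_s))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def load_lattice(path, region_mask: np.ndarray | None = None) -> VoxelLattice:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    if data.ndim != 4:
        raise ValueError("expected a 4D NIfTI volume")
    tr = float(img.header.get_zooms()[3]) or 2.0
    if region_mask is None:
        region_mask = np.zeros(data.shape[:3], dtype=bool)
    return VoxelLattice(data=data, TR_s=tr, region_mask=region_mask)
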