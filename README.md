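# biomotion

A simulation and analysis toolkit for point-light (PL) biological-motion
psychophysics and response-contingent event-related fMRI, built for studying
how the perception of human movement degrades — in masking noise, under
kinematic perturbation, and in clinical populations such as schizophrenia —
without requiring human participants or motion-capture data.

A PL animation reduces a human action to 12 dots at the head, torso and
major joints. Three classic paradigms are implemented end to end on
*simulated observers*:

1. **Detection in noise.** 2IFC trials (biological vs. spatially scrambled
   sequence, both buried in trajectory-matched noise dots) driven by a
   transformed two-up/one-down staircase: noise increases after two
   consecutive correct responses and decreases after each error, so the
   track converges on the level where P(correct) = √½ ≈ 70.7%. Thresholds
   are the mean of the last six of 16 reversals.
2. **Perturbation discrimination.** Constant stimuli; each trial shows two
   morphs of the same action whose per-dot positions are displaced toward a
   scrambled template by λ and λ+15% (λ ∈ {0, 15, 30, 45}%); the observer
   picks the more natural one. Individual accuracies are classified as
   above chance by the exact binomial criterion (26/40 at one-sided α=.05).
3. **Categorization + imaging.** 216 yes/no trials (biological, scrambled,
   37%-scrambled), scored with equal-variance signal detection theory,
   d′ = z(H) − z(F). A synthetic voxel lattice carries a "biological-motion
   region" whose event responses are amplitude-scaled per response category
   (hit / correct rejection / false alarm); the analysis localizes the
   region with a GLM contrast at FDR q<.05 (fallback uncorrected p<.003),
   and measures peak percent signal change from response-contingent
   event-related averages.

Stimulus manipulations preserve an exact algebra: scrambling randomizes
first-frame dot positions while keeping every dot's displacement
trajectory, and the λ-morph is a per-dot constant translation, so local
motion (and hence motion energy) is identical at every perturbation level.

## Worked example

Simulate the detection experiment for the two shipped observer cohorts
("control" and "patient" presets) and compare thresholds:

```python
from biomotion.experiments import run_group_exp1, run_group_exp3
from biomotion.sdt import two_sample_t

co, _ = run_group_exp1("control", n=12, seed=7)
pa, _ = run_group_exp1("patient", n=15, seed=8)
print(f"control threshold {co.mean:.2f} ({co.se:.2f}) noise dots")
print(f"patient threshold {pa.mean:.2f} ({pa.se:.2f}) noise dots")
t, df, p = two_sample_t(co.endpoints, pa.endpoints)
print(f"t({df:.0f}) = {t:.2f}, p = {p:.3f}")
```

prints

```
control threshold 50.71 (6.15) noise dots
patient threshold 38.20 (5.15) noise dots
t(25) = 1.57, p = 0.129
```

i.e. the simulated control cohort tolerates roughly 12 more noise dots than
the patient cohort before detection fails (cohorts are drawn with wide
between-observer spread, so a 12+15 sample need not reach significance on
one draw). The categorization arm behaves analogously:

```python
co3, _ = run_group_exp3("control", n=10, seed=7)
pa3, _ = run_group_exp3("patient", n=10, seed=8)
```

gives mean d′ 3.36 (SE 0.23) for controls vs 2.61 (0.15) for patients, with
false-alarm rates 6.0% vs 16.8% and "biological" responses to the
37%-scrambled class at 4.6% vs 18.8% — the patient deficit shows up as a
tendency to see intact human motion in scrambled displays.

The same pipelines are scriptable from the shell:

```bash
biomotion gen-action --preset walk --seed 1 -o walk.json
biomotion mask walk.json --n-noise 40 --seed 3 -o walk_masked.json
biomotion exp1 --group patient --n 15 --seed 4 -o exp1_out/
biomotion bold-analyze --group control --seed 5 -o roi.json
```

`bold-analyze` reports the localized region size, the threshold that
localized it, and per-category peak percent signal change, classified as a
"selective" (hit ≈ false alarm > correct rejection) or "undifferentiated"
activation pattern.

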