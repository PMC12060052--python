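# expviol

Simulation and analysis of **expectation-violation psychophysics with
pupillometry**: dual-report orientation judgments on a target grating
embedded in either a predictably rotating or a random stimulus sequence,
with pupil diameter recorded as a physiological index of surprise.

## The scientific problem

Predictive-coding accounts hold that a sensory input which deviates from a
learned expectation generates a *prediction error*. Whether such violations
degrade or enhance the perceptual representation of the unexpected stimulus
is contested. The experimental paradigm this package analyzes tackles the
question behaviorally: observers watch a rapid stream of gratings (250 ms
each, 32 ms blank ISI) — 5–12 initial gratings, a penultimate grating, then
a target. In the **sequential** condition the stream rotates consistently by
±30° per grating, so the target orientation is expected at
`penultimate + 30°·direction`; the target is drawn at random, violating that
expectation by a signed angle Δ ∈ (−90°, 90°]. In the **random** condition
every pre-target orientation is independent and no expectation exists.
Observers make a speeded binary judgment (clockwise/counterclockwise of
vertical, 2-s deadline) and then reproduce the target orientation by
rotating a bar. Penultimate/target pairs are matched one-to-one across
conditions, so condition contrasts compare identical judged stimuli.

The package provides every stage needed to run this analysis on simulated
(or suitably formatted real) data, with a generative observer model so that
each stage can be validated against known ground truth.

## Core statistics

- **Axial circular statistics.** Orientations are axial (θ ≡ θ+180°).
  Angles are doubled onto the full circle; with R̄ the mean resultant length
  of the doubled angles, reproduction *precision* is the angular standard
  deviation ½·√(−2 ln R̄) (lower = more precise), and *bias* is the halved
  mean resultant direction.
- **Violation tuning curves.** RT and precision as a function of Δ in 8
  equal-width bins over (−90°, 90°], per condition, compared with a two-way
  within-subjects ANOVA (condition × bin).
- **Cluster-mass permutation test.** For time-resolved pupil contrasts: a
  paired t at every sample; contiguous same-sign runs of pointwise-significant
  samples scored by summed t; the max cluster mass under within-observer
  sign flips (n = 1000 permutations) gives the 95th-percentile threshold
  that controls the familywise error.
- **Skipped Pearson correlation.** Bivariate outliers flagged by the
  projection method (robust centre, boxplot-rule fences with ideal-fourths
  quartiles on every projection), Pearson's r on the retained points.
- **Pupil preprocessing.** Divisive normalization to each observer's grand
  mean, −500..1500 ms epochs around target onset, subtraction of an OLS line
  fit to the 500-ms pre-onset baseline, linear blink interpolation, and
  exclusion of observers more than 3 group SDs from the mean diameter.

## Worked example

```python
from expviol import RunConfig, run_pipeline

manifest = run_pipeline(RunConfig(seed=3, n_observers=24,
                                  pupil_dt_ms=5.0, n_perm=500))
r = manifest["results"]
print(r["n_excluded_accuracy"])   # 1
print(r["rt_t"])                  # {'t': -3.1613..., 'df': 22, 'p': 0.004525...}
print(r["precision_t"])           # {'t': -2.9048..., 'df': 22, 'p': 0.008213...}
print(r["cluster_window_ms"])     # (215.0, 1500.0)
```

One of the 24 simulated observers falls below the 75%-correct criterion
and is excluded. The negative paired-t statistics mean the sequential
condition is *faster* (mean RT lower) and *more precise* (angular SD lower)
than the random condition across the remaining observers — the signature of
prioritized processing for expectation-violating stimuli, aggregated over
the uniform violation distribution. The cluster window is the period over
which the sequential-minus-random pupil difference (large-violation trials)
is significantly positive under the one-tailed cluster-mass test, i.e. the
pupillometric surprise response.

A thin CLI wraps the same pipeline:

```bash
expviol report --seed 3            # prints the manifest JSON
expviol simulate --seed 1 --out out/   # writes the raw dataset tables
expviol analyze --data out/behavior.tsv
```

## Layout

| module | contents |
| --- | --- |
| `expviol.design` | trial/session construction, matching, counterbalancing, session IO |
| `expviol.simulate` | generative observer model (behavior + pupil), cohort simulation |
| `expviol.circstats` | axial wrap, axial mean, angular SD |
| `expviol.behavior` | exclusions, condition summaries, tuning/bias curves, median split |
| `expviol.pupil` | normalization, epoching, baselining, interpolation, differences |
| `expviol.stats` | paired t, RM-ANOVA, cluster permutation test, skipped correlation |
| `expviol.pipeline` | configs, orchestration, tabular formats, deposit loading |
| `expviol.cli` | `expviol simulate / analyze / report` |

See `docs/methods.md` for the model, parameter and design rationale.
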