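# Methods

This note documents the generative model, the analysis conventions, the
numerical choices, and the known limitations of the package. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Orientation conventions

Orientations are axial with period 180°, stored on [0, 180), 0° = vertical,
positive = clockwise. Signed axial differences (expectation violations,
reproduction errors) are wrapped to (−90°, 90°]; the boundary value −90°
maps to +90°. This makes the two-alternative boundary (vertical) the sign
of the wrapped orientation, and makes the violation distribution of
sequential trials uniform on the signed interval.

"Angular standard deviation" is the circular-SD form ½·√(−2 ln R̄) on
doubled angles (the convention of the CircStat toolbox's `circ_std` first
output); the angular-deviation form ½·√(2(1 − R̄)) is available via
`angular_sd(..., convention="angular_deviation")` because the two outputs
are easy to confuse in downstream reports. In the small-dispersion limit
the circular SD converges to the linear SD (verified to 2% at σ = 5–8°).

## Session construction

Experiment 1 sessions default to 16 blocks × 24 trials, half sequential and
half random per block, interleaved pseudorandomly (uniform shuffle within
block). Sequence length (5–12) × rotation direction (±) is counterbalanced
across the session's 192 sequential trials (16 cells × 12 repeats); an
independent counterbalanced set is used for random trials. Each sequential
trial generates a matched random trial with identical penultimate and
target orientations, so the multiset of judged stimuli is identical across
conditions. Counterbalancing across the session (not within block) was an
open choice; within-block balancing would constrain 24 trials over 16
cells, which is impossible, so the session-level scheme is the only
consistent reading.

The random condition has no defined expectation; for binning purposes its
"expected" orientation is defined as the penultimate orientation, so both
conditions are grouped on the same penultimate-to-target axis.

Targets are drawn continuous-uniform; `integer_degrees=True` snaps to the
1–180° grid for designs that quantize orientation.

Experiment 2 adds spatial dynamics: polar position advances 12.85° per
grating around a 6°-radius circle (direction counterbalanced), the cue axis
(up/down/left/right → polar 90/270/180/0°; 0° = right, counterclockwise
positive — the mapping is a package convention) is fixed within block and
random between blocks, and half of each block's trials are validly cued
(target lands on the cue axis) while the rest present the target 1–4 steps
before the axis.

## Generative observer model

The simulator exists so that every analysis stage has input with known
ground truth. Its effect structure mirrors the phenomena the analyses are
designed to detect; all amplitudes are per-observer parameters drawn from a
truncated-normal population.

Speeded RT (ms), with G(x; w) = exp(−x²/2w²):

    RT = rt_base
         − rt_len_slope · (n_initial − 5)                      (motor priming)
         + [sequential] · ( rt_pred_amp · G(Δ; w_pred)         (slowing at Δ≈0)
                          − rt_surprise_amp · (1 − G(Δ; w_pred)) )  (speedup for
                                                                large violations)
         − rt_integration_amp · G(δ_pt; w_int)                 (temporal
                                                                integration)
         + lognormal(log rt_sigma, rt_shape) noise,

where Δ is the expectation violation and δ_pt the penultimate-to-target
difference. Responses slower than 2000 ms are recorded as missed.
The `rt_surprise_amp` term complements the suppressive Gaussian so that,
averaged over the uniform violation distribution, sequential trials come
out *faster* than random trials while remaining slower at Δ ≈ 0 — the
qualitative pattern the analyses must recover. Reproduction noise is
wrapped normal with SD built the same way (base + suppressive penalty −
surprise benefit − integration benefit, floored at 1°), plus a repulsive
bias `bias_amp · DoG(Δ; bias_width)` (derivative-of-Gaussian, unit peak at
Δ = bias_width, sign matching Δ) on sequential trials. The binary choice
passes the signed target through Gaussian sensory noise (SD 8°) and a lapse
process (default rate 0.08); these defaults put simulated accuracy near
0.9, so a realistic minority of simulated observers falls below the 0.75
exclusion criterion.

Pupil traces (arbitrary tracker units, 1 kHz default) sum a baseline,
a random-walk drift (SD 30 a.u./√s), white measurement noise, a unit-peak
gamma-shaped dilation kernel per grating (peak latency 930 ms — the
canonical pupillary impulse-response peak — SD 400 ms, amplitude 30 a.u.),
and, on sequential trials, a surprise kernel with amplitude
`pupil_surprise_gain · |Δ|` at target onset. Blinks are a Poisson process
(0.15 Hz, 120 ms) marked missing. Gaussian tuning of the behavioral
effects and the gamma pupil kernel are modeling conveniences: the true
generative shapes in humans are unknown, and only qualitative features
(suppressive centre, surprise-scaled dilation, latency order) should be
read into them.

Two latent standard-normal factors per observer induce the between-observer
covariance the analyses probe with robust correlations: a *general
performance* factor loading (0.8) on `rt_base` and `repro_sd_base` (slow
observers are also imprecise), and a *surprise sensitivity* factor loading
(0.7) on `rt_surprise_amp`, `repro_sd_surprise_amp` and
`pupil_surprise_gain` (the behavioral and pupillary consequences of
violation share a mechanism). Loadings preserve each parameter's marginal
population SD.

What the simulator does **not** emulate: inter-trial sequential
dependencies, learning/fatigue across blocks, eye position and gaze
artifacts, luminance-driven pupil responses, biophysical pupil dynamics,
and any dependence of the choice process on the expectation manipulation.
Passing recovery tests therefore demonstrates that the pipeline detects
effects of the injected kind at realistic sizes — not that real data are
free of confounds the simulator omits.

## Analysis conventions

- Missed trials are dropped before the accuracy denominator (the exclusion
  rule needs a defined proportion correct; treating misses as errors is the
  plausible alternative and is trivially recovered by not dropping them).
- Accuracy exclusion is strict (`< 0.75`); an observer at exactly 0.75 is
  kept. Precision, bias and RT statistics then use correct-choice trials
  only (`correct_only=False` reinstates all trials).
- Violation bins are half-open (lo, hi], rightmost edge closed, 8 × 22.5°
  signed by default; unsigned folding uses 8 × 11.25° with the first bin
  closed at zero. Signed binning is the default because the repulsive-bias
  analysis needs the sign; the folded variant is one flag away.
- The RM-ANOVA is the classical fully-within-subjects partition, each
  effect tested against its own effect-by-subject interaction; subjects
  with any empty cell are dropped listwise. Zero effect variance gives
  F = 0; zero error variance gives an infinite F with a warning.
- Pupil processing order: normalize → epoch → baseline → interpolate.
  Interpolation is deliberately last so the baseline regression uses only
  measured samples. Normalization is divisive (subtractive available).
  The epoch grid includes both endpoints (2001 samples at 1 kHz). Blink
  samples adjacent to tracker gaps are not padded.
- The cluster test forms clusters at pointwise α = 0.05 with the same tail
  as the final test; the null permutes condition labels within observer
  (sign flips of difference series), records the maximum sign-homogeneous
  cluster mass per permutation (positive and negative runs scored
  separately in two-tailed mode), and removes clusters at or below the
  95th-percentile threshold. Every observed cluster is compared to the
  same max-mass null (standard max-statistic familywise control). Cluster
  boundaries are reported as the first/last pointwise-significant sample.
- The skipped correlation centres on the coordinatewise median by default
  (deterministic); the minimum-covariance-determinant centre of the
  originating robust-statistics literature is available via
  `center="mcd"`. Quartiles use the ideal-fourths estimator. More than
  50% flagged points is treated as a failure of the outlier model and
  raises instead of returning a number. The p-value is the usual t-based
  Pearson p on the retained points (slightly liberal after trimming; the
  package reports the outlier count alongside so users can judge).
- The pupil-behavior correlations use the per-observer mean difference over
  the detected significant cluster window, against the random-minus-
  sequential RT and precision differences.

## Validation problem sizes

The test suite validates calibration and recovery at sizes chosen to keep
the full run deterministic and brief while leaving negligible Monte-Carlo
slack: familywise-error calibration over 500 null cohorts (20 observers ×
200 samples, 1000 permutations each); exhaustive-vs-Monte-Carlo threshold
agreement at n = 8 (2⁸ = 256 sign patterns); end-to-end parameter recovery
over 100 cohorts of 52 observers with pupil epochs simulated at a 5-ms
step (the kernel and window logic are sampling-rate agnostic; the
acceptance script runs the single study-scale cohort at 1 kHz).

## Known limitations

- The lognormal RT noise and Gaussian tuning shapes are conventions; real
  RT tuning may be asymmetric or non-Gaussian.
- Simulated pupil effect sizes give a high signal-to-noise contrast, so the
  detected cluster window is wider than what modest empirical effects would
  produce; onset/offset values from simulation should not be read as
  predictions of empirical latencies.
- The deposit loader maps long-format delimited tables only; it does not
  parse raw eye-tracker files.
- No sphericity correction is applied in the RM-ANOVA by default; with
  8 violation bins a Greenhouse–Geisser correction would be a conservative
  alternative for real data.
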