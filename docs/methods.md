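# Methods

This note documents the models implemented in `petlearn`, the defaults and
why they were chosen, what the simulators do and do not emulate, and the
numerical decisions that affect results.

## Reference-tissue kinetic models

The simplified reference tissue model (SRTM) relates a target-region
time-activity curve (TAC) to a reference-region curve assumed free of
specific binding (cerebellum for striatal D1/D2 ligands):

    C_t(t) = R1 C_ref(t) + (k2 − R1 k2a) [C_ref ⊗ e^(−k2a t)](t),
    k2a = k2 / (1 + BP).

Parameters: R1 (relative tracer delivery, unitless), k2 (target efflux,
1/min), BP (non-displaceable binding potential, unitless).  Derived:
k2′ = k2/R1, the reference-region efflux rate.

*Fitting.*  Basis-function method: for each k2a on a 64-point log-spaced grid
over [0.01, 1.0] /min the model is linear in (R1, k2 − R1·k2a) and solved by
least squares against the frame-averaged curve; the grid minimum is refined
by a bounded scalar search in log k2a (tolerance 1e-8) and the refined
residual is asserted never to exceed the grid minimum.  The grid covers the
physiological k2a range of the relevant ligands; the refinement removes grid
bias.  A negative fitted BP (possible under noise) is clamped to zero with a
warning flag rather than raised, matching parametric-imaging practice.

*Global k2′.*  SRTM is fitted to signal-rich regions (caudate, putamen) and
the per-region k2/R1 values are pooled by median (mean available via
`combine=`).  The median is robust to a single failed region at the n = 2–3
regions typical here.

*Logan reference plot.*  With k2′ fixed,

    y(T) = ∫₀ᵀ C_t / C_t(T)  regressed on  x(T) = [∫₀ᵀ C_ref + C_ref(T)/k2′] / C_t(T)

over frames with mid-time ≥ t*; the slope is DVR and BPnd = DVR − 1.
Integrals are cumulative trapezoids over frame mid-times with an implicit
(0, 0) origin (tracer starts at zero activity).  Default t* = 30 min,
standard for the equilibration of these ligands and configurable; on
noiseless SRTM curves the Logan bias decreases monotonically as t* grows
(asserted in tests).  Frames with nonpositive target activity are dropped
with a warning; fewer than three usable frames is an error.  The voxelwise
version vectorizes the same closed-form OLS over all in-mask voxels and
propagates per-voxel failures as missing values.

*Percent change.*  ROI means of pre- and post-injection BPnd images;
100·(post − pre)/pre; two receptor conditions are compared by an
equal-variance two-sample t-test on per-animal percent changes
(df = n1 + n2 − 2).

## Frame schedule and numerics

The default schedule is the study acquisition: 6×10 s, 6×30 s, 11×60 s,
15×180 s, 3×600 s — 41 frames, 90 min.  All generative and fitted curves
live on a uniform fine grid of 2 s: this spacing divides every frame
duration exactly, so frame averages are exact trapezoid means over grid
cells and no frame is biased by partial cells (a 6-s grid, for instance,
does not tile the 10-s frames).  Convolution with e^(−k2a t) uses an O(n)
trapezoidal recursion.  At default rates the discretization error of frame
averages is < 0.1 % (verified against quadrature and an adaptive ODE
integrator in tests).  A measured (framed) reference TAC used as a
continuous input is linearly interpolated through its frame mid-points and
the origin.

## Voxelwise GLM

BPnd maps are smoothed with a separable Gaussian (sigma = FWHM/2.3548 per
axis, converted to voxels; default FWHM 2.0 mm) using normalized
convolution, so kernel mass falling outside the volume or mask is
redistributed and constant images are preserved exactly.  The per-voxel
model regresses BPnd on [intercept, behavioral score, global-mean BPnd];
the reported statistic is the t of the score with df = n − 3.  Because a
20-scan analysis is also conventionally run with the global mean handled by
proportional scaling (each scan divided by its global mean, no covariate
column, df = n − 2 = 18), that variant is available as
`global_mean="scale"`; both conventions are tested.  Thresholding uses the
two-sided t p-value at an uncorrected threshold (default 0.05) and
26-connectivity clustering (6 available); no multiple-comparison correction
is applied, matching the original analysis scope.  Scatter values for a
peak voxel are partial-regression residuals, z-scored; the identity
t = r·sqrt(df/(1−r²)) against the voxel's GLM t is asserted to 1e-10.
Voxels with an exactly linear fit (zero residual) get |t| capped at 1e12 and
a flag.  The null calibration suite verifies the voxelwise false-positive
rate at p < 0.05 sits inside its binomial interval.

## Behavioral statistics

*Errors to criterion.*  Sessions are the unit of the criterion: a session
attains it when its correct count reaches criterion × session size (default
0.90 × 100).  The nominal session size is the denominator, so sessions
truncated by an abort cannot spuriously attain the criterion.  Errors count
unrewarded trials in all sessions up to and including the criterion session;
a phase that never attains is flagged and contributes its total errors.
Aborted sessions contribute their completed trials.

*Consecutive-pair statistics.*  Win-stay = P(repeat stimulus | previous
trial rewarded); lose-shift = P(switch stimulus | previous unrewarded);
simple side stickiness = P(repeat side) over all pairs; reward-associated
side stickiness conditions on pairs where repeating the previously touched
side would have been rewarded (the reward-mapped stimulus sits on that side
in the current trial).  Pairs never span session boundaries (overnight gaps
break the "next trial" relation).  With no qualifying pairs the value is
NaN — never 0 — and is excluded from group means.

*Change points.*  Recursive bisection of the cumulative-correct record: the
candidate split maximizes the deviation from the chord joining the segment
endpoints and is retained if a two-proportion test between the sub-segments
rejects.  Because the candidate is the most extreme of all interior
positions, the raw test at the argmax is strongly anticonservative (a ~30 %
familywise false-alarm rate on stationary n = 200 sequences at alpha 0.05);
the p-value is therefore Bonferroni-adjusted by the number of candidate
positions in the segment.  This restores calibration (measured familywise
rate 0.004 at alpha 0.05 over 1,000 stationary replicates) while a
p = 0.1→0.9 step at trial 100 is still recovered as a single change point
within ±10 trials in ≥ 98 % of replicates.  The split test is Fisher exact
for segments up to 200 trials and chi-square beyond; a t-test variant of
the original recursive method can be emulated by forcing `test="chi2"`.

*Learning stages.*  Bias/perseveration ends at the last trial whose running
(cumulative-from-trial-1) correct ratio is significantly below chance by a
one-sided exact binomial test at alpha 0.01.  Applied verbatim, that rule
overshoots after a genuinely poor start — the cumulative ratio stays
significantly below 0.5 long after trial-level performance has recovered —
so the default (`bias_mode="segment"`) caps it at the end of the last
*initial* change-point segment that is itself below chance; the verbatim
rule remains available (`bias_mode="cumulative"`).  Improvement runs from
just after the last change point whose following segment is significantly
above chance to the last trial (with no change points, an above-chance
sequence is all improvement); chance is the remainder.  The three intervals
are asserted to partition trials 1..n on every call.  At the reference
effect sizes (p = 0.1/0.5/0.95 with boundaries at 50 and 150) both
boundaries land within ±10 trials in about 75 % of runs and ±20 in about
90 % — the localization variance of the argmax estimator, not a bug; the
tests encode those measured rates.

*Response times.*  Each phase contributes its final 20 completed trials
(configurable); with four novel and four reversal repeats per period this
pools 160 values per side.  The comparison is a two-sided Mann-Whitney U
with normal approximation and tie correction (exact method available for
small pools).

*Mixed ANOVA.*  Classical balanced split-plot decomposition, one between-
(group) and two within-subject factors (task, repeat): the between effect is
tested against subjects-within-groups (df N − g); each within effect and its
interaction with group against its effect×subjects-within-groups stratum
(df (levels−1)(N − g)); the within-within and three-way interactions against
the highest-order stratum.  The 5+5+4 cohort with 2 tasks and 4 repeats
yields the design-forced dfs (2,11), (1,11), (3,33).  The full table (SS,
df, F, p) is validated against R's `aov` with `Error(subject/(task*repeat))`
strata to six significant digits on random designs.  Diagnostics: Levene
across groups on subject means; Mauchly's sphericity per within factor with
≥ 3 levels, using orthonormal contrasts and the second-order Box correction
(the ezANOVA form, cross-checked against pingouin).  Fisher's LSD post hocs
use the appropriate stratum error MS.  Unbalanced *within* cells are
rejected; unequal group sizes are handled (the design's own groups are
5/5/4).

## Actigraphy

Activity is 30-s binned counts.  The daily weighted centre is
Σ tᵢcᵢ / Σ cᵢ over a midnight-anchored 24-h window, tᵢ the bin mid-time in
hours; a day with zero counts is NaN and a day without full coverage is an
error.  The linear (non-circular) mean over the fixed daily window is the
default because the summaries are defined per calendar day; a circular-mean
variant is provided for phase-wrapped profiles.  Nighttime activity sums
counts in [lights-off, lights-off + 3 h) per night (window configurable);
incomplete windows are skipped with a warning.  Pre/post comparison of daily
centres is a two-sided Mann-Whitney with a direction call from the median
difference.  Normalized locomotion divides the summed totals of the first
three complete post weekdays by the last three complete pre weekdays
(calendar weekdays, Mon–Fri).

## Simulators and what they do (not) emulate

*Choice agent.*  Two-option Q-learner: only the chosen stimulus's value is
updated, Q ← (1−α)Q + αR, R ∈ {0,1}; choice is softmax on
βQ + side bias + stimulus/side stickiness, mixed with a uniform lapse.  A
per-trial abort hazard truncates the session (a session aborted before its
first response appears in the trial log as a single no-response row with
empty choice fields, which analyses skip but count as an aborted session).
Response times are log-normal and do not depend on trial difficulty.
Left/right placement is counterbalanced exactly within each session with a
seeded shuffle.  Q-values reset at each novel phase and carry into that
pair's reversal, producing perseveration.  The battery runs phases
N1–N2, N3:R3…N6:R6 (pre), then N7:R7…N10:R10 (post) with the post-period
parameter set; sessions are 100 trials, criterion 0.90, at most 15 sessions
per phase.

Preset cohort: 5 "D1R-KD" + 5 "D2R-KD" + 4 control animals.  Only the
D2R-KD post parameters differ from the shared pre set — lower β (2.8 vs
5.0), higher lapse, stronger side stickiness, abort hazard 0.005/trial
(≈ 0.4 session-level abort probability vs ≈ 0.18 pre), and ~1.8× slower
log-normal response times — emulating a knockdown that degrades choice
precision and task engagement while leaving learning rate α intact.  The
magnitudes are round numbers chosen to produce a clear but
battery-compatible phenotype (phases still finish; errors stay in the tens,
which is milder than real animals); they are not fitted to any data.

*PET.*  The reference input is a difference of exponentials
A(e^(−λs t) − e^(−λf t)) with closed-form frame averages — smooth, positive,
and qualitatively like a bolus reference curve, but not a measured input
function.  Target curves are exact SRTM responses; real tissue violates
SRTM's one-compartment approximation.  Frame noise is Gaussian with sd
∝ 1/√(frame duration), a count-statistics proxy; no attenuation, scatter,
motion, partial-volume effects or reconstruction correlations are modelled.
Phantoms assign one parameter set per ROI with independent voxel noise —
no anatomical texture or spatial noise correlation, which is why pipeline
recovery tolerances on phantoms (e.g. −40 % ± 3 %) say nothing about
registration or partial-volume errors in real images.

*Actigraphy.*  Poisson counts from a raised-cosine day/night profile
(lights 7:00–19:00, 1-h transitions), optionally phase-shifted.  Real
actigraphy is bursty and autocorrelated; Poisson bins make the simulated
Mann-Whitney power an upper bound.

## Determinism and provenance

Every simulator accepts a seed (or Generator) and is bit-reproducible;
every CSV written by the I/O layer carries a `#`-comment provenance header
(package version, seed, config hash) which readers skip, so round-trips are
lossless and identical configurations reproduce files byte for byte.

## Problem sizes used in the validation suites

Parameter-recovery grids use 27 noiseless SRTM curves; percent-change
recovery uses a 10×10×6 phantom with 60 caudate voxels at noise_sd0 = 1;
change-point calibration uses 1,000 stationary and 200 step replicates at
n = 200; GLM calibration uses 200 replicates of 20 scans × 100 voxels;
ANOVA cross-validation uses 20 random designs.  These sizes give
Monte-Carlo intervals comfortably tighter than the asserted tolerances
while keeping the full suite around a minute of compute.

## Known limitations

- SRTM fitting assumes the reference region is binding-free; a biased
  reference biases BPnd multiplicatively, and nothing in the pipeline
  detects it.
- The Logan estimator is noise-biased toward lower DVR at high noise; only
  the noiseless bias behaviour is characterized here.
- The mixed ANOVA requires complete within-subject data; animals missing a
  phase must be dropped or imputed upstream.
- Stage segmentation inherits the change-point detector's localization
  variance (see above); single-animal stage counts should be read with
  ±10-trial uncertainty.
- The voxel GLM treats scans as exchangeable and ignores the pairing of
  pre/post scans within animal, as in the original design; with 2 scans per
  subject the effective df is optimistic.
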