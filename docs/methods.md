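# Methods

## The measurement protocol

`pacehrv` models an intraoperative electrophysiology manoeuvre used to probe
the parasympathetic (vagal) response of the sinus node: during an
electrophysiological study, a short burst of rapid atrial pacing (30 s at
100 bpm, i.e. a paced cycle length of 600 ms) transiently raises vagal tone,
which shows up as an immediate increase in beat-to-beat cycle-length
variability and a modest prolongation of the sinus cycle length. Because the
surge is brief, it must be captured with *ultra-short* HRV windows: four
consecutive sinus PP intervals.

Each patient undergoes two identical pacing protocols two minutes apart.
Four measurement periods result:

| period | definition |
|--------|------------|
| A | last 4 sinus PP intervals immediately before the first pacing burst |
| B | first 4 sinus cycles after the return of sinus rhythm following burst 1 |
| C | as A, before the second burst (≥ 2 min after burst 1) |
| D | as B, after the second burst |

Two indices are computed per window:

* `RMSSD = sqrt( Σ_{i=1}^{n-1} (PP_{i+1} − PP_i)² / (n−1) )` with `n = 4`;
* `ΔPP = PP_max − PP_min`, the window's range.

The pause from the last pacing stimulus to the first spontaneous sinus beat
is the sinus node recovery time (SNRT); `cSNRT = SNRT − baseline cycle
length`. The atrioventricular Wenckebach point (WP) is the highest pacing
rate of an incremental ramp still conducted 1:1.

**Recovery-beat convention.** Whether the SNRT pause counts as the first of
the "first 4 cycles after the return of sinus rhythm" is ambiguous; the
package *excludes* it by default, because the SNRT is reported as a separate
electrophysiological parameter and including the pause would conflate two
metrics (a post-pacing ΔPP would otherwise be dominated by the pause).
`include_recovery_beat: true` selects the other convention.

## The synthetic cohort generator

No public patient-level dataset exists for this protocol, so the package
ships a generator that emulates the statistical structure the analysis
assumes, with per-patient ground truth for recovery tests.

**Sinus rhythm.** Each patient draws a baseline cycle length `CL_i` from a
lognormal matched to a cohort median of 815 ms and IQR 759–957 ms. Sinus PP
intervals are `CL_i + RSA(t) + e`, where the deviations `e` are independent
zero-mean Gaussians with SD `sd_succ_diff/√2`, so that the SD of successive
PP differences equals `sd_succ_diff` and the 4-beat RMSSD estimates it up to
small-sample factors. The deviations are deliberately *independent* (no
random-walk component): the 4-beat windows cannot distinguish richer
autocorrelation structure, and independence makes every generator parameter
directly interpretable in metric units. Draws are truncated at ±3 SD to keep
intervals positive without rejection loops.

**Respiratory sinus arrhythmia.** `RSA(t)` is a sinusoid (default 5 ms at
0.25 Hz). At a 4-beat window length (~3 s, inside one respiratory cycle) its
contribution to successive differences is a few ms — small against the
pacing surge, which is the basis of the claim that these ultra-short windows
are respiration-independent. The generator does not model breath-to-breath
frequency or amplitude variation.

**Pacing and the vagal surge.** Stimuli are spaced exactly 600 ms apart for
30 s; each non-edge stimulus can fail to capture with probability
`capture_failure_prob` (a gap in the stimulus train flags the epoch
ineffective). The first spontaneous sinus beat follows the last stimulus
after `CL_i + snrt_excess` (default excess 330 ms, lognormal across patients
and jittered ~8% between the two protocols). From that beat the surge is
active: the deviation SD is multiplied by `k` (default 2.7, lognormal
between-patient spread on `k − 1`) and the target cycle length is prolonged
additively (default 40 ms). Both effects hold at full amplitude for a short
plateau (4 s, covering the 4-beat measurement window — physiologically the
vagal surge peaks within the first seconds) and then decay exponentially
with a shared time constant `tau` (default 25 s). No quantitative decay
time course is established for this manoeuvre beyond "recovered within
2 minutes"; with `tau = 25 s` the residual at the next baseline window is
`exp(−116/25) < 1%` of the surge amplitude, and the plateau makes the
post-window RMSSD scale exactly with `k` in expectation (scale equivariance),
which is what the Monte-Carlo recovery test checks. `k = 1` is the null of
no variability surge; full-null simulations also set
`surge_cl_prolongation: 0`.

**Wenckebach ramp.** Beat series carry no ventricular events, so AV
conduction is summarized per protocol as a rate → conducted-ratio map
(incremental ramp 100–200 bpm in 10-bpm steps) embedded in the series
metadata. Conduction follows a fixed-threshold rule: a paced cycle length at
or above the patient's AV threshold (normal around 370 ± 30 ms, jittered
~10 ms between protocols) conducts 1:1, faster rates show Wenckebach group
beating. Patients whose threshold lies below the ramp's fastest cycle length
never block within the ramp and are reported missing for WP.

**Contamination and the repeat rule.** Ectopic beats and artifact
annotations are inserted as Poisson processes (default rates 0: the
reference dataset is post-repeat, i.e. complete). A window is invalid if a
labeled ectopic/artifact event falls inside its time span, or if one
interval deviates more than 20% from the median of the other three (an
operational catch for unlabeled premature beats — the protocol excludes
extrasystole-contaminated windows without stating a rule). Invalid windows
are re-measured on a spare pacing epoch at least 2 minutes after the
contaminated one; the generator appends one spare epoch by default so the
default cohort, like the reference one, is complete. Every discard is
written to the audit log. Inserted contaminants do not perturb sinus timing;
they model annotation-level noise, not true coupled extrasystoles.

**Determinism.** Each patient uses an independent substream
(`SeedSequence(master_seed, spawn_key=(patient_index,))`), so patient `i` is
identical regardless of cohort size, and a fixed (seed, index) pair is
byte-reproducible. Event times are rounded to integer milliseconds (the
measurements being emulated are manual caliper readings; sub-ms precision
would be spurious), with collisions resolved by a +1 ms bump.

## Calibration

Defaults are calibrated so that a simulated 50-patient cohort reproduces the
reference cohort's location and spread: `sd_succ_diff = 19 ms` with
between-patient lognormal sigma 0.35 places the cohort medians of baseline
and post-pacing RMSSD and ΔPP inside the reference IQRs (baseline RMSSD
~9.7–23.7 ms, post ~25.6–59.6 ms; baseline ΔPP ~19–56 ms, post ~60–152 ms),
with `k = 2.7` matching the observed ~2.7× post/pre RMSSD ratio and the
40 ms prolongation matching the ~35–45 ms cycle-length shift. The
calibration lives in `configs/default.yaml` (and the `SimParams` defaults),
not in analysis code.

## Statistical analysis

Per prespecified plan, mirrored exactly by `pacehrv.stats`:

* **Friedman** non-parametric ANOVA across A–D (listwise complete); an
  all-tied cohort returns statistic 0, p = 1 rather than an error.
* **Wilcoxon signed-rank**, two-sided, on A–B and C–D against the Bonferroni
  threshold `alpha / 2 = 0.025`; A–C and B–D are descriptive. Zero
  differences are dropped (classical convention — documented because n is
  small); the exact null distribution is used for ≤ 25 non-zero pairs, the
  normal approximation with continuity correction above.
* **Bland-Altman** per pair: bias (mean of first-listed minus second), SD of
  the differences (n−1), and relative bias = 100 × bias / grand mean of the
  pooled pair. Limits of agreement are deliberately *not* computed: on
  4-cycle windows their sampling distribution is too unstable to interpret.
* **Positive-delta frequency**: strict increases (post − pre > 0) as count
  and percent of complete pairs; ties are not increases.
* **SODP**: per patient Δ1 = B−A, Δ2 = C−B, Δ3 = D−C, plotted as (Δ1,Δ2)
  and (Δ2,Δ3) with quadrant labels; Δ1+Δ2+Δ3 = D−A telescopes by
  construction and is property-tested. Under the calibrated surge the
  dominant pattern is (+,−) then (−,+): rise after pacing, recovery, rise
  again.
* **Repeatability** (A–C, B–D): Shapiro-Wilk on the paired differences
  gates interpretation; Spearman's ρ is always computed (the plan's
  practice once normality failed; Pearson is intentionally not implemented
  to avoid code paths the plan never exercised). ICC is fixed to ICC(A,1) —
  two-way random effects, absolute agreement, single measurement, the
  standard test-retest form (computed via pingouin) — and Lin's CCC uses
  population-moment covariances. Both are reported as secondary: they are
  known to collapse under low between-subject variance and 4-cycle
  measurement noise.
* **Missing data**: pairwise complete for paired statistics, listwise for
  Friedman and SODP. The three metrics (RMSSD, ΔPP, SR CL) are analyzed
  independently with no cross-metric multiplicity correction.

## What passing tests do and do not show

The generator reproduces the *marginal* and *contrast-level* structure of
the reference cohort: per-period medians/IQRs, near-nominal type-I error for
baseline contrasts, ~90% positive-delta rates, and low ICC/CCC with moderate
Spearman ρ at re-test. It does not emulate slow autonomic drift, true
respiratory coupling, baroreflex feedback loops, inter-metric correlation
beyond what the shared noise process induces, or annotation error on
individual beats; agreement statistics on real recordings may therefore be
worse than simulated ones, and passing recovery tests validate the
*pipeline*, not any clinical claim.

Monte-Carlo problem sizes used by the test suite — 200 replicate 50-patient
cohorts for the null type-I check, 40 replicates for the calibrated-surge
recovery check, 1000 patients for the k-recovery oracle — were chosen to
put the Monte-Carlo standard error well below the tested tolerances while
keeping the default suite fast; quiet protocol segments (rest/tail, and the
inter-protocol gap where periods C/D are not under test) are shortened in
simulation-heavy tests since no measurement window touches them.

## Known limitations

* The WP conduction model is a fixed-threshold rule on a 10-bpm grid; real
  AV-nodal Wenckebach dynamics (fatigue, dual pathways) are out of scope.
* Ectopic events are annotation-level: they invalidate windows but do not
  reset sinus timing or produce compensatory pauses.
* `ΔPP` as defined has no established normative values; it is reported
  because the protocol reports it, with the same caveats.
* The generator's surge is a single shared time constant for variability and
  cycle length; real recovery kinetics of the two channels may differ.
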