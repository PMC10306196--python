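# Methods

## Trace model and analysis pipeline

The analysis operates on a phase-labeled diameter trace: one sample per
cardiac extremum (systolic or diastolic), timestamped on a clock whose
zero is cuff deflation, spanning a baseline window, a cuff-occlusion gap,
and at least 180 s of post-deflation recording.

**Beat pairing.** A cardiac cycle is a diastolic sample plus the nearest
*following* systolic sample, accepted only if it arrives within 1.5× the
median inter-diastole interval and before the next diastolic sample. This
tolerates dropped frames without mispairing across cycles; unpaired
samples are discarded. The beat time is the diastolic sample time.

**Pressures.** SBP and DBP are trace-wide 95%-trimmed means of the
beat-by-beat plethysmography series; a single (SBP, DBP) pair is used for
every beat's β. Per-beat pressures are deliberately not propagated — the
diameter trace and pressure device are not beat-synchronized, and the
trace-constant convention matches how such analyses are run in practice.

**β and local PWV.** Per beat, β = ln(SBP/DBP) / strain with strain =
(D_syst − D_diast)/D_diast, and PWV = √(β · DBP_Pa / 2ρ) with ρ = 1050
kg m⁻³ and DBP converted at 133.322 Pa/mmHg. The square root is required
dimensionally (β·P/ρ has units of velocity squared); the composite admits
the closed form PWV = √(ln(SBP/DBP) · DBP_Pa / (2ρ·strain)), which the
tests verify to 1e-12 relative. β uses the raw mmHg ratio (unit-free).

**Windows and bins.** Baseline summaries are 95%-trimmed means over the
last 60 s before cuff inflation and require ≥ 5 beats. Post-deflation
extremes use half-open 10-s bins [0,10), …, [170,180); each bin is the
arithmetic mean of its beats, empty bins are dropped with a warning, and
ties go to the earliest bin. Occlusion-period samples are excluded by
construction: no summary window overlaps them, which the tests check by
deleting them and comparing results bit-for-bit.

**Trimmed mean.** "Retain the central f" with floor((1−f)/2·n) values
trimmed per tail; at f = 0.95 nothing is trimmed below n = 40, which is
intentional — small baseline windows should not lose data to trimming.

**Diameter channel.** FMD (D_bas, D_peak) is computed on the per-beat
*diastolic* series by default, the end-diastolic convention of FMD
guidelines; `AnalysisConfig.channel` switches to systolic or cycle-mean.

**Artifact gate.** Beats with strain outside (0, 0.25] are excluded from
the β/PWV series (with a logged count): negative or >25% single-cycle
strain indicates wall-tracking loss, not physiology. The diastolic
diameter of such beats still contributes to FMD.

## Agreement statistics

**CV.** Per subject, SD of the replicate pair (n−1 denominator) divided
by |pair mean| × 100; the default reports the across-subject mean of
these, the most common convention in FMD repeatability work. A
root-mean-square variant is available (`cv_method="rms"`). Ratio CVs are
unstable when the outcome crosses zero (as %FMS can); the report computes
them anyway and leaves interpretation to the ICC.

**ICC.** Single-measure, absolute-agreement, two-way ICC — ICC(2,1) in
the Shrout–Fleiss numbering — from the two-way ANOVA mean squares:
(MS_R − MS_E) / (MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E)). The 95% CI is
the McGraw–Wong F-interval (quantile expressions are spelled out in the
`icc_a1` docstring), identical to the R `irr::icc` implementation;
pingouin's ICC(A,1) is used as an independent cross-check in the test
suite. Qualitative bands: poor < 0.50, moderate 0.50–0.74, good
0.75–0.90, excellent > 0.90; the printed band edges leave (0.74, 0.75)
unassigned and we classify that gap as "good" so the bands are
exhaustive.

**Bland–Altman.** Differences are column 1 − column 2; bias is their
mean, LOA = bias ± 1.96·SD (sample SD). Proportional bias is the OLS
slope of difference on pair mean with a two-sided t-test; the simulation
suite checks its type-I error is 5% under the null.

**Sample size.** Subjects needed to detect ICC ρ₁ against null ρ₀ with k
ratings: the Walter–Eliasziw–Donner normal approximation
n = 1 + 2k(z_α + z_β)² / ((k−1)·ln²C₀) with
C₀ = (1−ρ₁)(1+(k−1)ρ₀) / ((1−ρ₀)(1+(k−1)ρ₁)), two-sided α, rounded to
the nearest integer — the convention of the R ICC sample-size package
this reproduces (ρ₁ = 0.80, ρ₀ = 0.40, α = 0.05, power = 0.90, k = 2
→ n = 24). Note the exact-F power iteration would give 25 here; the
closed form is what the reference tooling computes.

**Comparison families.** From a subject × day × rater × replicate long
table the report builds: intra-rater intra-day (per rater, replicate 1
vs 2 on the first day), intra-rater inter-day (per rater, day 1 vs 2,
replicates averaged), inter-rater intra-day (per day, rater 1 vs 2,
replicates averaged), and inter-rater inter-day (rater 1 vs 2, days and
replicates averaged). Subjects with a missing cell are removed listwise
per comparison, with a log record.

## Synthetic data

The generator commits to population parameters typical of a healthy
adult male cohort — D_bas 4.01 (0.56) mm, SBP/DBP 125 (14)/76 (11) mmHg,
HR 60 (8) bpm, %FMD 6.41 (3.41), %FMS −7.25 (3.82), PWV_bas 8.58 (0.73)
m/s — with 90 s baseline, 300 s occlusion, 240 s post-deflation.
Rejection sampling keeps draws physiologic (DBP ≥ 40 mmHg, pulse
pressure ≥ 10 mmHg, HR 40–100 bpm, positive dilation, negative slowing,
baseline strain in (0, 0.25)).

Baseline strain is obtained by exact algebraic inversion of the β/PWV
pair (strain = ln(SBP/DBP)·DBP_Pa / (2ρ·PWV²)), so a subject's PWV_bas
is reproduced to machine precision. The dilation response is a
gamma-variate g(t) = (t/t_p)^s·exp(s(1−t/t_p)) (s = 2.5), zero before
deflation, unit peak at t_p ~ U(45, 75) s — a smooth unimodal family
whose peak sits away from the bin-window edges so the 10-s-bin peak
detection is genuinely exercised. Hyperemia is modeled as a strain
increase at constant pressures — the minimal mechanism by which these
equations make PWV fall — with amplitude a = (1 + FMS/100)⁻² − 1 solved
at the curve peak so the point minimum of PWV equals the target. Both
extrema of a cycle see the beat-time curve value; the systolic sample is
merely timestamped 35% of a period later. Gaussian noise (default 0.02
mm on diameters, 2 mmHg on pressures) is added per sample; all
randomness flows from one seed (subject- and session-scoped via CRC32 of
the identifiers), so identical configs and seeds give byte-identical
files.

Because the amplitude is solved against the curve peak rather than the
binned peak, 10-s binning attenuates recovered responses by ≤ 0.07
percentage points at cohort-mean parameters — well inside the ±0.15
tolerance the recovery tests assert.

Repeated-measures tables follow the crossed random-effects model
y = μ + S_subject + D_subject×day + R_subject×rater + e, with components
per outcome. Any comparison family's true absolute-agreement ICC follows
in closed form (effects shared by both columns count as signal;
averaging an axis divides its variance by the number of levels), and
estimator-recovery tests target those analytic truths, never guessed
numbers. Default components place ICCs in the good-to-excellent range
observed for trained raters.

### What the generator does and does not emulate

It emulates the *structure* of the real data — phase-labeled extremum
samples, maneuver timing, beat-locked pressures, subject heterogeneity,
rater/day variance components — but not ultrasound physics: no wall-edge
detection error correlated in time, no probe-repositioning drift, no
shear-dependent dilation kinetics, no HR variability. Passing tests
therefore establish that the *analysis* is correct and well calibrated
given data of this structure; they do not certify performance against
device-specific artifact modes.

## Known limitations and numerical notes

- **Extremum-selection bias under noise.** `PWV_min` (and `D_peak`) are
  extrema over ~18 noisy bin means; under measurement noise the selected
  minimum is biased low, so noisy-trace FMS is systematically more
  negative than truth (several percentage points at the default noise).
  This is intrinsic to min/max-over-bins estimators, visible in the
  README example, and is one reason FMS repeats less well than FMD.
- Strain is tiny relative to diameter noise (0.13 mm pulse amplitude vs
  0.02 mm noise), so per-beat PWV is far noisier than per-beat diameter;
  the trimmed baseline mean suppresses this for PWV_bas but not for the
  binned minimum.
- CV is undefined for a zero pair mean (error naming the subject) and
  unstable near zero; use the ICC for outcomes that cross zero.
- Perfect-agreement matrices (MS_E = 0) short-circuit the ICC CI to the
  degenerate interval [1, 1]; tiny negative error sums from float
  cancellation are clamped at 1e-12 of the total sum of squares.
- Problem sizes in the simulation tests (100 noise-free subjects for
  pipeline recovery; 500 replicates at n = 200 and n = 24 for ICC bias
  and coverage; 10,000 replicates for the type-I error of the
  proportional-bias test) were chosen so Monte-Carlo error is comfortably
  below each asserted tolerance.
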