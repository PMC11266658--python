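# Methods

## The model

A promoter is a continuous-time Markov chain over a few *microstates*; the
observer only resolves the coarse-grained *mesostates* ON (a nascent
transcription site is visible) and OFF.  The time spent in a mesostate
before leaving it — a dwell or sojourn — follows a phase-type law.  For a
mesostate with member states `M`, entry distribution `pi`, sub-generator `A`
(the full generator restricted to `M`) and exit-rate vector `r`, the dwell
density is

    f(t) = r' exp(A t) pi = sum_k c_k exp(lambda_k t),

a sum of as many exponentials as `M` has states (a biexponential for two ON
microstates).  The entry distribution is the stationary flux into each
member state from outside, which is what a dwell harvested from a long
steady-state record actually sees.  A defective 2x2 sub-generator (equal
eigenvalues) yields the degenerate form `(c + d t) exp(lambda t)` and is
flagged rather than perturbed.

Classification of a density: *monotone* when every spectral coefficient is
nonnegative (it then decreases from `t = 0`); *maximally peaked* when
`|f(0)| <= 1e-6 * max f`; otherwise *peaked*.  These tolerances apply to
exact spectral densities; fitted densities use looser, noise-appropriate
rules (below).

### The clock model and its thermodynamics

The three-state clock has ON microstates 1, 2 and OFF microstate 3, forward
rates `w13` (3→1), `w21` (1→2), `w32` (2→3), an internal ON reverse edge
`w12` (2→1), and a single reverse rate `alpha` on both anticlockwise edges
1→3 and 3→2.  `rate(i, j)` always means the rate from state `j` to state
`i`, so the printed formulas read literally.  Detailed balance holds exactly
at the cycle condition `w32 w21 w13 = alpha^2 w12`, i.e. at
`alpha_eq = sqrt(w32 w21 w13 / w12)`.  For this single cycle the
steady-state entropy-production rate reduces to

    sigma = J+ * Delta_s,   Delta_s = 2 k_B ln(alpha_eq / alpha),
    J+ = w13 p3 - w31 p1,

with `p` the stationary distribution and `k_B = 1` internally.  At
`alpha = 0` the entropy per cycle diverges (reported as `inf` with a
warning): fully excluding the reverse transitions would cost infinite
entropy.  Two structural facts are exercised numerically throughout the
tests: a reversible (detailed-balance) process can only produce monotone
dwell densities, and `f(0) = 0` — the maximally peaked boundary — occurs in
the 3-state family exactly at `alpha = 0`, where the chain enters ON via
microstate 1 and leaves via microstate 2 with no reverse path.

## Synthetic data

The generator stands in for live-cell imaging of a PP7-tagged gene under
a multifocus microscope.  Its defaults are the study conditions used by
every test:

| parameter | default | note |
|---|---|---|
| frame interval | 2.5 s | 500 frames over a 1250 s window |
| focal planes | 7, 500 nm apart | for image-stack synthesis |
| initiation rate (ON) | 1.4 /s | Poisson initiations while ON |
| transcript residence | 7.5 s, fixed delay | exponential option available |
| brightness | 1 a.u./transcript | plateau ~10.5 transcripts when ON |
| noise | sigma(n) = 1.05 + 0.1 n a.u. | low-noise OFF, high-noise ON; ON SNR = 5 |
| observability floor | ~3 transcripts | sites below it may be invisible |
| bleaching | 2e-4 /s, signal only | ~22% decay over the window |
| background | per cell, 2.0 +/- 0.8 a.u. | forces the mode-subtraction step |

The transcript count is a birth-death process (births at the initiation
rate during ON sojourns, each transcript removed after its residence time);
count shot noise, not camera noise, dominates the ON-state variance, as in
real nascent-site data.

The four-state scenario adds a long-lived OFF state 4 reached from ON
microstate 2 (branching `w42 / (w32 + w42)`) and left via 4→1, so both
cycles share the ON path.  Scenario presets encode the qualitative strain
phenotypes: the wild-type-like clock is maximally irreversible
(`alpha = 0`, ON density with `f(0) = 0`); the remodeler-mutant-like
presets reopen the reverse path slightly (peaked but `f(0) > 0`) and slow
the long-OFF exit; the activator-mutant-like preset sits at the upper
cycle's equilibrium point (monotone ON density), raises the long-OFF
branching from 0.39 to 0.65 and slows the long-OFF exit most.  Internal
ON/OFF dwell means stay within ~15–20% of the wild-type-like preset across
strains, while the external (long-lived) OFF scale orders
wild type < chd1-like < isw2-like < pho4-like.

Two generator choices were calibrated once, deliberately, so that the
central inference loop is statistically closable at cohort scale (~200
cells): the wild-type ON dwell's exponent ratio is ~3.8 with fast-component
amplitude `a ~ 0.36` (more extreme ratios make the fast exponent
unidentifiable from a few hundred periods — even exact maximum likelihood
on ground-truth durations then misses 20% accuracy), and the long-lived OFF
mean equals one window length, which yields ~350–400 internal ON periods
per 200-cell cohort.  The short-lived OFF mean (40 s, 16 frames) keeps most
inter-burst gaps resolvable at the frame interval.

What the generator does *not* emulate: real elongation/termination
kinetics (residence is a single fixed delay), diffusing cytoplasmic spots,
cell crowding and segmentation of touching nuclei, z-drift beyond a small
random walk, and camera EM-gain statistics.  Passing tests therefore show
the estimators are correct on data satisfying the model's assumptions, not
that those assumptions hold for any particular microscope.

## Trace segmentation

Preprocessing follows the standard chain: a mono-exponential bleach trend
is regressed on the cohort-average trace and divided out; each trace's
background is the mode of a Gaussian KDE of its intensities (valid because
zero nascent transcripts is the most likely state).

Change points use a window-based search: two adjacent half-windows (default
12 frames) slide along the trace, with the Gaussian cost
`c(y) = len(y) log(var(y))` — sensitive to changes in both mean and
variance, because ON and OFF differ in both.  Discrepancy peaks above a
threshold (default 6 nats) become change points, subject to a minimum
segment length of 3 frames.  The log-variance cost makes the whole search
invariant to affine intensity rescaling.  A variance floor of 1e-12 guards
constant windows.

Labelling: 2-means on standardised (segment mean, log segment variance)
locates the cohort's OFF and ON intensity levels; a segment is then called
ON when its mean exceeds `off + 0.3 (on - off)`.  The cut sits near the
~3-transcript observability floor rather than halfway between the levels:
the OFF level is a tight, low-noise cluster while ON intensities spread
widely, and a midpoint rule mislabels transient mid-burst dips in the
transcript count as OFF, cutting true ON periods in two.  A separation
guard declares the whole cohort OFF when the two levels are not separated
beyond the OFF cluster's own spread (a signal-free cohort would otherwise
have its noise split in half).  Maximal
same-label runs become periods; a run touching the first or last frame is
external (left/right/both), the rest internal; durations are half-open
frame counts times the frame interval and sum exactly to the window per
cell.

`tune_cpd` implements hyperparameter selection on the step-free-OFF
principle: among grid candidates retaining at least 95% of high-amplitude
steps (those found by the most sensitive setting with amplitude above three
robust noise SDs), pick the one with the fewest adjacent OFF–OFF segment
pairs; ties prefer the larger threshold.

## Survival statistics

The biexponential survival model is

    S(t) = -a exp(lambda1 t) + (1 + a) exp(lambda2 t),  lambda1, lambda2 < 0,

with density coefficients `c1 = a lambda1`, `c2 = -(1 + a) lambda2`
(`S(0) = 1` and unit normalisation hold identically).  Fitting is least
squares of the model against the empirical survival curve evaluated at the
sorted durations — the published estimator, kept deliberately instead of
maximum likelihood — with two numerical refinements: residuals are weighted
by the inverse binomial standard error `sqrt(S(1-S)/n + 1/n^2)`, and the
exponents are bounded to decay scales resolvable from the data range.
Multi-start initialisation is deterministic (slow exponent from a
log-linear tail fit; fast exponent from a fixed multiplier ladder; fixed
tie-break by residual).  The constrained variant enforces `f(0) >= 0` by
falling back to the boundary fit with `f(0) = 0` — which pins
`a = lambda2/(lambda1 - lambda2)` and leaves two free exponents — whenever
the free optimum violates it; the `pinned` variant fits on that boundary
outright and is the right tool for exponent recovery when the dwell law is
maximally peaked.  Near-degenerate optima (`lambda1 ~ lambda2`) are refit
as single exponentials and flagged.  Fitted-density classification uses a
5% relative tolerance on `f(0)` for the maximally peaked call, a numeric
grid argmax for the peak position (the analytic formula is ill-conditioned
near degeneracy), and calls a peak below `weak_peak_time` (default one
frame interval) *weakly peaked* — such a peak is invisible at the sampling
resolution.

**Resolution floor.**  Segmentation cannot emit periods shorter than
`min_size` frames, so period tables are left-truncated.  Left truncation of
an exponential mixture preserves both the exponents and the signs of the
coefficients, so the bootstrap fits each replicate in shifted time
`t - duration_floor` (floor = shortest measurable period); without the
shift, the artificially flat head of the survival curve makes monotone
dwell laws classify as spuriously peaked.

**Bootstrap.**  Cells (sample paths), not periods, are resampled with
replacement, respecting within-cell dependence; each of the (default) 300
replicates is refit unconstrained.  Replicates whose exponent ratio exceeds
50 are virtually discontinuous at `t = 0` and recorded as exponential
(monotone).  Summaries report the density at the probe time
`t = 0.01` (mean ± SD across replicates), the mean dwell, and the class
fractions.

**External OFF periods.**  Their length is exponential and window-censored.
In a stationary record the observed portion of a left-external period is a
residual and that of a right-external period is an age — both exponential
with the dwell mean, by memorylessness — so singly censored portions enter
the censored-exponential MLE as complete samples.  A period spanning the
whole window is the censored tail of *both* sampling lines and enters as
two right-censored observations at the window length; counting it once
underestimates the exposure and biases the mean ~35% low at the test
geometry (true mean 2000 s, window 1250 s).

**Burst runs.**  For every internal ON period with a successor OFF period,
the successor is classed long-lived if it persists to the window edge
(external), else short-lived; `p_long` is the long-lived fraction.  With
the long-lived OFF much longer than the window this recovers the ON →
long-OFF branching probability of the generator.  The classification rule
is switchable in principle (a mixture decomposition would be the
alternative) but externality is the implemented and tested rule.

## Spot quantification

Per time point: maximum projection over the focal planes;
difference-of-Gaussians band-pass with `sigma_small = psf/sqrt(2)`,
`sigma_large = 2 psf` (psf ~ 1.5 px); local maxima above the mean + 5 SD of
the filtered image with a 4 px non-maximum-suppression window; nuclei by
Otsu threshold + connected components + hole filling on the time-averaged
projection; per nucleus the brightest candidate wins, with carry-forward of
the last position and brightest-nuclear-pixel fallbacks (provenance
recorded); finally an iterative Gaussian-mask estimator on the raw
projection returns sub-pixel position and integrated intensity
(`sum(w s)/sum(w^2) * 2 pi psf^2` over a median-background-subtracted local
patch, iterated to 0.01 px or 50 iterations).

## Pipeline

`RunConfig` (YAML) drives simulate → segment → fit → report with one master
seed; per-stage and per-cell seeds derive from it through
`numpy.random.SeedSequence`, so a full run is reproducible bit-for-bit and
any stage can be re-run from persisted intermediates (traces.csv,
periods.csv, fits.json, bootstrap.csv) with identical results.  Reports are
JSON plus a plain-text rendering; `compare_strains` tabulates external-OFF
means, internal means, classifications and `p_long` without inferential
statistics beyond the bootstrap SDs.

## Problem sizes used in the test suite

Closed-loop checks run 200-cell cohorts (500 frames each) with 300
bootstrap replicates; dwell-law versus simulation agreement uses 50 random
clock models with 1e5 sampled sojourns each; the censored-mean check runs
100 repeats of 300 cells; the imaging loop runs 100 cells of 100 frames at
64 x 64 px and 7 planes.  Unit tests use smaller cohorts (~40 cells).

## Known limitations

- Dwell densities with complex sub-generator spectra (possible for >= 3
  microstates per mesostate in general graphs) are not supported; the
  promoter models used here have real spectra.
- The entropy-production reduction `sigma = J+ Delta_s` is the single-cycle
  form; general multi-cycle graphs are out of scope.
- The unconstrained biexponential fit has heavy-tailed exponent error at a
  few hundred durations; exponent recovery should use the pinned variant
  (when `f(0) = 0` is justified) or more data.
- Segmentation cannot see periods shorter than `min_size` frames, and
  bursts separated by gaps of less than ~2 frames of clean background are
  merged; downstream fits handle the truncation (duration floor) but not
  the merging, which slightly biases the slow exponent at high burst
  frequency.
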