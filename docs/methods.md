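# Methods

This note documents the models, conventions and numerical choices behind
`lickometry`, and what the synthetic-data generator does and does not
emulate.

## Lick-event model and I/O conventions

Lick timestamps are integer milliseconds from session start, matching the
1-ms resolution of contact lickometers. Sub-millisecond input is rejected
rather than rounded, because silent rounding could create duplicate
timestamps and corrupt ILI statistics. Within a subject–session, timestamps
must be strictly increasing; duplicates are validation errors.

Brief-access trial windows are **half-open**: a trial's counting window is
`[first_lick, first_lick + duration)`, so a lick landing exactly on the
closing boundary is excluded. This makes lick counting unambiguous and makes
"every lick belongs to at most one trial" an invariant rather than a
convention. The trial duration defaults to 15 s with a 30-s initiation
limit; both are configurable (some protocols run 30-s trials).

Trials in which the animal never licks within the initiation limit are
recorded as **missing, not zero**. A zero would conflate motivation (the
animal never sampled the tube) with taste-driven avoidance (it sampled and
rejected); the `n_trials_used` column lets downstream analyses see how many
presentations actually contributed.

## Standardized lick ratio

The ILI validity filter keeps intervals **strictly** inside (50 ms, 200 ms).
Boundary values are excluded: 50 ms is below the physiological minimum of
the lick central pattern generator and 200 ms already implies a missed lick
or a pause. The per-subject baseline pools all water-training sessions
(pooling weights every valid ILI equally, which is appropriate when training
sessions are homogeneous). Maximum potential licks = trial duration / mean
valid ILI, unrounded.

SLR values above 1 are reported, not clipped — they are informative
(stimulus licking faster than the water-training rhythm) and clipping would
bias group means downward asymmetrically. When sessions from multiple test
days are supplied, lick counts are pooled across days before averaging by
default; a per-session table is available via `average_over_sessions=False`.

## Meal and burst segmentation

* A **meal** opens at the earliest lick `i` (scanning forward from the end
  of the previous meal) such that licks `i .. i+4` span ≤ 1 s, and closes at
  the last lick followed by a gap ≥ 600 s. The gap test is
  threshold-inclusive; the initiation window likewise (5 licks spanning
  exactly 1.000 s initiate).
* A **burst** splits at every ILI strictly greater than 1 s; an ILI of
  exactly 1 s stays within the burst.
* Licks that never head a qualifying initiation run are **orphans**: they
  belong to no meal but still count toward `session_licks` (conservation:
  meal licks + orphan licks = session licks, and burst licks partition every
  meal).

Session summaries average each variable per meal, then across meals with
equal weight (not lick-weighted); lick-weighted averaging would let one
large meal dominate intra-meal statistics. Meals with a single burst
contribute no pause observation — they are excluded from the pause mean, not
counted as zero. "Licks in the first minute" is computed under both
conventions found in practice: anchored at the session's first lick
(`licks_first_minute`, the default reported value) and per-meal anchored at
each meal onset and averaged (`licks_first_minute_meal`).

These rules are verified against an exhaustive brute-force reference
implementation on a thousand adversarial random streams, including streams
with gaps exactly at the 1-s and 600-s thresholds.

## CT nerve processing

Rectification precedes integration: whole-nerve multiunit activity is
zero-mean, so the leaky integrator must see |x|. The integrator uses the
exact exponential update `y[n] = y[n-1] + (1 − e^(−Δt/τ))(|x[n]| − y[n-1])`
with `y[0] = |x[0]|` and τ = 1.5 s by default; constant input is a fixed
point and the step response follows the first-order closed form, both of
which are asserted in tests.

Response magnitude is the integrated value at the sample nearest
onset + 20 s minus the mean over a 5-s pre-onset baseline window. The
measurement is instantaneous (nearest sample) rather than a short average;
with a 1.5-s integrator the trace is already smooth at that timescale. The
baseline window length is a package choice (protocols rarely state one);
5 s is long enough to average baseline noise and short enough to avoid the
previous stimulus' decay at typical inter-stimulus spacing.

Bracket QC: deviation = |pre − post| / mean(pre, post), pass iff ≤ 0.10
(inclusive). The mean denominator makes the criterion symmetric in the two
brackets; alternatives (relative to the first bracket, or to the max) are
configurable via the tolerance argument but the symmetric form is the
default. One reference application may close one stimulus series and open
the next. Normalized magnitudes are still computed for failing series but
flagged excluded, so QC decisions remain auditable.

## Statistics

The split-plot (mixed) ANOVA uses the classical balanced decomposition:
group is tested against subjects-within-group; the within factor and the
group×within interaction against the level×subject-within-group stratum,
with df (g−1), g(n−1), (l−1), (g−1)(l−1), g(n−1)(l−1). Unbalanced or
incomplete designs raise — no imputation. No sphericity correction is
applied by default (none is reported in the analyses this battery mirrors);
the within-stratum p-values are exact under compound symmetry. The SS
decomposition is tested to 1e-8 against sequential least-squares projections
on explicit dummy design matrices, cross-checked against `pingouin`, and its
group-effect test is calibrated to a 5 % type-I rate under a 5,000-replicate
null simulation with subject random effects.

Two-tailed p-values come from the central t distribution,
`p = 2(1 − F_t(|t|; df))`, at full precision; display rounds to 3 decimals
with a `<0.001` floor. Bonferroni adjustment is `min(1, p·m)` where the
family size m defaults to the number of pairwise tests within the analysis
and is always recorded in the output. The paired-t routine pairs by input
order; callers pairing across independent groups by subject sort order get
an explicit design warning.

## Synthetic-data generator

The generator emulates the three study paradigms with a hierarchical point
process, and its defaults are set to the scale of a chronically tested
mouse cohort:

* Within-burst ILIs: truncated normal, mean 120 ms, sd 20 ms, truncated to
  (50, 300) ms — the rodent local lick rhythm.
* Burst length: geometric, mean 37 licks (≈ 4.4-s bursts).
* Bursts per meal: Poisson, mean 45, multiplied by the lick drive; intra-meal
  pauses lognormal with mean 55 s (clipped to (1.05, 550) s so they always
  split bursts but never terminate meals).
* Meals per session: Poisson, mean 8; inter-meal pauses lognormal with mean
  4000 s, clipped ≥ 650 s so every generated meal boundary is recoverable by
  the 600-s rule. Each meal's first burst is forced to ≥ 5 licks spanning
  < 1 s so the initiation rule holds at the true onset, making ground-truth
  meal counts exactly recoverable.

At these defaults a control session on 200 mM sucrose produces ≈ 10–12
thousand licks in ≈ 8 meals of ≈ 2,200 s with ≈ 37 bursts of ≈ 4.3 s —
the magnitude reported for mice drinking strong sucrose.

Concentration → drive uses a Hill curve rising from 0.35 (water level) to 1
for appetitive tastants and falling to 0.05 for aversive ones; no published
functional form exists for lick drive, only monotone concentration and
group effects, which any saturating monotone curve reproduces. Treatment
suppression is a multiplicative factor in (0, 1] on the drive for sweet and
salt tastants (applied to burst counts in long-term sessions and to bout
continuation in brief-access trials), so expected session licks scale
monotonically with the factor.

Brief-access trials draw a latency (shifted exponential, capped at the
initiation limit), then run a bout process: after each lick the train
continues at a within-burst ILI with probability equal to the drive,
otherwise inserts a 1–4 s pause. With drive 1 and no pauses the SLR
recovers ≈ 1 end to end. Initiation probability is 0.85 + 0.15·drive.

CT traces are zero-mean Gaussian "carriers" scaled so the rectified mean
equals the true amplitude times an envelope (exponential ramp, τ = 0.4 s, to
plateau during application; exponential decay, τ = 2 s, after rinse), plus
additive baseline noise. Rectify-and-integrate therefore recovers the true
amplitudes, and normalized magnitudes recover true test/reference ratios.
The integrated trace's stochastic ripple scales as 1/√(2·τ·fs); at the
1 kHz default sampling rate single-measurement ratio recovery is reliable
to well within 5 %.

All randomness flows from one seed through generators keyed by
(subject, session, purpose) via `SeedSequence`, so enlarging a cohort never
perturbs already-generated streams.

### What the generator does not emulate

Circadian structure (licks are uniform in time apart from the renewal
process), lick-duration/contact-time signals, drinking-volume per lick,
session-to-session learning or habituation, latency–palatability coupling,
and any physiological mechanism behind the group suppression factor.
Passing recovery tests therefore demonstrates that the segmentation,
normalization and statistical machinery are correct on data with the right
temporal hierarchy and effect structure — not that real cohorts of any
particular preparation will show these effect sizes.

## Problem sizes used in the test suite

Monte-Carlo checks use 20 subjects/group for cohort comparisons, 500 cohort
replicates for the false-positive-rate calibration, 1,000 random streams for
the segmentation oracle, and 5,000 replicates for the ANOVA type-I
calibration — sizes at which the binomial uncertainty of the estimated rates
is several times smaller than the asserted tolerances.
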