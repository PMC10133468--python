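# Methods

## Place-frequency model

Electrode contacts are located as arc-length distances `d` (mm) along the
lateral cochlear wall, measured from the round window; the lateral wall is
traced from round window to helicotrema and a contact's depth is the arc
length to the polyline point nearest its marker (projection onto segments,
not vertices). The tonotopic frequency of a contact is the Greenwood map

    F(x) = A (10^{a·x} − K),    x = (CDL − d) / CDL,

with the published human constants A = 165.4 Hz, a = 2.1, K = 0.88 and `x`
the proportion of cochlear length from the apex. The constants are
configurable (`GreenwoodParams`). The map is applied to lateral-wall
distance directly — no organ-of-Corti or spiral-ganglion length correction —
but `place_frequencies` exposes a multiplicative length-correction factor
(default 1.0) for users who want one. Contact 1 is the most apical contact
throughout; all tables carry explicit contact indices.

## Frequency allocation tables

A FAT is an ordered set of contiguous bands over the processor range
[238, 8,598] Hz. The **standard** table defaults to 16 log-spaced bands
(channel k lower bound `238·(8598/238)^{(k−1)/16}`); an explicit table of
lower bounds can be supplied instead, since clinical default tables are
device-specific and not log-exact. The **tonotopic** table is built from a
subject's place frequencies:

1. a virtual (phantom) channel — index 0, modelling stimulation apical to
   the first contact — spans 238 Hz up to the apical contact's place
   frequency;
2. each physical channel's lower bound is its contact's place frequency;
   contacts whose place frequency falls below the 238 Hz floor are spread
   geometrically between the floor and the first in-range place frequency;
3. channels at or above 8,598 Hz are disabled (their band is donated to the
   most basal enabled channel, capped at the ceiling);
4. the low-frequency rule set — at least 2 enabled channels below 1,000 Hz,
   4 below 2,000 Hz, 7 below 4,000 Hz, virtual channel included — is
   enforced by a deterministic repair: for each unmet threshold, the
   offending channels (counted apically) are moved onto a geometric grid
   strictly between the last compliant bound and the threshold, leaving all
   other channels untouched. No trade-off beyond minimal perturbation is
   attempted, because the clinical rule set itself is an arbitrary
   compromise between tonotopic alignment and low-frequency coverage; any
   repair satisfying the minima is admissible, and a deterministic one keeps
   runs reproducible.

Fewer than eight usable channels (largest minimum count + the basal
channel) raises an unsatisfiable-rules error rather than silently producing
a non-compliant map.

**Mismatch.** Per enabled physical channel, mismatch is
`log2(f_place / f_assigned)` octaves. The assigned frequency defaults to the
geometric mean of the band edges — the conventional band-center choice, and
the honest one for the standard table, whose lower bounds were never meant
to be tonotopic — and can be switched to the lower bound, under which a
freshly built tonotopic table has exactly zero mismatch on unrepaired
channels. Published mismatch summaries do not state which representative
they used, so the choice is a config switch and summary statistics (median,
IQR, per contact and pooled) are reported for whichever is selected.

## Randomization

Schedules assign test/control per day over 84 days (first fitting to
+12 weeks, configurable) with an exact overall 1:1 ratio (odd lengths differ
by one, surplus arm random) and run caps of 2 within days 1–28 and 4 from
day 29; a run straddling the boundary is capped on each in-window portion.
Generation is constrained sequential sampling: each day a fair coin chooses
among the labels whose choice leaves the remaining days completable, where
completability is decided exactly by a memoized recursion over (day,
remaining test days, trailing in-window run). This is linear-time, never
discards a partial schedule, gives every valid schedule nonzero probability,
and makes no uniformity claim (none is needed for a within-subject
exposure-balancing schedule). Blinding labels are an independent fair coin
per fitting visit.

**Compliance** is the share of scheduled test-fitting days on which the
diary reports the other fitting, over reported days, × 100. Unreported days
are dropped from numerator and denominator. Equivalently: the intended test
share minus the share of days the test fitting was worn as scheduled. A
fully followed schedule scores 0 %; a diary reporting control on every
scheduled test day scores 50 % on a balanced schedule.

## Scoring rules

Applied to raw visit tables, idempotently:

* CNC word score per visit = mean of the test and retest lists;
* sentence-in-quiet visits skipped as too difficult score 20 % (guessing
  correction for the closed-set matrix test);
* SRT is only accepted when the same visit's quiet score is ≥ 50 %;
  otherwise 15 dB SNR is assigned;
* measured SRTs above 15 dB SNR, or outside the presented level range when
  that range is recorded, are marked invalid and excluded (not interpolated
  over as missing — they become gaps).

## Learning curves and statistics

Primary outcomes at visit weeks {0–8, 10, 12} are interpolated to daily
curves over days 0–84: linear between non-missing visits, interior gaps
bridged linearly, boundary gaps carried flat (interpolation is specified
clinically; extrapolation is not, and flat carry-out is the least
structured choice). Parameters: Begin = day 0, End = day 84,
AUC = trapezoidal integral over [0, 84] (units × days; a day/week abscissa
switch would rescale by 7 — days are used), learning rate =
(day 28 − day 0)/28.

Paired comparisons use the Wilcoxon signed-rank test, two-sided, zeros
dropped, exact distribution for ≤ 25 informative pairs (normal
approximation above, or when ties preclude the exact tables), with medians,
IQRs, the median paired difference, and a seeded percentile bootstrap
(default 10,000 resamples) 95 % CI of the median difference. Begin and End
p-values are Holm–Bonferroni corrected within each measure.

Psychoacoustics: listening-effort levels are SRT + {−6, −3, 0, +3, +6, +9}
dB; ACALOS loudness-growth AUCs integrate each frequency's categorical
loudness (11 categories mapped to 0–50 CU in steps of 5) over a 0–105 dB HL
level range with flat extrapolation beyond sampled levels, and the overall
AUC sums per-frequency integrals on a 17-point log-spaced 250–4,000 Hz grid
with linear interpolation in log-frequency (grid, range and CU mapping are
config knobs; the companion loudness-surface method is not published in
detail, so this surface is a documented stand-in). The SMRT staircase is
1-up/1-down from 0.5 ripples/octave in 0.2 steps, floored at 0.5, stopping
after 10 reversals with the threshold the mean of the last 6 (stopping rule
chosen here; start, step and rule are the published part), guarded at 150
trials.

## Synthetic cohort

The generator emulates the trial's structure, not its patients:

* anatomy — CDL ~ N(35, 2) mm truncated to [28, 42]; apical insertion depth
  ~ N(22, 2) mm truncated to [12, CDL − 1]; 16 contacts at 0.95 mm pitch.
  The mean geometry's apical place frequency is ≈ 851 Hz, inside the
  725–957 Hz range expected for full-length arrays;
* outcomes — per arm and measure, S(t) = asymptote + (baseline −
  asymptote)·e^{−t/τ}, with arm-level medians set to the trial-scale values
  (CNC control asymptote 68 %, test 47 %, τ = 21 d; quiet 90/80 %; SRT
  improving downward from the 15 dB SNR ceiling toward 0.3/1.9 dB SNR,
  τ = 25 d; satisfaction VAS 7.0/4.7 and 6.9/4.5). Between-subject ability
  is a shared Normal(0, 8) shift, within-subject arm idiosyncrasy
  Normal(0, 6), visit noise 5–6 % for speech scores and 3 dB for SRT
  (test–retest spread typical of matrix-test SRTs in CI users; it also lets
  borderline tracks exceed the 15 dB validity ceiling, so the exclusion
  rule is exercised). Observations are clipped to each measure's scale and
  dropped independently with probability 0.11 (the trial-scale missingness);
* quiet visits are flagged "too difficult" when the same arm's noise-free
  CNC expectation is below 10 %, mimicking the clinical judgement that
  triggers the 20 % substitution;
* diaries mis-report each day with probability 0.05, giving expected
  compliance deviations of 2.5 % (Binomial(42, 0.05)/84), the order observed
  clinically.

Subject streams are spawned from a master `SeedSequence`, so cohorts are
byte-reproducible and single subjects can be regenerated independently.

What the generator does **not** model: per-electrode neural survival,
carry-over between fittings worn on alternating days (arms are conditionally
independent given the subject effect), non-Gaussian floor/ceiling response
distributions beyond clipping, drop-out (missingness is independent per
visit, not visit-block structured), or any acoustic signal path. Passing
tests therefore demonstrate that the pipeline's algorithms are correct and
calibrated (type-I error ≈ α, power > 0.8 for a 20-point asymptote gap at
n = 14), not that real patients behave like the model.

## Numerical choices

* Feasibility memoization for schedules is exact (no rejection sampling);
  10,000 schedule draws take seconds.
* FAT contiguity uses 1e−9 relative tolerance; disabled channels keep their
  out-of-range bound as degenerate bookkeeping bounds.
* CSVs are written at `repr` precision and read with round-trip float
  parsing, making write-then-read the identity.
* Bootstrap and simulation sizes in the test suite (500 replicate cohorts
  for calibration checks, 1,000-geometry fuzz for FAT invariants, 10,000
  schedules) were chosen to keep the default suite at a few minutes on one
  core while leaving Monte-Carlo bands narrow enough to be meaningful.

## Known limitations

* The real clinical standard FAT's band edges are not public; the log-spaced
  default reproduces its floor, ceiling, and channel count but not its exact
  band widths, so absolute standard-FAT mismatch values depend on that
  choice (the imaging-based ≤ standard mismatch ordering does not).
* The rule-set repair is one deterministic algorithm among many admissible
  ones; clinical repairs made interactively may differ per subject.
* The exact published mismatch medians derive from the trial's deposited
  patient data and are not reproducible from simulation; this package
  reproduces the procedure and its invariants, not those point estimates.
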