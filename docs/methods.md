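# Methods

`apcsim` is a desk-scale simulator of a gravity-fed optical particle
counter of the kind used to count and dispense first-instar (L1) mosquito
larvae for mass rearing.  The physical device feeds a stirred larval
suspension from a reservoir through a 1 mm ID capillary past an optical
sensor; a streaming algorithm counts the light-occlusion pulses and a
pinch valve upstream of the sensor stops the flow when a user-set target
count is reached.  The package models each stage of that loop and the
statistics used to characterise its accuracy (mean percent deviation of
the number dispensed from the target) and precision (the dispersion of
dispensed counts).

## Hydraulics

Flow is gravity-driven, so the volumetric rate is a function of the water
column standing above the capillary outlet.  The two available
calibration measurements (0.77 ml/s at 31 cm of head, 0.48 ml/s at 24 cm)
are inconsistent with both a Torricelli (∝√h) and a pure Poiseuille (∝h)
law — unsurprising given the pinch-valve tubing in the path — so the
head→flow map is an *empirical* piecewise-linear interpolation through
calibration points, linearly extrapolated beyond them and clamped at
zero.  Users can supply more points; the default two-point calibration
reaches zero flow near 12.4 cm of head.  Flows below 10⁻¹² ml/s clamp to
exactly zero so a draining reservoir reaches a true steady state.

Stream velocity uses the plug-flow mean v = Q/A.  In a 1 mm bore this is
justified by hydrodynamic focusing — larvae align with the faster central
stream — and it reproduces the device's measured transit speed
(980 mm/s at 0.77 ml/s), giving a ~2.04 ms visibility window for the 2 mm
sensor.  A parabolic-profile centreline velocity (2Q/A) would not.

Reservoir drainage uses explicit Euler steps: head changes per sensor
sample are ~10⁻⁶ of the head itself, so nothing stiffer is warranted.
Within a dispensing run the reservoir is treated as quasi-static at its
initial head (the study conditions keep it topped up near the high mark);
the depletion-coupled arrival mode exposes full drain-down dynamics when
wanted.

## Synthetic streams

Arrivals are Poisson.  The reservoir is stirred, so larvae reach the
capillary independently at rate = concentration × flow; in fixed-rate
mode that rate is the configured LPS (larvae per second), in
depletion-coupled mode it declines with the draining flow (simulated by
thinning against the initial rate).  Sequential exponential-gap
generation means extending a run's horizon extends, never reshuffles, the
event prefix — the dispenser relies on this for deterministic horizon
doubling.

The sensor samples at 10 per msec (10 kHz), giving ~20 samples per pulse.
Each larva subtracts a rectangular occlusion dip of duration
(sensor window + body length)/velocity — diagnostic traces from the
device show near-rectangular below-baseline peaks, and at ~20 samples a
finer pulse shape would be invisible; an optional 1-sample ramp softens
edges.  Overlapping larvae superimpose additively and the series is
floored at zero (full occlusion).  The baseline sits at 500 intensity
units with Gaussian sensor noise (sd 6 by default, comfortably inside the
device's calibration gate of sd < 18) and optional linear drift standing
in for slowly changing water absorbance.

Pulse amplitudes are truncated-normal: mean 100, sd 20, floor 10 units.
The device's pulse-height distribution is unpublished; these defaults are
chosen so that trigger thresholds of 2.5–6 baseline standard deviations
detect essentially every pulse while thresholds of 7–8 (threshold 42–48
units) begin to miss the weak tail — the qualitative regime the device
exhibits.  Contaminants (larval food, eggshells, electronic glitches) are
short (0.5 ms) dips with exponentially distributed amplitude (mean 30);
their rate defaults to 0 (clean water).  The debris-laden scenario used
in the demo and acceptance script sets 1.5 events/s, chosen a priori so
that at the recommended 3.5-sd threshold and 25 LPS the expected net
accuracy error is in the −2% ballpark.

Each run derives independent arrival/noise/contaminant random streams
from one root seed, so components are individually reproducible.

## Detection

Three streaming counters operate sample-by-sample on the deviation
(baseline − intensity; larvae block light, so deeper occlusion = larger
deviation):

* **Smoothed z-score** (the algorithm of interest).  A moving window of
  `lag` samples (default 500 = 50 ms: long against a 2 ms pulse, short
  against drift) maintains the baseline mean μ and sd σ.  A sample is
  flagged when deviation > `z_start`·σ; `n_above` consecutive flagged
  samples (default 3) emit a count.  Flagged samples enter the baseline
  window with weight `influence` (default 0: a passing larva must not
  inflate σ; only slow drift is tracked).  After a count the counter is
  suppressed until the signal *re-arms*: immediately once the deviation
  returns to the baseline mean (the pulse is over), or — while the pulse
  continues — once the cluster-split rule fires: a deviation drop of
  `decline_amount` (default 50 units, half the mean pulse amplitude) from
  the post-count peak, or alternatively `n_decline` consecutive declining
  deviations.  The depth-based default matters: a count-based rule of a
  few samples fires on plateau noise (a 3-long declining run occurs with
  probability 1/24 at any position) and double-counts isolated larvae,
  while requiring a 50-unit drop only triggers on the genuine valley
  between two larvae sharing one merged pulse.  The re-arm-on-return rule
  likewise prevents threshold chattering from splitting one pulse into
  many counts when the threshold sits near the pulse amplitude, which
  keeps the count non-increasing in `z_start` under frozen baseline
  statistics.
* **Threshold reset**: fixed deviation threshold, `n_above` consecutive
  samples above to count, `n_below` consecutive below to re-arm.
* **Refractory period**: count at each upward threshold crossing,
  ignoring crossings within `refractory` ms of the last counted one.

σ is floored at 10⁻⁶ units so z stays computable on noiseless synthetic
traces.  The first `lag` samples initialise μ/σ and cannot emit counts.
A pulse truncated by end-of-trace still counts once it has satisfied
`n_above`.  An offline brute-force re-implementation of each algorithm
(whole-series, structurally independent: window statistics recomputed
from scratch each sample, run-length encodings for the fixed-threshold
algorithms) serves as a cross-check; streaming and offline counts agree
on every seeded random trace in the suite.

## Dispensing loop

`run_dispense` simulates one closed-loop run: arrivals → trace →
streaming detection → valve closure when the count reaches the target
(plus an optional `closure_lag` of continued flow, default 0).  Because
the device calibrates before dispensing, the detector's warm-up window is
filled with larva-free stream before the valve opens; without this the
first 50 ms of larvae would pass uncounted and bias every run toward
over-dispensing.

The valve is upstream of the sensor, so closure freezes the whole column:
larvae already past the sensor but still inside the 15 mm dead segment
below it (transit ~15 ms) are *counted but not dispensed* and are flushed
out, uncounted, at the start of the next run (`run_chain` propagates this
carry-over).  Conservation holds exactly: over any chain,
Σ dispensed = Σ counted − final residual + initial carry-over (perfect
detection).

The realized mean residual at 25 LPS is ~1.4 larvae, not the naive
rate × transit expectation of 0.38: the larva whose detection completes
the target is itself always still in the dead segment at closure, adding
one by construction.  This inspection effect reproduces the device's
observed residual (mean 1.4) without invoking any valve-closure delay.
Residuals and carry-over cancel in the long-run mean — they add variance,
not bias — so with ideal detection the mean dispensed equals the target.

Directional error mechanisms, both emergent rather than scripted:
excessive thresholds (7–8 sd) miss weak or baseline-inflated pulses, so
extra larvae pass per completed count and the device *over*-dispenses;
debris pulses at ordinary thresholds trigger spurious counts, close the
valve early and *under*-dispense (the net at the debris scenario is
about −1.5%, combining ~−2.5% spurious counts with ~+1% pulse-merging
losses at 25 LPS).  A related emergent prediction: dead-segment occupancy
grows with supply rate (~0.015% of a 100-larva target per LPS), so a
weak negative rate–accuracy relation exists when rates are varied across
runs; the no-rate-effect null used for the correlation type-I check is
therefore a chain at a fixed nominal rate, where the measured LPS varies
only through run-to-run fluctuation.

## Run statistics

Accuracy summaries use the t-based 95% CI of the mean percent error;
integer modes report all tied maxima; range proportions cover
target ± 2 and target ± 5; normality via Shapiro–Wilk and skew by the
sign of the sample skewness.  Degenerate inputs are reported as
unavailable (`None`), never fabricated: a single run has no CI, a
zero-variance sample no Shapiro p.

One-way ANOVA across detector-threshold groups works from raw counts or
from published-style summaries (n, mean, 95% CI).  From summaries, the
between-group SS comes from (n, mean) and within-group variance is
recovered as sd = CI·√n / t₀.₉₇₅,ₙ₋₁; groups lacking a CI are excluded
from the recovery with a warning.  Pairwise comparisons use Tukey's
honestly-significant-difference statistic evaluated at a
Bonferroni-adjusted α (α/n_pairs) — a belt-and-braces convention some
laboratories use even though HSD already controls the family-wise rate; a
flag restores plain HSD — and a greedy insert-and-absorb compact letter
display assigns shared letters to indistinguishable groups.  Display
rounding (nearest integer percent for headline accuracy, one decimal for
rates) is always separate from stored precision.

The two-sample t-test from summary statistics (pooled by default, Welch
by flag) reproduces reference implementations exactly.  Note that the
pooled test applied to the *rounded* published flow summaries
(0.77 ± 0.012, n=6 vs 0.48 ± 0.007, n=7) gives p ≈ 1×10⁻¹⁴; tests assert
the order of magnitude, not a digit-exact p, since the inputs are rounded.

## What the synthetic generator does and does not capture

It emulates Poisson arrival statistics, rectangular occlusion pulses with
amplitude spread, additive pulse overlap, Gaussian sensor noise, baseline
drift, debris, reservoir depletion, and dead-segment carry-over.  It does
not model real larval behaviour (swimming against the flow, clumping
beyond Poisson, size growth), optical detail (partial occlusion geometry,
sensor nonlinearity), or valve/tubing mechanics.  Passing tests therefore
demonstrate the correctness and internal consistency of the algorithms
and the direction of the error mechanisms — not that a physical device
will achieve any particular accuracy on live larvae.

## Problem sizes

Monte-Carlo campaigns in the test suite and acceptance script use
100 ideal-detection runs, 30–60 full detection-loop runs at target 100
and 25 LPS, ~1000 random traces for the streaming/offline equivalence
battery, and 120 s arrival streams for rate recovery — sizes at which
every check completes in seconds on a single core while keeping
Monte-Carlo standard errors a few times smaller than the effects being
asserted.
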