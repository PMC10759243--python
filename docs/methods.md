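# Methods

This note documents the models, parameter choices and numerical conventions
behind `gazesa`, and what the synthetic-data tests do and do not establish
about real recordings.

## Fixation classification (I-VT)

Gaze speed is computed between consecutive *valid* samples as Euclidean
pixel distance divided by the inter-sample interval (px/ms). A sample pair
continues a fixation iff its speed is **strictly below** the threshold
(default 0.42 px/ms, the spatial-fixation filter constant of high-rate
screen-mounted tracker software); a speed exactly at the threshold counts as
saccade. The threshold is used in pixel units deliberately — no
viewing-geometry conversion to deg/s is attempted, since the screen
geometry of the monitoring display is part of the task definition.

Two tunables shape the event stream:

- `min_fix_ms` (default 60 ms): candidate runs shorter than this are
  re-labelled saccade time. Sixty milliseconds is the conventional floor
  below which stable-gaze episodes are not treated as information uptake.
- `max_gap_ms` (default 75 ms): track-loss gaps no longer than this are
  bridged when the speed implied across the gap stays below threshold, so a
  short blink does not split a dwell; longer gaps always terminate the
  fixation. Both values are configurable and declared, not derived.

Fixation centroids are unweighted means of member sample positions. No
post-hoc merging of adjacent fixations is performed beyond gap bridging; the
classifier is therefore exactly equivalent to a run-length scan over the
thresholded speed sequence, which the test suite exploits as a brute-force
oracle. `classify_segments` exposes the complementary partition view
(fixation/saccade/gap segments summing exactly to the recording span).

## AOI metrics

AOI rectangles are half-open, `[x0, x1) × [y0, y1)`, so a point belongs to
at most one named AOI; the remainder of the screen is the complement region
("AOI I"). Fixations are assigned by **centroid**, the simplest
deterministic rule consistent with mapping whole fixations to regions; a
per-sample majority rule would differ only for fixations straddling an AOI
edge. Centroids outside the screen (possible after jitter near the display
edge) fall to the complement with a warning.

Windowed metrics clip by overlap for duration (conservative: a fixation
contributes only the time it actually spends inside the window) and by onset
for counts (unambiguous: each fixation is counted in exactly one window of a
tiling). Percent denominators are the window totals over *all* regions —
the whole display treated as an AOI — so percents across the partition sum
to 100 whenever the window contains any fixation. Windows with no fixations
report NaN percents rather than zeros, so empty windows cannot masquerade as
"zero attention" in downstream group statistics.

## Pupillogram pipeline

Order: per-eye **interpolate → smooth**, then **average → baseline →
normalize**. Interpolation precedes smoothing because local polynomial
smoothing across unfilled gaps is ill-defined; the smoother then never
converts missing spans to data, and interpolation never alters measured
points (both are invariants under test).

- *Gap interpolation*: for each interior gap no longer than `max_gap_ms`
  (default 500 ms — covers blinks, not sustained track loss), the fill line's
  slope is the least-squares slope through the 10 valid points before and 10
  after the gap (the 21-point window counting the gap anchor), and the line
  is anchored at the last valid pre-gap point. This recovers affine signals
  exactly. Gaps at the trace extremes, or flanked by fewer than 10 valid
  points, stay missing with a warning.
- *Savitzky-Golay*: window 21 samples, polyorder 3 by default. The window
  echoes the interpolation window and a cubic is the conventional order for
  physiological smoothing; both are explicit parameters because nothing in
  the task pins them. Interior behaviour is checked against the closed-form
  window-5/order-2 kernel (−3, 12, 17, 12, −3)/35 and the
  polynomial-reproduction property.
- *Binocular averaging*: pointwise mean where both eyes are present, the
  single value where one is; with independent per-eye noise this halves the
  noise variance, which the generator makes testable.
- *Baseline*: mean diameter over the first 5 s by default (a pre-task
  window; configurable). Output `d` is change in pupil diameter (mm);
  `d_norm = (d − b)/b` is the dimensionless relative change used for
  cross-participant comparison. Only the subtractive stage is pinned by the
  convention of reporting dilation in mm; the ratio form is provided
  alongside it.

## Group statistics

Kruskal-Wallis uses midranks and the tie-corrected statistic; the Dunn
post-hoc uses the pooled mean-rank difference with the tie-corrected
standard error and two-sided normal p-values, Bonferroni-multiplied by the
number of pairs. Pairs are reported with groups sorted by ascending mean
rank (the layout of standard statistical-software pairwise tables), making
the printed mean-rank differences non-positive. In a balanced tie-free
design the se is constant across pairs — `dunn_se(66, 22, 22) = 5.788` at
3 dp — which is the package's exactly reproducible numeric anchor.

Note the se is in mean-rank units and grows ≈ √N with the design (ranks grow
with the pooled sample); what shrinks with more data is the se *relative* to
the rank scale, and, at fixed N, the se of better-filled pairs.

The AOI-wise comparison treats per-participant AOI metric values as
independent observations per region group (an H(2, 66)-style layout of
3 × 22). This ignores within-participant correlation across regions — the
three shares of one participant sum to 100 — and is documented as such; the
package reproduces the arithmetic of that design, not a claim of its
optimality. `compare_expert_novices` positions the expert by
`(expert − novice mean)/novice sample sd` per region and metric.

## Alerting

The baseline stores, per scenario phase and region, the expert mean and a
dispersion floored at `dispersion_floor` (default 10 percentage points; with
a single expert recording the floor *is* the dispersion, since one recording
carries no between-expert variance). Monitoring slides a window (default
30 s, step 10 s) over the subject's recording:

- windows that straddle a phase boundary are skipped — comparing a
  mixed-phase window against a single-phase baseline would manufacture
  deficits at every phase transition;
- attention deviation is one-sided (deficit only, default k = 2
  dispersions): the operational concern is attention that is missing, not
  attention in excess;
- track loss fires when the valid-sample fraction drops below 0.6
  (eyes closed / away: the tracker can capture neither fixations nor pupil);
- pupil constriction fires when the baselined pupil level falls below
  −0.5 mm.

Raised alerts are rate-limited to `max_alert_rate` (default 1) per
10-minute span, keeping highest severity first — the ceiling human-factors
guidance considers acceptable for monitoring personnel. The limiter is
greedy over severity-ordered candidates and guarantees (property-tested)
that no 10-minute interval ever contains more than the cap. Streaming is
emulated by windowed batch over a recorded file; socket-level streaming is
out of scope.

## Synthetic-data generator

The generator exists to make the pipeline's qualitative contrasts
reproducible *in direction*; none of its distributional constants are
measurements. Defaults, chosen as plausible for a monitoring task and fixed
once:

| parameter | default | rationale |
|---|---|---|
| scenario | 300 s at 300 Hz, anomaly 120–170 s | study design of the emulated scenario |
| cohort | 23 novices + 1 expert | study design |
| attention weights (base) | AOI I/II/III = 0.55/0.25/0.20 | complement dominates routine scanning |
| expert anomaly weights | 0.10/0.20/0.70 | attention shifts to the anomaly indicators |
| novice anomaly weights | 0.70/0.20/0.10 | attention stays on the familiar region |
| fixation duration | lognormal, median 300 ms, σ = 0.4, floor 100 ms | typical monitoring dwells |
| within-fixation jitter | 0.25 px sd | keeps within-fixation speeds below 0.42 px/ms with probability > 0.999 at 300 Hz (Rayleigh tail bound) |
| saccades | 20–60 ms, ≥ 40 px amplitude | guarantees above-threshold speed so events are recoverable |
| blinks | 15/min, 100–300 ms | both channels invalid during a blink |
| pupil | baseline 3.0 mm; dilation 0.4 mm (expert) / 0.15 mm (novice), 2 s lag; per-eye noise 0.05 mm | shared latent signal + independent eye noise |

Pre- and post-anomaly phases of the two profiles are identical, isolating
the contrast to the anomaly response. Cohort novices get per-participant
Dirichlet jitter on the weights (α = 80·w) and mild pupil parameter spread;
all member seeds derive from one `SeedSequence` and are distinct.

What the generator does **not** emulate — and passing tests therefore do not
establish for real data: smooth pursuit against the moving chart, saccade
main-sequence dynamics, luminance-driven pupil changes, pupil foreshortening
with gaze angle, drift/calibration error, or asymmetric per-eye track loss.
The directional cohort results (expert anomaly-window AOI III share above
the novice mean; alerts for the novice and none for the expert) are claims
about this generative model, at the stated effect sizes.

## Problem sizes and numerical conventions

Unit tests run on a scaled 60 s / 120 Hz scenario; the cohort-level
directional checks run 20 replicates of the full 300 s / 300 Hz cohort. The
fixation-detector oracle comparison uses 1 000 randomized streams up to
10⁴ samples. Exact-permutation checks of the omnibus p-value enumerate all
assignments at N ≤ 8. Output tables print 3 decimals (statistics and
significances alike); ties in rank computations use midranks throughout;
recordings validate that the declared sampling rate matches the median
inter-sample interval within 10 %.
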