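# Methods

This note documents the models and procedures implemented in `peristartle`,
the assumptions behind them, the parameters that matter, and what the
synthetic-data tests do and do not demonstrate.

## Signal model

The pipeline consumes per-frame 2-D keypoint coordinates of a receiver bird
standing inside a bower (beak tip, left/right feet, left/right inter-tarsal
joints, image convention with *y* increasing downward, 30 fps by default) and
a log of the courting male's display elements. It assumes the receiver is
*stationary in depth*: a single camera cannot separate longitudinal movement
from movement amplitude, so bouts where the receiver translates along the
camera axis should be excluded upstream. Under that assumption the bird's
apparent body height — |beak *y* − mean ITJ *y*|, averaged over the bout — is
a stable per-bout length scale, and dividing the beak's frame-to-frame
Euclidean displacement by it yields the dimensionless **relative
displacement** RD, comparable across birds, bouts and camera distances. RD is
undefined at frame 0 and wherever the beak record of the frame or its
predecessor is invalid. When both ITJs are valid their *y* values are
averaged; with one side valid, that side is used — the ITJs sit symmetrically,
so averaging only reduces noise.

### Track cleaning

Pose detectors occasionally detect a branch or bower decoration as a body
part. A keypoint whose frame-to-frame displacement exceeds `hard` (default
0.5) body heights — an instantaneous velocity of one body height per frame —
is invalidated; displacements in (`soft`=0.25, 0.5] are plausible but sudden
and are flagged and retained, replacing visual inspection with a
machine-readable list. Displacements are evaluated once on the raw series:
removing a record does not create new candidate jumps between its former
neighbours (an iterative-to-fixed-point variant exists, default off).
Invalidation is per keypoint, not per frame. Data-loss fractions are reported
against both defensible denominators (frames, and frame×keypoint records).

### Peri-event statistic

For an element starting at frame *s*, baseline = RD[*s−b+1 … s*] and post =
RD[*s … s+w−1*]; the occurrence frame deliberately belongs to both segments.
Δ_mean subtracts segment means, Δ_max segment maxima. Baseline subtraction
removes tracking noise common to both segments and per-individual baseline
restlessness. Only the element's *start* frame anchors the window, also for
multi-frame elements. Under the default **strict** policy a Δ record exists
only when every frame of both segments is inside the bout with RD defined;
otherwise the event is skipped with a logged reason. A **tolerant** policy
(mean over defined frames, per-segment coverage ≥ 0.8 by default) is provided
for noisier material. Windows of closely spaced elements are evaluated
independently, one record per element occurrence.

The group-level statistic is the unweighted mean over males of each male's
mean Δ. Individual element counts vary over an order of magnitude, and the
average-of-averages prevents data-rich individuals from driving the result;
tests assert the statistic is invariant to inflating one male's sample size.

## Bootstrap null

The test asks whether Δ after display elements exceeds Δ at arbitrary moments
of the same recordings. A frame is *eligible* as a pseudo-event iff its full
baseline and post segments lie inside one bout with RD defined — the same
admission rule as for observed records, so observed and null statistics share
their construction exactly. One replicate: for each male independently, draw
(uniformly, with replacement, pooled across his bouts) as many eligible frames
as he contributed Δ records, evaluate Δ at each, average within male, then
average the male means. B replicates (default 1000) give the 2.5/97.5%
quantiles; the p-value is add-one empirical,

    p_upper = (1 + #{null ≥ observed}) / (B + 1),

two-sided p = min(1, 2·min(p_upper, p_lower)). The two-sided default reflects
that both elevated (startle) and depressed (freezing) responses are
meaningful; one-sided tails are available. The number of frames drawn per male
defaults to his count of elements of the class under test and can be
overridden (`balance_class`). Males with no usable records or no eligible
frames are excluded with a warning. On small problems an exhaustive mode
enumerates every unordered with-replacement draw and is used in tests as an
exact reference for the Monte-Carlo sampler.

Sampling uses one `numpy` Generator per test, consumed male-by-male in sorted
order, so identical (data, config, seed) reproduce bit-identical nulls. Sweep
cells derive their seed from the master seed and the cell coordinates
(status, class, baseline, post) via `SeedSequence` spawn keys, making any cell
reproducible in isolation. Leave-one-out rows share one derived seed: common
random numbers isolate the effect of the omitted male, and omitting either of
two identical males provably yields identical rows.

### Robustness sweeps

Because the species' startle latency is unknown, the post window sweeps 4–50
frames (133 ms to ~1.7 s at 30 fps) at fixed baseline, and the whole analysis
repeats at baselines 5, 10, 15 and 20. A cell is flagged significant when its
observed Δ lies outside the null's [2.5%, 97.5%] band. No multiple-testing
correction is applied across the grid — the sweep is a sensitivity display,
not a family of confirmatory tests.

## Bower-exit contrast

Each exit is attributed to the most recent element of the same bout whose
start frame does not come after it (no maximum lag by default; configurable);
an element's binary outcome is 1 iff at least one exit is attributed to it.
The default test of the status effect is a **cluster permutation**: statistic
= difference between status groups in the unweighted mean of per-male exit
proportions; the null permutes status labels across males, preserving each
male's outcome vector, because elements within a male are not exchangeable
(shared identity, date, bower). All C(n, k) assignments are enumerated when
below 50 000 (two-sided p = share of assignments with |statistic| ≥ observed,
observed assignment included), else sampled with the add-one correction. The
paper-style binomial GLMM (status fixed effect, random intercepts for male and
date, likelihood-ratio test against the null model) is available as
`method="mixed_model"`, fitted through R's lme4 in a subprocess; it requires
≥ a handful of males per group to converge and is treated as a contract-level
alternative, not the default.

## Annotation agreement

Automatic and manual tracks are joined on (bout, frame, keypoint) over valid
records; per keypoint the package reports shared-frame count, mean ± sd
Euclidean error in pixels and in body-height fractions (pixel error divided by
the bout's mean body height, exactly), and the Pearson correlation of each
coordinate axis. This deliberately reports a superset of common validation
summaries rather than committing to one.

## Synthetic-data generator

`SimulationConfig`/`simulate_dataset` emulate the statistical structure the
analysis assumes, so every stage is testable end to end without field data:

| parameter | default | meaning / rationale |
|---|---|---|
| n_owners / n_subordinates | 9 / 8 | tracked-subset design |
| bouts_per_male | 4–32 | observed per-male range |
| bout_length_frames | 300–1000 | a few hundred to ~1000 frames at 30 fps |
| body_height_px | 100 ± 10 | plausible apparent size at 1–2 m camera distance |
| jitter_sd | 0.01 body heights/frame | typical pose-detector keypoint noise |
| misdetect_rate | 2×10⁻⁵ /frame/keypoint | mis-detections are rare after training |
| misdetect_magnitude | U(0.15, 0.75) body heights | straddles both cleaning thresholds |
| element_rate | 4 / 100 frames | ~10–25 high-intensity elements per long bout |
| high_fraction | 0.4 | share of elements that are high-intensity |
| high_duration_frames | 36.69 ± 35.92 | observed high-intensity durations |
| min_element_gap | 15 frames | renewal spacing; windows may still overlap |
| startle_latency_frames | U{2, 3} | below the 50–100 ms starling reaction-time range there is no anchor; free parameter |
| startle_duration_frames | 3 | brief reflexive movement |
| startle_probability | 0.5 | not every element elicits a startle |
| startle_magnitude | owner 0.1, subordinate 0 | owner-only effect, per status |
| exit_probability | 0.2 both statuses | no status effect in exits |

Each bout is a single static pose (the stationarity assumption) plus Gaussian
keypoint jitter. A startle is a transient displacement pulse of the beak only:
during the pulse the beak zig-zags along *x* with a bounded offset, so each
pulse frame's frame-to-frame displacement equals the configured magnitude
exactly — the injected RD contribution is known in closed form, enabling
parameter-recovery oracles. One subtlety matters for those oracles: at pulse
frames the pulse step *replaces* the jitter displacement (they add as
vectors), so each pulse frame contributes E[Rice(A, s)] − E[Rayleigh(s)]
(A = pulse magnitude, s = √2·jitter sd) to Δ_mean rather than A; with jitter
off the contribution is exactly A. Mis-detections are single-frame jumps in a
random direction. Exits follow high-intensity elements with per-status
probability. With the given minimum gap a pulse can never leak into the next
element's baseline, which keeps the injected-Δ expectation exact.

**What passing synthetic tests do not show:** the generator has no depth
motion, no occlusions, no autocorrelated detector error, no receiver
locomotion between stations, no courter-movement crosstalk, and elements are
a renewal process rather than structured display sequences. Results on real
recordings additionally depend on the upstream pose detector and on the
stationarity-based bout selection.

## Test and simulation sizes

The statistical checks run at sizes chosen to keep the full suite fast while
retaining power: bootstrap calibration uses 250 no-startle datasets (6 males,
2 bouts of 500–700 frames each) at B = 200, asserting a 3–7% two-sided
rejection band around α = 0.05; short bouts are avoided there because
with-replacement null draws then frequently hit overlapping windows, whose
correlation inflates null variance and makes the test visibly conservative —
at study-scale bout lengths the effect is negligible. Power/recovery uses 100
datasets with 0.3-body-height pulses (detection in ≥ 90%, recovered mean
Δ_mean within 3 Monte-Carlo SE of the closed-form expectation). The
window-sweep check injects an owner-only effect and expects owner significance
at every post size 4–50 with chance-level (≤ 10% of rows) subordinate
significance — a calibrated test cannot be expected to show literally zero
false positives across 47 correlated cells — plus the dilution signature of a
3-frame pulse (observed Δ shrinking roughly as 1/w). Exact-equivalence tests
(RD, Δ, eligibility, exhaustive null, exhaustive permutation) compare against
naive-loop reference implementations at 1e−12 tolerance.

## Numerical choices and degenerate inputs

Quantiles use numpy's default (linear interpolation). Significance flags use
the [2.5%, 97.5%] band; p-values use the add-one estimator — the two agree up
to the discreteness of B. Δ on a window where RD is constant is exactly 0 (no
catastrophic cancellation at these magnitudes). Zero mean body height raises a
degenerate-geometry error; empty status groups, all-males-excluded groups, an
empty null and single-male leave-one-out raise typed errors rather than
returning NaN. Events at the same start frame are all evaluated; exhaustive
enumeration aborts above a configurable combination limit. CSV interchange is
comma-separated, dot-decimal, UTF-8 with required headers; coordinates
round-trip at full printed precision.

## Known limitations

Only 2-D, beak-based kinematics: no angular or postural features, no courter
movement. The intensity-class mapping ships as a replaceable data table; the
sequence analysis that produced it is out of scope. The GLMM path depends on
an external R installation and is minimally validated (contract-level smoke
test). The bootstrap is slightly conservative for very short bouts (see
above); report bout lengths with results.
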