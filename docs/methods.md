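# Methods

## Behavioral-state model

The pipeline treats foraging behavior as a two-state process observed at
interval resolution. Tracked centroid positions (micrometres, arbitrary
plate frame) are reduced to two per-frame features:

- **Speed** — Euclidean displacement between consecutive frames divided by
  the elapsed time, assigned to the leading frame of each pair. The
  leading-frame convention keeps interval assignment causal (the speed
  sample at frame *i* describes motion that starts at frame *i*); any
  consistent convention would do. `time_s` is authoritative and
  `frame_index` is bookkeeping, because dropped frames are routine in
  tracking and elapsed time, not frame count, is what normalises a
  displacement.
- **Midpoint bending angle** — with M the skeleton point nearest 50% of
  arc length and A, P the points nearest 25% and 75%, the angle is
  180° − ∠(A−M, P−M). A straight (collinear) worm scores 0°, a worm folded
  fully back scores 180°, so dwelling (high curvature) scores high. The
  25%/75% reference points are a concrete scale-free choice; trackers do
  not publish their exact formula, and when an export already carries a
  `bend_deg` column it is passed through untouched rather than recomputed.

Both features are averaged over fixed windows (default `interval_s = 10` s,
the assay's plotting resolution). A frame at time *t* belongs to interval
⌊(*t* − *t*₀)/10 s⌋. Intervals holding fewer than
`min_interval_coverage × interval_s × frame_rate` frames (default 50% of
the nominal 37.5 frames) are dropped: a half-empty window's mean is too
noisy to classify, but demanding completeness would discard data around
every tracking gap. Frames with degenerate skeleton geometry (coincident
reference points) are excluded from the bend mean and logged.

## Cutoff placement and classification

Classification draws a horizontal line on the speed-vs-bending-angle
plane: intervals with mean speed strictly above the cutoff are roaming,
the rest dwelling (ties go to dwelling — the line itself is not "above"
the line). The cutoff is placed from the **control condition** of each
experiment: a Gaussian KDE (SciPy's Scott-bandwidth default) is fitted to
the control interval speeds, and the cutoff is the density minimum between
the two highest modes, clipped into `cutoff_bounds_um_s = [7, 12]` µm/s —
the band within which this assay's cutoffs fall. With fewer than 50
control intervals, or a unimodal density, the midpoint 9.5 µm/s is used
and logged. The valley criterion is this package's operationalisation of
"place the line from the control distribution"; the clip bounds guarantee
it never strays outside the assay's established range, and the
monotonicity property (raising the cutoff never increases fraction
roaming) is tested.

Fraction of time roaming is the per-animal proportion of retained
intervals labelled roaming; it and the dwelling fraction sum to exactly 1.

## Bouts

State bouts are maximal same-label runs with
`n_intervals ≥ min_bout_intervals` (default 6, i.e. *strictly longer than
five* 10-s intervals — the literal reading of "longer than 50 s" at this
granularity; the exactly-five case is ambiguous in the assay description,
so the threshold is configurable). Shorter runs are excluded from bout
statistics but still count toward fraction roaming. Bout duration is
`n_intervals × interval_s`; total bout time therefore never exceeds total
retained interval time.

## ROUT outlier filtering

Per-animal fraction-roaming values within a genotype/condition group are
filtered with a univariate ROUT-style test at Q = 1%: residuals are taken
from the sample median; the robust scale (RSDR) is the 68.27th percentile
of the absolute residuals times n/(n−1); at most ⌊0.3 n⌋ candidates,
scanned from the most extreme, are tested with a step-down rule flagging
rank *i* when the two-tailed t-probability (n−1 df) of its scaled residual
is below Q·(n−i+1)/n; all points up to the last flagged rank are removed.
A sample whose residuals are all zero passes through untouched. One edge
case the published procedure leaves open — RSDR = 0 while extreme points
exist (more than ~68% of values exactly at the median) — uses the smallest
positive absolute residual as the scale, so the extremes remain testable
instead of dividing by zero. Which quantity the filter applies to is an
analysis choice; fraction roaming per animal is the default here and the
filter is exposed for any univariate sample.

Error control is verified empirically: on standard-normal samples
(n = 50), the mean flagged fraction stays ≤ 2%, while a single injected
point at 10 robust SDs is caught in ≥ 99% of replicates.

## Exploration assay

The score is the number of distinct grid squares (side `grid_mm = 3.5` mm)
containing any point of the track. Cells are half-open (a point on a
boundary belongs to the higher-index cell) so they partition the plane.
Between frames the path is assumed straight — at 3.75 Hz the inter-frame
step is small relative to a 3.5 mm cell — and each segment is split at
every gridline crossing; the cell of each sub-segment is read off its
midpoint. This is exact (no rasterisation error) and is tested against a
dense 1-µm resampling oracle. The grid origin defaults to the coordinate
origin, since the physical grid's placement on the plate is arbitrary; an
origin-offset option supports sensitivity sweeps. Only the centroid track
is scored — squares merely touched by the worm's body width, which a
manual count might include, are not.

## Fluorescence quantification

Per-animal reporter expression is the **maximum** pixel intensity within a
circular ROI over the neuron (default radius 5 px for synthetic images;
manual ROIs supported to mirror the original workflow). No background
subtraction is applied by default, matching raw-maximum reporting; a
rolling-minimum flattening flag exists. Automatic ROI placement smooths
with a Gaussian (σ = 2 px) and picks the brightest well-separated local
maxima; identity assignment beyond ranked brightness is out of scope.

Condition effects are reported as the **ratio of group means** of the
per-animal maxima (the aggregation behind printed fold-changes is not
stated anywhere authoritative; mean-of-groups is the convention adopted
here, and reciprocal ratios multiply to 1). The reference fold changes
exercised throughout — 8.1 for wild type and 1.7 for the *scd-2*
gain-of-function mutant, non-ingestible over ingestible food — are used
as *generating* truth for synthetic tables; tests check that the estimator
recovers them within 15% at n = 30/group and lognormal σ = 0.2.

## Synthetic-data generator

The trajectory generator is a test fixture with ground truth, not a
mechanistic model of the ingestion → *daf-7* → roaming feedback loop (no
equations exist for that loop). It emulates exactly the structure the
analysis assumes:

- a two-state Markov chain over 10-s intervals, started from its
  stationary distribution (`p_dr`, `p_rd` per-interval transition
  probabilities; stationary roaming occupancy p_dr/(p_dr+p_rd));
- state-conditional lognormal speeds — roaming median 25 µm/s (log-SD
  0.3), dwelling median 2 µm/s (log-SD 0.4). The medians bracket the
  7–12 µm/s cutoff band with a wide margin, the qualitative ordering
  (roaming fast, dwelling slow) being the only constraint the biology
  fixes; the specific values are this package's choice of a
  well-separated regime;
- state-conditional truncated-normal bending angles on [0, 180]° —
  roaming 10 ± 5°, dwelling 45 ± 15° (roaming straight, dwelling curved);
- a persistent-random-walk heading (turn SD = (1 − persistence)·π rad per
  frame, persistence 0.9) with specular reflection at a circular arena of
  radius 30 mm (the 6 cm ring used in the tracker assay), sampled at
  3.75 frames/s.

Switching at interval granularity aligns the ground-truth labels with the
analysis grid, so label-recovery accuracy is meaningful frame-for-frame.
One integer seed drives all randomness; identical seeds give bit-identical
outputs, and cohort members get child seeds derived from the cohort seed.

**What the generator does not emulate** — and what passing tests therefore
do not demonstrate about real data: within-interval state changes (real
worms switch asynchronously to any 10-s grid), gradual speed ramps at
state transitions, tracking artifacts (dropped frames, centroid jitter,
skeleton head/tail flips), lawn-edge behavior, and between-animal
parameter heterogeneity. In particular, near-perfect label recovery on
synthetic data reflects the generator's well-separated emission regime;
real speed distributions overlap near the cutoff, and classification
accuracy there is unknowable without annotated video. The persistent
random walk also under-disperses relative to real roaming worms, so
synthetic exploration counts are small compared to counts from real 2-h
assays; the exploration score is validated by its exact geometry oracle,
not by matching empirical count magnitudes.

## Statistics

Group comparisons use the unpaired two-tailed t-test, Student's
pooled-variance form by default (df = n_a + n_b − 2) because the named
test's conventional default is pooled variance; Welch's form is available
behind a flag. Two constant groups with equal means return t = 0, p = 1;
with unequal means the statistic is undefined and an error is raised.
Reports carry the significance markers `*`, `**`, `***`, `****` for
p < 0.05, 0.01, 0.001, 0.0001.

## Problem sizes and reproducibility

The default test and acceptance runs use 10⁴-interval recordings
(≈ 27.8 h simulated at 3.75 Hz) for parameter recovery, 1000 replicates
of n = 50 for ROUT error control, 500 replicates for fold-change
coverage, and 100-trajectory batches for the geometry oracles — sizes at
which the binomial/Monte-Carlo tolerances quoted above are comfortably
resolved. `scripts/acceptance.py --seed N --out f.json` regenerates
everything from the seed; all randomness flows through
`numpy.random.default_rng` children of that seed.

## Known limitations

- The bending-angle formula is a reconstruction; trackers may report the
  interior rather than the supplementary angle, which would flip the
  high/low convention. The classification cutoff acts only on speed, so
  state labels are unaffected, but bend summaries should be compared with
  a specific tracker's output before mixing data sources.
- The ROUT adaptation is univariate (no regression component), suitable
  for the per-animal scalar summaries used here.
- Cutoff placement is algorithmic; assays that placed cutoffs manually
  per experiment may differ within the [7, 12] band. All downstream
  quantities are monotone or stable in the cutoff within that band, and
  the bounds themselves are configurable.
- Fluorescence ROI detection assumes spot-like, well-separated cell
  bodies in a single channel; 3-D stacks and colocalisation are out of
  scope.
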