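# Methods

## The analysis problem

Small shoals of fish (here: groups of four, individually identifiable,
swimming in an annular channel filmed at 25 fps) are tracked to per-frame
(x, y) coordinates.  The scientific questions are (i) whether a
between-group factor — social familiarity of the group members — changes
the expression of collective motion, and (ii) how pairwise alignment is
structured in speed, distance and relative position.  shoalkit implements
the full chain from raw trajectories to those answers, plus a synthetic
generator so the chain can be exercised and validated without any tracked
video.

## Response variables

Per trial and per sampling window:

- **Mean polarization** (group level).  Per frame,
  `P = ||Σᵢ hᵢ|| / m` where `hᵢ` are the `m` valid unit headings — the
  standard order parameter of collective motion, bounded [0, 1].  Frames
  with fewer than two valid headings are skipped, not zero-filled; the
  response is the arithmetic mean over usable frames.  For n = 4
  independent uniformly random headings E[P] ≈ 0.45, which is the
  "unaligned" reference point for 4-fish groups (not 0: the resultant of
  finitely many random vectors has positive expected length).
- **Median speed** per fish (mm/s).  The median, not the mean, because
  instantaneous speed distributions are positively skewed.
- **Mean nearest-neighbour distance** per fish (mm), averaged over frames
  where the fish and at least one other fish have valid fixes, so
  occlusion gaps do not bias cohesion estimates.

Kinematics come from central differences
(`v_k = (p_{k+1} − p_{k−1})·fps/2`, one-sided at the ends).  On a circular
path of angular rate ω this underestimates the arc speed by exactly
`sin(ωΔt)/(ωΔt)` — about 0.1% for realistic turning at 25 fps, and the
closed form is used as a test oracle.  Headings are only accepted when
speed ≥ `min_heading_speed` (default 1 mm/s): headings of a near-
stationary fish are tracking jitter and would corrupt polarization.  No
smoothing is applied by default (an optional moving average exists but
everything downstream assumes raw positions).

## Pairwise and focal-frame surfaces

For every unordered pair and frame where both headings are valid:
directional correlation `r = h_a · h_b = cos Δθ ∈ [−1, 1]`, mutual speed
`(s_a + s_b)/2`, and pair distance.  Observations are averaged on a
half-open speed × distance grid (defaults 0–200 mm/s and 0–200 mm in
10-unit steps); observations outside the grid are counted in an overflow
tally so that `Σ count + overflow = N` always holds, and cells with fewer
than `min_count` (default 10) observations are reported as undefined
rather than as noise.

For the focal-frame map every fish serves as focal in turn (ordered
pairs, pooled over fish, frames and trials of a treatment × period): the
world is translated so the focal fish is at the origin and rotated by the
negative of its heading angle, so the focal fish travels along +x.
Partner positions are binned on a −100..100 mm grid (10 mm cells) and per
cell we report the circular mean of the heading differences Δθ (wrapped
to (−π, π]) and their mean resultant length R.  By construction, R of a
cell equals the polarization operator applied to that cell's Δθ values as
unit headings; this cross-module identity is asserted to 1e−12 in the
tests, as is invariance of the entire map under a global rotation of the
arena coordinates.

## Repeated-measures inference

The design is a split-plot: familiarity (familiar/unfamiliar) varies
between groups, sampling period (on release vs after 30 min) within
groups.  Models are linear mixed models fitted by REML via statsmodels:

- group response (mean polarization): random intercept per group;
- individual responses (natural-log median speed, natural-log mean NND):
  random intercepts for group and for fish nested within group.

Fixed effects are coded familiarity = 1(familiar), time = 1(period 2),
plus their interaction, so the familiarity estimate is the
familiar-minus-unfamiliar difference in the first period.

t statistics use **containment degrees of freedom**,
`df_level = m_level − (m_parent + p_level)`: a term constant within
groups is tested against the number of groups, a within-subject term
against the observation level.  For the standard design (12 groups, 4
fish each, 2 periods) this gives df = 10 for familiarity and df = 10
(group model) / 46 (individual models) for the within terms.  The
implementation is cross-validated in the test suite against R's
`nlme::lme` (REML, same df convention) on identically structured data;
estimates, standard errors, t, df and p agree to numerical precision.
Because variance components can sit on the zero boundary, the REML
criterion is optimised with both L-BFGS and Powell and the better
restricted likelihood is kept; L-BFGS alone can stall short of a boundary
optimum.

Confidence intervals are reported on the fitted (transformed) scale
only; no back-transformation of CI endpoints is attempted.

Diagnostics: Shapiro–Wilk per design cell, median-centred Levene across
cells, and Q–Q data exports.  Degenerate (constant) cells are flagged
rather than fatal; Levene is skipped when fewer than two cells exist.

Multiple testing: the nine per-term tests (three terms × three
responses) form one family and are corrected with the Benjamini–Hochberg
step-up procedure at q = 0.05 (sort ascending, find the largest k with
`p_(k) ≤ k·q/m`, reject the k smallest).  The significance set is always
a prefix of the sorted p-values and is monotone in each p-value; both
properties are tested, along with agreement with
`statsmodels.stats.multitest.multipletests`.

## Synthetic shoal generator

The generator emulates the study system: four fish in an annulus of
inner radius 135 mm and outer radius 330 mm (195 mm channel), 25 fps,
5-minute windows.  Agents are kinematic: per step each fish forms a
desired direction as the normalised sum of alignment (weight × mean
neighbour heading within `interaction_range`), attraction (weight × unit
vector to the neighbour centroid) and a wall term (inward/outward normal
ramping linearly within 20 mm of either wall), turns toward it by
`turn_rate` of the angular difference, receives wrapped-normal heading
noise, and advances by a lognormal step; wall crossings reflect the
position radially and flip the radial heading component.  Fixes are
deleted at `gap_rate` per frame to mimic occlusions.  Runs are
bit-reproducible from the seed; per-trial streams are spawned from the
master seed via `numpy.random.SeedSequence`.

Defaults (chosen once, during design, to place default runs in an
empirically sensible regime): alignment 0.5, attraction 0.5, wall 1.0,
heading noise 0.7 rad/step, lognormal speed with median 60 mm/s and
log-sd 0.45 (guppies of 28–38 mm body length cruise at roughly 1–3 body
lengths per second, and the lognormal reproduces the positive skew of
real speed distributions), interaction range 200 mm (the whole channel
width — in a 4-fish group everyone is a neighbour), gap rate 0.005.
Under these defaults mean polarization sits near 0.78 (unfamiliar
baseline), and the study emulation injects +1.0 alignment weight for
familiar groups, lifting polarization by ≈ 0.065 — the same order as
effects reported for real familiar shoals.  Period 2 is generated with
alignment × 0.8 and speed median × 0.85, mimicking habituation-related
slowing and loosening.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data:

- **Cohesion scale.**  The constant-magnitude attraction term has no
  short-range repulsion, so simulated shoals are tighter (mean NND
  ~5–10 mm) than real guppy shoals (~1 body length).  All analysis
  operators are scale-agnostic, and no test calibrates against an
  absolute NND, but absolute distances in simulated Fig-2/Fig-3-style
  surfaces are compressed relative to real data.
- **Period heteroscedasticity.**  The period-2 parameter shifts lower
  alignment, which *raises* the between-group variance of mean
  polarization in period 2.  The homoscedastic mixed model pools the two
  periods' variances, which makes the familiarity test mildly
  conservative (measured Type-I ≈ 2.6% at nominal 5%) when the period
  shifts are active.  Under the full null — all effect injection off —
  the test is calibrated (measured 4.4%, and 5.3% for the fitter on
  ideal normal split-plot data).  Real data may violate homoscedasticity
  in the same direction; Levene's test in the diagnostics is the check.
- No body shape, vision cones, hydrodynamics, or identity-swap errors;
  tracking gaps are independent Bernoulli deletions rather than
  occlusion bursts.

## Problem sizes used in validation

Replicate experiments (parameter recovery, 200 replicates; Type-I
calibration, 1000 replicates) simulate 15-second segments (375 frames)
per trial rather than full 5-minute windows; segment length only scales
the per-trial measurement noise, which the mixed model absorbs, and the
recovery check calibrates its own expected effect from 200 independent
segments per arm at the same length.  Single-trial checks use 30–120 s.
The end-to-end pipeline writes full 5-minute windows when run with
defaults.

## Numerical conventions

- Angles wrapped to (−π, π], with −π mapped to +π.
- Binning is half-open `[lo, hi)`; values equal to the outermost edge
  are overflow, so counts are conserved exactly.
- Gap interpolation is linear, only for interior runs of ≤ `max_gap`
  frames (default 5 = 0.2 s); runs touching the trial ends stay masked;
  the operation never alters a measured fix and is idempotent.
- Canonical trajectory CSVs store coordinates in mm with shortest
  round-trip float formatting; write → read is bit-exact.
- "<0.001" in published tables is encoded as 0.0005 when a number is
  required for the BH worked example; the outcome is insensitive to any
  encoding ≤ 0.001 (tested).
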