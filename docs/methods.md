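# Methods

## Problem and data model

`neomotion` quantifies how much a neonate moves from contactless pose
tracking. The input is a time series of 33 body landmarks per video frame
(the standard full-body pose-landmark convention: nose = 0 … right foot
index = 32), each landmark an `(x, y, z)` tuple with `x, y` normalized to
[0, 1] relative to the image edges and `z` a signed relative depth
(negative = closer to the camera), plus a Unix-millisecond timestamp per
frame. Coordinates are kept dimensionless end to end; no pixel rescaling
happens anywhere in a metric path, because rescaling would silently change
every total.

The frame rate is derived as `1000 / median inter-frame gap` rather than
from the mean gap, so occasional dropped frames do not bias it. Rows whose
finite `x` or `y` falls outside [0, 1] are rejected by default (clamping is
available but fabricates motion, so it is opt-in); NaN coordinates mark a
landmark invalid in that frame, and any frame containing an invalid
landmark *within the analysed region* is dropped before quantification.
Transitions whose gap exceeds `gap_factor` (default 3) times the median gap
are excluded from totals — a recording dropout would otherwise register as
one large spurious movement. The gap threshold uses the median gap of the
sequence being quantified; for regular recordings this makes windowed and
whole-sequence computations exactly consistent.

## Body regions

The nine analysis regions are fixed index sets over the 33 landmarks
(config-overridable via a JSON `{region: [indices]}` file):

| region | indices |
|---|---|
| whole_body | 0–32 |
| head | 0–10 |
| left_arm / right_arm | 11,13,15,17,19,21 / 12,14,16,18,20,22 |
| trunk | 11,12,23,24 (shoulder–hip quadrilateral) |
| left_leg / right_leg | 23,25,27,29,31 / 24,26,28,30,32 |
| upper_body / lower_body | 0–22 / 23–32 |

Upper and lower body partition the whole body at the waist. The hips
(23, 24) belong to both the trunk and the legs: the trunk is defined as the
shoulder–hip quadrilateral because a hip-less "trunk" of two shoulder
points would carry almost no postural information.

## The nine quantifiers

Every quantifier accumulates a per-step measure over all frame transitions
and all landmarks of the selected region ("cumulative motion difference").

**Distance metrics** (per landmark, per transition, on the displacement
`D = P_{i+1} − P_i`): Euclidean `|D|₂`, Manhattan `|D|₁`, Chebyshev
`|D|∞`, Minkowski `|D|_p` with default `p = 3` (p = 1 and p = 2 reduce
exactly to Manhattan and Euclidean; large p approaches Chebyshev; p was
chosen > 2 so that the metric is genuinely distinct from the other three,
and it is configurable), and Mahalanobis `sqrt(Dᵀ S⁻¹ D)`.

The Mahalanobis covariance `S` is estimated from all `(x, y, z)` samples
pooled over the frames and landmarks of the analysis window, so windows are
self-contained (usable in streaming). When the condition number of `S`
exceeds 1e8 a diagonal ridge `1e-9 · trace(S)/3` is added (escalated
tenfold until the Cholesky factorization succeeds); a window with no real
motion (trace at rounding-noise level) falls back to an identity
covariance, flagged `degenerate`, which makes the metric coincide with the
Euclidean one. Distances are evaluated through the Cholesky factor, never
an explicit inverse.

**Differential acceleration**: per interior frame, velocity differences
`(P_{i+1} − 2 P_i + P_{i−1}) · fps`, absolute values summed over
dimensions and landmarks. Zero for uniform linear motion.

**Angular displacement**: the turning angle between successive displacement
vectors `a = P_i − P_{i−1}` and `b = P_{i+1} − P_i`,
`θ = arccos(a·b / |a||b|)` with the cosine argument clamped to [−1, 1];
a zero-length segment contributes zero angle. Using successive
displacements (rather than position vectors from the image origin) makes θ
translation-invariant, i.e. independent of camera framing. Totals are
radians summed.

**Lucas–Kanade (landmark form)**: per landmark and interior frame, the
central-difference gradient row `g = (P_{i+1} − P_{i−1})/2` and temporal
difference `b = P_{i+1} − P_i` form the system `A v = b` with `A` stacking
`g` once per dimension of the three-frame stencil; the system is solved by
pseudoinverse, giving `‖v‖ = |Σ_d b_d| / (3|g|)` and exactly 0 when
`g = 0`. The assembly for a single tracked point is genuinely
underdetermined in the classical formulation; this stacking is the minimal
reading that keeps the estimator defined, and it is documented here
precisely so that the oracle tests are well-posed. Stencils with `g = 0`
but `b ≠ 0` are flagged ill-conditioned, never raised.

**Farnebäck (dense flow on rasterized frames)**: each frame is drawn as a
grayscale image — landmarks as filled circles (default 256×256 px, radius
3, intensity 255 on black; x→column, y→row; `z` is *not* rendered, a
documented limitation) — and dense optical flow is estimated between
consecutive images with a polynomial-expansion estimator implemented in
this package (separable Gaussian-weighted quadratic fits per pixel,
displacement from the transformation of the local polynomials, box-window
averaging of the normal equations, iterative refinement over an image
pyramid; defaults pyramid scale 0.5, 3 levels, window 15, 3 iterations,
poly_n 5, poly_sigma 1.2). The per-transition contribution is the sum over
pixels of the flow-vector magnitude, so flow totals are in pixel units and
scale with the render resolution; they are only comparable at a fixed
render configuration. For the single-level, single-iteration configuration
a batched code path (single-precision, block-processed) computes identical
results ~50× faster; the equality of the two paths is asserted in tests.
Landmark centers are rounded to integer pixels when stamping, so sub-pixel
motion below the rounding scale produces zero flow for that transition —
consistent with the known insensitivity/instability of pixel-based flow on
very small displacements.

## Windowing and summaries

Recordings are segmented by timestamp (not frame count, since frame rate
varies across recordings) into consecutive half-open windows
`[t0 + kL, t0 + (k+1)L)` of exactly L seconds; the trailing partial window
is discarded (a partial window would bias totals downward and break the
duration-proportionality analyses). Cross-boundary transitions are counted
in neither window, keeping windows independent. Default intervals are 30,
60, 120 and 180 s.

Each (subject, interval, region, method) combination is persisted as one
JSON summary: the list of per-window totals plus min / max / mean / median
and the **population** standard deviation (the descriptive "spread of the
values list"; the sample SD or the SEM would be defensible alternatives,
but the summaries are descriptive, not inferential, so the population SD
is used throughout — also in the CV). With the default grid, a ten-subject
cohort yields 10·4·9·9 = 3240 files.

For the bulk emitter, per-step contributions are computed once per
(subject, region, method) and re-summed per interval — exactly equal to
per-window recomputation for every method except Mahalanobis, which is
re-fitted per window because its covariance scope *is* the analysis
window; tests assert the equivalence.

## Cohort statistics

* **Percent change**: `100·(late − early)/early` on mean per-window totals
  of the same subject/region/method/interval; which sessions count as
  "near admission" and "near discharge" is an explicit input (the pairing
  is by session label), not inferred from dates. Zero-baseline records are
  flagged undefined and excluded from cohort means. Changes are computed
  per subject and then averaged across subjects, not pooled.
* **Cohort table**: methods × 9 regions of cohort-mean percent changes,
  an Average column over the eight non-whole-body regions, and a CV
  column `100·σ/μ`. The population over which a single "CV per method"
  should be computed is genuinely ambiguous; the default policy uses the
  per-subject whole-body percent changes, with `regions` and
  `subjects_all` selectable. No test pins CV values to external numbers.
* **Region similarity**: `100·|region − whole_body|/whole_body` on
  cohort-mean values (the similarity heatmap is a cohort-level view, so
  per-subject similarity is out of scope), with a strict `< 10%` threshold
  marking a region an acceptable whole-body proxy.
* **Interval proportionality**: mean per-window totals per interval
  divided by the 30 s baseline; for stationary motion these sit near
  2 / 4 / 6 for 60 / 120 / 180 s.
* **Timing profile**: median wall time per (method, region) over ≥ 3
  repeats, reported but never asserted — timings are host-dependent.

## Synthetic motion generator

Each landmark follows `base pose + amplitude · (sinusoid + random-walk
jitter)`, where the amplitude is per fine region (head, arms, trunk+hips,
legs), the sinusoid (default 0.25 Hz, amplitude 0.005, random phase per
landmark and dimension) provides a smooth periodic component, and the
jitter is a Gaussian **random walk** (default step SD 0.002 per frame at
10 fps over 185 s). The walk — rather than i.i.d. noise around the base
pose — is what makes expected path length grow linearly with observation
time, the stationarity property behind the interval-proportionality
analyses. The base pose is a fixed table of 33 plausible supine-infant
coordinates; its exact values are arbitrary and only its anatomical layout
matters. Coordinates are clipped to [0, 1] with clip events counted;
profiles used in tests are scaled so that clipping is negligible (long
random walks drift, so long-duration test profiles use proportionally
smaller jitter — e.g. 2e-4 for the 9030 s proportionality run).

Cohorts pair an "admission" and a "discharge" sequence per subject; a
per-subject lognormal amplitude effect (σ = 0.2 on the log scale) models
between-infant activity differences while leaving each subject's
early-to-late amplitude ratio at the profile-specified value, so a cohort
generated with ratio r has expected mean percent change `100·(r − 1)`.
An occlusion operator marks a region's landmarks NaN in a chosen fraction
of frames, emulating blanket coverage.

What the generator does **not** emulate: pose-estimator noise structure
(landmark-confidence-dependent error, identity swaps), biomechanical
coupling between joints, caregiving interruptions, or activity-state
changes. Passing tests therefore demonstrate the correctness of the
computational pipeline and its statistical behavior under stationary
conditions, not clinical validity on real recordings.

## Problem sizes for desk-scale runs

The default generated recording is 185 s at 10 fps (1851 frames), giving
6 / 3 / 1 / 1 windows at 30 / 60 / 120 / 180 s. The full combinatorial run
(10 subjects × 4 × 9 × 9) uses a reduced flow configuration (64 px render,
single level, single iteration) — the file-count and schema results do not
depend on flow resolution, and the reduced configuration keeps the run in
the minutes range on one core. Proportionality uses one 9030 s recording
(≥ 50 windows at 180 s); parameter recovery uses 4 subjects × 3030 s
sessions (≥ 100 windows per session).

## Known limitations

* The flow quantifier ignores `z` and sub-pixel motion; its totals are
  resolution-dependent. This mirrors the instability that makes flow-based
  quantifiers poor candidates for neonatal monitoring in the first place.
* The landmark Lucas–Kanade assembly is one defensible reading of an
  underdetermined formulation; alternative assemblies would change its
  scale (but not its zero set or ordering behavior under uniform motion).
* Published per-method CV values cannot be reproduced from the shipped
  cohort table alone (their computation population is not recoverable),
  so the package reports CVs only under its own documented policies.
* Windows shorter than 2 frames are dropped silently (logged); heavily
  occluded regions can therefore yield summaries with fewer windows than
  the nominal count.
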