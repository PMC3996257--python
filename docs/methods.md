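# Methods

## Measurement model

All geometry lives in a μm-scale plane with the foveola at the origin,
+y superior, and nasal = +x for right eyes (OD), −x for left eyes (OS).
The modified ETDRS grid is the 1 / 3 / 6 mm ring set with five
subfields: the central 1 mm disc and four quadrants bounded by the ±45°
diagonals (points exactly on a diagonal go to the vertical quadrant; the
3 mm ring is carried in the grid type but creates no subfield boundary).
Laterality only relabels the horizontal quadrants.

**VLA.** Candidate vessels are root-to-periphery centerline chains. Each
chain is clipped to the 0.5–3 mm annulus with exact circle–segment
intersections (every re-entry counted), assigned to the quadrant of its
clipped portion's arc-length midpoint, and kept only if *radial*: the
length-weighted mean angle between the local tangent and the local
outward fovea→point direction is ≤ 30° (default, configurable). Using
the signed outward angle rather than a line angle means a chain that
leaves the annulus and doubles back scores near 180° and is excluded —
only fovea-directed courses count. Per quadrant the five longest clipped
chains are averaged (policy `top5`, a deterministic stand-in for a
human picking "recognizable" vessels; `all-radial` is available); fewer
than three radial candidates flags the quadrant missing rather than
reporting a mean of one or two vessels.

**FBL.** Branch points are graph nodes of degree 3 inside the 6 mm disc
but outside the central subfield, ordered by foveola distance (ties by
counterclockwise angle from the temporal axis). FBL is the sum of the
straight-line (not along-vessel) foveola distances of the five nearest
points in the superior or inferior quadrant. The pre-operative visit
selects the five points; the post-operative value re-measures the *same*
points through a cross-visit correspondence — stable labels on synthetic
trees, mutual nearest neighbours within 300 μm on registered images. If
any selected point has no partner, the pair is flagged missing; missing
values propagate through every downstream delta and test.

**Deltas.** ΔVLA = pre − post (per quadrant and summed), ΔFBL = post −
pre, ΔMT/ΔCMT = pre − post, ΔBCVA = pre − post, so every delta is
positive when surgery improves the eye. Deltas are computed on access
from the stored pre/post values and can never drift out of sync.

## Statistics

Paired pre/post comparisons use the Wilcoxon signed-rank test with the
classic zero-handling rule (zero differences dropped before ranking;
Pratt handling available). For effective n ≤ 25 the two-sided p is
exact: the null distribution of the positive-rank sum W+ over all 2^n
sign assignments is built by dynamic programming in doubled-integer
arithmetic (average ranks are half-integers), and p is the null mass of
deviations |W+ − T/2| at least as large as observed. This equals full
enumeration to machine precision while costing O(n·T) rather than 2^n.
Beyond n = 25 a tie-corrected normal approximation with continuity
correction is used; the study-sized n = 16 cohort always takes the exact
path. Spearman's rho uses average ranks; its two-sided p is exact by
full permutation enumeration for n ≤ 9 and a t approximation otherwise.
Quartiles are linear-interpolation quantiles (pinned, because packages
differ). No multiple-testing correction is applied, matching the
analysis plan this reproduces.

## Synthetic study generator

The generator is the study's data source, not a test fixture; its
defaults are the study conditions.

**Vasculature.** `arcades` (default 8) trunks leave the perifovea
(r ≈ 330–430 μm) on evenly spaced bearings offset from the quadrant
diagonals, march past the 6 mm ring (r ≈ 3400–3900 μm) as perturbed rays
(sinusoidal wobble, 15–35 μm amplitude), and carry `branch_depth`
(default 3) side branches at radii ≈ 700–2750 μm; side branches diverge
by 18–30° and relax exponentially back to a radial course, and carry one
grandchild each at depth 3. Calibers: 50 μm trunks decaying by 0.8 per
generation — macular arteriole/venule scale. This yields ≥ 5 branch
points per vertical quadrant (required for FBL) and 3+ radial VLA
candidates everywhere; generation retries a bounded number of times and
raises if the requested geometry is unsatisfiable (e.g. depth 1).

**Contraction.** The pre-operative state applies a smooth point map:
inward radial displacement `amplitude · r · exp(−r²/(2·sigma_r²))`
(zero at the foveola, vanishing far away; `sigma_r` = 1500 μm), times an
anchoring envelope that is exactly zero at the optic disc (4.5 mm nasal)
and ramps to `nasal_attenuation` (default 0.3) across a 150 μm band at
the vertical midline — blended smoothly so vessels crossing the midline
do not tear. Wrinkling is a tangential sinusoid phased on radius
(amplitude `wrinkle_amp_um`, frequency 3 cycles/mm, faded out at the
foveola and disc). Phasing the wrinkle on radius rather than per-edge
arc length makes the map a single well-defined point map, so shared
branch nodes and their incident polylines deform consistently; for
radial vessels radius ≈ arc length, so the intended
perpendicular-to-the-vessel wrinkle is preserved. Amplitude ≤ 0.5 with
this envelope keeps the radial map monotone (no fold-through). The
post-operative state is the identity — surgery releases all traction;
residual traction can be modelled by contracting the post visit with a
smaller amplitude. In cohorts, `wrinkle_amp_um = 170 · amplitude`, so a
strongly contracted eye is also strongly wrinkled.

These two ingredients produce both clinical signatures: wrinkles add
annulus arc length (VLA higher pre-operatively, ΔVLA > 0) and the inward
pull shortens branch-point distances (FBL lower pre-operatively,
ΔFBL > 0), with both effects attenuated nasally.

**Thickness and acuity.** Each subfield's pre-operative thickness is
baseline (N(290, 25²) μm) plus `mt_slope` (0.55) times the subfield's
mechanical dose plus N(0, 10²) noise; post-operative is baseline plus
noise. The dose is the mean displacement magnitude of the contraction
field over the subfield; for the central subfield it is taken over the
r ≤ 750 μm perifoveal margin, because displacement vanishes at the
foveola by symmetry while central thickening physically comes from the
surrounding tissue drawn inward. BCVA (logMAR): post ~ N(0.08, 0.05²),
pre = post + 1.3·amplitude + N(0, 0.05²), clipped to plausible ranges —
means match a typical surgical ERM cohort. Cohorts draw amplitudes
uniformly from (0.05, 0.3) and alternate OD/OS.

**Rendering.** Vessels are dark bands (depth 92 gray levels, soft
1.2 px edges) built from a distance transform of the rasterised
centerlines, on a ~178-gray background with a gentle illumination
gradient and optional additive Gaussian noise (cohort default σ = 3).
Default raster 768×768 px at 11.7 μm/px (≈ 9 mm across, a plausible 30°
field); pairs are generated pre-registered, emulating tracked follow-up
imaging. Everything is deterministic given seeds; no hidden global
randomness.

**What the generator does not emulate:** choroidal and nerve-fibre
texture, the optic disc itself (only its anchoring), vessel caliber
changes, pathology other than contraction, registration error between
visits, and media opacity. Passing tests therefore demonstrate that the
measurement machinery recovers known geometry under realistic vessel
layouts and noise — not that the extractor is robust to every property
of clinical infrared imagery.

## Vessel extraction

Manual tracing is replaced by a deterministic pipeline: multiscale
Frangi vesselness (scales 1.0/1.6/2.4 px, dark ridges, border margin
suppressed, gated by a grey-closing darkness map so bright-side filter
ringing never registers as vessel), threshold 0.15 of the map maximum,
removal of components below 30 px, topology-preserving skeletonization,
and conversion to a node/edge graph (branch ≥ 3 neighbours, end = 1,
adjacent node pixels merged at their centroid; crossings legitimately
create cycles). Spurs shorter than 100 μm are pruned iteratively.

Three repairs address systematic junction errors that would otherwise
bias FBL by 100–400 μm:

* **Gap bridging by dark tracing.** Where a daughter vessel has just
  separated from its parent the two bands merge and the ridge filter
  goes quiet, leaving the daughter's proximal stretch disconnected. Each
  dangling end is extended by greedy ridge-following on the darkness map
  until it meets another centerline, which is split there and joined.
* **Crossing collapse.** Junction pairs closer than 130 μm along a
  connecting edge are contracted: an artery/vein crossing often
  skeletonizes as two 3-way nodes, and the contracted 4-way node is then
  recognised as a crossing, not a branching. Degree-≥4 nodes and nodes
  on hugging parallel-edge cycles (doubled centerlines) are excluded
  from FBL candidates.
* **Junction relocation by side widths.** A skeleton bifurcation sits at
  the distal end of the band-overlap zone. Walking fovea-ward along the
  parent centerline, the dark band is one-sidedly widened by the
  adjacent daughter until the true junction, where both one-sided widths
  (probed perpendicular to the chain on the darkness map) return to the
  parent baseline; the node is relocated there (margin 1.0 px, walk
  ≤ 40 px).

VLA candidate chains are read from the graph per connected component,
from fovea-proximal vessel origins (end nodes within 700 μm of the
foveola) to every peripheral end, choosing for each end the origin with
the lowest cost of path length plus a turn penalty (2.5 μm/deg beyond
15° per junction) so chains do not switch vessels at crossings. Chains
are smoothed with a short moving average (window 5, endpoints fixed)
before length measurement, which removes 8-connected staircase
inflation.

Against the analytic polyline oracle on noiseless renders (20 seeds),
per-quadrant VLA agrees to ≤ 3.6 % (mean 0.3 %) and FBL to ≤ 1.9 %
(mean 0.7 %); through the noisy image pipeline, measured ΔVLA/ΔFBL
rank-correlate ≥ 0.94 with ground truth on 16-eye cohorts.

## Numerical and design choices

* Clipping uses closed-form quadratic circle–segment intersections;
  the ground-truth oracle deliberately uses dense 2 μm resampling (a
  different code path) so the two can check each other. Clipped plus
  unclipped pieces conserve total length to 1e-9 relative.
* Sub-seeds are derived with `numpy` seed sequences; every stage takes
  an explicit seed and extraction contains no randomness at all.
* Degenerate inputs fail loudly: zero-length paths, mis-labelled
  visits, invalid contraction parameters, rasters too small for the
  6 mm ring, unsatisfiable tree geometry.
* Problem sizes used by the shipped verification: 20 trees for the
  oracle-equivalence check, one 16-eye image-pipeline cohort for
  recovery, 50 simulated 16-eye cohorts (polyline measurement path) for
  the directional pattern of the paired tests — sizes chosen to give
  stable pass/fail behaviour at interactive runtimes.
* The three-observer repeated-measurement protocol of the clinical
  workflow is not modelled beyond an optional foveola-jitter re-run; it
  is off by default.

## Known limitations

* At contraction amplitudes near the top of the cohort range, heavy
  wrinkling can push a quadrant's vessels past the 30° radial tolerance
  and the quadrant is reported missing — arguably what a strict human
  rater would also do, but a divergence from raters who trace "through"
  the wrinkles.
* Junction localisation inside dense crossing tangles (three or more
  vessels within ~100 μm) is not refined; such nodes keep their skeleton
  position.
* Mutual-nearest-neighbour correspondence can fail for branch points
  displaced close to half the inter-point spacing; those FBL pairs are
  reported missing rather than guessed (about 1–3 eyes per simulated
  16-eye cohort at default settings).
* VLA candidate chains that share a trunk are not de-duplicated; the
  top-5 rule measures the five longest courses, which may overlap. The
  same rule is applied to ground truth and measurement, so comparisons
  are consistent.
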