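# Methods

## Patches and the local frame

A contour map is a binary raster; a patch is the 69 × 69 window centered
on a contour pixel (center at 0-based (34, 34)). Coordinates are
row-major with the row index increasing downward; tangent angles are
measured from the vertical and reduced mod 180°. Chains are maximal
8-connected pixel paths; at branch pixels tracing continues along the
straightest unvisited neighbor (smallest turning angle, ties broken by
lexicographic pixel order), which makes the decomposition deterministic
without lookahead.

The local frame at the center uses the 41 chain pixels spanning ±20 from
the center (closed chains wrap). Curvature ρ comes from an algebraic
(Kåsa) least-squares circle fit — robust to rasterization noise and
yielding a radius directly — with ρ = 1/R and the convex-side normal the
unit vector from the center toward the fitted circle center. For curved
contours the tangent is taken perpendicular to that radius, which is less
sensitive than a line fit to asymmetry of the chain window; for straight
contours (ρ < `rho_tol` = 1e-3 /px, the degenerate case) the tangent is
the principal axis of the window and the convex side defaults to the left
of the traversal direction. A chain that curves both ways inside the
window gets the single circle fit of the whole window; the inflection
ambiguity is inherent and noted rather than resolved.

## Cue indices

**Convexity** = ln(1 + |ρ|). The natural logarithm is a convention; only
monotonicity matters downstream. For the curvature ranges spanned by the
stimulus classes the index lies in [0, 0.258].

**Closure**: probes at ±5 px from the center along the convex normal; 16
rays per probe at 22.5° increments (full circle), the first ray along the
normal. A ray counts once if it intersects the unit cell of any contour
pixel — an exact slab test, with no marching step; because the patch
square is convex and all contour pixels lie inside it, clipping the ray
to the patch changes nothing. N_convex is the count from the probe
displaced *toward* the convex side: a contour closing around the convex
side encloses that probe, all 16 of its rays cross, and Closure is
positive — matching the convention that positive cues pull the figure
percept toward the convex side. Range −16…16, integers.

**Symmetry**: dos(θ, x) rotates the patch by θ about its center
(nearest-neighbor resampling via an explicit affine map), translates by x
columns, and counts contour pixels coinciding with their mirror image
about the central column — implemented equivalently as a mirror about
column 34 − x of the unshifted rotated image. By default the rotated
image is dilated by a 1-pixel disk before overlap to absorb rasterization
jitter (a flag disables dilation for exact-arithmetic checks). The count
is normalized by the pixel count of the same rotated-and-dilated image:
this keeps dos in [0, 1] with dos = 1 exactly at pixel-perfect mirror
symmetry. Normalizing instead by the pre-dilation contour length would
make the ceiling shape-dependent (the dilation thickens a straight line
by ×3.03 but a closed blob only by ×2.4), letting near-straight contours
outscore perfectly symmetric ones — which would break the defining
property that the corpus-maximum patch is the perfectly symmetric one.
For an untransformed, undilated patch the value is the plain
overlap-over-length ratio.

The optimal axis is an exhaustive grid search, θ ∈ {0, 1, …, 179}°,
x ∈ {−34, …, 34} px, ties broken by smallest θ then smallest x. The
Symmetry index is max dos divided by the largest max-dos in the working
corpus (computed over whatever corpus is being analyzed, so the index is
corpus-relative by design), signed negative iff the optimal axis's
in-patch extent on the convex side of the center — points classified by
the sign of their dot product with the convex normal — is strictly
shorter than on the concave side. "Side of the contour" is only locally
defined for a curved contour; the tangent-plane classification uses the
same local frame as the other two cues.

Nearest-neighbor rotation plus dilation leaves residual anisotropy: dos
of the same shape evaluated at axes of different orientation can differ
by up to ~20 % (grid-aligned axes score highest). Invariance tests
therefore use 90° rotations (exact for Closure, ~2 % for dos), and the
planted-axis recovery tolerance is one grid step.

## Stimulus stratification

Patches whose thinned contour has a pixel where ≥ 4 chain branches meet
(counted as connected runs of the 8-neighborhood ring, so T-junctions
with 3 branches pass) are excluded as X-junctions. The remaining patches
are binned: convexity with printed outer bins [0, 0.018) and
[0.222, 0.258] and three equal-width interior bins — equal width being
the simplest partition consistent with the printed edges; closure with
bins [−8, −6), [−6, −2), [−2, 2], (2, 6], (6, 8]; orientation with the
eight unequal printed intervals (0–15°, 15–30°, 30–60°, 60–90°, 90–120°,
120–150°, 150–165°, 165–180°, lower-inclusive). 5 × 5 × 8 = 200 classes;
one member is drawn uniformly per non-empty class under an explicit seed.
Two further screening heuristics (contour-density ceiling, large-enclosure
detection) stand in for judgments that are inherently human visual
inspection; they are documented, off by default, and claim no fidelity to
those judgments. Display stimuli are the binary patch weighted by a
Gaussian envelope, σ = 17 px, peak 1 at the center.

## Similarity analysis

Dissimilarity = 5 − mean rating over repetitions (linear and
order-preserving; nonmetric MDS uses only ranks, so the particular affine
map is immaterial). Nonmetric MDS minimizes stress iteratively (SMACOF)
from a classical-scaling start plus 9 random restarts by default,
returning the lowest-stress solution; stress is reported as Kruskal's
stress-1 (the square root of the normalized squared discrepancy between
configuration distances and their isotonic fit on the dissimilarity
order, ties left unconstrained — the primary approach). Topographic
configurations z-standardize each selected cue across the stimulus set:
Procrustes removes global scale but not per-axis anisotropy, so the axes
must be made commensurate. Each factor set is compared against a
perceptual configuration of its own dimensionality.

Procrustes alignment allows translation, rotation, reflection and uniform
scaling (reflections because MDS solutions are chiral-ambiguous); the
*Error* is the raw squared-sum of aligned point distances. The null
scrambles similarity by permuting stimulus labels of the dissimilarity
matrix — permuting independent cells would break symmetry and yield
invalid matrices — refits the MDS, and realigns; 100 null draws by
default. The normalized Error divides by the null mean (dividing by each
draw separately would only rescale the distribution); the p-value is a
one-sided one-sample t-test of the null distribution against the observed
Error, since the observed value is a single number per observer. Analyses
are per observer; group results are means over observers, compared across
factor sets by paired t-tests.

## Figure–ground analysis

An answer counts as convex-chosen iff its direction (right/left for the
vertical session group — contours within 45° of vertical — top/bottom for
the horizontal group) has positive dot product with the patch's convex
normal. Degenerate-frame (straight) patches are excluded with a logged
count. Rates are pooled across observers per patch for the headline
regression (a per-observer option exists). The regression is OLS of rate
on the three raw indices plus their three pairwise products — raw, not
standardized, so coefficients keep their natural scale, and a linear
probability model rather than a logistic link, keeping the analysis model
identical to the choice model it is usually read against (rates here stay
well inside (0, 1)).

## Synthetic data

The generators plant known ground truth: `generate_arc` rasterizes a
circular arc through the center with tangent at a stated orientation and
curvature exactly 1/radius (extent 360° gives closed circles for the
enclosure fixtures); `generate_blob` builds a closed radial-harmonic
contour touching the center, with cosine-only phases giving an exact
mirror axis — when the planted axis is vertical the pixel set is
explicitly symmetrized so the raster symmetry is exact; and
`generate_open_curve` grows a heading random walk from the center in both
directions (step 0.7 px) until it leaves the patch, emulating the single
open natural contours that dominate segmentation datasets. The per-curve
heading-noise scale is 0.3/smoothness radians multiplied by a lognormal
draw (sd 0.8 in log space), so one smoothness setting yields curves from
near-straight to tightly curled: 2000 draws at the default populate ≥ 60 %
of the 25 convexity × closure cells, while high smoothness concentrates
convexity in the lowest bin. Rasterized point sequences are thinned to
minimal 8-paths (a pixel is dropped when its chain neighbors are already
8-adjacent) so tracing and chain geometry are unambiguous.

Observers are latent-variable models. Similarity: latent dissimilarity =
weighted Euclidean distance in z-scored cue space plus Gaussian trial
noise (sd 0.3 by default — a moderate observer that still orders pairs
reliably over 4 repetitions), cut at thresholds (0.5, 1.2, 2.0, 3.0) into
the 5-point scale; the simplest mechanism producing ordinal ratings whose
ranks reflect the planted structure. Figure–ground: P(choose convex) is
the clipped-to-[0, 1] linear predictor of seven weights (intercept, three
cues, three products) — clipped-linear rather than logistic so the
analysis model matches the generator and exact recovery is a meaningful
test; the default planted weights are intercept 0.490 and Closure 0.0755
with all else zero, i.e. a closure-driven observer whose choice
probabilities stay strictly inside (0, 1) for the cue ranges the
stratification spans.

What the simulations do not emulate: natural contour statistics (the cue
indices of real segmentation datasets are correlated and non-uniform),
human rating idiosyncrasies (sequence effects, criterion drift,
individual thresholds), and any perceptual validity of the symmetry
measure. Passing tests therefore certify the estimators and the analysis
chain — that planted structure is recovered, invariances hold and nulls
are calibrated — not that human data would reproduce any particular
number.

## Problem sizes and determinism

Every stochastic stage takes an explicit seed; a pipeline run expands one
top-level seed into per-stage seeds via numpy's SeedSequence, and
identical configurations reproduce outputs byte for byte. Default
problem sizes keep a full synthetic run and the test suite desk-scale:
corpora of tens of patches (the exhaustive axis search costs ~0.15 s per
patch), 14–16 stimuli with 10–20 scrambling draws and 2–4 MDS restarts in
the simulation studies, and 100-replicate parameter-recovery loops.
Users analyzing real corpora should raise `n_random` to 100 and restarts
to 10 (the library defaults for single calls).

## Known limitations

- dos anisotropy under nearest-neighbor rotation (above) means axis
  orientation is recovered to ±1 grid step, not exactly, for planted
  oblique axes.
- The X-junction detector operates on the skeletonized raster; very dense
  tangles can hide a crossing inside a thick cluster.
- The Error normalization is corpus- and dimension-specific; normalized
  Errors are comparable across factor sets for the same observer, not
  across experiments with different stimulus counts.
- The linear probability model can predict outside (0, 1) for extreme cue
  combinations; the simulated observer clips, the fitted model does not.
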