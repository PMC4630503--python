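# contourcues

Quantification of local contour shape for figure–ground research, with the
two psychophysical analyses built on it. The package is aimed at visual
psychophysicists and computational neuroscientists who study how local
Gestalt cues — convexity, closure and mirror symmetry — are represented
perceptually and how they drive border-ownership (which side of a contour
looks like the figure).

A stimulus is a 69 × 69-pixel binary contour patch whose center pixel lies
on a contour. Three indices label each patch:

- **Convexity** = log(1 + |ρ|), where ρ is the curvature at the patch
  center estimated from a 41-pixel chain window (least-squares circle fit;
  the side containing the osculating-circle center is the *convex* side).
- **Closure** = N_convex − N_concave: two probe points are placed ±5 px
  from the center along the contour normal and 16 radial lines are cast
  from each at 22.5° steps; N counts the lines that cross the contour.
  Positive values mean the convex side is the more enclosed one.
- **Symmetry**: the degree of symmetry dos(θ, x) is the fraction of
  contour pixels coinciding with their mirror image about a candidate
  axis (patch rotated by θ, translated by x, mirrored about the central
  column). The optimal axis is found by exhaustive search over
  θ ∈ {0..179°}, x ∈ {−34..34}; max dos is normalized by the largest dos
  in the working corpus and signed negative when the optimal axis runs
  mainly through the concave side. The corpus-maximum, perfectly
  mirror-symmetric patch gets Symmetry = 1.

Two analyses consume the indices:

1. **Perceptual similarity** — 5-point pair ratings are aggregated into a
   dissimilarity matrix, embedded by nonmetric (Kruskal) MDS with stress-1
   `stress = sqrt( Σ[θ(d_ij) − d̂_ij]² / Σ d̂_ij² )`, and compared against
   topographic configurations built from cue subsets via full Procrustes
   alignment. The squared-sum of aligned point distances (*Error*) is
   normalized by its mean over configurations fitted to label-scrambled
   ratings, with a one-sided t-test against that null.
2. **Figure–ground choice** — 2AFC figure-direction answers are scored
   against each patch's convex normal into convex-choice rates, regressed
   by OLS on the three cues and their pairwise products (linear
   probability model, adjusted R²).

Synthetic generators (arcs with planted curvature, radial-harmonic blobs
with exact planted mirror axes, smoothed random-walk open curves) and
latent-variable observer models make the whole pipeline testable without
natural-image segmentation data or human participants.

## Worked example

`python examples/compute_cues.py` builds a closed circle (radius 12 px)
and a mirror-symmetric blob and prints their indices:

```
corpus-max dos = 1.000 (normalizes the Symmetry index)

circle_r12:
  tangent    0.0 deg   curvature rho 0.0834 /px
  Convexity 0.0801   Closure +12   Symmetry +1.000
  optimal axis: theta* 0 deg, x* -12 px, dos* 1.000
```

The circle's Convexity sits at log(1 + 1/12) ≈ 0.0800; its Closure is
positive because the probe on the convex side is enclosed (all 16 of its
rays cross the contour) while the outside probe's rays mostly escape; and
its Symmetry magnitude is 1 because its raster is exactly mirror-symmetric
about the vertical diameter, the best axis in this two-patch corpus.

The other examples each demonstrate one capability end to end:
`select_stimuli.py` (X-junction screening and 5×5×8 stratified selection),
`similarity_analysis.py` (a simulated observer whose ratings are driven by
closure+convexity: that factor pair reaches normalized Error 0.005 while
symmetry alone stays at 0.997, p = 0.45 vs the scrambled null) and
`figure_ground_analysis.py` (recovers a planted Closure coefficient of
0.0755 exactly to three decimals at 100 trials per patch, adjusted
R² = 0.98, with all other terms non-significant).

A thin CLI wraps the same stages for scripted runs:

```sh
contourcues run-all --seed 7 --out run7    # simulate -> features -> select -> similarity -> fg
contourcues validate run7/ratings.csv ratings
```

## Layout

- `src/contourcues/geometry.py` — contour maps, tracing, patches, local frame
- `src/contourcues/cues.py` — Convexity, Closure, dos, optimal axis, Symmetry
- `src/contourcues/stimuli.py` — screening, 5×5×8 classes, selection, rendering
- `src/contourcues/mds.py` — dissimilarities, nonmetric MDS, Procrustes, Error
- `src/contourcues/figure_ground.py` — choice rates, six-term regression
- `src/contourcues/synth.py` — patch generators and observer models
- `src/contourcues/workbench.py`, `cli.py`, `io.py` — pipeline plumbing
- `docs/methods.md` — models, parameter choices, numerical details, limits
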