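# Methods

This note records the models and procedures `larvatray` implements, the
choices made where the design was genuinely open, and what the synthetic
generators do and do not emulate.

## Equal-area region geometry

The water surface of a container is tiled by three regions of exactly equal
area, ordered from the wall inwards: edge, intermediate, central.

- **Circles** (diameter d, radius R = d/2): boundary radii R·√(1/3) and
  R·√(2/3), so the central disc, middle annulus and outer annulus each hold
  one third of πR².
- **Rectangles** (L × W): constant-width margins measured from the wall. The
  outer margin m satisfies (L−2m)(W−2m) = (2/3)LW and the inner margin
  (L−2m)(W−2m) = (1/3)LW; each is the smaller root of
  4m² − 2(L+W)m + (1−f)LW = 0, whose discriminant is positive for all
  positive L, W, f ∈ (0,1). Constant-width frames were chosen over scaled
  similar rectangles (which also give equal areas) because a wall-hugging
  strip of uniform thickness is the natural "edge" for an edge-attraction
  analysis; this is a package choice, as equal areas alone do not pin the
  ring shapes down.

Both cases reduce to one classification rule on the distance from the
nearest wall, with thresholds d₁ < d₂: edge if d ≤ d₁, intermediate if
d₁ < d ≤ d₂, central otherwise. **Boundary convention:** a point exactly on
a boundary belongs to the more wall-ward region, fixed so rasterisation is
deterministic. Raster masks classify pixel centres; image coordinates are
row/column with origin at the top-left and a configurable px/cm scale.

For the three study containers (27.00 × 20.70 cm, 18.00 × 11.00 cm, ⌀
10.00 cm) the region areas are 186.30, 66.00 and 26.18 cm².

## Image-processing chain

Photograph → crop to water surface → invert (larvae bright) → 8-bit
quantisation (16-bit and float inputs are mapped by their full dtype range;
RGB by luminance) → threshold → despeckle → small-component removal →
per-region pixel counts.

- **Threshold.** Automatic by Otsu's between-class-variance criterion, with
  a manual override so a human-chosen per-image value can be reproduced.
  The mask is `pixel ≥ threshold`. A single-grey-level image has no
  histogram to split and raises a degenerate-histogram error.
- **Despeckle.** One pass of a 3×3 median filter with reflective padding
  (the border behaviour had to be fixed somewhere; reflection avoids
  manufacturing foreground at the frame). A single pass removes isolated
  pixels; convex corners of solid shapes erode by design of the median.
- **Food-particle removal.** 8-connected components with area ≤
  `max_particle_area_px` (default 12 px) are deleted — the automated
  surrogate for hand-painting particles out. The default suits the
  generator's defaults (particles ≤ 2 px radius, larvae ≈ 20–30 px after
  filtering at 25 px/cm); real images need this calibrated to their scale,
  which is why it lives in the run config.

Counts are exact integers per region; coverage conservation (region totals
tile the surface, larval totals sum over regions) is asserted in tests.

## Occupancy quantities

For region r with larval pixels l_r, region pixels t_r and image pixels T:

- raw coverage c_r = l_r / t_r;
- corrected coverage c_r · (t_r / T) — compensating for regions that differ
  slightly in pixel count after manual cropping. Algebraically this equals
  l_r / T; the implementation keeps the two-factor form and the tests assert
  the identity;
- preference p_r = corrected_r / Σ corrected (sums to 1). An image with no
  detected larvae has undefined preference and is flagged, never silently
  zeroed;
- regional density p_r · N / (V/3) in larva/ml, treating the regions as
  equal-volume vertical prisms (V/3 each); depth variation is ignored.
  N is the treatment's nominal stocked count, not a per-image estimate, so
  mortality between stocking and photography biases densities upward
  slightly;
- crowding ratio p_r / (1/3), the density relative to a uniform
  distribution.

## Productivity index and sensitivity analysis

PI = ln(100·F·S)/D per tray, with F mean first-clutch fecundity
(eggs/female), S larva-to-adult survival (proportion), D mean development
time (days). The factor 100 expresses an assumed 100% egg hatch as a
percentage. The variant ln(F·S)/D is available behind
`analysis.pi_formula = "lnfs"` because tray-level productivity summaries
appear in the literature in both parenthesisations. A log argument ≤ 0 is a
domain error; arguments in (0,1) give a negative PI with a warning.

**Sensitivity.** For each scenario (none, D, S, F, SF) the held traits are
frozen at their unweighted grand mean over trays, PI is recomputed, and a
two-way fixed-effects ANOVA PI ~ size * treatment is fitted. η² =
SS(term)/SS(total) with a sequential (Type I) decomposition in the fixed
order size → treatment → interaction, so the η² values plus the residual
share sum to exactly 1; for balanced designs this coincides with the
Type II/III decompositions, and the study designs are balanced or nearly
so. Random tray effects are deliberately excluded — the exported tables are
fit-ready for external mixed-model refits if those are wanted. If a
scenario freezes every trait, PI is constant and all η² are exactly 0.

## Repeatability (ICC)

One-way random-effects intra-class correlation,
R = (MSB − MSW)/(MSB + (k−1)·MSW), with k the harmonic-mean group size
(equal to the common size for balanced designs). R is the proportion of
measurement variance attributable to differences among containers rather
than among repeated photographs of the same container. Negative estimates
are clamped to 0 and flagged. The CI is a percentile bootstrap over whole
groups (default 1000 resamples), seeded, making the analysis deterministic
given a seed and cheap compared with MCMC mixed-model alternatives while
targeting the same estimand. R is invariant to affine transforms of the
measurements.

## Kruskal–Wallis and Dunn

Tie-corrected Kruskal–Wallis H (via scipy); the degenerate all-identical
case returns H = 0, p = 1. Dunn pairwise z statistics are computed from
pooled mean ranks with the tie correction Σ(t³−t)/(12(N−1)) subtracted from
N(N+1)/12; p-values are two-sided normal. The default multiplicity
adjustment is none (pairwise p reported as-is); Holm is available by flag.
The Dunn test is implemented in-package because none of the installed
statistics libraries provide it.

## Synthetic photograph generator

Emulates photographs of day-2–4 larvae on light water: background grey
≈ 210 with a lateral illumination gradient (±12) and Gaussian sensor noise
(σ 4); larvae as quadratic-Bézier strokes (0.40 × 0.12 cm, curvature up to
0.35 of body length, intensity ≈ 40 ± 10); food particles as dark blobs of
1–2 px radius at 0.4 cm⁻²; default scale 25 px/cm. Each larva's region is
drawn from the placement distribution — default (0.7594, 0.1505, 0.0900),
the observed mean preferences, normalised from their printed sum of
0.9999 — and its position is uniform within the region. By default the
whole body is resampled until it lies inside its assigned region
(`confine_to_region`), so the per-region pixel-mass truth matches the count
truth exactly; disabling it lets bodies straddle boundaries, which blurs
the intermediate region upward by ~0.015 at the default geometry. The truth
table records per-image region counts and true pixel counts from the union
mask.

Not emulated: optics (blur, reflections, meniscus shadows), larval overlap
at high density beyond simple occlusion in the union mask, movement between
shots, and depth (diving larvae). Passing recovery tests therefore show the
measurement chain is correct on well-separated dark-on-light targets, not
that segmentation is robust to arbitrary real-world photography.

## Synthetic life-history generator

Per size × treatment cell: tray development time D ~ mean + N(0, d_sd)
(floored at 1 day), survival S ~ Beta with given mean and sd (exact when sd
is 0), per-female winglength ~ N(mean, sd) in mm; per-female fecundity =
intercept + slope·winglength + N(0, σ), clipped at 0, averaged per tray
(default slope 55 eggs/mm, intercept −95, so 3.3 mm → ≈ 86 eggs). Zero
dispersions reproduce the configured means exactly. All randomness flows
through one seeded generator per call.

Presets encode the two study designs: a diet preset (3 diets × 3 sizes × 5
trays; development slows and adults shrink as diet drops, with the low-diet
container effect of ≈ +1.2/+2.7 days for large vs medium/small) and a
density preset (2 densities × 3 sizes, 4–5 trays; high density slows
development by ~1–3 days more in larger containers, lowers survival,
shrinks adults). A third configuration routes container effects exclusively
through D (S and fecundity dispersion-free; container offsets 0/1.5/3.0
days, tray noise 0.3 days) for demonstrating that holding D constant
eliminates the container η².

## Problem sizes and numerical choices

The shipped occupancy experiments use 12–50 images of the low-density
large-container treatment (200 larvae / 1000 ml), where larval overlap is
negligible and pixel mass is proportional to counts; high-density
simulations (1400 larvae) are possible but overlap makes pixel-based
preferences conservative, as pixel methods inherently are. ICC recovery
uses 40 groups of 3 (between-variance 4, within-variance 1, true R = 0.8)
with 500–1000 bootstrap resamples; the permutation check uses 2000 label
permutations of 30 values in three groups. Region-area equality is enforced
to 1e-9 relative; the corrected-coverage identity holds to 1e-12; boundary
ties are resolved wall-ward as above.

## Known limitations

- Pixel-mass preferences undercount overlapping larvae; estimates at high
  density are conservative.
- The ANOVA η² decomposition is order-dependent for unbalanced designs
  (documented fixed order); mixed-model η² variants are out of scope.
- Regions are 2-D; depth use (diving) is invisible to surface photographs.
- The geometry supports circles and axis-aligned rectangles only.
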