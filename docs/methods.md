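# Methods

This note documents the models, algorithms and numerical choices behind
`seedshape`, and what the synthetic validation does and does not show.

## The dorsal model family

Seeds are compared, in dorsal (back) view, against nine fixed closed plane
curves. The family splits by convexity of the enclosed region — a region is
convex when the segment joining any two interior points stays inside it.
Convex dorsal views ("dorso plana") are matched by DM1–DM4; non-convex
views ("dorso canaliculata", carrying a longitudinal channel whose exits
indent the outline at the ends of the long axis) by DM5–DM9.

* **DM1** is the superellipse `|3x/2|³ + |y|³ = 1`: semi-axes 2/3 and 1,
  aspect ratio 1.5, a "squared circle" slightly flattened at the poles.
* **DM2–DM8** are *two-arc* curves: the zero set of a product of two
  factors, each linear in `y`, so the region is bounded by an upper and a
  lower arc of the form

  `arc(x) = ±β·√(c − x^k) + m(x)`

  with `c = 40, k = 2` for the convex models and `c = 33, k ∈ {2, 4}` for
  the non-convex ones. The modulation `m(x)` carries a high-power tip term
  `t·(x²/c^{2/k})^p` (squares or upturns the tips; convex models), an
  optional small linear skew of the lower arc (DM4, the one left-right
  asymmetric model), and for the non-convex models the shared channel term
  `b/(x⁴ + x² + 6)` subtracted from the upper arc and added to the lower
  arc, which digs the dorsal channel into both ends of the long axis.
* **DM9** is polar: `ρ(θ) = (cos²⁰θ + 4 sin²θ)^(−2/3)`. The sharp
  `cos²⁰` term makes `ρ` dip to 1 at `θ = 0, π` between bulges of ~1.21,
  producing the two channel dimples; the curve is even in both axes.

### Provenance of the coefficients

The two-arc equations circulate in typographically corrupted form
(fractions, radicals and exponents collapse in extraction), so each
`ModelSpec` carries a `provenance_note` stating which coefficients were
transcribed and which reconstructed. Reconstruction was validated against
two published anchors, not against any fitting target: (i) the silhouette
class — DM1–DM4 rasters must have solidity ≥ 0.97, DM5–DM9 below — and
(ii) the aspect ratio of the species each model describes (means ± SD
roughly: DM1 1.54, DM2 1.43–1.48, DM3 1.47, DM4 1.56, DM5 1.43, DM6 1.69,
DM7 1.17, DM8 2.00, DM9 2.24). DM1 and DM9 are transcribed verbatim. For
DM5–DM8 the arc structure, asymmetries and the channel denominator are
transcribed while channel depths (and for DM7/DM8 the vertical amplitudes)
are reconstructed: the literal readings leave the rasters convex and, for
DM7/DM8, outside their species aspect-ratio ranges. All nine models pass
both anchors at a 300 px raster.

### Rasterization

Model coordinates are mathematical (x right, y up); rasters are row/col
with row 0 on top, and the rasterizer owns the y-flip. A pixel is
foreground iff its center lies inside the boundary polygon (even-touch
fill, via a dense boundary polyline and a point-in-polygon test), with a
half-pixel offset so the filled extent spans exactly `height_px` rows.
Two-arc endpoints are joined by vertical segments when the arcs do not
meet within 1e-9 model units (logged); arcs that cross before the nominal
domain end (channel terms of unequal depth) are trimmed to the crossing,
found by bisection. Rasters are resolution-stable (≤ 2% foreground XOR
between a height-h raster and a downsampled height-2h raster) and converge
to the polygon area within 0.5% at height 400.

## Morphometry

Descriptors follow ImageJ's particle-analysis conventions: `L` and `W` are
the major/minor axes of the ellipse with matching second moments ("Fit
ellipse"), not Feret diameters; `AR = L/W`; `C = 4πA/P²`; `R = 4A/(πL²)`.
The perimeter is the arc length of the marching-squares 0.5-level contour
of the *lightly Gaussian-smoothed* (σ = 1 px) binary image: contouring the
raw 0/1 field yields a pixel staircase that overestimates smooth
boundaries by ~5%, while the smoothed contour tracks a rasterized circle
to < 1% and keeps the 0°/45° anisotropy near 0.3%. Consequently a disk
measures `C ≈ 0.99` and a 2:1 ellipse `R ≈ 0.50`. On coarse rasters `C`
and `R` may exceed 1 by up to ~2% (documented allowance). Boundary
roughness lengthens the contour and so lowers `C` while leaving `R`
essentially unchanged — the reason both are reported.

Convexity is decided by solidity (area / convex-hull area) with default
threshold **0.97**: small surface protuberances (colliculae) cost little
hull area and must not flip the label, while the dorsal channel of the
non-convex models costs 4–11%. The threshold is configurable and recorded
in every report.

## J-index registration

`J = S/T × 100` on a shared pixel grid; an empty union is an error, not 0.
The model is always resampled onto the seed grid (the seed's pixel counts
stay fixed across models) with bilinear interpolation thresholded at 0.5,
which smooths the otherwise pixel-quantized objective. The search runs
over `(tx, ty, log s, φ)` per mirror state:

1. **Initialization** by moment matching: centroids aligned, scale
   `s₀ = √(area ratio)`, principal axes aligned with both polarities
   (φ, φ+π). Mirror candidates are added only when the model raster is
   not mirror-symmetric about its centroid column (within 2% XOR) —
   of the nine models only DM4 needs them. Near-circular masks (moment
   anisotropy < 1e-3) get φ = 0, logged.
2. **Refinement** by Nelder–Mead (iteration cap 200, J tolerance 1e-3,
   initial simplex steps 2 px / 0.04 in log s / 0.06 rad), keeping the
   best evaluation seen, so the refined J never falls below the
   initializer's. Scale is confined to [0.5, 2] × s₀ to prevent
   degenerate collapse. Exceeding the cap returns best-so-far with
   `converged=False`.
3. For masks above ~80 px the candidate stage runs on a 2× downsampled
   grid and only the winner is polished at full resolution; on 64-px
   masks the full search matches an exhaustive 27,951-point transform
   grid to within 0.5 J (and typically exactly).

Anisotropic or non-rigid warps are deliberately out of scope — they would
inflate J and break comparability with rigid superposition. A fit is
labelled good when `J > 90`.

## Average silhouette

Masks are standardized (centroid centered, principal axis vertical via a
two-pass moment estimate, heavier half — judged about the bbox mid-row —
down, optional mirror canonicalization by the sign of the column third
moment), stacked, and thresholded at coverage ≥ `τ·N`. The published
protocol's display-software recipe (layer opacity, magic-wand tolerance)
is reinterpreted as this coverage fraction; "where most of the seeds
coincided" reads naturally as majority coverage, so **τ = 0.5** is the
default and τ is exposed. `τ = 1` gives the stack intersection (verified
against the closed-form lens area of two offset disks to 2%), `τ → 1/N`
the union, and silhouette area is non-increasing in τ. Scale
normalization is off by default (populations are stacked at true scale);
`align=False` stacks masks as placed for pre-superimposed input. The
largest connected component is kept.

## Synthetic seeds

The generator emulates outline-shape variation between seeds of one
accession, not photographs: the model boundary is perturbed radially by a
band-limited harmonic field (wavenumbers 4–12, coefficient SD ∝ 1/k,
normalized so the *peak* displacement equals `ε·mean radius`), then
rotated (±10°), scaled (±5%) and translated (±3%) — small jitters of
manual seed placement. Defaults: `ε = 0.02`, long-axis size 160 px,
population size 20, matching typical accession images. A perturbation
that self-intersects is damped by halving ε (logged). Optional
"colliculae" add narrow Gaussian boundary bumps that lower `C` with `R`
unchanged within 2%. One global integer seed drives counter-indexed
substreams per seed, so populations are order-independent and
bit-reproducible.

What passing synthetic tests shows: the registration recovers the
generating model in well over 90% of draws at ε = 0.02 (100% in the
seeded acceptance run), own-model J exceeds
cross-model J for every model pair, convex/non-convex classes survive
generation noise, and shape CVs stay below size CVs. What it does not
show: robustness to illumination, focus, touching seeds, surface texture
or biological variation beyond smooth outline noise — real images remain
the test for those.

## Population statistics

`CV = SD/mean × 100` per trait and group (SD with n−1; single
observations report SD 0; zero-mean traits leave CV missing with a
warning). Group comparisons: Kruskal–Wallis omnibus for ≥ 3 groups,
two-sided Mann–Whitney for 2. The published stepwise-stepdown post hoc is
replaced by pairwise two-sided Mann–Whitney tests with Holm correction
feeding a greedy compact-letter display (groups ordered by median; a
group joins every letter set it is non-significant with, else founds one;
subset letters are absorbed) — the output contract (shared letter ⇔ not
significantly different at α = 0.05) is preserved; exact agreement with
the original stepping rules is not claimed. Simulation at n = 50/group:
null retention ≥ 90/100 replicates, and 0/1/2 SD location shifts are
detected with three distinct letters in ≥ 95% of replicates.

## Problem sizes used in validation

Model-class gates run at 300 px rasters; registration contracts at
64–160 px; the recovery study uses 50 seeds per non-convex model (tests)
and 20 per model (acceptance script) at the generator defaults; statistics
simulations use 100 (null) and 40 (power) replicates. These sizes were
chosen so the full validation runs on a laptop-class single core in
minutes while every Monte-Carlo margin stays wide (recovery 100% vs the
90% bound; own-vs-cross J margin ~7 points).

## Known limitations

* The DM2–DM8 coefficient sets are reconstructions constrained by class
  and aspect ratio, not a decoding of the original plotting code; fitted
  J values against real photographs may shift by a few points.
* J is resolution-dependent at the ~0.1–0.5 point level through
  resampling; comparisons should keep a consistent working resolution.
* The lateral-view model family is not included.
* Automatic ruler reading is out of scope; physical scale must be
  supplied.
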