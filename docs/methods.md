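# Methods

## Surface recovery

The capture model is Lambertian: `I_i(x,y) = ϱ(x,y) · max(0, ⟨N(x,y), L_i⟩)`
for each of N ≥ 3 unit light vectors `L_i`, plus an additive ambient level.
The ambient frame is subtracted (clamped at zero) from every lit frame, the
leaf foreground is segmented by Otsu's global threshold on the mean
corrected frame (largest connected component kept), and the scaled normal
`m = ϱN` is solved per pixel by linear least squares over all lights. The
solve requires the light azimuths not to be collinear; the `LightRig`
constructor rejects rank-deficient rigs outright. Albedo is `|m|` and the
gradients follow from the `N ∝ [-p, -q, 1]` convention (x = column index
rightward, y = row index downward, z toward the camera; these signs are
used consistently everywhere, including the renderer).

Conditioning: pixels with albedo below `1e-4` of full scale or a normal
z-component below `0.05` are flagged invalid and their gradients zeroed.
Both floors are arbitrary but configurable arguments of `solve_normals`.
No per-pixel light rejection is attempted: attached shadows are assumed
absent on the gently curved blades the method targets, and the renderer
only produces them at extreme slopes.

Depth integration uses the Fourier-domain least-squares integrability
projection (Frankot–Chellappa) under periodic boundary conditions, mean-free
output. It exists for visualisation; no extraction stage reads it, because
enforcing integrability distorts exactly the high-frequency relief the vein
features live in.

## Shape measures

First derivatives are taken as `(z_x, z_y) = (-p, -q)`, Gaussian-smoothed at
`sigma_px` (default 2 px); second derivatives are Gaussian-derivative
filters at the same scale, with the mixed derivative averaged over its two
estimates. Principal curvatures are the eigenvalues `H ± √(H² − K)` of the
shape operator of the Monge patch `z = f(x,y)`, with the overall sign chosen
so that *convex toward the camera is positive* — a raised vein then has
positive curvature across its crest (shape index +0.5) and a recessed vein
negative (−0.5). The smoothing scale trades noise suppression against
blurring of narrow veins; 2 px suits vein half-widths of ~2–3 px and is a
parameter of every entry point.

Shape index is computed as `s = (2/π)·arctan2(k1 + k2, k1 − k2)`, which
makes the umbilic limits exact (±1 at `k1 = k2 ≠ 0`) instead of relying on
a ratio that degenerates numerically. Curvedness is `√((k1² + k2²)/2)`.
Pixels with curvedness below `1e-6` of its image maximum form the planarity
mask: shape index is undefined (NaN) there rather than forced to a value,
and such pixels get zero weight in every downstream map. The nine shape
categories tile `[-1, 1]` with end caps of width 0.125 and interior bands
of width 0.25, each half-open on the right (the rut band is
`[-0.625, -0.375)`; +1 belongs to the spherical cap).

The Butterworth-style weight uses `|s − s_m|` in the base so non-integer
orders stay well defined. With the defaults (order 4, cut-off 0.4) the
weight exceeds 0.999 across the whole matching category band, halves exactly
at `|s − s_m| = 0.4`, and is identically zero for shapes of the opposite
convexity, making the ridge and rut weight maps disjoint in support.

## Venation extraction

The Gabor bank has 10 orientations over [0, π), carrier wavelength 10 px
(≈ 4× the default vein half-width — the band the vein cross-section lives
in), unit octave bandwidth, complex kernels with their means subtracted so
the response to constant input is zero. The response is the pixelwise
maximum magnitude over orientations, computed by FFT convolution.

Otsu thresholds (for the venation response, the pseudo venation and
foreground segmentation statistics) are computed over foreground pixels
only, since the background zeros would otherwise dominate the histogram.
The analysis mask is the segmented foreground eroded by 2 px (configurable)
so the curvedness discontinuity at the blade outline cannot enter the
statistics. Small-region cleanup removes 8-connected components below
0.01% of the foreground area (configurable). The pseudo-venation threshold
inflation factor defaults to 1.2; values ≤ 1 are executed with a warning.
An exact score tie — never observed in practice — yields an explicit
"undetermined" verdict.

## Synthetic leaves

The generator emulates a four-light capture rig: unit light vectors at 45°
elevation and azimuths 45°/135°/225°/315°, a fifth ambient-only frame,
i.i.d. Gaussian sensor noise (default 0.5% of full scale) added before
clipping to [0, 1], and an ambient level of 5%.

The blade is an ellipse (semi-axes 0.42·W, 0.34·H) whose height field
continues smoothly into the background — the figure/ground distinction is
carried by albedo (blade ≈ 0.65, background ≈ 0.06), as with a segmented
leaf on a dark stage, so no artificial cliff rings the blade. Undulation is
a pair of random-phase sinusoid products (amplitude 2 height units,
wavelength 80 px). Veins are signed Gaussian tubes of amplitude 4 and
half-width 2.5 px along architecture-specific skeletons (pinnate midrib
with alternating secondaries; palmate primaries radiating from the petiole;
transverse = pinnate + connecting tertiaries; reticulate = Delaunay mesh
over minimum-separation random points). Vein relief is therefore ≈ 2% of
the blade extent, the regime of sub-millimetre veins on centimetre-scale
leaves, and remains fully configurable. The reticulate sampler enforces a
minimum point separation of 0.30× the blade semi-minor axis: without it,
mesh cells can shrink to the width of the vein band itself, which no real
net-like venation exhibits (adjacent tubes merge into a corrugation with no
blade between them).

Stored gradients are central differences of the built height field — the
distance-transform-based tube profile has no closed-form derivative on the
skeleton and medial axis — which keeps the render→solve round-trip oracle a
genuine test of the solver against the forward model. The albedo pattern
(smooth Gaussian-filtered noise, relative contrast 0.5) is seeded
independently of the geometry, so colouring is statistically unrelated to
the vein mask; reshuffling it changes every rendered frame but no ground
truth. What the generator does *not* model: cast shadows, specular
reflectance, translucency/sub-surface scattering of near-infrared light,
perspective, and defocus. Passing tests therefore demonstrate correctness
of the algorithmic chain under Lambertian assumptions, not performance on
real captures.

## Numerical and design choices

- Least squares over all N lights (not best-3 selection) for N ≥ 4:
  standard overdetermined photometric stereo.
- `arctan2` form of the shape index; planar pixels masked, never imputed.
- Mixed second derivative symmetrised from both gradient channels, which
  also damps solver noise that violates integrability.
- Gabor DC correction by kernel mean subtraction (exact, per kernel).
- Small-region filtering via labelled component sizes (scipy), 8-connected.
- Pipeline determinism: every random draw in the generator flows from the
  leaf seed (geometry, rendering and albedo use fixed derived streams), and
  the pipeline itself is deterministic, so identical config + inputs give
  byte-identical reports.
- Problem sizes: the default raster is 256×256 px with ~1800–3600 vein
  pixels per leaf; the nine-leaf polarity panel (five rut-veined, four
  ridge-veined, seeds 1–9, all four architectures) runs the full pipeline
  eighteen times (once per leaf plus once per negated copy) in a few
  seconds on one CPU.

## Known limitations

- Gaussian vein tubes have concave flanks beyond one half-width (the
  profile's inflection), so a ridge is always rimmed by weak rut-like
  halos and vice versa; the polarity rule relies on crest pixels dominating
  the pseudo venation, which holds when inter-vein spacing is realistic but
  degrades if vein bands nearly tile the blade.
- Curvature estimates within ~2·sigma_px of the image border use filter
  padding and should not be trusted; the analysis-mask erosion hides the
  blade rim but not the raster border (irrelevant when the blade is
  interior, as generated).
- Otsu binarisation assumes the venation response is bimodal on the
  foreground; a leaf with no veins at all raises an error instead of
  returning an empty mask.
- No radiometric camera model: frames are assumed linear in irradiance.
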