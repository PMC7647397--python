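# Methods

`widefield_mc` simulates where widefield fluorescence from mouse cortex
originates. It has three parts: a Monte Carlo photon-transport core for
layered scattering tissue, simulation front-ends for illumination,
collection, and vessel shadowing, and an analysis layer that combines the
transport results with laminar indicator-expression profiles.

## Transport model

Photon packets perform a random walk through a cylindrical volume
(default radius 8 mm, tissue depth 4 mm, z = 0 at the planar tissue
surface, z increasing downward). Free paths are exponential with rate
mu_a + mu_s; deflection cosines are drawn from the Henyey–Greenstein
phase function by its inverse CDF (isotropic limit 2u − 1 at g = 0) with
uniform azimuths, applied by the standard spherical rotation with a
stable branch near the poles.

Absorption uses MCML-style weighted packets: at each interaction a packet
deposits `weight · mu_a / (mu_a + mu_s)` and continues with its weight
multiplied by the single-scattering albedo. Below weight 1e-4 a packet
plays Russian roulette with survival probability 0.1; survivors carry
weight/0.1, which keeps the walk unbiased. The roulette ledger (killed
weight minus survivor boosts) is tallied, so

    launched = deposited + exited + roulette_net (+ cap-killed)

holds to floating-point precision and is asserted in the tests. Weighted
packets have far lower variance than binary absorption in the deep-tissue
tails this model cares about; all reported fractions are weight fractions
and equal photon-counting statistics in expectation. A step cap of 1e5
interactions per packet guards pathological non-absorbing configurations
and never binds for the default coefficients.

When a sampled step would cross a medium boundary the packet moves to the
boundary and re-samples the remaining optical depth in the new medium —
the standard unbiased treatment of layered media. Interfaces are
index-matched (n = 1 throughout): no Fresnel reflection or refraction.
Media are grey matter (480 nm: mu_a 0.37, mu_s 11 mm^-1, g 0.89; 560 nm:
0.26, 10, 0.89; an alternative mouse-slice value mu_s = 21.1 mm^-1 at
480 nm is bundled), skull (0.12, 35, 0.9), and non-interacting coverslip
glass. A cranial window is a 7.5 mm-diameter, 0.17 mm-thick (#1.5 cover
glass; thickness is configurable and physically inert since glass neither
scatters nor absorbs) coverslip; skull, when present, either surrounds
the window or covers the whole surface (presets `skull-<um>`). Surface
vessels are horizontal cylinders tangent to the surface (centre depth =
radius) in which all weight is absorbed on entry.

The production engine is a Numba kernel (single-threaded, seeded,
bit-reproducible); `transport.propagate` is a plainly written reference
walker with the same semantics, and the two are cross-checked in the
tests. The kernel was validated against an exact benchmark: for a
semi-infinite isotropically scattering half-space with albedo 0.9 under a
normal pencil beam, the simulated diffuse reflectance matches the
Chandrasekhar H-function value 1 − sqrt(0.1)·H(1) = 0.41497 within Monte
Carlo error.

## Recorders

Fluence is estimated by track length (path length × weight per bin),
which has lower variance than absorption-weighted estimation and
normalises identically for relative profiles.

* **Depth profiles** are tallied in 10 um z-bins inside a central
  cylinder (default radius 2 mm). The illumination disc (11 mm field of
  view) is wider than the 7.5 mm window, so integrating over the full
  volume would mix window and through-skull entry paths; inside the
  central cylinder the beam is uniform and the laterally averaged fluence
  equals the on-axis intensity-vs-depth curve. Two normalisations are
  provided: to the first tissue bin ("surface") and to unit total in
  tissue ("total").
* **Peak depth** is the argmax after a 7-bin (70 um) boxcar. The profile
  top is flat over tens of micrometres, so the raw argmax jitters at
  Monte Carlo noise scale; a boxcar comparable to the flat-top width
  stabilises it without shifting a symmetric peak.
* **Mean propagation-angle cosine** per depth bin is the track-length-
  weighted mean z-direction cosine, all passes included. Note a property
  of this estimator: beyond ~1 transport length it settles to a small
  positive plateau (~0.3) rather than zero, because absorption and escape
  select for forward-going photons at every depth.
* **Under-vessel columns** are (d, z) histograms perpendicular to the
  vessel axis, restricted to the central ±1 mm along the axis, with the
  central 10 um bin centred on the axis.
* Optional cylindrical (r, z) maps (and the surface exit positions of
  every photon) support kernels and figures. A full 3-D grid at 10 um
  over the whole volume (~10^9 voxels) is deliberately not allocated.

## Illumination

Photons enter at positions uniform over the field-of-view disc with
directions uniform over the solid-angle cone of half-angle asin(NA)
(5.74° at NA 0.1) about the inward normal — Koehler-style even
illumination with position and angle decoupled. A "focused" variant
back-projects each photon from a focal-plane point so that every point at
the focal depth receives a full converging cone; it exists to demonstrate
that the focal depth (1 vs 2 mm) leaves the illumination profile
unchanged, which the tests assert. Photons launch at the top of the local
window/skull stack, so intact-skull configurations scatter the beam in
bone before it reaches tissue.

## Collection

Fluorescence photons are emitted isotropically from a point source
(sources at depth 0 are nudged 1 nm into tissue) and walked at the 560 nm
coefficients. At the last upward crossing of z = 0 the exit position is
recorded; the exit direction is the terminal direction (glass does not
scatter; skull, when crossed, does). A photon is *collected* when its
exit position lies in the field of view and its exit ray satisfies the
acceptance criterion:

* `"aperture"` (default): the ray reaches the objective's front window —
  its intersection with the front plane one working distance (56.3 mm)
  above the surface falls within the 7 mm front-window radius. For an
  on-axis source this is a 7.09° half-angle (solid-angle fraction 0.382%
  of the sphere), and it is the criterion under which the collection
  efficiencies here are quoted (0.56% for a surface source through a
  window).
* `"cone"`: the nominal NA gate, angle ≤ asin(NA) to the normal (5.74° at
  NA 0.1, direct solid-angle fraction 0.2505%). Used for NA-dependence
  comparisons, since the aperture criterion does not involve NA.

Surface-spread diameters are central-interval quantiles of the *1-D*
histogram of exit positions along one surface axis (the representation
surface distributions are reported in): the diameter for fraction f is
twice the weighted f-quantile of |x − x_source|, optionally resolved on a
10 um histogram grid (rounded up to whole bins, never below one bin).
Radial (2-D) quantiles are available via `convention="radial"`; for the
same cloud they are wider (for a Gaussian, the radial median is 1.75× the
marginal one), and the two should not be mixed when comparing numbers.

The per-pixel collection kernel K(z, r) is the radial histogram of
collected-photon exit distances per source depth, normalised per emitted
photon; by lateral translation symmetry it equals the source-sensitivity
profile of a single surface pixel.

## Vessel shadowing

Relative fluorescence under a vessel is the product of two paired-run
ratios: the illumination fluence ratio in the one-voxel column under the
centre line (averaged over ±2 depth bins around the requested depth, with
the window clamped below the vessel bottom so in-vessel bins never enter)
and the collection-fraction ratio for point sources directly under the
centre. Paired runs use independent seeds; total absorption slightly
overestimates the shadow of smaller vessels, as the bundled Beer–Lambert
calculation (6% transmission through 200 um of half-oxygenated blood)
quantifies.

## Expression profiles and attribution

Expression versus depth lives on a normalised axis: surface = 0, layer-6/
white-matter border = 1 mm. Profiles can be extracted from grayscale
section images (row sums over a 0.75 mm-wide strip, depth axis rescaled
linearly, peak-normalised — invariant to global intensity scaling) or
generated synthetically. The synthetic generator emulates the laminar
patterns of six GCaMP lines (Slc17a7: all layers; Cux2: L2/3–L4; Rorb:
L4; Rbp4: L5; Fezf2: L5–L6; Ntsr1: L6) as a uniform neuropil baseline
(default 0.3, "moderate expression" from dendrites and axons) plus
plateaus of height 1 over the somatic layers, blurred by a 40 um Gaussian
(soma-size/edge-alignment scale), normalised to max 1. It is
deterministic, and it does not reproduce per-animal idiosyncrasies of
real sections — within-layer banding, strip-placement variability,
imaging vignetting — so tests built on it validate the attribution
machinery and qualitative orderings, not line-specific percentages.

Layer boundaries on the normalised axis default to conventional mouse V1
proportions (L1 0–0.10, L2/3 0.10–0.30, L4 0.30–0.42, L5 0.42–0.62, L6
0.62–1.0). They are a convention, not a measurement; they are
configurable, and every boundary-dependent output records the table used.

Attribution multiplies illumination I(z), expression E(z), and collection
C(z) on a common 10 um grid over 0–1 mm (pia to the base of layer 6;
deeper tissue is excluded from the totals) and integrates over layer
spans; percentages are renormalised to sum to exactly 100 and are
invariant to rescaling any input curve. Fractional-change (ΔF/F)
scenarios multiply each layer's weight by the linear mixture
f_np·r + (1 − f_np), with f_np the neuropil volume fraction (0.994 in L1,
0.8 — the midpoint of the 0.77–0.84 literature range — elsewhere) and r
the neuropil/soma ΔF/F ratio, plus an optional layer-1 multiplier; the
linear mixture is this package's interpretation, chosen for its
transparency. Source-volume maps rank (r, z) cells by per-voxel
contribution I·E·K and report the volume of the smallest set of cells
reaching each cumulative fraction (whole cells, matching a flatten-and-
sort oracle exactly; ties break by stable order).

## Numerical and design choices

* Voxel pitch 10 um everywhere; half-open bins; origin on the optical
  axis.
* All randomness derives from one root seed through NumPy
  `SeedSequence` spawning; the kernel consumes a single 31-bit child
  seed, and identical seeds give bit-identical outputs.
* Default photon counts: 1e6 per transport run for headline numbers
  (the scale at which the quoted results were obtained), 1e4–2e5 in unit
  tests and examples. At 1e6, a collection run takes tens of seconds on
  one core.
* Boundary crossings nudge the packet 1e-7 mm past the surface to avoid
  re-intersection; recorders iterate bin indices (not floating steps) so
  bin-edge degeneracies cannot stall.
* A packet whose weight reaches exactly zero (pure absorber) terminates
  as absorbed rather than entering roulette.

## Known limitations

* No Fresnel reflection or refraction at interfaces; with a realistic
  tissue index (~1.36) internal reflection would raise near-surface
  fluence and collection somewhat.
* Grey matter is homogeneous: no capillary texture, no cell-scale
  heterogeneity, no wavelength dependence within a run.
* The camera-side optics are reduced to acceptance gates; image
  formation on the chip (focal-plane blur, aberrations) is out of scope,
  so "surface spread" means the distribution at the tissue surface.
* Vessels absorb totally; small vessels transmit a few percent in
  reality.
* The model's illumination peak through a window sits at ~200 um
  (mu_s = 11 mm^-1) and ~150 um (21.1 mm^-1) — the concentration effect
  is robust, but the exact peak depth is sensitive to the near-surface
  boundary treatment and should be read with that in mind.
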