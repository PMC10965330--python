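# Methods

This note records the models, estimators, numerical choices and limitations
behind `villimorph`, in the order the pipeline runs them.

## Phantoms

**Voxelization rule.** A voxel/pixel is foreground iff its *center* lies
strictly inside the continuous generating shape (no partial-volume
weighting). This makes discretization bias attributable: measured volumes
and areas converge to the analytic values as the voxel size shrinks, and
every phantom records the analytic truth of the continuous shape, not of
the raster. Raster grids are sized to an even pixel count with the shape
centred exactly on the grid centre, so no sub-pixel offset enters analytic
comparisons.

**3D primitives.** Spheres and capped cylinders (cylinder of length *L*
closed by two hemispherical caps). Closed forms: sphere V = 4πR³/3,
SA = 4πR²; capped cylinder V = πR²L + 4πR³/3, SA = 2πRL + 4πR². SA:V is
reported in mm⁻¹ (µm²/µm³ × 10³), which puts tissue-scale objects
(R ≈ 40–70 µm) in the tens-of-mm⁻¹ range.

**Cross-sections.** Background / trophoblast ring / stroma / capillary
lumens on a 2D grid. The basal (inner trophoblast) contour is
r(θ) = r₀ − d·g(θ) with g a periodic train of Gaussian bumps: `count` bumps
per revolution, depth `d`, and arc-length FWHM `width`. This is a minimal
invagination model with a monotone handle on P:A — perimeter grows and area
shrinks strictly with depth — chosen because no quantitative description of
real invagination geometry (depth, spacing) is available to us; phantom
invaginations are illustrative, not anatomical. Ground-truth perimeter and
area come from the generating contour polygon (2048 vertices; shapely),
which agrees with a shoelace/arc-length computation to 1e-9 relative and
understates the continuous area by only ~2π²/3n² ≈ 1.6e-6. Capillaries must
lie strictly inside the basal contour and not overlap; violations raise
geometry errors rather than producing broken topology.

**Intensity rendering.** intensity = class mean + i.i.d. Gaussian noise
(single SD), seeded. Real microCT/EM noise is textured and correlated; this
renderer only exists so that threshold segmentation can be tested against
known labels, and passing those tests says nothing about performance on
real image noise.

**Cohorts.** The default study design emulates two groups: human-like
(n = 5 placentas, smooth basal membrane, SA:V 43.34 ± 6.78 mm⁻¹,
P:A 0.12 ± 0.03 µm⁻¹) and equid-like (n = 12, 12 invaginations per section,
SA:V 73.47 ± 14.91 mm⁻¹, P:A 0.24 ± 0.07 µm⁻¹), five villi per placenta at
4.8 µm voxels (3D) and 0.25 µm pixels (2D; finer than needed, far coarser
than the 15 nm EM native scale, keeping rasters small). Summary statistics
are defined over per-placenta means, so the generator puts the target SD at
the between-placenta level and adds a smaller within-placenta villus jitter
(log-normal, CV 10 % by default — a plausible within-organ spread; no
empirical value available). Placenta-level values are drawn log-normally
(strictly positive sizes) and then affinely standardized so the realized
group mean and SD equal the targets exactly: the generator emulates a study
whose summary statistics are *given*, and leaving them to drift with the
draw would make any single cohort an unfaithful stand-in at these small n
(at n = 5 and CV 25 % a free draw misses the group mean by >10 % about a
third of the time). Ordering and spacing of placentas, and all villus-level
variation, remain random. 3D villi are spheres with R = 3000/SA:V µm;
2D sections solve the invagination depth by bisection so the contour P:A
hits the sampled target (smooth sections use r = 2/P:A exactly, equid-like
sections start from a base circle 1.6× larger so the invaginations carry
the remainder — 1.6 sits comfortably inside the attainable band). Targets
that cannot be voxelized (R < 3 voxels) or reached by the contour family
raise feasibility errors instead of clipping silently.

## Segmentation

Masked thresholding with foreground = high intensity (heavy-metal-stained
tissue is bright; an `invert` flag flips this). `threshold="otsu"` computes
Otsu's threshold from within-mask intensities only — the original curation
software's threshold-selection rule is unknown, so Otsu-within-mask is this
package's default, not a reproduction. Connected components below
`min_component_voxels` (default 1000, read as the plain meaning of "1 k";
configurable) are removed with *strict* less-than semantics; connectivity
defaults to 26 in 3D and 8 in 2D, matching common imaging-suite defaults.
Subvolume cropping returns cubes (default edge 128 voxels) with objects
clipped at the faces retained. Manual curation is out of band: the pipeline
accepts an externally edited label volume; no editor is built, and watershed
separation of touching villi is deliberately not attempted.

## Morphometry

**Volume** = foreground voxel count × voxel_size³ — exact for the digital
object.

**Surface area.** Default estimator: marching-cubes triangulated isosurface
at the 0.5 level of the indicator smoothed with a Gaussian of σ = 1 voxel.
Meshing the raw binary volume inherits staircase area (a few per cent
high); the light smoothing recentres the isosurface on the true interface
and brings a 10-voxel-radius sphere within ~2.5 % of 4πR². Objects so small
that smoothing drops their peak below 0.5 fall back to the unsmoothed mesh.
The exposed-voxel-face count (× voxel_size²) is retained as
`method="voxel_faces"` for sensitivity analysis only: it runs ≈ 1.5× high on
spheres (→ 4/π ≈ 1.27 for axis-aligned faces of a smooth convex body, worse
with curvature at coarse voxels), which is why it is never the default.
Which estimator the original analysis software used is unknown; this is the
main reason measured SA:V values should be compared with externally reported
ones only at a tolerance of order ±15 %.

**Scaling correction.** Whole-volume segmentations leave touching villi
connected; manually curated 128³ subvolumes measure the bias. The
correction factors are the means over subvolume pairs of curated/raw volume
and curated/raw surface area (dimensionless, hence unit-independent), and
corrected whole-volume records multiply raw measurements by them, with
SA:V recomputed from the corrected values. With the study's factors
(volume 0.96, surface 1.11) the corrected SA:V is ×1.156 the raw one.
Degenerate pairs (zero raw measurement) are reported by index.

**P:A.** The inner compartment is the union of stroma and capillary pixels
with holes filled — capillary lumens are *interior* (vessels bound by
stroma), so only the basal-membrane contour contributes perimeter. Area is
the filled pixel count × pixel_size². Perimeter is the marching-squares
contour length at the 0.5 level of the σ = 1 px smoothed indicator:
counting pixel edges instead would overestimate discs by up to ~4/π, while
the sub-pixel contour is accurate to ~0.5 % at 40 pixels per radius. P:A is
reported in µm⁻¹. (Units for both ratios are package conventions chosen so
tissue-scale phantoms land on magnitudes comparable to externally reported values;
externally reported numbers are typically unitless.)

## Transport

**Discretization.** Finite volume directly on the label pixel grid — no
unstructured meshing, so segmented images are usable as-is. Unknowns live at
tissue (trophoblast + stroma) pixel centers; 5-point fluxes D(cᵢ−cⱼ) per
face; Dirichlet boundaries (outer villus surface c = 1, capillary surfaces
c = 0) enter through half-cell closures (conductance 2D per boundary face).
Diffusivity is normalized to 1 in both compartments (only normalized
concentrations are meaningful here) and is configurable per compartment.
Topology is validated at build time: stroma or capillary touching the
exterior, capillary touching trophoblast, or missing tissue classes raise
geometry errors.

**Membrane.** In `simple` mode the trophoblast↔stroma interface is
transparent (harmonic-mean conductance; concentration continuous) — the
reading of passive gas transfer. An infinite-permeability facilitated solve
is the cross-check: at membrane number V_max·rₒ/(D·c_ref) = 10³ the two
fields agree to < 0.2 % sup-norm on the annulus benchmark. In `facilitated`
mode the concentration is double-valued across each membrane face; the flux
density obeys J = V_max(c₁/(K_m+c₁) − c₂/(K_m+c₂)) with c₁, c₂
reconstructed at the interface from the adjacent half-cells, and flux
continuity ties the half-cell diffusive fluxes to J.

**Nonlinear solve.** Per membrane face, q = J(c_T − qh/2D_T, c_S + qh/2D_S)
is solved exactly by monotone bisection (the right side is strictly
decreasing in q), vectorized over faces. Globally, the sparse matrix carries
an upper-bound linearization of the membrane — series resistance of the two
half-cells plus the initial-slope permeability V_max/K_m, which bounds the
transporter's secant conductance from above — and a Picard loop updates the
per-face defect between that linear flux and the exact balance. Because the
linearized conductance dominates the true one everywhere, the sweep is
contractive without under-relaxation; damping 1.0 is the default
(≤ ~55 iterations across membrane numbers 0.1–10³ on benchmark geometries,
versus ~2× more at 0.5), `damping` and `max_iter` (100) remain parameters,
and non-convergence raises with the last residual. Convergence is measured
as the sup-norm change of the membrane flux vector relative to V_max
(tol 1e-8). After convergence one final solve imposes the converged fluxes
as fixed face sources, which makes the discrete balance outer influx =
membrane integral = capillary uptake hold to solver precision (imbalance
~1e-12, audited by `flux_report`; the imbalance denominator is floored so
the sealed-membrane all-zero-flux case reports 0, not 0/0).

**Verification.** On a digital annulus (rₒ = 100 µm, rᵢ = 20 µm, 512²
grid) the simple-mode field matches c(r) = ln(r/rᵢ)/ln(rₒ/rᵢ) to 0.44 %
sup-norm and the uptake matches 2π/ln 5 to 0.05 %; the error decreases
monotonically under grid refinement, and the discrete maximum principle
(0 ≤ c ≤ 1) holds in both modes. Remaining boundary error is the O(h)
staircase representation of curved Dirichlet boundaries, inherent to
solving on label grids.

**Permeability regimes.** "Low / medium / high" membrane permeability is
mapped to membrane numbers V_max·rₒ/(D·c_ref) = 0.1, 1, 10 — a declared
package convention (no empirical membrane parameter values to adopt beyond the
K_m = 0.5 default). In the membrane-limited regime uptake ≈ L_m·J(≈1, ≈0),
so the invaginated/smooth uptake ratio approaches the membrane-length
ratio; in the diffusion-limited regime it approaches the ratio of
simple-mode uptakes. The discrete membrane length (face count × h) is a
staircase measure, ~4/π high for generic orientations on both geometries,
so ratios of membrane lengths are far more trustworthy than their absolute
values.

## Statistics

Group summaries and tests operate on mean values per biological placenta —
villus replicates within a placenta are averaged first (unweighted), and
placentas with fewer than five replicates trigger a warning. Routing:
Shapiro normality per group and Levene variance homogeneity across groups,
both at α = 0.05 (shared with the significance threshold); all pass → a
two-sided two-sample t-test, any fail (or a group below Shapiro's n = 3
minimum, or zero spread) → two-sided Mann–Whitney U (exact for group sizes
≤ 8, asymptotic above). Whether the original analysis used Student's or
Welch's t is unstated; this package uses Welch's when group sizes differ
(conservative with 5 vs 12 placentas) and Student's when balanced, and
records the variant, the assumption p-values and the routing in every
result. Species within the equid-like group are pooled by default;
per-species grouping is a matter of passing different group labels.

## Pipeline

One directory per run (`morphometry/`, `stats/`, `transport/`,
`report.json`); every table carries software version, seed and a config
hash (the hash excludes the output path). Identical config + seed reproduce
`report.json` byte-for-byte. Voxel/pixel size defaults are 4.8 µm (3D) and
0.015 µm (2D native EM scale) for file input, always overridable; phantom
cohorts default to 0.25 µm sections as above. Inputs are never mutated.

## Problem sizes used in validation

Benchmarks and the acceptance script run at: sphere R = 48 µm at 4.8 µm
voxels (~4.2 k foreground voxels); annulus at 512² (accuracy) and 256²
(regime sweeps); equal-area smooth/invaginated pair at 0.5 µm pixels
(~250² grids); the default cohort of 17 placentas × 5 villi with full 3D/2D
measurement; and 200 replicate cohort draws at ground-truth level for the
detection-rate estimate (re-rasterizing and re-measuring 17 000 villi would
add measurement noise that is characterized separately, not sampling
information). The whole validation completes in about a minute on one CPU.

## Known limitations

* Phantom villi are spheres/cylinders and single cross-sections — no
  branching trees, no 3D transport, no blood flow or advection, no
  time dependence, no multi-solute coupling.
* The invagination model is a periodic radial perturbation; real basal
  infolding is irregular and also exists at a nanoscale not represented
  here at all.
* Surface-area and perimeter estimators carry resolution-dependent bias
  (≤ ~3 % at ≥ 10 voxels per radius; unbounded below that) — compare
  against external measurements only with an estimator-mismatch tolerance.
* The Gaussian-noise renderer does not emulate real image artefacts;
  segmentation robustness claims are limited accordingly.
* `simple` mode treats the membrane as fully transparent; if an external
  passive-diffusion scenario included finite membrane resistance, the
  facilitated mode at a chosen V_max is the closer analogue.
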