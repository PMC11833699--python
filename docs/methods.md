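# Methods

This note documents the models, numerical choices and limitations behind
`nirdosim`: what is simulated, with which assumptions, and what a green test
does and does not establish.

## Optical model

Light transport in tissue is parameterized per voxel by the absorption
coefficient μₐ (mm⁻¹), scattering coefficient μₛ (mm⁻¹), Henyey–Greenstein
anisotropy *g* (mean single-scattering deflection cosine) and refractive
index *n*.  Derived quantities: reduced scattering μₛ′ = (1−g)μₛ and the
effective attenuation coefficient

    μ_eff = sqrt(3 μₐ (μₐ + μₛ′)),

the asymptotic decay rate of diffuse fluence far from sources in the
diffusion regime.  (This radical form is the standard diffusion-theory
expression; sources that typeset it without the square root are treated as
typographic loss.)

**Spectral library.**  `(tissue, wavelength) → (μₐ, μₛ, g, n)` with exact
lookup at stored nodes, per-property linear interpolation between nodes, and
refusal to extrapolate.  The shipped default table covers head and ocular
tissue classes at 670/810/850/980/1070 nm with literature-plausible values
(water-dominated media — CSF, aqueous, vitreous — follow the water
absorption spectrum with its 980 nm peak).  These defaults are configurable
stand-ins, not measurements; any quantitative study should substitute its
own measured table via `load_library`.

**Voxel mixing rule.**  A voxel with tissue probabilities `w_i` receives the
arithmetic probability-weighted mean of μₐ, μₛ and *n*.  The anisotropy is
averaged with weights `w_i·μₛᵢ`: *g* describes the scattering phase
function, so only scattering components should shape it; where nothing
scatters the plain weighted mean is used.  A probability deficit (Σw < 1)
contributes air (μₐ = μₛ = 0, n = 1) rather than renormalizing — this keeps
sinus and background voxels inert and mirrors how SPM-style probabilistic
segmentations behave at boundaries.  Every mixed parameter is convex in its
inputs (property-tested).

## Phantom synthesis

Probability maps on a shared RAS grid (0-based voxel indices, voxel-center
world coordinates, origin at the anterior commissure, 1 mm isotropic by
default) are mapped wavelength-by-wavelength through the mixing rule.  The
head mask marks voxels whose total tissue probability (excluding explicit
air) exceeds 0.01 — a threshold chosen to be robust against probabilistic
map noise; everything outside is ambient.

**Artifact cleanup** removes connected components below a size threshold at
6/18/26-connectivity (the largest component always survives).  Only the
component-size rule is automated; the manual recalibration a human operator
would apply to *attached* artifacts is out of scope.

**Sparse-annotation interpolation** refines property fields along explicit
1-D profile polylines (the workflow used for small ocular structures):
annotated nodes pin exact values, and voxels touched by the polyline are
re-assigned from the interpolant evaluated at the arc length of the voxel
center.  `"linear"` is piecewise linear; `"hermite"` is the natural cubic
interpolant — zero second derivative at the profile ends and C² across
interior nodes, i.e. gradient continuity at tissue boundaries.  With two
nodes both methods coincide (the natural conditions force the cubic to a
straight line).  The implementation evaluates scipy's natural `CubicSpline`;
the test oracle is an independent tridiagonal second-derivative solve.
Interpolation is deliberately 1-D along profiles, not 3-D scattered
interpolation, to keep the operation auditable.

**Rigid resampling** applies a given world-space rotation+translation
(checked orthonormal to 1e-6) on the same grid with nearest or trilinear
interpolation; estimating registrations is out of scope.

## Monte Carlo engine

Photon packets are launched from disk, rectangle or isotropic-point sources
(the point source exists for physics validation against closed-form
solutions).  Emission is collimated along the source normal by default; a
cosine-lobe option exists because real LED divergence profiles are rarely
specified.  Packets are allocated to sources in proportion to source power
with launch weights arranged so total launched weight equals `n_photons`
exactly.

Propagation is 3-D DDA voxel traversal with a dimensionless scattering
optical depth τ = −ln ξ consumed as μₛ·ℓ across voxel segments:

- **Fluence tally** is track-length: each segment adds
  `w·(1−exp(−μₐ·ℓ))/μₐ` (→ `w·ℓ` as μₐ→0) to its voxel, later divided by
  voxel volume and launched weight.  This estimator stays unbiased in
  non-absorbing voxels such as CSF.
- **Absorption is continuous**: the weight decays `exp(−μₐ·ℓ)` along the
  segment, so absorbed energy ≡ fluence × μₐ × voxel volume holds exactly
  per voxel and launched = absorbed + escaped (+ capped) holds to
  floating-point rounding with roulette off.  Arguments μₐ·ℓ < 0.005 use a
  4th-order series for the exponential (error < 3e−14).
- **Scattering** draws the Henyey–Greenstein deflection cosine by inverse
  CDF (g clamped to |g| ≤ 0.999; g = 0 is the isotropic limit) and a
  trig-free uniform azimuth via unit-disk rejection.
- **Refractive-index steps** at voxel faces apply unpolarized Fresnel
  reflection/refraction (Snell bending, total internal reflection),
  including entry from and escape to the ambient medium (n = 1 by default).
  Photons escaping the grid are tallied as escaped and never re-enter.
- **Russian roulette** below weight 1e−4 with survival 0.1 (MCML
  convention, configurable).  Roulette is unbiased, so the energy balance
  holds in expectation when it is on; a `max_path_mm` cap (with its own
  tally) guards degenerate zero-attenuation geometries.
- **Time** advances by Σ ℓᵢ·nᵢ/c and indexes optional fixed-width gates
  (0.3 ns default).  A segment's deposit is gated by its voxel-entry time,
  and the final gate is a catch-all so the gate sum always equals the
  steady-state tally exactly.
- **Determinism**: randomness comes from an inline xorshift128+ stream
  seeded via splitmix64 from `SimConfig.seed`; a run is bit-reproducible
  single-threaded.  Property volumes are passed to the kernel as one
  interleaved float32 array for cache locality; tallies are float64.

Face/corner coincidences are resolved by carrying the voxel index
incrementally across faces (a position may sit exactly on a face without
ambiguity); entry into the grid bounding box uses a 1e−7 mm nudge.

Validation: Beer–Lambert decay in a pure absorber is reproduced essentially
exactly (the continuous estimator has zero variance there); fluence around
an isotropic point source in a high-albedo medium (μₐ = 0.01, μₛ′ = 1 mm⁻¹)
matches the diffusion solution φ(r) = exp(−μ_eff r)/(4πDr) within a few
percent at r = 10–20 mm — well inside the 15% band expected of
diffusion-theory agreement.

## Dosimetry analysis

- **Dose tables**: per-region deposition sums absorbed energy over atlas
  voxels; per-tissue deposition weights it by class probability; both are
  reported as percent of absorbed and percent of launched energy together
  with mean fluence rate (scaled by total source power: fluence per unit
  launched weight × Σ power_density × area) and region volume.  Over an
  exhaustive disjoint partition the percent-of-absorbed column sums to 100.
- **Energy flow** (Sankey input) needs per-source tallies
  (`SimConfig(per_source=True)`) and conserves energy at every node, with
  `unlabeled`/`remainder` catch-alls.
- **tPSF**: per-gate ROI mean fluence; the gate sum equals the steady-state
  ROI mean by construction.
- **Penetration rate** through extracerebral tissue is defined here as
  (GM + WM + CSF deposition) / total absorbed energy — the source
  literature uses the phrase without defining it, so this operational
  definition is stated prominently.
- **Statistics**: Pearson correlation matrices flag (rather than drop)
  undefined entries from constant rows; hierarchical clustering is UPGMA
  (unweighted average Euclidean distance) via scipy's average linkage,
  cross-checked against a brute-force oracle; regression is OLS with a
  two-tailed slope t-test on n−2 df; two-group comparison follows the
  normality (KS against a fitted normal) → variance (Levene) → t-test /
  Wilcoxon decision tree at α = 0.05.  No multiple-testing correction is
  applied by default (matching common practice in small pilot analyses); a
  Benjamini–Hochberg adjustment can be applied by the caller on the
  reported p values.

## ANSI Z136.1 exposure limits

Only the long-exposure continuous-wave branches relevant to LED therapy are
implemented; other branches raise rather than silently falling back.  With
λ in μm and α in mrad:

- Skin (t > 10 s): limit = 0.2·C_A W/cm², C_A = 10^(2(λ−0.700)) below
  1.050 μm, 5.0 above.  At 810 nm: 3.32 mW/mm²; at 1070 nm: 10.00 mW/mm².
- Extended-source ocular (α ≥ 1.5 mrad, t ≥ T₂): C_E = min(α,100)/1.5,
  T₂ = 10·10^((min(α,100)−1.5)/98.5) s; limit = 1.8·C_A·C_E·T₂^(−1/4)
  mW/cm² below 1.050 μm, 9.0·C_C·C_E·T₂^(−1/4) above (C_C = 1 up to
  1.150 μm).  At α = 100 mrad: 0.63 mW/mm² (810 nm), 1.90 mW/mm² (1070 nm).
- Limits are computed in the standard's W/cm² or mW/cm² and reported in
  mW/mm² (1 W/cm² = 10 mW/mm²).  The ~0.2% C_A step at 1.050 μm is inherent
  to the standard's piecewise definition and is asserted, not smoothed.
- A margin check passes when measured/limit ≤ 1 (boundary inclusive).  The
  20 mW/cm² device irradiance (= 0.20 mW/mm²) sits ≥ 10× below the 810 nm
  skin limit.

## Synthetic fixtures: what they emulate and what they don't

The **layered head** is a scalp (80 mm) / skull (73 mm) / inner-table
(66 mm) shell set concentric on the world origin, with the brain (gray-matter
shell 49 mm → white-matter core 38 mm radii about its own center) offset
(0, 8, 10) mm anterior-superior; everything inside the inner table that is
not brain is CSF.  The offset
encodes the single anatomical fact the paradigm comparison rests on: frontal
cortex lies close behind the forehead, while the face, mouth and nose have
progressively more extracerebral tissue between source and brain.  Scalp-to-
gray-matter distances along the six paradigm rays (forehead 15, head-top 19,
eye 21–24, nasal 27, oral 30, occipital 37 mm) were fixed from geometry
before any simulation was run.  Gray matter is labeled by hemisphere
(optionally octants) for region analysis.  The **slab** fixtures provide
planar layers for physics tests, including an ocular layer sequence
(eyelid/cornea/aqueous/lens/vitreous/sclera-retina/orbital fat).

What the fixtures do *not* emulate: cortical folding (sulci/gyri), real
skull thickness variation, nasal/oral cavities as air-filled passages,
hair/follicle absorption, anatomical asymmetry between hemispheres, and any
AD-specific atrophy.  A green paradigm-ordering test therefore establishes
that the engine resolves centimeter-scale geometric dose differences — not
that the synthetic head reproduces patient-derived deposition percentages.
On this fixture the ocular and nasal analogs happen to deposit statistically
indistinguishable gray-matter fractions (≈1.37% of absorbed at 810 nm,
difference ≈ 0.007 percentage points); the ordering test treats that pair
within its Monte Carlo noise envelope rather than pretending to resolve it.

## Performance and test scaling

The numba kernel processes ≈ 1.4×10⁷ photon-events/s on one CPU core.  Test
photon counts are sized for a single-CPU CI budget: the diffusion-theory
acceptance check runs 3×10⁵ photons with spherical-shell averaging (the
shell mean over thousands of voxels makes the Monte Carlo error ≪ the 15%
tolerance), and the paradigm-ordering check runs 1.5×10⁵ photons per
placement-seed (the forehead margin exceeds 5σ at that size).  Photon count
is a `SimConfig` value; production runs should use 10⁷–10⁸ packets.

## Known limitations

- Voxel (not mesh) geometry: curved interfaces are staircase-approximated;
  Fresnel events happen only at axis-aligned faces.
- Collimated default emission; no measured LED divergence profiles.
- No polarization, coherence, fluorescence or thermal modeling.
- The default spectral library is a documented stand-in; absolute dose
  numbers inherit its uncertainty directly.
- Only the long-exposure ANSI branches are implemented; pulsed protocols
  need the standard's other rules.
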