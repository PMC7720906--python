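# Methods

## Model

`ramanmc` simulates light transport in turbid media as a sequence of
straight photon flights interrupted by four competing interaction
events: elastic scattering, absorption, fluorescence re-emission and
Raman (Stokes) scattering.  Photons are quantized, unweighted particles
— there is no packet-weight attenuation; absorption is a per-segment
Bernoulli "Russian roulette" on the same footing as the other events.

Per-event sampling (all from explicit uniform variates):

- **Free path** between elastic scattering events: exponential,
  `l = −ln(1−ξ₁)/μs(λ)`.  (Some published statements of this law carry a
  spurious extra μ factor inside the CDF; the bounded standard form is
  the only self-consistent one and is what we implement.)
- **Azimuth** `φ = 2πξ₂`; **polar deflection** from the closed-form
  Henyey–Greenstein inverse CDF with anisotropy `g(λ)`; the isotropic
  limit `cos θ = 2ξ₃−1` is used below `|g| < 1e−6` where the HG inverse
  is singular.
- **Absorption**: absorbed iff `ξ₄ < 1 − exp(−μa(λ)·l)` over the
  actually traveled segment length, including segments truncated at a
  material interface.
- **Fluorescence / Raman**: each material carries cumulative conversion
  CDFs ρF (per absorption event) and ρR (per propagation step) over the
  discrete emission wavelength grid.  A uniform variate is compared
  against the CDF; the shortest wavelength whose cumulative value
  exceeds the variate is selected, and a variate above the final CDF
  value means no conversion.  CDFs are built by *discrete summation*
  of scale·rate over the grid (not trapezoid integration): the decision
  rule only ever consumes cumulative mass per grid point.
- **Boundaries**: unpolarized Fresnel reflectance (average of the two
  polarizations, with total internal reflection beyond the critical
  angle) decides reflect-vs-refract via `ξ₇ < R`; refraction follows
  Snell's law.

## Event loop

Each in-medium iteration: (1) Raman check against the local ρR (the
conversion is located at the iteration's start point, i.e. the previous
collision site or the entry point; its depth `z` is recorded); (2) free
path + scattering angles sampled at the current wavelength, direction
rotated, then the photon attempts to travel; (3) if a material change
lies within the segment, the photon moves to it, survives the roulette
over the traveled length, reflects or refracts, and samples a **fresh
full step** in the new medium (no residual-path rescaling — a modeling
choice, documented because the source algorithm is silent on it); (4)
completed segments undergo the roulette; (5) on absorption, ξ₅ against
ρF decides annihilation versus isotropic re-emission at a CDF-sampled
wavelength (the grid includes the source wavelength as index 0, so
re-emission at the original wavelength is representable).  Everything
outside the defined structures is void: photons there fly straight,
either escaping (terminal record) or re-entering through a Fresnel
boundary.  A per-photon iteration cap (default 1e5) guards against
infinite loops; capped photons are counted and reported.

Wavelengths live on a fixed grid — index 0 is the 785 nm source
wavelength, indices 1–100 are 100 equally spaced emission wavelengths
over 810–932 nm.  Optical properties are precomputed per (material,
grid wavelength): μs from the power law `a₁λ^(−a₂)`, g and n affine in
λ, μa interpolated from tables; tabulated overrides for μs/g/n are
supported.

## Geometry

Right-handed coordinates in mm with +z pointing *into* the medium and
the top surface at z = 0; depth is z ≥ 0.  Two geometry kinds: layered
slabs (closed-form plane intersections) and voxel label volumes
(Amanatides–Woo 3-D DDA traversal; voxel `i` owns the half-open cube
`[i·pitch, (i+1)·pitch)`).  Label 0 is void.  Two exact fast paths skip
the DDA when a segment provably stays in one material (uniform volumes;
z-stratified volumes within one equal-label run of slices); they change
no results, only speed.

## Probe model

The source is a monochromatic 785 nm beam with a Gaussian radial
profile (default std 0.1 µm) truncated at the fiber radius (200 µm),
launched uniformly in solid angle within an 8° half-angle cone.
Detection selects photons escaping the top surface with exit point
within the collection aperture and exit direction (in void, after
refraction) within 30° of the surface normal.

**Aperture reading.** The probe's collection port is described as a
600 µm-diameter cylinder surrounding a 400 µm-diameter illumination
disk, which admits two readings: the full 600 µm disk, or the annulus
between 400 and 600 µm.  We default to the **disk** (inner radius 0):
measured on the depth-study media, the disk reading reproduces the
published sensing-depth extremes at both ends of the optical-property
grid (e.g. ~10 µm at μa=1.4, μs′=30, ρR=1e−6), while the annulus
overshoots them by roughly 2x everywhere.  The annular reading remains
one parameter away (`DetectorSpec(inner_radius_mm=0.2, ...)`).  At low
μs′ the aperture choice is the dominant systematic in the absolute
sensing-depth scale — see Limitations.

## Sensing depth

`d_X` is the depth *beyond which* a fraction X of detected Raman
photons were generated: the (1−X) empirical quantile (nearest-rank) of
the conversion depths of detected Raman photons, measured from the
surface.  Under this convention d90 ≤ d75, consistent with the published
tables (the 75% column exceeding the 90% column); the complementary
"X% from above" reading is available as a flag.  Uncertainty is
reported as a percentile bootstrap CI over the detected-depth sample.

## Synthetic data

The fixtures module builds everything the tests and the acceptance
script consume:

- **Depth-study media**: homogeneous 2×2×2 cm³ slab on a 256³ voxel
  grid (the semi-infinite approximation used in the source analysis),
  g=0.9, n=1.4, μs=μs′/(1−g), a flat per-step Raman rate integrating to
  the requested total, no fluorescence.
- **Validation phantoms**: PDMS-like and nylon-like materials with
  power-law μs′ and linear μa pinned to the published endpoint values
  over 500–1000 nm (the measured curves are not tabulated anywhere, so
  these are smooth stand-ins, not digitizations); synthetic Raman
  spectra are sums of narrow Lorentzians at fixed, profile-specific
  grid positions (disjoint between profiles by ≥3 bins so layered
  simulations can attribute peaks), fluorescence a broad hump.  Phantom
  I/II are 10 mm single layers on 256³ grids; phantom III is a 913 µm
  PDMS-like layer over a 10 mm nylon-like substrate on a 501×501×203
  grid.
- Absolute conversion probabilities are free parameters (no published
  cross sections exist for these materials); defaults ρR-scale=1e−3 and
  ρF-scale=2e−3 per event sit inside the range the depth study sweeps.

What a green end-to-end test establishes: that conversion, transport,
detection, baseline removal and normalization together recover the
*positions* and layer attribution of known synthetic peaks.  It does
not establish absolute intensities, real PDMS/nylon peak wavenumbers,
or instrument response (replaced by a known synthetic system here).

## Numerical choices

- Surfaces: positions are nudged 1e−9 mm off boundaries after every
  reflection/refraction; interface candidates closer than 1e−9 mm are
  ignored; photons launch 1 µm above the surface in void.
- RNG: the compiled engine uses an in-kernel xoshiro256++ generator
  (splitmix64-seeded); per-batch seeds derive from
  `SeedSequence([seed, batch])`.  Runs are deterministic given (seed,
  photon count, batch count) per engine.
- Two engines: a scalar Python reference (readable, slow) and a
  numba-compiled batch kernel (~1e7 event-loop iterations/s/core).
  They mirror each other expression-for-expression, including libm
  binding for sin/cos, so that driven by one recorded variate stream
  they produce byte-identical records — the equivalence oracle run in
  the test suite.  Exact shortcuts (e.g. skipping `expm1` when
  `ξ₄ ≥ μa·l`, since `1−e^(−x) < x`) are applied in both.
- Rolling-ball baseline: 1-D grayscale opening (moving minimum then
  maximum) over a flat window of `2·half_width+1` bins with replicated
  edges; `half_width` is a required parameter (the algorithm's radius
  is never specified upstream; tests use ~4–6 bins ≈ several peak
  FWHMs).  SNV uses the sample (N−1) standard deviation.

## Limitations

- **Detected-Raman statistics.** With the probe aperture and realistic
  per-step Raman probabilities (ρR ≤ 1e−6), only ~1–2 detected Raman
  photons arise per 1e7 launched in the low-scattering media; sensing
  depths quoted at those settings are near-single-sample quantiles
  unless photon budgets far exceed desk scale.  This is inherent to
  direct (analog) Monte Carlo; variance-reduction and perturbation
  re-weighting are deliberately out of scope.  The acceptance suite
  asserts minimum sample sizes so that starved estimates fail loudly.
- **Aperture systematics.** At μs′ ≈ 1 mm⁻¹ the absolute d75 scale
  moves by tens of percent between the disk and annulus readings of the
  collection port; qualitative trends (d75 decreasing in ρR, μs′, μa)
  are insensitive to the reading.
- The entry deflection convention (scattering angles are sampled at the
  start of each iteration, so a photon's direction is redrawn at the
  first in-medium iteration after crossing the surface) follows the
  stated event-management flowchart rather than the
  move-then-scatter convention of classical multilayer MC codes.
- No polarization, time-of-flight, stimulated/nonlinear Raman, GPU
  execution, or camera-based wide-field detection (pinhole-camera
  parameters are accepted in configs for compatibility but not
  simulated).
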