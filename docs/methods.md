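# Methods

`sonopath` simulates B-mode ultrasound images from labelled voxel
anatomies.  The model has two stages: a stochastic ray tracer that
computes, per scanline, the large-scale intensity returned to the
transducer (reflection, refraction, attenuation and shadowing), and a
convolutional speckle stage that turns that intensity map plus a random
sub-wavelength scatterer field into RF lines, which a conventional display
chain (envelope, TGC, log compression, scan conversion) renders as an
8-bit image.  This note records the model, its assumptions, the defaults,
and the design decisions taken where the design was genuinely open.

## Scene representation

The world is an integer label per voxel (0 = ambient medium) with a tissue
record per label: impedance `Z` (kg/m²s), attenuation `α` (dB/(cm·MHz)),
sound speed `c` (m/s), the scatterer-model parameters `μ0, σ0`
(amplitude distribution) and `μ1` (generation probability), and the
echo-shaping coefficients `τ ∈ [0,3]` (diffuse–specular scale) and
`γ ∈ [-2,2]` (angular exponent).  Voxel indices are 0-based; world
coordinates are voxel-centre based (the origin is the centre of voxel
(0,0,0)); axes are x lateral, y elevation, z axial.

For every nonzero label a narrow-band signed distance grid is computed by
exact Euclidean distance transforms of the binary mask (inside and
outside), signed by membership, shifted by half a voxel so the zero level
sits on the boundary face, and clamped to ±band (default 4 voxels, at
least 2·max(spacing)).  The transform runs on the label's bounding box
plus a band margin; everything farther out is clamped positive.  Surface
normals come from central differences of the trilinearly interpolated SDF
with a 2-voxel stencil — the wide stencil suppresses the voxel-scale
staircase noise of the distance transform at the cost of smoothing
features below ~2 voxels.  On a voxelized 10 mm sphere at 0.5 mm voxels
this yields normals within ~4° of radial on average; the error budget is
dominated by voxelization, not interpolation (on an analytically filled
SDF grid the same estimator is accurate to well under 2°).

Dense arrays are used throughout; sparse tree storage is a GPU-era
performance optimization that is irrelevant at the problem sizes this
package targets.

## Acoustic physics

At an impedance discontinuity, intensity reflection/transmission follow

    R = ((Z₂cosθ₂ − Z₁cosθ₁)/(Z₂cosθ₂ + Z₁cosθ₁))²,  T = 1 − R,

with the incidence cosine `cosθ₁ = |n·v|` (the SDF normal is flipped
toward the incident ray).  The refraction cosine is
`cosθ₂ = sqrt(1 − r²(1 − cos²θ₁))` with ratio `r = Z₁/Z₂` by default;
this impedance-ratio convention is deliberately kept as the model's
printed form even though Snell's law would use the sound-speed ratio — a
config switch (`SimConfig.refraction_ratio="speed"`) selects `c₁/c₂`
instead.  A negative radicand flags total internal reflection (R = 1).

Attenuation is applied in the dB domain as an intensity factor
`10^(−α·f·l/10)` with `l` in cm and `f` the centre frequency in MHz —
the standard clinical parameterization; it is the exponential decay law
with the constant absorbed into α.

A boundary deposits an echo intensity

    I_R = ((Z₂−Z₁)/(Z₂+Z₁))² · I · τ · cosθ^γ

using the **entered** tissue's τ and γ (the boundary "belongs" to the
structure being hit; the ambient medium's τ = 0 suppresses exit echoes
into water).  For γ < 0 the cosine is floored at 1e−3 so grazing
incidence cannot produce unbounded echoes.

## Monte-Carlo path tracing

Per scanline, N rays (default 1000; the packaged experiments use 64–128)
are launched along the beam axis.  Rays march through the voxel grid at a
uniform step of min(spacing)/2 with bisection refinement of each label
crossing to 1/16 voxel — same event semantics as hierarchical traversal,
portable and testable against a fine-step oracle.  An acoustically
matched label change (relative impedance difference < 1e−9) is a
segmentation boundary, not a wave boundary: the ray passes through
unchanged and the crossing does not count as a collision.  Without this
rule, cone resampling at the impedance-matched lesion boundaries of the
contrast phantom would fabricate shadows behind purely echogenicity-
contrasted lesions.

At a true boundary the ray (i) deposits the surface echo, then
(ii) reflects with probability R, else refracts (Russian roulette: one
continuation per bounce, no splitting).  The *reflected* continuation
direction is drawn from a cone around the mirror axis: polar angle
φ ~ truncated-normal ψ(μ, σ, a, b) (defaults μ=0, σ=π/4, a=0, b=π/2)
via inverse-transform sampling, azimuth uniform; the solid-angle density
is ψ(φ)/(2π sinφ), floored at 1e−6 where sinφ → 0 makes it unbounded.
The *refracted* continuation is deterministic along the refraction axis by
default (`SimConfig.cone_refraction=True` scatters it too): the physical
picture behind the cone — a reflected wavefront taking the shape of the
curved structure it bounced off — applies to reflection; scattering the
transmitted beam by σ = π/4 would destroy collimation within one or two
interfaces and with it any deep anatomy.

Per bounce the carried intensity is multiplied by `f·cosθ₁` with
`f = R` or `T` by branch.  The cone density is treated as the scattering
lobe itself, so the importance-sampling density cancels exactly against
the lobe in the estimator ratio and no explicit pdf division is applied;
this keeps the estimator bounded (a passive boundary never amplifies),
behaves correctly in the collapsed-cone limit σ → 0, and reduces to the
exhaustively enumerable branch process the test suite checks against.
`SimConfig.pdf_weighting=True` restores the explicit `f·cosθ/p(ω)`
weight for experimentation.

Between boundaries the carried intensity, attenuated within the medium,
is deposited at the radial samples of the scanline by projecting sample
points onto the scanline axis (one sample per traversed radial bin;
deposits projecting outside [0, depth] are discarded).  Every deposit is
weighted by the beam-coherence factor

    w_R = C0 / (C0 + d),   C0 default 0.1,

where `d` is the perpendicular distance of the deposit point from the
**current main beam** — the deterministic reflect/refract axis, which
re-anchors at every bounce.  Measuring `d` from the original scanline
axis instead would annihilate every physically bent (refracted) beam,
since typical deflections reach millimetres within a centimetre of travel
while C0 is 0.1 mm.  On the primary beam d = 0 and w_R = 1, so simple
scenes are unaffected.

Thin-structure rule: a ray that refracts into and out of a structure
thinner than one wavelength along its path (default threshold c/f0,
`SimConfig.thin_structure_mm`; 0 disables) exits parallel to its
pre-entry direction.  Geometric refraction is meaningless below the
diffraction limit; without this rule a 0.6 mm nylon wire acts as a strong
cylindrical lens and deflects the beam off every deeper target.

Rays terminate after `max_collisions` bounces (default 7), when the
carried intensity underflows 1e−12, or after a total path of 1.5× the
imaging depth.  Randomness is counter-based: one Philox stream per
(scanline, ray) pair keyed by (seed, scanline, ray), so frames are
bit-reproducible regardless of execution order.  When a ray encounters no
stochastic branch point, all remaining rays of that scanline would retrace
it exactly and are skipped — an exact shortcut, not an approximation.

The tracer returns two per-scanline radial arrays: the diffuse intensity
I_Tr(r) that weights the scatterer field, and the boundary-echo
intensities kept separate so they can be injected as coherent impulses
into the RF model rather than multiplying the speckle.

## Scatterers and convolutional RF synthesis

Scatterer candidates are Poisson-distributed over the imaged region —
per mm² of the imaging plane in 2-D mode (the default; all scatterers in
the elevation midplane), per mm³ in 3-D mode.  Each candidate survives
with its tissue's probability μ1; amplitudes are drawn from
Normal(μ0, σ0) truncated at zero.  Echogenicity contrast in dB is
realized by scaling both μ0 and σ0 by 10^(dB/20), which scales the
envelope exactly by that factor.

Per scanline, scatterers within the beam support are projected onto the
axis, binned to the nearest radial sample, weighted by
`w_q·a_q·I_Tr(r_q)` where the analytic beam weight is the
depth-independent Gaussian

    w_q = exp(−½(ΔL²/σ_L² + ΔE²/σ_E²)),

and the binned train plus the echo impulses (scaled by `echo_gain`) is
convolved with the 1-D axial pulse: a Gaussian envelope (σ_r, default
0.25 mm, truncated at ±3σ_r) modulated at the round-trip spatial carrier
2f₀/c (≈ 4.7 cycles/mm at 3.6 MHz).  The lateral/elevational PSF factors
are realized entirely by w_q; scatterers with w_q < 1e−3 are skipped.
A precomputed pulse-echo field table over (depth, ΔL, ΔE) can replace the
analytic profile (`PSFConfig.weighting="field-table"`); producing such a
table with an external beam simulator is the user's concern, and lookups
outside its support return 0.

`echo_gain` (default 100) sets the relative scale of boundary-echo
impulses against the scatterer train.  The two quantities have no common
physical normalization in this model class — echoes are ray-traced
intensities, speckle amplitudes are dimensionless hyperparameters — so
the ratio is a display-calibration parameter, chosen so tissue interfaces
render clearly brighter than fully developed speckle at the default
tissue table.

RF sample spacing is c/(2·f_s) (round-trip time base): 0.0154 mm at
50 MHz sampling and 1540 m/s.

## Display chain

Envelope detection is the magnitude of the analytic signal (Hilbert
transform) — exact for narrowband pulses.  TGC multiplies each sample by
`10^(slope·z_cm/20)` (amplitude domain; default 1.5 dB/cm).  Log
compression maps `v = 20log10(x/x_max)` linearly from [−DR, 0] to [0, 1]
(default DR 75 dB); the reject threshold (default 40 dB) is applied after
normalization as a dB floor below the peak, zeroing anything quieter.
Scan conversion resamples the (beam, radius) fan to a Cartesian 8-bit
raster by bilinear interpolation at 0.23 mm pixels, with a fan mask;
linear geometry resamples rectilinearly.  The chain preserves isolated
maxima to within one pixel, which is what the distance experiment needs.

## Validation phantoms

All validation scenes are built programmatically; ground truth (wire
centres, lesion centres/radii/nominal contrasts) is emitted alongside
each scene.  Scenes use the background tissue as the ambient medium so
only the embedded targets are voxelized.

* **Speckle slab** — fixed-amplitude (1.0) scatterers uniform over a
  40×40 mm plane at 600/mm² (the density unit is ambiguous in this model
  class; the per-mm² reading gives far more than the ≥10 scatterers per
  resolution cell that fully developed speckle requires), imaged by a
  linear array with σ_L = σ_E = 2 mm and a unit intensity profile (no
  boundaries, no ray tracing).
* **Lesion phantom** — spherical lesions (radius 4 mm) in homogeneous
  background, acoustically matched (identical Z, c, α) so the measured
  contrast isolates the scatterer model: anechoic (μ1 = 0) at (0, 28) mm,
  +15 dB at (−14, 42) mm, +6 dB at (+14, 42) mm.
* **Wire phantom** — 0.3 mm-radius nylon wires perpendicular to the
  imaging plane: a vertical column at x = 3 mm, depths 15–135 mm in
  10 mm steps, and horizontal rows at 40 mm (x = −30..30) and 120 mm
  (x = −40..40).  The column is offset from the sector axis so that no
  two wires share a scanline (a 7-collision budget cannot traverse a
  13-wire column) and offset from the row depths so no blobs merge.
  A wire is far below the resolution cell, so it responds as a *single
  coherent point target* planted at its exact centre (wire tissue
  μ1 = 0; the impedance step keeps weak facet echoes, τ = 0.05, and the
  boundary physics).  Filling wires with random scatterers instead gives
  fully developed speckle whose envelope-maximum jitter (~0.3 mm,
  independent of scatterer count) would bury the axial accuracy.
* **Artefact spheres** — fluid mode: impedance-matched, scatterer-free,
  α = 0.02 (post-acoustic enhancement); attenuating mode: Z = 7.8e6,
  α = 10 (shadowing).
* **Toy heart** — two ellipsoidal blood-filled chambers in a myocardium
  shell inside soft tissue, optional bone rib occluder; for end-to-end
  smoke tests of chamber visibility and rib shadowing.

## Validation metrics

gCNR is 1 minus the overlap of the lesion and background histograms
(bin-wise minimum of unit-mass histograms over a shared binning, default
256 bins), computed on **pre-compression envelope** samples by default;
because gCNR is invariant under monotone transforms, the value carries
over to the compressed image.  The optimal classification threshold ε₀
(the bin edge minimizing the equal-prior error) is reported with it.
CNR is |μ_l − μ_b|/√(σ_l² + σ_b²) on the same domain; contrast is
20·log10 of the envelope-mean ratio, matching the ±dB amplitude
convention of the nominal lesion labels, and is computed on the envelope
floored at the display reject level (env_max·10^(−reject/20)) — values
below the reject never reach the image, so the floor is the system's
effective noise floor and bounds how negative an anechoic contrast can
read.  gCNR and CNR stay on the raw envelope (the floor only relocates
the far-left tail and measurably changes neither).  Background patches are discs of
the same radius at the same depth as the lesion patch (sample sizes equal
by construction); patches use 0.8× the lesion radius to avoid
partial-volume mixing at the rim.

Speckle statistics: envelope SNR = mean/std (theory √(π/(4−π)) ≈ 1.913
for Rayleigh), maximum-likelihood Rayleigh scale √(E[x²]/2), and the sum
of squared differences between the normalized histogram densities (100
bins) and the fitted Rayleigh density at the bin centres.

TRE samples the image along a straight line through each target group
(vertical line for the column, horizontal for the rows), detects local
maxima with a prominence threshold (0.15 of the line's range), refines
them to sub-pixel by three-point quadratic interpolation (reported errors
are below the 0.23 mm pixel), and matches peaks to expected positions by
nearest neighbour within a 3 mm gate; unmatched targets are counted as
missed and excluded from the means.

## What the synthetic experiments do and do not show

The phantoms exercise the full pipeline — SDF construction, marching,
echo physics, Russian-roulette branching, COLE synthesis, display chain —
under controlled geometry, so passing tests demonstrate internal
consistency and correct first-order statistics (Rayleigh speckle,
amplitude-ratio contrast, sub-pixel geometric fidelity, attenuation
artefacts in the right direction).  They do not demonstrate realism of
real anatomy: the analytic Gaussian beam has no sidelobes and no
depth-dependent width, tissues are internally homogeneous, and
reverberation, nonlinear propagation and elevation-aperture effects are
absent.  Two visible consequences in the lesion experiment: only mainlobe
leakage fills an anechoic lesion (raw-envelope contrast ≈ −23 dB;
≈ −17 dB once the display reject floor is applied) where a sidelobed
system saturates around −13 dB, and a +6 dB lesion scores a
histogram-overlap gCNR around 0.4 where beam and system noise push real
and fully-simulated systems down to ≈ 0.2.

## Problem sizes and numerical choices

The packaged experiments run 10 stochastic repeats each: speckle uses
~10⁶ scatterers and no tracing; lesions use 96 scanlines × 64 rays and
100 scatterers/mm²; wires use 255 scanlines × 64 rays and 30/mm².
These sizes hold the Monte-Carlo spread of every reported statistic well
inside its quoted tolerance.  Numerical floors: ray intensity 1e−12,
cone pdf 1e−6, beam-weight cutoff 1e−3, grazing-cosine clamp 1e−3,
bisection tolerance 1/16 voxel.  Degenerate inputs raise errors rather
than guessing: empty label sets, non-positive impedances, zero-variance
envelopes, missing tissue fields.

## Known limitations

No reverberation (would need time-of-flight summation), no nonlinear
propagation or harmonics, no elevation-aperture modelling beyond the
Gaussian ΔE weight, no cardiac motion or probe-pressure deformation.
The impedance-ratio refraction convention bends rays more strongly than
Snell's law for high-contrast interfaces.  Scatterer amplitudes and τ/γ
are hyperparameters, not measured tissue properties; the default tissue
table is a plausible starting point meant to be replaced per application.
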