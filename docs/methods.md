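# Methods

This note records the models implemented in `fusmark`, their assumptions,
the defaults that matter, and the design choices made where more than one
reasonable construction existed. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Conventions

Arrays are indexed `(z, y, x)` with z the acoustic propagation axis
(transducer at negative z, natural focus at the origin); every physical
3-vector (spacing, position, sigma, displacement) uses the same order, in
SI units. Experiment configs take lengths in millimetres and convert at the
config boundary. All generators draw from `numpy.random.default_rng(seed)`
and are bit-reproducible under a fixed seed.

## Acoustic forward model

The source is a spherically focused bowl (defaults: 1 MHz, 13 cm radius of
curvature, 15.4 cm aperture) vibrating with unit normal velocity in water
(c = 1482 m/s at 20 °C; the gelatin value 1549 m/s is used only when a
gelatin path is modeled). Pressure is the Rayleigh integral over the cap,
evaluated on a deterministic midpoint product grid in (cos θ, φ) — exactly
equal-area on the sphere — with ≥ 40 000 points by default. The φ count is
forced even so the point set is mirror-symmetric in x and y, making the
simulated field axisymmetric to machine precision. Because the focus is
equidistant from every cap point, the focal value is quadrature-exact; the
test suite checks the on-axis field against the closed-form bowl solution
(0.5 % tolerance, observed ~1e−12 at the focus and <0.02 % at ±6 mm) and
that halving the discretization moves the focal value by <0.1 %.

A biopsy marker is represented acoustically as a thin circular
complex-transmission screen: inside its radius the field is multiplied by
`t·exp(iφ_s)`, outside it passes unchanged. Full-wave scattering (FDTD /
k-space), attenuation and nonlinearity are out of scope; the screen
reproduces the occlusion/diffraction phenomenology the downstream focus
metrics respond to. With a screen present the chain is: Rayleigh source →
screen plane (on a grid twice the scan window), complex transmission,
angular-spectrum propagation to the measurement plane. The screen must not
lie beyond the measurement plane.

### Angular-spectrum projection

`project_plane` zero-pads the plane by `pad_factor` (default 2) per axis to
suppress circular-convolution wraparound, applies
`H = exp(i·kz·Δz)`, `kz = √(k² − kx² − ky²)`, and crops back. Evanescent
components (`kx² + ky² > k²`) are zeroed in both directions — decaying them
exponentially would be unstable under the backward projections used in the
offset-scan validation, and a scan plane several wavelengths from any
source carries no usable evanescent signal. `Δz = 0` returns the input
unchanged so the identity contract holds for arbitrary (even
non-band-limited) input. A heuristic warns when a target is farther from
the measured plane than the padding can angularly cover
(`|Δz| > half-window·(2·pad_factor − 2)`).

Reconstruction volume defaults mirror hydrophone practice: 0.5 mm in-plane
(native scan spacing), 0.5 mm axially over a 4 cm z range.

### Focus metrics

* Focus volume: largest contiguous region with amplitude strictly greater
  than half that field's own maximum; 6-connectivity (faces) by default,
  configurable to 18/26.
* Displacement: voxel argmax of test minus control, ties broken by first
  occurrence in `(z, y, x)` raster order; optional 3-point parabolic
  sub-voxel refinement, off by default (the choice of peak over centroid is
  a convention, stated rather than hidden).
* Insertion loss: `−20·log10(peak_test/peak_control)` on volume peaks; a
  single-plane variant (`insertion_loss_from_planes`) is provided because
  "in-plane" loss can also be read per scan plane.
* RMSD between volumes: `√(mean(|p_t| − |p_r|)²)` normalized by the
  reference peak by default; reference-RMS and joint-peak normalizations
  are selectable since the normalizer is a convention.

## MR thermometry forward model and inversion

The synthetic series has unit magnitude on the phantom support, zero
outside, with the marker's signal void carved out (zero inside
`void_radius`, one-voxel smoothstep roll-off; intravoxel-dephasing physics
is deliberately not modeled). Ground-truth heating is an instantaneous
Gaussian deposit evolving by the heat kernel,

    ΔT(r, τ) = ΔT_peak · Π_a √(σ_a²/(σ_a² + 2Dτ)) · exp(−Σ_a r_a²/(2(σ_a² + 2Dτ))),

with D = 0.143 mm²/s (gelatin) by default; the truth frames are returned
with the series. Phase encodes temperature through
`Δφ = 2π·γ·α·B0·TE·ΔT` (γ = 42.577 MHz/T, α = −0.01 ppm/°C, B0 = 3 T,
TE = 12 ms, 2.16 s dynamics by default) on top of a static point-dipole
marker term `A·(3cos²θ − 1)/r³` with a single amplitude constant (rad·m³)
rather than device susceptibility constants — downstream code needs a
realistic spatial pattern, not device-specific field maps. Heating the
marker scales the dipole amplitude by
`1 + c_T·ΔT(marker position)`, emulating temperature-dependent
susceptibility. Noise is circular complex Gaussian; SNR is mean phantom
magnitude over per-channel noise sd.

Inversion: principal-value phase difference against the complex-averaged
baseline frames, divided by the PRF constant. No temporal unwrapping is
applied (at a 2.16 s dynamic the expected per-frame change is far below π);
a warning is logged when any frame-to-frame step on signal-carrying voxels
exceeds π/2. The instantaneous-deposit generator triggers this warning by
construction on its first heated frame — a real sonication ramps over many
frames. A sign flag accommodates scanners with the opposite phase
convention.

SNR mask (construction unspecified in the source experiments, so defined
here): voxel kept iff its time-mean magnitude strictly exceeds `k·σ`,
k = 5, with σ estimated from the real and imaginary parts of a
user-supplied background region. Masked voxels carry no temperature and
never contribute to dose or hot volumes.

Dose uses rectangular integration at the frame interval, Δt in minutes,
matching the acquisition cadence; dose is additive over concatenated
sonications. Thresholds follow the stated wording exactly: dose volume "at
least 240 CEM43" is inclusive (≥) and contiguous (largest component); hot
volume "greater than 10 °C" is strict (>) and deliberately noncontiguous.
The hot-volume statistic uses the temporal maximum of ΔT by default, with a
per-frame variant exposed.

## Signal-void segmentation

Threshold = 1.25 × mean over the no-signal region; candidates are strictly
below it and inside the phantom mask; the result is the largest connected
candidate component (the interactive region pick of a human operator is
not reproducible, so "largest" is the deterministic resolution; a
seed-point override handles multi-void images). Extent per axis is the
maximum over lines parallel to that axis of the number of mask voxels on
the line, times the spacing (the bounding-box reading is available behind
a flag). The rule is invariant under positive image scaling because the
threshold scales with the noise mean.

The phantom-image generator uses piecewise-constant levels (background and
void at the noise floor, phantom at signal level) with additive Gaussian
fluctuation, default sd = noise_mean/10 — it emulates the high-SNR
magnitude images used for planning rather than Rician noise statistics;
with Rayleigh-distributed background at mean 10 against a threshold of
12.5, no single-voxel threshold rule could recover a void accurately, and
real workflows rely on exactly this kind of high-CNR image.

## Gross-pathology volumetry

`V = Σᵢ Aᵢtᵢ` and `u(V)² = Σᵢ (tᵢ²u(Aᵢ)² + Aᵢ²u(tᵢ)²)` (first-order GUM
propagation, independent components). Zero-area slices contribute nothing.
When no per-slice area uncertainty is supplied, the default is a
boundary-pixel heuristic, `u(A) = n_boundary·pixel_area/√12` — annotation
uncertainty concentrates at the ablated-region boundary, and ±half-pixel
uniform error per boundary pixel has sd `pixel/√12`. It is overridable.

The slice generator cuts an ellipsoid at per-slice thicknesses drawn from
N(mean, sd) (defaults 1.5 ± 0.1 mm); each mask is the cross-section at the
slice's mid-depth rasterized at 0.1 mm/pixel, with in-plane radii jittered
by `area_noise_fraction` (default 0.02) to emulate biological irregularity.
Recorded thicknesses are the true values quantized to the 0.05 mm caliper
resolution, with recorded spread `0.05/√12` mm (quantization uncertainty).
The slicing phase relative to the ellipsoid is random (a slicer starts at
an arbitrary position), which also removes the systematic Riemann-sum bias
a perfectly symmetric alignment would introduce. On 200 seeded replicates
the estimate falls within 2u(V) of the true ellipsoid volume in ≥ 90 % of
cases (computed by the suite and the acceptance script); the residual
non-coverage is sectioning error — the area-at-mid-depth × thickness model
itself — which the propagated measurement uncertainty does not claim to
cover.

## Experiment orchestration

The acoustic experiment places the screen at six positions (axial planes 0
and +7 mm; transverse offsets (0,0), (3,0), (0,3) mm), scans 1 mm beyond
the screen plane, reconstructs marker and control volumes and tabulates
focus metrics; marker and control share seeds, and control outputs are
independent of all marker parameters. The thermometry experiment runs a
sonication schedule (default two shots of 24 acoustic W for 21 s) through
both arms; acoustic power enters only as a scaling of peak ΔT
(default 0.75 °C/W, chosen so a 24 W single-point shot yields ~18 °C peak
rise, comfortably above the 10 °C proxy threshold) — no acoustic-to-thermal
coupling model is attempted because that coupling is a measured, not
modeled, quantity. Every run writes a manifest (config hash, seed, package
version, output list) with no timestamps, so repeated runs are
byte-identical.

## Problem sizes and numerical choices

The suite and acceptance script run the acoustic stages at the native scan
geometry (41×41 at 0.5 mm, 40 000 source points) and scale the orchestrated
experiments to smaller grids (e.g. 15–41 point windows, 2 000–20 000 source
points, 12–25 voxel MR grids), sizes chosen to keep the whole verification
chain fast on a single CPU while leaving every tolerance comfortably met at
the native stages. Voxelized-volume comparisons against closed forms use
even grid counts so sphere centres fall between voxels (lattice-centred
voxelization systematically overcounts). Connected components use
face-connectivity (6) throughout unless configured otherwise; component
ties break toward the first label in raster order.

## Known limitations

* The marker screen is not a scatterer: no reflection back toward the
  transducer, no mode conversion, no standing waves.
* The continuous-bowl source ignores the 256-element array layout, so the
  free-field focal dimensions differ slightly from an element-wise model.
* Signal voids are geometric (radius + smooth roll-off), not computed from
  intravoxel dephasing; no B0 mapping, fat signal, motion, or multibaseline
  thermometry.
* The instantaneous Gaussian deposit approximates a sonication's heating;
  ramped deposition and perfusion are not modeled.
* Synthetic slice masks are ellipse cross-sections; real ablation
  boundaries are irregular and annotated by trained observers.

Passing tests therefore demonstrate correctness of the analysis chain on
fields with these idealized properties, not fidelity of the generators to
any particular device or tissue.
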