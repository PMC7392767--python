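# Methods

## The reconstruction problem

A trans-illumination (bright-field) wide-field microscope images attenuation
contrast — absorption plus weak scattering — of an unstained, translucent
sample on a bright background. A single focal stack cannot section the
sample: the wide-field optical transfer function (OTF) has a *missing cone*
of axial spatial frequencies, so axial resolution is far worse than lateral
resolution (ratio ≈ 4n/NA for the intensity PSF). Classic optical projection
tomography (OPT) recovers 3D structure from angular projections with
filtered back-projection, but its straight-ray model ignores diffraction:
structures beyond the depth of field (≈ λn/NA²) are tangentially smeared,
and the artifact grows with distance from the rotation axis.

This package implements the multi-view alternative: acquire a full focal
stack at each of N rotation angles, reslice every stack into xz sections
orthogonal to the rotation axis, rotate each section about the axis by its
view angle, and average. The rotated copies of the OTF tile frequency space,
filling the missing cone, so the fused reconstruction has isotropic in-plane
resolution without the OPT diffraction artifact. Optional per-section
deconvolution (Wiener or Richardson–Lucy, with the theoretical 2D PSF)
sharpens the fused image further.

## Sampling design

With paraxial aperture angle θ ≈ NA/n, the design rules implemented in
`mvbf.design` are

    Δα   = θ = NA/n                angular step, radians
    N    = 2π/Δα = 2πn/NA          views over 360°
    Δk_z = NA²/(2λn)               axial OTF cutoff, 1/µm
    Δz   = 1/(2Δk_z) = λn/NA²      axial stage step (Nyquist), µm
    M    = L/Δz                    planes per stack for thickness L
    N_TOT = N·M = 2πLNA/λ          total images

`num_views` rounds to the nearest integer (2π/0.13 → 48); `num_z_steps`
takes the ceiling so the stated thickness is always covered (300/31.36 →
10). The paraxial form is the default so that the standard printed instances
(N ≈ 48, Δz ≈ 30 µm, M ≈ 10 at NA = 0.13, λ = 530 nm, n = 1) reproduce
exactly; an exact `asin` option exists. Note these instances assume n = 1;
the calculator takes n explicitly.

A full 360° of views is the default. Half coverage (180°, exploiting OTF
inversion symmetry) is exposed via `make_angle_list(..., full_circle=False)`
but is less robust in the presence of scattering; no quantitative rule for
choosing between them is implemented.

## PSF/OTF model

The detection PSF is generated from the Ewald-sphere construction
(`mvbf.optics`): the coherent transfer function is the spherical cap of
radius n/λ within half-angle asin(NA/n) of the optical axis; the intensity
PSF is |FFT(cap)|², unit-normalised, and the OTF is its Fourier transform
with OTF(0) = 1. Illumination is modelled only through the detection path
(incoherent, detection-only model) even though the instrument matches
NA_ill = NA_det; a partially coherent transfer model is out of scope.

Two cap discretisations:

* **Binary shell** (default): voxels within half a (direction-projected)
  frequency step of the sphere and inside the aperture. Faithful to the
  geometric recipe, but the carrier at k_z ≈ n/λ forces axial voxels finer
  than λ/(2n).
* **Demodulated height field** (`demodulate=True`): the cap is written as
  k_z(k_x,k_y) = √((n/λ)² − k_r²) over the pupil disk, the band centre is
  subtracted (a global k_z translation that leaves the intensity PSF
  unchanged), and each pupil sample is deposited into the two nearest k_z
  bins with linear weights. Only the axial *bandwidth* must fit the grid,
  so PSFs spanning hundreds of µm of defocus can be computed on coarse
  axial grids. Pupil weighting is uniform (no apodisation).

Grids are centred (peak/DC at `shape//2`); odd shapes are recommended. All
normalisation is pinned by the unit-sum (PSF) and OTF(0)=1 contracts, so the
FFT library's scaling convention cannot leak into results. The two
constructions agree on fine grids (FWHMs within a few percent); which one a
simulation uses is recorded implicitly by its grid. The 2D PSF for
deconvolution is the central y section of the 3D PSF, renormalised, and is
generated on the resampled isotropic grid that the reconstruction operates
on.

## Forward simulator

`mvbf.simulate` produces multi-view stacks from 3D attenuation phantoms:

    I(r) = I₀ · (1 − (A_α ⊛ PSF₃D)(r)),   A_α = phantom rotated by −α.

The contrast model is *linear* attenuation convolved with the intensity PSF
(first-Born-like), not exponential Beer–Lambert projection. This matches
what the fusion step assumes — recorded intensities are averaged without a
log transform — and keeps the whole pipeline linear in the phantom, which
the linearity and oracle tests exploit. Attenuation is capped at 1 per
voxel so intensities stay non-negative; the model is intended for weak
absorbers. Multiple scattering, refraction and fluorescence are not
simulated.

The phantom is blurred at the full grid resolution and only then sampled at
the M acquisition planes (linear interpolation at fractional plane
positions), emulating a continuously translating stage. Noise options are
additive Gaussian read noise and Poisson shot noise at a configurable photon
scale; the default is noise-free, which the oracle tests require. Per-view
noise seeds derive deterministically from the base seed and view index.

Sign convention, fixed once and pinned by a round-trip test: the sample
rotation for view α is a rotation of the phantom by −α about the axis
(x toward z), so the reconstruction rotation by +α undoes it.

What the simulator deliberately does not reproduce about real data:
exponential attenuation of strong absorbers, refraction at mounting-tube
walls, partially coherent illumination, depth-dependent aberrations, and
sample drift/wobble. Passing tests therefore demonstrate the correctness of
the *processing*, not the completeness of the *imaging* model.

## Rotation-axis search

Two-step procedure (`mvbf.axis`):

1. **x_c** — minimum- (default) or mean-intensity projections of two views
   180° apart are mirror images about the axis; the 180° projection is
   flipped along x and registered by phase correlation (integer pixels by
   default, subpixel optional). x_c = (W−1)/2 + Δx/2 in 0-based pixel
   coordinates (image centre of a width-W image is (W−1)/2; flip maps column
   i → W−1−i). Minimum projection is the default because absorbing
   structures are dark on a bright background. A normalised correlation
   score below a configurable floor flags the result as low-confidence.
2. **z_c** — a single xz section is fused for each candidate z_c; the
   correct axis maximises the reconstruction contrast, measured as the
   Fourier energy excluding DC (unnormalised DFT): Σ'|F|² =
   N_pix·Σx² − (Σx)² by Parseval, an identity the implementation satisfies
   exactly and that makes the metric offset-invariant. "Energy" (|F|²) is
   used rather than |F| because it admits that exact identity. Candidates
   are offsets on the resampled isotropic grid relative to the section's z
   centre; ties break toward the centre; a flat curve raises a no-signal
   error.

For a tilted axis, x_c/z_c estimated at ≥ 2 y positions are fitted linearly
in y (exact interpolation for two samples).

## Fusion, deconvolution, baseline

`mvbf.recon` reslices each stack into per-y xz sections and linearly
resamples z to the lateral pixel size *before* rotation, so rotations act on
square pixels; deconvolution, when requested, also runs on this isotropic
grid with the matching 2D PSF. Rotation is inverse-mapped bilinear
interpolation about the continuous axis position; out-of-support pixels take
the plane's border median (the bright background dominates borders in
trans-illumination), overridable. Views are summed in sorted-angle order and
divided by N — fill values included, so the operator is linear and
order-independent; a per-pixel-coverage weighting is deliberately not the
default.

Deconvolution operates on the inverted plane (signal = background −
intensity, background = border median) because Wiener and Richardson–Lucy
assume additive signal on a zero background, then inverts back. Wiener is
the direct frequency-domain filter H*/(|H|² + K); since the PSF is unit-sum,
peak |H|² = 1 and K (default 10⁻²) is effectively relative regularisation.
Richardson–Lucy (default 20 iterations) delegates to
`skimage.restoration.richardson_lucy` with clipping disabled and output
clamped non-negative. Both defaults are exposed; no systematic
regularisation study is implied.

The OPT baseline (`fbp_baseline`) exists only for artifact comparison: each
view contributes the single fixed-focus plane nearest the axis, converted to
attenuation (background − I), and the per-y sinogram is reconstructed with a
ramp-filtered inverse Radon transform (`skimage.transform.iradon`, theta
negated to match this package's rotation sense; axis shifted to the column
centre beforehand). An extended-depth-of-field merge is deliberately not
used — the fixed-focus projection is what produces the diffraction-artifact
phenomenology the multi-view method is compared against.

`fwhm` measures widths by bilinear profile sampling (0.25 px steps) with
linear interpolation at the half-maximum crossings; it raises when a profile
never reaches half maximum inside the grid (callers treat that as a width
lower-bounded by the grid).

## Numerical choices and problem sizes

* Tolerances: PSF symmetry and Parseval identities are exact to float
  round-off; interpolation-based round trips use 2% of dynamic range;
  axis recovery is asserted at 1 px / 1 candidate step.
* Degenerate inputs: empty candidate lists, flat contrast curves, mixed
  plane shapes, non-finite images, RGB or truncated TIFFs and invalid
  manifests all raise typed errors rather than propagating garbage.
* Test problem sizes were chosen as the smallest grids that keep the
  physics honest: 129³ frequency grids for the NA 0.13 OTF (axial voxels
  0.25 µm < λ/2n), 97² sections with an NA 0.5 / 65³-PSF system for axis
  and fusion statistics, and a 461² scene at 2 µm pixels for the off-axis
  artifact comparison, where 200 px = 400 µm ≫ the 31 µm depth of field of
  the NA 0.13 system. Single-y-section phantoms use an exact 2D reduction
  of the 3D convolution for speed.
* The isotropy and artifact-reduction experiments use the design-formula
  acquisition parameters themselves (48 views / Δz = 31.36 µm at NA = 0.13;
  45 views at 8° for the comparison scene).

## Known limitations

* The linear attenuation model saturates for optically thick samples; no
  log-domain option is provided for the multi-view path (only the FBP
  baseline converts to attenuation).
* Axis wobble (time-varying axis) and fiducial-based registration are out
  of scope; only a linear tilt in y is modelled.
* The depth-invariant PSF assumption ignores aberrations and
  sample-induced refraction.
* GPU acceleration is not implemented; the per-y independence of
  `reconstruct_volume` is the parallelisation contract.
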