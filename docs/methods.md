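# Methods

## Physical model

ZTE acquisitions play a short rectangular RF pulse of duration τ while the
frequency-encoding gradient **G** is already at full amplitude. In the
small-tip regime the transverse magnetization created at position **r** is
proportional to the Fourier transform of the pulse envelope evaluated at the
local off-resonance, i.e. a normalized sinc along the gradient direction:

    w(r) = nsinc( τ (γ̄ G·r − Δf) ),    nsinc(x) = sin(πx)/(πx),

with γ̄ = γ/2π in Hz/T and Δf the carrier offset of the pulse. The package
works with this analytic profile rather than a Bloch simulation: all
comparisons are relative, so the absolute flip-angle scale is dropped, and
for flip angles of a few degrees the Fourier (small-tip) profile and the
Bloch profile are indistinguishable at the tolerances used here. The
profile is treated as real, which corresponds to referencing time to the
pulse's effective amplitude center; the measured pulse asymmetry (default
0.53, i.e. the effective center sits at 53% of the duration) therefore does
not enter the simulated weight, only the NCO phase bookkeeping
(`nco_phase_correction`), which is what a sequence programmer needs to keep
the shifted pulse and the receiver phase-coherent.

Derived quantities: first zero crossing r_zc = 1/(γ̄ G τ); FWHM =
2·x_half·r_zc with x_half ≈ 0.603355 the numerical root of nsinc(x) = 1/2.
At τ = 8 µs, G = 20 mT/m this gives 14.68 cm and 17.71 cm. The FWHM is
commonly quoted as 17.5 cm for these parameters; the ~1.3% discrepancy is
rounding in the quoted figure, and the analytic value is authoritative here.

Excitation schemes: `ideal` (profile ≡ 1, a non-physical reference),
`isocenter` (IsoEx, Δf = 0 every shot) and `offcenter` (OffEx,
Δf = γ̄ G·r₀ recomputed per shot from that shot's gradient). OffEx with
r₀ = 0 is bit-identical to IsoEx by construction.

## Trajectory

Radial spokes have constant gradient magnitude and direction-only updates.
Sample radii are k_j = γ̄ G (t_dead + j·dwell), starting at the dead-time
gap k_gap = γ̄ G t_dead. 3D directions use spiral-phyllotaxis ordering
(z_i = 1 − 2(i+0.5)/n, azimuth i·golden angle), a documented stand-in for
scanner spiral orderings: only coverage uniformity, not shot order, affects
the simulated images. 2D mode uses uniform azimuths (half circle by
default, full circle for the demos, where no conjugate synthesis is done).
The gap is filled by single point imaging: all Cartesian lattice points
with |k| ≤ k_gap at spacing 1/FOV, each acquired at encoding time TE with
gradient G = k/(γ̄ TE). With TE equal to the dead time (the default) the
outermost SPI points carry the full radial gradient; the "SPI is nearly
ideal" intuition therefore holds only for objects compact relative to
r_zc — a regime the tests respect and state.

k-space is measured in cycles/meter; the forward kernel is e^{−i2πk·r}, the
adjoint/reconstruction kernel e^{+i2πk·r}.

## Forward simulation

Each shot weights the phantom by w(r) for that shot's gradient and Δf and
evaluates the plain discrete Fourier sum at its sample positions (times the
voxel volume). The direct sum — not an interpolating NUFFT — is the
contract, so forward-model accuracy never depends on gridding parameters;
radial spokes use the separability of k = k·d̂ to keep this cheap. Optional
complex white Gaussian noise (per-component σ, seeded) can be added;
default off. Relaxation (T2* during readout) and coil sensitivities are
deliberately omitted.

Sinograms are computed through the central-slice theorem: the full-diameter
radial k-line of the profile-weighted image, inverse-FFT'd to the detector
grid. Antipodal spokes share one weighted image because the sinc is even in
(G·r − Δf).

## Reconstruction

Pipeline: density compensation → optional Fourier-shift modulation
e^{+i2πk·r₀} of the samples (moves the object at r₀ to the image center) →
Kaiser–Bessel convolution gridding onto a 1.5× oversampled grid (width 4
cells, β from Beatty's expression) → optional radial Hamming window
0.54 + 0.46·cos(π|k|/k_max) up to the spherical sample edge k_max (not the
grid corner) → inverse FFT → deapodization by the kernel's analytic
transform, floored at 10⁻⁶ of its peak → crop to the nominal matrix.
Kernel footprints wrap periodically at the grid edge, which is exact in the
DFT sense for samples at the Nyquist boundary.

Density compensation (`radial_analytic`, default): radial samples get the
analytic shell volume |k|^(d−1)·Δk_r·(2π or 4π)/n_spokes with the radius
floored at max(k_gap, Δk/2); SPI points get the Cartesian cell volume Δk^d;
samples in the one-cell overlap shell at k_gap are halved on both sides; and
all samples inside the central Cartesian cell are renormalized to share one
cell volume in total (this makes dead-time-free spokes, which all pass
through DC, well-behaved). With these cell-volume weights the gridded
inverse transform approximates ∫S(k)e^{+i2πk·r}dk, so the reconstructed
amplitude is directly comparable to the phantom. A Voronoi mode (2D) and a
`uniform` mode (no compensation, for demonstrating its necessity) exist.
Known limitation: when the SPI core spans only a few Cartesian cells, the
blocky lattice boundary against the first radial shell leaves a few percent
of shell-weighting error; the Voronoi mode handles such geometries better.

On ≤48² problems the full gridding chain agrees with the explicit adjoint
DFT to NRMSE ≈ 3·10⁻³ (tested at <10⁻²).

## Phantoms

Deterministic, voxel-center sampled (edges are ideal steps); an optional 2×
supersampled anti-aliased mode produces band-limited-friendlier edges and
is used where a test compares against continuum formulas (Airy disk
transform, rotate-and-sum projections, reconstruction fidelity) — a
voxel-sharp step has energy above Nyquist that no Fourier method can
recover, so those comparisons would otherwise measure the substrate, not
the method. Axis convention: (x, y[, z]) index order, coordinate of index
i is (i − n/2)·voxel, so index n/2 is the isocenter. Available: uniform
disk/ball, a resolution pattern (rim plus three bar groups of pitch 8/6/4
voxels), and the two-object phantom (one disk at the isocenter, one at
polar position (r₀, θ₀)) used for the sinogram trade-off experiment.

## Edge-sharpness metric

Line profiles (linear interpolation at one-voxel spacing) are fitted by
nonlinear least squares to SI(i) = c₁/(1 + 10^{s(c₀−i)}) + c₂ — base-10
literally, so s is "decades per sample". Profiles are oriented dark→bright
before fitting, removing the sign ambiguity in s; initialization uses the
profile extrema, the half-range crossing and the 10–90% width; tolerances
1e-10, at most 500 function evaluations, non-convergence returns the best
parameters flagged. Noiseless synthetic sigmoids are recovered to 1e-6;
with 1%-of-range noise the median fitted s over 100 realizations stays
within 5% of truth. `roi_snr` is mean(|signal ROI|)/std(|noise ROI|) — a
package convention, stated because SNR definitions vary.

## Packaged experiments and what they show

`run_sinogram_demo` (128², 180 angles, 20 mT/m): two-object phantom with
the off-center disk at r_zc. Errors vs the ideal sinogram are restricted to
each object's *exclusive* support (its support minus the other object's),
because the two objects' projections overlap at many angles and the
deliberately sacrificed isocenter object would otherwise contaminate the
off-center object's score. Result: OffEx cuts the off-center object's error
~30× while the isocenter object's error grows by a similar factor — the
scheme's defining trade-off.

`run_recon_demo` (96², offsets {0, 5, 10} cm, G ∈ {20, 30} mT/m): disk
phantom simulated under all three schemes, reconstructed with the full
pipeline, scored by NRMSE vs the ideal-excitation reconstruction over the
object support and by median rim sharpness. Two desk-scale choices matter:

1. **Dead time 6 µs, not the clinical 0.05 ms.** The demo matrix is 96, so
   k_max ≈ 120 cycles/m instead of ~1000 at clinical resolution. Keeping
   the clinical dead time would make the SPI core — whose samples are
   nearly profile-clean — cover a third of the k-space radius and hide the
   radial-spoke artifact the experiment exists to measure. Scaling the
   dead time preserves the clinical gap-to-extent ratio (~5%); the
   trajectory default elsewhere remains 0.05 ms.
2. **Sharpness segments sit on the outward rim sector** (±45° around the
   offset azimuth), where the profile distortion is strongest — matching
   how edge profiles are chosen in practice (in the regions with the
   largest visible distortion). Inner-rim edges are nearly artifact-free
   and would dilute the median.

Result at 10 cm / 20 mT/m: median s ≈ 0.85 (OffEx) vs 0.27 (IsoEx), a >3×
contrast; IsoEx error grows monotonically with offset and with gradient
amplitude.

What the synthetic experiments do *not* show: absolute in-vivo sharpness or
SNR values (they depend on scanner data, coil profiles, relaxation and
noise not modeled here), multi-channel behavior, gradient-nonlinearity
distortion, or second-echo effects. The demos reproduce directions and
ratios, not scanner-specific magnitudes.

## Numerical choices and degenerate inputs

Zero gradient on a radial shot, overlapping two-object placements, disks
crossing the FOV boundary, flat line profiles, empty ROIs and a pulse
longer than the NCO raster are all rejected with specific errors; a zero
gradient in SPI is valid (DC point, weight 1). Zero gradient or zero τ in
the zero-crossing/FWHM analytics raises a dedicated "unbounded profile"
condition rather than returning infinity. All randomness (acquisition
noise) flows through a single integer seed; phantom generation and both
demo reports are bit-reproducible, and JSON reports are written with sorted
keys and no timestamps so reruns are byte-identical.
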