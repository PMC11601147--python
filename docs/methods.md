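# Methods

`opusdmi` implements non-iterative ("direct") model-based inversion (DMI)
for pulse-echo ultrasound imaging with very low channel counts — the regime
of optical ultrasound (OpUS) probes, where each of a few dozen
photoacoustic sources fires in turn and a single fibre-optic detector
records the backscatter. This note documents the model, its assumptions,
the numerical choices, and the limits of what the synthetic studies show.

## Imaging model

The medium is water-like, homogeneous (speed of sound `c`, default
1500 m/s), with weak, temporally invariant scattering contrast `R(r)`.
Under linear propagation and the Born approximation the recorded B-scan is
linear in the reflectivity, `B = P R`, where each column of the system
matrix `P` is the flattened multi-channel record of a unit point scatterer
in one image pixel. The pulse-echo trace of source `k` for a scatterer at
`r_img` is assembled in the frequency domain as

    B(k, w) = H(r_img − r_src,k, w)
              · exp(−i w |r_img − r_rec| / c) / (4π |r_img − r_rec|)
              · i w v(k, w),

with `H` the spectrum of the spatial impulse response (SIR) of a circular
piston of radius `a` (default 100 µm) in a rigid baffle, the free-space
Green's function for the scatterer→receiver leg (the receiver is a point
detector with flat frequency response), and `i w v` the time-differentiated
surface-velocity signature. Absolute transduction amplitudes are not
modelled; all images are presented normalised.

Assumptions inherited by every result: single (Born) scattering, lossless
non-dispersive homogeneous background, identical sources, point receiver,
temporally static contrast.

### SIR evaluation

The rigid-baffle circular-piston SIR has closed piecewise form — a
rectangle of height `c` while the full disc is visible, then a
`(c/π)·arccos` branch between the near-edge and far-edge arrivals `R1/c`
and `R2/c`. Its spectrum is evaluated as an exact Fourier integral: the
rectangle analytically, the arccos branch by Gauss–Legendre quadrature
whose node count scales with the time–bandwidth product
`ω_max (R2 − R1)/(2c)` of the pair. Node counts are quantised to a fixed
ladder (8…128) that depends only on the pixel–source pair itself, so a
matrix column is identical no matter how pixels are blocked during
assembly. `quad_density` scales the node budget and is the convergence
knob; halving it changes traces by well under 0.5 % (asserted in the test
suite). Near-axis pairs — whose SIR support shrinks below a nanosecond and
cannot be sampled on any practical time grid — are handled exactly by the
analytic rectangle term.

### Sampling convention

Spectra are evaluated on the rfft bin grid of an `oversample`× (default
8×, i.e. 500 MSa/s) zero-padded record and the acquisition-rate trace is
obtained by alias-folding the one-sided spectrum, which is mathematically
identical to point-sampling the continuous trace at the ADC instants (an
ADC without an anti-alias filter; the tone-burst studies carry negligible
energy near the folded band). Point sampling was chosen over ideal
low-pass resampling because it preserves causality: traces vanish to below
1e-6 of peak before the geometric onset, whereas sinc tails of a band
limitation to fs/2 sit orders of magnitude higher. The padded length
covers the record plus the signature duration plus the rigorous SIR-support
bound `2a/c`, so circular wrap-around cannot reach the stored samples.

A fully independent time-domain route (`channel_trace_timedomain`:
bin-averaged closed-form SIR on a 128× grid, numerical differentiation,
convolution, Green's delay and scaling) exists for cross-validation; the
two routes agree to ≤1 % relative L2 and the test suite asserts it on
random pairs.

## Inversion

The economy SVD `P ≈ U S Vᵀ` is truncated to normalised singular values
`S/max(S) ≥ sv_threshold` (default 1e-4). Reconstruction applies a
regularised reciprocal `S⁺` — TSVD hard thresholding (`1/s` where
`s ≥ α·max S`, ties kept) or the Tikhonov filter `s/(s² + (α·max S)²)` —
through the two-stage product `R = V [(S⁺ Uᵀ) B]`; the full pseudo-inverse
is never materialised, and changing the regulariser or `α` only rebuilds
the cheap `S⁺ Uᵀ` stage. The default `α = 1 %` Tikhonov is the
best-trade-off setting of the underlying study; smaller `α` sharpens but
amplifies noise, larger `α` over-smooths (image norm is monotonically
non-increasing in `α`, asserted as a property test).

Two deterministic factorisation backends exist. Matrices whose smaller
dimension is ≤2048 use LAPACK `gesdd` in double precision (exact; all
factor invariants, including U/V orthonormality to 1e-4 and the
Eckart–Young residual bound, are validated on this path). Larger matrices
use a Gram route — `PᵀP` accumulated in float64 via a BLAS rank-k update,
`dsyevd`, then `U = P V S⁻¹` in single precision — which is an order of
magnitude faster at the sizes used here. Its retained singular values are
accurate down to ~1e-6 of the largest, comfortably below the 1e-4
truncation threshold, but the orthonormality of U columns degrades towards
the smallest retained values (≈`eps32·σmax/σ`), so the backend is labelled
approximate; at `α = 1 %` the effect on images is at the 1e-6 level
because those directions carry almost no reconstruction weight. Stored
factors are single precision; the two-stage products accumulate in double.

## Delay-and-sum baseline

The comparison baseline sums, for every pixel, the RF samples of all
channels at the geometric round-trip delay
`τ = (|r_src − r_img| + |r_img − r_rec|)/c` (linear interpolation; samples
outside the record contribute zero; no apodisation — the wing-shaped
grating-lobe artefacts of the sparse aperture are deliberately left
untouched). Envelope detection is the magnitude of the axial (column-wise)
analytic signal, applied after summation; the same envelope is applied to
DMI images before metrics so the two algorithms are measured identically.

Because neither algorithm deconvolves the source signature, the axial
point-spread function carries the burst envelope. For D&S this also
shifts the envelope peak ~`c·T/4` (≈140 µm for the four-cycle 11 MHz
burst) beyond the scatterer; DMI, which models the burst inside `P`,
localises the scatterer on its true pixel.

## Synthetic data

The simulator is an independently discretised single-scattering
(Rayleigh-integral) forward model: each source disc is tiled into square
sub-elements (default pitch 25 µm = a/4, with the tile areas normalised to
the exact disc area), each (sub-element, scatterer, receiver) path
contributes a `1/r`-weighted copy of the differentiated signature at its
exact delay, delays are placed by linear interpolation on the 8×
oversampled grid, and an ADC anti-aliasing filter removes content above
the acquisition Nyquist before the record is sampled, as a real digitiser
front-end does. Aperture integration, delay quantisation and code path
all differ from the analytic-SIR spectral assembly; the two models agree
to a few percent on point targets but are never bit-identical — the test
suite asserts both the agreement and the non-identity, which is the
guard against the "inverse crime" of reconstructing data generated by the
inversion's own model.

The signature is a four-cycle 11 MHz tone burst with a Hann window by
default (rectangular and Gaussian windows are switchable). A windowed
burst is what the underlying study's wave-solver tone burst produces, and
a rectangular window would roughly double the axial envelope width.

Phantom builders reproduce the four synthetic scenes of the study: a point
scatterer at 5 mm depth (Born reflectivity `2·Δc/c0` for the +70 m/s
assignment), three 2 mm discs at 3.5 mm depth with sound speeds drawn
uniformly from ±3/±20/±60 m/s bands, two 3 mm-layer media with contrast in
speed only (1450/1500/1540 m/s) or density only (967/1000/1027 kg/m³)
whose interfaces carry the plane-wave reflection coefficient
`(Z2−Z1)/(Z2+Z1)`, and a vessel-lumen cross-section (lumen c = 1570 m/s)
with an optional needle (c = 2000 m/s, ρ = 1500 kg/m³) as a strong linear
reflector. Direct source→receiver cross-talk — which exceeds the echo
amplitude because it travels one leg instead of two — can be simulated
separately and subtracted, mirroring the acquisition practice. White
Gaussian noise at a prescribed SNR is available; all randomness flows
through explicit seeds (package default 20241121).

What the simulator does **not** model: full-wave propagation (refraction,
shadowing, reverberation through the layered media), elevationally
extended ("2-D") scenes, attenuation, non-linear detector response.
Consequently the layered/vessel scenes are qualitative here, and measured
clutter levels on clean 3-D synthetic data are systematically lower than
on wave-solver or experimental data — see "Desk-scale study" below.

## Desk-scale study and metrics

The quantitative configuration uses 64 sources uniformly spaced over a
15 mm aperture (the physical probe's irregular layout is unpublished;
uniform spacing with optional seeded jitter is the stand-in — with 200 µm
discs at 238 µm pitch there is little room for jitter anyway), receiver
central, 62.5 MSa/s records cropped to the two-way span of each window.
The study's system matrix uses the impulse (delta) signature; the tone
burst lives only in the data and is not inverted for, which bounds the
axial point-spread function of DMI and D&S identically.

Resolution and signal-to-clutter are measured on a 4×3 mm window centred
on the point target at the native 50×25 µm pitch (81×121 pixels; matrix
32 768×9 801); grating lobes are measured on a laterally widened 7×1.5 mm
window at the same pitch, cropped around the wing-shaped artefact region
and the main lobe (141×61 pixels). The 50×25 µm pitch is not cosmetic:
the axial pitch must sample the two-way band of the data (c/2 per ADC
Nyquist interval ≈ 24 µm) for the image grid to be able to *represent*
burst-bearing data through an impulse-signature matrix — on coarser grids
the unrepresentable residual of the least-squares fit surfaces as
wing-region clutter. On one CPU core the whole study runs in roughly a
quarter of an hour, dominated by the two factorisations.

Metrics: FWHM is the −6 dB width of the envelope profile through the image
peak with linear sub-pixel crossing interpolation (the −20 dB width is
reported alongside by `fwhm_profile_widths` since display conventions
differ); signal-to-clutter ratio is `20·log10(peak in a 0.5×0.5 mm signal
box / RMS outside a 1.5×1.5 mm exclusion box)`, both centred on the image
peak and reported with every value; grating-lobe reduction is the
difference of the two images' lobe-region peaks, each in dB relative to
its own maximum, over the declared region `|x| ≥ 2.5 mm`.

### What the desk-scale study does and does not reproduce

Resolutions reproduce: with the impulse-signature matrix neither
algorithm deconvolves the burst, both point-spread functions carry the
burst envelope axially and the aperture diffraction limit laterally, and
the D&S and DMI widths agree with each other and with the expected
~150–200 µm scale.

Clutter and lobe metrics are floor-limited quantities and the floors here
differ structurally from those of the original-scale study, which
measured them on a 2-D pseudo-spectral simulation (elevationally extended
sources and scatterer lines, solver noise, a full 10×7 mm reconstruction
field, and a heavily truncated operator — a quarter of the singular
spectrum retained). In this package's clean 3-D Born scenes:

* the noiseless D&S image has a clutter floor far *below* the tabulated
  D&S signal-to-clutter value — coherent summation over 64 channels of
  artefact-free data simply leaves very little clutter in a small window;
* the DMI image's floor is set by the part of the burst-bearing data that
  an impulse-signature operator cannot represent on the image grid (the
  depth-to-delay slope of a reflectivity comb is angle-dependent, so a
  single axial burst profile cannot match all 64 channels at once over a
  ±56° aperture). That residual reproduces the tabulated DMI
  signal-to-clutter magnitude, but it concentrates partly in the
  wing-shaped lobe region, where the tightly cropped reconstruction
  window offers the least-squares fit nowhere else to put it. The
  original-scale operator, with its much larger field and far heavier
  effective truncation, absorbs and damps this residual instead.

Consequently the D&S-vs-DMI clutter ordering and the grating-lobe
reduction of the original study do not carry over to these reduced,
noiseless conditions, and the acceptance script reports what the package
actually computes. When the system matrix is instead built with the
tone-burst signature (supported; used by the parameter-recovery tests),
the representation residual disappears, DMI localises the scatterer on
its true pixel, sharpens beyond the D&S resolution and strongly
suppresses the wing artefacts — at the price of no longer matching the
study design in which the signature is deliberately not inverted for.

## Known limitations

* Uniform source spacing makes the transmit aperture exactly periodic;
  grating-lobe behaviour of a genuinely irregular probe will differ in
  detail.
* The gram factorisation backend's U-columns lose orthonormality at the
  smallest retained singular values (documented above).
* No attenuation, dispersion, multiple scattering, or finite receiver
  aperture; no measured per-source signatures.
* The CLI `demo`/acceptance configurations are desk-scale reductions; the
  full-size 10×7 mm, 1004-sample configuration is supported by the same
  code but its ~13.5 GiB matrix and factorisation are workstation-class
  jobs, not test-suite jobs.
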