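# Methods

This note records the models, parameter choices and numerical decisions
behind `holoplankton`, and what the synthetic experiments do and do not
demonstrate.

## Recording model

The simulator implements a transmission off-axis DH microscope in its
simplest faithful form. The object is a *pure phase* transparency: the
object wave is `O = A·e^{iψ_o}` with unit amplitude everywhere (`A = 1`
by default; fixed diatoms also absorb, which is not modeled). The
reference is a unit-amplitude tilted plane wave
`R = e^{−i[2π(fx·x + fy·y) − φ_R]}` with `φ_R = 0` by default — only the
phase difference matters, and the bias dimension of the augmentation
lattice absorbs constant offsets. The recorded intensity is `|R + O|²`
evaluated pointwise; optional additive Gaussian read noise (standard
deviation `noise_sd` on an intensity scale of 0–4) is clipped at zero.
Coordinates are row-major with pixel (0, 0) at top-left,
`x = column·pitch`, `y = row·pitch`.

Defaults: wavelength 532 nm, pixel pitch 5.5 µm, sensor size
configurable (2048² default, smaller in tests). The carrier is placed
bin-aligned at 0.35 cycles/pixel per axis (≈ 99% of the Nyquist magnitude
along the diagonal), which maximizes the separation of the +1 order from
the DC term and hence the usable object bandwidth.

## Phantom morphology

Each class draws one object from four parametric families echoing diatom
morphology: pennate outlines with longitudinal striae, centric valves
with m-fold azimuthal ornament (m ∈ {6, 8}, weighted by ρ² so the
gradient stays finite at the center), concentric rings, and rounded
rectangular valves (superellipse exponent 4) with transverse ridges.
The envelope is a flat core with a wide Gaussian shoulder rescaled to
reach exactly zero at 1.6× the nominal radius — no truncation step, which
would ring through the bandpass. Peak phase is drawn from 6.5–7.2 rad
(beyond 2π, so the extracted phase genuinely wraps), nominal radii from
11–14 px (support diameters ≈ 160–210 µm at 5.5 µm pitch, the upper range
of test-slide diatoms), ridge periods 11–15 px, modulation depth 0.15.

These values are deliberately calibrated so that the objects are
*resolvable by the simulated optics*: the maximum phase gradient stays
inside the demodulation passband (≈ 0.25 cycles/pixel). Steeper phantoms
are physically unrecordable by the modeled system — their reconstructed
amplitudes carry strong truncation artifacts and contrast-metric
autofocus degenerates, exactly as it would on over-steep real samples.

Objects are placed on a jittered grid in reading order (one per cell),
mirroring a commercial slide layout; placement raises if the requested
count cannot fit disjointly.

## Reconstruction

*Demodulation* multiplies the intensity by the conjugate carrier (an
exact spectral shift for any carrier, bin-aligned or not) and applies a
circular low-pass of radius `f_c/2` whose outer 30% rolls off as a raised
cosine. A hard-edged filter was measured to displace the Tamura autofocus
minimum by several final-bracket widths through focus-plane ringing; the
soft edge removes most of that bias. Optionally (default: 2 iterations)
the estimate is refined against the forward model — re-synthesize
`|R + O_est|²`, bandpass the residual, add it back — which suppresses the
leakage of the DC autocorrelation and twin-image tails into the passband
for strongly defocused objects. Plain textbook demodulation is available
via `soft_edge_frac=0, iterations=0`.

*Propagation* uses the Angular Spectrum transfer function
`exp(i·2π·dz·√(1/λ² − f_x² − f_y²))` with evanescent components zeroed
(also stabilizes back-propagation). At 5.5 µm pitch no propagating
frequency is evanescent, so propagation is unitary and exactly
invertible, which the round-trip tests exploit.

*Autofocus* minimizes the Tamura coefficient `√(σ/μ)` of the amplitude
(population standard deviation) — the standard DH contrast-metric choice
for pure-phase objects — over a 21-point coarse grid followed by 3
grid-halving refinement rounds and one final parabolic candidate. The
parabolic point is *evaluated*, so the reported `z_best` is always the
argmin over evaluated distances. A warning (never an exception) is issued
when the coarse minimum sits on the search boundary.

Measured recovery under the wet study conditions (single objects drawn
uniformly in a ±3.5 mm volume, searched over ±4 mm; final bracket 50 µm):
median error ≈ 9 µm over 40 draws, 98% within one bracket. The residual
tail is intrinsic to the metric: a strongly retarding phase object acts
as a weak lens and displaces the amplitude-flatness plane by tens of
micrometers — ~2% of draws show a displaced Tamura minimum of up to a few
hundred micrometers. This is a property of contrast-metric autofocus, not
of the implementation.

*Piston compensation.* Numerical refocusing by `z` multiplies the whole
field by `exp(i·2π·z/λ)` — at millimeter distances and 532 nm an
essentially uniform random global phase; real recordings accumulate
comparable offsets from the reference arm. The pipeline therefore
rotates every reconstructed field so the argument of its complex mean
(background-dominated for a transparent scene) is zero before phase
extraction. This is the constant term of the usual aberration
compensation; its *residuals* are exactly what the bias dimension of the
augmentation lattice models, and the wet fixtures re-inject a random
residual bias in [0, π] on top.

*Phase extraction* takes the per-pixel argument with the half-open
convention `wrap(π) = −π`; all stored phase images satisfy
`−π ≤ ψ < π` as an enforced type invariant.

## Segmentation

Otsu's threshold (256-bin, via scikit-image) on |phase|, hole filling
(wrapping creates near-zero rings *inside* strong objects, so filling is
load-bearing), 8-connected labeling, minimum area 100 px, 8 px crop
padding with background zeroed. Objects are returned sorted by bounding
box origin — slide-layout order for a well-separated slide. On synthetic
slides, class identities are assigned by one-to-one linear-assignment
matching of centroids against ground truth (gate: 2 px).

## Augmentation

The lattice is the Cartesian product of 21 scales per axis (±20%, 2%
steps, anisotropic — the only reading consistent with a 21×21 count), 36
rotations (10° steps) and 11 biases evenly spaced on [0, π] (a
random-draw mode exists behind a flag): 174,636 tuples per class,
8,731,800 over 50 classes. Transforms apply in the fixed order resize →
rotate → bias, each followed by the 2π-modulation operator. Interpolation
acts on wrapped values directly, so localized artifacts appear where
bilinear interpolation crosses a wrap discontinuity — the deliberate
consequence of keeping every intermediate in WQPI format. The transformed
crop is trimmed to its support before the bias is added and the result is
center-placed on a phase-0 canvas (default 256², 56² at desk scale);
oversized objects raise.

Sampling a per-class subset is without replacement, per-class
deterministic substreams; the 80/20 split is stratified per class with
`round(0.8·n)` training rows (21,000 → 16,800/4,200 exactly).

## Classifier and ensemble

Desk scale uses small numpy CNNs (two 3×3-conv + ReLU + 2×2-max-pool
blocks and a linear softmax head; ~5k–9k parameters) on 56² phase
canvases average-pooled to 28². Three members of different widths stand
in for the distinct deep families a GPU-scale study would fine-tune; they
share data and differ in width and seed. The training protocol is fixed:
mini-batch SGD, momentum 0.9, weight decay 0.001, early stopping after 5
epochs without validation-loss improvement (cap 200; the desk pipeline
caps at 30), and restoration of the minimum-validation-loss checkpoint.
The protocol's 0.001 learning rate targets fine-tuning of pretrained
networks; training from random initialization at desk scale uses 0.01
(the `TrainConfig` default remains 0.001). Cross-entropy is the loss;
inputs are gray values in [0, 1] mapped linearly from [−π, π); a
channel-replication flag exists for 3-channel architectures.

Max voting takes the per-sample modal label; ties break by highest mean
confidence among the tied labels' voters, then lowest class id — a
documented deterministic rule verified against brute-force mode
computation. `select_ensemble` keeps models with accuracy strictly above
the threshold (default 0.90) and warns when none qualifies.

## Wet-fixture evaluation

Each wet test object re-renders its class's ground-truth phase at a
random pose (rotation 0–360°, per-axis scale ±20%), embeds it in a 128²
single-object volume, records it with a random defocus in ±3.5 mm and
intensity noise 0.05, then runs the full recovery chain: demodulate →
autofocus → propagate to `z_best` → piston compensation → extract →
segment → trim to support → add a random residual bias in [0, π] →
classify. Train and test therefore share no images: training sees only
augmentations of the *reconstructed dry* generator, testing only
refocused noisy re-renders of the *ground truth*.

Both recordings share the instrument, so the dry training hologram
carries the same read noise (0.05) as the wet ones; training on a
noise-free dry recording measurably fails to transfer, because the
classifier never sees background speckle. Likewise the wet crop is
trimmed to its object support before the residual bias is added, giving
it the same biased-rectangle geometry the augmented training images
have.

## Problem sizes

The package's own study conditions are desk-scale: a 5-class 512² slide,
500 sampled augmentations per class (80/20 split), three ensemble
members, and 20 wet objects per class; the 50-class slide for the
segmentation count runs at 1024². Full-scale quantities (174,636/class;
21,000 sampled; 8,731,800 total) are verified analytically on the lattice
and the manifest plan rather than materialized.

## What the synthetic experiments do not show

The phantoms are smooth parametric objects with exact pure-phase
behavior, no absorption, no aberrations, no partial coherence, no camera
response, and no within-species biological variability beyond the pose
lattice. Passing the end-to-end test demonstrates that the chain —
recording, demodulation, refocusing, segmentation, lattice augmentation,
protocol training, max voting — is internally consistent and recovers
ground truth; it does not certify accuracy on real diatoms, which depends
on optical quality and on how well one specimen represents its species.
Phase unwrapping and aberration compensation are out of scope (the bias
augmentation models residual constant offsets only).
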