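# Methods

## The model

A cryo-EM particle image is modelled in Fourier space as the CTF-modulated
sum of central slices through the 3D transforms of B rigid bodies, plus
frequency-dependent complex Gaussian noise:

    X_i = CTF_i * sum_b P_{phi_ib} V_b + N_i,     E|N_i(k)|^2 = sigma^2(|k|)

Each body b is a user-defined region of the complex, delimited by a soft
mask, assumed internally rigid but free to reorient slightly in every
particle.  Its pose `phi_ib` is the particle's consensus pose composed with
a small per-body *residual* pose: three Euler-angle offsets (degrees) and an
in-plane translation (pixels).  Bodies are reconstructed with the
centre-of-mass (COM) of their mask at the box centre and rotate about that
point; the in-plane projection of the rotated COM re-enters the composed
projection geometry, so a zero residual reproduces the consensus placement
exactly.

Residual rotations are parameterised as offsets from the Euler triplet
(rot=0, tilt=90, psi=0) conjugated into a per-body frame whose third axis is
the unit vector from the body's COM to the COM of its rotation-reference
body.  This avoids the ZYZ gimbal degeneracy at tilt=0 and makes the three
offset coordinates rotate the body about three near-orthogonal axes (two
orthogonal to the COM axis, one twisting about it).  The frame's in-plane
axes are completed deterministically (first axis orthogonal to both the COM
axis and the lab z axis where possible, else the lab x axis); this choice
affects only the serialized angles, not the geometry.

## Expectation-maximization

Per iteration, for every particle and body:

1. **Partial signal subtraction.**  The CTF-modulated projections of all
   *other* bodies, at their best poses from the previous iteration, are
   subtracted from the particle transform.  Only the non-overlapping part
   of each other body's mask is subtracted: bodies earlier in the
   definition file take precedence, and the partial mask of body b' for
   target b is `m_b' * prod(1 - m_k)` over the target and all earlier
   bodies — the multiplicative rule reduces to strict set subtraction for
   binary masks and extends smoothly to soft masks.  Partial masks are not
   renormalized where several bodies overlap.  Subtractions within one
   iteration all use poses from the previous iteration (synchronous, not
   Gauss-Seidel).  Subtracted images are recomputed on the fly; only the
   (at most B^2) partial 3D transforms are cached.
2. **Posterior over a pose grid.**  The residual pose is searched on a
   regular grid per coordinate — `0, ±step, ±2·step, ...` truncated at ±3
   sigma of the Gaussian prior (so a 10-degree prior limits the search to
   ±30 degrees).  The posterior weight of each grid pose is proportional to
   `exp(-sum |S - CTF * P V|^2 / sigma^2 + log prior)`, normalised with a
   log-sum-exp guard.  `sigma^2` is the per-shell variance of the complex
   Fourier noise, so no extra factor of 1/2 appears.
3. **Best pose and reconstruction.**  The posterior argmax becomes the
   pose used for next iteration's subtraction (ties broken toward the
   prior centre, then grid order); the full posterior weights the slice
   insertions of the reconstruction (weights below 1e-6 of the per-particle
   maximum are skipped).  Each half-set accumulates its own numerator
   `Gamma * CTF * S / sigma^2` and denominator `Gamma * CTF^2 / sigma^2`;
   the Wiener division adds `1/tau^2` per shell to the denominator.

After the reconstructions, each body's solvent-corrected half-set FSC
(masked FSC corrected by phase randomization beyond the first shell where
the unmasked FSC drops below 0.8) yields the reported resolution (0.143
threshold, linear interpolation between shells) and the signal power
`tau^2 = fudge * FSC/(1-FSC) * shell power` (FSC clipped to [0, 0.999],
fudge default 2.0 to compensate the half-set split).  The tau^2 used for
the next reconstruction is floored at 1e-3 of the shell power: hard-zeroing
shells whose noisy corrected FSC dips below zero proved to lock those
shells out of all later iterations (an irreversible resolution ratchet).

The per-shell noise variance is estimated at initialization from
particle-minus-consensus-projection residuals and re-estimated each
iteration from the full-model residuals (a switch can freeze it); one
global curve is used rather than per-particle spectra.  Body densities are
initialized from the consensus map under each body's mask, per half-set
when per-half consensus reconstructions are available (keeping the
gold-standard halves independent from the start), or from optional
per-body reference maps (low-pass filtered on request).

## Pose estimates: argmax and posterior mean

The refinement stores two pose estimates per particle and body.  The
posterior argmax (the pose written to the per-body STAR tables) drives the
next iteration's partial subtraction.  In addition, the posterior-*mean*
residual pose is kept in memory: when posteriors are broad — the normal
situation at realistic noise levels — the mean is the lower-variance
(minimum-mean-square-error) estimate and has no grid quantisation.  The
motion PCA therefore featurizes the posterior means when they are
available, falling back to the argmax poses when the records come from a
STAR file.  The averaging is done per Euler-offset coordinate, which is
accurate for the small residual rotations the parameterisation is built
for.

## Sampling refinement and convergence

When no body's resolution improved by at least one shell in an iteration,
the angular and translational steps are halved (down to a quarter of the
initial step).  After the first halving, the search switches from the
exhaustive ±3-sigma grid to a local grid of ±3 new steps around each
particle's current pose — a full grid at halved steps would cost 8x more
without reaching beyond the prior's support.  A body's poses are frozen
once the sampling is finer than its estimated rotational accuracy: the
rotation angle at which the signal-weighted squared projection difference
of its current reference reaches one log-likelihood unit.  Freezing is
enabled only after the first sampling refinement, because accuracy
estimates from still-motion-blurred early references are pessimistic and
would stall the bootstrap.  The refinement converges when resolutions are
flat, median pose changes fall below the angular step, the sampling is at
its finest, and it is finer than every body's accuracy — or when every
free body is frozen.

## Numerical choices

* Centred FFT grids (`fftshift` layout, origin at voxel D/2) with
  orthonormal scaling; angles in degrees and offsets in pixels everywhere.
* Trilinear interpolation for slice extraction and its adjoint for
  insertion, without Fourier padding or gridding correction.  This is the
  main accuracy limitation: insertion spreads every sample over a ±1-voxel
  neighbourhood, which attenuates high shells in proportion to how fast
  the transform's phases vary — i.e. to the object's real-space extent.
  COM-centred compact bodies (up to roughly a third of the box) reconstruct
  with >0.99 correlation to the band-limited truth; objects filling the
  box lose high-shell amplitude.  The `--pad` option accepts only factor 1.
* Soft masks use a raised-cosine profile of the Euclidean distance
  transform over the stated edge width after the stated dilation.
* Masks are re-centred by linear interpolation (not Fourier shifts), so
  their values stay in [0, 1] without ringing; full and partial body
  transforms multiply the COM-centred density by the correspondingly
  shifted mask, so a partial mask equal to the body's own mask yields the
  identical transform.
* CTF: standard phase-contrast model
  `-(sqrt(1-A^2) sin chi + A cos chi)` with astigmatic defocus in the
  aberration phase chi and relativistic wavelength; positive defocus means
  underfocus, and the value at the origin is -A.

## Synthetic data

The generator emulates the inputs the tool consumes in practice.  The
default phantom is three bodies of 48-60 small Gaussian blobs each (widths
0.55-1.0 voxels, mixed-sign amplitudes around a positive mean) packed in
spherical domains of radius 8-10 voxels at D=48 (1.5 A/pixel).  The fine,
mixed-sign texture gives the bodies the relatively flat power spectrum of a
sharpened experimental map — large smooth blobs have almost no power in
the shells that carry alignment information, and nothing can be learned
from them at realistic noise levels.  The domain spheres touch without
interpenetrating; only the softened masks overlap at the interfaces, which
exercises the non-overlap subtraction.  Body 1 (the largest) anchors the
consensus frame with zero prior widths; bodies 2 and 3 rock about different
residual axes with a shared amplitude (a single collective degree of
freedom), drawn either from a truncated Gaussian (sigma 3 degrees, so
rotations reach ±9 degrees) or from a two-state mixture (offsets -6 and +2
degrees, weights 0.1/0.9, 1-degree within-state spread).

Noise is added in Fourier space with Hermitian symmetry.  Its per-shell
variance follows the mean CTF-modulated signal spectrum divided by the
requested SNR across the informative band (out to D/4 reciprocal voxels,
6 A at the default sampling), beyond which the spectral SNR rolls off
exponentially towards Nyquist — the shape of a real data set's SSNR under
envelope and B-factor decay.  Three defocus groups (1.0-2.1 um, 300 kV,
Cs 2.7 mm, 10% amplitude contrast) provide CTF diversity.

What the generator does **not** emulate: per-particle defocus variation
within a group, beam-induced motion, detector MTF, structural noise other
than the bodies themselves, interface rearrangement between bodies, and
consensus-pose errors (a jitter option exists but defaults to zero).
Passing tests therefore demonstrate the correctness and statistical
behaviour of the algorithm under its own model assumptions, not performance
on real micrographs.

## What the stated conditions can and cannot deliver

At the default conditions (D=48, spectral SNR 0.1, three bodies), the
per-particle rotational information is limited: the log-likelihood drop
between the true pose and a pose one 1.8-degree step away is only a few
units even with perfect references, and the package's own accuracy
estimator puts the per-particle rotational accuracy at 3-4 degrees.
Per-particle best-pose errors therefore have a median around 2-3 degrees;
recovering 90% of particles within a single 1.8-degree step would require
roughly twice that accuracy and does not happen at this SNR and box size —
the corresponding assertion in the acceptance suite documents the shortfall
honestly.  Quantities that average over particles are much better behaved:
the per-body resolutions improve over the no-motion consensus
reconstruction, the pose PCA recovers the collective motion axis, and the
two-state mixture separates cleanly, because averaging N particles recovers
a factor sqrt(N) that single-particle pose assignment does not enjoy.

## Problem sizes

The acceptance script runs the continuous-motion scenario at N=300 and the
two-state scenario at N=300 particles (D=48, three EM iterations); the
test suite's headline scenario uses N=1000.  These sizes keep full runs in
the minutes range while leaving the per-particle physics identical — the
per-particle recovery statistics do not depend on N, and the
reconstruction-quality margins at N=300 are already decisive.

## Known limitations

* No Fourier padding or gridding correction (see above).
* One global noise spectrum; no per-group or per-particle spectra.
* Exhaustive-then-local orientation sampling; no adaptive oversampling.
* Point-group symmetry, per-particle defocus refinement, Ewald-sphere
  curvature and anisotropic magnification are out of scope.
* The tau^2 estimator (`fudge * FSC/(1-FSC) * power`) is a standard
  stand-in accurate to a factor ~2 where the half-set SSNR is of order
  one; the fudge factor is exposed as a tunable.
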