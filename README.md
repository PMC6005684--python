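# multibody

Multi-body refinement and rigid-body motion analysis for cryo-EM
single-particle data.

Macromolecular complexes are often flexible: a single consensus
reconstruction blurs the moving parts.  This package models a complex as a
user-defined set of B rigid bodies that reorient independently in every
particle image.  In Fourier space each image is

    X_i = CTF_i ( Σ_b P_{φ_ib} V_b ) + N_i

where `P_φ` extracts a central slice through the body transform `V_b` at
pose `φ_ib` (the consensus pose composed with a small per-body residual
rotation/translation) and `N_i` is frequency-dependent Gaussian noise.  An
expectation-maximization refinement alternates, for every particle and
body, (1) *partial signal subtraction* — removing the CTF-modulated
projections of all other bodies at their current best poses, using only the
non-overlapping parts of their masks — (2) a posterior over a pose grid
under a Gaussian prior centred on the consensus placement, and (3)
posterior-weighted Wiener reconstruction of two independent half-sets per
body, regularized by the signal power τ² estimated from the
solvent-corrected half-set FSC.  After convergence, a PCA over six
variables per body (three residual Euler angles plus the in-plane
translation lifted onto the 3D grid, each column weighted by how much the
body's map changes per degree/pixel) extracts the dominant collective
motions, renders eigen-motion map series, and selects particle subsets by
amplitude.

The intended users are methods developers and practitioners who want a
compact, fully testable implementation of multi-body refinement: every
stage runs on synthetic data with known ground truth generated by the
built-in phantom simulator.

## Worked example

```python
from multibody import MultiBodyRefiner, MotionPCA
from multibody.flex import feature_scales, poses_to_features
from multibody.simulate import make_dataset

# three-body phantom, bodies 2+3 rock up to +/-9 deg, spectral SNR 0.1
data, phantom, truth = make_dataset(box=48, n_particles=300,
                                    motion="continuous", snr=0.1, seed=1)

refiner = MultiBodyRefiner(angular_step=1.8, trans_step=0.25,
                           max_iter=3, seed=2, verbose=1)
refiner.fit(data)          # consensus reconstruction computed on the fly
for b, res in refiner.resolutions_.items():
    print(f"body {b+1}: {res:.2f} A")

pca = MotionPCA().fit(poses_to_features(refiner.records_),
                      scales=feature_scales(refiner.bodies_))
print("variance fractions:", pca.explained_variance_ratio_[:3].round(3))
```

Output from this exact run:

```
iter   1 ( 101.3 s)  body1: 4.10 A, body2: 3.68 A, body3: 3.54 A
iter   2 ( 102.1 s)  body1: 3.00 A, body2: 3.00 A, body3: 3.00 A
iter   3 ( 248.0 s)  body1: 3.00 A, body2: 3.00 A, body3: 3.00 A
body 1: 3.00 A
body 2: 3.00 A
body 3: 3.00 A
variance fractions: [0.41  0.198 0.125]
```

The per-body resolutions (solvent-corrected gold-standard FSC at the 0.143
threshold) reach the Nyquist limit of the simulation as the partial
subtraction and poses sharpen; reconstructing the *same* images with no
motion model leaves the moving bodies at 3.87 and 3.84 A.  The first
principal component of the refined poses is the generator's collective
rocking motion: its cosine with the true motion axis is 0.92 in this run,
and it carries twice the variance of any other component (the remainder is
per-particle pose noise — see `docs/methods.md` on what the per-particle
information content at this SNR does and does not allow).

The same pipeline is available from the shell:

```sh
multibody simulate --box 48 -N 300 --motion continuous --seed 1 --out sim/
multibody refine --particles sim/particles.star --bodies sim/bodies.star --out run/
multibody flexanalyse --data run/run_data.star --bodies sim/bodies.star \
    --maps run/ --movie-component 1 --out flex/
```

`refine` writes per-iteration half-maps, pose tables
(`run_it###_data.star` with one `data_images_body_b` table per body) and a
JSON-lines log; `flexanalyse` writes the eigenvalue table, per-particle
amplitudes, an eigen-motion map series (M=10 maps by default), optional
amplitude-selected particle subsets, and re-centred subtracted particle
stacks for focused refinement outside the multi-body framework.

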