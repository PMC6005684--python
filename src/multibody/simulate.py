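"""Synthetic multi-body phantoms and particle stacks with known ground truth.

The generator emulates the inputs of a multi-body refinement: a phantom
complex built from Gaussian blobs grouped into rigid bodies, per-body soft
masks, and a stack of noisy CTF-modulated projection images whose per-body
residual poses are drawn from a configurable motion model.  Every stage of
the package can be exercised against the generator's ground truth without
any experimental data.

Motion models
-------------
continuous : a single collective degree of freedom.  Each particle draws an
    amplitude a ~ N(0, magnitude) truncated at +/- 3 sigma; each moving
    body's residual Euler-angle offsets are ``axis_b * a`` (degrees).
two_state : a discrete mixture.  Each particle draws a state with the given
    weights; its amplitude is the state offset plus N(0, within-state
    spread) jitter, applied along the same per-body axes.

Noise is added in Fourier space with Hermitian symmetry (real images); its
per-shell variance tracks the mean signal power spectrum so that the
spectral signal-to-noise ratio equals the requested value across the
informative band (out to box/4 reciprocal voxels) and rolls off
exponentially towards Nyquist, like a real data set's SSNR under envelope
and B-factor decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .fourier import (
    CTFParams,
    evaluate_ctf,
    extract_slice,
    fft2_centered,
    fft3_centered,
    ifft2_centered,
    shell_indices_2d,
)
from .orientations import Pose, compose_projection_pose, matrix_to_euler, residual_frame
from .star_io import BodySpec, ParticleRecord, assign_half_sets
from .volumes import SoftMask, Volume, centre_of_mass, make_soft_mask
from .refine import MultiBodyData, translate_volume

__all__ = [
    "Blob",
    "MotionModel",
    "GroundTruth",
    "Phantom",
    "make_phantom",
    "default_three_body_blueprints",
    "default_body_specs",
    "default_motion_model",
    "frames_from_specs",
    "simulate_particles",
    "make_dataset",
    "save_simulation",
]


@dataclass(frozen=True)
class Blob:
    """One Gaussian blob: centre (voxels, relative to box centre), width, amplitude."""

    centre: tuple[float, float, float]
    sigma: float
    amplitude: float = 1.0


@dataclass
class MotionModel:
    """Ground-truth motion of the bodies across the data set.

    ``axes`` maps 0-based body index -> 3-vector of Euler-offset directions
    (degrees per unit amplitude); bodies not listed do not move.  For the
    two-state model, ``state_offsets`` are the amplitudes of the discrete
    states and ``weights`` their mixture fractions.
    """

    kind: str = "continuous"  # "continuous" | "two_state"
    axes: dict[int, np.ndarray] = field(default_factory=dict)
    magnitude: float = 3.0            # degrees (std of the continuous amplitude)
    state_offsets: tuple[float, ...] = (-6.0, 2.0)
    weights: tuple[float, ...] = (0.1, 0.9)
    within_state_sigma: float = 1.0

    def __post_init__(self):
        if self.kind not in ("continuous", "two_state"):
            raise ValueError(f"unknown motion model kind: {self.kind}")
        if self.kind == "two_state":
            if abs(sum(self.weights) - 1.0) > 1e-9:
                raise ValueError("mixture weights must sum to 1")
            if len(self.weights) != len(self.state_offsets):
                raise ValueError("one weight per state offset required")
        if self.within_state_sigma < 0:
            raise ValueError("within-state spread must be >= 0")

    def draw(self, n: int, rng: np.random.Generator):
        """Per-particle amplitudes (and state labels for the mixture)."""
        if self.kind == "continuous":
            a = rng.normal(0.0, self.magnitude, size=n)
            a = np.clip(a, -3.0 * self.magnitude, 3.0 * self.magnitude)
            return a, None
        states = rng.choice(len(self.weights), size=n, p=np.asarray(self.weights))
        a = np.asarray(self.state_offsets)[states] + \
            rng.normal(0.0, self.within_state_sigma, size=n)
        return a, states

    def residual_poses(self, amplitude: float, n_bodies: int) -> list[Pose]:
        poses = []
        for b in range(n_bodies):
            if b in self.axes:
                r, t, p = np.asarray(self.axes[b], dtype=float) * amplitude
                poses.append(Pose(rot=r, tilt=t, psi=p))
            else:
                poses.append(Pose())
        return poses

    def feature_direction(self, n_bodies: int) -> np.ndarray:
        """Unit motion direction in the raw 6-features-per-body space."""
        d = np.zeros(6 * n_bodies)
        for b, axis in self.axes.items():
            d[6 * b: 6 * b + 3] = axis
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("motion model moves no body")
        return d / n


@dataclass
class GroundTruth:
    """True per-particle poses and generator parameters (reproducible by seed)."""

    consensus_poses: list[Pose]
    residual_poses: list[list[Pose]]
    amplitudes: np.ndarray
    state_labels: np.ndarray | None
    sigma2: np.ndarray
    seed: int


@dataclass
class Phantom:
    """A multi-body phantom: per-body volumes, soft masks, and the combined map."""

    body_volumes: list[Volume]
    masks: list[SoftMask]
    combined: Volume
    voxel_size: float

    @property
    def n_bodies(self) -> int:
        return len(self.body_volumes)

    @property
    def coms(self) -> list[np.ndarray]:
        return [centre_of_mass(m) for m in self.masks]


def _blob_volume(box: int, blobs: list[Blob]) -> tuple[np.ndarray, np.ndarray]:
    """Density and (absolute-amplitude) envelope of a set of Gaussian blobs."""
    c = box // 2
    ax = np.arange(box) - c
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    vol = np.zeros((box,) * 3)
    env = np.zeros((box,) * 3)
    for blob in blobs:
        bx, by, bz = blob.centre
        r2 = (x - bx) ** 2 + (y - by) ** 2 + (z - bz) ** 2
        g = np.exp(-r2 / (2.0 * blob.sigma**2))
        vol += blob.amplitude * g
        env += abs(blob.amplitude) * g
    return vol, env


def _blob_cluster(centre, radius, n_blobs, rng, box_scale=1.0,
                  sigma_range=(0.55, 1.0), amp_range=(-1.0, 1.2)) -> list[Blob]:
    blobs = []
    for _ in range(n_blobs):
        while True:
            p = rng.uniform(-radius, radius, 3)
            if np.linalg.norm(p) <= radius:
                break
        c = (np.asarray(centre) + p) * box_scale
        blobs.append(Blob(tuple(c), float(rng.uniform(*sigma_range) * box_scale),
                          float(rng.uniform(*amp_range))))
    return blobs


def default_three_body_blueprints(box: int = 48) -> list[list[Blob]]:
    """Three asymmetric bodies with protein-like internal detail.

    Each body is a fixed cluster of small Gaussian blobs inside a compact
    spherical domain.  Blob widths are fractions of a voxel up to one voxel
    (side-chain/secondary-structure-scale features at typical pixel sizes)
    and amplitudes are mixed-sign around a positive mean, giving the bodies
    the relatively flat power spectrum of a sharpened experimental map
    rather than the steeply decaying spectrum of large smooth blobs.  Body
    1 is the largest (the anchor); bodies 2 and 3 are smaller domains whose
    spheres touch without interpenetrating, so only the softened masks
    overlap at the interfaces (exercising the non-overlap subtraction
    path).  The layout is deterministic: it is part of the phantom
    definition, not of the simulation randomness.
    """
    s = box / 48.0
    rng = np.random.default_rng(1234)  # fixed: the phantom is a constant
    return [
        _blob_cluster((-9, -5, 0), 10.0, 60, rng, s),
        _blob_cluster((9, -6, 1), 8.3, 48, rng, s),
        _blob_cluster((4, 10, -2), 8.5, 48, rng, s),
    ]


def make_phantom(box: int, body_blueprints: list[list[Blob]],
                 voxel_size: float = 1.5, mask_threshold: float = 0.2,
                 extend_px: float = 1.0, soft_edge_px: float = 3.0) -> Phantom:
    """Build per-body volumes, binary-then-softened masks, and the combined map."""
    if box % 2:
        raise ValueError("box size must be even")
    body_volumes = []
    masks = []
    for blobs in body_blueprints:
        if not blobs:
            raise ValueError("every body needs at least one blob")
        vol, env = _blob_volume(box, blobs)
        binary = env > mask_threshold * env.max()
        masks.append(make_soft_mask(binary, extend_px, soft_edge_px, voxel_size))
        body_volumes.append(Volume(vol, voxel_size))
    combined = Volume(np.sum([v.data for v in body_volumes], axis=0), voxel_size)
    return Phantom(body_volumes=body_volumes, masks=masks, combined=combined,
                   voxel_size=voxel_size)


def default_body_specs(phantom: Phantom, sigma_angles: float = 3.0,
                       sigma_offset: float = 0.0,
                       fixed_bodies: tuple[int, ...] = (0,)) -> list[BodySpec]:
    """Body definitions for the default scenario: anchor body fixed, others free.

    The anchor (body 1) keeps zero prior widths so its consensus placement
    is pinned; moving bodies rotate relative to the anchor with a Gaussian
    rotational prior (degrees) and optional translational prior (pixels).
    """
    specs = []
    B = phantom.n_bodies
    for b in range(B):
        fixed = b in fixed_bodies
        rel = 2 if b == 0 else 1
        specs.append(BodySpec(
            body_index=b + 1,
            mask_path=f"body_{b + 1}_mask.mrc",
            rotate_relative_to=min(rel, B),
            sigma_angles=0.0 if fixed else sigma_angles,
            sigma_offset=0.0 if fixed else sigma_offset,
        ))
    return specs


def default_motion_model(kind: str = "continuous", magnitude: float = 3.0,
                         **kwargs) -> MotionModel:
    """Collective rocking of bodies 2 and 3 about different residual axes."""
    axes = {1: np.array([1.0, 0.0, 0.0]), 2: np.array([0.0, 1.0, 0.0])}
    return MotionModel(kind=kind, axes=axes, magnitude=magnitude, **kwargs)


def frames_from_specs(phantom: Phantom, specs: list[BodySpec]) -> list[np.ndarray]:
    """Residual-rotation frames implied by the body definitions' COM geometry."""
    coms = phantom.coms
    return [residual_frame(coms[s.body_index - 1], coms[s.rotate_relative_to - 1])
            for s in specs]


def _default_ctf_groups() -> list[CTFParams]:
    return [
        CTFParams(defocus_u=10000.0, defocus_v=11000.0, astig_angle=15.0),
        CTFParams(defocus_u=15000.0, defocus_v=14500.0, astig_angle=-30.0),
        CTFParams(defocus_u=21000.0, defocus_v=20000.0, astig_angle=60.0),
    ]


def simulate_particles(
    phantom: Phantom,
    n_particles: int,
    motion_model: MotionModel,
    ctf_groups: list[CTFParams] | None = None,
    snr: float = 0.1,
    noise_sigma2: np.ndarray | None = None,
    seed: int = 0,
    shift_range: float = 2.0,
    consensus_jitter: float = 0.0,
    stack_name: str = "particles.mrcs",
    frames: list[np.ndarray | None] | None = None,
) -> tuple[np.ndarray, list[ParticleRecord], GroundTruth]:
    """Forward-simulate a particle stack from the multi-body image model.

    Each particle draws a uniform consensus rotation and a small in-plane
    shift, residual body poses from the motion model, and is synthesised as
    the CTF-modulated sum of central slices through the COM-centred body
    transforms, plus Hermitian Fourier-space Gaussian noise.  When
    ``noise_sigma2`` is not given, the noise spectrum is the mean signal
    power spectrum divided by ``snr`` (constant per-shell SNR).
    ``consensus_jitter`` (degrees) perturbs the *recorded* consensus angles
    to emulate consensus-refinement error; the images use the true poses.
    ``frames`` are the per-body residual-rotation frames (from
    :func:`frames_from_specs`); residual poses are interpreted in the same
    convention the refinement uses, so ground truth and refined poses are
    directly comparable.
    """
    rng = np.random.default_rng(seed)
    box = phantom.combined.data.shape[0]
    B = phantom.n_bodies
    voxel = phantom.voxel_size
    ctf_groups = ctf_groups or _default_ctf_groups()
    coms = phantom.coms
    # COM-centred body transforms (the same quantities the refiner models)
    F_bodies = [
        fft3_centered(translate_volume(v.data, -com))
        for v, com in zip(phantom.body_volumes, coms)
    ]
    ctf_images = [evaluate_ctf(p, box, voxel) for p in ctf_groups]
    if frames is None:
        frames = [None] * B

    amplitudes, states = motion_model.draw(n_particles, rng)
    rotations = Rotation.random(n_particles, rng=rng)
    consensus_poses = []
    residual_poses = []
    noiseless = np.empty((n_particles, box, box), dtype=np.complex128)
    for i in range(n_particles):
        rot, tilt, psi = matrix_to_euler(rotations[i].as_matrix())
        dx, dy = rng.uniform(-shift_range, shift_range, size=2)
        cons = Pose(rot=rot, tilt=tilt, psi=psi, dx=dx, dy=dy)
        consensus_poses.append(cons)
        res = motion_model.residual_poses(amplitudes[i], B)
        residual_poses.append(res)
        ctf = ctf_images[i % len(ctf_groups)]
        F = np.zeros((box, box), dtype=np.complex128)
        for b in range(B):
            R, sx, sy = compose_projection_pose(cons, res[b], coms[b], frames[b])
            F += extract_slice(F_bodies[b], R, sx, sy)
        noiseless[i] = ctf * F

    shells = shell_indices_2d(box)
    n_shells = box // 2 + 1
    if noise_sigma2 is None:
        keep = shells < n_shells
        mean_power = (np.abs(noiseless) ** 2).mean(axis=0)
        power = np.bincount(shells[keep].ravel(), weights=mean_power[keep].ravel(),
                            minlength=n_shells)
        counts = np.bincount(shells[keep].ravel(), minlength=n_shells)
        shell_power = power / np.maximum(counts, 1)
        # noise tracks the signal spectrum so the spectral SNR equals ``snr``
        # across the informative band (out to ~ box/4 reciprocal voxels),
        # then the SNR rolls off exponentially towards Nyquist -- the shape
        # of a real data set's SSNR under envelope/B-factor decay
        k = np.arange(n_shells, dtype=float)
        k0, w = box / 4.0, box / 13.0
        snr_curve = snr * np.minimum(1.0, np.exp(-(k - k0) / w))
        sigma2 = shell_power / snr_curve
        sigma2 = np.maximum(sigma2, sigma2[1:].max() * 1e-9)
    else:
        sigma2 = np.asarray(noise_sigma2, dtype=float)
        if len(sigma2) != n_shells:
            raise ValueError("noise_sigma2 must have D/2+1 shells")

    images = np.empty((n_particles, box, box))
    amp = np.sqrt(sigma2[np.minimum(shells, n_shells - 1)])
    for i in range(n_particles):
        noise_F = fft2_centered(rng.standard_normal((box, box))) * amp
        images[i] = ifft2_centered(noiseless[i] + noise_F).real

    records = []
    for i in range(n_particles):
        cons = consensus_poses[i]
        if consensus_jitter > 0:
            cons = Pose(
                rot=cons.rot + rng.normal(0, consensus_jitter),
                tilt=cons.tilt + rng.normal(0, consensus_jitter),
                psi=cons.psi + rng.normal(0, consensus_jitter),
                dx=cons.dx, dy=cons.dy)
        records.append(ParticleRecord(
            image_ref=(stack_name, i),
            ctf=ctf_groups[i % len(ctf_groups)],
            consensus_pose=cons,
            body_poses=[Pose() for _ in range(B)],
        ))
    assign_half_sets(records, seed=seed + 1)
    truth = GroundTruth(
        consensus_poses=consensus_poses, residual_poses=residual_poses,
        amplitudes=np.asarray(amplitudes),
        state_labels=states, sigma2=sigma2, seed=seed)
    return images, records, truth


def make_dataset(
    box: int = 48,
    n_particles: int = 1000,
    motion: MotionModel | str = "continuous",
    snr: float = 0.1,
    sigma_angles: float = 3.0,
    sigma_offset: float = 0.0,
    seed: int = 0,
    consensus_map: Volume | None = None,
    **sim_kwargs,
) -> tuple[MultiBodyData, Phantom, GroundTruth]:
    """One-call construction of the default three-body study conditions.

    D=48, B=3 (anchor fixed, bodies 2 and 3 rocking up to +/- 3 sigma of the
    motion magnitude), 3 defocus groups, flat Fourier noise at the requested
    per-pixel SNR.  Returns the data bundle ready for MultiBodyRefiner
    (without a consensus map unless one is supplied; see
    reconstruct_consensus).
    """
    if isinstance(motion, str):
        motion = default_motion_model(kind=motion.replace("-", "_"))
    phantom = make_phantom(box, default_three_body_blueprints(box))
    specs = default_body_specs(phantom, sigma_angles=sigma_angles,
                               sigma_offset=sigma_offset)
    images, records, truth = simulate_particles(
        phantom, n_particles, motion, snr=snr, seed=seed,
        frames=frames_from_specs(phantom, specs), **sim_kwargs)
    data = MultiBodyData(
        images=images, records=records, body_specs=specs, masks=phantom.masks,
        voxel_size=phantom.voxel_size, consensus_map=consensus_map)
    return data, phantom, truth


def save_simulation(outdir, phantom: Phantom, images: np.ndarray,
                    records: list[ParticleRecord], truth: GroundTruth,
                    specs: list[BodySpec]) -> dict:
    """Write a simulated data set to disk in the formats the tool consumes.

    Produces the particle stack (MRCS), the particle STAR file, the body
    definition STAR file, per-body soft masks and body maps (MRC), the
    combined consensus-like map, and a ground-truth STAR file carrying the
    true poses plus amplitude/state columns.  Returns the path map.
    """
    from .star_io import write_body_star, write_particles_star
    from .volumes import write_map, write_stack

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    stack = outdir / "particles.mrcs"
    write_stack(images, phantom.voxel_size, stack)
    paths["stack"] = stack
    for rec in records:
        rec.image_ref = ("particles.mrcs", rec.image_ref[1])
    star = outdir / "particles.star"
    write_particles_star(records, star)
    paths["particles"] = star
    for spec, mask, vol in zip(specs, phantom.masks, phantom.body_volumes):
        mpath = outdir / spec.mask_path
        write_map(mask, mpath)
        write_map(vol, outdir / f"body_{spec.body_index}.mrc")
    bodies_star = outdir / "bodies.star"
    write_body_star(specs, bodies_star)
    paths["bodies"] = bodies_star
    write_map(phantom.combined, outdir / "combined.mrc")
    paths["map"] = outdir / "combined.mrc"
    truth_records = []
    for i, rec in enumerate(records):
        truth_records.append(ParticleRecord(
            image_ref=rec.image_ref, ctf=rec.ctf,
            consensus_pose=truth.consensus_poses[i],
            body_poses=list(truth.residual_poses[i]),
            half_set=rec.half_set))
    extra = {"mbTrueAmplitude": truth.amplitudes}
    if truth.state_labels is not None:
        extra["mbTrueState"] = truth.state_labels.astype(float)
    truth_star = outdir / "ground_truth.star"
    write_particles_star(truth_records, truth_star, extra_columns=extra)
    paths["ground_truth"] = truth_star
    return paths
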