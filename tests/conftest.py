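"""Shared fixtures: small phantoms, self-consistent noiseless data sets."""

from __future__ import annotations

import numpy as np
import pytest

from multibody.fourier import CTFParams
from multibody.orientations import Pose
from multibody.refine import MultiBodyData
from multibody.simulate import (
    Blob,
    MotionModel,
    _blob_cluster,
    frames_from_specs,
    make_phantom,
    simulate_particles,
)
from multibody.star_io import BodySpec
from multibody.volumes import SoftMask, Volume, make_soft_mask


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_phantom():
    """Three-body phantom at D=32 (scaled-down default blueprints)."""
    from multibody.simulate import default_three_body_blueprints

    return make_phantom(32, default_three_body_blueprints(32))


def make_disjoint_selfconsistent(box=32, n_particles=24, seed=5,
                                 grid_values=(-3.6, -1.8, 0.0, 1.8, 3.6),
                                 sigma_angles=3.0):
    """Noiseless data synthesized exactly from the refiner's own initial models.

    Bodies are far apart with *binary, disjoint* masks, and the body volumes
    are the masked consensus map itself, so partial-mask subtraction and the
    alignment references reproduce the data without any model mismatch.
    True residual rotations sit exactly on the search grid.
    """
    rng = np.random.default_rng(seed)
    blueprints = [
        _blob_cluster((-9, -5, 0), 5.0, 20, rng_ := np.random.default_rng(77)),
        _blob_cluster((9, -4, 1), 4.5, 16, rng_),
        _blob_cluster((0, 9, -1), 4.0, 14, rng_),
    ]
    phantom = make_phantom(box, blueprints, voxel_size=1.5)
    # binary, disjoint masks
    masks = []
    for m in phantom.masks:
        masks.append(SoftMask((m.data > 0.999).astype(float),
                              voxel_size=phantom.voxel_size))
    for i in range(3):
        for j in range(i + 1, 3):
            assert not np.any(masks[i].data * masks[j].data), \
                "fixture masks must be disjoint"
    combined = phantom.combined.data
    body_vols = [Volume(combined * m.data, phantom.voxel_size) for m in masks]
    phantom.masks = masks
    phantom.body_volumes = body_vols
    phantom.combined = Volume(sum(v.data for v in body_vols), phantom.voxel_size)

    specs = [
        BodySpec(1, "m1.mrc", 2, 0.0, 0.0),
        BodySpec(2, "m2.mrc", 1, sigma_angles, 0.0),
        BodySpec(3, "m3.mrc", 1, sigma_angles, 0.0),
    ]
    motion = MotionModel(kind="continuous",
                         axes={1: np.array([1.0, 0.0, 0.0]),
                               2: np.array([0.0, 1.0, 0.0])})

    class GridMotion:
        axes = motion.axes

        def draw(self, n, rng):
            return rng.choice(np.asarray(grid_values), size=n), None

        def residual_poses(self, amplitude, n_bodies):
            return motion.residual_poses(amplitude, n_bodies)

    frames = frames_from_specs(phantom, specs)
    images, records, truth = simulate_particles(
        phantom, n_particles, GridMotion(), snr=1e9, seed=seed, frames=frames,
        shift_range=1.0)
    data = MultiBodyData(images=images, records=records, body_specs=specs,
                         masks=masks, voxel_size=phantom.voxel_size,
                         consensus_map=phantom.combined)
    # re-synthesize the images from the refiner's *own* initialized body
    # transforms, making the data exactly self-consistent with the model
    from multibody.fourier import (evaluate_ctf, extract_slice, fft2_centered,
                                   ifft2_centered)
    from multibody.orientations import compose_projection_pose
    from multibody.refine import initialize_state

    probe = initialize_state(data, sigma2=np.ones(box // 2 + 1), seed=0)
    signal_power = 0.0
    for i, rec in enumerate(records):
        F = np.zeros((box, box), dtype=complex)
        ctf = probe.ctf_images[i]
        for b, body in enumerate(probe.bodies):
            R, sx, sy = compose_projection_pose(
                rec.consensus_pose, truth.residual_poses[i][b], body.com,
                body.frame)
            F += ctf * extract_slice(body.F_half[rec.half_set], R, sx, sy)
        data.images[i] = ifft2_centered(F).real
        signal_power += np.mean(np.abs(F) ** 2) / n_particles
    sigma2 = np.full(box // 2 + 1, signal_power * 1e-4)  # flat, tiny
    return data, phantom, truth, sigma2


@pytest.fixture(scope="session")
def selfconsistent():
    return make_disjoint_selfconsistent()


@pytest.fixture()
def default_ctf():
    return CTFParams(defocus_u=15000.0, defocus_v=14000.0, astig_angle=20.0,
                     voltage=300.0, cs=2.7, amplitude_contrast=0.1)


@pytest.fixture()
def gaussian_volume():
    """Isotropic 3D Gaussian blob at the box centre (closed-form transform)."""
    box, sigma = 32, 2.0
    ax = np.arange(box) - box // 2
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    vol = np.exp(-(x**2 + y**2 + z**2) / (2 * sigma**2))
    return vol, sigma
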