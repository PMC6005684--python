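"""Euler-angle conventions, residual-rotation frames, pose priors and pose grids.

Rotations follow the ZYZ convention common in single-particle analysis:
``R = Rz(psi) @ Ry(tilt) @ Rz(rot)`` with angles in degrees.  A particle's
consensus pose carries the full projection geometry; each rigid body
additionally carries a small *residual* pose relative to that consensus
placement.  To avoid the gimbal degeneracy at tilt = 0, residual rotations are
parameterised as offsets from the Euler triplet (rot=0, tilt=90, psi=0),
conjugated into a body-specific frame derived from the vector between the
body's centre-of-mass and that of its rotation-reference body.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Pose",
    "IDENTITY_POSE",
    "PosePrior",
    "PoseGrid",
    "euler_to_matrix",
    "matrix_to_euler",
    "residual_frame",
    "residual_matrix",
    "residual_pose_from_matrix",
    "compose_projection_pose",
    "prior_log_density",
    "build_pose_grid",
    "build_local_pose_grid",
    "residual_matrices",
    "rotation_distance",
]

_EPS = 1e-12


@dataclass(frozen=True)
class Pose:
    """Three ZYZ Euler angles (degrees) and an in-plane translation (pixels).

    For *residual* poses the angles are stored as offsets from the
    (0, 90, 0) convention, so the identity residual is ``Pose()``.
    """

    rot: float = 0.0
    tilt: float = 0.0
    psi: float = 0.0
    dx: float = 0.0
    dy: float = 0.0

    def angles(self) -> np.ndarray:
        return np.array([self.rot, self.tilt, self.psi], dtype=float)

    def shifts(self) -> np.ndarray:
        return np.array([self.dx, self.dy], dtype=float)


IDENTITY_POSE = Pose()


def euler_to_matrix(rot: float, tilt: float, psi: float) -> np.ndarray:
    """Rotation matrix ``Rz(psi) @ Ry(tilt) @ Rz(rot)``, angles in degrees."""
    r, t, p = np.deg2rad([rot, tilt, psi])
    cr, sr = np.cos(r), np.sin(r)
    ct, st = np.cos(t), np.sin(t)
    cp, sp = np.cos(p), np.sin(p)
    return np.array(
        [
            [cp * ct * cr - sp * sr, -cp * ct * sr - sp * cr, cp * st],
            [sp * ct * cr + cp * sr, -sp * ct * sr + cp * cr, sp * st],
            [-st * cr, st * sr, ct],
        ]
    )


def matrix_to_euler(R: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`euler_to_matrix`; returns tilt in [0, 180] degrees.

    At the gimbal singularities (tilt = 0 or 180) rot is set to zero and the
    in-plane rotation is carried entirely by psi.
    """
    R = np.asarray(R, dtype=float)
    ct = float(np.clip(R[2, 2], -1.0, 1.0))
    tilt = np.degrees(np.arccos(ct))
    st = np.sqrt(max(0.0, 1.0 - ct * ct))
    if st > 1e-8:
        psi = np.degrees(np.arctan2(R[1, 2], R[0, 2]))
        rot = np.degrees(np.arctan2(R[2, 1], -R[2, 0]))
    elif ct > 0:  # tilt = 0: pure in-plane rotation Rz(psi + rot)
        rot = 0.0
        psi = np.degrees(np.arctan2(R[1, 0], R[0, 0]))
    else:  # tilt = 180
        rot = 0.0
        psi = np.degrees(np.arctan2(-R[1, 0], -R[0, 0]))
    return float(rot), float(tilt), float(psi)


_E90 = euler_to_matrix(0.0, 90.0, 0.0)
_Z = np.array([0.0, 0.0, 1.0])
_X = np.array([1.0, 0.0, 0.0])


def residual_frame(body_com: np.ndarray, reference_com: np.ndarray) -> np.ndarray:
    """Orthonormal frame (columns) for a body's residual-rotation convention.

    The third column is the unit vector from the body's centre-of-mass to the
    centre-of-mass of its rotation-reference body; the first two columns are a
    deterministic orthogonal completion (first axis orthogonal to both the
    COM axis and the lab z axis when possible, else to the lab x axis).
    Residual tilt/rot offsets then rotate the body about axes orthogonal to
    the COM axis, and psi offsets twist about the COM axis itself.
    """
    body_com = np.asarray(body_com, dtype=float)
    reference_com = np.asarray(reference_com, dtype=float)
    d = reference_com - body_com
    n = np.linalg.norm(d)
    if n < 1e-9:
        raise ValueError("body and reference centres-of-mass coincide")
    u = d / n
    a = np.cross(_Z, u)
    if np.linalg.norm(a) < 1e-6:
        a = np.cross(_X, u)
    a /= np.linalg.norm(a)
    b = np.cross(u, a)
    return np.stack([a, b, u], axis=1)


def residual_matrix(pose: Pose, frame: np.ndarray | None = None) -> np.ndarray:
    """World rotation matrix of a residual pose.

    The stored Euler angles are ``(rot, 90 + tilt, psi)``; the rotation is the
    deviation from the (0, 90, 0) reference, conjugated by the body frame.
    ``frame=None`` uses the identity frame.
    """
    return residual_matrices(np.array([[pose.rot, pose.tilt, pose.psi]]), frame)[0]


def residual_matrices(angles: np.ndarray, frame: np.ndarray | None = None) -> np.ndarray:
    """Batched :func:`residual_matrix` for an (n, 3) array of Euler offsets."""
    ang = np.asarray(angles, dtype=float)
    r, t, p = np.deg2rad(ang[:, 0]), np.deg2rad(ang[:, 1] + 90.0), np.deg2rad(ang[:, 2])
    cr, sr = np.cos(r), np.sin(r)
    ct, st = np.cos(t), np.sin(t)
    cp, sp = np.cos(p), np.sin(p)
    R = np.empty((len(ang), 3, 3))
    R[:, 0, 0] = cp * ct * cr - sp * sr
    R[:, 0, 1] = -cp * ct * sr - sp * cr
    R[:, 0, 2] = cp * st
    R[:, 1, 0] = sp * ct * cr + cp * sr
    R[:, 1, 1] = -sp * ct * sr + cp * cr
    R[:, 1, 2] = sp * st
    R[:, 2, 0] = -st * cr
    R[:, 2, 1] = st * sr
    R[:, 2, 2] = ct
    A = R @ _E90.T
    if frame is not None:
        A = frame @ A @ frame.T
    return A


def residual_pose_from_matrix(
    A: np.ndarray, frame: np.ndarray | None = None, dx: float = 0.0, dy: float = 0.0
) -> Pose:
    """Inverse of :func:`residual_matrix` (translation passed through)."""
    if frame is not None:
        A = frame.T @ np.asarray(A) @ frame
    rot, tilt, psi = matrix_to_euler(A @ _E90)
    return Pose(rot=rot, tilt=tilt - 90.0, psi=psi, dx=dx, dy=dy)


def compose_projection_pose(
    consensus_pose: Pose,
    residual_pose: Pose,
    body_com: np.ndarray,
    frame: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float]:
    """Effective projection geometry for a COM-centred body volume.

    Returns ``(R_eff, sx, sy)``: extracting the central slice at rotation
    ``R_eff`` from the COM-centred body transform and phase-shifting by
    ``(sx, sy)`` reproduces the body's contribution to the particle image.
    The shift combines the consensus in-plane offsets, the residual offsets,
    and the in-plane projection of the rotated centre-of-mass (bodies are
    reconstructed COM-centred, so their in-situ position re-enters here).
    """
    R_cons = euler_to_matrix(consensus_pose.rot, consensus_pose.tilt, consensus_pose.psi)
    A = residual_matrix(residual_pose, frame)
    R_eff = R_cons @ A
    com_proj = R_cons @ np.asarray(body_com, dtype=float)
    sx = consensus_pose.dx + residual_pose.dx + com_proj[0]
    sy = consensus_pose.dy + residual_pose.dy + com_proj[1]
    return R_eff, float(sx), float(sy)


@dataclass(frozen=True)
class PosePrior:
    """Gaussian prior on residual poses, centred on the zero residual.

    sigma_angles (degrees) applies independently to the three Euler-angle
    offsets, sigma_offset (pixels) to the two translations.  A zero sigma
    fixes the corresponding coordinates at zero.  Support is truncated at
    +/- 3 sigma, matching the search range of the pose grid.
    """

    sigma_angles: float
    sigma_offset: float

    def __post_init__(self):
        if self.sigma_angles < 0 or self.sigma_offset < 0:
            raise ValueError("prior standard deviations must be >= 0")

    @property
    def fixed(self) -> bool:
        return self.sigma_angles == 0.0 and self.sigma_offset == 0.0


def prior_log_density(pose: Pose, prior: PosePrior) -> float:
    """Unnormalised Gaussian log-density of a residual pose; -inf outside 3 sigma."""
    logp = 0.0
    tol = 1e-9
    for v in pose.angles():
        if prior.sigma_angles == 0.0:
            if abs(v) > tol:
                return -np.inf
        elif abs(v) > 3.0 * prior.sigma_angles + tol:
            return -np.inf
        else:
            logp -= 0.5 * (v / prior.sigma_angles) ** 2
    for v in pose.shifts():
        if prior.sigma_offset == 0.0:
            if abs(v) > tol:
                return -np.inf
        elif abs(v) > 3.0 * prior.sigma_offset + tol:
            return -np.inf
        else:
            logp -= 0.5 * (v / prior.sigma_offset) ** 2
    return float(logp)


def _symmetric_samples(sigma: float, step: float) -> np.ndarray:
    """0, +/-step, +/-2 step, ... truncated at 3 sigma (always contains 0)."""
    if sigma == 0.0:
        return np.array([0.0])
    if step <= 0:
        raise ValueError("sampling step must be > 0 for a free coordinate")
    k = int(np.floor(3.0 * sigma / step + 1e-9))
    offs = np.arange(-k, k + 1, dtype=float) * step
    return offs


@dataclass
class PoseGrid:
    """Factored grid of candidate residual poses with their prior log-densities.

    Rotational offsets and in-plane translations are stored separately
    (``rot_offsets`` of shape (n_rot, 3), ``trans_offsets`` of shape
    (n_trans, 2)); the full grid is their Cartesian product in
    rotation-major order.
    """

    rot_offsets: np.ndarray
    trans_offsets: np.ndarray
    log_prior: np.ndarray  # shape (n_rot, n_trans)
    angular_step: float
    trans_step: float

    @property
    def n_rot(self) -> int:
        return self.rot_offsets.shape[0]

    @property
    def n_trans(self) -> int:
        return self.trans_offsets.shape[0]

    def __len__(self) -> int:
        return self.n_rot * self.n_trans

    def pose(self, index: int) -> Pose:
        ir, it = divmod(index, self.n_trans)
        r, t, p = self.rot_offsets[ir]
        dx, dy = self.trans_offsets[it]
        return Pose(rot=r, tilt=t, psi=p, dx=dx, dy=dy)

    @property
    def poses(self) -> list[Pose]:
        return [self.pose(i) for i in range(len(self))]

    def centre_index(self) -> int:
        ir = int(np.argmin(np.abs(self.rot_offsets).sum(axis=1)))
        it = int(np.argmin(np.abs(self.trans_offsets).sum(axis=1)))
        return ir * self.n_trans + it


def build_pose_grid(prior: PosePrior, angular_step: float, trans_step: float) -> PoseGrid:
    """Regular search grid within +/- 3 sigma of the prior, including the centre.

    For a fixed prior (both sigmas zero) the grid contains only the centre
    pose, which keeps the body pinned to its consensus placement.
    """
    ang = _symmetric_samples(prior.sigma_angles, angular_step)
    tra = _symmetric_samples(prior.sigma_offset, trans_step)
    rot_offsets = np.array(list(itertools.product(ang, ang, ang)), dtype=float)
    trans_offsets = np.array(list(itertools.product(tra, tra)), dtype=float)
    log_prior = np.zeros((len(rot_offsets), len(trans_offsets)))
    if prior.sigma_angles > 0:
        log_prior += (-0.5 * (rot_offsets / prior.sigma_angles) ** 2).sum(axis=1)[:, None]
    if prior.sigma_offset > 0:
        log_prior += (-0.5 * (trans_offsets / prior.sigma_offset) ** 2).sum(axis=1)[None, :]
    return PoseGrid(
        rot_offsets=rot_offsets,
        trans_offsets=trans_offsets,
        log_prior=log_prior,
        angular_step=angular_step,
        trans_step=trans_step,
    )


def _local_samples(centre: float, sigma: float, step: float, half_width: int) -> np.ndarray:
    if sigma == 0.0:
        return np.array([0.0])
    vals = centre + np.arange(-half_width, half_width + 1, dtype=float) * step
    vals = vals[np.abs(vals) <= 3.0 * sigma + 1e-9]
    if len(vals) == 0:
        vals = np.array([np.clip(centre, -3.0 * sigma, 3.0 * sigma)])
    return vals


def build_local_pose_grid(prior: PosePrior, centre: Pose, angular_step: float,
                          trans_step: float, half_width: int = 3) -> PoseGrid:
    """Local search grid centred on a particle's current residual pose.

    Used after the sampling steps have been refined: each coordinate is
    sampled at ``centre +/- k * step`` for k up to ``half_width``, truncated
    to the prior's +/- 3 sigma support.  Log-prior densities refer to the
    absolute residual coordinates, so posteriors remain comparable with the
    full-grid search.
    """
    angs = [_local_samples(c, prior.sigma_angles, angular_step, half_width)
            for c in (centre.rot, centre.tilt, centre.psi)]
    tras = [_local_samples(c, prior.sigma_offset, trans_step, half_width)
            for c in (centre.dx, centre.dy)]
    rot_offsets = np.array(list(itertools.product(*angs)), dtype=float)
    trans_offsets = np.array(list(itertools.product(*tras)), dtype=float)
    log_prior = np.zeros((len(rot_offsets), len(trans_offsets)))
    if prior.sigma_angles > 0:
        log_prior += (-0.5 * (rot_offsets / prior.sigma_angles) ** 2).sum(axis=1)[:, None]
    if prior.sigma_offset > 0:
        log_prior += (-0.5 * (trans_offsets / prior.sigma_offset) ** 2).sum(axis=1)[None, :]
    return PoseGrid(rot_offsets=rot_offsets, trans_offsets=trans_offsets,
                    log_prior=log_prior, angular_step=angular_step,
                    trans_step=trans_step)


def rotation_distance(R1: np.ndarray, R2: np.ndarray) -> float:
    """Geodesic angle (degrees) between two rotation matrices."""
    c = (np.trace(np.asarray(R1).T @ np.asarray(R2)) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
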