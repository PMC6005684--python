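"""Post-refinement motion analysis: PCA over per-body residual poses,
eigen-motion map series, amplitude-based particle subsets, and export of
re-centred subtracted particle images.

Each particle contributes six variables per body: the three residual
Euler-angle offsets (degrees) and the in-plane translation lifted onto the
3D grid of the reconstruction (pixels; the component along the projection
direction is unobserved and set to zero).  Before the PCA each column is
multiplied by a scale measuring how much the corresponding body's map
changes under a one-degree rotation or one-pixel translation along that
coordinate, so that one unit of every feature represents a comparable
amount of density change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .fourier import ifft2_centered, freq_grid_2d
from .orientations import Pose, euler_to_matrix, matrix_to_euler, residual_matrix
from .refine import BodyModel, RefinementState, subtract_signal, translate_volume
from .star_io import ParticleRecord, write_particles_star

__all__ = [
    "MotionPCA",
    "EigenMapSeries",
    "poses_to_features",
    "normalize_features",
    "feature_scales",
    "eigen_map_series",
    "find_histogram_valley",
    "select_subset",
    "write_subtracted_particles",
]


def poses_to_features(records: list[ParticleRecord],
                      n_bodies: int | None = None,
                      source: str = "auto") -> np.ndarray:
    """Raw (N, 6B) feature matrix from per-body residual poses.

    Per body: [rot, tilt, psi, lift_x, lift_y, lift_z], where the lift is
    the in-plane shift rotated into the reconstruction frame by the inverse
    consensus rotation (the along-projection component is zero by
    construction).

    ``source`` selects which pose estimate to featurize: "best" (the
    stored argmax poses), "mean" (the posterior-mean poses the refinement
    attaches in memory; lower-variance, preferred for the motion PCA), or
    "auto" (means when every record carries them, else best).
    """
    if not records:
        raise ValueError("no particle records")
    B = n_bodies if n_bodies is not None else len(records[0].body_poses)
    if B == 0:
        raise ValueError("records carry no body poses")
    if source == "auto":
        source = "mean" if all(len(r.body_pose_means) == B for r in records) \
            else "best"
    out = np.zeros((len(records), 6 * B))
    for i, rec in enumerate(records):
        poses = rec.body_pose_means if source == "mean" else rec.body_poses
        if len(poses) != B:
            raise ValueError("records have inconsistent body-pose counts")
        p = rec.consensus_pose
        Rc = euler_to_matrix(p.rot, p.tilt, p.psi)
        for b, bp in enumerate(poses):
            lift = Rc.T @ np.array([bp.dx, bp.dy, 0.0])
            out[i, 6 * b: 6 * b + 3] = [bp.rot, bp.tilt, bp.psi]
            out[i, 6 * b + 3: 6 * b + 6] = lift
    return out


def _rotate_about_centre(vol: np.ndarray, R: np.ndarray) -> np.ndarray:
    c = np.array(vol.shape) // 2
    Rin = np.asarray(R).T
    off = c - Rin @ c
    return ndimage.affine_transform(vol, Rin, offset=off, order=1, mode="constant")


def _axis_rotation(axis: np.ndarray, degrees: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    th = np.deg2rad(degrees)
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def feature_scales(bodies: list[BodyModel],
                   volumes: list[np.ndarray] | None = None) -> np.ndarray:
    """Per-column normalization scales from the body densities.

    Angular columns: summed squared voxel difference between the body map
    and the map rotated one degree about the corresponding residual-rotation
    axis (the body-frame axes, through the centre-of-mass).  Translational
    columns: the same for a one-pixel shift along each Cartesian axis.
    """
    scales = np.zeros(6 * len(bodies))
    for b, body in enumerate(bodies):
        if volumes is not None:
            vol = volumes[b]
        else:
            vol = 0.5 * (translate_volume(body.density_half[1], -body.com)
                         + translate_volume(body.density_half[2], -body.com))
            vol = vol * body.mask_centred
        if not np.any(vol):
            raise ValueError(f"body {b + 1} has an empty map")
        for j in range(3):
            axis = body.frame[:, j]
            rot = _rotate_about_centre(vol, _axis_rotation(axis, 1.0))
            scales[6 * b + j] = np.sum((vol - rot) ** 2)
        for j, shift in enumerate(np.eye(3)):
            moved = translate_volume(vol, shift)
            scales[6 * b + 3 + j] = np.sum((vol - moved) ** 2)
    return scales


def normalize_features(features: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """Multiply each column by its map-change scale (see :func:`feature_scales`)."""
    return np.asarray(features) * np.asarray(scales)[None, :]


class MotionPCA(BaseEstimator, TransformerMixin):
    """PCA over normalized per-body pose features.

    Fit on the raw (N, 6B) feature matrix with per-column scales; the
    transformer stores the scales, the feature mean, the eigenvectors
    (rows of ``components_``, in normalized feature space) and eigenvalues,
    and the per-particle amplitudes of the training set (``amplitudes_``).
    ``transform`` maps raw features of new particles onto the components.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X: np.ndarray, y=None, scales: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        n, d = X.shape
        if n <= d:
            raise ValueError(
                f"need more particles ({n}) than features ({d}) for a stable PCA")
        self.scales_ = np.ones(d) if scales is None else np.asarray(scales, dtype=float)
        Z = X * self.scales_[None, :]
        self._pca = PCA(n_components=self.n_components, svd_solver="full")
        self.amplitudes_ = self._pca.fit_transform(Z)
        self.mean_ = self._pca.mean_
        self.components_ = self._pca.components_
        self.eigenvalues_ = self._pca.explained_variance_
        self.explained_variance_ratio_ = self._pca.explained_variance_ratio_
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self._pca.transform(np.asarray(X, dtype=float) * self.scales_[None, :])

    def inverse_pose_features(self, amplitude: float, component: int) -> np.ndarray:
        """Raw-space feature vector at a given amplitude along one component."""
        z = self.mean_ + amplitude * self.components_[component]
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(self.scales_ > 0, z / self.scales_, 0.0)
        return raw


@dataclass
class EigenMapSeries:
    """M combined maps along one eigen-motion, with their bin amplitudes."""

    component: int
    maps: list[np.ndarray]
    bin_amplitudes: np.ndarray
    bin_edges: np.ndarray


def _reposition_bodies(bodies: list[BodyModel], raw_features: np.ndarray,
                       volumes: list[np.ndarray] | None = None) -> np.ndarray:
    """Place every body at the poses encoded in a raw feature vector and sum."""
    box = (volumes[0] if volumes is not None else bodies[0].mask_centred).shape[0]
    combined = np.zeros((box,) * 3)
    for b, body in enumerate(bodies):
        if volumes is not None:
            vol = volumes[b]
        else:
            vol = 0.5 * (translate_volume(body.density_half[1], -body.com)
                         + translate_volume(body.density_half[2], -body.com))
            vol = vol * body.mask_centred
        rot, tilt, psi, lx, ly, lz = raw_features[6 * b: 6 * b + 6]
        A = residual_matrix(Pose(rot=rot, tilt=tilt, psi=psi), body.frame)
        moved = _rotate_about_centre(vol, A)
        combined += translate_volume(moved, np.array([lx, ly, lz]) + body.com)
    return combined


def eigen_map_series(pca: MotionPCA, component: int, bodies: list[BodyModel],
                     M: int = 10,
                     volumes: list[np.ndarray] | None = None) -> EigenMapSeries:
    """Combined maps along one eigenvector from M equi-populated amplitude bins.

    The amplitudes along the component are split into M bins of equal
    population (within one particle); the median amplitude of each bin is
    mapped back through the eigenvector and the un-normalization to
    per-body poses, each body map is rigidly repositioned (rotation about
    its centre-of-mass, then translated back to its in-situ position), and
    the repositioned bodies are summed into one map per bin.
    """
    amps = pca.amplitudes_[:, component]
    if M < 2:
        raise ValueError("need at least two bins")
    if M > len(amps):
        raise ValueError("more bins than particles")
    order = np.sort(amps)
    splits = np.array_split(order, M)
    centres = np.array([np.median(s) for s in splits])
    edges = np.array([s[0] for s in splits] + [order[-1]])
    maps = []
    for a in centres:
        raw = pca.inverse_pose_features(a, component)
        maps.append(_reposition_bodies(bodies, raw, volumes))
    return EigenMapSeries(component=component, maps=maps,
                          bin_amplitudes=centres, bin_edges=edges)


def find_histogram_valley(amplitudes: np.ndarray, bins: int = 25,
                          trim_percent: float = 2.0):
    """Valley between the two principal modes of an amplitude histogram.

    The histogram (trimmed of extreme percentiles, lightly smoothed) is
    searched for its main mode and for the highest secondary mode at least
    three bins away; the valley is the minimum between them.  Returns
    ``(valley_position, valley_count, (main_peak, secondary_peak))`` —
    a unimodal distribution yields a shallow "valley" comparable to the
    secondary peak, so the depth ratio doubles as a bimodality measure.
    """
    amps = np.asarray(amplitudes, dtype=float)
    lo, hi = np.percentile(amps, [trim_percent, 100.0 - trim_percent])
    hist, edges = np.histogram(amps[(amps >= lo) & (amps <= hi)], bins=bins)
    centres = 0.5 * (edges[:-1] + edges[1:])
    smooth = np.convolve(hist.astype(float), np.ones(3) / 3.0, mode="same")
    main = int(np.argmax(smooth))
    # secondary mode: highest *local* maximum at least three bins from the
    # main one (a flank of the main mode is never a local maximum)
    second = None
    for j in range(len(smooth)):
        if abs(j - main) < 3:
            continue
        left = smooth[j - 1] if j > 0 else -np.inf
        right = smooth[j + 1] if j < len(smooth) - 1 else -np.inf
        if smooth[j] >= left and smooth[j] >= right:
            if second is None or smooth[j] > smooth[second]:
                second = j
    if second is None:
        for j in range(len(smooth)):
            if abs(j - main) >= 3 and (second is None or smooth[j] > smooth[second]):
                second = j
    if second is None:
        raise ValueError("histogram too narrow to locate two modes")
    a, b = sorted((main, second))
    j_val = int(np.argmin(smooth[a: b + 1])) + a
    return (float(centres[j_val]), float(smooth[j_val]),
            (float(smooth[main]), float(smooth[second])))


def select_subset(pca: MotionPCA, records: list[ParticleRecord], component: int,
                  amin: float, amax: float, path=None) -> list[ParticleRecord]:
    """Particles with amplitude a in [amin, amax) along one component.

    Optionally written as a standard particle STAR file; an empty selection
    produces a warning and a valid empty file.
    """
    amps = pca.amplitudes_[:, component]
    keep = [rec for rec, a in zip(records, amps) if amin <= a < amax]
    if not keep:
        import warnings

        warnings.warn("amplitude selection is empty", stacklevel=2)
    if path is not None:
        write_particles_star(keep, path)
    return keep


def write_subtracted_particles(state: RefinementState, keep_body: int,
                               stack_path=None, star_path=None):
    """Subtract all bodies except one and re-centre on its projected COM.

    For every particle the other bodies are removed at their refined poses
    (partial signal subtraction); the image is then shifted in Fourier
    space so the kept body's projected centre-of-mass sits at the box
    centre.  The returned records carry the composed projection geometry of
    the kept body as their consensus pose (zero offsets), ready for a
    downstream focused refinement of the centred body.
    """
    if not (0 <= keep_body < state.n_bodies):
        raise ValueError(f"keep_body {keep_body} out of range")
    body = state.bodies[keep_body]
    box = state.box
    images = np.empty((state.n_particles, box, box), dtype=np.float32)
    records = []
    for i, rec in enumerate(state.records):
        S = subtract_signal(state, i, keep_body)
        p = rec.consensus_pose
        Rc = euler_to_matrix(p.rot, p.tilt, p.psi)
        bp = rec.body_poses[keep_body]
        com_proj = Rc @ body.com
        sx = p.dx + bp.dx + com_proj[0]
        sy = p.dy + bp.dy + com_proj[1]
        kx, ky = freq_grid_2d(box)
        S = S * np.exp(2j * np.pi * (kx * sx + ky * sy) / box)
        images[i] = ifft2_centered(S).real
        R_eff = Rc @ residual_matrix(bp, body.frame)
        rot, tilt, psi = matrix_to_euler(R_eff)
        records.append(ParticleRecord(
            image_ref=(str(stack_path) if stack_path else rec.image_ref[0], i),
            ctf=rec.ctf,
            consensus_pose=Pose(rot=rot, tilt=tilt, psi=psi, dx=0.0, dy=0.0),
            body_poses=[],
            half_set=rec.half_set,
        ))
    if stack_path is not None:
        from .volumes import write_stack

        write_stack(images, state.voxel_size, stack_path)
    if star_path is not None:
        write_particles_star(records, star_path)
    return images, records
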