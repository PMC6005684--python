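"""Multi-body refinement: expectation-maximization over per-body residual poses
with iteratively improved partial signal subtraction.

The forward model treats a particle image as the CTF-modulated sum of central
slices through B rigid-body transforms, each at the consensus pose composed
with a small per-body residual pose, plus frequency-dependent Gaussian noise:

    X_i = CTF_i ( sum_b P_{phi_b} V_b ) + N_i

Each expectation step aligns one body at a time against a partially
subtracted image S_ib, obtained by removing the projections of all other
bodies at their best poses from the previous iteration (only the
non-overlapping parts of their masks are subtracted, in file order).  The
posterior over a truncated Gaussian-prior pose grid weights the slice
insertions of the maximization step, which produces per-half-set Wiener
reconstructions regularized by the signal power tau^2 estimated from the
solvent-corrected half-set FSC.  Best poses (posterior argmax) feed the next
iteration's subtraction.
"""

from __future__ import annotations

import copy
import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import _kernels
from .fourier import (
    CTFParams,
    evaluate_ctf,
    extract_slice,
    fft2_centered,
    fft3_centered,
    ifft3_centered,
    freq_grid_2d,
    resolution_at_threshold,
    estimate_tau2,
    shell_average_power,
    shell_indices_2d,
    shell_indices_3d,
    solvent_correct_fsc,
    compute_fsc,
)
from .orientations import (
    Pose,
    PosePrior,
    PoseGrid,
    build_pose_grid,
    build_local_pose_grid,
    compose_projection_pose,
    euler_to_matrix,
    residual_frame,
    residual_matrix,
    residual_matrices,
    rotation_distance,
)
from .star_io import BodySpec, ParticleRecord, assign_half_sets
from .volumes import (
    MaskDecomposition,
    SoftMask,
    Volume,
    centre_of_mass,
    decompose_overlaps,
)

__all__ = [
    "BodyModel",
    "PosteriorGrid",
    "RefinementState",
    "MultiBodyData",
    "MultiBodyRefiner",
    "initialize_state",
    "run_iteration",
    "check_convergence_and_sampling",
    "subtract_signal",
    "log_likelihood",
    "compute_posterior",
    "best_pose",
    "reconstruct_body",
    "reconstruct_consensus",
    "translate_volume",
]


# ---------------------------------------------------------------------------
# small helpers

def translate_volume(vol: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Shift a real volume by a (possibly fractional) 3D vector via phases."""
    box = vol.shape[0]
    k = np.arange(box) - box // 2
    kx, ky, kz = np.meshgrid(k, k, k, indexing="ij")
    F = fft3_centered(vol)
    sx, sy, sz = np.asarray(shift, dtype=float)
    F = F * np.exp(-2j * np.pi * (kx * sx + ky * sy + kz * sz) / box)
    return ifft3_centered(F).real


def _disc(box: int, rmax: float):
    """Flat pixel arrays (kx, ky, shell) of the centred disc of radius rmax."""
    kx, ky = freq_grid_2d(box)
    sel = (kx**2 + ky**2) <= rmax**2
    shells = shell_indices_2d(box)
    return (kx[sel].astype(np.float64), ky[sel].astype(np.float64),
            shells[sel], sel)


def lowpass_volume(vol: np.ndarray, voxel_size: float, resolution: float) -> np.ndarray:
    """Gaussian-edged low-pass filter of a volume to a target resolution (A)."""
    box = vol.shape[0]
    cutoff_shell = box * voxel_size / resolution
    shells = shell_indices_3d(box)
    F = fft3_centered(vol)
    soft = 1.0 / (1.0 + np.exp((shells - cutoff_shell) / 1.0))
    return ifft3_centered(F * soft).real


# ---------------------------------------------------------------------------
# model containers

@dataclass
class BodyModel:
    """Current state of one rigid body during refinement."""

    spec: BodySpec
    mask: SoftMask                      # in-situ soft mask
    com: np.ndarray                     # voxels, relative to box centre
    frame: np.ndarray                   # residual-rotation frame (3x3)
    prior: PosePrior
    mask_centred: np.ndarray | None = None
    density_half: dict = field(default_factory=dict)   # half -> in-situ volume
    F_half: dict = field(default_factory=dict)         # half -> centred transform
    F_partial: dict = field(default_factory=dict)      # target -> half -> transform
    tau2: np.ndarray | None = None
    fsc: np.ndarray | None = None
    resolution: float = np.inf
    res_shell: int = 0
    frozen: bool = False

    @property
    def fixed(self) -> bool:
        return self.spec.fixed


@dataclass
class PosteriorGrid:
    """Posterior weights over a factored pose grid for one particle/body."""

    grid: PoseGrid
    log_posterior: np.ndarray           # (n_rot, n_trans), un-normalized
    gamma: np.ndarray                   # (n_rot, n_trans), sums to 1

    @property
    def flat_gamma(self) -> np.ndarray:
        return self.gamma.ravel()


@dataclass
class MultiBodyData:
    """Input bundle: particle images + records, body definitions, consensus map."""

    images: np.ndarray                  # (N, D, D) real images
    records: list[ParticleRecord]
    body_specs: list[BodySpec]
    masks: list[SoftMask]
    voxel_size: float = 1.0
    consensus_map: Volume | None = None
    consensus_halves: tuple[np.ndarray, np.ndarray] | None = None
    references: list[Volume] | None = None   # optional per-body initial maps

    def __post_init__(self):
        if len(self.records) != self.images.shape[0]:
            raise ValueError("record count does not match image stack")
        if len(self.body_specs) != len(self.masks):
            raise ValueError("one mask per body is required")


@dataclass
class RefinementState:
    """Everything the EM iterations read and update."""

    bodies: list[BodyModel]
    records: list[ParticleRecord]
    images_F: np.ndarray                # (N, D, D) centred 2D transforms
    ctf_images: list[np.ndarray]        # per particle (shared instances cached)
    sigma2: np.ndarray                  # per-shell noise variance (complex power)
    voxel_size: float
    box: int
    decomp: MaskDecomposition
    angular_step: float
    trans_step: float
    iteration: int = 0
    converged: bool = False
    history: list[dict] = field(default_factory=list)
    options: dict = field(default_factory=dict)
    mean_ctf2: np.ndarray | None = None
    _partial_masks_centred: dict = field(default_factory=dict)

    @property
    def n_particles(self) -> int:
        return len(self.records)

    @property
    def n_bodies(self) -> int:
        return len(self.bodies)


# ---------------------------------------------------------------------------
# likelihood / posterior primitives (reference, numpy path)

def log_likelihood(S: np.ndarray, model_projection: np.ndarray,
                   sigma2_px: np.ndarray) -> float:
    """-sum |S - projection|^2 / sigma^2 over pixels; maximal (0) at equality.

    ``sigma2_px`` is the per-pixel noise variance of the complex Fourier
    components; all populated pixels must have positive variance.
    """
    sigma2_px = np.asarray(sigma2_px, dtype=float)
    if np.any(sigma2_px <= 0):
        raise ValueError("noise variance must be positive in all populated shells")
    d = np.asarray(S) - np.asarray(model_projection)
    return float(-np.sum((d.real**2 + d.imag**2) / sigma2_px))


def best_pose(posterior: PosteriorGrid) -> Pose:
    """Grid pose of maximal posterior weight.

    Ties are broken by the largest prior log-density (smallest
    prior-weighted distance from the grid centre), then by grid order.
    """
    g = posterior.gamma
    mx = g.max()
    tie = np.argwhere(g >= mx * (1.0 - 1e-12))
    if len(tie) > 1:
        lp = posterior.grid.log_prior[tie[:, 0], tie[:, 1]]
        tie = tie[np.argsort(-lp, kind="stable")]
    ir, it = tie[0]
    return posterior.grid.pose(int(ir) * posterior.grid.n_trans + int(it))


def _normalize_log_posterior(logpost: np.ndarray) -> np.ndarray:
    m = logpost.max()
    if not np.isfinite(m):
        raise ValueError("all grid poses have zero posterior probability")
    g = np.exp(logpost - m)
    return g / g.sum()


# ---------------------------------------------------------------------------
# state construction

def _body_models(body_specs, masks, voxel_size) -> list[BodyModel]:
    coms = [centre_of_mass(m) for m in masks]
    bodies = []
    for spec, mask, com in zip(body_specs, masks, coms):
        if spec.rotate_relative_to == spec.body_index:
            frame = np.eye(3)  # single-body case: no reference vector exists
        else:
            ref_com = coms[spec.rotate_relative_to - 1]
            frame = residual_frame(com, ref_com)
        prior = PosePrior(sigma_angles=spec.sigma_angles, sigma_offset=spec.sigma_offset)
        body = BodyModel(spec=spec, mask=mask, com=com, frame=frame, prior=prior)
        body.mask_centred = _shift_mask(mask.data, -com)
        bodies.append(body)
    return bodies


def _shift_mask(mask: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Shift a mask with linear interpolation (no Fourier ringing, stays in [0,1])."""
    from scipy import ndimage

    return np.clip(ndimage.shift(np.asarray(mask, dtype=float), shift,
                                 order=1, mode="constant"), 0.0, 1.0)


def _rebuild_transforms(state: RefinementState) -> None:
    """Refresh full and partial body transforms from the in-situ densities.

    Both the full and the partial transforms multiply the COM-centred
    density by a COM-centred (shifted) mask, so a partial mask identical to
    the body's own mask yields exactly the same transform as the full one.
    """
    for b, body in enumerate(state.bodies):
        for half in (1, 2):
            centred = translate_volume(body.density_half[half], -body.com)
            body.F_half[half] = np.ascontiguousarray(
                fft3_centered(centred * body.mask_centred))
    for target in range(state.n_bodies):
        for bp, partial_mask in state.decomp.partials[target].items():
            body = state.bodies[bp]
            body.F_partial.setdefault(target, {})
            key = (target, bp)
            if key not in state._partial_masks_centred:
                state._partial_masks_centred[key] = _shift_mask(
                    partial_mask, -body.com)
            pm_centred = state._partial_masks_centred[key]
            for half in (1, 2):
                centred = translate_volume(body.density_half[half], -body.com)
                body.F_partial[target][half] = np.ascontiguousarray(
                    fft3_centered(centred * pm_centred))


def _estimate_sigma2(state: RefinementState, model_F: np.ndarray,
                     max_particles: int = 300) -> np.ndarray:
    """Per-shell noise variance from particle-minus-projection residuals."""
    box = state.box
    shells = shell_indices_2d(box).ravel()
    n_shells = box // 2 + 1
    keep = shells < n_shells
    power = np.zeros(n_shells)
    counts = np.zeros(n_shells)
    n = min(state.n_particles, max_particles)
    for i in range(n):
        rec = state.records[i]
        p = rec.consensus_pose
        R = euler_to_matrix(p.rot, p.tilt, p.psi)
        proj = state.ctf_images[i] * extract_slice(model_F, R, p.dx, p.dy)
        resid = (state.images_F[i] - proj).ravel()[keep]
        power += np.bincount(shells[keep], weights=np.abs(resid) ** 2, minlength=n_shells)
        counts += np.bincount(shells[keep], minlength=n_shells)
    sigma2 = power / np.maximum(counts, 1)
    floor = max(sigma2.max() * 1e-8, 1e-30)
    return np.maximum(sigma2, floor)


def initialize_state(
    data: MultiBodyData,
    angular_step: float = 1.8,
    trans_step: float = 0.25,
    sigma2: np.ndarray | None = None,
    seed: int = 0,
    reference_lowpass: float | None = None,
    options: dict | None = None,
) -> RefinementState:
    """Build the initial refinement state from a consensus model.

    Body densities start as the consensus map under each body's mask (or
    from the body's initial reference map when one is given, optionally
    low-pass filtered); the noise spectrum is estimated from
    particle-minus-consensus-projection residuals unless supplied; particles
    without a half-set label are split randomly into two equal halves.
    """
    box = data.images.shape[1]
    if data.consensus_map is None:
        raise ValueError("a consensus map is required to initialize the refinement")
    if data.consensus_map.data.shape[0] != box:
        raise ValueError("consensus map and particle images have different box sizes")
    for m in data.masks:
        if m.data.shape != data.consensus_map.data.shape:
            raise ValueError("body mask grid does not match the consensus map")
    bodies = _body_models(data.body_specs, data.masks, data.voxel_size)
    records = [copy.deepcopy(r) for r in data.records]
    assign_half_sets(records, seed=seed)
    B = len(bodies)
    for rec in records:
        if len(rec.body_poses) == 0:
            rec.body_poses = [Pose() for _ in range(B)]
        elif len(rec.body_poses) != B:
            raise ValueError("record body-pose count does not match body definitions")

    images_F = np.stack([fft2_centered(img) for img in data.images])
    ctf_cache: dict[CTFParams, np.ndarray] = {}
    ctf_images = []
    for rec in records:
        if rec.ctf not in ctf_cache:
            ctf_cache[rec.ctf] = evaluate_ctf(rec.ctf, box, data.voxel_size)
        ctf_images.append(ctf_cache[rec.ctf])
    mean_ctf2 = np.mean([c**2 for c in ctf_cache.values()], axis=0)

    decomp = decompose_overlaps([b.mask for b in bodies])
    state = RefinementState(
        bodies=bodies, records=records, images_F=images_F, ctf_images=ctf_images,
        sigma2=np.ones(box // 2 + 1), voxel_size=data.voxel_size, box=box,
        decomp=decomp, angular_step=angular_step, trans_step=trans_step,
        options=options or {}, mean_ctf2=mean_ctf2,
    )
    state.options.setdefault("seed", seed)
    state.options.setdefault("initial_angular_step", angular_step)

    consensus = data.consensus_map.data
    halves = data.consensus_halves or (consensus, consensus)
    for b, body in enumerate(bodies):
        if data.references is not None and data.references[b] is not None:
            ref = data.references[b].data
            if reference_lowpass:
                ref = lowpass_volume(ref, data.voxel_size, reference_lowpass)
            body.density_half = {1: ref.copy(), 2: ref.copy()}
        else:
            # per-half initial densities keep the gold-standard halves
            # independent from the first iteration on
            body.density_half = {1: halves[0] * body.mask.data,
                                 2: halves[1] * body.mask.data}
    _rebuild_transforms(state)

    if sigma2 is None:
        state.sigma2 = _estimate_sigma2(state, fft3_centered(consensus))
    else:
        sigma2 = np.asarray(sigma2, dtype=float)
        if len(sigma2) != box // 2 + 1:
            raise ValueError("sigma2 curve must have D/2+1 shells")
        state.sigma2 = np.maximum(sigma2, sigma2[sigma2 > 0].max() * 1e-12)
    return state


# ---------------------------------------------------------------------------
# expectation-step pieces

def subtract_signal(state: RefinementState, particle_index: int,
                    target_body: int) -> np.ndarray:
    """Partially subtracted image S_ib for one particle and target body.

    Subtracts the CTF-modulated projections of every other body at its best
    pose from the previous iteration, using only the non-overlapping part of
    each body's mask (file-order precedence).  Recomputed on the fly from
    the current body reconstructions.
    """
    rec = state.records[particle_index]
    half = rec.half_set
    S = state.images_F[particle_index].copy()
    ctf = state.ctf_images[particle_index]
    for bp, body in enumerate(state.bodies):
        if bp == target_body:
            continue
        F = body.F_partial[target_body][half]
        R, sx, sy = compose_projection_pose(
            rec.consensus_pose, rec.body_poses[bp], body.com, body.frame)
        S -= ctf * extract_slice(F, R, sx, sy)
    return S


def _trans_phases(kx: np.ndarray, ky: np.ndarray, trans_offsets: np.ndarray,
                  box: int) -> np.ndarray:
    return np.ascontiguousarray(np.exp(
        -2j * np.pi * (kx[None, :] * trans_offsets[:, 0:1]
                       + ky[None, :] * trans_offsets[:, 1:2]) / box))


def _grid_machinery(state: RefinementState, body: BodyModel, rmax: float,
                    local: bool = False) -> dict:
    """Per-body, per-iteration precomputation for the grid search.

    In global mode the full +/- 3 sigma grid and its rotation matrices are
    shared by all particles; in local mode (after sampling refinement) the
    grid is built per particle around its current pose.
    """
    kx, ky, shells, sel = _disc(state.box, rmax)
    mach = {
        "kx": kx, "ky": ky, "sel": sel,
        "inv_sigma2": np.ascontiguousarray(1.0 / state.sigma2[shells]),
        "local": local,
    }
    if not local:
        grid = build_pose_grid(body.prior, state.angular_step, state.trans_step)
        mach["grid"] = grid
        mach["A"] = residual_matrices(grid.rot_offsets, body.frame)
        mach["tp"] = _trans_phases(kx, ky, grid.trans_offsets, state.box)
    return mach


def compute_posterior(state: RefinementState, particle_index: int,
                      body_index: int, grid_mach: dict | None = None,
                      S: np.ndarray | None = None) -> PosteriorGrid:
    """Posterior Gamma over the pose grid for one particle and body.

    Gamma is proportional to exp(log-likelihood + log-prior), normalized
    over the grid with a log-sum-exp guard so the weights sum to one
    exactly.
    """
    body = state.bodies[body_index]
    if grid_mach is None:
        rmax = state.options.get("rmax_align") or _default_rmax(state, body)
        local = state.angular_step < state.options.get(
            "initial_angular_step", state.angular_step) - 1e-9
        grid_mach = _grid_machinery(state, body, rmax, local=local)
    kx, ky, sel = grid_mach["kx"], grid_mach["ky"], grid_mach["sel"]
    inv_sigma2 = grid_mach["inv_sigma2"]
    rec = state.records[particle_index]
    if grid_mach["local"]:
        grid = build_local_pose_grid(body.prior, rec.body_poses[body_index],
                                     state.angular_step, state.trans_step)
        A = residual_matrices(grid.rot_offsets, body.frame)
        tp = _trans_phases(kx, ky, grid.trans_offsets, state.box)
    else:
        grid, A, tp = grid_mach["grid"], grid_mach["A"], grid_mach["tp"]
    if S is None:
        S = subtract_signal(state, particle_index, body_index)
    R_cons = euler_to_matrix(rec.consensus_pose.rot, rec.consensus_pose.tilt,
                             rec.consensus_pose.psi)
    com_proj = R_cons @ body.com
    sx0 = rec.consensus_pose.dx + com_proj[0]
    sy0 = rec.consensus_pose.dy + com_proj[1]
    s_tilde = S[sel] * np.exp(2j * np.pi * (kx * sx0 + ky * sy0) / state.box)
    ctf_px = state.ctf_images[particle_index][sel]
    R_eff = np.ascontiguousarray(np.einsum("ij,njk->nik", R_cons, A))
    loglik = np.empty((grid.n_rot, grid.n_trans))
    _kernels.grid_log_likelihood(
        body.F_half[rec.half_set], R_eff, np.ascontiguousarray(s_tilde),
        np.ascontiguousarray(ctf_px), inv_sigma2,
        kx, ky, tp, loglik)
    logpost = loglik + grid.log_prior
    gamma = _normalize_log_posterior(logpost)
    return PosteriorGrid(grid=grid, log_posterior=logpost, gamma=gamma)


def _default_rmax(state: RefinementState, body: BodyModel) -> float:
    base = state.options.get("rmax_start") or state.box // 2 - 1
    return float(min(state.box // 2 - 1, base))


# ---------------------------------------------------------------------------
# maximization-step pieces

def reconstruct_body(num: np.ndarray, den: np.ndarray,
                     tau2: np.ndarray | None, box: int) -> np.ndarray:
    """Wiener-style division of the slice-insertion accumulators.

    The denominator receives 1/tau^2 per shell (infinite regularization,
    tau^2 = 0, zeroes the shell; tau2=None disables regularization up to a
    tiny ridge for numerical safety), after which the centred transform is
    inverted to a real COM-centred volume.
    """
    shells = shell_indices_3d(box)
    denom = den.copy()
    zero_mask = None
    if tau2 is not None:
        tau2 = np.asarray(tau2, dtype=float)
        inv_tau2 = np.zeros_like(tau2)
        pos = tau2 > 0
        inv_tau2[pos] = 1.0 / tau2[pos]
        reg = np.zeros(shells.max() + 1)
        reg[: len(tau2)] = inv_tau2
        valid = shells < len(tau2)
        denom[valid] += reg[shells[valid]]
        zero_mask = valid & (~pos)[np.minimum(shells, len(tau2) - 1)]
    ridge = max(denom.max() * 1e-9, 1e-30)
    V = np.zeros(num.shape, dtype=complex)
    filled = den > 0
    V[filled] = num[filled] / (denom[filled] + ridge)
    if tau2 is not None:
        V[shells >= len(tau2)] = 0.0  # no signal power defined beyond the curve
        if zero_mask is not None:
            V[zero_mask] = 0.0
    return ifft3_centered(V).real


def reconstruct_consensus(images: np.ndarray, records: list[ParticleRecord],
                          voxel_size: float, sigma2: np.ndarray | None = None,
                          ctf_images: list[np.ndarray] | None = None):
    """No-motion (single-reference) Wiener reconstruction at consensus poses.

    Returns (combined, half1, half2) real volumes.  This is both the
    initial consensus model for multi-body refinement and the baseline
    against which per-body improvements are measured.
    """
    box = images.shape[1]
    if ctf_images is None:
        cache: dict[CTFParams, np.ndarray] = {}
        ctf_images = []
        for rec in records:
            if rec.ctf not in cache:
                cache[rec.ctf] = evaluate_ctf(rec.ctf, box, voxel_size)
            ctf_images.append(cache[rec.ctf])
    if sigma2 is None:
        sigma2 = np.ones(box // 2 + 1)
    kx, ky, shells, sel = _disc(box, box // 2 - 1)
    inv_sig = 1.0 / sigma2[shells]
    halves = {}
    for half in (1, 2):
        num = np.zeros((box,) * 3, dtype=complex)
        den = np.zeros((box,) * 3)
        for i, rec in enumerate(records):
            if rec.half_set != half:
                continue
            p = rec.consensus_pose
            R = np.ascontiguousarray(euler_to_matrix(p.rot, p.tilt, p.psi))
            ctf = ctf_images[i][sel]
            Fimg = fft2_centered(images[i])[sel]
            vals = Fimg * np.exp(2j * np.pi * (kx * p.dx + ky * p.dy) / box)
            _kernels.scatter_slice(num, den, vals * ctf * inv_sig,
                                   (ctf**2) * inv_sig, kx, ky, R)
        halves[half] = reconstruct_body(num, den, None, box)
    combined = 0.5 * (halves[1] + halves[2])
    return combined, halves[1], halves[2]


# ---------------------------------------------------------------------------
# one EM iteration

def run_iteration(state: RefinementState) -> RefinementState:
    """One full expectation-maximization iteration over all bodies.

    For every particle and every non-fixed, non-frozen body: partial signal
    subtraction, posterior over the pose grid, best-pose update.  All
    subtractions use poses from the previous iteration (synchronous update).
    Reconstructions accumulate posterior-weighted slice insertions per half
    set, after which tau^2 and the per-body resolutions are refreshed from
    the solvent-corrected half-set FSC.
    """
    state.iteration += 1
    box = state.box
    B = state.n_bodies
    gamma_threshold = state.options.get("gamma_threshold", 1e-6)
    kxr, kyr, shells_r, sel_r = _disc(box, box // 2 - 1)
    inv_sig_r = 1.0 / state.sigma2[shells_r]

    local = state.angular_step < state.options.get(
        "initial_angular_step", state.angular_step) - 1e-9
    machinery = []
    for b, body in enumerate(state.bodies):
        if body.fixed or body.frozen:
            machinery.append(None)
        else:
            rmax = state.options.get("rmax_align") or _default_rmax(state, body)
            machinery.append(_grid_machinery(state, body, rmax, local=local))

    num = {b: {h: np.zeros((box,) * 3, dtype=complex) for h in (1, 2)} for b in range(B)}
    den = {b: {h: np.zeros((box,) * 3) for h in (1, 2)} for b in range(B)}
    new_poses: list[list[Pose]] = [list(rec.body_poses) for rec in state.records]
    new_means: list[list[Pose]] = [list(rec.body_poses) for rec in state.records]
    resid_power = np.zeros(box // 2 + 1)
    resid_count = np.zeros(box // 2 + 1)
    shells2 = shell_indices_2d(box).ravel()
    keep2 = shells2 < box // 2 + 1

    for i, rec in enumerate(state.records):
        half = rec.half_set
        ctf_full = state.ctf_images[i]
        p = rec.consensus_pose
        R_cons = euler_to_matrix(p.rot, p.tilt, p.psi)
        for b, body in enumerate(state.bodies):
            S = subtract_signal(state, i, b)
            com_proj = R_cons @ body.com
            sx0 = p.dx + com_proj[0]
            sy0 = p.dy + com_proj[1]
            if machinery[b] is None:
                selected = [(rec.body_poses[b], 1.0)]
            else:
                post = compute_posterior(state, i, b, grid_mach=machinery[b], S=S)
                new_poses[i][b] = best_pose(post)
                g = post.gamma
                # posterior-mean residual pose (valid for the small angular
                # offsets of the residual parameterisation)
                w_rot = g.sum(axis=1)
                w_tr = g.sum(axis=0)
                mr = w_rot @ post.grid.rot_offsets
                mt = w_tr @ post.grid.trans_offsets
                new_means[i][b] = Pose(rot=float(mr[0]), tilt=float(mr[1]),
                                       psi=float(mr[2]), dx=float(mt[0]),
                                       dy=float(mt[1]))
                mx = g.max()
                idx = np.argwhere(g >= mx * gamma_threshold)
                selected = [(post.grid.pose(int(ir) * post.grid.n_trans + int(it)),
                             float(g[ir, it])) for ir, it in idx]
            S_px = S[sel_r]
            ctf_px = ctf_full[sel_r]
            for pose, weight in selected:
                A = residual_matrix(pose, body.frame)
                R_eff = np.ascontiguousarray(R_cons @ A)
                sx = sx0 + pose.dx
                sy = sy0 + pose.dy
                vals = S_px * np.exp(2j * np.pi * (kxr * sx + kyr * sy) / box)
                _kernels.scatter_slice(
                    num[b][half], den[b][half],
                    vals * (weight * ctf_px * inv_sig_r),
                    weight * (ctf_px**2) * inv_sig_r, kxr, kyr, R_eff)
            if b == B - 1:
                # full-model residual (last body subtracted on top of S) for sigma^2
                R_eff, sx, sy = compose_projection_pose(
                    p, new_poses[i][b], body.com, body.frame)
                resid = (S - ctf_full * extract_slice(body.F_half[half], R_eff, sx, sy))
                r = resid.ravel()[keep2]
                resid_power += np.bincount(shells2[keep2], weights=np.abs(r) ** 2,
                                           minlength=box // 2 + 1)
                resid_count += np.bincount(shells2[keep2], minlength=box // 2 + 1)

    # ---- maximization: reconstruct, FSC, tau^2, resolutions
    pose_changes = {}
    solvent_correct = state.options.get("solvent_correct_fsc", True)
    fudge = state.options.get("tau2_fudge", 2.0)
    for b, body in enumerate(state.bodies):
        old = [rec.body_poses[b] for rec in state.records]
        new = [new_poses[i][b] for i in range(state.n_particles)]
        dists = [rotation_distance(residual_matrix(o, body.frame),
                                   residual_matrix(n, body.frame))
                 for o, n in zip(old, new)]
        pose_changes[b] = float(np.median(dists))
        for half in (1, 2):
            vol = reconstruct_body(num[b][half], den[b][half], body.tau2, box)
            body.density_half[half] = translate_volume(vol, body.com)
        h1 = translate_volume(body.density_half[1], -body.com)
        h2 = translate_volume(body.density_half[2], -body.com)
        if solvent_correct:
            body.fsc = solvent_correct_fsc(h1, h2, body.mask_centred,
                                           seed=state.options.get("seed", 0) + 13 * b)
        else:
            body.fsc = compute_fsc(h1 * body.mask_centred, h2 * body.mask_centred)
        res = resolution_at_threshold(body.fsc, state.voxel_size, box,
                                      state.options.get("fsc_threshold", 0.143))
        body.resolution = res.resolution
        crossing = np.nonzero(body.fsc < state.options.get("fsc_threshold", 0.143))[0]
        body.res_shell = int(crossing[0]) if len(crossing) else box // 2
        combined = 0.5 * (h1 + h2) * body.mask_centred
        power = shell_average_power(combined)
        tau2 = fudge * estimate_tau2(body.fsc, power)
        # floor: shells with noisy (even negative) corrected FSC are damped
        # ~1000-fold rather than hard-zeroed, which would lock them out of
        # all later iterations
        body.tau2 = np.maximum(tau2, 1e-3 * power)

    for i, rec in enumerate(state.records):
        rec.body_poses = new_poses[i]
        rec.body_pose_means = new_means[i]
    _rebuild_transforms(state)

    if state.options.get("update_sigma2", True):
        sigma2 = resid_power / np.maximum(resid_count, 1)
        floor = max(sigma2.max() * 1e-8, 1e-30)
        state.sigma2 = np.maximum(sigma2, floor)

    state.history.append({
        "iteration": state.iteration,
        "angular_step": state.angular_step,
        "trans_step": state.trans_step,
        "resolutions": {b: state.bodies[b].resolution for b in range(B)},
        "res_shells": {b: state.bodies[b].res_shell for b in range(B)},
        "pose_change_median": pose_changes,
        "frozen": {b: state.bodies[b].frozen for b in range(B)},
    })
    return state


# ---------------------------------------------------------------------------
# convergence / sampling control

def estimate_angular_accuracy(state: RefinementState, body_index: int,
                              n_axes: int = 6) -> float:
    """Rotation angle at which the expected log-likelihood drops by one unit.

    The body's current reference is compared against itself rotated by test
    angles about random axes; the drop is the signal-weighted squared
    projection difference ``sum |P_0 V - P_d V|^2 <CTF^2> / sigma^2``.  The
    smallest angle with a drop >= 1 (linear interpolation between scanned
    angles) is the estimated accuracy: sampling finer than this cannot be
    expected to improve the alignments.
    """
    body = state.bodies[body_index]
    box = state.box
    rmax = _default_rmax(state, body)
    kx, ky, shells, sel = _disc(box, rmax)
    inv_sigma2 = 1.0 / state.sigma2[shells]
    ctf2 = state.mean_ctf2[sel]
    F = 0.5 * (body.F_half[1] + body.F_half[2])
    rng = np.random.default_rng(state.options.get("seed", 0) + 101 * body_index)
    step = state.angular_step
    deltas = np.array([0.25, 0.5, 1.0, 2.0, 4.0]) * step
    base = extract_slice(F, np.eye(3))[sel]
    drops = np.zeros(len(deltas))
    for _ in range(n_axes):
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        for j, d in enumerate(deltas):
            K = np.array([[0, -axis[2], axis[1]],
                          [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            th = np.deg2rad(d)
            R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
            rot = extract_slice(F, R)[sel]
            drops[j] += np.sum(np.abs(base - rot) ** 2 * ctf2 * inv_sigma2)
    drops /= n_axes
    if drops[0] >= 1.0:
        return float(deltas[0])
    for j in range(1, len(deltas)):
        if drops[j] >= 1.0:
            frac = (1.0 - drops[j - 1]) / (drops[j] - drops[j - 1])
            return float(deltas[j - 1] + frac * (deltas[j] - deltas[j - 1]))
    return float(deltas[-1] * 2.0)


def check_convergence_and_sampling(state: RefinementState) -> RefinementState:
    """Freeze bodies, refine sampling, and flag global convergence.

    A body's poses are kept fixed once the angular sampling is finer than
    its estimated rotational accuracy.  When no body improved its resolution
    by at least one shell in the last iteration the sampling steps are
    halved.  The refinement converges once resolutions are flat, pose
    changes are below the angular step, and the sampling is finer than every
    body's accuracy (or every free body is frozen).
    """
    min_iter = state.options.get("min_iter", 3)
    if len(state.history) < 2 or state.iteration < min_iter:
        return state
    last, prev = state.history[-1], state.history[-2]
    improved = any(last["res_shells"][b] > prev["res_shells"][b]
                   for b in range(state.n_bodies))
    refined_once = state.angular_step < state.options.get(
        "initial_angular_step", state.angular_step) - 1e-9
    accuracies = {}
    for b, body in enumerate(state.bodies):
        if body.fixed or body.frozen:
            continue
        accuracies[b] = estimate_angular_accuracy(state, b)
        # freeze only once the sampling has been refined at least once:
        # early accuracy estimates are pessimistic while the references are
        # still motion-blurred, and freezing then would stall the bootstrap
        if refined_once and state.angular_step < accuracies[b]:
            body.frozen = True
    free = [b for b, body in enumerate(state.bodies) if not (body.fixed or body.frozen)]
    min_ang = state.options.get(
        "min_angular_step", state.options.get("initial_angular_step", 1.8) / 4.0)
    at_finest = state.angular_step <= min_ang + 1e-9
    if not improved and free and not at_finest:
        state.angular_step = max(state.angular_step / 2.0, min_ang)
        state.trans_step = max(state.trans_step / 2.0,
                               state.options.get("min_trans_step", 0.05))
    changes_small = all(last["pose_change_median"][b] <= state.angular_step
                        for b in range(state.n_bodies))
    fine_enough = all(state.angular_step < acc for acc in accuracies.values()) \
        if accuracies else True
    if not free:
        state.converged = True
    elif (not improved) and changes_small and fine_enough and at_finest:
        state.converged = True
    state.history[-1]["accuracies"] = accuracies
    state.history[-1]["converged"] = state.converged
    return state


# ---------------------------------------------------------------------------
# estimator facade

class MultiBodyRefiner(BaseEstimator):
    """Scikit-learn-style estimator running multi-body refinement to convergence.

    Parameters mirror the refinement tunables: initial sampling steps
    (degrees / pixels), the maximum number of EM iterations, the posterior
    truncation threshold used during reconstruction, the FSC threshold
    defining reported resolutions, whether the half-set FSC is
    solvent-corrected, whether the noise spectrum is re-estimated every
    iteration, the tau^2 multiplier, the alignment frequency radius in
    reciprocal voxels (None uses the full band up to D/2 - 1), and the
    random seed (half-set split, phase randomization).

    After :meth:`fit`, ``bodies_`` holds the refined :class:`BodyModel`s,
    ``records_`` the particles with refined residual poses, ``history_``
    per-iteration statistics, and ``resolutions_`` the final per-body
    solvent-corrected FSC resolutions in Angstrom.
    """

    def __init__(self, angular_step=1.8, trans_step=0.25, max_iter=10,
                 min_iter=3, gamma_threshold=1e-6, fsc_threshold=0.143,
                 solvent_correct_fsc=True, update_sigma2=True, tau2_fudge=2.0,
                 rmax_start=None, seed=0, verbose=0):
        self.angular_step = angular_step
        self.trans_step = trans_step
        self.max_iter = max_iter
        self.min_iter = min_iter
        self.gamma_threshold = gamma_threshold
        self.fsc_threshold = fsc_threshold
        self.solvent_correct_fsc = solvent_correct_fsc
        self.update_sigma2 = update_sigma2
        self.tau2_fudge = tau2_fudge
        self.rmax_start = rmax_start
        self.seed = seed
        self.verbose = verbose

    def fit(self, X: MultiBodyData, y=None, sigma2=None, callback=None):
        if not isinstance(X, MultiBodyData):
            raise TypeError("MultiBodyRefiner.fit expects a MultiBodyData bundle")
        if X.consensus_map is None:
            assign_half_sets(X.records, seed=self.seed)
            combined, h1, h2 = reconstruct_consensus(
                X.images, X.records, X.voxel_size)
            X.consensus_map = Volume(combined, X.voxel_size)
            X.consensus_halves = (h1, h2)
        options = {
            "min_iter": self.min_iter,
            "gamma_threshold": self.gamma_threshold,
            "fsc_threshold": self.fsc_threshold,
            "solvent_correct_fsc": self.solvent_correct_fsc,
            "update_sigma2": self.update_sigma2,
            "tau2_fudge": self.tau2_fudge,
            "rmax_start": self.rmax_start,
            "seed": self.seed,
        }
        state = initialize_state(
            X, angular_step=self.angular_step, trans_step=self.trans_step,
            sigma2=sigma2, seed=self.seed, options=options)
        for it in range(self.max_iter):
            t0 = time.time()
            run_iteration(state)
            check_convergence_and_sampling(state)
            if self.verbose:
                res = ", ".join(f"body{b + 1}: {r:.2f} A"
                                for b, r in state.history[-1]["resolutions"].items())
                print(f"iter {state.iteration:3d} ({time.time() - t0:6.1f} s)  {res}")
            if callback is not None:
                callback(state)
            if state.converged:
                break
        self.state_ = state
        self.bodies_ = state.bodies
        self.records_ = state.records
        self.history_ = state.history
        self.sigma2_ = state.sigma2
        self.n_iter_ = state.iteration
        self.converged_ = state.converged
        self.resolutions_ = {b: body.resolution for b, body in enumerate(state.bodies)}
        return self
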