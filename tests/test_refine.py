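"""EM machinery: likelihoods, posteriors, subtraction, reconstruction,
iteration behaviour and convergence control."""

import copy

import numpy as np
import pytest

from multibody import _kernels
from multibody.fourier import (
    extract_slice,
    fft2_centered,
    fft3_centered,
    freq_grid_2d,
    shell_indices_2d,
    shell_indices_3d,
)
from multibody.orientations import (
    Pose,
    PoseGrid,
    build_pose_grid,
    compose_projection_pose,
    residual_matrix,
    rotation_distance,
)
from multibody.refine import (
    MultiBodyData,
    MultiBodyRefiner,
    PosteriorGrid,
    _normalize_log_posterior,
    best_pose,
    compute_posterior,
    initialize_state,
    log_likelihood,
    reconstruct_body,
    reconstruct_consensus,
    run_iteration,
    check_convergence_and_sampling,
    subtract_signal,
    translate_volume,
)
from multibody.simulate import (
    MotionModel,
    make_dataset,
    simulate_particles,
)
from multibody.volumes import Volume

from conftest import make_disjoint_selfconsistent


class TestLogLikelihood:
    def test_matches_brute_force_pixel_loop(self, rng):
        S = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        proj = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        sigma2 = rng.uniform(0.5, 2.0, (16, 16))
        expected = 0.0
        for i in range(16):
            for j in range(16):
                d = S[i, j] - proj[i, j]
                expected -= (d.real**2 + d.imag**2) / sigma2[i, j]
        assert np.isclose(log_likelihood(S, proj, sigma2), expected, rtol=1e-12)

    def test_equal_images_give_zero(self, rng):
        S = rng.standard_normal((8, 8)).astype(complex)
        assert log_likelihood(S, S, np.ones((8, 8))) == 0.0

    def test_doubling_sigma2_halves_differences(self, rng):
        S = rng.standard_normal((8, 8)).astype(complex)
        p1 = rng.standard_normal((8, 8)).astype(complex)
        p2 = rng.standard_normal((8, 8)).astype(complex)
        s2 = rng.uniform(0.5, 2, (8, 8))
        d1 = log_likelihood(S, p1, s2) - log_likelihood(S, p2, s2)
        d2 = log_likelihood(S, p1, 2 * s2) - log_likelihood(S, p2, 2 * s2)
        assert np.isclose(d1, 2 * d2, rtol=1e-12)

    def test_zero_sigma2_rejected(self, rng):
        S = rng.standard_normal((8, 8)).astype(complex)
        with pytest.raises(ValueError):
            log_likelihood(S, S, np.zeros((8, 8)))


class TestPosteriorNormalization:
    def test_single_pose_grid(self):
        gamma = _normalize_log_posterior(np.array([[-123.0]]))
        assert gamma.shape == (1, 1) and gamma[0, 0] == 1.0

    def test_two_equal_poses(self):
        gamma = _normalize_log_posterior(np.array([[-5.0], [-5.0]]))
        assert np.allclose(gamma, 0.5)

    def test_sums_to_one_on_random_grids(self, rng):
        for _ in range(10):
            lp = rng.uniform(-1e4, 0, (rng.integers(2, 30), rng.integers(1, 5)))
            gamma = _normalize_log_posterior(lp)
            assert abs(gamma.sum() - 1.0) < 1e-12

    def test_matches_naive_normalization_when_well_conditioned(self, rng):
        lp = rng.uniform(-20, 0, (7, 3))
        naive = np.exp(lp) / np.exp(lp).sum()
        assert np.allclose(_normalize_log_posterior(lp), naive, atol=1e-12)

    def test_prior_constant_shift_leaves_posterior(self, rng):
        lp = rng.uniform(-100, 0, (9, 2))
        assert np.allclose(_normalize_log_posterior(lp),
                           _normalize_log_posterior(lp + 123.456), atol=1e-12)


class TestBestPose:
    @staticmethod
    def _posterior(gamma, grid):
        return PosteriorGrid(grid=grid, log_posterior=np.log(gamma + 1e-300),
                             gamma=gamma)

    def test_concentrated(self):
        from multibody.orientations import PosePrior

        grid = build_pose_grid(PosePrior(3.0, 0.0), 1.8, 0.25)
        gamma = np.zeros((grid.n_rot, grid.n_trans))
        gamma[7, 0] = 1.0
        assert best_pose(self._posterior(gamma, grid)) == grid.pose(7 * grid.n_trans)

    def test_uniform_breaks_tie_at_centre(self):
        from multibody.orientations import PosePrior

        grid = build_pose_grid(PosePrior(3.0, 1.0), 1.8, 0.5)
        gamma = np.full((grid.n_rot, grid.n_trans),
                        1.0 / (grid.n_rot * grid.n_trans))
        assert best_pose(self._posterior(gamma, grid)) == Pose()

    def test_random_matches_linear_scan(self, rng):
        from multibody.orientations import PosePrior

        grid = build_pose_grid(PosePrior(3.0, 0.0), 1.8, 0.25)
        gamma = rng.uniform(0, 1, (grid.n_rot, grid.n_trans))
        gamma /= gamma.sum()
        expected = grid.pose(int(np.argmax(gamma.ravel())))
        assert best_pose(self._posterior(gamma, grid)) == expected


@pytest.fixture(scope="module")
def sc_state():
    """Initialized state over self-consistent noiseless disjoint data."""
    data, phantom, truth, sigma2 = make_disjoint_selfconsistent(n_particles=12)
    state = initialize_state(data, angular_step=1.8, trans_step=0.25, seed=0,
                             sigma2=sigma2,
                             options={"update_sigma2": False,
                                      "solvent_correct_fsc": False})
    return state, phantom, truth


class TestSubtraction:
    def test_single_body_subtracts_nothing(self):
        from multibody.star_io import BodySpec

        data, phantom, truth, sigma2 = make_disjoint_selfconsistent(n_particles=3)
        # collapse to one body: the subtracted image is the raw image
        data.body_specs = [BodySpec(1, "m1.mrc", 1, 3.0, 0.0)]
        data.masks = [data.masks[0]]
        for rec in data.records:
            rec.body_poses = rec.body_poses[:1]
        state = initialize_state(data, sigma2=sigma2, seed=0)
        S = subtract_signal(state, 0, 0)
        assert np.array_equal(S, state.images_F[0])

    def test_noiseless_selfconsistent_leaves_pure_body_signal(self, sc_state):
        state, phantom, truth = sc_state
        state = copy.deepcopy(state)
        for rec, res in zip(state.records, truth.residual_poses):
            rec.body_poses = list(res)
        for i in (0, 1):
            rec = state.records[i]
            for b in (1, 2):
                body = state.bodies[b]
                S = subtract_signal(state, i, b)
                R, sx, sy = compose_projection_pose(
                    rec.consensus_pose, truth.residual_poses[i][b],
                    body.com, body.frame)
                pred = state.ctf_images[i] * extract_slice(
                    body.F_half[rec.half_set], R, sx, sy)
                resid = np.linalg.norm(S - pred) / np.linalg.norm(S)
                assert resid < 1e-3

    def test_wrong_pose_increases_residual_power(self, sc_state):
        state, phantom, truth = sc_state
        state = copy.deepcopy(state)
        for rec, res in zip(state.records, truth.residual_poses):
            rec.body_poses = list(res)
        rec = state.records[0]
        b = 1
        body = state.bodies[b]
        S = subtract_signal(state, 0, b)

        def resid(pose):
            R, sx, sy = compose_projection_pose(rec.consensus_pose, pose,
                                                body.com, body.frame)
            pred = state.ctf_images[0] * extract_slice(
                body.F_half[rec.half_set], R, sx, sy)
            return np.sum(np.abs(S - pred) ** 2)

        true_pose = truth.residual_poses[0][b]
        r_true = resid(true_pose)
        for off in (3.6, 7.2):
            assert resid(Pose(rot=true_pose.rot + off)) > r_true
            assert resid(Pose(rot=true_pose.rot - off)) > r_true


class TestReconstruction:
    @staticmethod
    def _compact_volume(box, rng, radius=5.0):
        # compact (~1/3 box) like a COM-centred body; objects filling the
        # box suffer the +/- 1 voxel insertion smear far more strongly
        ax = np.arange(box) - box // 2
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        vol = np.zeros((box,) * 3)
        for _ in range(10):
            while True:
                p = rng.uniform(-radius, radius, 3)
                if np.linalg.norm(p) <= radius:
                    break
            s = rng.uniform(1.8, 2.8)
            vol += rng.uniform(0.5, 1.2) * np.exp(
                -((x - p[0]) ** 2 + (y - p[1]) ** 2 + (z - p[2]) ** 2)
                / (2 * s * s))
        return vol

    def test_many_ideal_slices_recover_volume(self, rng):
        from scipy.spatial.transform import Rotation

        box = 32
        truth_vol = self._compact_volume(box, np.random.default_rng(1))
        F = fft3_centered(truth_vol)
        kx, ky = freq_grid_2d(box)
        sel = (kx**2 + ky**2) <= (box // 2 - 1) ** 2
        kxf = kx[sel].astype(float)
        kyf = ky[sel].astype(float)
        num = np.zeros((box,) * 3, dtype=complex)
        den = np.zeros((box,) * 3)
        for R in Rotation.random(300, rng=rng).as_matrix():
            sl = extract_slice(F, R)[sel]
            _kernels.scatter_slice(num, den, sl, np.ones(len(kxf)), kxf, kyf,
                                   np.ascontiguousarray(R))
        vol = reconstruct_body(num, den, None, box)
        # compare against the band-limited truth: the reconstruction only
        # contains frequencies up to the insertion radius
        shells3 = shell_indices_3d(box)
        F_t = fft3_centered(truth_vol)
        F_t[shells3 > box // 2 - 1] = 0.0
        from multibody.fourier import ifft3_centered

        truth_lp = ifft3_centered(F_t).real
        corr = np.corrcoef(vol.ravel(), truth_lp.ravel())[0, 1]
        assert corr >= 0.99

    def test_zero_tau2_kills_output(self, rng):
        box = 16
        num = (rng.standard_normal((box,) * 3)
               + 1j * rng.standard_normal((box,) * 3))
        den = np.ones((box,) * 3)
        vol = reconstruct_body(num, den, np.zeros(box // 2 + 1), box)
        assert np.allclose(vol, 0.0)

    def test_unnormalized_gamma_invariance(self, rng):
        """Scaling all posterior weights leaves the Wiener ratio unchanged."""
        box = 16
        R = np.ascontiguousarray(np.eye(3))
        kx, ky = freq_grid_2d(box)
        sel = (kx**2 + ky**2) <= 6**2
        kxf, kyf = kx[sel].astype(float), ky[sel].astype(float)
        img = (rng.standard_normal(sel.sum())
               + 1j * rng.standard_normal(sel.sum()))
        out = []
        for scale in (1.0, 0.5):
            num = np.zeros((box,) * 3, dtype=complex)
            den = np.zeros((box,) * 3)
            _kernels.scatter_slice(num, den, img * scale,
                                   np.full(sel.sum(), scale), kxf, kyf, R)
            out.append(reconstruct_body(num, den, None, box))
        assert np.allclose(out[0], out[1], atol=1e-10)

    def test_consensus_reconstruction_recovers_still_phantom(self, rng):
        """No-motion Wiener reconstruction of a smooth phantom from its own
        noiseless projections recovers the volume up to interpolation loss."""
        from multibody.simulate import Phantom, make_phantom, Blob

        box = 32
        blobs = [[Blob(tuple(rng.uniform(-8, 8, 3)), float(rng.uniform(2, 3.2)),
                       float(rng.uniform(0.5, 1.2))) for _ in range(8)]]
        phantom = make_phantom(box, blobs, voxel_size=1.5)
        still = MotionModel(kind="continuous", axes={0: np.array([1.0, 0, 0])},
                            magnitude=1e-9)
        images, records, truth = simulate_particles(phantom, 200, still,
                                                    snr=1e9, seed=2)
        combined, h1, h2 = reconstruct_consensus(images, records,
                                                 phantom.voxel_size)
        from multibody.fourier import ifft3_centered

        F_t = fft3_centered(phantom.combined.data)
        F_t[shell_indices_3d(box) > box // 2 - 1] = 0.0
        truth_lp = ifft3_centered(F_t).real
        corr = np.corrcoef(combined.ravel(), truth_lp.ravel())[0, 1]
        assert corr > 0.95


class TestInitialization:
    def test_disjoint_partition_of_consensus(self, sc_state):
        state, phantom, truth = sc_state
        total = np.zeros_like(phantom.combined.data)
        union = np.zeros_like(phantom.combined.data)
        for body in state.bodies:
            total += body.density_half[1]
            union = np.maximum(union, body.mask.data)
        expected = phantom.combined.data * union
        assert np.allclose(total, expected, atol=1e-8)

    def test_mask_grid_mismatch_rejected(self):
        data, phantom, truth, sigma2 = make_disjoint_selfconsistent(n_particles=3)
        data.consensus_map = Volume(np.zeros((16, 16, 16)))
        with pytest.raises(ValueError):
            initialize_state(data)

    def test_sigma2_estimate_close_to_truth(self):
        """Noise spectrum estimated from consensus-model residuals matches the
        generator's noise within 20% in the populated shells (no motion)."""
        still = MotionModel(kind="continuous", axes={1: np.array([1.0, 0, 0])},
                            magnitude=1e-9)
        data, phantom, truth = make_dataset(box=32, n_particles=500,
                                            motion=still, snr=0.1, seed=4)
        data.consensus_map = phantom.combined
        state = initialize_state(data, seed=0)
        band = slice(2, 14)
        ratio = state.sigma2[band] / truth.sigma2[band]
        assert np.all(ratio > 0.8) and np.all(ratio < 1.2)


class TestIteration:
    def test_fixed_body_poses_never_move(self, sc_state):
        state, phantom, truth = sc_state
        state = copy.deepcopy(state)
        for rec, res in zip(state.records, truth.residual_poses):
            rec.body_poses = list(res)
        run_iteration(state)
        for rec in state.records:
            assert rec.body_poses[0] == Pose()  # body 1 is fixed

    def test_selfconsistent_truth_is_fixed_point(self, sc_state):
        state, phantom, truth = sc_state
        state = copy.deepcopy(state)
        for rec, res in zip(state.records, truth.residual_poses):
            rec.body_poses = list(res)
        run_iteration(state)
        for i, rec in enumerate(state.records):
            for b in (1, 2):
                d = rotation_distance(
                    residual_matrix(rec.body_poses[b], state.bodies[b].frame),
                    residual_matrix(truth.residual_poses[i][b],
                                    state.bodies[b].frame))
                assert d < 1e-3, f"particle {i} body {b} drifted by {d} deg"

    def test_iteration_reduces_total_residual_power(self, sc_state):
        """Starting from identity residuals on data with true motion, one
        iteration moves poses closer to truth, shrinking the model residual."""
        state, phantom, truth = sc_state
        state = copy.deepcopy(state)
        reference = copy.deepcopy(state)  # evaluate both pose sets on one model

        def total_residual(state):
            total = 0.0
            for i, rec in enumerate(state.records):
                for b in (1, 2):
                    body = state.bodies[b]
                    S = subtract_signal(state, i, b)
                    R, sx, sy = compose_projection_pose(
                        rec.consensus_pose, rec.body_poses[b], body.com,
                        body.frame)
                    pred = state.ctf_images[i] * extract_slice(
                        body.F_half[rec.half_set], R, sx, sy)
                    total += np.sum(np.abs(S - pred) ** 2)
            return total

        before = total_residual(reference)
        run_iteration(state)
        for rec_ref, rec_new in zip(reference.records, state.records):
            rec_ref.body_poses = list(rec_new.body_poses)
        after = total_residual(reference)
        assert after < before

    def test_half_set_separation(self):
        """Permuting particles within half-set 1 leaves half-set 2's
        reconstruction bitwise unchanged."""
        data, phantom, truth, sigma2 = make_disjoint_selfconsistent(n_particles=10)
        opts = {"update_sigma2": False, "solvent_correct_fsc": False}
        s1 = initialize_state(copy.deepcopy(data), sigma2=sigma2, seed=0,
                              options=dict(opts))
        run_iteration(s1)
        ref_half2 = {b: s1.bodies[b].density_half[2].copy() for b in range(3)}

        idx1 = [i for i, r in enumerate(data.records) if r.half_set == 1]
        data2 = copy.deepcopy(data)
        # swap two half-1 particles (images + records together)
        a, b_ = idx1[0], idx1[1]
        data2.images[[a, b_]] = data2.images[[b_, a]]
        data2.records[a], data2.records[b_] = data2.records[b_], data2.records[a]
        s2 = initialize_state(data2, sigma2=sigma2, seed=0, options=dict(opts))
        run_iteration(s2)
        for b in range(3):
            assert np.allclose(s2.bodies[b].density_half[2], ref_half2[b],
                               atol=1e-10)

    def test_posterior_sums_to_one_in_pipeline(self, sc_state):
        state, phantom, truth = sc_state
        post = compute_posterior(state, 0, 1)
        assert abs(post.gamma.sum() - 1.0) < 1e-12


class TestConvergenceControl:
    def _toy_state(self, sc_state):
        state, phantom, truth = sc_state
        return copy.deepcopy(state)

    def test_improving_resolution_keeps_steps(self, sc_state, monkeypatch):
        state = self._toy_state(sc_state)
        state.iteration = 4
        mk = lambda shells: {
            "iteration": 0, "angular_step": state.angular_step,
            "trans_step": state.trans_step,
            "resolutions": {b: 3.0 for b in range(3)},
            "res_shells": dict(enumerate(shells)),
            "pose_change_median": {b: 0.1 for b in range(3)},
            "frozen": {b: False for b in range(3)},
        }
        state.history = [mk([8, 8, 8]), mk([9, 10, 9])]
        monkeypatch.setattr("multibody.refine.estimate_angular_accuracy",
                            lambda s, b, n_axes=6: 10.0)
        step_before = state.angular_step
        check_convergence_and_sampling(state)
        assert state.angular_step == step_before
        assert not state.converged

    def test_stall_halves_steps(self, sc_state, monkeypatch):
        state = self._toy_state(sc_state)
        state.iteration = 4
        mk = lambda shells, dp: {
            "iteration": 0, "angular_step": state.angular_step,
            "trans_step": state.trans_step,
            "resolutions": {b: 3.0 for b in range(3)},
            "res_shells": dict(enumerate(shells)),
            "pose_change_median": {b: dp for b in range(3)},
            "frozen": {b: False for b in range(3)},
        }
        state.history = [mk([9, 9, 9], 2.0), mk([9, 9, 9], 2.0)]
        monkeypatch.setattr("multibody.refine.estimate_angular_accuracy",
                            lambda s, b, n_axes=6: 10.0)
        step_before = state.angular_step
        check_convergence_and_sampling(state)
        assert state.angular_step == step_before / 2
        assert not state.converged

    def test_all_bodies_frozen_converges(self, sc_state):
        state = self._toy_state(sc_state)
        state.iteration = 4
        for body in state.bodies:
            body.frozen = True
        entry = {
            "iteration": 0, "angular_step": state.angular_step,
            "trans_step": state.trans_step,
            "resolutions": {b: 3.0 for b in range(3)},
            "res_shells": {b: 9 for b in range(3)},
            "pose_change_median": {b: 0.0 for b in range(3)},
            "frozen": {b: True for b in range(3)},
        }
        state.history = [entry, dict(entry)]
        check_convergence_and_sampling(state)
        assert state.converged

    def test_flat_and_fine_at_finest_sampling_converges(self, sc_state,
                                                        monkeypatch):
        state = self._toy_state(sc_state)
        state.iteration = 6
        state.angular_step = state.options["initial_angular_step"] / 4.0
        entry = lambda: {
            "iteration": 0, "angular_step": state.angular_step,
            "trans_step": state.trans_step,
            "resolutions": {b: 3.0 for b in range(3)},
            "res_shells": {b: 9 for b in range(3)},
            "pose_change_median": {b: 0.01 for b in range(3)},
            "frozen": {b: False for b in range(3)},
        }
        state.history = [entry(), entry()]
        monkeypatch.setattr("multibody.refine.estimate_angular_accuracy",
                            lambda s, b, n_axes=6: 10.0)
        check_convergence_and_sampling(state)
        assert state.converged


class TestEstimatorFacade:
    def test_sklearn_params_roundtrip(self):
        ref = MultiBodyRefiner(angular_step=0.9, seed=7)
        params = ref.get_params()
        assert params["angular_step"] == 0.9
        ref2 = MultiBodyRefiner(**params)
        assert ref2.get_params() == params

    def test_fit_rejects_wrong_input(self):
        with pytest.raises(TypeError):
            MultiBodyRefiner().fit(np.zeros((3, 3)))
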