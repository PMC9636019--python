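import numpy as np
import pandas as pd
import pytest

from acmpose.smoother import (
    EMOptions,
    NoiseParams,
    StateSpaceSpec,
    UTParams,
    count_em_params,
    em_fit,
    fit_pose_per_frame,
    fit_single_pose,
    make_measurements,
    propagate_uncertainty,
    relax_limits,
    surface_trajectories,
    ukf_rts_smooth,
    unscented_transform,
)
from acmpose.skeleton import count_state_dim, forward_kinematics_batch
from helpers import kalman_filter_rts


class _LinearSpec:
    """Affine measurement stand-in with the StateSpaceSpec interface."""

    def __init__(self, H, b=None):
        self.H = H
        self.b = np.zeros(H.shape[0]) if b is None else b
        self.n = H.shape[1]
        self.m = H.shape[0]

    def h(self, X):
        return np.atleast_2d(X) @ self.H.T + self.b


class TestUnscentedTransform:
    def test_identity_is_exact(self, rng):
        mean = rng.normal(size=4)
        C = rng.normal(size=(4, 4))
        cov = C @ C.T
        my, Sy, Cxy = unscented_transform(mean, cov, lambda X: X)
        assert np.allclose(my, mean, atol=1e-12)
        assert np.allclose(Sy, cov, atol=1e-8)
        assert np.allclose(Cxy, cov, atol=1e-8)

    def test_affine_oracle(self, rng):
        # with unit-scale sigma points the affine pushforward is exact
        ut = UTParams(alpha=1.0, beta=0.0, kappa=0.0)
        A = rng.normal(size=(3, 5))
        b = rng.normal(size=3)
        mean = rng.normal(size=5)
        C = rng.normal(size=(5, 5))
        cov = C @ C.T
        my, Sy, Cxy = unscented_transform(mean, cov,
                                          lambda X: X @ A.T + b, ut)
        assert np.allclose(my, A @ mean + b, atol=1e-10)
        assert np.allclose(Sy, A @ cov @ A.T, atol=1e-10)
        assert np.allclose(Cxy, cov @ A.T, atol=1e-10)

    def test_scalar_square_closed_form(self):
        # E[x^2] = mu^2 + sigma^2 for x ~ N(mu, sigma^2)
        ut = UTParams(alpha=1.0, beta=2.0, kappa=2.0)
        my, _, _ = unscented_transform(np.array([1.5]), np.array([[0.49]]),
                                       lambda X: X**2, ut)
        assert my[0] == pytest.approx(1.5**2 + 0.49, abs=1e-10)


class TestCountEMParams:
    def test_full_rat_setup(self, rat, rat_params, rig):
        spec = StateSpaceSpec(rat[0], rat_params, rig, rat[3])
        assert spec.n == 50
        assert spec.m == 344
        assert count_em_params(spec) == 2944

    @pytest.mark.parametrize("n,m,expected", [(1, 1, 4), (2, 0, 8)])
    def test_small_counts(self, n, m, expected):
        assert count_em_params((n, m)) == expected


class TestKalmanEquivalence:
    def _make_problem(self, rng, T=100, n=2, m=3):
        H = rng.normal(size=(m, n))
        Q = 0.3 * np.eye(n)
        r = np.full(m, 0.5)
        mu0 = rng.normal(size=n)
        P0 = np.eye(n)
        x = np.zeros((T, n))
        x[0] = mu0 + rng.multivariate_normal(np.zeros(n), P0)
        for t in range(1, T):
            x[t] = x[t - 1] + rng.multivariate_normal(np.zeros(n), Q)
        y = x @ H.T + rng.normal(0, np.sqrt(0.5), size=(T, m))
        return H, Q, r, mu0, P0, y

    def test_moments_match_closed_form(self, rng):
        H, Q, r, mu0, P0, y = self._make_problem(rng)
        mask = np.ones_like(y, dtype=bool)
        spec = _LinearSpec(H)
        noise = NoiseParams(mu0, P0, Q, r)
        res = ukf_rts_smooth(spec, noise, y, mask, UTParams(alpha=1.0))
        ref = kalman_filter_rts(y, mask, np.eye(2), H, Q, np.diag(r), mu0, P0)
        assert np.allclose(res.filtered_means, ref["filtered_means"], atol=1e-6)
        assert np.allclose(res.filtered_covs, ref["filtered_covs"], atol=1e-6)
        assert np.allclose(res.smoothed_means, ref["smoothed_means"], atol=1e-6)
        assert np.allclose(res.smoothed_covs, ref["smoothed_covs"], atol=1e-6)
        assert res.loglik == pytest.approx(ref["loglik"], rel=1e-6)

    def test_masking_equals_row_deletion(self, rng):
        H, Q, r, mu0, P0, y = self._make_problem(rng)
        mask = rng.random(y.shape) > 0.3
        mask[0] = True
        spec = _LinearSpec(H)
        noise = NoiseParams(mu0, P0, Q, r)
        res = ukf_rts_smooth(spec, noise, y, mask, UTParams(alpha=1.0))
        ref = kalman_filter_rts(y, mask, np.eye(2), H, Q, np.diag(r), mu0, P0)
        assert np.allclose(res.smoothed_means, ref["smoothed_means"], atol=1e-9)
        assert np.allclose(res.smoothed_covs, ref["smoothed_covs"], atol=1e-9)

    def test_fully_missing_frame_keeps_prediction(self, rng):
        H, Q, r, mu0, P0, y = self._make_problem(rng, T=10)
        mask = np.ones_like(y, dtype=bool)
        mask[5] = False
        spec = _LinearSpec(H)
        res = ukf_rts_smooth(spec, NoiseParams(mu0, P0, Q, r), y, mask,
                             UTParams(alpha=1.0))
        # random-walk transition: prediction at t equals the filtered state
        # at t-1 (mean unchanged, covariance inflated by Q)
        assert np.allclose(res.filtered_means[5], res.filtered_means[4],
                           atol=1e-12)
        assert np.allclose(res.filtered_covs[5],
                           res.filtered_covs[4] + Q, atol=1e-12)

    def test_smoothing_never_increases_uncertainty(self, rng):
        H, Q, r, mu0, P0, y = self._make_problem(rng)
        mask = np.ones_like(y, dtype=bool)
        res = ukf_rts_smooth(_LinearSpec(H), NoiseParams(mu0, P0, Q, r), y,
                             mask, UTParams(alpha=1.0))
        for t in range(len(y)):
            assert (np.trace(res.smoothed_covs[t])
                    <= np.trace(res.filtered_covs[t]) + 1e-9)


class TestEM:
    def test_recovers_random_walk_variances(self):
        rng = np.random.default_rng(7)
        q, r = 0.5, 1.0
        T = 2000
        x = np.cumsum(rng.normal(0, np.sqrt(q), T))
        y = (x + rng.normal(0, np.sqrt(r), T))[:, None]
        mask = np.ones((T, 1), dtype=bool)
        spec = _LinearSpec(np.eye(1))
        init = NoiseParams.default(1, 1)
        noise, trace, _ = em_fit(spec, y, mask, init,
                                 EMOptions(max_iter=60, rel_tol=1e-6,
                                           ut=UTParams(alpha=1.0)))
        assert noise.Q[0, 0] == pytest.approx(q, rel=0.10)
        assert noise.r[0] == pytest.approx(r, rel=0.10)
        assert trace.monotone

    def test_elbo_nondecreasing(self):
        rng = np.random.default_rng(3)
        T = 200
        y = np.cumsum(rng.normal(0, 1, T))[:, None] + rng.normal(0, 1, (T, 1))
        mask = np.ones((T, 1), dtype=bool)
        _, trace, _ = em_fit(_LinearSpec(np.eye(1)), y, mask,
                             NoiseParams.default(1, 1),
                             EMOptions(max_iter=25, rel_tol=0,
                                       ut=UTParams(alpha=1.0)))
        diffs = np.diff(trace.elbo)
        assert np.all(diffs >= -1e-8 * np.maximum(1, np.abs(trace.elbo[:-1])))

    def test_zero_iterations_returns_init(self, rng):
        y = rng.normal(size=(20, 1))
        mask = np.ones((20, 1), dtype=bool)
        init = NoiseParams.default(1, 1)
        noise, trace, _ = em_fit(_LinearSpec(np.eye(1)), y, mask, init,
                                 EMOptions(max_iter=0))
        assert noise.Q[0, 0] == init.Q[0, 0]
        assert noise.r[0] == init.r[0]
        assert trace.n_iter == 0


class TestMakeMeasurements:
    def test_full_confidence_all_observed(self, small_scene):
        sc = small_scene
        y, mask = make_measurements(sc.clean_detections, sc.rig, sc.layout,
                                    n_frames=sc.n_frames)
        assert mask.all()
        assert y.shape == (sc.n_frames, 344)

    def test_low_confidence_masks_exactly_two_coordinates(self, small_scene):
        sc = small_scene
        df = sc.clean_detections.copy()
        hit = (df["frame"] == 0) & (df["camera"] == 1) & (df["marker"] == "nose")
        assert hit.sum() == 1
        df.loc[hit, "confidence"] = 0.89
        y, mask = make_measurements(df, sc.rig, sc.layout, n_frames=sc.n_frames)
        _, full = make_measurements(sc.clean_detections, sc.rig, sc.layout,
                                    n_frames=sc.n_frames)
        changed = np.nonzero(full[0] & ~mask[0])[0]
        M = len(sc.layout)
        base = 2 * (1 * M + sc.layout.index["nose"])
        assert list(changed) == [base, base + 1]

    def test_empty_frame_fully_missing(self, small_scene):
        sc = small_scene
        df = sc.clean_detections[sc.clean_detections["frame"] != 3]
        _, mask = make_measurements(df, sc.rig, sc.layout, n_frames=sc.n_frames)
        assert not mask[3].any()

    def test_unknown_marker_rejected(self, small_scene):
        sc = small_scene
        df = sc.clean_detections.copy()
        df.loc[df.index[0], "marker"] = "whisker"
        with pytest.raises(KeyError, match="whisker"):
            make_measurements(df, sc.rig, sc.layout)


class TestVariants:
    def test_relaxed_limits_preserve_state_dim(self, rat):
        graph = rat[0]
        relaxed = relax_limits(graph)
        assert count_state_dim(relaxed) == count_state_dim(graph)
        bone = relaxed.bones[relaxed.bone_index["femur_left"]]
        assert np.allclose(bone.limits_deg[0], [-180.0, 180.0])
        frozen = relaxed.bones[relaxed.bone_index["clavicle_left"]]
        assert frozen.dof_axes == ()

    def test_per_frame_fit_reprojects_cleanly(self, small_scene):
        sc = small_scene
        spec = StateSpaceSpec(sc.graph, sc.params_true, sc.rig, sc.layout)
        y, mask = make_measurements(sc.clean_detections, sc.rig, sc.layout,
                                    n_frames=5)
        x0 = sc.poses_true[0] + 0.05
        poses, flags = fit_pose_per_frame(spec, y[:5], mask[:5], x0,
                                          max_nfev=100)
        resid = spec.h(poses) - y[:5]
        assert np.abs(resid[mask[:5]]).max() < 0.1        # < 0.1 px
        assert not flags.any()

    def test_sparse_frame_carries_pose_forward(self, small_scene):
        sc = small_scene
        spec = StateSpaceSpec(sc.graph, sc.params_true, sc.rig, sc.layout)
        y, mask = make_measurements(sc.clean_detections, sc.rig, sc.layout,
                                    n_frames=3)
        mask[1] = False
        x0 = sc.poses_true[0] + 0.05
        poses, flags = fit_pose_per_frame(spec, y, mask, x0, max_nfev=40)
        assert flags[1] and not flags[0] and not flags[2]
        assert np.allclose(poses[1], poses[0])

    def test_surface_uses_top_two_confidences(self, small_scene):
        sc = small_scene
        out = surface_trajectories(sc.clean_detections, sc.rig, sc.layout,
                                   n_frames=3)
        err = np.linalg.norm(out - sc.markers_true[:3], axis=2)
        assert np.nanmax(err) < 1e-6


class TestPropagateUncertainty:
    def test_zero_covariance_matches_forward_kinematics(self, small_scene):
        sc = small_scene
        spec = StateSpaceSpec(sc.graph, sc.params_true, sc.rig, sc.layout)
        from acmpose.smoother import SmootherResult

        T = 3
        res = SmootherResult(
            filtered_means=sc.poses_true[:T],
            filtered_covs=np.zeros((T, spec.n, spec.n)),
            smoothed_means=sc.poses_true[:T],
            smoothed_covs=np.zeros((T, spec.n, spec.n)),
            gains=np.zeros((T - 1, spec.n, spec.n)),
            loglik=0.0, loglik_per_frame=np.zeros(T),
        )
        out = propagate_uncertainty(res, spec, n_samples=50, seed=1)
        assert np.allclose(out["joint_sd"], 0.0, atol=1e-7)
        joints, _, _ = forward_kinematics_batch(sc.graph, sc.params_true,
                                                sc.poses_true[:T])
        assert np.allclose(out["joint_mean"], joints, atol=1e-7)

    def test_deterministic_given_seed(self, small_scene):
        sc = small_scene
        spec = StateSpaceSpec(sc.graph, sc.params_true, sc.rig, sc.layout)
        from acmpose.smoother import SmootherResult

        T = 2
        cov = 1e-4 * np.eye(spec.n)
        res = SmootherResult(
            filtered_means=sc.poses_true[:T],
            filtered_covs=np.tile(cov, (T, 1, 1)),
            smoothed_means=sc.poses_true[:T],
            smoothed_covs=np.tile(cov, (T, 1, 1)),
            gains=np.zeros((T - 1, spec.n, spec.n)),
            loglik=0.0, loglik_per_frame=np.zeros(T),
        )
        a = propagate_uncertainty(res, spec, n_samples=100, seed=42)
        b = propagate_uncertainty(res, spec, n_samples=100, seed=42)
        assert np.array_equal(a["joint_mean"], b["joint_mean"])
        assert np.array_equal(a["joint_sd"], b["joint_sd"])
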