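import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from acmpose.analysis import (
    angular_velocity_from_orientation,
    autocorrelation,
    compare_traces_by_peaks,
    correlate_kinematics,
    evaluate_against_floor_truth,
    extract_gait_cycles,
    finite_diff,
    fit_damped_sinusoid,
    fourier_peak,
    jump_distance,
    joint_angles,
    normalize_coordinates,
    peak_periodicity,
    segment_jump,
)
from helpers import spearman_bruteforce


class TestNormalizeCoordinates:
    def test_invariant_under_rigid_world_motion(self, small_scene, rng):
        sc = small_scene
        base = normalize_coordinates(sc.joints_true[:20], sc.graph)
        psi = rng.uniform(0, 2 * math.pi)
        Rz = Rotation.from_rotvec([0.0, 0.0, psi]).as_matrix()
        shift = rng.normal(size=3) * 10
        shift[2] = 0.0   # horizontal motion: heading + translation
        moved = sc.joints_true[:20] @ Rz.T + shift
        assert np.allclose(normalize_coordinates(moved, sc.graph), base,
                           atol=1e-9)

    def test_origin_joint_at_zero(self, small_scene):
        sc = small_scene
        norm = normalize_coordinates(sc.joints_true[:10], sc.graph)
        o = sc.graph.joint_index["lumbar_sacrum"]
        assert np.allclose(norm[:, o], 0.0, atol=1e-12)

    def test_axis_joint_has_zero_y(self, small_scene):
        sc = small_scene
        norm = normalize_coordinates(sc.joints_true[:10], sc.graph)
        a = sc.graph.joint_index["cervical_thoracic"]
        assert np.allclose(norm[:, a, 1], 0.0, atol=1e-9)


class TestFiniteDiff:
    def test_constant_trace_has_zero_derivative(self):
        assert np.allclose(finite_diff(np.full(50, 3.7), 0.01), 0.0,
                           atol=1e-10)

    def test_quintic_is_differentiated_exactly(self):
        t = np.arange(30, dtype=float)
        d = finite_diff(t**5, 1.0)
        expected = 5 * t**4
        interior = slice(4, -4)
        assert np.allclose(d[interior], expected[interior],
                           rtol=1e-8, atol=1e-6)

    def test_eighth_order_convergence(self):
        # coarse grids keep truncation error above the float rounding floor
        errs = []
        for n in (25, 50):
            t = np.linspace(0, 1, n, endpoint=False)
            dt = t[1] - t[0]
            d = finite_diff(np.sin(2 * np.pi * t), dt)
            true = 2 * np.pi * np.cos(2 * np.pi * t)
            errs.append(np.abs(d[4:-4] - true[4:-4]).max())
        order = np.log2(errs[0] / errs[1])
        assert order > 7.5

    def test_second_derivative(self):
        t = np.arange(40, dtype=float)
        d2 = finite_diff(t**4, 1.0, order=2)
        assert np.allclose(d2[4:-4], 12 * t[4:-4]**2, rtol=1e-8, atol=1e-6)

    def test_first_applied_twice_matches_second(self):
        t = np.linspace(0, 2, 300)
        y = np.exp(-t) * np.sin(5 * t)
        dt = t[1] - t[0]
        twice = finite_diff(finite_diff(y, dt), dt)
        once = finite_diff(y, dt, order=2)
        inner = slice(8, -8)
        assert np.allclose(twice[inner], once[inner], atol=1e-4)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="9 samples"):
            finite_diff(np.arange(5, dtype=float), 1.0)


class TestGaitCycles:
    def test_sinusoidal_swing_counting(self):
        fs, f0, T = 100.0, 3.0, 10.0
        t = np.arange(int(fs * T)) / fs
        v = 40.0 * np.sin(2 * np.pi * f0 * t)
        cycles = extract_gait_cycles({"limb": v}, fs, v_threshold=25.0)
        peaks = cycles.peaks["limb"]
        assert 27 <= len(peaks) <= 30
        spacing = np.diff(peaks).mean() / fs * 1000.0
        assert spacing == pytest.approx(1000.0 / f0, abs=5.0)

    def test_below_threshold_yields_no_cycles(self):
        t = np.arange(1000) / 100.0
        v = 10.0 * np.sin(2 * np.pi * 3.0 * t)
        cycles = extract_gait_cycles({"limb": v}, 100.0, v_threshold=25.0)
        assert len(cycles.peaks["limb"]) == 0

    def test_identical_cycles_have_zero_sd(self):
        # 2.5 Hz at 100 Hz sampling puts every peak on an exact sample
        t = np.arange(2000) / 100.0
        v = 40.0 * np.sin(2 * np.pi * 2.5 * t)
        cycles = extract_gait_cycles({"limb": v}, 100.0)
        assert np.nanmax(cycles.sd["limb"]) < 1e-9


class TestDampedSinusoid:
    def test_recovers_constructed_parameters(self):
        fs = 100.0
        tau = np.arange(200) / fs
        y = np.exp(-2.0 * tau) * np.cos(2 * np.pi * 3.0 * tau)
        f, lam, r2 = fit_damped_sinusoid(y, fs)
        assert f == pytest.approx(3.0, abs=0.01)
        assert lam == pytest.approx(2.0, abs=0.01)
        assert r2 > 0.999

    def test_undamped_limit(self):
        fs = 100.0
        tau = np.arange(300) / fs
        y = np.cos(2 * np.pi * 2.5 * tau)
        _, lam, r2 = fit_damped_sinusoid(y, fs)
        assert lam < 0.01
        assert r2 > 0.999

    def test_white_noise_reports_poor_fit(self, rng):
        x = rng.normal(size=2000)
        ac = autocorrelation(x, 150)
        _, _, r2 = fit_damped_sinusoid(ac, 100.0)
        assert r2 < 0.5        # no periodic structure to explain


class TestFourierPeak:
    def test_common_peak_across_limbs(self, rng):
        fs, T = 100.0, 10.0
        t = np.arange(int(fs * T)) / fs
        traces = {
            f"limb{i}": np.sin(2 * np.pi * 3.0 * t + phase)
            for i, phase in enumerate([0, 1, 2, 3])
        }
        peaks, shared = fourier_peak(traces, fs)
        assert shared
        for v in peaks.values():
            assert v == pytest.approx(3.0, abs=0.1)

    def test_differing_peaks_not_shared(self):
        t = np.arange(1000) / 100.0
        traces = {"a": np.sin(2 * np.pi * 2.0 * t),
                  "b": np.sin(2 * np.pi * 3.0 * t)}
        _, shared = fourier_peak(traces, 100.0)
        assert not shared

    def test_constant_trace_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            fourier_peak({"a": np.ones(100)}, 100.0)


class TestPeakPeriodicity:
    def test_sawtooth_intervals(self):
        # 10 Hz sawtooth sampled at 100 Hz: peaks every 10 frames
        t = np.arange(1000)
        saw = (t % 10).astype(float)
        mean, sd, n = peak_periodicity(saw, 100.0, "max", filter_len=8)
        assert mean == pytest.approx(100.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_jittered_interval_sd(self, rng):
        fps = 100.0
        jitter_sd = 3.0      # frames
        gaps = np.maximum(np.round(rng.normal(60, jitter_sd, 200)), 40).astype(int)
        peaks = np.cumsum(gaps)
        trace = np.zeros(peaks[-1] + 50)
        trace[peaks] = 1.0
        mean, sd, n = peak_periodicity(trace, fps, "max", filter_len=30)
        assert n > 150
        assert sd / 10.0 == pytest.approx(jitter_sd, rel=0.15)

    def test_monotone_trace_has_no_intervals(self):
        with pytest.raises(ValueError, match="two extrema"):
            peak_periodicity(np.arange(100, dtype=float), 100.0, "max", 120)


class TestAngularVelocity:
    def test_constant_orientation_is_zero(self):
        R = np.tile(np.eye(3), (50, 1, 1))
        assert np.allclose(angular_velocity_from_orientation(R, 100.0), 0.0)

    def test_constant_spin_rate(self):
        # 1.2 deg per frame at 100 fps -> 120 deg/s
        angles = np.radians(np.arange(100) * 1.2)
        R = Rotation.from_rotvec(np.outer(angles, [1.0, 0.0, 0.0])).as_matrix()
        w = angular_velocity_from_orientation(R, 100.0)
        assert np.allclose(w, 120.0, atol=1e-9)

    def test_magnitude_ignores_spin_axis(self):
        angles = np.radians(np.arange(60) * 0.8)
        wx = angular_velocity_from_orientation(
            Rotation.from_rotvec(np.outer(angles, [1, 0, 0])).as_matrix(), 100.0)
        wz = angular_velocity_from_orientation(
            Rotation.from_rotvec(np.outer(angles, [0, 0, 1])).as_matrix(), 100.0)
        assert np.allclose(wx, wz, atol=1e-9)

    def test_non_orthonormal_rejected(self):
        R = np.tile(np.eye(3) * 1.1, (5, 1, 1))
        with pytest.raises(ValueError, match="orthonormal"):
            angular_velocity_from_orientation(R, 100.0)


class TestCompareTraces:
    def test_affine_related_traces(self):
        # 2.5 Hz puts every peak on an exact sample: no rounding ties
        t = np.arange(600) / 100.0
        a = np.sin(2 * np.pi * 2.5 * t)
        b = 2.0 * a + 1.0
        rs, diffs = compare_traces_by_peaks(a, b, np.array([0, 200, 400, 600]),
                                            filter_len=40)
        assert np.allclose(rs, 1.0, atol=1e-12)
        assert np.all(diffs == 0)

    def test_anticorrelated(self):
        t = np.arange(400) / 100.0
        a = np.sin(2 * np.pi * 2.0 * t)
        rs, _ = compare_traces_by_peaks(a, -a, np.array([0, 200, 400]),
                                        filter_len=40)
        assert np.allclose(rs, -1.0, atol=1e-12)

    def test_shift_shows_in_peak_differences(self):
        t = np.arange(1000) / 100.0
        a = np.sin(2 * np.pi * 1.0 * t)
        b = np.roll(a, 3)
        _, diffs = compare_traces_by_peaks(a, b, np.array([0, 1000]),
                                           filter_len=60)
        vals, counts = np.unique(diffs, return_counts=True)
        assert vals[np.argmax(counts)] == 3


class TestJump:
    def _jump_trace(self, noise=0.0, rng=None):
        # five-extremum pattern: min, max, global min, max, min
        t = np.linspace(0, 1, 200)
        knots_t = [0.0, 0.1, 0.3, 0.5, 0.7, 0.9, 1.0]
        knots_v = [80.0, 60.0, 90.0, 30.0, 95.0, 65.0, 85.0]
        trace = np.interp(t, knots_t, knots_v)
        from scipy.ndimage import gaussian_filter1d

        trace = gaussian_filter1d(trace, 5)
        if noise and rng is not None:
            trace = trace + rng.normal(0, noise, size=trace.shape)
        return trace

    def test_constructed_pattern_segmentation(self):
        trace = self._jump_trace()
        seg = segment_jump(trace)
        assert seg.start < seg.mid < seg.end
        assert trace[seg.mid] == trace.min()
        assert abs(seg.start - 20) < 15       # near the first local min
        assert abs(seg.end - 180) < 15

    def test_monotone_trace_unsegmentable(self):
        with pytest.raises(ValueError, match="pattern absent|flat"):
            segment_jump(np.linspace(0, 1, 100))

    def test_robust_to_small_noise(self, rng):
        clean = self._jump_trace()
        noisy = self._jump_trace(noise=0.2, rng=rng)
        a, b = segment_jump(clean), segment_jump(noisy)
        assert abs(a.start - b.start) <= 3
        assert abs(a.mid - b.mid) <= 3
        assert abs(a.end - b.end) <= 3

    def test_jump_distance_planar(self, small_scene):
        sc = small_scene
        joints = np.stack([sc.joints_true[0], sc.joints_true[0]])
        assert jump_distance(joints, sc.graph, 0, 1) == pytest.approx(0.0)
        shifted = joints.copy()
        shifted[1] += np.array([30.0, 0.0, 5.0])   # z displacement is ignored
        assert jump_distance(shifted, sc.graph, 0, 1) == pytest.approx(30.0)

    def test_jump_distance_hand_computed(self, small_scene):
        sc = small_scene
        joints = np.stack([sc.joints_true[0], sc.joints_true[0]])
        idx = [sc.graph.joint_index[f"{j}_{s}"]
               for s in ("left", "right") for j in ("ankle", "mtp", "toe")]
        joints2 = joints.copy()
        joints2[1, idx[0]] += np.array([6.0, 0.0, 0.0])  # one joint moves 6 cm
        # centroid moves 1 cm in x
        assert jump_distance(joints2, sc.graph, 0, 1) == pytest.approx(1.0)


class TestCorrelateKinematics:
    def test_monotone_gives_unit_rank_correlation(self, rng):
        x = rng.normal(size=30)
        out = correlate_kinematics({"cubic": (x, x**3), "neg": (x, -x)})
        r = out.set_index("pair")["spearman_r"]
        assert r["cubic"] == pytest.approx(1.0)
        assert r["neg"] == pytest.approx(-1.0)

    def test_matches_bruteforce_rank_oracle(self):
        rng = np.random.default_rng(8)
        cov = [[1.0, 0.8], [0.8, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, size=30)
        out = correlate_kinematics({"pair": (xy[:, 0], xy[:, 1])})
        assert out["spearman_r"].iloc[0] == pytest.approx(
            spearman_bruteforce(xy[:, 0], xy[:, 1]), abs=1e-12)

    def test_constant_series_flagged(self):
        out = correlate_kinematics({"flat": (np.ones(10), np.arange(10.0))})
        assert out["constant"].iloc[0]
        assert np.isnan(out["spearman_r"].iloc[0])

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="3"):
            correlate_kinematics({"p": (np.arange(2.0), np.arange(2.0))})

    def test_lagged_sweep_finds_the_predictive_lag(self, rng):
        from acmpose.analysis import lagged_correlation_sweep

        # outcome is exactly the trace value 40 frames before the end
        n, T = 25, 200
        traces = rng.normal(size=(n, T)).cumsum(axis=1)
        outcomes = traces[:, 160]
        out = lagged_correlation_sweep(outcomes, traces, reference_frame=199,
                                       lags=np.array([0, 20, 39, 60]))
        best = out.loc[out["spearman_r"].idxmax()]
        assert best["lag"] == 39
        assert best["spearman_r"] == pytest.approx(1.0)


class TestFloorEvaluation:
    def _tables(self, shift=(0.0, 0.0), rotate_deg=0.0):
        rows_t, rows_r = [], []
        for t in range(20):
            center = np.array([t * 0.5, 1.0])
            digit = center + np.array([1.0, 0.0])
            rows_t += [(t, "hind_left", "center", *center),
                       (t, "hind_left", "digit", *digit)]
            c2 = center + shift
            ang = math.radians(rotate_deg)
            d2 = c2 + np.array([math.cos(ang), math.sin(ang)])
            rows_r += [(t, "hind_left", "center", *c2),
                       (t, "hind_left", "digit", *d2)]
        cols = ["frame", "paw", "point", "x_cm", "y_cm"]
        return pd.DataFrame(rows_r, columns=cols), pd.DataFrame(rows_t,
                                                                columns=cols)

    def test_identical_reconstruction_has_zero_errors(self):
        recon, truth = self._tables()
        per_frame, _ = evaluate_against_floor_truth(recon, truth)
        assert np.allclose(per_frame["position_error_cm"], 0.0, atol=1e-12)
        assert np.allclose(per_frame["angle_error_deg"], 0.0, atol=1e-9)

    def test_three_four_five_position_error(self):
        recon, truth = self._tables(shift=(3.0, 4.0))
        per_frame, _ = evaluate_against_floor_truth(recon, truth)
        assert np.allclose(per_frame["position_error_cm"], 5.0, atol=1e-12)

    def test_sixty_degree_axis_rotation(self):
        recon, truth = self._tables(rotate_deg=60.0)
        per_frame, _ = evaluate_against_floor_truth(recon, truth)
        assert np.allclose(per_frame["angle_error_deg"], 60.0, atol=1e-9)

    def test_occlusion_binning_drops_small_bins(self):
        recon, truth = self._tables(shift=(1.0, 0.0))
        detected = pd.DataFrame({
            "paw": "hind_left", "frame": np.arange(20),
            "detected": [True] * 12 + [False] * 8,
        })
        _, binned = evaluate_against_floor_truth(recon, truth, detected,
                                                 smoothed=False,
                                                 min_bin_count=10)
        assert (binned["count"] >= 10).all()
        # twelve frames sit at occlusion distance zero
        assert 0 in binned["occlusion_frames"].values

    def test_unsynchronized_tables_rejected(self):
        recon, truth = self._tables()
        truth = truth.assign(frame=truth["frame"] + 1000)
        with pytest.raises(ValueError, match="synchronized"):
            evaluate_against_floor_truth(recon, truth)
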