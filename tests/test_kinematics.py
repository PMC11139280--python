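import numpy as np
import pytest
from scipy import signal

from conftest import make_trajectory
from oracles import brute_force_extrema

from nodphon.kinematics import (
    FilterSpec,
    PeakSpec,
    compute_nod_measures,
    detect_extrema,
    normalize_pose,
    smooth_trajectory,
)
from nodphon.pose_io import AnnotationSpan, PoseFrame, PoseSequence


def build_sequence(nose_y, collar=(500.0, 400.0), hip=(500.0, 1000.0), fps=50.0, scale_coords=1.0):
    frames = []
    for i, ny in enumerate(nose_y):
        body = np.zeros((25, 3))
        face = np.zeros((70, 3))
        body[1] = (collar[0] * scale_coords, collar[1] * scale_coords, 1.0)
        body[8] = (hip[0] * scale_coords, hip[1] * scale_coords, 1.0)
        face[30] = (collar[0] * scale_coords, ny * scale_coords, 1.0)
        frames.append(PoseFrame(i, body, face))
    return PoseSequence(frames=frames, fps=fps)


class TestNormalizePose:
    def test_fixed_geometry_arithmetic(self):
        # collarbone (500,400), hip (500,1000) -> scale 600; nose_y 280
        traj = normalize_pose(build_sequence([280.0] * 5))
        assert traj.scale_npix == 600.0
        np.testing.assert_allclose(traj.y, 0.2)

    def test_scale_invariance_of_trace(self):
        nose = 400.0 - 30 * np.sin(np.linspace(0, 4 * np.pi, 100))
        a = normalize_pose(build_sequence(nose))
        b = normalize_pose(build_sequence(nose, scale_coords=2.0))
        np.testing.assert_allclose(a.y, b.y, atol=1e-12)

    def test_upward_pixel_motion_is_positive(self):
        traj = normalize_pose(build_sequence([400.0, 300.0]))  # nose rises in image
        assert traj.y[1] > traj.y[0]

    def test_low_confidence_nose_interpolated_and_counted(self):
        seq = build_sequence([280.0] * 10)
        seq.frames[4].face[30, 2] = 0.0
        traj = normalize_pose(seq)
        assert traj.interpolated_fraction == pytest.approx(0.1)
        np.testing.assert_allclose(traj.y, 0.2)

    def test_frame_gap_becomes_interpolated_sample(self):
        seq = build_sequence([280.0] * 5)
        seq.frames.pop(2)
        traj = normalize_pose(seq)
        assert len(traj) == 5  # dense grid restored
        assert traj.interpolated_fraction == pytest.approx(0.2)

    def test_no_valid_scale_frames_is_an_error(self):
        seq = build_sequence([280.0] * 5)
        for f in seq.frames:
            f.body[1, 2] = 0.0
        with pytest.raises(ValueError, match="collarbone"):
            normalize_pose(seq)


class TestSmoothTrajectory:
    def test_constant_passes_unchanged(self):
        traj = make_trajectory(np.full(100, 0.3))
        out = smooth_trajectory(traj)
        np.testing.assert_allclose(out.y, 0.3, atol=1e-12)

    @pytest.mark.parametrize("freq_hz, spec", [(1.0, FilterSpec()), (24.0, FilterSpec())])
    def test_frequency_response_matches_transfer_function(self, freq_hz, spec):
        """Measured attenuation equals |H|^2 of the Butterworth design
        (forward-backward application squares the magnitude response)."""
        fps = 50.0
        t = np.arange(2000) / fps
        traj = make_trajectory(np.sin(2 * np.pi * freq_hz * t), fps)
        out = smooth_trajectory(traj, spec)
        b, a = signal.butter(spec.order, spec.cutoff_hz / (fps / 2), btype="low")
        _, h = signal.freqz(b, a, worN=[2 * np.pi * freq_hz / fps])
        expected_gain = np.abs(h[0]) ** 2
        core = slice(200, -200)  # away from edge transients
        measured_gain = out.y[core].std() / traj.y[core].std()
        assert measured_gain == pytest.approx(expected_gain, rel=0.02)

    def test_zero_phase_no_lag_and_small_attenuation_below_cutoff(self):
        fps = 50.0
        t = np.arange(500) / fps
        traj = make_trajectory(np.sin(2 * np.pi * 1.0 * t), fps)
        out = smooth_trajectory(traj)
        xc = np.correlate(out.y - out.y.mean(), traj.y - traj.y.mean(), mode="full")
        assert np.argmax(xc) == len(t) - 1  # peak at lag 0
        assert out.y.std() / traj.y.std() > 0.98

    def test_above_cutoff_attenuated(self):
        fps = 50.0
        t = np.arange(1000) / fps
        traj = make_trajectory(np.sin(2 * np.pi * 24.0 * t), fps)
        out = smooth_trajectory(traj)
        assert out.y[100:-100].std() / traj.y[100:-100].std() < 0.5

    def test_cutoff_at_nyquist_rejected(self):
        traj = make_trajectory(np.zeros(100))
        with pytest.raises(ValueError, match="Nyquist"):
            smooth_trajectory(traj, FilterSpec(cutoff_hz=25.0))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            smooth_trajectory(make_trajectory(np.zeros(5)))


class TestDetectExtrema:
    def test_monotone_trajectory_has_no_extrema(self):
        ext = detect_extrema(make_trajectory(np.linspace(0, 1, 100)), PeakSpec())
        assert len(ext.max_indices) == 0 and len(ext.min_indices) == 0

    def test_two_hz_sinusoid_extrema_count_and_values(self):
        fps = 50.0
        t = np.arange(50) / fps
        ext = detect_extrema(make_trajectory(0.1 * np.sin(2 * np.pi * 2 * t), fps),
                             PeakSpec(min_prominence=0.05, min_separation=5))
        assert len(ext.max_indices) == 2 and len(ext.min_indices) == 2
        np.testing.assert_allclose(ext.max_values, 0.1, rtol=0.01)
        np.testing.assert_allclose(ext.min_values, -0.1, rtol=0.01)

    def test_close_peaks_keep_only_the_higher(self):
        y = np.zeros(40)
        y[10] = 1.0
        y[13] = 0.8  # 3 frames from a higher peak
        y[30] = 0.9
        ext = detect_extrema(make_trajectory(y), PeakSpec(min_prominence=0.1, min_separation=5))
        assert list(ext.max_indices) == [10, 30]

    @pytest.mark.parametrize("seed", range(12))
    def test_agrees_with_exhaustive_prominence_search(self, seed):
        """Implementation vs brute-force topographic prominence on random
        smooth trajectories of <= 500 samples."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 500))
        y = np.cumsum(rng.normal(0, 0.02, n))
        y = signal.filtfilt(*signal.butter(2, 0.2), y)
        spec = PeakSpec(min_prominence=float(rng.uniform(0.01, 0.1)),
                        min_separation=int(rng.integers(2, 10)))
        ext = detect_extrema(make_trajectory(y), spec)
        assert list(ext.max_indices) == brute_force_extrema(y, spec.min_prominence, spec.min_separation)
        assert list(ext.min_indices) == brute_force_extrema(-y, spec.min_prominence, spec.min_separation)


class TestNodMeasures:
    def test_constant_span(self):
        traj = make_trajectory(np.zeros(100))
        m = compute_nod_measures(traj, AnnotationSpan(500, 1500, "sn"))
        assert m.duration == 1.0
        assert m.velocity == 0.0
        assert m.max_amplitude == 0.0
        assert m.n_peaks == 0

    def test_sinusoid_closed_form(self):
        # y = A sin(2 pi f t): peak-to-trough 2A, mean |dy/dt| = 4 A f
        fps, A, f = 50.0, 0.05, 2.0
        t = np.arange(100) / fps
        traj = make_trajectory(A * np.sin(2 * np.pi * f * t), fps)
        spec = PeakSpec(min_prominence=0.05, min_separation=5)
        m = compute_nod_measures(traj, AnnotationSpan(0.5, 1999.0, "sn"), spec)
        assert m.max_amplitude == pytest.approx(2 * A, rel=0.02)
        assert m.velocity == pytest.approx(4 * A * f, rel=0.05)
        assert not m.amplitude_fallback

    def test_amplitude_fallback_when_prominence_removes_extrema(self):
        fps = 50.0
        t = np.arange(100) / fps
        traj = make_trajectory(0.01 * np.sin(2 * np.pi * 2 * t), fps)
        m = compute_nod_measures(traj, AnnotationSpan(0.5, 1999.0, "sn"), PeakSpec())
        assert m.amplitude_fallback
        assert m.max_amplitude == pytest.approx(0.02, rel=0.02)

    def test_peak_rate_consistency(self):
        fps = 50.0
        t = np.arange(150) / fps
        traj = make_trajectory(0.2 * np.sin(2 * np.pi * 2 * t), fps)
        m = compute_nod_measures(traj, AnnotationSpan(0.5, 2995.0, "sn"),
                                 PeakSpec(min_prominence=0.1, min_separation=5))
        assert m.peak_rate == pytest.approx(m.n_peaks / m.duration)

    def test_span_outside_trajectory_rejected(self):
        traj = make_trajectory(np.zeros(50))
        with pytest.raises(ValueError, match="outside"):
            compute_nod_measures(traj, AnnotationSpan(900, 2000, "sn"))

    def test_span_shorter_than_two_frames_rejected(self):
        traj = make_trajectory(np.zeros(100))
        with pytest.raises(ValueError, match="2 frames"):
            compute_nod_measures(traj, AnnotationSpan(501, 514, "sn"))


class TestMeasureInvariances:
    def test_full_pixel_scale_invariance_of_measures(self):
        rng = np.random.default_rng(3)
        nose = 400.0 - 40 * np.sin(np.linspace(0, 6 * np.pi, 200)) + rng.normal(0, 2, 200)
        span = AnnotationSpan(500, 3500, "hnn")
        results = []
        for c in (1.0, 3.7):
            seq = build_sequence(nose, scale_coords=c)
            traj = smooth_trajectory(normalize_pose(seq))
            results.append(compute_nod_measures(traj, span))
        assert results[0].duration == results[1].duration
        assert results[0].velocity == pytest.approx(results[1].velocity, rel=1e-9)
        assert results[0].max_amplitude == pytest.approx(results[1].max_amplitude, rel=1e-9)
        assert results[0].n_peaks == results[1].n_peaks

    def test_monotone_in_amplitude_and_frequency(self):
        fps = 50.0
        t = np.arange(200) / fps
        span = AnnotationSpan(100, 3900, "hnn")
        spec = PeakSpec(min_prominence=0.005, min_separation=5)

        amps = [0.02, 0.04, 0.08, 0.16]
        measured = [
            compute_nod_measures(make_trajectory(a / 2 * np.sin(2 * np.pi * 1.5 * t), fps), span, spec)
            for a in amps
        ]
        amp_vals = [m.max_amplitude for m in measured]
        vel_vals = [m.velocity for m in measured]
        assert amp_vals == sorted(amp_vals) and len(set(amp_vals)) == len(amp_vals)
        assert vel_vals == sorted(vel_vals) and len(set(vel_vals)) == len(vel_vals)

        freqs = [1.0, 1.5, 2.0, 3.0]
        vels = [
            compute_nod_measures(make_trajectory(0.05 * np.sin(2 * np.pi * f * t), fps), span, spec).velocity
            for f in freqs
        ]
        assert vels == sorted(vels) and len(set(vels)) == len(vels)
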