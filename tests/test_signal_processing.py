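import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from festorque.signal_processing import (
    TORQUE_NM_PER_VOLT,
    LoopFeatureSeries,
    RawRecording,
    blank_artifact,
    compute_loop_features,
    default_diff_threshold,
    normalize_series,
    remove_residual_artifacts,
    scale_torque,
    segment_loops,
    smooth_mav,
)


def make_recording(n_pulses=3, f_samp=4096.0, f_stim=40.0, extra=0):
    times = np.arange(n_pulses) / f_stim
    n = int(round(times[-1] * f_samp)) + int(round(f_samp / f_stim)) + extra
    return RawRecording(
        f_samp=f_samp,
        emg=np.zeros(n),
        torque_voltage=np.zeros(n),
        pulse_times=times,
        pulse_widths=np.full(n_pulses, 200.0),
        f_stim=f_stim,
    )


class TestSegmentLoops:
    def test_ranges_at_4096_40(self):
        # onsets 0, 0.025, 0.050 s -> samples 0, round(102.4)=102, round(204.8)=205
        rec = make_recording(3)
        assert segment_loops(rec) == [(0, 102), (102, 205), (205, 307)]

    def test_single_pulse_range(self):
        rec = RawRecording(
            f_samp=4096.0,
            emg=np.zeros(102),
            torque_voltage=np.zeros(102),
            pulse_times=np.array([0.0]),
            pulse_widths=np.array([200.0]),
            f_stim=40.0,
        )
        assert segment_loops(rec) == [(0, 102)]

    def test_pulse_beyond_recording_errors(self):
        rec = make_recording(3)
        bad = RawRecording(
            f_samp=rec.f_samp,
            emg=rec.emg[:250],
            torque_voltage=rec.torque_voltage[:250],
            pulse_times=rec.pulse_times,
            pulse_widths=rec.pulse_widths,
            f_stim=rec.f_stim,
        )
        with pytest.raises(ValueError, match="truncated"):
            segment_loops(bad)

    def test_empty_pulses_rejected_at_construction(self):
        with pytest.raises(ValueError, match="no stimulation events"):
            RawRecording(4096.0, np.zeros(10), np.zeros(10), np.array([]), np.array([]))

    def test_ranges_partition_stimulated_span(self):
        rec = make_recording(17)
        ranges = segment_loops(rec)
        # contiguous, disjoint, covering [first start, last end)
        for (s0, e0), (s1, e1) in zip(ranges, ranges[1:]):
            assert e0 == s1
        lengths = [e - s for s, e in ranges]
        assert set(lengths) <= {102, 103}


class TestBlankArtifact:
    def test_41_samples_zeroed_at_4096(self):
        x = np.ones(102)
        out = blank_artifact(x, 10.0, 4096.0)
        assert math.ceil(0.010 * 4096) == 41
        assert np.all(out[:41] == 0) and np.all(out[41:] == 1)

    def test_zero_window_identity(self, rng):
        x = rng.normal(size=102)
        np.testing.assert_array_equal(blank_artifact(x, 0.0, 4096.0), x)

    def test_all_zero_loop(self):
        np.testing.assert_array_equal(blank_artifact(np.zeros(50), 10.0, 4096.0), np.zeros(50))

    def test_window_exceeding_loop_errors(self):
        with pytest.raises(ValueError, match="exceeds loop"):
            blank_artifact(np.ones(10), 10.0, 4096.0)

    def test_length_preserved_input_untouched(self, rng):
        x = rng.normal(size=102)
        x0 = x.copy()
        out = blank_artifact(x, 10.0, 4096.0)
        assert out.size == x.size
        np.testing.assert_array_equal(x, x0)


class TestRemoveResidualArtifacts:
    def test_hand_traced_example(self):
        x = np.array([0.0, 0.1, 5.0, 0.2, 0.0])
        out = remove_residual_artifacts(x, diff_threshold=1.0, template_half_width=1)
        np.testing.assert_array_equal(out, np.zeros(5))

    def test_threshold_above_max_diff_is_identity(self, rng):
        x = rng.normal(size=60)
        np.testing.assert_array_equal(
            remove_residual_artifacts(x, diff_threshold=1e9), x
        )

    def test_constant_signal_unchanged(self):
        x = np.full(40, 3.3)
        np.testing.assert_array_equal(remove_residual_artifacts(x, 0.01), x)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError, match="invalid threshold"):
            remove_residual_artifacts(np.zeros(5), 0.0)

    @given(
        st.lists(st.floats(-10, 10), min_size=3, max_size=60),
        st.floats(0.1, 5.0),
        st.integers(0, 3),
    )
    @settings(max_examples=100, deadline=None)
    def test_idempotent(self, samples, thr, hw):
        x = np.asarray(samples)
        once = remove_residual_artifacts(x, thr, hw)
        twice = remove_residual_artifacts(once, thr, hw)
        np.testing.assert_array_equal(once, twice)

    def test_single_pass_would_not_be_idempotent(self):
        # zeroing creates a fresh above-threshold edge; fixpoint handles it
        x = np.array([0.0, 10.0, 10.1, 10.2])
        out = remove_residual_artifacts(x, diff_threshold=5.0, template_half_width=0)
        np.testing.assert_array_equal(out, np.zeros(4))


class TestScaleTorque:
    def test_paper_scaling_1v(self):
        assert scale_torque(1.0) == 8.64

    def test_zero(self):
        assert scale_torque(0.0) == 0.0

    def test_linearity_negative(self):
        assert scale_torque(-0.5) == pytest.approx(-4.32)

    def test_vectorized(self):
        np.testing.assert_allclose(scale_torque(np.array([0.5, 2.0])), [4.32, 17.28])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            scale_torque(float("nan"))


class TestNormalizeSeries:
    def test_half(self):
        assert normalize_series([1.0], 2.0)[0] == 0.5

    def test_reference_maps_to_one(self):
        assert normalize_series([2.0], 2.0)[0] == 1.0

    def test_zero_reference_errors(self):
        with pytest.raises(ValueError, match="invalid normalization reference"):
            normalize_series([1.0], 0.0)


class TestSmoothMav:
    def test_window_loop_count(self):
        # 0.8 s at 40 Hz -> 32 loops: first 32 outputs are prefix means
        u = np.zeros(64)
        u[0] = 32.0
        out = smooth_mav(u, 0.8, 40.0)
        assert out[31] == pytest.approx(1.0)
        assert out[32] == 0.0

    def test_constant_series_unchanged(self):
        u = np.full(50, 2.5)
        np.testing.assert_allclose(smooth_mav(u, 0.8, 40.0), u)

    def test_matches_bruteforce_prefix_clipped_mean(self, rng):
        u = rng.uniform(0, 1, 10)
        out = smooth_mav(u, 3 / 40.0, 40.0)  # 3-loop window
        expect = np.array([np.mean(u[max(0, i - 2) : i + 1]) for i in range(10)])
        np.testing.assert_allclose(out, expect)

    def test_causal(self, rng):
        u = rng.uniform(0, 1, 40)
        out1 = smooth_mav(u, 0.2, 40.0)
        u2 = u.copy()
        u2[30:] += 5.0  # future change must not affect earlier outputs
        out2 = smooth_mav(u2, 0.2, 40.0)
        np.testing.assert_array_equal(out1[:30], out2[:30])


class TestComputeLoopFeatures:
    def _rec_from_loops(self, emg_loops, torque_v=0.0):
        emg = np.concatenate(emg_loops)
        n = emg.size
        f_samp, f_stim = 4096.0, 4096.0 / emg_loops[0].size
        times = np.arange(len(emg_loops)) * emg_loops[0].size / f_samp
        return RawRecording(
            f_samp=f_samp,
            emg=emg,
            torque_voltage=np.full(n, torque_v),
            pulse_times=times,
            pulse_widths=np.full(len(emg_loops), 100.0),
            f_stim=f_stim,
        )

    def test_mav_of_constant_negative_loop(self):
        rec = self._rec_from_loops([np.full(102, -0.5)])
        feats = compute_loop_features(rec, segment_loops(rec), blank_window_ms=0.0)
        assert feats.u[0] == pytest.approx(0.5)

    def test_mav_alternating(self):
        loop = np.tile([1.0, -1.0], 51)
        rec = self._rec_from_loops([loop])
        # large half-width would zero everything; disable residual stage
        feats = compute_loop_features(
            rec, segment_loops(rec), blank_window_ms=0.0, diff_threshold=1e9
        )
        assert feats.u[0] == pytest.approx(1.0)

    def test_torque_scaling_paths(self):
        rec = self._rec_from_loops([np.zeros(102)], torque_v=3.0)
        ranges = segment_loops(rec)
        unit = compute_loop_features(rec, ranges, torque_scale=1.0)
        biodex = compute_loop_features(rec, ranges)
        assert unit.tau[0] == pytest.approx(3.0)
        assert biodex.tau[0] == pytest.approx(3.0 * 8.64)

    def test_mav_sign_flip_invariant(self, noiseless_session):
        rec = noiseless_session.recording
        ranges = segment_loops(rec)
        feats = compute_loop_features(rec, ranges)
        flipped = RawRecording(
            f_samp=rec.f_samp,
            emg=-rec.emg,
            torque_voltage=rec.torque_voltage,
            pulse_times=rec.pulse_times,
            pulse_widths=rec.pulse_widths,
            f_stim=rec.f_stim,
        )
        feats2 = compute_loop_features(flipped, segment_loops(flipped))
        np.testing.assert_allclose(feats2.u, feats.u, rtol=1e-12)

    def test_pipeline_mav_matches_clean_oracle(self, noiseless_session):
        """Blanking + thresholding recovers the artifact-free MAV within 1 %."""
        sess = noiseless_session
        rec = sess.recording
        feats = compute_loop_features(rec, segment_loops(rec))
        active = sess.clean_u > 1e-6
        rel = np.abs(feats.u[active] - sess.clean_u[active]) / sess.clean_u[active]
        assert np.max(rel) < 0.01
        np.testing.assert_allclose(feats.u[~active], 0.0, atol=1e-12)

    def test_blank_threshold_order_stable(self, noiseless_session):
        """When artifacts sit inside the blanking window, blanking before or
        after thresholding yields the same MAV."""
        rec = noiseless_session.recording
        ranges = segment_loops(rec)
        f = rec.f_samp
        for s, e in ranges[:40]:
            loop = rec.emg[s:e]
            a = blank_artifact(loop, 10.0, f)
            thr_a = default_diff_threshold(a)
            if np.isfinite(thr_a):
                a = remove_residual_artifacts(a, thr_a)
            thr_b = default_diff_threshold(loop)
            b = loop if not np.isfinite(thr_b) else remove_residual_artifacts(loop, thr_b)
            b = blank_artifact(b, 10.0, f)
            assert np.mean(np.abs(a)) == pytest.approx(np.mean(np.abs(b)), rel=1e-9, abs=1e-12)


class TestLoopFeatureSeriesInvariants:
    def test_negative_mav_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            LoopFeatureSeries(
                k=np.arange(2), u=np.array([-1.0, 0.0]), tau=np.zeros(2),
                pw=np.zeros(2), f_stim=40.0,
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            LoopFeatureSeries(
                k=np.arange(3), u=np.zeros(2), tau=np.zeros(3),
                pw=np.zeros(3), f_stim=40.0,
            )

    def test_f_stim_bounds(self):
        with pytest.raises(ValueError, match="f_stim"):
            LoopFeatureSeries(
                k=np.arange(1), u=np.zeros(1), tau=np.zeros(1),
                pw=np.zeros(1), f_stim=2000.0,
            )
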