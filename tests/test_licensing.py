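"""Unit and property tests for the G1 licensing simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryptcycle import licensing as lic


class TestTrajectory:
    def test_unit_rate_is_linear_ramp(self):
        """rate=1 licenses fully in exactly the minimum G1 period."""
        params = lic.LicensingParams(rate=1.0, n_steps=10)
        traj = lic.simulate_trajectory(params)
        np.testing.assert_allclose(traj.samples, np.arange(1, 11) / 10)
        assert traj.step_duration == pytest.approx(0.1)

    def test_pause_and_ramp_timing(self):
        """Analytic timing: pause ends at u*n steps, ramp ends at (u + 1/rate)*n."""
        params = lic.LicensingParams(rate=2.0, unlicensed_fraction=0.25)
        traj = lic.simulate_trajectory(params)
        samples = traj.samples
        assert samples.size == 10_000
        # licensing begins after step 2,500
        assert np.all(samples[:2500] == 0.0)
        assert samples[2500] > 0.0
        # full licensing is first reached at step 7,500 (sample index 7,499)
        full = samples >= 1.0 - 1e-12
        assert not full[7498] and full[7499]
        assert full.sum() == 10_000 - 7500 + 1

    def test_default_recording_length(self):
        params = lic.LicensingParams(rate=2.0, unlicensed_fraction=0.25)
        assert lic.simulate_trajectory(params).samples.size == 10_000

    def test_slow_licensing_extends_recording(self):
        """Cells that cannot finish within minimum G1 are recorded until exit."""
        params = lic.LicensingParams(rate=0.5)
        traj = lic.simulate_trajectory(params)
        assert traj.samples.size == 20_000
        assert traj.samples[-1] == pytest.approx(1.0)

    @given(
        rate=st.floats(0.1, 20),
        u=st.floats(0, 2),
        checkpoint=st.floats(0.05, 1.0),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_monotone_and_bounded(self, rate, u, checkpoint):
        params = lic.LicensingParams(
            rate=rate, unlicensed_fraction=u, checkpoint_threshold=checkpoint,
            n_steps=500,
        )
        samples = lic.simulate_trajectory(params).samples
        assert np.all(np.diff(samples) >= 0)
        assert samples[0] >= 0 and samples[-1] <= checkpoint + 1e-12

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"rate": 0.0},
            {"rate": -1.0},
            {"n_steps": 0},
            {"n_bins": 1},
            {"background": 1.0},
            {"push_fraction": 1.0},
            {"checkpoint_threshold": 0.0},
            {"unlicensed_fraction": -0.1},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            lic.LicensingParams(**kwargs)


class TestHistogram:
    def test_default_bin_count(self):
        traj = lic.simulate_trajectory(lic.LicensingParams())
        assert lic.build_histogram(traj).n_bins == 101

    def test_all_zero_samples_fall_in_bottom_bin(self):
        traj = lic.LicensingTrajectory(samples=np.zeros(50), step_duration=0.02)
        hist = lic.build_histogram(traj)
        assert hist.counts[0] == 50 and hist.counts[1:].sum() == 0

    def test_binning_matches_brute_force(self):
        """Nearest-center binning of i/10,000 vs an independent per-sample loop."""
        traj = lic.simulate_trajectory(lic.LicensingParams(rate=1.0))
        hist = lic.build_histogram(traj)
        expected = np.zeros(101)
        for s in traj.samples:
            # nearest center, half-up: ties go to the larger bin
            best = min(range(101), key=lambda j: (abs(s * 100 - j), -j))
            expected[best] += 1
        np.testing.assert_array_equal(hist.counts, expected)
        # near-uniform occupancy: ~100 per interior percent bin
        assert np.all(np.abs(hist.counts[1:-1] - 100) <= 1)

    def test_background_shifts_bottom_to_five_percent(self):
        hist = lic.LicensingHistogram(
            bin_centers=np.linspace(0, 100, 101),
            counts=np.eye(101)[0] * 1000,
        )
        shifted = lic.apply_background(hist, 0.05)
        assert shifted.counts[5] == 1000 and shifted.counts.sum() == 1000
        assert shifted.stage == "background_adjusted"

    def test_zero_background_is_identity(self):
        traj = lic.simulate_trajectory(lic.LicensingParams(rate=2.0))
        hist = lic.build_histogram(traj)
        np.testing.assert_array_equal(
            lic.apply_background(hist, 0.0).counts, hist.counts
        )

    def test_background_clips_at_top_bin(self):
        hist = lic.LicensingHistogram(
            bin_centers=np.linspace(0, 100, 101),
            counts=np.eye(101)[100] * 7,
        )
        shifted = lic.apply_background(hist, 0.05)
        assert shifted.counts[100] == 7

    def test_smoothing_matches_sequential_reference(self):
        """Both passes, bin for bin, against an independently coded loop."""
        counts = np.zeros(101)
        counts[50] = 1000.0
        hist = lic.LicensingHistogram(np.linspace(0, 100, 101), counts)
        smoothed = lic.smooth_histogram(hist, 0.8)

        ref = counts.tolist()
        for i in range(len(ref) - 1):  # ascending, top bin keeps its count
            ref[i + 1] += ref[i] * 0.8
            ref[i] *= 0.2
        for i in range(len(ref) - 1, 0, -1):  # descending, bottom bin keeps
            ref[i - 1] += ref[i] * 0.8
            ref[i] *= 0.2
        np.testing.assert_allclose(smoothed.counts, ref, rtol=1e-12)
        assert smoothed.total == pytest.approx(1000.0, rel=1e-12)

    @given(
        data=st.lists(st.floats(0, 1e6), min_size=5, max_size=101),
        background=st.floats(0, 0.5),
        push=st.floats(0, 0.99),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_total_conserved(self, data, background, push):
        counts = np.asarray(data)
        hist = lic.LicensingHistogram(
            np.linspace(0, 100, counts.size), counts
        )
        total = hist.total
        adjusted = lic.apply_background(hist, background)
        smoothed = lic.smooth_histogram(adjusted, push)
        assert adjusted.total == pytest.approx(total, rel=1e-9, abs=1e-9)
        assert smoothed.total == pytest.approx(total, rel=1e-9, abs=1e-9)


class TestSnapshotOracle:
    def test_fast_rate_accumulates_fully_licensed(self):
        """With a checkpoint and fast licensing, cells wait fully licensed."""
        params = lic.LicensingParams(rate=100.0)
        snap = lic.population_snapshot_oracle(params, 20_000, seed=7)
        assert snap.counts[-1] / snap.total > 0.95

    def test_occupancy_inverse_to_rate(self):
        """Doubling the licensing rate halves mid-ramp occupancy."""
        slow = lic.LicensingParams(rate=2.0)
        fast = lic.LicensingParams(rate=4.0)
        f_slow = lic.population_snapshot_oracle(slow, 100_000, seed=11).frequencies()
        f_fast = lic.population_snapshot_oracle(fast, 100_000, seed=13).frequencies()
        mid = slice(30, 70)
        ratio = f_slow[mid].sum() / f_fast[mid].sum()
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_rejects_empty_population(self):
        with pytest.raises(ValueError):
            lic.population_snapshot_oracle(lic.LicensingParams(), 0, seed=1)


class TestPeakDetection:
    @staticmethod
    def _pipeline(params):
        hist = lic.build_histogram(lic.simulate_trajectory(params), params.n_bins)
        return lic.smooth_histogram(
            lic.apply_background(hist, params.background), params.push_fraction
        )

    def test_long_pause_creates_peak(self):
        params = lic.LicensingParams(rate=4.0, unlicensed_fraction=0.5)
        assert lic.detect_unlicensed_peak(self._pipeline(params)).present

    def test_uniform_ramp_has_no_peak(self):
        params = lic.LicensingParams(rate=1.0)
        assert not lic.detect_unlicensed_peak(self._pipeline(params)).present

    def test_checkpoint_loss_has_no_peak(self):
        """Cells licensing immediately and minimally show no unlicensed peak."""
        params = lic.LicensingParams(rate=2.0, checkpoint_threshold=0.3)
        assert not lic.detect_unlicensed_peak(self._pipeline(params)).present

    def test_peak_fraction_matches_timing(self):
        """Peak mass equals the unlicensed dwell time over total G1 time,
        plus the ramp time spent below the window's licensing ceiling (the
        window spans one background-width above the peak, i.e. raw licensing
        up to ~5.5%, which takes 0.055/rate to traverse)."""
        for rate, u in [(4.0, 0.5), (2.0, 0.25), (4.0, 0.25)]:
            params = lic.LicensingParams(rate=rate, unlicensed_fraction=u)
            hist = lic.apply_background(
                lic.build_histogram(lic.simulate_trajectory(params))
            )
            report = lic.detect_unlicensed_peak(hist)
            g1_time = max(1.0, u + 1.0 / rate)
            expected = (u + 0.055 / rate) / g1_time
            assert report.peak_fraction == pytest.approx(expected, abs=0.02)

    def test_empty_histogram_rejected(self):
        hist = lic.LicensingHistogram(np.linspace(0, 100, 101), np.zeros(101))
        with pytest.raises(ValueError):
            lic.detect_unlicensed_peak(hist)


class TestFit:
    def test_self_generated_input_has_zero_distance(self):
        params = lic.LicensingParams(rate=2.0, unlicensed_fraction=0.3, n_steps=2000)
        observed = lic.process_histogram(params)
        result = lic.fit_params(
            observed,
            rates=[1.5, 2.0, 2.5],
            unlicensed_fractions=[0.2, 0.3, 0.4],
            n_steps=2000,
        )
        assert result.distance == pytest.approx(0.0, abs=1e-12)
        assert result.best_rate == 2.0
        assert result.best_unlicensed_fraction == 0.3

    def test_checkpoint_loss_fit_prefers_no_pause(self):
        """An immediately-licensing, low-checkpoint histogram fits u at the grid minimum."""
        truth = lic.LicensingParams(
            rate=2.0, checkpoint_threshold=0.3, n_steps=2000
        )
        observed = lic.process_histogram(truth)
        result = lic.fit_params(
            observed,
            rates=[1.0, 2.0, 4.0],
            unlicensed_fractions=[0.0, 0.2, 0.4],
            checkpoint_thresholds=[0.3, 1.0],
            n_steps=2000,
        )
        assert result.best_unlicensed_fraction == 0.0
        assert result.best_checkpoint_threshold == 0.3
        assert not lic.detect_unlicensed_peak(observed).present

    def test_empty_grid_rejected(self):
        observed = lic.process_histogram(lic.LicensingParams(n_steps=500))
        with pytest.raises(ValueError):
            lic.fit_params(observed, rates=[], unlicensed_fractions=[0.1])
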