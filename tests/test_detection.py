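"""Personalized-threshold extraction and observation-window detection."""

import numpy as np
import pytest

from imcluster import (
    ClusterGeometry,
    GaitParams,
    NoiseModel,
    PerturbationParams,
    detect_windows,
    extract_thresholds,
    inject_perturbation,
    local_extrema,
    periodicity,
    reference_scenario,
    simulate_cluster_readings,
    synth_gait_trajectory,
)
from imcluster.baselines import process
from imcluster.detection import (
    AperiodicSignalError,
    ThresholdExtractionError,
    zero_crossings,
)


class TestLocalExtrema:
    def test_sine_lobes_give_quarter_period_extrema(self):
        t = np.arange(401) / 200.0  # 2 s
        ext = local_extrema(t, np.sin(2 * np.pi * t))
        maxima = [e for e in ext if e.kind > 0]
        minima = [e for e in ext if e.kind < 0]
        assert len(maxima) == 2 and len(minima) == 2
        assert np.allclose([e.time for e in maxima], [0.25, 1.25], atol=1 / 200)
        assert np.allclose([e.value for e in maxima], 1.0, atol=1e-3)
        assert np.allclose([e.time for e in minima], [0.75, 1.75], atol=1 / 200)

    def test_all_positive_signal_warns_and_returns_empty(self):
        t = np.arange(100) / 200.0
        with pytest.warns(UserWarning, match="zero crossings"):
            assert local_extrema(t, np.cos(t) + 2.0) == []

    def test_gait_maxima_count_matches_generated_touchdowns(self, baseline_truth):
        ext = local_extrema(baseline_truth.t, baseline_truth.alpha[:, 1])
        floor = 2 * baseline_truth.meta["background_amplitude"]
        maxima = [e for e in ext if e.kind > 0 and e.value > floor]
        assert len(maxima) == len(baseline_truth.meta["touchdown_times"])

    def test_zero_crossings_are_interpolated(self):
        t = np.arange(5, dtype=float)
        x = np.array([1.0, 0.5, -0.5, -1.0, 1.0])
        cr = zero_crossings(t, x)
        assert np.allclose(cr, [1.5, 3.5])


class TestPeriodicity:
    def test_pure_sinusoid_period_within_one_sample(self):
        f, rate = 1.25, 200.0
        t = np.arange(4000) / rate
        assert periodicity(np.sin(2 * np.pi * f * t), rate) == pytest.approx(
            1 / f, abs=1 / rate
        )

    def test_noisy_sinusoid_period_within_two_percent(self):
        rng = np.random.default_rng(5)
        f, rate = 0.9, 200.0
        t = np.arange(6000) / rate
        x = np.sin(2 * np.pi * f * t) + 0.1 * rng.normal(size=len(t))  # ~20 dB SNR
        assert periodicity(x, rate) == pytest.approx(1 / f, rel=0.02)

    def test_white_noise_is_aperiodic(self):
        rng = np.random.default_rng(6)
        with pytest.raises(AperiodicSignalError):
            periodicity(rng.normal(size=4000), 200.0)


class TestExtractThresholds:
    def test_avg_local_max_matches_generator_peaks(self, baseline_truth):
        thr = extract_thresholds(
            baseline_truth.omega[:, 1], baseline_truth.alpha[:, 1], baseline_truth.rate
        )
        mean_peak = np.mean(baseline_truth.meta["touchdown_peaks"])
        assert thr.alpha.avg_local_max == pytest.approx(mean_peak, rel=0.05)
        assert thr.touchdown_rate == pytest.approx(
            baseline_truth.meta["touchdown_rate"], rel=0.02
        )
        assert thr.alpha.global_max >= thr.alpha.avg_local_max > 0
        assert thr.alpha.global_min <= thr.alpha.avg_local_min < 0

    def test_constant_baseline_raises(self):
        flat = np.zeros(4000)
        with pytest.raises((ThresholdExtractionError, AperiodicSignalError)):
            extract_thresholds(flat, flat, 200.0)

    def test_human_regime_thresholds_in_reported_ranges(self):
        """Walking parameterized to the human regime yields averaged local
        maxima inside the ranges observed across participants."""
        truth = synth_gait_trajectory(GaitParams.human_regime(duration=30.0, seed=21))
        thr = extract_thresholds(truth.omega[:, 1], truth.alpha[:, 1], truth.rate)
        assert 28.626 <= thr.alpha.avg_local_max <= 70.744
        assert 0.499 <= thr.omega.avg_local_max <= 1.343


@pytest.fixture(scope="module")
def processed_pair():
    """IMC-processed baseline and a perturbed trial under the full error model."""
    geometry, _ = reference_scenario()
    nominal = ClusterGeometry()
    base_truth = synth_gait_trajectory(GaitParams(duration=30.0, seed=1))
    trial_truth = synth_gait_trajectory(GaitParams(duration=40.0, seed=2))
    base = process(
        nominal,
        simulate_cluster_readings(geometry, base_truth, NoiseModel(seed=11)),
        "imc",
    )
    return geometry, nominal, base, trial_truth


class TestDetectWindows:
    def run_trial(self, processed_pair, multiplier, seed=12):
        geometry, nominal, base, trial_truth = processed_pair
        thr = extract_thresholds(base.omega[:, 1], base.alpha[:, 1], base.rate)
        if multiplier is None:
            truth, true_win = trial_truth, None
        else:
            truth, true_win = inject_perturbation(
                trial_truth, PerturbationParams(onset=20.0, multiplier=multiplier)
            )
        fused = process(
            nominal,
            simulate_cluster_readings(geometry, truth, NoiseModel(seed=seed)),
            "imc",
        )
        wins = detect_windows(fused.omega[:, 1], fused.alpha[:, 1], thr, fused.rate)
        return wins, true_win

    def test_pure_baseline_yields_no_windows(self, processed_pair):
        wins, _ = self.run_trial(processed_pair, None)
        assert wins == []

    def test_injected_perturbation_detected_with_good_overlap(self, processed_pair):
        wins, true_win = self.run_trial(processed_pair, 2.0)
        assert len(wins) == 1
        w = wins[0]
        inter = max(0.0, min(w.t_off, true_win[1]) - max(w.t_on, true_win[0]))
        union = max(w.t_off, true_win[1]) - min(w.t_on, true_win[0])
        assert inter / union >= 0.5
        assert not w.flags["unrecovered"]

    def test_sub_threshold_injection_yields_no_windows(self, processed_pair):
        wins, _ = self.run_trial(processed_pair, 1.05)
        assert wins == []

    def test_detection_count_monotone_in_multiplier(self, processed_pair):
        counts = [len(self.run_trial(processed_pair, m)[0]) for m in (1.05, 1.6, 2.5)]
        assert counts == sorted(counts)

    def test_scaling_both_signals_leaves_detections_unchanged(self, processed_pair):
        geometry, nominal, base, trial_truth = processed_pair
        truth, _ = inject_perturbation(
            trial_truth, PerturbationParams(onset=20.0, multiplier=2.0)
        )
        fused = process(
            nominal,
            simulate_cluster_readings(geometry, truth, NoiseModel(seed=12)),
            "imc",
        )
        c = 3.7
        thr1 = extract_thresholds(base.omega[:, 1], base.alpha[:, 1], base.rate)
        thr2 = extract_thresholds(c * base.omega[:, 1], c * base.alpha[:, 1], base.rate)
        w1 = detect_windows(fused.omega[:, 1], fused.alpha[:, 1], thr1, fused.rate)
        w2 = detect_windows(c * fused.omega[:, 1], c * fused.alpha[:, 1], thr2, fused.rate)
        assert [(w.t_on, w.t_off) for w in w1] == [(w.t_on, w.t_off) for w in w2]

    def test_determinism(self, processed_pair):
        a, _ = self.run_trial(processed_pair, 2.0)
        b, _ = self.run_trial(processed_pair, 2.0)
        assert [(w.t_on, w.t_off) for w in a] == [(w.t_on, w.t_off) for w in b]


def test_numdiff_thresholds_exceed_imc_thresholds(processed_pair):
    """Thresholds extracted from differentiated single-IMU signals are
    inflated by differentiation noise relative to the cluster's."""
    geometry, nominal, base_imc, _ = processed_pair
    base_truth = synth_gait_trajectory(GaitParams(duration=30.0, seed=1))
    series = simulate_cluster_readings(geometry, base_truth, NoiseModel(seed=11))
    base_nd = process(nominal, series, "numdiff")
    thr_imc = extract_thresholds(base_imc.omega[:, 1], base_imc.alpha[:, 1], base_imc.rate)
    thr_nd = extract_thresholds(base_nd.omega[:, 1], base_nd.alpha[:, 1], base_nd.rate)
    assert thr_nd.alpha.global_max > thr_imc.alpha.global_max
    assert thr_nd.alpha.avg_local_max > thr_imc.alpha.avg_local_max
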