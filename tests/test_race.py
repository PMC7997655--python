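"""Race-model primitives: drift conversion, drift scaling, ex-Gaussian,
guess mixture, accumulator simulation and noise calibration."""

import numpy as np
import pytest

from stoprace.race import (
    ExGaussParams,
    GeneratingModel,
    GuessMixture,
    ModelKind,
    RaceParams,
    calibrate_noise,
    drift_from_latency,
    fit_exgauss,
    guess_probability_by_ssd,
    race_go_trials,
    race_stop_trials,
    sample_guess_rt,
    simulate_go_trial,
    simulate_stop_trial,
    ssd_drift_scale,
)


class TestDriftFromLatency:
    def test_grand_mean_conversion(self):
        assert drift_from_latency(543, 100, 50) == pytest.approx(100 / 493)

    def test_unit_drift(self):
        assert drift_from_latency(150, 100, 50) == pytest.approx(1.0)

    def test_latency_at_nondecision_time_is_domain_error(self):
        with pytest.raises(ValueError):
            drift_from_latency(50, 100, 50)


class TestDriftScale:
    def test_zero_at_zero_ssd(self):
        assert ssd_drift_scale(0) == 0.0

    def test_turns_positive_just_above_ten_ms(self):
        assert ssd_drift_scale(10) == 0.0
        assert ssd_drift_scale(11) > 0.0

    def test_value_at_staircase_start(self):
        assert ssd_drift_scale(50) == pytest.approx(0.40052, abs=1e-4)

    def test_saturates_at_one(self):
        assert ssd_drift_scale(550) == pytest.approx(1.0)
        assert ssd_drift_scale(800) == 1.0

    def test_negative_ssd_rejected(self):
        with pytest.raises(ValueError):
            ssd_drift_scale(-1)


class TestExGauss:
    def test_parameter_recovery(self, rng):
        true = ExGaussParams(300.0, 50.0, 150.0)
        x = sample_guess_rt(true, rng, size=50_000)
        fit = fit_exgauss(x)
        assert fit.mu == pytest.approx(true.mu, rel=0.05)
        assert fit.sigma == pytest.approx(true.sigma, rel=0.05)
        assert fit.tau == pytest.approx(true.tau, rel=0.05)

    def test_location_equivariance(self, rng):
        x = sample_guess_rt(ExGaussParams(300.0, 50.0, 150.0), rng, size=20_000)
        a, b = fit_exgauss(x), fit_exgauss(x + 100.0)
        assert b.mu - a.mu == pytest.approx(100.0, abs=5.0)
        assert b.sigma == pytest.approx(a.sigma, rel=0.05)
        assert b.tau == pytest.approx(a.tau, rel=0.05)

    def test_small_or_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_exgauss(np.arange(5, dtype=float))
        with pytest.raises(ValueError):
            fit_exgauss(np.full(100, 400.0))

    def test_guess_samples_always_positive(self, rng):
        # heavy left mass: mu < 0 forces many rejections
        x = sample_guess_rt(ExGaussParams(-50.0, 80.0, 100.0), rng, size=100_000)
        assert np.all(x > 0)

    def test_guess_sample_mean_and_determinism(self):
        p = ExGaussParams(300.0, 50.0, 150.0)
        a = sample_guess_rt(p, np.random.default_rng(5), size=200_000)
        b = sample_guess_rt(p, np.random.default_rng(5), size=200_000)
        assert np.array_equal(a, b)
        assert a.mean() == pytest.approx(p.mean, rel=0.01)


class TestGuessMixtureSolver:
    def test_midpoint_accuracy_gives_half(self):
        assert guess_probability_by_ssd(0.70, 0.90, 0.50) == pytest.approx(0.5)

    def test_go_accuracy_means_no_guessing(self):
        assert guess_probability_by_ssd(0.90, 0.90, 0.50) == 0.0

    def test_chance_accuracy_means_all_guesses(self):
        assert guess_probability_by_ssd(0.50, 0.90, 0.50) == 1.0

    def test_out_of_range_accuracies_clipped(self):
        assert guess_probability_by_ssd(0.95, 0.90, 0.50) == 0.0
        assert guess_probability_by_ssd(0.40, 0.90, 0.50) == 1.0

    def test_equal_reference_accuracies_unidentifiable(self):
        with pytest.raises(ValueError):
            guess_probability_by_ssd(0.7, 0.8, 0.8)

    def test_mixture_from_accuracy_curve_pins_ssd0(self):
        mix = GuessMixture.from_accuracy_curve(
            {0: 0.5, 100: 0.7, 300: 0.85, 500: 0.9},
            acc_go=0.9,
            guess_dist=ExGaussParams(300, 50, 150),
        )
        assert mix.p_guess_at(0) == 1.0
        assert mix.p_guess_at(100) == pytest.approx(0.5)
        assert mix.p_guess_at(500) == pytest.approx(0.0)
        # linear interpolation between grid points
        assert mix.p_guess_at(200) == pytest.approx((0.5 + 0.125) / 2, abs=1e-9)


class TestAccumulators:
    def test_nearly_deterministic_race_hits_mean_latency(self, rng):
        p = RaceParams(mu_go=0.2, mu_stop=0.4, sigma=0.05, error_ratio=0.5)
        rt, correct, omission = race_go_trials(p, rng, 20_000)
        assert rt.mean() == pytest.approx(p.threshold / p.mu_go + p.ndt, rel=0.01)
        assert correct.mean() > 0.999
        assert omission.mean() == 0.0

    def test_calibrated_noise_reproduces_target_accuracy(self, abcd_race_params, rng):
        rt, correct, omission = race_go_trials(abcd_race_params, rng, 100_000)
        assert correct[~omission].mean() == pytest.approx(0.90, abs=0.01)

    def test_fast_drift_eliminates_omissions(self, rng):
        p = RaceParams(mu_go=1.0, mu_stop=0.4, sigma=1.0)
        _, _, omission = race_go_trials(p, rng, 50_000)
        assert omission.mean() == 0.0

    def test_unattainable_calibration_targets_rejected(self):
        with pytest.raises(ValueError):
            calibrate_noise(0.2, target_accuracy=0.5)
        with pytest.raises(ValueError):
            calibrate_noise(0.2, target_accuracy=1.0)

    def test_calibration_self_consistency(self, rng):
        sigma = calibrate_noise(0.25, rng=np.random.default_rng(2), n_trials=40_000)
        p = RaceParams(mu_go=0.25, mu_stop=0.4, sigma=sigma)
        _, correct, omission = race_go_trials(p, rng, 100_000)
        assert correct[~omission].mean() == pytest.approx(0.90, abs=0.015)


class TestStopTrialMechanics:
    def test_stop_cannot_win_at_very_long_delay(self, abcd_race_params, rng):
        responded, _, _ = race_stop_trials(
            ModelKind.INDEPENDENT_RACE, 2500.0, abcd_race_params, rng, size=5_000
        )
        assert responded.mean() > 0.99

    def test_slowed_go_failures_at_zero_drift_have_chance_accuracy(
        self, abcd_race_params, rng
    ):
        """At SSD 0 the go drift is zero, so any stop failure is a toss-up
        between the two (now identical) accumulators."""
        responded, _, correct = race_stop_trials(
            ModelKind.SLOWED_GO, 50.0, abcd_race_params, rng, size=400_000
        )
        acc = correct[responded].mean()
        assert acc < 0.88  # visibly impaired relative to the 0.90 baseline
        responded0, _, correct0 = race_stop_trials(
            ModelKind.SLOWED_GO,
            np.zeros(400_000),
            RaceParams(mu_go=0.2, mu_stop=0.05, sigma=1.4),
            rng,
        )
        if responded0.sum() >= 50:
            assert correct0[responded0].mean() == pytest.approx(0.5, abs=0.15)

    def test_guessing_at_ssd0_is_all_guesses_at_chance(self, abcd_race_params, rng):
        model = GeneratingModel(ModelKind.GUESSING, abcd_race_params)
        responded, rt, correct = race_stop_trials(
            model.kind, 0.0, abcd_race_params, rng, mixture=model.mixture, size=200_000
        )
        assert responded.mean() > 0.02
        assert correct[responded].mean() == pytest.approx(0.5, abs=0.02)

    def test_guessing_without_mixture_is_config_error(self, abcd_race_params, rng):
        with pytest.raises(ValueError):
            race_stop_trials(
                ModelKind.GUESSING, 100.0, abcd_race_params, rng, size=10
            )

    def test_scalar_wrappers_round_trip(self, abcd_race_params):
        rng = np.random.default_rng(0)
        rt, correct = simulate_go_trial(abcd_race_params, rng)
        assert rt is None or rt > abcd_race_params.ndt
        model = GeneratingModel(ModelKind.CONFUSION, abcd_race_params)
        responded, rt, correct = simulate_stop_trial(model, 200.0, rng)
        assert responded in (True, False)
        if not responded:
            assert rt is None and correct is None
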