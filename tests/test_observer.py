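"""Generative SDT observer: closed-form marginals, coupling, drift."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import norm

import lickreport as lr
from lickreport.observer import ObserverParams
from lickreport.session import Outcome, StimulusKind, StimulusSpec

CATCH = StimulusSpec(kind=StimulusKind.CATCH_TACTILE)


def target(intensity):
    return StimulusSpec(kind=StimulusKind.TARGET_OPTO, intensity_mw_mm2=intensity)


def mc_responses(params, stimulus, n, seed=0):
    rng = np.random.default_rng(seed)
    licks = np.empty(n, dtype=bool)
    reflexes = np.empty(n, dtype=bool)
    for i in range(n):
        licks[i], reflexes[i] = lr.simulate_trial(params, stimulus, 1, rng)
    return licks, reflexes


class TestMarginals:
    def test_catch_lick_rate_matches_normal_cdf(self):
        # c0 = 0.5, no drift: P(lick | catch) = Phi(-0.5) ~ 0.309
        params = ObserverParams(lick_criterion_start=0.5, lick_criterion_drift=0.0,
                                channel_correlation=0.0, rng_seed=0)
        licks, _ = mc_responses(params, CATCH, 100_000)
        expected = norm.cdf(-0.5)
        se = np.sqrt(expected * (1 - expected) / licks.size)
        assert abs(licks.mean() - expected) < 4 * se

    def test_target_lick_rate_matches_lapse_scaled_cdf(self):
        # arbitrary rho, no drift: P(lick | I) = (1 - lapse) * Phi(delta - c0)
        params = ObserverParams(lick_criterion_start=0.5, lick_criterion_drift=0.0,
                                channel_correlation=0.6, lapse_rate=0.05)
        stim = target(1.0)
        delta = params.sensitivity(stim)
        licks, _ = mc_responses(params, stim, 100_000, seed=3)
        expected = (1 - params.lapse_rate) * norm.cdf(delta - 0.5)
        se = np.sqrt(expected * (1 - expected) / licks.size)
        assert abs(licks.mean() - expected) < 4 * se

    def test_unreachable_criterion_never_licks(self):
        params = ObserverParams(lick_criterion_start=50.0, lick_criterion_drift=0.0)
        licks, _ = mc_responses(params, CATCH, 2_000)
        assert not licks.any()

    def test_control_stimuli_carry_no_drive(self):
        params = ObserverParams(lick_criterion_start=0.5, lick_criterion_drift=0.0)
        control = StimulusSpec(kind=StimulusKind.CONTROL_OPTO, intensity_mw_mm2=5.0)
        assert params.sensitivity(control) == 0.0

    def test_hit_rate_nondecreasing_in_intensity(self):
        params = replace(lr.DEFAULT_OBSERVER, lick_criterion_drift=0.0,
                         lick_criterion_start=0.5)
        rates = []
        for I in (0.14, 0.35, 0.87, 2.18, 5.45):
            licks, _ = mc_responses(params, target(I), 10_000, seed=int(I * 100))
            rates.append(licks.mean())
        # allow 2 SE of Monte-Carlo slack between neighbours
        slack = 2 * np.sqrt(0.25 / 10_000)
        assert all(b >= a - slack for a, b in zip(rates, rates[1:]))

    def test_sensitivity_map_saturates_and_floors(self):
        p = ObserverParams(sensitivity_gain=3.5, sensitivity_origin=-0.97,
                           sensitivity_max=3.0)
        assert p.sensitivity(target(0.14)) > 0
        assert p.sensitivity(target(5.45)) == 3.0
        assert p.sensitivity(CATCH) == 0.0


class TestCoupling:
    def test_perfect_coupling_gives_identical_channels(self):
        params = ObserverParams(
            lick_criterion_start=1.0, lick_criterion_drift=0.0,
            reflex_criterion=1.0, channel_correlation=1.0,
            reflex_sensitivity_boost=0.0, lapse_rate=0.0,
        )
        for stim in (CATCH, target(1.0)):
            licks, reflexes = mc_responses(params, stim, 3_000)
            assert np.array_equal(licks, reflexes)

    def test_agreement_near_criterion_increases_with_coupling(self):
        agreements = []
        for rho in (0.0, 0.9):
            params = ObserverParams(
                lick_criterion_start=0.5, lick_criterion_drift=0.0,
                reflex_criterion=0.5, channel_correlation=rho,
                reflex_sensitivity_boost=0.0, lapse_rate=0.0,
            )
            stim = target(0.35)  # delta near the criterion
            licks, reflexes = mc_responses(params, stim, 30_000, seed=9)
            agreements.append((licks == reflexes).mean())
        assert agreements[1] > agreements[0] + 0.1

    def test_agreement_saturates_far_from_criterion_regardless_of_rho(self):
        for rho in (0.0, 0.9):
            params = ObserverParams(
                lick_criterion_start=0.5, lick_criterion_drift=0.0,
                reflex_criterion=0.5, channel_correlation=rho,
                reflex_sensitivity_boost=0.0, lapse_rate=0.0,
                sensitivity_max=6.0, sensitivity_gain=8.0,
            )
            licks, reflexes = mc_responses(params, target(5.45), 5_000, seed=2)
            assert (licks == reflexes).mean() > 0.99


class TestSessionSimulation:
    def test_session_fills_every_scheduled_trial(self, testing_schedule, default_session):
        assert len(default_session) == testing_schedule.n_trials
        assert all(t.outcome is not None for t in default_session)

    def test_simulation_is_deterministic(self, testing_schedule):
        params = replace(lr.DEFAULT_OBSERVER, rng_seed=101)
        a = lr.simulate_session(params, testing_schedule)
        b = lr.simulate_session(params, testing_schedule)
        assert [(t.licked, t.reflex_response, t.rewarded) for t in a] == [
            (t.licked, t.reflex_response, t.rewarded) for t in b
        ]

    def test_outcomes_consistent_with_responses(self, default_session):
        for t in default_session:
            if t.stimulus.is_catch:
                assert t.outcome in (Outcome.FALSE_ALARM, Outcome.CORRECT_REJECTION)
            else:
                assert t.outcome is (Outcome.HIT if t.licked else Outcome.MISS)
            if t.rewarded:
                assert t.outcome is Outcome.HIT

    def test_asymptotic_hit_rate_exceeds_90_percent(self, default_cohort):
        top = []
        for _, trials in default_cohort:
            hits = [t.licked for t in trials
                    if not t.stimulus.is_catch
                    and abs(t.stimulus.intensity_mw_mm2 - 5.45) < 1e-9]
            top.extend(hits)
        assert np.mean(top) > 0.90

    def test_cohort_shapes(self, default_cohort):
        assert len(default_cohort) == 40
        solo = lr.simulate_cohort([lr.DEFAULT_OBSERVER], 1, seed=0)
        assert len(solo) == 1
        assert len(solo[0][1]) == 360

    def test_criterion_drift_raises_criterion_and_lowers_fa(self, default_cohort):
        # within-session: second-half catch FA below first-half catch FA on average
        deltas = []
        for _, trials in default_cohort:
            half = len(trials) // 2
            fa1 = np.mean([t.licked for t in trials[:half] if t.stimulus.is_catch])
            fa2 = np.mean([t.licked for t in trials[half:] if t.stimulus.is_catch])
            deltas.append(fa1 - fa2)
        assert np.mean(deltas) > 0.05


class TestTrainingAndManipulations:
    def test_zero_learning_rate_freezes_performance(self):
        curve = lr.simulate_training_curve(lr.DEFAULT_OBSERVER, 4, learning_rate=0.0)
        assert max(curve) - min(curve) < 8.0  # session-to-session noise only

    def test_learning_improves_percent_correct(self):
        curve = lr.simulate_training_curve(lr.DEFAULT_OBSERVER, 12, learning_rate=0.25)
        assert np.mean(curve[-3:]) > np.mean(curve[:3]) + 10.0

    def test_saline_control_leaves_parameters_unchanged(self):
        out = lr.apply_manipulation(lr.DEFAULT_OBSERVER, "saline_control")
        assert out == lr.DEFAULT_OBSERVER

    def test_lidocaine_collapses_hits_to_false_alarm_floor(self):
        base = ObserverParams(lick_criterion_start=0.5, lick_criterion_drift=0.0,
                              lapse_rate=0.0)
        lido = lr.apply_manipulation(base, "lidocaine")
        assert lido.sensitivity(target(3.79)) == 0.0
        licks, _ = mc_responses(lido, target(3.79), 20_000, seed=1)
        floor = norm.cdf(-0.5)
        se = np.sqrt(floor * (1 - floor) / licks.size)
        assert abs(licks.mean() - floor) < 4 * se

    def test_unknown_manipulation_rejected(self):
        with pytest.raises(ValueError):
            lr.apply_manipulation(lr.DEFAULT_OBSERVER, "capsaicin")

    def test_hit_probability_calibration(self):
        base = ObserverParams(lick_criterion_start=0.5, lick_criterion_drift=0.0,
                              lapse_rate=0.0)
        cal = lr.calibrate_hit_probability(base, 3.79, 0.97)
        licks, _ = mc_responses(cal, target(3.79), 50_000, seed=4)
        assert abs(licks.mean() - 0.97) < 0.01

    def test_calibration_requires_drift_free_criterion(self):
        with pytest.raises(ValueError):
            lr.calibrate_hit_probability(lr.DEFAULT_OBSERVER, 3.79, 0.97)


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(channel_correlation=1.5),
            dict(lapse_rate=0.5),
            dict(lick_criterion_drift=-0.1),
            dict(sensitivity_gain=-1.0),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ObserverParams(**kwargs)

    def test_response_probability_inversion(self):
        for p in (0.309, 0.152, 0.5):
            c = lr.criterion_for_response_probability(p)
            assert norm.cdf(-c) == pytest.approx(p, abs=1e-12)
        with pytest.raises(ValueError):
            lr.criterion_for_response_probability(0.0)
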