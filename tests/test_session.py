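"""Session scheduling, outcome classification and task consequences."""

import numpy as np
import pytest

from lickreport.session import (
    Consequence,
    Outcome,
    StimulusKind,
    StimulusSpec,
    TrialRecord,
    apply_consequences,
    build_schedule,
    classify_outcome,
    default_intensities,
    reward_probability_for_day,
)


class TestBuildSchedule:
    def test_standard_testing_session_has_360_trials(self, testing_schedule):
        assert testing_schedule.n_trials == 360

    @pytest.mark.parametrize("seed", [0, 7, 1234])
    def test_per_stimulus_counts_are_conserved(self, seed):
        sched = build_schedule("testing", seed=seed)
        intensities = default_intensities()
        counts = {}
        n_catch = 0
        for t in sched.trials:
            if t.stimulus.is_catch:
                n_catch += 1
            else:
                counts[t.stimulus.intensity_mw_mm2] = (
                    counts.get(t.stimulus.intensity_mw_mm2, 0) + 1
                )
        assert n_catch == 20
        assert len(counts) == 17
        assert all(v == 20 for v in counts.values())
        assert set(np.round(list(counts), 9)) == set(np.round(intensities, 9))

    def test_minimal_design_is_one_target_plus_one_catch(self):
        sched = build_schedule("testing", intensities=[1.0], reps_per_stimulus=1, seed=0)
        kinds = sorted(t.stimulus.kind for t in sched.trials)
        assert kinds == [StimulusKind.CATCH_TACTILE, StimulusKind.TARGET_OPTO]

    def test_bit_reproducible_for_fixed_seed(self):
        a = build_schedule("testing", seed=42)
        b = build_schedule("testing", seed=42)
        assert [t.stimulus for t in a.trials] == [t.stimulus for t in b.trials]
        assert [t.isi_s for t in a.trials] == [t.isi_s for t in b.trials]
        c = build_schedule("testing", seed=43)
        assert [t.stimulus for t in a.trials] != [t.stimulus for t in c.trials]

    def test_isis_and_response_windows(self, testing_schedule):
        isis = np.array([t.isi_s for t in testing_schedule.trials])
        assert np.all((isis >= 3.0) & (isis <= 6.0))
        assert all(t.response_window_s == 1.0 for t in testing_schedule.trials)

    def test_training_window_is_one_session_level_draw(self):
        sched = build_schedule("training", seed=3, training_day=2)
        windows = {t.response_window_s for t in sched.trials}
        assert len(windows) == 1
        (w,) = windows
        assert 0.8 <= w <= 1.5
        assert sched.phase == "training_day_2"
        assert sched.reward_probability == pytest.approx(0.95)

    def test_control_sessions_use_595_nm_stimuli(self):
        sched = build_schedule("control_595", seed=0)
        targets = [t for t in sched.trials if not t.stimulus.is_catch]
        assert all(t.stimulus.kind is StimulusKind.CONTROL_OPTO for t in targets)
        assert all(t.stimulus.wavelength_nm == 595 for t in targets)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(reps_per_stimulus=0),
            dict(intensities=[0.01]),
            dict(intensities=[9.0]),
            dict(intensities=[]),
        ],
    )
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            build_schedule("testing", seed=0, **kwargs)

    def test_unknown_phase_rejected(self):
        with pytest.raises(ValueError):
            build_schedule("washout", seed=0)


class TestClassifyOutcome:
    @pytest.mark.parametrize(
        "kind,licked,expected",
        [
            (StimulusKind.TARGET_OPTO, True, Outcome.HIT),
            (StimulusKind.TARGET_OPTO, False, Outcome.MISS),
            (StimulusKind.CATCH_TACTILE, True, Outcome.FALSE_ALARM),
            (StimulusKind.CATCH_TACTILE, False, Outcome.CORRECT_REJECTION),
            (StimulusKind.CONTROL_OPTO, True, Outcome.HIT),
            (StimulusKind.CONTROL_OPTO, False, Outcome.MISS),
        ],
    )
    def test_total_mapping(self, kind, licked, expected):
        intensity = 0.0 if kind is StimulusKind.CATCH_TACTILE else 1.0
        stim = StimulusSpec(kind=kind, intensity_mw_mm2=intensity)
        assert classify_outcome(stim, licked) is expected


class TestRewardTaper:
    @pytest.mark.parametrize(
        "day,step,expected", [(1, 0.05, 1.0), (5, 0.05, 0.80), (50, 0.05, 0.80), (3, 0.10, 0.80)]
    )
    def test_taper_reaches_floor(self, day, step, expected):
        assert reward_probability_for_day(day, step) == pytest.approx(expected)

    @pytest.mark.parametrize("step", [0.01, 0.2, -0.05])
    def test_step_outside_range_rejected(self, step):
        with pytest.raises(ValueError):
            reward_probability_for_day(1, step)


class TestConsequences:
    def _trial(self, stim, licked, premature=False):
        return TrialRecord(
            trial_index=1,
            stimulus=stim,
            isi_s=4.2,
            response_window_s=1.0,
            licked=licked,
            outcome=classify_outcome(stim, licked),
            premature_lick=premature,
        )

    def test_miss_triggers_extra_stimuli(self):
        target = StimulusSpec(kind=StimulusKind.TARGET_OPTO, intensity_mw_mm2=1.0)
        assert apply_consequences(self._trial(target, False)).consequence is Consequence.EXTRA_STIMULI

    def test_false_alarm_triggers_warning_pulses(self):
        catch = StimulusSpec(kind=StimulusKind.CATCH_TACTILE)
        assert apply_consequences(self._trial(catch, True)).consequence is Consequence.WARNING_PULSES

    def test_premature_lick_gets_isi_length_timeout(self):
        target = StimulusSpec(kind=StimulusKind.TARGET_OPTO, intensity_mw_mm2=1.0)
        out = apply_consequences(self._trial(target, True, premature=True))
        assert out.consequence is Consequence.TIMEOUT
        assert out.isi_s == pytest.approx(4.2)

    def test_hit_has_no_aversive_consequence(self):
        target = StimulusSpec(kind=StimulusKind.TARGET_OPTO, intensity_mw_mm2=1.0)
        assert apply_consequences(self._trial(target, True)).consequence is Consequence.NONE

    def test_unclassified_trial_rejected(self):
        target = StimulusSpec(kind=StimulusKind.TARGET_OPTO, intensity_mw_mm2=1.0)
        stub = TrialRecord(trial_index=1, stimulus=target, isi_s=4.0, response_window_s=1.0)
        with pytest.raises(ValueError):
            apply_consequences(stub)


class TestDomainTypes:
    def test_catch_trials_carry_no_irradiance(self):
        with pytest.raises(ValueError):
            StimulusSpec(kind=StimulusKind.CATCH_TACTILE, intensity_mw_mm2=1.0)

    def test_wavelength_defaults_by_kind(self):
        t = StimulusSpec(kind=StimulusKind.TARGET_OPTO, intensity_mw_mm2=1.0)
        c = StimulusSpec(kind=StimulusKind.CONTROL_OPTO, intensity_mw_mm2=1.0)
        assert (t.wavelength_nm, c.wavelength_nm) == (470, 595)

    def test_reflex_response_follows_score_grouping(self):
        target = StimulusSpec(kind=StimulusKind.TARGET_OPTO, intensity_mw_mm2=1.0)
        for score, expected in [(0, False), (1, False), (2, True), (3, True)]:
            t = TrialRecord(
                trial_index=1, stimulus=target, isi_s=4.0, response_window_s=1.0, reflex_score=score
            )
            assert t.reflex_response is expected
        with pytest.raises(ValueError):
            TrialRecord(
                trial_index=1,
                stimulus=target,
                isi_s=4.0,
                response_window_s=1.0,
                reflex_score=3,
                reflex_response=False,
            )

    def test_only_hits_can_be_rewarded(self):
        catch = StimulusSpec(kind=StimulusKind.CATCH_TACTILE)
        with pytest.raises(ValueError):
            TrialRecord(
                trial_index=1,
                stimulus=catch,
                isi_s=4.0,
                response_window_s=1.0,
                licked=True,
                outcome=Outcome.FALSE_ALARM,
                rewarded=True,
            )
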