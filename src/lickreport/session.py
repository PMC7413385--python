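"""Session schedules and trial outcome classification for the go/no-go
lick-detection task.

A session interleaves *target* optogenetic stimuli (470 nm, 10 ms pulses
over a 0.14-5.45 mW/mm^2 irradiance range) with *catch* tactile stimuli.
The standard testing session presents 20 repetitions of each of 17 target
intensities plus 20 catch trials, 360 trials total, in seeded random
order.  Licking within the post-stimulus response window on a target
trial is a hit; licking on a catch trial is a false alarm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "StimulusKind",
    "Outcome",
    "Consequence",
    "StimulusSpec",
    "TrialRecord",
    "SessionSchedule",
    "default_intensities",
    "build_schedule",
    "classify_outcome",
    "reward_probability_for_day",
    "apply_consequences",
    "INTENSITY_MIN",
    "INTENSITY_MAX",
]

INTENSITY_MIN = 0.14  # mW/mm^2, weakest target irradiance
INTENSITY_MAX = 5.45  # mW/mm^2, strongest target irradiance

ISI_RANGE_S = (3.0, 6.0)
TESTING_RESPONSE_WINDOW_S = 1.0
TRAINING_RESPONSE_WINDOW_RANGE_S = (0.8, 1.5)
REWARD_FLOOR = 0.80


class StimulusKind(str, Enum):
    TARGET_OPTO = "target_opto"
    CATCH_TACTILE = "catch_tactile"
    CONTROL_OPTO = "control_opto"


class Outcome(str, Enum):
    HIT = "hit"
    MISS = "miss"
    FALSE_ALARM = "false_alarm"
    CORRECT_REJECTION = "correct_rejection"


class Consequence(str, Enum):
    NONE = "none"
    EXTRA_STIMULI = "extra_stimuli"
    WARNING_PULSES = "warning_pulses"
    TIMEOUT = "timeout"


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulus: an optogenetic target, a tactile catch, or a 595 nm
    control pulse delivered over the same irradiance range as targets."""

    kind: StimulusKind
    intensity_mw_mm2: float = 0.0
    wavelength_nm: Optional[int] = None
    pulse_width_ms: float = 10.0

    def __post_init__(self) -> None:
        kind = StimulusKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if self.pulse_width_ms <= 0:
            raise ValueError("pulse_width_ms must be positive")
        if self.intensity_mw_mm2 < 0:
            raise ValueError("irradiance cannot be negative")
        if kind is StimulusKind.CATCH_TACTILE:
            if self.intensity_mw_mm2 != 0.0:
                raise ValueError("catch (tactile) trials carry no irradiance")
            if self.wavelength_nm is not None:
                raise ValueError("catch trials have no stimulation wavelength")
        else:
            default_wl = 470 if kind is StimulusKind.TARGET_OPTO else 595
            wl = self.wavelength_nm if self.wavelength_nm is not None else default_wl
            object.__setattr__(self, "wavelength_nm", wl)
            lo, hi = INTENSITY_MIN, INTENSITY_MAX
            if not (lo - 1e-9 <= self.intensity_mw_mm2 <= hi + 1e-9):
                raise ValueError(
                    f"optogenetic irradiance {self.intensity_mw_mm2} mW/mm^2 "
                    f"outside the calibrated range [{lo}, {hi}]"
                )

    @property
    def is_target(self) -> bool:
        return self.kind is StimulusKind.TARGET_OPTO

    @property
    def is_catch(self) -> bool:
        return self.kind is StimulusKind.CATCH_TACTILE


@dataclass
class TrialRecord:
    """One behavioral trial: stimulus, timing, responses and SDT outcome.

    Response fields are ``None`` on schedule stubs and are filled by the
    synthetic observer or by ingesting a real trial log.
    """

    trial_index: int
    stimulus: StimulusSpec
    isi_s: float
    response_window_s: float
    licked: Optional[bool] = None
    lick_latency_s: Optional[float] = None
    reflex_score: Optional[int] = None
    reflex_response: Optional[bool] = None
    outcome: Optional[Outcome] = None
    rewarded: bool = False
    premature_lick: bool = False
    consequence: Consequence = Consequence.NONE

    def __post_init__(self) -> None:
        if self.trial_index < 1:
            raise ValueError("trial_index is 1-based")
        if self.reflex_score is not None:
            if self.reflex_score not in (0, 1, 2, 3):
                raise ValueError("reflex_score must be in {0,1,2,3}")
            expected = self.reflex_score in (2, 3)
            if self.reflex_response is None:
                self.reflex_response = expected
            elif self.reflex_response != expected:
                raise ValueError("reflex_response inconsistent with 0-3 score")
        if self.rewarded and self.outcome is not Outcome.HIT:
            raise ValueError("only hit trials can be rewarded")
        if self.outcome is not None:
            on_catch = self.stimulus.is_catch
            catch_outcomes = (Outcome.FALSE_ALARM, Outcome.CORRECT_REJECTION)
            if on_catch != (self.outcome in catch_outcomes):
                raise ValueError(
                    f"outcome {self.outcome.value} inconsistent with "
                    f"stimulus kind {self.stimulus.kind.value}"
                )


@dataclass
class SessionSchedule:
    """An ordered 360-trial (by default) session plan plus its RNG seed."""

    session_id: str
    phase: str
    trials: list[TrialRecord]
    reward_probability: float
    rng_seed: int

    def __post_init__(self) -> None:
        if not (REWARD_FLOOR - 1e-9 <= self.reward_probability <= 1.0 + 1e-9):
            raise ValueError("reward probability must lie in [0.8, 1.0]")

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def default_intensities(
    n: int = 17,
    low: float = INTENSITY_MIN,
    high: float = INTENSITY_MAX,
) -> np.ndarray:
    """The 17 target irradiances, log10-spaced across 0.14-5.45 mW/mm^2.

    Log spacing is the psychophysical convention for a stimulus range
    spanning ~1.6 decades: it concentrates sampling near the detection
    threshold rather than at the saturated top of the psychometric curve.
    """
    return np.logspace(math.log10(low), math.log10(high), n)


def classify_outcome(stimulus: StimulusSpec, licked: bool) -> Outcome:
    """Map (stimulus kind, lick-in-window) to the four SDT outcomes.

    A lick within the response window is a hit on target (or 595 nm
    control) trials and a false alarm on catch trials; absence of a lick
    is a miss or a correct rejection respectively.
    """
    if stimulus.is_catch:
        return Outcome.FALSE_ALARM if licked else Outcome.CORRECT_REJECTION
    return Outcome.HIT if licked else Outcome.MISS


def reward_probability_for_day(day: int, step: float = 0.05) -> float:
    """Reward-chance taper across training days.

    Rewards on hits start certain and are reduced by ``step`` (5-10%)
    each subsequent training day until reaching the 80% floor used for
    all testing sessions.
    """
    if day < 1:
        raise ValueError("training day is 1-based")
    if not (0.05 - 1e-12 <= step <= 0.10 + 1e-12):
        raise ValueError("taper step must lie in [0.05, 0.10]")
    return max(REWARD_FLOOR, 1.0 - (day - 1) * step)


def build_schedule(
    phase: str,
    intensities: Optional[Sequence[float]] = None,
    reps_per_stimulus: int = 20,
    seed: int = 0,
    session_id: Optional[str] = None,
    training_day: int = 1,
    reward_step: float = 0.05,
) -> SessionSchedule:
    """Build a seeded, permuted session schedule.

    Parameters
    ----------
    phase
        ``"testing"``, ``"training"`` or ``"control_595"``.  Control
        sessions reuse the testing geometry with 595 nm stimuli.
    intensities
        Target irradiances in mW/mm^2; defaults to the 17 log-spaced
        values spanning 0.14-5.45.
    reps_per_stimulus
        Repetitions of each target intensity; the same number of catch
        trials is appended, so the default yields 17*20 + 20 = 360 trials.
    seed
        Seeds the trial permutation, the ISIs and (for training) the
        session response window; schedules are bit-reproducible.
    """
    if phase not in ("testing", "training", "control_595"):
        raise ValueError(f"unknown session phase: {phase!r}")
    if reps_per_stimulus < 1:
        raise ValueError("reps_per_stimulus must be >= 1")
    if intensities is None:
        intensities = default_intensities()
    intensities = [float(v) for v in intensities]
    if not intensities:
        raise ValueError("need at least one target intensity")

    target_kind = (
        StimulusKind.CONTROL_OPTO if phase == "control_595" else StimulusKind.TARGET_OPTO
    )
    stimuli = [
        StimulusSpec(kind=target_kind, intensity_mw_mm2=v)
        for v in intensities
        for _ in range(reps_per_stimulus)
    ]
    stimuli += [StimulusSpec(kind=StimulusKind.CATCH_TACTILE)] * reps_per_stimulus

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(stimuli))
    isis = rng.uniform(*ISI_RANGE_S, size=len(stimuli))
    if phase == "training":
        # one response window per training session, drawn in [0.8, 1.5] s
        window = float(rng.uniform(*TRAINING_RESPONSE_WINDOW_RANGE_S))
        reward_p = reward_probability_for_day(training_day, reward_step)
        phase_label = f"training_day_{training_day}"
    else:
        window = TESTING_RESPONSE_WINDOW_S
        reward_p = REWARD_FLOOR
        phase_label = phase

    trials = [
        TrialRecord(
            trial_index=i + 1,
            stimulus=stimuli[j],
            isi_s=float(isis[i]),
            response_window_s=window,
        )
        for i, j in enumerate(order)
    ]
    if session_id is None:
        session_id = f"{phase_label}_seed{seed}"
    return SessionSchedule(
        session_id=session_id,
        phase=phase_label,
        trials=trials,
        reward_probability=reward_p,
        rng_seed=seed,
    )


def apply_consequences(trial: TrialRecord) -> TrialRecord:
    """Attach the task's programmed consequence to a classified trial.

    Misses trigger up to 10 extra stimuli (100 ms ISI); false alarms
    trigger up to 10 warning pulses at the maximal irradiance; a lick
    before stimulus onset yields a timeout lasting the trial's ISI.
    Reward eligibility on hits is decided by the session engine with the
    session reward probability and is not modified here.
    """
    if trial.outcome is None:
        raise ValueError("classify the trial outcome before applying consequences")
    if trial.premature_lick:
        consequence = Consequence.TIMEOUT
    elif trial.outcome is Outcome.MISS:
        consequence = Consequence.EXTRA_STIMULI
    elif trial.outcome is Outcome.FALSE_ALARM:
        consequence = Consequence.WARNING_PULSES
    else:
        consequence = Consequence.NONE
    return replace(trial, consequence=consequence)
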