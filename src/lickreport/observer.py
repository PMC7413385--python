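"""Generative signal-detection observer standing in for the behaving mouse.

The observer is an equal-variance Gaussian SDT model with two coupled
response channels:

* a *lick* channel (the learned self-report) whose decision criterion may
  drift linearly within a session, mimicking the conservativeness that
  accrues as the animal becomes sated, and
* a *reflex* channel (the hind-quarter withdrawal) with a static criterion.

On each trial both channels observe the stimulus evidence ``delta(I)``
(the reflex channel with an additive sensitivity boost, see
:class:`ObserverParams`) corrupted by noise that is partially shared
between channels::

    lick   evidence = delta(I)     + sqrt(rho) * shared + sqrt(1 - rho) * e_lick
    reflex evidence = delta_r(I)   + sqrt(rho) * shared + sqrt(1 - rho) * e_reflex

with ``shared``, ``e_lick``, ``e_reflex`` independent standard normals,
so each marginal evidence is N(delta, 1) and the two channels have
correlation ``rho``.  The sensitivity map is piecewise linear in log10
irradiance with saturation:

    delta(I) = clip(gain * (log10 I - origin), 0, d_max)

Catch (tactile) trials and 595 nm control stimuli carry no optogenetic
drive: delta = 0 on both channels, so responses there are pure false
alarms governed by the criteria alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .session import (
    Outcome,
    SessionSchedule,
    StimulusKind,
    StimulusSpec,
    TrialRecord,
    apply_consequences,
    build_schedule,
    classify_outcome,
)

__all__ = [
    "ObserverParams",
    "simulate_trial",
    "simulate_session",
    "simulate_cohort",
    "simulate_training_curve",
    "apply_manipulation",
    "criterion_for_response_probability",
    "calibrate_hit_probability",
    "DEFAULT_OBSERVER",
]


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of the generative SDT mouse.

    Attributes
    ----------
    sensitivity_gain
        d' units gained per decade of irradiance above ``sensitivity_origin``.
    sensitivity_origin
        log10 irradiance (mW/mm^2) at which sensitivity departs from zero.
    sensitivity_max
        Saturating sensitivity; 3.0 puts the top intensities well past
        the criterion so the asymptotic hit rate exceeds 90%.
    lick_criterion_start, lick_criterion_drift
        Intercept c0 and per-trial slope beta of the lick criterion
        c(t) = c0 + beta * t; beta > 0 reproduces the within-session
        increase in lick response bias.
    reflex_criterion
        Static criterion of the withdrawal channel.
    channel_correlation
        rho in [0, 1]: weight of the noise shared between channels.
    reflex_sensitivity_boost
        Extra d' added to the reflex channel's target-trial evidence.
        The withdrawal circuit pairs a conservative criterion with a
        higher sensitivity: behaving cohorts show reflex d' above lick
        d' while hit rates match, which under equal-variance SDT
        requires the reflex evidence to sit higher by about the
        criterion gap.  The default 0.528 equals the gap between the
        reflex criterion (1.028) and the session-mean lick criterion
        (0.5), making expected hit rates identical across channels
        while false-alarm rates differ.
    lapse_rate
        Probability of a stimulus-independent attentional lapse on
        target trials, forcing no response on *both* channels (the
        animal disengages, not one effector); never applied to catch
        trials.
    """

    sensitivity_gain: float = 3.5
    sensitivity_origin: float = -0.97
    sensitivity_max: float = 3.0
    lick_criterion_start: float = 0.5
    lick_criterion_drift: float = 0.0
    reflex_criterion: float = 1.028
    channel_correlation: float = 0.6
    reflex_sensitivity_boost: float = 0.528
    lapse_rate: float = 0.02
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sensitivity_gain < 0 or self.sensitivity_max < 0:
            raise ValueError("sensitivity gain and ceiling must be nonnegative")
        if not 0.0 <= self.channel_correlation <= 1.0:
            raise ValueError("channel_correlation must lie in [0, 1]")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must lie in [0, 0.1]")
        if self.lick_criterion_drift < 0:
            raise ValueError("criterion drift must be >= 0")

    def sensitivity(self, stimulus: StimulusSpec) -> float:
        """delta(I): nondecreasing, saturating map from irradiance to d'."""
        if not stimulus.is_target or stimulus.intensity_mw_mm2 <= 0:
            return 0.0
        raw = self.sensitivity_gain * (
            math.log10(stimulus.intensity_mw_mm2) - self.sensitivity_origin
        )
        return float(min(self.sensitivity_max, max(0.0, raw)))

    def lick_criterion(self, trial_index: int) -> float:
        return self.lick_criterion_start + self.lick_criterion_drift * trial_index


#: Observer used throughout the examples and the qualitative test suite.
#: The lick criterion climbs by ~0.8 over a 360-trial session; its start
#: is chosen so the criterion at mid-session is 0.5, making the expected
#: session-mean lick false-alarm rate Phi(-0.5) ~ 31%, and the static
#: reflex criterion gives Phi(-1.028) ~ 15% — the session-mean rates
#: observed in the behavioral cohort.
DEFAULT_OBSERVER = ObserverParams(
    lick_criterion_start=0.1,
    lick_criterion_drift=0.8 / 360.0,
)


def criterion_for_response_probability(p: float) -> float:
    """Criterion c such that a delta=0 channel responds with probability p.

    With unit-variance evidence, P(respond | no signal) = Phi(-c), so
    c = -Phi^-1(p).  Used to pin an observer's catch-trial (false alarm)
    rate to an empirical session mean.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("response probability must lie strictly in (0, 1)")
    return float(-norm.ppf(p))


def calibrate_hit_probability(
    params: ObserverParams, intensity_mw_mm2: float, p_hit: float
) -> ObserverParams:
    """Return params whose hit probability at one intensity equals ``p_hit``.

    Solves delta(I) = c0 + Phi^-1(p_hit / (1 - lapse)) by rescaling the
    sensitivity gain (drift must be zero, since a drifting criterion has
    no single hit probability).  Raises if the requested probability is
    unreachable given the lapse rate.
    """
    if params.lick_criterion_drift != 0:
        raise ValueError("calibration requires a drift-free criterion")
    effective = p_hit / (1.0 - params.lapse_rate)
    if not 0.0 < effective < 1.0:
        raise ValueError("requested hit probability unreachable at this lapse rate")
    delta = params.lick_criterion_start + float(norm.ppf(effective))
    span = math.log10(intensity_mw_mm2) - params.sensitivity_origin
    if span <= 0:
        raise ValueError("intensity at or below the sensitivity origin")
    gain = max(0.0, delta) / span
    return replace(
        params,
        sensitivity_gain=gain,
        sensitivity_max=max(params.sensitivity_max, delta),
    )


def _evidence(
    delta: float, rho: float, shared: float, own: float
) -> float:
    return delta + math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * own


def simulate_trial(
    params: ObserverParams,
    stimulus: StimulusSpec,
    trial_index: int,
    rng: Optional[np.random.Generator] = None,
) -> tuple[bool, bool]:
    """Simulate one trial; returns (licked, reflex_response).

    The lick channel compares its evidence with the drifting criterion
    c(t); the reflex channel uses its static criterion and its
    sensitivity boost.  An attentional lapse (target trials only)
    forces no response on both channels regardless of evidence.
    """
    if trial_index < 1:
        raise ValueError("trial_index is 1-based")
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    delta = params.sensitivity(stimulus)
    delta_reflex = delta + params.reflex_sensitivity_boost if delta > 0 else delta
    rho = params.channel_correlation
    shared, e_lick, e_reflex = rng.standard_normal(3)
    licked = _evidence(delta, rho, shared, e_lick) > params.lick_criterion(trial_index)
    reflex = _evidence(delta_reflex, rho, shared, e_reflex) > params.reflex_criterion
    if stimulus.is_target and rng.random() < params.lapse_rate:
        licked = False
        reflex = False
    return bool(licked), bool(reflex)


def simulate_session(
    params: ObserverParams, schedule: SessionSchedule
) -> list[TrialRecord]:
    """Fill every scheduled trial with simulated responses and outcomes.

    Deterministic given ``(params.rng_seed, schedule.rng_seed)``.  Lick
    latencies on lick trials are drawn uniformly inside the response
    window; reflex scores are drawn as 2/3 for responses and 0/1
    otherwise.  Rewards on hits are Bernoulli draws at the session
    reward probability.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=(params.rng_seed, schedule.rng_seed))
    )
    records: list[TrialRecord] = []
    for stub in schedule.trials:
        licked, reflex = simulate_trial(params, stub.stimulus, stub.trial_index, rng)
        outcome = classify_outcome(stub.stimulus, licked)
        rewarded = bool(
            outcome is Outcome.HIT and rng.random() < schedule.reward_probability
        )
        latency = (
            float(rng.uniform(0.05, stub.response_window_s)) if licked else None
        )
        score = int(rng.integers(2, 4)) if reflex else int(rng.integers(0, 2))
        trial = TrialRecord(
            trial_index=stub.trial_index,
            stimulus=stub.stimulus,
            isi_s=stub.isi_s,
            response_window_s=stub.response_window_s,
            licked=licked,
            lick_latency_s=latency,
            reflex_score=score,
            reflex_response=reflex,
            outcome=outcome,
            rewarded=rewarded,
        )
        records.append(apply_consequences(trial))
    return records


def simulate_cohort(
    params_per_mouse: Sequence[ObserverParams],
    sessions_per_mouse: int = 8,
    seed: int = 0,
    phase: str = "testing",
    intensities: Optional[Sequence[float]] = None,
    reps_per_stimulus: int = 20,
) -> list[tuple[SessionSchedule, list[TrialRecord]]]:
    """Simulate a cohort: the default 5 observers x 8 sessions = 40 logs.

    Every session gets distinct schedule and observer seeds derived from
    ``seed``, so the cohort is reproducible from a single integer.
    """
    if not params_per_mouse:
        raise ValueError("need at least one observer")
    if sessions_per_mouse < 1:
        raise ValueError("sessions_per_mouse must be >= 1")
    master = np.random.default_rng(seed)
    out: list[tuple[SessionSchedule, list[TrialRecord]]] = []
    for m, base in enumerate(params_per_mouse):
        for s in range(sessions_per_mouse):
            sched_seed = int(master.integers(0, 2**31))
            obs_seed = int(master.integers(0, 2**31))
            schedule = build_schedule(
                phase,
                intensities=intensities,
                reps_per_stimulus=reps_per_stimulus,
                seed=sched_seed,
                session_id=f"mouse{m + 1}_session{s + 1}",
            )
            params = replace(base, rng_seed=obs_seed)
            out.append((schedule, simulate_session(params, schedule)))
    return out


def simulate_training_curve(
    params: ObserverParams,
    n_days: int,
    learning_rate: float = 0.2,
    initial_gain_fraction: float = 0.15,
    initial_criterion_excess: float = 1.0,
    reps_per_stimulus: int = 20,
) -> list[float]:
    """Percent-correct per simulated training day under exponential learning.

    Sensitivity gain and the lick criterion relax exponentially toward
    their asymptotic (trained) values::

        gain(d) = g_inf - (g_inf - g_0) * exp(-r * (d - 1))
        c0(d)   = c_inf + (c_0 - c_inf) * exp(-r * (d - 1))

    ``learning_rate = 0`` freezes day-1 performance.  Percent correct is
    (hits + correct rejections) / trials over a full training session.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if learning_rate < 0:
        raise ValueError("learning_rate must be >= 0")
    g_inf = params.sensitivity_gain
    g0 = initial_gain_fraction * g_inf
    c_inf = params.lick_criterion_start
    c0 = c_inf + initial_criterion_excess
    curve: list[float] = []
    for day in range(1, n_days + 1):
        decay = math.exp(-learning_rate * (day - 1))
        day_params = replace(
            params,
            sensitivity_gain=g_inf - (g_inf - g0) * decay,
            lick_criterion_start=c_inf + (c0 - c_inf) * decay,
            rng_seed=params.rng_seed + day,
        )
        schedule = build_schedule(
            "training",
            reps_per_stimulus=reps_per_stimulus,
            seed=params.rng_seed * 1000 + day,
            training_day=day,
        )
        trials = simulate_session(day_params, schedule)
        correct = sum(
            t.outcome in (Outcome.HIT, Outcome.CORRECT_REJECTION) for t in trials
        )
        curve.append(100.0 * correct / len(trials))
    return curve


def apply_manipulation(params: ObserverParams, manipulation: str) -> ObserverParams:
    """Pharmacological manipulations of the simulated paw.

    ``"lidocaine"`` (intraplantar local anesthetic) abolishes afferent
    drive: delta(I) = 0 for every intensity, collapsing the hit rate to
    the false-alarm floor.  ``"saline_control"`` leaves the observer
    unchanged.
    """
    if manipulation == "lidocaine":
        return replace(params, sensitivity_gain=0.0, sensitivity_max=0.0)
    if manipulation == "saline_control":
        return replace(params)
    raise ValueError(f"unknown manipulation: {manipulation!r}")
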