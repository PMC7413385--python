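"""Sensitivity (d') and response bias (criterion) under equal-variance SDT.

Both statistics are computed from hit and false-alarm rates with a small
offset that prevents the normal quantile from saturating at rates of
exactly 0 or 1::

    d'        = Z(hit rate - offset) - Z(false alarm rate + offset)
    criterion = -(Z(hit rate - offset) + Z(false alarm rate + offset)) / 2

where Z is the standard-normal quantile function and offset = 0.001 by
default.  Adjusted rates are clamped into [offset, 1 - offset] before Z:
the raw offset arithmetic still produces infinities when a rate sits at
the "wrong" corner (e.g. hit rate 0), and clamping reproduces the
intended saturation behavior at both corners.

The module also provides the 50-trial sliding-window series used to
track within-session criterion drift, and the session-inclusion rule
(d' > 1.0 over the first 250 trials and over the whole session).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .session import Outcome, TrialRecord, classify_outcome

__all__ = [
    "SdtParams",
    "SdtRecord",
    "SdtSeries",
    "FaSource",
    "UndefinedRateError",
    "rates",
    "dprime",
    "criterion",
    "sliding_series",
    "passes_inclusion",
]


class UndefinedRateError(ValueError):
    """Raised when a hit or false-alarm rate has an empty denominator."""


class FaSource(str, Enum):
    IN_WINDOW = "in_window"
    FALLBACK_SESSION = "fallback_session"


@dataclass(frozen=True)
class SdtParams:
    offset: float = 0.001
    window_trials: int = 50
    inclusion_dprime: float = 1.0
    inclusion_span_trials: int = 250

    def __post_init__(self) -> None:
        if not 0.0 < self.offset < 0.5:
            raise ValueError("offset must lie in (0, 0.5)")
        if self.window_trials < 2:
            raise ValueError("window_trials must be >= 2")


@dataclass(frozen=True)
class SdtRecord:
    trial_index: int
    hit_rate: float
    fa_rate: float
    dprime: float
    criterion: float
    fa_source: FaSource


@dataclass
class SdtSeries:
    """Per-trial sliding-window d'/criterion plus session-level values."""

    records: list[SdtRecord]
    session_dprime: float
    session_criterion: float
    params: SdtParams = field(default_factory=SdtParams)

    def __len__(self) -> int:
        return len(self.records)

    def column(self, name: str) -> np.ndarray:
        return np.asarray([getattr(r, name) for r in self.records], dtype=float)


def _channel_outcome(trial: TrialRecord, channel: str) -> Outcome:
    if channel == "lick":
        if trial.outcome is not None:
            return trial.outcome
        if trial.licked is None:
            raise ValueError("trial has no lick response")
        return classify_outcome(trial.stimulus, trial.licked)
    if channel == "reflex":
        if trial.reflex_response is None:
            raise ValueError("trial has no reflex response")
        return classify_outcome(trial.stimulus, trial.reflex_response)
    raise ValueError(f"unknown response channel: {channel!r}")


def _counts(outcomes: Sequence[Outcome]) -> tuple[int, int, int, int]:
    hits = sum(o is Outcome.HIT for o in outcomes)
    targets = hits + sum(o is Outcome.MISS for o in outcomes)
    fas = sum(o is Outcome.FALSE_ALARM for o in outcomes)
    catches = fas + sum(o is Outcome.CORRECT_REJECTION for o in outcomes)
    return hits, targets, fas, catches


def rates(
    trials: Sequence[TrialRecord], channel: str = "lick"
) -> tuple[float, float]:
    """(hit rate, false-alarm rate) = (hits/targets, false alarms/catches)."""
    outcomes = [_channel_outcome(t, channel) for t in trials]
    hits, targets, fas, catches = _counts(outcomes)
    if targets == 0:
        raise UndefinedRateError("no target trials: hit rate undefined")
    if catches == 0:
        raise UndefinedRateError("no catch trials: false-alarm rate undefined")
    return hits / targets, fas / catches


def _adjust(rate: float, offset: float, sign: int) -> float:
    # add/subtract the offset, then clamp into [offset, 1 - offset]
    return float(np.clip(rate + sign * offset, offset, 1.0 - offset))


def dprime(hit_rate: float, fa_rate: float, offset: float = 0.001) -> float:
    """Z(hit - offset) - Z(fa + offset), clamped to avoid saturation."""
    _validate_rates(hit_rate, fa_rate, offset)
    return float(
        norm.ppf(_adjust(hit_rate, offset, -1)) - norm.ppf(_adjust(fa_rate, offset, +1))
    )


def criterion(hit_rate: float, fa_rate: float, offset: float = 0.001) -> float:
    """-(Z(hit - offset) + Z(fa + offset)) / 2; positive = conservative."""
    _validate_rates(hit_rate, fa_rate, offset)
    return float(
        -(norm.ppf(_adjust(hit_rate, offset, -1)) + norm.ppf(_adjust(fa_rate, offset, +1)))
        / 2.0
    )


def _validate_rates(hit_rate: float, fa_rate: float, offset: float) -> None:
    if not 0.0 < offset < 0.5:
        raise ValueError("offset must lie in (0, 0.5)")
    if not (0.0 <= hit_rate <= 1.0 and 0.0 <= fa_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")


def sliding_series(
    trials: Sequence[TrialRecord],
    params: SdtParams = SdtParams(),
    channel: str = "lick",
) -> SdtSeries:
    """Trailing sliding-window d'/criterion series, one record per trial.

    Windows of ``params.window_trials`` end at each trial from the
    window size through the last trial (series length n - w + 1).  Hit
    rate uses the target trials inside the window.  With 20 catch trials
    in 360, many 50-trial windows contain few or no catches; a window
    with no catch trial falls back to the running session false-alarm
    rate up to that trial (the full-session rate if no catch has
    occurred yet), and ``fa_source`` records which convention fed each
    record so the two can be compared downstream.
    """
    n = len(trials)
    w = params.window_trials
    if n < w:
        raise ValueError(f"need at least window_trials={w} trials, got {n}")
    outcomes = [_channel_outcome(t, channel) for t in trials]
    is_hit = np.array([o is Outcome.HIT for o in outcomes], dtype=int)
    is_target = np.array(
        [o in (Outcome.HIT, Outcome.MISS) for o in outcomes], dtype=int
    )
    is_fa = np.array([o is Outcome.FALSE_ALARM for o in outcomes], dtype=int)
    is_catch = np.array(
        [o in (Outcome.FALSE_ALARM, Outcome.CORRECT_REJECTION) for o in outcomes],
        dtype=int,
    )
    if is_catch.sum() == 0:
        raise UndefinedRateError("session contains no catch trials")
    if is_target.sum() == 0:
        raise UndefinedRateError("session contains no target trials")

    cum_hit = np.concatenate([[0], np.cumsum(is_hit)])
    cum_target = np.concatenate([[0], np.cumsum(is_target)])
    cum_fa = np.concatenate([[0], np.cumsum(is_fa)])
    cum_catch = np.concatenate([[0], np.cumsum(is_catch)])

    session_fa = cum_fa[-1] / cum_catch[-1]
    records: list[SdtRecord] = []
    for end in range(w, n + 1):  # window covers trials [end - w + 1, end]
        start = end - w
        targets = cum_target[end] - cum_target[start]
        hits = cum_hit[end] - cum_hit[start]
        if targets == 0:
            raise UndefinedRateError(
                f"window ending at trial {end} contains no target trials"
            )
        hit_rate = hits / targets
        catches = cum_catch[end] - cum_catch[start]
        if catches > 0:
            fa_rate = (cum_fa[end] - cum_fa[start]) / catches
            source = FaSource.IN_WINDOW
        else:
            running_catch = cum_catch[end]
            fa_rate = cum_fa[end] / running_catch if running_catch else session_fa
            source = FaSource.FALLBACK_SESSION
        records.append(
            SdtRecord(
                trial_index=trials[end - 1].trial_index,
                hit_rate=float(hit_rate),
                fa_rate=float(fa_rate),
                dprime=dprime(hit_rate, fa_rate, params.offset),
                criterion=criterion(hit_rate, fa_rate, params.offset),
                fa_source=source,
            )
        )
    sess_hit, sess_fa_rate = rates(trials, channel)
    return SdtSeries(
        records=records,
        session_dprime=dprime(sess_hit, sess_fa_rate, params.offset),
        session_criterion=criterion(sess_hit, sess_fa_rate, params.offset),
        params=params,
    )


def passes_inclusion(
    trials: Sequence[TrialRecord],
    params: SdtParams = SdtParams(),
    channel: str = "lick",
) -> bool:
    """Session-inclusion rule: d' above threshold over the first 250
    trials AND over the whole session (both strict)."""
    span = params.inclusion_span_trials
    if len(trials) < span:
        raise ValueError(f"inclusion rule needs at least {span} trials")
    early = dprime(*rates(trials[:span], channel), params.offset)
    overall = dprime(*rates(trials, channel), params.offset)
    return early > params.inclusion_dprime and overall > params.inclusion_dprime
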