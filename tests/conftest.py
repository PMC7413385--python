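import numpy as np
import pytest

import lickreport as lr
from lickreport.session import StimulusKind, StimulusSpec, TrialRecord, classify_outcome

TARGET = StimulusSpec(kind=StimulusKind.TARGET_OPTO, intensity_mw_mm2=1.0)
CATCH = StimulusSpec(kind=StimulusKind.CATCH_TACTILE)


def make_trials(flags):
    """Build classified trials from (is_target, responded) pairs.

    The response is stored on both channels so SDT helpers can consume
    either one.
    """
    trials = []
    for i, (is_target, responded) in enumerate(flags, start=1):
        stim = TARGET if is_target else CATCH
        trials.append(
            TrialRecord(
                trial_index=i,
                stimulus=stim,
                isi_s=4.0,
                response_window_s=1.0,
                licked=responded,
                reflex_response=responded,
                outcome=classify_outcome(stim, responded),
            )
        )
    return trials


@pytest.fixture(scope="session")
def testing_schedule():
    return lr.build_schedule("testing", seed=7)


@pytest.fixture(scope="session")
def default_session(testing_schedule):
    from dataclasses import replace

    params = replace(lr.DEFAULT_OBSERVER, rng_seed=101)
    return lr.simulate_session(params, testing_schedule)


@pytest.fixture(scope="session")
def default_cohort():
    """40 simulated sessions (5 observers x 8 sessions) at default params."""
    return lr.simulate_cohort([lr.DEFAULT_OBSERVER] * 5, 8, seed=1)


@pytest.fixture(scope="session")
def default_report(default_cohort):
    """Full analysis report for the default cohort (computed once)."""
    from lickreport.reporting import analyze_cohort

    return analyze_cohort([(s.session_id, t) for s, t in default_cohort])
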