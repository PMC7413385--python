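"""Trial-by-trial similarity between lick and reflex responses.

For each stimulus intensity within a session (20 trials per intensity)
the two binary response vectors are compared with the Euclidean
distance

    sqrt( sum_i (lick_i - reflex_i)^2 )

which for 0/1 vectors equals the square root of the number of
disagreeing trials (the Hamming distance).  Reference lines mark the
distance the channels would show if they agreed on 95% (19/20 trials,
distance 1) or 50% (10/20 trials, distance sqrt(10) ~ 3.16) of trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .session import TrialRecord

__all__ = [
    "SimilarityProfile",
    "euclidean_distance",
    "similarity_reference",
    "session_distances",
    "profile_across_sessions",
]


def euclidean_distance(lick: Sequence[int], reflex: Sequence[int]) -> float:
    """Euclidean distance between two equal-length binary response vectors."""
    a = np.asarray(lick, dtype=float)
    b = np.asarray(reflex, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("response vectors must be 1-D and of equal length")
    for v in (a, b):
        if not np.all(np.isin(v, (0.0, 1.0))):
            raise ValueError("response vectors must be binary (0/1)")
    return float(np.linalg.norm(a - b))


def similarity_reference(n_trials: int, agree_fraction: float) -> float:
    """Distance when the channels agree on a given fraction of trials.

    sqrt(n - round(f * n)): for 20 trials, 95% agreement (19 trials)
    gives 1.0 and 50% agreement (10 trials) gives sqrt(10).
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if not 0.0 <= agree_fraction <= 1.0:
        raise ValueError("agree_fraction must lie in [0, 1]")
    return float(np.sqrt(n_trials - round(agree_fraction * n_trials)))


def session_distances(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Per-intensity lick-vs-reflex distance for one session.

    Vectors are ordered by trial occurrence (the metric is order
    invariant, but the ordering fixes the contract).  Intensities with
    any missing reflex annotation are omitted with a warning column.
    Catch trials are excluded: similarity is defined over the target
    intensities.
    """
    rows = []
    by_intensity: dict[float, list[TrialRecord]] = {}
    for t in trials:
        if t.stimulus.is_catch:
            continue
        by_intensity.setdefault(t.stimulus.intensity_mw_mm2, []).append(t)
    for intensity in sorted(by_intensity):
        group = sorted(by_intensity[intensity], key=lambda t: t.trial_index)
        if any(t.licked is None or t.reflex_response is None for t in group):
            import warnings

            warnings.warn(
                f"intensity {intensity:g}: missing lick/reflex annotation, cell omitted",
                stacklevel=2,
            )
            continue
        lick = [int(bool(t.licked)) for t in group]
        reflex = [int(bool(t.reflex_response)) for t in group]
        rows.append(
            {
                "intensity_mw_mm2": intensity,
                "distance": euclidean_distance(lick, reflex),
                "n_trials": len(group),
            }
        )
    return pd.DataFrame(rows, columns=["intensity_mw_mm2", "distance", "n_trials"])


@dataclass
class SimilarityProfile:
    """Per-intensity distances across sessions with bootstrap CIs."""

    distances: pd.DataFrame  # columns: session_id, intensity_mw_mm2, distance, n_trials
    summary: pd.DataFrame  # columns: intensity_mw_mm2, mean, ci_low, ci_high, n_sessions
    reference_95: float
    reference_50: float

    @property
    def intensities(self) -> np.ndarray:
        return self.summary["intensity_mw_mm2"].to_numpy()


def profile_across_sessions(
    session_logs: Sequence[tuple[str, Sequence[TrialRecord]]],
    n_bootstrap: int = 10_000,
    ci: float = 0.95,
    seed: int = 0,
    n_trials_reference: Optional[int] = None,
) -> SimilarityProfile:
    """Distance profile over a cohort of sessions.

    Parameters
    ----------
    session_logs
        Pairs of (session_id, completed trial list).
    n_bootstrap, ci, seed
        Percentile bootstrap of the per-intensity mean across sessions
        (resampling sessions with replacement, seeded).
    n_trials_reference
        Trials per intensity used for the 95%/50% reference lines;
        defaults to the modal per-intensity trial count in the data.
    """
    if not session_logs:
        raise ValueError("no sessions supplied")
    frames = []
    for session_id, trials in session_logs:
        df = session_distances(trials)
        df.insert(0, "session_id", session_id)
        frames.append(df)
    distances = pd.concat(frames, ignore_index=True)
    if distances.empty:
        raise ValueError("no per-intensity distances could be computed")

    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci) / 2.0
    rows = []
    for intensity, group in distances.groupby("intensity_mw_mm2"):
        vals = group["distance"].to_numpy()
        idx = rng.integers(0, len(vals), size=(n_bootstrap, len(vals)))
        boot_means = vals[idx].mean(axis=1)
        rows.append(
            {
                "intensity_mw_mm2": float(intensity),
                "mean": float(vals.mean()),
                "ci_low": float(np.quantile(boot_means, alpha)),
                "ci_high": float(np.quantile(boot_means, 1.0 - alpha)),
                "n_sessions": len(vals),
            }
        )
    summary = pd.DataFrame(rows).sort_values("intensity_mw_mm2", ignore_index=True)
    if n_trials_reference is None:
        n_trials_reference = int(distances["n_trials"].mode().iloc[0])
    return SimilarityProfile(
        distances=distances,
        summary=summary,
        reference_95=similarity_reference(n_trials_reference, 0.95),
        reference_50=similarity_reference(n_trials_reference, 0.50),
    )
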