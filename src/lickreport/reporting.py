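"""End-to-end driver: simulate a cohort, analyze it, report the panels.

``simulate_to_files`` writes one trial-log CSV per session plus a
manifest; ``analyze_cohort`` runs the whole analysis stack (SDT series
and inclusion rule, psychometric fits for both channels, similarity
profile, rank-test comparison table) and returns a JSON-serializable
report.  All randomness is seeded through the config, so identical
configs produce identical reports.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import psychometric, sdt, similarity, stats
from .io import RunConfig, read_trial_log, trials_to_frame, write_trial_log
from .observer import simulate_cohort
from .session import Outcome, TrialRecord

__all__ = [
    "simulate_to_files",
    "analyze_cohort",
    "ingest_video_scores",
    "VIDEO_EPOCH_BOUNDS_MS",
]

PathLike = Union[str, Path]

#: Video scoring epoch relative to stimulus onset (pre, post) in ms.
VIDEO_EPOCH_BOUNDS_MS = (-250.0, 500.0)


def _cohort(config: RunConfig):
    params = [replace(config.observer) for _ in range(config.n_mice)]
    return simulate_cohort(
        params, sessions_per_mouse=config.sessions_per_mouse, seed=config.seed
    )


def simulate_to_files(config: RunConfig, out_dir: Optional[PathLike] = None) -> Path:
    """Simulate the configured cohort and write per-session trial logs.

    Returns the output directory; a ``manifest.json`` lists every file
    with its session id and the config that produced it.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for schedule, trials in _cohort(config):
        fname = f"{schedule.session_id}.csv"
        write_trial_log(out / fname, trials, session_id=schedule.session_id, phase=schedule.phase)
        entries.append(
            {
                "file": fname,
                "session_id": schedule.session_id,
                "phase": schedule.phase,
                "n_trials": len(trials),
                "schedule_seed": schedule.rng_seed,
            }
        )
    manifest = {"config": json.loads(config.to_json()), "sessions": entries}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return out


def _per_intensity_counts(
    sessions: Sequence[Sequence[TrialRecord]], channel: str
) -> list[tuple[float, int, int]]:
    counts: dict[float, list[int]] = {}
    for trials in sessions:
        for t in trials:
            if t.stimulus.is_catch:
                continue
            responded = t.licked if channel == "lick" else t.reflex_response
            n_k = counts.setdefault(t.stimulus.intensity_mw_mm2, [0, 0])
            n_k[0] += 1
            n_k[1] += int(bool(responded))
    return [(i, nk[0], nk[1]) for i, nk in sorted(counts.items())]


def analyze_cohort(
    session_logs: Sequence[tuple[str, Sequence[TrialRecord]]],
    config: Optional[RunConfig] = None,
) -> dict:
    """Full behavioral analysis of a cohort of completed sessions.

    Applies the d' > 1.0 inclusion rule, computes per-session SDT
    summaries and sliding series for the lick and reflex channels,
    pooled psychometric fits with thresholds and the near-threshold
    band, the lick-vs-reflex similarity profile against the 95%/50%
    reference lines, and the rank-test comparison table.
    """
    if not session_logs:
        raise ValueError("no sessions to analyze")
    config = config or RunConfig()
    params = config.sdt

    included, excluded = [], []
    for session_id, trials in session_logs:
        trials = list(trials)
        if len(trials) >= params.inclusion_span_trials and sdt.passes_inclusion(
            trials, params
        ):
            included.append((session_id, trials))
        else:
            excluded.append(session_id)
    if not included:
        raise ValueError("every session failed the d' inclusion rule")

    per_session = []
    drift_slopes = {"lick": [], "reflex": []}
    for session_id, trials in included:
        row = {"session_id": session_id, "n_trials": len(trials)}
        for channel in ("lick", "reflex"):
            hit, fa = sdt.rates(trials, channel)
            series = sdt.sliding_series(trials, params, channel)
            crit = series.column("criterion")
            xs = np.arange(len(crit))
            slope = float(np.polyfit(xs, crit, 1)[0]) if len(crit) > 1 else 0.0
            drift_slopes[channel].append(slope)
            row.update(
                {
                    f"{channel}_hit_rate": hit,
                    f"{channel}_fa_rate": fa,
                    f"{channel}_dprime": series.session_dprime,
                    f"{channel}_criterion": series.session_criterion,
                    f"{channel}_criterion_slope_per_trial": slope,
                }
            )
        per_session.append(row)
    sess_df = pd.DataFrame(per_session)

    fits = {}
    thresholds = {}
    sessions_only = [t for _, t in included]
    fa_means = {
        "lick": float(sess_df["lick_fa_rate"].mean()),
        "reflex": float(sess_df["reflex_fa_rate"].mean()),
    }
    for channel in ("lick", "reflex"):
        counts = _per_intensity_counts(sessions_only, channel)
        fit = psychometric.fit_psychometric(counts, fa_rate=fa_means[channel])
        fits[channel] = fit
        thresholds[channel] = None if fit.degenerate else fit.threshold_mw_mm2
    band = psychometric.near_threshold_band(
        fits["lick"], low=config.band_low, high=config.band_high
    )

    profile = similarity.profile_across_sessions(
        included, n_bootstrap=config.bootstrap_resamples, seed=config.seed
    )

    comparisons = [
        stats.paired_rank_compare(
            sess_df["lick_fa_rate"], sess_df["reflex_fa_rate"], "fa_lick_vs_reflex"
        ),
        stats.paired_rank_compare(
            sess_df["lick_dprime"], sess_df["reflex_dprime"], "dprime_lick_vs_reflex"
        ),
        stats.paired_rank_compare(
            sess_df["lick_criterion"],
            sess_df["reflex_criterion"],
            "criterion_lick_vs_reflex",
        ),
    ]

    report = {
        "n_sessions_included": len(included),
        "excluded_sessions": sorted(excluded),
        "per_session": sess_df.to_dict(orient="records"),
        "mean_rates": {
            "lick_hit_rate": float(sess_df["lick_hit_rate"].mean()),
            "reflex_hit_rate": float(sess_df["reflex_hit_rate"].mean()),
            "lick_fa_rate": fa_means["lick"],
            "reflex_fa_rate": fa_means["reflex"],
        },
        "criterion_drift_slope_mean": {
            k: float(np.mean(v)) for k, v in drift_slopes.items()
        },
        "psychometric": {
            channel: {
                "location_mu": fit.location_mu,
                "spread_sigma": fit.spread_sigma,
                "guess_gamma": fit.guess_gamma,
                "lapse_lambda": fit.lapse_lambda,
                "threshold_mw_mm2": thresholds[channel],
                "fa_reference": fit.fa_reference,
                "degenerate": fit.degenerate,
            }
            for channel, fit in fits.items()
        },
        "near_threshold_band": list(band.member_intensities),
        "similarity": {
            "summary": profile.summary.to_dict(orient="records"),
            "reference_95": profile.reference_95,
            "reference_50": profile.reference_50,
        },
        "comparisons": [
            {
                "comparison_id": c.comparison_id,
                "statistic": c.statistic,
                "p_value": c.p_value,
                "alpha": c.alpha,
                "n_comparisons": c.n_comparisons,
                "corrected_alpha": c.corrected_alpha,
                "significant": c.significant,
                "note": c.note,
            }
            for c in comparisons
        ],
    }
    return report


def analyze_files(
    paths: Sequence[PathLike], config: Optional[RunConfig] = None
) -> dict:
    """Read trial-log CSVs and run :func:`analyze_cohort` on them."""
    if not paths:
        raise ValueError("no trial logs supplied")
    logs = [(Path(p).stem, read_trial_log(p)) for p in paths]
    return analyze_cohort(logs, config)


def ingest_video_scores(
    trials: Sequence[TrialRecord],
    scores: pd.DataFrame,
    session_id: str = "",
) -> list[TrialRecord]:
    """Merge 0-3 video reflex scores into a trial log.

    ``scores`` needs columns ``trial_index`` and ``score``; multiple
    rows per trial (several blinded observers) are reconciled by
    majority vote on the response/no-response grouping, ties resolving
    to no-response.  Scores of 2 or 3 count as a withdrawal response,
    0 or 1 as none.  The scoring epoch bounds (-250/+500 ms around
    stimulus onset) are recorded in the returned metadata convention via
    :data:`VIDEO_EPOCH_BOUNDS_MS`.
    """
    if not {"trial_index", "score"} <= set(scores.columns):
        raise ValueError("score table needs columns trial_index, score")
    bad = scores[~scores["score"].isin([0, 1, 2, 3])]
    if not bad.empty:
        raise ValueError(
            f"scores outside 0-3 at rows {bad.index.tolist()}"
        )
    by_trial = {int(t.trial_index): t for t in trials}
    unknown = sorted(set(scores["trial_index"].astype(int)) - set(by_trial))
    if unknown:
        raise ValueError(f"score table references unknown trials: {unknown}")
    out: dict[int, TrialRecord] = {int(t.trial_index): replace(t) for t in trials}
    for idx, group in scores.groupby("trial_index"):
        votes = (group["score"] >= 2).astype(int)
        response = int(votes.sum()) * 2 > len(votes)  # strict majority
        rep_score = int(group["score"].max() if response else group["score"].min())
        trial = out[int(idx)]
        trial.reflex_score = rep_score
        trial.reflex_response = response
    return [out[k] for k in sorted(out)]
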