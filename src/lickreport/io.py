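"""Text-format contracts shared by every pipeline stage.

Trial logs travel as UTF-8 CSV with a header row and one row per trial;
empty strings encode absent optionals.  Observer / run configuration is
JSON with explicit seeds for every source of randomness.  CAP
recordings are two-column delimited text (time_s, voltage) plus a
one-onset-per-line stimulus-times file.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cap import Recording
from .observer import DEFAULT_OBSERVER, ObserverParams
from .sdt import SdtParams, SdtSeries
from .session import (
    Consequence,
    Outcome,
    StimulusKind,
    StimulusSpec,
    TrialRecord,
)

__all__ = [
    "TRIAL_LOG_COLUMNS",
    "trials_to_frame",
    "frame_to_trials",
    "write_trial_log",
    "read_trial_log",
    "write_sdt_series",
    "RunConfig",
    "read_recording",
    "write_recording",
]

PathLike = Union[str, Path]

TRIAL_LOG_COLUMNS = [
    "trial_index",
    "session_id",
    "phase",
    "stim_kind",
    "wavelength_nm",
    "intensity_mw_mm2",
    "pulse_width_ms",
    "isi_s",
    "response_window_s",
    "lick_latency_s",
    "licked",
    "reflex_score",
    "reflex_response",
    "outcome",
    "rewarded",
    "premature_lick",
    "consequence",
]


def _opt(value) -> str:
    return "" if value is None else value


def trials_to_frame(
    trials: Sequence[TrialRecord], session_id: str = "", phase: str = ""
) -> pd.DataFrame:
    """Serialize trials into the shared trial-log column contract."""
    rows = []
    for t in trials:
        rows.append(
            {
                "trial_index": t.trial_index,
                "session_id": session_id,
                "phase": phase,
                "stim_kind": t.stimulus.kind.value,
                "wavelength_nm": _opt(t.stimulus.wavelength_nm),
                "intensity_mw_mm2": t.stimulus.intensity_mw_mm2,
                "pulse_width_ms": t.stimulus.pulse_width_ms,
                "isi_s": t.isi_s,
                "response_window_s": t.response_window_s,
                "lick_latency_s": _opt(t.lick_latency_s),
                "licked": _opt(t.licked),
                "reflex_score": _opt(t.reflex_score),
                "reflex_response": _opt(t.reflex_response),
                "outcome": _opt(t.outcome.value if t.outcome else None),
                "rewarded": t.rewarded,
                "premature_lick": t.premature_lick,
                "consequence": t.consequence.value,
            }
        )
    return pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)


def _parse_bool(value) -> Optional[bool]:
    if value is None or value == "" or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "1"):
        return True
    if s in ("false", "0"):
        return False
    raise ValueError(f"cannot parse boolean from {value!r}")


def _parse_opt_float(value) -> Optional[float]:
    if value is None or value == "" or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    """Parse a trial-log frame back into validated records.

    Raises ``ValueError`` naming the first offending row on malformed
    input.
    """
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log missing columns: {missing}")
    trials: list[TrialRecord] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        try:
            kind = StimulusKind(row.stim_kind)
            wavelength = _parse_opt_float(row.wavelength_nm)
            stim = StimulusSpec(
                kind=kind,
                intensity_mw_mm2=float(row.intensity_mw_mm2),
                wavelength_nm=int(wavelength) if wavelength is not None else None,
                pulse_width_ms=float(row.pulse_width_ms),
            )
            score = _parse_opt_float(row.reflex_score)
            outcome = Outcome(row.outcome) if _opt(row.outcome) != "" else None
            trials.append(
                TrialRecord(
                    trial_index=int(row.trial_index),
                    stimulus=stim,
                    isi_s=float(row.isi_s),
                    response_window_s=float(row.response_window_s),
                    licked=_parse_bool(row.licked),
                    lick_latency_s=_parse_opt_float(row.lick_latency_s),
                    reflex_score=int(score) if score is not None else None,
                    reflex_response=_parse_bool(row.reflex_response),
                    outcome=outcome,
                    rewarded=bool(_parse_bool(row.rewarded)),
                    premature_lick=bool(_parse_bool(row.premature_lick)),
                    consequence=Consequence(row.consequence),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed trial log row {pos + 2} (1-based, after header): {exc}") from exc
    return trials


def write_trial_log(
    path: PathLike, trials: Sequence[TrialRecord], session_id: str = "", phase: str = ""
) -> None:
    trials_to_frame(trials, session_id=session_id, phase=phase).to_csv(path, index=False)


def read_trial_log(path: PathLike) -> list[TrialRecord]:
    df = pd.read_csv(
        path, keep_default_na=False, na_values=[], float_precision="round_trip"
    )
    return frame_to_trials(df)


def write_sdt_series(path: PathLike, series: SdtSeries) -> None:
    pd.DataFrame(
        {
            "trial_index": series.column("trial_index").astype(int),
            "hit_rate": series.column("hit_rate"),
            "fa_rate": series.column("fa_rate"),
            "dprime": series.column("dprime"),
            "criterion": series.column("criterion"),
            "fa_source": [r.fa_source.value for r in series.records],
        }
    ).to_csv(path, index=False)


@dataclass
class RunConfig:
    """End-to-end run configuration; round-trips losslessly through JSON."""

    seed: int = 0
    n_mice: int = 5
    sessions_per_mouse: int = 8
    observer: ObserverParams = field(
        default_factory=lambda: replace(DEFAULT_OBSERVER)
    )
    sdt: SdtParams = field(default_factory=SdtParams)
    band_low: float = 0.25
    band_high: float = 0.75
    bootstrap_resamples: int = 10_000
    out_dir: str = "lickreport_out"

    def __post_init__(self) -> None:
        if self.n_mice < 1 or self.sessions_per_mouse < 1:
            raise ValueError("cohort sizes must be >= 1")
        if not 0.0 <= self.band_low <= self.band_high <= 1.0:
            raise ValueError("near-threshold band bounds must satisfy 0<=low<=high<=1")

    def to_json(self, path: Optional[PathLike] = None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: PathLike) -> "RunConfig":
        path = Path(source)
        payload = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(payload, dict):
            raise ValueError("config must be a JSON object")
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "observer" in payload:
            payload["observer"] = ObserverParams(**payload["observer"])
        if "sdt" in payload:
            payload["sdt"] = SdtParams(**payload["sdt"])
        return cls(**payload)


def write_recording(path: PathLike, stim_path: PathLike, rec: Recording) -> None:
    """Recording as (time_s, voltage) CSV plus one-onset-per-line text."""
    t = np.arange(len(rec.voltage)) / rec.sample_rate_hz
    pd.DataFrame({"time_s": t, "voltage": rec.voltage}).to_csv(path, index=False)
    Path(stim_path).write_text(
        "\n".join(f"{v:.9f}" for v in rec.stim_times_s) + "\n", encoding="utf-8"
    )


def read_recording(path: PathLike, stim_path: PathLike) -> Recording:
    df = pd.read_csv(path)
    if not {"time_s", "voltage"} <= set(df.columns):
        raise ValueError("recording CSV needs columns time_s, voltage")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("recording too short")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("recording must be uniformly sampled")
    stim = np.array(
        [float(line) for line in Path(stim_path).read_text().split() if line.strip()]
    )
    return Recording(
        sample_rate_hz=1.0 / float(dt[0]),
        voltage=df["voltage"].to_numpy(),
        stim_times_s=stim,
    )
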