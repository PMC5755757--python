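"""Scan-path CSV readers and writers.

The canonical scan-path file has one row per fixation step: subject, block,
trial, step, location token, observed cue token, plus per-trial choice,
correctness, score and an optional externally supplied inter-saccade
interval column (never modelled). Files are UTF-8, comma-separated, "."
decimal, upper-case tokens, sorted by (subject, block, trial, step).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .labels import LOCATIONS, WHAT_OUTCOMES
from .simulate import TrialRecord

SCHEMA = (
    "subject_id",
    "block",
    "trial",
    "step",
    "location",
    "outcome",
    "choice",
    "correct",
    "score_delta",
    "isi_ms",
)


@dataclass
class Trial:
    """One trial's rows, regrouped: path of (step, location, outcome)."""

    subject_id: str
    block: int
    trial: int
    path: list[tuple[int, str, str]] = field(default_factory=list)
    choice: str | None = None
    correct: int | None = None
    score_delta: float | None = None


class ScanPathFormatError(ValueError):
    """A scan-path file violates the schema; message names the row."""


def records_to_frame(
    records: list[TrialRecord],
    subject_id: str,
    block: int,
    first_trial: int = 1,
    isi_ms: float | None = None,
) -> pd.DataFrame:
    """Flatten simulator TrialRecords into the canonical row schema."""
    rows = []
    for ti, rec in enumerate(records, start=first_trial):
        correct = "" if rec.feedback is None else int(rec.feedback == "RIGHT")
        for step, loc, out in rec.path:
            rows.append(
                {
                    "subject_id": subject_id,
                    "block": block,
                    "trial": ti,
                    "step": step,
                    "location": loc,
                    "outcome": out,
                    "choice": rec.choice or "",
                    "correct": correct,
                    "score_delta": rec.score_delta,
                    "isi_ms": "" if isi_ms is None else isi_ms,
                }
            )
    return pd.DataFrame(rows, columns=list(SCHEMA))


def write_scanpaths(frame: pd.DataFrame, path: str | Path) -> None:
    """Write scan-path rows to CSV in the canonical dialect."""
    missing = [c for c in SCHEMA if c not in frame.columns]
    if missing:
        raise ScanPathFormatError(f"missing column(s): {missing}")
    frame[list(SCHEMA)].to_csv(path, index=False)


def read_scanpaths(path: str | Path) -> pd.DataFrame:
    """Read and validate a scan-path CSV; returns the row frame.

    Validation errors carry 1-based data row numbers. Use
    :func:`frame_to_trials` to regroup rows into per-trial structures.
    """
    frame = pd.read_csv(path, dtype={"subject_id": str}, keep_default_na=False)
    missing = [c for c in SCHEMA if c not in frame.columns]
    if missing:
        raise ScanPathFormatError(f"missing column(s): {missing}")
    validate_frame(frame)
    return frame


def validate_frame(frame: pd.DataFrame) -> None:
    """Check tokens, ordering and the FIX start of every trial."""
    loc_ok = frame["location"].isin(LOCATIONS)
    if not loc_ok.all():
        i = int(np.argmax(~loc_ok.to_numpy()))
        raise ScanPathFormatError(
            f"row {i + 1}: unknown location token {frame['location'].iloc[i]!r}"
        )
    out_ok = frame["outcome"].isin(WHAT_OUTCOMES)
    if not out_ok.all():
        i = int(np.argmax(~out_ok.to_numpy()))
        raise ScanPathFormatError(
            f"row {i + 1}: unknown outcome token {frame['outcome'].iloc[i]!r}"
        )
    key = frame[["subject_id", "block", "trial", "step"]]
    if not key.equals(key.sort_values(["subject_id", "block", "trial", "step"])):
        raise ScanPathFormatError(
            "rows are not sorted by (subject_id, block, trial, step)"
        )
    firsts = frame.groupby(["subject_id", "block", "trial"], sort=False).head(1)
    bad = firsts[firsts["location"] != "FIX"]
    if len(bad):
        i = int(bad.index[0])
        raise ScanPathFormatError(f"row {i + 1}: trial does not start at FIX")


def frame_to_trials(frame: pd.DataFrame) -> dict[tuple[str, int], list[Trial]]:
    """Group validated rows into Trials keyed by (subject_id, block)."""
    grouped: dict[tuple[str, int], list[Trial]] = {}
    for (subj, block, trial), g in frame.groupby(
        ["subject_id", "block", "trial"], sort=True
    ):
        t = Trial(
            subject_id=str(subj),
            block=int(block),
            trial=int(trial),
            path=[
                (int(r.step), str(r.location), str(r.outcome))
                for r in g.itertuples()
            ],
            choice=str(g["choice"].iloc[0]) or None,
            correct=(
                int(g["correct"].iloc[0]) if str(g["correct"].iloc[0]) != "" else None
            ),
            score_delta=(
                float(g["score_delta"].iloc[0])
                if str(g["score_delta"].iloc[0]) != ""
                else None
            ),
        )
        grouped.setdefault((str(subj), int(block)), []).append(t)
    return grouped


def behaviour_from_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-subject behavioural measures from scan-path rows.

    Returns mean score per trial, percentage correct, mean saccades per
    trial, and (when the column is populated) mean inter-saccade interval.
    """
    rows = []
    for subj, g in frame.groupby("subject_id", sort=True):
        trials = [t for ts in frame_to_trials(g).values() for t in ts]
        n = len(trials)
        saccades = [
            len(t.path) - 1 - (1 if t.choice else 0) for t in trials
        ]
        row = {
            "subject_id": subj,
            "mean_score_per_trial": float(
                np.mean([t.score_delta for t in trials if t.score_delta is not None])
            ),
            "pct_correct": 100.0 * sum(t.correct == 1 for t in trials) / n,
            "mean_saccades_per_trial": float(np.mean(saccades)),
        }
        isi = pd.to_numeric(g["isi_ms"], errors="coerce").dropna()
        if len(isi):
            row["mean_isi_ms"] = float(isi.mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")
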