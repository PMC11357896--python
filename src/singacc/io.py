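"""Readers and writers for the CSV/JSON interchange formats.

All files are UTF-8, comma-separated, dot-decimal. Lines beginning with
``#`` are comments (the pipeline stamps a config hash and seed there).
Numeric values are written with 12 significant digits, lossless well past
the 1e-9 round-trip tolerance the formats promise.

Formats
-------
notes CSV         : onset_s,duration_s,f0_hz[,pitch_semitone,score_index]
segments CSV      : kind,start_s,end_s
participants CSV  : participant_id,bais_v,bais_c,years_performing,years_theory,primary_instrument
score JSON        : {label, tempo_bpm, notes: [{pitch_semitone, onset_beats, duration_beats}]}
"""

from __future__ import annotations

import json
import math
import os
from typing import Iterable, Optional

import pandas as pd

from .errors import DomainError, FormatError
from .model import (
    NoteEvent,
    ParticipantRecord,
    Score,
    ScoreNote,
    Segment,
    SegmentKind,
)

__all__ = [
    "read_notes_csv",
    "write_notes_csv",
    "read_segments_csv",
    "write_segments_csv",
    "read_participants_csv",
    "write_participants_csv",
    "read_score_json",
    "write_score_json",
]

_FLOAT_FMT = "%.12g"


def _read_table(path: str, required: tuple[str, ...]) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FormatError(f"{path}: no such file")
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def _numeric(df: pd.DataFrame, path: str, cols: Iterable[str]) -> pd.DataFrame:
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, plus header line
            raise FormatError(f"{path}: non-numeric value in column '{c}', line {row}")
        df[c] = coerced
    return df


def read_notes_csv(path: str) -> list[NoteEvent]:
    """Read a Tony/Sonic Visualiser–style note annotation export.

    Rows must be in strictly increasing onset order; a violation is reported
    with its line number rather than silently re-sorted.
    """
    df = _read_table(path, ("onset_s", "duration_s"))
    if "f0_hz" not in df.columns and "pitch_semitone" not in df.columns:
        raise FormatError(f"{path}: need an f0_hz or pitch_semitone column")
    num_cols = [c for c in ("onset_s", "duration_s", "f0_hz", "pitch_semitone", "score_index")
                if c in df.columns]
    df = _numeric(df, path, num_cols)

    notes: list[NoteEvent] = []
    prev = -math.inf
    for i, row in df.iterrows():
        line = int(i) + 2
        onset = float(row["onset_s"])
        if onset <= prev:
            raise FormatError(
                f"{path}: onset_s at line {line} ({onset}) not greater than its predecessor"
            )
        prev = onset

        def _opt(col: str) -> Optional[float]:
            if col not in df.columns or pd.isna(row[col]):
                return None
            return float(row[col])

        sidx = _opt("score_index")
        try:
            notes.append(
                NoteEvent(
                    onset_s=onset,
                    duration_s=float(row["duration_s"]),
                    f0_hz=_opt("f0_hz"),
                    pitch_semitone=_opt("pitch_semitone"),
                    score_index=None if sidx is None else int(sidx),
                )
            )
        except DomainError as e:
            raise FormatError(f"{path}: line {line}: {e}") from e
    return notes


def write_notes_csv(notes: list[NoteEvent], path: str, header_comment: str = "") -> None:
    """Write notes re-readable by :func:`read_notes_csv` (lossless to 1e-9)."""
    df = pd.DataFrame(
        {
            "onset_s": [n.onset_s for n in notes],
            "duration_s": [n.duration_s for n in notes],
            "f0_hz": [n.f0_hz for n in notes],
            "pitch_semitone": [n.pitch_semitone for n in notes],
            "score_index": [n.score_index for n in notes],
        }
    )
    if len(df):
        df["score_index"] = df["score_index"].astype("Int64")
    _write_csv(df, path, header_comment)


def _write_csv(df: pd.DataFrame, path: str, header_comment: str = "") -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_segments_csv(path: str) -> list[Segment]:
    df = _read_table(path, ("kind", "start_s", "end_s"))
    df = _numeric(df, path, ("start_s", "end_s"))
    segs = []
    for i, row in df.iterrows():
        line = int(i) + 2
        kind = str(row["kind"]).strip()
        try:
            segs.append(
                Segment(SegmentKind(kind), float(row["start_s"]), float(row["end_s"]))
            )
        except (ValueError, DomainError) as e:
            raise FormatError(f"{path}: line {line}: {e}") from e
    return segs


def write_segments_csv(segments: list[Segment], path: str, header_comment: str = "") -> None:
    df = pd.DataFrame(
        {
            "kind": [s.kind.value for s in segments],
            "start_s": [s.start_s for s in segments],
            "end_s": [s.end_s for s in segments],
        }
    )
    _write_csv(df, path, header_comment)


PARTICIPANT_COLUMNS = (
    "participant_id",
    "bais_v",
    "bais_c",
    "years_performing",
    "years_theory",
    "primary_instrument",
)


def read_participants_csv(path: str) -> list[ParticipantRecord]:
    """Read the participant table; BAIS values outside [1, 7] are rejected."""
    df = _read_table(path, PARTICIPANT_COLUMNS)
    df = _numeric(df, path, ("bais_v", "bais_c", "years_performing", "years_theory"))
    dup = df["participant_id"].astype(str).duplicated()
    if dup.any():
        pid = df["participant_id"][dup].iloc[0]
        raise FormatError(f"{path}: duplicate participant_id {pid!r}")
    records = []
    for i, row in df.iterrows():
        line = int(i) + 2
        try:
            records.append(
                ParticipantRecord(
                    participant_id=str(row["participant_id"]),
                    bais_v=float(row["bais_v"]),
                    bais_c=float(row["bais_c"]),
                    years_performing=float(row["years_performing"]),
                    years_theory=float(row["years_theory"]),
                    primary_instrument=str(row["primary_instrument"]),
                )
            )
        except DomainError as e:
            raise FormatError(f"{path}: line {line}: {e}") from e
    return records


def write_participants_csv(
    records: list[ParticipantRecord], path: str, header_comment: str = ""
) -> None:
    df = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "bais_v": [r.bais_v for r in records],
            "bais_c": [r.bais_c for r in records],
            "years_performing": [r.years_performing for r in records],
            "years_theory": [r.years_theory for r in records],
            "primary_instrument": [r.primary_instrument for r in records],
        }
    )
    _write_csv(df, path, header_comment)


def read_score_json(path: str) -> Score:
    try:
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
    except FileNotFoundError:
        raise FormatError(f"{path}: no such file") from None
    except json.JSONDecodeError as e:
        raise FormatError(f"{path}: invalid JSON ({e})") from e
    try:
        notes = [
            ScoreNote(
                pitch_semitone=float(n["pitch_semitone"]),
                onset_beats=float(n["onset_beats"]),
                duration_beats=float(n["duration_beats"]),
            )
            for n in obj["notes"]
        ]
        return Score(notes=notes, tempo_bpm=float(obj["tempo_bpm"]), label=str(obj.get("label", "")))
    except (KeyError, TypeError, ValueError) as e:
        raise FormatError(f"{path}: malformed score object ({e})") from e
    # DomainError from Score.__post_init__ propagates: the file parsed but the
    # score it encodes is invalid, which is a data problem, not a format one.


def write_score_json(score: Score, path: str) -> None:
    obj = {
        "label": score.label,
        "tempo_bpm": score.tempo_bpm,
        "notes": [
            {
                "pitch_semitone": n.pitch_semitone,
                "onset_beats": n.onset_beats,
                "duration_beats": n.duration_beats,
            }
            for n in score.notes
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1)
        fh.write("\n")
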