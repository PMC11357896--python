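"""Domain types for scores, performances, and participants.

Conventions
-----------
* Time is in seconds (floats); pitch is in semitones on the MIDI scale
  (69 = A4 = 440 Hz, 12 semitones per octave).
* Segment boundaries are half-open ``[start_s, end_s)`` so adjacent
  segments share a boundary without overlapping.
* Tasks: ``Normal`` (sing throughout), ``Toggled`` (alternate singing and
  audiating on visual cue), ``TVD`` (Toggled with a speech distractor
  during audiated spans).
* Feedback conditions: two controls (NF room feedback, HF headphone
  feedback), two delayed-auditory-feedback conditions (200 ms, 600 ms) and
  two upward pitch shifts (+quarter tone, +whole tone).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .errors import DomainError

__all__ = [
    "Task",
    "Condition",
    "AAF_CONDITIONS",
    "CONTROL_CONDITION",
    "DAF_CONDITIONS",
    "SHIFT_SEMITONES",
    "hz_to_semitone",
    "semitone_to_hz",
    "ScoreNote",
    "Score",
    "NoteEvent",
    "Segment",
    "Performance",
    "ParticipantRecord",
    "validate_performance",
]

A4_HZ = 440.0
A4_SEMITONE = 69.0

#: Default singable range used by Score validation (C2..C6 on the MIDI scale).
DEFAULT_PITCH_RANGE = (36.0, 84.0)


class Task(str, Enum):
    NORMAL = "Normal"
    TOGGLED = "Toggled"
    TVD = "TVD"


class Condition(str, Enum):
    NF = "NF"
    HF = "HF"
    D200 = "D200"
    D600 = "D600"
    PS_QUARTER = "PS_QUARTER"
    PS_WHOLE = "PS_WHOLE"


#: Altered-feedback conditions analysed against the HF control baseline.
AAF_CONDITIONS = (
    Condition.D200,
    Condition.D600,
    Condition.PS_QUARTER,
    Condition.PS_WHOLE,
)

#: Headphone feedback is the control baseline for the AAF conditions.
CONTROL_CONDITION = Condition.HF

DAF_CONDITIONS = (Condition.D200, Condition.D600)

#: Upward feedback pitch-shift size per condition, in semitones.
SHIFT_SEMITONES = {Condition.PS_QUARTER: 0.5, Condition.PS_WHOLE: 1.0}


def hz_to_semitone(f0_hz: float) -> float:
    """Convert a fundamental frequency in Hz to MIDI-scale semitones.

    ``69 + 12 * log2(f0 / 440)``; strictly increasing in ``f0_hz``.

    Raises
    ------
    DomainError
        If ``f0_hz`` is not strictly positive.
    """
    if f0_hz <= 0:
        raise DomainError(f"f0_hz must be > 0, got {f0_hz!r}")
    return A4_SEMITONE + 12.0 * math.log2(f0_hz / A4_HZ)


def semitone_to_hz(pitch_semitone: float) -> float:
    """Inverse of :func:`hz_to_semitone`."""
    return A4_HZ * 2.0 ** ((pitch_semitone - A4_SEMITONE) / 12.0)


@dataclass(frozen=True)
class ScoreNote:
    """One expected note: pitch in semitones, onset and duration in beats."""

    pitch_semitone: float
    onset_beats: float
    duration_beats: float


@dataclass
class Score:
    """The expected note sequence plus nominal tempo — the normalization reference."""

    notes: Sequence[ScoreNote]
    tempo_bpm: float
    label: str = ""
    pitch_range: tuple[float, float] = DEFAULT_PITCH_RANGE

    def __post_init__(self) -> None:
        if len(self.notes) < 2:
            raise DomainError("a Score needs at least 2 notes")
        if self.tempo_bpm <= 0:
            raise DomainError(f"tempo_bpm must be > 0, got {self.tempo_bpm}")
        lo, hi = self.pitch_range
        prev = -math.inf
        for i, n in enumerate(self.notes):
            if n.onset_beats < 0:
                raise DomainError(f"score note {i}: onset_beats < 0")
            if n.duration_beats <= 0:
                raise DomainError(f"score note {i}: duration_beats <= 0")
            if n.onset_beats <= prev:
                raise DomainError(f"score note {i}: onsets must be strictly increasing")
            if not (lo <= n.pitch_semitone <= hi):
                raise DomainError(
                    f"score note {i}: pitch {n.pitch_semitone} outside singable "
                    f"range [{lo}, {hi}]"
                )
            prev = n.onset_beats

    @property
    def beat_period_s(self) -> float:
        return 60.0 / self.tempo_bpm

    def onset_seconds(self) -> list[float]:
        """Nominal onset times of the score notes at the nominal tempo."""
        return [n.onset_beats * self.beat_period_s for n in self.notes]


#: Tolerance for agreement between an explicit semitone pitch and the one
#: implied by f0_hz on the same note.
PITCH_CONSISTENCY_TOL = 1e-6


@dataclass
class NoteEvent:
    """One sung note: onset/duration in seconds plus pitch (Hz or semitones).

    At least one of ``f0_hz`` and ``pitch_semitone`` is required; if both are
    given they must agree through the Hz→semitone conversion to 1e-6
    semitones. ``score_index`` optionally pins the note to a score position
    (explicit alignment).
    """

    onset_s: float
    duration_s: float
    f0_hz: Optional[float] = None
    pitch_semitone: Optional[float] = None
    score_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise DomainError(f"onset_s must be >= 0, got {self.onset_s}")
        if self.duration_s <= 0:
            raise DomainError(f"duration_s must be > 0, got {self.duration_s}")
        if self.f0_hz is None and self.pitch_semitone is None:
            raise DomainError("NoteEvent needs f0_hz or pitch_semitone")
        if self.f0_hz is not None:
            implied = hz_to_semitone(self.f0_hz)
            if self.pitch_semitone is None:
                self.pitch_semitone = implied
            elif abs(self.pitch_semitone - implied) > PITCH_CONSISTENCY_TOL:
                raise DomainError(
                    f"f0_hz {self.f0_hz} implies {implied:.6f} st but "
                    f"pitch_semitone is {self.pitch_semitone}"
                )

    @property
    def semitone(self) -> float:
        assert self.pitch_semitone is not None
        return self.pitch_semitone


class SegmentKind(str, Enum):
    SUNG = "sung"
    AUDIATED = "audiated"


@dataclass(frozen=True)
class Segment:
    """A sung or audiated span of a performance, half-open in time."""

    kind: SegmentKind
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise DomainError(
                f"segment end ({self.end_s}) must exceed start ({self.start_s})"
            )

    def contains(self, t: float) -> bool:
        return self.start_s <= t < self.end_s


@dataclass
class Performance:
    """One participant × task × condition rendition."""

    participant_id: str
    task: Task
    condition: Condition
    notes: list[NoteEvent]
    segments: list[Segment]
    score_ref: Score

    def sung_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.kind == SegmentKind.SUNG]

    def audiated_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.kind == SegmentKind.AUDIATED]


@dataclass
class ParticipantRecord:
    """Questionnaire and experience covariates for one singer.

    BAIS-V (vividness) and BAIS-C (control) are 7-point self-report scales;
    ``bais_avg`` is their arithmetic mean and is the grouping variable for
    the median split.
    """

    participant_id: str
    bais_v: float
    bais_c: float
    years_performing: float
    years_theory: float
    primary_instrument: str = ""
    bais_group: Optional[str] = None  # "high" / "low" once assigned

    def __post_init__(self) -> None:
        for name, v in (("bais_v", self.bais_v), ("bais_c", self.bais_c)):
            if not (1.0 <= v <= 7.0):
                raise DomainError(f"{name}={v} outside the BAIS range [1, 7]")
        if self.years_performing < 0 or self.years_theory < 0:
            raise DomainError("experience covariates must be >= 0")

    @property
    def bais_avg(self) -> float:
        return (self.bais_v + self.bais_c) / 2.0


def validate_performance(p: Performance) -> list[str]:
    """Check all Performance invariants; return violation messages.

    Total: never raises on a well-typed Performance. An empty list means the
    performance is clean.
    """
    out: list[str] = []
    segs = p.segments
    for i in range(1, len(segs)):
        if segs[i].start_s < segs[i - 1].start_s:
            out.append(f"segments out of order at index {i}")
        if segs[i].start_s < segs[i - 1].end_s:
            out.append(f"segments {i - 1} and {i} overlap")
        elif segs[i].start_s > segs[i - 1].end_s:
            out.append(f"gap between segments {i - 1} and {i}: span not covered")
    sung = p.sung_segments()
    for j, n in enumerate(p.notes):
        if not any(s.contains(n.onset_s) for s in sung):
            out.append(f"note {j} (onset {n.onset_s:.3f}s) outside any sung segment")
        if n.score_index is not None and not (
            0 <= n.score_index < len(p.score_ref.notes)
        ):
            out.append(f"note {j}: score_index {n.score_index} out of range")
    if p.task == Task.NORMAL and len(sung) != 1:
        out.append(f"Normal-task performance must have exactly 1 sung segment, has {len(sung)}")
    return out
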