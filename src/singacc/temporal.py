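"""Temporal accuracy: IOI variability (CV) and missed beats during audiation.

The coefficient of variation (CV) of inter-onset intervals (IOIs) is the
sample SD of the IOIs divided by their mean, reported in percent. It is
unit-free: uniformly slowing down leaves CV unchanged, so it captures
dispersion around the performer's own tempo rather than deviation from the
nominal one. The first onset of each sung span is consumed, not emitted,
and no IOI ever spans an audiated gap.

During audiated (silent) spans timing cannot be observed directly. The
missed-beats (MB) metric extrapolates the last vocalized tempo through the
silent span and counts how many beats the singer's re-entry is early or
late: mb = |elapsed / beat_period - expected_beats|.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np

from .errors import (
    AlignmentError,
    DomainError,
    InsufficientDataError,
)
if TYPE_CHECKING:  # pragma: no cover
    from .model import Performance, Segment

__all__ = [
    "IOISeries",
    "AudiatedSectionTiming",
    "iois_from_onsets",
    "compute_iois",
    "cv",
    "cv_of_performance",
    "missed_beats_section",
    "missed_beats_performance",
    "extract_audiated_sections",
    "mb_of_performance",
]


@dataclass
class IOISeries:
    """IOIs (milliseconds) within one sung segment."""

    iois_ms: np.ndarray
    source_segment: Optional["Segment"] = None


@dataclass
class AudiatedSectionTiming:
    """Timing anchors for one audiated span.

    t_off_s       : onset of the last beat vocalized before the span —
                    the anchor the silent tempo is extrapolated from.
    t_resume_s    : first sung onset after the span.
    beat_period_s : period of the last beat(s) vocalized.
    expected_beats: score beats between the anchor and the resume note.
    """

    t_off_s: float
    t_resume_s: float
    beat_period_s: float
    expected_beats: float

    def __post_init__(self) -> None:
        if self.t_resume_s <= self.t_off_s:
            raise DomainError("t_resume_s must exceed t_off_s")
        if self.expected_beats <= 0:
            raise DomainError("expected_beats must be > 0")


def iois_from_onsets(onsets_s: Sequence[float]) -> np.ndarray:
    """IOIs in ms from onset times in seconds; the first onset is consumed."""
    on = np.asarray(onsets_s, dtype=float)
    if len(on) < 2:
        raise InsufficientDataError(
            f"need at least 2 onsets for an IOI, got {len(on)}"
        )
    return 1000.0 * np.diff(on)


def compute_iois(perf: "Performance") -> list[IOISeries]:
    """Per-sung-segment IOI series for a performance.

    Sung segments containing fewer than two notes yield no IOIs and are
    skipped; if *no* segment yields an IOI the performance is too sparse and
    an error is raised.
    """
    out: list[IOISeries] = []
    for seg in perf.sung_segments():
        onsets = [n.onset_s for n in perf.notes if seg.contains(n.onset_s)]
        if len(onsets) >= 2:
            out.append(IOISeries(iois_ms=iois_from_onsets(onsets), source_segment=seg))
    if not out:
        raise InsufficientDataError(
            "no sung segment contains 2 or more notes; cannot form IOIs"
        )
    return out


def cv(iois_ms: Sequence[float]) -> float:
    """CV in percent: 100 * sample SD / mean of the IOIs."""
    x = np.asarray(iois_ms, dtype=float)
    if len(x) < 2:
        raise InsufficientDataError(f"CV needs >= 2 IOIs, got {len(x)}")
    m = float(np.mean(x))
    if m <= 0:
        raise DomainError("mean IOI must be positive")
    return 100.0 * float(np.std(x, ddof=1)) / m


def cv_of_performance(perf: "Performance") -> float:
    """CV over all within-segment IOIs of a performance, concatenated.

    IOIs never bridge an audiated gap: each sung segment contributes its own
    differences and the series are pooled before the SD/mean ratio.
    """
    series = compute_iois(perf)
    pooled = np.concatenate([s.iois_ms for s in series])
    return cv(pooled)


def missed_beats_section(s: AudiatedSectionTiming) -> float:
    """Absolute beats missed across one audiated span.

    The silent span is assumed to continue at the last vocalized tempo;
    the metric is |(t_resume - t_off) / beat_period - expected_beats|.
    """
    if s.beat_period_s <= 0:
        raise DomainError(f"beat_period_s must be > 0, got {s.beat_period_s}")
    elapsed_beats = (s.t_resume_s - s.t_off_s) / s.beat_period_s
    return abs(elapsed_beats - s.expected_beats)


def missed_beats_performance(
    sections: Sequence[AudiatedSectionTiming],
    normalization: str = "mean_abs",
) -> float:
    """Average missed beats over the audiated sections of one performance.

    normalization = "mean_abs" (headline): plain mean of per-section |MB|.
    normalization = "per_beat": total |MB| divided by total expected beats,
    weighting long sections more.

    A performance without audiated sections (Normal task) has no defined MB;
    that is an error here, never a zero.
    """
    if not sections:
        raise InsufficientDataError(
            "MB undefined without audiated sections (Normal task is N/A)"
        )
    mbs = np.array([missed_beats_section(s) for s in sections])
    if normalization == "mean_abs":
        return float(np.mean(mbs))
    if normalization == "per_beat":
        total_expected = sum(s.expected_beats for s in sections)
        return float(np.sum(mbs) / total_expected)
    raise DomainError(f"unknown normalization {normalization!r}")


def extract_audiated_sections(
    perf: "Performance", k_ioi: int = 1
) -> list[AudiatedSectionTiming]:
    """Derive section timings from a performance's segments and notes.

    ``k_ioi`` controls the tempo estimate for the silent span: the mean of
    the last k within-segment IOIs before toggle-off (default 1, the literal
    last beat vocalized; larger k trades literalness for noise reduction).
    Anchor and resume notes must carry score_index so the expected beat span
    can be read off the score.
    """
    if k_ioi < 1:
        raise DomainError("k_ioi must be >= 1")
    sections: list[AudiatedSectionTiming] = []
    notes = perf.notes
    score = perf.score_ref
    for seg in perf.audiated_segments():
        before = [n for n in notes if n.onset_s < seg.start_s]
        after = [n for n in notes if n.onset_s >= seg.end_s]
        if not before or not after:
            continue  # span at the very start/end has no anchor or no resume
        anchor, resume = before[-1], after[0]
        if anchor.score_index is None or resume.score_index is None:
            raise AlignmentError(
                "audiated-section timing needs score_index on the notes "
                "around each silent span"
            )
        # last beat(s) vocalized: IOIs from the sung span ending at the
        # anchor only — an IOI must never reach back across an earlier
        # silent gap, which would wreck the tempo estimate
        run = [n for n in before
               if any(s.contains(n.onset_s) and s.contains(anchor.onset_s)
                      for s in perf.sung_segments())]
        prior_onsets = [n.onset_s for n in run[-(k_ioi + 1):]]
        if len(prior_onsets) < 2:
            continue  # no IOI before toggle-off; tempo unobservable
        period = float(np.mean(np.diff(prior_onsets)))
        expected = (
            score.notes[resume.score_index].onset_beats
            - score.notes[anchor.score_index].onset_beats
        )
        if expected <= 0 or period <= 0:
            continue
        sections.append(
            AudiatedSectionTiming(
                t_off_s=anchor.onset_s,
                t_resume_s=resume.onset_s,
                beat_period_s=period,
                expected_beats=expected,
            )
        )
    return sections


def mb_of_performance(
    perf: "Performance", normalization: str = "mean_abs", k_ioi: int = 1
) -> float:
    """MB average for a performance; NaN when no audiated section exists."""
    sections = extract_audiated_sections(perf, k_ioi=k_ioi)
    if not sections:
        return float("nan")
    return missed_beats_performance(sections, normalization=normalization)
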