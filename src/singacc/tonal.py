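"""Tonal reference deviation (TRD).

An unaccompanied singer has no external tuning reference; their internal
tonal center must be estimated from the sung notes themselves. After
*score normalization* (subtracting each expected score pitch from the
corresponding sung pitch, leaving per-note deviations in semitones), a
sliding window of N notes (default 5: the note plus two neighbours either
side) averages the deviations into a *tonal reference trajectory*. The
standard deviation of that trajectory is the TRD, in semitones: a measure
of how much the internal reference fluctuates. A constant transposition
moves every window mean equally and so contributes nothing; an abrupt key
change is penalized at the step and then smoothed if the singer continues
consistently in the new key.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .errors import AlignmentError, DomainError, InsufficientDataError
from .model import SegmentKind, hz_to_semitone, semitone_to_hz  # noqa: F401  (re-export)

if TYPE_CHECKING:  # pragma: no cover
    from .model import NoteEvent, Performance, Score, Segment

__all__ = [
    "TRDConfig",
    "TonalTrajectory",
    "hz_to_semitone",
    "align_to_score",
    "score_normalize",
    "correct_octave_errors",
    "tonal_trajectory",
    "trd",
    "trd_of_performance",
]


@dataclass(frozen=True)
class TRDConfig:
    """Tunable parameters of the TRD statistic.

    window_n    : odd window size, default 5 ("two notes directly before and
                  after"); must be >= 3.
    sd_kind     : "sample" (n-1 denominator, default) or "population".
    edge_policy : "full_windows_only" (trajectory defined only where a full
                  centered window exists, default) or "shrink" (windows
                  shrink symmetrically toward the edges, one trajectory
                  value per note).
    octave_correction : snap sung pitches by whole octaves toward the
                  expected pitch before normalization. Off by default; the
                  number of corrected notes is reported when used.
    """

    window_n: int = 5
    sd_kind: str = "sample"
    edge_policy: str = "full_windows_only"
    octave_correction: bool = False

    def __post_init__(self) -> None:
        if self.window_n < 3 or self.window_n % 2 == 0:
            raise DomainError(f"window_n must be an odd integer >= 3, got {self.window_n}")
        if self.sd_kind not in ("sample", "population"):
            raise DomainError(f"unknown sd_kind {self.sd_kind!r}")
        if self.edge_policy not in ("full_windows_only", "shrink"):
            raise DomainError(f"unknown edge_policy {self.edge_policy!r}")


@dataclass
class TonalTrajectory:
    """Windowed estimate of the internal reference offset, one value per
    evaluable note position."""

    values: np.ndarray
    positions: np.ndarray


def align_to_score(
    notes: Sequence["NoteEvent"],
    score: "Score",
    segments: Sequence["Segment"] = (),
) -> list[tuple[float, float]]:
    """Pair each sung note with its expected score pitch (both in semitones).

    If every note carries an explicit ``score_index`` the pairing follows the
    indices verbatim. Otherwise pairing is ordinal: the k-th sung note maps
    to the k-th *non-audiated* score note, where score notes whose nominal
    onset time falls inside an audiated segment are excluded from the
    expectation (audiated pitches are not sung and not scored).
    """
    if not notes:
        return []
    indexed = [n.score_index is not None for n in notes]
    if any(indexed) and not all(indexed):
        raise AlignmentError(
            "score_index must be present on every note or on none"
        )
    if all(indexed):
        pairs = []
        for n in notes:
            assert n.score_index is not None
            pairs.append((n.semitone, score.notes[n.score_index].pitch_semitone))
        return pairs

    audiated = [s for s in segments if s.kind == SegmentKind.AUDIATED]
    period = score.beat_period_s
    available = [
        sn
        for sn in score.notes
        if not any(a.contains(sn.onset_beats * period) for a in audiated)
    ]
    if len(notes) > len(available):
        raise AlignmentError(
            f"{len(notes)} sung notes but only {len(available)} available "
            "score notes under ordinal alignment; provide score_index"
        )
    return [(n.semitone, sn.pitch_semitone) for n, sn in zip(notes, available)]


def correct_octave_errors(
    pairs: Sequence[tuple[float, float]]
) -> tuple[list[tuple[float, float]], int]:
    """Snap each sung pitch by whole octaves to within 6 st of its expectation.

    Returns the corrected pairs and how many notes were moved. Intended for
    annotation pipelines where octave jumps are tracker artifacts; the
    default pipeline leaves pitches untouched.
    """
    out = []
    n_moved = 0
    for sung, expected in pairs:
        shift = 12.0 * round((sung - expected) / 12.0)
        if shift != 0.0:
            n_moved += 1
        out.append((sung - shift, expected))
    return out, n_moved


def score_normalize(pairs: Sequence[tuple[float, float]]) -> np.ndarray:
    """Per-note deviations d_k = sung_k - expected_k, order preserved."""
    if len(pairs) == 0:
        return np.empty(0)
    arr = np.asarray(pairs, dtype=float)
    return arr[:, 0] - arr[:, 1]


def tonal_trajectory(
    deviations: Sequence[float], cfg: TRDConfig = TRDConfig()
) -> TonalTrajectory:
    """Centered moving average of the deviations: the reference trajectory."""
    d = np.asarray(deviations, dtype=float)
    n = len(d)
    w = cfg.window_n
    half = w // 2
    if cfg.edge_policy == "full_windows_only":
        if n < w:
            raise InsufficientDataError(
                f"need at least window_n={w} deviations, got {n}"
            )
        values = np.convolve(d, np.full(w, 1.0 / w), mode="valid")
        positions = np.arange(half, n - half)
    else:  # shrink
        if n < 1:
            raise InsufficientDataError("need at least 1 deviation")
        cums = np.concatenate([[0.0], np.cumsum(d)])
        idx = np.arange(n)
        h = np.minimum(np.minimum(idx, n - 1 - idx), half)
        values = (cums[idx + h + 1] - cums[idx - h]) / (2 * h + 1)
        positions = idx
    return TonalTrajectory(values=values, positions=positions)


def trd(trajectory: TonalTrajectory, cfg: TRDConfig = TRDConfig()) -> float:
    """Standard deviation of the tonal reference trajectory, in semitones."""
    v = np.asarray(trajectory.values, dtype=float)
    if len(v) < 2:
        raise InsufficientDataError(
            f"TRD needs a trajectory of length >= 2, got {len(v)}"
        )
    ddof = 1 if cfg.sd_kind == "sample" else 0
    return float(np.std(v, ddof=ddof))


def trd_of_performance(
    perf: "Performance", cfg: TRDConfig = TRDConfig()
) -> float:
    """Full TRD pipeline for one performance: align → normalize → window → SD."""
    pairs = align_to_score(perf.notes, perf.score_ref, perf.segments)
    if cfg.octave_correction:
        pairs, _ = correct_octave_errors(pairs)
    deviations = score_normalize(pairs)
    traj = tonal_trajectory(deviations, cfg)
    return trd(traj, cfg)


def trajectory_of_performance(
    perf: "Performance", cfg: TRDConfig = TRDConfig()
) -> TonalTrajectory:
    """Trajectory export hook (position, offset) for plotting/debugging."""
    pairs = align_to_score(perf.notes, perf.score_ref, perf.segments)
    if cfg.octave_correction:
        pairs, _ = correct_octave_errors(pairs)
    return tonal_trajectory(score_normalize(pairs), cfg)


def write_trajectory_csv(trajectory: TonalTrajectory, path: str) -> None:
    """Export a trajectory as position,offset_semitones CSV."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("position,offset_semitones\n")
        for pos, val in zip(trajectory.positions, trajectory.values):
            fh.write(f"{int(pos)},{val:.12g}\n")
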