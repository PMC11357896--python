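"""Synthetic singer-cohort simulator.

Generates cohorts of performances with the statistical structure the
analysis pipeline assumes, with plantable group effects and full seed
control. The generative model per performance:

* **Tonal center**: a per-note random walk (downward bias + Gaussian
  innovations) plus, under pitch-shifted feedback of size *s* semitones, a
  compensation ramp that moves the center linearly across the performance
  by ``-gain * s`` (opposition response; a matching mode flips the sign).
  The ramp, rather than an instantaneous offset, is what a
  sliding-window reference statistic registers: a permanent constant
  offset would vanish from the trajectory SD once the window passes.
  Sung pitch = expected + center + i.i.d. note noise.
* **Timing**: onsets sit on the singer's internal beat grid (nominal
  score beats, uniformly slowed under delayed feedback) perturbed by
  Gaussian phase noise calibrated so the IOI coefficient of variation hits
  the profile's ``tempo_noise_cv`` (plus ``daf_extra_cv`` under DAF).
* **Audiation** (Toggled/TVD tasks): the screen toggles sing/wait at
  uniform 5–15 s intervals; notes falling in wait spans are audiated
  (not emitted). The singer re-enters at the predicted grid time plus
  ``Normal(0, audiation_beat_sd)`` beats of jitter, and carries on from
  wherever they resumed (jitter is not corrected afterwards). The TVD task
  multiplies audiation and tonal noise by a distraction factor.

Seeding: every participant owns named substreams derived from
``(master_seed, participant index)``, so enlarging a cohort never perturbs
existing participants, and identical seeds give bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import DomainError
from .model import (
    DAF_CONDITIONS,
    SHIFT_SEMITONES,
    Condition,
    NoteEvent,
    ParticipantRecord,
    Performance,
    Score,
    ScoreNote,
    Segment,
    SegmentKind,
    Task,
)

__all__ = [
    "SingerProfile",
    "SimulationConfig",
    "generate_score",
    "simulate_performance",
    "simulate_cohort",
    "default_config",
    "null_config",
]

MAJOR_SCALE = (0, 2, 4, 5, 7, 9, 11)


@dataclass(frozen=True)
class SingerProfile:
    """Generative parameters for one singer (or one group's typical singer).

    tonal_drift_step_sd : random-walk innovation SD, semitones per note.
    tonal_drift_bias    : deterministic drift per note (negative = downward).
    note_noise_sd       : i.i.d. per-note pitch scatter, semitones.
    shift_response_gain : fraction of a feedback pitch-shift the tonal
                          center absorbs across the performance, in [0, 1].
    tempo_noise_cv      : IOI coefficient of variation (unit-free).
    daf_slowing         : fractional IOI inflation under delayed feedback.
    daf_extra_cv        : change in timing CV under delayed feedback (may be
                          negative: performers often tighten up under DAF).
    audiation_beat_sd   : SD of the re-entry error after a silent span, beats.
    imagery_group       : "high" or "low" — which group this profile models.
    """

    tonal_drift_step_sd: float = 0.035
    tonal_drift_bias: float = -0.003
    note_noise_sd: float = 0.35
    shift_response_gain: float = 0.2
    tempo_noise_cv: float = 0.097
    daf_slowing: float = 0.04
    daf_extra_cv: float = -0.025
    audiation_beat_sd: float = 0.42
    imagery_group: str = "high"

    def __post_init__(self) -> None:
        for name in ("tonal_drift_step_sd", "note_noise_sd", "tempo_noise_cv",
                     "audiation_beat_sd"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if not (0.0 <= self.shift_response_gain <= 1.0):
            raise DomainError("shift_response_gain must be in [0, 1]")
        if self.tempo_noise_cv + self.daf_extra_cv < 0:
            raise DomainError("daf_extra_cv cannot push the timing CV below 0")


@dataclass
class SimulationConfig:
    """Study design plus generative parameters for a cohort."""

    n_per_group: int = 8
    tasks: tuple[Task, ...] = (Task.NORMAL, Task.TOGGLED, Task.TVD)
    conditions: tuple[Condition, ...] = tuple(Condition)
    profiles: dict[str, SingerProfile] = field(default_factory=dict)
    score: Optional[Score] = None  # None → one generated piece per participant
    score_n_notes: int = 120
    tempo_bpm_range: tuple[float, float] = (84.0, 116.0)
    toggle_min_s: float = 5.0
    toggle_max_s: float = 15.0
    tvd_noise_multiplier: float = 1.25
    quarter_response_scale: float = 0.35
    compensation_mode: str = "oppose"  # or "match"
    participant_spread: float = 0.15  # lognormal sigma of per-singer noise scaling
    bais_separation: float = 1.0  # 0 → groups drawn from a common BAIS range
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not (5.0 <= self.toggle_min_s < self.toggle_max_s <= 15.0):
            raise DomainError(
                "toggle bounds must satisfy 5 <= min < max <= 15 seconds"
            )
        if self.compensation_mode not in ("oppose", "match"):
            raise DomainError(f"unknown compensation_mode {self.compensation_mode!r}")
        if not self.profiles:
            self.profiles = {
                "high": SingerProfile(imagery_group="high"),
                "low": SingerProfile(imagery_group="low"),
            }


def default_config(master_seed: int = 0, **overrides) -> SimulationConfig:
    """The default study: 16 singers, a planted imagery effect on pitch-shift
    compensation.

    The low-imagery group absorbs a whole-tone feedback shift almost fully
    (gain 1.0) while the high group largely ignores it (gain 0.1); the
    quarter-tone response is scaled down (×0.35) for both, reflecting that
    small shifts feel like chorusing and provoke less compensation. All
    other parameters are identical between groups.
    """
    profiles = {
        "high": SingerProfile(imagery_group="high", shift_response_gain=0.1),
        "low": SingerProfile(imagery_group="low", shift_response_gain=1.0),
    }
    return SimulationConfig(profiles=profiles, master_seed=master_seed, **overrides)


def null_config(master_seed: int = 0, **overrides) -> SimulationConfig:
    """No planted effects anywhere: identical group profiles and no
    condition- or task-dependent parameters. Used for type-I calibration."""
    base = SingerProfile(
        shift_response_gain=0.0, daf_slowing=0.0, daf_extra_cv=0.0
    )
    profiles = {
        "high": replace(base, imagery_group="high"),
        "low": replace(base, imagery_group="low"),
    }
    return SimulationConfig(
        profiles=profiles,
        tvd_noise_multiplier=1.0,
        bais_separation=0.0,
        master_seed=master_seed,
        **overrides,
    )


def generate_score(
    n_notes: int,
    tempo_bpm: float = 100.0,
    seed: int = 0,
    rhythm: str = "isochronous",
) -> Score:
    """A melodically plausible diatonic score.

    Pitches follow a bounded random walk over two octaves of a major scale
    (mostly stepwise, occasional leaps). ``rhythm="isochronous"`` gives one
    note per beat — the working assumption behind beat-level IOI analysis —
    while ``"varied"`` mixes halves, quarters and eighths.
    """
    if n_notes < 10:
        raise DomainError(f"generate_score needs n_notes >= 10, got {n_notes}")
    rng = np.random.default_rng(seed)
    tonic = 55 + int(rng.integers(0, 6))  # G3..C4 keeps two octaves singable
    n_slots = 15  # two octaves of scale degrees
    pos = 7 + int(rng.integers(-2, 3))
    positions = []
    for _ in range(n_notes):
        positions.append(pos)
        u = rng.random()
        if u < 0.08:
            step = 0
        elif u < 0.78:
            step = int(rng.choice((-1, 1)))
        else:
            step = int(rng.choice((-3, -2, 2, 3)))
        pos = min(max(pos + step, 0), n_slots - 1)
    pitches = [tonic + 12 * (p // 7) + MAJOR_SCALE[p % 7] for p in positions]

    if rhythm == "isochronous":
        durations = np.ones(n_notes)
    elif rhythm == "varied":
        durations = rng.choice((0.5, 0.5, 1.0, 1.0, 1.0, 2.0), size=n_notes)
    else:
        raise DomainError(f"unknown rhythm {rhythm!r}")
    onsets = np.concatenate([[0.0], np.cumsum(durations[:-1])])
    notes = [
        ScoreNote(float(p), float(o), float(d))
        for p, o, d in zip(pitches, onsets, durations)
    ]
    return Score(notes=notes, tempo_bpm=tempo_bpm, label=f"synthetic-melody-{seed}")


def _toggle_windows(rng: np.random.Generator, total_s: float,
                    lo: float, hi: float) -> np.ndarray:
    """Toggle boundaries: [0, t1, t2, ...] with U(lo, hi) spacing, first
    window is a sing window."""
    bounds = [0.0]
    while bounds[-1] < total_s:
        bounds.append(bounds[-1] + float(rng.uniform(lo, hi)))
    return np.array(bounds)


def simulate_performance(
    profile: SingerProfile,
    score: Score,
    task: Task,
    condition: Condition,
    seed: int | np.random.Generator = 0,
    participant_id: str = "sim",
    toggle_min_s: float = 5.0,
    toggle_max_s: float = 15.0,
    tvd_noise_multiplier: float = 1.25,
    quarter_response_scale: float = 0.35,
    compensation_mode: str = "oppose",
) -> Performance:
    """Render one performance of ``score`` under the given task/condition."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = len(score.notes)
    period = score.beat_period_s
    expected = np.array([sn.pitch_semitone for sn in score.notes])
    onset_beats = np.array([sn.onset_beats for sn in score.notes])
    dur_beats = np.array([sn.duration_beats for sn in score.notes])

    tvd_mult = tvd_noise_multiplier if task == Task.TVD else 1.0
    is_daf = condition in DAF_CONDITIONS
    shift = SHIFT_SEMITONES.get(condition, 0.0)

    # --- timing: internal grid + phase noise -------------------------------
    slow = 1.0 + (profile.daf_slowing if is_daf else 0.0)
    cv_eff = max(0.0, profile.tempo_noise_cv + (profile.daf_extra_cv if is_daf else 0.0))
    grid = onset_beats * period * slow
    sigma_onset = cv_eff * period * slow / math.sqrt(2.0)
    onsets = grid + rng.normal(0.0, sigma_onset, n) if sigma_onset > 0 else grid.copy()
    onsets[0] = 0.0
    # phase noise is tiny relative to an IOI; guard against collisions anyway
    min_ioi = 0.1 * period * slow
    onsets = np.concatenate([[0.0], np.maximum(np.diff(onsets), min_ioi)]).cumsum()
    durations = np.maximum(0.6 * dur_beats * period * slow, 1e-3)

    # --- pitch: random walk + compensation ramp + note noise ---------------
    walk = np.cumsum(
        profile.tonal_drift_bias
        + rng.normal(0.0, profile.tonal_drift_step_sd * tvd_mult, n)
    )
    gain = profile.shift_response_gain * (
        quarter_response_scale if condition == Condition.PS_QUARTER else 1.0
    )
    sign = -1.0 if compensation_mode == "oppose" else 1.0
    ramp = sign * gain * shift * np.linspace(0.0, 1.0, n)
    noise = rng.normal(0.0, profile.note_noise_sd * tvd_mult, n) \
        if profile.note_noise_sd > 0 else 0.0
    sung_pitch = expected + walk + ramp + noise

    # --- audiation toggling ------------------------------------------------
    if task == Task.NORMAL:
        sung_mask = np.ones(n, dtype=bool)
    else:
        total = onsets[-1] + durations[-1]
        bounds = _toggle_windows(rng, total, toggle_min_s, toggle_max_s)
        window = np.searchsorted(bounds, onsets, side="right") - 1
        sung_mask = window % 2 == 0
        sung_mask[0] = True  # the singer always starts singing
        # re-entry jitter: each resumed run shifts all later onsets
        aud_sd = profile.audiation_beat_sd * tvd_mult * period * slow
        resumes = np.flatnonzero(sung_mask & ~np.roll(sung_mask, 1))
        resumes = resumes[resumes > 0]
        for k in resumes:
            onsets[k:] += rng.normal(0.0, aud_sd) if aud_sd > 0 else 0.0

    idx = np.flatnonzero(sung_mask)
    notes = [
        NoteEvent(
            onset_s=float(onsets[i]),
            duration_s=float(durations[i]),
            pitch_semitone=float(sung_pitch[i]),
            score_index=int(i),
        )
        for i in idx
    ]

    # --- segments around the realized sung runs ----------------------------
    segments: list[Segment] = []
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for ri, r in enumerate(runs):
        first = float(onsets[r[0]])
        end = float(onsets[r[-1]] + durations[r[-1]])
        if ri == 0:
            segments.append(Segment(SegmentKind.SUNG, 0.0, end))
        elif first > segments[-1].end_s:
            segments.append(Segment(SegmentKind.AUDIATED, segments[-1].end_s, first))
            segments.append(Segment(SegmentKind.SUNG, first, end))
        else:
            # pathological re-entry jitter collapsed the gap; merge the runs
            segments[-1] = Segment(SegmentKind.SUNG, segments[-1].start_s, end)
    if task != Task.NORMAL and idx[-1] < n - 1:
        # piece ended during a wait span
        tail_end = float(onsets[-1] + durations[-1])
        if tail_end > segments[-1].end_s:
            segments.append(
                Segment(SegmentKind.AUDIATED, segments[-1].end_s, tail_end)
            )

    return Performance(
        participant_id=participant_id,
        task=task,
        condition=condition,
        notes=notes,
        segments=segments,
        score_ref=score,
    )


# BAIS ranges observed in actively performing singers; used as generation
# bounds so synthetic questionnaire scores stay realistic.
BAIS_V_RANGE = (4.14, 6.57)
BAIS_C_RANGE = (3.79, 6.43)

INSTRUMENTS = ("voice", "voice", "voice", "voice", "voice", "voice", "voice",
               "voice", "voice", "piano", "piano", "guitar", "guitar",
               "flute", "dhol", "electronic")


def _draw_participant(
    rng: np.random.Generator, pid: str, group: str, separation: float
) -> ParticipantRecord:
    if separation > 0:
        half = min(separation / 2.0, 0.55)
        lo_band = (4.05, 5.02 - half * 0.1)
        hi_band = (5.02 + half * 0.1, 6.4)
        band = hi_band if group == "high" else lo_band
    else:
        band = (4.05, 6.4)
    avg = float(rng.uniform(*band))
    delta = float(rng.uniform(-0.35, 0.35))
    v = float(np.clip(avg + delta, *BAIS_V_RANGE))
    c = float(np.clip(avg - delta, *BAIS_C_RANGE))
    avg_real = (v + c) / 2.0
    years_perf = float(np.clip(-20.3 + 6.1 * avg_real + rng.normal(0, 3.5), 1.0, 30.0))
    years_theory = float(np.clip(1.0 + 1.2 * (avg_real - 4.0) + rng.normal(0, 4.0),
                                 0.5, 25.0))
    return ParticipantRecord(
        participant_id=pid,
        bais_v=v,
        bais_c=c,
        years_performing=years_perf,
        years_theory=years_theory,
        primary_instrument=str(rng.choice(INSTRUMENTS)),
    )


def _jitter_profile(rng: np.random.Generator, p: SingerProfile,
                    spread: float) -> SingerProfile:
    """Per-singer heterogeneity: lognormal scaling of the noise parameters."""
    if spread <= 0:
        return p
    s = lambda: float(rng.lognormal(0.0, spread))
    return replace(
        p,
        note_noise_sd=p.note_noise_sd * s(),
        tonal_drift_step_sd=p.tonal_drift_step_sd * s(),
        tempo_noise_cv=p.tempo_noise_cv * s(),
        audiation_beat_sd=p.audiation_beat_sd * s(),
    )


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[list[Performance], list[ParticipantRecord]]:
    """Simulate the full cohort: every participant completes every
    task × condition cell once. Returns (performances, participants)."""
    performances: list[Performance] = []
    participants: list[ParticipantRecord] = []
    n_total = 2 * cfg.n_per_group
    for pidx in range(n_total):
        group = "high" if pidx < cfg.n_per_group else "low"
        pid = f"P{pidx + 1:02d}"
        prng = np.random.default_rng([cfg.master_seed, 1000 + pidx])
        rec = _draw_participant(prng, pid, group, cfg.bais_separation)
        participants.append(rec)
        profile = _jitter_profile(prng, cfg.profiles[group], cfg.participant_spread)
        score = cfg.score or generate_score(
            cfg.score_n_notes,
            tempo_bpm=float(prng.uniform(*cfg.tempo_bpm_range)),
            seed=int(prng.integers(2**31)),
        )
        for ti, task in enumerate(cfg.tasks):
            for ci, condition in enumerate(cfg.conditions):
                rng = np.random.default_rng(
                    [cfg.master_seed, 1000 + pidx, 17 + ti * len(cfg.conditions) + ci]
                )
                performances.append(
                    simulate_performance(
                        profile,
                        score,
                        task,
                        condition,
                        seed=rng,
                        participant_id=pid,
                        toggle_min_s=cfg.toggle_min_s,
                        toggle_max_s=cfg.toggle_max_s,
                        tvd_noise_multiplier=cfg.tvd_noise_multiplier,
                        quarter_response_scale=cfg.quarter_response_scale,
                        compensation_mode=cfg.compensation_mode,
                    )
                )
    return performances, participants
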