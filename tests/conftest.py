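import numpy as np
import pytest

import singacc as sa


@pytest.fixture(scope="session")
def small_cohort():
    """One default 16-singer cohort with shortened pieces (shared, read-only)."""
    cfg = sa.default_config(master_seed=7, score_n_notes=60)
    performances, participants = sa.simulate_cohort(cfg)
    return performances, participants


@pytest.fixture(scope="session")
def small_measures(small_cohort):
    performances, _ = small_cohort
    return sa.measure_performances(performances)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def simple_score():
    """Ten isochronous C-major scale-ish notes at 120 BPM."""
    notes = [
        sa.ScoreNote(pitch_semitone=60.0 + i % 5, onset_beats=float(i), duration_beats=1.0)
        for i in range(10)
    ]
    return sa.Score(notes=notes, tempo_bpm=120.0, label="fixture")
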