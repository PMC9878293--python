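"""Shared fixtures: small stimulus sets and session builders.

All fixtures are generated programmatically and deterministically; nothing
is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from revcorr import (
    NoiseParams,
    Session,
    StimulusSet,
    TrialRecord,
    build_stimulus_set,
    synthetic_base_face,
)


@pytest.fixture(scope="session")
def small_params() -> NoiseParams:
    return NoiseParams(image_size=32, rng_seed=7)


@pytest.fixture(scope="session")
def small_set(small_params) -> StimulusSet:
    """Six inverse pairs at 32 px — enough structure for every invariant."""
    return build_stimulus_set(synthetic_base_face(32), small_params, n_pairs=6)


@pytest.fixture(scope="session")
def ten_pair_set() -> StimulusSet:
    params = NoiseParams(image_size=32, rng_seed=11)
    return build_stimulus_set(synthetic_base_face(32), params, n_pairs=10)


def make_session(
    sset: StimulusSet,
    choices,
    session_id: str = "s1",
    participant_id: str = "pp1",
    task: str = "resemblance",
) -> Session:
    """Build a session from a list of 'first'/'second'/'none' per pair (in set order)."""
    trials = [
        TrialRecord(i, pid, choice)
        for i, (pid, choice) in enumerate(zip(sset.pair_ids, choices))
    ]
    return Session(session_id, participant_id, task, sset.set_id, trials)


def random_session(
    sset: StimulusSet,
    rng: np.random.Generator,
    session_id: str = "s1",
    task: str = "resemblance",
    p_none: float = 0.0,
) -> Session:
    choices = []
    for _ in sset.pair_ids:
        if p_none and rng.random() < p_none:
            choices.append("none")
        else:
            choices.append("first" if rng.random() < 0.5 else "second")
    return make_session(sset, choices, session_id=session_id,
                        participant_id=session_id, task=task)


def positivity_sessions_from_counts(sset: StimulusSet, first_counts, n_raters: int):
    """n_raters positivity sessions where exactly first_counts[i] raters choose
    the first member of pair i (raters 0..k-1 choose first)."""
    sessions = []
    for j in range(n_raters):
        choices = ["first" if j < k else "second" for k in first_counts]
        sessions.append(
            make_session(sset, choices, session_id=f"r{j}", participant_id=f"r{j}",
                         task="positivity")
        )
    return sessions
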