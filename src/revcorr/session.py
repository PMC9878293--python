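"""Trial-log handling and classification-image (CI) construction.

A session is one participant's two-alternative forced-choice run over a
stimulus set: on each trial an inverse pair is shown and the participant
picks the member that better matches the judgment ("which looks more like
me?" for resemblance, "which looks more positive?" for positivity) within a
3-second deadline; missing the deadline records ``choice='none'``.

The self-CI is the average of the noise fields of the selected stimuli,
rendered over the base face; the anti-CI averages the non-selected members.
Averaging happens in basis-weight space (the expansion to pixels is linear),
which is cheaper and keeps the self/anti cancellation exact: on a fully
answered session the two mean-noise matrices are exact negations.
Non-response trials are excluded from every average, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import stats as _stats
from .errors import EmptySessionError, InputError, SetMismatchError
from .noise import BaseFace, NoiseParams, StimulusSet, expand_weights, render_stimulus

__all__ = [
    "TrialRecord",
    "Session",
    "ValidationReport",
    "ClassificationImage",
    "ResemblanceCheckResult",
    "validate_session",
    "build_ci",
    "build_group_ci",
    "make_filler_ci",
    "resemblance_check",
    "read_trial_log",
    "write_trial_log",
]

CHOICES = ("first", "second", "none")
RESPONSE_DEADLINE_S = 3.0


@dataclass
class TrialRecord:
    """One 2AFC trial: which member of the pair was chosen, and how fast."""

    trial_index: int
    pair_id: str
    choice: Literal["first", "second", "none"]
    response_time: float | None = None

    def __post_init__(self):
        if self.choice not in CHOICES:
            raise InputError(f"trial {self.trial_index}: choice must be one of {CHOICES}, got {self.choice!r}")
        if self.response_time is not None and np.isnan(self.response_time):
            self.response_time = None


@dataclass
class Session:
    """One participant's trial log for one RC task on one stimulus set."""

    session_id: str
    participant_id: str
    task: Literal["resemblance", "positivity"]
    stimulus_set_id: str
    trials: list[TrialRecord] = field(default_factory=list)

    def __post_init__(self):
        if self.task not in ("resemblance", "positivity"):
            raise InputError(f"session {self.session_id}: unknown task {self.task!r}")

    @property
    def answered(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.choice != "none"]

    @property
    def n_non_response(self) -> int:
        return sum(1 for t in self.trials if t.choice == "none")


@dataclass
class ValidationReport:
    session_id: str
    n_trials: int
    n_answered: int
    n_non_response: int
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_session(session: Session, sset: StimulusSet) -> ValidationReport:
    """Check a trial log against its stimulus set.

    Hard errors (wrong set, duplicate or unknown pair ids, negative response
    times) are listed separately from warnings (over-deadline response
    times, non-responses are merely counted).
    """
    report = ValidationReport(
        session_id=session.session_id,
        n_trials=len(session.trials),
        n_answered=len(session.answered),
        n_non_response=session.n_non_response,
    )
    if session.stimulus_set_id != sset.set_id:
        report.errors.append(
            f"session references stimulus set {session.stimulus_set_id!r}, "
            f"validated against {sset.set_id!r}"
        )
    known = set(sset.pair_ids)
    seen: set[str] = set()
    for t in session.trials:
        if t.pair_id in seen:
            report.errors.append(f"trial {t.trial_index}: duplicate pair_id {t.pair_id!r}")
        seen.add(t.pair_id)
        if t.pair_id not in known:
            report.errors.append(f"trial {t.trial_index}: pair_id {t.pair_id!r} not in manifest")
        if t.response_time is not None:
            if t.response_time < 0:
                report.errors.append(f"trial {t.trial_index}: negative response time {t.response_time}")
            elif t.response_time > RESPONSE_DEADLINE_S and t.choice != "none":
                report.warnings.append(
                    f"trial {t.trial_index}: response time {t.response_time:.3f}s "
                    f"exceeds the {RESPONSE_DEADLINE_S:.0f}s deadline"
                )
    return report


@dataclass(eq=False)
class ClassificationImage:
    """Average selected noise rendered over the base face."""

    kind: Literal["self", "anti", "group", "filler"]
    n_trials_used: int
    mean_weights: np.ndarray
    params: NoiseParams
    base: BaseFace
    display_scale: float
    _mean_noise: np.ndarray | None = field(default=None, repr=False)

    @property
    def mean_noise(self) -> np.ndarray:
        """Mean noise contrast matrix (expanded lazily from mean weights)."""
        if self._mean_noise is None:
            self._mean_noise = expand_weights(self.mean_weights, self.params)
        return self._mean_noise

    @property
    def rendering(self) -> np.ndarray:
        """8-bit grayscale rendering at the stimulus set's display scale."""
        ci_field = type("_F", (), {"values": self.mean_noise})()
        return render_stimulus(self.base, ci_field, self.display_scale)


def _selected_weights(session: Session, sset: StimulusSet, selected: bool) -> np.ndarray:
    """Stack the weight vectors of the (un)selected stimuli of answered trials.

    Trials are ordered by pair_id so the floating-point average is invariant
    to presentation order.
    """
    rows = []
    for t in sorted(session.answered, key=lambda t: t.pair_id):
        first, second = sset.pair(t.pair_id)
        chosen_first = t.choice == "first"
        stim = (first if chosen_first else second) if selected else (second if chosen_first else first)
        rows.append(stim.noise.weights)
    return np.asarray(rows)


def build_ci(
    session: Session,
    sset: StimulusSet,
    kind: Literal["self", "anti"] = "self",
    display_scale: float | None = None,
) -> ClassificationImage:
    """Build the self-CI (selected stimuli) or anti-CI (non-selected) of a session.

    Only answered trials enter the average; a session with zero answered
    trials cannot be averaged and raises :class:`EmptySessionError`.
    """
    if kind not in ("self", "anti"):
        raise InputError(f"kind must be 'self' or 'anti', got {kind!r}")
    if session.stimulus_set_id != sset.set_id:
        raise SetMismatchError(
            f"session {session.session_id} is on set {session.stimulus_set_id!r}, not {sset.set_id!r}"
        )
    w = _selected_weights(session, sset, selected=(kind == "self"))
    if w.size == 0:
        raise EmptySessionError(f"session {session.session_id} has no answered trials")
    return ClassificationImage(
        kind=kind,
        n_trials_used=w.shape[0],
        mean_weights=w.mean(axis=0),
        params=sset.params,
        base=sset.base,
        display_scale=sset.display_scale if display_scale is None else display_scale,
    )


def build_group_ci(
    sessions: Sequence[Session],
    sset: StimulusSet,
    kind: Literal["group", "filler"] = "group",
    selected: bool = True,
    display_scale: float | None = None,
) -> ClassificationImage:
    """Pool all answered trials of several sessions into one trial-weighted CI.

    With ``selected=False`` the non-selected members are pooled instead
    (the group anti-CI, e.g. the standard anti-positive-CI).
    """
    if not sessions:
        raise InputError("build_group_ci requires at least one session")
    bad = [s.session_id for s in sessions if s.stimulus_set_id != sset.set_id]
    if bad:
        raise SetMismatchError(f"sessions {bad} reference a different stimulus set than {sset.set_id!r}")
    stacks = [w for s in sessions if (w := _selected_weights(s, sset, selected)).size]
    if not stacks:
        raise EmptySessionError("no answered trials across the provided sessions")
    pooled = np.concatenate(stacks, axis=0)
    return ClassificationImage(
        kind=kind,
        n_trials_used=pooled.shape[0],
        mean_weights=pooled.mean(axis=0),
        params=sset.params,
        base=sset.base,
        display_scale=sset.display_scale if display_scale is None else display_scale,
    )


def make_filler_ci(sset: StimulusSet, n_choosers: int = 20, seed: int = 0) -> ClassificationImage:
    """Group CI of simulated uniform-random choosers, for use as a filler-CI.

    Fillers are control images unrelated to any participant; averaging many
    random selections yields noise near zero, i.e. an image close to the
    base face.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(104,)))
    sessions = []
    for i in range(n_choosers):
        trials = [
            TrialRecord(j, pid, "first" if rng.random() < 0.5 else "second")
            for j, pid in enumerate(sset.pair_ids)
        ]
        sessions.append(
            Session(f"filler_ch{i}", f"filler_ch{i}", "resemblance", sset.set_id, trials)
        )
    ci = build_group_ci(sessions, sset)
    ci.kind = "filler"
    return ci


@dataclass
class ResemblanceCheckResult:
    """Paired self-vs-filler resemblance comparison (manipulation check)."""

    mean_self: float
    mean_filler: float
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    confidence_intervals: dict[str, tuple[float, float]]


def resemblance_check(
    self_ratings: np.ndarray,
    filler_ratings: np.ndarray,
    per_filler: bool = False,
) -> ResemblanceCheckResult:
    """Paired t-test of self-CI resemblance ratings against filler-CI ratings.

    ``filler_ratings`` is participants x fillers; by default the fillers are
    averaged within participant before the paired test.  ``per_filler=True``
    instead pairs each (participant, filler) rating with that participant's
    self rating (long format).
    """
    self_ratings = np.asarray(self_ratings, dtype=np.float64)
    filler_ratings = np.atleast_2d(np.asarray(filler_ratings, dtype=np.float64))
    if filler_ratings.shape[0] != self_ratings.shape[0]:
        raise InputError(
            f"participant counts differ: {self_ratings.shape[0]} self vs "
            f"{filler_ratings.shape[0]} filler rows"
        )
    if self_ratings.shape[0] < 2:
        raise InputError("resemblance check needs at least 2 participants")
    if per_filler:
        n_f = filler_ratings.shape[1]
        x = np.repeat(self_ratings, n_f)
        y = filler_ratings.ravel()
    else:
        x = self_ratings
        y = filler_ratings.mean(axis=1)
    res = _stats.paired_t(x, y)
    return ResemblanceCheckResult(
        mean_self=float(x.mean()),
        mean_filler=float(y.mean()),
        t_statistic=res.t,
        degrees_of_freedom=res.dof,
        p_value=res.p,
        confidence_intervals={
            "self": _stats.mean_ci(x),
            "filler": _stats.mean_ci(y),
            "difference": res.ci,
        },
    )


_LOG_COLUMNS = [
    "session_id", "participant_id", "task", "stimulus_set_id",
    "trial_index", "pair_id", "choice", "response_time",
]


def read_trial_log(path: str | Path) -> list[Session]:
    """Read a trial-log CSV into Sessions (one per distinct session_id)."""
    df = pd.read_csv(path)
    missing = [c for c in _LOG_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"trial log {path} missing columns {missing}")
    sessions = []
    for sid, grp in df.groupby("session_id", sort=True):
        head = grp.iloc[0]
        trials = [
            TrialRecord(
                trial_index=int(r.trial_index),
                pair_id=str(r.pair_id),
                choice=str(r.choice),
                response_time=None if pd.isna(r.response_time) else float(r.response_time),
            )
            for r in grp.sort_values("trial_index").itertuples()
        ]
        sessions.append(
            Session(
                session_id=str(sid),
                participant_id=str(head.participant_id),
                task=str(head.task),
                stimulus_set_id=str(head.stimulus_set_id),
                trials=trials,
            )
        )
    return sessions


def write_trial_log(sessions: Sequence[Session], path: str | Path) -> None:
    rows = [
        {
            "session_id": s.session_id,
            "participant_id": s.participant_id,
            "task": s.task,
            "stimulus_set_id": s.stimulus_set_id,
            "trial_index": t.trial_index,
            "pair_id": t.pair_id,
            "choice": t.choice,
            "response_time": t.response_time,
        }
        for s in sessions
        for t in s.trials
    ]
    pd.DataFrame(rows, columns=_LOG_COLUMNS).to_csv(path, index=False, float_format="%.6g")
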