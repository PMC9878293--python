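"""Synthetic studies with known latent parameters, for parameter recovery.

No human data ships with the toolkit, so every stage is validated against a
generative model in which the ground truth is known:

- Each stimulus pair carries a latent positivity ``q`` (uniform on [0, 1]
  for the first member, complement for the second) — the quantity the
  positivity table estimates.
- Each simulated participant has a latent self-valence ``v`` in [0, 1] and
  a decisiveness (choice slope) ``d``; on a resemblance trial they choose
  the first member with probability
  ``logistic(d * (v - 0.5) * (q_first - q_second))`` — participants who see
  themselves positively preferentially select positive-looking stimuli,
  the mechanism implied by the observed score-trait correlations.  Trials
  time out (choice='none') with a fixed non-response probability.
- Positivity raters choose the first member with probability
  ``logistic(rater_slope * (q_first - q_second))``.
- Item-level raters score a CI's latent valence on a 1-9 bipolar scale as
  ``clip(round(1 + 8 * valence + item_bias + N(0, noise_sd)), 1, 9)``.

:func:`recovery_study` runs the full pipeline — stimuli, latent q,
positivity sessions, table, resemblance sessions, computational scores, and
simulated independent ratings — and reports how well each latent quantity
is recovered.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError, DegenerateDataError, InputError
from .noise import NoiseParams, StimulusSet, build_stimulus_set, synthetic_base_face
from .scoring import build_positivity_table, score_cohort, write_positivity_table, write_scores
from .session import Session, TrialRecord, build_group_ci, write_trial_log
from .stats import RatingMatrix, pearson_ci, pearson_r

__all__ = [
    "LatentParticipant",
    "LatentStimulusValence",
    "SimConfig",
    "assign_latent_valence",
    "simulate_resemblance_session",
    "simulate_positivity_session",
    "simulate_item_ratings",
    "ItemRatings",
    "recovery_study",
    "RecoveryReport",
]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass
class LatentParticipant:
    """Ground-truth state of one simulated participant."""

    participant_id: str
    self_valence: float          # v in [0, 1]
    decisiveness: float          # choice slope, > 0
    non_response_rate: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.self_valence <= 1.0:
            raise ConfigurationError(f"self_valence must be in [0, 1], got {self.self_valence}")
        if self.decisiveness <= 0:
            raise ConfigurationError(f"decisiveness must be > 0, got {self.decisiveness}")
        if not 0.0 <= self.non_response_rate < 1.0:
            raise ConfigurationError(
                f"non_response_rate must be in [0, 1), got {self.non_response_rate}"
            )


@dataclass
class LatentStimulusValence:
    """True positivity of one stimulus; complements its pair partner exactly."""

    stimulus_id: str
    pair_id: str
    q_true: float


@dataclass
class SimConfig:
    """Study conditions of a synthetic experiment.

    Defaults describe the reference recovery study: 200 participants with
    uniform latent valence and log-normal decisiveness (median ~7.4), 40
    positivity raters with slope 3, 300 stimulus pairs, a 2% trial
    non-response rate, and 30 independent raters x 7 bipolar items with
    unit rating noise.  Stimuli render at 128 px (resolution affects no
    scored quantity).
    """

    n_participants: int = 200
    n_positivity_raters: int = 40
    n_pairs: int = 300
    image_size: int = 128
    decisiveness_log_mean: float = 2.0
    decisiveness_log_sd: float = 0.5
    rater_slope: float = 3.0
    non_response_rate: float = 0.02
    n_item_raters: int = 30
    n_items: int = 7
    rating_noise_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("n_participants", "n_positivity_raters", "n_pairs",
                     "n_item_raters", "n_items"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not 0.0 <= self.non_response_rate < 1.0:
            raise ConfigurationError(
                f"non_response_rate must be in [0, 1), got {self.non_response_rate}"
            )

    @classmethod
    def from_toml(cls, path: str | Path) -> "SimConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**data)


def assign_latent_valence(sset: StimulusSet, seed: int) -> list[LatentStimulusValence]:
    """Draw ground-truth positivity per pair: q_first ~ U(0,1), q_second = 1 - q_first."""
    rng = _rng(seed, 1)
    out = []
    for a, b in sset.pairs:
        q = float(rng.random())
        out.append(LatentStimulusValence(a.stimulus_id, a.pair_id, q))
        out.append(LatentStimulusValence(b.stimulus_id, b.pair_id, 1.0 - q))
    return out


def _q_by_pair(valences: Sequence[LatentStimulusValence], sset: StimulusSet) -> np.ndarray:
    """q_true of the *first* member per pair, in set pair order."""
    qmap = {v.stimulus_id: v.q_true for v in valences}
    try:
        return np.array([qmap[a.stimulus_id] for a, _ in sset.pairs])
    except KeyError as exc:
        raise ConfigurationError(f"latent valences do not cover stimulus {exc}") from None


def _choices_to_session(
    sset: StimulusSet,
    p_first: np.ndarray,
    rng: np.random.Generator,
    session_id: str,
    participant_id: str,
    task: str,
    non_response_rate: float,
) -> Session:
    u = rng.random(sset.n_pairs)
    timeouts = rng.random(sset.n_pairs) < non_response_rate
    rts = rng.uniform(0.4, 2.8, sset.n_pairs)
    trials = []
    for j, pid in enumerate(sset.pair_ids):
        if timeouts[j]:
            trials.append(TrialRecord(j, pid, "none", None))
        else:
            trials.append(
                TrialRecord(j, pid, "first" if u[j] < p_first[j] else "second", float(rts[j]))
            )
    return Session(session_id, participant_id, task, sset.set_id, trials)


def simulate_resemblance_session(
    participant: LatentParticipant,
    valences: Sequence[LatentStimulusValence],
    sset: StimulusSet,
    seed: int,
) -> Session:
    """Simulate one self-resemblance RC session under the logistic choice model."""
    q = _q_by_pair(valences, sset)
    p_first = expit(
        participant.decisiveness * (participant.self_valence - 0.5) * (q - (1.0 - q))
    )
    rng = _rng(seed, 2)
    return _choices_to_session(
        sset, p_first, rng,
        session_id=f"res_{participant.participant_id}",
        participant_id=participant.participant_id,
        task="resemblance",
        non_response_rate=participant.non_response_rate,
    )


def simulate_positivity_session(
    rater_slope: float,
    valences: Sequence[LatentStimulusValence],
    sset: StimulusSet,
    seed: int,
    rater_id: str = "rater",
    non_response_rate: float = 0.0,
) -> Session:
    """Simulate one positivity-judgment session: P(first) = logistic(slope * dq)."""
    q = _q_by_pair(valences, sset)
    p_first = expit(rater_slope * (q - (1.0 - q)))
    rng = _rng(seed, 3)
    return _choices_to_session(
        sset, p_first, rng,
        session_id=f"pos_{rater_id}",
        participant_id=rater_id,
        task="positivity",
        non_response_rate=non_response_rate,
    )


@dataclass
class ItemRatings:
    """Item-level bipolar ratings: targets x raters x items, on 1..9."""

    values: np.ndarray
    item_biases: np.ndarray

    def rater_matrix(self) -> RatingMatrix:
        """Targets x raters (item means per rater) — input for ICC."""
        return RatingMatrix(self.values.mean(axis=2), scale_min=1, scale_max=9)

    def item_matrix(self) -> RatingMatrix:
        """Targets x items (rater means per item) — input for Cronbach's alpha."""
        return RatingMatrix(self.values.mean(axis=1), scale_min=1, scale_max=9)

    def mean_ratings(self) -> np.ndarray:
        """One independent valence rating per target (all items, all raters)."""
        return self.values.mean(axis=(1, 2))


def simulate_item_ratings(
    ci_valence: np.ndarray,
    n_raters: int = 30,
    n_items: int = 7,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> ItemRatings:
    """Simulate 9-point bipolar item ratings of targets with latent valence in [0, 1].

    ``rating = clip(round(1 + 8 * valence + item_bias + noise), 1, 9)`` with
    item biases drawn once (N(0, 0.5)) and i.i.d. N(0, noise_sd) rating noise.
    """
    v = np.asarray(ci_valence, dtype=np.float64)
    if v.ndim != 1 or np.any((v < 0) | (v > 1)):
        raise ConfigurationError("ci_valence must be a vector with entries in [0, 1]")
    rng = _rng(seed, 4)
    biases = rng.normal(0.0, 0.5, n_items) if noise_sd > 0 else np.zeros(n_items)
    raw = (
        1.0 + 8.0 * v[:, None, None]
        + biases[None, None, :]
        + rng.normal(0.0, noise_sd, (v.size, n_raters, n_items)) * (noise_sd > 0)
    )
    return ItemRatings(values=np.clip(np.round(raw), 1.0, 9.0), item_biases=biases)


@dataclass
class RecoveryReport:
    """How well the pipeline recovers the latent quantities it simulated."""

    config: SimConfig
    r_score_valence: float
    r_score_valence_ci: tuple[float, float]
    r_score_ratings: float
    r_score_ratings_ci: tuple[float, float]
    r_table_qtrue: float
    r_table_qtrue_ci: tuple[float, float]
    score_mean: float
    score_sd: float
    n_participants_scored: int
    group_positive_score: float
    cohort_mean_self_score: float

    def summary(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if k != "config"}
        d["config"] = asdict(self.config)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=1, sort_keys=True))


def _simulate_cohort(config: SimConfig, sset: StimulusSet,
                     valences: list[LatentStimulusValence]):
    """Participants, their resemblance sessions, and the positivity raters."""
    rng = _rng(config.rng_seed, 5)
    participants = [
        LatentParticipant(
            participant_id=f"pp{i:04d}",
            self_valence=float(rng.random()),
            decisiveness=float(rng.lognormal(config.decisiveness_log_mean,
                                             config.decisiveness_log_sd)),
            non_response_rate=config.non_response_rate,
        )
        for i in range(config.n_participants)
    ]
    res_sessions = [
        simulate_resemblance_session(p, valences, sset, seed=config.rng_seed * 1000 + i)
        for i, p in enumerate(participants)
    ]
    pos_sessions = [
        simulate_positivity_session(
            config.rater_slope, valences, sset,
            seed=config.rng_seed * 1000 + 500_000 + j, rater_id=f"rr{j:03d}",
        )
        for j in range(config.n_positivity_raters)
    ]
    return participants, res_sessions, pos_sessions


def recovery_study(config: SimConfig, out_dir: str | Path | None = None) -> RecoveryReport:
    """Run the full synthetic pipeline and measure parameter recovery.

    Reports Pearson correlations (with Fisher 95% CIs) between:
    (a) computational scores and latent self-valence,
    (b) computational scores and simulated independent valence ratings,
    (c) positivity-table scores and true stimulus positivity,
    plus the rater-consistency check that the group positive-CI selection
    out-scores the cohort's mean self-CI score under the table itself.

    With ``out_dir`` set, writes trial logs, the table, scores, the recovery
    JSON, and CI PNG renderings into that directory (deterministically).
    """
    params = NoiseParams(image_size=config.image_size, rng_seed=config.rng_seed & 0x7FFFFFFF)
    base = synthetic_base_face(config.image_size)
    sset = build_stimulus_set(base, params, n_pairs=config.n_pairs)
    valences = assign_latent_valence(sset, seed=config.rng_seed)
    participants, res_sessions, pos_sessions = _simulate_cohort(config, sset, valences)

    table = build_positivity_table(pos_sessions, sset)
    scores_df, errors = score_cohort(res_sessions, table)
    if errors:
        raise RuntimeError(f"scoring stage failed for sessions {sorted(errors)}")

    v_by_pid = {p.participant_id: p.self_valence for p in participants}
    v = scores_df["participant_id"].map(v_by_pid).to_numpy()
    cs = scores_df["score"].to_numpy()

    # true-valence analog of each self-CI: mean q_true of the selected stimuli
    qmap = {lv.stimulus_id: lv.q_true for lv in valences}
    members = {a.pair_id: (a.stimulus_id, b.stimulus_id) for a, b in sset.pairs}
    ci_valence = []
    by_id = {s.session_id: s for s in res_sessions}
    for sid in scores_df["session_id"]:
        s = by_id[sid]
        qs = [
            qmap[members[t.pair_id][0] if t.choice == "first" else members[t.pair_id][1]]
            for t in s.answered
        ]
        ci_valence.append(float(np.mean(qs)))
    ci_valence = np.asarray(ci_valence)
    ratings = simulate_item_ratings(
        ci_valence, config.n_item_raters, config.n_items,
        config.rating_noise_sd, seed=config.rng_seed,
    ).mean_ratings()

    def _safe_r(x, y):
        """Pearson result, or NaN on degenerate inputs (tiny/constant studies)."""
        try:
            return pearson_r(x, y)
        except (InputError, DegenerateDataError):
            return type("R", (), {"r": float("nan"), "n": 0})()

    r_cv = _safe_r(cs, v)
    r_cr = _safe_r(cs, ratings)
    all_ids = [s.stimulus_id for s in sset.stimuli()]
    r_tq = _safe_r(
        np.array([table.scores[i] for i in all_ids]),
        np.array([qmap[i] for i in all_ids]),
    )

    # rater-consistency check: the pooled positivity selections should out-score
    # the cohort's mean self-CI score under the table itself
    pos_total = Fraction(0)
    pos_n = 0
    for s in pos_sessions:
        for t in s.answered:
            first_id, second_id = members[t.pair_id]
            pos_total += table.exact_score(first_id if t.choice == "first" else second_id)
            pos_n += 1
    group_positive_score = float(pos_total / pos_n)

    report = RecoveryReport(
        config=config,
        r_score_valence=r_cv.r,
        r_score_valence_ci=pearson_ci(r_cv.r, r_cv.n),
        r_score_ratings=r_cr.r,
        r_score_ratings_ci=pearson_ci(r_cr.r, r_cr.n),
        r_table_qtrue=r_tq.r,
        r_table_qtrue_ci=pearson_ci(r_tq.r, r_tq.n),
        score_mean=float(scores_df["score"].mean()),
        score_sd=float(scores_df["score"].std(ddof=1)) if len(scores_df) > 1 else 0.0,
        n_participants_scored=int(len(scores_df)),
        group_positive_score=group_positive_score,
        cohort_mean_self_score=float(scores_df["score"].mean()),
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_trial_log(res_sessions, out_dir / "resemblance_trials.csv")
        write_trial_log(pos_sessions, out_dir / "positivity_trials.csv")
        write_positivity_table(table, out_dir / "positivity_table.csv")
        write_scores(scores_df, out_dir / "computational_scores.csv")
        truth = pd.DataFrame(
            {
                "participant_id": [p.participant_id for p in participants],
                "self_valence": [p.self_valence for p in participants],
                "decisiveness": [p.decisiveness for p in participants],
            }
        )
        truth.to_csv(out_dir / "latent_participants.csv", index=False, float_format="%.12g")
        report.to_json(out_dir / "recovery_report.json")
        from PIL import Image

        pos_ci = build_group_ci(pos_sessions, sset)
        anti_ci = build_group_ci(pos_sessions, sset, selected=False)
        self_ci = build_group_ci(res_sessions, sset)
        for name, ci in (("positive_ci", pos_ci), ("anti_positive_ci", anti_ci),
                         ("group_self_ci", self_ci)):
            Image.fromarray(ci.rendering, mode="L").save(out_dir / f"{name}.png", format="PNG")
    return report
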