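"""Two-Step Task environment.

The task is a two-stage sequential decision problem: at stage 1 the
participant chooses between two spaceships, each of which travels to its
"common" planet with probability 0.7 and to the other planet otherwise; at
stage 2 they choose between the two aliens on the planet they reached, and
are rewarded with probability given by one of four independent Gaussian
random walks.  Because the walks drift, participants must keep learning
throughout the session, which is what lets model-based and model-free
valuation be separated behaviourally.

This module defines the environment (transition structure, reward walks,
trial sequencing), the trial-log containers, and the CSV dialect used to
persist sessions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TransitionStructure",
    "RewardWalkSet",
    "TaskConfig",
    "Trial",
    "SessionData",
    "Policy",
    "generate_reward_walks",
    "sample_transition",
    "run_session",
    "read_session_csv",
    "write_session_csv",
]

SESSIONS = ("baseline", "followup")
GROUPS = ("MUD", "control", "unknown")


class TaskConfigError(ValueError):
    """Invalid task configuration (bounds, lengths, probabilities)."""


class TrialLogParseError(ValueError):
    """Malformed trial-log file; message names the offending row."""


@dataclass(frozen=True)
class TransitionStructure:
    """First-stage action -> second-stage state transition rule.

    Action 0's common state is state 0, action 1's common state is state 1;
    each action's rare state is the other action's common state.  The task
    proper uses common_prob > 0.5; the degenerate symmetric case 0.5 is
    permitted for the sampler itself.
    """

    common_prob: float = 0.7

    def __post_init__(self) -> None:
        if not 0.5 <= self.common_prob <= 1.0:
            raise TaskConfigError(
                f"common_prob must lie in [0.5, 1], got {self.common_prob}"
            )

    def common_state(self, c1: int) -> int:
        return int(c1)

    def rare_state(self, c1: int) -> int:
        return 1 - int(c1)


@dataclass(frozen=True)
class RewardWalkSet:
    """Four bounded Gaussian random walks of reward probabilities.

    ``probs`` has shape (n_trials, 4); column ``2*state + alien`` is the
    reward probability of that alien on that planet.
    """

    probs: np.ndarray
    step_sd: float
    bounds: tuple[float, float]
    seed: Optional[int] = None

    @property
    def n_trials(self) -> int:
        return self.probs.shape[0]

    def prob(self, t: int, state: int, alien: int) -> float:
        """Reward probability on 0-based trial ``t`` for (state, alien)."""
        return float(self.probs[t, 2 * state + alien])

    def permuted(self, order: Sequence[int]) -> "RewardWalkSet":
        return dataclasses.replace(self, probs=self.probs[:, list(order)])


# Column permutations used for counterbalancing: identity, planets swapped,
# aliens swapped within planet, both.
_COUNTERBALANCE_ORDERS = (
    (0, 1, 2, 3),
    (2, 3, 0, 1),
    (1, 0, 3, 2),
    (3, 2, 1, 0),
)


@dataclass(frozen=True)
class TaskConfig:
    """Session layout: 200 main trials preceded by a 50-trial tutorial
    (10 response-training + 20 stage-2-only + 20 full practice trials)."""

    n_trials: int = 200
    n_practice_response: int = 10
    n_practice_stage2: int = 20
    n_practice_full: int = 20
    common_prob: float = 0.7
    walk_step_sd: float = 0.025
    walk_bounds: tuple[float, float] = (0.25, 0.75)
    counterbalance_id: int = 0

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise TaskConfigError("n_trials must be positive")
        lo, hi = self.walk_bounds
        if not (0.0 <= lo < hi <= 1.0):
            raise TaskConfigError(f"invalid walk bounds [{lo}, {hi}]")

    @property
    def n_practice_total(self) -> int:
        return (
            self.n_practice_response
            + self.n_practice_stage2
            + self.n_practice_full
        )

    @property
    def structure(self) -> TransitionStructure:
        return TransitionStructure(self.common_prob)


@dataclass
class Trial:
    """One main trial.  ``None`` marks a missing value.

    A missing stage-1 response voids the whole trial; a missing stage-2
    response keeps the stage-1 data but carries no reward.
    """

    t: int
    c1: Optional[int] = None
    side1: Optional[str] = None
    transition: Optional[str] = None
    s: Optional[int] = None
    c2: Optional[int] = None
    side2: Optional[str] = None
    r: Optional[int] = None
    rt1: Optional[float] = None
    rt2: Optional[float] = None

    @property
    def stage1_valid(self) -> bool:
        return self.c1 is not None

    @property
    def stage2_valid(self) -> bool:
        return self.c2 is not None

    @property
    def complete(self) -> bool:
        return self.c1 is not None and self.c2 is not None


@dataclass
class SessionData:
    """A participant-session's ordered trial log."""

    subject_id: str
    session: str = "baseline"
    group: str = "unknown"
    trials: list[Trial] = field(default_factory=list)
    walk_ref: int = 0

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def to_arrays(self) -> dict[str, np.ndarray]:
        """Integer-array view for the likelihood kernels.

        Missing entries are coded -1; ``valid1``/``valid2`` flag observed
        stage-1/stage-2 choices and ``complete`` flags trials that update
        the latent values (both choices observed).
        """
        n = self.n_trials
        c1 = np.full(n, -1, dtype=np.int64)
        s = np.full(n, -1, dtype=np.int64)
        c2 = np.full(n, -1, dtype=np.int64)
        r = np.full(n, -1, dtype=np.int64)
        for i, tr in enumerate(self.trials):
            if tr.c1 is not None:
                c1[i] = tr.c1
            if tr.s is not None:
                s[i] = tr.s
            if tr.c2 is not None:
                c2[i] = tr.c2
            if tr.r is not None:
                r[i] = tr.r
        return {
            "c1": c1,
            "s": s,
            "c2": c2,
            "r": r,
            "valid1": (c1 >= 0),
            "valid2": (c2 >= 0),
        }


# A policy supplies choices given what the agent has seen so far.  Stateful
# policies (learning agents) implement ``observe``; ``reset`` is called once
# per session.
class Policy:
    def reset(self) -> None:  # pragma: no cover - trivial default
        pass

    def choose_stage1(self, t: int) -> Optional[int]:
        raise NotImplementedError

    def choose_stage2(self, t: int, state: int) -> Optional[int]:
        raise NotImplementedError

    def observe(self, trial: Trial) -> None:  # pragma: no cover
        pass


class CallablePolicy(Policy):
    """Adapts plain functions ``(t) -> c1`` and ``(t, state) -> c2``."""

    def __init__(self, stage1: Callable, stage2: Callable):
        self._stage1 = stage1
        self._stage2 = stage2

    def choose_stage1(self, t):
        return self._stage1(t)

    def choose_stage2(self, t, state):
        return self._stage2(t, state)


def generate_reward_walks(config: TaskConfig, seed: int) -> RewardWalkSet:
    """Generate the four reflected Gaussian reward-probability walks.

    Initial values are drawn uniformly inside the bounds; each step adds
    N(0, step_sd) noise and reflects at the bounds.  The same seed always
    yields the identical matrix.
    """
    lo, hi = config.walk_bounds
    if not (0.0 <= lo < hi <= 1.0):
        raise TaskConfigError(f"invalid walk bounds [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    n = config.n_trials
    probs = np.empty((n, 4))
    x = rng.uniform(lo, hi, size=4)
    probs[0] = x
    for t in range(1, n):
        x = x + rng.normal(0.0, config.walk_step_sd, size=4)
        x = _reflect(x, lo, hi)
        probs[t] = x
    order = _COUNTERBALANCE_ORDERS[config.counterbalance_id % 4]
    return RewardWalkSet(
        probs=probs[:, list(order)],
        step_sd=config.walk_step_sd,
        bounds=(lo, hi),
        seed=seed,
    )


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect values into [lo, hi] (handles multiple bounces)."""
    width = hi - lo
    y = np.mod(x - lo, 2 * width)
    y = np.where(y > width, 2 * width - y, y)
    return lo + y


def load_walks(path, step_sd: float = 0.025,
               bounds: tuple[float, float] = (0.25, 0.75)) -> RewardWalkSet:
    """Load pre-determined walks from a 4-column CSV of probabilities."""
    df = pd.read_csv(path)
    if df.shape[1] != 4:
        raise TrialLogParseError(
            f"walk file must have 4 columns, found {df.shape[1]}"
        )
    probs = df.to_numpy(dtype=float)
    if np.any(probs < 0) or np.any(probs > 1):
        raise TrialLogParseError("walk file contains values outside [0, 1]")
    return RewardWalkSet(probs=probs, step_sd=step_sd, bounds=bounds)


def save_walks(walks: RewardWalkSet, path) -> None:
    pd.DataFrame(
        walks.probs, columns=["s0_a0", "s0_a1", "s1_a0", "s1_a1"]
    ).to_csv(path, index=False)


def sample_transition(
    c1: int, structure: TransitionStructure, rng: np.random.Generator
) -> tuple[int, str]:
    """Sample the second-stage state reached after stage-1 action ``c1``."""
    if c1 not in (0, 1):
        raise ValueError(f"c1 must be 0 or 1, got {c1}")
    if rng.random() < structure.common_prob:
        return structure.common_state(c1), "common"
    return structure.rare_state(c1), "rare"


def run_session(
    policy: Policy,
    walks: RewardWalkSet,
    config: TaskConfig,
    rng: np.random.Generator,
    subject_id: str = "sim",
    session: str = "baseline",
    group: str = "unknown",
    rt_sampler: Optional[Callable[[np.random.Generator], tuple[float, float]]] = None,
) -> SessionData:
    """Run one session of ``config.n_trials`` main trials.

    Stimulus left/right placement is randomized each trial and the response
    side recorded, so that key-based quality-control filters can operate on
    simulated data.  Rewards are Bernoulli draws from the walk probability
    of the chosen alien on the visited planet.
    """
    if walks.n_trials < config.n_trials:
        raise TaskConfigError(
            f"walks provide {walks.n_trials} trials, need {config.n_trials}"
        )
    structure = config.structure
    policy.reset()
    trials: list[Trial] = []
    for t in range(config.n_trials):
        # left/right placement of the two options at each stage
        flip1 = bool(rng.random() < 0.5)
        flip2 = bool(rng.random() < 0.5)
        trial = Trial(t=t + 1)
        c1 = policy.choose_stage1(t)
        if c1 is None:
            trials.append(trial)
            policy.observe(trial)
            continue
        trial.c1 = int(c1)
        trial.side1 = _side_of(trial.c1, flip1)
        state, label = sample_transition(trial.c1, structure, rng)
        trial.s = state
        trial.transition = label
        if rt_sampler is not None:
            trial.rt1 = rt_sampler(rng)[0]
        c2 = policy.choose_stage2(t, state)
        if c2 is not None:
            trial.c2 = int(c2)
            trial.side2 = _side_of(trial.c2, flip2)
            trial.r = int(rng.random() < walks.prob(t, state, trial.c2))
            if rt_sampler is not None:
                trial.rt2 = rt_sampler(rng)[1]
        trials.append(trial)
        policy.observe(trial)
    return SessionData(
        subject_id=subject_id,
        session=session,
        group=group,
        trials=trials,
        walk_ref=config.counterbalance_id,
    )


def _side_of(choice: int, flipped: bool) -> str:
    # option 0 appears on the left unless the placement was flipped
    left_option = 1 if flipped else 0
    return "left" if choice == left_option else "right"


# ---------------------------------------------------------------------------
# Trial-log CSV dialect

_CSV_COLUMNS = [
    "subject_id", "group", "session", "trial", "c1", "side1", "transition",
    "state", "c2", "side2", "reward", "rt1", "rt2",
]


def write_session_csv(sessions: Iterable[SessionData], path) -> None:
    """Write sessions in the trial-log CSV dialect (missing = empty field)."""
    rows = []
    for sess in sessions:
        for tr in sess.trials:
            rows.append({
                "subject_id": sess.subject_id,
                "group": sess.group,
                "session": sess.session,
                "trial": tr.t,
                "c1": tr.c1,
                "side1": tr.side1,
                "transition": tr.transition,
                "state": tr.s,
                "c2": tr.c2,
                "side2": tr.side2,
                "reward": tr.r,
                "rt1": tr.rt1,
                "rt2": tr.rt2,
            })
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    df.to_csv(path, index=False)


def read_session_csv(path, common_prob: float = 0.7) -> list[SessionData]:
    """Read a trial-log CSV back into SessionData objects.

    Validates trial-index monotonicity and the consistency of the recorded
    transition label with (c1, state); raises :class:`TrialLogParseError`
    naming the offending row.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing_cols = set(_CSV_COLUMNS) - set(df.columns)
    if missing_cols:
        raise TrialLogParseError(
            f"trial log missing columns: {sorted(missing_cols)}"
        )
    structure = TransitionStructure(common_prob)
    sessions: list[SessionData] = []
    if df.empty:
        return sessions
    for (sid, sess_label), grp in df.groupby(
        ["subject_id", "session"], sort=False
    ):
        groups = grp["group"].dropna().unique()
        group = str(groups[0]) if len(groups) else "unknown"
        if group not in GROUPS:
            raise TrialLogParseError(
                f"unknown group code {group!r} for subject {sid}"
            )
        if sess_label not in SESSIONS:
            raise TrialLogParseError(
                f"unknown session code {sess_label!r} for subject {sid}"
            )
        trials = []
        expected_t = 1
        for row_idx, row in grp.iterrows():
            t = _as_int(row["trial"], row_idx, "trial")
            if t != expected_t:
                raise TrialLogParseError(
                    f"row {row_idx}: trial index {t} out of order "
                    f"(expected {expected_t}) for subject {sid}"
                )
            expected_t += 1
            trial = Trial(
                t=t,
                c1=_opt_int(row["c1"], row_idx, "c1", {0, 1}),
                side1=_opt_str(row["side1"], row_idx, "side1",
                               {"left", "right"}),
                transition=_opt_str(row["transition"], row_idx, "transition",
                                    {"common", "rare"}),
                s=_opt_int(row["state"], row_idx, "state", {0, 1}),
                c2=_opt_int(row["c2"], row_idx, "c2", {0, 1}),
                side2=_opt_str(row["side2"], row_idx, "side2",
                               {"left", "right"}),
                r=_opt_int(row["reward"], row_idx, "reward", {0, 1}),
                rt1=_opt_float(row["rt1"]),
                rt2=_opt_float(row["rt2"]),
            )
            if trial.c1 is None and (
                trial.s is not None or trial.c2 is not None
                or trial.r is not None
            ):
                raise TrialLogParseError(
                    f"row {row_idx}: downstream fields present despite "
                    "missing stage-1 choice"
                )
            if trial.c1 is not None and trial.s is not None:
                expected = (
                    "common"
                    if trial.s == structure.common_state(trial.c1)
                    else "rare"
                )
                if trial.transition != expected:
                    raise TrialLogParseError(
                        f"row {row_idx}: transition label "
                        f"{trial.transition!r} inconsistent with c1="
                        f"{trial.c1}, state={trial.s}"
                    )
            if trial.r is not None and trial.c2 is None:
                raise TrialLogParseError(
                    f"row {row_idx}: reward present without stage-2 choice"
                )
            trials.append(trial)
        sessions.append(
            SessionData(
                subject_id=str(sid), session=str(sess_label), group=group,
                trials=trials,
            )
        )
    return sessions


def _as_int(value, row_idx, name) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise TrialLogParseError(
            f"row {row_idx}: non-integer {name}: {value!r}"
        ) from None


def _opt_int(value, row_idx, name, allowed) -> Optional[int]:
    if pd.isna(value):
        return None
    iv = _as_int(value, row_idx, name)
    if iv not in allowed:
        raise TrialLogParseError(
            f"row {row_idx}: {name}={iv} not in {sorted(allowed)}"
        )
    return iv


def _opt_str(value, row_idx, name, allowed) -> Optional[str]:
    if pd.isna(value):
        return None
    sv = str(value)
    if sv not in allowed:
        raise TrialLogParseError(
            f"row {row_idx}: {name}={sv!r} not in {sorted(allowed)}"
        )
    return sv


def _opt_float(value) -> Optional[float]:
    if pd.isna(value):
        return None
    return float(value)
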