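"""Hybrid model-based/model-free Q-learning agent.

Five parameters govern behaviour:

* ``alpha`` — shared learning *and* forgetting rate: chosen options are
  updated toward reward with weight (1 - alpha) on the old value, and all
  unchosen options decay by the same factor each trial.
* ``beta_mb`` — weight of the model-based stage-1 value (the maximum alien
  value in each spaceship's common planet).
* ``beta_mf`` — weight of the model-free stage-1 value (the cached value of
  the alien last chosen after taking that spaceship).
* ``beta_rep`` — value-independent bias to repeat the previous stage-1
  choice (positive = perseveration, negative = alternation).
* ``beta_consistency`` — stage-2 inverse temperature.

Both stage choices are softmax in these quantities.  The module provides
the per-trial update operations, a readable reference log-likelihood that
composes them, a compiled log-likelihood used by the fitting code, the
generative simulator, and the random-choice (chance) null model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import _kernels
from .task import (
    Policy,
    RewardWalkSet,
    SessionData,
    TaskConfig,
    TransitionStructure,
    Trial,
    run_session,
)

__all__ = [
    "ParameterSet",
    "LatentValues",
    "update_stage2",
    "mb_stage1_values",
    "mf_stage1_update",
    "stage1_choice_probs",
    "stage2_choice_probs",
    "session_loglik",
    "session_loglik_reference",
    "simulate_agent",
    "chance_loglik",
    "HybridPolicy",
]

LOG_HALF = math.log(0.5)
PARAM_NAMES = ("alpha", "beta_mb", "beta_mf", "beta_rep", "beta_consistency")


@dataclass(frozen=True)
class ParameterSet:
    """The five hybrid-model parameters in natural space."""

    alpha: float
    beta_mb: float
    beta_mf: float
    beta_rep: float
    beta_consistency: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError(f"non-finite parameter in {self}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        for name in ("beta_mb", "beta_mf", "beta_consistency"):
            if getattr(self, name) < 0.0:
                raise ValueError(
                    f"{name} must be non-negative, got {getattr(self, name)}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta_mb, self.beta_mf,
                         self.beta_rep, self.beta_consistency])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(PARAM_NAMES, self.as_array()))

    @classmethod
    def from_array(cls, arr) -> "ParameterSet":
        return cls(*[float(v) for v in arr])


@dataclass
class LatentValues:
    """The Q tables carried across trials (all initialized to zero)."""

    q_stage1: np.ndarray = field(
        default_factory=lambda: np.zeros(2))          # model-free, per spaceship
    q_stage2: np.ndarray = field(
        default_factory=lambda: np.zeros((2, 2)))     # per (planet, alien)

    def copy(self) -> "LatentValues":
        return LatentValues(self.q_stage1.copy(), self.q_stage2.copy())

    def q_mb(self, structure: TransitionStructure) -> np.ndarray:
        return mb_stage1_values(self.q_stage2, structure)


def update_stage2(q: float, alpha: float, r: int) -> float:
    """Reward update of a chosen alien: (1 - alpha) * q + r."""
    return (1.0 - alpha) * q + r


def mb_stage1_values(
    q_stage2: np.ndarray, structure: TransitionStructure
) -> np.ndarray:
    """Model-based stage-1 values: for each spaceship, the maximum alien
    value on its common planet."""
    q_stage2 = np.asarray(q_stage2)
    return np.array([
        q_stage2[structure.common_state(a)].max() for a in (0, 1)
    ])


def mf_stage1_update(
    values: LatentValues, trial: Trial, alpha: float
) -> LatentValues:
    """End-of-trial latent-value update.

    The chosen alien learns from reward; the chosen spaceship's model-free
    value is set to that freshly updated alien value; every unchosen
    spaceship and alien decays by (1 - alpha).  Missing (incomplete) trials
    leave the values untouched.
    """
    if not trial.complete:
        return values
    out = values.copy()
    decay = 1.0 - alpha
    out.q_stage2 *= decay
    # the chosen alien's decay is part of its reward update, not double decay
    out.q_stage2[trial.s, trial.c2] = update_stage2(
        values.q_stage2[trial.s, trial.c2], alpha, trial.r
    )
    chosen_value = out.q_stage2[trial.s, trial.c2]
    out.q_stage1 *= decay
    out.q_stage1[trial.c1] = chosen_value
    return out


def stage1_choice_probs(
    values: LatentValues,
    params: ParameterSet,
    prev_c1: Optional[int],
    structure: TransitionStructure = TransitionStructure(),
) -> np.ndarray:
    """Softmax stage-1 choice probabilities.

    Preference of each spaceship is beta_mb * Q_MB + beta_mf * Q_MF plus
    beta_rep if it repeats the previous stage-1 choice; on the first trial
    (no previous choice) the repetition term is zero for both.
    """
    v = (params.beta_mb * values.q_mb(structure)
         + params.beta_mf * values.q_stage1)
    if prev_c1 is not None:
        v = v + params.beta_rep * np.array(
            [prev_c1 == 0, prev_c1 == 1], dtype=float
        )
    return _softmax(v)


def stage2_choice_probs(
    q_stage2: np.ndarray, s: int, params: ParameterSet
) -> np.ndarray:
    """Softmax over the two aliens of the visited planet."""
    return _softmax(params.beta_consistency * np.asarray(q_stage2)[s])


def _softmax(v: np.ndarray) -> np.ndarray:
    e = np.exp(v - v.max())
    return e / e.sum()


def session_loglik(params: ParameterSet, session: SessionData) -> float:
    """Log-likelihood of the observed choices under the hybrid model.

    Runs the latent-value recursion in trial order (compiled kernel) and
    sums log probabilities of every observed stage-1 and stage-2 choice.
    Missing choices contribute nothing and incomplete trials do not update
    the latent values.
    """
    arrs = session.to_arrays()
    if not arrs["valid1"].any():
        warnings.warn(
            f"session {session.subject_id}/{session.session} has no valid "
            "trials; log-likelihood is 0", stacklevel=2,
        )
        return 0.0
    return float(_kernels.session_loglik_kernel(
        arrs["c1"], arrs["s"], arrs["c2"], arrs["r"],
        arrs["valid1"], arrs["valid2"],
        params.alpha, params.beta_mb, params.beta_mf,
        params.beta_rep, params.beta_consistency,
    ))


def session_loglik_reference(
    params: ParameterSet, session: SessionData
) -> float:
    """Single-trial-stepping reference likelihood.

    Composes the documented per-trial operations one trial at a time; the
    compiled kernel is required to match this to high precision.
    """
    structure = TransitionStructure()
    values = LatentValues()
    prev_c1: Optional[int] = None
    ll = 0.0
    for trial in session.trials:
        if not trial.stage1_valid:
            continue
        p1 = stage1_choice_probs(values, params, prev_c1, structure)
        ll += math.log(max(p1[trial.c1], 1e-12))
        prev_c1 = trial.c1
        if not trial.stage2_valid:
            continue
        p2 = stage2_choice_probs(values.q_stage2, trial.s, params)
        ll += math.log(max(p2[trial.c2], 1e-12))
        values = mf_stage1_update(values, trial, params.alpha)
    return ll


def chance_loglik(session: SessionData) -> float:
    """Log-likelihood of the random-choice null model: every observed
    choice at either stage has probability one half."""
    n_choices = sum(
        int(tr.stage1_valid) + int(tr.stage2_valid) for tr in session.trials
    )
    return n_choices * LOG_HALF


class HybridPolicy(Policy):
    """Generative policy sampling choices from the hybrid model."""

    def __init__(self, params: ParameterSet, rng: np.random.Generator,
                 structure: TransitionStructure = TransitionStructure(),
                 miss_prob: float = 0.0):
        self.params = params
        self.rng = rng
        self.structure = structure
        self.miss_prob = miss_prob
        self.reset()

    def reset(self) -> None:
        self.values = LatentValues()
        self.prev_c1: Optional[int] = None

    def choose_stage1(self, t: int) -> Optional[int]:
        if self.miss_prob and self.rng.random() < self.miss_prob:
            return None
        p = stage1_choice_probs(
            self.values, self.params, self.prev_c1, self.structure
        )
        return int(self.rng.random() >= p[0])

    def choose_stage2(self, t: int, state: int) -> Optional[int]:
        if self.miss_prob and self.rng.random() < self.miss_prob:
            return None
        p = stage2_choice_probs(self.values.q_stage2, state, self.params)
        return int(self.rng.random() >= p[0])

    def observe(self, trial: Trial) -> None:
        if trial.stage1_valid:
            self.prev_c1 = trial.c1
        self.values = mf_stage1_update(self.values, trial, self.params.alpha)


def simulate_agent(
    params: ParameterSet,
    walks: RewardWalkSet,
    config: TaskConfig,
    rng: np.random.Generator,
    subject_id: str = "sim",
    session: str = "baseline",
    group: str = "unknown",
    miss_prob: float = 0.0,
    rt_sampler=None,
) -> SessionData:
    """Simulate one session of hybrid-agent behaviour on the given walks."""
    policy = HybridPolicy(params, rng, config.structure, miss_prob=miss_prob)
    return run_session(
        policy, walks, config, rng,
        subject_id=subject_id, session=session, group=group,
        rt_sampler=rt_sampler,
    )
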