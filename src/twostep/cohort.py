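"""Synthetic two-group, two-session cohort generator and QC filters.

Generates a cohort with the statistical structure the downstream analyses
assume: per-group Gaussian parameter distributions on the unconstrained
scale (the MUD-like group shifted toward lower model-free weight, lower
repetition bias and higher stage-2 consistency than the control-like
group), correlated baseline/follow-up parameters, follow-up attrition,
occasional missing responses, log-normal reaction times, and an optional
admixture of pathological response patterns (high missingness, single-key
responding, implausibly fast RTs, random choosing) that the engagement
filters are meant to catch.

Every choice is reproducible from (seed, spec), and the generating
parameters are returned as a ground-truth table for testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .agent import PARAM_NAMES, HybridPolicy, ParameterSet
from .fitting import to_natural
from .task import SessionData, TaskConfig, generate_reward_walks, run_session

__all__ = ["GroupDistribution", "CohortSpec", "generate_cohort",
           "generate_use_table", "QCReport", "apply_qc_filters"]

PATHOLOGY_KINDS = ("high_missing", "single_key", "fast_rt", "random")


@dataclass(frozen=True)
class GroupDistribution:
    """Gaussian parameter distribution on the unconstrained scale
    (order: logit-alpha, log beta_mb, log beta_mf, beta_rep,
    log beta_consistency)."""

    mean: tuple[float, ...]
    sd: tuple[float, ...] = (0.8, 0.6, 0.5, 0.5, 0.4)

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        return np.asarray(self.mean) + np.asarray(self.sd) * rng.normal(
            size=5
        )


# Defaults encode only the reported direction of group differences
# (MUD: lower beta_mf, lower beta_rep, higher beta_consistency) at a
# moderate effect size; alpha and beta_mb do not differ.
CONTROL_DIST = GroupDistribution(mean=(0.0, -0.3, 0.5, 0.9, 0.8))
MUD_DIST = GroupDistribution(mean=(0.0, -0.3, 0.1, 0.5, 1.1))


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate a cohort deterministically."""

    n_mud: int = 30
    n_control: int = 31
    mud_dist: GroupDistribution = MUD_DIST
    control_dist: GroupDistribution = CONTROL_DIST
    session_corr: float = 0.7            # baseline/follow-up theta correlation
    attrition_mud: float = 7 / 30
    attrition_control: float = 5 / 31
    missing_trial_rate: float = 0.02
    pathological_fracs: dict = field(default_factory=dict)
    rt_log_mean: float = np.log(0.7)     # seconds, subject-level location
    rt_subject_sd: float = 0.15
    rt_trial_sd: float = 0.3
    fast_rt_log_mean: float = np.log(0.18)
    task: TaskConfig = field(default_factory=TaskConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mud < 2 or self.n_control < 2:
            raise ValueError("need at least 2 subjects per group")
        for name in ("attrition_mud", "attrition_control",
                     "missing_trial_rate", "session_corr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for k in self.pathological_fracs:
            if k not in PATHOLOGY_KINDS:
                raise ValueError(f"unknown pathology kind {k!r}")


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[SessionData], pd.DataFrame]:
    """Generate the cohort; returns (sessions, ground-truth table).

    The four reward walks are generated once per cohort and reassigned to
    subjects round-robin through the four counterbalance permutations;
    each subject keeps the same walks at follow-up.
    """
    rng = np.random.default_rng(spec.seed)
    roster = (
        [("MUD", i) for i in range(spec.n_mud)]
        + [("control", i) for i in range(spec.n_control)]
    )
    # assign pathologies deterministically from the spec'd fractions
    n_total = len(roster)
    pathology = ["none"] * n_total
    cursor = 0
    for kind in PATHOLOGY_KINDS:
        frac = spec.pathological_fracs.get(kind, 0.0)
        n_k = int(round(frac * n_total))
        for _ in range(n_k):
            if cursor < n_total:
                pathology[cursor] = kind
                cursor += 1
    perm = rng.permutation(n_total)
    pathology = [pathology[perm[i]] for i in range(n_total)]

    sessions: list[SessionData] = []
    truth_rows = []
    walk_seed = int(rng.integers(2 ** 31))
    for idx, (group, _) in enumerate(roster):
        sid = f"{group[:1].upper()}{idx:03d}"
        dist = spec.mud_dist if group == "MUD" else spec.control_dist
        theta1 = dist.draw(rng)
        mean = np.asarray(dist.mean)
        sd = np.asarray(dist.sd)
        rho = spec.session_corr
        theta2 = (mean + rho * (theta1 - mean)
                  + np.sqrt(1 - rho ** 2) * sd * rng.normal(size=5))
        attr_p = (spec.attrition_mud if group == "MUD"
                  else spec.attrition_control)
        has_followup = rng.random() >= attr_p
        cfg = replace(spec.task, counterbalance_id=idx % 4)
        walks = generate_reward_walks(cfg, seed=walk_seed)
        kind = pathology[idx]
        for sess_label, theta in (("baseline", theta1),
                                  ("followup", theta2)):
            if sess_label == "followup" and not has_followup:
                continue
            params = to_natural(theta)
            sess = _simulate_session(
                params, walks, cfg, rng, sid, sess_label, group, spec, kind
            )
            sessions.append(sess)
            truth_rows.append({
                "subject_id": sid, "group": group, "session": sess_label,
                "pathology": kind,
                **params.as_dict(),
                **{f"theta_{n}": t for n, t in zip(PARAM_NAMES, theta)},
            })
    return sessions, pd.DataFrame(truth_rows)


def _simulate_session(params, walks, cfg, rng, sid, sess_label, group,
                      spec, kind):
    miss = spec.missing_trial_rate / 2.0
    rt_loc = spec.rt_log_mean + spec.rt_subject_sd * rng.normal()
    if kind == "high_missing":
        miss = 0.10                         # ~19% of trials affected
    elif kind == "fast_rt":
        rt_loc = spec.fast_rt_log_mean
    elif kind == "random":
        params = ParameterSet(0.5, 0.0, 0.0, 0.0, 0.0)

    def rt_sampler(r):
        return (float(np.exp(rt_loc + spec.rt_trial_sd * r.normal())),
                float(np.exp(rt_loc + spec.rt_trial_sd * r.normal())))

    policy = HybridPolicy(
        params if kind != "single_key" else ParameterSet(0.5, 0, 0, 0, 0),
        rng, cfg.structure, miss_prob=miss,
    )
    sess = run_session(
        policy, walks, cfg, rng, subject_id=sid, session=sess_label,
        group=group, rt_sampler=rt_sampler,
    )
    if kind == "single_key":
        # the subject presses the left key regardless of stimulus; their
        # recorded response side is 'left' on almost every trial
        for tr in sess.trials:
            if tr.side1 is not None and rng.random() < 0.97:
                tr.side1 = "left"
            if tr.side2 is not None and rng.random() < 0.97:
                tr.side2 = "left"
    return sess


def generate_use_table(
    truth: pd.DataFrame,
    rng: np.random.Generator,
    link_param: str = "beta_consistency",
    link_strength: float = 2.0,
) -> pd.DataFrame:
    """Synthetic substance-use metadata for the MUD group.

    Frequency of use rises monotonically with ``link_param`` (plus noise);
    days-since-last-use and severity (SDS) are unrelated to the model
    parameters.  Only meant to exercise the correlation/regression
    analyses, not to mimic real clinical distributions.
    """
    base = truth[(truth["group"] == "MUD")
                 & (truth["session"] == "baseline")]
    rows = []
    for _, r in base.iterrows():
        rows.append({
            "subject_id": r["subject_id"],
            "days_since_last_use": float(np.exp(rng.normal(2.5, 0.6))),
            "frequency_of_use": float(
                10.0 + link_strength * r[link_param] + rng.normal(0, 1.0)
            ),
            "sds": float(np.clip(rng.normal(8, 3), 0, 15)),
            "dosage": float(np.exp(rng.normal(-0.5, 0.5))),
        })
    return pd.DataFrame(rows)


@dataclass
class QCReport:
    """Per subject-session engagement metrics and exclusion flags."""

    table: pd.DataFrame     # subject_id, session, missing_frac,
    #                         max_same_key_frac, mean_rt, excluded, reasons

    @property
    def excluded(self) -> pd.DataFrame:
        return self.table[self.table["excluded"]]

    def passed_sessions(
        self, sessions: Sequence[SessionData]
    ) -> list[SessionData]:
        bad = {(r.subject_id, r.session)
               for r in self.excluded.itertuples()}
        return [s for s in sessions
                if (s.subject_id, s.session) not in bad]


def apply_qc_filters(
    sessions: Sequence[SessionData],
    missing_threshold: float = 0.10,
    same_key_threshold: float = 0.95,
    rt_sd_threshold: float = 2.0,
) -> QCReport:
    """Flag sessions showing suboptimal engagement.

    Three rules: missing more than 10% of trials; responding with the same
    key (response side, pooled over both stages) on more than 95% of
    trials; and a mean reaction time more than two standard deviations
    faster than the other participants' mean RTs (leave-one-out).
    """
    if len(sessions) < 3:
        raise ValueError("RT screening needs at least 3 sessions")
    metrics = []
    for s in sessions:
        n = s.n_trials
        n_missing = sum(1 for tr in s.trials if not tr.complete)
        sides = [tr.side1 for tr in s.trials if tr.side1 is not None]
        sides += [tr.side2 for tr in s.trials if tr.side2 is not None]
        if sides:
            counts = pd.Series(sides).value_counts()
            same_key = float(counts.max() / len(sides))
        else:
            same_key = np.nan
        rts = [tr.rt1 for tr in s.trials if tr.rt1 is not None]
        rts += [tr.rt2 for tr in s.trials if tr.rt2 is not None]
        mean_rt = float(np.mean(rts)) if rts else np.nan
        metrics.append({
            "subject_id": s.subject_id, "session": s.session,
            "missing_frac": n_missing / n if n else np.nan,
            "max_same_key_frac": same_key,
            "mean_rt": mean_rt,
        })
    df = pd.DataFrame(metrics)
    mean_rts = df["mean_rt"].to_numpy()
    reasons_col, excluded_col = [], []
    for i, row in df.iterrows():
        reasons = []
        if row["missing_frac"] > missing_threshold:
            reasons.append(
                f"missing>{missing_threshold:.0%}"
            )
        if (np.isfinite(row["max_same_key_frac"])
                and row["max_same_key_frac"] > same_key_threshold):
            reasons.append(f"same_key>{same_key_threshold:.0%}")
        if np.isfinite(row["mean_rt"]):
            others = np.delete(mean_rts, i)
            others = others[np.isfinite(others)]
            if len(others) >= 2:
                mu, sd = float(np.mean(others)), float(np.std(others, ddof=1))
                if sd > 0 and row["mean_rt"] < mu - rt_sd_threshold * sd:
                    reasons.append(f"rt<{rt_sd_threshold:g}sd_fast")
        reasons_col.append(",".join(reasons))
        excluded_col.append(bool(reasons))
    df["excluded"] = excluded_col
    df["reasons"] = reasons_col
    return QCReport(table=df)
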