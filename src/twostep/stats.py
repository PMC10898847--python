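"""Overt-behaviour and group-level statistics.

Covers the full behavioural analysis battery: trial-pair stay/switch
coding, the baseline and longitudinal mixed logistic regressions of Stay
on Previous Win x Previous Transition x Group (x Time), Tukey-adjusted
marginal-mean contrasts, Mann-Whitney comparisons of fitted parameters,
2x2 Group-by-Time mixed ANOVAs, and the substance-use correlation /
multiple-regression analyses.

Coding conventions: Previous Win and Previous Transition are effect-coded
-1/+1; Group is control=0, MUD=1 and Time is baseline=0, follow-up=1
(treatment coding), so a negative Group x Previous Win estimate means the
MUD group's reward sensitivity is reduced relative to controls.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .glmm import MixedLogitResult, SeparationError, fit_mixed_logit
from .task import SESSIONS, SessionData

__all__ = [
    "code_stay_records",
    "RegressionResult",
    "fit_stay_glmm",
    "marginal_means_posthoc",
    "GroupTestResult",
    "compare_parameter_groups",
    "anova_group_by_time",
    "correlate_params_use",
]

GROUP_CODES = {"control": 0, "MUD": 1}
BASELINE_TERMS = [
    "const", "prev_win", "prev_transition", "group",
    "prev_win:prev_transition", "group:prev_win", "group:prev_transition",
    "group:prev_win:prev_transition",
]
LONGITUDINAL_TERMS = BASELINE_TERMS + [
    "time", "group:time", "time:prev_win", "time:prev_transition",
    "time:prev_win:prev_transition", "time:group:prev_win",
    "time:group:prev_transition", "time:group:prev_win:prev_transition",
]


def code_stay_records(sessions: Sequence[SessionData]) -> pd.DataFrame:
    """Build the stay/switch regression table.

    One row per consecutive pair of trials in which the earlier trial is
    complete (choice, transition and reward all observed) and the later
    trial has a stage-1 choice; pairs spanning a missing trial are dropped.
    """
    rows = []
    for sess in sessions:
        g = GROUP_CODES.get(sess.group, np.nan)
        time = SESSIONS.index(sess.session)
        for prev, cur in zip(sess.trials, sess.trials[1:]):
            if not (prev.complete and cur.stage1_valid):
                continue
            rows.append({
                "subject_id": sess.subject_id,
                "group": g,
                "time": time,
                "stay": int(cur.c1 == prev.c1),
                "prev_win": 1 if prev.r == 1 else -1,
                "prev_transition": 1 if prev.transition == "common" else -1,
            })
    return pd.DataFrame(
        rows, columns=["subject_id", "group", "time", "stay",
                       "prev_win", "prev_transition"],
    )


@dataclass
class RegressionResult:
    """Mixed logistic regression output in a printed-table-like layout."""

    table: pd.DataFrame            # term, estimate, se, z, p, OR, CI
    cov_params: pd.DataFrame
    re_sd: dict[str, float]
    n_obs: int
    n_subjects: int
    converged: bool
    longitudinal: bool

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]

    def summary(self) -> str:
        hdr = ("Longitudinal" if self.longitudinal else "Baseline")
        lines = [f"{hdr} stay/switch mixed logistic regression "
                 f"(n={self.n_obs}, subjects={self.n_subjects})"]
        for name, sd in self.re_sd.items():
            lines.append(f"  random {name} sd: {sd:.3f}")
        lines.append(self.table.to_string(
            float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)


def _design(records: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    cols = {"const": np.ones(len(records))}
    for term in terms:
        if term == "const":
            continue
        parts = term.split(":")
        v = np.ones(len(records))
        for p in parts:
            v = v * records[p].to_numpy(dtype=float)
        cols[term] = v
    return pd.DataFrame(cols, index=records.index)


def fit_stay_glmm(
    records: pd.DataFrame,
    longitudinal: bool = False,
    n_quad: int = 12,
) -> RegressionResult:
    """Fit the stay/switch mixed logistic regression.

    The baseline model regresses Stay on the full Previous Win x Previous
    Transition x Group factorial with a random intercept per participant;
    the longitudinal model additionally crosses every term with Time and
    adds an independent random Time slope per participant.
    """
    records = records.dropna(subset=["group"])
    n_per_group = records.groupby("group")["subject_id"].nunique()
    if (n_per_group < 2).any() or len(n_per_group) < 2:
        raise ValueError(
            "need at least 2 subjects in each of two groups, got "
            f"{n_per_group.to_dict()}"
        )
    terms = LONGITUDINAL_TERMS if longitudinal else BASELINE_TERMS
    X = _design(records, terms)
    cell_cols = ["group", "prev_win"] + (["time"] if longitudinal else [])
    res: MixedLogitResult = fit_mixed_logit(
        X, records["stay"], records["subject_id"],
        slope=records["time"] if longitudinal else None,
        n_quad=n_quad,
        check_cells=records[cell_cols],
    )
    table = res.odds_ratios()
    table.insert(0, "term", table.index)
    return RegressionResult(
        table=table,
        cov_params=res.cov_params,
        re_sd=res.re_sd,
        n_obs=res.n_obs,
        n_subjects=records["subject_id"].nunique(),
        converged=res.converged,
        longitudinal=longitudinal,
    )


def _cell_vector(columns, group, prev_win, time=0.0):
    """Design vector of a (group, prev_win) cell with prev_transition
    averaged out (its effect-coded levels cancel at 0)."""
    vals = {"const": 1.0, "group": group, "prev_win": prev_win,
            "prev_transition": 0.0, "time": time}
    x = np.zeros(len(columns))
    for i, term in enumerate(columns):
        v = 1.0
        for p in term.split(":"):
            v *= vals[p] if p != "const" else 1.0
        x[i] = v
    return x


def marginal_means_posthoc(
    result: RegressionResult,
    contrasts: Optional[Sequence[tuple]] = None,
    time: float = 0.0,
) -> pd.DataFrame:
    """Estimated-marginal-mean contrasts among the Group x Previous-Win
    cells, Tukey-adjusted over the contrast family.

    Each cell is the model's stay log-odds for a group after reward
    (prev_win=+1) or non-reward (-1), with Previous Transition averaged
    out.  ``contrasts`` is a list of ((g, pw), (g, pw)) cell pairs; the
    default family is all six pairwise comparisons of the four cells.
    A single requested contrast is returned unadjusted.
    """
    cells = list(itertools.product((0, 1), (-1, 1)))   # (group, prev_win)
    if contrasts is None:
        contrasts = list(itertools.combinations(cells, 2))
    cols = list(result.cov_params.columns)
    beta = result.table["estimate"].reindex(cols).to_numpy()
    V = result.cov_params.to_numpy()
    k = len(cells)
    rows = []
    for (c1, c2) in contrasts:
        x1 = _cell_vector(cols, *c1, time=time)
        x2 = _cell_vector(cols, *c2, time=time)
        d = x1 - x2
        est = float(d @ beta)
        se = float(np.sqrt(d @ V @ d))
        z = est / se if se > 0 else np.nan
        if len(contrasts) == 1:
            p = float(2.0 * sps.norm.sf(abs(z)))
        else:
            # Tukey HSD on the family of k marginal means
            p = float(sps.studentized_range.sf(
                abs(z) * np.sqrt(2.0), k, 1e6
            ))
        zq = sps.norm.ppf(0.975)
        rows.append({
            "cell_1": _cell_name(*c1), "cell_2": _cell_name(*c2),
            "estimate": est, "se": se, "z": z,
            "OR": float(np.exp(est)),
            "OR_lo": float(np.exp(est - zq * se)),
            "OR_hi": float(np.exp(est + zq * se)),
            "p_adj": p,
        })
    return pd.DataFrame(rows)


def _cell_name(group, prev_win):
    gname = {0: "control", 1: "MUD"}[group]
    wname = {1: "rewarded", -1: "unrewarded"}[prev_win]
    return f"{gname}|{wname}"


@dataclass
class GroupTestResult:
    parameter: str
    test: str
    statistic: float
    p: float
    direction: str
    effect: float        # rank-biserial (MW) or partial eta^2 (ANOVA)


def compare_parameter_groups(
    param_table: pd.DataFrame,
    parameter: str,
    groups: tuple[str, str] = ("control", "MUD"),
    group_col: str = "group",
) -> GroupTestResult:
    """Two-sided Mann-Whitney U comparison of a fitted parameter between
    groups (rank-based, since parameter distributions are skewed)."""
    a = param_table.loc[param_table[group_col] == groups[0], parameter]
    b = param_table.loc[param_table[group_col] == groups[1], parameter]
    a, b = a.dropna().to_numpy(), b.dropna().to_numpy()
    if min(len(a), len(b)) < 3:
        raise ValueError("need at least 3 observations per group")
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn(f"{parameter} is constant; p set to 1", stacklevel=2)
        return GroupTestResult(parameter, "mann-whitney",
                               len(a) * len(b) / 2.0, 1.0, "none", 0.0)
    method = "exact" if max(len(a), len(b)) <= 20 else "asymptotic"
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    rb = 2.0 * u / (len(a) * len(b)) - 1.0     # rank-biserial correlation
    direction = (f"{groups[0]} > {groups[1]}" if rb > 0
                 else f"{groups[1]} > {groups[0]}" if rb < 0 else "none")
    return GroupTestResult(parameter, "mann-whitney", float(u), float(p),
                           direction, float(rb))


def anova_group_by_time(
    param_table: pd.DataFrame,
    parameter: str,
    group_col: str = "group",
) -> pd.DataFrame:
    """2 (Group, between) x 2 (Time, within) mixed ANOVA on a parameter.

    Subjects without both sessions are dropped (with a warning naming the
    count).  Returns the pingouin ANOVA table with rows Group, Session
    (time) and Interaction.
    """
    import pingouin as pg

    counts = param_table.groupby("subject_id")["session"].nunique()
    complete = counts[counts == 2].index
    dropped = counts.index.difference(complete)
    if len(dropped):
        warnings.warn(
            f"dropping {len(dropped)} subject(s) without both sessions",
            stacklevel=2,
        )
    df = param_table[param_table["subject_id"].isin(complete)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        aov = pg.mixed_anova(
            data=df, dv=parameter, within="session",
            subject="subject_id", between=group_col,
        )
    return aov


def correlate_params_use(
    param_table: pd.DataFrame,
    use_table: pd.DataFrame,
    use_vars: Sequence[str],
    covariate: str = "days_since_last_use",
    outlier_limits: Optional[dict[str, float]] = None,
) -> dict:
    """Substance-use correlation and regression analyses (MUD group).

    Computes the Spearman correlation matrix over the five model
    parameters, the use-pattern variables and the covariate, then for each
    use variable fits an OLS regression of the (mean-centred) outcome on
    the five parameters plus the days-since-last-use covariate, reporting
    variance-inflation factors.  ``outlier_limits`` maps a column name to
    a maximum value; rows exceeding it are excluded from analyses that
    involve that column.
    """
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import (
        variance_inflation_factor,
    )

    from .agent import PARAM_NAMES

    df = param_table.merge(use_table, on="subject_id")
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    outlier_limits = outlier_limits or {}
    predictors = list(PARAM_NAMES) + [covariate]

    def _clean(cols):
        sub = df.dropna(subset=cols)
        for col, lim in outlier_limits.items():
            if col in cols:
                sub = sub[sub[col] <= lim]
        return sub

    all_vars = list(PARAM_NAMES) + list(use_vars) + [covariate]
    sub = _clean(all_vars)
    rho = pd.DataFrame(
        sps.spearmanr(sub[all_vars].to_numpy())[0],
        index=all_vars, columns=all_vars,
    )
    regressions = {}
    for var in use_vars:
        cols = predictors + [var]
        sub = _clean(cols)
        if len(sub) < len(predictors) + 2:
            raise ValueError(
                f"too few complete cases ({len(sub)}) to regress {var} on "
                f"{len(predictors)} predictors"
            )
        y = sub[var] - sub[var].mean()
        X = sm.add_constant(sub[predictors])
        fit = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
        Xp = X.to_numpy()
        vifs = pd.Series(
            [variance_inflation_factor(Xp, i + 1)
             for i in range(len(predictors))],
            index=predictors,
        )
        regressions[var] = {
            "coef": pd.Series(fit.params, index=["const"] + predictors),
            "p": pd.Series(fit.pvalues, index=["const"] + predictors),
            "F": float(fit.fvalue),
            "F_p": float(fit.f_pvalue),
            "r2": float(fit.rsquared),
            "n": int(fit.nobs),
            "vif": vifs,
        }
    return {"spearman": rho, "regressions": regressions}
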