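"""Stay/switch coding, regressions, post-hocs and group tests."""

import numpy as np
import pandas as pd
import pytest

from twostep.agent import ParameterSet, simulate_agent
from twostep.glmm import SeparationError
from twostep.stats import (
    RegressionResult,
    anova_group_by_time,
    code_stay_records,
    compare_parameter_groups,
    correlate_params_use,
    fit_stay_glmm,
    marginal_means_posthoc,
)
from twostep.task import SessionData, TaskConfig, Trial, \
    generate_reward_walks

CFG = TaskConfig(n_trials=150)


def _trial(t, c1, transition, r):
    s = c1 if transition == "common" else 1 - c1
    return Trial(t=t, c1=c1, s=s, transition=transition, c2=0, r=r)


def _agent_sessions(params_by_group, n_per_group, seed, session="baseline",
                    cfg=CFG):
    """Simulate labelled two-group sessions from given parameters."""
    rng = np.random.default_rng(seed)
    walks = generate_reward_walks(cfg, seed=seed)
    sessions = []
    for group, params in params_by_group.items():
        for i in range(n_per_group):
            sessions.append(simulate_agent(
                params, walks, cfg, rng,
                subject_id=f"{group}{i}", session=session, group=group,
            ))
    return sessions


class TestStayCoding:
    def test_hand_coded_four_trial_example(self):
        sess = SessionData("x", group="MUD", trials=[
            _trial(1, 0, "common", 1),
            _trial(2, 0, "common", 0),
            _trial(3, 1, "rare", 1),
            _trial(4, 1, "common", 0),
        ])
        rec = code_stay_records([sess])
        assert list(rec["stay"]) == [1, 0, 1]
        assert list(rec["prev_win"]) == [1, -1, 1]
        assert list(rec["prev_transition"]) == [1, 1, -1]

    def test_constant_and_alternating_choosers(self):
        stay_all = SessionData("a", group="control", trials=[
            _trial(t + 1, 0, "common", 1) for t in range(5)
        ])
        alternating = SessionData("b", group="control", trials=[
            _trial(t + 1, t % 2, "common", 1) for t in range(5)
        ])
        assert code_stay_records([stay_all])["stay"].eq(1).all()
        assert code_stay_records([alternating])["stay"].eq(0).all()

    def test_pairs_spanning_missing_trials_dropped(self):
        trials = [_trial(t + 1, 0, "common", 1) for t in range(6)]
        trials[2] = Trial(t=3)          # fully missing trial
        sess = SessionData("x", group="MUD", trials=trials)
        rec = code_stay_records([sess])
        # pairs (1,2), (4,5), (5,6) survive; (2,3) and (3,4) are dropped
        assert len(rec) == 3


class TestStayRegression:
    def test_model_free_cohort_shows_reward_effect_only(self):
        params = ParameterSet(0.6, 0.0, 4.0, 0.2, 3.0)
        sessions = _agent_sessions(
            {"MUD": params, "control": params}, n_per_group=8, seed=31
        )
        res = fit_stay_glmm(code_stay_records(sessions))
        assert res["prev_win"]["estimate"] > 0
        assert res["prev_win"]["p"] < 0.001
        # both groups generated identically: interactions near zero
        assert res["group:prev_win"]["p"] > 0.01
        assert abs(res["group:prev_win"]["estimate"]) < 0.2

    def test_flipping_prev_win_codes_flips_coefficient_sign(self):
        params = ParameterSet(0.6, 1.0, 2.0, 0.5, 2.0)
        sessions = _agent_sessions(
            {"MUD": params, "control": params}, n_per_group=6, seed=32
        )
        rec = code_stay_records(sessions)
        res1 = fit_stay_glmm(rec)
        flipped = rec.assign(prev_win=-rec["prev_win"])
        res2 = fit_stay_glmm(flipped)
        assert res2["prev_win"]["estimate"] == pytest.approx(
            -res1["prev_win"]["estimate"], abs=1e-4
        )

    def test_longitudinal_model_has_full_time_crossed_terms(self):
        cfg = TaskConfig(n_trials=80)
        params = ParameterSet(0.6, 0.5, 2.0, 0.5, 2.0)
        sessions = _agent_sessions(
            {"MUD": params, "control": params}, n_per_group=6, seed=35,
            cfg=cfg,
        )
        sessions += _agent_sessions(
            {"MUD": params, "control": params}, n_per_group=6, seed=36,
            session="followup", cfg=cfg,
        )
        res = fit_stay_glmm(code_stay_records(sessions), longitudinal=True,
                            n_quad=7)
        assert len(res.table) == 16
        assert "time:group:prev_win:prev_transition" in res.table.index
        assert "time:group:prev_win" in res.table.index
        assert "slope" in res.re_sd          # random Time slope
        assert res.longitudinal

    def test_all_stay_raises_separation_error(self):
        sessions = [
            SessionData(f"s{i}", group=g, trials=[
                _trial(t + 1, 0, "common", 1) for t in range(20)
            ])
            for i, g in enumerate(["MUD", "MUD", "control", "control"])
        ]
        with pytest.raises(SeparationError):
            fit_stay_glmm(code_stay_records(sessions))

    def test_single_group_is_rejected(self):
        params = ParameterSet(0.5, 1.0, 1.0, 0.5, 1.0)
        sessions = _agent_sessions({"MUD": params}, n_per_group=4, seed=33)
        with pytest.raises(ValueError, match="2 subjects"):
            fit_stay_glmm(code_stay_records(sessions))


def _null_result(group_beta=0.0, se=0.05):
    """Hand-built RegressionResult with known coefficients."""
    terms = ["const", "prev_win", "prev_transition", "group",
             "prev_win:prev_transition", "group:prev_win",
             "group:prev_transition", "group:prev_win:prev_transition"]
    est = pd.Series([1.0, 0.4, 0.0, group_beta, 0.0, 0.0, 0.0, 0.0],
                    index=terms)
    cov = pd.DataFrame(np.eye(8) * se ** 2, index=terms, columns=terms)
    table = pd.DataFrame({"term": terms, "estimate": est,
                          "se": np.sqrt(np.diag(cov))}, index=terms)
    return RegressionResult(table=table, cov_params=cov,
                            re_sd={"intercept": 0.5}, n_obs=1000,
                            n_subjects=20, converged=True,
                            longitudinal=False)


class TestMarginalMeans:
    def test_null_group_effect_gives_unit_or(self):
        res = _null_result(group_beta=0.0)
        ph = marginal_means_posthoc(res, contrasts=[((1, 1), (0, 1))])
        assert ph["OR"].iloc[0] == pytest.approx(1.0)
        assert ph["p_adj"].iloc[0] == pytest.approx(1.0)

    def test_single_contrast_is_unadjusted(self):
        from scipy import stats as sps

        res = _null_result(group_beta=0.12)
        ph = marginal_means_posthoc(res, contrasts=[((1, 1), (0, 1))])
        z = ph["z"].iloc[0]
        assert ph["p_adj"].iloc[0] == pytest.approx(2 * sps.norm.sf(abs(z)))

    def test_tukey_adjustment_is_conservative(self):
        res = _null_result(group_beta=0.12)
        family = marginal_means_posthoc(res)      # 6 contrasts
        single = marginal_means_posthoc(res, contrasts=[((1, 1), (0, 1))])
        row = family[(family["cell_1"] == "control|rewarded")
                     & (family["cell_2"] == "MUD|rewarded")]
        assert row["p_adj"].iloc[0] > single["p_adj"].iloc[0]

    def test_reward_insensitive_group_contrast_direction(self):
        """Group whose stay behaviour ignores reward: its rewarded-stay OR
        vs the intact group is below 1."""
        intact = ParameterSet(0.6, 0.0, 4.0, 0.5, 3.0)
        insensitive = ParameterSet(0.6, 0.0, 0.0, 0.5, 3.0)
        sessions = _agent_sessions(
            {"control": intact, "MUD": insensitive}, n_per_group=8, seed=34
        )
        res = fit_stay_glmm(code_stay_records(sessions))
        assert res["group:prev_win"]["OR"] < 1.0
        ph = marginal_means_posthoc(res, contrasts=[((1, 1), (0, 1))])
        assert ph["OR"].iloc[0] < 1.0
        assert ph["p_adj"].iloc[0] < 0.05


class TestGroupComparisons:
    def _table(self, a, b):
        rows = [{"subject_id": f"a{i}", "group": "control", "alpha": v}
                for i, v in enumerate(a)]
        rows += [{"subject_id": f"b{i}", "group": "MUD", "alpha": v}
                 for i, v in enumerate(b)]
        return pd.DataFrame(rows)

    def test_exact_small_sample_example(self):
        res = compare_parameter_groups(
            self._table([1, 2, 3], [10, 11, 12]), "alpha"
        )
        assert res.statistic == 0.0
        assert res.p == pytest.approx(0.1)
        assert res.direction == "MUD > control"

    def test_identical_samples_give_p_one(self):
        with pytest.warns(UserWarning, match="constant"):
            res = compare_parameter_groups(
                self._table([1.0] * 5, [1.0] * 5), "alpha"
            )
        assert res.p == 1.0

    def test_invariance_to_monotone_transform(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 12)
        r1 = compare_parameter_groups(self._table(a, b), "alpha")
        r2 = compare_parameter_groups(
            self._table(np.exp(a), np.exp(b)), "alpha"
        )
        assert r1.statistic == r2.statistic
        assert r1.p == r2.p


class TestGroupByTimeAnova:
    def _long_table(self, effect_time=0.0, effect_interaction=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, gname in enumerate(["control", "MUD"]):
            for i in range(15):
                base = rng.normal(0, 1)
                for t, sess in enumerate(["baseline", "followup"]):
                    rows.append({
                        "subject_id": f"{gname}{i}", "group": gname,
                        "session": sess,
                        "alpha": base + effect_time * t
                        + effect_interaction * t * g + rng.normal(0, 0.3),
                    })
        return pd.DataFrame(rows)

    def test_additive_time_shift_detected_without_interaction(self):
        aov = anova_group_by_time(self._long_table(effect_time=1.0), "alpha")
        aov = aov.set_index("Source")
        assert aov.loc["session", "p_unc"] < 0.001
        assert aov.loc["Interaction", "p_unc"] > 0.05

    def test_group_label_swap_preserves_f(self):
        tab = self._long_table(effect_interaction=0.8, seed=1)
        aov1 = anova_group_by_time(tab, "alpha").set_index("Source")
        swapped = tab.assign(group=tab["group"].map(
            {"control": "MUD", "MUD": "control"}
        ))
        aov2 = anova_group_by_time(swapped, "alpha").set_index("Source")
        assert aov1.loc["Interaction", "F"] == pytest.approx(
            aov2.loc["Interaction", "F"], rel=1e-6
        )

    def test_incomplete_subjects_dropped_with_warning(self):
        tab = self._long_table()
        tab = tab.drop(tab[(tab.subject_id == "control0")
                           & (tab.session == "followup")].index)
        with pytest.warns(UserWarning, match="without both sessions"):
            anova_group_by_time(tab, "alpha")


class TestUseCorrelations:
    def _tables(self, seed=0, n=28, link=2.0):
        rng = np.random.default_rng(seed)
        params = pd.DataFrame({
            "subject_id": [f"m{i}" for i in range(n)],
            "group": "MUD",
            "session": "baseline",
            "alpha": rng.uniform(0.2, 0.8, n),
            "beta_mb": rng.lognormal(0, 0.5, n),
            "beta_mf": rng.lognormal(0, 0.5, n),
            "beta_rep": rng.normal(0.5, 0.5, n),
            "beta_consistency": rng.lognormal(0.5, 0.5, n),
        })
        use = pd.DataFrame({
            "subject_id": params["subject_id"],
            "frequency_of_use":
                10 + link * params["beta_consistency"] + rng.normal(0, 0.5, n),
            "days_since_last_use": rng.lognormal(2.5, 0.5, n),
        })
        return params, use

    def test_monotone_link_yields_positive_rho(self):
        params, use = self._tables(seed=5)
        out = correlate_params_use(params, use, ["frequency_of_use"])
        rho = out["spearman"].loc["beta_consistency", "frequency_of_use"]
        assert rho > 0.5
        reg = out["regressions"]["frequency_of_use"]
        assert reg["p"]["beta_consistency"] < 0.05

    def test_permuted_outcome_shows_no_relationship(self):
        params, use = self._tables(seed=6, link=0.0)
        out = correlate_params_use(params, use, ["frequency_of_use"])
        rhos = out["spearman"].loc[
            ["alpha", "beta_mb", "beta_mf", "beta_rep", "beta_consistency"],
            "frequency_of_use",
        ]
        assert rhos.abs().max() < 0.5

    def test_outlier_limit_excludes_extreme_days(self):
        params, use = self._tables(seed=7)
        use.loc[0, "days_since_last_use"] = 151.0
        out = correlate_params_use(
            params, use, ["frequency_of_use"],
            outlier_limits={"days_since_last_use": 100.0},
        )
        assert out["regressions"]["frequency_of_use"]["n"] == len(use) - 1

    def test_too_few_cases_raise(self):
        params, use = self._tables(seed=8)
        with pytest.raises(ValueError, match="complete cases"):
            correlate_params_use(
                params.head(5), use.head(5), ["frequency_of_use"]
            )

    def test_near_orthogonal_predictors_have_low_vif(self):
        params, use = self._tables(seed=9, n=60, link=0.0)
        out = correlate_params_use(params, use, ["frequency_of_use"])
        assert out["regressions"]["frequency_of_use"]["vif"].max() < 2.0
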