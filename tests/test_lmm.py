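import numpy as np
import pandas as pd
import pytest

from dcgradient import (
    CohortSpec,
    ConfigurationError,
    DataError,
    EffectSizes,
    covariate_substitution_refit,
    fit_lmm,
    lsmeans,
    reduce_model,
    simple_slopes,
    simulate_connection_table,
    type3_tests,
    vif_check,
)
from dcgradient.lmm import LMMSpec, prepare_connection_table

#: Type III F statistics, Satterthwaite denominator dfs and the ML
#: log-likelihood obtained from R (lmerTest::anova type 3, contr.sum) on
#: the deterministic fixture table; estimated marginal means from
#: emmeans.  Computed once with lme4 1.1-37 / lmerTest 3.1-3.
LMER_ORACLE = {
    "F": {
        "direction": 39.7131,
        "state": 0.0024,
        "duration_before_implant": 1.0651,
        "direction : state": 0.3824,
        "direction : duration_before_implant": 1.0256,
        "duration_before_implant : state": 0.0738,
        "direction : duration_before_implant : state": 0.1793,
    },
    "df_den": {
        "direction": 214.284,
        "state": 214.284,
        "duration_before_implant": 27.353,
        "direction : state": 214.284,
        "direction : duration_before_implant": 214.284,
        "duration_before_implant : state": 214.284,
        "direction : duration_before_implant : state": 214.284,
    },
    "loglik": 401.1669,
    "emmeans_direction": {"cr": 0.203, "rc": 0.305},
    "emmeans_contrast": -0.101,
}


@pytest.fixture(scope="module")
def fixture_fit(lmm_table):
    return fit_lmm(lmm_table, LMMSpec.model2())


class TestFitAgainstOracles:
    def test_loglik_and_estimates_match_statsmodels(self, lmm_table, fixture_fit):
        statsmodels = pytest.importorskip("statsmodels.formula.api")
        data = lmm_table.copy()
        data["g"] = 1
        model = statsmodels.mixedlm(
            "dc ~ C(direction, Sum)*C(state, Sum)*duration_before_implant",
            data,
            groups="g",
            vc_formula={
                "ps": "0 + C(participant):C(stream_id)",
                "pl": "0 + C(participant):C(level_pair)",
            },
        )
        ref = model.fit(reml=False)
        assert fixture_fit.loglik == pytest.approx(ref.llf, abs=1e-5)
        assert fixture_fit.sigma2 == pytest.approx(ref.scale, rel=1e-5)
        assert np.allclose(
            np.sort(fixture_fit.params.to_numpy()),
            np.sort(np.asarray(ref.fe_params)),
            atol=1e-7,
        )

    def test_type3_table_matches_lmerTest(self, fixture_fit):
        table = type3_tests(fixture_fit)
        assert fixture_fit.loglik == pytest.approx(LMER_ORACLE["loglik"], abs=1e-3)
        for term, f_expected in LMER_ORACLE["F"].items():
            assert table.loc[term, "F"] == pytest.approx(f_expected, abs=2e-3), term
            assert table.loc[term, "df_den"] == pytest.approx(
                LMER_ORACLE["df_den"][term], rel=0.01
            ), term

    def test_lsmeans_match_emmeans(self, fixture_fit):
        means, comps = lsmeans(fixture_fit, ["direction"])
        by_dir = means.set_index("direction")["estimate"]
        for level, expected in LMER_ORACLE["emmeans_direction"].items():
            assert by_dir[level] == pytest.approx(expected, abs=1.5e-3)
        assert comps["estimate"].iloc[0] == pytest.approx(
            LMER_ORACLE["emmeans_contrast"], abs=1.5e-3
        )


class TestFitBehaviour:
    def test_refit_is_deterministic(self, lmm_table, fixture_fit):
        again = fit_lmm(lmm_table, LMMSpec.model2())
        assert np.array_equal(again.params.to_numpy(), fixture_fit.params.to_numpy())
        assert again.loglik == fixture_fit.loglik

    def test_direction_effect_recovered_within_2se(self):
        spec = CohortSpec(seed=21, n_participants=16, session_plan=(("ON", 16),))
        sens, base = 0.08, 0.10
        tab = simulate_connection_table(spec, seed=21, dc_sensitivity=sens)
        res = fit_lmm(tab, LMMSpec(blocks=(("direction",),)))
        means, comps = lsmeans(res, ["direction"])
        est = comps["estimate"].iloc[0]
        se = comps["se"].iloc[0]
        g_rc, g_cr = (
            spec.coupling_base + spec.effect_sizes.direction,
            spec.coupling_base,
        )
        # truth on the DC scale is sensitivity * direction gain difference,
        # up to the per-participant covariate terms averaging out
        truth = abs(sens * (g_rc - g_cr))
        assert abs(abs(est) - truth) < 2.5 * se

    def test_zero_between_participant_variance_hits_boundary(self):
        rng = np.random.default_rng(3)
        spec = CohortSpec(seed=3, n_participants=10, session_plan=(("ON", 10),),
                          effect_sizes=EffectSizes().null())
        tab = simulate_connection_table(
            spec, seed=3, stream_sd=0.0, level_sd=0.0, noise_sd=0.05
        )
        res = fit_lmm(tab, LMMSpec.model2())
        # true between-participant variance is zero; estimates collapse
        assert max(res.vcomp.values()) < 1e-4
        assert res.sigma2 == pytest.approx(0.05**2, rel=0.1)

    def test_missing_variable_rejected(self, lmm_table):
        spec = LMMSpec(blocks=(("direction", "nonexistent"),))
        with pytest.raises(DataError, match="nonexistent"):
            fit_lmm(lmm_table, spec)

    def test_unbalanced_sessions_fit_without_imputation(self):
        spec = CohortSpec(seed=4, n_participants=8,
                          session_plan=(("ON", 8), ("OFF", 6), ("ON2", 5)))
        tab = simulate_connection_table(spec, seed=4)
        res = fit_lmm(tab, LMMSpec.model2())
        assert res.n_obs == (8 + 6 + 5) * 48
        assert set(res.data["state"]) == {"ON", "OFF", "ON2"}


class TestTypeIII:
    def test_balanced_design_equals_classical_anova(self):
        # with no random terms the mixed-model Type III machinery must
        # reproduce the classical fixed-effects ANOVA exactly
        smf = pytest.importorskip("statsmodels.formula.api")
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        cells = [(a, b) for a in "xyz" for b in "uv"]
        rows = []
        for a, b in cells:
            for r in range(12):
                rows.append(dict(fa=a, fb=b, dc=rng.normal(0.3 * (a == "x"), 1.0)))
        data = pd.DataFrame(rows)
        spec = LMMSpec(blocks=(("fa", "fb"),), random=())
        res = fit_lmm(data, spec, reml=True)
        mine = type3_tests(res)
        ols = smf.ols("dc ~ C(fa, Sum)*C(fb, Sum)", data).fit()
        ref = sm.stats.anova_lm(ols, typ=3)
        assert mine.loc["fa", "F"] == pytest.approx(ref.loc["C(fa, Sum)", "F"], abs=1e-6)
        assert mine.loc["fb", "F"] == pytest.approx(ref.loc["C(fb, Sum)", "F"], abs=1e-6)
        assert mine.loc["fa : fb", "F"] == pytest.approx(
            ref.loc["C(fa, Sum):C(fb, Sum)", "F"], abs=1e-6
        )
        assert mine.loc["fa", "df_den"] == pytest.approx(ols.df_resid, rel=1e-6)

    def test_large_effect_detected_consistently(self):
        hits = 0
        for seed in range(10):
            spec = CohortSpec(seed=seed, n_participants=10, session_plan=(("ON", 10),))
            tab = simulate_connection_table(spec, seed=seed)
            res = fit_lmm(tab, LMMSpec(blocks=(("direction",),)))
            p = type3_tests(res).loc["direction", "p"]
            if p < 0.05:
                hits += 1
        assert hits >= 9


class TestReduction:
    def test_parsimonious_model_unchanged(self):
        spec = CohortSpec(seed=5, n_participants=10, session_plan=(("ON", 10),))
        tab = simulate_connection_table(spec, seed=5)
        model_spec = LMMSpec(blocks=(("direction",),))
        res = reduce_model(tab, model_spec)
        assert res.reduction_history == []
        assert res.terms == model_spec.initial_terms()

    def test_pure_direction_truth_prunes_interactions(self):
        kept_main, removed_inter = 0, 0
        n = 5
        for seed in range(n):
            spec = CohortSpec(
                seed=seed,
                n_participants=12,
                session_plan=(("ON", 12), ("OFF", 11)),
                effect_sizes=EffectSizes(
                    direction=0.75, state_direction=0.0,
                    state_direction_duration=0.0, vat_direction=0.0,
                    ledd_direction=0.0,
                ),
            )
            tab = simulate_connection_table(spec, seed=300 + seed)
            res = reduce_model(tab, LMMSpec.model2())
            if frozenset(["direction"]) in res.terms:
                kept_main += 1
            if not any(len(t) >= 2 for t in res.terms):
                removed_inter += 1
        assert kept_main == n
        assert removed_inter >= n - 1

    def test_marginality_no_orphaned_interactions(self):
        spec = CohortSpec(seed=6, n_participants=10,
                          session_plan=(("ON", 10), ("OFF", 9)))
        tab = simulate_connection_table(spec, seed=6)
        res = reduce_model(tab, LMMSpec.model2())
        for term in res.terms:
            for sub in term:
                assert frozenset([sub]) in res.terms

    def test_history_reconstructs_final_terms(self):
        spec = CohortSpec(seed=13, n_participants=10,
                          session_plan=(("ON", 10), ("OFF", 9)),
                          effect_sizes=EffectSizes().null())
        tab = simulate_connection_table(spec, seed=13)
        model_spec = LMMSpec.model2()
        res = reduce_model(tab, model_spec)
        removed = {h["term"] for h in res.reduction_history}
        expected = {
            " : ".join(sorted(t))
            for t in model_spec.initial_terms()
        } - removed
        assert {" : ".join(sorted(t)) for t in res.terms} == expected


class TestVIF:
    def test_orthogonal_predictors_give_unit_vif(self):
        rng = np.random.default_rng(1)
        n = 64
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        data = pd.DataFrame({"a": a, "b": b, "dc": rng.normal(size=n)})
        table = vif_check(data, ["a", "b"])
        assert np.allclose(table["vif"], 1.0, atol=1e-10)

    def test_duplicated_predictor_reported_unbounded(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        data = pd.DataFrame({"a": x, "b": x.copy(), "dc": rng.normal(size=50)})
        table = vif_check(data, ["a", "b"])
        assert np.isinf(table["vif"]).all()
        assert table["flagged"].all()

    def test_two_predictor_closed_form(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=200)
        b = 0.6 * a + 0.8 * rng.normal(size=200)
        data = pd.DataFrame({"a": a, "b": b, "dc": rng.normal(size=200)})
        r = np.corrcoef(a, b)[0, 1]
        table = vif_check(data, ["a", "b"])
        assert np.allclose(table["vif"], 1.0 / (1.0 - r**2), atol=1e-8)

    def test_needs_two_predictors(self):
        with pytest.raises(ConfigurationError):
            vif_check(pd.DataFrame({"a": [1.0, 2.0]}), ["a"])


class TestPosthoc:
    def test_identical_groups_give_null_contrast(self):
        spec = CohortSpec(seed=7, n_participants=12,
                          session_plan=(("ON", 12), ("OFF", 11)),
                          effect_sizes=EffectSizes().null())
        tab = simulate_connection_table(spec, seed=7)
        res = fit_lmm(tab, LMMSpec.model2())
        means, comps = lsmeans(res, ["state"])
        assert np.abs(comps["estimate"]).max() < 0.01
        assert (comps["p_tukey"] > 0.05).all()

    def test_tukey_p_never_below_unadjusted(self, fixture_fit):
        _, comps = lsmeans(fixture_fit, ["direction", "state"])
        assert (comps["p_tukey"] >= comps["p_unadjusted"] - 1e-12).all()

    def test_confidence_bounds_bracket_estimate(self, fixture_fit):
        means, _ = lsmeans(fixture_fit, ["direction"])
        assert (means["ci_lower"] < means["estimate"]).all()
        assert (means["estimate"] < means["ci_upper"]).all()

    def test_simple_slope_sign_recovery(self):
        recovered = 0
        n = 5
        for seed in range(n):
            spec = CohortSpec(seed=seed, n_participants=20,
                              session_plan=(("ON", 20), ("OFF", 18)))
            tab = simulate_connection_table(spec, seed=600 + seed)
            res = fit_lmm(tab, LMMSpec.model2())
            slopes, _ = simple_slopes(res, "duration_before_implant",
                                      ["state", "direction"])
            rc = slopes[slopes.direction == "rostro-caudal"].set_index("state")
            if rc.loc["ON", "estimate"] < rc.loc["OFF", "estimate"]:
                recovered += 1
        assert recovered >= n - 1

    def test_non_factor_rejected(self, fixture_fit):
        with pytest.raises(ConfigurationError):
            lsmeans(fixture_fit, ["duration_before_implant"])


class TestSubstitution:
    def _table(self, time_since_zero: bool):
        spec = CohortSpec(seed=8, n_participants=12,
                          session_plan=(("ON", 12), ("OFF", 11)))
        tab = simulate_connection_table(spec, seed=8)
        if time_since_zero:
            tab["time_since_implant"] = 0.0
        return tab

    def test_identity_substitution_reproduces_fit(self):
        # with time_since_implant identically 0 the overall disease
        # duration IS the pre-implantation duration, so the control
        # refit must agree with the original model
        tab = self._table(time_since_zero=True)
        spec = LMMSpec.model2()
        original = reduce_model(tab, spec)
        control = covariate_substitution_refit(tab, spec, "overall_disease_duration")
        assert control.loglik == pytest.approx(original.loglik, abs=1e-6)
        assert control.control_tag == "overall_disease_duration"

    def test_chronological_age_is_sum_of_time_covariates(self):
        tab = self._table(time_since_zero=False)
        control = covariate_substitution_refit(tab, LMMSpec.model2(), "chronological_age")
        data = control.data
        assert np.allclose(
            data["chronological_age"],
            data["age_at_onset"] + data["duration_before_implant"]
            + data["time_since_implant"],
        )

    def test_unknown_substitution_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown substitution"):
            covariate_substitution_refit(self._table(False), LMMSpec.model2(), "bogus")

    def test_constant_derived_covariate_rejected(self):
        tab = self._table(False)
        tab["age_at_onset"] = 50.0
        tab["duration_before_implant"] = 10.0
        tab["time_since_implant"] = 5.0
        with pytest.raises(DataError, match="constant"):
            covariate_substitution_refit(tab, LMMSpec.model2(), "chronological_age")


def test_prepare_connection_table_builds_stream_ids(grid, rng):
    from dcgradient.connectivity import DCMatrix
    from dcgradient.network import extract_stream_connections

    k = grid.n_analyzed
    dc = DCMatrix(dc=rng.uniform(0, 1, (k, k)), band=(0.06, 0.12),
                  channel_ids=list(grid.analyzed["id"]))
    table = extract_stream_connections(dc, grid, participant="P1", state="ON")
    prepared = prepare_connection_table(table)
    assert prepared["stream_id"].nunique() == 8  # hemisphere-specific streams
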