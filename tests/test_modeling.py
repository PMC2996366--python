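import numpy as np
import pandas as pd
import pytest

from airshed import (
    FittedLUR,
    RunConfig,
    automated_stepwise,
    bivariate_screen,
    fit_glm,
    fit_terms,
    predict,
    select_candidates,
    sequential_partial_r2,
    session_interactions,
    structured_stepwise,
)
from airshed.modeling import (
    RankDeficiencyError,
    base_metric,
    categorize,
    design_matrix,
    term_metadata,
)

from oracles import normal_equations_ols

PUBLISHED = dict(
    intercept=12.64,
    session_effects={"S1": 2.18, "S2": 1.89, "S3": 0.0},
    coefficients={
        "dist_terminal": -0.00140,
        "traffic_density_100": 0.00830,
        "len_class1_100": 0.0230,
        "len_class2_200": 0.00381,
        "dist_class3": -0.00286,
    },
)


def noise_cov(n=300, n_noise=6, seed=0, sessions=("S1", "S2", "S3")):
    """Covariate table whose covariates are pure noise."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "record_id": [f"r{i}" for i in range(n)],
        "session": rng.choice(sessions, size=n),
        "fence_flag": rng.integers(0, 2, n),
    })
    names = ["dist_terminal", "dist_class3", "traffic_density_100",
             "len_class1_100", "len_class2_200", "len_all_100"][:n_noise]
    for name in names:
        df[name] = rng.standard_normal(n)
    eff = {"S1": 2.0, "S2": 1.5, "S3": 0.0}
    df["no2_ppb"] = (10.0 + df["session"].map(eff)
                     + rng.normal(0, 2.0, n))
    return df


class TestFitGLM:
    def test_exact_interpolation(self):
        x = np.arange(5.0)
        X = pd.DataFrame({"const": 1.0, "x": x})
        fit = fit_glm(2 + 3 * x, X)
        assert fit.params["const"] == pytest.approx(2.0, abs=1e-10)
        assert fit.params["x"] == pytest.approx(3.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            X = rng.standard_normal((50, 3))
            X[:, 0] = 1.0
            y = X @ rng.uniform(-2, 2, 3) + rng.standard_normal(50)
            Xdf = pd.DataFrame(X, columns=["const", "a", "b"])
            fit = fit_glm(y, Xdf)
            beta, se, r2 = normal_equations_ols(X, y)
            assert np.allclose(fit.params.to_numpy(), beta, rtol=1e-10)
            assert np.allclose(fit.se.to_numpy(), se, rtol=1e-10)
            assert fit.r2 == pytest.approx(r2, rel=1e-10)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"const": 1.0, "x": rng.standard_normal(40)})
        y = 1 + 2 * X["x"] + rng.standard_normal(40)
        fit1 = fit_glm(y, X)
        perm = rng.permutation(40)
        fit2 = fit_glm(y.to_numpy()[perm], X.iloc[perm].reset_index(drop=True))
        assert np.allclose(fit1.params, fit2.params)
        assert fit1.r2 == pytest.approx(fit2.r2, rel=1e-12)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(30)
        X = pd.DataFrame({"const": 1.0, "a": x, "b": 2 * x})
        with pytest.raises(RankDeficiencyError) as exc:
            fit_glm(rng.standard_normal(30), X)
        assert set(exc.value.columns) & {"a", "b"}


class TestPredict:
    def test_published_intercept_at_reference_session(self):
        model = FittedLUR.from_coefficients(**PUBLISHED,
                                            sessions_order=["S1", "S2", "S3"])
        rows = pd.DataFrame({"session": ["S3"],
                             **{t: [0.0] for t in PUBLISHED["coefficients"]}})
        assert predict(model, rows)[0] == pytest.approx(12.64, abs=1e-12)

    def test_published_session1_shift(self):
        model = FittedLUR.from_coefficients(**PUBLISHED,
                                            sessions_order=["S1", "S2", "S3"])
        rows = pd.DataFrame({"session": ["S1"],
                             **{t: [0.0] for t in PUBLISHED["coefficients"]}})
        assert predict(model, rows)[0] == pytest.approx(12.64 + 2.18, abs=1e-12)

    def test_all_zero_coefficients_predict_zero(self):
        model = FittedLUR.from_coefficients(
            0.0, {"S1": 0.0, "S2": 0.0}, {"dist_terminal": 0.0},
            sessions_order=["S1", "S2"])
        rows = pd.DataFrame({"session": ["S1", "S2"],
                             "dist_terminal": [123.0, 456.0]})
        assert np.allclose(predict(model, rows), 0.0)

    def test_missing_term_rejected(self):
        model = FittedLUR.from_coefficients(**PUBLISHED,
                                            sessions_order=["S1", "S2", "S3"])
        rows = pd.DataFrame({"session": ["S3"], "dist_terminal": [0.0]})
        with pytest.raises(KeyError):
            predict(model, rows)


class TestBivariateScreen:
    def test_perfect_predictor_dominates(self):
        df = noise_cov(n=200, seed=3)
        eff = {"S1": 2.0, "S2": 1.5, "S3": 0.0}
        df["dist_terminal"] = df["no2_ppb"] - df["session"].map(eff)
        scr = bivariate_screen(df, RunConfig()).set_index("term")
        assert scr.loc["dist_terminal", "estimate"] == pytest.approx(1.0, abs=1e-6)
        assert scr.loc["dist_terminal", "p"] < 1e-100

    def test_zero_variance_covariate_skipped(self):
        df = noise_cov(n=100, seed=4)
        df["dist_terminal"] = 7.0
        scr = bivariate_screen(df, RunConfig())
        assert "dist_terminal" in scr.attrs["skipped"]
        assert "dist_terminal" not in set(scr["term"])

    def test_default_campaign_ranks_terminal_best_airport_proxy(self, campaign, cfg):
        scr = bivariate_screen(campaign["cov"], cfg)
        airport = scr[scr["category"] == "airport_proxy"]
        assert airport.iloc[0]["term"] == "dist_terminal"


class TestSelectCandidates:
    def screen_frame(self, rows):
        return pd.DataFrame(rows, columns=["term", "estimate", "se", "t", "p",
                                           "category", "base_metric"])

    def test_smallest_p_wins(self):
        scr = self.screen_frame([
            ("a", 1, 0.1, 3.0, 0.001, "airport_proxy", "a"),
            ("b", 1, 0.1, 2.0, 0.040, "airport_proxy", "b"),
        ])
        assert select_candidates(scr)["airport_proxy"] == "a"

    def test_p_tie_broken_by_larger_t(self):
        scr = self.screen_frame([
            ("weak", 1, 0.1, 6.1, 0.001, "traffic_proxy", "weak"),
            ("strong", 1, 0.1, 8.2, 0.001, "traffic_proxy", "strong"),
        ])
        assert select_candidates(scr)["traffic_proxy"] == "strong"

    def test_nonsignificant_category_omitted(self):
        scr = self.screen_frame([
            ("a", 1, 0.1, 1.0, 0.30, "dist_road_class", "a"),
            ("b", 1, 0.1, 5.0, 0.001, "airport_proxy", "b"),
        ])
        out = select_candidates(scr)
        assert "dist_road_class" not in out
        assert out["airport_proxy"] == "b"


class TestStructuredStepwise:
    def test_all_noise_returns_sessions_only(self):
        fit = structured_stepwise(noise_cov(n=400, seed=5), RunConfig())
        assert fit.covariate_terms == []
        assert set(fit.terms) == {"const", "session_S1", "session_S2"} \
            or len(fit.terms) == 3

    def test_no_base_metric_repeated(self, campaign, cfg):
        fit = structured_stepwise(campaign["cov"], cfg)
        bases = [base_metric(t) for t in fit.covariate_terms]
        assert len(bases) == len(set(bases))

    def test_all_retained_terms_significant(self, campaign, cfg):
        fit = structured_stepwise(campaign["cov"], cfg)
        for t in fit.covariate_terms:
            assert fit.p[t] < cfg.p_enter

    def test_recovers_published_model_structure(self, campaign, cfg):
        fit = structured_stepwise(campaign["cov"], cfg)
        terms = fit.covariate_terms
        assert any(categorize(t) == "airport_proxy" for t in terms)
        assert any("class1" in t or "class2" in t or "class3" in t for t in terms)


class TestAutomatedStepwise:
    def test_r2_at_least_structured(self, campaign, cfg):
        structured = structured_stepwise(campaign["cov"], cfg)
        auto, report = automated_stepwise(campaign["cov"], cfg, structured=structured)
        assert auto.r2 >= structured.r2 - 1e-9
        assert "terms_only_in_automated" in report

    def test_collinear_pair_flagged(self):
        rng = np.random.default_rng(6)
        n = 400
        x1 = rng.standard_normal(n)
        x2 = x1 + 0.15 * rng.standard_normal(n)   # rho ~ 0.99
        df = pd.DataFrame({
            "record_id": [str(i) for i in range(n)],
            "session": "S1",
            "fence_flag": 0,
            "traffic_density_100": x1,
            "adt_len_100": x2,
            "no2_ppb": 10 + 2.0 * x1 - 1.0 * x2 + 0.3 * rng.standard_normal(n),
        })
        auto, report = automated_stepwise(df, RunConfig(), sessions_order=["S1"])
        assert set(auto.covariate_terms) == {"traffic_density_100", "adt_len_100"}
        assert report["collinear_pairs"]

    def test_low_collinearity_truth_selected_by_both_routes(self):
        rng = np.random.default_rng(7)
        n = 500
        df = noise_cov(n=n, seed=7)
        # two independent true predictors, orthogonal by construction
        df["dist_terminal"] = rng.standard_normal(n)
        df["len_class1_100"] = rng.standard_normal(n)
        eff = {"S1": 2.0, "S2": 1.5, "S3": 0.0}
        df["no2_ppb"] = (10 + df["session"].map(eff)
                         - 1.0 * df["dist_terminal"]
                         + 1.0 * df["len_class1_100"]
                         + rng.normal(0, 1.0, n))
        cfg = RunConfig()
        s = structured_stepwise(df, cfg)
        a, _ = automated_stepwise(df, cfg)
        assert set(s.covariate_terms) == {"dist_terminal", "len_class1_100"}
        assert set(a.covariate_terms) == set(s.covariate_terms)


class TestSessionInteractions:
    def test_detects_session_varying_slope(self):
        rng = np.random.default_rng(8)
        n = 600
        df = noise_cov(n=n, seed=8, n_noise=1)
        x = rng.standard_normal(n)
        df["dist_terminal"] = x
        slope = np.where(df["session"] == "S1", 3.0, 1.0)
        eff = {"S1": 2.0, "S2": 1.5, "S3": 0.0}
        df["no2_ppb"] = 10 + df["session"].map(eff) + slope * x + rng.normal(0, 1.0, n)
        fit = fit_terms(df, ["dist_terminal"])
        report = session_interactions(fit, df).set_index("term")
        row = report.loc["dist_terminal"]
        assert row["interaction_p"] < 1e-6
        assert row["slope_S1"] == pytest.approx(3.0, abs=0.3)
        assert row["slope_S3"] == pytest.approx(1.0, abs=0.3)

    def test_null_interaction_not_flagged(self):
        df = noise_cov(n=600, seed=9, n_noise=1)
        rng = np.random.default_rng(9)
        df["dist_terminal"] = rng.standard_normal(600)
        df["no2_ppb"] = df["no2_ppb"] + 1.0 * df["dist_terminal"]
        fit = fit_terms(df, ["dist_terminal"])
        report = session_interactions(fit, df)
        assert report["interaction_p"].iloc[0] > 0.01


class TestPartialR2:
    def test_orthogonal_predictors_add_marginals(self):
        rng = np.random.default_rng(10)
        n = 256
        # exactly orthogonal, mean-zero columns
        a = np.tile([1.0, -1.0], n // 2)
        b = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)
        df = pd.DataFrame({"session": "S1", "a": a, "b": b})
        df["no2_ppb"] = 2 * a + 1 * b + rng.normal(0, 0.5, n)
        seq = sequential_partial_r2(df, ["a", "b"], sessions_order=["S1"])
        y = df["no2_ppb"]
        marg_a = np.corrcoef(a, y)[0, 1] ** 2
        marg_b = np.corrcoef(b, y)[0, 1] ** 2
        assert seq["a"] == pytest.approx(marg_a, abs=1e-10)
        assert seq["b"] == pytest.approx(marg_b, abs=1e-10)

    def test_increments_telescope_to_total(self, campaign, cfg):
        fit = structured_stepwise(campaign["cov"], cfg)
        assert sum(fit.partial_r2.values()) == pytest.approx(fit.r2, abs=1e-10)

    def test_duplicated_predictor_adds_nothing(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({"session": "S1", "a": rng.standard_normal(100)})
        df["b"] = df["a"]
        df["no2_ppb"] = df["a"] + rng.normal(0, 1, 100)
        seq = sequential_partial_r2(df, ["a", "b"], sessions_order=["S1"])
        assert seq["b"] == pytest.approx(0.0, abs=1e-10)


class TestTermMetadata:
    def test_every_column_registered_once(self, campaign):
        meta = term_metadata(campaign["cov"].columns)
        assert meta.index.is_unique
        assert "no2_ppb" not in meta.index

    @pytest.mark.parametrize("term,cat,base", [
        ("dist_terminal", "airport_proxy", "dist_terminal"),
        ("dist_runway_5_23", "airport_proxy", "dist_runway_5_23"),
        ("dist_class3", "dist_road_class", "dist_class3"),
        ("len_class3_200", "traffic_proxy", "len_class3"),
        ("len_class3_400", "traffic_proxy", "len_class3"),
        ("windlen_class3", "traffic_proxy", "len_class3"),
        ("traffic_density_100", "traffic_proxy", "adt_density"),
        ("adt_len_200", "traffic_proxy", "adt_density"),
        ("len_all_100", "traffic_proxy", "len_all"),
    ])
    def test_category_and_base_assignment(self, term, cat, base):
        assert categorize(term) == cat
        assert base_metric(term) == base
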