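"""OLS machinery, AICc selection, mixed-model screen, gate and stepwise."""

import numpy as np
import pandas as pd
import pytest

from dioica.errors import GateError, ValidationError
from dioica.models import (
    ModelSpec,
    StepwiseResult,
    aicc,
    all_subsets_select,
    bai_vs_delta13c,
    build_design,
    fit_ols,
    normality_gate,
    random_intercept_support,
    stepwise_regression,
    variance_inflation,
)


def make_pentad_data(
    rng,
    n_trees=30,
    n_pentads=12,
    beta_sex=0.5,
    beta_memory=0.4,
    beta_size=0.05,
    beta_pentad=0.0,
    beta_interaction=0.02,
    tree_sd=0.0,
    noise_sd=0.5,
):
    """Pentad table generated under the sex+memory+size+pentad:sex structure."""
    rows = []
    pentads = 1940 + 5 * np.arange(n_pentads)
    center = pentads.mean()
    for i in range(n_trees):
        sex = "male" if i % 2 == 0 else "female"
        code = 1.0 if sex == "male" else -1.0
        dbh = rng.uniform(10, 25)
        intercept = 3.0 + rng.normal(0, tree_sd)
        prev = rng.normal(3, 0.5)
        for p in pentads:
            mu = (
                intercept
                + beta_sex * code
                + beta_memory * prev
                + beta_size * dbh
                + beta_pentad * p
                + beta_interaction * (p - center) * code
            )
            y = mu + rng.normal(0, noise_sd)
            rows.append(
                {
                    "tree_id": f"T{i}",
                    "sex": sex,
                    "pentad_start_year": int(p),
                    "bai_mean": y,
                    "bai_prev": prev,
                    "dbh_hist": dbh,
                }
            )
            prev = y
            dbh += rng.uniform(0.2, 0.8)
    return pd.DataFrame(rows)


class TestFitOls:
    def test_exact_linear_noiseless(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"Intercept": np.ones(10), "x": x})
        fit = fit_ols(X, 2.0 + 3.0 * x)
        assert fit.r2_adj == pytest.approx(1.0)
        assert fit.params["x"] == pytest.approx(3.0)
        assert fit.conf_int.loc["x", "high"] - fit.conf_int.loc["x", "low"] < 1e-8

    def test_intercept_only_is_sample_mean(self, rng):
        y = rng.normal(5, 1, 25)
        X = pd.DataFrame({"Intercept": np.ones(25)})
        fit = fit_ols(X, y)
        assert fit.params["Intercept"] == pytest.approx(y.mean())

    def test_six_point_hand_normal_equations(self):
        # y = b0 + b1 x with x = 0..5, y chosen so hand solution is simple
        x = np.arange(6.0)
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        # normal equations: b1 = Sxy/Sxx, b0 = ybar - b1 xbar
        b1 = ((x - x.mean()) @ (y - y.mean())) / ((x - x.mean()) ** 2).sum()
        b0 = y.mean() - b1 * x.mean()
        fit = fit_ols(pd.DataFrame({"Intercept": np.ones(6), "x": x}), y)
        assert fit.params["Intercept"] == pytest.approx(b0)
        assert fit.params["x"] == pytest.approx(b1)

    def test_rank_deficiency_names_columns(self):
        x = np.arange(8.0)
        X = pd.DataFrame({"Intercept": np.ones(8), "a": x, "b": 2 * x})
        with pytest.raises(ValidationError, match="rank"):
            fit_ols(X, x)

    def test_type3_equals_type1_in_orthogonal_design(self, rng):
        """With balanced sum-to-zero coding and centered covariates the
        drop-one F equals the sequential F for every term."""
        n = 40
        sex = np.tile([1.0, -1.0], n // 2)
        z = rng.normal(0, 1, n)
        z -= z.mean()
        z -= sex * (z @ sex) / (sex @ sex)  # orthogonalize against sex
        y = 1.0 + 0.5 * sex + 0.8 * z + rng.normal(0, 0.3, n)
        X = pd.DataFrame({"Intercept": np.ones(n), "sex": sex, "z": z})
        fit = fit_ols(X, y)
        # sequential F for z (added last) equals drop-one F always; for sex,
        # orthogonality makes order irrelevant
        rss_null = float(((y - y.mean()) ** 2).sum())
        beta_s = (y @ sex) / (sex @ sex)
        rss_sex_only = float(((y - y.mean() - beta_s * sex) ** 2).sum())
        sigma2 = fit.rss / (n - 3)
        f_seq_z = (rss_sex_only - fit.rss) / sigma2
        assert fit.type3.loc["z", "F"] == pytest.approx(f_seq_z, rel=1e-9)


class TestAicc:
    def test_hand_value(self):
        assert aicc(rss=20.0, n=20, k=3) == pytest.approx(7.5)

    def test_penalty_monotone_in_k(self):
        assert aicc(10.0, 30, 4) > aicc(10.0, 30, 3)

    def test_correction_vanishes_as_n_grows(self):
        k = 4
        small = aicc(100.0, 20, k) - (20 * np.log(100 / 20) + 2 * k)
        large = aicc(1e6, 20000, k) - (20000 * np.log(1e6 / 20000) + 2 * k)
        assert large < small
        assert large == pytest.approx(0.0, abs=0.01)

    def test_undefined_correction_reports_inf(self):
        assert aicc(5.0, 6, 5) == float("inf")


class TestAllSubsets:
    def test_ranking_matches_independent_enumeration(self, rng):
        data = make_pentad_data(rng, n_trees=10, n_pentads=8)
        spec = ModelSpec("bai_mean", "bai_prev")
        res = all_subsets_select(data, spec)
        # independent enumeration: recompute AICc for every listed subset
        X_full = build_design(data, spec.candidate_terms)
        y = data["bai_mean"].to_numpy()
        for _, row in res.table.iterrows():
            cols = ["Intercept", *row["terms"]]
            beta, _, _, _ = np.linalg.lstsq(X_full[cols].to_numpy(), y, rcond=None)
            rss = float(((y - X_full[cols].to_numpy() @ beta) ** 2).sum())
            assert row["aicc"] == pytest.approx(aicc(rss, len(y), len(cols) + 1))
        assert res.table["aicc"].is_monotonic_increasing

    def test_marginality_never_violated(self, rng):
        data = make_pentad_data(rng, n_trees=8, n_pentads=6)
        res = all_subsets_select(data, ModelSpec("bai_mean", "bai_prev"))
        for terms in res.table["terms"]:
            if "pentad:sex" in terms:
                assert "pentad" in terms and "sex" in terms

    def test_memory_only_model_recovered(self, rng):
        """Strong memory effect and nothing else selects the memory term."""
        hits = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            data = make_pentad_data(
                r, n_trees=20, n_pentads=10,
                beta_sex=0.0, beta_size=0.0, beta_interaction=0.0,
                beta_memory=0.8, noise_sd=0.4,
            )
            res = all_subsets_select(data, ModelSpec("bai_mean", "bai_prev"))
            if "bai_prev" in res.best_terms:
                hits += 1
        assert hits >= 36

    def test_identical_models_not_superior(self, rng):
        data = make_pentad_data(rng, n_trees=10, n_pentads=8, noise_sd=5.0,
                                beta_sex=0, beta_memory=0, beta_size=0,
                                beta_interaction=0)
        res = all_subsets_select(data, ModelSpec("bai_mean", "bai_prev"))
        # delta between best and runner-up defines superiority
        gap = res.table["aicc"].iloc[1] - res.table["aicc"].iloc[0]
        assert res.superior == (gap >= 2.0)


class TestRandomIntercept:
    def test_zero_between_tree_variance_gives_no_support(self, rng):
        data = make_pentad_data(rng, tree_sd=0.0, n_trees=15, n_pentads=8)
        res = random_intercept_support(data, ModelSpec("bai_mean", "bai_prev"))
        assert not res.support

    def test_strong_tree_effect_supported(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            data = make_pentad_data(rng, tree_sd=1.0, noise_sd=0.5,
                                    n_trees=30, n_pentads=10)
            res = random_intercept_support(data, ModelSpec("bai_mean", "bai_prev"))
            hits += res.support
        assert hits >= 18

    def test_too_few_groups_raises(self, rng):
        data = make_pentad_data(rng, n_trees=3, n_pentads=8)
        from dioica.errors import SelectionError

        with pytest.raises(SelectionError):
            random_intercept_support(data, ModelSpec("bai_mean", "bai_prev"))


class TestNormalityGate:
    def test_normal_residuals_pass_untransformed(self, rng):
        x = rng.normal(0, 1, 200)
        y = 5 + 2 * x + rng.normal(0, 1, 200)
        X = pd.DataFrame({"Intercept": np.ones(200), "x": x})
        fit = normality_gate(X, y)
        assert fit.transform_applied == "none"

    def test_lognormal_response_triggers_log_refit(self, rng):
        x = rng.normal(0, 1, 200)
        y = np.exp(1 + 1.5 * x + rng.normal(0, 0.5, 200))
        X = pd.DataFrame({"Intercept": np.ones(200), "x": x})
        fit = normality_gate(X, y)
        assert fit.transform_applied == "log"
        assert fit.params["x"] == pytest.approx(1.5, abs=0.15)

    def test_transform_on_nonpositive_response_raises(self, rng):
        x = np.linspace(0, 1, 50)
        y = np.exp(4 * x + rng.normal(0, 1, 50)) - 10
        X = pd.DataFrame({"Intercept": np.ones(50), "x": x})
        from scipy import stats

        resid = fit_ols(X, y).residuals
        if stats.shapiro(resid).pvalue < 0.05:  # construction guarantees this
            with pytest.raises(GateError):
                normality_gate(X, y)


class TestStepwise:
    def _candidates(self, rng, n=60, n_noise=10):
        X = pd.DataFrame(
            {f"noise{i}": rng.normal(0, 1, n) for i in range(n_noise)}
        )
        X["signal"] = rng.normal(0, 1, n)
        return X

    def test_true_predictor_enters_first_in_most_seeds(self):
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            X = self._candidates(rng)
            # partial R^2 ~ 0.3  =>  beta ~ sqrt(0.3/0.7)
            y = 0.65 * X["signal"].to_numpy() + rng.normal(0, 1, 60)
            res = stepwise_regression(X, y)
            entered = res.trace[res.trace["action"] == "enter"]
            if len(entered) and entered.iloc[0]["term"] == "signal":
                hits += 1
        assert hits / n_seeds >= 0.8

    def test_perfectly_collinear_duplicates_never_coselected(self, rng):
        X = self._candidates(rng, n_noise=3)
        X["dup"] = X["signal"] * 1.0
        y = 0.8 * X["signal"].to_numpy() + rng.normal(0, 0.5, 60)
        res = stepwise_regression(X, y)
        assert not ({"signal", "dup"} <= set(res.selected))

    def test_zero_p_enter_yields_intercept_only(self, rng):
        X = self._candidates(rng, n_noise=4)
        y = X["signal"].to_numpy() + rng.normal(0, 0.1, 60)
        res = stepwise_regression(X, y, p_enter=0.0, p_remove=0.0)
        assert res.selected == []
        assert list(res.fit.params.index) == ["Intercept"]

    def test_deterministic_traces(self, rng):
        X = self._candidates(rng)
        y = 0.7 * X["signal"].to_numpy() + np.asarray(
            np.random.default_rng(1).normal(0, 1, 60)
        )
        r1 = stepwise_regression(X.copy(), y.copy())
        r2 = stepwise_regression(X.copy(), y.copy())
        pd.testing.assert_frame_equal(r1.trace, r2.trace)
        assert r1.selected == r2.selected

    def test_p_enter_above_p_remove_rejected(self, rng):
        X = self._candidates(rng, n_noise=2)
        with pytest.raises(ValidationError):
            stepwise_regression(X, X["signal"], p_enter=0.2, p_remove=0.1)


class TestBaiVsDelta13c:
    def _table(self, slopes, rng, n_pentads=20, noise=0.0):
        rows = []
        for sex, slope in slopes.items():
            d13 = np.linspace(17, 19, n_pentads) + rng.normal(0, 0.05, n_pentads)
            bai = 10 + slope * d13 + rng.normal(0, noise, n_pentads)
            for i in range(n_pentads):
                rows.append(
                    {
                        "tree_id": f"{sex}1",
                        "sex": sex,
                        "pentad_start_year": 1900 + 5 * i,
                        "bai_mean": bai[i],
                        "delta13c": d13[i],
                    }
                )
        return pd.DataFrame(rows)

    def test_exact_affine_relation_gives_r2_one(self, rng):
        out = bai_vs_delta13c(self._table({"male": -1.2, "female": -0.5}, rng))
        assert out.loc["male", "r2"] == pytest.approx(1.0)
        assert out.loc["male", "slope"] == pytest.approx(-1.2)

    def test_five_point_hand_computation(self):
        from scipy import stats

        d13 = np.array([17.0, 17.5, 18.0, 18.5, 19.0])
        bai = np.array([4.0, 3.0, 3.5, 2.0, 1.5])
        rows = [
            {
                "tree_id": "m1", "sex": "male",
                "pentad_start_year": 1900 + 5 * i,
                "bai_mean": bai[i], "delta13c": d13[i],
            }
            for i in range(5)
        ]
        out = bai_vs_delta13c(pd.DataFrame(rows))
        ref = stats.linregress(d13, bai)
        assert out.loc["male", "slope"] == pytest.approx(ref.slope)
        assert out.loc["male", "r2"] == pytest.approx(ref.rvalue**2)

    def test_null_slope_p_roughly_uniform(self):
        ps = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            rows = [
                {
                    "tree_id": "m1", "sex": "male",
                    "pentad_start_year": 1900 + 5 * i,
                    "bai_mean": rng.normal(3, 1),
                    "delta13c": rng.normal(18, 0.5),
                }
                for i in range(20)
            ]
            out = bai_vs_delta13c(pd.DataFrame(rows))
            ps.append(out.loc["male", "p"])
        ps = np.asarray(ps)
        assert 0.2 <= (ps < 0.5).mean() <= 0.8  # not degenerate


class TestVif:
    def test_orthogonal_predictors_have_vif_one(self, rng):
        a = np.tile([1.0, -1.0], 20)
        b = np.tile([1.0, 1.0, -1.0, -1.0], 10)
        X = pd.DataFrame({"Intercept": np.ones(40), "a": a, "b": b})
        v = variance_inflation(X)
        assert v["a"] == pytest.approx(1.0)
        assert v["b"] == pytest.approx(1.0)

    def test_duplicate_column_infinite_vif(self, rng):
        x = rng.normal(0, 1, 30)
        X = pd.DataFrame({"Intercept": np.ones(30), "a": x, "b": x})
        assert np.isinf(variance_inflation(X)["a"])
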