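import numpy as np
import pandas as pd
import pytest

from hrvc.diagnostics import (compare_groups, logistic_fit, univariable_screen,
                              stepwise_select, adjusted_models, roc_auc,
                              CollinearityError, DegenerateComparisonError,
                              ADJUSTMENT_MODELS)


def _cohort(hf_values, control_values, name="x"):
    return pd.DataFrame({
        "group": ["HF"] * len(hf_values) + ["control"] * len(control_values),
        name: list(hf_values) + list(control_values),
    })


class TestCompareGroups:
    def test_identical_samples_are_not_significant(self):
        c = _cohort([1, 2, 3], [1, 2, 3])
        out = compare_groups(c, "x")
        assert out.p > 0.9

    def test_perfectly_associated_2x2_uses_fisher(self):
        c = _cohort([1] * 10, [0] * 10)
        out = compare_groups(c, "x")
        assert out.method == "fisher"
        assert out.p < 0.001

    def test_large_balanced_binary_uses_chi_square(self, rng):
        c = _cohort(rng.integers(0, 2, 80), rng.integers(0, 2, 80))
        assert compare_groups(c, "x").method == "chi-square"

    def test_normal_data_dispatches_to_t(self, rng):
        c = _cohort(rng.normal(0, 1, 60), rng.normal(1, 1, 60))
        assert compare_groups(c, "x").method == "t"

    def test_skewed_data_dispatches_to_mann_whitney(self, rng):
        c = _cohort(rng.lognormal(0, 1.5, 60), rng.lognormal(0.5, 1.5, 60))
        assert compare_groups(c, "x").method == "mann-whitney"

    def test_zero_variance_everywhere_is_degenerate(self):
        c = _cohort([5.0, 5.0, 5.00001], [5.0, 5.0, 5.0])
        c.loc[:, "x"] = 5.0
        with pytest.raises(DegenerateComparisonError):
            compare_groups(c, "x")


def _logit_cohort(rng, n=2000, b0=-1.0, b1=2.0):
    x = rng.standard_normal(n)
    p = 1 / (1 + np.exp(-(b0 + b1 * x)))
    y = rng.random(n) < p
    return pd.DataFrame({"group": np.where(y, "HF", "control"), "x": x})


class TestLogisticFit:
    def test_binary_predictor_matches_cross_product_ratio(self):
        # 2x2 table: exposed 30/10 cases/controls, unexposed 20/40
        rows = ([("HF", 1)] * 30 + [("control", 1)] * 10
                + [("HF", 0)] * 20 + [("control", 0)] * 40)
        df = pd.DataFrame(rows, columns=["group", "x"])
        fit = logistic_fit(df, terms=["x"])
        assert fit.table.loc["x", "or_"] == pytest.approx(
            (30 * 40) / (10 * 20), rel=1e-6)

    def test_parameter_recovery(self, rng):
        fit = logistic_fit(_logit_cohort(rng), terms=["x"])
        assert fit.table.loc["const", "coef"] == pytest.approx(-1.0, abs=0.2)
        assert fit.table.loc["x", "coef"] == pytest.approx(2.0, abs=0.2)

    def test_wald_ci_coverage_of_null(self, rng):
        covered = 0
        for _ in range(100):
            x = rng.integers(0, 2, 500).astype(float)
            y = np.where(rng.random(500) < 0.4, "HF", "control")
            fit = logistic_fit(pd.DataFrame({"group": y, "x": x}),
                               terms=["x"])
            lo, hi = fit.table.loc["x", ["ci_low", "ci_high"]]
            covered += lo <= 1.0 <= hi
        assert covered >= 93

    def test_perfect_separation_is_flagged(self):
        df = pd.DataFrame({"group": ["HF"] * 20 + ["control"] * 20,
                           "x": [1.0] * 20 + [0.0] * 20})
        fit = logistic_fit(df, terms=["x"])
        assert fit.separation
        assert not np.isfinite(fit.table.loc["x", "or_"])

    def test_duplicate_column_raises_collinearity(self, rng):
        df = _logit_cohort(rng, n=200)
        df["x2"] = df["x"]
        with pytest.raises(CollinearityError, match="x2"):
            logistic_fit(df, terms=["x", "x2"])

    def test_constant_term_rejected(self, rng):
        df = _logit_cohort(rng, n=100)
        df["c"] = 3.0
        with pytest.raises(ValueError, match="constant"):
            logistic_fit(df, terms=["c"])


class TestStepwise:
    def test_true_association_is_retained(self, rng):
        df = _logit_cohort(rng, n=1000, b1=np.log(3))
        fit = stepwise_select(df, ["x"])
        assert fit.terms == ["x"]

    def test_noise_candidates_mostly_eliminated(self, rng):
        retained = []
        for _ in range(20):
            n = 500
            df = pd.DataFrame(rng.standard_normal((n, 5)),
                              columns=[f"z{i}" for i in range(5)])
            df["group"] = np.where(rng.random(n) < 0.4, "HF", "control")
            fit = stepwise_select(df, [f"z{i}" for i in range(5)])
            retained.append(len(fit.terms))
        assert np.mean(retained) < 1.0

    def test_candidate_order_invariance(self, rng):
        df = _logit_cohort(rng, n=600, b1=1.0)
        df["z1"] = rng.standard_normal(len(df))
        df["z2"] = rng.standard_normal(len(df))
        terms = ["x", "z1", "z2"]
        a = stepwise_select(df, terms)
        b = stepwise_select(df, terms[::-1])
        assert a.terms == b.terms

    def test_empty_candidates_give_empty_model(self, rng):
        fit = stepwise_select(_logit_cohort(rng, n=100), [])
        assert fit.terms == []


def _confounded_cohort(rng, n=3000, gamma=0.0):
    """Outcome depends on hrv and (optionally) a confounder c that also
    shifts hrv; true conditional log-OR of hrv is -1."""
    c = rng.standard_normal(n)
    hrv = rng.standard_normal(n) + gamma * c
    logit = -0.5 - 1.0 * hrv + gamma * c
    y = rng.random(n) < 1 / (1 + np.exp(-logit))
    df = pd.DataFrame({"group": np.where(y, "HF", "control"), "hrv": hrv})
    for col in ("age", "male", "creatinine", "glucose_ac", "cad", "dm",
                "htn", "dyslipidemia", "beta_blocker", "ccb", "acei_arb"):
        df[col] = rng.standard_normal(n) if col in ("age", "creatinine",
                                                    "glucose_ac") \
            else rng.integers(0, 2, n)
    df["confounder"] = c
    return df


class TestAdjustedModels:
    def test_five_models_with_expected_covariates(self, rng):
        df = _confounded_cohort(rng, n=800)
        fits = adjusted_models(df, "hrv")
        assert set(fits) == set(ADJUSTMENT_MODELS)
        assert fits["model1"].terms == ["hrv"]
        assert set(fits["model5"].terms) == {"hrv"} | set(
            ADJUSTMENT_MODELS["model5"])

    def test_independent_covariates_leave_or_unchanged(self, rng):
        df = _confounded_cohort(rng, n=4000, gamma=0.0)
        fits = adjusted_models(df, "hrv")
        or1 = fits["model1"].table.loc["hrv", "or_"]
        or5 = fits["model5"].table.loc["hrv", "or_"]
        assert np.log(or5) == pytest.approx(np.log(or1), abs=0.15)

    def test_adjustment_moves_or_toward_truth(self, rng):
        df = _confounded_cohort(rng, n=6000, gamma=1.0)
        crude = logistic_fit(df, terms=["hrv"]).table.loc["hrv", "coef"]
        adj = logistic_fit(df, terms=["hrv", "confounder"]
                           ).table.loc["hrv", "coef"]
        assert abs(adj - (-1.0)) < abs(crude - (-1.0))
        assert adj == pytest.approx(-1.0, abs=0.15)

    def test_missing_covariate_is_named(self, rng):
        df = _confounded_cohort(rng, n=200).drop(columns=["creatinine"])
        with pytest.raises(KeyError, match="creatinine"):
            adjusted_models(df, "hrv")

    def test_constant_hrv_term_rejected(self, rng):
        df = _confounded_cohort(rng, n=200)
        df["hrv"] = 1.0
        with pytest.raises(ValueError):
            adjusted_models(df, "hrv")


class TestROC:
    def test_disjoint_groups_give_auc_one(self):
        out = roc_auc(_cohort([1, 2, 3], [5, 6, 7]), "x")
        assert out.auc_oriented == 1.0
        assert out.orientation == "lower"

    def test_identical_distributions_near_half(self, rng):
        v = rng.standard_normal(400)
        out = roc_auc(_cohort(v[:200], v[200:]), "x")
        assert out.auc_oriented == pytest.approx(0.5, abs=0.1)

    def test_hand_example_with_ties(self):
        # HF={1,2,3}, control={2,3,4}; lower values predict HF.
        # Correct pairs among the 9: (1,2)(1,3)(1,4)(2,3)(2,4)(3,4)=6 wins,
        # ties (2,2),(3,3) count one half -> (6 + 1)/9 = 7/9
        out = roc_auc(_cohort([1, 2, 3], [2, 3, 4]), "x")
        assert out.auc_oriented == pytest.approx(7 / 9, abs=1e-12)
        assert out.orientation == "lower"

    def test_all_tied_is_degenerate_half(self):
        out = roc_auc(_cohort([5, 5, 5], [5, 5, 5]), "x")
        assert out.auc == 0.5
        assert out.degenerate

    def test_curve_endpoints_and_monotonicity(self, rng):
        out = roc_auc(_cohort(rng.normal(1, 1, 50), rng.normal(0, 1, 70)), "x")
        assert (out.fpr[0], out.tpr[0]) == (0.0, 0.0)
        assert (out.fpr[-1], out.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(out.fpr) >= 0)
        assert np.all(np.diff(out.tpr) >= 0)

    def test_trapezoid_equals_pair_counting_oracle(self, rng):
        for _ in range(25):
            n1, n0 = rng.integers(5, 40, 2)
            v1 = np.round(rng.normal(0.5, 1, n1), 1)  # rounding forces ties
            v0 = np.round(rng.normal(0.0, 1, n0), 1)
            out = roc_auc(_cohort(v1, v0), "x")
            wins = sum((a > b) + 0.5 * (a == b) for a in v1 for b in v0)
            assert out.auc == pytest.approx(wins / (n1 * n0), abs=1e-12)


def test_univariable_screen_flags_significant_terms(rng):
    df = _logit_cohort(rng, n=800, b1=1.5)
    df["noise"] = rng.standard_normal(len(df))
    fits, sig = univariable_screen(df, ["x", "noise"])
    assert sig == ["x"]
    assert fits["noise"].table.loc["noise", "p"] > 0.05
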