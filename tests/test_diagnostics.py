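"""Little's MCAR test, the dropout GLMM and inverse probability weights."""

import numpy as np
import pandas as pd
import pytest

import growthsens as gs
from growthsens.diagnostics import (
    compute_ip_weights,
    fit_dropout_glmm,
    little_mcar_test,
)
from conftest import simulate_cohort


class TestLittleMcar:
    def test_centered_patterns_give_zero_statistic(self):
        """If every pattern's observed means equal the grand means the
        statistic vanishes."""
        full = np.array([[1.0, 2.0], [-1.0, -2.0], [2.0, 1.0], [-2.0, -1.0]])
        part = np.array([[3.0, np.nan], [-3.0, np.nan]])
        res = little_mcar_test(pd.DataFrame(np.vstack([full, part]), columns=["a", "b"]))
        assert res.statistic == pytest.approx(0.0, abs=1e-6)
        assert res.n_patterns == 2

    def test_degrees_of_freedom(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(50, 3))
        y[rng.random(50) < 0.4, 2] = np.nan
        res = little_mcar_test(pd.DataFrame(y, columns=list("abc")))
        # complete pattern contributes 3, incomplete 2; minus 3 variables
        assert res.df == 2

    def test_single_pattern_undefined(self):
        y = pd.DataFrame(np.random.default_rng(1).normal(size=(20, 3)))
        with pytest.raises(ValueError, match="undefined"):
            little_mcar_test(y)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(100, 3))
        y[rng.random(100) < 0.3, 1] = np.nan
        df = pd.DataFrame(y, columns=list("abc"))
        a = little_mcar_test(df)
        df2 = df.copy()
        df2["a"] = 7.0 * df2["a"] - 3.0
        df2["b"] = -0.5 * df2["b"] + 11.0
        b = little_mcar_test(df2)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-5)

    def test_rejects_outcome_dependent_dropout_at_scale(self):
        """With dropout driven by the outcome, the MCAR hypothesis is
        rejected at the cohort's sample size."""
        ds = simulate_cohort(
            538, 25, 200,
            gs.DropoutSpec(
                mechanism="DK_OUTCOME",
                coefficients={"intercept": 0.0, "outcome_w0": -0.3, "outcome_w1": -0.7},
                target_rate=0.61,
            ),
        )
        person = ds.person_table()
        res = little_mcar_test(person[["y0", "y1", "reas", "sc"]])
        assert res.p_value < 0.05


class TestDropoutGlmm:
    def test_no_random_intercept_matches_plain_logit_oracle(self):
        """GLMM with the random intercept disabled equals an independent
        logistic-regression fit (statsmodels) to 1e-6."""
        import statsmodels.api as sm

        ds = simulate_cohort(40, 10, 201, gs.mar_table3_spec(target_rate=0.5))
        sel = ["reas", "sc", "sex", "outcome_w0"]
        res = fit_dropout_glmm(ds, sel, school_random_intercept=False)
        person = ds.person_table()
        X = np.column_stack(
            [np.ones(len(person)), person["reas"], person["sc"], person["sex"], person["y0"]]
        )
        d = 1 - person["responded"].to_numpy()
        oracle = sm.Logit(d, X).fit(disp=0)
        assert np.allclose(res.coef, oracle.params, atol=1e-6)

    def test_quadrature_stability(self):
        """Adaptive quadrature is converged: refining the node count leaves
        the estimates unchanged (moderate school heterogeneity; with the
        extreme 2.89-sd school intercept the integrand needs more nodes and
        the coarse 7-node rule is not expected to be exact)."""
        spec = gs.DropoutSpec(
            mechanism="MAR_COVARIATE",
            coefficients={"reas": -0.3, "sc": -0.2, "mode_home": 1.0},
            school_re_sd=1.0, target_rate=0.4,
        )
        ds = simulate_cohort(60, 8, 202, spec)
        sel = ["reas", "sc", "mode_home"]
        fits = [
            fit_dropout_glmm(ds, sel, quad_nodes=q).coef for q in (7, 15, 21)
        ]
        assert np.abs(fits[0] - fits[1]).max() < 1e-3
        assert np.abs(fits[1] - fits[2]).max() < 1e-3

    def test_null_model_estimates_near_zero(self):
        """Zero-coefficient truth: all estimates within sampling error."""
        ds = simulate_cohort(80, 10, 203, gs.DropoutSpec(mechanism="MCAR", target_rate=0.4))
        sel = ["reas", "sc", "sex"]
        res = fit_dropout_glmm(ds, sel, school_random_intercept=False)
        z = np.abs(res.coef[1:]) / res.se[1:]
        assert z.max() < 3.0

    def test_zero_random_intercept_truth_hits_boundary(self):
        ds = simulate_cohort(80, 10, 204, gs.DropoutSpec(mechanism="MCAR", target_rate=0.4))
        res = fit_dropout_glmm(ds, ["reas"], school_random_intercept=True)
        assert res.re_sd < 0.15 or res.boundary

    def test_complete_separation_names_covariate(self):
        ds = simulate_cohort(20, 6, 205)
        # force dropout to coincide exactly with a binary covariate
        person = ds.person_table()
        sex = person.set_index("person_id")["sex"]
        w1 = ds.frame["wave"] == 1
        drop_ids = set(person.loc[person["sex"] == 1, "person_id"])
        mask = w1 & ds.frame["person_id"].isin(drop_ids)
        ds.frame.loc[mask, "responded"] = 0
        ds.frame.loc[mask, "outcome"] = np.nan
        with pytest.raises(ValueError, match="sex"):
            fit_dropout_glmm(ds, ["sex", "reas"], school_random_intercept=False)

    def test_constant_indicator_rejected(self):
        ds = simulate_cohort(10, 5, 206)  # nobody drops out
        with pytest.raises(ValueError, match="constant"):
            fit_dropout_glmm(ds, ["reas"], school_random_intercept=False)


class TestIPWeights:
    def test_full_response_gives_unit_weights(self):
        ds = simulate_cohort(10, 5, 300)
        res = compute_ip_weights(ds, ["reas"])
        assert (res.person["weight"] == 1.0).all()

    def test_two_strata_closed_form(self):
        """Response rates .5 and 1.0 by stratum give pre-normalization
        weights 2.0 and 1.0."""
        ds = simulate_cohort(20, 20, 301)
        person = ds.person_table().sort_values("person_id").reset_index(drop=True)
        stratum = (np.arange(len(person)) % 2 == 0).astype(float)
        smap = dict(zip(person["person_id"], stratum))
        ds.frame["stratum"] = ds.frame["person_id"].map(smap)
        drop = (stratum == 1.0) & (np.arange(len(person)) % 4 == 0)  # half of stratum 1
        drop_ids = set(person.loc[drop, "person_id"])
        mask = (ds.frame["wave"] == 1) & ds.frame["person_id"].isin(drop_ids)
        ds.frame.loc[mask, "responded"] = 0
        ds.frame.loc[mask, "outcome"] = np.nan
        res = compute_ip_weights(ds, ["stratum"], normalize=False)
        tab = res.person.merge(person[["person_id"]], on="person_id")
        tab["stratum"] = tab["person_id"].map(smap)
        resp = tab[tab["responded"] == 1]
        w1 = resp.loc[resp["stratum"] == 1.0, "weight"]
        w0 = resp.loc[resp["stratum"] == 0.0, "weight"]
        assert np.allclose(w1, 2.0, atol=0.01)
        assert np.allclose(w0, 1.0, atol=0.01)

    def test_normalization_mean_one(self):
        ds = simulate_cohort(60, 8, 302, gs.mar_table3_spec(target_rate=0.5))
        res = compute_ip_weights(ds, ["reas", "sc", "mode_home", "outcome_w0"])
        resp = res.person[res.person["responded"] == 1]
        assert resp["weight"].mean() == pytest.approx(1.0, abs=1e-9)

    def test_horvitz_thompson_identity(self):
        """Weighted wave-1 respondent mean recovers the full-sample wave-1
        mean under covariate-driven dropout (weights from the true
        selection variables, no clustering in the response process)."""
        spec = gs.DropoutSpec(
            mechanism="MAR_COVARIATE",
            coefficients={"reas": -0.6, "sc": -0.4, "mode_home": 1.5, "outcome_w0": -0.3},
            target_rate=0.5,
        )
        ds = simulate_cohort(300, 25, 303, spec)
        res = compute_ip_weights(
            ds, ["reas", "sc", "mode_home", "outcome_w0"], normalize=False
        )
        person = ds.person_table().merge(res.person[["person_id", "weight"]], on="person_id")
        truth = ds.truth.set_index("person_id")
        full_mean = truth["y1_true"].mean()
        resp = person[person["responded"] == 1]
        weighted = np.average(resp["y1"], weights=resp["weight"])
        naive = resp["y1"].mean()
        assert weighted == pytest.approx(full_mean, abs=0.03)
        assert abs(naive - full_mean) > abs(weighted - full_mean)

    def test_row_weights_layout(self):
        ds = simulate_cohort(20, 6, 304, gs.DropoutSpec(mechanism="MCAR", target_rate=0.4))
        res = compute_ip_weights(ds, ["reas"])
        w = res.row_weights(ds)
        assert w.size == len(ds.frame)
        person = ds.person_table()
        nonresp = set(person.loc[person["responded"] == 0, "person_id"])
        rows_nr = ds.frame["person_id"].isin(nonresp)
        assert np.allclose(w[rows_nr.to_numpy()], 1.0)
        # a respondent's two rows share one weight
        pid = person.loc[person["responded"] == 1, "person_id"].iloc[0]
        rows = w[(ds.frame["person_id"] == pid).to_numpy()]
        assert rows[0] == rows[1]
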