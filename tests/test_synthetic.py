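"""Generator: covariate moments, outcome model, dropout mechanisms."""

import numpy as np
import pandas as pd
import pytest

import growthsens as gs
from growthsens.synthetic import (
    DEFAULT_COVARIATE_CORR,
    DEFAULT_GCM_PARAMS,
    DEFAULT_VARIANCE_COMPONENTS,
)


def _person_frame(ds):
    return ds.frame[ds.frame["wave"] == 0]


class TestCovariates:
    def test_marginal_moments_match_cohort_descriptives(self):
        cfg = gs.GeneratorConfig(n_schools=538, students_per_school=25, seed=1)
        pf = _person_frame(gs.generate_covariates(cfg))
        assert pf["sc_raw"].mean() == pytest.approx(2.522, abs=0.03)
        assert pf["sc_raw"].std() == pytest.approx(0.921, abs=0.03)
        assert pf["reas_raw"].mean() == pytest.approx(8.654, abs=0.08)
        assert pf["sex"].mean() == pytest.approx(0.497, abs=0.02)
        assert pf["mode_home"].mean() == pytest.approx(0.313, abs=0.02)
        # z-standardized analysis covariates
        assert pf["reas"].mean() == pytest.approx(0.0, abs=1e-10)
        assert pf["sc"].std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_identity_correlation_gives_independent_covariates(self):
        cfg = gs.GeneratorConfig(
            n_schools=500, students_per_school=200,
            covariate_corr=np.eye(6), seed=2,
        )
        pf = _person_frame(gs.generate_covariates(cfg))
        cols = ["sc_raw", "reas_raw", "sex", "migration", "age", "mode_home"]
        corr = pf[cols].corr().to_numpy()
        off = corr[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.02

    def test_covariates_constant_within_person(self):
        ds = gs.generate_covariates(gs.GeneratorConfig(n_schools=10, students_per_school=5, seed=3))
        g = ds.frame.groupby("person_id")[["reas", "sc", "sex", "age"]].nunique()
        assert (g == 1).all().all()

    def test_school_type_constant_within_school(self):
        ds = gs.generate_covariates(gs.GeneratorConfig(n_schools=40, students_per_school=8, seed=4))
        g = ds.frame.groupby("school_id")[["school_basic", "school_intermediate", "school_other"]].nunique()
        assert (g == 1).all().all()

    def test_non_positive_definite_correlation_rejected(self):
        bad = np.full((6, 6), 0.99)
        np.fill_diagonal(bad, 1.0)
        bad[0, 1] = bad[1, 0] = -0.99
        cfg = gs.GeneratorConfig(covariate_corr=bad)
        with pytest.raises(ValueError, match="covariate_corr"):
            gs.generate_covariates(cfg)


class TestOutcomes:
    def test_degenerate_all_zero(self):
        ds = gs.generate_covariates(gs.GeneratorConfig(n_schools=5, students_per_school=4, seed=5))
        ds = gs.generate_outcomes(
            ds, gs.GCMParams(), gs.VarianceComponents(0.0, 0.0, 0.0), seed=6
        )
        assert np.allclose(ds.frame["outcome"], 0.0)

    def test_reasoning_outcome_correlation_targets_cohort_value(self):
        cfg = gs.GeneratorConfig(n_schools=1000, students_per_school=100, seed=7)
        ds = gs.generate_outcomes(gs.generate_covariates(cfg), seed=8)
        pf = ds.frame[ds.frame["wave"] == 0]
        r = np.corrcoef(pf["reas"], pf["outcome"])[0, 1]
        assert r == pytest.approx(0.494, abs=0.02)
        r_sc = np.corrcoef(pf["sc"], pf["outcome"])[0, 1]
        assert r_sc == pytest.approx(0.347, abs=0.02)

    def test_intraclass_correlations(self):
        """Residual correlation within person ~.63 and within school ~.31."""
        cfg = gs.GeneratorConfig(n_schools=800, students_per_school=25, seed=9)
        ds = gs.generate_outcomes(gs.generate_covariates(cfg), seed=10)
        view = gs.person_view(ds)
        gam = DEFAULT_GCM_PARAMS.as_array()
        r0 = view.y0 - view.X0 @ gam
        r1 = view.y1 - view.X1 @ gam
        assert np.corrcoef(r0, r1)[0, 1] == pytest.approx(0.63, abs=0.02)
        # schoolmates: pairwise intraclass correlation of wave-0 residuals,
        # E[r_i r_j] over distinct schoolmates divided by var(r)
        df = pd.DataFrame({"s": view.school, "r": r0})
        g = df.groupby("s")["r"]
        sums, sumsq, cnt = g.sum(), g.apply(lambda x: (x**2).sum()), g.count()
        pair_cov = ((sums**2 - sumsq) / (cnt * (cnt - 1))).mean()
        rho_school = pair_cov / np.var(r0)
        assert rho_school == pytest.approx(0.31, abs=0.02)

    def test_variance_decomposition_recovered(self):
        cfg = gs.GeneratorConfig(n_schools=600, students_per_school=30, seed=11)
        ds = gs.generate_outcomes(gs.generate_covariates(cfg), seed=12)
        tr = ds.truth
        assert np.var(tr["u"]) == pytest.approx(0.32, abs=0.02)
        assert np.var(tr.groupby("school_id")["v"].first()) == pytest.approx(0.31, abs=0.03)

    def test_fixed_effect_recovery_by_ols(self):
        """OLS on the generating design is consistent for the fixed effects."""
        cfg = gs.GeneratorConfig(n_schools=1000, students_per_school=50, seed=13)
        ds = gs.generate_outcomes(
            gs.generate_covariates(cfg),
            gs.GCMParams(0.037, 0.6, 0.525, 0.299, -0.1, 0.02),
            seed=14,
        )
        view = gs.person_view(ds)
        X = np.vstack([view.X0, view.X1])
        y = np.concatenate([view.y0, view.y1])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert beta[1] == pytest.approx(0.6, abs=0.02)

    def test_missing_design_column_raises(self):
        ds = gs.generate_covariates(gs.GeneratorConfig(n_schools=5, students_per_school=4, seed=15))
        ds.frame = ds.frame.drop(columns=["sc"])
        with pytest.raises(ValueError, match="sc"):
            gs.generate_outcomes(ds, seed=16)


@pytest.fixture(scope="module")
def complete():
    cfg = gs.GeneratorConfig(n_schools=538, students_per_school=25, seed=17)
    return gs.generate_outcomes(gs.generate_covariates(cfg), seed=18)


class TestDropout:

    def test_zero_target_rate_keeps_everyone(self, complete):
        out = gs.apply_dropout(complete, gs.DropoutSpec(mechanism="MCAR", target_rate=0.0, seed=1))
        assert (out.frame["responded"] == 1).all()

    def test_mcar_rate_matches_cohort_attrition(self, complete):
        out = gs.apply_dropout(complete, gs.DropoutSpec(mechanism="MCAR", target_rate=0.61, seed=2))
        assert out.dropout_rate() == pytest.approx(0.61, abs=0.01)

    def test_wave0_never_masked_and_truth_retained(self, complete):
        out = gs.apply_dropout(complete, gs.DropoutSpec(mechanism="MCAR", target_rate=0.5, seed=3))
        w0 = out.frame[out.frame["wave"] == 0]
        assert w0["outcome"].notna().all() and (w0["responded"] == 1).all()
        # masked values retained in the sidecar
        person = out.person_table()
        dropped = person[person["responded"] == 0]
        tr = out.truth.set_index("person_id")
        assert tr.loc[dropped["person_id"], "y1_true"].notna().all()

    def test_mar_mode_effect_dominates(self, complete):
        """Home-tested students drop out far more often than school-tested
        (assessment-mode coefficient 5.037)."""
        out = gs.apply_dropout(complete, gs.mar_table3_spec(target_rate=0.61, seed=4))
        person = out.person_table()
        rate_home = 1 - person.loc[person["mode_home"] == 1, "responded"].mean()
        rate_school = 1 - person.loc[person["mode_home"] == 0, "responded"].mean()
        assert rate_home > rate_school + 0.3

    def test_dropout_depends_on_low_outcomes_under_dk(self, complete):
        spec = gs.DropoutSpec(
            mechanism="DK_OUTCOME",
            coefficients={"intercept": 0.0, "outcome_w0": -0.3, "outcome_w1": -0.7},
            target_rate=0.4, seed=5,
        )
        out = gs.apply_dropout(complete, spec)
        person = out.person_table()
        y0_drop = person.loc[person["responded"] == 0, "y0"].mean()
        y0_resp = person.loc[person["responded"] == 1, "y0"].mean()
        assert y0_drop < y0_resp - 0.2

    def test_absent_covariate_rejected(self, complete):
        spec = gs.DropoutSpec(mechanism="MAR_COVARIATE", coefficients={"nonexistent": 1.0})
        with pytest.raises(ValueError, match="nonexistent"):
            gs.apply_dropout(complete, spec)

    def test_invalid_target_rate_rejected(self):
        with pytest.raises(ValueError, match="target_rate"):
            gs.DropoutSpec(mechanism="MCAR", target_rate=1.5).validate()

    def test_mechanism_coefficient_whitelist(self):
        with pytest.raises(ValueError, match="not defined"):
            gs.DropoutSpec(mechanism="DK_OUTCOME", coefficients={"u": 1.0}).validate()


class TestReproducibility:
    def test_identical_seeds_bitwise_identical(self):
        cfg = gs.GeneratorConfig(n_schools=20, students_per_school=6, seed=42)
        a = gs.generate_outcomes(gs.generate_covariates(cfg), seed=43)
        b = gs.generate_outcomes(gs.generate_covariates(cfg), seed=43)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_distinct_seeds_differ(self):
        cfg = gs.GeneratorConfig(n_schools=20, students_per_school=6, seed=42)
        a = gs.generate_covariates(cfg)
        b = gs.generate_covariates(gs.GeneratorConfig(n_schools=20, students_per_school=6, seed=43))
        assert not a.frame["sc_raw"].equals(b.frame["sc_raw"])


class TestIO:
    def test_csv_roundtrip_excludes_truth(self, tmp_path):
        cfg = gs.GeneratorConfig(n_schools=10, students_per_school=4, seed=50)
        ds = gs.generate_outcomes(gs.generate_covariates(cfg), seed=51)
        ds = gs.apply_dropout(ds, gs.DropoutSpec(mechanism="MCAR", target_rate=0.4, seed=52))
        p = tmp_path / "data.csv"
        tp = tmp_path / "truth.csv"
        ds.to_csv(p, truth_path=tp)
        text = p.read_text()
        assert "u" not in text.splitlines()[0].split(",")  # no latent columns
        back = gs.LongDataset.from_csv(p, truth_path=tp)
        back.validate()
        assert back.dropout_rate() == pytest.approx(ds.dropout_rate())
        # masked outcomes are empty fields, restored as NaN
        w1 = back.frame[back.frame["wave"] == 1]
        assert w1["outcome"].isna().sum() == ds.frame[ds.frame["wave"] == 1]["outcome"].isna().sum()
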