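"""Joint selection models (DK, WC) and the pattern mixture."""

import numpy as np
import pytest

import growthsens as gs
from growthsens import mnar
from growthsens.mnar import (
    fit_diggle_kenward,
    fit_pattern_mixture,
    fit_wu_carroll,
    joint_loglik_selection_disabled,
)
from conftest import dk_spec, simulate_cohort, wc_spec


@pytest.fixture(scope="module")
def dk_dataset():
    return simulate_cohort(50, 8, 800, dk_spec())


@pytest.fixture(scope="module")
def complete_dataset():
    return simulate_cohort(30, 8, 801)


class TestSharedKernel:
    @pytest.mark.parametrize("method", ["dk", "wc"])
    def test_selection_disabled_equals_observed_data_loglik(self, method, dk_dataset):
        p = gs.GCMParams(0.05, 0.6, 0.5, 0.3, -0.1, 0.02)
        vc = gs.VarianceComponents(0.32, 0.31, 0.37)
        joint = joint_loglik_selection_disabled(method, p, vc, dk_dataset)
        ref = gs.lmm_loglik(p, vc, dk_dataset, use_rows="observed_rows")
        assert joint == pytest.approx(ref, abs=1e-6)

    def test_school_relabeling_invariance(self, dk_dataset):
        p = gs.GCMParams(0.05, 0.6, 0.5, 0.3, -0.1, 0.02)
        vc = gs.VarianceComponents(0.32, 0.31, 0.37)
        relabeled = dk_dataset.copy()
        relabeled.frame["school_id"] = "z" + relabeled.frame["school_id"].astype(str)
        shuffled = relabeled.frame.sample(frac=1.0, random_state=3).reset_index(drop=True)
        relabeled.frame = shuffled
        a = joint_loglik_selection_disabled("dk", p, vc, dk_dataset)
        b = joint_loglik_selection_disabled("dk", p, vc, relabeled)
        assert a == pytest.approx(b, abs=1e-8)


class TestReductions:
    def test_dk_with_zero_outcome_coefficients_equals_fiml(self, dk_dataset):
        fiml = gs.fit_lmm(dk_dataset, use_rows="observed_rows")
        red = fit_diggle_kenward(
            dk_dataset, quad_nodes=9, quad_nodes_y1=13,
            fix={"psi_y0": 0.0, "psi_y1": 0.0}, compute_se=False,
        )
        assert np.allclose(red.params.as_array(), fiml.params.as_array(), atol=1e-3)
        assert np.allclose(red.vc.as_array(), fiml.vc.as_array(), atol=1e-3)
        # the free selection intercept becomes the marginal dropout logit
        rate = dk_dataset.dropout_rate()
        assert red.selection["psi_intercept"] == pytest.approx(
            np.log(rate / (1 - rate)), abs=0.01
        )

    def test_wc_with_lambda_zero_equals_fiml_plus_independent_probit(self, dk_dataset):
        from scipy.stats import norm

        fiml = gs.fit_lmm(dk_dataset, use_rows="observed_rows")
        red = fit_wu_carroll(dk_dataset, quad_nodes=9, fix={"lambda": 0.0}, compute_se=False)
        assert np.allclose(red.params.as_array(), fiml.params.as_array(), atol=1e-3)
        rate = dk_dataset.dropout_rate()
        assert red.selection["psi_intercept"] == pytest.approx(norm.ppf(rate), abs=1e-3)

    def test_pattern_mixture_without_dropout_equals_single_fit(self, complete_dataset):
        res = fit_pattern_mixture(complete_dataset)
        ref = gs.fit_lmm(complete_dataset)
        pm1 = res.class_params[res.class_params["class"] == "pm1"]
        assert np.allclose(pm1["estimate"].to_numpy(), ref.params.as_array(), atol=1e-6)
        assert res.proportions == {"pm1": 1.0, "pm0": 0.0}


class TestErrors:
    def test_no_dropout_unidentified(self, complete_dataset):
        with pytest.raises(ValueError, match="unidentified"):
            fit_diggle_kenward(complete_dataset)
        with pytest.raises(ValueError, match="unidentified"):
            fit_wu_carroll(complete_dataset)

    def test_too_few_quadrature_nodes(self, dk_dataset):
        with pytest.raises(ValueError, match="nodes"):
            fit_diggle_kenward(dk_dataset, quad_nodes=2)

    def test_unknown_selection_covariate(self, dk_dataset):
        with pytest.raises(ValueError, match="not in data"):
            fit_wu_carroll(dk_dataset, selection_covariates=["ghost"])


class TestQuadrature:
    def test_refinement_stability(self, dk_dataset):
        """The converged DK log-likelihood and estimates are insensitive to
        the number of adaptive quadrature nodes."""
        fit = fit_diggle_kenward(dk_dataset, quad_nodes=7, quad_nodes_y1=15, compute_se=False)
        from growthsens.data import person_view
        from growthsens.mnar import _dk_loglik

        view = person_view(dk_dataset)
        d = ~view.resp
        Xs = np.empty((view.n_persons, 0))
        theta = np.concatenate([
            fit.params.as_array(), 0.5 * np.log(fit.vc.as_array()),
            [fit.selection["psi_intercept"], fit.selection["psi_y0"], fit.selection["psi_y1"]],
        ])
        lls = []
        for q in (7, 15, 25):
            gh = np.polynomial.hermite.hermgauss(q)
            ghy = np.polynomial.hermite.hermgauss(max(q, 15))
            lls.append(_dk_loglik(theta, view, d, Xs, gh, gh, ghy))
        assert abs(lls[1] - lls[0]) < 1e-3
        assert abs(lls[2] - lls[1]) < 1e-3

    def test_wc_refinement_stability(self, dk_dataset):
        fits = [
            fit_wu_carroll(dk_dataset, quad_nodes=q, compute_se=False).params.as_array()
            for q in (7, 15, 25)
        ]
        assert np.abs(fits[2] - fits[1]).max() < 1e-3
        assert np.abs(fits[1] - fits[0]).max() < 1e-3


@pytest.fixture(scope="module")
def data():
    return simulate_cohort(60, 10, 802, dk_spec())


class TestPatternMixture:

    def test_pm1_equals_completer_fit_with_free_variances(self, data):
        res = fit_pattern_mixture(data, equal_variances=False)
        ref = gs.fit_lmm(data, use_rows="complete_persons")
        pm1 = res.class_params[res.class_params["class"] == "pm1"]
        est = dict(zip(pm1["term"], pm1["estimate"]))
        for t, v in zip(ref.terms, ref.params.as_array()):
            assert est[t] == pytest.approx(v, abs=1e-6)

    def test_completers_outscore_dropouts(self, data):
        """Outcome-dependent dropout: the completer class has the higher
        intercept."""
        res = fit_pattern_mixture(data)
        cp = res.class_params.set_index(["class", "term"])["estimate"]
        assert cp[("pm1", "intercept")] > cp[("pm0", "intercept")]

    def test_time_terms_na_without_restriction(self, data):
        res = fit_pattern_mixture(data, restriction="none")
        cp = res.class_params.set_index(["class", "term"])["estimate"]
        for t in ("time", "time:reas", "time:sc"):
            assert np.isnan(cp[("pm0", t)])
        mix = res.mixture.set_index("term")["estimate"]
        assert np.isnan(mix["time"])
        assert np.isfinite(mix["intercept"])

    def test_equal_growth_restriction_enables_mixture_time_effect(self, data):
        res = fit_pattern_mixture(data, restriction="equal_growth")
        mix = res.mixture.set_index("term")["estimate"]
        assert np.isfinite(mix["time"])
        cp = res.class_params.set_index(["class", "term"])["estimate"]
        assert cp[("pm0", "time")] == cp[("pm1", "time")]

    def test_proportions_sum_to_one(self, data):
        res = fit_pattern_mixture(data)
        assert sum(res.proportions.values()) == pytest.approx(1.0)

    def test_tiny_class_rejected(self):
        ds = simulate_cohort(10, 4, 803)
        person = ds.person_table()
        one = person["person_id"].iloc[0]
        mask = (ds.frame["wave"] == 1) & (ds.frame["person_id"] == one)
        ds.frame.loc[mask, "responded"] = 0
        ds.frame.loc[mask, "outcome"] = np.nan
        with pytest.raises(ValueError, match="at least 2"):
            fit_pattern_mixture(ds)
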