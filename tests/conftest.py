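"""Shared fixtures: small simulated cohorts and the replicate studies used
by the acceptance suite (run once per session and shared across tests)."""

import numpy as np
import pytest

import growthsens as gs
from growthsens import mnar
from growthsens.diagnostics import compute_ip_weights
from growthsens.imputation import ImputationConfig, fit_mi

TRUE_GAMMA = gs.synthetic.DEFAULT_GCM_PARAMS.as_array()
TRUE_VC = gs.synthetic.DEFAULT_VARIANCE_COMPONENTS.as_array()

WE_SELECTION = ["reas", "sc", "sex", "migration", "age", "outcome_w0"]


def simulate_cohort(n_schools, students, seed, dropout_spec=None):
    """One synthetic cohort from the default growth-model truth."""
    ss = np.random.SeedSequence(seed).generate_state(3)
    cfg = gs.GeneratorConfig(
        n_schools=n_schools, students_per_school=students, seed=int(ss[0])
    )
    ds = gs.generate_outcomes(gs.generate_covariates(cfg), seed=int(ss[1]))
    if dropout_spec is not None:
        spec = dropout_spec
        spec.seed = int(ss[2])
        ds = gs.apply_dropout(ds, spec)
    return ds


def dk_spec(target_rate=0.4):
    """Outcome-driven dropout: low current performance raises dropout."""
    return gs.DropoutSpec(
        mechanism="DK_OUTCOME",
        coefficients={"intercept": 0.0, "outcome_w0": -0.3, "outcome_w1": -0.7},
        target_rate=target_rate,
    )


def wc_spec(target_rate=0.4):
    """Shared-parameter dropout: low person intercepts drop out."""
    return gs.DropoutSpec(
        mechanism="WC_RANDOM_EFFECT", link="probit",
        coefficients={"intercept": 0.0, "u": -1.2}, target_rate=target_rate,
    )


@pytest.fixture(scope="session")
def small_mcar_dataset():
    return simulate_cohort(30, 8, 101, gs.DropoutSpec(mechanism="MCAR", target_rate=0.3))


@pytest.fixture(scope="session")
def small_complete_dataset():
    return simulate_cohort(30, 8, 102)


@pytest.fixture(scope="session")
def dk_replicate_study():
    """Replicated fits under the outcome-driven (DK) dropout mechanism.

    20 replicates of 100 schools x 8 students with ~40% dropout; per
    replicate the listwise, observed-data ML, weighted and DK fits.
    """
    out = {k: [] for k in ("lwd", "fiml", "we", "dk")}
    for r in range(20):
        ds = simulate_cohort(100, 8, 5000 + r, dk_spec())
        view = gs.person_view(ds)
        out["lwd"].append(gs.fit_lmm(view, use_rows="complete_persons").params.as_array())
        out["fiml"].append(gs.fit_lmm(view).params.as_array())
        w = compute_ip_weights(ds, WE_SELECTION)
        out["we"].append(
            gs.fit_lmm(
                view, use_rows="complete_persons",
                weights=w.person_weights(view.person_id),
            ).params.as_array()
        )
        out["dk"].append(
            mnar.fit_diggle_kenward(
                view, quad_nodes=9, quad_nodes_y1=13, compute_se=False
            ).params.as_array()
        )
    return {k: np.array(v) for k, v in out.items()}


@pytest.fixture(scope="session")
def wc_replicate_study():
    """Replicated fits under the shared-parameter (WC) dropout mechanism."""
    out = {k: [] for k in ("lwd", "fiml", "wc")}
    lams = []
    for r in range(20):
        ds = simulate_cohort(100, 8, 6000 + r, wc_spec())
        view = gs.person_view(ds)
        out["lwd"].append(gs.fit_lmm(view, use_rows="complete_persons").params.as_array())
        out["fiml"].append(gs.fit_lmm(view).params.as_array())
        fit = mnar.fit_wu_carroll(view, quad_nodes=9, compute_se=False)
        out["wc"].append(fit.params.as_array())
        lams.append(fit.selection["lambda"])
    res = {k: np.array(v) for k, v in out.items()}
    res["lambda"] = np.array(lams)
    return res


@pytest.fixture(scope="session")
def mcar_replicate_study():
    """All six likelihood-based methods on 20 MCAR replicates."""
    methods = ("lwd", "fiml", "mi", "we", "dk", "wc")
    out = {m: [] for m in methods}
    for r in range(20):
        ss = np.random.SeedSequence(7000 + r).generate_state(2)
        ds = simulate_cohort(
            60, 8, 7000 + r, gs.DropoutSpec(mechanism="MCAR", target_rate=0.3)
        )
        view = gs.person_view(ds)
        out["lwd"].append(gs.fit_lmm(view, use_rows="complete_persons").params.as_array())
        out["fiml"].append(gs.fit_lmm(view).params.as_array())
        pooled, _ = fit_mi(ds, ImputationConfig(m=5, seed=int(ss[1])))
        out["mi"].append(pooled.qbar[:6])
        w = compute_ip_weights(ds, WE_SELECTION)
        out["we"].append(
            gs.fit_lmm(
                view, use_rows="complete_persons",
                weights=w.person_weights(view.person_id),
            ).params.as_array()
        )
        out["dk"].append(
            mnar.fit_diggle_kenward(
                view, quad_nodes=9, quad_nodes_y1=13, compute_se=False
            ).params.as_array()
        )
        out["wc"].append(
            mnar.fit_wu_carroll(view, quad_nodes=9, compute_se=False).params.as_array()
        )
    return {k: np.array(v) for k, v in out.items()}
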